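"""Forward noising, denoising transitions, training loss, COM handling,
the ligand-size model and the full sampling loop.

State convention: a diffused state is an :class:`~pocketdiff.molsys.AtomPointCloud`
whose coordinate and categorical channels are treated identically by the
Gaussian process (one-hot relaxation). Two center-of-mass conventions exist:

* ``pocket_anchor`` (conditional models): the complex is translated once so the
  pocket COM sits at the origin; the frame then stays fixed.
* ``joint``: the COM of the full ligand+pocket point set is subtracted before
  every denoising step and coordinate noise is projected to the COM-free
  subspace of the diffused set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .molsys import AtomPointCloud, decode_labels
from .schedule import Schedule, transition_coeffs

__all__ = [
    "NoisySystem",
    "SizeModel",
    "com_project",
    "forward_noise",
    "predict_data",
    "posterior_step",
    "training_loss",
    "draw_noise",
    "fit_size_model",
    "sample_ligand_size",
    "clip_zdata",
    "pocket_clip_radius",
    "generate",
]

_ALPHA_FLOOR = 1e-8


@dataclass
class NoisySystem:
    """A noised ligand state with its (clean or noised) pocket context."""

    z_t: AtomPointCloud
    t: int
    pocket: AtomPointCloud


def com_project(coords: np.ndarray, reference_index_set=None) -> np.ndarray:
    """Subtract the mean coordinate of the reference set from all rows."""
    coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
    if reference_index_set is None:
        ref = np.arange(coords.shape[0])
    else:
        ref = np.asarray(list(reference_index_set), dtype=int)
    if ref.size == 0:
        raise ValueError("reference index set must be non-empty")
    return coords - coords[ref].mean(axis=0)


def _stack(cloud: AtomPointCloud) -> np.ndarray:
    return np.hstack([cloud.coords, cloud.feats])


def _unstack(z: np.ndarray, d_feats: int, labels=()) -> AtomPointCloud:
    return AtomPointCloud(z[:, :3], z[:, 3:3 + d_feats], labels)


def draw_noise(rng: np.random.Generator, n: int, d_feats: int, com_free: bool = False) -> np.ndarray:
    """Standard normal draw of shape (n, 3 + d_feats); optionally with the
    coordinate block projected onto the zero-COM subspace."""
    eps = rng.standard_normal((n, 3 + d_feats))
    if com_free:
        eps[:, :3] -= eps[:, :3].mean(axis=0)
    return eps


def forward_noise(
    z_data: AtomPointCloud, t: int, sched: Schedule, noise: np.ndarray
) -> AtomPointCloud:
    """``z_t = alpha_t * z_data + sigma_t * noise`` over all channels."""
    if not (0 <= t <= sched.T):
        raise ValueError(f"t={t} outside [0, {sched.T}]")
    z = _stack(z_data)
    noise = np.asarray(noise, dtype=np.float64)
    if noise.shape != z.shape:
        raise ValueError(f"noise shape {noise.shape} != state shape {z.shape}")
    z_t = sched.alpha[t] * z + sched.sigma[t] * noise
    return _unstack(z_t, z_data.n_feats, z_data.labels)


def predict_data(
    z_t: AtomPointCloud, eps_hat: np.ndarray, t: int, sched: Schedule
) -> AtomPointCloud:
    """Invert the noising: ``z_data_hat = z_t / alpha_t - (sigma_t / alpha_t) eps_hat``."""
    if t < 1:
        raise ValueError("predict_data requires t >= 1")
    a_t = sched.alpha[t]
    if a_t < _ALPHA_FLOOR:
        raise ValueError(f"alpha_t={a_t} below numerical floor")
    z = _stack(z_t)
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    if eps_hat.shape != z.shape:
        raise ValueError(f"eps_hat shape {eps_hat.shape} != state shape {z.shape}")
    z_hat = z / a_t - (sched.sigma[t] / a_t) * eps_hat
    return _unstack(z_hat, z_t.n_feats, z_t.labels)


def posterior_mean_var(
    z_t: np.ndarray, z_ref: np.ndarray, s: int, t: int, sched: Schedule
) -> tuple[np.ndarray, float]:
    alpha_ts, sigma2_ts = transition_coeffs(sched, s, t)
    sig2_s, sig2_t = float(sched.sigma[s] ** 2), float(sched.sigma[t] ** 2)
    mean = (alpha_ts * sig2_s / sig2_t) * z_t + (float(sched.alpha[s]) * sigma2_ts / sig2_t) * z_ref
    var = sigma2_ts * sig2_s / sig2_t
    return mean, var


def posterior_step(
    z_t: AtomPointCloud,
    z_ref: AtomPointCloud,
    s: int,
    t: int,
    sched: Schedule,
    rng: np.random.Generator,
    com_project_after: bool = False,
    noise: np.ndarray | None = None,
) -> AtomPointCloud:
    """Draw ``z_s`` from the closed-form Gaussian transition given ``z_t`` and a
    reference state (clean data at training time, the model prediction when
    sampling)."""
    if s >= t:
        raise ValueError(f"require s < t, got s={s}, t={t}")
    mean, var = posterior_mean_var(_stack(z_t), _stack(z_ref), s, t, sched)
    if noise is None:
        noise = rng.standard_normal(mean.shape)
    z_s = mean + np.sqrt(var) * noise
    if com_project_after:
        z_s[:, :3] -= z_s[:, :3].mean(axis=0)
    return _unstack(z_s, z_t.n_feats, z_t.labels)


def training_loss(eps: np.ndarray, eps_hat: np.ndarray) -> float:
    """Simplified epsilon objective: half the squared error over all entries."""
    eps = np.asarray(eps, dtype=np.float64)
    eps_hat = np.asarray(eps_hat, dtype=np.float64)
    if eps.shape != eps_hat.shape:
        raise ValueError(f"shape mismatch {eps.shape} vs {eps_hat.shape}")
    diff = eps - eps_hat
    return 0.5 * float((diff * diff).sum())


# ---------------------------------------------------------------------------
# ligand-size model
# ---------------------------------------------------------------------------

@dataclass
class SizeModel:
    """Gaussian-smoothed empirical joint distribution of (N_L, N_P)."""

    joint: np.ndarray  # (max_NL, max_NP) table, index 0 <-> size 1
    smoothing_sigma: float = 1.0
    mean_shift: int = 0

    @property
    def max_nl(self) -> int:
        return self.joint.shape[0]

    @property
    def max_np(self) -> int:
        return self.joint.shape[1]

    def conditional(self, n_p: int) -> np.ndarray:
        """p(N_L | N_P), clamping N_P to the support with nonzero mass."""
        col = int(np.clip(n_p, 1, self.max_np)) - 1
        slice_ = self.joint[:, col]
        if slice_.sum() <= 0:
            nonzero = np.nonzero(self.joint.sum(axis=0) > 0)[0]
            col = nonzero[np.argmin(np.abs(nonzero - col))]
            slice_ = self.joint[:, col]
        return slice_ / slice_.sum()


def fit_size_model(training_pairs, smoothing_sigma: float = 1.0, mean_shift: int = 0) -> SizeModel:
    pairs = [(int(a), int(b)) for a, b in training_pairs]
    if not pairs:
        raise ValueError("need at least one (N_L, N_P) pair")
    if any(a < 1 or b < 1 for a, b in pairs):
        raise ValueError("sizes must be positive")
    pad = max(3, int(np.ceil(4 * smoothing_sigma)))
    max_nl = max(a for a, _ in pairs) + pad
    max_np = max(b for _, b in pairs) + pad
    hist = np.zeros((max_nl, max_np))
    for a, b in pairs:
        hist[a - 1, b - 1] += 1.0
    if smoothing_sigma > 0:
        hist = gaussian_filter(hist, sigma=smoothing_sigma, mode="constant")
    joint = hist / hist.sum()
    return SizeModel(joint=joint, smoothing_sigma=smoothing_sigma, mean_shift=mean_shift)


def sample_ligand_size(model: SizeModel, n_p: int, rng: np.random.Generator) -> int:
    probs = model.conditional(n_p)
    n_l = int(rng.choice(model.max_nl, p=probs)) + 1
    return max(1, n_l + model.mean_shift)


# ---------------------------------------------------------------------------
# sampling loop
# ---------------------------------------------------------------------------

FEAT_CLIP = 2.0  # generous bound for scaled one-hot channels of z_data_hat


def clip_zdata(z_hat: AtomPointCloud, radius: float | None) -> AtomPointCloud:
    """Clamp a predicted clean state to the pocket vicinity.

    The epsilon parameterization divides by ``alpha_t``, so early in the
    reverse process a poor prediction can throw atoms arbitrarily far; once an
    atom leaves every distance cut-off it receives no further updates and its
    position grows by ``1/alpha_{t|s}`` per step. Bounding the predicted data
    (coordinates to a ball that keeps atoms within edge range of the pocket,
    features to a generous box) removes this failure mode without touching the
    learned distribution in the bulk.
    """
    if radius is None:
        return z_hat
    coords = z_hat.coords.copy()
    norms = np.linalg.norm(coords, axis=1, keepdims=True)
    factor = np.where(norms > radius, radius / np.maximum(norms, 1e-12), 1.0)
    coords *= factor
    feats = np.clip(z_hat.feats, -FEAT_CLIP, FEAT_CLIP)
    return AtomPointCloud(coords, feats, z_hat.labels)


def pocket_clip_radius(pocket_scaled: AtomPointCloud, cutoffs: dict) -> float:
    """Ball radius (pocket-anchored frame) that keeps clamped atoms within
    ligand-pocket edge range of the shell."""
    return float(np.linalg.norm(pocket_scaled.coords, axis=1).max() + cutoffs["LL"] / 2)


def _sample_one_cond(model, pocket_scaled, sched, rng, n_l, coord_transform=None,
                     clip_radius=None):
    """Reverse diffusion for one ligand in the (scaled, pocket-anchored) frame."""
    d = len(model.alphabet)

    def draw(n):
        eps = rng.standard_normal((n, 3 + d))
        if coord_transform is not None:
            eps[:, :3] = eps[:, :3] @ np.asarray(coord_transform).T
        return eps

    z = _unstack(draw(n_l), d)
    for t in range(sched.T, 0, -1):
        eps_hat = model.predict_eps(z, pocket_scaled, t)
        z_hat = clip_zdata(predict_data(z, eps_hat, t, sched), clip_radius)
        noise = draw(n_l)
        z = posterior_step(z, z_hat, t - 1, t, sched, rng, noise=noise)
    return z


def generate(
    model,
    pocket: AtomPointCloud,
    n_samples: int,
    mode: str = "cond",
    sched: Schedule | None = None,
    rng=0,
    sizes=None,
    coord_transform=None,
) -> list[AtomPointCloud]:
    """Sample ligands for an (unscaled) featurized pocket.

    ``model`` must provide ``predict_eps(z_t, pocket, t)``, plus ``alphabet``,
    ``scaling`` and ``size_model`` attributes. ``rng`` may be an integer master
    seed (one child generator is derived per sample) or a ``numpy`` Generator.
    ``sizes`` optionally fixes the atom count per sample. ``coord_transform``
    applies a 3x3 matrix to every coordinate-noise draw (equivariance harness).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if mode not in ("cond", "joint"):
        raise ValueError(f"mode must be 'cond' or 'joint', got {mode!r}")
    sched = sched if sched is not None else model.schedule
    if mode == "joint":
        from .inpaint import generate_joint

        return generate_joint(model, pocket, n_samples, sched, rng, sizes=sizes)

    scaling = model.scaling
    shift = pocket.coords.mean(axis=0)  # pocket-anchored frame
    pocket_scaled = AtomPointCloud(
        (pocket.coords - shift) * scaling.coord_factor,
        pocket.feats * scaling.feat_factor,
        pocket.labels,
    )
    if isinstance(rng, np.random.Generator):
        child_rngs = rng.spawn(n_samples)
        size_rng = rng
    else:
        child_rngs = [np.random.default_rng([int(rng), i]) for i in range(n_samples)]
        size_rng = np.random.default_rng([int(rng), n_samples])
    clip_radius = pocket_clip_radius(pocket_scaled, model.scaled_cutoffs)
    out = []
    for i in range(n_samples):
        n_l = (
            int(sizes[i]) if sizes is not None
            else sample_ligand_size(model.size_model, pocket.n_atoms, size_rng)
        )
        z0 = _sample_one_cond(model, pocket_scaled, sched, child_rngs[i], n_l,
                              coord_transform=coord_transform,
                              clip_radius=clip_radius)
        coords = z0.coords / scaling.coord_factor + shift
        labels = decode_labels(z0.feats, model.alphabet)
        feats = np.zeros((n_l, len(model.alphabet)))
        feats[np.arange(n_l), [model.alphabet.index(el) for el in labels]] = 1.0
        out.append(AtomPointCloud(coords, feats, labels))
    return out
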