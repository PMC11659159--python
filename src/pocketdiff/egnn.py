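"""SE(3)-equivariant graph neural network denoiser.

Message passing follows the attention-weighted EGNN layer: invariant messages
are built from node embeddings, squared distances and edge-type attributes;
coordinates receive a distance-normalized radial update and, optionally, a
normalized cross-product term that changes sign under reflection and thereby
restricts the symmetry group from E(3) to SE(3). Pocket (fixed-mask) nodes
never receive coordinate updates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import cdist

from .nnet import MLP, Module, Tensor, concat, cross
from .molsys import EDGE_TYPES, LIGAND_ALPHABET, FeatureScaling, AtomPointCloud
from .schedule import Schedule, build_schedule
from .diffusion import SizeModel

__all__ = ["EgnnConfig", "EGNN", "EGNNDenoiser", "save_checkpoint", "load_checkpoint"]

_EPS = 1e-12


@dataclass(frozen=True)
class EgnnConfig:
    n_layers: int = 4
    hidden_dim: int = 128
    reflection_sensitive: bool = True
    time_encoding: str = "scalar"  # "scalar" (t/T) or "sinusoidal"
    n_frequencies: int = 4  # used by sinusoidal encoding

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_dim < 1:
            raise ValueError("n_layers and hidden_dim must be >= 1")
        if self.time_encoding not in ("scalar", "sinusoidal"):
            raise ValueError(f"unknown time encoding {self.time_encoding!r}")

    @property
    def time_dim(self) -> int:
        return 1 if self.time_encoding == "scalar" else 2 * self.n_frequencies


def _build_edges(coords: np.ndarray, n_lig: int, cutoffs: dict, include_pp: bool = True):
    """Vectorized typed-edge construction (both directed arcs).

    Returns receiver indices, sender indices and edge-type one-hot attributes.
    Agrees with :func:`pocketdiff.molsys.build_graph` by construction (tested).
    """
    n = coords.shape[0]
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    is_lig = np.arange(n) < n_lig
    ll = is_lig[:, None] & is_lig[None, :]
    pp = ~is_lig[:, None] & ~is_lig[None, :]
    lp = ~(ll | pp)
    adj = (ll & (d <= cutoffs["LL"])) | (lp & (d <= cutoffs["LP"]))
    if include_pp:
        adj |= pp & (d <= cutoffs["PP"])
    ei, ej = np.nonzero(adj)
    a = np.zeros((len(ei), len(EDGE_TYPES)))
    types = np.where(ll[ei, ej], 0, np.where(lp[ei, ej], 1, 2))
    a[np.arange(len(ei)), types] = 1.0
    return ei, ej, a


class _Layer(Module):
    def __init__(self, config: EgnnConfig, rng: np.random.Generator):
        h, e_in = config.hidden_dim, 2 * config.hidden_dim + 1 + len(EDGE_TYPES)
        self.phi_e = MLP([e_in, h, h], rng)
        self.phi_att = MLP([h, 1], rng, final_activation="sigmoid")
        self.phi_h = MLP([2 * h, h, h], rng)
        self.phi_x_d = MLP([e_in, h, 1], rng)
        self.reflection_sensitive = config.reflection_sensitive
        if config.reflection_sensitive:
            self.phi_x_cross = MLP([e_in, h, 1], rng)

    def __call__(self, h: Tensor, x: Tensor, ei, ej, a: np.ndarray, update_mask: np.ndarray):
        n = h.shape[0]
        if len(ei) == 0:
            # empty sums: features still pass through phi_h, coordinates unchanged
            agg = Tensor(np.zeros((n, h.shape[1])))
            return self.phi_h(concat([h, agg], axis=1)), x
        hi, hj = h.gather(ei), h.gather(ej)
        xi, xj = x.gather(ei), x.gather(ej)
        diff = xi - xj
        d2 = diff.square().sum(axis=1, keepdims=True)
        d = (d2 + _EPS).sqrt()
        edge_in = concat([hi, hj, d2, Tensor(a)], axis=1)

        m = self.phi_e(edge_in)
        att = self.phi_att(m)
        agg = (att * m).scatter_add(ei, n)
        h_new = self.phi_h(concat([h, agg], axis=1))

        upd = ((diff / (d + 1.0)) * self.phi_x_d(edge_in)).scatter_add(ei, n)
        if self.reflection_sensitive:
            xbar = x.mean(axis=0, keepdims=True)
            c = cross(xi - xbar, xj - xbar)
            cn = (c.square().sum(axis=1, keepdims=True) + _EPS).sqrt()
            upd = upd + ((c / (cn + 1.0)) * self.phi_x_cross(edge_in)).scatter_add(ei, n)
        x_new = x + upd * Tensor(update_mask[:, None].astype(float))
        return h_new, x_new


class EGNN(Module):
    """Stack of equivariant layers with separate ligand/pocket encoders."""

    def __init__(self, config: EgnnConfig, d_ligand: int, d_pocket: int,
                 rng: np.random.Generator):
        h = config.hidden_dim
        self.config = config
        self.d_ligand = d_ligand
        self.d_pocket = d_pocket
        self.lig_encoder = MLP([d_ligand + config.time_dim, h, h], rng)
        self.pocket_encoder = MLP([d_pocket + config.time_dim, h, h], rng)
        self.layers = [_Layer(config, rng) for _ in range(config.n_layers)]
        self.lig_readout = MLP([h, h, d_ligand], rng)
        self.pocket_readout = MLP([h, h, d_pocket], rng)

    def time_features(self, t: int, T: int, n: int) -> np.ndarray:
        frac = t / T
        if self.config.time_encoding == "scalar":
            row = np.array([frac])
        else:
            freqs = 2.0 ** np.arange(self.config.n_frequencies)
            row = np.concatenate([np.sin(2 * np.pi * freqs * frac),
                                  np.cos(2 * np.pi * freqs * frac)])
        return np.tile(row, (n, 1))

    def embed_nodes(self, lig_feats: np.ndarray, pocket_feats: np.ndarray,
                    t: int, T: int) -> Tensor:
        """Joint embedding: separate encoders, ligand rows first."""
        lig_feats = np.atleast_2d(lig_feats)
        pocket_feats = np.atleast_2d(pocket_feats)
        if lig_feats.shape[1] != self.d_ligand:
            raise ValueError(f"ligand feature width {lig_feats.shape[1]} != {self.d_ligand}")
        if pocket_feats.shape[1] != self.d_pocket:
            raise ValueError(f"pocket feature width {pocket_feats.shape[1]} != {self.d_pocket}")
        h_l = self.lig_encoder(Tensor(
            np.hstack([lig_feats, self.time_features(t, T, lig_feats.shape[0])])))
        h_p = self.pocket_encoder(Tensor(
            np.hstack([pocket_feats, self.time_features(t, T, pocket_feats.shape[0])])))
        return concat([h_l, h_p], axis=0)

    def forward(
        self,
        lig_coords: np.ndarray,
        lig_feats: np.ndarray,
        pocket_coords: np.ndarray,
        pocket_feats: np.ndarray,
        t: int,
        T: int,
        cutoffs: dict,
        update_pocket: bool = False,
        com_project_eps: bool = False,
    ):
        """One full network call in the scaled frame.

        Returns Tensors ``(eps_x, eps_h_lig, eps_h_pocket)``. ``eps_x`` covers
        all nodes but is zero on non-updated (fixed) rows. The graph is built
        once from the input coordinates and held fixed across layers.
        """
        n_l, n_p = lig_coords.shape[0], pocket_coords.shape[0]
        coords0 = np.vstack([lig_coords, pocket_coords])
        ei, ej, a = _build_edges(coords0, n_l, cutoffs)
        update_mask = np.concatenate([np.ones(n_l, bool),
                                      np.full(n_p, update_pocket, dtype=bool)])
        h = self.embed_nodes(lig_feats, pocket_feats, t, T)
        x = Tensor(coords0)
        x0 = x
        for layer in self.layers:
            h, x = layer(h, x, ei, ej, a, update_mask)
        eps_x = x - x0  # equivariant displacement readout
        if com_project_eps:
            # project onto the COM-free subspace of the diffused rows
            n_diff = n_l + (n_p if update_pocket else 0)
            diffused = np.concatenate(
                [np.ones(n_l), np.ones(n_p) if update_pocket else np.zeros(n_p)])
            w = Tensor((diffused / diffused.sum())[:, None])
            mean = (eps_x * w).sum(axis=0, keepdims=True)
            eps_x = (eps_x - mean) * Tensor(update_mask[:, None].astype(float))
        h_lig = h.gather(np.arange(n_l))
        eps_h_lig = self.lig_readout(h_lig)
        eps_h_pocket = None
        if update_pocket:
            eps_h_pocket = self.pocket_readout(h.gather(np.arange(n_l, n_l + n_p)))
        return eps_x, eps_h_lig, eps_h_pocket


class EGNNDenoiser(Module):
    """The denoiser plus everything needed to run it: schedule, scaling,
    size model, alphabet, cut-offs and conditioning mode."""

    def __init__(
        self,
        config: EgnnConfig | None = None,
        alphabet=LIGAND_ALPHABET,
        d_pocket: int | None = None,
        scaling: FeatureScaling | None = None,
        schedule: Schedule | None = None,
        size_model: SizeModel | None = None,
        cutoffs: dict | None = None,
        mode: str = "cond",
        seed: int = 0,
    ):
        from .molsys import DEFAULT_CUTOFFS

        self.config = config or EgnnConfig()
        self.alphabet = tuple(alphabet)
        self.scaling = scaling or FeatureScaling()
        self.schedule = schedule or build_schedule()
        self.size_model = size_model
        self.cutoffs = dict(cutoffs or DEFAULT_CUTOFFS)
        self.mode = mode
        d_lig = len(self.alphabet)
        self.d_pocket = d_pocket if d_pocket is not None else d_lig
        self.net = EGNN(self.config, d_lig, self.d_pocket, np.random.default_rng(seed))

    @property
    def scaled_cutoffs(self) -> dict:
        return self.scaling.scale_cutoffs(self.cutoffs)

    def _check_t(self, t: int) -> None:
        if not (0 <= t <= self.schedule.T):
            raise ValueError(f"t={t} outside [0, {self.schedule.T}]")

    def predict_eps(self, z_t: AtomPointCloud, pocket: AtomPointCloud, t: int) -> np.ndarray:
        """Conditional-mode noise prediction for the ligand block (numpy).

        Inputs live in the scaled, pocket-anchored frame; the pocket receives
        no noise prediction and its coordinates are untouched.
        """
        self._check_t(t)
        eps_x, eps_h, _ = self.net.forward(
            z_t.coords, z_t.feats, pocket.coords, pocket.feats,
            t, self.schedule.T, self.scaled_cutoffs,
            update_pocket=False, com_project_eps=False,
        )
        n_l = z_t.n_atoms
        return np.hstack([eps_x.data[:n_l], eps_h.data])

    def predict_eps_joint(self, z_lig: AtomPointCloud, z_pocket: AtomPointCloud, t: int):
        """Joint-mode prediction: both blocks are diffused; the coordinate
        noise is projected onto the COM-free subspace of the full system."""
        self._check_t(t)
        eps_x, eps_h_l, eps_h_p = self.net.forward(
            z_lig.coords, z_lig.feats, z_pocket.coords, z_pocket.feats,
            t, self.schedule.T, self.scaled_cutoffs,
            update_pocket=True, com_project_eps=True,
        )
        n_l = z_lig.n_atoms
        eps_lig = np.hstack([eps_x.data[:n_l], eps_h_l.data])
        eps_pocket = np.hstack([eps_x.data[n_l:], eps_h_p.data])
        return eps_lig, eps_pocket

    def loss_tensors(self, z_lig, z_pocket, t, eps_target_lig, eps_target_pocket=None,
                     update_pocket=False):
        """Training-time epsilon loss as a differentiable Tensor."""
        eps_x, eps_h_l, eps_h_p = self.net.forward(
            z_lig.coords, z_lig.feats, z_pocket.coords, z_pocket.feats,
            t, self.schedule.T, self.scaled_cutoffs,
            update_pocket=update_pocket, com_project_eps=update_pocket,
        )
        n_l = z_lig.n_atoms
        tgt = np.asarray(eps_target_lig)
        pred = concat([eps_x.gather(np.arange(n_l)), eps_h_l], axis=1)
        diff = pred - Tensor(tgt)
        loss = diff.square().sum() * 0.5
        if update_pocket:
            tgt_p = np.asarray(eps_target_pocket)
            n_p = z_pocket.n_atoms
            pred_p = concat([eps_x.gather(np.arange(n_l, n_l + n_p)), eps_h_p], axis=1)
            diff_p = pred_p - Tensor(tgt_p)
            loss = loss + diff_p.square().sum() * 0.5
        return loss


# ---------------------------------------------------------------------------
# checkpointing: one archive with weights + config + schedule + scaling +
# alphabet + size model
# ---------------------------------------------------------------------------

def save_checkpoint(model: EGNNDenoiser, path) -> None:
    meta = {
        "config": asdict(model.config),
        "alphabet": list(model.alphabet),
        "d_pocket": model.d_pocket,
        "scaling": {"feat_factor": model.scaling.feat_factor,
                    "coord_factor": model.scaling.coord_factor},
        "schedule": {"T": model.schedule.T, "offset": model.schedule.offset,
                     "clip_lo": model.schedule.clip_lo},
        "cutoffs": model.cutoffs,
        "mode": model.mode,
        "size_model": None if model.size_model is None else {
            "smoothing_sigma": model.size_model.smoothing_sigma,
            "mean_shift": model.size_model.mean_shift,
        },
    }
    arrays = {f"w{i}": a for i, a in enumerate(model.state_arrays())}
    if model.size_model is not None:
        arrays["size_joint"] = model.size_model.joint
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> EGNNDenoiser:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        size_model = None
        if meta["size_model"] is not None:
            size_model = SizeModel(
                joint=data["size_joint"],
                smoothing_sigma=meta["size_model"]["smoothing_sigma"],
                mean_shift=meta["size_model"]["mean_shift"],
            )
        model = EGNNDenoiser(
            config=EgnnConfig(**meta["config"]),
            alphabet=meta["alphabet"],
            d_pocket=meta["d_pocket"],
            scaling=FeatureScaling(**meta["scaling"]),
            schedule=build_schedule(**meta["schedule"]),
            size_model=size_model,
            cutoffs=meta["cutoffs"],
            mode=meta["mode"],
        )
        n = len(model.state_arrays())
        model.load_state_arrays([data[f"w{i}"] for i in range(n)])
    return model
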