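"""Substructure-conditioned generation via the replacement method.

At every denoising step the rows belonging to the fixed substructure are
overwritten with a forward-noised version of the clean reference, translated
so its COM matches the generated counterpart, before the combined state
advances. Optional resampling repeats each step ``r`` times with one-step
re-noising in between to harmonize fixed and generated regions.

Joint-mode ligand generation (noised pocket) is the same code path with the
pocket playing the role of the fixed substructure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molsys import AtomPointCloud, decode_labels
from .schedule import Schedule, transition_coeffs
from .diffusion import (
    clip_zdata,
    forward_noise,
    pocket_clip_radius,
    posterior_step,
    predict_data,
    sample_ligand_size,
)

__all__ = [
    "InpaintTask",
    "DegenerateScaffoldError",
    "com_align_fixed",
    "inpaint_step",
    "inpaint_generate",
    "generate_joint",
    "build_mask",
]


class DegenerateScaffoldError(ValueError):
    """Raised when a scaffold-based mask is requested for an acyclic molecule."""


@dataclass
class InpaintTask:
    """A fixed-substructure generation task.

    ``reference`` is the parent molecule (unscaled, featurized); ``mask`` the
    indices of atoms to hold fixed. In the combined diffusion state the fixed
    atoms occupy the first ``len(mask)`` rows (in mask order) and generated
    atoms follow; ``permutation`` records the combined-state row order in
    reference indexing for ``diversify`` tasks.
    """

    reference: AtomPointCloud
    mask: tuple[int, ...]
    n_generated: int = 0
    regime: str = "de_novo"  # "de_novo" | "diversify"
    t_start: int | None = None  # required for diversify
    resamplings: int = 10

    def __post_init__(self):
        self.mask = tuple(int(i) for i in self.mask)
        n_ref = self.reference.n_atoms
        if len(self.mask) == 0:
            raise ValueError("mask must not be empty")
        if len(set(self.mask)) != len(self.mask):
            raise ValueError("mask contains duplicate indices")
        if any(i < 0 or i >= n_ref for i in self.mask):
            raise ValueError("mask indices outside reference")
        if self.regime not in ("de_novo", "diversify"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "diversify":
            if self.t_start is None:
                raise ValueError("diversify requires t_start")
            # diversify keeps the reference's own non-fixed atoms
            self.n_generated = n_ref - len(self.mask)
        if self.n_generated < 0:
            raise ValueError("n_generated must be >= 0")
        if self.resamplings < 1:
            raise ValueError("resamplings must be >= 1")

    @property
    def n_fixed(self) -> int:
        return len(self.mask)

    @property
    def permutation(self) -> np.ndarray:
        """Reference indices in combined-state row order (diversify only)."""
        rest = [i for i in range(self.reference.n_atoms) if i not in set(self.mask)]
        return np.array(list(self.mask) + rest, dtype=int)


def com_align_fixed(x_input: np.ndarray, x_gen_fixed: np.ndarray) -> np.ndarray:
    """Translate the clean/noised input block so its COM coincides with the
    generated counterpart. Pure translation: internal distances unchanged."""
    x_input = np.atleast_2d(np.asarray(x_input, dtype=np.float64))
    x_gen_fixed = np.atleast_2d(np.asarray(x_gen_fixed, dtype=np.float64))
    if x_input.shape[0] == 0:
        raise ValueError("empty fixed-atom set")
    if x_input.shape != x_gen_fixed.shape:
        raise ValueError("fixed blocks must have matching shapes")
    return x_input + (x_gen_fixed.mean(axis=0) - x_input.mean(axis=0))


# ---------------------------------------------------------------------------
# generic replacement step over one or more diffused blocks
# ---------------------------------------------------------------------------

def _replacement_step(z_blocks, t, eps_fn, fixed_spec, sched, rng, joint_com=False,
                      clip_radius=None):
    """One reverse step with substitution of fixed rows.

    ``z_blocks``: list of diffused AtomPointClouds. ``eps_fn(z_blocks, t)``
    returns one noise matrix per block. ``fixed_spec`` is a list of
    ``(block_index, row_indices, clean_cloud)``; clean data is forward-noised
    to ``t-1``, COM-aligned to its generated counterpart and spliced in. At
    ``s = 0`` the (near-zero variance) noise draw on the fixed block is
    dropped so the final sample contains the unperturbed reference.
    """
    s = t - 1
    eps = eps_fn(z_blocks, t)
    z_gen = []
    for zb, e in zip(z_blocks, eps):
        z_hat = clip_zdata(predict_data(zb, e, t, sched), clip_radius)
        z_gen.append(posterior_step(zb, z_hat, s, t, sched, rng))
    if joint_com:
        all_coords = np.vstack([z.coords for z in z_gen])
        com = all_coords.mean(axis=0)
        z_gen = [AtomPointCloud(z.coords - com, z.feats, z.labels) for z in z_gen]
    for bi, rows, clean in fixed_spec:
        if s > 0:
            noise = rng.standard_normal((clean.n_atoms, 3 + clean.n_feats))
            z_inp = forward_noise(clean, s, sched, noise)
        else:
            z_inp = AtomPointCloud(sched.alpha[0] * clean.coords,
                                   sched.alpha[0] * clean.feats, clean.labels)
        target = z_gen[bi]
        x_aligned = com_align_fixed(z_inp.coords, target.coords[rows])
        coords, feats = target.coords.copy(), target.feats.copy()
        coords[rows] = x_aligned
        feats[rows] = z_inp.feats
        z_gen[bi] = AtomPointCloud(coords, feats, target.labels)
    return z_gen


def _renoise_one_step(z_blocks, t, sched, rng, joint_com=False):
    """Forward-noise the combined state from t-1 back to t (resampling)."""
    alpha_ts, sigma2_ts = transition_coeffs(sched, t - 1, t)
    sig = np.sqrt(sigma2_ts)
    out = []
    noises = [rng.standard_normal((z.n_atoms, 3 + z.n_feats)) for z in z_blocks]
    if joint_com:
        all_coord_noise = np.vstack([n[:, :3] for n in noises])
        com = all_coord_noise.mean(axis=0)
        for n in noises:
            n[:, :3] -= com
    for z, n in zip(z_blocks, noises):
        zt = alpha_ts * np.hstack([z.coords, z.feats]) + sig * n
        out.append(AtomPointCloud(zt[:, :3], zt[:, 3:], z.labels))
    return out


def _run_chain(z_blocks, t_start, eps_fn, fixed_spec, sched, rng, r, joint_com=False,
               clip_radius=None):
    for t in range(t_start, 0, -1):
        for k in range(r):
            z_next = _replacement_step(z_blocks, t, eps_fn, fixed_spec, sched, rng,
                                       joint_com=joint_com, clip_radius=clip_radius)
            if k < r - 1:
                z_blocks = _renoise_one_step(z_next, t, sched, rng, joint_com=joint_com)
            else:
                z_blocks = z_next
    return z_blocks


# ---------------------------------------------------------------------------
# conditional-model substructure inpainting
# ---------------------------------------------------------------------------

def inpaint_step(
    z_t: AtomPointCloud,
    t: int,
    task: InpaintTask,
    model,
    pocket_scaled: AtomPointCloud,
    fixed_clean_scaled: AtomPointCloud,
    sched: Schedule,
    rng: np.random.Generator,
) -> AtomPointCloud:
    """Single replacement step for a ligand substructure (scaled frame)."""
    expected = task.n_fixed + task.n_generated
    if z_t.n_atoms != expected:
        raise ValueError(f"state has {z_t.n_atoms} rows, index map expects {expected}")

    def eps_fn(blocks, tt):
        return [model.predict_eps(blocks[0], pocket_scaled, tt)]

    rows = np.arange(task.n_fixed)
    (z_s,) = _replacement_step([z_t], t, eps_fn, [(0, rows, fixed_clean_scaled)],
                               sched, rng)
    return z_s


def inpaint_generate(
    task: InpaintTask,
    model,
    pocket: AtomPointCloud,
    sched: Schedule | None = None,
    rng=0,
    n_samples: int = 1,
) -> list[AtomPointCloud]:
    """Run the full inpainting chain and decode the results (unscaled frame).

    Output row order is fixed atoms (mask order) first, generated atoms after.
    """
    sched = sched if sched is not None else model.schedule
    scaling = model.scaling
    if task.regime == "diversify" and task.t_start > sched.T:
        raise ValueError("t_start exceeds T")
    shift = pocket.coords.mean(axis=0)
    pocket_scaled = AtomPointCloud((pocket.coords - shift) * scaling.coord_factor,
                                   pocket.feats * scaling.feat_factor, pocket.labels)
    ref_scaled = AtomPointCloud((task.reference.coords - shift) * scaling.coord_factor,
                                task.reference.feats * scaling.feat_factor,
                                task.reference.labels)
    mask = np.array(task.mask, dtype=int)
    fixed_clean = AtomPointCloud(ref_scaled.coords[mask], ref_scaled.feats[mask])
    d = len(model.alphabet)

    if isinstance(rng, np.random.Generator):
        child_rngs = rng.spawn(n_samples)
    else:
        child_rngs = [np.random.default_rng([int(rng), i]) for i in range(n_samples)]

    def eps_fn(blocks, tt):
        return [model.predict_eps(blocks[0], pocket_scaled, tt)]

    rows = np.arange(task.n_fixed)
    clip_radius = pocket_clip_radius(pocket_scaled, model.scaled_cutoffs)
    out = []
    for i in range(n_samples):
        child = child_rngs[i]
        if task.regime == "de_novo":
            n_total = task.n_fixed + task.n_generated
            z = AtomPointCloud(*np.hsplit(child.standard_normal((n_total, 3 + d)), [3]))
            t_start = sched.T
        else:
            perm = task.permutation
            combined = AtomPointCloud(ref_scaled.coords[perm], ref_scaled.feats[perm])
            if task.t_start == 0:
                out.append(_decode(combined, model, scaling, shift))
                continue
            noise = child.standard_normal((combined.n_atoms, 3 + d))
            z = forward_noise(combined, task.t_start, sched, noise)
            t_start = task.t_start
        (z,) = _run_chain([z], t_start, eps_fn, [(0, rows, fixed_clean)],
                          sched, child, task.resamplings, clip_radius=clip_radius)
        out.append(_decode(z, model, scaling, shift))
    return out


def _decode(z: AtomPointCloud, model, scaling, shift) -> AtomPointCloud:
    labels = decode_labels(z.feats, model.alphabet)
    n = z.n_atoms
    feats = np.zeros((n, len(model.alphabet)))
    feats[np.arange(n), [model.alphabet.index(el) for el in labels]] = 1.0
    coords = z.coords / scaling.coord_factor + shift
    return AtomPointCloud(coords, feats, labels)


# ---------------------------------------------------------------------------
# joint-mode generation: pocket as the fixed substructure
# ---------------------------------------------------------------------------

def generate_joint(model, pocket: AtomPointCloud, n_samples: int,
                   sched: Schedule | None = None, rng=0, sizes=None,
                   resamplings: int = 1) -> list[AtomPointCloud]:
    """Joint-mode sampling: the full ligand+pocket system is diffused and
    the pocket block is inpainted (replaced with its forward-noised ground
    truth) at every step. Same replacement code path as substructure
    inpainting, with the pocket as the mask.

    The reference protocol uses ``resamplings=10``; the default here is 1
    for speed, configurable by callers.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    sched = sched if sched is not None else model.schedule
    scaling = model.scaling
    shift = pocket.coords.mean(axis=0)
    pocket_clean = AtomPointCloud((pocket.coords - shift) * scaling.coord_factor,
                                  pocket.feats * scaling.feat_factor, pocket.labels)
    d_l, d_p = len(model.alphabet), pocket.n_feats

    def eps_fn(blocks, tt):
        return list(model.predict_eps_joint(blocks[0], blocks[1], tt))

    if isinstance(rng, np.random.Generator):
        child_rngs = rng.spawn(n_samples)
        size_rng = rng
    else:
        child_rngs = [np.random.default_rng([int(rng), i]) for i in range(n_samples)]
        size_rng = np.random.default_rng([int(rng), n_samples])

    rows = np.arange(pocket.n_atoms)
    clip_radius = pocket_clip_radius(pocket_clean, model.scaled_cutoffs)
    out = []
    for i in range(n_samples):
        child = child_rngs[i]
        n_l = (int(sizes[i]) if sizes is not None
               else sample_ligand_size(model.size_model, pocket.n_atoms, size_rng))
        z_lig = AtomPointCloud(*np.hsplit(child.standard_normal((n_l, 3 + d_l)), [3]))
        z_pock = AtomPointCloud(*np.hsplit(child.standard_normal((pocket.n_atoms, 3 + d_p)), [3]))
        z_lig_f, z_pock_f = _run_chain(
            [z_lig, z_pock], sched.T, eps_fn, [(1, rows, pocket_clean)],
            sched, child, resamplings, joint_com=True, clip_radius=clip_radius,
        )
        # re-anchor: translate so the output pocket COM matches the input pocket
        delta = pocket_clean.coords.mean(axis=0) - z_pock_f.coords.mean(axis=0)
        z_lig_f = AtomPointCloud(z_lig_f.coords + delta, z_lig_f.feats)
        out.append(_decode(z_lig_f, model, scaling, shift))
    return out


# ---------------------------------------------------------------------------
# automatic mask construction
# ---------------------------------------------------------------------------

def build_mask(molecule, task_kind: str, cut_bonds=None) -> tuple[int, ...]:
    """Derive the fixed-atom index set from an RDKit molecule.

    ``scaffold_elaboration`` fixes the Bemis-Murcko scaffold atoms,
    ``scaffold_hopping`` fixes their complement, ``linker_design`` fixes the
    terminal fragments obtained by deleting ``cut_bonds`` (pairs of atom
    indices). Indices are 0-based RDKit atom indices.
    """
    from rdkit import Chem
    from rdkit.Chem.Scaffolds import MurckoScaffold

    n = molecule.GetNumAtoms()
    if task_kind in ("scaffold_elaboration", "scaffold_hopping"):
        scaffold = MurckoScaffold.GetScaffoldForMol(molecule)
        if scaffold.GetNumAtoms() == 0:
            raise DegenerateScaffoldError(
                "molecule has no rings: Bemis-Murcko scaffold is empty")
        match = molecule.GetSubstructMatch(scaffold)
        if not match:
            raise DegenerateScaffoldError("scaffold could not be matched back")
        scaffold_idx = set(match)
        if task_kind == "scaffold_elaboration":
            return tuple(sorted(scaffold_idx))
        return tuple(sorted(set(range(n)) - scaffold_idx))
    if task_kind == "linker_design":
        if not cut_bonds:
            raise ValueError("linker_design requires cut_bonds")
        cuts = {frozenset(b) for b in cut_bonds}
        adj = {i: set() for i in range(n)}
        for bond in molecule.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if frozenset((i, j)) not in cuts:
                adj[i].add(j)
                adj[j].add(i)
        comps, seen = [], set()
        for start in range(n):
            if start in seen:
                continue
            stack, comp = [start], set()
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp.add(u)
                stack.extend(adj[u] - comp)
            seen |= comp
            comps.append(comp)
        fixed: set[int] = set()
        for comp in comps:
            touched = sum(1 for cut in cuts if any(a in comp for a in cut))
            if touched == 1:  # terminal fragment: touches exactly one cut
                fixed |= comp
        if not fixed:
            raise ValueError("cut_bonds produced no terminal fragments")
        return tuple(sorted(fixed))
    raise ValueError(f"unknown task kind {task_kind!r}")
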