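"""Evolutionary molecule optimization by partial noising/denoising.

Candidates are produced by noising a seed ligand a small number of steps and
running the conditional reverse process back to ``t = 0``; an external oracle
ranks the resulting molecules and the top-k seed the next generation. A
dual-objective variant prunes candidates that regress relative to a baseline
on either an on-target or an off-target score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .molsys import AtomPointCloud
from .schedule import Schedule
from .diffusion import (clip_zdata, forward_noise, pocket_clip_radius,
                        posterior_step, predict_data)

logger = logging.getLogger(__name__)

__all__ = [
    "OptimizerConfig",
    "DualObjectiveBaseline",
    "Oracle",
    "ArchiveRecord",
    "diversify",
    "evolve",
    "dual_objective_select",
]

WORST_SCORE = -np.inf


@dataclass(frozen=True)
class OptimizerConfig:
    population: int = 100
    top_k: int = 10
    t_min: int = 10
    t_max: int = 150
    generations: int = 5
    elitism: bool = True

    def __post_init__(self):
        if self.top_k > self.population:
            raise ValueError("top_k must be <= population")
        if not (1 <= self.t_min <= self.t_max):
            raise ValueError("require 1 <= t_min <= t_max")
        if self.population < 1 or self.generations < 1:
            raise ValueError("population and generations must be >= 1")


@dataclass(frozen=True)
class DualObjectiveBaseline:
    """Oracle values of the reference molecule (docking convention: lower is
    better binding) for on- and off-target."""

    on_score: float
    off_score: float

    def __post_init__(self):
        if not (np.isfinite(self.on_score) and np.isfinite(self.off_score)):
            raise ValueError("baseline scores must be finite")


class Oracle:
    """Wraps a scoring callable with a sign convention.

    ``sign=+1`` means the raw score is already higher-is-better (QED);
    ``sign=-1`` flips lower-is-better scores (docking) so that, after
    normalization, higher is always better.
    """

    def __init__(self, fn, sign: int = 1, name: str = "oracle"):
        if sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        self.fn = fn
        self.sign = sign
        self.name = name

    def __call__(self, mol) -> float:
        return self.sign * float(self.fn(mol))


@dataclass
class ArchiveRecord:
    generation: int
    index: int
    cloud: AtomPointCloud
    mol: object  # rdkit Mol or None
    score: float
    parent: int  # archive index of the parent, -1 for the seed
    t: int
    flagged: str = ""  # non-empty when postprocessing or the oracle failed


def diversify(
    molecule: AtomPointCloud,
    pocket: AtomPointCloud,
    t: int,
    model,
    sched: Schedule | None = None,
    rng: np.random.Generator | None = None,
) -> AtomPointCloud:
    """Noise the ligand ``t`` steps and denoise back with the conditional
    model. ``t = 0`` is an explicit identity escape. Atom count is unchanged."""
    sched = sched if sched is not None else model.schedule
    if not (0 <= t <= sched.T):
        raise ValueError(f"t={t} outside [0, {sched.T}]")
    if t == 0:
        return molecule.copy()
    rng = rng if rng is not None else np.random.default_rng()
    scaling = model.scaling
    shift = pocket.coords.mean(axis=0)
    pocket_scaled = AtomPointCloud((pocket.coords - shift) * scaling.coord_factor,
                                   pocket.feats * scaling.feat_factor, pocket.labels)
    lig = AtomPointCloud((molecule.coords - shift) * scaling.coord_factor,
                         molecule.feats * scaling.feat_factor)
    n, d = lig.n_atoms, lig.n_feats
    clip_radius = pocket_clip_radius(pocket_scaled, model.scaled_cutoffs)
    z = forward_noise(lig, t, sched, rng.standard_normal((n, 3 + d)))
    for tau in range(t, 0, -1):
        eps_hat = model.predict_eps(z, pocket_scaled, tau)
        z_hat = clip_zdata(predict_data(z, eps_hat, tau, sched), clip_radius)
        z = posterior_step(z, z_hat, tau - 1, tau, sched, rng)
    from .inpaint import _decode

    return _decode(z, model, scaling, shift)


def _postprocess_and_score(cloud: AtomPointCloud, oracle) -> tuple[object, float, str]:
    from .chemio import postprocess

    result = postprocess(cloud)
    if not result.ok:
        return None, WORST_SCORE, f"postprocess:{result.stage}"
    try:
        return result.mol, float(oracle(result.mol)), ""
    except Exception as exc:  # oracle failure must never crash the loop
        logger.warning("oracle failed: %s", exc)
        return result.mol, WORST_SCORE, f"oracle:{exc}"


def evolve(
    seed_molecule: AtomPointCloud,
    pocket: AtomPointCloud,
    config: OptimizerConfig,
    model,
    sched: Schedule | None = None,
    rng=0,
    oracle=None,
) -> list[ArchiveRecord]:
    """Run the evolutionary loop; returns the full archive.

    Each generation holds exactly ``config.population`` records. With elitism
    the first slot of every generation carries the incumbent best forward
    unchanged (a ``t = 0`` diversification), which guarantees that the
    best-of-generation score is non-decreasing for deterministic oracles.
    Selection is a stable sort by (score, insertion order). The pocket is
    never modified.
    """
    if oracle is None:
        raise ValueError("an oracle is required")
    sched = sched if sched is not None else model.schedule
    master = int(rng) if not isinstance(rng, np.random.Generator) else None

    archive: list[ArchiveRecord] = []
    # parents: list of (archive_index, cloud); seed has index -1
    parents: list[tuple[int, AtomPointCloud]] = [(-1, seed_molecule)]
    elite: tuple[int, AtomPointCloud, float] | None = None  # (idx, cloud, score)

    counter = 0
    for gen in range(config.generations):
        records: list[ArchiveRecord] = []
        for i in range(config.population):
            if master is not None:
                child = np.random.default_rng([master, gen, i])
            else:
                child = rng.spawn(1)[0]
            if config.elitism and elite is not None and i == 0:
                parent_idx, parent_cloud = elite[0], elite[1]
                t = 0
            else:
                parent_idx, parent_cloud = parents[i % len(parents)]
                t = int(child.integers(config.t_min, config.t_max + 1))
            variant = diversify(parent_cloud, pocket, t, model, sched, child)
            mol, score, flag = _postprocess_and_score(variant, oracle)
            records.append(ArchiveRecord(
                generation=gen, index=counter, cloud=variant, mol=mol,
                score=score, parent=parent_idx, t=t, flagged=flag,
            ))
            counter += 1
        archive.extend(records)
        ranked = sorted(records, key=lambda r: -r.score)  # stable: ties keep order
        top = ranked[: config.top_k]
        parents = [(r.index, r.cloud) for r in top]
        best = top[0]
        if elite is None or best.score >= elite[2]:
            elite = (best.index, best.cloud, best.score)
        if config.elitism and elite is not None:
            if elite[0] not in {p[0] for p in parents}:
                parents.append((elite[0], elite[1]))
    return archive


def dual_objective_select(candidates, baseline: DualObjectiveBaseline, top_k: int):
    """Prune candidates that regress on either axis, then rank by on-target.

    ``candidates`` is a sequence of objects with ``on_score`` and ``off_score``
    attributes (or ``(on, off)`` tuples). Docking convention: lower on-score is
    better binding (keep ``on <= baseline.on``); a higher off-score means
    weaker off-target binding, i.e. better selectivity (keep
    ``off >= baseline.off``). Returns the surviving candidates sorted by
    on-target score (best binder first), at most ``top_k``; empty with a
    warning when everything is pruned.
    """
    def scores(c):
        if hasattr(c, "on_score"):
            return float(c.on_score), float(c.off_score)
        return float(c[0]), float(c[1])

    survivors = [c for c in candidates
                 if scores(c)[0] <= baseline.on_score and scores(c)[1] >= baseline.off_score]
    if not survivors:
        logger.warning("dual-objective pruning removed all candidates; "
                       "caller should reseed from previous parents")
        return []
    survivors.sort(key=lambda c: scores(c)[0])  # stable
    return survivors[:top_k]
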