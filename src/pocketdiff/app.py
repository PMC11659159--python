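"""Run configuration, seeding and the training loop."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .diffusion import draw_noise, forward_noise
from .egnn import EGNNDenoiser, EgnnConfig, save_checkpoint
from .molsys import AtomPointCloud, FeatureScaling
from .nnet import Adam
from .schedule import build_schedule

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "train", "training_frame"]

_SCHEMA = {
    "mode": {"cond", "joint"},
    "seed": None,
    "schedule": {"T", "offset", "clip_lo"},
    "scaling": {"feat", "coord"},
    "egnn": {"n_layers", "hidden_dim", "reflection_sensitive", "time_encoding",
             "n_frequencies"},
    "cutoffs": {"ll", "lp", "pp"},
    "optimizer": {"population", "top_k", "t_min", "t_max", "generations", "elitism"},
    "pocket": {"mode"},
    "train": {"n_steps", "lr", "clip_grad_norm"},
    "paths": {"out"},
}


@dataclass
class RunConfig:
    mode: str = "cond"
    seed: int = 0
    schedule: dict = field(default_factory=lambda: {"T": 500, "offset": 1e-5,
                                                    "clip_lo": 0.001})
    scaling: dict = field(default_factory=lambda: {"feat": 0.25, "coord": 1.0})
    egnn: dict = field(default_factory=lambda: {"n_layers": 4, "hidden_dim": 128,
                                                "reflection_sensitive": True,
                                                "time_encoding": "scalar"})
    cutoffs: dict = field(default_factory=lambda: {"ll": 5.0, "lp": 5.0, "pp": 5.0})
    optimizer: dict = field(default_factory=dict)
    pocket: dict = field(default_factory=lambda: {"mode": "c_alpha"})
    train: dict = field(default_factory=lambda: {"n_steps": 1000, "lr": 1e-3,
                                                 "clip_grad_norm": 10.0})
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in _SCHEMA["mode"]:
            raise ValueError(f"mode must be cond or joint, got {self.mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, allowed in _SCHEMA.items():
            if key in raw and isinstance(allowed, set) and isinstance(raw[key], dict):
                extra = set(raw[key]) - allowed
                if extra:
                    raise ValueError(f"unknown keys under {key!r}: {sorted(extra)}")
        cfg = cls()
        for key, value in raw.items():
            if isinstance(getattr(cfg, key), dict) and isinstance(value, dict):
                getattr(cfg, key).update(value)
            else:
                setattr(cfg, key, value)
        cfg.__post_init__()
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def build_model(self, d_pocket: int, size_model=None) -> EGNNDenoiser:
        egnn_cfg = EgnnConfig(
            n_layers=int(self.egnn.get("n_layers", 4)),
            hidden_dim=int(self.egnn.get("hidden_dim", 128)),
            reflection_sensitive=bool(self.egnn.get("reflection_sensitive", True)),
            time_encoding=self.egnn.get("time_encoding", "scalar"),
            n_frequencies=int(self.egnn.get("n_frequencies", 4)),
        )
        return EGNNDenoiser(
            config=egnn_cfg,
            d_pocket=d_pocket,
            scaling=FeatureScaling(self.scaling.get("feat", 0.25),
                                   self.scaling.get("coord", 1.0)),
            schedule=build_schedule(int(self.schedule.get("T", 500)),
                                    float(self.schedule.get("offset", 1e-5)),
                                    float(self.schedule.get("clip_lo", 0.001))),
            size_model=size_model,
            cutoffs={"LL": self.cutoffs.get("ll", 5.0),
                     "LP": self.cutoffs.get("lp", 5.0),
                     "PP": self.cutoffs.get("pp", 5.0)},
            mode=self.mode,
            seed=int(self.seed),
        )


def training_frame(system, mode: str, scaling) -> tuple[AtomPointCloud, AtomPointCloud]:
    """Center a complex per the COM convention and move it to the scaled frame.

    cond: translate once so the pocket COM is at the origin; joint: subtract
    the COM of the full ligand+pocket point set.
    """
    lig, pocket = system.ligand, system.pocket
    if mode == "cond":
        shift = pocket.coords.mean(axis=0)
    else:
        shift = np.vstack([lig.coords, pocket.coords]).mean(axis=0)
    lig_s = AtomPointCloud((lig.coords - shift) * scaling.coord_factor,
                           lig.feats * scaling.feat_factor, lig.labels)
    pocket_s = AtomPointCloud((pocket.coords - shift) * scaling.coord_factor,
                              pocket.feats * scaling.feat_factor, pocket.labels)
    return lig_s, pocket_s


def train(
    dataset,
    model: EGNNDenoiser,
    n_steps: int,
    seed: int = 0,
    lr: float = 1e-3,
    clip_grad_norm: float = 10.0,
    optimizer: Adam | None = None,
    start_step: int = 0,
    checkpoint_path=None,
    checkpoint_every: int | None = None,
    log_every: int | None = None,
):
    """Denoising-score-matching training on a dataset of ComplexSystems.

    Per step: draw a complex and ``t ~ U[1, T]``, noise it, predict the noise
    and take an Adam step on the epsilon loss (averaged over entries for a
    step-size that is stable across molecule sizes). The per-step random
    stream is keyed by ``(seed, absolute step)`` so resumed runs continue the
    identical trajectory. Returns ``(losses, optimizer)``.
    """
    if not dataset:
        raise ValueError("dataset is empty")
    mode = model.mode
    frames = [training_frame(sys_, mode, model.scaling) for sys_ in dataset]
    if optimizer is None:
        optimizer = Adam(model.parameters(), lr=lr, clip_grad_norm=clip_grad_norm)
    T = model.schedule.T
    losses = []
    for step in range(start_step, start_step + n_steps):
        rng = np.random.default_rng([seed, step])
        lig, pocket = frames[int(rng.integers(len(frames)))]
        t = int(rng.integers(1, T + 1))
        if mode == "cond":
            eps_l = draw_noise(rng, lig.n_atoms, lig.n_feats)
            z_lig = forward_noise(lig, t, model.schedule, eps_l)
            loss = model.loss_tensors(z_lig, pocket, t, eps_l)
            n_entries = eps_l.size
        else:
            eps_l = draw_noise(rng, lig.n_atoms, lig.n_feats)
            eps_p = draw_noise(rng, pocket.n_atoms, pocket.n_feats)
            com = np.vstack([eps_l[:, :3], eps_p[:, :3]]).mean(axis=0)
            eps_l[:, :3] -= com
            eps_p[:, :3] -= com
            z_lig = forward_noise(lig, t, model.schedule, eps_l)
            z_pock = forward_noise(pocket, t, model.schedule, eps_p)
            loss = model.loss_tensors(z_lig, z_pock, t, eps_l, eps_p, update_pocket=True)
            n_entries = eps_l.size + eps_p.size
        value = float(loss.data)
        if not np.isfinite(value):
            raise RuntimeError(
                f"NaN/inf loss at step {step} (t={t}, n_lig={lig.n_atoms}); "
                "aborting with diagnostic dump: "
                f"lig_coords_norm={np.linalg.norm(z_lig.coords):.3g}"
            )
        optimizer.zero_grad()
        loss.backward(np.full_like(loss.data, 1.0 / n_entries))
        optimizer.step()
        losses.append(value / n_entries)
        if log_every and (step + 1) % log_every == 0:
            logger.info("step %d loss %.5f", step + 1, float(np.mean(losses[-log_every:])))
        if checkpoint_path and checkpoint_every and (step + 1) % checkpoint_every == 0:
            save_checkpoint(model, checkpoint_path)
    if checkpoint_path:
        save_checkpoint(model, checkpoint_path)
    return losses, optimizer
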