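"""Variance-preserving polynomial noise schedule.

The raw signal curve is ``1 - (t/T)^2``; squared step ratios are clipped for
numerical stability near ``t = T``, the curve is rebuilt as a running product
of the clipped ratios, and a tiny offset keeps ``alpha_0 < 1``. Throughout,
``alpha_t^2 + sigma_t^2 = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Schedule", "build_schedule", "transition_coeffs"]


@dataclass(frozen=True)
class Schedule:
    T: int
    alpha: np.ndarray  # alpha_t, t = 0..T
    sigma: np.ndarray  # sigma_t, t = 0..T
    offset: float
    clip_lo: float

    def snr(self) -> np.ndarray:
        return self.alpha**2 / self.sigma**2

    def to_table(self) -> str:
        """Two-column text table (t, alpha_t, sigma_t) for inspection."""
        lines = ["t\talpha\tsigma"]
        for t in range(self.T + 1):
            lines.append(f"{t}\t{self.alpha[t]:.12e}\t{self.sigma[t]:.12e}")
        return "\n".join(lines)


def build_schedule(T: int = 500, offset: float = 1e-5, clip_lo: float = 0.001) -> Schedule:
    if T < 2:
        raise ValueError("T must be >= 2")
    if not (0 < offset < 0.5):
        raise ValueError("offset must be a small positive number")
    if not (0 < clip_lo < 1):
        raise ValueError("clip_lo must be in (0, 1)")
    t = np.arange(T + 1, dtype=np.float64)
    alpha_tilde = 1.0 - (t / T) ** 2
    # squared one-step ratios, clipped, then the curve rebuilt by product
    ratios_sq = np.ones(T + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios_sq[1:] = (alpha_tilde[1:] / alpha_tilde[:-1]) ** 2
    ratios_sq = np.clip(ratios_sq, clip_lo, 1.0)
    alpha_tilde_sq = np.cumprod(ratios_sq)
    alpha_sq = (1.0 - 2.0 * offset) * alpha_tilde_sq + offset
    sigma_sq = 1.0 - alpha_sq
    return Schedule(T=T, alpha=np.sqrt(alpha_sq), sigma=np.sqrt(sigma_sq),
                    offset=offset, clip_lo=clip_lo)


def transition_coeffs(sched: Schedule, s: int, t: int) -> tuple[float, float]:
    """Return ``(alpha_{t|s}, sigma^2_{t|s})`` for grid steps ``s < t``."""
    if not (0 <= s < t <= sched.T):
        raise ValueError(f"require 0 <= s < t <= T, got s={s}, t={t}")
    alpha_ts = float(sched.alpha[t] / sched.alpha[s])
    sigma2_ts = float(sched.sigma[t] ** 2 - alpha_ts**2 * sched.sigma[s] ** 2)
    return alpha_ts, max(sigma2_ts, 0.0)
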