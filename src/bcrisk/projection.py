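"""Absolute-risk projection with competing mortality.

The same yearly recursion serves both the clinical (Gail) and the genetic
(PRS) engine: given per-year disease hazards ``lam[t]`` and competing
mortality hazards ``m[t]``, the probability of a disease event in year ``t``
is ``lam/(lam+m) * (1 - exp(-(lam+m)))`` times the probability of having
survived (free of both events) to the start of the year, and the horizon
risk is the sum over years.  With ``m = 0`` and constant ``lam`` this
reduces to the closed form ``1 - exp(-lam * T)``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["project_absolute_risk"]


def project_absolute_risk(hazards: Sequence[float], mortality: Sequence[float]) -> float:
    """Cumulative event probability over ``len(hazards)`` one-year steps."""
    lam = np.asarray(hazards, dtype=float)
    m = np.asarray(mortality, dtype=float)
    if lam.shape != m.shape:
        raise ValueError("hazard and mortality sequences must have equal length")
    if lam.size == 0:
        raise ValueError("horizon must cover at least one year")
    if (lam < 0).any() or (m < 0).any():
        raise ValueError("hazards must be non-negative")
    total = lam + m
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, lam / np.where(total > 0, total, 1.0), 0.0)
    yearly = frac * (1.0 - np.exp(-total))
    survival = np.concatenate([[1.0], np.cumprod(np.exp(-total))[:-1]])
    return float(np.sum(yearly * survival))
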