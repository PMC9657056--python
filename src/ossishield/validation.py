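"""Stiffness fitting and Bland-Altman experiment/model agreement.

Construct stiffness is the slope of the load-displacement record within
its linear region, by ordinary least squares; when no window is given,
the contiguous window covering at least half the samples with the
highest R^2 is selected. Agreement between measured and predicted
stresses uses Bland-Altman limits of agreement: bias = mean difference,
limits = bias +- 1.96 * sample SD of the differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, InputError


@dataclass(frozen=True)
class StiffnessFit:
    stiffness_kn_per_mm: float
    r_squared: float
    window_load_n: tuple[float, float]
    n_used: int


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_outside: int
    n: int


def _ols_slope(disp: np.ndarray, load: np.ndarray) -> tuple[float, float]:
    if np.ptp(disp) == 0:
        raise FitError("zero-variance displacement; cannot fit a slope")
    res = stats.linregress(disp, load)
    return float(res.slope), float(res.rvalue**2)


def fit_stiffness(
    record: pd.DataFrame, window: tuple[float, float] | None = None
) -> StiffnessFit:
    """Least-squares stiffness (kN/mm) of a load-displacement record.

    ``record`` needs columns ``load_n`` and ``displacement_mm``, ordered
    by load. ``window`` restricts the fit to an inclusive load range
    (N); otherwise the most linear contiguous window of at least 50% of
    the samples is used.
    """
    for col in ("load_n", "displacement_mm"):
        if col not in record.columns:
            raise InputError(f"record missing column {col!r}")
    rec = record.sort_values("load_n", kind="mergesort").reset_index(drop=True)
    load = rec["load_n"].to_numpy(dtype=float)
    disp = rec["displacement_mm"].to_numpy(dtype=float)
    if np.any(disp < 0):
        raise InputError("displacements must be non-negative")

    if window is not None:
        lo, hi = window
        mask = (load >= lo) & (load <= hi)
        if mask.sum() < 3:
            raise FitError("fewer than 3 samples in the requested window")
        slope, r2 = _ols_slope(disp[mask], load[mask])
        return StiffnessFit(
            slope / 1000.0,
            r2,
            (float(load[mask].min()), float(load[mask].max())),
            int(mask.sum()),
        )

    n = len(load)
    if n < 3:
        raise FitError("need at least 3 samples")
    min_len = max(3, math.ceil(n / 2))
    best: tuple[float, int, int] | None = None  # (r2, i, j) j exclusive
    for i in range(0, n - min_len + 1):
        for j in range(i + min_len, n + 1):
            slope, r2 = _ols_slope(disp[i:j], load[i:j])
            # prefer higher r2, then longer window, then earlier start
            key = (r2, j - i, -i)
            if best is None or key > (best[0], best[2] - best[1], -best[1]):
                best = (r2, i, j)
    _, i, j = best
    slope, r2 = _ols_slope(disp[i:j], load[i:j])
    return StiffnessFit(
        slope / 1000.0, r2, (float(load[i]), float(load[j - 1])), j - i
    )


def bland_altman(measured, predicted) -> AgreementResult:
    """Bland-Altman limits of agreement between two measurement series.

    Differences are measured - predicted; limits use the sample (n-1)
    standard deviation. ``n_outside`` counts differences strictly beyond
    the limits.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape or m.ndim != 1:
        raise InputError("measured and predicted must be equal-length 1-D arrays")
    if len(m) < 2:
        raise InputError("need at least 2 paired values")
    diff = m - p
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    n_outside = int(((diff < lo) | (diff > hi)).sum())
    return AgreementResult(bias, sd, lo, hi, n_outside, len(m))


def agreement_frame(result: AgreementResult) -> pd.DataFrame:
    return pd.DataFrame([result.__dict__])
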