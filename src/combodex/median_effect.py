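"""Median-effect modelling and Chou-Talalay Combination Index analysis.

The mass-action median-effect equation relates dose D to the fraction of
cells affected fa through

    fa / fu = (D / Dm)^m,        fu = 1 - fa,

where Dm is the median-effect dose (fa = 0.5) and m the sigmoidicity.
Taking log10 of both sides gives a straight line in log10 D, fitted here
by ordinary least squares.  For a fixed-ratio combination treated as a
single agent at total dose D1 + D2, the Combination Index at effect
level fa is

    CI = D1/Dx1 + D2/Dx2 + alpha * (D1*D2)/(Dx1*Dx2)

with Dx_i the single-agent dose producing the same fa and alpha = 0 for
mutually exclusive (1 for mutually non-exclusive) drugs.  CI < 1 marks
synergy, CI = 1 additivity, CI > 1 antagonism.  The Dose-Reduction Index
DRI_i = Dx_i / D_i is the fold by which the combination spares each
agent at that effect level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from combodex.errors import InsufficientDataError

#: fa window retained for linearization; log-odds diverge outside it
FA_WINDOW = (0.01, 0.99)

#: default additive band half-width for CI classification
CI_TOLERANCE = 0.05


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters from the linearized OLS fit.

    ``r`` is the Pearson correlation of the linearized regression (the
    conventional goodness-of-fit statistic for median-effect plots);
    ``reliable`` is False when the slope is non-positive, which for
    inhibition data signals an unusable fit.
    """

    dm: float
    m: float
    r: float
    n_points: int
    reliable: bool = True

    def to_dict(self) -> dict:
        return {"dm": self.dm, "m": self.m, "r": self.r,
                "n_points": self.n_points, "reliable": self.reliable}


@dataclass(frozen=True)
class CIResult:
    fa: float
    d1: float
    d2: float
    dx1: float
    dx2: float
    alpha: int
    ci: float
    classification: str

    def to_dict(self) -> dict:
        return {"fa": self.fa, "d1": self.d1, "d2": self.d2,
                "dx1": self.dx1, "dx2": self.dx2, "alpha": self.alpha,
                "ci": self.ci, "classification": self.classification}


@dataclass
class FaCICurve:
    """Combination Index evaluated over a grid of effect levels."""

    grid: list[CIResult] = field(default_factory=list)

    @property
    def fa_values(self) -> np.ndarray:
        return np.array([r.fa for r in self.grid])

    @property
    def ci_values(self) -> np.ndarray:
        return np.array([r.ci for r in self.grid])

    def to_dict(self) -> dict:
        return {"grid": [r.to_dict() for r in self.grid]}


@dataclass(frozen=True)
class DRIResult:
    """Fold dose reduction per agent at one observed effect level."""

    dri_a: Optional[float]
    dri_b: Optional[float]

    def to_dict(self) -> dict:
        return {"dri_a": self.dri_a, "dri_b": self.dri_b}


def linearize(
    doses: Sequence[float], fa: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, str]]]:
    """Median-effect linearization: (log10 D, log10(fa/(1-fa))).

    Points with non-positive dose or fa outside [0.01, 0.99] are excluded
    and reported as (index, reason) pairs.  Fewer than two retained points
    is an error.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.shape != fa.shape:
        raise ValueError("doses and fa must have equal length")
    excluded: list[tuple[int, str]] = []
    xs, ys = [], []
    for i, (d, f) in enumerate(zip(doses, fa)):
        if d <= 0:
            excluded.append((i, "non-positive dose (log undefined)"))
            continue
        if not (FA_WINDOW[0] <= f <= FA_WINDOW[1]):
            excluded.append((i, f"fa={f:g} outside window {FA_WINDOW}"))
            continue
        xs.append(math.log10(d))
        ys.append(math.log10(f / (1.0 - f)))
    if len(xs) < 2:
        raise InsufficientDataError(
            f"median-effect linearization retained {len(xs)} point(s); need >= 2"
        )
    return np.array(xs), np.array(ys), excluded


def fit_median_effect(doses: Sequence[float], fa: Sequence[float]) -> MedianEffectFit:
    """OLS fit of the linearized median-effect plot.

    m is the slope; Dm = 10^(-intercept/m); r the linear correlation of
    the retained points.  A non-positive slope is returned but flagged
    unreliable.
    """
    x, y, _ = linearize(doses, fa)
    slope, intercept = np.polyfit(x, y, 1)
    if np.std(x) > 0 and np.std(y) > 0:
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        r = 0.0
    m = float(slope)
    reliable = m > 0
    dm = float(10.0 ** (-intercept / m)) if m != 0 else float("nan")
    return MedianEffectFit(dm=dm, m=m, r=r, n_points=len(x), reliable=reliable)


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing effect fa: Dx = Dm * (fa/(1-fa))^(1/m)."""
    if not 0.0 < fa < 1.0:
        raise ValueError("fa must lie strictly in (0, 1)")
    if fit.m == 0:
        raise ValueError("median-effect slope m must be non-zero")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def effect_at_dose(fit: MedianEffectFit, dose: float) -> float:
    """Effect at a dose: fa = (D/Dm)^m / (1 + (D/Dm)^m)."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    ratio = (dose / fit.dm) ** fit.m
    return ratio / (1.0 + ratio)


def classify_ci(ci: float, tolerance: float = CI_TOLERANCE) -> str:
    """Interpret a Combination Index: synergistic below 1, antagonistic
    above, additive inside the ±tolerance band around 1."""
    if ci <= 0:
        raise ValueError("CI must be positive")
    if abs(ci - 1.0) <= tolerance:
        return "additive"
    return "synergistic" if ci < 1.0 else "antagonistic"


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    d1: float,
    d2: float,
    fa_obs: float,
    alpha: int = 0,
    tolerance: float = CI_TOLERANCE,
) -> CIResult:
    """Combination Index for component doses (d1, d2) producing fa_obs."""
    if not 0.0 < fa_obs < 1.0:
        raise ValueError("fa_obs must lie strictly in (0, 1)")
    if alpha not in (0, 1):
        raise ValueError("alpha must be 0 or 1")
    dx1 = dose_for_effect(fit_a, fa_obs)
    dx2 = dose_for_effect(fit_b, fa_obs)
    ci = d1 / dx1 + d2 / dx2 + alpha * (d1 * d2) / (dx1 * dx2)
    return CIResult(fa=fa_obs, d1=d1, d2=d2, dx1=dx1, dx2=dx2,
                    alpha=alpha, ci=float(ci),
                    classification=classify_ci(ci, tolerance))


def default_fa_grid(fa_min: float = 0.25, fa_max: float = 0.90,
                    fa_step: float = 0.05) -> np.ndarray:
    """Inclusive fa grid; defaults span 0.25-0.90 in steps of 0.05."""
    n = int(round((fa_max - fa_min) / fa_step))
    grid = fa_min + fa_step * np.arange(n + 1)
    return grid[(grid > 0) & (grid < 1)]


def fa_ci_curve(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_combo: MedianEffectFit,
    ratio: tuple[float, float],
    grid: Optional[Sequence[float]] = None,
    alpha: int = 0,
    tolerance: float = CI_TOLERANCE,
) -> FaCICurve:
    """Fa-CI curve for a fixed-ratio combination.

    The combination is modelled as a single agent at total dose with
    mixing weights ``ratio``; at each grid fa the total combination dose
    comes from the combo fit and is split into components by the weights.
    """
    if grid is None:
        grid = default_fa_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("fa grid must be non-empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("fa grid must be strictly increasing")
    w = np.asarray(ratio, dtype=float)
    w = w / w.sum()
    results = []
    for fa in grid:
        dc = dose_for_effect(fit_combo, float(fa))
        results.append(
            combination_index(fit_a, fit_b, dc * w[0], dc * w[1], float(fa),
                              alpha=alpha, tolerance=tolerance)
        )
    return FaCICurve(grid=results)


def dose_reduction_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    d1: float,
    d2: float,
    fa_obs: float,
) -> DRIResult:
    """DRI_i = Dx_i(single) / d_i(combination); None for a zero dose."""
    if not 0.0 < fa_obs < 1.0:
        raise ValueError("fa_obs must lie strictly in (0, 1)")
    dri_a = dose_for_effect(fit_a, fa_obs) / d1 if d1 > 0 else None
    dri_b = dose_for_effect(fit_b, fa_obs) / d2 if d2 > 0 else None
    return DRIResult(dri_a=dri_a, dri_b=dri_b)
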