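"""Four-parameter logistic (4PL) dose-response fitting and absolute IC50.

The model is the descending viability curve

    V(D) = bottom + (top - bottom) / (1 + (D / ec50)^hill)

with V(0) = top, so dose-0 control points anchor the upper asymptote.
The absolute IC50 is the dose at which the *fitted curve* crosses 50 % of
control, which coincides with ``ec50`` only when top = 100 and
bottom = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from combodex.errors import InsufficientDataError
from combodex.plate_io import DoseResponseSeries


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters (percent scale, ec50 in µM)."""

    top: float
    bottom: float
    hill: float
    ec50: float
    rss: float
    converged: bool

    def predict(self, dose: float | np.ndarray) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(dose > 0, dose / self.ec50, 0.0)
        return self.bottom + (self.top - self.bottom) / (1.0 + ratio**self.hill)

    def to_dict(self) -> dict:
        return {
            "top": self.top,
            "bottom": self.bottom,
            "hill": self.hill,
            "ec50": self.ec50,
            "rss": self.rss,
            "converged": self.converged,
        }


def inhibition_fraction(viability: float) -> float:
    """Convert percent viability to the fraction affected fa.

    fa = 1 - viability/100, clamped to [0, 1]; stimulation above 100 %
    therefore maps to zero inhibition.  Negative viability is a domain
    error.
    """
    if viability < 0:
        raise ValueError("viability must be non-negative")
    return max(0.0, min(1.0, 1.0 - viability / 100.0))


def _four_pl(dose: np.ndarray, top: float, bottom: float, hill: float,
             ec50: float) -> np.ndarray:
    ratio = np.where(dose > 0, dose / ec50, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio**hill)


def fit_four_pl(series: DoseResponseSeries) -> FourPLFit:
    """Least-squares 4PL fit to the replicate-mean viabilities of a series.

    Requires at least four distinct doses.  Multi-start over hill slopes
    {0.5, 1, 2, 4} guards against the local minima typical of 6-point
    curves; the best start by SSE wins.  Non-convergence is reported via
    the ``converged`` flag rather than an exception.
    """
    doses = series.doses
    means = series.viabilities
    if len(np.unique(doses)) < 4:
        raise InsufficientDataError(
            f"4PL fit needs >= 4 distinct doses, got {len(np.unique(doses))}"
        )

    vmax, vmin = float(means.max()), float(means.min())
    pos = doses[doses > 0]
    # ec50 guess: dose where viability is nearest the half-range
    half = (vmax + vmin) / 2.0
    ec50_guess = float(pos[np.argmin(np.abs(means[doses > 0] - half))]) if len(pos) else 1.0

    lo = np.array([0.9 * vmax, 0.0, 0.1, pos.min() / 10.0 if len(pos) else 1e-6])
    hi = np.array([1.1 * vmax + 5.0, max(vmin, 1e-9), 10.0,
                   10.0 * doses.max() if doses.max() > 0 else 1e6])

    def residuals(theta: np.ndarray) -> np.ndarray:
        top, bottom, hill, ec50 = theta
        return _four_pl(doses, top, bottom, hill, ec50) - means

    best: Optional[tuple[np.ndarray, float, bool]] = None
    for hill0 in (0.5, 1.0, 2.0, 4.0):
        x0 = np.clip(np.array([vmax, vmin, hill0, ec50_guess]), lo, hi)
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi),
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[1] - 1e-10:
            best = (sol.x, sse, bool(sol.success))
    if best is None:
        return FourPLFit(vmax, vmin, 1.0, ec50_guess, float("inf"), False)
    theta, sse, ok = best
    return FourPLFit(top=float(theta[0]), bottom=float(theta[1]),
                     hill=float(theta[2]), ec50=float(theta[3]),
                     rss=sse, converged=ok)


def absolute_ic50(fit: FourPLFit) -> Optional[float]:
    """Dose at which the fitted curve crosses 50 % viability.

    Solves V(D) = 50 in closed form; returns ``None`` when the curve
    never crosses 50 (bottom >= 50 or top <= 50).
    """
    if fit.bottom >= 50.0 or fit.top <= 50.0:
        return None
    # 50 = bottom + (top-bottom)/(1+r^h)  =>  r^h = (top-50)/(50-bottom)
    ratio = (fit.top - 50.0) / (50.0 - fit.bottom)
    return float(fit.ec50 * ratio ** (1.0 / fit.hill))
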