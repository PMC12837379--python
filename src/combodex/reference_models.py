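"""Bliss Independence and Highest Single Agent (HSA) reference models.

Both models predict the combined effect of two agents from their
single-agent effects, on the inhibition-fraction scale:

* Bliss (probabilistic independence):  Eexp = EA + EB - EA*EB
* HSA (no interaction beyond the better single agent):  Eexp = max(EA, EB)

The deviation delta = Eobs - Eexp classifies the interaction: positive
beyond tolerance is synergy, negative antagonism.  Note the sign
convention differs from the Combination Index, where synergy is CI < 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from combodex.dose_response import inhibition_fraction
from combodex.median_effect import classify_ci  # noqa: F401  (shared CI thresholds)
from combodex.plate_io import DoseResponseSeries

#: default additive band half-width on delta
BLISS_TOLERANCE = 0.01


@dataclass(frozen=True)
class BlissResult:
    e_a: float
    e_b: float
    e_obs: float
    e_exp: float
    delta: float
    classification: str

    def to_dict(self) -> dict:
        return {"e_a": self.e_a, "e_b": self.e_b, "e_obs": self.e_obs,
                "e_exp": self.e_exp, "delta": self.delta,
                "classification": self.classification}


@dataclass(frozen=True)
class HSAResult:
    e_a: float
    e_b: float
    e_obs: float
    e_exp: float
    delta: float
    classification: str

    def to_dict(self) -> dict:
        return {"e_a": self.e_a, "e_b": self.e_b, "e_obs": self.e_obs,
                "e_exp": self.e_exp, "delta": self.delta,
                "classification": self.classification}


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def bliss_expected(e_a: float, e_b: float) -> float:
    """Bliss-independent expectation EA + EB - EA*EB (symmetric, bounded
    below by max(EA, EB) and above by 1)."""
    _check_fraction("e_a", e_a)
    _check_fraction("e_b", e_b)
    return e_a + e_b - e_a * e_b


def hsa_expected(e_a: float, e_b: float) -> float:
    """Highest-single-agent expectation max(EA, EB)."""
    _check_fraction("e_a", e_a)
    _check_fraction("e_b", e_b)
    return max(e_a, e_b)


def delta_bliss(
    e_obs: float, e_exp: float, tolerance: float = BLISS_TOLERANCE
) -> tuple[float, str]:
    """Deviation from an expectation and its classification.

    delta = Eobs - Eexp; synergistic above +tolerance, antagonistic below
    -tolerance, additive within the band.
    """
    _check_fraction("e_obs", e_obs)
    _check_fraction("e_exp", e_exp)
    delta = e_obs - e_exp
    if delta > tolerance:
        cls = "synergistic"
    elif delta < -tolerance:
        cls = "antagonistic"
    else:
        cls = "additive"
    return delta, cls


def _single_effect_at(
    series: DoseResponseSeries, dose: float, interpolate: bool
) -> Optional[float]:
    doses = series.doses
    via = series.viabilities
    hit = np.flatnonzero(np.isclose(doses, dose, rtol=1e-9, atol=1e-12))
    if hit.size:
        return inhibition_fraction(float(via[hit[0]]))
    if not interpolate:
        return None
    if dose < doses.min() or dose > doses.max():
        return None
    fa = np.array([inhibition_fraction(v) for v in via])
    return float(np.interp(dose, doses, fa))


def synergy_table(
    series_a: DoseResponseSeries,
    series_b: DoseResponseSeries,
    combo: DoseResponseSeries,
    tolerance: float = BLISS_TOLERANCE,
    interpolate: bool = False,
) -> list[dict]:
    """Per-dose-pair Bliss and HSA results for a fixed-ratio combination.

    For every measured combination total dose the component doses are
    recovered from the stored mixing ratio; EA and EB are the single-agent
    inhibition fractions at exactly those component doses (linear
    interpolation on fa only when ``interpolate`` is set).  A component
    dose absent from a single-agent series yields a per-pair error entry
    rather than failing the whole table.
    """
    if combo.ratio is None:
        raise ValueError("combo series must carry a mixing ratio")
    order = combo.agents
    if series_a.label != order[0]:
        series_a, series_b = series_b, series_a
    rows: list[dict] = []
    for pt in combo.points:
        if pt.total_dose == 0:
            continue
        da, db = combo.component_doses(pt.total_dose)
        e_a = _single_effect_at(series_a, da, interpolate)
        e_b = _single_effect_at(series_b, db, interpolate)
        entry: dict = {"total_dose": pt.total_dose, "dose_a": da, "dose_b": db}
        if e_a is None or e_b is None:
            missing = series_a.label if e_a is None else series_b.label
            entry["error"] = (
                f"component dose not measured in single-agent series {missing!r}"
            )
            rows.append(entry)
            continue
        e_obs = inhibition_fraction(pt.mean_viability)
        e_exp_b = bliss_expected(e_a, e_b)
        d_b, cls_b = delta_bliss(e_obs, e_exp_b, tolerance)
        entry["bliss"] = BlissResult(e_a, e_b, e_obs, e_exp_b, d_b, cls_b)
        e_exp_h = hsa_expected(e_a, e_b)
        d_h, cls_h = delta_bliss(e_obs, e_exp_h, tolerance)
        entry["hsa"] = HSAResult(e_a, e_b, e_obs, e_exp_h, d_h, cls_h)
        rows.append(entry)
    return rows
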