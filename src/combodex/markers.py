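"""Redox and apoptosis marker quantification.

Group-replicate marker panels (ROS fold change, SOD/CAT activity, GSH,
MDA), Annexin/PI quadrant apoptosis totals, relative qPCR expression by
the 2^-ddCt method, and cross-marker Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MARKER_UNITS = (
    "U_per_mg_protein",
    "umol_per_mg_protein",
    "nmol_per_mg_protein",
    "fold_of_control",
    "percent_of_control",
    "percent_cells",
    "MFI",
)


@dataclass
class MarkerPanel:
    """Replicate values per treatment group for one marker."""

    marker: str
    units: str
    groups: dict[str, list[float]]

    def __post_init__(self) -> None:
        if self.units not in MARKER_UNITS:
            raise ValueError(f"unknown units {self.units!r}")
        for g, vals in self.groups.items():
            if not vals:
                raise ValueError(f"group {g!r} has no replicate values")
            if self.units != "percent_of_control" and any(v < 0 for v in vals):
                raise ValueError(f"negative value in group {g!r}")

    def summary(self) -> pd.DataFrame:
        rows = [
            {"group": g, "mean": float(np.mean(v)),
             "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
             "n": len(v)}
            for g, v in self.groups.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class QuadrantCounts:
    """Annexin/PI quadrant percentages.

    Convention: Q1 necrotic (Annexin-/PI+), Q2 late apoptotic
    (Annexin+/PI+), Q3 viable (Annexin-/PI-), Q4 early apoptotic
    (Annexin+/PI-).  Beware that published figure captions sometimes swap
    Q3/Q4; this package fixes Q4 = early apoptotic.
    """

    q1: float
    q2: float
    q3: float
    q4: float

    def __post_init__(self) -> None:
        for name, v in zip(("q1", "q2", "q3", "q4"),
                           (self.q1, self.q2, self.q3, self.q4)):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100]")
        total = self.q1 + self.q2 + self.q3 + self.q4
        if not 99.0 <= total <= 101.0:
            raise ValueError(f"quadrants must sum to ~100, got {total:g}")


@dataclass(frozen=True)
class QPCRMeasurement:
    """One qPCR well pair: target and reference Ct for a group replicate."""

    group: str
    target: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target),
                         ("ct_reference", self.ct_reference)):
            if not 1.0 <= ct <= 45.0:
                raise ValueError(f"{name} must lie in [1, 45] cycles")


def fold_change(treated: Sequence[float], control: Sequence[float]) -> float:
    """Ratio of group means, mean(treated)/mean(control)."""
    if len(control) == 0 or len(treated) == 0:
        raise ValueError("treated and control groups must be non-empty")
    cm = float(np.mean(control))
    if cm <= 0:
        raise ValueError("control mean must be positive")
    return float(np.mean(treated)) / cm


def percent_change(treated: Sequence[float], control: Sequence[float]) -> float:
    """Signed percent change of means: (mean_t/mean_c - 1) * 100."""
    return (fold_change(treated, control) - 1.0) * 100.0


def total_apoptosis(q: QuadrantCounts) -> float:
    """Total apoptotic fraction: early + late = Q2 + Q4 (percent)."""
    return q.q2 + q.q4


def relative_quantity(
    control: Sequence[QPCRMeasurement], treated: Sequence[QPCRMeasurement]
) -> float:
    """Relative expression by the 2^-ddCt method.

    Per group, dCt is the mean of per-replicate (Ct_target -
    Ct_reference) — replicates are paired within a well, so the reference
    is subtracted before averaging.  ddCt = dCt_treated - dCt_control and
    RQ = 2^-ddCt.
    """
    if not control or not treated:
        raise ValueError("both measurement sets must be non-empty")
    targets = {m.target for m in control} | {m.target for m in treated}
    if len(targets) > 1:
        raise ValueError(f"mismatched targets {sorted(targets)}")
    dct_control = float(np.mean([m.ct_target - m.ct_reference for m in control]))
    dct_treated = float(np.mean([m.ct_target - m.ct_reference for m in treated]))
    ddct = dct_treated - dct_control
    return float(2.0 ** (-ddct))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; needs length >= 3 and non-zero
    variance in each vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("pearson_r needs at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def read_marker_table(path) -> list[MarkerPanel]:
    """Read a tidy marker CSV {marker, units, group, replicate, value}
    into panels, one per (marker, units)."""
    df = pd.read_csv(path)
    panels = []
    for (marker, units), sub in df.groupby(["marker", "units"], sort=True):
        groups: dict[str, list[float]] = {}
        for g, gsub in sub.groupby("group", sort=True):
            groups[str(g)] = [float(v) for v in gsub["value"]]
        panels.append(MarkerPanel(marker=str(marker), units=str(units),
                                  groups=groups))
    return panels


def read_qpcr_table(path) -> list[QPCRMeasurement]:
    """Read a tidy qPCR CSV {group, target, replicate, ct_target,
    ct_reference}."""
    df = pd.read_csv(path)
    return [
        QPCRMeasurement(group=str(r.group), target=str(r.target),
                        ct_target=float(r.ct_target),
                        ct_reference=float(r.ct_reference))
        for r in df.itertuples(index=False)
    ]


def marker_report(
    panels: Sequence[MarkerPanel], control_group: str = "control"
) -> dict:
    """Fold-change and percent-of-control summaries per marker and group."""
    out: dict = {}
    for panel in panels:
        if control_group not in panel.groups:
            out[panel.marker] = {"error": f"no control group {control_group!r}"}
            continue
        ctrl = panel.groups[control_group]
        entry = {"units": panel.units, "groups": {}}
        for g, vals in panel.groups.items():
            entry["groups"][g] = {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n": len(vals),
                "fold_change": fold_change(vals, ctrl),
                "percent_change": percent_change(vals, ctrl),
            }
        out[panel.marker] = entry
    return out


def qpcr_report(
    measurements: Sequence[QPCRMeasurement], control_group: str = "control"
) -> dict:
    """RQ (2^-ddCt) per target and non-control group."""
    by_target: dict[str, dict[str, list[QPCRMeasurement]]] = {}
    for m in measurements:
        by_target.setdefault(m.target, {}).setdefault(m.group, []).append(m)
    out: dict = {}
    for target, groups in sorted(by_target.items()):
        if control_group not in groups:
            out[target] = {"error": f"no control group {control_group!r}"}
            continue
        ctrl = groups[control_group]
        out[target] = {
            g: relative_quantity(ctrl, ms)
            for g, ms in sorted(groups.items())
            if g != control_group
        }
    return out
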