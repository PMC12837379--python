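"""End-to-end orchestration: ingest/simulate -> fits -> synergy -> markers.

Also houses :func:`reproduce_paper`, which reruns the desk-scale worked
examples of the packaged study tables and reports computed values next to
the printed ones.  Several printed numbers are mutually inconsistent (see
:mod:`combodex.datasets`), so the reproduction deliberately reports both
sides rather than asserting equality.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from combodex import datasets
from combodex.config import RunConfig
from combodex.dose_response import absolute_ic50, fit_four_pl, inhibition_fraction
from combodex.errors import CombodexError, ConfigError
from combodex.markers import (
    marker_report,
    pearson_r,
    qpcr_report,
    read_marker_table,
    read_qpcr_table,
    relative_quantity,
)
from combodex.median_effect import (
    combination_index,
    default_fa_grid,
    dose_reduction_index,
    fa_ci_curve,
    fit_median_effect,
)
from combodex.plate_io import (
    DoseResponseSeries,
    build_series,
    read_well_table,
    write_report,
)
from combodex.reference_models import bliss_expected, delta_bliss, synergy_table
from combodex.synthetic_data import (
    SyntheticConfig,
    simulate_markers,
    simulate_qpcr,
    simulate_screen,
)

log = logging.getLogger("combodex")


class PipelineStageError(CombodexError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunReport:
    """Structured pipeline output; serializes to a stable JSON document."""

    metadata: dict[str, Any]
    results: dict[str, Any] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {"metadata": self.metadata, "results": self.results,
                "warnings": self.warnings}

    def write(self, path) -> None:
        write_report(self.to_dict(), path)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _series_fa(series: DoseResponseSeries) -> tuple[np.ndarray, np.ndarray]:
    mask = series.doses > 0
    doses = series.doses[mask]
    fa = np.array([inhibition_fraction(v) for v in series.viabilities[mask]])
    return doses, fa


def run_pipeline(config: RunConfig, out: Optional[str] = None) -> RunReport:
    """Execute the full analysis and return (optionally write) the report.

    Stages: acquire wells (simulate or read) -> build series -> 4PL fits
    and IC50s -> median-effect fits, Fa-CI curve, per-point CI and DRI ->
    Bliss/HSA table -> marker and qPCR summaries.  Re-running with the
    same config and seed reproduces the report exactly.
    """
    report = RunReport(metadata={
        "version": _version(),
        "seed": config.seed,
        "config_hash": _config_hash(config),
    })
    warn = report.warnings.append

    # ----- stage: acquire wells
    stage = "acquire"
    try:
        if config.simulate is not None:
            sim_raw = dict(config.simulate)
            sim_raw.setdefault("seed", config.seed)
            sim = SyntheticConfig(**sim_raw)
            records = simulate_screen(sim)
            log.info("acquire: simulated %d wells (mode=%s)", len(records),
                     sim.interaction_mode)
        elif config.io.wells:
            records = read_well_table(config.io.wells)
            sim = None
            log.info("acquire: read %d wells from %s", len(records),
                     config.io.wells)
        else:
            raise ConfigError("config needs io.wells or a simulate block")
    except CombodexError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    # ----- stage: series
    stage = "series"
    try:
        series = build_series(records, config.io.control_label)
    except CombodexError as exc:
        raise PipelineStageError(stage, str(exc)) from exc
    singles = [s for s in series if s.ratio is None and len(s.points) > 1]
    combos = [s for s in series if s.ratio is not None]
    log.info("series: %d single-agent, %d combination", len(singles), len(combos))
    for s in series:
        for fl in s.flags:
            warn(f"{s.label}: {fl}")

    # ----- stage: dose-response fits
    stage = "dose_response"
    dr_block: dict[str, Any] = {}
    ic50s: dict[str, Optional[float]] = {}
    for s in singles + combos:
        try:
            fit = fit_four_pl(s)
        except CombodexError as exc:
            warn(f"{s.label}: 4PL fit skipped ({exc})")
            continue
        ic50 = absolute_ic50(fit)
        if ic50 is None:
            warn(f"{s.label}: fitted curve never crosses 50% viability; "
                 "absolute IC50 undefined")
        if not fit.converged:
            warn(f"{s.label}: 4PL optimizer did not converge")
        ic50s[s.label] = ic50
        dr_block[s.label] = {**fit.to_dict(), "ic50_absolute": ic50}
    report.results["dose_response"] = dr_block
    if len(singles) == 2:
        a, b = singles[0].label, singles[1].label
        if ic50s.get(a) and ic50s.get(b):
            hi, lo = max(ic50s[a], ic50s[b]), min(ic50s[a], ic50s[b])
            report.results["potency_ratio"] = {
                "numerator": a if ic50s[a] >= ic50s[b] else b,
                "denominator": b if ic50s[a] >= ic50s[b] else a,
                "ratio": hi / lo,
            }
    log.info("dose_response: fitted %d series", len(dr_block))

    # ----- stage: synergy
    stage = "synergy"
    syn = config.synergy
    synergy_block: dict[str, Any] = {}
    me_fits = {}
    for s in singles + combos:
        doses, fa = _series_fa(s)
        try:
            me_fits[s.label] = fit_median_effect(doses, fa)
        except CombodexError as exc:
            warn(f"{s.label}: median-effect fit skipped ({exc})")
    synergy_block["median_effect"] = {
        label: fit.to_dict() for label, fit in me_fits.items()
    }
    for fit in me_fits.values():
        if not fit.reliable:
            warn("median-effect fit with non-positive slope flagged unreliable")

    if combos and len(singles) == 2:
        combo = combos[0]
        fit_a = me_fits.get(combo.agents[0])
        fit_b = me_fits.get(combo.agents[1])
        fit_c = me_fits.get(combo.label)
        if fit_a and fit_b and fit_c:
            grid = default_fa_grid(syn.fa_min, syn.fa_max, syn.fa_step)
            curve = fa_ci_curve(fit_a, fit_b, fit_c, combo.ratio, grid,
                                alpha=syn.alpha, tolerance=syn.ci_tolerance)
            synergy_block["fa_ci_curve"] = curve.to_dict()
            points = []
            for pt in combo.points:
                if pt.total_dose == 0:
                    continue
                fa_obs = inhibition_fraction(pt.mean_viability)
                if not 0.0 < fa_obs < 1.0:
                    warn(f"{combo.label}: fa={fa_obs:g} at total dose "
                         f"{pt.total_dose:g} outside (0,1); CI skipped")
                    continue
                d1, d2 = combo.component_doses(pt.total_dose)
                ci = combination_index(fit_a, fit_b, d1, d2, fa_obs,
                                       alpha=syn.alpha,
                                       tolerance=syn.ci_tolerance)
                dri = dose_reduction_index(fit_a, fit_b, d1, d2, fa_obs)
                points.append({**ci.to_dict(), "dri": dri.to_dict()})
            synergy_block["observed_points"] = points
            log.info("synergy: CI grid of %d points, %d observed dose pairs",
                     len(curve.grid), len(points))
        try:
            table = synergy_table(
                singles[0], singles[1], combo,
                tolerance=syn.bliss_tolerance,
                interpolate=syn.interpolate_singles,
            )
            synergy_block["reference_models"] = [
                {k: (v.to_dict() if hasattr(v, "to_dict") else v)
                 for k, v in row.items()}
                for row in table
            ]
        except (CombodexError, ValueError) as exc:
            warn(f"reference models skipped ({exc})")
    report.results["synergy"] = synergy_block

    # ----- stage: markers
    stage = "markers"
    try:
        panels = None
        qpcr = None
        if config.simulate is not None and sim is not None:
            if sim.marker_spec:
                panels = simulate_markers(sim)
            if sim.qpcr_spec:
                qpcr = simulate_qpcr(sim)
        if config.io.markers:
            panels = read_marker_table(config.io.markers)
        if config.io.qpcr:
            qpcr = read_qpcr_table(config.io.qpcr)
        if panels:
            report.results["markers"] = marker_report(
                panels, config.markers.control_group)
        if qpcr:
            report.results["qpcr"] = qpcr_report(
                qpcr, config.markers.control_group)
    except CombodexError as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    if out is not None:
        report.write(out)
    return report


def reproduce_paper(out: Optional[str] = None) -> RunReport:
    """Recompute the study's desk-scale worked examples from the packaged
    tables, reporting computed and printed values side by side.

    Covers: inhibition fractions of the printed viabilities; 4PL fits and
    absolute IC50s of the printed series; the printed-IC50 potency ratio;
    the Bliss table for the two fully printed combination pairs; the CI
    and DRI at the printed Q80+GEM8 observation; the ROS-apoptosis
    Pearson correlation; marker fold/percent summaries; and qPCR fold
    recovery.  Discrepancies are reported, never overwritten.
    """
    report = RunReport(metadata={"version": _version(), "fixture": "packaged study tables"})
    res = report.results

    q = datasets.q_series()
    gem = datasets.gem_series()
    combo = datasets.combo_series()

    # (a) inhibition fractions from printed viabilities
    res["inhibition_fractions"] = {
        "Q": {f"{d:g}": inhibition_fraction(v)
              for d, v in zip(datasets.Q_DOSES, datasets.Q_VIABILITY)},
        "GEM": {f"{d:g}": inhibition_fraction(v)
                for d, v in zip(datasets.GEM_DOSES, datasets.GEM_VIABILITY)},
    }

    # (b) 4PL fits and absolute IC50s from the printed series
    dr = {}
    for s in (q, gem):
        fit = fit_four_pl(s)
        dr[s.label] = {
            **fit.to_dict(),
            "ic50_absolute_computed": absolute_ic50(fit),
            "ic50_printed": datasets.PRINTED_IC50[s.label],
        }
    res["dose_response"] = dr
    if (dr["GEM"]["ic50_absolute_computed"] is not None
            and abs(dr["GEM"]["ic50_absolute_computed"]
                    - datasets.PRINTED_IC50["GEM"]) > 2.0):
        report.warnings.append(
            "computed GEM IC50 differs from the printed 17.2 µM; the printed "
            "GEM series already shows >50% inhibition at 8 µM")

    # (c) potency ratio from the printed IC50s
    ratio = datasets.PRINTED_IC50["Q"] / datasets.PRINTED_IC50["GEM"]
    res["potency_ratio"] = {
        "computed": ratio,
        "computed_rounded": round(ratio, 1),
        "printed": datasets.PRINTED_POTENCY_FOLD,
    }

    # (d) Bliss/HSA for the two fully printed combination pairs
    bliss_rows = []
    for (dq, dg), viab, src in zip(datasets.COMBO_DOSES,
                                   datasets.COMBO_VIABILITY,
                                   datasets.COMBO_VIABILITY_SOURCE):
        if not src.startswith("printed"):
            continue
        e_a = inhibition_fraction(
            datasets.Q_VIABILITY[datasets.Q_DOSES.index(dq)])
        e_b = inhibition_fraction(
            datasets.GEM_VIABILITY[datasets.GEM_DOSES.index(dg)])
        e_obs = inhibition_fraction(viab)
        e_exp = bliss_expected(e_a, e_b)
        delta, cls = delta_bliss(e_obs, e_exp)
        bliss_rows.append({
            "pair": f"Q{dq:g}+GEM{dg:g}", "e_a": e_a, "e_b": e_b,
            "e_obs": e_obs, "e_exp_bliss": e_exp, "delta_bliss": delta,
            "classification": cls,
        })
    res["bliss_printed_pairs"] = bliss_rows

    # (e) CI and DRI at the printed Q80+GEM8 observation (62% reduction)
    dq_, fa_q = _series_fa(q)
    dg_, fa_g = _series_fa(gem)
    fit_q = fit_median_effect(dq_, fa_q)
    fit_g = fit_median_effect(dg_, fa_g)
    ci = combination_index(fit_q, fit_g, 80.0, 8.0, 0.62, alpha=0)
    dri = dose_reduction_index(fit_q, fit_g, 80.0, 8.0, 0.62)
    res["ci_q80_gem8"] = {**ci.to_dict(), "dri": dri.to_dict(),
                          "median_effect_fits": {"Q": fit_q.to_dict(),
                                                 "GEM": fit_g.to_dict()}}
    res["printed_fa_ci_points"] = {f"{k:g}": v for k, v in datasets.PRINTED_CI.items()}

    # (f) ROS-apoptosis correlation over the four treatment groups
    order = ("control", "Q", "GEM", "Q+GEM")
    ros = [datasets.ROS_FOLD[g] for g in order]
    apo = [datasets.APOPTOSIS_PERCENT[g] for g in order]
    res["ros_apoptosis_correlation"] = {
        "ros_fold": ros, "apoptosis_percent": apo,
        "pearson_r": pearson_r(ros, apo), "printed_bound": 0.9,
    }

    # (g) marker summaries and qPCR recovery
    res["marker_percent_change"] = {
        marker: {g: vals[g] - 100.0 for g in order}
        for marker, vals in datasets.OXIDATIVE_PANEL_PERCENT.items()
    }
    res["marker_folds"] = {"ROS": datasets.ROS_FOLD,
                           "caspase3": datasets.CASPASE3_FOLD}
    qpcr = datasets.paper_qpcr_measurements()
    by_gene: dict[str, dict[str, list]] = {}
    for m in qpcr:
        by_gene.setdefault(m.target, {}).setdefault(m.group, []).append(m)
    res["qpcr_rq"] = {
        gene: {
            group: {
                "computed": relative_quantity(groups["control"], ms),
                "printed": datasets.QPCR_FOLDS[gene][group],
            }
            for group, ms in groups.items() if group != "control"
        }
        for gene, groups in by_gene.items()
    }

    if out is not None:
        report.write(out)
    return report


def _version() -> str:
    from combodex import __version__

    return __version__
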