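"""Packaged study tables: quercetin (Q) + gemcitabine (GEM) on MDA-MB-231.

These constants transcribe the published summary numbers of the
quercetin/gemcitabine combination study on MDA-MB-231 triple-negative
breast-cancer cells (48 h MTT viability, fixed-ratio 10:1 combinations,
redox and apoptosis marker panels, qPCR fold changes).  Values are stored
exactly as printed — including the study's internal inconsistencies (a
control viability of 98 % despite normalization to control; a GEM IC50 of
17.2 µM that the printed GEM series does not support) — so that computed
and printed numbers can be compared side by side.

Three of the five combination viabilities were not printed; the stand-ins
here are SYNTHETIC reconstructions consistent with the study's statements
(all combinations supra-additive; strongest Bliss excess, +15 points, at
Q40+GEM4) and are flagged as such in :data:`COMBO_VIABILITY_SOURCE`.
"""

from __future__ import annotations

from combodex.markers import QPCRMeasurement
from combodex.plate_io import DoseResponseSeries, SeriesPoint, WellRecord

# ---------------------------------------------------------------- viability

#: Q single-agent doses (µM) and mean viability (% of control)
Q_DOSES = (0.0, 10.0, 20.0, 40.0, 80.0, 100.0)
Q_VIABILITY = (98.0, 87.0, 82.0, 76.0, 56.0, 42.0)

#: GEM single-agent doses (µM) and mean viability (% of control)
GEM_DOSES = (0.0, 1.0, 2.0, 4.0, 8.0, 10.0)
GEM_VIABILITY = (98.0, 78.0, 66.0, 58.0, 46.0, 28.0)

#: fixed-ratio combination design, component doses (Q µM, GEM µM)
COMBO_DOSES = ((10.0, 1.0), (20.0, 2.0), (40.0, 4.0), (80.0, 8.0), (100.0, 10.0))

#: combination viability (% of control); see COMBO_VIABILITY_SOURCE
COMBO_VIABILITY = (62.9, 44.1, 29.1, 38.0, 24.0)
COMBO_VIABILITY_SOURCE = (
    "synthetic (Bliss excess +5 pts assumed)",
    "synthetic (Bliss excess +10 pts assumed)",
    "synthetic (printed Bliss excess +15 pts)",
    "printed (62% reduction)",
    "printed (76% reduction)",
)

#: Q:GEM mixing ratio of the fixed-ratio design
COMBO_RATIO = (10.0 / 11.0, 1.0 / 11.0)

#: printed IC50s (µM) and the potency statement derived from them
PRINTED_IC50 = {"Q": 82.4, "GEM": 17.2}
PRINTED_POTENCY_FOLD = 4.8

#: printed Combination Index values on the Fa-CI plot
PRINTED_CI = {0.7: 1.32, 0.9: 0.78}

# ------------------------------------------------------------------ markers

#: fold change over control (treatments at single-agent IC50 doses)
ROS_FOLD = {"control": 1.0, "Q": 1.6, "GEM": 2.4, "Q+GEM": 2.8}
CASPASE3_FOLD = {"control": 1.0, "Q": 2.1, "GEM": 3.0, "Q+GEM": 3.6}

#: total apoptotic cells (%, Annexin/PI early + late quadrants)
APOPTOSIS_PERCENT = {"control": 2.8, "Q": 24.6, "GEM": 38.4, "Q+GEM": 44.2}

#: percent of control; SOD and CAT combination values were described only
#: qualitatively and are synthetic stand-ins (95 = "slight reduction",
#: 100 = "no significant change")
OXIDATIVE_PANEL_PERCENT = {
    "SOD": {"control": 100.0, "Q": 125.0, "GEM": 110.0, "Q+GEM": 95.0},
    "CAT": {"control": 100.0, "Q": 120.0, "GEM": 100.0, "Q+GEM": 100.0},
    "GSH": {"control": 100.0, "Q": 90.0, "GEM": 75.0, "Q+GEM": 60.0},
    "MDA": {"control": 100.0, "Q": 140.0, "GEM": 180.0, "Q+GEM": 220.0},
}

#: qPCR fold change versus control (2^-ddCt scale)
QPCR_FOLDS = {
    "HIF1A": {"Q": 0.6, "GEM": 0.4, "Q+GEM": 0.2},
    "VEGF": {"Q": 0.8, "GEM": 0.6, "Q+GEM": 0.4},
    "BAX": {"Q": 1.6, "GEM": 2.3, "Q+GEM": 2.5},
    "BCL2": {"Q": 0.6, "GEM": 0.4, "Q+GEM": 0.3},
    "CASP3": {"Q": 2.4, "GEM": 2.8, "Q+GEM": 3.2},
}

N_REPLICATES = 3


def paper_well_records() -> list[WellRecord]:
    """The packaged viability table as well records.

    16 conditions (control, 5 Q, 5 GEM, 5 combinations) × 3 replicates =
    48 records.  Replicate SDs were not printed, so the replicate values
    equal the condition mean.
    """
    records: list[WellRecord] = []

    def add(agent_a, dose_a, agent_b, dose_b, viability):
        for rep in range(1, N_REPLICATES + 1):
            records.append(
                WellRecord(agent_a=agent_a, dose_a=dose_a, agent_b=agent_b,
                           dose_b=dose_b, replicate=rep, response=viability,
                           response_kind="percent_viability")
            )

    add("control", 0.0, None, 0.0, Q_VIABILITY[0])
    for d, v in zip(Q_DOSES[1:], Q_VIABILITY[1:]):
        add("Q", d, None, 0.0, v)
    for d, v in zip(GEM_DOSES[1:], GEM_VIABILITY[1:]):
        add("GEM", d, None, 0.0, v)
    for (dq, dg), v in zip(COMBO_DOSES, COMBO_VIABILITY):
        add("Q", dq, "GEM", dg, v)
    return records


def _series(label: str, doses, viabilities, ratio=None, agents=()) -> DoseResponseSeries:
    pts = [SeriesPoint(total_dose=d, mean_viability=v, sd=0.0, n=N_REPLICATES)
           for d, v in zip(doses, viabilities)]
    return DoseResponseSeries(label=label, points=pts, ratio=ratio, agents=agents)


def q_series() -> DoseResponseSeries:
    return _series("Q", Q_DOSES, Q_VIABILITY, agents=("Q",))


def gem_series() -> DoseResponseSeries:
    return _series("GEM", GEM_DOSES, GEM_VIABILITY, agents=("GEM",))


def combo_series() -> DoseResponseSeries:
    """Fixed-ratio combination as a single agent at total dose Q+GEM."""
    totals = [dq + dg for dq, dg in COMBO_DOSES]
    return _series("Q+GEM", [0.0] + totals,
                   [Q_VIABILITY[0]] + list(COMBO_VIABILITY),
                   ratio=COMBO_RATIO, agents=("Q", "GEM"))


def paper_qpcr_measurements(
    ct_reference: float = 16.0, ct_target_control: float = 24.0
) -> list[QPCRMeasurement]:
    """Synthetic Ct tables encoding the printed qPCR fold changes.

    Ct values themselves were not printed; these are constructed so that
    the 2^-ddCt method recovers :data:`QPCR_FOLDS` exactly:
    Ct_target(group) = Ct_target(control) - log2(fold).
    """
    import math

    out: list[QPCRMeasurement] = []
    for gene, folds in QPCR_FOLDS.items():
        for rep in range(N_REPLICATES):
            out.append(QPCRMeasurement("control", gene, ct_target_control,
                                       ct_reference))
        for group, fold in folds.items():
            ct = ct_target_control - math.log2(fold)
            for rep in range(N_REPLICATES):
                out.append(QPCRMeasurement(group, gene, ct, ct_reference))
    return out
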