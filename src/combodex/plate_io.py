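"""Plate-style table ingest and dose-response series construction.

The on-disk format is one tidy CSV with the columns

    agent_a, dose_a, agent_b, dose_b, replicate, response, response_kind

(doses in µM; ``response_kind`` one of ``raw_signal`` /
``percent_viability``; an empty ``agent_b`` cell means a single-agent
well).  :func:`build_series` groups wells into per-agent and per-fixed-
ratio dose-response series, normalizing raw signals to percent of the
mean control.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from combodex.config import RunConfig, parse_config
from combodex.errors import FormatError, GroupingError, NormalizationError

RESPONSE_KINDS = ("raw_signal", "percent_viability")

REQUIRED_COLUMNS = (
    "agent_a",
    "dose_a",
    "agent_b",
    "dose_b",
    "replicate",
    "response",
    "response_kind",
)


@dataclass(frozen=True)
class WellRecord:
    """One well: agent(s), dose(s) in µM, replicate index and response."""

    agent_a: str
    dose_a: float
    replicate: int
    response: float
    response_kind: str
    agent_b: Optional[str] = None
    dose_b: float = 0.0

    def __post_init__(self) -> None:
        if self.dose_a < 0 or self.dose_b < 0:
            raise ValueError("doses must be non-negative")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")
        if self.response < 0:
            raise ValueError("response must be non-negative")
        if self.response_kind not in RESPONSE_KINDS:
            raise FormatError(
                f"unknown response_kind {self.response_kind!r}; "
                f"expected one of {RESPONSE_KINDS}"
            )
        if self.agent_b is None and self.dose_b > 0:
            raise ValueError("dose_b > 0 requires agent_b")

    @property
    def is_combination(self) -> bool:
        return self.agent_b is not None and self.dose_b > 0

    @property
    def total_dose(self) -> float:
        return self.dose_a + self.dose_b


@dataclass(frozen=True)
class SeriesPoint:
    """Aggregated replicates at one total dose."""

    total_dose: float
    mean_viability: float
    sd: float
    n: int


@dataclass
class DoseResponseSeries:
    """Mean viability (% of control) versus total dose for one agent or
    one fixed-ratio combination.

    ``ratio`` is the (w_a, w_b) mixing proportion of a combination,
    normalized to sum to one; ``None`` for single agents.
    """

    label: str
    points: list[SeriesPoint]
    ratio: Optional[tuple[float, float]] = None
    agents: tuple[str, ...] = ()
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        doses = [p.total_dose for p in self.points]
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("total_dose must be strictly increasing")

    @property
    def doses(self) -> np.ndarray:
        return np.array([p.total_dose for p in self.points])

    @property
    def viabilities(self) -> np.ndarray:
        return np.array([p.mean_viability for p in self.points])

    def component_doses(self, total_dose: float) -> tuple[float, float]:
        """Split a combination total dose into its two components."""
        if self.ratio is None:
            raise ValueError(f"series {self.label!r} is not a combination")
        return total_dose * self.ratio[0], total_dose * self.ratio[1]


def read_well_table(path: str | Path) -> list[WellRecord]:
    """Read a tidy well-level CSV into :class:`WellRecord` objects.

    Row order is preserved.  Missing required columns raise a
    :class:`FormatError` naming the column; unparseable numeric cells
    raise a :class:`FormatError` carrying the 1-based data row index.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    records: list[WellRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        agent_b = row.agent_b.strip() or None
        try:
            dose_a = float(row.dose_a)
            dose_b = float(row.dose_b) if str(row.dose_b).strip() else 0.0
            replicate = int(row.replicate)
            response = float(row.response)
        except ValueError as exc:
            raise FormatError(f"row {i}: non-numeric value ({exc})") from exc
        records.append(
            WellRecord(
                agent_a=row.agent_a.strip(),
                dose_a=dose_a,
                agent_b=agent_b,
                dose_b=dose_b,
                replicate=replicate,
                response=response,
                response_kind=row.response_kind.strip(),
            )
        )
    return records


def write_well_table(records: Iterable[WellRecord], path: str | Path) -> None:
    """Write records back to the tidy CSV schema read by
    :func:`read_well_table`."""
    rows = [
        {
            "agent_a": r.agent_a,
            "dose_a": r.dose_a,
            "agent_b": r.agent_b or "",
            "dose_b": r.dose_b,
            "replicate": r.replicate,
            "response": r.response,
            "response_kind": r.response_kind,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def _round_sig(x: float, sig: int = 6) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def _is_control(rec: WellRecord, control_label: str) -> bool:
    return (rec.dose_a == 0 and rec.dose_b == 0) or rec.agent_a == control_label


def build_series(
    records: Sequence[WellRecord], control_label: str = "control"
) -> list[DoseResponseSeries]:
    """Group wells into dose-response series and normalize to percent of
    control.

    Wells are keyed by the unordered agent pair plus the mixing ratio
    (rounded to 6 significant digits, so float jitter does not split a
    fixed-ratio design).  Raw signals are converted to percent of the mean
    control signal; percent-viability input passes through unchanged.
    When control wells are present each series gains a dose-0 anchor
    point.  Grouping is order-independent.
    """
    records = list(records)
    if not records:
        return []

    controls = [r for r in records if _is_control(r, control_label)]
    treated = [r for r in records if not _is_control(r, control_label)]

    kinds = {r.response_kind for r in records}
    if len(kinds) > 1:
        raise FormatError("mixed response_kind values within one table")
    raw = kinds == {"raw_signal"}

    if raw:
        if not controls:
            raise NormalizationError(
                "raw_signal wells require at least one control well (all doses 0)"
            )
        control_mean = float(np.mean([r.response for r in controls]))
        if control_mean <= 0:
            raise NormalizationError("control mean signal must be positive")
        to_percent = lambda v: 100.0 * v / control_mean  # noqa: E731
    else:
        to_percent = lambda v: v  # noqa: E731

    # group key -> {total_dose -> [viability values]}
    groups: dict[tuple, dict[float, list[float]]] = {}
    meta: dict[tuple, dict[str, Any]] = {}
    pair_ratios: dict[tuple, float] = {}
    for rec in treated:
        if rec.is_combination:
            pair = tuple(sorted((rec.agent_a, rec.agent_b)))
            total = rec.total_dose
            # ratio expressed in the sorted-pair order
            first_dose = rec.dose_a if pair[0] == rec.agent_a else rec.dose_b
            w = _round_sig(first_dose / total)
            seen = pair_ratios.setdefault(pair, w)
            if seen != w:
                raise GroupingError(
                    f"inconsistent mixing ratio within combination "
                    f"{pair[0]}+{pair[1]}: {seen:g} vs {w:g}"
                )
            key = ("combo", pair, w)
            label = f"{rec.agent_a}+{rec.agent_b}"
            ratio_label_order = (
                rec.dose_a / total,
                rec.dose_b / total,
            )
        else:
            key = ("single", rec.agent_a)
            label = rec.agent_a
            ratio_label_order = None
        info = meta.setdefault(
            key,
            {"label": label, "ratio": ratio_label_order, "agents": (rec.agent_a,)
             if ratio_label_order is None else (rec.agent_a, rec.agent_b)},
        )
        if ratio_label_order is not None:
            prev = info["ratio"]
            if not math.isclose(prev[0], ratio_label_order[0], rel_tol=1e-5):
                raise GroupingError(
                    f"inconsistent mixing ratio within combination {label!r}"
                )
        groups.setdefault(key, {}).setdefault(rec.total_dose, []).append(
            to_percent(rec.response)
        )

    control_point: Optional[SeriesPoint] = None
    if controls:
        vals = np.array([to_percent(r.response) for r in controls])
        control_point = SeriesPoint(
            total_dose=0.0,
            mean_viability=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            n=len(vals),
        )

    series: list[DoseResponseSeries] = []
    for key in sorted(groups, key=str):
        dose_map = groups[key]
        pts = []
        if control_point is not None:
            pts.append(control_point)
        for dose in sorted(dose_map):
            vals = np.array(dose_map[dose])
            pts.append(
                SeriesPoint(
                    total_dose=dose,
                    mean_viability=float(vals.mean()),
                    sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    n=len(vals),
                )
            )
        flags = [
            f"viability {p.mean_viability:.4g}% > 100% at dose {p.total_dose:g} µM (stimulation)"
            for p in pts
            if p.total_dose > 0 and p.mean_viability > 100
        ]
        series.append(
            DoseResponseSeries(
                label=meta[key]["label"],
                points=pts,
                ratio=meta[key]["ratio"],
                agents=tuple(meta[key]["agents"]),
                flags=flags,
            )
        )

    if not treated and control_point is not None:
        series.append(
            DoseResponseSeries(
                label=control_label, points=[control_point], agents=(control_label,)
            )
        )
    return series


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` or a missing-keys file
    yields defaults."""
    if path is None:
        return parse_config({})
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw)


def write_report(results: dict[str, Any], path: str | Path) -> None:
    """Serialize a results mapping to pretty JSON.

    Output is byte-stable for identical inputs (sorted keys, fixed
    formatting) and round-trips losslessly through :func:`read_report`.
    """
    payload = json.dumps(_jsonable(results), indent=2, sort_keys=True)
    Path(path).write_text(payload + "\n", encoding="utf-8")


def read_report(path: str | Path) -> dict[str, Any]:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        return None
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    return obj
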