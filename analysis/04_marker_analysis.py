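#!/usr/bin/env python
"""Quantify the simulated redox/apoptosis markers.

Fold-change and percent-of-control summaries per marker, 2^-ddCt
relative expression for the simulated qPCR tables, and the ROS-apoptosis
style cross-marker correlation.  Writes results/marker_report.json.
"""

from pathlib import Path

from combodex.markers import (
    marker_report,
    pearson_r,
    qpcr_report,
    read_marker_table,
    read_qpcr_table,
)
from combodex.plate_io import write_report

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panels = read_marker_table(OUT / "sim_markers.csv")
    qpcr = read_qpcr_table(OUT / "sim_qpcr.csv")
    markers = marker_report(panels)
    rq = qpcr_report(qpcr)
    order = ("control", "Q", "GEM", "Q+GEM")
    for marker, block in markers.items():
        folds = {g: block["groups"][g]["fold_change"] for g in order}
        print(f"{marker}: " + ", ".join(f"{g} {f:.2f}x" for g, f in folds.items()))
    for gene, groups in rq.items():
        print(f"{gene} RQ: " + ", ".join(f"{g} {v:.2f}" for g, v in groups.items()))
    ros = [markers["ROS"]["groups"][g]["mean"] for g in order]
    cas = [markers["caspase3"]["groups"][g]["mean"] for g in order]
    r = pearson_r(ros, cas)
    print(f"ROS vs caspase-3 Pearson r = {r:.3f}")
    write_report({"markers": markers, "qpcr": rq, "ros_caspase_r": r},
                 OUT / "marker_report.json")
    print(f"wrote {OUT / 'marker_report.json'}")


if __name__ == "__main__":
    main()
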