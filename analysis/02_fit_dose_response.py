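#!/usr/bin/env python
"""Fit dose-response curves to the simulated screen.

Reads results/sim_wells.csv (run 01_simulate_screen.py first), builds
per-agent and combination series, fits the 4PL model and reports absolute
IC50s and the single-agent potency ratio.  Writes results/dose_response.csv.
"""

from pathlib import Path

import pandas as pd

from combodex.dose_response import absolute_ic50, fit_four_pl
from combodex.plate_io import build_series, read_well_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    wells = read_well_table(OUT / "sim_wells.csv")
    series = build_series(wells)
    rows = []
    ic50s = {}
    for s in series:
        fit = fit_four_pl(s)
        ic50 = absolute_ic50(fit)
        ic50s[s.label] = ic50
        rows.append({"series": s.label, "top": fit.top, "bottom": fit.bottom,
                     "hill": fit.hill, "ec50_uM": fit.ec50,
                     "ic50_absolute_uM": ic50, "rss": fit.rss,
                     "converged": fit.converged})
        print(f"{s.label:>8}: IC50 = {ic50:.2f} µM (hill {fit.hill:.2f}, "
              f"rss {fit.rss:.3g})")
    if ic50s.get("Q") and ic50s.get("GEM"):
        print(f"potency ratio Q/GEM = {ic50s['Q'] / ic50s['GEM']:.2f}-fold")
    pd.DataFrame(rows).to_csv(OUT / "dose_response.csv", index=False)
    print(f"wrote {OUT / 'dose_response.csv'}")


if __name__ == "__main__":
    main()
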