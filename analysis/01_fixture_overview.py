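"""Descriptive indicators of the packaged hospital panel.

Recomputes throughput (annual patients per bed) and 2024-vs-2015 percent
changes for every staffing/capacity/activity series, the contextual
indicators used to interpret the efficiency results.

Usage: python analysis/01_fixture_overview.py [--out results]
"""

import argparse
from pathlib import Path

import pandas as pd

from hospdea.panel import (
    derive_throughput,
    load_fixture_panel,
    percent_change,
    round_half_away,
)

SERIES = (
    "physicians_employed", "physicians_contract", "nurses_employed",
    "nurses_contract", "other_medical_staff", "beds", "hospitalisations",
    "avg_length_of_stay", "bed_occupancy", "net_revenue", "operating_costs",
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results", help="output directory")
    args = ap.parse_args()
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = load_fixture_panel()
    years = panel.years

    rows = []
    for hosp in panel.hospitals:
        row = {"hospital": hosp, "indicator": "throughput"}
        for y in years:
            row[str(y)] = round_half_away(derive_throughput(panel[(hosp, y)]))
        first = derive_throughput(panel[(hosp, years[0])])
        last = derive_throughput(panel[(hosp, years[-1])])
        row["pct_change"] = round_half_away(percent_change(first, last))
        rows.append(row)
        for field in SERIES:
            row = {"hospital": hosp, "indicator": field}
            for y in years:
                row[str(y)] = getattr(panel[(hosp, y)], field)
            a = getattr(panel[(hosp, years[0])], field)
            b = getattr(panel[(hosp, years[-1])], field)
            row["pct_change"] = (
                round_half_away(percent_change(a, b)) if a else float("nan")
            )
            rows.append(row)

    table = pd.DataFrame(rows)
    dest = outdir / "fixture_indicators.csv"
    table.to_csv(dest, index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {dest}")


if __name__ == "__main__":
    main()
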