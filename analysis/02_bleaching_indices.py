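#!/usr/bin/env python
"""Score the survey: category breakdowns, BRI, prevalence, density, BSI.

Reads results/survey.csv (from 01_simulate_survey.py or any canonical
long-format survey) and writes the genus- and site-level summary tables,
printing the seascape-wide headline numbers.
"""

import argparse
import os

from reefbleach.indices import (
    category_breakdown,
    mortality_change,
    prevalence,
    summary_tables,
)
from reefbleach.pipeline import write_table
from reefbleach.survey_io import read_survey


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", default="results")
    ap.add_argument("--min-n", type=int, default=5, help="BSI inclusion threshold")
    args = ap.parse_args()

    ds = read_survey(os.path.join(args.results_dir, "survey.csv"))
    p1, p2 = ds.periods
    for period in (p1, p2):
        bd = category_breakdown(ds, period=period)
        print(
            f"{period}: {bd.n_total} colonies, prevalence "
            f"{prevalence(bd):.1f}%, dead share {bd.percentages[5]:.1f}%"
        )
    print(f"dead-share change ({p2} - {p1}): {mortality_change(ds):+.1f} points")

    genus_table, site_table = summary_tables(ds, min_n=args.min_n)
    header = [f"# bleaching indices, min_n={args.min_n}"]
    write_table(genus_table, os.path.join(args.results_dir, "genus_table.csv"), header)
    write_table(site_table, os.path.join(args.results_dir, "site_table.csv"), header)

    worst = site_table[site_table["period"] == p1].nlargest(1, "bri").iloc[0]
    print(
        f"most affected site during the event: {worst['site']} "
        f"(BRI {worst['bri']}, prevalence {worst['prevalence_pct']}%, "
        f"BSI {worst['bsi']})"
    )
    print("-> genus_table.csv, site_table.csv")


if __name__ == "__main__":
    main()
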