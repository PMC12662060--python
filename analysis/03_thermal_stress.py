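#!/usr/bin/env python
"""Thermal stress: climatology, MMM, degree heating weeks, alert levels.

Reads results/sst.csv, computes the monthly climatology and the trailing
12-week DHW accumulation, classifies each day against the 4/8 °C-week
risk thresholds, and writes results/dhw_table.csv.
"""

import argparse
import os

import pandas as pd

from reefbleach.pipeline import write_table
from reefbleach.thermal import (
    alert_level,
    dhw_series,
    monthly_climatology,
    read_sst,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", default="results")
    ap.add_argument("--window", type=int, default=84)
    ap.add_argument("--floor", type=float, default=1.0)
    args = ap.parse_args()

    frames = []
    for sst in read_sst(os.path.join(args.results_dir, "sst.csv")):
        clim = monthly_climatology(sst)
        dhw = dhw_series(sst, clim, window_days=args.window, hotspot_floor=args.floor)
        alerts = [alert_level(v) for v in dhw.values.to_numpy()]
        peak_day = dhw.values.idxmax()
        peak = float(dhw.values.max())
        print(
            f"{sst.location}: MMM {clim.mmm:.2f} °C, peak DHW {peak:.1f} °C-weeks "
            f"on {peak_day.date()} -> {alert_level(peak)}"
        )
        frames.append(
            pd.DataFrame(
                {
                    "location": sst.location,
                    "date": sst.dates.strftime("%Y-%m-%d"),
                    "sst_c": sst.values.to_numpy(),
                    "mmm_c": clim.mmm,
                    "dhw_cweeks": dhw.values.round(6).to_numpy(),
                    "window_supported": dhw.supported.to_numpy(),
                    "alert": alerts,
                }
            )
        )
    out = os.path.join(args.results_dir, "dhw_table.csv")
    write_table(
        pd.concat(frames, ignore_index=True),
        out,
        [f"# dhw window={args.window} floor={args.floor}"],
    )
    print(f"-> {out}")


if __name__ == "__main__":
    main()
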