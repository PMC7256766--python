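"""Build the percent-change table and rupture verdicts.

By default this reproduces the published comparison from the printed POI
tables shipped with the package: percent increase of each loading model
over its reference (RH over settling for the ex vivo pair; TBI, shaking
and AHT over the healthy baseline), row averages, and the threshold rule
— a model predicts hemorrhage when its increase exceeds the ex vivo
increase for any metric at any POI.  Pass --tables to report freshly
computed scenario CSVs (from 04_run_scenarios.py) instead.

Usage: python analysis/05_report.py [--tables results/scenarios]
"""
import argparse
import json
from pathlib import Path

import pandas as pd

from retmech.reporting import (PoiTable, build_change_table,
                               load_printed_tables, rupture_decision,
                               save_verdicts)

ROOT = Path(__file__).resolve().parents[1]


def load_computed_tables(directory: Path) -> dict:
    frames = [pd.read_csv(p) for p in sorted(directory.glob("*.csv"))
              if not p.stem.endswith(("_flow", "_stress"))]
    df = pd.concat(frames, ignore_index=True)
    tables = {}
    pois = ["poi1", "poi2", "poi3", "poi4"]
    for label, grp in df.groupby("label"):
        kw = {"label": label}
        for _, row in grp.iterrows():
            key = row["metric"] if row["variant"] in ("static", "average") \
                else f"{row['metric']}_max"
            kw[key] = row[pois].to_numpy(dtype=float)
        tables[label] = PoiTable(**kw)
    return tables


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--tables", type=Path, default=None,
                    help="directory of scenario CSVs (default: printed fixtures)")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "report")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    tables = load_computed_tables(args.tables) if args.tables \
        else load_printed_tables()
    change = build_change_table(tables)
    verdicts = rupture_decision(change)

    change.to_csv(args.out / "change_table.csv")
    save_verdicts(verdicts, args.out / "verdicts.json")

    print(change.presented().to_string(index=False))
    print()
    for model, v in verdicts.items():
        flag = "RH predicted" if v["rh_predicted"] else "below ex vivo threshold"
        print(f"{model:8s}: {flag} ({v['n_exceeding_cells']} exceeding cells)")
    print(f"\nwrote {args.out}/change_table.csv and verdicts.json")


if __name__ == "__main__":
    main()
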