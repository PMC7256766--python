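"""Analyze the (synthetic) perfusion experiment like the wet-lab protocol.

Calibrates the line-loss correction from the open-tube run, corrects each
trace, detects the perfusion peak / settling plateau / rupture pressure,
and runs the statistical battery: Anderson-Darling normality per group,
Levene equal variance, and one-tailed t-tests of rupture and perfusion
pressures against settling.  Writes results/experiment/stats.json.

Usage: python analysis/02_perfusion_stats.py
"""
import argparse
import json
from pathlib import Path

import numpy as np

from retmech.experiment_stats import (PressureTrace, calibrate_line_loss,
                                      compare_pressures, correct_trace,
                                      detect_events, normality_check,
                                      variance_check)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "experiment")
    args = ap.parse_args()
    data = args.data

    pairs = np.loadtxt(data / "open_tube.csv", delimiter=",", skiprows=1)
    model = calibrate_line_loss(pairs)
    print(f"line loss: {model.slope:.4f} mmHg/(µl/min) + {model.intercept:.3f} mmHg")

    detected = []
    for path in sorted((data / "traces").glob("*.csv")):
        trace = PressureTrace.from_csv(path, eye_id=path.stem)
        detected.append(detect_events(correct_trace(trace, model)))

    groups = {
        "perfusion": np.array([r.perfusion for r in detected if r.perfusion]),
        "settling": np.array([r.settling for r in detected if r.settling]),
        "rh": np.array([r.rh for r in detected if r.rh]),
    }
    report = {
        "n_eyes": len(detected),
        "line_loss": {"slope": model.slope, "intercept": model.intercept},
        "groups": {k: {"n": len(v), "mean": float(v.mean()), "sd": float(v.std(ddof=1))}
                   for k, v in groups.items()},
        "normality_p": {k: normality_check(v) for k, v in groups.items()},
        "variance_p": variance_check(list(groups.values())),
        "alpha": 0.05,
    }
    for name, a, b in (("perfusion_vs_settling", "perfusion", "settling"),
                       ("rh_vs_settling", "rh", "settling")):
        res = compare_pressures(groups[a], groups[b])
        report[name] = {"t": res.t, "p": res.p,
                        "mean_difference_mmhg": res.mean_difference}

    out = data / "stats.json"
    out.write_text(json.dumps(report, indent=2) + "\n")
    print(json.dumps(report, indent=2))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
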