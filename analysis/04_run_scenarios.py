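"""Run the six loading scenarios on the default geometry.

settling / rh mirror the ex vivo perfusion states; baseline / tbi are the
healthy (63 mmHg) and hypertensive (79.6 mmHg) infant models; shaking /
aht add the sinusoidal angular-motion body load (peak angular
acceleration 1068.3 rad/s²) to each pressure level.  Writes one POI
metrics CSV per scenario plus field exports under results/scenarios/.

Usage: python analysis/04_run_scenarios.py [--resolution UM] [--scenario NAME]
"""
import argparse
import csv
from pathlib import Path

from retmech.geometry import UM, build_vessel_geometry, generate_mesh, place_pois
from retmech.scenarios import make_scenario, run_scenario
from retmech.structure import SweepPoiMetrics
from retmech.synthetic_data import GeneratorSpec, gen_angular_velocity

ROOT = Path(__file__).resolve().parents[1]
ALL = ("settling", "rh", "baseline", "tbi", "shaking", "aht")


def write_metrics(path: Path, name: str, metrics) -> None:
    swept = isinstance(metrics, SweepPoiMetrics)
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["label", "metric", "variant", "poi1", "poi2", "poi3", "poi4"])
        variants = (("max", metrics.max), ("average", metrics.avg)) if swept \
            else (("static", metrics),)
        for variant, m in variants:
            w.writerow([name, "von_mises", variant, *(f"{v:.4f}" for v in m.von_mises)])
            w.writerow([name, "displacement_um", variant,
                        *(f"{v:.4f}" for v in m.displacement_um)])
            w.writerow([name, "vol_strain", variant,
                        *(f"{v:.7f}" for v in m.vol_strain)])


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--resolution", type=float, default=4.0)
    ap.add_argument("--scenario", choices=ALL, default=None,
                    help="run a single scenario (default: all six)")
    ap.add_argument("--sweep-steps", type=int, default=50)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "scenarios")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    geom = build_vessel_geometry()
    pois_m = place_pois(geom) * UM
    mesh = generate_mesh(geom, args.resolution)
    motion = gen_angular_velocity(GeneratorSpec())

    names = (args.scenario,) if args.scenario else ALL
    for name in names:
        sc = make_scenario(name, angular_motion=motion
                           if name in ("shaking", "aht") else None)
        res = run_scenario(sc, mesh, pois_m, n_sweep_steps=args.sweep_steps)
        write_metrics(args.out / f"{name}.csv", name, res.metrics)
        if res.flow is not None:
            res.flow.export_csv(args.out / f"{name}_flow.csv")
        if res.solid is not None:
            res.solid.export_csv(args.out / f"{name}_stress.csv")
        m = res.metrics.max if isinstance(res.metrics, SweepPoiMetrics) else res.metrics
        print(f"{name:9s} von Mises (Pa): "
              + "  ".join(f"{v:8.1f}" for v in m.von_mises))
    print(f"wrote per-scenario CSVs to {args.out}")


if __name__ == "__main__":
    main()
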