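"""Comparative percent-change arithmetic and the rupture decision rule.

The study's headline logic: compute, per POI and metric, the percent
increase of each loading model over its reference — the RH perfusion
state over the settling state for the ex vivo pair, and the TBI
(hypertension-only), shaking-only and AHT (combined) models over the
healthy baseline — then flag every model cell whose increase exceeds the
ex vivo increase required to produce hemorrhage.  A model "predicts RH"
if it exceeds the ex vivo threshold for at least one metric at one POI;
in the printed study only the combined AHT loading does.

Swept (shaking) scenarios contribute their per-POI maxima to the change
table.  Percent changes for the (negative, compressive) volumetric
strain are computed on magnitudes.  Exceed flags are evaluated on raw
floats; rounding (half away from zero) happens only at presentation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

POIS = ["poi1", "poi2", "poi3", "poi4"]
METRICS = ["von_mises", "displacement_um", "vol_strain"]
MODEL_REFERENCE = {"rh": "settling", "tbi": "baseline",
                   "shaking": "baseline", "aht": "baseline"}
#: presentation label of each compared model
MODEL_ROW = {"rh": "exvivo", "tbi": "tbi", "shaking": "shaking", "aht": "aht"}
ALL_LABELS = ["settling", "rh", "baseline", "tbi", "shaking", "aht"]


class ReportingError(ValueError):
    pass


@dataclass
class PoiTable:
    """Per-POI metric values for one labelled model.

    For swept scenarios ``*_max`` holds the per-POI sweep maxima and the
    base arrays the sweep averages.
    """

    label: str
    von_mises: np.ndarray
    displacement_um: np.ndarray
    vol_strain: np.ndarray
    von_mises_max: np.ndarray | None = None
    displacement_um_max: np.ndarray | None = None
    vol_strain_max: np.ndarray | None = None

    def __post_init__(self):
        for name in METRICS:
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (4,):
                raise ReportingError(f"{self.label}.{name} must have 4 POI values")
            setattr(self, name, v)
        if np.any(self.von_mises < 0):
            raise ReportingError("von Mises stress cannot be negative")

    def metric(self, name: str, prefer_max: bool = True) -> np.ndarray:
        if prefer_max:
            mx = getattr(self, f"{name}_max")
            if mx is not None:
                return np.asarray(mx, dtype=float)
        return getattr(self, name)


def round_half_away(x):
    """Round half away from zero (presentation rounding of the tables)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def percent_change(value, reference) -> float:
    """100 * (value - reference) / reference; reference must be positive."""
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise ReportingError("percent change needs a positive reference")
    return 100.0 * (np.asarray(value, dtype=float) - reference) / reference


@dataclass
class ChangeTable:
    """Percent changes per model x metric x POI, with exceed flags."""

    data: pd.DataFrame   # columns: model, metric, poi1..poi4, average

    def row(self, model: str, metric: str) -> np.ndarray:
        sel = self.data[(self.data.model == model) & (self.data.metric == metric)]
        if sel.empty:
            raise ReportingError(f"no row for model={model} metric={metric}")
        return sel[POIS].to_numpy(dtype=float)[0]

    def average(self, model: str, metric: str) -> float:
        sel = self.data[(self.data.model == model) & (self.data.metric == metric)]
        return float(sel["average"].iloc[0])

    def presented(self) -> pd.DataFrame:
        out = self.data.copy()
        out[POIS] = round_half_away(out[POIS].to_numpy())
        out["average"] = round_half_away(out["average"].to_numpy())
        return out

    def exceed_flags(self) -> pd.DataFrame:
        """True where a simulated model's change exceeds the ex vivo change."""
        rows = []
        for metric in METRICS:
            ref = self.row("exvivo", metric)
            for model in ("tbi", "shaking", "aht"):
                flags = self.row(model, metric) > ref
                rows.append({"model": model, "metric": metric,
                             **dict(zip(POIS, flags))})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.presented().to_csv(path, index=False)


def build_change_table(tables: dict) -> ChangeTable:
    """Assemble the full percent-change table from six labelled PoiTables.

    Swept scenarios contribute their maxima; row averages are means of
    the four per-POI percent changes; volumetric strain is compared on
    magnitudes.
    """
    missing = [lbl for lbl in ALL_LABELS if lbl not in tables]
    if missing:
        raise ReportingError(f"missing scenario table(s): {missing}")
    rows = []
    for model, ref_label in MODEL_REFERENCE.items():
        mdl, ref = tables[model], tables[ref_label]
        for metric in METRICS:
            v = mdl.metric(metric, prefer_max=True)
            r = ref.metric(metric, prefer_max=True)
            if metric == "vol_strain":
                v, r = np.abs(v), np.abs(r)
            pc = percent_change(v, r)
            rows.append({"model": MODEL_ROW[model], "metric": metric,
                         **dict(zip(POIS, pc)), "average": float(np.mean(pc))})
    return ChangeTable(pd.DataFrame(rows))


def rupture_decision(change: ChangeTable) -> dict:
    """Per-model verdicts: 'RH predicted' iff any metric exceeds the ex
    vivo increase at one or more POIs."""
    flags = change.exceed_flags()
    verdicts = {}
    for model in ("tbi", "shaking", "aht"):
        sel = flags[flags.model == model][POIS].to_numpy()
        verdicts[model] = {
            "rh_predicted": bool(sel.any()),
            "n_exceeding_cells": int(sel.sum()),
        }
    return verdicts


def save_verdicts(verdicts: dict, path) -> None:
    Path(path).write_text(json.dumps(verdicts, indent=2) + "\n")


def load_printed_tables(path=None) -> dict:
    """The study's printed POI tables, shipped verbatim as a fixture."""
    if path is None:
        src = resources.files("retmech").joinpath("data/printed_poi_tables.csv")
        df = pd.read_csv(src.open())
    else:
        df = pd.read_csv(path)
    tables = {}
    for label, grp in df.groupby("label"):
        kw = {"label": label}
        for _, row in grp.iterrows():
            vals = row[POIS].to_numpy(dtype=float)
            key = row["metric"] if row["variant"] in ("static", "average") \
                else f"{row['metric']}_max"
            kw[key] = vals
        tables[label] = PoiTable(**kw)
    return tables


def tables_from_results(results: dict) -> dict:
    """PoiTables from in-memory ScenarioResult objects keyed by label."""
    from .structure import SweepPoiMetrics

    out = {}
    for label, res in results.items():
        m = res.metrics
        if isinstance(m, SweepPoiMetrics):
            out[label] = PoiTable(
                label=label,
                von_mises=m.avg.von_mises, displacement_um=m.avg.displacement_um,
                vol_strain=m.avg.vol_strain,
                von_mises_max=m.max.von_mises,
                displacement_um_max=m.max.displacement_um,
                vol_strain_max=m.max.vol_strain)
        else:
            out[label] = PoiTable(label=label, von_mises=m.von_mises,
                                  displacement_um=m.displacement_um,
                                  vol_strain=m.vol_strain)
    return out
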