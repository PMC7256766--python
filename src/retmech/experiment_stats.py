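"""Analysis of the ex vivo porcine perfusion experiment.

A cannulated eye is perfused at a controlled flow rate while the line
pressure is recorded.  The trace shows a clot-breakthrough peak (the
perfusion pressure), a drop to a steady settling plateau, and a slow
pressure ramp during which retinal hemorrhage (RH) is first seen at an
annotated timestamp.  A line-loss correction — calibrated from open-tube
recordings — removes the pressure dropped between the transducer and the
cannulation point.

Statistics follow the experiment's protocol: Anderson-Darling normality,
Levene equal-variance, and one-tailed pooled-variance two-sample t-tests
at alpha = 0.05.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal, stats
from statsmodels.stats.diagnostic import normal_ad

ALPHA = 0.05


class StatsError(ValueError):
    pass


@dataclass
class PressureTrace:
    """Recorded perfusion pressure over time for one eye.

    time in seconds (strictly increasing), pressure in mmHg, flow in
    µl/min; events are (time_s, label) annotations, e.g. ('rh', t).
    """

    time: np.ndarray
    pressure: np.ndarray
    flow: np.ndarray
    events: list = field(default_factory=list)
    eye_id: str = ""

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise StatsError("trace time must be strictly increasing")
        if np.any(self.flow < 0):
            raise StatsError("flow rate must be non-negative")

    def to_csv(self, path) -> None:
        marks = {}
        for t, lbl in self.events:
            idx = int(np.argmin(np.abs(self.time - t)))
            marks[idx] = lbl
        with open(path, "w") as f:
            f.write("time_s,pressure_mmhg,flow_ul_min,event\n")
            for i in range(len(self.time)):
                f.write(f"{self.time[i]:.3f},{self.pressure[i]:.5f},"
                        f"{self.flow[i]:.3f},{marks.get(i, '')}\n")

    @classmethod
    def from_csv(cls, path, eye_id: str = "") -> "PressureTrace":
        import pandas as pd
        df = pd.read_csv(path)
        events = [(float(t), str(e)) for t, e in
                  zip(df["time_s"], df["event"].fillna("")) if e]
        return cls(df["time_s"].to_numpy(), df["pressure_mmhg"].to_numpy(),
                   df["flow_ul_min"].to_numpy(), events, eye_id)


@dataclass
class PerfusionRecord:
    """Per-eye pressure outcomes (mmHg)."""

    eye_id: str
    perfusion: float | None = None      # clot-breakthrough peak
    settling: float | None = None       # post-peak steady plateau
    choroid: float | None = None
    rh: float | None = None             # pressure at first observed RH

    def __post_init__(self):
        for name in ("perfusion", "settling", "choroid", "rh"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise StatsError(f"{name} pressure must be positive where present")


@dataclass(frozen=True)
class LineLossModel:
    """Linear transducer-to-eye pressure loss: loss = slope*flow + intercept."""

    slope: float        # mmHg per µl/min
    intercept: float    # mmHg

    def predict(self, flow) -> np.ndarray:
        return self.slope * np.asarray(flow, dtype=float) + self.intercept


def calibrate_line_loss(open_tube_records) -> LineLossModel:
    """Least-squares line through open-tube (flow, pressure) pairs."""
    arr = np.asarray(open_tube_records, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise StatsError("need at least two (flow, pressure) pairs")
    flows, pressures = arr[:, 0], arr[:, 1]
    if np.ptp(flows) == 0:
        raise StatsError("calibration requires at least two distinct flow rates")
    res = stats.linregress(flows, pressures)
    model = LineLossModel(slope=float(res.slope), intercept=float(res.intercept))
    fitted = model.predict(flows)
    if np.any(fitted < -1e-9):
        warnings.warn("calibrated line loss predicts negative losses in range",
                      stacklevel=2)
    return model


def correct_trace(trace: PressureTrace, model: LineLossModel) -> PressureTrace:
    """Subtract the modeled line loss; corrected pressure is clipped at 0."""
    corrected = np.clip(trace.pressure - model.predict(trace.flow), 0.0, None)
    return replace(trace, pressure=corrected)


def _smooth(x: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return x.copy()
    kernel = np.ones(n) / n
    pad = np.concatenate([np.full(n // 2, x[0]), x, np.full(n - 1 - n // 2, x[-1])])
    return np.convolve(pad, kernel, mode="valid")


def detect_events(trace: PressureTrace, plateau_slope: float = 0.2,
                  plateau_min_duration: float = 20.0,
                  smooth_window_s: float = 2.0,
                  peak_prominence: float = 2.0) -> PerfusionRecord:
    """Extract perfusion, settling and RH pressures from a corrected trace.

    perfusion: vertex of a local quadratic fit around the first prominent
    smoothed peak; settling: mean over the longest low-slope plateau
    (|dP/dt| < plateau_slope over >= plateau_min_duration, trimmed by the
    smoothing window); rh: smoothed pressure at the first 'rh' annotation.
    Missing features yield None fields with a warning.
    """
    t, p = trace.time, trace.pressure
    dt = float(np.median(np.diff(t)))
    nwin = max(1, int(round(smooth_window_s / dt)) | 1)
    ps = _smooth(p, nwin)

    perfusion = None
    peak_idx = None
    peaks, _ = signal.find_peaks(ps, prominence=peak_prominence)
    if len(peaks):
        peak_idx = int(peaks[0])
        half = max(2, int(round(1.5 / dt)))
        lo, hi = max(0, peak_idx - half), min(len(p), peak_idx + half + 1)
        coef = np.polyfit(t[lo:hi] - t[peak_idx], p[lo:hi], 2)
        if coef[0] < 0:
            perfusion = float(np.polyval(coef, -coef[1] / (2 * coef[0])))
        else:
            perfusion = float(ps[peak_idx])
    else:
        warnings.warn(f"trace {trace.eye_id or '?'}: no perfusion peak found",
                      stacklevel=2)

    # slope on the smoothing-window scale: sample-to-sample gradients of a
    # noisy trace would fragment the plateau
    lag = max(1, int(round(smooth_window_s / dt)))
    hi_i = np.minimum(np.arange(len(ps)) + lag, len(ps) - 1)
    lo_i = np.maximum(np.arange(len(ps)) - lag, 0)
    slope = (ps[hi_i] - ps[lo_i]) / (t[hi_i] - t[lo_i])
    quiet = np.abs(slope) < plateau_slope
    if peak_idx is not None:
        quiet[: peak_idx + 1] = False
    settling = None
    best_run = None
    i = 0
    n = len(quiet)
    while i < n:
        if quiet[i]:
            j = i
            while j + 1 < n and quiet[j + 1]:
                j += 1
            if t[j] - t[i] >= plateau_min_duration:
                if best_run is None or (t[j] - t[i]) > (t[best_run[1]] - t[best_run[0]]):
                    best_run = (i, j)
            i = j + 1
        else:
            i += 1
    if best_run is not None:
        i0, j0 = best_run
        trim = int(round(smooth_window_s / dt))
        i0, j0 = i0 + trim, j0 - trim
        if j0 > i0:
            settling = float(np.mean(p[i0:j0 + 1]))
    if settling is None:
        warnings.warn(f"trace {trace.eye_id or '?'}: no settling plateau found",
                      stacklevel=2)

    rh = None
    rh_times = sorted(tt for tt, lbl in trace.events if lbl == "rh")
    if rh_times:
        rh = float(np.interp(rh_times[0], t, ps))

    return PerfusionRecord(eye_id=trace.eye_id, perfusion=perfusion,
                           settling=settling, rh=rh)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    mean_difference: float
    alternative: str


def compare_pressures(a, b, alternative: str = "greater") -> TTestResult:
    """One-tailed pooled-variance two-sample t-test of group a vs group b.

    Returns the t statistic, the one-tailed p-value, and mean(a) - mean(b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each group needs n >= 2")
    if np.var(a) == 0 and np.var(b) == 0:
        raise StatsError("both groups have zero variance; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=True, alternative=alternative)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue),
                       mean_difference=float(np.mean(a) - np.mean(b)),
                       alternative=alternative)


def normality_check(values) -> float:
    """Anderson-Darling normality p-value (requires n >= 8)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 8:
        raise StatsError("normality check requires n >= 8")
    _, p = normal_ad(values)
    return float(p)


def variance_check(groups) -> float:
    """Levene equal-variance p-value across groups.

    Degenerate boundary: when every group has (numerically) identical
    spread the statistic is 0/undefined and p = 1.0 is returned.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise StatsError("need at least two groups")
    stat, p = stats.levene(*arrays)
    if not np.isfinite(p) or stat == 0:
        return 1.0
    return float(p)
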