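"""Synthetic generators for every pipeline input, with known ground truth.

The raw per-eye data are not deposited; only group means and standard
deviations are printed.  These generators are distributional stand-ins:
truncated-normal per-eye pressure outcomes with the printed moments,
piecewise pressure traces with a rounded clot-breakthrough peak, settling
plateau, slow ramp and an annotated rupture event, open-tube calibration
recordings with a known line-loss line, and a sinusoidal angular-velocity
profile with a configurable peak angular acceleration (1068.3 rad/s^2,
the strongest shaking measured on anthropomorphic dummies, by default).

Every generator is a pure function of its spec (seed included).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .experiment_stats import LineLossModel, PerfusionRecord, PressureTrace
from .scenarios import AngularMotion

#: printed ex vivo group summaries (mean, SD) in mmHg
PERFUSION_MEAN_SD = (39.89, 15.73)
SETTLING_MEAN_SD = (28.61, 15.40)
CHOROID_MEAN_SD = (32.14, 14.11)
RH_MEAN_SD = (39.45, 11.43)


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic ex vivo experiment."""

    seed: int = 0
    perfusion: tuple = PERFUSION_MEAN_SD
    settling: tuple = SETTLING_MEAN_SD
    choroid: tuple = CHOROID_MEAN_SD
    rh: tuple = RH_MEAN_SD
    n_eyes: int = 17
    n_choroid: int = 8                  # eyes with observed choroid perfusion
    trace_noise_sd: float = 0.5         # mmHg
    flow_ul_min: float = 100.0          # modal pump flow
    sample_rate_hz: float = 10.0
    line_loss: tuple = (0.03, 0.5)      # ground-truth (slope, intercept)
    shaking_frequency_hz: float = 3.0
    peak_angular_accel: float = 1068.3  # rad/s^2
    shaking_duration_s: float = 1.0

    def __post_init__(self):
        if self.n_eyes < 2:
            raise ValueError("need at least two eyes")
        for name in ("perfusion", "settling", "choroid", "rh"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} SD must be non-negative")

    def line_loss_model(self) -> LineLossModel:
        return LineLossModel(*self.line_loss)


def _draw_positive(rng, mean, sd, size=None):
    """Normal draw truncated at 0 by resampling (physical non-negativity)."""
    if sd == 0:
        return np.full(size, mean) if size else float(mean)
    x = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = x <= 0
        if not np.any(bad):
            break
        x = np.where(bad, rng.normal(mean, sd, size=size), x)
    return x


def gen_perfusion_records(spec: GeneratorSpec, n: int | None = None) -> list:
    """Per-eye pressure outcomes.

    Settling is resampled until it does not exceed the eye's perfusion
    pressure, and the RH pressure until it exceeds settling (rupture
    happens on the post-plateau ramp); both conditionings are mild
    truncations of the printed marginals.
    """
    n = n or spec.n_eyes
    rng = np.random.default_rng([spec.seed, 101])
    records = []
    choroid_eyes = set(rng.choice(n, size=min(spec.n_choroid, n), replace=False).tolist())
    for k in range(n):
        perf = float(_draw_positive(rng, *spec.perfusion))
        settle = float(_draw_positive(rng, *spec.settling))
        for _ in range(1000):
            if settle <= perf:
                break
            settle = float(_draw_positive(rng, *spec.settling))
        else:
            settle = perf
        rh = float(_draw_positive(rng, *spec.rh))
        for _ in range(1000):
            if rh > settle:
                break
            rh = float(_draw_positive(rng, *spec.rh))
        else:
            rh = settle * 1.01
        choroid = float(_draw_positive(rng, *spec.choroid)) if k in choroid_eyes else None
        records.append(PerfusionRecord(eye_id=f"eye{k:02d}", perfusion=perf,
                                       settling=settle, choroid=choroid, rh=rh))
    return records


def gen_pressure_trace(record: PerfusionRecord, spec: GeneratorSpec,
                       model: LineLossModel | None = None) -> PressureTrace:
    """Synthetic transducer trace for one eye.

    Shape: ramp to a rounded (quadratic-cap) clot-breakthrough peak at the
    perfusion pressure, drop to the settling plateau, slow ramp with an
    'rh' annotation where the trace crosses the eye's RH pressure.  The
    ground-truth line loss (for the recorded constant flow) is added so the
    correction stage is exercised end to end; Gaussian measurement noise on
    top.
    """
    if record.perfusion is None or record.settling is None or record.rh is None:
        raise ValueError("record must have perfusion, settling and rh pressures")
    model = model or spec.line_loss_model()
    eye_index = int("".join(c for c in record.eye_id if c.isdigit()) or 0)
    rng = np.random.default_rng([spec.seed, 202, eye_index])

    fs = spec.sample_rate_hz
    cap_half = 2.0          # s, half-width of the quadratic peak cap
    cap_drop = 4.0          # mmHg dropped across the cap half-width
    ramp_t, drop_t, plateau_t = 30.0, 6.0, 60.0
    slow_rate = 0.3         # mmHg/s post-plateau ramp, above the plateau
                            # slope threshold so detection can separate them
    p0 = max(1.0, 0.3 * record.settling)

    t_peak = ramp_t
    t_drop0 = t_peak + cap_half
    t_plate0 = t_drop0 + drop_t
    t_plate1 = t_plate0 + plateau_t
    t_rh = t_plate1 + max(0.0, record.rh - record.settling) / slow_rate
    t_end = t_rh + 20.0

    t = np.arange(0.0, t_end, 1.0 / fs)
    p = np.empty_like(t)
    cap = np.abs(t - t_peak) <= cap_half
    seg_ramp = t < t_peak - cap_half
    p[seg_ramp] = np.interp(t[seg_ramp], [0.0, t_peak - cap_half],
                            [p0, record.perfusion - cap_drop])
    p[cap] = record.perfusion - cap_drop * ((t[cap] - t_peak) / cap_half) ** 2
    seg_drop = (t > t_peak + cap_half) & (t < t_plate0)
    p[seg_drop] = np.interp(t[seg_drop], [t_drop0, t_plate0],
                            [record.perfusion - cap_drop, record.settling])
    seg_plate = (t >= t_plate0) & (t <= t_plate1)
    p[seg_plate] = record.settling
    seg_slow = t > t_plate1
    p[seg_slow] = record.settling + slow_rate * (t[seg_slow] - t_plate1)

    flow = np.full_like(t, spec.flow_ul_min)
    measured = p + model.predict(flow)
    if spec.trace_noise_sd > 0:
        measured = measured + rng.normal(0.0, spec.trace_noise_sd, size=len(t))
    return PressureTrace(time=t, pressure=measured, flow=flow,
                         events=[(float(t_rh), "rh")], eye_id=record.eye_id)


def gen_angular_velocity(spec: GeneratorSpec) -> AngularMotion:
    """Sinusoidal shaking profile omega(t) = A sin(2 pi f t).

    The amplitude A = peak_accel / (2 pi f) makes the peak angular
    acceleration equal the configured value; sampling is at least 40
    points per period so the finite-difference peak stays within 5%.
    """
    f = spec.shaking_frequency_hz
    if f <= 0:
        raise ValueError("shaking frequency must be positive")
    amp = spec.peak_angular_accel / (2 * np.pi * f)
    n = max(int(np.ceil(spec.shaking_duration_s * f * 40)) + 1, 41)
    t = np.linspace(0.0, spec.shaking_duration_s, n)
    omega = amp * np.sin(2 * np.pi * f * t)
    return AngularMotion(time=t, omega=omega, peak_accel=spec.peak_angular_accel,
                         duration=spec.shaking_duration_s)


def gen_open_tube(model: LineLossModel, flows, noise_sd: float = 0.1,
                  seed: int = 0) -> np.ndarray:
    """Open-tube calibration pairs (flow, pressure) with Gaussian noise."""
    flows = np.asarray(flows, dtype=float)
    if len(flows) < 2:
        raise ValueError("need at least two calibration flows")
    rng = np.random.default_rng([seed, 303])
    pressures = model.predict(flows)
    if noise_sd > 0:
        pressures = pressures + rng.normal(0.0, noise_sd, size=len(flows))
    return np.column_stack([flows, pressures])
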