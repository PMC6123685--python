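"""Analysis of dual cytoplasmic/ER Ca2+ fluorescence time series.

HEK293 cells expressing RyR channels are imaged with a cytoplasmic indicator
(G-GECO1.1-like) and an ER-luminal indicator (R-CEPIA1er-like).  Spontaneous
store-overload Ca2+ release shows up as cytoplasmic spikes with antiphase
sawtooth depletion of the ER; caffeine application either dumps the store
(wild-type-like) or does nothing (caffeine-insensitive mutants).

Provided here: min-max calibration normalization (F - Fmin)/(Fmax - Fmin)
with channel-specific default floors, a deterministic oscillation detector,
the upper-[Ca2+]_ER envelope estimator, Hill dose-response fitting for the
caffeine EC50, and five-number/mean +/- SEM summaries for per-cell scalars.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

#: average calibration floor of the ER indicator, as a fraction of Fmax
#: (cytoplasmic indicators bleach to a true zero; the ER sensor does not).
ER_FMIN_FRACTION = 0.07655


class CalibrationError(ValueError):
    """Fmin/Fmax anchors are missing or inconsistent."""


class InsufficientDataError(ValueError):
    """The trace is too short or too sparsely sampled for the analysis."""


@dataclass
class Trace:
    """A timestamped single-channel fluorescence trace with calibration anchors.

    `events` holds labeled application windows, e.g.
    ``{"label": "caffeine-10mM", "start_s": 120.0, "end_s": 180.0}``.
    """

    time: np.ndarray
    F: np.ndarray
    channel: str  # "cyto" | "ER"
    Fmin: float | None = None
    Fmax: float | None = None
    events: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.time.shape != self.F.shape:
            raise ValueError("time and F must have the same shape")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def sampling_hz(self) -> float:
        return (self.time.size - 1) / self.duration_s

    def window(self, start_s: float, end_s: float) -> "Trace":
        mask = (self.time >= start_s) & (self.time <= end_s)
        if not mask.any():
            raise InsufficientDataError("requested window contains no samples")
        return replace(self, time=self.time[mask], F=self.F[mask])


@dataclass
class OscillationConfig:
    """Deterministic detector settings (seconds and MAD-sigma units)."""

    baseline_window_s: float = 15.0
    k_mad: float = 5.0
    hysteresis: float = 0.5  # fall threshold as a fraction of the rise threshold
    refractory_s: float = 2.0
    smooth_s: float = 0.3  # pre-detection moving average


@dataclass
class OscillationReport:
    event_count: int
    frequency_per_min: float
    mean_amplitude: float
    baseline: float
    peak_times_s: list[float] = field(default_factory=list)


@dataclass
class DoseResponseFit:
    EC50_mM: float
    hill: float
    floor: float
    ceiling: float
    r_squared: float
    ec50_in_range: bool
    converged: bool
    stderr: dict[str, float | None] = field(default_factory=dict)


def normalize(trace: Trace) -> Trace:
    """Calibrated normalization (F - Fmin)/(Fmax - Fmin) -> [~0, ~1].

    When a per-cell Fmin is absent, the channel default applies: 0 for the
    cytoplasmic indicator, ER_FMIN_FRACTION * Fmax for the ER indicator.
    The result is invariant under any positive affine transform applied
    jointly to F, Fmin and Fmax.
    """
    if trace.Fmax is None:
        raise CalibrationError("Fmax calibration anchor is required")
    fmin = trace.Fmin
    if fmin is None:
        fmin = ER_FMIN_FRACTION * trace.Fmax if trace.channel == "ER" else 0.0
    if not (trace.Fmax > fmin):
        raise CalibrationError(f"Fmax ({trace.Fmax!r}) must exceed Fmin ({fmin!r})")
    norm = (trace.F - fmin) / (trace.Fmax - fmin)
    return replace(trace, F=norm, Fmin=0.0, Fmax=1.0)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="same")[pad:pad + x.size]


def detect_oscillations(
    trace: Trace, config: OscillationConfig | None = None
) -> OscillationReport:
    """Count Ca2+ release events in a normalized cytoplasmic trace.

    Events are excursions of the (lightly smoothed) signal above a rolling
    median baseline plus ``k_mad`` robust sigmas, with hysteresis: an event
    opens when the signal crosses the rise threshold and closes when it falls
    back below ``hysteresis`` of it; events closer than ``refractory_s`` to
    the previous one are merged.  Entirely deterministic given the config.
    """
    cfg = config or OscillationConfig()
    if trace.duration_s < 30.0 or trace.sampling_hz < 1.0:
        raise InsufficientDataError(
            f"need >= 30 s at >= 1 Hz, got {trace.duration_s:.1f} s "
            f"at {trace.sampling_hz:.2f} Hz"
        )
    fs = trace.sampling_hz
    x = _moving_average(trace.F, max(1, int(round(cfg.smooth_s * fs))))
    win = max(3, int(round(cfg.baseline_window_s * fs)) | 1)
    baseline = (
        pd.Series(x).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    resid = x - baseline
    sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    rise = cfg.k_mad * sigma
    fall = cfg.hysteresis * rise

    events: list[tuple[int, int, int]] = []  # (start, peak, end) indices
    inside = False
    start = peak = 0
    for i, r in enumerate(resid):
        if not inside:
            if r > rise:
                inside, start, peak = True, i, i
        else:
            if r > resid[peak]:
                peak = i
            if r < fall:
                events.append((start, peak, i))
                inside = False
    if inside:
        events.append((start, peak, resid.size - 1))

    merged: list[tuple[int, int, int]] = []
    for ev in events:
        if merged and trace.time[ev[0]] - trace.time[merged[-1][2]] < cfg.refractory_s:
            prev = merged[-1]
            peak = ev[1] if resid[ev[1]] > resid[prev[1]] else prev[1]
            merged[-1] = (prev[0], peak, ev[2])
        else:
            merged.append(ev)

    amplitudes = [resid[p] for _, p, _ in merged]
    duration_min = trace.duration_s / 60.0
    return OscillationReport(
        event_count=len(merged),
        frequency_per_min=len(merged) / duration_min,
        mean_amplitude=float(np.mean(amplitudes)) if amplitudes else 0.0,
        baseline=float(np.median(baseline)),
        peak_times_s=[float(trace.time[p]) for _, p, _ in merged],
    )


def upper_er_level(
    trace: Trace, window: tuple[float, float] | None = None, percentile: float = 95.0
) -> float:
    """Upper envelope of the normalized ER signal within a window.

    The ER trace under spontaneous oscillation is a sawtooth; its refilled
    "upper level" is estimated as a high percentile (default 95th) for noise
    robustness, rather than the raw maximum.
    """
    sub = trace if window is None else trace.window(*window)
    return float(np.percentile(sub.F, percentile))


def hill_dose_response(
    dose: np.ndarray, floor: float, ceiling: float, ec50: float, hill: float
) -> np.ndarray:
    d = np.asarray(dose, dtype=float)
    return floor + (ceiling - floor) * d**hill / (d**hill + ec50**hill)


def caffeine_dose_response(
    doses_mM: Sequence[float], responses: Sequence[float]
) -> DoseResponseFit:
    """Fit a monotone Hill dose-response (floor, ceiling, EC50, hill).

    ``doses_mM``/``responses`` are paired observations (replicate cells may
    simply repeat a dose).  Requires >= 4 distinct doses spanning >= 1.5 log
    units; flags fits whose EC50 falls outside the tested dose range.
    """
    d = np.asarray(doses_mM, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.unique(d).size < 4:
        raise InsufficientDataError("need >= 4 distinct doses")
    span = math.log10(d.max() / d.min())
    if span < 1.5:
        raise InsufficientDataError(f"dose range spans {span:.2f} log units (< 1.5)")

    params = lmfit.Parameters()
    params.add("floor", value=float(y.min()), min=-1.0, max=2.0)
    params.add("ceiling", value=float(y.max()), min=-1.0, max=5.0)
    params.add("log_ec50", value=float(np.log10(np.sqrt(d.min() * d.max()))),
               min=-4.0, max=4.0)
    params.add("hill", value=1.0, min=0.1, max=8.0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        return hill_dose_response(
            d, p["floor"].value, p["ceiling"].value,
            10.0 ** p["log_ec50"].value, p["hill"].value,
        ) - y

    res = lmfit.minimize(residual, params, method="least_squares")
    p = res.params
    ec50 = 10.0 ** p["log_ec50"].value
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(res.residual**2)) / ss_tot if ss_tot > 0 else math.nan
    ec50_se = (
        ec50 * math.log(10) * p["log_ec50"].stderr
        if p["log_ec50"].stderr is not None
        else None
    )
    return DoseResponseFit(
        EC50_mM=ec50,
        hill=p["hill"].value,
        floor=p["floor"].value,
        ceiling=p["ceiling"].value,
        r_squared=r2,
        ec50_in_range=bool(d.min() <= ec50 <= d.max()),
        converged=bool(res.success),
        stderr={"EC50_mM": ec50_se, "hill": p["hill"].stderr},
    )


def summarize_cells(values: Sequence[float]) -> dict[str, float]:
    """Five-number summary plus mean +/- SEM for per-cell scalars.

    Quartiles use linear interpolation; SEM = sample SD / sqrt(n), reported
    as NaN for n = 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise InsufficientDataError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    sem = float(np.std(v, ddof=1) / math.sqrt(v.size)) if v.size > 1 else math.nan
    return {
        "n": int(v.size),
        "min": float(v.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(v.max()),
        "mean": float(v.mean()),
        "sem": sem,
    }
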