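"""Raw-channel conditioning: EMG, sonomicrometry length, and buckle force.

EMG is optionally zero-phase FIR band-pass filtered, baseline-corrected and
full-wave rectified.  Sonomicrometry voltage is converted to fascicle length
using a calibration gain, corrected for the crystal epoxy coating (additive
length offset) and for the fascicle segment not spanned by the crystal pair
(multiplicative factor), then smoothed with a quintic smoothing spline.
Tendon-buckle voltage is calibrated against motor force by per-contraction
least squares over the tetanic force rise, and the averaged slope converts
in vivo voltage to force after rest-window baseline correction.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats
from scipy.interpolate import PchipInterpolator, UnivariateSpline
from scipy.signal import filtfilt, firwin, iirnotch

from .core import Trace, Trial
from .errors import ConfigurationError, MissingChannelError

__all__ = [
    "FilterSpec",
    "SonoConfig",
    "CalibrationModel",
    "condition_emg",
    "integrate_emg",
    "sono_to_length",
    "smooth_quintic",
    "fit_buckle_calibration",
    "apply_buckle_calibration",
    "resample_and_sync",
]


@dataclass
class FilterSpec:
    """Zero-phase FIR band-pass (plus optional mains notch) for EMG."""

    band: tuple = (30.0, 1000.0)  # Hz
    numtaps: int = 201
    notch_60hz: bool = False
    notch_q: float = 30.0

    def apply(self, values: np.ndarray, rate: float) -> np.ndarray:
        if self.numtaps >= values.size:
            raise ConfigurationError(
                f"filter order ({self.numtaps}) exceeds trace length ({values.size})"
            )
        lo, hi = self.band
        hi = min(hi, 0.999 * rate / 2)
        taps = firwin(self.numtaps, (lo, hi), pass_zero=False, fs=rate)
        out = filtfilt(taps, [1.0], values)
        if self.notch_60hz:
            b, a = iirnotch(60.0, self.notch_q, fs=rate)
            out = filtfilt(b, a, out)
        return out


def condition_emg(
    raw: Trace,
    baseline_window: tuple,
    filter_spec: Optional[FilterSpec] = None,
) -> Trace:
    """Filter (optional), baseline-correct and full-wave rectify an EMG trace.

    The baseline window must lie inside the trace and contain no burst; its
    mean (after filtering) is subtracted before rectification, so the output
    is ``|filtered(raw) - baseline mean|`` and nonnegative everywhere.
    """
    values = raw.values
    if filter_spec is not None:
        values = filter_spec.apply(values, raw.rate)
    filtered = Trace(values, raw.rate, raw.t0, raw.units)
    base = filtered.window_values(*baseline_window)
    if base.size == 0:
        raise ValueError("empty baseline window")
    rectified = np.abs(values - float(np.mean(base)))
    return Trace(rectified, raw.rate, raw.t0, raw.units)


def integrate_emg(rectified: Trace, window: tuple) -> float:
    """Trapezoidal integral (mV*s) of a rectified EMG over ``window``.

    Endpoints are handled by linear interpolation, which makes the integral
    exactly additive over adjacent windows.
    """
    t_start, t_end = window
    if t_end < t_start:
        raise ValueError("inverted integration window")
    if t_start < rectified.t0 - 1e-9 or t_end > rectified.t_end + 1e-9:
        raise ValueError("integration window outside trace")
    sl = rectified.window_slice(t_start, t_end)
    times = rectified.t0 + np.arange(sl.start, sl.stop) / rectified.rate
    grid_t = np.concatenate(([t_start], times, [t_end]))
    grid_v = np.concatenate(
        ([rectified.value_at(t_start)], rectified.values[sl], [rectified.value_at(t_end)])
    )
    # de-duplicate in case the window edges coincide with sample times
    keep = np.concatenate(([True], np.diff(grid_t) > 1e-12))
    return float(np.trapezoid(grid_v[keep], grid_t[keep]))


@dataclass
class SonoConfig:
    """Sonomicrometry conversion: gain, epoxy offset, segment correction.

    ``gain`` (mm/V) comes from a synchronized calibration recording;
    ``epoxy_offset`` (mm) corrects the transit-time bias of the crystal
    coating; ``segment_factor`` (>= 1) scales the crystal-spanned length to
    the whole fascicle; ``spline_sd`` is the quintic-spline smoothing
    parameter expressed as an admissible residual fraction of the signal
    range (conventional band 0.01-0.05).
    """

    gain: float
    epoxy_offset: float = 0.0
    segment_factor: float = 1.0
    spline_sd: Optional[float] = 0.02
    spline_sd_band: tuple = (0.01, 0.05)

    def __post_init__(self):
        if not self.gain > 0:
            raise ConfigurationError("sono gain must be positive")
        if self.segment_factor < 1:
            raise ConfigurationError("segment factor must be >= 1")
        if self.spline_sd is not None:
            lo, hi = self.spline_sd_band
            if not (lo <= self.spline_sd <= hi):
                raise ConfigurationError(
                    f"spline_sd {self.spline_sd} outside configured band [{lo}, {hi}]"
                )


def sono_to_length(raw: Trace, cfg: SonoConfig, smooth: bool = True) -> Trace:
    """Convert sonomicrometry voltage to whole-fascicle length (mm).

    ``length = (gain * V - epoxy_offset) * segment_factor`` followed by
    quintic-spline smoothing.  Nonpositive computed lengths are transduction
    dropouts: they are masked as NaN (with a warning), never silently
    interpolated.
    """
    length = (cfg.gain * raw.values - cfg.epoxy_offset) * cfg.segment_factor
    bad = length <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} nonpositive length samples masked as transduction dropouts",
            stacklevel=2,
        )
        length = np.where(bad, np.nan, length)
    out = Trace(length, raw.rate, raw.t0, "mm")
    if smooth and cfg.spline_sd is not None and not np.any(bad):
        out = smooth_quintic(out, cfg.spline_sd)
    elif smooth and cfg.spline_sd is not None and np.any(bad):
        good = ~bad
        if good.sum() >= 7:
            t = out.times()
            sm = _quintic_fit(t[good], length[good], cfg.spline_sd)
            length = np.where(bad, np.nan, sm(t))
            out = Trace(length, raw.rate, raw.t0, "mm")
    return out


def _quintic_fit(t: np.ndarray, v: np.ndarray, sd: float) -> UnivariateSpline:
    rng_v = float(np.max(v) - np.min(v))
    s = t.size * (sd * rng_v) ** 2
    return UnivariateSpline(t, v, k=5, s=s)


def smooth_quintic(trace: Trace, sd: float) -> Trace:
    """Quintic smoothing-spline pass with a normalized roughness budget.

    ``sd`` is the admissible RMS residual as a fraction of the signal range
    (the spline's residual budget is ``n * (sd * range)**2``).  Polynomials
    of degree <= 5 are reproduced exactly; for noisy data the output
    variance does not exceed the input variance appreciably.
    """
    if not sd > 0:
        raise ConfigurationError("spline sd must be positive")
    if trace.n < 7:
        raise ValueError("quintic smoothing needs at least 7 samples")
    if np.ptp(trace.values) == 0:
        return trace.copy_with(values=trace.values.copy())
    spl = _quintic_fit(trace.times(), trace.values, sd)
    return trace.copy_with(values=spl(trace.times()))


@dataclass
class CalibrationModel:
    """Linear buckle-voltage -> force calibration.

    ``slope`` is the mean of the per-contraction regression slopes (V/N);
    ``r2`` is the pooled coefficient of determination across contractions,
    with the per-contraction values kept alongside.
    """

    slope: float  # V per N
    intercept: float  # V
    r2: float
    n_samples: int
    source_trials: list = field(default_factory=list)
    r2_per_pair: list = field(default_factory=list)
    slope_per_pair: list = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ConfigurationError("r2 must be in [0, 1]")
        if self.n_samples < 2:
            raise ConfigurationError("calibration needs at least 2 samples")


def fit_buckle_calibration(
    pairs: Sequence[tuple],
    rise_windows: Sequence[tuple],
    source_trials: Optional[Sequence] = None,
) -> CalibrationModel:
    """Regress gauge voltage on motor force over each tetanic force rise.

    ``pairs`` is a sequence of ``(gauge Trace in V, motor Trace in N)``;
    ``rise_windows`` gives, per pair, the (t_start, t_end) of the force rise
    from stimulation onset to the force peak.  The model slope/intercept are
    the means of the per-pair OLS estimates.
    """
    if len(pairs) < 1:
        raise ValueError("need at least one calibration contraction pair")
    if len(rise_windows) != len(pairs):
        raise ValueError("one rise window per contraction pair is required")
    slopes, intercepts, r2s = [], [], []
    all_v, all_f = [], []
    for (gauge, motor), window in zip(pairs, rise_windows):
        sl = motor.window_slice(*window)
        f = motor.values[sl]
        t = motor.t0 + np.arange(sl.start, sl.stop) / motor.rate
        v = gauge.value_at(t) if (gauge.rate != motor.rate or gauge.t0 != motor.t0) else gauge.values[sl]
        if np.ptp(f) == 0:
            raise ValueError("zero-variance force in rise window")
        res = sstats.linregress(f, v)
        slopes.append(res.slope)
        intercepts.append(res.intercept)
        r2s.append(res.rvalue**2)
        all_v.append(v)
        all_f.append(f)
    vv = np.concatenate(all_v)
    ff = np.concatenate(all_f)
    pooled = sstats.linregress(ff, vv)
    return CalibrationModel(
        slope=float(np.mean(slopes)),
        intercept=float(np.mean(intercepts)),
        r2=min(float(pooled.rvalue**2), 1.0),
        n_samples=int(vv.size),
        source_trials=list(source_trials) if source_trials is not None else [],
        r2_per_pair=[float(r) for r in r2s],
        slope_per_pair=[float(s) for s in slopes],
    )


def apply_buckle_calibration(
    gauge: Trace, model: CalibrationModel, rest_window: tuple
) -> Trace:
    """Convert buckle voltage to force (N), zeroed over a resting window.

    ``force = (V - mean(V in rest_window)) / slope`` so the rest-window mean
    maps to exactly 0 N; for noiseless data this inverts the simulator's
    voltage map.
    """
    if model.slope <= 0:
        raise ConfigurationError("calibration slope must be positive")
    rest = float(np.mean(gauge.window_values(*rest_window)))
    force = (gauge.values - rest) / model.slope
    return Trace(force, gauge.rate, gauge.t0, "N")


def resample_and_sync(trial: Trial, target_rate: float) -> Trial:
    """Put all channels of a trial on one clock at ``target_rate``.

    Requires a ``sync`` channel (TTL square wave); the common time grid is
    anchored on the first rising edge of the sync marker, so after
    resampling the edge falls on a grid sample in every channel.
    Resampling uses shape-preserving (PCHIP) interpolation.
    """
    if not trial.has_channel("sync"):
        raise MissingChannelError("sync", trial.channels.keys())
    sync = trial.channel("sync")
    above = sync.values >= 0.5
    if not above.any():
        raise ValueError("sync channel has no rising edge")
    t_edge = sync.times()[int(np.argmax(above))]
    t_start = max(ch.t0 for ch in trial.channels.values())
    t_end = min(ch.t_end for ch in trial.channels.values())
    k0 = int(np.ceil((t_start - t_edge) * target_rate - 1e-9))
    k1 = int(np.floor((t_end - t_edge) * target_rate + 1e-9))
    grid = t_edge + np.arange(k0, k1 + 1) / target_rate
    channels = {}
    for name, ch in trial.channels.items():
        if ch.n >= 2:
            interp = PchipInterpolator(ch.times(), ch.values)
            vals = interp(grid)
        else:
            vals = np.full(grid.size, ch.values[0])
        channels[name] = Trace(vals, target_rate, float(grid[0]), ch.units)
    return Trial(channels=channels, meta=trial.meta, truth=trial.truth)
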