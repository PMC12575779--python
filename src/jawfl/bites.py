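"""In vivo bite segmentation and per-power-stroke feature extraction.

For each bite the pipeline reports seven response variables: integrated
rectified EMG (mV*s), fascicle length at power-stroke onset (L_MAX), at EMG
onset (L_ACT) and at peak force (L_MIN), the fascicle shortening strain over
the power stroke (T_ACT to T_MIN, in units of tetanic L_O), the force rise
magnitude and the peak force F_MAX.  Power strokes are delimited by an
EMG-onset detector (baseline mean + k*SD with a persistence requirement on
the envelope-smoothed rectified signal) and the post-onset force peak.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .conditioning import (
    CalibrationModel,
    FilterSpec,
    SonoConfig,
    apply_buckle_calibration,
    condition_emg,
    integrate_emg,
    resample_and_sync,
    sono_to_length,
)
from .core import Trace, Trial
from .errors import NoActivationError

__all__ = [
    "BiteFeatures",
    "BiteConfig",
    "detect_activation_onset",
    "segment_power_stroke",
    "extract_bite_features",
    "condition_bite_trial",
    "process_bite_trial",
]


@dataclass
class BiteFeatures:
    """The seven per-bite response variables plus derived quantities."""

    iEMG: float  # mV*s over [T_ACT, T_MIN]
    L_MAX: float  # mm, fascicle length at power-stroke onset
    L_ACT: float  # mm, fascicle length at EMG onset
    L_MIN: float  # mm, fascicle length at peak force
    strain_powerstroke: float  # (L@T_MIN - L@T_ACT)/L_O_tet, negative = shortening
    force_rise: float  # N, F_MAX - force at T_ACT
    F_MAX: float  # N
    T_ACT: float  # s
    T_MIN: float  # s
    L_O_tet: float  # mm, normalization used
    rel_L_MAX: float = 0.0  # L_MAX / L_O_tet
    rel_L_ACT: float = 0.0
    rel_L_MIN: float = 0.0
    subject: str = ""
    food: str = ""
    food_E: Optional[float] = None
    cycle_number: Optional[int] = None
    flags: list = field(default_factory=list)


@dataclass
class BiteConfig:
    """Detection and conditioning settings for bite processing."""

    onset_k: float = 3.0  # threshold multiplier on baseline SD
    onset_min_duration: float = 0.010  # s of persistence above threshold
    lmax_lead: float = 0.050  # s before T_ACT searched for the length peak
    force_smooth: float = 0.020  # s, moving average used to locate the force peak
    fmax_halfwidth: float = 0.010  # s, local mean half-width for the F_MAX readout
    peak_refine_halfwidth: float = 0.040  # s, local quadratic fit around the peak
    emg_filter: Optional[FilterSpec] = None  # hardware-filtered by default
    baseline_window: Optional[tuple] = None  # defaults to the pre-bite rest
    rest_window: Optional[tuple] = None  # force baseline window
    target_rate: float = 4000.0


def _envelope_smooth(values: np.ndarray, rate: float, duration: float) -> np.ndarray:
    """Centered moving average over ``duration`` seconds (envelope estimate)."""
    w = max(int(round(duration * rate)), 1)
    kernel = np.ones(w) / w
    return np.convolve(values, kernel, mode="same")


def detect_activation_onset(
    rectified_emg: Trace,
    baseline_window: tuple,
    k: float = 3.0,
    min_duration: float = 0.010,
) -> float:
    """First time the rectified EMG envelope exceeds baseline mean + k*SD.

    The threshold is baseline mean + ``k`` standard deviations of the raw
    rectified signal; the crossing is evaluated on an envelope-smoothed copy
    (moving average of width ``min_duration`` — a full-wave rectified
    interference signal crosses zero every few carrier periods, so a raw
    persistence test would never hold).  Because the smoothed baseline
    fluctuates far less than the raw rectified signal, this threshold also
    suppresses false positives from baseline noise.  The onset is the start
    of the first run that stays above threshold for ``min_duration``.
    """
    base = rectified_emg.window_values(*baseline_window)
    if base.size == 0:
        raise ValueError("empty baseline window")
    thr = float(np.mean(base)) + k * float(np.std(base))
    env = _envelope_smooth(rectified_emg.values, rectified_emg.rate, min_duration)
    above = env > thr
    # restrict the search to after the baseline window
    start_idx = rectified_emg.window_slice(*baseline_window).stop
    above[:start_idx] = False
    need = max(int(round(min_duration * rectified_emg.rate)), 1)
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= need:
            onset_idx = i - run + 1
            return rectified_emg.t0 + onset_idx / rectified_emg.rate
    raise NoActivationError("no activation detected: EMG never exceeded the onset threshold")


def segment_power_stroke(
    trial: Trial,
    T_ACT: float,
    force_channel: str = "force",
    search_window: Optional[tuple] = None,
    smooth_duration: float = 0.020,
) -> tuple:
    """Delimit the power stroke ``[T_ACT, T_MIN]``.

    ``T_MIN`` is the time of the calibrated-force peak after activation
    onset (optionally restricted to ``search_window`` when a trial contains
    more than one bite).  The peak is located on an envelope-smoothed copy
    of the force so that single noisy samples cannot pull it around.  A
    force that only decays after onset has no peak and is an error.
    """
    force = trial.channel(force_channel)
    t_end = search_window[1] if search_window else force.t_end
    t_start = max(T_ACT, search_window[0]) if search_window else T_ACT
    sl = force.window_slice(t_start, t_end)
    smoothed = (
        _envelope_smooth(force.values, force.rate, smooth_duration)
        if smooth_duration > 0
        else force.values
    )
    seg = smoothed[sl]
    ipk = int(np.argmax(seg))
    if ipk == 0:
        raise ValueError("no force peak after activation onset (force only decays)")
    T_MIN = force.t0 + (sl.start + ipk) / force.rate
    return (T_ACT, T_MIN)


def _refine_force_peak(force: Trace, T_MIN: float, cfg: "BiteConfig") -> tuple:
    """Refine the force-peak time and value with a local quadratic fit.

    A degree-2 least-squares fit over ``peak_refine_halfwidth`` around the
    preliminary peak averages the per-sample noise away; the vertex gives
    the peak time and force.  Falls back to a short local mean when the fit
    is not concave or its vertex leaves the window.
    """
    w = cfg.peak_refine_halfwidth
    if w > 0:
        t0 = max(T_MIN - w, force.t0)
        t1 = min(T_MIN + w, force.t_end)
        sl = force.window_slice(t0, t1)
        t = force.t0 + np.arange(sl.start, sl.stop) / force.rate
        y = force.values[sl]
        if t.size >= 5:
            a, b, c = np.polyfit(t - T_MIN, y, 2)
            if a < 0:
                dt = -b / (2 * a)
                if abs(dt) <= w:
                    return float(T_MIN + dt), float(c - b**2 / (4 * a))
    hw = cfg.fmax_halfwidth
    if hw > 0:
        F = float(
            np.mean(force.window_values(max(T_MIN - hw, force.t0), min(T_MIN + hw, force.t_end)))
        )
    else:
        F = float(force.value_at(T_MIN))
    return float(T_MIN), F


def extract_bite_features(
    trial: Trial,
    L_O_tet: float,
    config: Optional[BiteConfig] = None,
) -> BiteFeatures:
    """Extract the seven response variables from one conditioned bite trial.

    Expects channels ``emg`` (rectified mV), ``length`` (mm) and ``force``
    (N) on a common clock.  Strain and relative lengths use the tetanic
    optimal length of the same preparation.  The power-stroke onset for
    L_MAX is the fascicle-length maximum in ``[T_ACT - lead, T_MIN]`` — the
    fascicles typically reach peak length at bite onset, before EMG onset
    of this muscle, because other jaw adductors activate earlier.
    """
    cfg = config or BiteConfig()
    emg = trial.channel("emg")
    length = trial.channel("length")
    force = trial.channel("force")
    baseline = cfg.baseline_window or (emg.t0 + 0.02, emg.t0 + 0.30)
    T_ACT = detect_activation_onset(emg, baseline, cfg.onset_k, cfg.onset_min_duration)
    T_ACT_, T_MIN = segment_power_stroke(trial, T_ACT, smooth_duration=cfg.force_smooth)
    T_MIN, F_MAX = _refine_force_peak(force, T_MIN, cfg)
    iemg = integrate_emg(emg, (T_ACT, T_MIN))
    L_ACT = float(length.value_at(T_ACT))
    L_MIN = float(length.value_at(T_MIN))
    L_MAX = float(np.max(length.window_values(max(T_ACT - cfg.lmax_lead, length.t0), T_MIN)))
    F_at_onset = float(force.value_at(T_ACT))
    meta = trial.meta
    return BiteFeatures(
        iEMG=iemg,
        L_MAX=L_MAX,
        L_ACT=L_ACT,
        L_MIN=L_MIN,
        strain_powerstroke=(L_MIN - L_ACT) / L_O_tet,
        force_rise=F_MAX - F_at_onset,
        F_MAX=F_MAX,
        T_ACT=T_ACT,
        T_MIN=T_MIN,
        L_O_tet=L_O_tet,
        rel_L_MAX=L_MAX / L_O_tet,
        rel_L_ACT=L_ACT / L_O_tet,
        rel_L_MIN=L_MIN / L_O_tet,
        subject=meta.subject,
        food=meta.food.name if meta.food else "",
        food_E=meta.food.E if meta.food else None,
        cycle_number=meta.cycle_number,
    )


def condition_bite_trial(
    raw: Trial,
    calibration: CalibrationModel,
    sono_cfg: SonoConfig,
    config: Optional[BiteConfig] = None,
) -> Trial:
    """Raw in vivo trial -> conditioned trial (emg rectified, length mm, force N).

    Channels are synchronized and resampled to one clock, EMG is
    baseline-corrected and rectified (band-pass filtering optional), the
    sonomicrometry voltage is converted to smoothed fascicle length, and the
    buckle voltage is calibrated to force with rest-window baseline zeroing.
    """
    cfg = config or BiteConfig()
    synced = resample_and_sync(raw, cfg.target_rate)
    t0 = synced.channel("emg").t0
    baseline = cfg.baseline_window or (t0 + 0.02, t0 + 0.30)
    rest = cfg.rest_window or baseline
    emg = condition_emg(synced.channel("emg"), baseline, cfg.emg_filter)
    length = sono_to_length(synced.channel("sono_voltage"), sono_cfg)
    force = apply_buckle_calibration(synced.channel("buckle_voltage"), calibration, rest)
    channels = {"emg": emg, "length": length, "force": force}
    if synced.has_channel("gape"):
        channels["gape"] = synced.channel("gape")
    return Trial(channels=channels, meta=raw.meta, truth=raw.truth)


def process_bite_trial(
    raw: Trial,
    calibration: CalibrationModel,
    sono_cfg: SonoConfig,
    L_O_tet: float,
    config: Optional[BiteConfig] = None,
) -> BiteFeatures:
    """Convenience: condition a raw bite trial and extract its features."""
    conditioned = condition_bite_trial(raw, calibration, sono_cfg, config)
    return extract_bite_features(conditioned, L_O_tet, config)
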