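"""Synthetic muscle and recording generator with known ground truth.

Everything the downstream pipeline consumes — in situ ergometry ladders
(twitch and submaximal tetanic contractions at a series of set lengths),
buckle-calibration contraction pairs, and in vivo bite trials with
hardness-dependent activation — can be generated here from a
:class:`MuscleTruth` whose force-length curves, calibration constants and
bite features are known exactly.  That makes every analysis stage testable
by parameter recovery.

Model summary
-------------
* Active stress-strain curve: unimodal flat-topped exponential
  ``exp(-|eps/w|**p)`` with separate ascending/descending half-widths, peak
  at strain 0 (relative to tetanic optimal length ``L_O``).
* Twitch curve: the tetanic shape translated right by ``shift_pct`` percent
  of tetanic L_O and scaled by ``twitch_ratio`` — a pure plateau shift.
* Passive curve: monotone exponential in strain, zero at and below a slack
  strain (default -0.1).
* Fixed-end contraction: fascicles shorten against a series elastic element
  linearly in force, by ``series_compliance`` mm at peak tetanic force.
* EMG: band-limited zero-mean noise modulated by a burst envelope whose
  amplitude saturates with food hardness (Young's modulus E).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import filtfilt, firwin

from .core import FOODS, FoodItem, Trace, Trial, TrialMeta
from .errors import ConfigurationError

__all__ = [
    "TruncNormal",
    "GeneratorConfig",
    "MuscleTruth",
    "BiteParams",
    "make_muscle_truth",
    "simulate_ergometry_session",
    "simulate_calibration_pair",
    "simulate_bite_trial",
    "default_ladder",
    "truth_plateau_band",
]

IN_SITU_RATE = 4000.0  #: Hz, transducer digitization rate
SONO_RATE = 520.0  #: Hz, sonomicrometry acquisition rate


# ---------------------------------------------------------------------------
# population draws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruncNormal:
    """Normal distribution truncated to ``[lower, upper]`` by rejection.

    ``sd = 0`` degenerates to the mean (must lie inside the bounds).
    """

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def validate(self, name: str = "parameter") -> None:
        if self.sd < 0:
            raise ConfigurationError(f"{name}: negative SD")
        if not (self.lower <= self.mean <= self.upper):
            raise ConfigurationError(f"{name}: mean outside truncation bounds")

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return self.mean
        for _ in range(10_000):
            x = rng.normal(self.mean, self.sd)
            if self.lower <= x <= self.upper:
                return float(x)
        raise ConfigurationError("truncated-normal rejection failed; bounds too tight")


@dataclass
class GeneratorConfig:
    """Population distributions and noise levels for synthetic muscles.

    Distribution means/SDs describe the study population: optimal lengths
    and peak tetanic forces span the range seen across rat superficial
    masseter preparations; the twitch-to-tetanic force ratio is ~12 %, the
    twitch-vs-tetanic plateau shift ~11.3 +/- 2.9 % of tetanic L_O, PCSA
    ~0.51 +/- 0.12 cm2 and fixed-end series compliance ~0.7 +/- 0.2 mm.
    """

    L_O_tet: TruncNormal = field(default_factory=lambda: TruncNormal(7.2, 2.0, 3.5, 13.0))
    F_O_tet: TruncNormal = field(default_factory=lambda: TruncNormal(5.8, 1.3, 2.0, 10.0))
    shift_pct: TruncNormal = field(default_factory=lambda: TruncNormal(11.3, 2.9, 1e-6, 25.0))
    twitch_ratio: TruncNormal = field(default_factory=lambda: TruncNormal(0.123, 0.043, 0.03, 0.6))
    pcsa: TruncNormal = field(default_factory=lambda: TruncNormal(0.51, 0.12, 0.2, 1.0))
    segment_factor: TruncNormal = field(default_factory=lambda: TruncNormal(1.15, 0.05, 1.0, 1.5))
    # series stretch at peak force, as a fraction of fascicle optimal length:
    # ~0.7 mm at the population-mean L_O of 7.2 mm; tendinous compliance scales
    # with muscle size, so drawing it relative to L_O keeps every preparation
    # anatomically plausible
    series_compliance_rel: TruncNormal = field(
        default_factory=lambda: TruncNormal(0.097, 0.028, 0.0, 0.15)
    )
    buckle_slope: TruncNormal = field(default_factory=lambda: TruncNormal(0.02, 0.004, 0.005, 0.05))
    sono_gain: TruncNormal = field(default_factory=lambda: TruncNormal(5.0, 0.0, 1.0, 20.0))
    epoxy_offset_mm: float = 0.8

    # active curve shape: exp(-|eps/w|**p); half-widths in strain units
    active_w_ascending: float = 0.45
    active_w_descending: float = 0.40
    active_plateau_exp: float = 2.0

    # passive curve: scale*(exp(k*(eps - eps_slack)) - 1) above the slack strain
    passive_k: float = 5.0
    passive_slack_strain: float = -0.1
    passive_frac_at_025: float = 0.20  # passive stress at +25 % strain / peak active stress

    # base noise levels (multiplied by the ``noise`` argument of simulators)
    ergometry_force_sd_N: float = 0.01
    ergometry_length_sd_mm: float = 0.01
    calib_target_r2: float = 0.92
    calib_intercept_V: float = 0.05

    def validate(self) -> None:
        for name in (
            "L_O_tet",
            "F_O_tet",
            "shift_pct",
            "twitch_ratio",
            "pcsa",
            "segment_factor",
            "series_compliance_rel",
            "buckle_slope",
            "sono_gain",
        ):
            getattr(self, name).validate(name)
        if self.pcsa.mean <= 0 or (self.pcsa.sd > 0 and self.pcsa.lower <= 0):
            raise ConfigurationError("pcsa must be positive")
        if not (0 < self.twitch_ratio.mean < 1) or (
            self.twitch_ratio.sd > 0
            and (self.twitch_ratio.lower <= 0 or self.twitch_ratio.upper >= 1)
        ):
            raise ConfigurationError("twitch_ratio must lie strictly in (0, 1)")
        if self.active_w_ascending <= 0 or self.active_w_descending <= 0:
            raise ConfigurationError("active curve half-widths must be positive")
        if self.active_plateau_exp < 1:
            raise ConfigurationError("active plateau exponent must be >= 1")
        if not (0 < self.calib_target_r2 < 1):
            raise ConfigurationError("calib_target_r2 must be in (0, 1)")


# ---------------------------------------------------------------------------
# ground-truth curves
# ---------------------------------------------------------------------------


def active_shape(strain, w_asc: float, w_desc: float, p: float):
    """Unimodal active FL shape, 1 at strain 0, flat-topped for ``p`` > 2."""
    s = np.asarray(strain, dtype=float)
    w = np.where(s < 0, w_asc, w_desc)
    return np.exp(-np.abs(s / w) ** p)


def passive_curve(strain, k: float, slack: float, scale: float):
    """Monotone exponential passive stress, zero at and below the slack strain."""
    s = np.asarray(strain, dtype=float)
    out = scale * np.expm1(k * np.maximum(s - slack, 0.0))
    return out


@dataclass
class MuscleTruth:
    """Ground-truth parameters of one synthetic muscle preparation."""

    L_O_tet: float  # mm, tetanic fascicle optimal length
    shift_pct: float  # twitch optimum right of tetanic, % of tetanic L_O
    F_O_tet: float  # N, peak tetanic active force
    twitch_ratio: float  # twitch peak active force / tetanic
    pcsa: float  # cm2
    active_curve_params: dict  # w_asc, w_desc, p
    passive_curve_params: dict  # k, slack, scale (N/cm2)
    buckle_slope: float  # V per N
    buckle_intercept: float  # V
    sono_gain: float  # mm per V
    epoxy_offset: float  # mm
    segment_factor: float  # >= 1
    series_compliance: float  # mm of fascicle shortening at F_O_tet
    seed: int
    noise: dict = field(default_factory=dict)

    # -- derived quantities -------------------------------------------------

    @property
    def stress_O(self) -> float:
        """Peak tetanic active stress, N/cm2."""
        return self.F_O_tet / self.pcsa

    @property
    def L_O_twitch(self) -> float:
        return self.L_O_tet * (1.0 + self.shift_pct / 100.0)

    def strain(self, length_mm) -> np.ndarray:
        """Strain relative to tetanic L_O."""
        return (np.asarray(length_mm, dtype=float) - self.L_O_tet) / self.L_O_tet

    def active_stress(self, strain, protocol: str = "tetanic") -> np.ndarray:
        """Active stress (N/cm2) at a strain relative to tetanic L_O.

        The twitch curve is the tetanic shape translated right by the
        plateau shift and scaled by the twitch ratio.
        """
        p = self.active_curve_params
        if protocol == "tetanic":
            return self.stress_O * active_shape(strain, p["w_asc"], p["w_desc"], p["p"])
        if protocol == "twitch":
            s = np.asarray(strain, dtype=float) - self.shift_pct / 100.0
            return self.twitch_ratio * self.stress_O * active_shape(
                s, p["w_asc"], p["w_desc"], p["p"]
            )
        raise ConfigurationError(f"unknown protocol {protocol!r}")

    def passive_stress(self, strain) -> np.ndarray:
        p = self.passive_curve_params
        return passive_curve(strain, p["k"], p["slack"], p["scale"])

    def length_to_sono_voltage(self, length_mm) -> np.ndarray:
        """Inverse of the conditioning map length = (gain*V - epoxy)*segment."""
        L = np.asarray(length_mm, dtype=float)
        return (L / self.segment_factor + self.epoxy_offset) / self.sono_gain

    def force_to_buckle_voltage(self, force_N) -> np.ndarray:
        return self.buckle_slope * np.asarray(force_N, dtype=float) + self.buckle_intercept


def truth_plateau_band(truth: MuscleTruth, frac: float = 0.95) -> tuple:
    """Strain interval where the truth active curve is >= ``frac`` of its peak."""
    p = truth.active_curve_params
    half = (-math.log(frac)) ** (1.0 / p["p"])
    return (-p["w_asc"] * half, p["w_desc"] * half)


def make_muscle_truth(
    config: Optional[GeneratorConfig] = None, seed: int = 0
) -> MuscleTruth:
    """Draw one ground-truth muscle from the configured population.

    Deterministic for a fixed seed; all-zero SDs reproduce the configured
    means exactly.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    L_O = cfg.L_O_tet.draw(rng)
    F_O = cfg.F_O_tet.draw(rng)
    shift = cfg.shift_pct.draw(rng)
    ratio = cfg.twitch_ratio.draw(rng)
    pcsa = cfg.pcsa.draw(rng)
    seg = cfg.segment_factor.draw(rng)
    compliance = cfg.series_compliance_rel.draw(rng) * L_O
    slope = cfg.buckle_slope.draw(rng)
    gain = cfg.sono_gain.draw(rng)
    stress_O = F_O / pcsa
    passive_scale = (
        cfg.passive_frac_at_025
        * stress_O
        / math.expm1(cfg.passive_k * (0.25 - cfg.passive_slack_strain))
    )
    return MuscleTruth(
        L_O_tet=L_O,
        shift_pct=shift,
        F_O_tet=F_O,
        twitch_ratio=ratio,
        pcsa=pcsa,
        active_curve_params={
            "w_asc": cfg.active_w_ascending,
            "w_desc": cfg.active_w_descending,
            "p": cfg.active_plateau_exp,
        },
        passive_curve_params={
            "k": cfg.passive_k,
            "slack": cfg.passive_slack_strain,
            "scale": passive_scale,
        },
        buckle_slope=slope,
        buckle_intercept=cfg.calib_intercept_V,
        sono_gain=gain,
        epoxy_offset=cfg.epoxy_offset_mm,
        segment_factor=seg,
        series_compliance=compliance,
        seed=seed,
        noise={
            "ergometry_force_sd_N": cfg.ergometry_force_sd_N,
            "ergometry_length_sd_mm": cfg.ergometry_length_sd_mm,
            "calib_target_r2": cfg.calib_target_r2,
        },
    )


# ---------------------------------------------------------------------------
# in situ ergometry
# ---------------------------------------------------------------------------


def default_ladder(
    truth: MuscleTruth, n: int = 9, span: float = 0.25, protocol: str = "tetanic"
) -> np.ndarray:
    """Set-length ladder spanning ``+/- span`` strain about the plateau.

    The ladder is centered on the protocol's own optimum (the experimenter
    brackets the plateau by adding contractions until force drops on both
    sides), so twitch sessions extend to longer set lengths than tetanic
    sessions from the same preparation.  Because the fascicles shorten
    against the series elastic element during fixed-end contraction, each
    set length is raised by the series stretch expected at that point's
    peak force, so that the *fascicle* lengths at peak span the plateau —
    in practice the operator positions the motor while watching the
    sonomicrometry readout over consecutive contractions.
    """
    center = truth.L_O_tet if protocol == "tetanic" else truth.L_O_twitch
    L_desired = center * (1.0 + np.linspace(-span, span, n))
    eps = truth.strain(L_desired)
    F_peak = truth.pcsa * (
        truth.active_stress(eps, protocol) + truth.passive_stress(eps)
    )
    return L_desired + truth.series_compliance * F_peak / truth.F_O_tet


def _raised_cosine(t, t_start, duration):
    """0 -> 1 half-cosine ramp over ``duration`` starting at ``t_start``."""
    x = np.clip((t - t_start) / duration, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def _activation_profile(t, protocol: str, stim_on: float, stim_off: float):
    """Mechanical activation level in [0, 1]; reaches exactly 1 at its peak."""
    if protocol == "tetanic":
        rise = _raised_cosine(t, stim_on, 0.10)
        fall = 1.0 - _raised_cosine(t, stim_off, 0.08)
    else:  # twitch: brief pulse peaking at stim_on + 30 ms
        t_peak = stim_on + 0.030
        rise = _raised_cosine(t, stim_on, 0.030)
        fall = 1.0 - _raised_cosine(t, t_peak, 0.080)
    return rise * fall


def _solve_contraction(truth: MuscleTruth, protocol: str, L_set: float, a: np.ndarray):
    """Time-resolved fixed-end contraction against the series elastic element.

    Solves, per sample, the fixed point
    ``L = L_set - c * F(L) / F_O_tet`` with
    ``F(L) = pcsa * (a * active(L) + passive(L))`` by damped iteration.
    Returns (fascicle length mm, total force N).
    """
    c = truth.series_compliance
    L = np.full_like(a, float(L_set))
    F = np.zeros_like(a)
    for _ in range(300):
        eps = truth.strain(L)
        stress = a * truth.active_stress(eps, protocol) + truth.passive_stress(eps)
        F = truth.pcsa * stress
        L_new = L_set - c * F / truth.F_O_tet
        if np.max(np.abs(L_new - L)) < 1e-13:
            L = L_new
            break
        L = 0.5 * (L + L_new)
    return L, F


def simulate_ergometry_session(
    truth: MuscleTruth,
    lengths: Optional[Sequence[float]] = None,
    protocol: str = "tetanic",
    noise: float = 1.0,
    seed: int = 0,
    rate: float = IN_SITU_RATE,
) -> list:
    """Simulate one in situ FL ladder: one fixed-end contraction per set length.

    Each trial holds calibrated ``length`` (mm, fascicle) and ``force`` (N)
    channels plus a ``stim`` marker.  Tetanic trials use a 250 ms train,
    twitch trials a single brief stimulus.  With ``noise=0`` the peak force
    and fascicle length at peak reproduce the truth curves exactly.
    """
    if protocol not in ("tetanic", "twitch"):
        raise ConfigurationError(f"protocol must be twitch|tetanic, got {protocol!r}")
    if lengths is None:
        lengths = default_ladder(truth, protocol=protocol)
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size < 4:
        raise ConfigurationError(
            "ladder needs at least 4 set lengths (cubic fit is underdetermined)"
        )
    rng = np.random.default_rng(seed)
    stim_on = 0.30
    stim_off = stim_on + (0.250 if protocol == "tetanic" else 0.002)
    duration = 1.0
    t = np.arange(0.0, duration, 1.0 / rate)
    trials = []
    for i, L_set in enumerate(lengths):
        a = _activation_profile(t, protocol, stim_on, stim_off)
        L, F = _solve_contraction(truth, protocol, L_set, a)
        ipk = int(np.argmax(F))
        truth_block = {
            "set_length": float(L_set),
            "L_prestim": float(L[0]),
            "passive_prestim": float(F[0]),
            "L_at_peak": float(L[ipk]),
            "peak_force": float(F[ipk]),
            "protocol": protocol,
        }
        if noise:
            F = F + rng.normal(0.0, truth.noise["ergometry_force_sd_N"] * noise, F.size)
            L = L + rng.normal(0.0, truth.noise["ergometry_length_sd_mm"] * noise, L.size)
        stim = ((t >= stim_on) & (t < stim_off)).astype(float)
        trials.append(
            Trial(
                channels={
                    "length": Trace(L, rate, units="mm"),
                    "force": Trace(F, rate, units="N"),
                    "stim": Trace(stim, rate, units="0/1"),
                },
                meta=TrialMeta(
                    subject=f"sim{truth.seed}",
                    protocol=protocol,
                    cycle_number=i,
                    set_length=float(L_set),
                    stim_on=stim_on,
                    stim_off=stim_off,
                    response_end=min(stim_off + 0.25, duration - 1.0 / rate),
                ),
                truth=truth_block,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# buckle calibration contractions
# ---------------------------------------------------------------------------


def simulate_calibration_pair(
    truth: MuscleTruth,
    n_contractions: int = 5,
    noise: float = 1.0,
    seed: int = 0,
    rate: float = IN_SITU_RATE,
) -> list:
    """Paired buckle-voltage / motor-force calibration contractions at ~L_O.

    Buckle voltage is linear in force plus Gaussian noise whose level is set
    from the force excursion during the tetanic rise so that the per-pair
    regression r2 lands in the configured target band (default ~0.92).
    """
    if n_contractions < 2:
        raise ConfigurationError("need at least 2 calibration contractions")
    rng = np.random.default_rng(seed)
    stim_on, stim_off = 0.30, 0.60  # 300 ms contractions
    duration = 1.0
    t = np.arange(0.0, duration, 1.0 / rate)
    r2 = truth.noise.get("calib_target_r2", 0.92)
    trials = []
    for i in range(n_contractions):
        a = _activation_profile(t, "tetanic", stim_on, stim_off)
        _, F = _solve_contraction(truth, "tetanic", truth.L_O_tet, a)
        ipk = int(np.argmax(F))
        t_peak = t[ipk]
        V = truth.force_to_buckle_voltage(F)
        rise = slice(int(stim_on * rate), ipk + 1)
        sd_signal = truth.buckle_slope * float(np.std(F[rise]))
        sigma_v = sd_signal * math.sqrt(1.0 / r2 - 1.0)
        if noise:
            V = V + rng.normal(0.0, sigma_v * noise, V.size)
        trials.append(
            Trial(
                channels={
                    "buckle_voltage": Trace(V, rate, units="V"),
                    "force": Trace(F, rate, units="N"),
                },
                meta=TrialMeta(
                    subject=f"sim{truth.seed}",
                    protocol="calibration",
                    cycle_number=i,
                    stim_on=stim_on,
                    stim_off=stim_off,
                    response_end=t_peak,
                ),
                truth={
                    "buckle_slope": truth.buckle_slope,
                    "buckle_intercept": truth.buckle_intercept,
                    "rise_window": (stim_on, float(t_peak)),
                    "peak_force": float(F[ipk]),
                },
            )
        )
    return trials


# ---------------------------------------------------------------------------
# in vivo bite trials
# ---------------------------------------------------------------------------


@dataclass
class BiteParams:
    """Timing, gape, activation and hardness-mapping parameters of one bite.

    The hardness maps are saturating in Young's modulus E (half-saturation
    near a few MPa), so activation and operating length rise steeply over
    soft foods and plateau above ~20 MPa.  Harder food gives longer relative
    fascicle lengths and a smaller strain excursion.
    """

    duration: float = 1.5  # s
    rest_dur: float = 0.4  # s of quiet rest (baseline windows)
    open_dur: float = 0.25  # s of jaw opening
    close_dur: float = 0.25  # s of gape closing (power stroke inside)
    max_gape: float = 1.0  # a.u.
    final_gape: float = 0.0  # a.u.; must return near zero (occlusion)

    # EMG burst
    emg_amp_max: float = 2.0  # mV at full recruitment
    emg_amp_floor: float = 0.25  # fraction of amp_max at E -> 0
    emg_E50: float = 4.0  # MPa, half-saturation of recruitment
    emg_burst_dur: float = 0.22  # s
    emg_band: tuple = (50.0, 900.0)  # Hz, content band of the interference signal
    emg_baseline_sd: float = 0.01  # mV
    emg_rise: float = 0.02  # s, burst envelope attack
    emg_fall: float = 0.08  # s, burst envelope release

    # fascicle-length mapping (strains relative to tetanic L_O)
    strain_min_base: float = -0.02  # strain at peak force, E -> 0
    strain_min_span: float = 0.24  # added at full hardness saturation
    strain_E50: float = 8.0  # MPa
    excursion_base: float = 0.145  # L_ACT -> L_MIN strain drop, E -> 0
    excursion_drop: float = 0.08  # reduction at full saturation
    strain_jitter_sd: float = 0.012
    excursion_jitter_sd: float = 0.008
    amp_jitter_sd: float = 0.05  # multiplicative, on EMG amplitude

    # force law: F_MAX = force_per_iemg * iEMG * (1 + jitter)
    force_per_iemg: float = 17.0  # N per mV*s
    force_jitter_sd: float = 0.06
    buckle_noise_V: float = 0.001  # V, amplified strain-bridge output noise (RMS)
    sono_noise_mm: float = 0.02  # mm equivalent, on the sono voltage channel
    subject_gain: float = 1.0  # per-subject multiplier on EMG amplitude

    def hardness_saturation(self, E: float, E50: float) -> float:
        return E / (E + E50)

    def emg_amplitude(self, E: float) -> float:
        s = self.hardness_saturation(E, self.emg_E50)
        return self.emg_amp_max * (self.emg_amp_floor + (1 - self.emg_amp_floor) * s)

    def strain_at_peak_force(self, E: float) -> float:
        return self.strain_min_base + self.strain_min_span * self.hardness_saturation(
            E, self.strain_E50
        )

    def strain_excursion(self, E: float) -> float:
        return self.excursion_base - self.excursion_drop * self.hardness_saturation(
            E, self.strain_E50
        )


def _band_limited_noise(n: int, rate: float, band: tuple, rng: np.random.Generator):
    """Zero-mean unit-variance noise confined to ``band`` Hz."""
    white = rng.standard_normal(n + 400)
    taps = firwin(201, band, pass_zero=False, fs=rate)
    x = filtfilt(taps, [1.0], white)[200 : 200 + n]
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _burst_envelope(t, t_on, dur, rise, fall):
    """Fast-attack, slow-release envelope in [0, 1] supported on [t_on, t_on+dur]."""
    up = _raised_cosine(t, t_on, rise)
    down = 1.0 - _raised_cosine(t, t_on + dur - fall, fall)
    env = np.minimum(up, down)
    return np.clip(env, 0.0, 1.0)


def simulate_bite_trial(
    truth: MuscleTruth,
    food: FoodItem,
    gape_params: Optional[BiteParams] = None,
    noise: float = 1.0,
    seed: int = 0,
    rate: float = IN_SITU_RATE,
    sono_rate: float = SONO_RATE,
) -> Trial:
    """One in vivo incisor bite with hardness-dependent recruitment.

    Emits raw channels as acquired: ``emg`` (mV), ``sono_voltage`` (V, at
    the sonomicrometer rate), ``buckle_voltage`` (V), ``gape`` (a.u.) and a
    ``sync`` TTL marker, everything except sonomicrometry at the transducer
    rate.  The returned trial's ``truth`` block holds the realized feature
    values (onset time, lengths, peak force, integrated EMG) that feature
    extraction must recover.
    """
    p = gape_params or BiteParams()
    if not food.E > 0:
        raise ConfigurationError("food Young's modulus must be positive")
    if abs(p.final_gape) > 0.05 * p.max_gape:
        raise ConfigurationError(
            "gape cycle does not close (final gape > 5 % of max); no power stroke"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, p.duration, 1.0 / rate)
    n = t.size

    t_open = p.rest_dur
    t_close = t_open + p.open_dur  # start of gape closing
    t_occl = t_close + p.close_dur  # occlusion
    t_act = t_close + 0.030  # EMG onset
    t_peak = t_occl - 0.020  # peak force, near occlusion
    t_lmax = t_act - 0.020  # fascicle length peak (power-stroke onset)

    # gape trace: open then close (schematic, a.u.)
    gape = p.max_gape * (
        _raised_cosine(t, t_open, p.open_dur)
        - (1.0 - p.final_gape / p.max_gape) * _raised_cosine(t, t_close, p.close_dur)
    )

    # fascicle length trajectory through pchip control points (mm)
    E = food.E
    strain_min = p.strain_at_peak_force(E) + (
        rng.normal(0.0, p.strain_jitter_sd) if noise else 0.0
    )
    excursion = max(
        p.strain_excursion(E) + (rng.normal(0.0, p.excursion_jitter_sd) if noise else 0.0),
        0.02,
    )
    strain_max = strain_min + excursion
    L_O = truth.L_O_tet
    L_min = L_O * (1.0 + strain_min)
    L_max = L_O * (1.0 + strain_max)
    L_rest = L_O * (1.0 + strain_min + 0.35 * excursion)
    knots_t = [0.0, t_open, t_lmax, t_peak, t_peak + 0.25, p.duration]
    knots_L = [L_rest, L_rest, L_max, L_min, L_rest, L_rest]
    length = PchipInterpolator(knots_t, knots_L)(t)

    # EMG: modulated band-limited noise + baseline noise
    amp = p.emg_amplitude(E) * p.subject_gain
    if noise:
        amp *= 1.0 + rng.normal(0.0, p.amp_jitter_sd)
    env = _burst_envelope(t, t_act, p.emg_burst_dur, p.emg_rise, p.emg_fall)
    carrier = _band_limited_noise(n, rate, p.emg_band, rng)
    burst = amp * env * carrier
    emg = burst + (rng.normal(0.0, p.emg_baseline_sd, n) * noise if noise else 0.0)

    # realized ground-truth features over the power stroke [t_act, t_peak]
    win = (t >= t_act) & (t <= t_peak)
    iemg = float(np.trapezoid(np.abs(burst[win]), t[win]))
    F_max = p.force_per_iemg * iemg
    if noise:
        F_max *= 1.0 + rng.normal(0.0, p.force_jitter_sd)
    F_max = max(F_max, 0.0)

    # force trace: quiet, raised-cosine rise to F_max at t_peak, symmetric release
    t_f_on = t_act + 0.040
    rise_dur = t_peak - t_f_on
    force = F_max * _raised_cosine(t, t_f_on, rise_dur)
    force = np.where(
        t <= t_peak, force, F_max * (1.0 - _raised_cosine(t, t_peak, rise_dur))
    )

    i_act = int(round(t_act * rate))
    i_peak = int(round(t_peak * rate))
    L_act = float(length[i_act])
    L_at_peak = float(length[i_peak])
    truth_block = {
        "t_act": float(t[i_act]),
        "t_peak": float(t[i_peak]),
        "L_MAX": float(L_max),
        "L_ACT": L_act,
        "L_MIN": L_at_peak,
        "F_MAX": float(force[i_peak]),
        "iEMG": iemg,
        "strain_powerstroke": (L_at_peak - L_act) / L_O,
        "strain_at_Fmax": (L_at_peak - L_O) / L_O,
        "force_rise": float(force[i_peak] - force[i_act]),
        "region": _truth_region((L_at_peak - L_O) / L_O, truth),
        "emg_amplitude": amp,
        "food_E": E,
    }

    # raw acquired channels
    buckle = truth.force_to_buckle_voltage(force)
    if noise:
        buckle = buckle + rng.normal(0.0, p.buckle_noise_V * noise, n)
    t_sono = np.arange(0.0, p.duration, 1.0 / sono_rate)
    L_sono = PchipInterpolator(knots_t, knots_L)(t_sono)
    sono_v = truth.length_to_sono_voltage(L_sono)
    if noise:
        sono_v = sono_v + rng.normal(
            0.0, p.sono_noise_mm / (truth.sono_gain * truth.segment_factor) * noise,
            t_sono.size,
        )
    sync = ((t >= 0.05) & (t < 0.10)).astype(float)

    return Trial(
        channels={
            "emg": Trace(emg, rate, units="mV"),
            "sono_voltage": Trace(sono_v, sono_rate, units="V"),
            "buckle_voltage": Trace(buckle, rate, units="V"),
            "gape": Trace(gape, rate, units="a.u."),
            "sync": Trace(sync, rate, units="0/1"),
        },
        meta=TrialMeta(subject=f"sim{truth.seed}", protocol="in_vivo", food=food),
        truth=truth_block,
    )


def _truth_region(strain: float, truth: MuscleTruth, frac: float = 0.95) -> str:
    lo, hi = truth_plateau_band(truth, frac)
    if strain < lo:
        return "ascending"
    if strain > hi:
        return "descending"
    return "plateau"
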