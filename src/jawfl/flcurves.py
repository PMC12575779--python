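"""Force-length curve construction from in situ ergometry ladders.

Each contraction trial is reduced to a passive point (pre-stimulation
fascicle length, passive force) and an active point (fascicle length at the
force peak, total peak force).  Cubic polynomials are fit to the passive and
active data on the fascicle-length axis; the passive cubic evaluated at the
peak-force length corrects the active force for fascicle shortening during
fixed-end stimulation.  Optimal length ``L_O`` is the interior maximum of
the active cubic, ``F_O`` the cubic's value there, and strain/stress
normalization uses PCSA and the fitted ``L_O``.  The twitch-vs-tetanic
plateau shift is expressed as a percentage of tetanic L_O.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import MusclePrep, Trial
from .errors import ConfigurationError, NoInteriorOptimumError

__all__ = [
    "ContractionSummary",
    "FLCurve",
    "summarize_contraction",
    "compute_pcsa",
    "normalize_stress_strain",
    "fit_fl_polynomial",
    "find_optimal_length",
    "adjust_passive_for_shortening",
    "compute_plateau_shift",
    "fatigue_check",
    "build_fl_curve",
]


@dataclass
class ContractionSummary:
    """Peak/passive readout of one fixed-end contraction."""

    set_length: float  # mm (motor/servo set length)
    fascicle_length_prestim: float  # mm
    fascicle_length_at_peak: float  # mm
    passive_force: float  # N
    total_peak_force: float  # N
    active_force: float  # N (filled by passive adjustment)
    protocol: str
    flags: list = field(default_factory=list)


@dataclass
class FLCurve:
    """A fitted passive + active FL relationship for one protocol.

    Cubic coefficients are on the fascicle-length axis (mm -> stress in
    N/cm2), highest degree first.  ``L_O`` is the interior argmax of the
    active cubic over the fit range; ``F_O = stress_O * pcsa``.  For twitch
    curves ``L_O_ref`` may hold the same preparation's tetanic L_O so that
    strain can be expressed in tetanic units.
    """

    protocol: str
    lengths_active: np.ndarray
    stress_active: np.ndarray
    lengths_passive: np.ndarray
    stress_passive: np.ndarray
    cubic_coeffs_active: np.ndarray
    cubic_coeffs_passive: np.ndarray
    L_O: float  # mm
    F_O: float  # N
    stress_O: float  # N/cm2
    pcsa: float  # cm2
    fit_range: tuple  # (mm, mm)
    L_O_ref: Optional[float] = None
    from_motor_length: bool = False
    flags: list = field(default_factory=list)

    def strain(self, lengths, L_O_ref: Optional[float] = None) -> np.ndarray:
        L0 = L_O_ref if L_O_ref is not None else self.L_O
        return (np.asarray(lengths, dtype=float) - L0) / L0

    def active_stress_at_length(self, lengths) -> np.ndarray:
        return np.polyval(self.cubic_coeffs_active, np.asarray(lengths, dtype=float))

    def active_stress_at_strain(self, strain) -> np.ndarray:
        L = self.L_O * (1.0 + np.asarray(strain, dtype=float))
        return self.active_stress_at_length(L)

    def passive_stress_at_length(self, lengths) -> np.ndarray:
        return np.polyval(self.cubic_coeffs_passive, np.asarray(lengths, dtype=float))

    @property
    def strain_range(self) -> tuple:
        lo, hi = self.fit_range
        return ((lo - self.L_O) / self.L_O, (hi - self.L_O) / self.L_O)


def compute_pcsa(mass_g: float, theta_deg: float, Lf_cm: float, rho: float = 1.06) -> float:
    """Physiological cross-sectional area, cm2.

    ``pcsa = mass * cos(theta) / (rho * Lf)`` with muscle mass in g,
    pennation angle in degrees, fascicle length in cm and muscle density in
    g/cm3 (default 1.06, mammalian skeletal muscle).
    """
    if mass_g <= 0 or Lf_cm <= 0 or rho <= 0:
        raise ConfigurationError("mass, fascicle length and density must be positive")
    if not (0 <= theta_deg < 90):
        raise ConfigurationError("pennation angle must be in [0, 90) degrees")
    return mass_g * math.cos(math.radians(theta_deg)) / (rho * Lf_cm)


def summarize_contraction(
    trial: Trial,
    stim_window: Optional[tuple] = None,
    passive_window: Optional[tuple] = None,
    length_channel: str = "length",
) -> ContractionSummary:
    """Reduce one ergometry trial to passive and peak force/length readouts.

    Passive force and pre-stimulation fascicle length are means over a
    pre-stimulation window; the total peak force is the maximum inside the
    stimulation/response window and fascicle length is read at the sample
    of that peak.
    """
    force = trial.channel("force")
    length = trial.channel(length_channel)
    meta = trial.meta
    if stim_window is None:
        if meta.stim_on is None:
            raise ValueError("no stimulation window given and none in trial metadata")
        stim_window = (meta.stim_on, meta.response_end or meta.stim_off or force.t_end)
    if stim_window[0] < force.t0 or stim_window[1] > force.t_end + 1e-9:
        raise ValueError("stimulation window outside trial")
    if passive_window is None:
        passive_window = (force.t0 + 0.02, stim_window[0] - 0.02)
    flags = []
    sl = force.window_slice(*stim_window)
    seg = force.values[sl]
    ipk = int(np.argmax(seg)) + sl.start
    if ipk in (sl.start, sl.stop - 1):
        flags.append("peak_at_window_edge")
    passive_force = float(np.mean(force.window_values(*passive_window)))
    total_peak = float(force.values[ipk])
    L_pre = float(np.mean(length.window_values(*passive_window)))
    t_pk = force.t0 + ipk / force.rate
    L_pk = float(length.value_at(t_pk))
    return ContractionSummary(
        set_length=meta.set_length if meta.set_length is not None else L_pre,
        fascicle_length_prestim=L_pre,
        fascicle_length_at_peak=L_pk,
        passive_force=passive_force,
        total_peak_force=total_peak,
        active_force=total_peak - passive_force,  # naive; refined by passive adjustment
        protocol=meta.protocol,
        flags=flags,
    )


def normalize_stress_strain(force_N, length_mm, pcsa: float, L_O: float) -> tuple:
    """Express force as stress (N/cm2) and length as strain ((L-L_O)/L_O)."""
    if pcsa <= 0:
        raise ConfigurationError("pcsa must be positive")
    if L_O <= 0:
        raise ConfigurationError("L_O must be positive")
    stress = np.asarray(force_N, dtype=float) / pcsa
    strain = (np.asarray(length_mm, dtype=float) - L_O) / L_O
    return strain, stress


def fit_fl_polynomial(points: Sequence[tuple]) -> np.ndarray:
    """Least-squares cubic through ``(x, y)`` points, highest degree first.

    Requires at least four distinct abscissae; a rank-deficient design is an
    error rather than a silently truncated fit.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (x, y) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 4:
        raise ValueError("cubic fit needs at least 4 distinct x values")
    with warnings.catch_warnings():
        warnings.simplefilter("error", np.exceptions.RankWarning)
        try:
            coeffs = np.polyfit(x, y, 3)
        except np.exceptions.RankWarning as exc:  # pragma: no cover - defensive
            raise ValueError("rank-deficient cubic design") from exc
    return coeffs


def find_optimal_length(coeffs, fit_range: tuple) -> float:
    """Interior argmax of a cubic over ``fit_range``.

    Only interior critical points with negative second derivative qualify;
    a cubic that is monotone over the range (optimum at an edge) raises
    :class:`NoInteriorOptimumError` instead of being clamped, because an
    edge optimum means the length ladder failed to bracket the plateau.
    """
    lo, hi = fit_range
    if not hi > lo:
        raise ValueError("empty fit range")
    coeffs = np.asarray(coeffs, dtype=float)
    der = np.polyder(coeffs)
    der2 = np.polyder(der)
    roots = np.roots(der)
    best = None
    for r in roots:
        if abs(r.imag) > 1e-9:
            continue
        x = float(r.real)
        if not (lo + 1e-12 < x < hi - 1e-12):
            continue
        if np.polyval(der2, x) >= 0:
            continue
        y = float(np.polyval(coeffs, x))
        if best is None or y > best[1]:
            best = (x, y)
    if best is None:
        raise NoInteriorOptimumError(
            "active cubic has no interior maximum in the fit range; "
            "the length ladder does not bracket the FL plateau"
        )
    return best[0]


def adjust_passive_for_shortening(
    summaries: Sequence[ContractionSummary],
    passive_coeffs,
    passive_fit_range: Optional[tuple] = None,
) -> list:
    """Correct active force for fascicle shortening during stimulation.

    Active force is the total peak force minus the passive cubic evaluated
    at the fascicle length *at the force peak* (not at the pre-stimulation
    length): the fascicles shorten against the series elastic element, which
    lowers their passive contribution.  Summaries whose peak length lies
    outside the passive fit range are flagged as extrapolated.
    """
    out = []
    for s in summaries:
        L = s.fascicle_length_at_peak
        passive_at_peak = float(np.polyval(passive_coeffs, L))
        flags = list(s.flags)
        if passive_fit_range is not None and not (
            passive_fit_range[0] - 1e-9 <= L <= passive_fit_range[1] + 1e-9
        ):
            flags.append("passive_extrapolated")
        out.append(
            ContractionSummary(
                set_length=s.set_length,
                fascicle_length_prestim=s.fascicle_length_prestim,
                fascicle_length_at_peak=L,
                passive_force=s.passive_force,
                total_peak_force=s.total_peak_force,
                active_force=s.total_peak_force - passive_at_peak,
                protocol=s.protocol,
                flags=flags,
            )
        )
    return out


def compute_plateau_shift(L_O_twitch: float, L_O_tet: float) -> float:
    """Twitch-vs-tetanic optimum separation, percent of tetanic L_O.

    Positive values mean the tetanic plateau sits left of (shorter than)
    the twitch plateau.
    """
    if L_O_tet <= 0:
        raise ConfigurationError("tetanic L_O must be positive")
    return 100.0 * (L_O_twitch - L_O_tet) / L_O_tet


def fatigue_check(F_final_at_LO: float, F_O: float) -> bool:
    """Pass iff the preparation retained at least 90 % of F_O (inclusive)."""
    if F_O <= 0:
        raise ConfigurationError("F_O must be positive")
    return F_final_at_LO >= 0.9 * F_O


def build_fl_curve(
    trials: Sequence[Trial],
    prep: MusclePrep,
    protocol: str,
    L_O_ref: Optional[float] = None,
) -> FLCurve:
    """Build a passive + active FL curve from one ergometry ladder.

    Steps: summarize each contraction; fit the passive cubic to
    (pre-stimulation length, passive stress); correct active stress for
    shortening using the passive cubic at the peak-force length; fit the
    active cubic; locate ``L_O`` at its interior maximum and evaluate
    ``F_O`` there.  Deterministic given its inputs.
    """
    length_channel = "motor_length" if prep.use_motor_length else "length"
    summaries = [summarize_contraction(tr, length_channel=length_channel) for tr in trials]
    pcsa = prep.pcsa_cm2
    L_pre = np.array([s.fascicle_length_prestim for s in summaries])
    L_pk = np.array([s.fascicle_length_at_peak for s in summaries])
    passive_stress = np.array([s.passive_force for s in summaries]) / pcsa
    passive_coeffs = fit_fl_polynomial(np.column_stack([L_pre, passive_stress]))
    passive_range = (float(L_pre.min()), float(L_pre.max()))
    # pass force-axis passive cubic to the shortening adjustment
    adjusted = adjust_passive_for_shortening(
        summaries, passive_coeffs * pcsa, passive_range
    )
    active_stress = np.array([s.active_force for s in adjusted]) / pcsa
    active_coeffs = fit_fl_polynomial(np.column_stack([L_pk, active_stress]))
    fit_range = (float(L_pk.min()), float(L_pk.max()))
    L_O = find_optimal_length(active_coeffs, fit_range)
    stress_O = float(np.polyval(active_coeffs, L_O))
    flags = sorted({f for s in adjusted for f in s.flags})
    return FLCurve(
        protocol=protocol,
        lengths_active=L_pk,
        stress_active=active_stress,
        lengths_passive=L_pre,
        stress_passive=passive_stress,
        cubic_coeffs_active=active_coeffs,
        cubic_coeffs_passive=passive_coeffs,
        L_O=L_O,
        F_O=stress_O * pcsa,
        stress_O=stress_O,
        pcsa=pcsa,
        fit_range=fit_range,
        L_O_ref=L_O_ref,
        from_motor_length=prep.use_motor_length,
        flags=flags,
    )
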