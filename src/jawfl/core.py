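"""Shared containers for multichannel muscle recordings.

A :class:`Trace` is one uniformly sampled channel (values + rate + start time
+ units); a :class:`Trial` is a set of named, synchronized traces with trial
metadata (subject, food item, protocol) and, for synthetic data, a ground
truth block used by recovery tests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigurationError, MissingChannelError

__all__ = [
    "Trace",
    "FoodItem",
    "FOODS",
    "TrialMeta",
    "Trial",
    "MusclePrep",
]


@dataclass
class Trace:
    """One uniformly sampled channel.

    Parameters
    ----------
    values : array-like
        Sample values.
    rate : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    units : str
        Physical units of the values (e.g. ``"mV"``, ``"mm"``, ``"N"``).
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("Trace values must be one-dimensional")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def t_end(self) -> float:
        return self.t0 + (self.n - 1) / self.rate

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def index_at(self, t: float, clip: bool = True) -> int:
        """Index of the sample nearest to time ``t``."""
        i = int(round((t - self.t0) * self.rate))
        if clip:
            return min(max(i, 0), self.n - 1)
        if i < 0 or i >= self.n:
            raise ValueError(f"time {t} s outside trace [{self.t0}, {self.t_end}] s")
        return i

    def window_slice(self, t_start: float, t_end: float) -> slice:
        """Slice of samples whose times fall in ``[t_start, t_end]``."""
        if t_end < t_start:
            raise ValueError("inverted window")
        i0 = int(math.ceil((t_start - self.t0) * self.rate - 1e-9))
        i1 = int(math.floor((t_end - self.t0) * self.rate + 1e-9))
        i0 = max(i0, 0)
        i1 = min(i1, self.n - 1)
        if i1 < i0:
            raise ValueError(f"window [{t_start}, {t_end}] s contains no samples")
        return slice(i0, i1 + 1)

    def window_values(self, t_start: float, t_end: float) -> np.ndarray:
        return self.values[self.window_slice(t_start, t_end)]

    def value_at(self, t) -> np.ndarray:
        """Linear interpolation of the trace at time(s) ``t``."""
        return np.interp(t, self.times(), self.values)

    def copy_with(self, **changes) -> "Trace":
        return replace(self, **changes)


@dataclass(frozen=True)
class FoodItem:
    """A food item characterised by its Young's modulus ``E`` (MPa)."""

    name: str
    E: float

    def __post_init__(self):
        if not self.E > 0:
            raise ConfigurationError("food Young's modulus E must be positive")


#: Default four-item hardness ladder spanning soft to hard (E in MPa).
FOODS = {
    "raisin": FoodItem("raisin", 0.22),
    "cheese": FoodItem("cheese", 0.45),
    "almond": FoodItem("almond", 19.4),
    "chow": FoodItem("chow", 50.44),
}


@dataclass
class TrialMeta:
    """Trial-level metadata carried through the pipeline."""

    subject: str = ""
    protocol: str = "in_vivo"  # in_vivo | twitch | tetanic | calibration
    food: Optional[FoodItem] = None
    cycle_number: Optional[int] = None
    set_length: Optional[float] = None  # mm, in situ only
    stim_on: Optional[float] = None  # s
    stim_off: Optional[float] = None  # s
    response_end: Optional[float] = None  # s, end of force-response search window


@dataclass
class Trial:
    """A synchronized multichannel recording plus metadata.

    ``channels`` maps names such as ``"emg"``, ``"length"``, ``"force"``,
    ``"sono_voltage"``, ``"buckle_voltage"``, ``"gape"``, ``"stim"``,
    ``"sync"`` to :class:`Trace` objects.  Synthetic trials carry a ``truth``
    dict with the generator's ground-truth quantities.
    """

    channels: dict
    meta: TrialMeta = field(default_factory=TrialMeta)
    truth: Optional[dict] = None

    def channel(self, name: str) -> Trace:
        try:
            return self.channels[name]
        except KeyError:
            raise MissingChannelError(name, self.channels.keys()) from None

    def has_channel(self, name: str) -> bool:
        return name in self.channels


@dataclass
class MusclePrep:
    """Morphometrics and normalization constants of one muscle preparation.

    PCSA is in cm2 and divides force (N) to give stress (N/cm2).  The
    segment-correction factor is whole-fascicle length divided by the
    crystal-spanned length and multiplies sonomicrometry lengths.
    ``use_motor_length`` marks preparations whose FL data come from motor
    position rather than fascicle sonomicrometry.
    """

    mass_g: float = 0.0
    pennation_deg: float = 0.0
    fascicle_length_mm: float = 0.0
    density_g_cm3: float = 1.06
    pcsa_cm2: float = 0.0
    segment_factor: float = 1.0
    L_REF_mm: Optional[float] = None
    fixed_end_compliance_mm: float = 0.7
    use_motor_length: bool = False

    def __post_init__(self):
        if not self.pcsa_cm2 > 0:
            raise ConfigurationError("pcsa must be positive")
        if not (0 <= self.pennation_deg < 90):
            raise ConfigurationError("pennation angle must be in [0, 90) degrees")
        if self.segment_factor < 1:
            raise ConfigurationError("segment factor must be >= 1")
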