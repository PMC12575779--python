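"""Superimpose in vivo bite operating points on the in situ FL curve.

Each bite maps to a (strain at peak force, peak stress) point in the
coordinates of the preparation's submaximal tetanic FL curve and is
classified onto the ascending limb, plateau, or descending limb.  The
plateau is the strain interval where the fitted active cubic stays at or
above a configurable fraction (default 95 %) of F_O.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .flcurves import FLCurve

__all__ = [
    "OperatingPoint",
    "plateau_band",
    "classify_fl_region",
    "map_operating_points",
    "summarize_operating_ranges",
]


@dataclass
class OperatingPoint:
    """One bite's position on the stress-strain FL plane."""

    strain_at_Fmax: float
    peak_stress: float  # N/cm2
    region: str  # ascending | plateau | descending
    subject: str = ""
    food: str = ""
    food_E: Optional[float] = None
    extrapolated: bool = False
    flags: list = field(default_factory=list)


def plateau_band(curve: FLCurve, plateau_frac: float = 0.95) -> tuple:
    """Strain interval where the active cubic >= ``plateau_frac * stress_O``.

    Edges are the roots of ``cubic - plateau_frac*stress_O`` bracketing L_O,
    clipped to the fit range, returned in strain units of the curve's L_O.
    """
    if not (0 < plateau_frac < 1):
        raise ConfigurationError("plateau fraction must be in (0, 1)")
    thr = plateau_frac * curve.stress_O
    coeffs = np.asarray(curve.cubic_coeffs_active, dtype=float).copy()
    coeffs[-1] -= thr
    roots = [float(r.real) for r in np.roots(coeffs) if abs(r.imag) < 1e-9]
    lo_edge, hi_edge = curve.fit_range
    lower = [r for r in roots if r < curve.L_O]
    upper = [r for r in roots if r > curve.L_O]
    L_lo = max(lower) if lower else lo_edge
    L_hi = min(upper) if upper else hi_edge
    L_lo = max(L_lo, lo_edge)
    L_hi = min(L_hi, hi_edge)
    return ((L_lo - curve.L_O) / curve.L_O, (L_hi - curve.L_O) / curve.L_O)


def classify_fl_region(
    strain: float, curve: FLCurve, plateau_frac: float = 0.95
) -> tuple:
    """Classify a strain as ascending | plateau | descending.

    Returns ``(region, extrapolated)`` where ``extrapolated`` flags strains
    outside the curve's fitted strain range (classified anyway, never
    silently extrapolated).
    """
    lo, hi = plateau_band(curve, plateau_frac)
    s_lo, s_hi = curve.strain_range
    extrapolated = not (s_lo - 1e-12 <= strain <= s_hi + 1e-12)
    if strain < lo:
        region = "ascending"
    elif strain > hi:
        region = "descending"
    else:
        region = "plateau"
    return region, extrapolated


def map_operating_points(
    features: Sequence,
    curve: FLCurve,
    pcsa: Optional[float] = None,
    plateau_frac: float = 0.95,
) -> list:
    """Map bite features onto the tetanic FL curve as operating points.

    ``strain_at_Fmax = (L_MIN - L_O)/L_O`` and ``peak_stress = F_MAX/pcsa``;
    the curve must be the preparation's submaximal tetanic curve and its
    own L_O is the strain normalization.
    """
    if curve.protocol != "tetanic":
        raise ConfigurationError("operating points map onto the tetanic FL curve")
    pcsa = pcsa if pcsa is not None else curve.pcsa
    if not pcsa or pcsa <= 0:
        raise ConfigurationError("a positive pcsa is required to express stress")
    points = []
    for f in features:
        strain = (f.L_MIN - curve.L_O) / curve.L_O
        region, extrap = classify_fl_region(strain, curve, plateau_frac)
        points.append(
            OperatingPoint(
                strain_at_Fmax=strain,
                peak_stress=f.F_MAX / pcsa,
                region=region,
                subject=f.subject,
                food=f.food,
                food_E=f.food_E,
                extrapolated=extrap,
                flags=["extrapolated"] if extrap else [],
            )
        )
    return points


def summarize_operating_ranges(
    points: Sequence[OperatingPoint], group_by: str = "food"
) -> pd.DataFrame:
    """Per-group min/median/max strain and stress plus region counts."""
    if not points:
        raise ValueError("no operating points to summarize")
    df = pd.DataFrame(
        {
            "group": [getattr(p, group_by) for p in points],
            "food_E": [p.food_E for p in points],
            "strain": [p.strain_at_Fmax for p in points],
            "stress": [p.peak_stress for p in points],
            "region": [p.region for p in points],
        }
    )
    rows = []
    for name, g in df.groupby("group", sort=True):
        counts = g["region"].value_counts()
        rows.append(
            {
                "group": name,
                "food_E": g["food_E"].iloc[0],
                "n": len(g),
                "strain_min": g["strain"].min(),
                "strain_median": g["strain"].median(),
                "strain_max": g["strain"].max(),
                "stress_min": g["stress"].min(),
                "stress_median": g["stress"].median(),
                "stress_max": g["stress"].max(),
                "n_ascending": int(counts.get("ascending", 0)),
                "n_plateau": int(counts.get("plateau", 0)),
                "n_descending": int(counts.get("descending", 0)),
            }
        )
    return pd.DataFrame(rows).set_index("group")
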