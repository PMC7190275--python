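"""Trypsin-differential quantification of oxidized vs reduced cryptdins.

Oxidized cryptdins (three intramolecular disulfide bonds) resist tryptic
digestion; the disulfide-null reduced conformers are destroyed by trypsin.
Fecal extract is therefore run with (Trp+) and without (Trp-) trypsin
treatment: the Trp- band is total cryptdin, the Trp+ band is the oxidized
fraction, and the reduced amount is their difference.  Band intensities are
converted to ng via a standard curve from synthetic oxCrp1 lanes.

In acid-urea PAGE the reduced conformers migrate more slowly than the
oxidized Crp1 marker, so a band is called oxidized iff its mobility is at
least the marker's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

__all__ = [
    "DensitometryRecord",
    "CrpQuantification",
    "MobilityCall",
    "StandardCurve",
    "fit_standard_curve",
    "quantify_lane",
    "resolve_conformers",
    "call_conformer",
    "quantify_record",
]


@dataclass(frozen=True)
class DensitometryRecord:
    """Band intensities for one fecal sample (arbitrary densitometry units)."""

    sample_id: str
    standard_ng: float
    standard_intensity: float
    trp_minus_intensity: float
    trp_plus_intensity: float
    feces_mass_normalizer: float = 500.0  # ug feces the ng amounts refer to

    def __post_init__(self) -> None:
        if self.standard_ng <= 0 or self.standard_intensity <= 0:
            raise ValueError("standard lane must have positive ng and intensity")
        if self.trp_minus_intensity < 0 or self.trp_plus_intensity < 0:
            raise ValueError("lane intensities must be >= 0")


@dataclass(frozen=True)
class CrpQuantification:
    sample_id: str
    ox_ng: float
    r_ng: float
    negative_r_flag: bool

    @property
    def total_ng(self) -> float:
        return self.ox_ng + self.r_ng


@dataclass(frozen=True)
class MobilityCall:
    band_id: str
    relative_mobility: float
    conformer: Literal["oxidized", "reduced"]


@dataclass(frozen=True)
class StandardCurve:
    """Linear-through-origin densitometry calibration: ng = slope * intensity."""

    slope: float  # ng per intensity unit

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope) or self.slope <= 0:
            raise ValueError("standard-curve slope must be finite and > 0")


def fit_standard_curve(records: Sequence[tuple[float, float]]) -> StandardCurve:
    """Least-squares through-origin fit of intensity -> ng.

    With a single standard point the slope is exactly ng/intensity; with
    several, slope = sum(x*y)/sum(x^2) with x = intensity, y = ng.
    """
    if not records:
        raise ValueError("need at least one standard point")
    sxy = sxx = 0.0
    for ng, intensity in records:
        if ng <= 0 or intensity < 0:
            raise ValueError("standard points need ng > 0 and intensity >= 0")
        sxy += intensity * ng
        sxx += intensity * intensity
    if sxx == 0.0:
        raise ValueError("all standard intensities are zero; cannot calibrate")
    return StandardCurve(sxy / sxx)


def quantify_lane(intensity: float, curve: StandardCurve) -> float:
    if intensity < 0 or not math.isfinite(intensity):
        raise ValueError(f"lane intensity must be finite and >= 0, got {intensity}")
    return curve.slope * intensity


def resolve_conformers(
    trp_minus_ng: float, trp_plus_ng: float, sample_id: str = ""
) -> CrpQuantification:
    """Split total cryptdin into conformers by trypsin sensitivity.

    ox = Trp+ amount, total = Trp- amount, r = total - ox.  A negative r
    (measurement noise when true r ~ 0) is retained unclamped and flagged so
    group means stay unbiased.
    """
    for name, v in (("trp_minus_ng", trp_minus_ng), ("trp_plus_ng", trp_plus_ng)):
        if not math.isfinite(v) or v < 0:
            raise ValueError(f"{name} must be finite and >= 0, got {v}")
    r = trp_minus_ng - trp_plus_ng
    return CrpQuantification(sample_id, trp_plus_ng, r, negative_r_flag=r < 0)


def call_conformer(
    band_mobility: float, ox_marker_mobility: float, band_id: str = ""
) -> MobilityCall:
    """Call a band's conformer from its AU-PAGE mobility vs the oxCrp1 marker.

    The marker line itself belongs to the oxidized zone; anything slower is
    reduced.
    """
    for name, v in (("band_mobility", band_mobility), ("ox_marker_mobility", ox_marker_mobility)):
        if not math.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and > 0, got {v}")
    conformer = "oxidized" if band_mobility >= ox_marker_mobility else "reduced"
    return MobilityCall(band_id, band_mobility, conformer)


def quantify_record(rec: DensitometryRecord) -> CrpQuantification:
    """Full per-sample pipeline: standard curve -> lane ng -> conformer split."""
    curve = fit_standard_curve([(rec.standard_ng, rec.standard_intensity)])
    total = quantify_lane(rec.trp_minus_intensity, curve)
    ox = quantify_lane(rec.trp_plus_intensity, curve)
    return resolve_conformers(total, ox, rec.sample_id)
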