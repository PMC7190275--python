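"""Control-calibrated ileal inflammatory scoring.

Each well-orientated crypt-villus axis of a rolled ileal section is graded
0-3 in three categories: (a) inflammatory infiltration (inflammatory cells
in the lamina propria), (b) villus distortion (villus length / crypt depth),
and (c) thickening of the muscle layer.  The score-0 band is calibrated on
the control strain (mean +/- 2 SD for the two "upper" categories, mean +/-
0.5 for the villus/crypt ratio), and the range between the band edge and the
most extreme diseased-strain value is split into three equal-width bins
mapping to scores 1, 2 and 3.  A mouse's category score is the mean of its
axis scores; crypt abscesses contribute 0.5 each; the total is the sum of
the four components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "AxisMeasurement",
    "SectionMeasurements",
    "CalibrationBins",
    "InflammatoryScore",
    "DegenerateCalibrationError",
    "calibrate_upper",
    "calibrate_lower",
    "score_axis",
    "score_mouse",
    "count_abnormal_cells",
    "PER_AXIS_CATEGORIES",
]

PER_AXIS_CATEGORIES = ("infiltration", "villus_distortion", "muscle")


class DegenerateCalibrationError(ValueError):
    """Raised when the control cohort cannot define a score-0 band (SD = 0)."""


@dataclass(frozen=True)
class AxisMeasurement:
    """Measurements for one crypt-villus axis (axis 1 is the most distal)."""

    axis_index: int
    inflammatory_cells: float
    villus_length: float  # um
    crypt_depth: float  # um
    muscle_thickness: float  # um

    def __post_init__(self) -> None:
        if self.inflammatory_cells < 0:
            raise ValueError("inflammatory_cells must be >= 0")
        for name in ("villus_length", "crypt_depth", "muscle_thickness"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def villus_ratio(self) -> float:
        return self.villus_length / self.crypt_depth

    def value(self, category: str) -> float:
        if category == "infiltration":
            return self.inflammatory_cells
        if category == "villus_distortion":
            return self.villus_ratio
        if category == "muscle":
            return self.muscle_thickness
        raise KeyError(category)


@dataclass(frozen=True)
class SectionMeasurements:
    """All scored axes of one mouse's section plus the section-wide abscess count."""

    mouse_id: str
    axes: Sequence[AxisMeasurement]
    crypt_abscess_count: int = 0
    eosinophilic_positive_cells_per_axis: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if not 1 <= len(self.axes) <= 10:
            raise ValueError("a section must contribute 1-10 crypt-villus axes")
        if self.crypt_abscess_count < 0:
            raise ValueError("crypt_abscess_count must be >= 0")


@dataclass(frozen=True)
class CalibrationBins:
    """Score-0 band and the trisected graded range for one category.

    For ``direction == "upper"`` disease is an increase: the graded range runs
    from the zero band's upper edge up to the diseased-cohort maximum, bins
    half-open ``(low, high]``.  For ``direction == "lower"`` disease is a
    decrease (villus/crypt ratio): the graded range runs from the diseased
    minimum up to the band's lower edge, bins ``[low, high)``, with bins
    nearer the diseased extremum scoring higher.  ``degenerate`` marks the
    case where no diseased value lies beyond the band; any out-of-band value
    in the disease direction then scores 3.
    """

    category: str
    direction: Literal["upper", "lower"]
    zero_band: tuple[float, float]
    bin_edges: tuple[float, ...]  # 4 edges delimiting bins 1,2,3; empty if degenerate
    control_mean: float
    control_sd: float
    case_extremum: float
    degenerate: bool = False

    def score(self, value: float) -> int:
        if not math.isfinite(value):
            raise ValueError(f"non-finite measurement for {self.category}: {value}")
        lo, hi = self.zero_band
        if lo <= value <= hi:
            return 0
        if self.direction == "upper":
            if value <= hi:  # healthy direction (below the band)
                return 0
            if self.degenerate or value > self.case_extremum:
                return 3
            e = self.bin_edges
            for k in (1, 2, 3):
                if e[k - 1] < value <= e[k]:
                    return k
            return 3  # numerically on the outer edge
        # lower direction: disease is a decrease
        if value >= lo:
            return 0
        if self.degenerate or value < self.case_extremum:
            return 3
        e = self.bin_edges  # ascending: case_min .. band lower edge
        for k, score in ((0, 3), (1, 2), (2, 1)):
            if e[k] <= value < e[k + 1]:
                return score
        return 3


@dataclass(frozen=True)
class InflammatoryScore:
    mouse_id: str
    category_scores: Mapping[str, float]
    abscess_score: float
    total: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "total", sum(self.category_scores.values()) + self.abscess_score
        )


def _check_cohorts(control_values: Sequence[float], case_values: Sequence[float]) -> None:
    if len(control_values) < 2:
        raise ValueError("need >= 2 control values to calibrate")
    if len(case_values) < 1:
        raise ValueError("need >= 1 diseased-cohort value to calibrate")
    for vals, name in ((control_values, "control"), (case_values, "case")):
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite {name} values in calibration input")


def calibrate_upper(
    control_values: Sequence[float],
    case_values: Sequence[float],
    k_sd: float = 2.0,
    category: str = "infiltration",
) -> CalibrationBins:
    """Calibrate a category where disease increases the measurement.

    Zero band is control ``mean +/- k_sd * SD`` (sample SD, n-1); the range
    from the band's upper edge to the diseased maximum is split into three
    equal-width bins scoring 1, 2, 3.
    """
    _check_cohorts(control_values, case_values)
    m = float(np.mean(control_values))
    s = float(np.std(control_values, ddof=1))
    if s == 0.0:
        raise DegenerateCalibrationError(
            f"{category}: control SD is 0; cannot define a score-0 band"
        )
    hi = m + k_sd * s
    case_max = float(np.max(case_values))
    if case_max <= hi:
        return CalibrationBins(category, "upper", (m - k_sd * s, hi), (), m, s, case_max, True)
    edges = tuple(np.linspace(hi, case_max, 4))
    return CalibrationBins(category, "upper", (m - k_sd * s, hi), edges, m, s, case_max)


def calibrate_lower(
    control_values: Sequence[float],
    case_values: Sequence[float],
    offset: float = 0.5,
    category: str = "villus_distortion",
) -> CalibrationBins:
    """Calibrate the villus/crypt ratio, where disease decreases the value.

    Zero band is control ``mean +/- offset``; the range from the diseased
    minimum up to the band's lower edge is split into three equal-width bins,
    the bin nearest the diseased minimum scoring 3.
    """
    _check_cohorts(control_values, case_values)
    m = float(np.mean(control_values))
    s = float(np.std(control_values, ddof=1))
    lo = m - offset
    case_min = float(np.min(case_values))
    if case_min >= lo:
        return CalibrationBins(category, "lower", (lo, m + offset), (), m, s, case_min, True)
    edges = tuple(np.linspace(case_min, lo, 4))
    return CalibrationBins(category, "lower", (lo, m + offset), edges, m, s, case_min)


def score_axis(
    m: AxisMeasurement, bins_by_category: Mapping[str, CalibrationBins]
) -> dict[str, int]:
    """Grade one axis 0-3 in every calibrated per-axis category."""
    missing = [c for c in PER_AXIS_CATEGORIES if c not in bins_by_category]
    if missing:
        raise ValueError(f"missing calibrations for categories: {missing}")
    return {c: bins_by_category[c].score(m.value(c)) for c in PER_AXIS_CATEGORIES}


def score_mouse(
    section: SectionMeasurements, bins_by_category: Mapping[str, CalibrationBins]
) -> InflammatoryScore:
    """Per-mouse score: mean axis score per category + 0.5 per crypt abscess."""
    axis_scores = [score_axis(a, bins_by_category) for a in section.axes]
    cat = {
        c: float(np.mean([s[c] for s in axis_scores])) for c in PER_AXIS_CATEGORIES
    }
    return InflammatoryScore(section.mouse_id, cat, 0.5 * section.crypt_abscess_count)


def count_abnormal_cells(section: SectionMeasurements) -> float | None:
    """Mean eosinophilic granule-positive (abnormal Paneth) cells per axis.

    Returns None when counts were not recorded -- an absent measurement is
    never reported as zero cells.
    """
    counts = section.eosinophilic_positive_cells_per_axis
    if counts is None or len(counts) == 0:
        return None
    return float(np.mean(counts))
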