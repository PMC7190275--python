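"""Deterministic aggregations for TEM, enteroid-secretion and killing assays."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PanethCellTEM",
    "SecretionMeasurement",
    "KillingAssayWell",
    "er_lumen_diameter",
    "secretion_percent",
    "survival_rate",
]

N_CISTERNAE = 5  # protocol: five ER cisternae per Paneth cell, nearest the nucleus first


@dataclass(frozen=True)
class PanethCellTEM:
    cell_id: str
    mouse_id: str
    granule_count: int
    cisterna_widths: Sequence[float]  # um, most expanded part of each cisterna

    def __post_init__(self) -> None:
        if len(self.cisterna_widths) != N_CISTERNAE:
            raise ValueError(
                f"expected {N_CISTERNAE} cisterna widths per cell, "
                f"got {len(self.cisterna_widths)}"
            )
        if any(w <= 0 for w in self.cisterna_widths):
            raise ValueError("cisterna widths must be > 0")
        if self.granule_count < 0:
            raise ValueError("granule_count must be >= 0")


@dataclass(frozen=True)
class SecretionMeasurement:
    cell_id: str
    pre_area: float  # um^2, granule area before stimulation
    post_area: float  # um^2, after

    def __post_init__(self) -> None:
        if self.pre_area < 0 or self.post_area < 0:
            raise ValueError("areas must be >= 0")


@dataclass(frozen=True)
class KillingAssayWell:
    peptide: str
    conformer: str
    concentration: float  # uM
    cfu_treated: int
    cfu_control: int

    def __post_init__(self) -> None:
        if self.cfu_treated < 0 or self.cfu_control < 0:
            raise ValueError("CFU counts must be >= 0")


def er_lumen_diameter(
    cells: Sequence[PanethCellTEM],
) -> tuple[dict[str, float], dict[str, float]]:
    """ER lumen diameter per cell (mean of its 5 widths) and per mouse.

    Returns ``(per_cell, per_mouse)`` where the per-mouse value is the mean
    of that mouse's per-cell means.
    """
    if not cells:
        raise ValueError("need at least one cell")
    per_cell = {c.cell_id: float(np.mean(c.cisterna_widths)) for c in cells}
    by_mouse: dict[str, list[float]] = {}
    for c in cells:
        by_mouse.setdefault(c.mouse_id, []).append(per_cell[c.cell_id])
    per_mouse = {m: float(np.mean(v)) for m, v in by_mouse.items()}
    return per_cell, per_mouse


def secretion_percent(m: SecretionMeasurement) -> float:
    """Percent granule area lost on stimulation: 100 * (pre - post) / pre.

    Negative when the measured area grows; not clamped.
    """
    if m.pre_area == 0:
        raise ValueError("pre-stimulation area must be > 0")
    return 100.0 * (m.pre_area - m.post_area) / m.pre_area


def survival_rate(well: KillingAssayWell) -> float:
    """Bacterial survival as percent of the peptide-unexposed control.

    May exceed 100% (growth during incubation); not clamped.
    """
    if well.cfu_control == 0:
        raise ValueError("control CFU must be > 0 for a valid survival rate")
    return 100.0 * well.cfu_treated / well.cfu_control
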