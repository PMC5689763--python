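"""Serial-section extrapolation: Cavalieri volumes, cell totals, densities.

The sampling scheme follows standard FFPE serial sectioning: 10 um
sections, slides in groups of ten, one analyzed section representing
each 200 um of tissue.  Volumes use the Cavalieri principle (section
area times inter-analysis spacing, summed); cell counts are
extrapolated by the spacing/thickness factor (20 by default) and
summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
import logging

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SamplingScheme",
    "BrainQuant",
    "cavalieri_volume",
    "extrapolate_counts",
    "whole_tumor_coverage",
    "nsc_density",
    "UM3_PER_MM3",
]

UM3_PER_MM3 = 1e9
UM_PER_MM = 1e3

#: Density range typically seen for NSCs homing to engrafted glioma
#: (per mm^3); values outside it are logged, not rejected.
DENSITY_SANITY_BAND = (1e3, 1e6)


@dataclass(frozen=True)
class SamplingScheme:
    """Serial-section sampling parameters (um)."""

    section_thickness_um: float = 10.0
    analysis_spacing_um: float = 200.0
    slides_per_group: int = 10

    def __post_init__(self) -> None:
        if self.section_thickness_um <= 0 or self.analysis_spacing_um <= 0:
            raise ValueError("thickness and spacing must be positive")
        ratio = self.analysis_spacing_um / self.section_thickness_um
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "analysis_spacing_um must be a positive multiple of "
                "section_thickness_um"
            )

    @property
    def count_factor(self) -> float:
        """Sections represented by each analyzed section (spacing/thickness)."""
        return self.analysis_spacing_um / self.section_thickness_um


@dataclass
class BrainQuant:
    """Per-animal aggregates over the serial-section stack."""

    brain_id: str
    tumor_volume_mm3: float
    total_nsc_count: float
    administered_nsc_count: float
    route: str = "ic"
    whole_tumor_coverage_pct: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.route not in ("ic", "iv"):
            raise ValueError("route must be 'ic' or 'iv'")

    @property
    def pct_at_tumor(self) -> float:
        """NSCs found at the tumor as percent of the administered dose."""
        if self.administered_nsc_count <= 0:
            raise ValueError("administered dose must be positive")
        return 100.0 * self.total_nsc_count / self.administered_nsc_count

    @property
    def nsc_density_per_mm3(self) -> float:
        return nsc_density(self.total_nsc_count, self.tumor_volume_mm3)


def cavalieri_volume(
    section_areas_um2: Sequence[float], scheme: SamplingScheme = SamplingScheme()
) -> float:
    """Cavalieri volume in mm^3 from ordered per-section areas (um^2).

    Each analyzed area is extrapolated over the analysis spacing; no
    end correction is applied.  An empty list yields 0.
    """
    areas = np.asarray(section_areas_um2, dtype=float)
    if areas.size == 0:
        return 0.0
    if np.any(areas < 0):
        raise ValueError("section areas must be non-negative")
    return float(areas.sum() * scheme.analysis_spacing_um / UM3_PER_MM3)


def extrapolate_counts(
    section_counts: Sequence[float], scheme: SamplingScheme = SamplingScheme()
) -> float:
    """Whole-stack cell total from per-analyzed-section counts.

    Each count is multiplied by spacing/thickness (each analyzed
    section stands for that many contiguous sections) and summed.
    """
    counts = np.asarray(section_counts, dtype=float)
    if counts.size == 0:
        return 0.0
    if np.any(counts < 0):
        raise ValueError("section counts must be non-negative")
    return float(counts.sum() * scheme.count_factor)


def whole_tumor_coverage(
    section_coverages_pct: Sequence[float] | Sequence[Mapping[float, float]],
    tumor_areas_um2: Sequence[float],
) -> float | dict[float, float]:
    """Area-weighted mean of per-section coverage.

    Accepts either one coverage value per section, or one
    {radius: percent} mapping per section (returning a mapping).
    """
    areas = np.asarray(tumor_areas_um2, dtype=float)
    if len(section_coverages_pct) != len(areas):
        raise ValueError("coverage and area lists must be matched by depth")
    total = areas.sum()
    if total <= 0:
        raise ValueError("whole-tumor coverage undefined for zero total area")
    first = section_coverages_pct[0]
    if isinstance(first, Mapping):
        radii = list(first.keys())
        return {
            r: float(
                sum(c[r] * a for c, a in zip(section_coverages_pct, areas)) / total
            )
            for r in radii
        }
    cov = np.asarray(section_coverages_pct, dtype=float)
    return float((cov * areas).sum() / total)


def nsc_density(total_count: float, tumor_volume_mm3: float) -> float:
    """NSCs per mm^3 of tumor; logs counts outside the usual band."""
    if tumor_volume_mm3 <= 0:
        raise ValueError("density undefined for zero tumor volume")
    density = total_count / tumor_volume_mm3
    lo, hi = DENSITY_SANITY_BAND
    if density > 0 and not lo <= density <= hi:
        logger.info(
            "NSC density %.3g per mm^3 outside the typical %g-%g band",
            density,
            lo,
            hi,
        )
    return density
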