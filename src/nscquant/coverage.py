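"""Percent tumor coverage within a radius of action of NSC regions.

A diffusible therapeutic secreted by NSCs is assumed effective out to
a fixed radius of action r (25 or 50 um here).  A tumor pixel is
covered when the Euclidean distance from its center to the nearest
NSC-marked pixel center is <= r; coverage is the covered fraction of
all tumor pixels, in percent.  The implementation thresholds the exact
Euclidean distance transform of the NSC-mask complement, which is
pixel-for-pixel identical to a brute-force nearest-NSC-pixel search.

Also provided: the theoretical maximum coverage for n cells spread
homogeneously through the tumor (non-overlapping effective disks), and
the coverage efficiency observed/theoretical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage

from .stains import BinaryMask

__all__ = [
    "CoverageParams",
    "coverage_fraction",
    "coverage_by_radii",
    "disk_union_coverage",
    "theoretical_max_coverage",
    "coverage_efficiency",
    "render_overlay",
    "DEFAULT_RADII_UM",
    "DEFAULT_CELL_RADIUS_UM",
]

#: Radii of action evaluated by default (um).
DEFAULT_RADII_UM = (25.0, 50.0)
#: Equivalent NSC radius for the homogeneous-distribution maximum,
#: from 8-10 um cell diameters.
DEFAULT_CELL_RADIUS_UM = 4.5


@dataclass(frozen=True)
class CoverageParams:
    """Radius of action and equivalent cell radius, both in um."""

    radius_um: float = 50.0
    cell_radius_um: float = DEFAULT_CELL_RADIUS_UM

    def __post_init__(self) -> None:
        if self.radius_um < 0 or self.cell_radius_um < 0:
            raise ValueError("radii must be non-negative")


def _check_pair(nsc_mask: BinaryMask, tumor_mask: BinaryMask) -> None:
    if nsc_mask.mask.shape != tumor_mask.mask.shape:
        raise ValueError("NSC and tumor masks must share a shape")
    if nsc_mask.pixel_size_um != tumor_mask.pixel_size_um:
        raise ValueError("NSC and tumor masks must share a pixel size")
    if not tumor_mask.mask.any():
        raise ValueError("coverage is undefined for an empty tumor mask")


def nsc_distance_map(nsc_mask: BinaryMask) -> np.ndarray:
    """Distance (um) from each pixel center to the nearest NSC pixel center.

    Infinite where the NSC mask is empty.
    """
    if not nsc_mask.mask.any():
        return np.full(nsc_mask.mask.shape, np.inf)
    dist_px = ndimage.distance_transform_edt(~nsc_mask.mask)
    return dist_px * nsc_mask.pixel_size_um


def coverage_fraction(
    nsc_mask: BinaryMask,
    tumor_mask: BinaryMask,
    params: CoverageParams | float = CoverageParams(),
) -> float:
    """Percent of tumor pixels within the radius of action of any NSC pixel.

    An empty NSC mask yields 0% (sections are evaluated whether or not
    NSCs are present); an empty tumor mask is an error.
    """
    radius = params.radius_um if isinstance(params, CoverageParams) else float(params)
    _check_pair(nsc_mask, tumor_mask)
    if not nsc_mask.mask.any():
        return 0.0
    dist = nsc_distance_map(nsc_mask)
    covered = tumor_mask.mask & (dist <= radius)
    return 100.0 * covered.sum() / tumor_mask.mask.sum()


def coverage_by_radii(
    nsc_mask: BinaryMask,
    tumor_mask: BinaryMask,
    radii_um: Iterable[float] = DEFAULT_RADII_UM,
) -> dict[float, float]:
    """Coverage percent at several radii from a single distance transform."""
    _check_pair(nsc_mask, tumor_mask)
    radii = [float(r) for r in radii_um]
    if not nsc_mask.mask.any():
        return {r: 0.0 for r in radii}
    dist = nsc_distance_map(nsc_mask)
    n_tumor = tumor_mask.mask.sum()
    return {
        r: 100.0 * (tumor_mask.mask & (dist <= r)).sum() / n_tumor for r in radii
    }


def disk_union_coverage(
    nsc_mask: BinaryMask, tumor_mask: BinaryMask, radius_um: float
) -> float:
    """Coverage via morphological dilation by an exact lattice disk.

    Independent route to the same quantity as :func:`coverage_fraction`
    (the union of lattice disks around NSC pixels equals the
    distance-threshold set); used as a cross-check.
    """
    _check_pair(nsc_mask, tumor_mask)
    if not nsc_mask.mask.any():
        return 0.0
    r_px = radius_um / nsc_mask.pixel_size_um
    n = int(np.floor(r_px))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    disk = (xx**2 + yy**2) <= r_px**2 + 1e-9
    covered = ndimage.binary_dilation(nsc_mask.mask, structure=disk) & tumor_mask.mask
    return 100.0 * covered.sum() / tumor_mask.mask.sum()


def theoretical_max_coverage(
    n_nsc: float, tumor_area_um2: float, params: CoverageParams = CoverageParams()
) -> float:
    """Maximum coverage percent for homogeneously distributed NSCs.

    n non-overlapping effective disks of radius (r + cell_radius) fully
    inside the tumor, capped at 100%.
    """
    if tumor_area_um2 <= 0:
        raise ValueError("theoretical maximum undefined for zero tumor area")
    if n_nsc < 0:
        raise ValueError("n_nsc must be non-negative")
    r_eff = params.radius_um + params.cell_radius_um
    return min(100.0, 100.0 * n_nsc * np.pi * r_eff**2 / tumor_area_um2)


def coverage_efficiency(observed_pct: float, theoretical_pct: float) -> float:
    """Observed / theoretical coverage.  Values > 1 can arise only from
    the 100% cap on the theoretical maximum and are returned unclipped."""
    if theoretical_pct <= 0:
        raise ValueError("efficiency undefined for zero theoretical coverage")
    return observed_pct / theoretical_pct


def render_overlay(
    nsc_mask: BinaryMask,
    tumor_mask: BinaryMask,
    radius_um: float,
    colors: Mapping[str, tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """RGB overlay: tumor dark green, covered tumor light green, NSC red."""
    palette = {
        "background": (255, 255, 255),
        "tumor": (0, 100, 0),
        "covered": (144, 238, 144),
        "nsc": (220, 20, 60),
    }
    if colors:
        palette.update(colors)
    dist = nsc_distance_map(nsc_mask)
    covered = tumor_mask.mask & (dist <= radius_um)
    out = np.empty(tumor_mask.mask.shape + (3,), dtype=np.uint8)
    out[:] = palette["background"]
    out[tumor_mask.mask] = palette["tumor"]
    out[covered] = palette["covered"]
    out[nsc_mask.mask] = palette["nsc"]
    return out
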