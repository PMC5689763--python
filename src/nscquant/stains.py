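"""Chromagen stain separation by optical-density color deconvolution.

Brightfield chromagens absorb light, so transmitted intensity follows
the Beer-Lambert law: ``I = I0 * 10**(-OD)`` per channel, with the
optical density ``OD`` a linear mixture of per-stain absorbances.
Each stain contributes along a characteristic unit RGB absorbance
vector; unmixing a pixel is solving the 3x3 linear system whose
columns are those vectors (Ruifrok-Johnston color deconvolution).

The module provides the RGB<->OD transforms, the unmixing step, and
fixed-threshold segmentation of an unmixed concentration channel into
a binary mask with small-object removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import morphology

__all__ = [
    "SectionImage",
    "StainVectors",
    "ODImage",
    "BinaryMask",
    "rgb_to_od",
    "od_to_rgb",
    "deconvolve",
    "segment_stain",
]

#: Published absorbance presets for the hematoxylin / DAB stain pair
#: (values from the original color-deconvolution calibration).
HEMATOXYLIN_RGB_OD = (0.650, 0.704, 0.286)
DAB_RGB_OD = (0.269, 0.568, 0.778)

#: Default absorbance vectors for the Prussian blue / pararosaniline
#: pair.  No published calibration exists for this pair; these are the
#: vectors used by the synthetic renderer (Prussian blue absorbs red
#: and green, pararosaniline absorbs green and some blue) and are
#: configurable for real slides.
PRUSSIAN_BLUE_RGB_OD = (0.75, 0.58, 0.32)
PARAROSANILINE_RGB_OD = (0.10, 0.79, 0.60)


@dataclass
class SectionImage:
    """One RGB section image with physical calibration.

    Parameters
    ----------
    pixels : ndarray, shape (H, W, 3)
        Channel intensities in [0, 255].  Float arrays are accepted
        (the synthetic renderer produces sub-integer intensities).
    pixel_size_um : float
        Physical size of one pixel in micrometres, > 0.
    depth_um : float
        Depth of the section below the reference surface.
    slide_id : str
        Identifier of the originating slide.
    stain_kind : str
        Either ``"nsc_prussian_blue"`` or ``"tumor_dab"``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    depth_um: float = 0.0
    slide_id: str = ""
    stain_kind: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected an (H, W, 3) RGB array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0 or hi > 255:
            raise ValueError(f"channel values outside [0, 255]: [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class ODImage:
    """Optical-density representation of a section (non-negative)."""

    od: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if not np.all(np.isfinite(self.od)):
            raise ValueError("optical density must be finite")
        if self.od.min() < 0:
            raise ValueError("optical density must be non-negative")


@dataclass
class BinaryMask:
    """Binary segmentation mask with physical calibration."""

    mask: np.ndarray
    pixel_size_um: float
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def area_um2(self) -> float:
        """Total marked area in square micrometres."""
        return float(self.mask.sum()) * self.pixel_size_um**2


@dataclass(frozen=True)
class StainVectors:
    """Optical-density color basis for a stain set.

    ``vectors`` holds one unit RGB absorbance vector per stain, rows in
    stain order.  Two or three stains may be supplied; a missing third
    basis vector is completed from the residual of the first two
    (per-channel ``sqrt(1 - a^2 - b^2)``, the plugin convention), so the
    unmixing system is always 3x3.
    """

    vectors: np.ndarray
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        vecs = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if vecs.shape[0] not in (2, 3) or vecs.shape[1] != 3:
            raise ValueError("expected 2 or 3 RGB stain vectors")
        if np.any(vecs < 0):
            raise ValueError("stain vectors must have non-negative components")
        norms = np.linalg.norm(vecs, axis=1)
        if np.any(norms == 0):
            raise ValueError("stain vectors must be non-zero")
        object.__setattr__(self, "vectors", vecs / norms[:, None])
        names = tuple(self.names) or tuple(f"stain_{i}" for i in range(vecs.shape[0]))
        if len(names) != vecs.shape[0]:
            raise ValueError("one name per stain vector required")
        object.__setattr__(self, "names", names)
        if np.linalg.matrix_rank(self.matrix()) < 3:
            raise ValueError("stain vectors are linearly dependent (singular basis)")

    @property
    def n_stains(self) -> int:
        return self.vectors.shape[0]

    def matrix(self) -> np.ndarray:
        """Full 3x3 mixing matrix, stain vectors as columns."""
        vecs = self.vectors
        if vecs.shape[0] == 2:
            resid = np.sqrt(np.clip(1.0 - vecs[0] ** 2 - vecs[1] ** 2, 0.0, None))
            n = np.linalg.norm(resid)
            if n == 0:
                raise ValueError("cannot complete residual basis vector")
            vecs = np.vstack([vecs, resid / n])
        return vecs.T

    @classmethod
    def h_dab(cls) -> "StainVectors":
        """Hematoxylin / DAB preset (tumor slide; DAB first)."""
        return cls(
            np.array([DAB_RGB_OD, HEMATOXYLIN_RGB_OD]),
            names=("dab", "hematoxylin"),
        )

    @classmethod
    def prussian_blue(cls) -> "StainVectors":
        """Prussian blue / pararosaniline preset (NSC slide; blue first)."""
        return cls(
            np.array([PRUSSIAN_BLUE_RGB_OD, PARAROSANILINE_RGB_OD]),
            names=("prussian_blue", "pararosaniline"),
        )


def rgb_to_od(
    image: SectionImage | np.ndarray, background_intensity: float = 255.0
) -> ODImage:
    """Convert transmitted RGB intensities to optical density.

    ``OD = -log10(max(I, 1) / background)`` per channel, clipped below
    at zero.  The intensity floor of 1 avoids infinite densities at
    fully opaque pixels.
    """
    if not 0 < background_intensity <= 255:
        raise ValueError("background_intensity must lie in (0, 255]")
    pixels = image.pixels if isinstance(image, SectionImage) else np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {pixels.shape}")
    source = image.slide_id if isinstance(image, SectionImage) else ""
    floored = np.maximum(pixels.astype(float), 1.0)
    od = np.clip(-np.log10(floored / background_intensity), 0.0, None)
    return ODImage(od=od, source=source)


def od_to_rgb(od: ODImage | np.ndarray, background_intensity: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (float intensities, not quantized)."""
    arr = od.od if isinstance(od, ODImage) else np.asarray(od, dtype=float)
    return background_intensity * 10.0 ** (-arr)


def deconvolve(od: ODImage | np.ndarray, stains: StainVectors) -> np.ndarray:
    """Unmix an OD image into per-stain concentration channels.

    Solves ``OD = M @ c`` per pixel, with M the 3x3 mixing matrix whose
    columns are the stain vectors.  Returns an (H, W, n) array holding
    one channel per *supplied* stain, in input order.  Raw (possibly
    negative) concentrations are preserved; clipping is deferred to the
    mask-building stage.
    """
    arr = od.od if isinstance(od, ODImage) else np.asarray(od, dtype=float)
    m = stains.matrix()
    try:
        minv = np.linalg.inv(m)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in StainVectors
        raise ValueError("singular stain matrix") from exc
    conc = arr.reshape(-1, 3) @ minv.T
    return conc.reshape(arr.shape[:2] + (3,))[..., : stains.n_stains]


def segment_stain(
    channel: np.ndarray,
    threshold: float,
    min_object_px: int = 0,
    pixel_size_um: float = 1.0,
    label: str = "",
) -> BinaryMask:
    """Threshold a concentration channel into a binary mask.

    Pixels with concentration >= ``threshold`` are kept; 8-connected
    components smaller than ``min_object_px`` pixels are removed.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if min_object_px < 0:
        raise ValueError("min_object_px must be non-negative")
    mask = np.asarray(channel) >= threshold
    if min_object_px > 1:
        # remove components strictly smaller than min_object_px
        mask = morphology.remove_small_objects(
            mask, max_size=min_object_px - 1, connectivity=2
        )
    return BinaryMask(mask=mask, pixel_size_um=pixel_size_um, label=label)


def otsu_threshold(channel: np.ndarray) -> float:
    """Otsu threshold of a concentration channel (optional mode)."""
    from skimage.filters import threshold_otsu

    return float(threshold_otsu(np.asarray(channel, dtype=float)))
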