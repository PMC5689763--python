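"""Reading and writing section images, masks, and phantom stacks."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .phantom import GroundTruth
from .stains import BinaryMask, SectionImage

__all__ = [
    "read_section_image",
    "write_section_image",
    "write_mask_png",
    "read_mask_png",
    "load_config",
    "write_phantom_stack",
]


def read_section_image(
    path: str | Path,
    pixel_size_um: float,
    depth_um: float = 0.0,
    stain_kind: str = "",
) -> SectionImage:
    """Read an RGB TIFF/PNG/JPEG section image."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    return SectionImage(
        arr,
        pixel_size_um=pixel_size_um,
        depth_um=depth_um,
        slide_id=path.stem,
        stain_kind=stain_kind,
    )


def write_section_image(image: SectionImage, path: str | Path) -> None:
    """Write a section image (quantized to 8 bit)."""
    path = Path(path)
    arr = np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def write_mask_png(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as a single-channel 0/255 PNG."""
    iio.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))


def read_mask_png(path: str | Path, pixel_size_um: float, label: str = "") -> BinaryMask:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return BinaryMask(arr > 127, pixel_size_um=pixel_size_um, label=label)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON pipeline configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def write_phantom_stack(
    pairs: list[tuple[SectionImage, SectionImage]],
    truth: GroundTruth,
    out_dir: str | Path,
) -> None:
    """Write a phantom as numbered TIFF pairs + truth JSON + centroid CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, (nsc_img, tumor_img) in enumerate(pairs):
        write_section_image(nsc_img, out / f"section_{k:03d}_nsc.tif")
        write_section_image(tumor_img, out / f"section_{k:03d}_tumor.tif")
    summary = {
        "section_depths_um": [float(d) for d in truth.section_depths_um],
        "tumor_areas_um2": truth.tumor_areas_um2,
        "section_nsc_counts": truth.section_nsc_counts,
        "coverage_pct": {str(r): v for r, v in truth.coverage_pct.items()},
        "whole_coverage_pct": {str(r): v for r, v in truth.whole_coverage_pct.items()},
        "volume_analytic_mm3": truth.volume_analytic_mm3,
        "volume_ellipsoid_mm3": truth.volume_ellipsoid_mm3,
        "volume_voxel_mm3": truth.volume_voxel_mm3,
        "n_nsc_total": truth.n_nsc_total,
        "administered_count": truth.administered_count,
        "retention_fraction": truth.retention_fraction,
    }
    (out / "truth.json").write_text(json.dumps(summary, indent=2))
    with (out / "centroids.csv").open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x_um", "y_um", "z_um"])
        for row in truth.nsc_points_xyz_um:
            writer.writerow([f"{v:.3f}" for v in row])
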