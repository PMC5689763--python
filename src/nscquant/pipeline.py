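"""End-to-end orchestration: slide pairs -> section/brain/cohort reports.

One run processes a cohort of brains.  Each brain is either a phantom
(generated from a seeded spec) or a list of registered slide-image
pairs.  Per section, the pipeline unmixes both slides, segments NSC
and tumor pixels, counts cells, measures tumor area, computes percent
coverage at each radius of action, and the clustering index; per
brain, it extrapolates Cavalieri volume, NSC totals, percent of
administered dose, density, and whole-tumor coverage; per cohort, it
fits the summary statistics relating these to dose, count, and volume.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import cells, coverage, spatial, stains, volumetry
from .phantom import PhantomSpec, generate_phantom
from .stains import BinaryMask, SectionImage, StainVectors
from .stats import StatResult, linear_regression_r2, spearman_r

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisParams",
    "SectionQuant",
    "process_section_pair",
    "process_brain",
    "run_pipeline",
]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable parameters of the per-section analysis."""

    nsc_stains: StainVectors = field(default_factory=StainVectors.prussian_blue)
    tumor_stains: StainVectors = field(default_factory=StainVectors.h_dab)
    nsc_threshold: float = 0.5
    tumor_threshold: float = 0.5
    min_object_px: int = 10
    mean_cell_area_um2: float = cells.DEFAULT_MEAN_CELL_AREA_UM2
    radii_um: tuple[float, ...] = coverage.DEFAULT_RADII_UM
    cell_radius_um: float = coverage.DEFAULT_CELL_RADIUS_UM
    clustering_radius_um: float = spatial.DEFAULT_CLUSTERING_RADIUS_UM
    detect_min_area_um2: float = 15.0
    detect_max_area_um2: float = 1e6
    background_intensity: float = 255.0
    registration_offset_px: tuple[int, int] = (0, 0)

    @classmethod
    def from_config(cls, cfg: dict[str, Any]) -> "AnalysisParams":
        kwargs: dict[str, Any] = {}
        for key in (
            "nsc_threshold",
            "tumor_threshold",
            "min_object_px",
            "mean_cell_area_um2",
            "cell_radius_um",
            "clustering_radius_um",
            "detect_min_area_um2",
            "detect_max_area_um2",
            "background_intensity",
        ):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "radii_um" in cfg:
            kwargs["radii_um"] = tuple(float(r) for r in cfg["radii_um"])
        if "registration_offset_px" in cfg:
            kwargs["registration_offset_px"] = tuple(cfg["registration_offset_px"])
        for key, preset in (("nsc_stain_vectors", "nsc_stains"), ("tumor_stain_vectors", "tumor_stains")):
            if key in cfg:
                kwargs[preset] = StainVectors(np.asarray(cfg[key], dtype=float))
        return cls(**kwargs)


@dataclass
class SectionQuant:
    """Per-section measurements."""

    slide_id: str
    depth_um: float
    nsc_count: float
    n_detected: int
    nsc_centroids: list[cells.CellDetection]
    tumor_area_um2: float
    coverage_pct: dict[float, float]
    clustering_index: float  # NaN when no cells are detected
    efficiency: dict[float, float]  # observed/theoretical per radius


def segment_pair(
    nsc_image: SectionImage,
    tumor_image: SectionImage,
    params: AnalysisParams = AnalysisParams(),
) -> tuple[BinaryMask, BinaryMask]:
    """Unmix and threshold one slide pair into NSC and tumor masks."""
    if nsc_image.pixel_size_um != tumor_image.pixel_size_um:
        raise ValueError("mismatched pixel calibrations in a slide pair")
    nsc_conc = stains.deconvolve(
        stains.rgb_to_od(nsc_image, params.background_intensity), params.nsc_stains
    )[..., 0]
    tumor_conc = stains.deconvolve(
        stains.rgb_to_od(tumor_image, params.background_intensity), params.tumor_stains
    )[..., 0]
    nsc_mask = stains.segment_stain(
        nsc_conc,
        params.nsc_threshold,
        params.min_object_px,
        nsc_image.pixel_size_um,
        label="nsc",
    )
    if params.registration_offset_px != (0, 0):
        shifted = ndimage.shift(
            nsc_mask.mask, params.registration_offset_px, order=0, cval=False
        )
        nsc_mask = BinaryMask(shifted, nsc_mask.pixel_size_um, label="nsc")
    tumor_mask = stains.segment_stain(
        tumor_conc,
        params.tumor_threshold,
        params.min_object_px,
        tumor_image.pixel_size_um,
        label="tumor",
    )
    return nsc_mask, tumor_mask


def process_section_pair(
    nsc_image: SectionImage,
    tumor_image: SectionImage,
    params: AnalysisParams = AnalysisParams(),
) -> SectionQuant:
    """All per-section quantities from one registered slide pair."""
    nsc_mask, tumor_mask = segment_pair(nsc_image, tumor_image, params)
    count = cells.count_cells_pixel_ratio(nsc_mask, params.mean_cell_area_um2)
    detections = cells.detect_cells(
        nsc_mask, params.detect_min_area_um2, params.detect_max_area_um2
    )
    area = cells.tumor_area(tumor_mask)
    if tumor_mask.mask.any():
        cov = coverage.coverage_by_radii(nsc_mask, tumor_mask, params.radii_um)
    else:
        cov = {float(r): float("nan") for r in params.radii_um}
    if detections:
        ci = spatial.cluster_points(detections, params.clustering_radius_um).ci
    else:
        ci = float("nan")
    efficiency: dict[float, float] = {}
    for r in params.radii_um:
        r = float(r)
        if area > 0 and count > 0:
            theo = coverage.theoretical_max_coverage(
                count,
                area,
                coverage.CoverageParams(radius_um=r, cell_radius_um=params.cell_radius_um),
            )
            efficiency[r] = coverage.coverage_efficiency(cov[r], theo)
        else:
            efficiency[r] = float("nan")
    return SectionQuant(
        slide_id=nsc_image.slide_id or tumor_image.slide_id,
        depth_um=nsc_image.depth_um,
        nsc_count=count,
        n_detected=len(detections),
        nsc_centroids=detections,
        tumor_area_um2=area,
        coverage_pct=cov,
        clustering_index=ci,
        efficiency=efficiency,
    )


def process_brain(
    pairs: Sequence[tuple[SectionImage, SectionImage]],
    brain_id: str,
    administered_dose: float,
    route: str = "ic",
    scheme: volumetry.SamplingScheme = volumetry.SamplingScheme(),
    params: AnalysisParams = AnalysisParams(),
) -> tuple[list[SectionQuant], volumetry.BrainQuant]:
    """Process a serial stack of slide pairs into per-brain aggregates."""
    quants = [process_section_pair(n, t, params) for n, t in pairs]
    areas = [q.tumor_area_um2 for q in quants]
    volume = volumetry.cavalieri_volume(areas, scheme)
    total = volumetry.extrapolate_counts([q.nsc_count for q in quants], scheme)
    tumor_sections = [q for q in quants if q.tumor_area_um2 > 0]
    if tumor_sections:
        whole = volumetry.whole_tumor_coverage(
            [q.coverage_pct for q in tumor_sections],
            [q.tumor_area_um2 for q in tumor_sections],
        )
    else:
        whole = {float(r): float("nan") for r in params.radii_um}
    brain = volumetry.BrainQuant(
        brain_id=brain_id,
        tumor_volume_mm3=volume,
        total_nsc_count=total,
        administered_nsc_count=administered_dose,
        route=route,
        whole_tumor_coverage_pct=whole,
    )
    return quants, brain


def _sections_frame(brain_id: str, quants: Sequence[SectionQuant]) -> pd.DataFrame:
    rows = []
    for q in quants:
        row: dict[str, Any] = {
            "brain_id": brain_id,
            "slide_id": q.slide_id,
            "depth_um": q.depth_um,
            "nsc_count": q.nsc_count,
            "n_detected": q.n_detected,
            "tumor_area_um2": q.tumor_area_um2,
            "clustering_index": q.clustering_index,
        }
        for r, v in q.coverage_pct.items():
            row[f"coverage_pct_r{r:g}"] = v
        for r, v in q.efficiency.items():
            row[f"efficiency_r{r:g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def _brain_record(brain: volumetry.BrainQuant, dose: float) -> dict[str, Any]:
    rec = {
        "brain_id": brain.brain_id,
        "route": brain.route,
        "administered_dose": dose,
        "tumor_volume_mm3": brain.tumor_volume_mm3,
        "total_nsc_count": brain.total_nsc_count,
        "pct_at_tumor": brain.pct_at_tumor if dose > 0 else float("nan"),
        "nsc_density_per_mm3": (
            brain.nsc_density_per_mm3 if brain.tumor_volume_mm3 > 0 else float("nan")
        ),
    }
    for r, v in brain.whole_tumor_coverage_pct.items():
        rec[f"whole_coverage_pct_r{r:g}"] = v
    return rec


def _cohort_stats(
    cohort: pd.DataFrame, sections: pd.DataFrame, radius: float
) -> list[dict[str, Any]]:
    """The figure-style cohort analyses; skips relations with too few points."""
    out: list[dict[str, Any]] = []

    def add(name: str, func, x, y) -> None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        try:
            res: StatResult = func(x[ok], y[ok])
        except ValueError as exc:
            logger.info("skipping %s: %s", name, exc)
            return
        out.append(
            {
                "analysis": name,
                "method": res.method,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n": res.n,
            }
        )

    cov_col = f"whole_coverage_pct_r{radius:g}"
    add("total_nsc_vs_dose", linear_regression_r2, cohort["administered_dose"], cohort["total_nsc_count"])
    add("pct_at_tumor_vs_dose", linear_regression_r2, cohort["administered_dose"], cohort["pct_at_tumor"])
    add("coverage_vs_dose", linear_regression_r2, cohort["administered_dose"], cohort[cov_col])
    add("coverage_vs_total_nsc", spearman_r, cohort["total_nsc_count"], cohort[cov_col])
    add("coverage_vs_volume", spearman_r, cohort["tumor_volume_mm3"], cohort[cov_col])
    add("density_vs_volume", spearman_r, cohort["tumor_volume_mm3"], cohort["nsc_density_per_mm3"])
    eff_col = f"efficiency_r{radius:g}"
    if eff_col in sections:
        add(
            "efficiency_vs_clustering_index",
            spearman_r,
            sections["clustering_index"],
            sections[eff_col],
        )
    return out


def run_pipeline(config: dict[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run a full cohort analysis from a configuration mapping.

    The config lists brains under ``cohort``; each brain carries either
    a ``phantom`` spec mapping or an ``images`` list of slide-pair
    entries, plus ``administered_dose`` and ``route``.  Writes
    per-section CSV, per-brain JSON, a cohort CSV, and a stats CSV;
    returns the collected tables.  Reruns with the same config are
    byte-identical.
    """
    from .io import read_section_image  # deferred: optional for in-memory use

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = AnalysisParams.from_config(config.get("analysis", {}))
    scheme_cfg = config.get("scheme", {})
    scheme = volumetry.SamplingScheme(
        section_thickness_um=scheme_cfg.get("section_thickness_um", 10.0),
        analysis_spacing_um=scheme_cfg.get("analysis_spacing_um", 200.0),
        slides_per_group=scheme_cfg.get("slides_per_group", 10),
    )
    base_seed = int(config.get("seed", 0))

    section_frames: list[pd.DataFrame] = []
    brain_records: list[dict[str, Any]] = []
    for i, entry in enumerate(config.get("cohort", [])):
        brain_id = str(entry.get("brain_id", f"brain_{i:02d}"))
        route = entry.get("route", "ic")
        if "phantom" in entry:
            ph_cfg = dict(entry["phantom"])
            ph_cfg.setdefault("seed", base_seed + i)
            spec = PhantomSpec(**ph_cfg)
            pairs, truth = generate_phantom(spec)
            dose = float(entry.get("administered_dose", truth.administered_count))
        elif "images" in entry:
            px = float(entry.get("pixel_size_um", 1.0))
            pairs = []
            for item in entry["images"]:
                if "nsc" not in item or "tumor" not in item:
                    raise ValueError(f"brain {brain_id}: a pair is missing a member")
                depth = float(item.get("depth_um", 0.0))
                pairs.append(
                    (
                        read_section_image(item["nsc"], px, depth, "nsc_prussian_blue"),
                        read_section_image(item["tumor"], px, depth, "tumor_dab"),
                    )
                )
            dose = float(entry.get("administered_dose", 0.0))
        else:
            raise ValueError(f"brain {brain_id}: need 'phantom' or 'images'")
        quants, brain = process_brain(
            pairs, brain_id, dose, route=route, scheme=scheme, params=params
        )
        frame = _sections_frame(brain_id, quants)
        frame.to_csv(out / f"{brain_id}_sections.csv", index=False)
        record = _brain_record(brain, dose)
        (out / f"{brain_id}.json").write_text(json.dumps(record, indent=2))
        section_frames.append(frame)
        brain_records.append(record)

    sections = (
        pd.concat(section_frames, ignore_index=True) if section_frames else pd.DataFrame()
    )
    cohort = pd.DataFrame(brain_records)
    cohort.to_csv(out / "cohort.csv", index=False)
    if not sections.empty:
        sections.to_csv(out / "sections.csv", index=False)

    stats_rows: list[dict[str, Any]] = []
    if len(cohort) >= 3:
        radius = float(config.get("stats_radius_um", 50.0))
        stats_rows = _cohort_stats(cohort, sections, radius)
    stats_frame = pd.DataFrame(stats_rows)
    stats_frame.to_csv(out / "stats.csv", index=False)
    return {"sections": sections, "cohort": cohort, "stats": stats_frame}
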