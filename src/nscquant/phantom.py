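"""Seeded synthetic-histology phantoms with exact ground truth.

A phantom brain is a 3-D tumor blob — an ellipsoid whose in-plane
boundary radius is modulated by low-order angular harmonics to mimic
irregular tumor margins — plus a 3-D NSC point pattern mixing three
components: uniform interior points, Thomas-process clusters (Gaussian
offspring around uniform parents), and points biased into a rim at the
tumor edge.  The blob is sampled as serial cross-sections on the
standard FFPE scheme (10 um sections, one analyzed per 200 um), and
each sampled depth is rendered as an aligned pair of chromagen slides
(Prussian blue / pararosaniline for NSCs; DAB / hematoxylin for tumor)
through the Beer-Lambert forward model that the deconvolution inverts.

Everything downstream of the seed is deterministic, and the ground
truth (masks, centroids, per-section and whole-tumor coverage, analytic
volume, administered dose) is computed independently of the analysis
pipeline, so the pipeline can be validated end-to-end without slide
data.

Geometry of the blob: with center (cx, cy, z0), semi-axes (a, b, c)
and boundary modulation s(theta), a point is inside the tumor iff

    u^2 + v^2 <= s(theta)^2 * (1 - w^2),    theta = atan2(v, u),

where u = (x-cx)/a, v = (y-cy)/b, w = (z-z0)/c.  Cross-section area is
then pi*a*b*(1-w^2)*K with K = 1 + 0.5*sum(amplitude^2), giving the
closed-form volume (4/3)*pi*a*b*c*K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .stains import SectionImage, StainVectors

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "place_nscs",
    "render_section",
    "rasterize_disks",
    "generate_section_pattern",
]

#: Angular harmonics used for boundary irregularity (low-order lobes).
_BOUNDARY_MODES = (2, 3, 4, 5)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic brain.

    Defaults emulate the study's imaging: 1 um/pixel sections, 10 um
    thick, analyzed every 200 um, cells of ~9 um diameter, and an NSC
    load that yields densities in the 10^4-10^5 per mm^3 range.  The
    512-px field is a desk-scale stand-in for whole-slide scans while
    preserving the physical sampling scheme.
    """

    image_size_px: int = 512
    pixel_size_um: float = 1.0
    n_sections: int = 12
    spacing_um: float = 200.0
    section_thickness_um: float = 10.0
    tumor_semi_axes_um: tuple[float, float, float] = (200.0, 160.0, 800.0)
    irregularity: float = 0.08
    n_nsc_total: int = 3000
    cluster_fraction: float = 0.5
    clusters_mean_offspring: float = 8.0
    cluster_sd_um: float = 25.0
    edge_bias: float = 0.2
    edge_rim_frac: float = 0.1
    retention_fraction: float = 0.55
    cell_radius_um: float = 4.5
    stain_amplitude: float = 1.0
    counterstain_amplitude: float = 0.25
    noise_sd: float = 2.0
    background_intensity: float = 255.0
    coverage_radii_um: tuple[float, ...] = (25.0, 50.0)
    nsc_stains: StainVectors = field(default_factory=StainVectors.prussian_blue)
    tumor_stains: StainVectors = field(default_factory=StainVectors.h_dab)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nsc_total < 0:
            raise ValueError("n_nsc_total must be non-negative")
        for p in (
            self.cluster_fraction,
            self.edge_bias,
            self.edge_rim_frac,
            self.retention_fraction,
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.cluster_fraction + self.edge_bias > 1 + 1e-12:
            raise ValueError("cluster_fraction + edge_bias must not exceed 1")
        if self.retention_fraction == 0 and self.n_nsc_total > 0:
            raise ValueError("retention_fraction must be positive when cells exist")
        a, b, _ = self.tumor_semi_axes_um
        field_um = self.image_size_px * self.pixel_size_um
        margin = 1.0 + 1.1 * self.irregularity * sum(
            1.0 / (m - 1) for m in _BOUNDARY_MODES
        )
        if 2 * max(a, b) * margin > field_um:
            raise ValueError("tumor is larger than the image field")

    @property
    def center_xy_um(self) -> tuple[float, float]:
        half = self.image_size_px * self.pixel_size_um / 2.0
        return (half, half)

    @property
    def section_depths_um(self) -> np.ndarray:
        return np.arange(self.n_sections) * self.spacing_um

    @property
    def irregularity_area_factor(self) -> float:
        amps = _boundary_amplitudes(self.irregularity)
        return 1.0 + 0.5 * float(np.sum(amps**2))


@dataclass
class GroundTruth:
    """Exact truth for one phantom, computed independently of the pipeline."""

    spec: PhantomSpec
    section_depths_um: np.ndarray
    tumor_masks: list[np.ndarray]
    tumor_areas_um2: list[float]
    nsc_masks: list[np.ndarray]
    nsc_centroids_by_section: list[np.ndarray]
    nsc_points_xyz_um: np.ndarray
    section_nsc_counts: list[int]
    coverage_pct: dict[float, list[float]]
    whole_coverage_pct: dict[float, float]
    volume_analytic_mm3: float
    volume_ellipsoid_mm3: float
    volume_voxel_mm3: float
    n_nsc_total: int
    administered_count: float
    retention_fraction: float


class _TumorShape:
    """Implicit 3-D tumor blob with frozen boundary harmonics."""

    def __init__(self, spec: PhantomSpec, rng: np.random.Generator):
        self.spec = spec
        self.amps = _boundary_amplitudes(spec.irregularity)
        self.phases = rng.uniform(0, 2 * np.pi, size=len(_BOUNDARY_MODES))
        a, b, c = spec.tumor_semi_axes_um
        self.a, self.b, self.c = a, b, c
        self.cx, self.cy = spec.center_xy_um
        span = (spec.n_sections - 1) * spec.spacing_um
        # Random axial offset so section depths never align with the
        # blob's symmetry plane (a too-kind case for Cavalieri sums).
        self.z0 = span / 2.0 + rng.uniform(-spec.spacing_um / 2, spec.spacing_um / 2)

    def boundary_scale(self, theta: np.ndarray) -> np.ndarray:
        s = np.ones_like(theta)
        for m, amp, ph in zip(_BOUNDARY_MODES, self.amps, self.phases):
            s = s + amp * np.cos(m * np.asarray(theta) + ph)
        return s

    def contains(self, points_xyz: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points_xyz)
        u = (pts[:, 0] - self.cx) / self.a
        v = (pts[:, 1] - self.cy) / self.b
        w = (pts[:, 2] - self.z0) / self.c
        theta = np.arctan2(v, u)
        return u**2 + v**2 <= self.boundary_scale(theta) ** 2 * (1 - w**2)

    def section_mask(self, depth_um: float) -> np.ndarray:
        spec = self.spec
        n = spec.image_size_px
        w = (depth_um - self.z0) / self.c
        if abs(w) >= 1:
            return np.zeros((n, n), dtype=bool)
        coords = (np.arange(n) + 0.0) * spec.pixel_size_um
        x, y = np.meshgrid(coords, coords)  # x varies with column
        u = (x - self.cx) / self.a
        v = (y - self.cy) / self.b
        theta = np.arctan2(v, u)
        return u**2 + v**2 <= self.boundary_scale(theta) ** 2 * (1 - w**2)

    def analytic_area_um2(self, depth_um: float) -> float:
        w = (depth_um - self.z0) / self.c
        if abs(w) >= 1:
            return 0.0
        k = 1.0 + 0.5 * float(np.sum(self.amps**2))
        return math.pi * self.a * self.b * (1 - w**2) * k

    @property
    def volume_analytic_mm3(self) -> float:
        k = 1.0 + 0.5 * float(np.sum(self.amps**2))
        return (4.0 / 3.0) * math.pi * self.a * self.b * self.c * k / 1e9

    @property
    def volume_ellipsoid_mm3(self) -> float:
        return (4.0 / 3.0) * math.pi * self.a * self.b * self.c / 1e9


def _boundary_amplitudes(irregularity: float) -> np.ndarray:
    return np.array([irregularity / (m - 1) for m in _BOUNDARY_MODES])


def _sample_uniform(shape: _TumorShape, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside the blob by rejection in normalized space."""
    if n == 0:
        return np.empty((0, 3))
    smax = 1.0 + float(np.sum(shape.amps))
    out: list[np.ndarray] = []
    got = 0
    while got < n:
        m = max(4 * (n - got), 64)
        u = rng.uniform(-smax, smax, m)
        v = rng.uniform(-smax, smax, m)
        w = rng.uniform(-1, 1, m)
        theta = np.arctan2(v, u)
        keep = u**2 + v**2 <= shape.boundary_scale(theta) ** 2 * (1 - w**2)
        pts = np.column_stack(
            [
                shape.cx + shape.a * u[keep],
                shape.cy + shape.b * v[keep],
                shape.z0 + shape.c * w[keep],
            ]
        )
        out.append(pts)
        got += len(pts)
    return np.concatenate(out)[:n]


def _sample_edge(shape: _TumorShape, n: int, rng: np.random.Generator) -> np.ndarray:
    """Points pushed into an in-plane rim at the tumor boundary."""
    if n == 0:
        return np.empty((0, 3))
    spec = shape.spec
    base = _sample_uniform(shape, n, rng)
    u = (base[:, 0] - shape.cx) / shape.a
    v = (base[:, 1] - shape.cy) / shape.b
    w = (base[:, 2] - shape.z0) / shape.c
    theta = np.arctan2(v, u)
    limit = shape.boundary_scale(theta) * np.sqrt(1 - w**2)
    q = np.hypot(u, v)
    # degenerate on-axis points: pick a random direction
    on_axis = q < 1e-12
    if np.any(on_axis):
        theta[on_axis] = rng.uniform(0, 2 * np.pi, on_axis.sum())
        u[on_axis] = np.cos(theta[on_axis]) * 1e-6
        v[on_axis] = np.sin(theta[on_axis]) * 1e-6
        q[on_axis] = np.hypot(u[on_axis], v[on_axis])
    target = limit * rng.uniform(1 - spec.edge_rim_frac, 1.0, n)
    scale = target / q
    return np.column_stack(
        [shape.cx + shape.a * u * scale, shape.cy + shape.b * v * scale, base[:, 2]]
    )


def _sample_clusters(
    shape: _TumorShape, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Thomas-process points: Gaussian offspring around uniform parents."""
    if n == 0:
        return np.empty((0, 3))
    spec = shape.spec
    n_parents = max(1, int(round(n / spec.clusters_mean_offspring)))
    parents = _sample_uniform(shape, n_parents, rng)
    assignment = rng.multinomial(n, np.full(n_parents, 1.0 / n_parents))
    pts = np.empty((n, 3))
    i = 0
    for parent, k in zip(parents, assignment):
        for _ in range(k):
            for _try in range(200):
                cand = parent + rng.normal(0, spec.cluster_sd_um, 3)
                if shape.contains(cand[None, :])[0]:
                    pts[i] = cand
                    break
            else:
                pts[i] = parent
            i += 1
    return pts


def place_nscs(
    shape: _TumorShape, spec: PhantomSpec, rng: np.random.Generator
) -> np.ndarray:
    """3-D NSC centroids: uniform + Thomas clusters + edge-rim mixture.

    Returns exactly ``spec.n_nsc_total`` points (um), all inside the
    tumor blob, in shuffled order so any prefix is an unbiased
    sub-dose.
    """
    n = spec.n_nsc_total
    n_cluster = int(round(spec.cluster_fraction * n))
    n_edge = int(round(spec.edge_bias * n))
    n_edge = min(n_edge, n - n_cluster)
    n_uniform = n - n_cluster - n_edge
    pts = np.concatenate(
        [
            _sample_uniform(shape, n_uniform, rng),
            _sample_clusters(shape, n_cluster, rng),
            _sample_edge(shape, n_edge, rng),
        ]
    )
    rng.shuffle(pts, axis=0)
    return pts


def rasterize_disks(
    points_xy_um: np.ndarray,
    radius_um: float,
    shape_px: tuple[int, int],
    pixel_size_um: float,
) -> np.ndarray:
    """Boolean union of disks: pixel centers within radius of any point."""
    mask = np.zeros(shape_px, dtype=bool)
    if len(points_xy_um) == 0:
        return mask
    r_px = radius_um / pixel_size_um
    nrow, ncol = shape_px
    for x_um, y_um in np.atleast_2d(points_xy_um):
        col_c = x_um / pixel_size_um
        row_c = y_um / pixel_size_um
        r0 = max(0, int(np.floor(row_c - r_px)))
        r1 = min(nrow - 1, int(np.ceil(row_c + r_px)))
        c0 = max(0, int(np.floor(col_c - r_px)))
        c1 = min(ncol - 1, int(np.ceil(col_c + r_px)))
        if r1 < r0 or c1 < c0:
            continue
        rows = np.arange(r0, r1 + 1)
        cols = np.arange(c0, c1 + 1)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        inside = (rr - row_c) ** 2 + (cc - col_c) ** 2 <= r_px**2
        mask[r0 : r1 + 1, c0 : c1 + 1] |= inside
    return mask


def _render_stain_pair(
    target_concentration: np.ndarray,
    stains: StainVectors,
    counterstain_amplitude: float,
    background: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Beer-Lambert forward model: OD = sum(c_s * vector_s), RGB = bg*10^-OD."""
    v_target, v_counter = stains.vectors[0], stains.vectors[1]
    od = (
        target_concentration[..., None] * v_target
        + counterstain_amplitude * v_counter
    )
    rgb = background * 10.0 ** (-od)
    if noise_sd > 0:
        rgb = rgb + rng.normal(0, noise_sd, rgb.shape)
    return np.clip(rgb, 0.0, 255.0)


def render_section(
    tumor_mask: np.ndarray,
    nsc_points_xy_um: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
    depth_um: float = 0.0,
    slide_id: str = "",
) -> tuple[SectionImage, SectionImage]:
    """Render one aligned (NSC-stain, tumor-stain) slide pair.

    The NSC slide shows Prussian-blue disks of ``cell_radius_um`` at
    each in-slab centroid over a uniform pararosaniline counterstain;
    the tumor slide shows DAB over the tumor mask with hematoxylin
    everywhere.  Intensities are kept as floats so the noise-free
    forward model is exactly invertible by the unmixing step.
    """
    shape_px = tumor_mask.shape
    nsc_conc = spec.stain_amplitude * rasterize_disks(
        nsc_points_xy_um, spec.cell_radius_um, shape_px, spec.pixel_size_um
    ).astype(float)
    tumor_conc = spec.stain_amplitude * tumor_mask.astype(float)
    nsc_rgb = _render_stain_pair(
        nsc_conc,
        spec.nsc_stains,
        spec.counterstain_amplitude,
        spec.background_intensity,
        spec.noise_sd,
        rng,
    )
    tumor_rgb = _render_stain_pair(
        tumor_conc,
        spec.tumor_stains,
        spec.counterstain_amplitude,
        spec.background_intensity,
        spec.noise_sd,
        rng,
    )
    common = dict(pixel_size_um=spec.pixel_size_um, depth_um=depth_um)
    return (
        SectionImage(
            nsc_rgb, slide_id=f"{slide_id}_nsc", stain_kind="nsc_prussian_blue", **common
        ),
        SectionImage(
            tumor_rgb, slide_id=f"{slide_id}_tumor", stain_kind="tumor_dab", **common
        ),
    )


def _truth_coverage(
    nsc_mask: np.ndarray,
    tumor_mask: np.ndarray,
    radii_um: Sequence[float],
    pixel_size_um: float,
) -> dict[float, float]:
    """Exact nearest-NSC-pixel coverage, independent of the pipeline's
    distance-transform route (per-pixel nearest-neighbor search)."""
    n_tumor = int(tumor_mask.sum())
    if n_tumor == 0:
        return {float(r): float("nan") for r in radii_um}
    if not nsc_mask.any():
        return {float(r): 0.0 for r in radii_um}
    nsc_px = np.argwhere(nsc_mask)
    tumor_px = np.argwhere(tumor_mask)
    dist_px, _ = cKDTree(nsc_px).query(tumor_px, k=1)
    dist_um = dist_px * pixel_size_um
    return {
        float(r): 100.0 * float((dist_um <= r).sum()) / n_tumor for r in radii_um
    }


def generate_phantom(spec: PhantomSpec) -> tuple[list[tuple[SectionImage, SectionImage]], GroundTruth]:
    """Generate one phantom brain: rendered slide pairs plus ground truth.

    Deterministic for a fixed spec (the seed drives every draw).
    """
    rng = np.random.default_rng(spec.seed)
    shape = _TumorShape(spec, rng)
    points = place_nscs(shape, spec, rng) if spec.n_nsc_total else np.empty((0, 3))

    depths = spec.section_depths_um
    half_t = spec.section_thickness_um / 2.0
    pairs: list[tuple[SectionImage, SectionImage]] = []
    tumor_masks: list[np.ndarray] = []
    nsc_masks: list[np.ndarray] = []
    centroids: list[np.ndarray] = []
    counts: list[int] = []
    areas: list[float] = []
    coverage: dict[float, list[float]] = {float(r): [] for r in spec.coverage_radii_um}

    for k, d in enumerate(depths):
        tumor_mask = shape.section_mask(d)
        in_slab = (
            points[(points[:, 2] >= d - half_t) & (points[:, 2] < d + half_t)][:, :2]
            if len(points)
            else np.empty((0, 2))
        )
        nsc_mask = rasterize_disks(
            in_slab, spec.cell_radius_um, tumor_mask.shape, spec.pixel_size_um
        )
        pair = render_section(
            tumor_mask, in_slab, spec, rng, depth_um=float(d), slide_id=f"s{k:02d}"
        )
        pairs.append(pair)
        tumor_masks.append(tumor_mask)
        nsc_masks.append(nsc_mask)
        centroids.append(in_slab)
        counts.append(len(in_slab))
        areas.append(float(tumor_mask.sum()) * spec.pixel_size_um**2)
        sec_cov = _truth_coverage(
            nsc_mask, tumor_mask, spec.coverage_radii_um, spec.pixel_size_um
        )
        for r, c in sec_cov.items():
            coverage[r].append(c)

    total_area = sum(areas)
    whole = {
        r: (
            sum(c * a for c, a in zip(covs, areas) if not math.isnan(c)) / total_area
            if total_area > 0
            else float("nan")
        )
        for r, covs in coverage.items()
    }
    administered = (
        spec.n_nsc_total / spec.retention_fraction if spec.n_nsc_total else 0.0
    )
    truth = GroundTruth(
        spec=spec,
        section_depths_um=depths,
        tumor_masks=tumor_masks,
        tumor_areas_um2=areas,
        nsc_masks=nsc_masks,
        nsc_centroids_by_section=centroids,
        nsc_points_xyz_um=points,
        section_nsc_counts=counts,
        coverage_pct=coverage,
        whole_coverage_pct=whole,
        volume_analytic_mm3=shape.volume_analytic_mm3,
        volume_ellipsoid_mm3=shape.volume_ellipsoid_mm3,
        volume_voxel_mm3=sum(areas) * spec.spacing_um / 1e9,
        n_nsc_total=spec.n_nsc_total,
        administered_count=administered,
        retention_fraction=spec.retention_fraction,
    )
    return pairs, truth


def generate_section_pattern(
    n_points: int,
    tumor_radius_um: float = 110.0,
    image_size_px: int = 256,
    pixel_size_um: float = 1.0,
    cluster_fraction: float = 0.5,
    clusters_mean_offspring: float = 8.0,
    cluster_sd_um: float = 25.0,
    edge_bias: float = 0.0,
    edge_rim_frac: float = 0.1,
    cell_radius_um: float = 4.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-section point-pattern phantom in a circular tumor.

    A lightweight 2-D counterpart of :func:`generate_phantom` for
    point-pattern studies (clustering sweeps, dose series): returns
    ``(points_xy_um, nsc_mask, tumor_mask)``.  Points are shuffled so
    prefixes give nested doses at fixed geometry.
    """
    rng = np.random.default_rng(seed)
    half = image_size_px * pixel_size_um / 2.0
    spec = PhantomSpec(
        image_size_px=image_size_px,
        pixel_size_um=pixel_size_um,
        n_sections=1,
        tumor_semi_axes_um=(tumor_radius_um, tumor_radius_um, 1.0),
        irregularity=0.0,
        n_nsc_total=n_points,
        cluster_fraction=cluster_fraction,
        clusters_mean_offspring=clusters_mean_offspring,
        cluster_sd_um=cluster_sd_um,
        edge_bias=edge_bias,
        edge_rim_frac=edge_rim_frac,
        cell_radius_um=cell_radius_um,
        seed=seed,
    )
    shape = _TumorShape(spec, rng)
    shape.z0 = 0.0
    shape.c = 1.0

    n_cluster = int(round(cluster_fraction * n_points))
    n_edge = min(int(round(edge_bias * n_points)), n_points - n_cluster)
    n_uniform = n_points - n_cluster - n_edge
    pts3 = np.concatenate(
        [
            _sample_uniform_2d(shape, n_uniform, rng),
            _sample_clusters_2d(shape, n_cluster, rng),
            _sample_edge_2d(shape, n_edge, rng),
        ]
    )
    rng.shuffle(pts3, axis=0)
    points = pts3[:, :2]
    tumor_mask = shape.section_mask(0.0)
    nsc_mask = rasterize_disks(
        points, cell_radius_um, tumor_mask.shape, pixel_size_um
    )
    return points, nsc_mask, tumor_mask


def _sample_uniform_2d(
    shape: _TumorShape, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points in the z = 0 cross-section (true planar CSR)."""
    if n == 0:
        return np.empty((0, 3))
    smax = 1.0 + float(np.sum(shape.amps))
    out: list[np.ndarray] = []
    got = 0
    while got < n:
        m = max(4 * (n - got), 64)
        u = rng.uniform(-smax, smax, m)
        v = rng.uniform(-smax, smax, m)
        theta = np.arctan2(v, u)
        keep = u**2 + v**2 <= shape.boundary_scale(theta) ** 2
        pts = np.column_stack(
            [
                shape.cx + shape.a * u[keep],
                shape.cy + shape.b * v[keep],
                np.zeros(keep.sum()),
            ]
        )
        out.append(pts)
        got += len(pts)
    return np.concatenate(out)[:n]


def _sample_edge_2d(
    shape: _TumorShape, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Planar points pushed into the boundary rim of the z = 0 section."""
    if n == 0:
        return np.empty((0, 3))
    spec = shape.spec
    theta = rng.uniform(0, 2 * np.pi, n)
    limit = shape.boundary_scale(theta)
    target = limit * rng.uniform(1 - spec.edge_rim_frac, 1.0, n)
    return np.column_stack(
        [
            shape.cx + shape.a * target * np.cos(theta),
            shape.cy + shape.b * target * np.sin(theta),
            np.zeros(n),
        ]
    )


def _sample_clusters_2d(
    shape: _TumorShape, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Planar Thomas process inside the z = 0 cross-section."""
    if n == 0:
        return np.empty((0, 3))
    spec = shape.spec
    n_parents = max(1, int(round(n / spec.clusters_mean_offspring)))
    parents = _sample_uniform_2d(shape, n_parents, rng)
    assignment = rng.multinomial(n, np.full(n_parents, 1.0 / n_parents))
    pts = np.empty((n, 3))
    i = 0
    for parent, k in zip(parents, assignment):
        for _ in range(k):
            for _try in range(200):
                cand = parent.copy()
                cand[:2] += rng.normal(0, spec.cluster_sd_um, 2)
                if shape.contains(cand[None, :])[0]:
                    pts[i] = cand
                    break
            else:
                pts[i] = parent
            i += 1
    return pts
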