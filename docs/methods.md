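# Methods

This note documents the models and procedures implemented in
`nscquant`, the defaults they use, what the synthetic phantoms do and
do not emulate, and the numerical choices that make results
reproducible.

## Stain model and separation

Brightfield chromagens are absorbers, so each RGB channel follows the
Beer–Lambert law, `I = I0·10^(−OD)`. In optical-density space the
contributions of co-localized stains add linearly: `OD = M·c`, where
the columns of M are unit RGB absorbance vectors (one per stain) and c
the per-pixel stain concentrations. Unmixing is the per-pixel solve of
this 3×3 system (Ruifrok–Johnston color deconvolution). Conversions
use base-10 logarithms with an intensity floor of 1 (so fully opaque
pixels yield finite density), and raw concentrations may be negative;
clipping happens only when masks are built.

When only two stain vectors are given, the third basis vector is
completed per channel as `sqrt(1 − a² − b²)` and normalized (the
convention of the widely used deconvolution plugin), so the system is
always invertible; a singular basis raises an error.

Defaults:

* hematoxylin/DAB vectors: the published calibration
  (H = (0.650, 0.704, 0.286), DAB = (0.269, 0.568, 0.778));
* Prussian blue/pararosaniline: no published calibration exists, so the
  defaults are the vectors used by the synthetic renderer
  (PB = (0.75, 0.58, 0.32), PR = (0.10, 0.79, 0.60), normalized) and
  are configurable for real slides, as are all thresholds;
* segmentation: fixed concentration threshold 0.5 (an Otsu mode is
  available), 8-connected components, objects under 10 px removed.
  8-connectivity is the natural choice for blob-like cells and is
  stated explicitly because it affects object counts.

## Cell counting

Two modes, as used in practice for densely labeled slides:

* **pixel-ratio**: marked area ÷ mean single-cell area. Default mean
  area 64 µm², i.e. a 9 µm-diameter cell from the 8–10 µm range
  typical of these NSCs; configurable. Counts are kept as reals so that
  serial-section extrapolation stays linear; rounding is a
  presentation decision.
* **object detection**: one count per 8-connected component within an
  area window, with unweighted pixel centroids for spatial statistics.
  Touching cells are not split (no watershed); the pixel-ratio mode is
  the robust counter in dense fields.

Coordinates are 0-based pixel indices with x = column·pixel size,
y = row·pixel size, origin at the center of the top-left pixel — one
convention, used everywhere including the phantom truth.

## Coverage within a radius of action

A tumor pixel is covered when the Euclidean distance from its center
to the nearest NSC-marked pixel center is ≤ r. This is computed by
thresholding the exact Euclidean distance transform of the NSC-mask
complement and is identical — not approximately, but pixel-for-pixel —
to a brute-force nearest-NSC search; the test suite enforces exact
agreement on random mask pairs, and a second independent route
(dilation by an exact lattice disk) is also checked. Pixel centers,
not corners, define distances. Measuring from the NSC *pixel* rather
than a reconstructed cell boundary matches the marked-area convention
at ~1 µm/pixel, where cells are only a few pixels wide.

The two stains live on consecutive sections; the pipeline assumes the
pair is registered and offers only a rigid-offset hook (phantoms are
generated aligned). Coverage of an empty NSC mask is 0% — sections are
evaluated with or without NSCs — while an empty tumor mask is an error.

The **theoretical maximum** for n cells in tumor area A assumes
homogeneously placed, non-overlapping effective disks fully inside the
tumor: `min(100, 100·n·π(r + r_cell)²/A)` with r_cell = 4.5 µm.
**Efficiency** is observed/theoretical; values can exceed 1 only
through the 100% cap and are returned unclipped so the anomaly stays
visible.

## Volumetry and serial-section extrapolation

The sampling scheme is 10 µm sections with one analyzed section per
200 µm. Volume is the plain Cavalieri sum `Σ Aᵢ·Δz` (no end
correction — the estimator is unbiased under a uniform random offset,
and the refinement property is tested in that averaged sense). Counts
extrapolate by the factor Δz/t = 20: each analyzed section stands for
its group. Whether one or both sections of a slide were counted in any
given historical dataset is not always recorded; the factor is
configurable. Whole-tumor coverage is the tumor-area-weighted mean of
per-section coverage, which equals the volume-exposure fraction under
the Cavalieri approximation. Unit conversions (µm³→mm³, factor 10⁹)
live in one place and are unit-tested.

## Diffusion model

For a ~60 kDa enzyme, free-solution D = 4.3×10⁻⁷ cm²/s and brain
tortuosity λ = 2.25 give `D* = D/λ² = 8.5×10⁻⁸ cm²/s`. The
steady-state relative concentration from a non-depleting source with
first-order elimination kₑ is `C/C₀ = exp(−x√(kₑ/D*))`. kₑ is never
defaulted — it must be supplied directly or as a half-life — because
elimination of a secreted enzyme is preparation-specific. Distances
are in µm and D* is converted internally (1 cm² = 10⁸ µm², exact).

A consequence of the closed form worth noting: it is multiplicative in
distance, so a profile passing 50% at 25 µm must pass exactly 25% at
50 µm. Published roundings sometimes quote ~24% at 50 µm for such a
profile; the formula as stated is implemented without adjustment.

## Clustering index

Clusters are single-linkage connected components of the graph joining
cell pairs with d ≤ 50 µm (ties at exactly the radius connect —
declared for determinism). `CI = 1 − n_clusters/N` is 0 when every
cell is isolated and reaches its maximum 1 − 1/N (strictly below 1)
when all cells form one cluster; the formula is taken as the
definition. Single linkage is the minimal rule consistent with
defining clustering purely by pairwise distances and one radius;
density-based alternatives would add unstated parameters.

## Synthetic phantoms

`phantom.generate_phantom` builds a 3-D tumor blob — an ellipsoid
whose in-plane boundary radius is modulated by cosine harmonics of
orders 2–5 (amplitude ∝ irregularity/(m−1), random phases) — and an
NSC point pattern mixing three components: uniform interior points, a
Thomas process (Gaussian offspring of sd `cluster_sd_um` around
uniform parents, ~8 offspring per parent), and points pushed into a
rim at the in-plane tumor edge. The Thomas process was chosen because
its two knobs (parent count, offspring spread) map directly onto
"how many clusters" and "how tight". Sections at 200 µm spacing are
rendered as aligned slide pairs through the same Beer–Lambert model
the unmixing inverts: stain concentration 1.0 on cells/tumor,
counterstain 0.25 everywhere, RGB = 255·10^(−OD) plus Gaussian
intensity noise (sd 2 by default), kept as floats so the noise-free
model is exactly invertible.

The modulated-ellipsoid geometry keeps the truth closed-form: the
cross-section at normalized depth w has area `πab(1−w²)·K` with
`K = 1 + ½Σ amplitude²`, so the volume is `(4/3)πabc·K`. Ground-truth
coverage is computed by exact per-pixel nearest-NSC-pixel search
(verified against a literal double loop and against lattice-disk
dilation), never by the pipeline's own code path.

Default study conditions: 512×512 px at 1 µm/px (a desk-scale stand-in
for ~15,000 px whole-slide scans), 12 sections at 200 µm, tumor
semi-axes (200, 160, 800) µm, irregularity 0.08, 3000 NSCs at 55%
retention of the administered dose — placing density in the
10⁴–10⁵ /mm³ range and the retained dose fraction in the 50–60% band
seen for intracerebral delivery — with 50% of cells clustered
(sd 25 µm) and 20% edge-biased, mirroring the common observation that
NSCs sit in clumps near tumor margins. The axial center gets a random
sub-spacing offset so section depths never align with the blob's
symmetry plane.

What phantoms deliberately do **not** emulate: brain anatomy and
texture, section tearing/folding and scanner artifacts, registration
error between consecutive slides, stain-vector variability between
batches, and partial-volume effects at cell boundaries. Passing tests
therefore demonstrate correctness of the measurement chain under known
optics and geometry, not robustness to histology artifacts — thresholds
and stain vectors must still be calibrated on real material.

Trend studies use single-section patterns
(`generate_section_pattern`). The efficiency-vs-clustering sweep runs
40 cells in a 240 µm-radius tumor at r = 25 µm so the theoretical
maximum stays below its 100% cap; in saturated geometries (big radius,
small tumor) efficiency is pinned near observed/100 and the clustering
signal disappears. Dose series use nested prefixes of one shuffled
realization, which makes coverage provably non-decreasing in dose at
fixed geometry.

## Statistics

OLS r² with the two-sided slope p, Spearman rank correlation with
mid-ranks for ties, and Welch's t with Welch–Satterthwaite degrees of
freedom — each validated against hand-computed closed forms to 1e-12.
Raw p-values are reported without multiple-testing correction, and
regressions are fitted on linear values (log-scale axes are a display
choice, available by flag, that never alters the fit).

## Problem sizes

Default analyses run at 512×512 px × 12 sections per brain and
30-phantom sweeps; these sizes make the full suite and the acceptance
script complete in minutes on one CPU while keeping the physical
sampling scheme (section thickness, spacing, cell size, radii) at its
real-world values.

## Known limitations

* Pixel-ratio counting undercounts when rendered cells overlap
  (merged disks share pixels); with the default clustering this bias
  is a few percent and is covered by the recovery tolerance.
* Serial-section count extrapolation is unbiased but noisy when cells
  cluster along the axis: only ~1/20 of cells fall in analyzed slabs
  and clusters enter slabs together, over-dispersing the counts. Under
  the default conditions the extrapolation error has a standard
  deviation near 8% of the true total, so individual realizations can
  occasionally miss by more than 15% purely through sampling.
* The coverage construction is 2-D within sections; no 3-D sphere
  union across sections is attempted.
* Clustering is planar and per-section; clusters spanning sections are
  not linked.
* The diffusion model is a steady-state point-source closed form — no
  geometry, binding, or prodrug-conversion kinetics.
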