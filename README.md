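# nscquant

Quantitative biodistribution of therapeutic neural stem cells (NSCs) in
serially sectioned, two-stain brightfield histology.

Tumor-tropic NSCs engineered to secrete a prodrug-activating enzyme
(e.g. carboxylesterase, which converts CPT-11/irinotecan to SN-38) are a
candidate delivery vehicle for brain-tumor chemotherapy. Assessing them
requires answering quantitative questions from conventional FFPE serial
sections: how many NSCs reached the tumor, what fraction of the
administered dose does that represent, how are they distributed in
space, and what fraction of the tumor would be exposed to the secreted
enzyme? `nscquant` implements that analysis as a tested, reusable
pipeline for pairs of consecutive sections — one slide stained for
iron-loaded NSCs (Prussian blue with pararosaniline counterstain), the
next for tumor cells (DAB with hematoxylin) — and ships a seeded
synthetic-histology generator with exact ground truth so every stage is
verifiable without slide data.

## What it computes

* **Stain separation** — Beer–Lambert optical density
  `OD = −log10(I/I0)` per channel, unmixed by color deconvolution:
  per-pixel solve of `OD = M·c` with M the 3×3 matrix of unit stain
  absorbance vectors (Ruifrok–Johnston), then fixed-threshold
  segmentation into NSC and tumor masks.
* **Cell quantification** — NSC counts by the pixel-ratio rule
  (marked area ÷ mean single-cell area, default 64 µm² from 8–10 µm
  cells) and by resolved connected components with centroids; tumor
  area per section.
* **Coverage mapping** — percent of tumor pixels within a radius of
  action *r* (default 25 and 50 µm) of the nearest NSC pixel, via the
  exact Euclidean distance transform; the theoretical maximum for *n*
  homogeneously spread cells, `min(100, 100·n·π(r+r_cell)²/A)`; and the
  coverage efficiency observed/theoretical.
* **Volumetry** — Cavalieri tumor volume `V = Σ Aᵢ·Δz` and
  whole-stack NSC totals `N = Σ nᵢ·(Δz/t)` for the standard scheme of
  10 µm sections analyzed every Δz = 200 µm; NSC density and percent
  of administered dose.
* **Spatial statistics** — pairwise Euclidean distances,
  single-linkage clusters at a 50 µm clustering radius, and the
  clustering index `CI = 1 − n_clusters/N` (0 = fully dispersed,
  → 1 − 1/N for one cluster).
* **Diffusion model** — tortuosity-adjusted coefficient `D* = D/λ²`
  (λ = 2.25 for a ~60 kDa enzyme in brain) and the steady-state
  profile `C/C₀ = exp(−x·√(kₑ/D*))` with `kₑ = ln 2 / t½`.
* **Cohort statistics** — OLS regressions (r², slope p), Spearman
  rank correlation, and Welch's unequal-variance t test.

## Worked example

```python
from nscquant.phantom import PhantomSpec, generate_phantom
from nscquant.pipeline import process_brain
from nscquant.diffusion import effective_diffusion

pairs, truth = generate_phantom(PhantomSpec(seed=1))   # 12 paired slides
quants, brain = process_brain(pairs, "demo", truth.administered_count)

print(f"D*                = {effective_diffusion(4.3e-7, 2.25):.2g} cm^2/s")
print(f"tumor volume      = {brain.tumor_volume_mm3:.4f} mm^3 "
      f"(true ellipsoid {truth.volume_ellipsoid_mm3:.4f})")
print(f"NSC total         = {brain.total_nsc_count:.0f} (seeded {truth.n_nsc_total})")
print(f"% dose at tumor   = {brain.pct_at_tumor:.1f}%")
print(f"coverage (50 um)  = {brain.whole_tumor_coverage_pct[50.0]:.1f}% of tumor")
```

Output:

```
D*                = 8.5e-08 cm^2/s
tumor volume      = 0.1082 mm^3 (true ellipsoid 0.1072)
NSC total         = 3064 (seeded 3000)
% dose at tumor   = 56.2%
coverage (50 um)  = 86.8% of tumor
```

The phantom seeds 3000 NSCs (55% retention of a ~5455-cell dose) into
an irregular ellipsoidal tumor; the pipeline recovers the total within
a few percent, the Cavalieri volume within 1%, and per-section coverage
exactly (the distance-transform coverage is provably identical to a
brute-force nearest-NSC search).

A CLI mirrors the library: `nscquant simulate | separate | quantify |
coverage | volume | diffusion | report` (see `nscquant --help`).

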