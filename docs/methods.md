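# Methods

This note documents the models, algorithms and parameter choices behind
canopygen, and what its synthetic-data experiments do and do not
demonstrate about real survey data.

## Canopy surfaces

**Ground classification.** Points are binned into horizontal cells
(default 1.0 m). Within each cell, points within `k_mad` (default 3)
median-absolute-deviations of the cell's lowest point are labelled
ground. The MAD measures terrain roughness and is pooled: it is the
median over cells of the per-cell MAD of height-above-cell-minimum
(computed over points within 0.5 m of the minimum). Pooling is what
makes the rule robust in cells dominated by trunk or crown returns —
a cell's own spread would otherwise widen its ground band and swallow
vegetation. On noise-free terrain the band collapses and only exact
cell minima are ground. This per-cell lowest-point rule is a
deliberately simple, fully deterministic stand-in for cloth-simulation
filtering; on the gently sloped, desk-scale terrain targeted here the
two are equivalent, and a cloth-simulation backend could be added
behind the same contract.

**Rasters.** The DTM is the per-cell mean of ground points, the DSM the
per-cell maximum of all points (point-to-raster), both at 0.25 m cells
by default (≥ 10 points/cell at typical close-range survey densities).
Empty cells are filled by inverse-distance weighting from the ≤ 8
nearest valid cells. CHM = DSM − DTM with negatives clamped to zero;
DSM and DTM themselves are never clamped. Height normalization
subtracts a bilinear interpolation of the DTM at each point; points
more than 0.5 m below ground are flagged noise, points outside the DTM
extent are an error.

## Tree segmentation

Apexes are cells that are the strict maximum of a circular CHM window
(radius 1.5 m — below half the minimum 6 m tree spacing, above
crown-texture scale) and at least 2.6 m tall; ties break toward the
smaller (row, col). Crowns grow from each apex over 4-connected cells
that exceed 0.45 × apex height and 0.55 × the crown's running mean
height, within 2.5 m of the apex; contested cells go to the nearer
apex. The 0.45/0.55 thresholds are the published defaults of the
Dalponte CHM-based algorithm; the 2.6 m / 2.5 m limits match the
plantation design this pipeline targets. Apexes are processed in
descending height and cells breadth-first, so segmentation is exactly
reproducible. Per-tree clouds take every non-ground point whose (x, y)
cell belongs to the crown; points above apex + 0.5 m and k-NN
statistical outliers (mean 8-neighbour distance > μ + 3σ) are removed,
and segments under 50 points are flagged sparse and excluded from trait
extraction.

## Trait extraction

All heights are above-ground. H is the global maximum height — a
conifer apex sits on the stem axis, so the maximum *outside* a trunk
radius (computed and logged for comparison) would miss it.

CBH bins points into 0.25 m slices and computes the standard deviation
of horizontal distance to the trunk axis (centroid of points below
min(1 m, 0.2 H)) per slice. The trunk baseline is the *narrowest*
slice spread in that axis region — the median would be contaminated
whenever the crown starts below 1 m. CBH is the lower edge of the
lowest slice at or above 0.3 m whose spread exceeds 3 × baseline for
two consecutive slices. A baseline above 0.12 m means there is no bare
trunk (a ground-hugging crown) and CBH = 0; no qualifying slice at all
(a bare pole) is an error and the trait is reported missing.

CW is the maximum over slices of the slice's convex-hull diameter, CWH
the mid-height of the arg-max slice (ties to the lowest). CA is the
area of the 2-D convex hull of the crown's (x, y) projection — the
parameter-free choice; an alpha-shape would track concave crowns more
tightly but needs a tuned radius. CV uses an ellipsoid of revolution
with semi-axes (CW/2, CW/2, CL/2): CW and CL are the only diameters
the point cloud provides. DBH is deliberately not computed: on young
plantations branching often starts below breast height.

Slice-quantized traits (CBH, CWH) are exact only to the 0.25 m slice;
the scale-covariance tests therefore scale the slice height together
with the cloud.

## Mixed models and REML

The phenotype model is `y = Xm + Z₁b + Z₂f + e` with fixed intercept
and site (site omitted in per-site fits), random block and family
effects, and optionally a family-by-site interaction or a genomic
effect with covariance σ²_g K. REML profiles the residual variance out
and maximizes the restricted likelihood over log variance ratios: a
bounded Brent search for one ratio, Nelder-Mead from the best point of
a coarse grid for several. When every random term is an incidence
matrix, solves use the Woodbury identity (cost scales with the number
of random levels, not n). A ratio shrinking below 1e-8 is reported as
an exact zero with a boundary flag; estimates are never clamped
otherwise. The genomic model is rotated into the eigenbasis of K so the
whole fit is one-dimensional; the eigendecomposition is reused by the
GWAS scan.

Correctness anchors: on balanced one-way designs REML equals the
closed-form ANOVA estimator to 1e-6; on tiny unbalanced data the
optimum beats a 50 × 50 grid over (σ²_f, σ²_e); the eigenbasis genomic
fit equals the direct dense fit to 1e-6.

**Heritability.** The open-pollination multiplier is 2.5 rather than
the idealized half-sib 4: open-pollinated families contain a mix of
half- and full-sibs plus selfs, so the effective additive relationship
is taken as 1/2.5. The same multiplier is applied in the genomic
formula; both are configurable (`h2_coefficient`). Estimates above 1
are reported with a warning, never truncated — transparency of the
formula's behaviour beats cosmetic clamping.

**Genetic correlations.** The family covariance of two traits uses the
sum-trait identity cov_f(i,j) = [var_f(i+j) − var_f(i) − var_f(j)]/2,
each variance from the scalar REML core — exactly equivalent to a
bivariate fit for this quantity and testable against the same oracles.
The default denominator is √(var_i · var_j); a sum-denominator variant
√(var_i + var_j) is available behind `printed_denominator=True` for
comparability with analyses that report it (it is not a correlation
and is not bounded by 1). The SNP-based correlation is the uncentered
correlation of per-SNP effect vectors, bounded in [−1, 1] by
Cauchy–Schwarz.

**Breeding values.** BV = G + G×E with G the family main-effect BLUP
from the pooled fit and G×E the family-by-site BLUP (zero for a single
site, so BV = G exactly). Standardized BVs are z-scores across families
within trait × site, the form used for multi-trait radar comparisons.

## GWAS

QC drops SNPs by call rate (< 0.9) then MAF (< 0.05, from non-missing
calls); survivors are mean-imputed. The thresholds are conventional
defaults and exposed in `RunConfig`. The kinship is the Yang (GCTA)
estimator with the adjusted diagonal; monomorphic SNPs are skipped with
a count. The scan estimates (σ²_g, σ²_e) once per trait under the
no-SNP null and tests every SNP by GLS with V fixed — the EMMAX/P3D
scheme that makes a 50k-SNP scan run in seconds — using a single
eigendecomposition of K. Wald statistics are referred to χ²(1);
a SNP collinear with the fixed effects gets a missing p with a flag.
Significance uses the fixed thresholds −log10 p > 4 (α≈0.05 class) and
> 5 (α≈0.01 class) with no further multiple-testing correction, and
the per-trait significant sets feed a cross-trait overlap table.
Population-structure PCs, LD pruning and genomic control are
deliberately out of scope: correction is by kinship only.

## Synthetic data

**Trees.** A trunk cylinder (radius 0.1 m) from the ground to CBH plus
a crown solid of revolution whose radius is (CW/2)·profile(z), with
profile = ((z−CBH)/(CWH−CBH))^κ below CWH and ((H−z)/(H−CWH))^κ above,
κ = 0.5 — a rounded young-conifer silhouette with the widest point
controllable. Crown points are a 50/50 mixture of envelope points
(density ∝ circumference, as photogrammetry reconstructs the outer
surface) and uniform-in-volume interior points; 5% of points sit on the
trunk, matching the weak trunk visibility of close-range RGB
photogrammetry. Isotropic Gaussian jitter (default 2 cm, the RTK/
reconstruction error scale) is added; the apex point is pinned so the
pre-jitter maximum equals H. Trait truth (CA = π(CW/2)², CL = H − CBH,
CV from the ellipsoid formula) comes from the parameters, never from
the cloud.

**Stands.** Trees on a 6 m × 8 m grid over a sloped plane, with ground
points at 20/m². What the generator does *not* emulate: occlusion,
multi-return physics, understory, crown asymmetry and interlocking
crowns. Passing segmentation tests therefore demonstrates algorithmic
correctness at the design spacing, not robustness to closed-canopy
stands.

**Genetics.** Each of 20 families has one mother drawn from
Hardy-Weinberg at allele frequencies uniform on [0.05, 0.5]; every
offspring receives one maternal gamete by Mendelian drop and one
pollen-pool gamete drawn at the population frequency (an independent
father per offspring — half-sibs, expected additive relationship 0.25,
checked empirically rather than assumed). Phenotypes follow the block +
family (+ family-by-site) model with chosen variances; QTLs are planted
by variance fraction, or a genome-wide polygenic background is scaled
to a target heritability ratio. No linkage map or recombination
hotspots: SNPs are transmitted independently, so LD exists only through
family structure.

## Verification experiment sizes

The acceptance experiments use: 100 randomized trees (H ∈ [4,12] m,
CBH ∈ [0.5,4] m, CW ∈ [1.5,5] m, 10⁴ points/tree, 2 cm noise); a
40-tree stand; 100 REML replicates per heritability level at 20
families × 20 trees; a 20 × 10 panel with 5,000 SNPs for kinship; 20
null GWAS replicates at n = 200 with 2,000 SNPs and polygenic h² = 0.3;
50 power replicates at n = 400 with one QTL at 15% of phenotypic
variance. These sizes mirror the scale of a real two-site,
20-family trial while keeping the full verification run around half a
minute on one CPU.

## Known limitations

- The CHM-based segmentation cannot separate crowns that merge at the
  raster scale; a point-cloud-native segmenter is out of scope.
- CBH detection assumes a visible trunk gap below the crown; densely
  branched trees to the ground return CBH = 0 by design.
- The 2.5 multiplier treats the open-pollination relationship as known;
  misspecification scales h² proportionally.
- The printed-denominator genetic-correlation variant is reported only
  for comparability and should not be interpreted as a correlation.
- GWAS p-values assume the P3D approximation (null variance reused per
  SNP); for very large single-SNP effects an exact per-SNP REML would
  differ slightly.
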