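# canopygen

UAV point-cloud phenotyping and quantitative genetics for conifer progeny
trials: extract crown morphology from 3-D point clouds of plantation
stands, estimate heritability, genetic correlations and breeding values
under a half-sib mixed model, and run a kinship-corrected per-SNP
association scan — all exercisable end to end on synthetic stands and
simulated open-pollinated genetics with known ground truth.

It is aimed at tree breeders and forest-genetics researchers who fly
photogrammetric (or lidar) surveys over young progeny trials and want a
tested, reproducible path from raw stand point clouds to per-SNP
association results.

## What it computes

**Canopy pipeline.** A stand cloud is ground-classified (per-cell
lowest-point rule with a robust MAD band), rastered into DTM / DSM and
their difference, the canopy height model (CHM). Trees are detected as
local CHM maxima (default minimum height 2.6 m) and crowns grown by
Dalponte-style region growing (default maximum crown radius 2.5 m). From
each normalized per-tree cloud seven traits are measured:

- `H` — tree height (max normalized height),
- `CBH` — crown base height, from the jump in per-slice horizontal
  spread above the trunk baseline,
- `CL = H − CBH` — crown length,
- `CW`, `CWH` — widest horizontal crown extent over 0.25 m height
  slices (convex-hull diameter) and the height at which it occurs,
- `CA` — projected crown area (2-D convex hull),
- `CV = (4/3)π (CW/2)² (CL/2)` — ellipsoid-of-revolution crown volume.

**Quantitative genetics.** Each trait is analysed under the half-sib
mixed model

```
y = X m + Z₁ b + Z₂ f + e ,    b ~ N(0, σ²_b),  f ~ N(0, σ²_f),  e ~ N(0, σ²_e)
```

fitted by REML (profiled restricted likelihood over log variance
ratios). Open-pollinated narrow-sense heritability uses the conventional
multiplier 2.5 (configurable):

```
h² = 2.5 σ²_f / (σ²_f + σ²_b + σ²_e)        (pedigree)
h²_SNP = 2.5 σ²_g / (σ²_g + σ²_e)           (genomic, V = σ²_g K + σ²_e I)
```

Genetic correlations come from the sum-trait variance identity
(pedigree) or the uncentered correlation of per-SNP effect vectors
(genomic). Family breeding values are `BV = G + G×E` (family BLUP plus
family-by-site BLUP), standardized within trait × site.

**GWAS.** SNPs pass MAF / call-rate QC, the Yang (GCTA) genomic
relationship matrix is built, and each SNP is tested by generalized
least squares with the polygenic covariance fixed at its null REML
estimate (the EMMAX/P3D scheme, one eigendecomposition of K per scan).
Significance classes use fixed −log10 p thresholds 4 and 5.

**Synthetic data.** Parametric conifers (trunk cylinder + crown solid of
revolution with a piecewise power profile) give point clouds whose seven
traits are known exactly; a gamete-drop simulator produces
open-pollinated families, SNP panels and phenotypes with known variance
components, planted QTLs or a polygenic background.

## Worked example

```bash
canopygen run --seed 3 --out demo --n-trees 4
```

simulates a 4-tree stand plus a 10-family × 2-site progeny trial, runs
every stage and writes 18 tables with a `manifest.json` of checksums.
`demo/trait_validation.csv` compares extracted traits against the
generator's truth:

```
trait  n    r2  rmse   bias
   CA  4 0.999 0.239 -0.113
  CBH  4 0.962 0.147 -0.041
   CL  4 0.997 0.120  0.012
   CV  4 0.999 1.530  1.220
   CW  4 0.999 0.048  0.043
  CWH  4 0.996 0.117  0.064
    H  4 1.000 0.059 -0.030
```

i.e. every trait is recovered with R² ≥ 0.96; RMSE is in metres (m² for
CA, m³ for CV). `demo/heritability.csv` holds the pooled pedigree
heritabilities of the simulated traits (planted at 0.5 here, estimated
0.36 and 0.42 — within sampling error for 10 families):

```
trait   site   method    h2  warning
   T1 pooled pedigree 0.363    False
   T2 pooled pedigree 0.415    False
```

`demo/gwas_T1.csv` carries per-SNP effects, Wald p-values and
significance classes; `demo/manhattan_T1.csv` adds cumulative genome
coordinates for plotting. Re-running with the same seed reproduces every
file bit-identically.

The same stages are available individually (`canopygen simulate |
surfaces | segment | traits | quantgen | gwas | validate`), each
accepting `--config` (YAML of every tunable parameter), `--seed` and
`--out`, and the underlying functions are importable from
`canopygen.surfaces`, `canopygen.traits`, `canopygen.quantgen`,
`canopygen.gwas`, etc.

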