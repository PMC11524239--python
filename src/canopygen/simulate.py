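"""Synthetic stands and half-sib genetics with known ground truth.

Two generators:

* parametric conifer point clouds — a trunk cylinder topped by a solid of
  revolution whose radius follows a piecewise power law in height, so the
  seven morphological traits (CA, CBH, CL, CV, CW, CWH, H) are known
  exactly from the parameters;
* an open-pollinated (half-sib) progeny trial — one known mother per
  family, a random pollen parent per offspring, Mendelian gamete drop at
  each SNP, and phenotypes drawn from the block + family (+ family-by-site)
  mixed model with optional planted QTLs or a polygenic background.

Everything is deterministic under a fixed seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (GROUND, NONGROUND, GenotypeMatrix, PointCloud,
                        TraitRecord, make_snp_metadata, trait_frame)


# ---------------------------------------------------------------------------
# parametric tree clouds
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTreeParams:
    """Parameters of one parametric conifer.

    The crown is a solid of revolution: radius at height z equals
    ``(cw/2) * profile(z)`` where the profile rises as
    ``((z-cbh)/(cwh-cbh))**kappa`` below the widest point and falls as
    ``((h-z)/(h-cwh))**kappa`` above it.  ``kappa=0.5`` gives the rounded
    conifer silhouette typical of young plantation pines.
    """

    x: float = 0.0
    y: float = 0.0
    height: float = 10.0          # H, m
    cbh: float = 3.0              # crown base height, m
    cw: float = 4.0               # maximum crown width (diameter), m
    cwh: float = 6.0              # height of maximum width, m
    kappa: float = 0.5
    trunk_radius: float = 0.1     # m
    n_points: int = 10_000        # total points for this tree
    trunk_fraction: float = 0.05  # share of points on the trunk; photogrammetric
                                  # clouds are strongly canopy-surface-dominated
    surface_fraction: float = 0.5  # crown points on the crown envelope vs
                                   # filling the interior; photogrammetry
                                   # reconstructs mostly the outer surface
    noise_sd: float = 0.02        # isotropic Gaussian jitter, m

    def validate(self) -> None:
        if not (0 <= self.cbh < self.cwh < self.height):
            raise ValueError(
                f"require 0 <= CBH < CWH < H, got CBH={self.cbh}, "
                f"CWH={self.cwh}, H={self.height}")
        if self.cw <= 0:
            raise ValueError("CW must be > 0")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")

    def truth(self, tree_id: int = 0) -> TraitRecord:
        """Trait ground truth from the parameters (not from any cloud)."""
        cl = self.height - self.cbh
        return TraitRecord(
            tree_id=tree_id, x=self.x, y=self.y,
            CA=math.pi * (self.cw / 2) ** 2,
            CBH=self.cbh, CL=cl,
            CV=(4.0 / 3.0) * math.pi * (self.cw / 2) ** 2 * (cl / 2),
            CW=self.cw, CWH=self.cwh, H=self.height)


def crown_profile(z: np.ndarray, p: SyntheticTreeParams) -> np.ndarray:
    """Relative crown radius in [0, 1]; 0 at CBH and H, 1 at CWH."""
    z = np.asarray(z, dtype=float)
    below = ((z - p.cbh) / (p.cwh - p.cbh)).clip(0, 1) ** p.kappa
    above = ((p.height - z) / (p.height - p.cwh)).clip(0, 1) ** p.kappa
    return np.where(z <= p.cwh, below, above) * ((z >= p.cbh) & (z <= p.height))


def generate_tree_cloud(params: SyntheticTreeParams,
                        seed: int | np.random.Generator = 0,
                        ) -> tuple[PointCloud, TraitRecord]:
    """Sample a single-tree point cloud; heights are above-ground (z=0 at base)."""
    params.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = params.n_points
    n_trunk = (max(1, int(round(params.trunk_fraction * n)))
               if params.cbh > 0 else 0)
    n_crown = n - n_trunk

    pts = []
    if n_trunk:
        zt = rng.uniform(0, params.cbh, n_trunk)
        ang = rng.uniform(0, 2 * math.pi, n_trunk)
        pts.append(np.column_stack([params.trunk_radius * np.cos(ang),
                                    params.trunk_radius * np.sin(ang), zt]))
    if n_crown:
        n_surf = int(round(params.surface_fraction * n_crown))
        n_vol = n_crown - n_surf
        chunks = []
        if n_vol:
            # interior points, uniform in volume: accept z w.p. (r/rmax)^2
            zc = np.empty(0)
            while zc.size < n_vol:
                cand = rng.uniform(params.cbh, params.height, 2 * n_vol)
                keep = (rng.uniform(size=cand.size)
                        < crown_profile(cand, params) ** 2)
                zc = np.concatenate([zc, cand[keep]])
            zc = zc[:n_vol]
            r = ((params.cw / 2) * crown_profile(zc, params)
                 * np.sqrt(rng.uniform(size=n_vol)))
            chunks.append((zc, r))
        if n_surf:
            # envelope points: z density ~ circumference, radius = r(z)
            zs = np.empty(0)
            while zs.size < n_surf:
                cand = rng.uniform(params.cbh, params.height, 2 * n_surf)
                keep = (rng.uniform(size=cand.size)
                        < crown_profile(cand, params))
                zs = np.concatenate([zs, cand[keep]])
            zs = zs[:n_surf]
            chunks.append((zs, (params.cw / 2) * crown_profile(zs, params)))
        for zc, r in chunks:
            ang = rng.uniform(0, 2 * math.pi, len(zc))
            pts.append(np.column_stack([r * np.cos(ang), r * np.sin(ang), zc]))
    xyz = np.vstack(pts)
    # apex point pinned so max z equals H before jitter
    xyz[-1] = (0.0, 0.0, params.height)
    if params.noise_sd > 0:
        xyz = xyz + rng.normal(0, params.noise_sd, xyz.shape)
    xyz[:, 0] += params.x
    xyz[:, 1] += params.y
    cloud = PointCloud(xyz, class_label=np.full(len(xyz), NONGROUND))
    return cloud, params.truth()


def generate_stand(tree_params: list[SyntheticTreeParams],
                   spacing: tuple[float, float] = (6.0, 8.0),
                   ground_slope: tuple[float, float] = (0.0, 0.0),
                   ground_density: float = 20.0,
                   ground_noise_sd: float = 0.0,
                   margin: float = 3.0,
                   seed: int = 0,
                   ) -> tuple[PointCloud, pd.DataFrame]:
    """Place trees on a regular grid and add sloped planar ground points.

    Trees fill the grid row-major at the given (dx, dy) spacing; absolute
    z = ground(x_apex, y_apex) + height-above-ground.  Returns the merged
    cloud (with truth class labels and tree ids) and the truth table of
    apex positions and traits.
    """
    if not tree_params:
        raise ValueError("need at least one tree")
    dx, dy = spacing
    if dx <= 0 or dy <= 0:
        raise ValueError("spacing must be > 0")
    rng = np.random.default_rng(seed)
    n = len(tree_params)
    ncol = max(1, int(round(math.sqrt(n * dy / dx))))
    gx, gy = ground_slope

    clouds, truths = [], []
    for k, p in enumerate(tree_params):
        p.x = (k % ncol) * dx
        p.y = (k // ncol) * dy
        cloud, truth = generate_tree_cloud(p, rng)
        zg = gx * p.x + gy * p.y
        cloud.xyz[:, 2] += zg
        truth.tree_id = k
        rec = truth.as_dict()
        rec["ground_z"] = zg
        truths.append(rec)
        cloud.tree_id = np.full(len(cloud), k)
        clouds.append(cloud)

    xmax = ((n - 1) % ncol) * dx if n <= ncol else (ncol - 1) * dx
    ymax = ((n - 1) // ncol) * dy
    x0, x1 = -margin, xmax + margin
    y0, y1 = -margin, ymax + margin
    n_ground = max(1, int(ground_density * (x1 - x0) * (y1 - y0)))
    gxs = rng.uniform(x0, x1, n_ground)
    gys = rng.uniform(y0, y1, n_ground)
    gzs = gx * gxs + gy * gys
    if ground_noise_sd > 0:
        gzs = gzs + rng.normal(0, ground_noise_sd, n_ground)
    ground = PointCloud(np.column_stack([gxs, gys, gzs]),
                        class_label=np.full(n_ground, GROUND),
                        tree_id=np.full(n_ground, -1))

    xyz = np.vstack([ground.xyz] + [c.xyz for c in clouds])
    labels = np.concatenate([ground.class_label]
                            + [c.class_label for c in clouds])
    tids = np.concatenate([ground.tree_id] + [c.tree_id for c in clouds])
    truth_df = pd.DataFrame(truths).drop(columns=["flags"])
    return PointCloud(xyz, labels, tids), truth_df


def random_tree_params(rng: np.random.Generator,
                       h_range=(4.0, 12.0),
                       cbh_range=(0.5, 4.0),
                       cw_range=(1.5, 5.0),
                       n_points: int = 10_000,
                       noise_sd: float = 0.02) -> SyntheticTreeParams:
    """Randomized tree parameters spanning realistic young-pine morphology."""
    h = rng.uniform(*h_range)
    cbh = rng.uniform(cbh_range[0], min(cbh_range[1], 0.6 * h))
    cwh = cbh + rng.uniform(0.25, 0.55) * (h - cbh)
    cw = rng.uniform(*cw_range)
    return SyntheticTreeParams(height=h, cbh=cbh, cw=cw, cwh=cwh,
                               n_points=n_points, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# half-sib genetics
# ---------------------------------------------------------------------------

@dataclass
class TraitModel:
    """Variance-component model for one simulated trait.

    ``sigma2_f`` is the half-sib family variance, ``sigma2_b`` the block
    variance, ``sigma2_fs`` the family-by-site interaction variance and
    ``sigma2_e`` the residual.  ``qtls`` plants causal SNPs as
    (snp_index, fraction of total phenotypic variance) pairs;
    ``polygenic_h2`` instead spreads a genome-wide additive background so
    that the SNP-based heritability ratio equals the given value.
    """

    name: str = "trait"
    mu: float = 0.0
    sigma2_f: float = 1.0
    sigma2_b: float = 0.5
    sigma2_e: float = 3.5
    sigma2_fs: float = 0.0
    qtls: list[tuple[int, float]] = field(default_factory=list)
    polygenic_h2: float = 0.0

    def validate(self) -> None:
        for nm in ("sigma2_f", "sigma2_b", "sigma2_e", "sigma2_fs"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")
        if sum(f for _, f in self.qtls) >= 1:
            raise ValueError("QTL variance fractions must sum to < 1")
        if not 0 <= self.polygenic_h2 < 1:
            raise ValueError("polygenic_h2 must be in [0, 1)")


@dataclass
class SimulationConfig:
    """Design and genetic architecture of a simulated progeny trial.

    Defaults mirror a two-site open-pollinated trial of 20 families with
    10 trees per family per site and a 5,000-SNP panel with minor allele
    frequencies uniform on [0.05, 0.5].
    """

    n_families: int = 20
    trees_per_family: int = 10     # per site
    n_sites: int = 2
    n_blocks: int = 10             # per site
    traits: list[TraitModel] = field(default_factory=lambda: [TraitModel()])
    family_corr: np.ndarray | None = None   # family-effect correlation across traits
    site_effect_step: float = 0.5  # fixed effect of site s = s * step
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    n_scaffolds: int = 10
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_families, self.trees_per_family, self.n_sites,
               self.n_blocks, self.n_snps) < 1:
            raise ValueError("design counts must be >= 1")
        for t in self.traits:
            t.validate()
            for idx, _ in t.qtls:
                if not 0 <= idx < self.n_snps:
                    raise ValueError(f"QTL index {idx} out of range")
        if self.family_corr is not None:
            R = np.asarray(self.family_corr)
            if R.shape != (len(self.traits), len(self.traits)):
                raise ValueError("family_corr shape must be n_traits x n_traits")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    design: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: dict


def _mendelian_offspring(mothers: np.ndarray, p: np.ndarray, n_off: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Gamete drop: one maternal allele + one pollen-pool allele per SNP.

    ``mothers`` is (m,) dosages of one family's mother; returns
    (n_off, m) offspring dosages.  The pollen pool is the base population,
    so each offspring has an independent random father (half-sibs).
    """
    m = mothers.shape[0]
    maternal = np.where(mothers == 1,
                        rng.integers(0, 2, size=(n_off, m)),
                        (mothers // 2)[None, :])
    paternal = (rng.uniform(size=(n_off, m)) < p[None, :]).astype(int)
    return maternal + paternal


def simulate_genetics(config: SimulationConfig) -> SimulatedDataset:
    """Simulate the half-sib trial: genotypes, design table and phenotypes.

    Phenotype model per trait:
    ``y = mu + site + block + family [+ family-by-site] + QTL/polygenic + e``
    with blocks nested in sites.  All realized effect values are stored in
    ``truth`` for downstream recovery checks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nf, tpf, ns = config.n_families, config.trees_per_family, config.n_sites
    n = nf * tpf * ns
    m = config.n_snps

    # founder allele frequencies and maternal genotypes
    p = rng.uniform(*config.maf_range, m)
    mothers = rng.binomial(2, p, size=(nf, m))
    dosage = np.empty((n, m), dtype=float)
    fam_idx = np.empty(n, dtype=int)
    site_idx = np.empty(n, dtype=int)
    block_idx = np.empty(n, dtype=int)
    row = 0
    for f in range(nf):
        off = _mendelian_offspring(mothers[f], p, tpf * ns, rng)
        for s in range(ns):
            sl = slice(row, row + tpf)
            dosage[sl] = off[s * tpf:(s + 1) * tpf]
            fam_idx[sl] = f
            site_idx[sl] = s
            block_idx[sl] = (f + np.arange(tpf)) % config.n_blocks
            row += tpf
    if config.missing_rate > 0:
        miss = rng.uniform(size=dosage.shape) < config.missing_rate
        dosage[miss] = np.nan

    # SNP metadata over scaffolds in input order
    per_scaffold = int(np.ceil(m / config.n_scaffolds))
    scaffolds = [f"scaffold{1 + i // per_scaffold}" for i in range(m)]
    positions = [1000 * (1 + i % per_scaffold) for i in range(m)]
    snp_ids = [f"{sc}_{pos}" for sc, pos in zip(scaffolds, positions)]
    geno = GenotypeMatrix(dosage, [f"ind{i:04d}" for i in range(n)],
                          make_snp_metadata(snp_ids, scaffolds, positions))

    design = pd.DataFrame({
        "individual_id": geno.individual_ids,
        "family_id": [f"fam{f:02d}" for f in fam_idx],
        "site_id": [f"site{s}" for s in site_idx],
        "block_id": [f"site{s}-block{b:02d}" for s, b in zip(site_idx, block_idx)],
    })

    # family effects, optionally correlated across traits
    nt = len(config.traits)
    sds = np.array([math.sqrt(t.sigma2_f) for t in config.traits])
    if config.family_corr is not None:
        cov = np.outer(sds, sds) * np.asarray(config.family_corr, dtype=float)
        fam_eff = rng.multivariate_normal(np.zeros(nt), cov, size=nf)
    else:
        fam_eff = rng.normal(0, 1, size=(nf, nt)) * sds[None, :]

    pheno = pd.DataFrame({"individual_id": geno.individual_ids})
    truth: dict = {"allele_freq": p, "family": fam_idx, "site": site_idx,
                   "block": block_idx, "family_effects": {}, "block_effects": {},
                   "qtl_effects": {}, "polygenic_values": {},
                   "mothers": mothers}
    centered = np.nan_to_num(dosage - 2 * p[None, :])  # missing -> mean
    for t_i, tm in enumerate(config.traits):
        blk_eff = rng.normal(0, math.sqrt(tm.sigma2_b), size=(ns, config.n_blocks))
        fs_eff = (rng.normal(0, math.sqrt(tm.sigma2_fs), size=(nf, ns))
                  if tm.sigma2_fs > 0 else np.zeros((nf, ns)))
        e = rng.normal(0, math.sqrt(tm.sigma2_e), n)
        base_var = tm.sigma2_f + tm.sigma2_b + tm.sigma2_e + tm.sigma2_fs
        g = np.zeros(n)
        betas = {}
        if tm.polygenic_h2 > 0:
            b = rng.normal(0, 1, m)
            raw = centered @ b
            sd_raw = raw.std()
            target = tm.polygenic_h2 / (1 - tm.polygenic_h2) * base_var
            scale = math.sqrt(target) / sd_raw if sd_raw > 0 else 0.0
            g = raw * scale
            betas["polygenic"] = b * scale
        for idx, frac in tm.qtls:
            x = centered[:, idx]
            vx = x.var()
            beta = math.sqrt(frac / (1 - frac) * base_var / vx) if vx > 0 else 0.0
            g = g + x * beta
            betas[idx] = beta
        y = (tm.mu + config.site_effect_step * site_idx
             + blk_eff[site_idx, block_idx] + fam_eff[fam_idx, t_i]
             + fs_eff[fam_idx, site_idx] + g + e)
        pheno[tm.name] = y
        truth["family_effects"][tm.name] = fam_eff[:, t_i]
        truth["block_effects"][tm.name] = blk_eff
        truth["qtl_effects"][tm.name] = betas
        truth["polygenic_values"][tm.name] = g

    return SimulatedDataset(geno, design, pheno, truth)
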