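"""End-to-end orchestration: simulate -> surfaces -> segment -> traits ->
quantgen -> gwas, with a manifest of outputs, checksums and timings.

A single master seed fans out to per-stage seeds by fixed offsets so any
stage can be rerun in isolation and reproduce bit-identically.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas as gwas_mod
from . import io as io_mod
from . import quantgen as qg
from . import segmentation as seg_mod
from . import surfaces as surf_mod
from . import traits as traits_mod
from .config import RunConfig
from .datatypes import TRAIT_NAMES
from .simulate import (SimulationConfig, SyntheticTreeParams, TraitModel,
                       generate_stand, random_tree_params, simulate_genetics)

STAGE_SEED_OFFSETS = {"simulate_stand": 1, "simulate_genetics": 2,
                      "surfaces": 3, "segment": 4, "traits": 5,
                      "quantgen": 6, "gwas": 7}


class PipelineError(RuntimeError):
    def __init__(self, msg, manifest=None):
        super().__init__(msg)
        self.manifest = manifest


@dataclass
class RunManifest:
    seed: int
    config: dict
    stages: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)   # name -> {path, sha256}
    warnings: list = field(default_factory=list)

    def add_output(self, name: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.outputs[name] = {"path": str(path), "sha256": digest}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def validate_traits(extracted: pd.DataFrame, truth: pd.DataFrame,
                    r2_min: float = 0.9) -> pd.DataFrame:
    """Per-trait R^2, RMSE and bias of extracted vs truth, matched on tree_id."""
    merged = extracted.merge(truth, on="tree_id", suffixes=("_est", "_true"))
    if len(merged) < 3:
        raise ValueError("need >= 3 matched trees to validate")
    rows = []
    for t in TRAIT_NAMES:
        est = merged[f"{t}_est"].to_numpy(dtype=float)
        tru = merged[f"{t}_true"].to_numpy(dtype=float)
        ok = np.isfinite(est) & np.isfinite(tru)
        est, tru = est[ok], tru[ok]
        ss_res = ((est - tru) ** 2).sum()
        ss_tot = ((tru - tru.mean()) ** 2).sum()
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        rows.append({"trait": t, "n": int(ok.sum()), "r2": r2,
                     "rmse": float(np.sqrt(((est - tru) ** 2).mean())),
                     "bias": float((est - tru).mean())})
    out = pd.DataFrame(rows)
    out.attrs["all_pass"] = bool((out["r2"] > r2_min).all())
    return out


def run_pipeline(config: RunConfig, outdir: str | Path,
                 n_trees: int = 8, n_families: int = 10,
                 trees_per_family: int = 10, n_sites: int = 2,
                 n_snps: int = 1000, gwas_traits: int = 1,
                 stages: list[str] | None = None) -> RunManifest:
    """Run the full synthetic pipeline and write every table to ``outdir``.

    ``stages`` restricts execution (default: all).  Any stage failure
    aborts with a PipelineError carrying the manifest of completed
    stages.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = stages or list(STAGE_SEED_OFFSETS)
    manifest = RunManifest(seed=config.seed, config=config.__dict__.copy())
    seeds = {k: config.seed * 1000 + v for k, v in STAGE_SEED_OFFSETS.items()}
    state: dict = {}

    def stage(name):
        def deco(fn):
            if name not in enabled:
                return lambda: None
            def run():
                t0 = time.perf_counter()
                try:
                    fn()
                except Exception as exc:
                    manifest.stages.append(
                        {"name": name, "status": "failed", "error": str(exc)})
                    raise PipelineError(f"{name}: {exc}", manifest) from exc
                manifest.stages.append(
                    {"name": name, "status": "ok",
                     "seconds": round(time.perf_counter() - t0, 3)})
            return run
        return deco

    @stage("simulate_stand")
    def _simulate_stand():
        rng = np.random.default_rng(seeds["simulate_stand"])
        params = [random_tree_params(rng, n_points=4000) for _ in range(n_trees)]
        cloud, truth = generate_stand(params, ground_slope=(0.02, 0.0),
                                      seed=seeds["simulate_stand"])
        p = outdir / "stand.xyz"
        io_mod.write_point_cloud(cloud, p)
        truth.to_csv(outdir / "stand_truth.csv", index=False)
        manifest.add_output("stand", p)
        manifest.add_output("stand_truth", outdir / "stand_truth.csv")
        state["cloud"], state["truth"] = cloud, truth

    @stage("simulate_genetics")
    def _simulate_genetics():
        traits = [TraitModel(name=f"T{i+1}", sigma2_f=0.2, sigma2_b=0.1,
                             sigma2_e=0.7) for i in range(max(2, gwas_traits))]
        sim = simulate_genetics(SimulationConfig(
            n_families=n_families, trees_per_family=trees_per_family,
            n_sites=n_sites, n_snps=n_snps, traits=traits,
            seed=seeds["simulate_genetics"]))
        io_mod.write_genotypes(sim.genotypes, outdir / "genotypes.csv")
        io_mod.write_design_table(sim.design, outdir / "design.csv")
        io_mod.write_phenotype_table(sim.phenotypes, outdir / "phenotypes.csv")
        for n in ("genotypes", "design", "phenotypes"):
            manifest.add_output(n, outdir / f"{n}.csv")
        state["sim"] = sim

    @stage("surfaces")
    def _surfaces():
        if "cloud" not in state:
            raise FileNotFoundError("surfaces: missing stand point cloud")
        cloud = surf_mod.classify_ground(state["cloud"], config.ground_cell,
                                         config.ground_k_mad)
        dtm = surf_mod.build_dtm(cloud, config.raster_cell)
        dsm = surf_mod.build_dsm(cloud, config.raster_cell)
        chm = surf_mod.build_chm(dsm, dtm)
        for name, grid in (("dtm", dtm), ("dsm", dsm), ("chm", chm)):
            io_mod.write_raster(grid, outdir / f"{name}.csv")
            manifest.add_output(name, outdir / f"{name}.csv")
        state["chm"] = chm
        state["normalized"] = surf_mod.normalize_heights(cloud, dtm)

    @stage("segment")
    def _segment():
        if "chm" not in state:
            raise FileNotFoundError("segment: missing CHM input")
        apexes = seg_mod.detect_apexes(state["chm"], config.min_tree_height,
                                       config.apex_window_radius)
        segs = seg_mod.grow_crowns(state["chm"], apexes, config.th_seed,
                                   config.th_crown, config.max_crown_radius)
        segs = seg_mod.extract_tree_clouds(state["normalized"], segs,
                                           state["chm"])
        seg_mod.segment_table(segs).to_csv(outdir / "segments.csv", index=False)
        manifest.add_output("segments", outdir / "segments.csv")
        state["segments"] = segs

    @stage("traits")
    def _traits():
        if "segments" not in state:
            raise FileNotFoundError("traits: missing segments input")
        df = traits_mod.extract_all_traits(
            state["segments"], config.slice_height, config.cbh_spread_factor,
            config.min_cbh, config.trunk_radius)
        io_mod.write_trait_table(df, outdir / "traits.csv")
        manifest.add_output("traits", outdir / "traits.csv")
        state["trait_table"] = df

    @stage("quantgen")
    def _quantgen():
        if "sim" not in state:
            raise FileNotFoundError("quantgen: missing phenotype input")
        sim = state["sim"]
        trait_names = [c for c in sim.phenotypes.columns
                       if c != "individual_id"]
        df = sim.design.merge(sim.phenotypes, on="individual_id")
        sites = sorted(df["site_id"].unique())
        X = np.column_stack([np.ones(len(df))]
                            + [(df["site_id"] == s).astype(float).to_numpy()
                               for s in sites[1:]])
        re_b = qg.incidence(df["block_id"]); re_b.name = "block"
        re_f = qg.incidence(df["family_id"]); re_f.name = "family"
        h2_rows = []
        for t in trait_names:
            fit = qg.fit_reml(qg.MixedModelSpec(df[t].to_numpy(), X,
                                                [re_b, re_f]))
            est = qg.heritability_pedigree(fit.vc, config.h2_coefficient,
                                           trait=t)
            h2_rows.append({"trait": t, "site": "pooled", "method": "pedigree",
                            "h2": est.h2, "warning": est.warning})
        pd.DataFrame(h2_rows).to_csv(outdir / "heritability.csv", index=False)
        manifest.add_output("heritability", outdir / "heritability.csv")
        bv = qg.breeding_values(sim.phenotypes, sim.design, trait_names)
        bv.to_csv(outdir / "breeding_values.csv", index=False)
        manifest.add_output("breeding_values", outdir / "breeding_values.csv")

    @stage("gwas")
    def _gwas():
        if "sim" not in state:
            raise FileNotFoundError("gwas: missing genotype input")
        sim = state["sim"]
        geno, report = gwas_mod.qc_filter(sim.genotypes, config.maf_min,
                                          config.call_rate_min)
        K, _ = gwas_mod.yang_kinship(geno)
        io_mod.write_kinship(K, geno.individual_ids, outdir / "kinship.csv")
        manifest.add_output("kinship", outdir / "kinship.csv")
        (outdir / "qc_report.txt").write_text(
            "\n".join(f"{k}={v}" for k, v in report.__dict__.items()) + "\n")
        manifest.add_output("qc_report", outdir / "qc_report.txt")
        trait_names = [c for c in sim.phenotypes.columns
                       if c != "individual_id"][:gwas_traits]
        df = sim.design.merge(sim.phenotypes, on="individual_id")
        sites = sorted(df["site_id"].unique())
        X = np.column_stack([np.ones(len(df))]
                            + [(df["site_id"] == s).astype(float).to_numpy()
                               for s in sites[1:]])
        results = {}
        eig = None
        for t in trait_names:
            res = gwas_mod.gls_scan(df[t].to_numpy(), X, geno, K, eig=eig)
            res = gwas_mod.classify_significance(res, config.log10p_sig05,
                                                 config.log10p_sig01)
            res.to_csv(outdir / f"gwas_{t}.csv", index=False)
            manifest.add_output(f"gwas_{t}", outdir / f"gwas_{t}.csv")
            gwas_mod.export_manhattan_table(res, outdir / f"manhattan_{t}.csv")
            manifest.add_output(f"manhattan_{t}", outdir / f"manhattan_{t}.csv")
            results[t] = res
        _, overlap = gwas_mod.significant_sets(results, config.log10p_sig05)
        overlap.to_csv(outdir / "trait_overlap.csv", index=False)
        manifest.add_output("trait_overlap", outdir / "trait_overlap.csv")

    for fn in (_simulate_stand, _simulate_genetics, _surfaces, _segment,
               _traits, _quantgen, _gwas):
        fn()

    if "trait_table" in state and "truth" in state:
        try:
            report = validate_traits(state["trait_table"], state["truth"])
            report.to_csv(outdir / "trait_validation.csv", index=False)
            manifest.add_output("trait_validation",
                                outdir / "trait_validation.csv")
        except ValueError as exc:
            manifest.warnings.append(f"validate_traits: {exc}")

    manifest.to_json(outdir / "manifest.json")
    return manifest
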