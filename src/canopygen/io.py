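"""Readers and writers for every external format the pipeline touches.

All tables are CSV with a header; point clouds travel as plain XYZ text
(whitespace- or comma-separated, ``#`` comments allowed); rasters are CSV
grids with origin/cell in ``#`` header comments.  Readers never silently
drop data — skipped records are counted and logged.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (GenotypeMatrix, PointCloud, RasterGrid, TraitRecord,
                        make_snp_metadata, trait_frame)

logger = logging.getLogger("canopygen")


def log_kv(event: str, **kw) -> None:
    """Structured key=value log line."""
    logger.info("%s %s", event, " ".join(f"{k}={v}" for k, v in kw.items()))


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

def read_point_cloud(path: str | Path, format: str = "xyz") -> PointCloud:
    """Read a point cloud from XYZ text.

    Columns are ``x y z [class] [tree_id]``; rows may be whitespace- or
    comma-separated; lines starting with ``#`` are comments.  LAS input is
    not supported in this build — convert to XYZ first.
    """
    path = Path(path)
    if format == "las":
        raise NotImplementedError(
            "LAS input is not supported in this build; convert to XYZ text "
            "(e.g. with pdal or las2txt) and use format='xyz'")
    if format != "xyz":
        raise ValueError(f"unknown point cloud format {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    rows, classes, tree_ids = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",") if "," in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
            try:
                xyz = [float(p) for p in parts[:3]]
            except ValueError:
                raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}") from None
            rows.append(xyz)
            classes.append(int(float(parts[3])) if len(parts) > 3 else 0)
            tree_ids.append(int(float(parts[4])) if len(parts) > 4 else -1)
    if not rows:
        raise ValueError(f"{path}: empty point cloud")
    cloud = PointCloud(np.array(rows),
                       np.array(classes) if any(classes) else None,
                       np.array(tree_ids) if any(t >= 0 for t in tree_ids) else None)
    log_kv("read_point_cloud", path=path, n_points=len(cloud))
    return cloud


def write_point_cloud(cloud: PointCloud, path: str | Path) -> None:
    path = Path(path)
    cols = [cloud.xyz]
    fmt = ["%.6f", "%.6f", "%.6f"]
    if cloud.class_label is not None or cloud.tree_id is not None:
        cols.append((cloud.class_label if cloud.class_label is not None
                     else np.zeros(len(cloud), dtype=int))[:, None])
        fmt.append("%d")
    if cloud.tree_id is not None:
        cols.append(cloud.tree_id[:, None])
        fmt.append("%d")
    data = np.hstack(cols)
    np.savetxt(path, data, fmt=fmt, header="x y z" + (" class" if len(fmt) > 3 else "")
               + (" tree_id" if len(fmt) > 4 else ""))
    log_kv("write_point_cloud", path=path, n_points=len(cloud))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "matrix_csv") -> GenotypeMatrix:
    """Read a biallelic genotype matrix.

    ``matrix_csv``: individuals in rows, SNPs in columns, header row of
    snp_ids, first column individual ids, missing encoded ``NA``.
    ``vcf``: plain-text VCF; biallelic records become alt-dosage columns,
    multiallelic records are skipped with a warning and counted.
    """
    path = Path(path)
    if format == "matrix_csv":
        df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
        dosage = np.full(df.shape, np.nan)
        for j, col in enumerate(df.columns):
            for i, val in enumerate(df.iloc[:, j]):
                v = val.strip()
                if v in ("NA", "", "nan", "NaN"):
                    continue
                if v not in ("0", "1", "2"):
                    raise ValueError(
                        f"{path}: invalid genotype {v!r} at individual "
                        f"{df.index[i]!r}, SNP {col!r}")
                dosage[i, j] = int(v)
        geno = GenotypeMatrix(dosage, [str(i) for i in df.index],
                              make_snp_metadata(list(df.columns)))
        log_kv("read_genotypes", path=path, n_individuals=geno.n_individuals,
               n_snps=geno.n_snps)
        return geno
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    ids: list[str] = []
    snp_rows = []
    dosage_cols = []
    n_multi = 0
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                ids = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            chrom, pos, vid, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                n_multi += 1
                continue
            fmt_keys = fields[8].split(":")
            gt_idx = fmt_keys.index("GT")
            col = []
            for sample in fields[9:]:
                gt = sample.split(":")[gt_idx].replace("|", "/")
                if "." in gt:
                    col.append(np.nan)
                else:
                    col.append(sum(int(a) for a in gt.split("/")))
            snp_id = vid if vid not in (".", "") else f"{chrom}_{pos}"
            snp_rows.append((snp_id, chrom, int(pos), ref, alt))
            dosage_cols.append(col)
    if n_multi:
        logger.warning("read_genotypes skipped multiallelic records: %d", n_multi)
    if not ids:
        raise ValueError(f"{path}: no #CHROM header line")
    dosage = (np.array(dosage_cols, dtype=float).T if dosage_cols
              else np.empty((len(ids), 0)))
    meta = make_snp_metadata([r[0] for r in snp_rows],
                             [r[1] for r in snp_rows], [r[2] for r in snp_rows],
                             [r[3] for r in snp_rows], [r[4] for r in snp_rows])
    geno = GenotypeMatrix(dosage, ids, meta)
    geno.n_multiallelic_skipped = n_multi  # type: ignore[attr-defined]
    log_kv("read_genotypes", path=path, n_individuals=geno.n_individuals,
           n_snps=geno.n_snps, multiallelic_skipped=n_multi)
    return geno


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write matrix CSV that round-trips bit-exactly with read_genotypes."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("individual_id," + ",".join(geno.snps["snp_id"]) + "\n")
        for i, ind in enumerate(geno.individual_ids):
            row = ["NA" if not np.isfinite(v) else str(int(v))
                   for v in geno.dosage[i]]
            fh.write(ind + "," + ",".join(row) + "\n")
    log_kv("write_genotypes", path=path, n_individuals=geno.n_individuals,
           n_snps=geno.n_snps)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_design_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    required = {"individual_id", "family_id", "site_id", "block_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design table missing columns {sorted(missing)}")
    if df["individual_id"].duplicated().any():
        dup = df["individual_id"][df["individual_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate individual_id {dup!r}")
    return df


def write_design_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_phenotype_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def write_trait_table(records: Sequence[TraitRecord] | pd.DataFrame,
                      path: str | Path) -> None:
    """CSV of the seven traits per tree, 6 significant digits."""
    df = records if isinstance(records, pd.DataFrame) else trait_frame(records)
    df.to_csv(path, index=False, float_format="%.6g")
    log_kv("write_trait_table", path=path, n_records=len(df))


def read_trait_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_kinship(K: np.ndarray, ids: Sequence[str], path: str | Path) -> None:
    pd.DataFrame(K, index=list(ids), columns=list(ids)).to_csv(path, float_format="%.10g")


def read_kinship(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(), [str(i) for i in df.index]


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# x0={grid.x0!r} y0={grid.y0!r} cell={grid.cell!r}\n")
        np.savetxt(fh, grid.values, delimiter=",", fmt="%.6g")


def read_raster(path: str | Path) -> RasterGrid:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing raster header comment")
        meta = dict(tok.split("=") for tok in header[1:].split())
        values = np.loadtxt(fh, delimiter=",", ndmin=2)
    return RasterGrid(float(meta["x0"]), float(meta["y0"]),
                      float(meta["cell"]), values)
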