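"""Core in-memory containers shared across the pipeline.

Coordinates are metric and planar (a projected CRS is assumed upstream);
``z`` is absolute elevation before height normalization and
height-above-ground after.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# point classification codes
UNCLASSIFIED = 0
GROUND = 1
NONGROUND = 2
NOISE = 3

CLASS_NAMES = {UNCLASSIFIED: "unclassified", GROUND: "ground",
               NONGROUND: "non-ground", NOISE: "noise"}

TRAIT_NAMES = ("CA", "CBH", "CL", "CV", "CW", "CWH", "H")


@dataclass
class PointCloud:
    """Georeferenced 3-D samples of a stand or a single tree.

    ``xyz`` is an (n, 3) float array; ``class_label`` and ``tree_id`` are
    optional per-point annotations (int arrays, -1 = unassigned tree).
    """

    xyz: np.ndarray
    class_label: np.ndarray | None = None
    tree_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point cloud contains non-finite coordinates")
        for name in ("class_label", "tree_id"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=int)
                if arr.shape != (len(self.xyz),):
                    raise ValueError(f"{name} length does not match points")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def subset(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.xyz[mask],
            None if self.class_label is None else self.class_label[mask],
            None if self.tree_id is None else self.tree_id[mask],
        )

    def require_nonempty(self, what: str = "operation") -> None:
        if len(self) == 0:
            raise ValueError(f"empty point cloud passed to {what}")


@dataclass
class RasterGrid:
    """Gridded surface (DTM/DSM/CHM).

    ``values[iy, ix]`` covers the square with lower-left corner
    ``(x0 + ix*cell, y0 + iy*cell)``; NaN entries are nodata.
    """

    x0: float
    y0: float
    cell: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.values.shape
        xs = self.x0 + (np.arange(nx) + 0.5) * self.cell
        ys = self.y0 + (np.arange(ny) + 0.5) * self.cell
        return xs, ys

    def cell_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ix = np.floor((np.asarray(x) - self.x0) / self.cell).astype(int)
        iy = np.floor((np.asarray(y) - self.y0) / self.cell).astype(int)
        return iy, ix

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (self.shape == other.shape
                and np.isclose(self.x0, other.x0)
                and np.isclose(self.y0, other.y0)
                and np.isclose(self.cell, other.cell))


@dataclass
class TraitRecord:
    """The seven morphological traits of one tree (metres / m^2 / m^3).

    NaN marks a trait that could not be computed; ``flags`` records why.
    """

    tree_id: int
    x: float = np.nan
    y: float = np.nan
    CA: float = np.nan
    CBH: float = np.nan
    CL: float = np.nan
    CV: float = np.nan
    CW: float = np.nan
    CWH: float = np.nan
    H: float = np.nan
    flags: str = ""

    def as_dict(self) -> dict:
        return {
            "tree_id": self.tree_id, "x": self.x, "y": self.y,
            "CA": self.CA, "CBH": self.CBH, "CL": self.CL, "CV": self.CV,
            "CW": self.CW, "CWH": self.CWH, "H": self.H, "flags": self.flags,
        }


def trait_frame(records: Iterable[TraitRecord]) -> pd.DataFrame:
    cols = ["tree_id", "x", "y", *TRAIT_NAMES, "flags"]
    rows = [r.as_dict() for r in records]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)[cols]


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages, individuals x SNPs.

    ``dosage`` holds alt-allele counts in {0, 1, 2} with NaN for missing
    calls.  ``snps`` carries per-SNP metadata (snp_id, scaffold_id,
    position, ref_allele, alt_allele) aligned with the columns.
    """

    dosage: np.ndarray
    individual_ids: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length mismatch")
        if len(self.snps) != m:
            raise ValueError("snp metadata length mismatch")
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("snp_id values must be unique")
        vals = self.dosage[np.isfinite(self.dosage)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2, missing}")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def select_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage[:, mask], list(self.individual_ids),
                              self.snps.loc[mask].reset_index(drop=True))


@dataclass
class TreeSegment:
    """One detected tree: its apex, CHM footprint and (later) point cloud."""

    tree_id: int
    apex_x: float
    apex_y: float
    apex_height: float
    cells: set = field(default_factory=set)
    cloud: PointCloud | None = None
    sparse: bool = False


def make_snp_metadata(snp_ids: Sequence[str],
                      scaffold_ids: Sequence[str] | None = None,
                      positions: Sequence[int] | None = None,
                      ref: Sequence[str] | None = None,
                      alt: Sequence[str] | None = None) -> pd.DataFrame:
    """Assemble SNP metadata, parsing 'scaffold_pos' ids when possible."""
    m = len(snp_ids)
    if scaffold_ids is None or positions is None:
        sc, pos = [], []
        for i, sid in enumerate(snp_ids):
            head, _, tail = str(sid).rpartition("_")
            if head and tail.isdigit():
                sc.append(head)
                pos.append(int(tail))
            else:
                sc.append("scaffold0")
                pos.append(i + 1)
        scaffold_ids = scaffold_ids or sc
        positions = positions or pos
    return pd.DataFrame({
        "snp_id": list(snp_ids),
        "scaffold_id": list(scaffold_ids),
        "position": list(positions),
        "ref_allele": list(ref) if ref is not None else ["A"] * m,
        "alt_allele": list(alt) if alt is not None else ["G"] * m,
    })
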