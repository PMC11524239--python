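"""CHM tree detection and Dalponte-style crown region growing.

Apexes are strict local maxima of the CHM within a circular window and at
least ``min_height`` tall; crowns grow from each apex over 4-connected
cells subject to seed/crown relative-height thresholds and a maximum
crown radius.  Processing order (apexes by descending height, cells
breadth-first, ties toward smaller row/column) is fixed so segmentation
is fully deterministic.
"""
from __future__ import annotations

from collections import deque

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import PointCloud, RasterGrid, TreeSegment
from .io import log_kv


def detect_apexes(chm: RasterGrid, min_height: float = 2.6,
                  window_radius: float = 1.5) -> list[TreeSegment]:
    """Local-maximum tree tops on the CHM.

    A cell is an apex when it is >= ``min_height`` and the strict maximum
    of its circular window; among tied maxima the smallest (row, col)
    wins.  Returns bare TreeSegments (apex only, no cells yet).
    """
    vals = np.nan_to_num(chm.values, nan=0.0)
    ny, nx = vals.shape
    r_cells = window_radius / chm.cell
    ri = int(np.floor(r_cells))
    offsets = [(dy, dx) for dy in range(-ri, ri + 1) for dx in range(-ri, ri + 1)
               if (dy, dx) != (0, 0) and dy * dy + dx * dx <= r_cells * r_cells]
    candidates = np.argwhere(vals >= min_height)
    apexes = []
    for iy, ix in candidates:
        v = vals[iy, ix]
        is_apex = True
        for dy, dx in offsets:
            jy, jx = iy + dy, ix + dx
            if 0 <= jy < ny and 0 <= jx < nx:
                w = vals[jy, jx]
                if w > v or (w == v and (jy, jx) < (iy, ix)):
                    is_apex = False
                    break
        if is_apex:
            apexes.append(TreeSegment(
                tree_id=len(apexes),
                apex_x=chm.x0 + (ix + 0.5) * chm.cell,
                apex_y=chm.y0 + (iy + 0.5) * chm.cell,
                apex_height=float(v), cells={(int(iy), int(ix))}))
    log_kv("detect_apexes", n_apexes=len(apexes), min_height=min_height)
    return apexes


def grow_crowns(chm: RasterGrid, apexes: list[TreeSegment],
                th_seed: float = 0.45, th_crown: float = 0.55,
                max_radius: float = 2.5) -> list[TreeSegment]:
    """Region-grow a crown around each apex on the CHM.

    A candidate cell joins a crown when its height exceeds
    ``th_seed`` x apex height and ``th_crown`` x the crown's current mean
    height, and it lies within ``max_radius`` of the apex.  A cell claimed
    by two crowns goes to the nearer apex.
    """
    vals = np.nan_to_num(chm.values, nan=0.0)
    ny, nx = vals.shape
    label = np.full((ny, nx), -1, dtype=int)
    order = sorted(range(len(apexes)),
                   key=lambda k: (-apexes[k].apex_height, apexes[k].tree_id))
    cells_by_seg: dict[int, set] = {a.tree_id: set() for a in apexes}

    def cell_xy(iy, ix):
        return (chm.x0 + (ix + 0.5) * chm.cell, chm.y0 + (iy + 0.5) * chm.cell)

    def dist_to_apex(iy, ix, seg):
        cx, cy = cell_xy(iy, ix)
        return np.hypot(cx - seg.apex_x, cy - seg.apex_y)

    for k in order:
        seg = apexes[k]
        (ay, ax), = seg.cells
        if label[ay, ax] != -1:
            continue  # apex swallowed by a taller crown
        label[ay, ax] = k
        cells_by_seg[seg.tree_id] = {(ay, ax)}
        total, count = vals[ay, ax], 1
        queue = deque([(ay, ax)])
        while queue:
            cy0, cx0 = queue.popleft()
            for dy, dx in ((-1, 0), (0, -1), (0, 1), (1, 0)):
                jy, jx = cy0 + dy, cx0 + dx
                if not (0 <= jy < ny and 0 <= jx < nx):
                    continue
                if label[jy, jx] == k:
                    continue
                h = vals[jy, jx]
                if h <= th_seed * seg.apex_height:
                    continue
                if h <= th_crown * (total / count):
                    continue
                if dist_to_apex(jy, jx, seg) > max_radius:
                    continue
                prev = label[jy, jx]
                if prev != -1:
                    # contested cell: nearer apex wins
                    if dist_to_apex(jy, jx, seg) >= dist_to_apex(jy, jx, apexes[prev]):
                        continue
                    cells_by_seg[apexes[prev].tree_id].discard((jy, jx))
                label[jy, jx] = k
                cells_by_seg[seg.tree_id].add((jy, jx))
                total += h
                count += 1
                queue.append((jy, jx))

    out = []
    for a in apexes:
        seg = TreeSegment(a.tree_id, a.apex_x, a.apex_y, a.apex_height,
                          cells=cells_by_seg[a.tree_id])
        out.append(seg)
    log_kv("grow_crowns", n_crowns=len(out),
           n_cells=sum(len(s.cells) for s in out))
    return out


def extract_tree_clouds(cloud: PointCloud, segments: list[TreeSegment],
                        chm: RasterGrid, min_points: int = 50,
                        knn: int = 8) -> list[TreeSegment]:
    """Attach per-tree normalized point clouds to crown segments.

    Each point falls to the segment whose crown footprint contains its
    (x, y) cell; unassigned points are discarded (count logged).  Noise
    removal per tree: points above apex height + 0.5 m, and statistical
    outliers whose mean k-nearest-neighbour distance exceeds mu + 3 sd.
    Segments with fewer than ``min_points`` points are flagged sparse.
    """
    cloud.require_nonempty("extract_tree_clouds")
    if cloud.class_label is not None:
        # terrain and flagged-noise points are not part of any tree
        from .datatypes import GROUND, NOISE
        cloud = cloud.subset((cloud.class_label != GROUND)
                             & (cloud.class_label != NOISE))
    label = np.full(chm.shape, -1, dtype=int)
    seg_index = {s.tree_id: s for s in segments}
    for s in segments:
        for (iy, ix) in s.cells:
            label[iy, ix] = s.tree_id
    iy, ix = chm.cell_index(cloud.x, cloud.y)
    ny, nx = chm.shape
    inside = (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
    pt_label = np.full(len(cloud), -1, dtype=int)
    pt_label[inside] = label[iy[inside], ix[inside]]
    n_unassigned = int((pt_label == -1).sum())
    log_kv("extract_tree_clouds", n_unassigned=n_unassigned)

    out = []
    for s in segments:
        mask = pt_label == s.tree_id
        sub = cloud.subset(mask)
        keep = sub.z <= s.apex_height + 0.5
        sub = sub.subset(keep)
        if len(sub) > knn:
            tree = cKDTree(sub.xyz)
            dist, _ = tree.query(sub.xyz, k=knn + 1)
            mean_d = dist[:, 1:].mean(axis=1)
            thr = mean_d.mean() + 3 * mean_d.std()
            sub = sub.subset(mean_d <= thr)
        seg = TreeSegment(s.tree_id, s.apex_x, s.apex_y, s.apex_height,
                          cells=set(s.cells), cloud=sub,
                          sparse=len(sub) < min_points)
        out.append(seg)
    n_sparse = sum(s.sparse for s in out)
    if n_sparse:
        log_kv("extract_tree_clouds", n_sparse=n_sparse)
    return out


def segment_table(segments: list[TreeSegment]):
    import pandas as pd
    return pd.DataFrame([{
        "tree_id": s.tree_id, "apex_x": s.apex_x, "apex_y": s.apex_y,
        "apex_h": s.apex_height,
        "n_points": 0 if s.cloud is None else len(s.cloud),
        "sparse": s.sparse,
    } for s in segments])
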