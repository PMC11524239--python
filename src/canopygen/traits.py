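"""The seven morphological traits from a normalized single-tree cloud.

H is the global maximum height (a conifer apex sits on the axis; the
outside-trunk variant is computed and logged for comparison).  CBH comes
from the vertical profile of horizontal spread: the crown begins where
the per-slice spread jumps above a trunk baseline.  CW/CWH are the widest
horizontal extent over height slices, CA the convex-hull area of the
crown's top-view projection, CL = H - CBH, and CV an ellipsoid of
revolution with semi-axes (CW/2, CW/2, CL/2).
"""
from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .datatypes import PointCloud, TraitRecord, TreeSegment, trait_frame
from .io import log_kv

# a trunk-slice spread larger than this means the crown reaches the ground
# (a bare conifer trunk is a narrow cylinder; its slice spread is at the
# noise scale, far below crown-slice spread)
_TRUNK_SPREAD_MAX = 0.12  # m
_BASELINE_FLOOR = 0.01    # m, avoids a zero baseline on noise-free trunks


class TraitError(ValueError):
    """A trait could not be derived from the cloud."""


def _trunk_axis(cloud: PointCloud) -> tuple[float, float, float]:
    """(x, y) of the trunk axis and the height of the region that defined it.

    Centroid of points below min(1 m, 0.2 H); if that region is empty the
    apex (x, y) of the highest point is used.
    """
    h = cloud.z.max()
    top = min(1.0, 0.2 * h)
    low = cloud.z <= top
    if low.any():
        return float(cloud.x[low].mean()), float(cloud.y[low].mean()), top
    k = int(np.argmax(cloud.z))
    return float(cloud.x[k]), float(cloud.y[k]), top


def _slice_indices(z: np.ndarray, slice_height: float) -> np.ndarray:
    return np.floor(z / slice_height).astype(int)


def estimate_height(cloud: PointCloud, trunk_radius: float = 0.25) -> float:
    """H = maximum normalized height over all points."""
    cloud.require_nonempty("estimate_height")
    h = float(cloud.z.max())
    ax, ay, _ = _trunk_axis(cloud)
    outside = np.hypot(cloud.x - ax, cloud.y - ay) > trunk_radius
    h_outside = float(cloud.z[outside].max()) if outside.any() else math.nan
    log_kv("estimate_height", H=round(h, 4), H_outside_trunk=round(h_outside, 4))
    return h


def estimate_cbh(cloud: PointCloud, slice_height: float = 0.25,
                 spread_factor: float = 3.0, min_cbh: float = 0.3) -> float:
    """Crown base height from the vertical profile of horizontal spread.

    Points are binned into height slices; per slice the sd of horizontal
    distance to the trunk axis is computed.  The baseline is the median
    slice-sd over trunk slices (those below the axis-defining region);
    CBH is the lower edge of the lowest slice at or above ``min_cbh``
    whose sd exceeds ``spread_factor`` x baseline for at least two
    consecutive slices.  A trunk baseline wider than 0.25 m means the
    crown reaches the ground and CBH = 0.
    """
    if len(cloud) < 50:
        raise TraitError("estimate_cbh needs >= 50 points")
    z = cloud.z
    if (z.max() - z.min()) < 2 * slice_height:
        raise TraitError("degenerate vertical extent (< 2 slices)")
    ax, ay, axis_top = _trunk_axis(cloud)
    r = np.hypot(cloud.x - ax, cloud.y - ay)
    sl = _slice_indices(z, slice_height)
    n_slices = sl.max() + 1
    sd = np.full(n_slices, np.nan)
    for s in range(max(0, sl.min()), n_slices):
        m = sl == s
        if m.sum() >= 3:
            sd[s] = r[m].std()
    trunk_slices = sd[: max(1, int(math.ceil(axis_top / slice_height)))]
    trunk_sd = trunk_slices[np.isfinite(trunk_slices)]
    if trunk_sd.size == 0:
        return 0.0
    # the narrowest slice in the trunk region is the trunk baseline; if even
    # that is wide, there is no bare trunk and the crown reaches the ground
    baseline = max(float(trunk_sd.min()), _BASELINE_FLOOR)
    if baseline > _TRUNK_SPREAD_MAX:
        return 0.0  # crown reaches the ground
    thresh = spread_factor * baseline
    exceeds = np.isfinite(sd) & (sd > thresh)
    first_allowed = int(math.ceil(min_cbh / slice_height))
    for s in range(first_allowed, n_slices - 1):
        if exceeds[s] and exceeds[s + 1]:
            return s * slice_height
    raise TraitError("no branching point found")


def _max_pairwise_2d(xy: np.ndarray) -> tuple[float, int, int]:
    """Max pairwise distance and the index pair achieving it."""
    if len(xy) > 3:
        try:
            hull = ConvexHull(xy)
            pts_idx = hull.vertices
        except QhullError:
            pts_idx = np.arange(len(xy))
    else:
        pts_idx = np.arange(len(xy))
    if len(pts_idx) > 2000:  # degenerate huge hulls: project onto main axis
        pts_idx = np.asarray(pts_idx)
    sub = xy[pts_idx]
    if len(sub) > 1500:
        c = sub - sub.mean(axis=0)
        d = c @ np.linalg.svd(c, full_matrices=False)[2][0]
        pair = (int(np.argmin(d)), int(np.argmax(d)))
        sub_pair = [pts_idx[pair[0]], pts_idx[pair[1]]]
        return float(np.hypot(*(xy[sub_pair[0]] - xy[sub_pair[1]]))), *sub_pair
    diff = sub[:, None, :] - sub[None, :, :]
    d2 = (diff ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return float(math.sqrt(d2[i, j])), int(pts_idx[i]), int(pts_idx[j])


def estimate_crown_width(crown: PointCloud, slice_height: float = 0.25,
                         ) -> tuple[float, float]:
    """(CW, CWH): widest horizontal extent over slices and its height.

    Per slice the width is the maximum pairwise horizontal distance
    (computed on the slice's 2-D convex hull); CW is the maximum over
    slices and CWH the mid-height of the arg-max slice (ties -> lowest).
    If no slice has >= 3 points, falls back to the global max pairwise
    distance with CWH the mean height of the extreme pair.
    """
    if len(crown) < 3:
        raise TraitError("estimate_crown_width needs >= 3 crown points")
    sl = _slice_indices(crown.z, slice_height)
    best_w, best_slice = -1.0, None
    for s in np.unique(sl):
        m = sl == s
        if m.sum() < 3:
            continue
        w, _, _ = _max_pairwise_2d(crown.xyz[m, :2])
        if w > best_w + 1e-12:
            best_w, best_slice = w, s
    if best_slice is None:
        w, i, j = _max_pairwise_2d(crown.xyz[:, :2])
        cwh = float((crown.z[i] + crown.z[j]) / 2)
        return w, cwh
    return best_w, (best_slice + 0.5) * slice_height


def compute_crown_length(H: float, CBH: float) -> float:
    """CL = H - CBH."""
    if H < CBH:
        raise TraitError(f"H ({H}) < CBH ({CBH})")
    return H - CBH


def compute_crown_volume(CW: float, CL: float) -> float:
    """Ellipsoid-of-revolution crown volume, semi-axes (CW/2, CW/2, CL/2)."""
    if CW < 0 or CL < 0:
        raise TraitError("CW and CL must be >= 0")
    return (4.0 / 3.0) * math.pi * (CW / 2) ** 2 * (CL / 2)


def compute_canopy_area(crown: PointCloud) -> float:
    """Projected crown area: 2-D convex hull of the crown's (x, y)."""
    if len(crown) < 3:
        warnings.warn("fewer than 3 crown points; CA = 0")
        return 0.0
    try:
        return float(ConvexHull(crown.xyz[:, :2]).volume)
    except QhullError:
        warnings.warn("degenerate (collinear) crown projection; CA = 0")
        return 0.0


def extract_traits_for_cloud(cloud: PointCloud, tree_id: int = 0,
                             x: float | None = None, y: float | None = None,
                             slice_height: float = 0.25,
                             spread_factor: float = 3.0,
                             min_cbh: float = 0.3,
                             trunk_radius: float = 0.25) -> TraitRecord:
    """All seven traits from one normalized tree cloud.

    Failed components are left NaN with the failure named in ``flags``;
    the record is always returned.
    """
    rec = TraitRecord(tree_id=tree_id)
    flags = []
    if x is None or y is None:
        k = int(np.argmax(cloud.z))
        x, y = float(cloud.x[k]), float(cloud.y[k])
    rec.x, rec.y = x, y
    try:
        rec.H = estimate_height(cloud, trunk_radius)
    except (TraitError, ValueError) as exc:
        flags.append(f"H:{exc}")
    try:
        rec.CBH = estimate_cbh(cloud, slice_height, spread_factor, min_cbh)
    except TraitError as exc:
        flags.append(f"CBH:{exc}")
    if np.isfinite(rec.H) and np.isfinite(rec.CBH):
        rec.CL = compute_crown_length(rec.H, rec.CBH)
        crown = cloud.subset(cloud.z >= rec.CBH)
        try:
            rec.CW, rec.CWH = estimate_crown_width(crown, slice_height)
            rec.CV = compute_crown_volume(rec.CW, rec.CL)
        except TraitError as exc:
            flags.append(f"CW:{exc}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec.CA = compute_canopy_area(crown)
    rec.flags = ";".join(flags)
    return rec


def extract_all_traits(segments: list[TreeSegment], slice_height: float = 0.25,
                       spread_factor: float = 3.0, min_cbh: float = 0.3,
                       trunk_radius: float = 0.25):
    """Trait table over segmented trees; sparse segments emit flagged rows."""
    records = []
    for seg in segments:
        if seg.sparse or seg.cloud is None or len(seg.cloud) == 0:
            records.append(TraitRecord(tree_id=seg.tree_id, x=seg.apex_x,
                                       y=seg.apex_y, flags="sparse"))
            continue
        rec = extract_traits_for_cloud(
            seg.cloud, seg.tree_id, seg.apex_x, seg.apex_y,
            slice_height, spread_factor, min_cbh, trunk_radius)
        records.append(rec)
    df = trait_frame(records)
    n_flagged = int((df["flags"] != "").sum()) if len(df) else 0
    log_kv("extract_all_traits", n_trees=len(df), n_flagged=n_flagged)
    return df
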