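import math

import numpy as np
import pytest

from canopygen.datatypes import PointCloud, TreeSegment
from canopygen.simulate import (SyntheticTreeParams, generate_tree_cloud,
                                random_tree_params)
from canopygen.traits import (TraitError, compute_canopy_area,
                              compute_crown_length, compute_crown_volume,
                              estimate_cbh, estimate_crown_width,
                              estimate_height, extract_all_traits,
                              extract_traits_for_cloud)


def _bare_pole(n=200, h=6.0, r=0.08, seed=0):
    rng = np.random.default_rng(seed)
    z = rng.uniform(0, h, n)
    ang = rng.uniform(0, 2 * math.pi, n)
    return PointCloud(np.column_stack([r * np.cos(ang), r * np.sin(ang), z]))


class TestHeight:
    def test_max_z(self):
        cloud = PointCloud(np.array([[0, 0, 1.0], [1, 1, 9.7], [2, 2, 3.0]]))
        assert estimate_height(cloud) == 9.7

    def test_single_point(self):
        assert estimate_height(PointCloud(np.array([[0, 0, 4.2]]))) == 4.2

    def test_recovers_truth_under_jitter(self, reference_tree):
        _, cloud, truth = reference_tree
        assert estimate_height(cloud) == pytest.approx(truth.H, abs=0.1)


class TestCrownBaseHeight:
    def test_recovers_truth_within_slice(self, reference_tree):
        _, cloud, truth = reference_tree
        assert estimate_cbh(cloud) == pytest.approx(truth.CBH, abs=0.25)

    def test_ground_hugging_crown_gives_zero(self):
        p = SyntheticTreeParams(height=3, cbh=0.0, cw=3, cwh=1.5,
                                n_points=3000, noise_sd=0.01)
        cloud, _ = generate_tree_cloud(p, seed=2)
        assert estimate_cbh(cloud) == 0.0

    def test_bare_pole_has_no_branching_point(self):
        with pytest.raises(TraitError, match="no branching point"):
            estimate_cbh(_bare_pole())

    def test_degenerate_vertical_extent_rejected(self):
        flat = PointCloud(np.column_stack([np.random.default_rng(0).uniform(0, 1, (60, 2)),
                                           np.full(60, 0.1)]))
        with pytest.raises(TraitError, match="slices|extent"):
            estimate_cbh(flat)


class TestCrownWidth:
    def test_recovers_truth(self, reference_tree):
        _, cloud, truth = reference_tree
        crown = cloud.subset(cloud.z >= truth.CBH)
        cw, cwh = estimate_crown_width(crown)
        assert cw == pytest.approx(truth.CW, rel=0.03)
        assert cwh == pytest.approx(truth.CWH, abs=0.25)

    def test_collinear_segment(self):
        xs = np.linspace(0, 2, 10)
        cloud = PointCloud(np.column_stack([xs, np.zeros(10),
                                            np.full(10, 1.1)]))
        cw, cwh = estimate_crown_width(cloud)
        assert cw == pytest.approx(2.0)
        assert cwh == pytest.approx(1.125)  # mid-height of slice [1.0, 1.25)

    def test_unit_triangle(self):
        cloud = PointCloud(np.array([[0, 0, 0.1], [1, 0, 0.1],
                                     [0.5, math.sqrt(3) / 2, 0.1]]))
        cw, _ = estimate_crown_width(cloud)
        assert cw == pytest.approx(1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(TraitError):
            estimate_crown_width(PointCloud(np.array([[0, 0, 1.0]])))


class TestDerivedTraits:
    @pytest.mark.parametrize("h,cbh,cl", [(10, 3, 7), (5, 0, 5), (4, 4, 0)])
    def test_crown_length(self, h, cbh, cl):
        assert compute_crown_length(h, cbh) == cl

    def test_crown_length_rejects_inverted(self):
        with pytest.raises(TraitError):
            compute_crown_length(3, 4)

    @pytest.mark.parametrize("cw,cl,cv", [
        (2, 2, 4 * math.pi / 3),      # sphere of diameter 2
        (0, 5, 0.0),
        (3, 6, 9 * math.pi),
    ])
    def test_crown_volume(self, cw, cl, cv):
        assert compute_crown_volume(cw, cl) == pytest.approx(cv)

    def test_crown_volume_rejects_negative(self):
        with pytest.raises(TraitError):
            compute_crown_volume(-1, 2)

    def test_canopy_area_unit_square(self):
        cloud = PointCloud(np.array([[0, 0, 1], [1, 0, 1], [1, 1, 1],
                                     [0, 1, 1.0]]))
        assert compute_canopy_area(cloud) == pytest.approx(1.0)

    def test_canopy_area_collinear_warns_zero(self):
        cloud = PointCloud(np.array([[0, 0, 1], [1, 1, 1], [2, 2, 1.0]]))
        with pytest.warns(UserWarning):
            assert compute_canopy_area(cloud) == 0.0

    def test_canopy_area_matches_disc(self, reference_tree):
        _, cloud, truth = reference_tree
        crown = cloud.subset(cloud.z >= truth.CBH)
        assert compute_canopy_area(crown) == pytest.approx(truth.CA, rel=0.05)


class TestExtractAllTraits:
    def test_record_invariants_hold(self):
        rng = np.random.default_rng(11)
        segs = []
        for i in range(5):
            p = random_tree_params(rng, n_points=4000)
            cloud, _ = generate_tree_cloud(p, rng)
            segs.append(TreeSegment(i, p.x, p.y, p.height, cloud=cloud))
        df = extract_all_traits(segs)
        assert len(df) == 5 and (df["flags"] == "").all()
        assert np.allclose(df["CL"], df["H"] - df["CBH"])
        assert (df["CBH"] <= df["CWH"] + 1e-9).all()
        assert (df["CWH"] <= df["H"] + 1e-9).all()

    def test_bare_pole_gives_partial_row(self):
        p = SyntheticTreeParams(n_points=2000)
        cloud, _ = generate_tree_cloud(p, seed=1)
        segs = [TreeSegment(0, 0, 0, 10, cloud=cloud),
                TreeSegment(1, 6, 0, 6, cloud=_bare_pole())]
        df = extract_all_traits(segs)
        assert len(df) == 2
        assert df.loc[0, "flags"] == ""
        assert "no branching point" in df.loc[1, "flags"]
        assert np.isnan(df.loc[1, "CBH"])

    def test_empty_segment_list(self):
        df = extract_all_traits([])
        assert len(df) == 0

    def test_scaling_laws(self):
        """Scaling the cloud (and the slice height with it) scales lengths
        by s, CA by s^2, CV by s^3."""
        p = SyntheticTreeParams(n_points=8000, noise_sd=0.0)
        cloud, _ = generate_tree_cloud(p, seed=4)
        base = extract_traits_for_cloud(cloud)
        s = 1.7
        scaled = extract_traits_for_cloud(PointCloud(cloud.xyz * s),
                                          slice_height=0.25 * s)
        for t, power in [("H", 1), ("CBH", 1), ("CW", 1), ("CWH", 1),
                         ("CL", 1), ("CA", 2), ("CV", 3)]:
            got = getattr(scaled, t)
            want = getattr(base, t) * s ** power
            assert got == pytest.approx(want, rel=0.01), t
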