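import numpy as np
import pandas as pd
import pytest

from canopygen.datatypes import GenotypeMatrix, make_snp_metadata
from canopygen.gwas import (classify_significance, export_manhattan_table,
                            gls_scan, qc_filter, significant_sets,
                            yang_kinship)


def _geno(dosage, ids=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    ids = ids or [f"i{k}" for k in range(n)]
    meta = make_snp_metadata([f"sc1_{100 * (j + 1)}" for j in range(m)])
    return GenotypeMatrix(dosage, ids, meta)


class TestQcFilter:
    def test_monomorphic_removed(self):
        g = _geno([[0, 1], [0, 1], [0, 0], [0, 2]])
        out, rep = qc_filter(g, maf_min=0.05, call_rate_min=0.9)
        assert out.n_snps == 1
        assert rep.n_low_maf == 1

    def test_call_rate_threshold(self):
        d = [[0, 0], [1, 1], [np.nan, 1], [2, 2]]
        g = _geno(d)
        out, rep = qc_filter(g, call_rate_min=0.9)  # 0.75 < 0.9 -> removed
        assert rep.n_low_call_rate == 1 and out.n_snps == 1
        out2, rep2 = qc_filter(_geno(d), call_rate_min=0.7)
        assert out2.n_snps == 2
        assert rep2.n_imputed == 1
        assert out2.dosage[2, 0] == pytest.approx(1.0)  # mean of 0,1,2

    def test_conservation(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, (30, 200)).astype(float)
        d[rng.uniform(size=d.shape) < 0.1] = np.nan
        _, rep = qc_filter(_geno(d), n_non_biallelic=7)
        assert rep.conserves()

    def test_nothing_retained_errors(self):
        g = _geno([[0, 0], [0, 0]])
        with pytest.raises(ValueError, match="no SNPs"):
            qc_filter(g)


class TestYangKinship:
    def test_single_snp_formula_arithmetic(self):
        # dosages (2, 2, 0, 0): p = 0.5, 2pq = 0.5
        g = _geno(np.array([[2.0], [2.0], [0.0], [0.0]]))
        K, _ = yang_kinship(g)
        # off-diagonal between the two hom-alt individuals: (1*1)/0.5 = 2
        assert K[0, 1] == pytest.approx(2.0)
        # diagonal for x=2: 1 + (4 - 2*2 + 0.5)/0.5 = 1 + 1 = 2
        assert K[0, 0] == pytest.approx(2.0)

    def test_heterozygote_diagonal(self):
        # dosages (1, 2, 0, 1): p = 0.5; diag for x=1: 1 + (1-2+0.5)/0.5 = 0
        g = _geno(np.array([[1.0], [2.0], [0.0], [1.0]]))
        K, _ = yang_kinship(g)
        assert K[0, 0] == pytest.approx(0.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        d = rng.integers(0, 3, (10, 50)).astype(float)
        g = _geno(d)
        K, skipped = yang_kinship(g)
        p = d.mean(0) / 2
        keep = (p > 0) & (p < 1)
        d2, p2 = d[:, keep], p[keep]
        m = d2.shape[1]
        oracle = np.zeros((10, 10))
        for j in range(10):
            for k in range(10):
                acc = 0.0
                for i in range(m):
                    den = 2 * p2[i] * (1 - p2[i])
                    if j == k:
                        acc += (d2[j, i] ** 2 - (1 + 2 * p2[i]) * d2[j, i]
                                + 2 * p2[i] ** 2) / den
                    else:
                        acc += ((d2[j, i] - 2 * p2[i])
                                * (d2[k, i] - 2 * p2[i])) / den
                oracle[j, k] = acc / m + (1.0 if j == k else 0.0)
        np.testing.assert_allclose(K, oracle, atol=1e-10)

    def test_missing_dosages_rejected(self):
        g = _geno([[0, 1], [np.nan, 1]])
        with pytest.raises(ValueError, match="imputed"):
            yang_kinship(g)


class TestGlsScan:
    def test_reduces_to_ols_when_no_polygenic_variance(self):
        rng = np.random.default_rng(4)
        n, m = 60, 25
        d = rng.integers(0, 3, (n, m)).astype(float)
        g = _geno(d)
        y = rng.normal(0, 1, n)
        X = np.ones((n, 1))
        s2e = 1.3
        res = gls_scan(y, X, g, K=np.eye(n), sigma2_g=0.0, sigma2_e=s2e)
        # explicit-inverse OLS oracle with fixed error variance
        for j in range(m):
            Xa = np.column_stack([X, d[:, j]])
            XtX_inv = np.linalg.inv(Xa.T @ Xa / s2e)
            beta = XtX_inv @ (Xa.T @ y / s2e)
            assert res["beta"][j] == pytest.approx(beta[1], abs=1e-8)
            assert res["se"][j] == pytest.approx(np.sqrt(XtX_inv[1, 1]),
                                                 abs=1e-8)

    def test_eigen_shortcut_matches_direct_gls(self):
        rng = np.random.default_rng(6)
        n, m = 50, 20
        d = rng.integers(0, 3, (n, m)).astype(float)
        g = _geno(d)
        B = rng.normal(0, 1, (n, 5))
        K = B @ B.T / 5 + np.eye(n) * 0.1
        y = rng.normal(0, 1, n)
        X = np.ones((n, 1))
        s2g, s2e = 0.7, 0.9
        res = gls_scan(y, X, g, K, sigma2_g=s2g, sigma2_e=s2e)
        V_inv = np.linalg.inv(s2g * K + s2e * np.eye(n))
        for j in range(m):
            Xa = np.column_stack([X, d[:, j]])
            C = np.linalg.inv(Xa.T @ V_inv @ Xa)
            beta = C @ (Xa.T @ V_inv @ y)
            assert res["beta"][j] == pytest.approx(beta[1], abs=1e-8)
            assert res["se"][j] == pytest.approx(np.sqrt(C[1, 1]), abs=1e-8)

    def test_collinear_snp_flagged_missing(self):
        n = 30
        d = np.ones((n, 2))
        d[:, 1] = np.arange(n) % 3
        g = _geno(d)
        rng = np.random.default_rng(2)
        res = gls_scan(rng.normal(0, 1, n), np.ones((n, 1)), g,
                       K=np.eye(n), sigma2_g=0.0, sigma2_e=1.0)
        assert res["flag"][0] == "collinear" and np.isnan(res["p"][0])
        assert res["flag"][1] == ""


class TestSignificance:
    @pytest.mark.parametrize("lp,cls", [(4.5, "sig05"), (5.2, "sig01"),
                                        (3.9, "none"), (4.0, "none"),
                                        (5.0, "sig05")])
    def test_threshold_classes(self, lp, cls):
        df = pd.DataFrame({"neglog10p": [lp]})
        assert classify_significance(df)["class"][0] == cls

    def test_trait_overlap_counts(self):
        a = pd.DataFrame({"snp_id": ["s1", "s2", "s3"],
                          "neglog10p": [6.0, 4.5, 1.0]})
        b = pd.DataFrame({"snp_id": ["s1", "s2", "s3"],
                          "neglog10p": [6.0, 1.0, 4.2]})
        sets, overlap = significant_sets({"CA": a, "H": b})
        assert sets["CA"] == {"s1", "s2"} and sets["H"] == {"s1", "s3"}
        table = overlap.set_index("traits")["n_snps"]
        assert table["CA+H"] == 1 and table["CA"] == 1 and table["H"] == 1


class TestManhattanExport:
    def test_cumulative_offsets(self, tmp_path):
        df = pd.DataFrame({
            "snp_id": ["a", "b"],
            "scaffold_id": ["sc1", "sc2"],
            "position": [100, 10],
            "neglog10p": [1.0, 6.0],
        })
        out = export_manhattan_table(df, tmp_path / "m.csv",
                                     scaffold_lengths={"sc1": 100, "sc2": 50})
        assert out["cumulative_position"].tolist() == [100, 110]
        back = pd.read_csv(tmp_path / "m.csv")
        assert back["class"].tolist() == ["none", "sig01"]

    def test_empty_results_header_only(self, tmp_path):
        df = pd.DataFrame(columns=["snp_id", "scaffold_id", "position",
                                   "neglog10p"])
        export_manhattan_table(df, tmp_path / "m.csv")
        assert len((tmp_path / "m.csv").read_text().strip().splitlines()) == 1
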