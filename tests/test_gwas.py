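"""Kinship MLM scans: oracle equality, calibration, consensus, LD decay."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_genotypes
from rootshape.gwas import (GwasResults, MixedLMScan, bonferroni_threshold,
                            consensus_qtl, inflation_lambda, ld_decay,
                            marker_pve, mlm_scan, vanraden_kinship)
from rootshape.simulate import generate_population


def dense_gls_pvalues(y, X0, dosage, K, sg2, se2):
    """Brute-force GLS with the full covariance, the scan's oracle."""
    n = len(y)
    V = sg2 * K + se2 * np.eye(n)
    Vi = np.linalg.inv(V)
    out = []
    for j in range(dosage.shape[1]):
        X = np.column_stack([X0, dosage[:, j]])
        XtVi = X.T @ Vi
        try:
            beta = np.linalg.solve(XtVi @ X, XtVi @ y)
            cov = np.linalg.inv(XtVi @ X)
        except np.linalg.LinAlgError:
            out.append(np.nan)
            continue
        r = y - X @ beta
        dof = n - X.shape[1]
        s2 = (r @ Vi @ r) / dof
        v = s2 * cov[-1, -1]
        if not np.isfinite(v) or v <= 0:
            out.append(np.nan)
            continue
        t = beta[-1] / np.sqrt(v)
        out.append(2 * stats.t.sf(abs(t), dof))
    return np.array(out)


class TestVanRadenKinship:
    def test_duplicated_accessions_share_relationship(self):
        rng = np.random.default_rng(0)
        d = rng.binomial(2, 0.4, size=(15, 80)).astype(float)
        d[4] = d[2]
        K = vanraden_kinship(make_genotypes(d))
        assert K.iloc[2, 4] == pytest.approx(K.iloc[2, 2], abs=1e-12)
        assert np.allclose(K, K.T)

    def test_within_population_relatedness_higher(self):
        geno, _ = generate_population(40, 600, 2, 0.3, 0.02, seed=1)
        K = vanraden_kinship(geno).to_numpy()
        groups = geno.group_array()
        same = groups[:, None] == groups[None, :]
        off = ~np.eye(len(groups), dtype=bool)
        assert K[same & off].mean() > K[~same].mean()

    def test_loco_excluding_only_chromosome_fails(self):
        geno, _ = generate_population(20, 50, 1, 0.2, 1.0,
                                      n_chromosomes=1, seed=2)
        with pytest.raises(ValueError):
            vanraden_kinship(geno, exclude_chromosome="chr1")


class TestMixedLMScan:
    def test_matches_dense_gls_oracle(self):
        """Rotated-space scan equals brute-force GLS within 1e-6."""
        from rootshape.gwas import _null_reml

        geno, _ = generate_population(40, 80, 2, 0.2, 0.3,
                                      n_chromosomes=2, seed=3)
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(size=40) + 0.4 * geno.imputed()[:, 7],
                      index=geno.accessions)
        res = mlm_scan(y, geno, "K")
        K = vanraden_kinship(geno).to_numpy()
        sg2, se2, _, _ = _null_reml(y.to_numpy(), np.ones((40, 1)), K)
        oracle = dense_gls_pvalues(y.to_numpy(), np.ones((40, 1)),
                                   geno.imputed(), K, sg2, se2)
        got = res.table["p"].to_numpy()
        assert np.array_equal(np.isnan(got), np.isnan(oracle))
        ok = ~np.isnan(oracle)
        assert np.max(np.abs(got[ok] - oracle[ok])) < 1e-6

    def test_collapses_to_ols_without_genetic_variance(self):
        """Unstructured phenotype: MLM p-values equal plain regression."""
        rng = np.random.default_rng(5)
        d = rng.binomial(2, 0.5, size=(60, 40)).astype(float)
        geno = make_genotypes(d)
        y = pd.Series(rng.normal(size=60), index=geno.accessions)
        res = mlm_scan(y, geno, "K")
        ols = []
        for j in range(40):
            X = np.column_stack([np.ones(60), d[:, j]])
            beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
            r = y.to_numpy() - X @ beta
            s2 = (r @ r) / 58
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            ols.append(2 * stats.t.sf(abs(beta[1] / se), 58))
        # sigma_g estimated near 0 -> near-exact OLS agreement
        assert np.nanmax(np.abs(res.table["p"].to_numpy()
                                - np.array(ols))) < 1e-4

    def test_k_loco_equals_k_when_kinship_uninformative(self):
        """Independent markers: LOCO and full-K scans agree closely."""
        rng = np.random.default_rng(6)
        m = 4000  # enough markers that the realised kinship is near I
        d = rng.binomial(2, 0.5, size=(50, m)).astype(float)
        geno = make_genotypes(d, chrom=["chr1"] * (m // 2)
                              + ["chr2"] * (m // 2),
                              pos=list(range(100, 100 + (m // 2) * 10,
                                             10)) * 2)
        y = pd.Series(rng.normal(size=50), index=geno.accessions)
        rk = mlm_scan(y, geno, "K").table["p"].to_numpy()
        rl = mlm_scan(y, geno, "K-LOCO").table["p"].to_numpy()
        assert np.nanmax(np.abs(rk - rl)) < 1e-3

    def test_structured_null_calibration(self):
        """lambda in [0.85, 1.15] and type-I near nominal under a
        polygenic null with population structure."""
        lams, t1 = [], []
        for seed in range(5):
            geno, _ = generate_population(120, 1000, 3, 0.2, 0.3,
                                          n_chromosomes=5, seed=seed)
            K = vanraden_kinship(geno).to_numpy()
            rng = np.random.default_rng(seed + 50)
            L = np.linalg.cholesky(K + 1e-6 * np.eye(120))
            y = pd.Series(L @ rng.normal(size=120)
                          + rng.normal(size=120),
                          index=geno.accessions)
            res = mlm_scan(y, geno, "K")
            lams.append(res.inflation())
            t1.append((res.table["p"] < 0.05).mean())
        assert 0.85 < np.mean(lams) < 1.15
        assert 0.03 < np.mean(t1) < 0.07


class TestThresholdAndLambda:
    @pytest.mark.parametrize("n,expected", [(6001, 5.1), (7263, 5.2),
                                            (1, 1.3)])
    def test_bonferroni_printed_values(self, n, expected):
        assert round(bonferroni_threshold(n, 0.05), 1) == expected

    def test_lambda_unity_on_uniform_quantiles(self):
        n = 1000
        p = stats.beta.median(np.arange(1, n + 1), n - np.arange(n))
        assert inflation_lambda(p) == pytest.approx(1.0, abs=0.01)

    def test_lambda_increases_with_deflated_p(self):
        n = 500
        p = stats.beta.median(np.arange(1, n + 1), n - np.arange(n))
        assert inflation_lambda(p / 10) > inflation_lambda(p)

    def test_lambda_shuffle_invariant(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=300)
        assert inflation_lambda(p) == pytest.approx(
            inflation_lambda(rng.permutation(p)), abs=1e-12)

    def test_lambda_needs_enough_pvalues(self):
        with pytest.raises(ValueError):
            inflation_lambda([0.5] * 5)


class TestMarkerPve:
    def test_perfect_marker_explains_everything(self):
        x = np.array([0.0, 1, 2, 0, 1, 2, 1])
        assert marker_pve(x, x) == pytest.approx(100.0)

    def test_independent_marker_vanishes_with_n(self):
        rng = np.random.default_rng(8)
        small = marker_pve(rng.binomial(2, 0.5, 30),
                           rng.normal(size=30))
        large = marker_pve(rng.binomial(2, 0.5, 30000),
                           rng.normal(size=30000))
        assert large < small and large < 0.1

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            marker_pve(np.ones(10), np.arange(10.0))


class TestConsensusQtl:
    @staticmethod
    def _result(model, panel, rows, trait="length"):
        tab = pd.DataFrame(rows, columns=["chrom", "pos", "score"])
        tab["beta"] = 1.0
        tab["se"] = 0.1
        tab["p"] = 10.0 ** (-tab["score"])
        return GwasResults(table=tab, model=model, panel=panel,
                           trait=trait, n=100, varcomp={})

    def test_two_models_one_call(self):
        r1 = self._result("K", "full", [("chr1", 1000, 6.0)])
        r2 = self._result("K-LOCO", "full", [("chr1", 1000, 5.5)])
        calls = consensus_qtl([r1, r2], {"full": 5.0})
        assert len(calls) == 1
        assert calls[0].models == ("K", "K-LOCO")
        assert calls[0].mean_score == pytest.approx(5.75)

    def test_single_model_single_panel_no_call(self):
        r1 = self._result("K", "full", [("chr1", 1000, 8.0)])
        assert consensus_qtl([r1], {"full": 5.0}) == []

    def test_both_panels_one_model_each_calls(self):
        r1 = self._result("K", "full", [("chr1", 1000, 6.0)])
        r2 = self._result("K", "subset", [("chr1", 1000, 6.0)])
        calls = consensus_qtl([r1, r2], {"full": 5.0, "subset": 5.0})
        assert len(calls) == 1
        assert calls[0].panels == ("full", "subset")

    def test_colocated_markers_merge(self):
        """Markers 82 kb apart at radius 100 kb become one locus."""
        r1 = self._result("K", "full", [("chr8", 13_814_906, 6.5),
                                        ("chr8", 13_897_126, 6.0)])
        r2 = self._result("K-LOCO", "full", [("chr8", 13_814_906, 6.2),
                                             ("chr8", 13_897_126, 6.1)])
        calls = consensus_qtl([r1, r2], {"full": 5.0},
                              merge_radius_bp=100_000)
        assert len(calls) == 1
        assert len(calls[0].members) == 2

    def test_beyond_radius_not_merged(self):
        r1 = self._result("K", "full", [("chr1", 1000, 6.0),
                                        ("chr1", 300_000, 6.0)])
        r2 = self._result("K-LOCO", "full", [("chr1", 1000, 6.0),
                                             ("chr1", 300_000, 6.0)])
        calls = consensus_qtl([r1, r2], {"full": 5.0},
                              merge_radius_bp=100_000)
        assert len(calls) == 2

    def test_input_order_invariance(self):
        rows = [("chr1", 1000, 6.0), ("chr2", 5000, 7.0)]
        rs = [self._result("K", "full", rows),
              self._result("K-LOCO", "full", rows),
              self._result("K", "subset", [("chr2", 5000, 5.6)])]
        thr = {"full": 5.0, "subset": 5.0}
        a = consensus_qtl(rs, thr)
        b = consensus_qtl(rs[::-1], thr)
        assert [(q.chromosome, q.position_bp, q.models, q.mean_score)
                for q in a] == \
            [(q.chromosome, q.position_bp, q.models, q.mean_score)
             for q in b]


class TestLdDecay:
    def test_duplicated_adjacent_markers_bin0(self):
        rng = np.random.default_rng(9)
        x = rng.binomial(2, 0.5, 50).astype(float)
        geno = make_genotypes(np.array([x, x]).T, pos=[1000, 3000])
        curve, _ = ld_decay(geno, max_dist_bp=100_000, bin_width_bp=10_000)
        assert curve["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_unlinked_background_level(self):
        """Mean r^2 of independent markers ~ 1/(n-1), small."""
        rng = np.random.default_rng(10)
        n = 200
        d = rng.binomial(2, 0.5, size=(n, 100)).astype(float)
        geno = make_genotypes(d, pos=list(range(1000, 101000, 1000)))
        curve, _ = ld_decay(geno, max_dist_bp=100_000,
                            bin_width_bp=100_000)
        assert curve["mean_r2"].iloc[0] == pytest.approx(1 / (n - 1),
                                                         abs=0.01)

    def test_constructed_decay_crossing(self):
        """Exponential-decay LD crosses r^2 = 0.1 near the analytic
        distance."""
        rng = np.random.default_rng(11)
        n, m, spacing = 400, 120, 10_000
        half_r2 = 100_000  # r2(d) = exp(-d/half_r2 * ln 10) hits 0.1 at d
        z = rng.normal(size=(n, m))
        base = rng.normal(size=n)
        cols = []
        for j in range(m):
            rho2 = 0.1 ** (j * spacing / half_r2)
            rho = np.sqrt(min(rho2, 1.0))
            cols.append(rho * base + np.sqrt(1 - rho ** 2) * z[:, j])
        d = np.array(cols).T
        d = (d > 0).astype(float) + (d > 1).astype(float)
        geno = make_genotypes(d, pos=[1000 + j * spacing
                                      for j in range(m)])
        # r2 on dosages is attenuated vs the latent correlation; compare
        # against the curve's own analytic construction loosely: the
        # crossing must be finite and below twice the design distance
        _, crossing = ld_decay(geno, max_dist_bp=1_000_000,
                               bin_width_bp=20_000)
        assert np.isfinite(crossing)
        assert crossing < 2 * half_r2
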