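"""Population structure: QC rules, pruning, PCA, admixture, trees, Fst."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_genotypes
from rootshape.popgen import (NEI_INF_SENTINEL, AdmixtureModel,
                              admixture_cv, filter_markers, ld_prune,
                              nei_distance_from_freqs, nj_tree,
                              pairwise_fst, pca_genotypes)
from rootshape.simulate import generate_population


class TestFilterMarkers:
    @staticmethod
    def _marker(n, hom_ref, het, hom_alt):
        col = [0.0] * hom_ref + [1.0] * het + [2.0] * hom_alt
        assert len(col) == n
        return col

    def test_min_per_hom_class_removes(self):
        n = 234
        bad = self._marker(n, 200, 30, 4)      # 4 hom-alt < 5
        good = self._marker(n, 100, 56, 78)
        geno = make_genotypes(np.array([bad, good]).T)
        out, log = filter_markers(geno)
        assert out.n_markers == 1
        assert log["min_per_hom_class"] == 1

    def test_modal_genotype_frequency_rule(self):
        # N = 234 -> threshold 1 - 5/234 ~= 0.9786; modal count 230 gives
        # 0.983 > threshold.  The hom-class rule is disabled here because
        # at equal counts it subsumes the frequency rule: the largest
        # possible modal share with both hom classes >= 5 is (N-5)/N,
        # exactly the threshold, and the rule is strictly 'greater'.
        n = 234
        bad = self._marker(n, 230, 0, 4)       # modal 0.983 > 0.9786
        balanced = self._marker(n, 78, 78, 78)
        geno = make_genotypes(np.array([bad, balanced]).T)
        out, log = filter_markers(geno, min_per_hom_class=0)
        assert log["max_genotype_freq"] == 1
        assert out.n_markers == 1

    def test_hom_class_rule_subsumes_frequency_rule_at_equal_count(self):
        # boundary: 229/0/5 has modal share exactly 1 - 5/234 -> kept
        n = 234
        edge = self._marker(n, 229, 0, 5)
        geno = make_genotypes(np.array([edge]).T)
        out, log = filter_markers(geno)
        assert out.n_markers == 1
        assert log["max_genotype_freq"] == 0

    def test_balanced_marker_retained(self):
        geno = make_genotypes(np.array([self._marker(234, 78, 78, 78)]).T)
        out, _ = filter_markers(geno)
        assert out.n_markers == 1

    def test_all_removed_raises(self):
        geno = make_genotypes(np.array([self._marker(10, 9, 1, 0)]).T)
        with pytest.raises(ValueError, match="all markers"):
            filter_markers(geno)

    def test_depth_rule_masks_calls(self):
        n = 20
        col = self._marker(n, 8, 6, 6)
        geno = make_genotypes(np.array([col]).T)
        depth = np.full((n, 1), 30.0)
        depth[:3] = 2.0
        out, _ = filter_markers(geno, min_per_hom_class=1,
                                min_depth=10, depth=depth)
        assert np.isnan(out.dosage[:3, 0]).all()


class TestLdPrune:
    def test_identical_adjacent_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.5, 40).astype(float)
        geno = make_genotypes(np.array([x, x]).T, pos=[1000, 2000])
        kept = ld_prune(geno)
        assert kept.tolist() == [0]

    def test_far_apart_markers_kept(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.5, 40).astype(float)
        geno = make_genotypes(np.array([x, x]).T, pos=[1000, 200_000])
        kept = ld_prune(geno, window_kb=50)
        assert kept.tolist() == [0, 1]

    def test_matches_brute_force_oracle(self):
        """Greedy scan equals all-pairs pruning on an LD-block fixture."""
        rng = np.random.default_rng(1)
        blocks = []
        pos = []
        p = 5000
        cols = []
        for b in range(3):
            anchor = rng.binomial(2, 0.5, 60).astype(float)
            for j in range(4):
                noise = rng.binomial(1, 0.08, 60)
                col = np.clip(anchor + noise - noise.mean(), 0, 2)
                cols.append(col if j else anchor)
                pos.append(p)
                p += 4000
            p += 100_000
        geno = make_genotypes(np.array(cols).T, pos=pos)
        kept = set(ld_prune(geno, window_kb=50, r2_cutoff=0.02).tolist())

        # oracle: scan markers in order, drop on high r2 with any kept
        # marker within the window
        def r2(a, b):
            return np.corrcoef(a, b)[0, 1] ** 2

        oracle = []
        for j in range(geno.n_markers):
            ok = True
            for i in oracle:
                if (geno.pos[j] - geno.pos[i] <= 50_000
                        and r2(geno.dosage[:, i],
                               geno.dosage[:, j]) > 0.02):
                    ok = False
                    break
            if ok:
                oracle.append(j)
        assert kept == set(oracle)


class TestPcaGenotypes:
    def test_duplicated_accessions_identical_scores(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, size=(20, 60)).astype(float)
        d[5] = d[3]
        geno = make_genotypes(d)
        scores, _ = pca_genotypes(geno)
        assert np.allclose(scores.iloc[3], scores.iloc[5], atol=1e-9)

    def test_two_populations_separate_on_pc1(self):
        geno, _ = generate_population(50, 800, 2, 0.3, 0.02, seed=4)
        scores, pct = pca_genotypes(geno)
        groups = geno.group_array()
        labels = pd.unique(groups)
        s1 = scores["PC1"].to_numpy()[groups == labels[0]]
        s2 = scores["PC1"].to_numpy()[groups == labels[1]]
        assert np.sign(np.median(s1)) != np.sign(np.median(s2))

    def test_pct_variance_bounded(self, small_population):
        geno, _ = small_population
        _, pct = pca_genotypes(geno, n_components=10)
        assert pct.sum() <= 100.0 + 1e-9
        assert np.all(np.diff(pct) <= 1e-9)

    def test_marker_order_invariance(self, small_population):
        geno, _ = small_population
        s1, _ = pca_genotypes(geno)
        perm = np.random.default_rng(5).permutation(geno.n_markers)
        # column permutation requires re-sorting positions; rebuild
        d = geno.dosage[:, perm]
        geno2 = make_genotypes(d)
        s2, _ = pca_genotypes(geno2)
        # scores are defined up to sign per component
        for c in s1.columns[:3]:
            r = np.corrcoef(s1[c], s2[c])[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-9)


class TestAdmixture:
    def test_k1_closed_form(self, small_population):
        geno, _ = small_population
        fit = AdmixtureModel(geno, 1).fit(seed=0, n_restarts=1)
        p = geno.allele_freq()
        assert np.abs(fit.f[0] - p).max() < 1e-4
        ll = np.sum(geno.dosage * np.log(np.clip(p, 1e-10, 1))
                    + (2 - geno.dosage)
                    * np.log(np.clip(1 - p, 1e-10, 1)))
        assert fit.loglik == pytest.approx(ll, abs=0.5)

    def test_loglik_monotone(self, small_population):
        geno, _ = small_population
        fit = AdmixtureModel(geno, 3).fit(seed=1, n_restarts=1)
        assert np.all(np.diff(fit.loglik_path) >= -1e-6)

    def test_separable_populations_recovered(self):
        G = np.vstack([np.zeros((15, 40)), np.full((15, 40), 2.0)])
        fit = AdmixtureModel(G, 2).fit(seed=2)
        q = fit.q
        col = int(np.argmax(q[:15].mean(axis=0)))  # label switching
        assert np.abs(q[:15, col] - 1).max() < 0.01
        assert np.abs(q[15:, 1 - col] - 1).max() < 0.01

    def test_label_permutation_invariant_loglik(self, small_population):
        geno, _ = small_population
        fit = AdmixtureModel(geno, 2).fit(seed=3, n_restarts=1)
        m = AdmixtureModel(geno, 2)
        ll_perm = m._loglik(fit.q[:, ::-1], fit.f[::-1])
        assert ll_perm == pytest.approx(fit.loglik, abs=1e-6)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            AdmixtureModel(np.zeros((3, 10)), 4)

    def test_cv_fold_determinism(self, small_population):
        geno, _ = small_population
        t1, k1 = admixture_cv(geno, [1, 2], n_folds=2, seed=9,
                              n_restarts=1, max_iter=50)
        t2, k2 = admixture_cv(geno, [1, 2], n_folds=2, seed=9,
                              n_restarts=1, max_iter=50)
        pd.testing.assert_frame_equal(t1, t2)
        assert k1 == k2

    def test_cv_no_overfit_for_single_population(self):
        """k_true=1: cv error does not improve with k (within noise)."""
        geno, _ = generate_population(60, 300, 1, 0.2, 1.0, seed=6)
        table, _ = admixture_cv(geno, [1, 3], n_folds=3, seed=1,
                                n_restarts=1)
        e = table.set_index("k")["cv_error"]
        assert e[3] >= e[1] - 0.02


class TestNeiDistance:
    def test_identical_profiles_zero(self):
        m, _ = nei_distance_from_freqs(np.array([[0.3, 0.6], [0.3, 0.6]]),
                                       ["a", "b"])
        assert m.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_value(self):
        m, _ = nei_distance_from_freqs(np.array([[1.0], [0.5]]),
                                       ["x", "y"])
        assert m.iloc[0, 1] == pytest.approx(-np.log(0.5 / np.sqrt(0.5)),
                                             abs=1e-6)

    def test_opposite_fixation_capped(self):
        m, _ = nei_distance_from_freqs(np.array([[1.0], [0.0]]),
                                       ["x", "y"])
        assert m.iloc[0, 1] == pytest.approx(NEI_INF_SENTINEL)


class TestNjTree:
    @staticmethod
    def _path_lengths(newick):
        import io

        import skbio

        tree = skbio.TreeNode.read(io.StringIO(newick))
        return tree.tip_tip_distances()

    def test_additive_tree_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) -> additive distances
        D = pd.DataFrame([[0, 3, 5, 3], [3, 0, 6, 4],
                          [5, 6, 0, 4], [3, 4, 4, 0]],
                         index=list("ABCD"), columns=list("ABCD"),
                         dtype=float)
        newick = nj_tree(D)
        dm = self._path_lengths(newick)
        for a in "ABCD":
            for b in "ABCD":
                assert dm[a, b] == pytest.approx(D.loc[a, b], abs=1e-9)

    def test_matches_skbio_on_random_additive(self):
        """NJ reproduces any additive matrix (n=6) to 1e-9."""
        rng = np.random.default_rng(7)
        # build a random additive matrix from a random tree via skbio
        import io

        import skbio

        nwk = "((a:%.3f,b:%.3f):%.3f,(c:%.3f,d:%.3f):%.3f,(e:%.3f,f:%.3f):%.3f);" % tuple(
            rng.uniform(0.5, 3.0, 9))
        tree = skbio.TreeNode.read(io.StringIO(nwk))
        dm = tree.tip_tip_distances()
        labels = list(dm.ids)
        D = pd.DataFrame(dm.data, index=labels, columns=labels)
        rebuilt = self._path_lengths(nj_tree(D))
        for a in labels:
            for b in labels:
                assert rebuilt[a, b] == pytest.approx(D.loc[a, b],
                                                      abs=1e-9)

    def test_equidistant_three_taxa_star(self):
        D = pd.DataFrame(2.0 * (1 - np.eye(3)), index=list("abc"),
                         columns=list("abc"))
        newick = nj_tree(D)
        assert newick.count(":1") == 3

    def test_label_permutation_isomorphic(self):
        D = pd.DataFrame([[0, 3, 5, 3], [3, 0, 6, 4],
                          [5, 6, 0, 4], [3, 4, 4, 0]],
                         index=list("ABCD"), columns=list("ABCD"),
                         dtype=float)
        perm = ["C", "A", "D", "B"]
        Dp = D.loc[perm, perm]
        d1 = self._path_lengths(nj_tree(D))
        d2 = self._path_lengths(nj_tree(Dp))
        for a in "ABCD":
            for b in "ABCD":
                assert d1[a, b] == pytest.approx(d2[a, b], abs=1e-9)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(pd.DataFrame(np.zeros((2, 2)), index=list("ab"),
                                 columns=list("ab")))


class TestPairwiseFst:
    def test_opposite_fixation_is_one(self):
        d = np.vstack([np.zeros((5, 10)), np.full((5, 10), 2.0)])
        geno = make_genotypes(d, groups=["x"] * 5 + ["y"] * 5)
        assert pairwise_fst(geno).iloc[0, 1] == pytest.approx(1.0)

    def test_identical_frequencies_zero(self):
        rng = np.random.default_rng(8)
        block = rng.binomial(2, 0.4, size=(6, 20)).astype(float)
        d = np.vstack([block, block])
        geno = make_genotypes(d, groups=["x"] * 6 + ["y"] * 6)
        assert pairwise_fst(geno).iloc[0, 1] == pytest.approx(0.0,
                                                              abs=1e-12)

    def test_hand_value_single_locus(self):
        # p1 = 0.2, p2 = 0.8 -> Ht = 0.5, Hs = 0.32, Fst = 0.36
        g1 = [0.0, 1, 0, 1, 0]   # freq 0.2
        g2 = [2.0, 1, 2, 1, 2]   # freq 0.8
        geno = make_genotypes(np.array([g1 + g2]).T,
                              groups=["x"] * 5 + ["y"] * 5)
        assert pairwise_fst(geno).iloc[0, 1] == pytest.approx(0.36,
                                                              abs=1e-6)

    def test_bounds_and_duplicate_group(self):
        rng = np.random.default_rng(9)
        d = rng.binomial(2, rng.uniform(0.1, 0.9, 30),
                         size=(12, 30)).astype(float)
        d = np.vstack([d, d[:6]])  # duplicate first group
        geno = make_genotypes(d, groups=["x"] * 6 + ["y"] * 6 + ["x2"] * 6)
        m = pairwise_fst(geno)
        assert ((m.fillna(0) >= 0) & (m.fillna(0) <= 1)).all().all()
        assert m.loc["x", "x2"] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_divergence(self):
        """Fst estimates ordered with the Balding-Nichols parameter."""
        means = []
        for F in (0.05, 0.1, 0.2, 0.4):
            vals = []
            for seed in range(3):
                geno, _ = generate_population(60, 2000, 2, F, 0.01,
                                              seed=seed)
                vals.append(pairwise_fst(geno).iloc[0, 1])
            means.append(np.mean(vals))
        assert np.all(np.diff(means) > 0)

    def test_hudson_consistent_for_bn_parameter(self):
        vals = []
        for seed in range(3):
            geno, _ = generate_population(80, 5000, 2, 0.2, 0.01,
                                          seed=seed)
            vals.append(pairwise_fst(geno, method="hudson").iloc[0, 1])
        assert np.mean(vals) == pytest.approx(0.2, abs=0.05)

    def test_small_group_rejected(self):
        d = np.zeros((3, 5))
        geno = make_genotypes(d, groups=["x", "x", "y"])
        with pytest.raises(ValueError):
            pairwise_fst(geno)
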