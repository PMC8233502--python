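import itertools

import numpy as np
import pandas as pd
import pytest

import phylokin as pk
from phylokin._gls import profile_loglik
from phylokin.signal import DegenerateTraitError


class TestAlphaBin:
    @pytest.mark.parametrize("p,expect", [
        (0.0005, "0.001"), (0.005, "0.01"), (0.03, "0.05"),
        (0.2, "ns"), (0.05, "ns"), (0.001, "0.01"), (1.0, "ns"),
    ])
    def test_bins(self, p, expect):
        assert pk.alpha_bin(p) == expect

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            pk.alpha_bin(0.0)


class TestPagelLambda:
    def test_zero_lambda_loglik_matches_independent_normal(self, bm_sample):
        """At lambda=0 the model is independent tips with depth-scaled
        variances; the profiled likelihood must match the closed form."""
        _, C, y = bm_sample
        d = np.diag(C.values)
        ll0, mu, s2 = profile_loglik(y, np.diag(d))
        w = 1.0 / d
        mu_exp = float(np.sum(w * y) / np.sum(w))
        s2_exp = float(np.mean((y - mu_exp) ** 2 / d))
        ll_exp = -0.5 * (len(y) * np.log(2 * np.pi * s2_exp)
                         + np.sum(np.log(d)) + len(y))
        assert mu == pytest.approx(mu_exp, rel=1e-10)
        assert s2 == pytest.approx(s2_exp, rel=1e-10)
        assert ll0 == pytest.approx(ll_exp, rel=1e-10)

    def test_bm_trait_estimates_high_lambda(self, bm_sample):
        _, C, y = bm_sample
        est = pk.PagelLambda().fit(C, y)
        assert est.lambda_ > 0.7
        assert est.p_value_ < 0.05
        assert 0 <= est.lambda_ <= est.lambda_max_

    def test_iid_trait_estimates_low_lambda(self, bm_sample):
        _, C, _ = bm_sample
        y = np.random.default_rng(5).standard_normal(len(C))
        est = pk.PagelLambda().fit(C, y)
        assert est.lambda_ < 0.3

    def test_recovery_within_profile_interval(self):
        """Generating lambda=1 data, the estimate should cover 1 within the
        chi-square profile interval in most seeded replicates."""
        hits = 0
        reps = 20
        rng = np.random.default_rng(42)
        tree = pk.simulate_yule_tree(200, seed=42)
        C = pk.bm_covariance(tree)
        A = C.to_numpy()
        L = np.linalg.cholesky(A + 1e-10 * np.eye(len(A)))
        D = np.diag(np.diag(A))
        off = A - D
        for _ in range(reps):
            y = L @ rng.standard_normal(len(A))
            est = pk.PagelLambda().fit(C, y)
            ll1 = profile_loglik(y, 1.0 * off + D)[0]
            hits += 2 * (est.loglik_ - ll1) <= 3.841
        assert hits >= int(0.9 * reps)


class TestBlombergK:
    def test_star_tree_equal_depths_gives_k_exactly_one(self):
        C = pd.DataFrame(np.eye(6) * 2.0,
                         index=list("ABCDEF"), columns=list("ABCDEF"))
        y = np.array([3.0, -1.0, 2.0, 0.5, -2.0, 1.0])
        est = pk.BlombergK(n_perm=19, seed=0).fit(C, y)
        assert est.statistic_ == pytest.approx(1.0, abs=1e-10)

    def test_constant_trait_is_error(self, bm_sample):
        _, C, _ = bm_sample
        with pytest.raises(DegenerateTraitError):
            pk.BlombergK(n_perm=19, seed=0).fit(C, np.ones(len(C)))

    def test_bm_trait_k_near_one_and_significant(self, bm_sample):
        tree, _, y = bm_sample
        K, Kstar, p = pk.blomberg_k(y, tree, n_perm=199, seed=1)
        assert 0.3 < K < 3.0
        assert p < 0.05

    def test_min_p_is_one_over_nperm_plus_one(self, bm_sample):
        _, C, y = bm_sample
        est = pk.BlombergK(n_perm=199, seed=1).fit(C, y)
        assert est.p_value_ >= 1.0 / 200


class TestMoranI:
    # two linked pairs: perfect block autocorrelation
    W_BLOCK = pd.DataFrame(
        [[0, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0]],
        index=list("ABCD"), columns=list("ABCD"), dtype=float)

    def test_block_weights_perfect_autocorrelation(self):
        I, _ = pk.morans_i(np.array([1.0, 1.0, -1.0, -1.0]),
                           self.W_BLOCK, n_perm=23, seed=0)
        assert I == pytest.approx(1.0)

    def test_block_weights_perfect_anticorrelation(self):
        I, _ = pk.morans_i(np.array([1.0, -1.0, 1.0, -1.0]),
                           self.W_BLOCK, n_perm=23, seed=0)
        assert I == pytest.approx(-1.0)

    def test_permutation_null_mean_by_exhaustive_enumeration(self):
        """The classical E[I] = -1/(n-1), checked by brute-force average of
        the statistic over all 24 permutations of a 4-tip example."""
        rng = np.random.default_rng(8)
        y = rng.standard_normal(4)
        W = pd.DataFrame(rng.uniform(0.1, 1.0, (4, 4)),
                         index=list("ABCD"), columns=list("ABCD"))
        W = (W + W.T) / 2
        np.fill_diagonal(W.values, 0.0)
        z = y - y.mean()
        s0 = W.values.sum()
        vals = []
        for perm in itertools.permutations(range(4)):
            zp = z[list(perm)]
            vals.append((4 / s0) * (zp @ W.values @ zp) / (zp @ zp))
        assert np.mean(vals) == pytest.approx(-1.0 / 3, rel=1e-10)
        est = pk.MoranI(n_perm=23, seed=0).fit(W, y)
        assert est.expected_ == pytest.approx(-1.0 / 3)


class TestCmean:
    def test_affine_invariance(self, bm_sample):
        tree, _, y = bm_sample
        A = pk.abouheif_proximity(tree)
        c1, _ = pk.abouheif_cmean(y, A, n_perm=49, seed=3)
        c2, _ = pk.abouheif_cmean(3.2 * y + 7.0, A, n_perm=49, seed=3)
        assert c1 == pytest.approx(c2, rel=1e-10)

    def test_clustered_trait_strongly_significant(self):
        tree = pk.simulate_yule_tree(60, seed=21)
        A = pk.abouheif_proximity(tree)
        labels = list(A.index)
        clade = [l.taxon.label for l in next(
            nd for nd in tree.preorder_internal_node_iter()
            if nd is not tree.seed_node
            and 15 <= sum(1 for _ in nd.leaf_iter()) <= 30).leaf_iter()]
        rng = np.random.default_rng(2)
        y = np.where(np.isin(labels, clade), 10.0, 0.0) + rng.normal(0, 0.1, 60)
        _, p = pk.abouheif_cmean(y, A, n_perm=999, seed=4)
        assert p <= 0.001

    def test_iid_trait_p_roughly_uniform(self):
        tree = pk.simulate_yule_tree(40, seed=13)
        A = pk.abouheif_proximity(tree)
        rng = np.random.default_rng(14)
        ps = [pk.abouheif_cmean(rng.standard_normal(40), A,
                                n_perm=99, seed=s)[1] for s in range(40)]
        assert 0.25 < np.mean(ps) < 0.75  # null p-values centered near 0.5


class TestSignalPanel:
    def test_strong_signal_presence_true(self, bm_sample):
        tree, C, y = bm_sample
        df = pd.DataFrame({"species": list(C.index), "group": "angiosperm",
                           "ptype": "C3", "kcatc": np.exp(y)})
        table = pk.log_transform(pk.TraitTable(df, provenance=("f",)))
        panel = pk.signal_panel("kcatc", table, tree,
                                pk.SignalConfig(n_perm=199, seed=0))
        assert panel.presence
        assert set(panel.results) == {"lambda", "K", "Kstar", "moran_I", "cmean"}
        assert sum(r.p_value < 0.05 for r in panel.results.values()) >= 3

    def test_no_signal_presence_false(self, bm_sample):
        tree, C, _ = bm_sample
        rng = np.random.default_rng(99)
        df = pd.DataFrame({"species": list(C.index), "group": "angiosperm",
                           "ptype": "C3",
                           "kcatc": np.exp(rng.normal(1.0, 0.3, len(C)))})
        table = pk.log_transform(pk.TraitTable(df, provenance=("f",)))
        panel = pk.signal_panel("kcatc", table, tree,
                                pk.SignalConfig(n_perm=199, seed=0))
        assert not panel.presence

    def test_alpha_bins_consistent_with_p_values(self, bm_sample):
        tree, C, y = bm_sample
        df = pd.DataFrame({"species": list(C.index), "group": "angiosperm",
                           "ptype": "C3", "kcatc": np.exp(y)})
        table = pk.log_transform(pk.TraitTable(df, provenance=("f",)))
        panel = pk.signal_panel("kcatc", table, tree,
                                pk.SignalConfig(n_perm=199, seed=0))
        for r in panel.results.values():
            assert r.alpha == pk.alpha_bin(r.p_value)

    def test_panels_bit_reproducible(self, bm_sample):
        tree, C, y = bm_sample
        df = pd.DataFrame({"species": list(C.index), "group": "angiosperm",
                           "ptype": "C3", "kcatc": np.exp(y)})
        table = pk.log_transform(pk.TraitTable(df, provenance=("f",)))
        cfg = pk.SignalConfig(n_perm=99, seed=5)
        p1 = pk.signal_panel("kcatc", table, tree, cfg)
        p2 = pk.signal_panel("kcatc", table, tree, cfg)
        for m in p1.results:
            assert p1.results[m].statistic == p2.results[m].statistic
            assert p1.results[m].p_value == p2.results[m].p_value
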