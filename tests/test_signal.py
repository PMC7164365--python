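"""Pagel's lambda, the D statistic, and PD/MPD/MNTD with SES nulls."""

import numpy as np
import pytest

import terebra as tb
from terebra.signal import mntd, mpd, patristic_distances
from terebra.tree import TreeError


class TestPagelsLambda:
    def test_lambda0_equals_independent_gaussian(self, yule100):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(yule100.n_tips)
        res = tb.pagels_lambda(yule100, x)
        # direct iid-Gaussian profile likelihood with variances = tip depths
        v = np.diag(tb.vcv_matrix(yule100))
        w = 1 / v
        mu = np.sum(w * x) / np.sum(w)
        s2 = np.mean((x - mu) ** 2 / v)
        n = x.size
        ll0 = -0.5 * (n * np.log(2 * np.pi * s2) + np.sum(np.log(v)) + n)
        assert res.loglik_lambda0 == pytest.approx(ll0, abs=1e-8)

    def test_bm_trait_estimates_near_one(self):
        t = tb.simulate_yule_tree(0.1, 200, seed=42)
        x = tb.simulate_bm(t, 1.0, seed=7)[:, 0]
        assert tb.pagels_lambda(t, x).lam > 0.85

    def test_iid_trait_estimates_near_zero(self):
        t = tb.simulate_yule_tree(0.1, 200, seed=43)
        x = np.random.default_rng(8).standard_normal(200)
        assert tb.pagels_lambda(t, x).lam < 0.15

    def test_respects_nesting_over_fixed_lambda(self, yule100):
        from terebra.signal import _gls_loglik, lambda_transform
        x = tb.simulate_bm(yule100, 1.0, seed=9)[:, 0] * 0.6 + \
            np.random.default_rng(10).standard_normal(100) * 0.4
        res = tb.pagels_lambda(yule100, x)
        V = tb.vcv_matrix(yule100)
        for lam in (0.0, 0.5, 1.0):
            ll = _gls_loglik(lambda_transform(V, lam), x)[0]
            assert res.loglik >= ll - 1e-6

    def test_too_few_species_rejected(self, three_tip_tree):
        with pytest.raises(ValueError):
            tb.pagels_lambda(three_tip_tree, [1.0, 2.0, 3.0])


class TestDStatistic:
    def test_complement_invariance(self, yule100):
        x = np.zeros(100, int)
        x[::3] = 1
        d1 = tb.fritz_purvis_d(yule100, x, n_null=200, seed=1)
        d2 = tb.fritz_purvis_d(yule100, 1 - x, n_null=200, seed=1)
        assert d1.d == pytest.approx(d2.d, abs=1e-9)

    def test_shuffled_trait_centers_at_one(self):
        ds = []
        for s in range(25):
            t = tb.simulate_yule_tree(0.1, 100, seed=500 + s)
            rng = np.random.default_rng(s)
            x = np.zeros(100, int)
            x[:50] = 1
            rng.shuffle(x)
            ds.append(tb.fritz_purvis_d(t, x, n_null=300, seed=s).d)
        assert abs(np.mean(ds) - 1.0) < 0.15

    def test_brownian_threshold_trait_centers_at_zero(self):
        ds = []
        for s in range(25):
            t = tb.simulate_yule_tree(0.1, 100, seed=700 + s)
            bm = tb.simulate_bm(t, 1.0, seed=s)[:, 0]
            x = (bm > np.median(bm)).astype(int)
            ds.append(tb.fritz_purvis_d(t, x, n_null=300, seed=s).d)
        assert abs(np.mean(ds)) < 0.15

    def test_invariant_under_branch_rescaling(self, yule100):
        x = np.zeros(100, int)
        x[:30] = 1
        scaled = tb.PhyloTree(yule100.parent.copy(),
                              yule100.lengths * 10.0,
                              list(yule100.labels), yule100.root)
        d1 = tb.fritz_purvis_d(yule100, x, n_null=300, seed=4)
        d2 = tb.fritz_purvis_d(scaled, x, n_null=300, seed=4)
        assert d1.d == pytest.approx(d2.d, abs=1e-9)

    def test_identity_from_stored_components(self, yule100):
        x = np.zeros(100, int)
        x[:40] = 1
        r = tb.fritz_purvis_d(yule100, x, n_null=200, seed=5)
        manual = (r.sum_changes_obs - r.null_brownian_mean) / (
            r.null_random_mean - r.null_brownian_mean)
        assert r.d == pytest.approx(manual, rel=1e-12)

    def test_monomorphic_rejected(self, yule100):
        with pytest.raises(ValueError, match="monomorphic"):
            tb.fritz_purvis_d(yule100, np.zeros(100, int), seed=0)


class TestFaithPd:
    def test_all_tips_sum_all_branches(self, three_tip_tree):
        assert tb.faith_pd(three_tip_tree, ["A", "B", "C"]) == pytest.approx(
            three_tip_tree.total_branch_length)

    def test_single_tip_root_path(self, three_tip_tree):
        assert tb.faith_pd(three_tip_tree, ["A"]) == pytest.approx(2.0)

    def test_monotone_in_taxa(self, balanced16_tree):
        labels = balanced16_tree.tip_labels
        prev = 0.0
        for k in range(1, len(labels) + 1):
            pd_k = tb.faith_pd(balanced16_tree, labels[:k])
            assert pd_k >= prev - 1e-12
            prev = pd_k

    def test_unknown_taxon_reported(self, three_tip_tree):
        with pytest.raises(TreeError, match="ZZ"):
            tb.faith_pd(three_tip_tree, ["A", "ZZ"])


class TestDistanceMetrics:
    def test_two_tip_community(self, three_tip_tree):
        d = patristic_distances(three_tip_tree)
        i = {l: k for k, l in enumerate(three_tip_tree.tip_labels)}
        rows = [i["A"], i["B"]]
        assert mpd(d, rows) == pytest.approx(2.0)
        assert mntd(d, rows) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_on_small_trees(self, seed):
        t = tb.simulate_yule_tree(0.3, 12, seed)

        def walk_distance(a, b):
            # path length by climbing to the root from both tips
            anc = {}
            v, d = a, 0.0
            while v >= 0:
                anc[v] = d
                d += t.lengths[v]
                v = t.parent[v]
            v, d = b, 0.0
            while v not in anc:
                d += t.lengths[v]
                v = t.parent[v]
            return d + anc[v]

        d = patristic_distances(t)
        tips = list(t.tip_ids)
        for i in range(len(tips)):
            for j in range(len(tips)):
                if i != j:
                    assert d[i, j] == pytest.approx(
                        walk_distance(tips[i], tips[j]), rel=1e-10)

        rows = list(range(5))
        sub = d[np.ix_(rows, rows)]
        pairs = [sub[i, j] for i in range(5) for j in range(i + 1, 5)]
        assert mpd(d, rows) == pytest.approx(np.mean(pairs))
        nearest = [min(sub[i, j] for j in range(5) if j != i)
                   for i in range(5)]
        assert mntd(d, rows) == pytest.approx(np.mean(nearest))


class TestSes:
    def test_clade_community_is_clustered(self, balanced16_tree):
        labels = balanced16_tree.tip_labels
        clade = [l for l in labels if l.startswith("t0")]  # one root side
        res = tb.ses_metric(balanced16_tree, {"clade": clade},
                            metric="MPD", n_rand=500, seed=2)["clade"]
        assert res.z < -2

    def test_null_draws_center_at_zero(self, yule100):
        rng = np.random.default_rng(3)
        labels = yule100.tip_labels
        zs = []
        for s in range(60):
            comm = list(rng.choice(labels, size=20, replace=False))
            zs.append(tb.ses_metric(yule100, {"c": comm}, metric="MNTD",
                                    n_rand=200, seed=s)["c"].z)
        assert abs(np.mean(zs)) < 3 / np.sqrt(60)

    def test_z_and_p_agree_in_sign(self, balanced16_tree):
        labels = balanced16_tree.tip_labels
        for comm in ([l for l in labels if l.startswith("t00")],
                     labels[::4]):
            for metric in ("PD", "MPD", "MNTD"):
                r = tb.ses_metric(balanced16_tree, {"c": comm},
                                  metric=metric, n_rand=400, seed=1)["c"]
                assert (r.p < 0.5) == (r.z < 0) or abs(r.z) < 0.2

    def test_identity_from_stored_components(self, yule100):
        comm = yule100.tip_labels[:10]
        r = tb.ses_metric(yule100, {"c": comm}, metric="MPD",
                          n_rand=200, seed=9)["c"]
        assert r.z == pytest.approx(
            (r.observed - r.null_mean) / r.null_sd, rel=1e-12)

    def test_singleton_community_rejected(self, yule100):
        with pytest.raises(ValueError):
            tb.ses_metric(yule100, {"c": yule100.tip_labels[:1]},
                          metric="MPD", n_rand=200, seed=0)
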