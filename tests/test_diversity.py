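"""Diversity statistics against closed forms and brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from symdiv import diversity as dv

# ---------------------------------------------------------------- oracles


def brute_force_pseudo_f(D: np.ndarray, labels) -> float:
    """PERMANOVA pseudo-F by direct loops over the definition."""
    labels = list(labels)
    n = len(labels)
    ss_total = sum(
        D[i, j] ** 2 for i in range(n) for j in range(i + 1, n)
    ) / n
    ss_within = 0.0
    groups = sorted(set(labels))
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        ss_within += sum(
            D[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    k = len(groups)
    return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))


def brute_force_anosim_r(D: np.ndarray, labels) -> float:
    labels = list(labels)
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = rankdata([D[i, j] for i, j in pairs])
    within = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    return (np.mean(between) - np.mean(within)) / (n * (n - 1) / 4)


def exhaustive_p(D: np.ndarray, labels, stat_fn) -> float:
    observed = stat_fn(D, labels)
    perms = set(itertools.permutations(labels))
    count = sum(1 for p in perms if stat_fn(D, p) >= observed - 1e-12)
    return count / len(perms)


def euclidean_dm(points: np.ndarray) -> dv.DistanceMatrix:
    return dv.DistanceMatrix(
        ids=tuple(f"s{i}" for i in range(len(points))),
        matrix=squareform(pdist(points)),
    )


# ---------------------------------------------------------------- alpha


class TestShannon:
    def test_uniform_vector_equals_log_richness(self):
        for k in (2, 4, 7):
            assert dv.shannon_index([10] * k) == pytest.approx(
                np.log(k), abs=1e-12
            )

    def test_single_taxon_is_zero(self):
        assert dv.shannon_index([100]) == 0.0

    def test_hand_computed_three_taxon_value(self):
        # -(0.25 ln 0.25 + 0.25 ln 0.25 + 0.5 ln 0.5)
        assert dv.shannon_index([5, 5, 10]) == pytest.approx(
            1.0397207708399179, abs=1e-12
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dv.shannon_index([0, 0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=1000), min_size=1,
                 max_size=12).filter(lambda v: sum(v) > 0)
    )
    def test_bounded_by_log_richness(self, v):
        h = dv.shannon_index(v)
        richness = sum(1 for x in v if x > 0)
        assert -1e-12 <= h <= np.log(max(richness, 1)) + 1e-12


class TestSqueeze:
    def test_maximal_evenness_maps_below_one(self):
        h = np.array([dv.shannon_index([10, 10, 10, 10])])
        y = dv.squeeze_to_unit_interval(h, "evenness", s_total=4)
        assert 0 < y[0] < 1

    def test_zero_diversity_strictly_positive_after_squeeze(self):
        y = dv.squeeze_to_unit_interval(np.zeros(5), "squeeze")
        assert (y > 0).all()

    def test_half_is_fixed_point(self):
        y = dv.squeeze_to_unit_interval(np.full(10, 0.5), "squeeze")
        assert np.allclose(y, 0.5)

    def test_evenness_requires_richness_two(self):
        with pytest.raises(ValueError):
            dv.squeeze_to_unit_interval(np.array([0.5]), "evenness", s_total=1)


class TestBetaRegression:
    def test_intercept_only_matches_grid_search_oracle(self, rng):
        y = rng.beta(4, 8, size=60)
        fit = dv.fit_beta_regression(y, ["all"] * 60)
        # independent grid search over (mu, phi)
        mus = np.linspace(0.15, 0.6, 400)
        phis = np.linspace(2, 60, 300)
        best = None
        from scipy.stats import beta as beta_dist

        for mu in mus:
            for phi in phis:
                ll = beta_dist.logpdf(y, mu * phi, (1 - mu) * phi).sum()
                if best is None or ll > best[0]:
                    best = (ll, mu, phi)
        assert fit.fitted_mean("all") == pytest.approx(best[1], abs=1e-3)
        assert fit.phi == pytest.approx(best[2], rel=0.05)

    def test_boundary_response_rejected(self):
        with pytest.raises(ValueError):
            dv.fit_beta_regression([0.2, 0.0, 0.7, 0.5], ["a", "a", "b", "b"])

    def test_parameter_recovery_quick(self, rng):
        g = np.array(["a"] * 100 + ["b"] * 100)
        mu = np.where(g == "a", 0.4, 0.6)
        y = rng.beta(mu * 30, (1 - mu) * 30)
        fit = dv.fit_beta_regression(y, g)
        truth = np.array([np.log(0.4 / 0.6), np.log(0.6 / 0.4) - np.log(0.4 / 0.6)])
        assert np.all(np.abs(fit.coef.to_numpy() - truth) < 3 * fit.se.to_numpy())


class TestPairwiseTests:
    def test_identical_groups_give_null_contrast(self, rng):
        half = rng.beta(5, 10, size=15)
        y = np.concatenate([half, half])
        fit = dv.fit_beta_regression(y, ["a"] * 15 + ["b"] * 15)
        tab = dv.pairwise_group_tests(fit, n_perm=99, seed=0)
        assert tab.estimate.iloc[0] == pytest.approx(0.0, abs=1e-3)
        assert tab.p_adj.iloc[0] > 0.9

    def test_three_groups_emit_three_contrasts(self, rng):
        y = rng.beta(5, 10, size=30)
        fit = dv.fit_beta_regression(y, ["a", "b", "c"] * 10)
        tab = dv.pairwise_group_tests(fit, p_mode="wald")
        assert len(tab) == 3
        assert set(zip(tab.group1, tab.group2)) == {
            ("a", "b"), ("a", "c"), ("b", "c")
        }

    def test_permutation_p_reproducible_under_seed(self, rng):
        y = rng.beta(5, 10, size=24)
        fit = dv.fit_beta_regression(y, ["a", "b"] * 12)
        t1 = dv.pairwise_group_tests(fit, n_perm=49, seed=11)
        t2 = dv.pairwise_group_tests(fit, n_perm=49, seed=11)
        assert t1.p.equals(t2.p)


# ---------------------------------------------------------------- beta


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        t = pd.DataFrame([[3, 2, 1], [3, 2, 1]])
        assert dv.bray_curtis(t).matrix[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        t = pd.DataFrame([[5, 0], [0, 9]])
        assert dv.bray_curtis(t).matrix[0, 1] == 1.0

    def test_hand_arithmetic_example(self):
        t = pd.DataFrame([[2, 1], [1, 3]])
        assert dv.bray_curtis(t).matrix[0, 1] == pytest.approx(3 / 7, abs=1e-12)

    def test_joint_rescaling_invariance(self, rng):
        X = rng.integers(0, 50, size=(4, 6)) + 1
        d1 = dv.bray_curtis(pd.DataFrame(X)).matrix
        d2 = dv.bray_curtis(pd.DataFrame(X * 13)).matrix
        assert np.allclose(d1, d2)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError):
            dv.bray_curtis(pd.DataFrame([[0, 0], [1, 2]]))


class TestNMDS:
    def test_collinear_points_embed_with_near_zero_stress(self):
        pts = np.arange(5, dtype=float)[:, None]
        res = dv.nmds(euclidean_dm(pts), k=1, n_restarts=4, seed=0)
        assert res.stress < 0.01

    def test_duplicated_points_no_crash(self):
        pts = np.array([[0.0], [0.0], [1.0], [2.0]])
        res = dv.nmds(euclidean_dm(pts), k=1, n_restarts=2, seed=0)
        assert np.isfinite(res.stress)

    def test_beats_pcoa_baseline(self, rng):
        pts = rng.standard_normal((8, 5))
        D = euclidean_dm(pts)
        # oracle: classical scaling embedding + one isotonic fit
        n = 8
        J = np.eye(n) - np.ones((n, n)) / n
        G = -0.5 * J @ (D.matrix**2) @ J
        evals, evecs = np.linalg.eigh((G + G.T) / 2)
        order = np.argsort(evals)[::-1]
        coords = evecs[:, order[:2]] * np.sqrt(np.maximum(evals[order[:2]], 0))
        d = pdist(coords)
        diss = D.condensed()
        dhat = IsotonicRegression(increasing=True).fit(diss, d).predict(diss)
        pcoa_stress = np.sqrt(((d - dhat) ** 2).sum() / (d**2).sum())
        res = dv.nmds(D, k=2, n_restarts=5, seed=0)
        assert res.stress <= pcoa_stress + 1e-9

    def test_stress_non_increasing_within_restart(self, rng):
        pts = rng.standard_normal((10, 6))
        res = dv.nmds(euclidean_dm(pts), k=2, n_restarts=3, seed=1)
        hist = np.array(res.stress_history)
        assert (np.diff(hist) <= 1e-10).all()

    def test_k_must_be_below_n(self):
        with pytest.raises(ValueError):
            dv.nmds(euclidean_dm(np.zeros((3, 1))), k=3)


class TestPermanova:
    def test_six_sample_instances_match_brute_force(self, rng):
        for _ in range(6):
            pts = rng.standard_normal((6, 3))
            D = euclidean_dm(pts)
            labels = ["a", "a", "a", "b", "b", "b"]
            res = dv.permanova(D, labels, n_perm="exhaustive")
            assert res.statistic == pytest.approx(
                brute_force_pseudo_f(D.matrix, labels), rel=1e-12
            )
            assert res.p_value == pytest.approx(
                exhaustive_p(D.matrix, labels, brute_force_pseudo_f), abs=1e-12
            )

    def test_perfect_separation_reaches_minimal_p(self, rng):
        # only permutations reproducing the original partition tie with the
        # observed F, so p sits at (or within a few ties of) its floor
        a = rng.normal(0, 0.01, size=(8, 2))
        b = rng.normal(100, 0.01, size=(8, 2))
        D = euclidean_dm(np.vstack([a, b]))
        res = dv.permanova(D, ["a"] * 8 + ["b"] * 8, n_perm=999, seed=0)
        assert res.p_value <= 5 / 1000

    def test_seed_reproducibility(self, rng):
        D = euclidean_dm(rng.standard_normal((8, 2)))
        labels = ["a"] * 4 + ["b"] * 4
        r1 = dv.permanova(D, labels, n_perm=199, seed=3)
        r2 = dv.permanova(D, labels, n_perm=199, seed=3)
        assert r1.p_value == r2.p_value

    def test_small_group_rejected(self, rng):
        D = euclidean_dm(rng.standard_normal((4, 2)))
        with pytest.raises(ValueError):
            dv.permanova(D, ["a", "b", "b", "b"])


class TestAnosim:
    def test_complete_separation_gives_r_one(self):
        a = np.zeros((4, 1))
        b = np.full((4, 1), 10.0) + np.arange(4)[:, None] * 0.1
        pts = np.vstack([a + np.arange(4)[:, None] * 0.01, b])
        res = dv.anosim(euclidean_dm(pts), ["a"] * 4 + ["b"] * 4,
                        n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_mean_r_over_permutations_near_zero(self, rng):
        D = euclidean_dm(rng.standard_normal((8, 3)))
        rank_sq = squareform(rankdata(D.condensed()), checks=False)
        labels = np.array(["a"] * 4 + ["b"] * 4, dtype=object)
        rs = [
            dv._anosim_r(rank_sq, np.asarray(p, dtype=object))
            for p in set(itertools.permutations(labels))
        ]
        assert abs(np.mean(rs)) < 1e-10

    def test_six_sample_instance_matches_brute_force(self, rng):
        pts = rng.standard_normal((6, 2))
        D = euclidean_dm(pts)
        labels = ["a", "b", "a", "b", "a", "b"]
        res = dv.anosim(D, labels, n_perm="exhaustive")
        assert res.statistic == pytest.approx(
            brute_force_anosim_r(D.matrix, labels), rel=1e-12
        )
        assert res.p_value == pytest.approx(
            exhaustive_p(D.matrix, labels, brute_force_anosim_r), abs=1e-12
        )


class TestBetadisper:
    def test_identical_group_geometry_gives_zero_f(self):
        square = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        pts = np.vstack([square, square + 50])
        res = dv.betadisper(euclidean_dm(pts), ["a"] * 4 + ["b"] * 4)
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.parametric_p > 0.99

    def test_tight_vs_diffuse_cluster_detected(self):
        tight = np.array([[0, 0], [0.1, 0], [0, 0.1], [0.1, 0.1]])
        diffuse = np.array([[50, 0], [58, 0], [50, 9], [61, 8]])
        pts = np.vstack([tight, diffuse])
        labels = ["a"] * 4 + ["b"] * 4
        res = dv.betadisper(euclidean_dm(pts), labels, n_perm=199, seed=0)
        assert res.statistic > 10
        assert res.parametric_p < 0.01
        # hand-computed centroid distances in the original space
        for g, block in (("a", tight), ("b", diffuse)):
            centroid = block.mean(axis=0)
            expected = np.linalg.norm(block - centroid, axis=1)
            got = res.extras["centroid_distances"][
                np.array(labels, dtype=object) == g
            ]
            assert np.allclose(np.sort(got), np.sort(expected), atol=1e-8)

    def test_euclidean_embedding_reproduces_distances(self, rng):
        pts = rng.standard_normal((9, 4))
        D = euclidean_dm(pts)
        coords, _ = dv._pcoa_embedding(D.matrix, k=None, lingoes=True)
        assert np.allclose(squareform(pdist(coords)), D.matrix, atol=1e-8)


class TestSkbioCrossCheck:
    def test_statistics_match_skbio(self, rng):
        skbio = pytest.importorskip("skbio")
        import skbio.stats.distance as skd

        pts = rng.standard_normal((10, 4))
        M = squareform(pdist(pts))
        ids = [str(i) for i in range(10)]
        D = dv.DistanceMatrix(ids=tuple(ids), matrix=M)
        labels = ["a"] * 5 + ["b"] * 5
        sk = skbio.DistanceMatrix(M, ids=ids)
        assert dv.permanova(D, labels, n_perm=9, seed=0).statistic == (
            pytest.approx(
                float(skd.permanova(sk, labels, permutations=9)["test statistic"])
            )
        )
        assert dv.anosim(D, labels, n_perm=9, seed=0).statistic == (
            pytest.approx(
                float(skd.anosim(sk, labels, permutations=9)["test statistic"])
            )
        )
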