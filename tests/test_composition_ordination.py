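import itertools

import numpy as np
import pandas as pd
import pytest

from betascape.beta_diversity import pairwise_matrix
from betascape.composition_ordination import (
    TREND_SURFACE_LABELS,
    cap_fit,
    cut_clusters,
    gower_pcoa,
    partition_composition,
    permutation_test,
    rank_by_marginal_contribution,
    select_model,
    single_covariate_test,
    trend_surface_terms,
    upgma,
)
from betascape.core_io import DissimilarityMatrix


def dmat(values, ids=None):
    v = np.asarray(values, dtype=float)
    ids = ids or tuple(f"s{i}" for i in range(len(v)))
    return DissimilarityMatrix(tuple(ids), v)


def random_dissimilarity(rng, n):
    # Euclidean-embeddable matrices scaled into [0, 1]
    pts = rng.normal(size=(n, 3))
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    return dmat(d / (d.max() + 1e-9))


def brute_force_upgma(d):
    """O(n^3) agglomerator tracking all pairwise leaf distances directly."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or h < best[0] - 1e-15:
                best = (h, a, b)
        h, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        heights.append(h)
        next_id += 1
    return np.array(heights)


def rda_constrained_pct(Y, X):
    """Direct redundancy analysis via per-column OLS on the raw table."""
    Yc = Y - Y.mean(axis=0)
    Xd = np.column_stack([np.ones(len(Y)), X])
    fitted = np.empty_like(Yc)
    for j in range(Yc.shape[1]):
        beta, *_ = np.linalg.lstsq(Xd, Yc[:, j], rcond=None)
        fitted[:, j] = Xd @ beta
    fitted -= fitted.mean(axis=0)
    return 100.0 * (fitted ** 2).sum() / (Yc ** 2).sum()


class TestUpgma:
    def test_hand_worked_merge_sequence(self):
        d = dmat([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        c = upgma(d)
        assert c.heights() == pytest.approx([0.2, 0.6])
        merged_first = {c.merge_tree[0][0], c.merge_tree[0][1]}
        assert merged_first == {0, 1}

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            d = random_dissimilarity(rng, 8)
            got = upgma(d).heights()
            want = brute_force_upgma(d.values)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_heights_monotone(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            h = upgma(random_dissimilarity(rng, 10)).heights()
            assert (np.diff(h) >= -1e-12).all()

    def test_equal_distances_merge_at_common_height(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 0.0)
        c = upgma(dmat(v))
        assert c.heights() == pytest.approx([0.5, 0.5, 0.5])

    def test_newick_round_trips(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(23)
        d = random_dissimilarity(rng, 7)
        c = upgma(d)
        tree = skbio.TreeNode.read([c.newick])
        assert {t.name for t in tree.tips()} == set(d.site_ids)
        # ultrametric: all root-to-tip depths equal half the final merge
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert np.allclose(list(depths.values()), c.heights()[-1] / 2, atol=1e-9)

    def test_nan_rejected_at_construction(self):
        v = np.array([[0, np.nan], [np.nan, 0]])
        with pytest.raises(ValueError, match="NaN"):
            dmat(v)


class TestCutClusters:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(24)
        d = random_dissimilarity(rng, 6)
        c = upgma(d)
        assert len(set(cut_clusters(c, 1).values())) == 1
        assert len(set(cut_clusters(c, 6).values())) == 6

    def test_requested_group_count(self):
        rng = np.random.default_rng(25)
        c = upgma(random_dissimilarity(rng, 9))
        for k in (2, 3, 5):
            assert len(set(cut_clusters(c, k).values())) == k

    def test_out_of_range_k(self):
        c = upgma(random_dissimilarity(np.random.default_rng(26), 5))
        with pytest.raises(ValueError):
            cut_clusters(c, 0)
        with pytest.raises(ValueError):
            cut_clusters(c, 6)


class TestGowerPcoa:
    def test_points_on_a_line_give_one_axis(self):
        x = np.array([0.0, 1.0, 2.0, 3.5])
        d = np.abs(x[:, None] - x[None, :]) / 10.0
        emb = gower_pcoa(dmat(d))
        assert len(emb.eigenvalues) == 1
        got = np.abs(np.diff(np.sort(emb.axes[:, 0])))
        want = np.abs(np.diff(np.sort(x / 10.0)))
        np.testing.assert_allclose(np.sort(got), np.sort(want), atol=1e-10)

    def test_2d_euclidean_reconstruction(self):
        rng = np.random.default_rng(31)
        pts = rng.normal(size=(8, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        emb = gower_pcoa(dmat(d / d.max()))
        assert len(emb.eigenvalues) == 2
        rec = np.linalg.norm(emb.axes[:, None] - emb.axes[None, :], axis=2)
        np.testing.assert_allclose(rec, d / d.max(), atol=1e-10)

    def test_matches_reference_pcoa(self, default_synthetic):
        skbio = pytest.importorskip("skbio")
        _, _, occ, _ = default_synthetic
        d = pairwise_matrix(occ, "sim")
        emb = gower_pcoa(d)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values, ids=d.site_ids)
        )
        ref_pos = np.sort(ref.eigvals.to_numpy())[::-1]
        ref_pos = ref_pos[ref_pos > 1e-9]
        np.testing.assert_allclose(emb.eigenvalues, ref_pos, rtol=1e-8)

    def test_inertia_bookkeeping(self, default_synthetic):
        _, _, occ, _ = default_synthetic
        emb = gower_pcoa(pairwise_matrix(occ, "sim"))
        assert emb.represented_inertia == pytest.approx(emb.eigenvalues.sum())
        assert 0.0 <= emb.discarded_abs_share < 0.5

    def test_lingoes_removes_negative_eigenvalues(self, default_synthetic):
        _, _, occ, _ = default_synthetic
        d = pairwise_matrix(occ, "sim")
        emb = gower_pcoa(d, neg_eigen_policy="lingoes")
        assert emb.discarded_abs_share <= 1e-9

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            gower_pcoa(dmat([[0, 0.1], [0.1, 0]]))


class TestTrendSurface:
    def test_nine_terms_polynomial_expansion(self):
        out = trend_surface_terms(np.array([1.0]), np.array([2.0]), center=False)
        assert tuple(out.columns) == TREND_SURFACE_LABELS
        assert out.iloc[0].tolist() == [2, 4, 8, 1, 1, 1, 2, 4, 2]

    def test_centering_does_not_change_full_model_fit(self):
        rng = np.random.default_rng(41)
        n = 15
        lat, lon = rng.uniform(36, 70, n), rng.uniform(-10, 60, n)
        d = random_dissimilarity(rng, n)
        pct_c = cap_fit(d, trend_surface_terms(lat, lon, center=True)).constrained_pct
        pct_u = cap_fit(d, trend_surface_terms(lat, lon, center=False)).constrained_pct
        assert pct_c == pytest.approx(pct_u, abs=1e-6)


class TestCapFit:
    def test_self_explanation_is_total(self):
        rng = np.random.default_rng(51)
        d = random_dissimilarity(rng, 10)
        emb = gower_pcoa(d)
        m = cap_fit(emb, emb.axes)
        assert m.constrained_pct == pytest.approx(100.0, abs=1e-8)

    def test_equals_direct_rda_on_euclidean_distances(self):
        rng = np.random.default_rng(52)
        for _ in range(50):
            n, p, q = 12, 5, 2
            Y = rng.normal(size=(n, p))
            X = rng.normal(size=(n, q))
            d = np.linalg.norm(Y[:, None] - Y[None, :], axis=2)
            m = cap_fit(dmat(d / d.max()), X)
            want = rda_constrained_pct(Y, X)
            assert m.constrained_pct == pytest.approx(want, abs=1e-8)

    def test_null_single_predictor_expectation(self):
        rng = np.random.default_rng(53)
        n = 20
        pcts = []
        for _ in range(300):
            d = random_dissimilarity(rng, n)
            z = rng.normal(size=(n, 1))
            pcts.append(cap_fit(d, z).constrained_pct)
        assert np.mean(pcts) == pytest.approx(100.0 / (n - 1), rel=0.15)

    def test_monotone_in_nested_term_sets(self):
        rng = np.random.default_rng(54)
        d = random_dissimilarity(rng, 14)
        X = pd.DataFrame(rng.normal(size=(14, 4)), columns=list("wxyz"))
        pcts = [cap_fit(d, X[list("wxyz"[: k + 1])]).constrained_pct for k in range(4)]
        assert all(b >= a - 1e-9 for a, b in zip(pcts, pcts[1:]))

    def test_df_bookkeeping(self):
        rng = np.random.default_rng(55)
        d = random_dissimilarity(rng, 10)
        m = cap_fit(d, rng.normal(size=(10, 3)))
        assert m.df == (3, 6)


class TestPermutationTest:
    def test_exhaustive_matches_independent_enumeration(self):
        rng = np.random.default_rng(61)
        d = random_dissimilarity(rng, 5)
        X = rng.normal(size=(5, 1))
        res = permutation_test(d, X, exhaustive=True, n_perm=120)
        # independent enumeration: naive pseudo-F over all 120 row orders
        emb = gower_pcoa(d)
        Y = emb.axes
        total = emb.represented_inertia

        def naive_f(Yp):
            Xd = np.column_stack([np.ones(5), X])
            beta, *_ = np.linalg.lstsq(Xd, Yp, rcond=None)
            fitted = Xd @ beta
            fitted -= fitted.mean(axis=0)
            c = (fitted ** 2).sum()
            return (c / 1) / ((total - c) / 3)

        f_obs = naive_f(Y)
        fs = [naive_f(Y[list(p)]) for p in itertools.permutations(range(5))]
        want = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert res["p_model"] == pytest.approx(want, abs=1e-12)

    def test_maximal_association_hits_floor(self):
        rng = np.random.default_rng(62)
        d = random_dissimilarity(rng, 12)
        emb = gower_pcoa(d)
        res = permutation_test(emb, emb.axes[:, :1], n_perm=99, seed=3)
        assert res["p_model"] == pytest.approx(1 / 100)

    def test_null_calibration_light(self):
        rng = np.random.default_rng(63)
        rej = 0
        n_rep = 60
        for _ in range(n_rep):
            d = random_dissimilarity(rng, 15)
            X = rng.normal(size=(15, 1))
            res = permutation_test(d, X, n_perm=99, seed=int(rng.integers(1 << 30)))
            rej += res["p_model"] < 0.05
        assert rej / n_rep <= 0.15

    def test_seed_required(self):
        rng = np.random.default_rng(64)
        d = random_dissimilarity(rng, 6)
        with pytest.raises(ValueError, match="seed"):
            permutation_test(d, rng.normal(size=(6, 1)), n_perm=99)


class TestMarginalRanking:
    def test_duplicated_predictor_contributes_nothing(self):
        rng = np.random.default_rng(71)
        d = random_dissimilarity(rng, 10)
        x = rng.normal(size=10)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=10)})
        ranked = dict(rank_by_marginal_contribution(d, X))
        assert ranked["a"] == pytest.approx(0.0, abs=1e-8)
        assert ranked["b"] == pytest.approx(0.0, abs=1e-8)

    def test_orthogonal_contributions_sum_to_model(self):
        rng = np.random.default_rng(72)
        n = 12
        d = random_dissimilarity(rng, n)
        raw = rng.normal(size=(n, 3))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = pd.DataFrame(Q, columns=list("abc"))
        full = cap_fit(d, X).constrained_pct
        contribs = dict(rank_by_marginal_contribution(d, X))
        assert sum(contribs.values()) == pytest.approx(full, abs=1e-8)

    def test_single_predictor_contribution_is_model(self):
        rng = np.random.default_rng(73)
        d = random_dissimilarity(rng, 9)
        X = pd.DataFrame({"only": rng.normal(size=9)})
        (name, contrib), = rank_by_marginal_contribution(d, X)
        assert contrib == pytest.approx(cap_fit(d, X).constrained_pct, abs=1e-10)


class TestSelectModel:
    def test_no_filtering_returns_full_model(self):
        rng = np.random.default_rng(81)
        d = random_dissimilarity(rng, 12)
        X = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
        m = select_model(d, X, alpha=1.0, max_terms=3, n_perm=99, seed=1)
        assert set(m.retained_terms) == {"a", "b", "c"}

    def test_planted_gradient_is_selected_first(self):
        rng = np.random.default_rng(82)
        n = 20
        grad = np.linspace(0, 1, n)
        pts = np.column_stack([grad, rng.normal(0, 0.02, n)])
        dv = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        d = dmat(dv / dv.max())
        X = pd.DataFrame({"grad": grad, "noise": rng.normal(size=n)})
        m = select_model(d, X, max_terms=1, n_perm=199, seed=2)
        assert m.retained_terms == ("grad",)

    def test_all_noise_mostly_empty(self):
        rng = np.random.default_rng(83)
        sizes = []
        for _ in range(40):
            d = random_dissimilarity(rng, 12)
            X = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("abc"))
            with np.errstate(all="ignore"):
                import warnings as w
                with w.catch_warnings():
                    w.simplefilter("ignore")
                    m = select_model(d, X, n_perm=99, seed=int(rng.integers(1 << 30)))
            sizes.append(len(m.retained_terms))
        assert np.mean([s == 0 for s in sizes]) >= 0.7


class TestPartitionComposition:
    def test_matches_independent_cap_refits(self):
        rng = np.random.default_rng(91)
        n = 14
        d = random_dissimilarity(rng, n)
        X_A = pd.DataFrame({"logA": rng.normal(size=n)})
        X_E = pd.DataFrame(rng.normal(size=(n, 2)), columns=["e1", "e2"])
        X_S = pd.DataFrame(rng.normal(size=(n, 2)), columns=["s1", "s2"])
        part = partition_composition(d, X_A, X_E, X_S)
        emb = gower_pcoa(d)
        want_full = cap_fit(emb, pd.concat([X_A, X_E, X_S], axis=1)).constrained_pct
        assert part.source_r2["A+E+S"] == pytest.approx(want_full, abs=1e-8)
        assert sum(part.fractions.values()) == pytest.approx(100.0, abs=1e-8)
        # spot-check one inclusion-exclusion identity
        uniq_E = part.source_r2["A+E+S"] - part.source_r2["A+S"]
        assert part.fractions["E"] == pytest.approx(uniq_E, abs=1e-8)

    def test_identical_sets_share_everything(self):
        rng = np.random.default_rng(92)
        n = 12
        d = random_dissimilarity(rng, n)
        X = pd.DataFrame({"x": rng.normal(size=n)})
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            part = partition_composition(d, pd.DataFrame(index=range(n)),
                                         X.copy(), X.copy())
        assert part.fractions["E"] == pytest.approx(0.0, abs=1e-8)
        assert part.fractions["S"] == pytest.approx(0.0, abs=1e-8)
        assert part.fractions["E&S"] == pytest.approx(part.source_r2["E"], abs=1e-8)

    def test_orthogonal_sets_share_nothing(self):
        rng = np.random.default_rng(93)
        n = 12
        raw = rng.normal(size=(n, 2))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        d = random_dissimilarity(rng, n)
        part = partition_composition(
            d, pd.DataFrame(index=range(n)), pd.DataFrame({"e": Q[:, 0]}),
            pd.DataFrame({"s": Q[:, 1]}),
        )
        assert abs(part.fractions["E&S"]) <= 0.5


class TestSingleCovariate:
    def test_first_axis_is_maximal(self):
        rng = np.random.default_rng(95)
        d = random_dissimilarity(rng, 12)
        emb = gower_pcoa(d)
        F, p = single_covariate_test(emb, emb.axes[:, 0], n_perm=99, seed=1)
        assert p == pytest.approx(1 / 100)

    def test_constant_covariate_rejected(self):
        d = random_dissimilarity(np.random.default_rng(96), 8)
        with pytest.raises(ValueError, match="constant"):
            single_covariate_test(d, np.ones(8), n_perm=99, seed=1)

    def test_df_bookkeeping(self, default_synthetic):
        _, _, occ, _ = default_synthetic
        d = pairwise_matrix(occ, "sim")
        m = cap_fit(d, occ.richness().astype(float)[:, None])
        assert m.df == (1, occ.n_sites - 2)
        assert np.isfinite(m.pseudo_F)
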