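"""Preprocessing, univariate tests, PCA, PLS-DA/VIP/Q2, GSEA statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from spherolipid import stats as st_mod
from spherolipid.stats import (
    InsufficientData,
    bh_qvalues,
    gsea_es,
    log_transform,
    optimal_components,
    pareto_scale,
    pca,
    plsda_fit,
    plsda_predict,
    preprocess,
    q2_cv,
    quantile_normalize,
    ttest_bh,
    vip,
)


def bh_bruteforce(p):
    """Independent step-up enumeration: q_i = min over all thresholds that
    would admit p_i of (m/k) * p_(k)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, i in enumerate(order):
        candidates = [p[order[k]] * m / (k + 1) for k in range(pos, m)]
        q[i] = min(1.0, min(candidates))
    return q


class TestQuantile:
    def test_identical_samples_unchanged(self):
        m = np.array([[1.0, 5.0, 2.0], [1.0, 5.0, 2.0]])
        assert np.allclose(quantile_normalize(m), m)

    def test_hand_enumerated_two_by_two(self):
        # samples [1,2] and [3,4]: sorted-mean reference is [2,3]
        out = quantile_normalize(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert np.allclose(out, [[2.0, 3.0], [2.0, 3.0]])

    def test_permuted_samples_become_identical_multisets(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(30)
        m = np.vstack([rng.permutation(base) for _ in range(4)])
        out = quantile_normalize(m)
        ref = np.sort(out[0])
        for row in out:
            assert np.allclose(np.sort(row), ref)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.lists(
                st.floats(-50, 50, allow_nan=False, allow_infinity=False),
                min_size=8, max_size=8, unique=True,
            ),
            min_size=3, max_size=5,
        )
    )
    def test_property_all_rows_share_one_distribution(self, rows):
        # tie-free samples: after normalization every row is the same multiset
        out = quantile_normalize(np.array(rows))
        ref = np.sort(out[0])
        for row in out[1:]:
            assert np.allclose(np.sort(row), ref, atol=1e-9)

    def test_constant_sample_maps_to_reference_mean(self):
        m = np.array([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        out = quantile_normalize(m)
        assert np.allclose(out[0], out[0].mean())


class TestPareto:
    def test_unit_sd_feature_is_just_centered(self):
        x = np.array([[0.0], [1.0], [2.0]])  # sd = 1 with ddof=1
        out = pareto_scale(x)
        assert np.allclose(out.ravel(), [-1.0, 0.0, 1.0])

    def test_constant_feature_all_zeros(self):
        x = np.full((4, 1), 3.5)
        assert np.allclose(pareto_scale(x), 0.0)

    def test_scales_by_sqrt_sd(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20, 3)) * 4.0
        out = pareto_scale(x)
        sd = x.std(axis=0, ddof=1)
        assert np.allclose(out, (x - x.mean(axis=0)) / np.sqrt(sd))


class TestTtestBH:
    def test_identical_groups_t0_p1(self):
        m = pd.DataFrame(
            [[1.0], [2.0], [1.0], [2.0]], index=list("abcd"), columns=["f"]
        )
        groups = pd.Series(["A", "A", "B", "B"], index=list("abcd"))
        res = ttest_bh(m, groups)
        assert res.table.loc["f", "t"] == pytest.approx(0.0)
        assert res.table.loc["f", "p"] == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        m = pd.DataFrame([[1.0], [1.0], [1.0], [1.0]], index=list("abcd"), columns=["f"])
        groups = pd.Series(["A", "A", "B", "B"], index=list("abcd"))
        res = ttest_bh(m, groups)
        assert bool(res.table.loc["f", "zero_variance"])
        assert res.table.loc["f", "p"] == pytest.approx(1.0)

    def test_bh_hand_example(self):
        assert np.allclose(bh_qvalues(np.array([0.01, 0.02, 0.03, 0.04])), 0.04)

    def test_bh_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.allclose(bh_qvalues(p), bh_bruteforce(p))

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        assert np.allclose(bh_qvalues(p), multipletests(p, method="fdr_bh")[1])

    def test_q_monotone_in_p_rank_and_q_ge_p(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(size=100)
        q = bh_qvalues(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_null_type_i_error_near_alpha(self):
        rng = np.random.default_rng(5)
        fracs = []
        for _ in range(100):
            m = pd.DataFrame(rng.standard_normal((10, 123)))
            groups = pd.Series(["A"] * 5 + ["B"] * 5, index=m.index)
            res = ttest_bh(m, groups)
            fracs.append((res.table["p"] < 0.05).mean())
        assert 0.03 < np.mean(fracs) < 0.07


class TestPca:
    def test_rank_one_explains_everything(self):
        u = np.outer([1.0, 2.0, 3.0, 4.0], [1.0, -1.0, 0.5])
        scores, loadings, evr = pca(pd.DataFrame(u), n_components=1)
        assert evr[0] == pytest.approx(1.0)

    def test_scores_orthogonal_and_reconstruction(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.standard_normal((8, 5)))
        scores, loadings, _ = pca(m, n_components=5)
        gram = scores.to_numpy().T @ scores.to_numpy()
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)
        centered = m - m.mean(axis=0)
        recon = scores.to_numpy() @ loadings.to_numpy().T
        assert np.allclose(recon, centered, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(7)
        m = pd.DataFrame(rng.standard_normal((6, 4)))
        _, loadings, _ = pca(m, n_components=2)
        for col in loadings.columns:
            v = loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0


class TestPlsda:
    def test_perfectly_separating_feature_r2_one(self):
        X = pd.DataFrame({"f": [0.0, 0.0, 1.0, 1.0]})
        y = pd.Series(["A", "A", "B", "B"])
        model = plsda_fit(X, y, n_components=1)
        assert model.r2y == pytest.approx(1.0)

    def test_matches_sklearn_pls1(self):
        from sklearn.cross_decomposition import PLSRegression

        rng = np.random.default_rng(8)
        X = rng.standard_normal((6, 4))
        y = np.array([0, 0, 0, 1, 1, 1])
        mine = plsda_predict(plsda_fit(X, y, 1), X)
        ref = PLSRegression(n_components=1, scale=False).fit(X, y.astype(float))
        assert np.allclose(mine, ref.predict(X).ravel(), atol=1e-8)

    def test_scores_orthogonal_weights_unit_norm(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((10, 12))
        y = np.array([0] * 5 + [1] * 5)
        model = plsda_fit(X, y, 4)
        T = model.scores
        off = T.T @ T - np.diag(np.diag(T.T @ T))
        assert np.abs(off).max() < 1e-8
        assert np.allclose(np.linalg.norm(model.weights, axis=0), 1.0)

    def test_feature_reordering_invariance(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.standard_normal((8, 6)), columns=list("abcdef"))
        y = pd.Series([0] * 4 + [1] * 4)
        perm = list("fabdec")
        v1 = pd.Series(vip(plsda_fit(X, y, 1)), index=X.columns)
        v2 = pd.Series(vip(plsda_fit(X[perm], y, 1)), index=perm)
        pd.testing.assert_series_equal(v1.sort_index(), v2.sort_index())

    def test_insufficient_data(self):
        with pytest.raises(InsufficientData):
            plsda_fit(np.zeros((3, 2)), np.array([0, 1, 1]), 1)


class TestVip:
    def test_single_feature_vip_is_one(self):
        X = pd.DataFrame({"f": [0.0, 1.0, 2.0, 3.0]})
        y = pd.Series([0, 0, 1, 1])
        assert vip(plsda_fit(X, y, 1))[0] == pytest.approx(1.0)

    def test_mean_square_identity_on_random_fits(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n, p = 8, int(rng.integers(3, 30))
            X = rng.standard_normal((n, p))
            y = np.array([0] * 4 + [1] * 4)
            model = plsda_fit(X, y, int(rng.integers(1, 4)))
            v = vip(model)
            assert np.mean(v**2) == pytest.approx(1.0, abs=1e-10)

    def test_planted_informative_features_rank_highest(self):
        rng = np.random.default_rng(12)
        wins = 0
        n_rep = 40
        for _ in range(n_rep):
            X = rng.standard_normal((10, 50))
            y = np.array([0] * 5 + [1] * 5)
            X[y == 1, :5] += 4.0  # 5 informative of 50
            v = vip(plsda_fit(X, y, 1))
            if v[:5].min() > v[5:].max():
                wins += 1
        assert wins / n_rep >= 0.95


class TestQ2:
    def test_exactly_predictable_y_gives_one(self):
        X = pd.DataFrame({"f": [0.0, 0.0, 0.0, 1.0, 1.0, 1.0]})
        y = pd.Series([0, 0, 0, 1, 1, 1])
        q2, press = q2_cv(X, y, n_components=1)
        assert q2 == pytest.approx(1.0, abs=1e-10)
        assert press.sum() == pytest.approx(0.0, abs=1e-12)

    def test_permuted_labels_mean_q2_nonpositive(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((10, 40))
        q2s = []
        for _ in range(60):
            y = rng.permutation([0] * 5 + [1] * 5)
            q2s.append(q2_cv(X, y, n_components=1)[0])
        assert np.mean(q2s) <= 0.0

    def test_stratified_kfold_keeps_classes(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((10, 8))
        y = np.array([0] * 5 + [1] * 5)
        q2, press = q2_cv(X, y, n_components=1, folds=5, seed=1)
        assert len(press) == 5
        assert np.isfinite(q2)

    def test_optimal_components_reports_best_q2(self):
        rng = np.random.default_rng(15)
        X = rng.standard_normal((10, 20))
        y = np.array([0] * 5 + [1] * 5)
        X[y == 1] += 2.0
        n_comp, q2 = optimal_components(X, y, max_components=3)
        assert 1 <= n_comp <= 3
        assert q2 >= q2_cv(X, y, n_components=1)[0] - 1e-12


class TestGsea:
    def test_single_top_gene_classic_ks_es_is_one(self):
        es = gsea_es(["a", "b", "c", "d"], [4.0, 3.0, 2.0, 1.0], ["a"], weight_exponent=0)
        assert es == pytest.approx(1.0)

    def test_bottom_concentrated_set_negative(self):
        genes = [f"g{i}" for i in range(20)]
        weights = np.linspace(2, -2, 20)
        es = gsea_es(genes, weights, genes[-4:], weight_exponent=1)
        assert es < 0

    def test_reversal_negates_classic_es(self):
        # enumerated: set {g0, g3} in a 10-gene universe has running sum
        # 1/2, 3/8, 1/4, 3/4, 5/8, ... -> unique extremum +0.75
        genes = [f"g{i}" for i in range(10)]
        weights = list(range(10, 0, -1))
        gene_set = ["g0", "g3"]
        forward = gsea_es(genes, weights, gene_set, weight_exponent=0)
        assert forward == pytest.approx(0.75)
        backward = gsea_es(genes[::-1], weights[::-1], gene_set, weight_exponent=0)
        assert backward == pytest.approx(-forward, abs=1e-12)

    def test_degenerate_sets_rejected(self):
        genes = ["a", "b", "c"]
        with pytest.raises(ValueError):
            gsea_es(genes, [3, 2, 1], [])
        with pytest.raises(ValueError):
            gsea_es(genes, [3, 2, 1], genes)


def test_preprocess_records_provenance(paper_table):
    table, _ = paper_table
    from spherolipid.quantify import is_normalize, species_composition

    amounts = is_normalize(table)
    designed = preprocess(species_composition(amounts).T, table.samples["group"])
    assert designed.transforms == ("quantile", "log", "pareto")
    assert not np.isnan(designed.matrix.to_numpy()).any()
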