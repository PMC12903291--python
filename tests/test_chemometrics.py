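"""Filtering, imputation, PCA, OPLS-DA, VIP, permutation and SDM selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from plasmaflux import (
    IntensityMatrix,
    OPLSDA,
    class_summary,
    compute_vip,
    filter_missing,
    fit_oplsda,
    impute_missing,
    pca,
    permutation_test,
    select_sdms,
)
from plasmaflux.chemometrics import OPLSDAResults
from plasmaflux.simulate import SyntheticMetabolomeConfig, generate_intensity_matrix


class TestFilterMissing:
    def test_complete_matrix_unchanged(self, toy_builder):
        m = toy_builder([[1, 2, 3], [4, 5, 6], [7, 8, 9], [10, 11, 12]], "llhh")
        out = filter_missing(m.subset(m.metabolite_ids), 0.5)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_hand_fixture_removes_only_fully_missing_metabolite(self, toy_builder):
        nan = np.nan
        m = toy_builder(
            [[1, 2, nan], [4, 5, nan], [7, 8, nan], [10, 11, nan]], "llhh"
        )
        out = filter_missing(m, 0.5)
        assert out.metabolite_ids == ["M0", "M1"]
        assert out.sample_ids == m.sample_ids  # samples never removed

    def test_exactly_half_missing_retained(self, toy_builder):
        nan = np.nan
        # M0 missing in exactly 50% of each group: strict > keeps it
        m = toy_builder([[nan, 2], [4, 5], [nan, 8], [10, 11]], "llhh")
        out = filter_missing(m, 0.5)
        assert out.metabolite_ids == ["M0", "M1"]

    def test_one_group_fully_observed_keeps_metabolite(self, toy_builder):
        nan = np.nan
        # M0 fully missing in high group but complete in low: kept under
        # "all", dropped under "any"
        m = toy_builder([[1, 2], [4, 5], [nan, 8], [nan, 11]], "llhh")
        assert filter_missing(m, 0.5, mode="all").metabolite_ids == ["M0", "M1"]
        assert filter_missing(m, 0.5, mode="any").metabolite_ids == ["M1"]

    def test_bad_threshold_rejected(self, toy_builder):
        m = toy_builder([[1, 2], [4, 5], [7, 8], [10, 11]], "llhh")
        with pytest.raises(ValueError):
            filter_missing(m, 1.0)

    def test_output_metabolites_subset_of_input(self):
        cfg = SyntheticMetabolomeConfig(n_metabolites=80, missing_rate=0.4, seed=13)
        m, _ = generate_intensity_matrix(cfg)
        out = filter_missing(m)
        assert set(out.metabolite_ids) <= set(m.metabolite_ids)
        assert out.sample_ids == m.sample_ids


class TestImpute:
    def test_complete_unchanged(self, toy_builder):
        m = toy_builder([[1, 2], [4, 5], [7, 8], [10, 11]], "llhh")
        pd.testing.assert_frame_equal(impute_missing(m).values, m.values)

    def test_half_min_definition(self, toy_builder):
        m = toy_builder([[4.0, 1], [8.0, 2], [np.nan, 3], [6.0, 4]], "llhh")
        out = impute_missing(m, "half_min")
        assert out.values.iloc[2, 0] == 2.0  # half of observed min(4, 8, 6)

    def test_zero_method(self, toy_builder):
        m = toy_builder([[4.0, 1], [8.0, 2], [np.nan, 3], [6.0, 4]], "llhh")
        assert impute_missing(m, "zero").values.iloc[2, 0] == 0.0

    def test_all_missing_metabolite_directs_to_filter(self, toy_builder):
        nan = np.nan
        m = toy_builder([[nan, 1], [nan, 2], [nan, 3], [nan, 4]], "llhh")
        with pytest.raises(ValueError, match="filter_missing"):
            impute_missing(m)


class TestPca:
    def test_rank_one_matrix(self, toy_builder):
        base = np.outer([1.0, 2.0, 3.0, 4.0], [1.0, 0.5, 2.0])
        m = toy_builder(base, "llhh")
        res = pca(m, 1, scaling="none")
        assert res.explained_variance_fraction[0] == pytest.approx(1.0)

    def test_matches_eigen_decomposition_oracle(self):
        """Scores/loadings agree with an eigendecomposition of the
        covariance matrix of the scaled data, to 1e-8 (up to fixed sign)."""
        rng = np.random.default_rng(0)
        X = rng.lognormal(3, 1, size=(10, 6))
        m = IntensityMatrix(
            pd.DataFrame(X, index=[f"s{i}" for i in range(10)],
                         columns=[f"M{j}" for j in range(6)]),
            pd.Series(["low"] * 5 + ["high"] * 5, index=[f"s{i}" for i in range(10)]),
            pd.Series("other", index=[f"M{j}" for j in range(6)]),
            ("low", "high"),
        )
        res = pca(m, 4, scaling="uv")

        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        evals, evecs = np.linalg.eigh(np.cov(Xs, rowvar=False))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for a in range(4):
            v = evecs[:, a]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(res.loadings.iloc[:, a], v, atol=1e-8)
            np.testing.assert_allclose(res.scores.iloc[:, a], Xs @ v, atol=1e-8)
            assert res.explained_variance_fraction[a] == pytest.approx(
                evals[a] / evals.sum(), abs=1e-10
            )

    def test_explained_fractions_non_increasing_and_bounded(self, separable_matrix):
        m, _ = separable_matrix
        res = pca(impute_missing(m), 5)
        evr = res.explained_variance_fraction
        assert (np.diff(evr) <= 1e-12).all()
        assert evr.sum() <= 1 + 1e-9

    def test_sample_duplication_invariance(self, toy_builder):
        X = np.random.default_rng(1).lognormal(2, 0.5, (4, 5))
        m = toy_builder(X, "llhh")
        m2 = toy_builder(np.vstack([X, X]), "llhhllhh")
        e1 = pca(m, 2).explained_variance_fraction
        e2 = pca(m2, 2).explained_variance_fraction
        np.testing.assert_allclose(e1, e2, atol=1e-10)

    def test_loadings_orthonormal(self, separable_matrix):
        m, _ = separable_matrix
        L = pca(m, 3).loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(3), atol=1e-10)

    def test_too_many_components_rejected(self, toy_builder):
        m = toy_builder(np.random.default_rng(0).random((4, 5)) + 1, "llhh")
        with pytest.raises(ValueError):
            pca(m, 4)


class TestOplsda:
    def test_separable_data_strong_model(self, separable_matrix):
        m, _ = separable_matrix
        res = fit_oplsda(m, cv_seed=0)
        assert res.r2y >= 0.99
        assert res.q2 >= 0.9

    def test_orthogonal_scores_uncorrelated_with_y(self, separable_matrix):
        m, _ = separable_matrix
        res = fit_oplsda(m, n_orth=2)
        y = m.y() - m.y().mean()
        for col in res.t_orth:
            t_o = res.t_orth[col].to_numpy()
            assert abs(np.dot(t_o, y)) / (np.linalg.norm(t_o) * np.linalg.norm(y)) <= 1e-8

    def test_zero_orth_equals_single_component_plsda(self, separable_matrix):
        """With n_orth=0 the predictive scores match a one-component PLS
        regression (sklearn oracle) up to scale and sign."""
        from sklearn.cross_decomposition import PLSRegression

        m, _ = separable_matrix
        res = fit_oplsda(m, n_orth=0)
        X = m.values.to_numpy()
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        pls = PLSRegression(n_components=1, scale=False).fit(Xs, m.y())
        t_ref = pls.x_scores_[:, 0]
        t_ours = res.t_p.to_numpy()
        cos = abs(t_ours @ t_ref) / (np.linalg.norm(t_ours) * np.linalg.norm(t_ref))
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_duplicate_metabolite_column_stability(self, separable_matrix):
        m, _ = separable_matrix
        ref = fit_oplsda(m).t_p
        values = m.values.copy()
        values["dup"] = values[m.metabolite_ids[0]]
        classes = pd.concat([m.classes, pd.Series({"dup": "other"})])
        m2 = IntensityMatrix(values, m.groups, classes, m.group_order)
        t2 = fit_oplsda(m2).t_p
        # same direction, nearly identical normalized scores (tolerance
        # frozen after calibration: the extra column shifts uv weight
        # normalization by ~3e-5 in cosine)
        a = ref.to_numpy() / np.linalg.norm(ref)
        b = t2.to_numpy() / np.linalg.norm(t2)
        assert np.abs(np.abs(a @ b) - 1) < 1e-4

    def test_q2_not_above_r2y_on_training_data(self, separable_matrix, null_matrix):
        m, _ = separable_matrix
        for mat in (m, null_matrix):
            res = fit_oplsda(mat)
            assert res.q2 <= res.r2y + 1e-9

    def test_null_data_low_q2(self):
        """Shuffled/no-effect data: mean Q2 across replicates stays low."""
        q2s = []
        for seed in range(10):
            cfg = SyntheticMetabolomeConfig(
                n_per_group=6, n_metabolites=50, frac_differential=0.0,
                missing_rate=0.0, seed=300 + seed,
            )
            m, _ = generate_intensity_matrix(cfg)
            q2s.append(fit_oplsda(m).q2)
        assert np.mean(q2s) <= 0.2

    def test_more_than_two_groups_rejected(self, toy_builder):
        with pytest.raises(ValueError, match="two groups"):
            toy_builder(np.ones((6, 3)), "llhhxx")

    def test_incomplete_matrix_rejected(self, toy_builder):
        m = toy_builder([[1, np.nan], [2, 3], [4, 5], [6, 7]], "llhh")
        with pytest.raises(ValueError, match="complete"):
            OPLSDA(m)

    def test_summary_reports_fit_statistics(self, separable_matrix):
        m, _ = separable_matrix
        text = fit_oplsda(m).summary()
        assert "R2Y" in text and "Q2" in text


class TestVip:
    def _results_with_weights(self, w):
        w = pd.Series(np.asarray(w, float), index=[f"M{i}" for i in range(len(w))])
        return OPLSDAResults(
            t_p=pd.Series(dtype=float), weights=w, loadings_p=w * 0, q=1.0,
            t_orth=pd.DataFrame(), w_orth=pd.DataFrame(), p_orth=pd.DataFrame(),
            r2x=0.5, r2y=0.9, q2=0.8, n_orth=1, scaling="uv", cv_folds=7,
            cv_seed=0, group_order=("low", "high"),
        )

    def test_single_loaded_variable_toy(self):
        vip = compute_vip(self._results_with_weights([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(vip.to_numpy(), [np.sqrt(3), 0.0, 0.0], atol=1e-12)

    def test_equal_weights_give_unit_vip(self):
        vip = compute_vip(self._results_with_weights([0.3] * 5))
        np.testing.assert_allclose(vip.to_numpy(), np.ones(5), atol=1e-12)

    def test_mean_squared_vip_identity(self, separable_matrix, null_matrix):
        m, _ = separable_matrix
        for mat in (m, null_matrix):
            vip = fit_oplsda(mat).vip()
            assert (vip**2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_metabolite_reordering_invariance(self, separable_matrix):
        m, _ = separable_matrix
        vip = fit_oplsda(m).vip()
        perm = list(np.random.default_rng(2).permutation(m.metabolite_ids))
        vip_perm = fit_oplsda(m.subset(perm)).vip()
        np.testing.assert_allclose(
            vip.reindex(perm).to_numpy(), vip_perm.to_numpy(), atol=1e-8
        )

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            compute_vip(self._results_with_weights([0.0, 0.0]))


class TestPermutation:
    def test_seeded_determinism(self, separable_matrix):
        m, _ = separable_matrix
        p1 = permutation_test(m, n_permutations=25, seed=5)
        p2 = permutation_test(m, n_permutations=25, seed=5)
        np.testing.assert_array_equal(p1.permuted_q2, p2.permuted_q2)
        np.testing.assert_array_equal(p1.permuted_r2y, p2.permuted_r2y)

    def test_separable_data_small_empirical_p(self, separable_matrix):
        m, _ = separable_matrix
        res = permutation_test(m, n_permutations=200, seed=1)
        assert res.p_q2 <= 0.01
        assert res.p_r2y <= 0.05

    def test_low_count_warns(self, separable_matrix):
        m, _ = separable_matrix
        with pytest.warns(UserWarning, match="resolution"):
            permutation_test(m, n_permutations=10, seed=0)

    def test_add_one_correction_bounds(self, separable_matrix):
        m, _ = separable_matrix
        res = permutation_test(m, n_permutations=30, seed=2)
        assert 0 < res.p_q2 <= 1
        assert res.p_q2 >= 1 / 31


class TestSelectSdms:
    def test_strict_thresholds(self, toy_builder):
        rng = np.random.default_rng(0)
        m = toy_builder(rng.lognormal(3, 0.2, (8, 3)), "llllhhhh")
        # force a clear group difference in M0 only
        m.values["M0"] *= np.where(m.groups == "high", 4.0, 1.0)
        vip = pd.Series([1.5, 1.0, 0.2], index=m.metabolite_ids)
        table = select_sdms(m, vip)
        assert bool(table.loc["M0", "selected"])
        # VIP exactly 1 is excluded even at tiny p
        assert table.loc["M1", "vip"] == 1.0
        assert not bool(table.loc["M1", "selected"])

    def test_up_down_partition(self, separable_matrix):
        m, _ = separable_matrix
        vip = fit_oplsda(m).vip()
        table = select_sdms(m, vip)
        sel = table[table.selected]
        assert len(sel) == (sel.direction == "up").sum() + (sel.direction == "down").sum()
        assert len(sel) > 0

    def test_sorted_by_vip_descending(self, separable_matrix):
        m, _ = separable_matrix
        table = select_sdms(m, fit_oplsda(m).vip())
        assert (np.diff(table["vip"].to_numpy()) <= 1e-12).all()

    def test_misaligned_vip_rejected(self, separable_matrix):
        m, _ = separable_matrix
        vip = pd.Series(1.0, index=[f"X{i}" for i in range(m.n_metabolites)])
        with pytest.raises(ValueError, match="aligned"):
            select_sdms(m, vip)

    def test_recovery_benchmark(self):
        """20% planted differentials at a large effect on complete data:
        sensitivity >= 0.8 and false-discovery proportion <= 0.2
        (averaged over seeds; thresholds frozen after calibration)."""
        sens, fdp = [], []
        for seed in range(5):
            cfg = SyntheticMetabolomeConfig(
                n_per_group=6, n_metabolites=100, frac_differential=0.2,
                effect_log2=2.0, missing_rate=0.0, seed=seed,
            )
            m, truth = generate_intensity_matrix(cfg)
            table = select_sdms(m, fit_oplsda(m).vip())
            sel = set(table.index[table.selected])
            tp = sel & truth.differential_ids
            sens.append(len(tp) / len(truth.differential_ids))
            fdp.append(1 - len(tp) / max(len(sel), 1))
        assert np.mean(sens) >= 0.8
        assert np.mean(fdp) <= 0.2


class TestClassSummary:
    def test_zscores_and_counts(self, toy_builder):
        rng = np.random.default_rng(1)
        m = toy_builder(
            rng.lognormal(3, 0.3, (6, 4)), "lllhhh",
            classes=["sugars", "sugars", "FFA", "PC"],
        )
        table = pd.DataFrame(
            {
                "vip": [1.5, 1.2, 1.1, 0.5],
                "p_value": [0.01, 0.02, 0.03, 0.5],
                "log2_fc": [1.0, -0.5, 2.0, 0.1],
                "direction": ["up", "down", "up", "up"],
                "selected": [True, True, True, False],
            },
            index=m.metabolite_ids,
        )
        counts, z = class_summary(table, m)
        assert counts.loc["sugars", "up"] == 1
        assert counts.loc["sugars", "down"] == 1
        assert counts.loc["FFA", "up"] == 1
        assert counts["total"].sum() == 3
        assert z.shape == (6, 3)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-10)

    def test_empty_selection_returns_empty_not_raises(self, toy_builder):
        m = toy_builder(np.random.default_rng(0).lognormal(3, 0.3, (4, 2)), "llhh")
        table = pd.DataFrame(
            {"vip": [0.5, 0.4], "p_value": [0.9, 0.8], "log2_fc": [0, 0],
             "direction": ["up", "up"], "selected": [False, False]},
            index=m.metabolite_ids,
        )
        counts, z = class_summary(table, m)
        assert counts.empty
        assert z.shape[1] == 0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_vip_mean_square_identity_property(seed):
    """mean(VIP^2) = 1 for any fitted model (algebraic invariant)."""
    cfg = SyntheticMetabolomeConfig(
        n_per_group=4, n_metabolites=15, frac_differential=0.3,
        missing_rate=0.0, seed=seed,
    )
    m, _ = generate_intensity_matrix(cfg)
    vip = fit_oplsda(m, cv_folds=4).vip()
    assert abs(float((vip**2).mean()) - 1.0) < 1e-10
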