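"""Univariate volcano, BH-FDR, PCA, PLS-DA/VIP, LOO-CV and anchor correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icmet.preprocess import FeatureTable, normalize, pareto_scale
from icmet.simulate import SimulationConfig, simulate_feature_table, simulate_library
from icmet.stats import (
    bh_adjust,
    correlate_to_anchor,
    euclidean_distance_matrix,
    loocv_validate,
    pca_fit,
    plsda_fit,
    univariate_table,
    volcano_select,
)


def _two_group_table(mat_a, mat_b, qc=None):
    n_feat = mat_a.shape[0]
    cols_a = [f"a{i}" for i in range(mat_a.shape[1])]
    cols_b = [f"b{i}" for i in range(mat_b.shape[1])]
    data = np.hstack([mat_a, mat_b])
    cols = cols_a + cols_b
    roles = ["sample"] * len(cols)
    groups = ["A"] * len(cols_a) + ["B"] * len(cols_b)
    if qc is not None:
        data = np.hstack([data, qc])
        cols = cols + [f"QC_{i}" for i in range(qc.shape[1])]
        roles += ["QC"] * qc.shape[1]
        groups += ["QC"] * qc.shape[1]
    intens = pd.DataFrame(
        data, index=[f"{i}.00_{100 + i}.0000" for i in range(n_feat)], columns=cols
    )
    meta = pd.DataFrame(
        {"group": groups, "batch": "1", "role": roles}, index=cols
    )
    return FeatureTable(intens, meta)


class TestBhAdjust:
    def test_hand_evaluated_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3] * 7), [0.3] * 7)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 200))
            ours = bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.max(np.abs(ours - ref)) < 1e-12

    def test_rejection_set_equals_classic_stepup(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.uniform(0, 1, size=100)
            q = bh_adjust(p)
            n = len(p)
            for alpha in (0.01, 0.05, 0.1, 0.25, 0.5):
                order = np.argsort(p)
                below = np.nonzero(p[order] <= alpha * np.arange(1, n + 1) / n)[0]
                classic = set(order[: below.max() + 1]) if len(below) else set()
                assert set(np.nonzero(q < alpha)[0]) <= set(np.nonzero(q <= alpha)[0])
                assert set(np.nonzero(q <= alpha)[0]) == classic

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=50)
    )
    def test_output_bounds_and_dominance(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p)) and np.all(q <= 1.0)


class TestUnivariate:
    def test_null_case_fold_changes_near_one(self):
        rng = np.random.default_rng(2)
        mat = rng.lognormal(10, 0.2, size=(50, 18))
        table = _two_group_table(mat[:, :9], mat[:, 9:])
        res = univariate_table(table, "A", "B")
        assert np.nanmedian(res["fold_change"]) == pytest.approx(1.0, abs=0.15)
        assert (res["direction"] == "unchanged").all()

    def test_constructed_fourfold_change(self):
        rng = np.random.default_rng(3)
        base = np.full((1, 9), 100.0) + rng.normal(0, 1e-6, (1, 9))
        table = _two_group_table(4 * base, base)
        res = univariate_table(table, "A", "B")
        assert res["fold_change"].iloc[0] == pytest.approx(4.0, rel=1e-6)

    def test_injected_effects_all_detected_with_few_false_positives(self):
        lib = simulate_library(50, seed=21)
        table, truth = simulate_feature_table(lib, SimulationConfig(seed=21))
        res = univariate_table(normalize(table, "sum"), "mutant", "wildtype")
        enriched, depleted = volcano_select(res)
        effects = set(truth.effect_features)
        assert effects <= set(enriched)
        assert len((set(enriched) | set(depleted)) - effects) <= 2

    def test_zero_group_mean_flags_undefined_fc(self):
        mat_a = np.vstack([[0.0] * 3, [5.0] * 3])
        mat_b = np.vstack([[0.0] * 3, [5.0] * 3])
        table = _two_group_table(mat_a, mat_b)
        res = univariate_table(table, "A", "B")
        assert np.isnan(res["fold_change"].iloc[0])

    @pytest.mark.parametrize("test", ["welch", "student", "mannwhitney"])
    def test_alternative_tests_supported(self, test):
        rng = np.random.default_rng(4)
        mat = rng.lognormal(10, 0.2, size=(10, 12))
        table = _two_group_table(mat[:, :6], mat[:, 6:])
        res = univariate_table(table, "A", "B", test=test)
        assert res["p"].between(0, 1).all()


class TestVolcanoSelect:
    def test_all_q_one_selects_nothing(self):
        res = pd.DataFrame({"fold_change": [4.0, 0.1], "q": [1.0, 1.0]})
        assert volcano_select(res) == ([], [])

    def test_rule_application_on_fixture(self):
        res = pd.DataFrame(
            {"fold_change": [4.0, 0.2, 3.0], "q": [0.01, 0.001, 0.2]},
            index=["up", "down", "ns"],
        )
        enriched, depleted = volcano_select(res)
        assert enriched == ["up"] and depleted == ["down"]

    def test_strong_anchor_feature_lands_in_enriched(self):
        # a 2-HG-like feature: huge FC, tiny q
        rng = np.random.default_rng(5)
        mat = rng.lognormal(10, 0.2, size=(30, 18))
        mat[0, :9] *= 50.0
        table = _two_group_table(mat[:, :9], mat[:, 9:])
        res = univariate_table(table, "A", "B")
        enriched, _ = volcano_select(res)
        assert table.features[0] in enriched


class TestPca:
    def test_diagonal_two_feature_data(self):
        rng = np.random.default_rng(6)
        t = rng.normal(0, 3, 40)
        x = pd.DataFrame({"f1": t, "f2": t + rng.normal(0, 1e-6, 40)})
        res = pca_fit(x, 2)
        load = np.abs(res.loadings["PC1"].to_numpy())
        np.testing.assert_allclose(load, [1 / np.sqrt(2)] * 2, rtol=1e-3)
        assert res.explained_variance_ratio[0] > 0.999

    def test_variance_fractions_and_score_definition(self):
        rng = np.random.default_rng(7)
        x = pd.DataFrame(rng.normal(size=(15, 6)))
        res = pca_fit(x, 4)
        assert res.explained_variance_ratio.sum() <= 1 + 1e-9
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
        centered = x.to_numpy() - x.to_numpy().mean(axis=0)
        np.testing.assert_allclose(
            res.scores.to_numpy(), centered @ res.loadings.to_numpy(), atol=1e-9
        )


def _nipals_pls(x, y, n_components):
    """Tiny independent NIPALS PLS2 for cross-checking the fitted model."""
    x = x - x.mean(axis=0)
    y = y - y.mean(axis=0)
    weights, scores, y_loads = [], [], []
    for _ in range(n_components):
        u = y[:, [np.argmax(y.var(axis=0))]]
        for _ in range(500):
            w = x.T @ u
            w /= np.linalg.norm(w)
            t = x @ w
            q = y.T @ t / (t.T @ t)
            u_new = y @ q / (q.T @ q)
            if np.linalg.norm(u_new - u) < 1e-12 * np.linalg.norm(u_new):
                u = u_new
                break
            u = u_new
        p = x.T @ t / (t.T @ t)
        x = x - t @ p.T
        y = y - t @ q.T
        weights.append(w)
        scores.append(t)
        y_loads.append(q)
    return (
        np.hstack(weights),
        np.hstack(scores),
        np.hstack(y_loads),
    )


class TestPlsda:
    def test_single_informative_feature_has_max_vip(self):
        rng = np.random.default_rng(8)
        x = pd.DataFrame(rng.normal(size=(20, 51)))
        groups = ["A"] * 10 + ["B"] * 10
        x.iloc[:10, 0] += 4.0
        model = plsda_fit(x, groups, 2)
        assert model.vip.idxmax() == x.columns[0]

    def test_vip_identity_sum_of_squares(self):
        rng = np.random.default_rng(9)
        x = pd.DataFrame(rng.normal(size=(18, 120)))
        groups = ["A"] * 9 + ["B"] * 9
        model = plsda_fit(x, groups, 2)
        assert float((model.vip**2).sum()) == pytest.approx(120, abs=1e-8)

    def test_one_feature_model_vip_is_one(self):
        rng = np.random.default_rng(10)
        x = pd.DataFrame({"only": np.r_[rng.normal(0, 1, 6), rng.normal(3, 1, 6)]})
        groups = ["A"] * 6 + ["B"] * 6
        model = plsda_fit(x, groups, 1)
        assert model.vip.iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_noise_feature_vip_concentrates_near_one(self):
        vips = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = pd.DataFrame(rng.normal(size=(18, 80)))
            model = plsda_fit(x, ["A"] * 9 + ["B"] * 9, 2)
            vips.append(model.vip.mean())
        assert 0.8 <= np.mean(vips) <= 1.2

    def test_scores_and_weights_match_independent_nipals(self):
        rng = np.random.default_rng(11)
        x = pd.DataFrame(rng.normal(size=(14, 9)))
        groups = ["A"] * 7 + ["B"] * 7
        y = np.array([[1.0, 0.0] if g == "A" else [0.0, 1.0] for g in groups])
        model = plsda_fit(x, groups, 2)
        w_ref, t_ref, _ = _nipals_pls(x.to_numpy(), y, 2)
        for a in range(2):
            # component sign is arbitrary
            sign = np.sign(w_ref[:, a] @ model.weights.iloc[:, a])
            np.testing.assert_allclose(
                model.weights.iloc[:, a], sign * w_ref[:, a], atol=1e-6
            )
            np.testing.assert_allclose(
                model.scores.iloc[:, a], sign * t_ref[:, a], atol=1e-6
            )


class TestLoocv:
    def test_separated_groups_classified_perfectly(self):
        rng = np.random.default_rng(12)
        x = pd.DataFrame(rng.normal(size=(18, 40)))
        x.iloc[:9, :10] += 5.0
        report = loocv_validate(x, ["A"] * 9 + ["B"] * 9, 2)
        assert report.accuracy == 1.0
        assert report.q2 <= report.r2
        assert 0 <= report.r2 <= 1

    def test_permuted_labels_have_no_predictive_power(self):
        rng = np.random.default_rng(13)
        x = pd.DataFrame(rng.normal(size=(16, 30)))
        x.iloc[:8, :8] += 3.0
        q2s, accs = [], []
        for _ in range(20):
            labels = list(rng.permutation(["A"] * 8 + ["B"] * 8))
            try:
                report = loocv_validate(x, labels, 2)
            except ValueError:
                continue
            q2s.append(report.q2)
            accs.append(report.accuracy)
        assert np.median(q2s) <= 0.1
        assert np.mean(accs) < 0.75  # near chance

    def test_minimal_viable_design_runs(self):
        # smallest design where every LOO fold keeps both classes
        x = pd.DataFrame(
            [[0.0, 1.0], [0.1, 0.9], [5.0, -4.0], [5.1, -3.9]], columns=["f1", "f2"]
        )
        report = loocv_validate(x, ["A", "A", "B", "B"], 1)
        for value in (report.r2, report.q2, report.accuracy):
            assert np.isfinite(value)
        assert 0 <= report.accuracy <= 1

    def test_fold_losing_a_class_is_an_error(self):
        # a lone-member class disappears from the fold that holds it out
        x = pd.DataFrame(np.random.default_rng(14).normal(size=(6, 3)))
        with pytest.raises(ValueError):
            loocv_validate(x, ["A", "A", "A", "A", "A", "B"], 1)


class TestCorrelation:
    def test_anchor_self_correlation_is_one(self, sim_dataset):
        table, _ = sim_dataset
        anchor = table.features[0]
        res = correlate_to_anchor(table, anchor)
        assert res.r[anchor] == pytest.approx(1.0)

    def test_exact_negative_linear_feature(self):
        rng = np.random.default_rng(15)
        anchor_vals = rng.lognormal(10, 0.5, 12)
        mat = np.vstack([anchor_vals, -anchor_vals + 2 * anchor_vals.max()])
        table = _two_group_table(mat[:, :6], mat[:, 6:])
        res = correlate_to_anchor(table, table.features[0])
        assert res.r.iloc[1] == pytest.approx(-1.0)
        assert table.features[1] in res.negative

    def test_hand_computed_small_vectors(self):
        mat = np.vstack([[1.0, 2.0, 3.0, 1.0], [1.0, 2.0, 4.0, 1.0]])
        intens = pd.DataFrame(
            mat, index=["1.00_101.0000", "2.00_102.0000"], columns=list("abcd")
        )
        meta = pd.DataFrame(
            {"group": ["A", "A", "B", "B"], "batch": "1", "role": "sample"},
            index=intens.columns,
        )
        res = correlate_to_anchor(FeatureTable(intens, meta), "1.00_101.0000")
        # r for (1,2,3,1) vs (1,2,4,1): hand computation
        a = np.array([1, 2, 3, 1.0])
        b = np.array([1, 2, 4, 1.0])
        expected = ((a - a.mean()) @ (b - b.mean())) / np.sqrt(
            ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
        )
        assert res.r.iloc[1] == pytest.approx(expected, rel=1e-12)

    def test_constant_anchor_rejected(self):
        mat = np.vstack([[1.0] * 6, [1.0, 2, 3, 4, 5, 6]])
        table = _two_group_table(mat[:, :3], mat[:, 3:])
        with pytest.raises(ValueError):
            correlate_to_anchor(table, table.features[0])


class TestTypeIControl:
    def test_null_simulations_rarely_reject(self):
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            mat = rng.lognormal(10, 0.3, size=(500, 18))
            table = _two_group_table(mat[:, :9], mat[:, 9:])
            res = univariate_table(table, "A", "B")
            counts.append(int((res["q"] < 0.05).sum()))
        assert np.mean(counts) <= 1.0


class TestDistanceMatrix:
    def test_metric_properties(self):
        rng = np.random.default_rng(16)
        x = pd.DataFrame(rng.normal(size=(8, 5)))
        d = euclidean_distance_matrix(x)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        manual = np.linalg.norm(x.iloc[0] - x.iloc[1])
        assert d.iloc[0, 1] == pytest.approx(manual)
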