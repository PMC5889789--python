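"""Node-degree reduction and PLS modeling of group membership."""

import numpy as np
import pandas as pd
import pytest

from efsubtype import (
    ConnectomeSpec,
    bootstrap_loadings,
    compare_group_scores,
    crossval_rmse,
    evaluate_split,
    fit_pls,
    generate_connectomes,
    node_degree,
    retain_components,
    top_loading_report,
)
from efsubtype.pls import ConnectomeSet, PlsError


def toy_connectomes():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 0.5
    w[1, 2] = w[2, 1] = 0.2
    return ConnectomeSet(
        participant_ids=["p0"],
        node_labels=["a", "b", "c"],
        matrices=w[None],
        groups=np.array(["g0"]),
    )


def separable_problem(rng, n=60, p=10):
    """Degree-like features where one column determines the group."""
    x = rng.normal(size=(n, p))
    groups = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    x[:, 0] = np.where(groups == "a", 5.0, -5.0) + 0.01 * rng.normal(size=n)
    return x, groups


class TestNodeDegree:
    def test_path_graph_degrees(self):
        deg = node_degree(toy_connectomes())
        assert deg.loc["p0"].tolist() == [1, 2, 1]

    def test_threshold_above_max_zeroes_degrees(self):
        deg = node_degree(toy_connectomes(), threshold=0.9)
        assert (deg.to_numpy() == 0).all()

    def test_complete_graph(self):
        w = 0.4 * (np.ones((5, 5)) - np.eye(5))
        conn = ConnectomeSet(["p"], list("abcde"), w[None], np.array(["g"]))
        assert (node_degree(conn).to_numpy() == 4).all()

    def test_weighted_strength_option(self):
        deg = node_degree(toy_connectomes(), weighted=True)
        assert deg.loc["p0"].tolist() == pytest.approx([0.5, 0.7, 0.2])

    def test_asymmetric_matrix_names_participant(self):
        conn = toy_connectomes()
        conn.matrices[0, 0, 1] = 0.9
        with pytest.raises(PlsError, match="p0"):
            node_degree(conn)


class TestFitPls:
    def test_rank_one_problem_explains_everything(self, rng):
        groups = np.array(["a", "b"] * 30)
        x = np.where(groups == "a", 5.0, -5.0)[:, None]
        model = fit_pls(x, groups, max_components=1)
        assert model.y_explained[0] == pytest.approx(100.0, abs=1e-6)

    def test_independent_features_explain_almost_nothing(self, rng):
        x = rng.normal(size=(500, 20))
        groups = rng.choice(["a", "b"], size=500)
        model = fit_pls(x, groups, max_components=1)
        assert model.y_explained[0] < 5.0

    def test_scores_mutually_orthogonal(self, rng):
        x = rng.normal(size=(40, 15))
        groups = np.repeat(["a", "b", "c"], [14, 13, 13])
        model = fit_pls(x, groups, max_components=3)
        t = model.scores
        for a in range(3):
            for b in range(a + 1, 3):
                assert abs(t[:, a] @ t[:, b]) < 1e-8

    def test_explained_variance_bounded(self, rng):
        x = rng.normal(size=(50, 8))
        groups = np.repeat(["a", "b", "c"], [17, 17, 16])
        model = fit_pls(x, groups, max_components=5)
        assert np.all(model.y_explained >= 0)
        assert model.y_explained.sum() <= 100 + 1e-6

    def test_feature_permutation_equivariance(self, rng):
        x = rng.normal(size=(30, 6))
        groups = np.repeat(["a", "b"], 15)
        perm = rng.permutation(6)
        base = fit_pls(x, groups, max_components=2)
        permuted = fit_pls(x[:, perm], groups, max_components=2)
        # loadings follow the column permutation up to component sign
        for c in range(2):
            direct = base.x_loadings[perm, c]
            got = permuted.x_loadings[:, c]
            sign = np.sign(direct @ got)
            assert np.allclose(got * sign, direct, atol=1e-8)

    def test_constant_column_dropped_with_warning(self, rng):
        x = rng.normal(size=(30, 5))
        x[:, 2] = 7.0
        groups = np.repeat(["a", "b"], 15)
        with pytest.warns(UserWarning, match="constant"):
            model = fit_pls(x, groups, max_components=1)
        assert model.x_loadings[2, 0] == 0.0

    def test_single_group_rejected(self, rng):
        with pytest.raises(PlsError):
            fit_pls(rng.normal(size=(10, 3)), np.repeat("a", 10))


class TestRetainComponents:
    def test_published_sequence(self):
        # three components above the 5% floor, the fourth below
        assert retain_components([21.23, 16.28, 10.57, 4.9], floor=5) == 3

    def test_all_below_floor(self):
        assert retain_components([4.0, 3.0], floor=5) == 0

    def test_prefix_rule_not_filter(self):
        assert retain_components([6.0, 3.0, 7.0], floor=5) == 1


class TestEvaluateSplit:
    def test_separable_problem_beats_null(self, rng):
        x, groups = separable_problem(rng)
        rmse, rmse_null, p = evaluate_split(x, groups, n_perm=99, seed=0)
        assert rmse < 0.1
        assert rmse_null > rmse
        assert p <= 0.05

    def test_null_problem_gives_large_p(self, rng):
        x = rng.normal(size=(60, 10))
        groups = np.array(["a", "b"] * 30)
        _, _, p = evaluate_split(x, groups, n_perm=49, seed=1)
        assert p > 0.05


class TestCrossval:
    def test_separable_problem_small_rmse(self, rng):
        x, groups = separable_problem(rng, n=80)
        mean, se = crossval_rmse(x, groups, k_folds=10, seed=0)
        assert mean < 0.05
        assert se >= 0

    def test_noise_matches_mean_predictor_baseline(self, rng):
        x = rng.normal(size=(200, 10))
        groups = np.array(["a", "b"] * 100)
        mean, _ = crossval_rmse(x, groups, k_folds=10, seed=2, max_components=1)
        baseline = 0.5  # RMSE of predicting the 50/50 indicator mean
        assert mean == pytest.approx(baseline, rel=0.1)

    def test_seed_determinism(self, rng):
        x, groups = separable_problem(rng)
        assert crossval_rmse(x, groups, seed=7) == crossval_rmse(x, groups, seed=7)


class TestBootstrapLoadings:
    def test_procrustes_self_alignment_is_identity(self, rng):
        from scipy.linalg import orthogonal_procrustes

        loadings = rng.normal(size=(10, 3))
        rot, _ = orthogonal_procrustes(loadings, loadings)
        assert np.allclose(rot, np.eye(3), atol=1e-10)

    def test_planted_effect_nodes_have_reliable_ratios(self):
        spec = ConnectomeSpec(seed=31)
        conn = generate_connectomes(spec)
        x = node_degree(conn).to_numpy(dtype=float)
        bsr = bootstrap_loadings(
            x, conn.groups, n_boot=200, seed=1, max_components=2
        )
        effect = sorted(set(spec.effect_nodes[0]) | set(spec.effect_nodes[1]))
        null = [i for i in range(spec.n_nodes) if i not in effect]
        flags = (np.abs(bsr) > 2).any(axis=1)
        assert flags[effect].mean() >= 0.9
        assert flags[null].mean() <= 0.2

    def test_degenerate_zero_variance_is_capped(self, rng):
        x, groups = separable_problem(rng, n=20, p=4)
        x[:, 1:] = np.round(x[:, 1:])  # keep some variation
        with pytest.warns(UserWarning, match="capped"):
            # constant-loading degenerate case: single dominating column and
            # a bootstrap that cannot vary it
            bsr = bootstrap_loadings(
                np.column_stack([x[:, 0], x[:, 0] * 2]),
                groups,
                n_boot=10,
                frac=1.0,
                replace=False,
                seed=0,
                max_components=1,
            )
        assert np.all(np.abs(bsr) <= 1e6)


class TestScoreComparison:
    def test_identical_distributions_not_significant(self, rng):
        scores = np.tile(rng.normal(size=(30, 2)), (2, 1))
        groups = np.repeat(["a", "b"], 30)
        out = compare_group_scores(scores, groups)
        assert (out["p_corrected"] == 1.0).all()

    def test_shifted_group_detected_and_family_sized(self, rng):
        scores = rng.normal(size=(150, 3))
        groups = np.repeat(["a", "b", "c"], 50)
        scores[groups == "b", 0] += 2.0
        out = compare_group_scores(scores, groups)
        assert len(out) == 9
        hit = out[(out["component"] == 1) & (out["group_b"] == "b")]
        assert (hit["p_corrected"] < 0.05).any()
        assert np.allclose(
            out["p_corrected"], np.minimum(1.0, 9 * out["p_raw"]), atol=1e-12
        )


class TestTopLoadingReport:
    def test_top_quarter_of_eight_nodes(self):
        bsr = np.array([[0.1], [0.2], [0.3], [0.4], [0.5], [0.6], [2.5], [3.0]])
        out = top_loading_report(bsr, [f"n{i}" for i in range(8)])
        assert len(out) == 2
        assert set(out["node"]) == {"n6", "n7"}
        assert out["significant"].all()

    def test_no_reliable_nodes_still_listed(self):
        bsr = np.linspace(0.1, 1.5, 8)[:, None]
        out = top_loading_report(bsr, [f"n{i}" for i in range(8)])
        assert len(out) == 2
        assert not out["significant"].any()

    def test_boundary_ties_all_included(self):
        bsr = np.array([[1.0]] * 8)
        out = top_loading_report(bsr, [f"n{i}" for i in range(8)])
        assert len(out) == 8
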