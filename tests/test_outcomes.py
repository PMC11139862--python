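"""Mortality models: filters, AUROC, classes, RF importance, ORs, DE, rho."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from sepsispatterns import (
    additive_auroc,
    auroc,
    classify_patterns,
    correlate_patterns,
    filter_known_outcome,
    pattern_logistic_auroc,
    pattern_odds_ratios,
    rf_importance_pipeline,
    scale_patterns,
    welch_bh_diffexp,
)
from sepsispatterns.outcomes import OutcomeModelError, benjamini_hochberg
from helpers import make_expression


def _meta_frame(outcomes, timepoint="0h", group="sepsis", start=0):
    rows = []
    for i, out in enumerate(outcomes, start=start):
        rows.append({
            "sample_id": f"s{i}_{timepoint}", "subject_id": f"subj{i}",
            "timepoint": timepoint, "hours": 0.0, "group": group,
            "outcome": out, "age": 50.0 + (i % 7), "sex": "M" if i % 2 else "F",
        })
    return pd.DataFrame(rows)


class TestFilterKnownOutcome:
    def test_study_composition_keeps_117(self):
        meta = _meta_frame(["survived"] * 63 + ["died"] * 54 + ["unknown"] * 3)
        kept, n = filter_known_outcome(meta)
        assert n == 117
        assert kept["subject_id"].nunique() == 117

    def test_no_unknowns_returns_unchanged(self):
        meta = _meta_frame(["survived"] * 5 + ["died"] * 5)
        kept, n = filter_known_outcome(meta)
        assert n == 10
        pd.testing.assert_frame_equal(kept.reset_index(drop=True), meta)

    def test_all_unknown_is_error(self):
        meta = _meta_frame(["unknown"] * 4)
        with pytest.raises(OutcomeModelError):
            filter_known_outcome(meta)

    def test_conservation_of_subjects(self):
        meta = _meta_frame(["survived"] * 6 + ["died"] * 3 + ["unknown"] * 2)
        kept, n = filter_known_outcome(meta)
        removed = meta.loc[~meta.index.isin(kept.index)]
        assert n + removed["subject_id"].nunique() == 11


class TestAuroc:
    def test_equals_mann_whitney_on_random_instances(self, rng):
        for _ in range(20):
            n1 = int(rng.integers(2, 25))
            n0 = int(rng.integers(2, 25))
            scores = rng.normal(size=n1 + n0)
            y = np.r_[np.ones(n1), np.zeros(n0)]
            u = stats.mannwhitneyu(scores[:n1], scores[n1:],
                                   alternative="two-sided").statistic
            assert auroc(scores, y) == pytest.approx(u / (n1 * n0))

    def test_constant_pattern_gives_half(self):
        meta = _meta_frame(["survived"] * 10 + ["died"] * 10)
        P = pd.DataFrame(np.ones((1, 20)), index=["p1"],
                         columns=meta["sample_id"])
        fit = pattern_logistic_auroc(P, meta, "p1", "0h")
        assert fit.auroc == 0.5

    def test_perfect_separation_gives_one(self, rng):
        meta = _meta_frame(["survived"] * 12 + ["died"] * 12)
        vals = np.r_[rng.uniform(0, 1, 12), rng.uniform(2, 3, 12)]
        P = pd.DataFrame(vals[None, :], index=["p1"],
                         columns=meta["sample_id"])
        fit = pattern_logistic_auroc(P, meta, "p1", "0h")
        assert fit.auroc == 1.0

    def test_binormal_auroc_near_closed_form(self, rng):
        n = 500
        meta = _meta_frame(["died"] * n + ["survived"] * n)
        vals = np.r_[rng.normal(1, 1, n), rng.normal(0, 1, n)]
        P = pd.DataFrame(vals[None, :], index=["p1"],
                         columns=meta["sample_id"])
        fit = pattern_logistic_auroc(P, meta, "p1", "0h")
        assert fit.auroc == pytest.approx(stats.norm.cdf(1 / np.sqrt(2)),
                                          abs=0.03)
        assert fit.n_died == n and fit.n_survived == n

    def test_too_few_per_class_rejected(self):
        meta = _meta_frame(["survived"] * 5 + ["died"])
        P = pd.DataFrame(np.ones((1, 6)), index=["p1"],
                         columns=meta["sample_id"])
        with pytest.raises(OutcomeModelError):
            pattern_logistic_auroc(P, meta, "p1", "0h")


class TestClassifyPatterns:
    @pytest.mark.parametrize("row,expected", [
        ((0.9, 0.9, 0.9, 0.9, 0.9), "prognostic"),
        ((0.55, 0.60, 0.65, 0.75, 0.80), "dynamic"),
        ((0.50, 0.50, 0.50, 0.50, 0.50), "uninformative"),
        ((0.69, 0.71, 0.72, 0.69, 0.69), "uninformative"),
    ])
    def test_dichotomy(self, row, expected):
        table = pd.DataFrame([row], index=["p1"],
                             columns=["0h", "6h", "24h", "48h", "72h"])
        assert classify_patterns(table, threshold=0.70)["p1"] == expected

    def test_missing_enrolment_column_rejected(self):
        table = pd.DataFrame([[0.8]], index=["p1"], columns=["6h"])
        with pytest.raises(OutcomeModelError):
            classify_patterns(table)


class TestScalePatterns:
    def test_known_row(self):
        P = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p1"])
        np.testing.assert_allclose(scale_patterns(P).to_numpy(),
                                   [[-1.0, 0.0, 1.0]])

    def test_constant_row_zeroed_with_warning(self):
        P = pd.DataFrame([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning):
            out = scale_patterns(P)
        np.testing.assert_array_equal(out.to_numpy()[0], 0.0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 1000))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        P = pd.DataFrame(rng.normal(size=(3, 8)))
        once = scale_patterns(P)
        twice = scale_patterns(once)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(),
                                   atol=1e-12)


def _signal_dataset(rng, n=200, k=30, effect=2.0):
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)].astype(int)
    X = rng.normal(size=(n, k))
    X[:, 0] += effect * y
    cols = [f"p{j + 1}" for j in range(k)]
    return pd.DataFrame(X, columns=cols), y


class TestRandomForestPipeline:
    def test_signal_pattern_ranks_first_in_most_resplits(self, rng):
        P0, y = _signal_dataset(rng)
        imp = rf_importance_pipeline(P0, y, seed=0, n_resplits=10,
                                     n_folds=5, n_repeats=1, n_trees=60)
        per = imp.per_resplit.to_numpy()
        top_counts = (per.argmax(axis=1) == 0).sum()
        assert top_counts >= 9
        assert imp.table.loc["p1", "rank"] == 1
        # univariate AUROC oracle agrees the signal feature is the best
        aucs = [auroc(P0[c], y) for c in P0.columns]
        assert int(np.argmax(np.abs(np.asarray(aucs) - 0.5))) == 0

    def test_importance_table_invariants(self, rng):
        P0, y = _signal_dataset(rng, n=80, k=6)
        imp = rf_importance_pipeline(P0, y, seed=1, n_resplits=3,
                                     n_folds=4, n_repeats=1, n_trees=40)
        assert (imp.table["mean_importance"] >= 0).all()
        assert sorted(imp.table["rank"]) == list(range(1, 7))

    def test_permuted_labels_heldout_auroc_near_chance(self, rng):
        P0, y = _signal_dataset(rng, n=200, k=10, effect=2.0)
        y_perm = rng.permutation(y)
        imp = rf_importance_pipeline(P0, y_perm, seed=2, n_resplits=8,
                                     n_folds=4, n_repeats=1, n_trees=60)
        assert 0.40 <= imp.heldout_auroc.mean() <= 0.60

    def test_reproducible_with_same_seed(self, rng):
        P0, y = _signal_dataset(rng, n=60, k=4)
        a = rf_importance_pipeline(P0, y, seed=3, n_resplits=2, n_folds=3,
                                   n_repeats=1, n_trees=25)
        b = rf_importance_pipeline(P0, y, seed=3, n_resplits=2, n_folds=3,
                                   n_repeats=1, n_trees=25)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_single_class_rejected(self, rng):
        P0, _ = _signal_dataset(rng, n=40, k=3)
        with pytest.raises(OutcomeModelError):
            rf_importance_pipeline(P0, np.ones(40, dtype=int))


class TestAdditiveAuroc:
    def test_signal_prefix_performs_then_noise_stable(self, rng):
        P0, y = _signal_dataset(rng, n=200, k=5)
        out = additive_auroc(P0, y, ["p1", "p2", "p3"], seed=0,
                             n_resplits=6, n_trees=80)
        assert len(out) == 3
        assert out.loc[0, "mean_auroc"] >= 0.80
        assert abs(out.loc[1, "mean_auroc"] - out.loc[0, "mean_auroc"]) < 0.05

    def test_single_pattern_ordering(self, rng):
        P0, y = _signal_dataset(rng, n=60, k=3)
        out = additive_auroc(P0, y, ["p1"], seed=0, n_resplits=3, n_trees=30)
        assert len(out) == 1

    def test_unknown_pattern_rejected(self, rng):
        P0, y = _signal_dataset(rng, n=60, k=3)
        with pytest.raises(OutcomeModelError):
            additive_auroc(P0, y, ["p1", "nope"], seed=0)


class TestOddsRatios:
    def test_two_by_two_closed_form(self):
        # exposure table: a=20 exposed-died, b=10 exposed-survived, c=10, d=20
        x = np.r_[np.ones(30), np.zeros(30)]
        y = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        P = pd.DataFrame({"p1": x})
        out = pattern_odds_ratios(P, y)
        assert out.loc["p1", "odds_ratio"] == pytest.approx(4.0, abs=1e-4)

    def test_null_predictor_ci_contains_one(self, rng):
        P = pd.DataFrame({"p1": rng.normal(size=2000)})
        y = rng.integers(0, 2, size=2000)
        out = pattern_odds_ratios(P, y)
        assert out.loc["p1", "ci_low"] < 1.0 < out.loc["p1", "ci_high"]

    def test_label_inversion_inverts_or(self, rng):
        P = pd.DataFrame({"p1": rng.normal(size=300)})
        y = (P["p1"] + rng.normal(size=300) > 0).astype(int).to_numpy()
        a = pattern_odds_ratios(P, y).loc["p1", "odds_ratio"]
        b = pattern_odds_ratios(P, 1 - y).loc["p1", "odds_ratio"]
        assert a == pytest.approx(1 / b, rel=1e-6)


class TestWelchBH:
    def test_identical_groups_null(self, rng):
        arr = rng.exponential(size=(12, 4))
        expr = make_expression(np.hstack([arr, arr]),
                               samples=[f"a{i}" for i in range(4)]
                               + [f"b{i}" for i in range(4)])
        out = welch_bh_diffexp(expr, [f"a{i}" for i in range(4)],
                               [f"b{i}" for i in range(4)])
        np.testing.assert_allclose(out["t"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["p"], 1.0)

    def test_bh_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]),
            [0.04, 0.04, 0.04, 0.04])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_bh_monotone_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=12)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_strong_shift_is_significant(self, rng):
        # Normal(0,1) vs Normal(2,1) shifted to a positive abundance scale
        # (a common +10 offset leaves the Welch statistic unchanged)
        a = rng.normal(10, 1, size=(3, 50))
        b = rng.normal(12, 1, size=(3, 50))
        expr = make_expression(np.hstack([a, b]),
                               samples=[f"a{i}" for i in range(50)]
                               + [f"b{i}" for i in range(50)])
        out = welch_bh_diffexp(expr, [f"a{i}" for i in range(50)],
                               [f"b{i}" for i in range(50)])
        assert (out["p"] < 1e-10).all()

    def test_welch_statistic_matches_closed_form(self, rng):
        xa = rng.normal(size=6)
        xb = rng.normal(2, 1.5, size=9)
        expr = make_expression(np.abs(np.vstack([np.r_[xa, xb]])) + 1,
                               samples=[f"a{i}" for i in range(6)]
                               + [f"b{i}" for i in range(9)])
        out = welch_bh_diffexp(expr, [f"a{i}" for i in range(6)],
                               [f"b{i}" for i in range(9)])
        va, vb = expr.to_numpy()[0, :6].var(ddof=1), expr.to_numpy()[0, 6:].var(ddof=1)
        t_manual = ((expr.to_numpy()[0, :6].mean() - expr.to_numpy()[0, 6:].mean())
                    / np.sqrt(va / 6 + vb / 9))
        assert out["t"].iloc[0] == pytest.approx(t_manual, rel=1e-10)

    def test_degenerate_zero_variance_flagged(self):
        arr = np.array([[1.0, 1.0, 2.0, 2.0]])
        expr = make_expression(arr, samples=["a1", "a2", "b1", "b2"])
        out = welch_bh_diffexp(expr, ["a1", "a2"], ["b1", "b2"])
        assert bool(out["degenerate"].iloc[0])
        assert out["p"].iloc[0] == 0.0


class TestCorrelatePatterns:
    def _p_and_cov(self, x, y):
        P = pd.DataFrame(x[None, :], index=["p1"],
                         columns=[f"s{i}" for i in range(len(x))])
        cov = pd.DataFrame({"c1": y}, index=P.columns)
        return P, cov

    def test_monotone_increasing_rho_one(self, rng):
        x = rng.normal(size=30)
        P, cov = self._p_and_cov(x, np.exp(x))
        rho, _ = correlate_patterns(P, cov)
        assert rho.loc["p1", "c1"] == pytest.approx(1.0)

    def test_negation_rho_minus_one(self, rng):
        x = rng.normal(size=30)
        P, cov = self._p_and_cov(x, -x)
        rho, _ = correlate_patterns(P, cov)
        assert rho.loc["p1", "c1"] == pytest.approx(-1.0)

    def test_small_vector_matches_rank_formula(self, rng):
        from helpers import spearman_rho_definition

        x = rng.normal(size=6)
        y = rng.normal(size=6)
        P, cov = self._p_and_cov(x, y)
        rho, _ = correlate_patterns(P, cov)
        assert rho.loc["p1", "c1"] == pytest.approx(
            spearman_rho_definition(x, y), rel=1e-10)

    def test_missing_values_excluded_pairwise(self, rng):
        x = rng.normal(size=12)
        y = x.copy()
        y[:3] = np.nan
        P, cov = self._p_and_cov(x, y)
        rho, _ = correlate_patterns(P, cov)
        assert rho.loc["p1", "c1"] == pytest.approx(1.0)

    def test_constant_covariate_reported_missing(self, rng):
        x = rng.normal(size=10)
        P, cov = self._p_and_cov(x, np.ones(10))
        rho, _ = correlate_patterns(P, cov)
        assert np.isnan(rho.loc["p1", "c1"])
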