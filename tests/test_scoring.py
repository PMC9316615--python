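import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from starlimit.scoring import (
    DEFAULT_CANDIDATES,
    ScoreModelSpec,
    composite_score,
    derive_expert_threshold,
    fit_discriminant,
    flag_outliers,
    select_score_model,
)


class TestCompositeScore:
    @pytest.mark.parametrize(
        "time_s, edge, expected",
        [
            (0.0, 0, 90.0),     # the formula's intercept
            (300.0, 0, 0.0),    # time cap cancels the intercept
            (0.0, 20, 100.0),   # fastest, cleanest repetition
            (100.0, 15, 67.5),
        ],
    )
    def test_printed_formula(self, time_s, edge, expected):
        assert composite_score(time_s, edge) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "time_s, edge, bound",
        [(-1.0, 0, "time_s"), (301.0, 0, "time_s"), (0.0, -1, "edge"), (0.0, 21, "edge")],
    )
    def test_out_of_bound_inputs_name_the_bound(self, time_s, edge, bound):
        with pytest.raises(ValueError, match=bound):
            composite_score(time_s, edge)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        t1=st.floats(0, 300), t2=st.floats(0, 300), e=st.integers(0, 20)
    )
    def test_strictly_decreasing_in_time(self, t1, t2, e):
        # strictness is asserted for gaps the float score can resolve
        if t1 + 1e-9 < t2:
            assert composite_score(t1, e) > composite_score(t2, e)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(t=st.floats(0, 300), e1=st.integers(0, 20), e2=st.integers(0, 20))
    def test_strictly_increasing_in_edge(self, t, e1, e2):
        if e1 < e2:
            assert composite_score(t, e1) < composite_score(t, e2)

    def test_range_over_feasible_domain_is_exactly_0_100(self):
        t = np.linspace(0, 300, 601)
        e = np.arange(0, 21)
        grid = composite_score(t[:, None] * np.ones_like(e), e[None, :] * np.ones((t.size, 1)))
        assert grid.min() == 0.0 and grid.max() == 100.0


def _grid_logistic_loglik(X, y, spans, n=41):
    """Brute-force oracle: best log-likelihood over a refined coefficient grid."""

    def loglik(beta):
        eta = X @ beta
        return float(np.sum(y * eta - np.log1p(np.exp(eta))))

    centers = np.zeros(X.shape[1])
    widths = np.array(spans, dtype=float)
    best = -np.inf
    for _ in range(6):  # successive refinement
        axes = [np.linspace(c - w, c + w, n) for c, w in zip(centers, widths)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        lls = np.array([loglik(b) for b in pts])
        k = int(np.argmax(lls))
        best = float(lls[k])
        centers = pts[k]
        widths = widths * (2.0 / (n - 1)) * 2.0
    return best


class TestDiscriminant:
    def test_no_information_case(self):
        # balanced labels, all-zero feature: chance-level log-likelihood
        n = 10
        feats = pd.DataFrame({"time_term": np.zeros(n)})
        labels = np.array(["novice", "expert"] * (n // 2))
        fit = fit_discriminant(feats, labels)
        assert fit.loglik == pytest.approx(n * np.log(0.5), abs=1e-6)
        assert np.allclose(fit.coefficients, 0.0, atol=1e-4)

    def test_loglik_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        x1 = rng.normal(0, 1, 8)
        x2 = rng.normal(0, 1, 8)
        labels = np.array(["novice"] * 4 + ["expert"] * 4)
        feats = pd.DataFrame({"time_term": x1, "edge": x2})
        fit = fit_discriminant(feats, labels)
        X = np.column_stack([np.ones(8), x1, x2])
        y = (labels == "expert").astype(float)
        oracle = _grid_logistic_loglik(X, y, spans=[6.0, 6.0, 6.0])
        assert fit.loglik == pytest.approx(oracle, abs=1e-3)

    def test_constant_feature_costs_two_aic_points(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 40)
        labels = np.where(x + rng.normal(0, 1, 40) > 0, "expert", "novice")
        base = fit_discriminant(pd.DataFrame({"time_term": x}), labels)
        padded = fit_discriminant(
            pd.DataFrame({"time_term": x, "edge": np.full(40, 3.0)}), labels
        )
        assert padded.loglik == pytest.approx(base.loglik, abs=1e-4)
        assert padded.aic == pytest.approx(base.aic + 2.0, abs=1e-3)

    def test_single_class_rejected(self):
        feats = pd.DataFrame({"time_term": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="both cohorts"):
            fit_discriminant(feats, np.array(["novice"] * 3))

    def test_separation_is_flagged_not_fatal(self):
        feats = pd.DataFrame({"time_term": [0.0, 0.1, 0.9, 1.0]})
        labels = np.array(["novice", "novice", "expert", "expert"])
        fit = fit_discriminant(feats, labels)
        assert np.isfinite(fit.aic)


class TestModelSelection:
    def test_single_candidate_ranks_first(self):
        rng = np.random.default_rng(2)
        feats = pd.DataFrame({"time_term": rng.normal(0, 1, 20)})
        labels = np.where(feats["time_term"] > 0, "expert", "novice")
        tbl = select_score_model([DEFAULT_CANDIDATES[0]], feats, labels)
        assert list(tbl.index) == [1]

    def test_noise_feature_ranks_below_parsimony(self):
        rng = np.random.default_rng(7)
        n = 200
        time_term = rng.normal(0, 1, n)
        labels = np.where(time_term + rng.normal(0, 1.0, n) > 0, "expert", "novice")
        feats = pd.DataFrame({"time_term": time_term, "edge": rng.normal(0, 1, n)})
        tbl = select_score_model(
            [ScoreModelSpec("time", ("time_term",)), ScoreModelSpec("time+edge", ("time_term", "edge"))],
            feats,
            labels,
        )
        assert tbl.iloc[0]["name"] == "time"

    def test_best_first_ordering(self):
        rng = np.random.default_rng(3)
        n = 60
        feats = pd.DataFrame(
            {
                "time_term": rng.normal(0, 1, n),
                "edge": rng.normal(0, 1, n),
                "clean_star": rng.normal(0, 1, n),
            }
        )
        labels = np.where(feats["time_term"] > 0, "expert", "novice")
        tbl = select_score_model(
            [c for c in DEFAULT_CANDIDATES if set(c.feature_set) <= set(feats.columns)],
            feats,
            labels,
        )
        assert tbl["aic"].is_monotonic_increasing

    def test_aic_ranking_invariant_to_affine_feature_rescale(self):
        rng = np.random.default_rng(13)
        n = 80
        feats = pd.DataFrame(
            {"time_term": rng.normal(0, 1, n), "edge": rng.normal(0, 1, n)}
        )
        labels = np.where(
            feats["time_term"] + 0.5 * feats["edge"] + rng.normal(0, 1, n) > 0,
            "expert",
            "novice",
        )
        cands = [
            ScoreModelSpec("time", ("time_term",)),
            ScoreModelSpec("time+edge", ("time_term", "edge")),
        ]
        tbl1 = select_score_model(cands, feats, labels)
        feats2 = feats.assign(edge=5.0 * feats["edge"] + 7.0)
        tbl2 = select_score_model(cands, feats2, labels)
        assert list(tbl1["name"]) == list(tbl2["name"])
        assert np.allclose(tbl1["aic"], tbl2["aic"], atol=1e-4)


class TestOutliers:
    def _summary(self, medians, cohort="novice"):
        return pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(len(medians))],
                "cohort": cohort,
                "median_time_s": medians,
            }
        )

    def test_tight_cluster_flags_nothing(self):
        assert flag_outliers(self._summary([100, 105, 110, 108])) == []

    def test_extreme_median_flagged(self):
        assert flag_outliers(self._summary([100, 105, 110, 290])) == ["S3"]

    def test_identical_medians_flag_nothing(self):
        assert flag_outliers(self._summary([120] * 6)) == []

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="fewer than 4"):
            flag_outliers(self._summary([100, 105, 110]))


class TestExpertThreshold:
    def test_separated_groups_cut_at_gap_midpoint(self):
        res = derive_expert_threshold([30, 35, 40], [80, 85, 90])
        assert res.threshold == pytest.approx(60.0)
        assert not res.low_separability

    def test_identical_distributions_warn(self):
        res = derive_expert_threshold([50, 60, 70], [50, 60, 70])
        assert res.low_separability

    def test_youden_scan_oracle(self):
        # exhaustive cutpoint scan maximizing sensitivity + specificity - 1
        res = derive_expert_threshold([50, 55, 60], [65, 70, 75])
        assert res.threshold == pytest.approx(62.5)
        assert res.threshold_rounded == pytest.approx(60.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            derive_expert_threshold([], [70])
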