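import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from starlimit.curves import get_curve
from starlimit.nlme import (
    compare_models,
    fit_nlme,
    marginal_loglik,
    predict_fixed_curve,
)


def _panel_frame(scores_by_subject, devices=("exoscope",)):
    """Long frame from {subject: {device: score array}}."""
    rows = []
    for sid, per_dev in scores_by_subject.items():
        for dev, scores in per_dev.items():
            for t, s in enumerate(scores, start=1):
                rows.append(
                    {"subject_id": sid, "device": dev, "trial": t, "score": float(s)}
                )
    return pd.DataFrame(rows)


def _simulate_frame(rng, n_subjects=6, trials=12, sd_A=4.0, sd_r=0.1, resid=5.0,
                    truth=(25.0, 65.0, -1.0, 1.5)):
    curve = get_curve("modified_weibull")
    P0, A, r, c = truth
    t = np.arange(1, trials + 1, dtype=float)
    data = {}
    for i in range(n_subjects):
        a_i = rng.normal(0, sd_A)
        rho_i = rng.normal(0, sd_r)
        per_dev = {}
        for dev, (Ad, rd) in {"exoscope": (A, r), "microscope": (A + 1.0, r - 0.3)}.items():
            mean = curve.value([P0, Ad + a_i, rd + rho_i, c], t)
            per_dev[dev] = mean + rng.normal(0, resid, size=t.size)
        data[f"S{i:02d}"] = per_dev
    return _panel_frame(data, devices=("exoscope", "microscope"))


class TestFitting:
    def test_noise_free_data_identifies_generating_curve(self):
        curve = get_curve("modified_weibull")
        truth = [25.0, 65.0, -1.0, 1.5]
        t = np.arange(1, 16, dtype=float)
        mean = curve.value(truth, t)
        frame = _panel_frame({f"S{i}": {"exoscope": mean} for i in range(4)})
        fit = fit_nlme(frame, "modified_weibull", shared=("P0", "c"), n_starts=2)
        est = {p: fit.fixed_effect(p)[0] for p in ("P0", "A", "r", "c")}
        for p, tv in zip(("P0", "A", "r", "c"), truth):
            assert est[p] == pytest.approx(tv, abs=1e-4), p
        assert fit.resid_sd < 1e-3

    def test_recovers_truth_at_moderate_size(self):
        rng = np.random.default_rng(42)
        frame = _simulate_frame(rng, n_subjects=12, trials=20)
        fit = fit_nlme(frame, "modified_weibull", n_starts=2, seed=0)
        A_exo = fit.fixed_effect("A", "exoscope")
        assert abs(A_exo[0] - 65.0) < 3 * A_exo[1] + 1.0
        assert fit.converged

    def test_subject_relabeling_leaves_loglik_unchanged(self):
        rng = np.random.default_rng(1)
        frame = _simulate_frame(rng, n_subjects=5, trials=8)
        fixed = {
            "P0": 25.0,
            "A": {"exoscope": 65.0, "microscope": 66.0},
            "r": {"exoscope": -1.0, "microscope": -1.3},
            "c": 1.5,
        }
        ll1 = marginal_loglik(frame, "modified_weibull", fixed, {"A": 4.0, "r": 0.1}, 5.0)
        relabel = {s: f"Z{k}" for k, s in enumerate(frame["subject_id"].unique()[::-1])}
        frame2 = frame.assign(subject_id=frame["subject_id"].map(relabel))
        ll2 = marginal_loglik(frame2, "modified_weibull", fixed, {"A": 4.0, "r": 0.1}, 5.0)
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_too_few_subjects_rejected(self):
        frame = _panel_frame({"S0": {"exoscope": [30, 40, 50, 55]}})
        with pytest.raises(ValueError, match="3 subjects"):
            fit_nlme(frame, "exponential")


class TestLaplaceAgainstQuadrature:
    def test_marginal_loglik_matches_numerical_integration(self):
        """Laplace vs adaptive 2-D quadrature on a tiny two-subject instance."""
        curve = get_curve("modified_weibull")
        truth = [25.0, 65.0, -1.0, 1.5]
        sd_A, sd_r, resid = 3.0, 0.02, 2.0
        rng = np.random.default_rng(3)
        t = np.arange(1, 5, dtype=float)
        data = {}
        for i in range(2):
            a_i = rng.normal(0, sd_A)
            mean = curve.value([25.0, 65.0 + a_i, -1.0, 1.5], t)
            data[f"S{i}"] = {"exoscope": mean + rng.normal(0, resid, t.size)}
        frame = _panel_frame(data)

        fixed = {"P0": 25.0, "A": 65.0, "r": -1.0, "c": 1.5}
        lap = marginal_loglik(frame, curve, fixed, {"A": sd_A, "r": sd_r}, resid)

        # independent oracle: direct 2-D integration of the joint density
        def subject_loglik(y):
            def integrand(rho, a):
                mean = curve.value([25.0, 65.0 + a, -1.0 + rho, 1.5], t)
                loglik_y = -0.5 * np.sum(
                    ((y - mean) / resid) ** 2
                ) - t.size * np.log(resid * np.sqrt(2 * np.pi))
                prior = (
                    -0.5 * (a / sd_A) ** 2
                    - np.log(sd_A * np.sqrt(2 * np.pi))
                    - 0.5 * (rho / sd_r) ** 2
                    - np.log(sd_r * np.sqrt(2 * np.pi))
                )
                return np.exp(loglik_y + prior + 30.0)  # scale to avoid underflow

            val, _ = integrate.dblquad(
                integrand, -8 * sd_A, 8 * sd_A, -8 * sd_r, 8 * sd_r,
                epsabs=1e-12, epsrel=1e-10,
            )
            return np.log(val) - 30.0

        oracle = sum(
            subject_loglik(frame[frame["subject_id"] == sid]["score"].to_numpy())
            for sid in ("S0", "S1")
        )
        assert lap == pytest.approx(oracle, abs=1e-3)


class TestModelComparison:
    def test_single_fit_ranks_first(self):
        rng = np.random.default_rng(4)
        frame = _simulate_frame(rng, n_subjects=5, trials=8)
        fit = fit_nlme(frame, "exponential", n_starts=1)
        tbl = compare_models([fit])
        assert list(tbl.index) == [1] and tbl.iloc[0]["curve"] == "exponential"

    def test_duplicate_fits_tie_stably_by_name(self):
        rng = np.random.default_rng(4)
        frame = _simulate_frame(rng, n_subjects=5, trials=8)
        fit = fit_nlme(frame, "exponential", n_starts=1)
        tbl = compare_models([fit, fit])
        assert tbl["aic"].nunique() == 1 and list(tbl["curve"]) == ["exponential"] * 2

    def test_mixed_datasets_rejected(self):
        rng = np.random.default_rng(4)
        f1 = fit_nlme(_simulate_frame(rng, n_subjects=5, trials=8), "exponential", n_starts=1)
        f2 = fit_nlme(_simulate_frame(rng, n_subjects=5, trials=8), "exponential", n_starts=1)
        with pytest.raises(ValueError, match="different datasets"):
            compare_models([f1, f2])


@pytest.fixture(scope="module")
def prediction_fit():
    rng = np.random.default_rng(8)
    frame = _simulate_frame(rng, n_subjects=6, trials=12)
    return fit_nlme(frame, "modified_weibull", n_starts=1, seed=0)


class TestPrediction:

    def test_large_t_reaches_device_plateau(self, prediction_fit):
        fit = prediction_fit
        plateau = fit.fixed_effect("A", "exoscope")[0]
        val = predict_fixed_curve(fit, "exoscope", [1e8])
        assert val[0] == pytest.approx(plateau, abs=1e-6)

    def test_grid_of_20_finite_values(self, prediction_fit):
        fit = prediction_fit
        vals = predict_fixed_curve(fit, "microscope", np.arange(1, 21))
        assert vals.shape == (20,) and np.all(np.isfinite(vals))

    def test_matches_direct_curve_evaluation(self, prediction_fit):
        fit = prediction_fit
        curve = get_curve("modified_weibull")
        params = [
            fit.fixed_effect(p, "exoscope")[0] for p in ("P0", "A", "r", "c")
        ]
        t = np.arange(1, 21, dtype=float)
        assert np.allclose(predict_fixed_curve(fit, "exoscope", t), curve.value(params, t))

    def test_unknown_device_rejected(self, prediction_fit):
        fit = prediction_fit
        with pytest.raises(KeyError, match="device"):
            predict_fixed_curve(fit, "loupes", [1, 2, 3])
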