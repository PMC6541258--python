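import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from lurefx.event_processing import CovariateMatrix, DetectionMatrix
from lurefx.experiments import enumeration_nll, likelihood_enumeration_max_error
from lurefx.occupancy_models import (
    STANDARD_MODEL_SET,
    ModelSpec,
    aicc,
    fit,
    neg_log_likelihood,
    predict_detection,
    run_model_set,
)
from lurefx.synthetic_data import simulate_occupancy_dataset


def make_matrix(y, species="sp"):
    y = np.asarray(y, dtype=float)
    dates = [dt.date(2013, 6, 1) + dt.timedelta(days=j) for j in range(y.shape[1])]
    sids = [f"S{i}" for i in range(y.shape[0])]
    return DetectionMatrix(species, sids, dates, y)


class TestLikelihood:
    def test_single_detection_closed_form(self):
        """One site, history (1): L = psi * p; at beta = 0, -log(0.25)."""
        dm = make_matrix([[1]])
        nll = neg_log_likelihood(np.zeros(2), dm, {}, ModelSpec())
        assert nll == pytest.approx(-np.log(0.25), abs=1e-12)

    def test_all_zero_history_closed_form(self):
        """One site, (0,0) at psi = p = 0.5: L = 0.5*0.25 + 0.5 = 0.625."""
        dm = make_matrix([[0, 0]])
        nll = neg_log_likelihood(np.zeros(2), dm, {}, ModelSpec())
        assert nll == pytest.approx(-np.log(0.625), abs=1e-12)

    def test_matches_enumeration_oracle_exhaustively(self):
        """Every 2-site x 3-occasion history agrees with the brute-force
        latent-state enumeration to 1e-10."""
        assert likelihood_enumeration_max_error(seed=0) < 1e-10

    def test_missing_cells_skipped(self):
        dm = make_matrix([[1, np.nan]])
        full = make_matrix([[1]])
        assert neg_log_likelihood(np.zeros(2), dm, {}, ModelSpec()) == pytest.approx(
            neg_log_likelihood(np.zeros(2), full, {}, ModelSpec())
        )

    def test_nonfinite_covariate_in_observed_cell_errors(self):
        dm = make_matrix([[1, 0]])
        cov = {"attractant_age": CovariateMatrix(
            "attractant_age", dm.station_ids, dm.dates, np.array([[0.0, np.inf]])
        )}
        with pytest.raises(ValueError, match="non-finite"):
            neg_log_likelihood(np.zeros(3), dm, cov, ModelSpec(("attractant_age",)))


class TestAicc:
    def test_closed_form_spot_value(self):
        assert aicc(-10.0, 2, 20) == pytest.approx(24 + 12 / 17, abs=1e-10)

    def test_degenerate_sample_size_errors(self):
        with pytest.raises(ValueError, match="AICc undefined"):
            aicc(-10.0, 2, 3)

    @pytest.mark.parametrize("K,n", [(2, 10), (3, 30), (4, 200)])
    def test_correction_always_positive(self, K, n):
        assert aicc(-5.0, K, n) > -2 * -5.0 + 2 * K


class TestFit:
    def test_saturated_data_flagged_at_boundary(self):
        f = fit(make_matrix(np.ones((4, 5))))
        assert not f.converged
        assert f.psi_hat > 0.9

    def test_all_zero_matrix_nonidentifiable(self):
        f = fit(make_matrix(np.zeros((4, 5))))
        assert not f.converged
        assert "non-identifiable" in f.message

    def test_constant_model_recovery(self):
        rng = np.random.default_rng(4)
        dm, cov, _ = simulate_occupancy_dataset(500, 20, 0.6, logit(0.3), 0.0, rng)
        f = fit(dm)
        assert f.converged
        assert abs(f.beta_psi - logit(0.6)) < 3 * f.se[0]
        assert abs(f.beta_p[0] - logit(0.3)) < 3 * f.se[1]

    def test_covariate_model_recovers_sign_and_truth(self):
        rng = np.random.default_rng(8)
        dm, cov, _ = simulate_occupancy_dataset(300, 70, 0.6, logit(0.25), -0.15, rng)
        f = fit(dm, {"attractant_age": cov}, ModelSpec(("attractant_age",)))
        assert f.converged
        assert f.beta_p[1] < 0
        assert abs(f.beta_p[1] - (-0.15)) < 3 * f.se[2]

    def test_station_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        dm, cov, _ = simulate_occupancy_dataset(40, 15, 0.5, logit(0.2), -0.1, rng)
        f1 = fit(dm, {"attractant_age": cov}, ModelSpec(("attractant_age",)))
        perm = rng.permutation(40)
        dm2 = DetectionMatrix("sim", [dm.station_ids[i] for i in perm],
                              dm.dates, dm.y[perm])
        cov2 = CovariateMatrix("attractant_age",
                               [cov.station_ids[i] for i in perm],
                               cov.dates, cov.x[perm])
        f2 = fit(dm2, {"attractant_age": cov2}, ModelSpec(("attractant_age",)))
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6)
        assert f1.beta_p[1] == pytest.approx(f2.beta_p[1], abs=1e-4)

    def test_nesting_monotonicity(self):
        """Adding a detection covariate never decreases the max loglik."""
        rng = np.random.default_rng(6)
        dm, cov, _ = simulate_occupancy_dataset(60, 30, 0.6, logit(0.2), -0.1, rng)
        f0 = fit(dm)
        f1 = fit(dm, {"attractant_age": cov}, ModelSpec(("attractant_age",)))
        assert f1.loglik >= f0.loglik - 1e-6


class TestModelSet:
    def test_table_structure_and_ranking(self):
        rng = np.random.default_rng(3)
        dm, cov, _ = simulate_occupancy_dataset(50, 25, 0.6, logit(0.2), -0.2, rng)
        inc = CovariateMatrix(
            "incremental_effort", cov.station_ids, cov.dates,
            np.tile(np.arange(1.0, 26.0), (50, 1)) + rng.normal(0, 0.01, (50, 25)),
        )
        tot = CovariateMatrix(
            "total_effort", cov.station_ids, cov.dates,
            np.tile(rng.integers(20, 30, 50)[:, None].astype(float), (1, 25)),
        )
        covs = {"attractant_age": cov, "incremental_effort": inc, "total_effort": tot}
        table, fits = run_model_set(dm, covs)
        assert len(table) == len(STANDARD_MODEL_SET) == 6
        assert table["delta_AICc"].iloc[0] == 0.0
        assert table["delta_AICc"].is_monotonic_increasing
        assert set(fits) == set(table["model"])

    def test_strong_attractant_effect_ranks_first(self):
        rng = np.random.default_rng(13)
        dm, cov, _ = simulate_occupancy_dataset(150, 60, 0.6, logit(0.2), -0.3, rng)
        inc = CovariateMatrix(
            "incremental_effort", cov.station_ids, cov.dates,
            np.tile(np.arange(1.0, 61.0), (150, 1)),
        )
        tot = CovariateMatrix(
            "total_effort", cov.station_ids, cov.dates,
            np.tile(rng.integers(50, 70, 150)[:, None].astype(float), (1, 60)),
        )
        table, _ = run_model_set(
            dm, {"attractant_age": cov, "incremental_effort": inc,
                 "total_effort": tot},
        )
        assert "attractant_age" in table.iloc[0]["model"]


@pytest.fixture(scope="module")
def attract_fit():
    rng = np.random.default_rng(17)
    dm, cov, _ = simulate_occupancy_dataset(150, 40, 0.6, logit(0.25), -0.2, rng)
    return fit(dm, {"attractant_age": cov}, ModelSpec(("attractant_age",)))


class TestPrediction:
    def test_zero_covariate_gives_intercept(self, attract_fit):
        pred = predict_detection(attract_fit, {"attractant_age": np.array([0.0])})
        assert pred["p_hat"].iloc[0] == pytest.approx(
            expit(attract_fit.beta_p[0]), abs=1e-10
        )

    def test_negative_slope_gives_decreasing_curve(self, attract_fit):
        grid = {"attractant_age": np.arange(0.0, 10.0)}
        pred = predict_detection(attract_fit, grid)
        assert attract_fit.beta_p[1] < 0
        assert pred["p_hat"].is_monotonic_decreasing
        assert ((pred["lo"] <= pred["p_hat"]) & (pred["p_hat"] <= pred["hi"])).all()

    def test_ci_matches_parametric_bootstrap(self):
        """Delta-method CI endpoints agree with a parametric-bootstrap
        oracle within 0.02 on a constant-detection fit."""
        rng = np.random.default_rng(23)
        dm, _, _ = simulate_occupancy_dataset(150, 12, 0.6, logit(0.3), 0.0, rng)
        f = fit(dm)
        pred = predict_detection(f, pd.DataFrame(index=range(1)))
        boots = []
        for _ in range(300):
            occ = rng.random(150) < f.psi_hat
            p = expit(f.beta_p[0])
            y = ((rng.random((150, 12)) < p) & occ[:, None]).astype(float)
            fb = fit(make_matrix(y), n_starts=1)
            boots.append(expit(fb.beta_p[0]))
        lo, hi = np.quantile(boots, [0.025, 0.975])
        assert pred["lo"].iloc[0] == pytest.approx(lo, abs=0.02)
        assert pred["hi"].iloc[0] == pytest.approx(hi, abs=0.02)
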