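"""Simulation studies validating the pipeline end to end.

These are the package's own verification experiments, shared by the test
suite and by ``scripts/acceptance.py``:

* an exhaustive-enumeration check of the occupancy likelihood on every
  2-site x 3-occasion binary history (the enumeration here is written
  independently of the production likelihood: plain probability sums over
  the latent occupancy states),
* parameter recovery and Wald-CI coverage for (psi, b0, b_attract),
* type-I calibration of the randomization test under a no-effect scenario,
* power of AICc selection and of the day-1 classification under an
  injected attractant effect,
* diagnostics of the circular activity density.
"""

from __future__ import annotations

import dataclasses
from itertools import product

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .activity_density import TWO_PI, fit_activity, sample_times
from .event_processing import (
    CovariateMatrix,
    DetectionMatrix,
    attach_refresh_times,
    build_covariate_matrix,
    build_detection_matrix,
    filter_independent,
)
from .occupancy_models import ModelSpec, fit, neg_log_likelihood, run_model_set
from .permutation_null import run_permutation_test
from .synthetic_data import (
    ScenarioConfig,
    SpeciesTruth,
    generate_layout,
    simulate_occupancy_dataset,
    simulate_species_captures,
)

__all__ = [
    "enumeration_nll",
    "likelihood_enumeration_max_error",
    "parameter_recovery",
    "null_calibration",
    "effect_power",
    "density_diagnostics",
]


# ---------------------------------------------------------------------------
# Likelihood enumeration oracle
# ---------------------------------------------------------------------------


def enumeration_nll(
    params: np.ndarray, histories: np.ndarray, covariates: np.ndarray
) -> float:
    """Brute-force negative log-likelihood by summing over the latent
    occupancy state of each site with plain ``math`` arithmetic.

    ``histories`` is (S, J) of 0/1; ``covariates`` is (T, S, J).
    Deliberately naive — no shared code with the production likelihood.
    """
    import math

    b_psi = params[0]
    psi = 1.0 / (1.0 + math.exp(-b_psi))
    total = 0.0
    S, J = histories.shape
    for i in range(S):
        site_prob = 0.0
        for z in (0, 1):
            prob_z = psi if z == 1 else 1.0 - psi
            cond = 1.0
            for j in range(J):
                eta = params[1]
                for t in range(covariates.shape[0]):
                    eta += params[2 + t] * covariates[t, i, j]
                p = 1.0 / (1.0 + math.exp(-eta))
                p_eff = p if z == 1 else 0.0
                cond *= p_eff if histories[i, j] == 1 else 1.0 - p_eff
            site_prob += prob_z * cond
        total += math.log(site_prob)
    return -total


def likelihood_enumeration_max_error(seed: int = 0) -> float:
    """Max |production NLL - enumeration NLL| over all 2x3 histories.

    Evaluated at randomized parameter/covariate values for each history.
    """
    import datetime as dt

    rng = np.random.default_rng(seed)
    dates = [dt.date(2013, 6, 1) + dt.timedelta(days=j) for j in range(3)]
    worst = 0.0
    for bits in product((0, 1), repeat=6):
        y = np.array(bits, dtype=float).reshape(2, 3)
        params = rng.normal(scale=1.0, size=3)
        X = rng.normal(scale=1.0, size=(1, 2, 3))
        dm = DetectionMatrix("sp", ["A", "B"], dates, y)
        cov = {
            "attractant_age": CovariateMatrix(
                "attractant_age", ["A", "B"], dates, np.abs(X[0])
            )
        }
        spec = ModelSpec(("attractant_age",))
        got = neg_log_likelihood(params, dm, cov, spec)
        want = enumeration_nll(params, y, np.abs(X))
        worst = max(worst, abs(got - want))
    return worst


# ---------------------------------------------------------------------------
# Parameter recovery / coverage
# ---------------------------------------------------------------------------


def parameter_recovery(
    n_reps: int = 200,
    n_stations: int = 200,
    n_occasions: int = 70,
    psi: float = 0.6,
    p0: float = 0.25,
    beta_attract: float = -0.15,
    seed: int = 0,
) -> dict:
    """Fit the attractant model on replicated simulated surveys.

    Reports mean point estimates, the fraction of replicates whose point
    estimate lies within 3 SE of truth, and 95% Wald-CI coverage for each
    of (psi-logit, detection intercept, attractant slope).
    """
    rng = np.random.default_rng(seed)
    beta0 = float(logit(p0))
    truth = np.array([float(logit(psi)), beta0, beta_attract])
    spec = ModelSpec(("attractant_age",))
    est = np.full((n_reps, 3), np.nan)
    se = np.full((n_reps, 3), np.nan)
    converged = np.zeros(n_reps, dtype=bool)
    for r in range(n_reps):
        dm, cov, _ = simulate_occupancy_dataset(
            n_stations, n_occasions, psi, beta0, beta_attract, rng
        )
        f = fit(dm, {"attractant_age": cov}, spec, n_starts=2,
                seed=int(rng.integers(2**31)))
        est[r] = [f.beta_psi, f.beta_p[0], f.beta_p[1]]
        se[r] = f.se
        converged[r] = f.converged
    ok = converged & np.all(np.isfinite(se), axis=1)
    z = np.abs(est[ok] - truth) / se[ok]
    within3 = (z <= 3.0).mean(axis=0)
    cover95 = (z <= stats.norm.ppf(0.975)).mean(axis=0)
    return {
        "n_reps": n_reps,
        "n_used": int(ok.sum()),
        "psi_hat_mean": float(expit(est[ok, 0]).mean()),
        "p0_hat_mean": float(expit(est[ok, 1]).mean()),
        "beta_attract_mean": float(est[ok, 2].mean()),
        "within_3se": dict(zip(["beta_psi", "p_intercept", "beta_attract"],
                               map(float, within3))),
        "coverage_95": dict(zip(["beta_psi", "p_intercept", "beta_attract"],
                                map(float, cover95))),
        "truth": {"psi": psi, "p0": p0, "beta_attract": beta_attract},
    }


# ---------------------------------------------------------------------------
# Randomization-test calibration and power
# ---------------------------------------------------------------------------


def _calibration_species(beta_attract: float = 0.0) -> SpeciesTruth:
    """The reference species for calibration/power runs: a nocturnal,
    moderately detectable carnivore (psi 0.6, daily detection 0.10)."""
    return SpeciesTruth(
        "probe", psi=0.6, beta0=float(logit(0.10)),
        beta_attract=beta_attract, diel_means_hours=(1.0,), diel_kappas=(2.0,),
    )


def null_calibration(
    n_reps: int = 500,
    n_randomizations: int = 1000,
    config: ScenarioConfig | None = None,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I behaviour of the randomization test under no attractant effect.

    One survey layout is drawn, then ``n_reps`` replicate species with
    beta_attract = 0 are simulated on it and each is run through the full
    observed-vs-null pipeline.  Reports the per-bin rate of any
    (decreased or increased) classification and per-bin KS uniformity
    p-values of the permutation p-values.
    """
    rng = np.random.default_rng(seed)
    config = config or ScenarioConfig(species=[_calibration_species()])
    layout = generate_layout(config, rng)
    sp = _calibration_species(0.0)
    pvals = np.full((n_reps, 7), np.nan)
    n_caps = np.zeros(n_reps)
    for r in range(n_reps):
        caps, _ = simulate_species_captures(sp, layout, rng)
        independent = filter_independent(caps)
        if len(independent) < 10:
            continue
        annotated = attach_refresh_times(independent, layout.refresh_events)
        res = run_permutation_test(
            sp.name, annotated, layout.deployments, layout.refresh_events,
            n_randomizations=n_randomizations,
            seed=int(rng.integers(2**31)), alpha=alpha,
        )
        pvals[r] = res.p_values
        n_caps[r] = len(independent)
    ok = ~np.isnan(pvals[:, 0])
    p = pvals[ok]
    sig = (p < alpha / 2) | (p > 1 - alpha / 2)
    ks = [float(stats.kstest(p[:, d], "uniform").pvalue) for d in range(7)]
    return {
        "n_reps": int(ok.sum()),
        "n_randomizations": n_randomizations,
        "mean_captures": float(n_caps[ok].mean()),
        "per_bin_rate": [float(x) for x in sig.mean(axis=0)],
        "overall_rate": float(sig.mean()),
        "ks_pvalues": ks,
        "min_ks_pvalue": float(min(ks)),
        "alpha": alpha,
    }


def effect_power(
    n_reps: int = 50,
    effect_size: float = -0.3,
    n_stations: int = 200,
    n_randomizations: int = 1000,
    seed: int = 0,
) -> dict:
    """Power under an injected attractant effect.

    A negative effect (detection highest at fresh bait) should put the
    attractant model first by AICc and classify day 1 as "increased"
    visitation.  Reports the rate of each over replicates.
    """
    rng = np.random.default_rng(seed)
    sp = dataclasses.replace(
        _calibration_species(effect_size), beta0=float(logit(0.15))
    )
    config = ScenarioConfig(n_stations=n_stations, species=[sp])
    aicc_first = 0
    day1_expected = 0
    sign_recovered = 0
    expected_class = "increased" if effect_size < 0 else "decreased"
    for r in range(n_reps):
        layout = generate_layout(config, rng)
        caps, _ = simulate_species_captures(sp, layout, rng)
        independent = filter_independent(caps)
        annotated = attach_refresh_times(independent, layout.refresh_events)
        dm = build_detection_matrix(annotated, layout.deployments, sp.name)
        covs = {
            "attractant_age": build_covariate_matrix(
                "attractant_age", layout.deployments, layout.refresh_events
            ),
            "total_effort": build_covariate_matrix(
                "total_effort", layout.deployments
            ),
            "incremental_effort": build_covariate_matrix(
                "incremental_effort", layout.deployments
            ),
        }
        table, fits = run_model_set(dm, covs, seed=int(rng.integers(2**31)))
        if "attractant_age" in table.iloc[0]["model"]:
            aicc_first += 1
        attract_fit = fits[ModelSpec(("attractant_age",)).name]
        if np.sign(attract_fit.beta_p[1]) == np.sign(effect_size):
            sign_recovered += 1
        res = run_permutation_test(
            sp.name, annotated, layout.deployments, layout.refresh_events,
            n_randomizations=n_randomizations,
            seed=int(rng.integers(2**31)),
        )
        if res.classification[0] == expected_class:
            day1_expected += 1
    return {
        "n_reps": n_reps,
        "effect_size": effect_size,
        "aicc_attract_first_rate": aicc_first / n_reps,
        "slope_sign_recovery_rate": sign_recovered / n_reps,
        "day1_classification_rate": day1_expected / n_reps,
        "expected_day1_class": expected_class,
    }


# ---------------------------------------------------------------------------
# Circular-density diagnostics
# ---------------------------------------------------------------------------


def density_diagnostics(seed: int = 0) -> dict:
    """Flatness under uniform input, normalization, and fit-sample-refit
    stability of the activity-density estimator."""
    # uniform limit: equally spaced times are the deterministic realization
    # of a uniform diel pattern
    uniform_times = np.arange(1000) * (24.0 / 1000.0)
    dens_u = fit_activity(uniform_times)
    uniform_height = 1.0 / TWO_PI
    flatness = float(np.max(np.abs(dens_u.grid - uniform_height)))

    def trapz_integral(d):
        g = np.append(d.grid, d.grid[0])
        return float(np.trapezoid(g, dx=TWO_PI / len(d.grid)))

    # a clustered nocturnal pattern, refit from its own samples
    rng = np.random.default_rng(seed)
    times = (rng.vonmises(1.0 * TWO_PI / 24.0, 4.0, size=500) % TWO_PI) * (
        24.0 / TWO_PI
    )
    dens = fit_activity(times)
    draws = sample_times(dens, 10_000, int(rng.integers(2**31)))
    refit = fit_activity(draws)
    sup_dist = float(np.max(np.abs(dens.grid - refit.grid)))
    return {
        "uniform_flatness_max_dev_frac": flatness / uniform_height,
        "integral_uniform": trapz_integral(dens_u),
        "integral_clustered": trapz_integral(dens),
        "fit_sample_refit_sup_dist": sup_dist,
    }
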