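"""Single-season occupancy models with detection covariates, AICc selection,
and delta-method detection curves.

The model is the standard zero-inflated detection-history likelihood: each
station i is occupied with probability psi; conditional on occupancy, the
species is detected on occasion j with probability p_ij, independently
across occasions.  Occupancy is held constant (intercept only) and detection
is modelled on the logit scale,

    logit(psi) = b_psi,      logit(p_ij) = b0 + sum_t b_t x_tij,

where x_t are observation-level covariates: attractant age (days since the
most recent refresh), incremental effort (active days accrued), and total
effort (trap-days per station, constant within a station).  The site
likelihood is

    L_i = psi * prod_j p_ij^y_ij (1 - p_ij)^(1 - y_ij)
          + (1 - psi) * 1{all y_ij = 0},

with the product over non-missing occasions only.  Models are ranked by
AICc with the number of stations as the effective sample size.

Covariates are z-scored internally for optimisation and the estimates and
covariance are mapped back to the natural scale for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .event_processing import CovariateMatrix, DetectionMatrix

__all__ = [
    "ModelSpec",
    "OccupancyFit",
    "neg_log_likelihood",
    "fit",
    "aicc",
    "run_model_set",
    "predict_detection",
    "STANDARD_MODEL_SET",
]

_VALID_TERMS = ("attractant_age", "total_effort", "incremental_effort")

# null; each covariate univariately; attractant additively with each effort
STANDARD_MODEL_SET: tuple[tuple[str, ...], ...] = (
    (),
    ("attractant_age",),
    ("total_effort",),
    ("incremental_effort",),
    ("attractant_age", "total_effort"),
    ("attractant_age", "incremental_effort"),
)


@dataclass(frozen=True)
class ModelSpec:
    """Constant-occupancy model with additive detection terms (no interactions)."""

    detection_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        terms = tuple(self.detection_terms)
        object.__setattr__(self, "detection_terms", terms)
        bad = [t for t in terms if t not in _VALID_TERMS]
        if bad:
            raise ValueError(f"unknown detection term(s) {bad}")
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate detection terms")

    @property
    def n_params(self) -> int:
        return 2 + len(self.detection_terms)

    @property
    def name(self) -> str:
        det = " + ".join(self.detection_terms) if self.detection_terms else "."
        return f"psi(.) p({det})"


@dataclass
class OccupancyFit:
    """Maximum-likelihood fit of one occupancy model specification."""

    spec: ModelSpec
    beta_psi: float
    beta_p: np.ndarray          # intercept + one coefficient per term (natural scale)
    se: np.ndarray              # SEs aligned with [beta_psi, *beta_p]
    cov: np.ndarray             # full covariance, natural scale
    loglik: float
    n_sites: int
    converged: bool
    message: str = ""

    @property
    def K(self) -> int:
        return self.spec.n_params

    @property
    def AICc(self) -> float:
        return aicc(self.loglik, self.K, self.n_sites)

    @property
    def psi_hat(self) -> float:
        return float(expit(self.beta_psi))

    def coefficients(self) -> pd.DataFrame:
        names = ["beta_psi", "p_intercept", *self.spec.detection_terms]
        est = np.concatenate([[self.beta_psi], self.beta_p])
        z = np.where(self.se > 0, est / self.se, np.nan)
        pval = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"term": names, "estimate": est, "se": self.se, "z": z, "p_value": pval}
        )


def _design(
    covariates: dict[str, CovariateMatrix], spec: ModelSpec, shape: tuple[int, int]
) -> np.ndarray:
    """Stack the spec's covariates into an (n_terms, S, J) array."""
    mats = []
    for term in spec.detection_terms:
        if term not in covariates:
            raise ValueError(f"covariate {term!r} not supplied")
        x = covariates[term].x
        if x.shape != shape:
            raise ValueError(f"covariate {term!r} misaligned with detection matrix")
        mats.append(x)
    if not mats:
        return np.empty((0, *shape))
    return np.stack(mats)


def neg_log_likelihood(
    params: np.ndarray,
    detection_matrix: DetectionMatrix,
    covariates: dict[str, CovariateMatrix],
    spec: ModelSpec,
) -> float:
    """Negative log-likelihood at params = [b_psi, b0, b_t...] (natural scale)."""
    params = np.asarray(params, dtype=float)
    if params.size != spec.n_params:
        raise ValueError(f"expected {spec.n_params} parameters, got {params.size}")
    y = detection_matrix.y
    obs = detection_matrix.observed
    X = _design(covariates, spec, y.shape)
    if X.size and not np.all(np.isfinite(X[:, obs])):
        raise ValueError("non-finite covariate value in a non-missing cell")
    return _nll_arrays(params, y, obs, X)


def _nll_arrays(
    params: np.ndarray, y: np.ndarray, obs: np.ndarray, X: np.ndarray
) -> float:
    b_psi, b0 = params[0], params[1]
    eta = np.full(y.shape, b0)
    for t in range(X.shape[0]):
        eta = eta + params[2 + t] * np.where(obs, X[t], 0.0)
    # Bernoulli log-density per cell, numerically stable via log1p(exp(.))
    # log p = eta - log(1 + e^eta); log(1-p) = -log(1 + e^eta)
    log1pe = np.logaddexp(0.0, eta)
    cell = np.where(obs, np.where(np.nan_to_num(y) > 0, eta, 0.0) - log1pe, 0.0)
    cond_ll = cell.sum(axis=1)                      # log P(history | occupied)
    all_zero = np.nansum(np.where(obs, y, 0.0), axis=1) == 0
    log_psi = -np.logaddexp(0.0, -b_psi)
    log_1mpsi = -np.logaddexp(0.0, b_psi)
    with np.errstate(divide="ignore"):
        site_ll = np.where(
            all_zero,
            np.logaddexp(log_psi + cond_ll, log_1mpsi),
            log_psi + cond_ll,
        )
    return float(-site_ll.sum())


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.zeros((k, k))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


def fit(
    detection_matrix: DetectionMatrix,
    covariates: dict[str, CovariateMatrix] | None = None,
    spec: ModelSpec = ModelSpec(),
    n_starts: int = 5,
    seed: int = 0,
    gtol: float = 1e-8,
) -> OccupancyFit:
    """Maximise the occupancy likelihood from multiple starts.

    Covariates are z-scored internally; estimates, SEs and the covariance
    are reported on the natural scale.  Standard errors come from the
    inverse numerical Hessian at the optimum.  The converged flag is honest:
    boundary estimates and singular Hessians clear it.
    """
    covariates = covariates or {}
    y = detection_matrix.y
    obs = detection_matrix.observed
    n_sites = len(detection_matrix.station_ids)
    X = _design(covariates, spec, y.shape)
    if X.size and not np.all(np.isfinite(X[:, obs])):
        raise ValueError("non-finite covariate value in a non-missing cell")

    # z-score each covariate over observed cells for optimisation conditioning
    n_terms = X.shape[0]
    mu = np.zeros(n_terms)
    sd = np.ones(n_terms)
    Xs = X.copy()
    for t in range(n_terms):
        vals = X[t][obs]
        mu[t] = vals.mean()
        sd[t] = vals.std() if vals.std() > 0 else 1.0
        Xs[t] = (X[t] - mu[t]) / sd[t]

    n_detected = int((np.nansum(np.where(obs, y, 0.0), axis=1) > 0).sum())
    warn = ""
    if n_detected == 0:
        warn = "no detections: occupancy and detection are non-identifiable"
    elif n_detected == n_sites and not np.any(np.where(obs, y, 1.0) == 0):
        warn = "all histories saturated: estimates at the boundary"

    def objective(theta: np.ndarray) -> float:
        return _nll_arrays(theta, y, obs, Xs)

    k = spec.n_params
    rng = np.random.default_rng(seed)
    naive_occ = np.clip(n_detected / max(n_sites, 1), 0.05, 0.95)
    naive_det = np.clip(
        np.nansum(np.where(obs, y, 0.0)) / max(obs.sum(), 1), 0.02, 0.98
    )
    starts = [np.concatenate([[logit(naive_occ), logit(naive_det)], np.zeros(k - 2)])]
    for _ in range(n_starts - 1):
        starts.append(rng.normal(scale=1.0, size=k))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B",
            options={"gtol": gtol, "ftol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    theta = best.x
    converged = bool(best.success) and not warn

    H = _numerical_hessian(objective, theta)
    se_std = np.full(k, np.nan)
    cov_std = np.full((k, k), np.nan)
    try:
        cov_std = np.linalg.inv(H)
        diag = np.diag(cov_std)
        if np.all(diag > 0):
            se_std = np.sqrt(diag)
        else:
            converged = False
    except np.linalg.LinAlgError:
        converged = False

    # map standardized-scale detection coefficients back to natural scale:
    # b_t = b_t_std / sd_t;  b0 = b0_std - sum_t b_t_std * mu_t / sd_t
    J = np.eye(k)
    for t in range(n_terms):
        J[1, 2 + t] = -mu[t] / sd[t]
        J[2 + t, 2 + t] = 1.0 / sd[t]
    theta_nat = J @ theta
    cov_nat = J @ cov_std @ J.T
    se_nat = np.sqrt(np.clip(np.diag(cov_nat), 0.0, np.inf))

    return OccupancyFit(
        spec=spec,
        beta_psi=float(theta_nat[0]),
        beta_p=theta_nat[1:].copy(),
        se=se_nat,
        cov=cov_nat,
        loglik=float(-best.fun),
        n_sites=n_sites,
        converged=converged,
        message=warn or best.message,
    )


def aicc(loglik: float, K: int, n_sites: int) -> float:
    """AICc = -2 loglik + 2K + 2K(K+1)/(n - K - 1); n is the station count."""
    if n_sites - K - 1 <= 0:
        raise ValueError(
            f"AICc undefined: n_sites={n_sites} must exceed K+1={K + 1}"
        )
    return -2.0 * loglik + 2.0 * K + 2.0 * K * (K + 1) / (n_sites - K - 1)


def run_model_set(
    detection_matrix: DetectionMatrix,
    covariates: dict[str, CovariateMatrix],
    model_set: Sequence[tuple[str, ...]] = STANDARD_MODEL_SET,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, OccupancyFit]]:
    """Fit the model set, rank by AICc, and tabulate coefficients.

    Returns the selection table (one row per model, best first) and the
    fitted models keyed by model name.
    """
    fits: dict[str, OccupancyFit] = {}
    rows = []
    for terms in model_set:
        spec = ModelSpec(detection_terms=tuple(terms))
        f = fit(detection_matrix, covariates, spec, seed=seed)
        fits[spec.name] = f
        coefs = f.coefficients()
        sig_terms = coefs.loc[
            coefs.term.isin(spec.detection_terms) & (coefs.p_value < 0.05), "term"
        ]
        rows.append(
            {
                "model": spec.name,
                "K": f.K,
                "loglik": f.loglik,
                "AICc": f.AICc,
                "psi_hat": f.psi_hat,
                "converged": f.converged,
                "significant_terms": ";".join(sig_terms),
            }
        )
    table = pd.DataFrame(rows).sort_values("AICc", kind="stable").reset_index(drop=True)
    table["delta_AICc"] = table["AICc"] - table["AICc"].iloc[0]
    return table, fits


def predict_detection(
    fit_result: OccupancyFit,
    covariate_grid: pd.DataFrame | dict[str, np.ndarray],
    level: float = 0.95,
) -> pd.DataFrame:
    """Detection probability over a covariate grid with delta-method CIs.

    The CI is computed on the logit scale from the coefficient covariance
    and transformed, so endpoints always bracket the point estimate inside
    (0, 1).
    """
    grid = pd.DataFrame(covariate_grid)
    terms = fit_result.spec.detection_terms
    missing = [t for t in terms if t not in grid.columns]
    if missing:
        raise ValueError(f"covariate grid missing column(s) {missing}")
    n = len(grid)
    Xg = np.column_stack([np.ones(n)] + [grid[t].to_numpy(float) for t in terms])
    beta = fit_result.beta_p
    eta = Xg @ beta
    # detection block of the covariance (skip the occupancy intercept)
    cov_p = fit_result.cov[1:, 1:]
    var_eta = np.einsum("ij,jk,ik->i", Xg, cov_p, Xg)
    se_eta = np.sqrt(np.clip(var_eta, 0.0, np.inf))
    zcrit = stats.norm.ppf(0.5 + level / 2)
    out = grid.copy()
    out["p_hat"] = expit(eta)
    out["lo"] = expit(eta - zcrit * se_eta)
    out["hi"] = expit(eta + zcrit * se_eta)
    return out
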