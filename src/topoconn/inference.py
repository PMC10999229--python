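"""Longitudinal statistical chain.

Behavioral standardization against baseline norms (with sign inversion for
reaction-time domains), change-score residualization on baseline, nuisance
(scrubbing) removal, OLS with standardized betas / raw-coefficient CIs /
partial eta-squared, per-domain Benjamini-Hochberg FDR families, joint-row
permutation tests, percentile-bootstrap mediation (product-of-coefficients
ACME), and exhaustive best-subset BIC model selection.

Conventions:

* standardized beta = raw coefficient * SD(predictor) / SD(outcome);
* CIs are on the raw-coefficient scale (t distribution);
* partial eta-squared = t^2 / (t^2 + residual df), which equals
  SS_effect / (SS_effect + SS_error) for a single-df OLS term;
* permutation p is the literal ratio count(null >= observed) / n_perm, so
  the minimum attainable p is 0; an optional (+1)/(N+1) correction exists;
* ACME bootstrap p is the two-sided percentile position of 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg as sla
from statsmodels.stats.multitest import multipletests

from .errors import (
    CollinearityError,
    DegenerateMediatorError,
    DegenerateScaleError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "ModelResult",
    "MediationResult",
    "standardize_behavior",
    "residualize_on_baseline",
    "remove_scrubbing",
    "fit_model",
    "fdr_family",
    "permutation_test",
    "mediation_bootstrap",
    "bic_search",
]


# --------------------------------------------------------------------------
# standardization and residualization


def standardize_behavior(scores, baseline_mean, baseline_sd, is_speed=False):
    """z-score raw task scores against the baseline norms.

    Follow-up scores use the *baseline* mean/SD, so their mean is generally
    nonzero.  For speed (reaction-time) tasks the z score is sign-inverted so
    higher always means better performance.
    """
    if baseline_sd <= 0:
        raise DegenerateScaleError(f"baseline SD must be positive, got {baseline_sd}")
    z = (np.asarray(scores, dtype=float) - baseline_mean) / baseline_sd
    return -z if is_speed else z


def residualize_on_baseline(change, baseline):
    """Residuals of an OLS fit of change scores on intercept + baseline.

    A constant baseline carries no information; the centered change is
    returned with a warning in that case.
    """
    change = np.asarray(change, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if change.shape != baseline.shape:
        raise InvalidParameterError("change and baseline must have equal length")
    if len(change) < 3:
        raise InsufficientDataError("need at least 3 observations to residualize")
    if np.ptp(baseline) == 0:
        warnings.warn(
            "baseline is constant; returning centered change", stacklevel=2
        )
        return change - change.mean()
    x = np.column_stack([np.ones_like(baseline), baseline])
    beta, *_ = np.linalg.lstsq(x, change, rcond=None)
    return change - x @ beta


def remove_scrubbing(measure, scrubbing):
    """Remove variance attributable to mean scrubbing from a brain measure.

    Mechanically identical to :func:`residualize_on_baseline` with the
    scrubbing covariate in place of baseline.
    """
    return residualize_on_baseline(measure, scrubbing)


# --------------------------------------------------------------------------
# OLS with standardized betas


@dataclass
class ModelResult:
    """Per-model regression output in the shape of a results-table row block.

    ``params`` is indexed by predictor name with columns
    ``coef, beta_std, ci_low, ci_high, p, eta_p2`` (``fdr_p`` is attached by
    the family-level correction, not here).
    """

    outcome: str
    n: int
    params: pd.DataFrame
    r2: float
    adj_r2: float
    bic: float
    fvalue: float
    f_pvalue: float
    df_resid: float


def _design(predictors: pd.DataFrame) -> pd.DataFrame:
    x = sm.add_constant(predictors.astype(float), has_constant="add")
    return x


def _check_rank(x: pd.DataFrame) -> None:
    arr = x.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns via pivoted QR
        _, _, piv = sla.qr(arr, mode="economic", pivoting=True)
        bad = [x.columns[i] for i in piv[rank:]]
        raise CollinearityError(
            f"design matrix is rank deficient; dependent columns: {bad}", bad
        )


def fit_model(outcome, predictors: pd.DataFrame, outcome_name: str = "y") -> ModelResult:
    """OLS of an outcome on named predictor columns (intercept added).

    Raises
    ------
    InsufficientDataError
        If n <= number of predictors + 1.
    CollinearityError
        If the design matrix is rank deficient (offending columns named).
    """
    y = np.asarray(outcome, dtype=float)
    if len(y) != len(predictors):
        raise InvalidParameterError("outcome and predictors differ in length")
    keep = np.isfinite(y) & np.isfinite(predictors.to_numpy(dtype=float)).all(axis=1)
    y = y[keep]
    predictors = predictors.loc[keep]
    if len(y) <= predictors.shape[1] + 1:
        raise InsufficientDataError(
            f"n={len(y)} too small for {predictors.shape[1]} predictors"
        )
    x = _design(predictors)
    _check_rank(x)
    fit = sm.OLS(y, x).fit()
    sd_y = y.std(ddof=1)
    rows = []
    ci = fit.conf_int(alpha=0.05)
    for name in predictors.columns:
        coef = fit.params[name]
        t = fit.tvalues[name]
        sd_x = predictors[name].to_numpy().std(ddof=1)
        rows.append(
            {
                "coef": coef,
                "beta_std": coef * sd_x / sd_y if sd_y > 0 else np.nan,
                "ci_low": ci.loc[name, 0],
                "ci_high": ci.loc[name, 1],
                "p": fit.pvalues[name],
                "eta_p2": t * t / (t * t + fit.df_resid),
            }
        )
    params = pd.DataFrame(rows, index=list(predictors.columns))
    return ModelResult(
        outcome=outcome_name,
        n=int(len(y)),
        params=params,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        bic=float(fit.bic),
        fvalue=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_resid=float(fit.df_resid),
    )


# --------------------------------------------------------------------------
# multiple testing


def fdr_family(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up correction over one family of hypotheses.

    Returns ``(adjusted_p, reject)`` aligned with the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InvalidParameterError("empty p-value family")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


# --------------------------------------------------------------------------
# permutation test


def permutation_test(
    outcome,
    predictors: pd.DataFrame,
    target: str,
    n_perm: int = 10000,
    seed: int = 0,
    add_one: bool = False,
) -> float:
    """Permutation p-value for one predictor's standardized beta.

    Whole rows of the predictor block are shuffled jointly against the
    outcome (within-row predictor assignment preserved); the statistic is
    the absolute standardized beta of ``target``.  p is the fraction of
    permutations whose null statistic meets or exceeds the observed one
    (``add_one`` switches to the (+1)/(N+1) convention).
    """
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    if target not in predictors.columns:
        raise InvalidParameterError(f"target {target!r} not among predictors")
    y = np.asarray(outcome, dtype=float)
    x = _design(predictors)
    _check_rank(x)
    arr = x.to_numpy()
    pinv = np.linalg.pinv(arr)
    t_idx = list(x.columns).index(target)
    sd_x = predictors[target].to_numpy().std(ddof=1)
    sd_y = y.std(ddof=1)
    scale = sd_x / sd_y

    observed = abs((pinv @ y)[t_idx]) * scale
    rng = np.random.default_rng(seed)
    n = len(y)
    count = 0
    y_inv = np.empty_like(y)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        # permuting predictor rows by `perm` equals applying the inverse
        # permutation to the outcome; reuse the fixed pseudoinverse
        y_inv[perm] = y
        stat = abs((pinv @ y_inv)[t_idx]) * scale
        if stat >= observed:
            count += 1
    if add_one:
        return (count + 1) / (n_perm + 1)
    return count / n_perm


# --------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    """Percentile-bootstrap mediation decomposition.

    ``acme`` is the product-of-coefficients indirect effect (path a * path
    b); ``direct`` the exposure effect adjusting for the mediator; ``total``
    their sum (exact for nested OLS).  CIs are percentile 95% intervals over
    participant resamples.
    """

    acme: float
    acme_ci: tuple
    acme_p: float
    direct: float
    direct_ci: tuple
    total: float
    total_ci: tuple
    proportion: float
    proportion_ci: tuple
    n: int
    n_boot: int
    seed: int


def _batched_coef(x: np.ndarray, y: np.ndarray, idx: np.ndarray, col: int) -> np.ndarray:
    """Coefficient ``col`` of OLS fits over bootstrap index matrix ``idx``."""
    out = np.empty(idx.shape[0])
    chunk = 512
    for s in range(0, idx.shape[0], chunk):
        ii = idx[s : s + chunk]
        xb = x[ii]  # (c, n, p)
        yb = y[ii]  # (c, n)
        g = np.einsum("cni,cnj->cij", xb, xb)
        h = np.einsum("cni,cn->ci", xb, yb)
        out[s : s + chunk] = np.linalg.solve(g, h[..., None])[:, col, 0]
    return out


def _percentile_p(boot: np.ndarray) -> float:
    """Two-sided percentile position of zero in a bootstrap distribution."""
    lo = np.mean(boot < 0)
    hi = np.mean(boot > 0)
    return float(min(1.0, 2.0 * min(lo, hi)))


def mediation_bootstrap(
    x,
    mediator,
    y,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 10000,
    seed: int = 0,
) -> MediationResult:
    """Three-step percentile-bootstrap mediation with fixed covariates.

    Step 1 fits ``mediator ~ x + covariates`` (path a); step 2 fits
    ``y ~ x + mediator + covariates`` (direct path c' and path b); the total
    effect comes from ``y ~ x + covariates``.  Participants are resampled
    with replacement as whole rows; 95% CIs are percentile intervals.
    """
    x = np.asarray(x, dtype=float)
    mediator = np.asarray(mediator, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = (
        covariates.to_numpy(dtype=float)
        if covariates is not None and covariates.shape[1] > 0
        else np.empty((len(x), 0))
    )
    keep = (
        np.isfinite(x)
        & np.isfinite(mediator)
        & np.isfinite(y)
        & np.isfinite(cov).all(axis=1)
    )
    x, mediator, y, cov = x[keep], mediator[keep], y[keep], cov[keep]
    n = len(x)
    if n < 30:
        raise InsufficientDataError(f"mediation requires n >= 30 complete cases, got {n}")
    if mediator.std() == 0:
        raise DegenerateMediatorError("mediator has zero variance")
    ones = np.ones((n, 1))
    xa = np.column_stack([ones, x[:, None], cov])  # mediator model
    xb = np.column_stack([ones, x[:, None], mediator[:, None], cov])  # outcome model
    xc = xa  # total-effect model shares the design of the mediator model

    def _coef(design, target, col):
        beta, *_ = np.linalg.lstsq(design, target, rcond=None)
        return beta[col]

    a = _coef(xa, mediator, 1)
    b = _coef(xb, y, 2)
    cprime = _coef(xb, y, 1)
    total = _coef(xc, y, 1)
    acme = a * b

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    a_b = _batched_coef(xa, mediator, idx, 1)
    beta_full = np.empty((n_boot, xb.shape[1]))
    chunk = 512
    for s in range(0, n_boot, chunk):
        ii = idx[s : s + chunk]
        g = np.einsum("cni,cnj->cij", xb[ii], xb[ii])
        h = np.einsum("cni,cn->ci", xb[ii], y[ii])
        beta_full[s : s + chunk] = np.linalg.solve(g, h[..., None])[..., 0]
    b_b = beta_full[:, 2]
    c_b = beta_full[:, 1]
    acme_b = a_b * b_b
    total_b = acme_b + c_b  # exact OLS identity replicate-wise
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_b = np.where(total_b != 0, acme_b / total_b, np.nan)

    def _ci(v):
        v = v[np.isfinite(v)]
        return tuple(np.percentile(v, [2.5, 97.5]))

    return MediationResult(
        acme=float(acme),
        acme_ci=_ci(acme_b),
        acme_p=_percentile_p(acme_b),
        direct=float(cprime),
        direct_ci=_ci(c_b),
        total=float(total),
        total_ci=_ci(total_b),
        proportion=float(acme / total) if total != 0 else np.nan,
        proportion_ci=_ci(prop_b),
        n=n,
        n_boot=n_boot,
        seed=seed,
    )


# --------------------------------------------------------------------------
# exhaustive BIC model search


def bic_search(outcome, candidates: pd.DataFrame, outcome_name: str = "y"):
    """Fit every non-empty predictor subset and rank ascending by BIC.

    Seven candidates yield 2^7 - 1 = 127 models.  Returns ``(table,
    winner)`` where ``table`` has one row per subset (predictors, k, bic,
    r2, adj_r2) sorted by BIC and ``winner`` is the full
    :class:`ModelResult` of the best model.
    """
    if candidates.shape[1] < 1:
        raise InvalidParameterError("at least one candidate predictor required")
    y = np.asarray(outcome, dtype=float)
    keep = np.isfinite(y) & np.isfinite(candidates.to_numpy(dtype=float)).all(axis=1)
    y = y[keep]
    candidates = candidates.loc[keep]
    if len(y) <= candidates.shape[1] + 1:
        raise InsufficientDataError(
            f"n={len(y)} too small for the largest subset "
            f"({candidates.shape[1]} predictors)"
        )
    names = list(candidates.columns)
    rows = []
    fits = {}
    for k in range(1, len(names) + 1):
        for subset in combinations(names, k):
            res = fit_model(y, candidates[list(subset)], outcome_name)
            fits[subset] = res
            rows.append(
                {
                    "predictors": "+".join(subset),
                    "k": k,
                    "bic": res.bic,
                    "r2": res.r2,
                    "adj_r2": res.adj_r2,
                }
            )
    table = pd.DataFrame(rows).sort_values("bic", kind="mergesort").reset_index(drop=True)
    winner = fits[tuple(table.loc[0, "predictors"].split("+"))]
    return table, winner
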