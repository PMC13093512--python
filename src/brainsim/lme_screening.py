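"""Cognitive score preprocessing and per-feature linear mixed-effects
screening of longitudinal cognition with Benjamini-Hochberg FDR control.

The screening model for a feature x and outcome y (z-scored) is

    y_it = b0 + b1 x_it + b2 t + b3 (x_it * t) + covariates + u_i + e_it

with a per-subject random intercept u_i ~ N(0, tau^2) and residual
e ~ N(0, sigma^2), fit by maximum likelihood so that log-likelihoods are
comparable across fixed-effect specifications.  The quantity of interest is
the feature-by-time interaction b3 (does the feature predict the slope of
cognitive change), tested with a Wald z-test and corrected across the
feature family with BH-FDR.

Because edgewise screening needs thousands of model fits, the random-
intercept model is fit with a dedicated profiled-likelihood routine: for a
given variance ratio psi = tau^2/sigma^2 the GLS estimates and the residual
variance have closed forms, leaving a one-dimensional concave-profile search
over psi.  This is exact ML for the random-intercept model (and is verified
against a general mixed-model implementation in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age", "sex", "education")


# ---------------------------------------------------------------------------
# score preprocessing
# ---------------------------------------------------------------------------

def zscore_cognition(
    raw: pd.DataFrame,
    columns: list[str],
    invert: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Z-score cognitive columns against the cohort mean/SD; tests listed in
    ``invert`` are negated first so that higher always means better."""
    out = raw.copy()
    for col in columns:
        vals = out[col].astype(float)
        if col in invert:
            vals = -vals
        sd = vals.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot z-score")
        out[col] = (vals - vals.mean()) / sd
    return out


def compose_pacc(scores: pd.DataFrame, components: list[str]) -> pd.Series:
    """Preclinical Alzheimer Cognitive Composite: per-row mean of already
    standardized component columns; rows missing a component use the rest."""
    if len(components) < 2:
        raise ValueError("PACC needs at least two component columns")
    sub = scores[components]
    n_missing = int(sub.isna().any(axis=1).sum())
    if n_missing:
        logger.info("PACC: %d rows with at least one missing component", n_missing)
    return sub.mean(axis=1, skipna=True).rename("pacc")


# ---------------------------------------------------------------------------
# random-intercept LME by profiled maximum likelihood
# ---------------------------------------------------------------------------

@dataclass
class LMEFit:
    """ML fit of a linear model with a per-subject random intercept."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglik: float
    sigma2: float          # residual variance
    tau2: float            # random-intercept variance
    r2_marginal: float     # fixed-effect variance / total (Nakagawa-Schielzeth)
    r2_conditional: float  # (fixed + random-intercept variance) / total
    nobs: int
    n_groups: int
    converged: bool = True


def _group_index(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted group codes and the start offsets of each group block."""
    codes, _ = pd.factorize(groups)
    order = np.argsort(codes, kind="stable")
    starts = np.flatnonzero(np.r_[1, np.diff(codes[order])])
    return order, starts


def fit_random_intercept_lme(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    param_names: list[str] | None = None,
) -> LMEFit:
    """Exact ML for ``y = X beta + u_group + e`` via the profiled likelihood.

    For psi = tau^2/sigma^2 the marginal covariance per group is
    sigma^2 (I + psi J); its inverse is I - psi/(1 + psi n_g) J, so the GLS
    normal equations reduce to group-sum corrections of X'X and X'y, and the
    profile log-likelihood is a smooth scalar function of psi maximized
    numerically (with the psi = 0 boundary checked explicitly).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient (degenerate predictor?)")
    order, starts = _group_index(np.asarray(groups))
    ys = y[order]
    Xs = X[order]
    sizes = np.diff(np.r_[starts, n]).astype(float)
    Gx = np.add.reduceat(Xs, starts, axis=0)      # per-group column sums of X
    Gy = np.add.reduceat(ys, starts)              # per-group sums of y
    XtX = Xs.T @ Xs
    Xty = Xs.T @ ys
    yty = float(ys @ ys)

    def gls(psi: float):
        c = psi / (1.0 + psi * sizes)             # shrink factor per group
        A = XtX - (Gx * c[:, None]).T @ Gx
        b = Xty - Gx.T @ (c * Gy)
        quad_y = yty - float(c @ (Gy**2))
        beta = np.linalg.solve(A, b)
        rss = quad_y - float(beta @ b)
        rss = max(rss, 1e-300)
        logdet = float(np.sum(np.log1p(psi * sizes)))
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
        return ll, beta, sigma2, A

    def neg_profile(theta: float) -> float:
        return -gls(np.exp(theta))[0]

    res = optimize.minimize_scalar(neg_profile, bounds=(-14.0, 14.0), method="bounded")
    candidates = [(gls(0.0)[0], 0.0), (-res.fun, float(np.exp(res.x)))]
    ll, psi = max(candidates)
    ll, beta, sigma2, A = gls(psi)
    tau2 = psi * sigma2

    # small-sample Wald inference: degrees-of-freedom-corrected residual
    # variance and a t reference with n - p df (the ML plug-in variance with
    # a normal reference is anticonservative in the far tails at screening
    # scale, which matters when thousands of edges share one FDR family)
    df_resid = max(n - p, 1)
    cov_beta = sigma2 * (n / df_resid) * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(z), df_resid)

    fitted_fixed = X @ beta
    var_f = float(np.var(fitted_fixed))
    total = var_f + tau2 + sigma2
    names = param_names or [f"x{i}" for i in range(p)]
    return LMEFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        loglik=float(ll),
        sigma2=float(sigma2),
        tau2=float(tau2),
        r2_marginal=var_f / total,
        r2_conditional=(var_f + tau2) / total,
        nobs=n,
        n_groups=len(starts),
        converged=bool(getattr(res, "success", True)),
    )


def _build_design(
    data: pd.DataFrame,
    predictors: list[str],
    covariates: tuple[str, ...],
    tiv_adjust: bool,
) -> tuple[np.ndarray, list[str]]:
    """[1, predictor..., time, predictor*time..., covariates (+ tiv)]."""
    t = data["visit_time"].to_numpy(dtype=float)
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for pname in predictors:
        cols.append(data[pname].to_numpy(dtype=float))
        names.append(pname)
    cols.append(t)
    names.append("time")
    for pname in predictors:
        cols.append(data[pname].to_numpy(dtype=float) * t)
        names.append(f"{pname}:time")
    cov_list = list(covariates) + (["tiv"] if tiv_adjust else [])
    for cname in cov_list:
        v = data[cname].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:  # constant covariate: absorbed by the intercept
            continue
        cols.append((v - v.mean()) / sd)
        names.append(cname)
    return np.column_stack(cols), names


@dataclass
class EdgeScreenResult:
    feature_id: str
    beta_interaction: float
    se_interaction: float
    p_interaction: float
    q_value: float = np.nan
    r_squared: float = np.nan          # marginal R^2
    r_squared_conditional: float = np.nan
    loglik: float = np.nan
    converged: bool = True
    significant: bool = False


def fit_interaction_lme(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    tiv_adjust: bool = False,
) -> EdgeScreenResult:
    """Fit the screening model for one feature and return its interaction term.

    ``data`` is long-format with ``subject_id`` and ``visit_time`` columns;
    rows with missing values in any used column are dropped.  A baseline-only
    predictor (constant within subject) simply enters as a time-constant
    covariate interacting with time.
    """
    used = ["subject_id", "visit_time", outcome, predictor, *covariates]
    if tiv_adjust:
        used.append("tiv")
    frame = data[used].dropna()
    if frame.empty:
        raise ValueError("no complete rows to fit")
    if frame[predictor].std() == 0:
        raise ValueError(f"predictor {predictor!r} is constant; interaction inestimable")
    X, names = _build_design(frame, [predictor], covariates, tiv_adjust)
    fit = fit_random_intercept_lme(
        frame[outcome].to_numpy(dtype=float), X, frame["subject_id"].to_numpy(), names
    )
    key = f"{predictor}:time"
    return EdgeScreenResult(
        feature_id=predictor,
        beta_interaction=float(fit.params[key]),
        se_interaction=float(fit.bse[key]),
        p_interaction=float(fit.pvalues[key]),
        r_squared=fit.r2_marginal,
        r_squared_conditional=fit.r2_conditional,
        loglik=fit.loglik,
        converged=fit.converged,
    )


# ---------------------------------------------------------------------------
# FDR and family-wise screening
# ---------------------------------------------------------------------------

def fdr_bh(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and significance mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


@dataclass
class ScreenSummary:
    marker_type: str
    outcome: str
    group: str
    results: list[EdgeScreenResult]
    alpha: float
    median_r2_significant: float = np.nan
    n_failed: int = 0
    extras: dict = field(default_factory=dict)

    @property
    def significant(self) -> list[EdgeScreenResult]:
        return [r for r in self.results if r.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_id": [r.feature_id for r in self.results],
                "outcome": self.outcome,
                "group": self.group,
                "marker_type": self.marker_type,
                "beta": [r.beta_interaction for r in self.results],
                "p": [r.p_interaction for r in self.results],
                "q": [r.q_value for r in self.results],
                "r2": [r.r_squared for r in self.results],
                "significant": [r.significant for r in self.results],
            }
        )


def screen_marker(
    data: pd.DataFrame,
    features: list[str],
    outcome: str,
    group: str = "",
    marker_type: str = "",
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
    tiv_adjust: bool = False,
) -> ScreenSummary:
    """Screen every feature of one marker family against one outcome.

    Each feature is fit independently; BH-FDR is applied within this family
    only (one family per marker-type x outcome x group, mirroring separate
    corrections per marker type).  Features whose fit fails are excluded
    from the family with a logged warning.
    """
    results: list[EdgeScreenResult] = []
    n_failed = 0
    for feat in features:
        try:
            results.append(
                fit_interaction_lme(data, outcome, feat, covariates, tiv_adjust)
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            logger.warning("feature %s excluded from FDR family: %s", feat, exc)
    if results:
        q, reject = fdr_bh(np.array([r.p_interaction for r in results]), alpha)
        for r, qv, sig in zip(results, q, reject):
            r.q_value = float(qv)
            r.significant = bool(sig)
    sig_r2 = [r.r_squared for r in results if r.significant]
    return ScreenSummary(
        marker_type=marker_type,
        outcome=outcome,
        group=group,
        results=results,
        alpha=alpha,
        median_r2_significant=float(np.median(sig_r2)) if sig_r2 else np.nan,
        n_failed=n_failed,
    )
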