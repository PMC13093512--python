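"""Pairwise nested-model comparison of two marker families.

For every pair (a, b) of screening-significant features from markers A and B
three random-intercept models are fit by maximum likelihood on identical
rows: a-only, b-only, and a full model containing both predictors and both
predictor-by-time interactions.  Likelihood-ratio tests of the full model
against each single-predictor model ask whether one feature adds predictive
information beyond the other; LRT p-values are BH-corrected within the
comparison family, and "A wins a pair" means the full model significantly
improves on the b-only model (A adds information beyond B).  Win frequencies
are then compared with a chi-squared test on the 2x2 wins/non-wins table, or
Fisher's exact test (reporting the odds ratio) when any expected cell count
is below five.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lme_screening import (
    DEFAULT_COVARIATES,
    _build_design,
    fdr_bh,
    fit_random_intercept_lme,
)

logger = logging.getLogger(__name__)


@dataclass
class PairwiseComparison:
    feature_a: str
    feature_b: str
    lrt_full_vs_a_only: float
    lrt_full_vs_b_only: float
    p_full_vs_a_only: float   # does B add beyond A?
    p_full_vs_b_only: float   # does A add beyond B?
    q_a: float = np.nan       # BH-adjusted p_full_vs_b_only (A's win test)
    q_b: float = np.nan       # BH-adjusted p_full_vs_a_only (B's win test)
    a_wins: bool = False
    b_wins: bool = False


@dataclass
class ComparisonSummary:
    marker_a: str
    marker_b: str
    wins_a: int
    wins_b: int
    n_pairs: int
    test_used: str            # "chi_squared" | "fisher"
    statistic: float | None
    odds_ratio: float | None
    p_value: float


def likelihood_ratio_test(
    full_loglik: float, reduced_loglik: float, df_diff: int
) -> tuple[float, float]:
    """LRT statistic 2*(ll_full - ll_reduced) (clipped at 0) and its
    chi-squared p-value with ``df_diff`` degrees of freedom."""
    stat = 2.0 * (full_loglik - reduced_loglik)
    if stat < -1e-6:
        logger.warning(
            "full-model log-likelihood below reduced (%.3g); statistic clipped "
            "- consider refitting", stat
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df_diff))
    return stat, p


def _fit_models(
    data: pd.DataFrame,
    feature_a: str,
    feature_b: str,
    outcome: str,
    covariates: tuple[str, ...],
    tiv_adjust: bool,
) -> tuple[float, float, float]:
    """Log-likelihoods of (a-only, b-only, full) on identical rows."""
    used = ["subject_id", "visit_time", outcome, feature_a, feature_b, *covariates]
    if tiv_adjust:
        used.append("tiv")
    frame = data[list(dict.fromkeys(used))].dropna()
    y = frame[outcome].to_numpy(dtype=float)
    groups = frame["subject_id"].to_numpy()
    lls = []
    specs = [[feature_a], [feature_b], [feature_a, feature_b]]
    for preds in specs:
        X, names = _build_design(frame, preds, covariates, tiv_adjust)
        lls.append(fit_random_intercept_lme(y, X, groups, names).loglik)
    return lls[0], lls[1], lls[2]


def compare_marker_pairs(
    data: pd.DataFrame,
    sig_a: list[str],
    sig_b: list[str],
    outcome: str,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
    tiv_adjust: bool = False,
    df_diff: int = 2,
) -> list[PairwiseComparison]:
    """All (a, b) pairs of significant features with two LRTs per pair.

    Each LRT has ``df_diff`` = 2 added fixed-effect terms (the extra
    predictor's main effect and its time interaction).  BH correction runs
    over all 2 * n_pairs LRT p-values of this comparison family.
    """
    if not sig_a or not sig_b:
        logger.info("empty significant set (A: %d, B: %d); no pairs", len(sig_a), len(sig_b))
        return []
    pairs: list[PairwiseComparison] = []
    for a, b in itertools.product(sig_a, sig_b):
        if a == b:
            continue
        try:
            ll_a, ll_b, ll_full = _fit_models(data, a, b, outcome, covariates, tiv_adjust)
        except (ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("pair (%s, %s) dropped: %s", a, b, exc)
            continue
        stat_vs_a, p_vs_a = likelihood_ratio_test(ll_full, ll_a, df_diff)
        stat_vs_b, p_vs_b = likelihood_ratio_test(ll_full, ll_b, df_diff)
        pairs.append(
            PairwiseComparison(
                feature_a=a,
                feature_b=b,
                lrt_full_vs_a_only=stat_vs_a,
                lrt_full_vs_b_only=stat_vs_b,
                p_full_vs_a_only=p_vs_a,
                p_full_vs_b_only=p_vs_b,
            )
        )
    if pairs:
        all_p = np.array(
            [p for pair in pairs for p in (pair.p_full_vs_b_only, pair.p_full_vs_a_only)]
        )
        q, reject = fdr_bh(all_p, alpha)
        for i, pair in enumerate(pairs):
            pair.q_a, pair.q_b = float(q[2 * i]), float(q[2 * i + 1])
            pair.a_wins, pair.b_wins = bool(reject[2 * i]), bool(reject[2 * i + 1])
    return pairs


def summarize_wins(
    pairs: list[PairwiseComparison],
    marker_a: str = "A",
    marker_b: str = "B",
) -> ComparisonSummary:
    """2x2 wins/non-wins table across the same pairs for both markers,
    tested with chi-squared, or Fisher's exact test (with OR) when any
    expected cell count is below five."""
    n_pairs = len(pairs)
    if n_pairs == 0:
        raise ValueError("cannot summarize zero pairs")
    wins_a = sum(p.a_wins for p in pairs)
    wins_b = sum(p.b_wins for p in pairs)
    table = np.array([[wins_a, n_pairs - wins_a], [wins_b, n_pairs - wins_b]])
    expected = stats.contingency.expected_freq(table) if table.sum() else np.zeros((2, 2))
    if (expected < 5).any():
        odds_ratio, p = stats.fisher_exact(table)
        return ComparisonSummary(
            marker_a, marker_b, wins_a, wins_b, n_pairs,
            "fisher", None, float(odds_ratio), float(p),
        )
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return ComparisonSummary(
        marker_a, marker_b, wins_a, wins_b, n_pairs,
        "chi_squared", float(chi2), None, float(p),
    )


def pairs_to_frame(pairs: list[PairwiseComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in pairs])
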