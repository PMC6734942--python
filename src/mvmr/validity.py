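"""Instrument-validity diagnostics for two-sample summary MVMR.

If every SNP is a valid instrument, each should imply the same causal
effects, so the residual heterogeneity of the MVMR regression should look
like sampling noise.  The adjusted Q statistic

    QA = sum_j (Gamma_j - (b1 pi_1j + ... + bK pi_Kj))^2 / sigma_Aj^2,
    sigma_Aj^2 = sigma_yj^2 + sum_k bk^2 sigma_kj^2
                 + 2 sum_{k<l} bk bl sigma_klj,

propagates the sampling uncertainty of the SNP-exposure estimates into the
weights, which makes QA asymptotically chi-square with L - K degrees of
freedom under the null of no pleiotropy — unlike the standard Cochran Q,
which weights by sigma_yj^2 alone and is over-dispersed.  The causal
estimates entering the weights are refreshed by "modified iterative"
weighting: alternate re-weighting and re-fitting until the estimates
stabilize.  Excess heterogeneity (large QA, small p) casts doubt on the
exclusion-restriction and exchangeability assumptions.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy import optimize, stats

from .datatypes import CovMode, EffectEstimate, SummaryDataset, TestStatistic
from .estimators import _wls_no_intercept, fit_mvmr_ivw
from .exceptions import (
    ConvergenceError,
    CovarianceValidityError,
    IdentificationError,
    ValidationError,
)

__all__ = ["q_validity", "q_standard", "chi2_critical"]

_MAX_ITER = 200
_TOL = 1e-8


def _cov_terms(summary: SummaryDataset, cov_mode):
    if cov_mode is None:
        cov_mode = CovMode.KNOWN if summary.cov_known else CovMode.ASSUMED_ZERO
    cov_mode = CovMode(cov_mode)
    K, L = summary.K, summary.L
    if cov_mode is CovMode.KNOWN:
        if not summary.cov_known:
            raise ValidationError(
                "cov_mode='known' requested but the dataset has no cross-exposure covariance"
            )
        pairs = [(k, l) for k in range(K) for l in range(k + 1, K)]
        cov = np.column_stack([summary.pair_cov(k, l) for k, l in pairs]) if pairs else np.zeros((L, 0))
    else:
        n_pairs = K * (K - 1) // 2
        cov = np.zeros((L, n_pairs))
        pairs = [(k, l) for k in range(K) for l in range(k + 1, K)]
    return cov, pairs, cov_mode


def _sigma_a2(beta: np.ndarray, summary: SummaryDataset, cov, pairs) -> np.ndarray:
    s = summary.var_gamma + summary.var_pi @ (beta**2)
    for idx, (k, l) in enumerate(pairs):
        s = s + 2.0 * beta[k] * beta[l] * cov[:, idx]
    return s


def q_validity(
    summary: SummaryDataset,
    cov_mode=None,
    init: Optional[EffectEstimate] = None,
    minimize: bool = False,
) -> TestStatistic:
    """Adjusted heterogeneity statistic QA for instrument validity.

    Starting from ``init`` (default: the multivariable IVW fit), alternately
    recompute the weights 1/sigma_Aj^2 at the current causal estimates and
    re-fit the no-intercept weighted regression of Gamma-hat on the pi-hat
    columns, until the estimates move by less than 1e-8.  With
    ``minimize=True`` the converged estimates are refined by directly
    minimizing QA over the causal effects (the fully analytical variant).
    """
    L, K = summary.L, summary.K
    if L < K + 1:
        raise IdentificationError(f"QA needs L >= K + 1 (L={L}, K={K})")
    if np.any(summary.var_gamma <= 0):
        raise ValidationError("outcome-side variance terms must be strictly positive")
    cov, pairs, cov_mode = _cov_terms(summary, cov_mode)
    P, g = summary.pi_hat, summary.gamma_hat

    beta = np.asarray((init or fit_mvmr_ivw(summary)).coef, dtype=float)[:K]
    for _ in range(_MAX_ITER):
        s = _sigma_a2(beta, summary, cov, pairs)
        if np.any(s <= 0):
            raise CovarianceValidityError("sigma_A^2 non-positive; covariances inconsistent")
        w = 1.0 / s
        new, _ = _wls_no_intercept(P, g, w)
        if np.max(np.abs(new - beta)) < _TOL:
            beta = new
            break
        beta = new
    else:
        raise ConvergenceError("modified-iterative weighting did not converge", last_iterate=beta)

    def qa_of(b: np.ndarray) -> float:
        s = _sigma_a2(b, summary, cov, pairs)
        if np.any(s <= 0):
            return np.inf
        return float(np.sum((g - P @ b) ** 2 / s))

    if minimize:
        res = optimize.minimize(qa_of, beta, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
        if qa_of(res.x) <= qa_of(beta):
            beta = np.asarray(res.x, dtype=float)

    s = _sigma_a2(beta, summary, cov, pairs)
    if np.any(s <= 0):
        raise CovarianceValidityError("sigma_A^2 non-positive at the converged estimates")
    per_snp = (g - P @ beta) ** 2 / s
    value = float(per_snp.sum())
    df = L - K
    return TestStatistic(
        name="q_validity",
        value=value,
        df=(df,),
        p_value=float(stats.chi2.sf(value, df)),
        per_snp=per_snp,
        nuisance={"beta": beta},
        cov_mode=cov_mode,
    )


def q_standard(summary: SummaryDataset, estimate: Optional[EffectEstimate] = None) -> TestStatistic:
    """Standard-weighted Cochran Q for the MVMR regression.

    Same residual sum as QA but weighted by 1/sigma_yj^2 only.  It ignores
    the sampling error of the SNP-exposure estimates, so it is over-dispersed
    relative to the chi-square reference and no p-value is attached; it is
    provided for comparison with :func:`q_validity`.
    """
    if estimate is None:
        estimate = fit_mvmr_ivw(summary)
    beta = np.asarray(estimate.coef, dtype=float)[: summary.K]
    if beta.size != summary.K:
        raise ValidationError("estimate must carry one coefficient per exposure")
    resid = summary.gamma_hat - summary.pi_hat @ beta
    per_snp = resid**2 / summary.var_gamma
    return TestStatistic(
        name="q_standard",
        value=float(per_snp.sum()),
        df=(summary.L - summary.K,),
        p_value=float("nan"),
        per_snp=per_snp,
        nuisance={"beta": beta},
    )


def chi2_critical(df: int, level: float) -> float:
    """Quantile of the chi-square reference distribution.

    ``chi2_critical(99, 0.95)`` is the 95% critical value used for the L=100
    under-identification tests (123.2).
    """
    if df < 1:
        raise ValidationError("df must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValidationError("level must lie strictly between 0 and 1")
    return float(stats.chi2.ppf(level, df))
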