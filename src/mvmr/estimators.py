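"""Causal-effect estimators for individual-level and summary data.

Individual-level: OLS (confounded benchmark) and classical two-stage least
squares (TSLS), with multiple endogenous exposures instrumented by the SNP
set.  Summary-level: the inverse-variance-weighted (IVW) combination of
per-SNP Wald ratios; its multivariable generalization, a no-intercept
weighted regression of the SNP-outcome effects on the SNP-exposure effects;
and MVMR-Egger, the same regression with an intercept after orienting each
SNP so its association with a chosen exposure is nonnegative.

Summary estimators use first-order weights 1/sigma_yj^2; the weighting that
also accounts for exposure-side uncertainty belongs to the Q diagnostics in
:mod:`mvmr.strength` and :mod:`mvmr.validity`.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .datatypes import EffectEstimate, IndividualDataset, SummaryDataset
from .exceptions import IdentificationError, RankError, ValidationError

__all__ = ["fit_ols", "fit_tsls", "fit_ivw", "fit_mvmr_ivw", "fit_mvmr_egger"]

logger = logging.getLogger(__name__)

_WALD_TOL = 1e-12


def _indices(idx, bound: int, default=None) -> np.ndarray:
    if idx is None:
        idx = default if default is not None else range(bound)
    arr = np.atleast_1d(np.asarray(idx, dtype=int))
    if arr.size == 0 or arr.min() < 0 or arr.max() >= bound:
        raise ValidationError(f"index set {arr.tolist()} out of bounds for size {bound}")
    return arr


def _solve_ls(A: np.ndarray, y: np.ndarray, what: str):
    AtA = A.T @ A
    cond = np.linalg.cond(AtA)
    if not np.isfinite(cond) or cond > 1e12:
        raise RankError(f"collinear {what}: normal-equation condition number {cond:.3g}")
    Ainv = np.linalg.inv(AtA)
    return Ainv @ (A.T @ y), Ainv


def fit_ols(data: IndividualDataset, exposures: Optional[Sequence[int]] = None) -> EffectEstimate:
    """Least squares of Y on the selected exposures plus an intercept.

    Confounded by construction whenever the latent confounder enters both
    the exposure and outcome equations; included as the observational
    benchmark the IV methods are compared against.
    """
    exp_idx = _indices(exposures, data.n_exposures)
    Xe = data.X[:, exp_idx]
    n = data.n
    if n <= exp_idx.size + 1:
        raise ValidationError("need n > number of exposures + 1")
    D = np.column_stack([np.ones(n), Xe])
    coef, Dinv = _solve_ls(D, data.Y, "exposures")
    resid = data.Y - D @ coef
    sigma2 = resid @ resid / (n - D.shape[1])
    se = np.sqrt(sigma2 * np.diag(Dinv))
    names = [f"x{k + 1}" for k in exp_idx]
    return EffectEstimate(
        method="ols", coef=coef[1:], se=se[1:], names=names, n_subjects=n
    )


def fit_tsls(
    data: IndividualDataset,
    exposures: Optional[Sequence[int]] = None,
    instruments: Optional[Sequence[int]] = None,
) -> EffectEstimate:
    """Classical two-stage least squares with SNP instruments.

    First stage: each selected exposure on all selected instruments plus an
    intercept.  Second stage: Y on the fitted exposures plus an intercept.
    Standard errors use second-stage residuals recomputed at the observed
    exposures (the standard TSLS covariance).
    """
    exp_idx = _indices(exposures, data.n_exposures)
    ins_idx = _indices(instruments, data.n_snps)
    if ins_idx.size < exp_idx.size:
        raise IdentificationError(
            f"under-identified: {ins_idx.size} instruments for {exp_idx.size} exposures"
        )
    n = data.n
    Z = np.column_stack([np.ones(n), data.G[:, ins_idx]])
    Xe = data.X[:, exp_idx]
    first, _ = _solve_ls(Z, Xe, "instruments (first stage)")
    Xhat = Z @ first
    D = np.column_stack([np.ones(n), Xhat])
    coef, Dinv = _solve_ls(D, data.Y, "fitted exposures")
    # residuals at observed exposures, not fitted ones
    resid = data.Y - coef[0] - Xe @ coef[1:]
    sigma2 = resid @ resid / (n - D.shape[1])
    se = np.sqrt(sigma2 * np.diag(Dinv))
    names = [f"x{k + 1}" for k in exp_idx]
    return EffectEstimate(
        method="tsls",
        coef=coef[1:],
        se=se[1:],
        names=names,
        n_snps=ins_idx.size,
        n_subjects=n,
    )


def _wls_no_intercept(P: np.ndarray, g: np.ndarray, w: np.ndarray):
    """Weighted LS of g on columns of P without intercept; returns coef, cov factor."""
    Pw = P * w[:, None]
    A = P.T @ Pw
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise RankError(f"collinear SNP-exposure effect columns: condition number {cond:.3g}")
    Ainv = np.linalg.inv(A)
    coef = Ainv @ (Pw.T @ g)
    return coef, Ainv


def _summary_se(P, g, w, coef, Ainv, n_params):
    """Multiplicative random-effects scale floored at 1."""
    L = g.shape[0]
    resid = g - P @ coef
    if L > n_params:
        scale = max(1.0, float(w @ resid**2) / (L - n_params))
    else:
        scale = 1.0
    return np.sqrt(scale * np.diag(Ainv))


def fit_ivw(summary: SummaryDataset, exposure: int = 0) -> EffectEstimate:
    """Inverse-variance-weighted average of per-SNP Wald ratios.

    Equivalent to the zero-intercept weighted regression of the SNP-outcome
    effects on the SNP-exposure effects with weights 1/sigma_yj^2.  SNPs with
    an exposure effect below 1e-12 in magnitude are excluded (their Wald
    ratio is unstable) with a warning.
    """
    k = int(exposure)
    if not 0 <= k < summary.K:
        raise ValidationError(f"exposure index {k} out of range")
    pi = summary.pi_hat[:, k]
    keep = np.abs(pi) > _WALD_TOL
    if not keep.any():
        raise ValidationError("degenerate instruments: all SNP-exposure effects are zero")
    if not keep.all():
        logger.warning("excluding %d SNP(s) with |pi_hat| < 1e-12 from IVW", (~keep).sum())
    pi = pi[keep]
    gam = summary.gamma_hat[keep]
    w = 1.0 / summary.var_gamma[keep]
    coef, Ainv = _wls_no_intercept(pi[:, None], gam, w)
    se = _summary_se(pi[:, None], gam, w, coef, Ainv, 1)
    return EffectEstimate(
        method="ivw",
        coef=coef,
        se=se,
        names=[f"x{k + 1}"],
        n_snps=int(keep.sum()),
        weights=pi**2 * w,
    )


def fit_mvmr_ivw(summary: SummaryDataset) -> EffectEstimate:
    """Multivariable IVW: weighted no-intercept regression of Gamma-hat on pi-hat.

    Fits Gamma_j = beta_1 pi_1j + ... + beta_K pi_Kj + e_j with weights
    1/sigma_yj^2; the direct effect of each exposure conditional on the
    others.  Reduces exactly to :func:`fit_ivw` when K = 1.
    """
    L, K = summary.L, summary.K
    if L < K:
        raise IdentificationError(f"under-identified: L={L} SNPs for K={K} exposures")
    w = 1.0 / summary.var_gamma
    coef, Ainv = _wls_no_intercept(summary.pi_hat, summary.gamma_hat, w)
    se = _summary_se(summary.pi_hat, summary.gamma_hat, w, coef, Ainv, K)
    return EffectEstimate(
        method="mvmr_ivw",
        coef=coef,
        se=se,
        names=[f"x{k + 1}" for k in range(K)],
        n_snps=L,
        weights=w,
    )


def orient_summary(summary: SummaryDataset, orient_to: int = 0) -> SummaryDataset:
    """Flip each SNP's effect signs so its association with one exposure is >= 0.

    Flipping multiplies the whole SNP row (all exposure effects and the
    outcome effect) by -1; variances and covariances are unchanged because
    both members of every product flip together.
    """
    k = int(orient_to)
    if not 0 <= k < summary.K:
        raise ValidationError(f"orient_to index {k} out of range")
    sign = np.where(summary.pi_hat[:, k] < 0, -1.0, 1.0)
    return SummaryDataset(
        pi_hat=summary.pi_hat * sign[:, None],
        gamma_hat=summary.gamma_hat * sign,
        var_pi=summary.var_pi.copy(),
        var_gamma=summary.var_gamma.copy(),
        cov_pi=None if summary.cov_pi is None else summary.cov_pi.copy(),
        snp_ids=list(summary.snp_ids),
        mode=summary.mode,
        n_source=dict(summary.n_source),
    )


def fit_mvmr_egger(summary: SummaryDataset, orient_to: int = 0) -> EffectEstimate:
    """Multivariable MR-Egger: the MVMR regression with a pleiotropy intercept.

    Gamma_j = beta_0 + beta_1 pi_1j + ... + e_j, weights 1/sigma_yj^2, after
    re-orienting SNPs to the chosen exposure.  A nonzero intercept signals
    directional pleiotropy beyond the modeled exposures.
    """
    L, K = summary.L, summary.K
    if L < K + 1:
        raise IdentificationError(f"MVMR-Egger needs L >= K + 1 (L={L}, K={K})")
    s = orient_summary(summary, orient_to)
    P = np.column_stack([np.ones(L), s.pi_hat])
    w = 1.0 / s.var_gamma
    coef, Ainv = _wls_no_intercept(P, s.gamma_hat, w)
    se = _summary_se(P, s.gamma_hat, w, coef, Ainv, K + 1)
    est = EffectEstimate(
        method="mvmr_egger",
        coef=coef,
        se=se,
        names=["intercept"] + [f"x{k + 1}" for k in range(K)],
        n_snps=L,
        weights=w,
    )
    z = coef[0] / se[0] if se[0] > 0 else np.inf
    est.nuisance = {"intercept_p": float(2 * stats.norm.sf(abs(z)))}
    return est
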