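"""Instrument-strength diagnostics.

Individual-level data: the conventional first-stage F statistic and the
Sanderson-Windmeijer conditional F, which measures how strongly the SNPs
predict one exposure *after* their ability to predict the other exposures is
accounted for, plus the Sargan over-identification test.

Two-sample summary data: the under-identification Q statistic.  If the SNP
effects on exposure 1 are (up to noise) proportional to those on exposure 2,

    pi_1j = delta * pi_2j + e_1j,

the SNPs cannot jointly predict both exposures and the MVMR model is
under-identified.  The statistic

    Qx1 = sum_j (pi1_j - delta_hat * pi2_j)^2 / sigma_x1j^2,
    sigma_x1j^2 = sigma_1j^2 + delta_hat^2 sigma_2j^2 - 2 delta_hat sigma_12j,

with delta_hat the efficient (Q-minimizing, iteratively weighted) estimate,
is asymptotically chi-square with L - 1 degrees of freedom under the null of
under-identification.  *Rejection* is the good outcome here: it indicates
the model is identified for that exposure.  Swapping the exposure roles
gives Qx2.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .datatypes import CovMode, IndividualDataset, SummaryDataset, TestStatistic
from .estimators import _indices, _solve_ls
from .exceptions import (
    ConvergenceError,
    CovarianceValidityError,
    IdentificationError,
    ValidationError,
)

__all__ = [
    "conventional_f",
    "conditional_f",
    "sargan_test",
    "estimate_delta",
    "q_strength",
]

_F_CAP = 1e15


def _first_stage_f(y: np.ndarray, Z: np.ndarray) -> tuple:
    """F statistic for all slope coefficients of the OLS of y on [1, Z]."""
    n, L = Z.shape
    W = np.column_stack([np.ones(n), Z])
    coef, _ = _solve_ls(W, y, "instruments")
    resid = y - W @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    df_den = n - L - 1
    if rss <= tss * 1e-14:
        return _F_CAP, L, df_den
    f = ((tss - rss) / L) / (rss / df_den)
    return f, L, df_den


def conventional_f(
    data: IndividualDataset,
    exposure: int = 0,
    instruments: Optional[Sequence[int]] = None,
) -> TestStatistic:
    """Joint F test of the first-stage regression of one exposure on the SNPs.

    The usual "F > 10" rule of thumb gauges whether the instruments are
    individually strong for this exposure.
    """
    ins_idx = _indices(instruments, data.n_snps)
    if data.n <= ins_idx.size + 1:
        raise ValidationError("need n > number of instruments + 1")
    x = data.X[:, int(exposure)]
    f, df_num, df_den = _first_stage_f(x, data.G[:, ins_idx])
    p = float(stats.f.sf(f, df_num, df_den))
    return TestStatistic(name="f_conventional", value=float(f), df=(df_num, df_den), p_value=p)


def conditional_f(
    data: IndividualDataset,
    target_exposure: int = 0,
    other_exposures: Optional[Sequence[int]] = None,
    instruments: Optional[Sequence[int]] = None,
) -> TestStatistic:
    """Sanderson-Windmeijer conditional F statistic for one exposure.

    Recipe: (1) regress every other exposure on the instruments and keep the
    fitted values; (2) regress the target exposure on those fitted values
    (the TSLS estimate delta-hat) and save the residuals at the *observed*
    other exposures; (3) regress the residuals on the instruments; (4) the
    step-3 F statistic, rescaled by L/(L - K + 1) as the degrees-of-freedom
    correction, is compared with conventional weak-instrument critical
    values on (L - K + 1, n - L - 1) degrees of freedom.
    """
    t = int(target_exposure)
    if other_exposures is None:
        other_exposures = [k for k in range(data.n_exposures) if k != t]
    oth_idx = _indices(other_exposures, data.n_exposures)
    if t in oth_idx:
        raise ValidationError("target exposure cannot appear among other_exposures")
    ins_idx = _indices(instruments, data.n_snps)
    K = oth_idx.size + 1
    L = ins_idx.size
    if L < K:
        raise IdentificationError(f"conditional F needs at least K={K} instruments, got {L}")
    n = data.n
    if n <= L + K:
        raise ValidationError("need n > L + K")

    Z = np.column_stack([np.ones(n), data.G[:, ins_idx]])
    X_oth = data.X[:, oth_idx]
    first, _ = _solve_ls(Z, X_oth, "instruments (auxiliary first stage)")
    X_oth_hat = Z @ first

    x_t = data.X[:, t]
    D = np.column_stack([np.ones(n), X_oth_hat])
    delta, _ = _solve_ls(D, x_t, "fitted auxiliary exposures")
    resid = x_t - delta[0] - X_oth @ delta[1:]

    f3, _, df_den = _first_stage_f(resid, data.G[:, ins_idx])
    df_num = L - K + 1
    fc = min(f3 * L / df_num, _F_CAP)
    p = float(stats.f.sf(fc, df_num, df_den))
    return TestStatistic(
        name="f_conditional",
        value=float(fc),
        df=(df_num, df_den),
        p_value=p,
        nuisance={"delta": delta[1:].copy()},
    )


def sargan_test(
    data: IndividualDataset,
    exposures: Optional[Sequence[int]] = None,
    instruments: Optional[Sequence[int]] = None,
) -> TestStatistic:
    """Sargan over-identification test of instrument validity.

    TSLS residuals Y - (b1 X1 + ... + bK XK) are regressed on the full set of
    instruments; the statistic is n times the R-squared of that regression,
    chi-square with L - K degrees of freedom under the null that all
    instruments are valid.  Requires over-identification (L > K).
    """
    from .estimators import fit_tsls

    exp_idx = _indices(exposures, data.n_exposures)
    ins_idx = _indices(instruments, data.n_snps)
    L, K = ins_idx.size, exp_idx.size
    if L == K:
        raise IdentificationError(
            "model is exactly identified (L = K); the Sargan statistic cannot be computed"
        )
    if L < K:
        raise IdentificationError(f"under-identified: L={L} < K={K}")
    est = fit_tsls(data, exposures=exp_idx, instruments=ins_idx)
    resid = data.Y - data.X[:, exp_idx] @ est.coef
    n = data.n
    W = np.column_stack([np.ones(n), data.G[:, ins_idx]])
    coef, _ = _solve_ls(W, resid, "instruments (Sargan auxiliary)")
    e = resid - W @ coef
    tss = float(((resid - resid.mean()) ** 2).sum())
    # degenerate: an (almost) exact structural fit leaves nothing to explain
    y_scale = max(1.0, float(np.mean(data.Y**2)))
    r2 = 0.0 if tss <= n * y_scale * 1e-24 else 1.0 - float(e @ e) / tss
    value = n * max(r2, 0.0)
    df = L - K
    return TestStatistic(
        name="sargan", value=float(value), df=(df,), p_value=float(stats.chi2.sf(value, df))
    )


def _strength_arrays(summary: SummaryDataset, target: int, cov_mode):
    """Target/other effect columns and their variance pieces for Qx."""
    t = int(target)
    if not 0 <= t < summary.K:
        raise ValidationError(f"target exposure index {t} out of range")
    if summary.K < 2:
        raise ValidationError("the under-identification Q needs at least two exposures")
    others = [k for k in range(summary.K) if k != t]
    if cov_mode is None:
        cov_mode = CovMode.KNOWN if summary.cov_known else CovMode.ASSUMED_ZERO
    cov_mode = CovMode(cov_mode)
    y = summary.pi_hat[:, t]
    X = summary.pi_hat[:, others]
    vy = summary.var_pi[:, t]
    vX = summary.var_pi[:, others]
    L = summary.L
    m = len(others)
    if cov_mode is CovMode.KNOWN:
        if not summary.cov_known:
            raise ValidationError(
                "cov_mode='known' requested but the dataset has no cross-exposure covariance"
            )
        c_ty = np.column_stack([summary.pair_cov(t, k) for k in others])
        C = np.empty((L, m, m))
        for a in range(m):
            for b in range(m):
                C[:, a, b] = summary.pair_cov(others[a], others[b]) if a != b else vX[:, a]
    else:
        c_ty = np.zeros((L, m))
        C = np.zeros((L, m, m))
        for a in range(m):
            C[:, a, a] = vX[:, a]
    return y, X, vy, c_ty, C, cov_mode


def _sigma_x2(delta: np.ndarray, vy, c_ty, C) -> np.ndarray:
    """Per-SNP variance of pi_t - delta' pi_others at a given delta."""
    return vy + np.einsum("a,jab,b->j", delta, C, delta) - 2 * (c_ty @ delta)


def estimate_delta(summary: SummaryDataset, target: int = 0, cov_mode=None):
    """Efficient proportionality coefficient delta-hat for the strength Q.

    For two exposures: an iteratively re-weighted fixed point (weights
    1/sigma_x^2(delta) refreshed each step, seeded at the 1/sigma_1^2 WLS
    slope) refined to the local minimizer of Qx(delta) in the surrounding
    basin; for more exposures, the iterative generalized-least-squares fixed
    point.  Returns (delta_hat, weights) with weights = 1/sigma_x^2(delta_hat).
    """
    y, X, vy, c_ty, C, _ = _strength_arrays(summary, target, cov_mode)
    L, m = X.shape
    if L < 2:
        raise ValidationError("need at least two SNPs to estimate delta")
    if np.any(vy <= 0) or np.any(np.einsum("jaa->ja", C) <= 0):
        raise ValidationError("variance terms must be strictly positive")

    if m == 1:
        x = X[:, 0]
        s2 = C[:, 0, 0]
        c = c_ty[:, 0]

        def q_of(d: float) -> float:
            s = vy + d * d * s2 - 2 * d * c
            if np.any(s <= 0):
                return np.inf
            return float(np.sum((y - d * x) ** 2 / s))

        denom = float(np.sum(x * x / vy))
        seed = float(np.sum(x * y / vy) / denom) if denom > 0 else 0.0
        # iteratively re-weighted fixed point, seeded at the 1/sigma_1^2 WLS slope
        d_fp = seed
        converged = False
        for _ in range(200):
            s = vy + d_fp * d_fp * s2 - 2 * d_fp * c
            if np.any(s <= 0):
                raise CovarianceValidityError(
                    "sigma_x^2(delta) non-positive during iteration; covariances inconsistent"
                )
            w = 1.0 / s
            new = float(np.sum(w * x * y) / np.sum(w * x * x))
            if abs(new - d_fp) < 1e-12 * (1.0 + abs(d_fp)):
                d_fp = new
                converged = True
                break
            d_fp = new
        if not converged:
            raise ConvergenceError("delta iteration did not converge", last_iterate=d_fp)
        # refine to the local minimizer of Q(delta) in the basin around the
        # fixed point.  Under the proportionality null this basin holds the
        # efficient estimate; under a strongly identified alternative Q(delta)
        # can decay monotonically toward a degenerate |delta| -> inf asymptote,
        # in which case the grid minimum sits on the window edge and the fixed
        # point itself is kept.
        width = 1.0 + abs(d_fp)
        grid = d_fp + np.linspace(-width, width, 201)
        qvals = np.array([q_of(g) for g in grid])
        i_min = int(np.argmin(qvals))
        if 0 < i_min < grid.size - 1:
            res = optimize.minimize_scalar(
                q_of,
                bounds=(grid[i_min - 1], grid[i_min + 1]),
                method="bounded",
                options={"xatol": 1e-12},
            )
            d_hat = float(res.x) if res.fun <= q_of(d_fp) else d_fp
        else:
            d_hat = d_fp
        delta = np.array([d_hat])
    else:
        # iterative GLS fixed point for the multi-exposure generalization
        w = 1.0 / vy
        delta = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ y)
        for _ in range(200):
            s = _sigma_x2(delta, vy, c_ty, C)
            if np.any(s <= 0):
                raise CovarianceValidityError(
                    "sigma_x^2(delta) non-positive during iteration; covariances inconsistent"
                )
            w = 1.0 / s
            new = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ y)
            if np.max(np.abs(new - delta)) < 1e-10:
                delta = new
                break
            delta = new
        else:
            raise ConvergenceError("delta iteration did not converge", last_iterate=delta)

    s = _sigma_x2(delta, vy, c_ty, C)
    if np.any(s <= 0):
        raise CovarianceValidityError(
            "sigma_x^2(delta_hat) non-positive; supplied covariances are inconsistent"
        )
    d_out = float(delta[0]) if m == 1 else delta
    return d_out, 1.0 / s


def q_strength(summary: SummaryDataset, target: int = 0, cov_mode=None) -> TestStatistic:
    """Under-identification Q statistic for one exposure (Qx1, Qx2, ...).

    chi-square with L - 1 degrees of freedom under the null that the SNP
    effects on the target exposure are proportional to those on the others;
    rejection indicates the MVMR model is identified for this exposure.
    With ``cov_mode='assumed_zero'`` the cross-exposure covariance terms are
    set to zero (the pragmatic approximation for summary-only data) and the
    choice is recorded on the returned statistic.
    """
    y, X, vy, c_ty, C, mode = _strength_arrays(summary, target, cov_mode)
    delta, w = estimate_delta(summary, target=target, cov_mode=mode)
    d_vec = np.atleast_1d(np.asarray(delta, dtype=float))
    per_snp = w * (y - X @ d_vec) ** 2
    value = float(per_snp.sum())
    df = summary.L - 1
    return TestStatistic(
        name="q_strength",
        value=value,
        df=(df,),
        p_value=float(stats.chi2.sf(value, df)),
        per_snp=per_snp,
        nuisance={"delta": delta},
        cov_mode=mode,
    )
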