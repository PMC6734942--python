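"""SNP-exposure and SNP-outcome summary statistics with sampling (co)variances.

Two regression modes are supported, matching how GWAS summary estimates are
produced in practice:

* ``joint`` — each exposure (and the outcome) is regressed on the entire set
  of SNPs simultaneously, with an intercept.  The sampling variance of the
  estimate for SNP j is the (j, j) element of the inverted cross-product
  matrix of the intercept-augmented design times the mean squared residual,
  and the cross-exposure covariance uses the cross-product of residuals:

      sigma_kj^2 = [(W'W)^-1]_jj * (1/n) sum_i vhat_ki^2
      sigma_12j  = [(W'W)^-1]_jj * (1/n) sum_i vhat_1i vhat_2i

* ``univariable`` — per-SNP simple regressions with an intercept, with the
  analogous per-SNP formulas using the residuals of the j'th regression.

The residual divisor is 1/n in both modes (large-sample convention; the
difference from 1/(n - p) is O(p/n)).  The cross-exposure covariance can only
be computed from individual data; summary tables loaded from disk without it
are flagged as covariance-unknown.
"""

from __future__ import annotations

import logging
from typing import List, Optional

import numpy as np

from .datatypes import IndividualDataset, SummaryDataset, SummarySource, _pair_index
from .exceptions import RankError, ValidationError

__all__ = [
    "compute_joint_summaries",
    "compute_univariable_summaries",
    "split_samples",
]

logger = logging.getLogger(__name__)


def _check_full_rank(G: np.ndarray) -> None:
    """Raise RankError naming (nearly) dependent columns of the centered design."""
    Gc = G - G.mean(axis=0)
    _, R = np.linalg.qr(Gc)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.max() > 0 else 1.0
    bad = np.where(diag < scale * 1e-10)[0]
    if bad.size:
        raise RankError(
            f"genotype matrix is rank deficient; offending SNP columns (0-based): {bad.tolist()}",
            columns=bad.tolist(),
        )


def _joint_fit(G: np.ndarray, targets: np.ndarray):
    """OLS of each target column on [1, G]; returns (coefs on SNPs, residuals, Minv_diag)."""
    n, L = G.shape
    W = np.column_stack([np.ones(n), G])
    WtW = W.T @ W
    Minv = np.linalg.inv(WtW)
    coef = Minv @ (W.T @ targets)
    resid = targets - W @ coef
    return coef[1:], resid, np.diag(Minv)[1:]


def compute_joint_summaries(
    data: IndividualDataset, outcome_data: Optional[IndividualDataset] = None
) -> SummaryDataset:
    """Summary statistics from multivariable (all-SNPs-at-once) regressions.

    ``outcome_data`` may be a different dataset with the same SNP panel to
    emulate a two- or three-sample design; by default the SNP-outcome
    regression uses the same sample as the SNP-exposure regressions.
    """
    if outcome_data is None:
        outcome_data = data
    n, L = data.G.shape
    if n <= L + 1:
        raise ValidationError(f"joint summaries need n > L + 1 (n={n}, L={L})")
    _check_full_rank(data.G)
    K = data.n_exposures

    pi_hat, resid, d = _joint_fit(data.G, data.X)
    var_pi = d[:, None] * (resid**2).mean(axis=0)[None, :]
    pairs = _pair_index(K)
    cov_pi = np.empty((L, len(pairs)))
    for idx, (k, l) in enumerate(pairs):
        cov_pi[:, idx] = d * (resid[:, k] * resid[:, l]).mean()

    if outcome_data is data:
        gcoef, gresid, dy = _joint_fit(data.G, data.Y[:, None])
    else:
        if outcome_data.G.shape[1] != L:
            raise ValidationError("outcome_data must have the same SNP panel")
        _check_full_rank(outcome_data.G)
        gcoef, gresid, dy = _joint_fit(outcome_data.G, outcome_data.Y[:, None])
    gamma_hat = gcoef[:, 0]
    var_gamma = dy * (gresid[:, 0] ** 2).mean()

    return SummaryDataset(
        pi_hat=pi_hat,
        gamma_hat=gamma_hat,
        var_pi=var_pi,
        var_gamma=var_gamma,
        cov_pi=cov_pi if len(pairs) else None,
        mode=SummarySource.JOINT,
        n_source={"exposure": data.n, "outcome": outcome_data.n},
    )


def compute_univariable_summaries(
    data: IndividualDataset, outcome_data: Optional[IndividualDataset] = None
) -> SummaryDataset:
    """Summary statistics from per-SNP simple regressions with an intercept.

    SNPs with zero dosage variance cannot be regressed on; they are dropped
    with a logged warning rather than aborting the whole table.
    """
    if outcome_data is None:
        outcome_data = data
    n, L = data.G.shape
    if n <= 2:
        raise ValidationError("univariable summaries need n > 2")
    K = data.n_exposures
    pairs = _pair_index(K)

    keep: List[int] = []
    rows_pi, rows_var, rows_cov = [], [], []
    rows_gamma, rows_vgam = [], []
    for j in range(L):
        g = data.G[:, j]
        gc = g - g.mean()
        sxx = gc @ gc
        if sxx <= 0:
            logger.warning("SNP column %d has zero variance; dropped from univariable summaries", j)
            continue
        slope = (gc @ data.X) / sxx
        resid = data.X - data.X.mean(axis=0) - np.outer(gc, slope)
        rows_pi.append(slope)
        rows_var.append((resid**2).mean(axis=0) / sxx)
        rows_cov.append([(resid[:, k] * resid[:, l]).mean() / sxx for k, l in pairs])

        go = outcome_data.G[:, j]
        goc = go - go.mean()
        syy = goc @ goc
        if syy <= 0:
            logger.warning("SNP column %d has zero variance in outcome sample; dropped", j)
            continue
        gslope = (goc @ outcome_data.Y) / syy
        gresid = outcome_data.Y - outcome_data.Y.mean() - goc * gslope
        rows_gamma.append(gslope)
        rows_vgam.append((gresid**2).mean() / syy)
        keep.append(j)

    if not keep:
        raise ValidationError("no SNP with positive dosage variance")
    return SummaryDataset(
        pi_hat=np.asarray(rows_pi),
        gamma_hat=np.asarray(rows_gamma),
        var_pi=np.asarray(rows_var),
        var_gamma=np.asarray(rows_vgam),
        cov_pi=np.asarray(rows_cov) if pairs else None,
        snp_ids=[f"snp{j + 1}" for j in keep],
        mode=SummarySource.UNIVARIABLE,
        n_source={"exposure": data.n, "outcome": outcome_data.n},
    )


def split_samples(data: IndividualDataset, n_groups: int, seed=None) -> List[IndividualDataset]:
    """Randomly partition subjects into ``n_groups`` near-equal disjoint groups.

    Used to build two- or three-sample designs in which each association
    source comes from a non-overlapping sample, forcing the cross-source
    estimation-error covariance to zero.
    """
    if n_groups < 2:
        raise ValidationError("n_groups must be >= 2")
    if data.n < n_groups:
        raise ValidationError("cannot split fewer subjects than groups")
    rng = np.random.default_rng(seed)
    order = rng.permutation(data.n)
    out = []
    for idx in np.array_split(order, n_groups):
        out.append(
            IndividualDataset(
                G=data.G[idx],
                X=data.X[idx],
                Y=data.Y[idx],
                U=None if data.U is None else data.U[idx],
                meta=data.meta,
            )
        )
    return out
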