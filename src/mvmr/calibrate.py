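"""Monte-Carlo calibration harnesses.

Three study designs are covered:

* :func:`calibrate_underidentification` — the null/power behaviour of the
  under-identification statistics Qx1 and Qx2 across the four identification
  regimes (full pipeline: simulate individual data, compute joint summaries,
  evaluate the Q statistics against the chi-square 95% critical value).
* :func:`calibrate_qa_null` — the null distribution of the adjusted validity
  statistic QA versus the standard-weighted Q, generated directly at the
  summary level (fixed per-SNP estimate variances, no pleiotropy).
* :func:`calibrate_estimands` — which estimand each estimator recovers in
  the four causal scenarios (direct effect, total effect, or biased).

All harnesses are deterministic given the seed: per-rep generators are
spawned from one ``SeedSequence``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import Design, Scenario, ScenarioConfig, SummaryDataset, SummarySource
from .estimators import fit_mvmr_ivw, fit_tsls
from .exceptions import ValidationError
from .simulate import simulate_identification_design, simulate_scenario
from .strength import q_strength
from .summarystats import compute_joint_summaries
from .validity import chi2_critical, q_standard, q_validity

__all__ = [
    "calibrate_underidentification",
    "calibrate_qa_null",
    "calibrate_estimands",
]


def _spawn(seed, reps: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(reps)]


def calibrate_underidentification(
    design,
    reps: int = 1000,
    n: int = 50_000,
    L: int = 100,
    *,
    delta_design: float = 1.0,
    level: float = 0.95,
    seed=None,
    **design_kwargs,
) -> pd.DataFrame:
    """Distribution of Qx1 and Qx2 under one identification regime.

    Each repetition simulates individual data, computes joint-regression
    summaries (so the cross-exposure covariance is known) and evaluates both
    strength Q statistics.  The report gives the Monte-Carlo mean, standard
    deviation and the rejection rate (percent) against the chi-square
    critical value on L - 1 degrees of freedom.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    design = Design(design)
    q1 = np.empty(reps)
    q2 = np.empty(reps)
    for r, rng in enumerate(_spawn(seed, reps)):
        data = simulate_identification_design(
            design, n=n, L=L, delta_design=delta_design, seed=rng, **design_kwargs
        )
        summ = compute_joint_summaries(data)
        q1[r] = q_strength(summ, target=0).value
        q2[r] = q_strength(summ, target=1).value
    crit = chi2_critical(L - 1, level)
    rows = []
    for name, q in (("Qx1", q1), ("Qx2", q2)):
        rows.append(
            {
                "statistic": name,
                "design": design.value,
                "mean": q.mean(),
                "sd": q.std(ddof=1) if reps > 1 else 0.0,
                "rejection_rate_pct": 100.0 * float(np.mean(q > crit)),
                "critical_value": crit,
                "df": L - 1,
                "reps": reps,
                "n": n,
                "L": L,
            }
        )
    return pd.DataFrame(rows)


def _qa_null_summary(
    rng: np.random.Generator,
    L: int,
    beta1: float,
    beta2: float,
    var_pi: float,
    var_gamma: float,
    pi_range,
    pleiotropy_sd: float,
) -> SummaryDataset:
    pi1 = rng.uniform(*pi_range, size=L)
    pi2 = rng.uniform(*pi_range, size=L)
    pi_hat = np.column_stack(
        [pi1 + rng.normal(0, np.sqrt(var_pi), L), pi2 + rng.normal(0, np.sqrt(var_pi), L)]
    )
    gamma = beta1 * pi1 + beta2 * pi2
    if pleiotropy_sd > 0:
        gamma = gamma + rng.normal(0, pleiotropy_sd, L)
    gamma_hat = gamma + rng.normal(0, np.sqrt(var_gamma), L)
    return SummaryDataset(
        pi_hat=pi_hat,
        gamma_hat=gamma_hat,
        var_pi=np.full((L, 2), var_pi),
        var_gamma=np.full(L, var_gamma),
        cov_pi=np.zeros((L, 1)),
        mode=SummarySource.EXTERNAL,
    )


def calibrate_qa_null(
    reps: int = 5000,
    L: int = 100,
    *,
    beta1: float = 1.0,
    beta2: float = 1.0,
    var_pi: float = 0.02,
    var_gamma: float = 0.02,
    pi_range=(0.5, 1.5),
    pleiotropy_sd: float = 0.0,
    level: float = 0.95,
    seed=None,
) -> pd.DataFrame:
    """Null (or pleiotropy-power) distribution of QA versus the standard Q.

    Summary statistics are drawn directly: per-SNP exposure-effect estimates
    with a common variance (default 0.02) and zero cross-exposure
    covariance, outcome effects built from beta1, beta2 with independent
    noise.  ``pleiotropy_sd > 0`` adds direct SNP-to-outcome effects to every
    SNP, turning the harness into a power study.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    qa = np.empty(reps)
    qs = np.empty(reps)
    for r, rng in enumerate(_spawn(seed, reps)):
        summ = _qa_null_summary(rng, L, beta1, beta2, var_pi, var_gamma, pi_range, pleiotropy_sd)
        stat = q_validity(summ)
        qa[r] = stat.value
        qs[r] = q_standard(summ).value
    crit = chi2_critical(L - 2, level)
    rows = []
    for name, q in (("QA", qa), ("Q_standard", qs)):
        rows.append(
            {
                "statistic": name,
                "mean": q.mean(),
                "sd": q.std(ddof=1) if reps > 1 else 0.0,
                "rejection_rate_pct": 100.0 * float(np.mean(q > crit)),
                "critical_value": crit,
                "df": L - 2,
                "reps": reps,
                "L": L,
            }
        )
    return pd.DataFrame(rows)


def calibrate_estimands(
    scenario,
    reps: int = 500,
    *,
    n: int = 10_000,
    l1: int = 10,
    l2: int = 10,
    l12: int = 10,
    seed=None,
    **config_overrides,
) -> pd.DataFrame:
    """Mean estimates of the effect of X1 on Y by method, in one scenario.

    Methods: multivariable TSLS (all SNPs), multivariable IVW on joint
    summaries, univariable TSLS with all SNPs, and univariable TSLS using
    only the X1-specific SNPs (oracle subset).  The direct effect is beta1;
    in the mediator scenario the total effect is beta1 + alpha1*beta2.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    scenario = Scenario(scenario)
    base = ScenarioConfig.for_scenario(scenario, n=n, l1=l1, l2=l2, l12=l12, **config_overrides)
    est = {m: np.empty(reps) for m in ("mvmr_tsls", "mvmr_ivw", "uni_all", "uni_subset")}
    for r, rng in enumerate(_spawn(seed, reps)):
        cfg = ScenarioConfig.from_dict({**base.to_dict(), "seed": None})
        cfg.seed = rng  # per-rep generator
        data = simulate_scenario(cfg)
        est["mvmr_tsls"][r] = fit_tsls(data, exposures=[0, 1])["x1"]
        summ = compute_joint_summaries(data)
        est["mvmr_ivw"][r] = fit_mvmr_ivw(summ)["x1"]
        est["uni_all"][r] = fit_tsls(data, exposures=[0])["x1"]
        est["uni_subset"][r] = fit_tsls(data, exposures=[0], instruments=range(l1))["x1"]
    direct = base.beta1
    total = base.beta1 + base.alpha1 * base.beta2 if scenario is Scenario.MEDIATOR else base.beta1
    rows = []
    for method, vals in est.items():
        rows.append(
            {
                "method": method,
                "scenario": scenario.value,
                "mean": vals.mean(),
                "sd": vals.std(ddof=1) if reps > 1 else 0.0,
                "se_of_mean": vals.std(ddof=1) / np.sqrt(reps) if reps > 1 else 0.0,
                "direct_effect": direct,
                "total_effect": total,
                "reps": reps,
                "n": n,
            }
        )
    return pd.DataFrame(rows)
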