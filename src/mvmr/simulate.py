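"""Synthetic data generation for MVMR under four causal scenarios.

The generator produces individual-level data under linear structural models
in which a set of L mutually independent SNPs instruments two exposures X1
and X2, with a latent confounder U entering every equation.  The secondary
exposure X2 plays one of four roles relative to X1 and the outcome Y:

* ``confounder``  — X2 causes both X1 and Y:
    X2 = pi2.G + U + v2;  X1 = pi1.G + alpha2*X2 + U + v1
* ``collider``    — X1 and Y both cause X2 (generation order X1, Y, X2):
    X1 = pi1.G + U + v1;  Y = b0 + b1*X1 + U + vy;
    X2 = pi2.G + alpha1*X1 + gamma_y*Y + U + v2
* ``pleiotropy``  — X2 is an independent pathway from G to Y:
    X1 = pi1.G + U + v1;  X2 = pi2.G + U + v2
* ``mediator``    — X1 causes X2:
    X1 = pi1.G + U + v1;  X2 = pi2.G + alpha1*X1 + U + v2

and, except for the collider, Y = b0 + b1*X1 + b2*X2 + U + vy.  The direct
effect of X1 on Y is b1 throughout; in the mediator model the total effect
is b1 + alpha1*b2.

Genotypes are additive dosages, Binomial(2, maf) per SNP with the minor
allele frequency drawn uniformly per SNP from ``maf_range``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .datatypes import Design, IndividualDataset, Scenario, ScenarioConfig
from .exceptions import ValidationError

__all__ = [
    "simulate_genotypes",
    "simulate_scenario",
    "simulate_identification_design",
]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(n: int, L: int, maf_range=(0.1, 0.4), seed=None) -> np.ndarray:
    """Draw an n x L dosage matrix, each column Binomial(2, maf_j).

    maf_j is sampled uniformly from ``maf_range`` per SNP; columns are
    independent. Identical seeds give identical matrices.
    """
    if n < 1 or L < 1:
        raise ValidationError("n and L must be >= 1")
    lo, hi = maf_range
    if not (0.0 <= lo <= hi <= 0.5):
        raise ValidationError(f"maf_range must satisfy 0 <= lo <= hi <= 0.5, got {maf_range}")
    rng = _rng(seed)
    maf = rng.uniform(lo, hi, size=L)
    return rng.binomial(2, maf, size=(n, L)).astype(float)


def _draw_pi(config: ScenarioConfig, rng: np.random.Generator):
    """Resolve (pi1, pi2), drawing unset nonzero entries from pi_magnitude_range."""
    L, l1, l2 = config.L, config.l1, config.l2
    lo, hi = config.pi_magnitude_range
    pi1 = config.pi1
    pi2 = config.pi2
    if pi1 is None:
        pi1 = np.zeros(L)
        mask = np.zeros(L, dtype=bool)
        mask[:l1] = True
        mask[l1 + l2 :] = True
        pi1[mask] = rng.uniform(lo, hi, size=mask.sum())
    if pi2 is None:
        pi2 = np.zeros(L)
        mask = np.zeros(L, dtype=bool)
        mask[l1 : l1 + l2] = True
        mask[l1 + l2 :] = True
        pi2[mask] = rng.uniform(lo, hi, size=mask.sum())
    return np.asarray(pi1, dtype=float), np.asarray(pi2, dtype=float)


def simulate_scenario(config: ScenarioConfig) -> IndividualDataset:
    """Generate an individual-level dataset under one of the four scenarios.

    Noise terms U, v_x1, v_x2, v_y are independent normals with the
    configured standard deviations; with all of them zero the structural
    equations hold exactly, which the tests exploit.
    """
    config.validate()
    if config.scenario is Scenario.IDENTIFICATION_DESIGN:
        raise ValidationError(
            "use simulate_identification_design() for the identification designs"
        )
    rng = _rng(config.seed)
    n = config.n
    G = simulate_genotypes(n, config.L, config.maf_range, seed=rng)
    pi1, pi2 = _draw_pi(config, rng)

    U = rng.normal(0.0, config.sd_u, size=n) if config.sd_u > 0 else np.zeros(n)
    v1 = rng.normal(0.0, config.sd_vx1, size=n) if config.sd_vx1 > 0 else np.zeros(n)
    v2 = rng.normal(0.0, config.sd_vx2, size=n) if config.sd_vx2 > 0 else np.zeros(n)
    vy = rng.normal(0.0, config.sd_vy, size=n) if config.sd_vy > 0 else np.zeros(n)

    g1 = G @ pi1
    g2 = G @ pi2
    b0, b1, b2 = config.beta0, config.beta1, config.beta2

    if config.scenario is Scenario.CONFOUNDER:
        X2 = config.pi0_2 + g2 + U + v2
        X1 = config.pi0_1 + g1 + config.alpha2 * X2 + U + v1
        Y = b0 + b1 * X1 + b2 * X2 + U + vy
    elif config.scenario is Scenario.COLLIDER:
        X1 = config.pi0_1 + g1 + U + v1
        Y = b0 + b1 * X1 + U + vy
        X2 = config.pi0_2 + g2 + config.alpha1 * X1 + config.gamma_y * Y + U + v2
    elif config.scenario is Scenario.PLEIOTROPY:
        X1 = config.pi0_1 + g1 + U + v1
        X2 = config.pi0_2 + g2 + U + v2
        Y = b0 + b1 * X1 + b2 * X2 + U + vy
    elif config.scenario is Scenario.MEDIATOR:
        X1 = config.pi0_1 + g1 + U + v1
        X2 = config.pi0_2 + g2 + config.alpha1 * X1 + U + v2
        Y = b0 + b1 * X1 + b2 * X2 + U + vy
    else:  # pragma: no cover
        raise ValidationError(f"unknown scenario {config.scenario}")

    meta = config
    if config.pi1 is None or config.pi2 is None:
        meta = ScenarioConfig.from_dict({**config.to_dict(), "pi1": pi1, "pi2": pi2})
    return IndividualDataset(G=G, X=np.column_stack([X1, X2]), Y=Y, U=U, meta=meta)


def simulate_identification_design(
    design,
    n: int = 50_000,
    L: int = 100,
    *,
    delta_design: float = 1.0,
    beta1: float = 1.0,
    beta2: float = 0.5,
    sd_u: float = 1.0,
    sd_vx1: float = 1.0,
    sd_vx2: float = 1.0,
    sd_vy: float = 1.0,
    maf_range=(0.1, 0.4),
    pi_magnitude_range=(0.1, 0.3),
    seed=None,
) -> IndividualDataset:
    """Generate data under one of the four identification regimes.

    All designs share the independent-pathways structure with a common
    confounder U of both exposures and the outcome:

        X1 = pi1.G + U + v1;  X2 = pi2.G + U + v2;  Y = b1*X1 + b2*X2 + U + vy

    * ``both_identified``     — distinct nonzero pi1, pi2 on every SNP;
    * ``x1_unidentified``     — pi1 = 0 (SNPs carry no information on X1);
    * ``x2_unidentified``     — pi2 = 0;
    * ``jointly_unidentified``— pi1 = delta_design * pi2: the SNP effects on
      the exposures are exactly proportional, so the SNPs cannot predict
      both exposures jointly even though each is individually predicted.
    """
    design = Design(design)
    if L < 2:
        raise ValidationError("identification designs need L >= 2 SNPs")
    rng = _rng(seed)
    G = simulate_genotypes(n, L, maf_range, seed=rng)
    lo, hi = pi_magnitude_range
    if design is Design.BOTH_IDENTIFIED:
        pi1 = rng.uniform(lo, hi, size=L)
        pi2 = rng.uniform(lo, hi, size=L)
    elif design is Design.X1_UNIDENTIFIED:
        pi1 = np.zeros(L)
        pi2 = rng.uniform(lo, hi, size=L)
    elif design is Design.X2_UNIDENTIFIED:
        pi1 = rng.uniform(lo, hi, size=L)
        pi2 = np.zeros(L)
    elif design is Design.JOINTLY_UNIDENTIFIED:
        pi2 = rng.uniform(lo, hi, size=L)
        pi1 = delta_design * pi2
    else:  # pragma: no cover
        raise ValidationError(f"unknown design {design}")

    U = rng.normal(0.0, sd_u, size=n) if sd_u > 0 else np.zeros(n)
    v1 = rng.normal(0.0, sd_vx1, size=n) if sd_vx1 > 0 else np.zeros(n)
    v2 = rng.normal(0.0, sd_vx2, size=n) if sd_vx2 > 0 else np.zeros(n)
    vy = rng.normal(0.0, sd_vy, size=n) if sd_vy > 0 else np.zeros(n)

    X1 = G @ pi1 + U + v1
    X2 = G @ pi2 + U + v2
    Y = beta1 * X1 + beta2 * X2 + U + vy
    return IndividualDataset(G=G, X=np.column_stack([X1, X2]), Y=Y, U=U, meta=None)
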