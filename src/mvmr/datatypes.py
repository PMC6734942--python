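"""Core containers shared across the package.

The individual-level side of the package works with :class:`IndividualDataset`
(genotype dosages ``G``, exposures ``X``, outcome ``Y`` and, for simulated
data, the latent confounder ``U``).  The two-sample summary side works with
:class:`SummaryDataset`, which holds per-SNP association estimates with each
exposure and with the outcome, their sampling variances, and — when available
— the per-SNP covariance between the exposure-effect estimates.  That
covariance is what distinguishes a fully specified analysis from the common
situation where only published GWAS columns are available, so its presence is
tracked explicitly rather than silently imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "Scenario",
    "Design",
    "CovMode",
    "SummarySource",
    "ScenarioConfig",
    "IndividualDataset",
    "SummaryDataset",
    "EffectEstimate",
    "TestStatistic",
]


class Scenario(str, Enum):
    """Structural role of the secondary exposure X2 in the data-generating model."""

    CONFOUNDER = "confounder"
    COLLIDER = "collider"
    PLEIOTROPY = "pleiotropy"
    MEDIATOR = "mediator"
    IDENTIFICATION_DESIGN = "identification_design"


class Design(str, Enum):
    """Identification regimes for the under-identification Q calibration."""

    BOTH_IDENTIFIED = "both_identified"
    X1_UNIDENTIFIED = "x1_unidentified"
    X2_UNIDENTIFIED = "x2_unidentified"
    JOINTLY_UNIDENTIFIED = "jointly_unidentified"


class CovMode(str, Enum):
    """How the cross-exposure estimate covariance enters a Q statistic."""

    KNOWN = "known"
    ASSUMED_ZERO = "assumed_zero"


class SummarySource(str, Enum):
    """How a :class:`SummaryDataset` was produced."""

    JOINT = "joint"
    UNIVARIABLE = "univariable"
    EXTERNAL = "external"


def _as_vector(x, L: int, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (L,):
        raise ValidationError(f"{name} must have length {L}, got shape {v.shape}")
    return v


@dataclass
class ScenarioConfig:
    """All structural parameters of the simulated causal models.

    SNPs are partitioned into ``l1`` variants affecting only X1, ``l2``
    affecting only X2 and ``l12`` affecting both; the zero patterns of
    ``pi1``/``pi2`` must match this partition exactly.  When ``pi1``/``pi2``
    are ``None`` the nonzero entries are drawn uniformly from
    ``pi_magnitude_range`` at simulation time.
    """

    scenario: Scenario = Scenario.PLEIOTROPY
    n: int = 10_000
    l1: int = 10
    l2: int = 10
    l12: int = 10
    beta0: float = 0.0
    beta1: float = 1.0
    beta2: float = 0.5
    pi0_1: float = 0.0
    pi0_2: float = 0.0
    pi1: Optional[np.ndarray] = None
    pi2: Optional[np.ndarray] = None
    alpha1: float = 0.0
    alpha2: float = 0.0
    gamma_y: float = 0.0
    delta_design: float = 1.0
    sd_u: float = 1.0
    sd_vx1: float = 1.0
    sd_vx2: float = 1.0
    sd_vy: float = 1.0
    maf_range: tuple = (0.1, 0.4)
    pi_magnitude_range: tuple = (0.1, 0.3)
    seed: Optional[int] = None

    def __post_init__(self):
        self.scenario = Scenario(self.scenario)
        self.validate()

    @property
    def L(self) -> int:
        return self.l1 + self.l2 + self.l12

    def validate(self) -> None:
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        if min(self.l1, self.l2, self.l12) < 0 or self.L < 2:
            raise ValidationError("SNP partition must be nonnegative with L >= 2")
        for name in ("sd_u", "sd_vx1", "sd_vx2", "sd_vy"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must satisfy 0 <= lo <= hi <= 0.5, got {self.maf_range}")
        if self.pi1 is not None:
            self.pi1 = _as_vector(self.pi1, self.L, "pi1")
            self._check_zero_pattern(self.pi1, x1=True)
        if self.pi2 is not None:
            self.pi2 = _as_vector(self.pi2, self.L, "pi2")
            self._check_zero_pattern(self.pi2, x1=False)
        # parameters only meaningful for particular structural models
        if self.gamma_y != 0.0 and self.scenario is not Scenario.COLLIDER:
            raise ValidationError("gamma_y (outcome-on-collider effect) requires scenario='collider'")
        if self.alpha2 != 0.0 and self.scenario is not Scenario.CONFOUNDER:
            raise ValidationError("alpha2 (X2 -> X1 effect) requires scenario='confounder'")
        if self.alpha1 != 0.0 and self.scenario not in (Scenario.COLLIDER, Scenario.MEDIATOR):
            raise ValidationError("alpha1 (X1 -> X2 effect) requires scenario 'collider' or 'mediator'")
        if self.scenario is Scenario.COLLIDER and self.beta2 != 0.0:
            raise ValidationError("the collider model sets beta2 = 0; X2 must not affect Y")

    def _check_zero_pattern(self, pi: np.ndarray, x1: bool) -> None:
        active = np.zeros(self.L, dtype=bool)
        if x1:
            active[: self.l1] = True
        else:
            active[self.l1 : self.l1 + self.l2] = True
        active[self.l1 + self.l2 :] = True
        label = "pi1" if x1 else "pi2"
        if np.any(pi[~active] != 0.0):
            raise ValidationError(f"{label} has nonzero entries outside its L1/L2/L12 partition")
        if np.any(pi[active] == 0.0):
            raise ValidationError(f"{label} has zero entries where the partition requires an effect")

    @classmethod
    def for_scenario(cls, scenario, **overrides) -> "ScenarioConfig":
        """Config with conventional defaults for one of the four causal scenarios.

        Confounder: X2 -> X1 with alpha2 = 0.5.  Collider: X1 -> X2 and
        Y -> X2 (alpha1 = gamma_y = 0.5, beta2 forced to 0).  Pleiotropy:
        X1 and X2 independent given G.  Mediator: X1 -> X2 with alpha1 = 0.5.
        """
        scenario = Scenario(scenario)
        defaults: dict = {"scenario": scenario}
        if scenario is Scenario.CONFOUNDER:
            defaults["alpha2"] = 0.5
        elif scenario is Scenario.COLLIDER:
            defaults.update(alpha1=0.5, gamma_y=0.5, beta2=0.0)
        elif scenario is Scenario.MEDIATOR:
            defaults["alpha1"] = 0.5
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = {
            k: (v.tolist() if isinstance(v, np.ndarray) else
                v.value if isinstance(v, Enum) else
                list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key in ("pi1", "pi2"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        for key in ("maf_range", "pi_magnitude_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class IndividualDataset:
    """Rectangular individual-level data: dosages, exposures, outcome.

    ``U`` is the latent confounder, retained only for simulated data so tests
    can assert structural properties; it plays no role in estimation.
    """

    G: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    U: Optional[np.ndarray] = None
    meta: Optional[ScenarioConfig] = None

    def __post_init__(self):
        self.G = np.atleast_2d(np.asarray(self.G, dtype=float))
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        n = self.G.shape[0]
        if self.X.shape[0] != n or self.Y.shape[0] != n:
            raise ValidationError("G, X and Y must have the same number of rows")
        if self.U is not None:
            self.U = np.asarray(self.U, dtype=float).ravel()
            if self.U.shape[0] != n:
                raise ValidationError("U must have the same number of rows as G")
        for name, arr in (("G", self.G), ("X", self.X), ("Y", self.Y)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"{name} contains missing or non-finite values")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def n_snps(self) -> int:
        return self.G.shape[1]

    @property
    def n_exposures(self) -> int:
        return self.X.shape[1]


def _pair_index(K: int):
    """Ordered exposure pairs (k, l), k < l, matching cov_pi columns."""
    return [(k, l) for k in range(K) for l in range(k + 1, K)]


@dataclass
class SummaryDataset:
    """Two-sample-style per-SNP summary statistics for an MVMR analysis.

    ``cov_pi`` holds the per-SNP covariance between exposure-effect estimates
    for each exposure pair (column order: (1,2), (1,3), ..., (K-1,K)).  When
    it cannot be computed — e.g. summaries read from a published GWAS — it is
    ``None`` and ``cov_known`` is False; downstream tests must then either
    assume zero covariance or be run on non-overlapping samples.
    """

    pi_hat: np.ndarray
    gamma_hat: np.ndarray
    var_pi: np.ndarray
    var_gamma: np.ndarray
    cov_pi: Optional[np.ndarray] = None
    snp_ids: Optional[Sequence[str]] = None
    mode: SummarySource = SummarySource.EXTERNAL
    n_source: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pi_hat = np.atleast_2d(np.asarray(self.pi_hat, dtype=float))
        if self.pi_hat.shape[0] == 1 and self.pi_hat.shape[1] > 1 and np.asarray(self.gamma_hat).size > 1:
            self.pi_hat = self.pi_hat.T
        self.gamma_hat = np.asarray(self.gamma_hat, dtype=float).ravel()
        self.var_pi = np.atleast_2d(np.asarray(self.var_pi, dtype=float))
        if self.var_pi.shape != self.pi_hat.shape and self.var_pi.T.shape == self.pi_hat.shape:
            self.var_pi = self.var_pi.T
        self.var_gamma = np.asarray(self.var_gamma, dtype=float).ravel()
        self.mode = SummarySource(self.mode)
        L, K = self.pi_hat.shape
        if self.gamma_hat.shape != (L,) or self.var_gamma.shape != (L,):
            raise ValidationError("gamma_hat/var_gamma length must match pi_hat rows")
        if self.var_pi.shape != (L, K):
            raise ValidationError("var_pi must have the same shape as pi_hat")
        if np.any(self.var_pi < 0) or np.any(self.var_gamma < 0):
            raise ValidationError("variances must be nonnegative")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{j + 1}" for j in range(L)]
        elif len(self.snp_ids) != L:
            raise ValidationError("snp_ids length must match number of SNPs")
        if self.cov_pi is not None:
            self.cov_pi = np.atleast_2d(np.asarray(self.cov_pi, dtype=float))
            if self.cov_pi.shape[0] != L:
                self.cov_pi = self.cov_pi.reshape(L, -1)
            n_pairs = K * (K - 1) // 2
            if self.cov_pi.shape != (L, n_pairs):
                raise ValidationError(f"cov_pi must be L x {n_pairs} for K={K} exposures")
            for idx, (k, l) in enumerate(_pair_index(K)):
                bound = np.sqrt(self.var_pi[:, k] * self.var_pi[:, l])
                if np.any(np.abs(self.cov_pi[:, idx]) > bound * (1 + 1e-10) + 1e-300):
                    raise ValidationError(
                        f"cov_pi for exposure pair ({k + 1},{l + 1}) violates Cauchy-Schwarz"
                    )

    @property
    def L(self) -> int:
        return self.pi_hat.shape[0]

    @property
    def K(self) -> int:
        return self.pi_hat.shape[1]

    @property
    def cov_known(self) -> bool:
        return self.cov_pi is not None

    def pair_cov(self, k: int, l: int) -> np.ndarray:
        """Per-SNP covariance between the effect estimates of exposures k and l."""
        if self.cov_pi is None:
            raise ValidationError("cross-exposure covariance is unknown for this dataset")
        if k == l:
            return self.var_pi[:, k].copy()
        a, b = min(k, l), max(k, l)
        idx = _pair_index(self.K).index((a, b))
        return self.cov_pi[:, idx]


@dataclass
class EffectEstimate:
    """A fitted causal-effect estimate with normal-theory 95% intervals."""

    method: str
    coef: np.ndarray
    se: np.ndarray
    names: Sequence[str]
    n_snps: int = 0
    n_subjects: int = 0
    weights: Optional[np.ndarray] = None
    ci_level: float = 0.95
    nuisance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float).ravel()
        self.se = np.asarray(self.se, dtype=float).ravel()
        if self.coef.shape != self.se.shape:
            raise ValidationError("coef and se must have matching shapes")
        if np.any(self.se < 0):
            raise ValidationError("standard errors must be nonnegative")

    @property
    def ci(self) -> np.ndarray:
        from scipy import stats

        z = stats.norm.ppf(0.5 + self.ci_level / 2)
        return np.column_stack([self.coef - z * self.se, self.coef + z * self.se])

    def __getitem__(self, name: str) -> float:
        return float(self.coef[list(self.names).index(name)])

    def summary_frame(self):
        import pandas as pd

        ci = self.ci
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "ci_low": ci[:, 0], "ci_high": ci[:, 1]},
            index=list(self.names),
        )


@dataclass
class TestStatistic:
    """A diagnostic statistic (F, conditional F, Sargan, Qx, QA).

    ``per_snp`` carries the individual terms of a Q sum (empty for the
    individual-level statistics); ``nuisance`` the weighting parameters
    (delta-hat for strength Q, the causal estimates for validity Q).
    """

    name: str
    value: float
    df: tuple
    p_value: float
    per_snp: np.ndarray = field(default_factory=lambda: np.empty(0))
    nuisance: dict = field(default_factory=dict)
    cov_mode: Optional[CovMode] = None

    def __post_init__(self):
        self.per_snp = np.asarray(self.per_snp, dtype=float).ravel()
        if not isinstance(self.df, tuple):
            self.df = (int(self.df),)

    @property
    def df_num(self) -> int:
        return self.df[0]
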