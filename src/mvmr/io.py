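"""Readers and writers for the package's plain-text interchange formats.

Individual-level data: TSV with header ``id, g1..gL, x1..xK, y[, u]``.
Summary data: GWAS-style TSV with header
``snp, beta_exp1, se_exp1, ..., beta_expK, se_expK, beta_out, se_out
[, cov_exp1_exp2, ...]``.  Missing covariance columns load as
covariance-unknown with a logged warning, since the validity/strength tests
then require either an assumed-zero covariance or non-overlapping samples.
Scenario configurations round-trip through YAML.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    IndividualDataset,
    ScenarioConfig,
    SummaryDataset,
    SummarySource,
    _pair_index,
)
from .exceptions import ValidationError

__all__ = [
    "write_individual_table",
    "load_individual_table",
    "write_summary_table",
    "load_summary_table",
    "save_config",
    "load_config",
]

logger = logging.getLogger(__name__)


def write_individual_table(data: IndividualDataset, path) -> None:
    cols = {"id": np.arange(1, data.n + 1)}
    for j in range(data.n_snps):
        cols[f"g{j + 1}"] = data.G[:, j]
    for k in range(data.n_exposures):
        cols[f"x{k + 1}"] = data.X[:, k]
    cols["y"] = data.Y
    if data.U is not None:
        cols["u"] = data.U
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def load_individual_table(path) -> IndividualDataset:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    g_cols = sorted([c for c in df.columns if re.fullmatch(r"g\d+", c)], key=lambda c: int(c[1:]))
    x_cols = sorted([c for c in df.columns if re.fullmatch(r"x\d+", c)], key=lambda c: int(c[1:]))
    if not g_cols or not x_cols or "y" not in df.columns:
        raise ValidationError(f"{path}: header must contain g1.., x1.. and y columns")
    if df.isna().any().any():
        bad = int(np.where(df.isna().any(axis=1))[0][0]) + 2
        raise ValidationError(f"{path}: missing value at line {bad}")
    return IndividualDataset(
        G=df[g_cols].to_numpy(float),
        X=df[x_cols].to_numpy(float),
        Y=df["y"].to_numpy(float),
        U=df["u"].to_numpy(float) if "u" in df.columns else None,
    )


def write_summary_table(summary: SummaryDataset, path) -> None:
    cols = {"snp": list(summary.snp_ids)}
    for k in range(summary.K):
        cols[f"beta_exp{k + 1}"] = summary.pi_hat[:, k]
        cols[f"se_exp{k + 1}"] = np.sqrt(summary.var_pi[:, k])
    cols["beta_out"] = summary.gamma_hat
    cols["se_out"] = np.sqrt(summary.var_gamma)
    if summary.cov_pi is not None:
        for idx, (k, l) in enumerate(_pair_index(summary.K)):
            cols[f"cov_exp{k + 1}_exp{l + 1}"] = summary.cov_pi[:, idx]
    # 17 significant digits + round-trip parsing in load_summary_table make
    # the numeric columns round-trip bit-identically
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_summary_table(path, k_exposures: Optional[int] = None) -> SummaryDataset:
    """Parse a summary TSV; absent covariance columns flag covariance-unknown."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise ValidationError(f"{path}: cannot parse summary table ({exc})") from exc
    if k_exposures is None:
        k_exposures = len([c for c in df.columns if re.fullmatch(r"beta_exp\d+", c)])
    K = int(k_exposures)
    if K < 1:
        raise ValidationError(f"{path}: no beta_exp<k> columns found")
    required = [f"beta_exp{k + 1}" for k in range(K)] + [f"se_exp{k + 1}" for k in range(K)]
    required += ["beta_out", "se_out"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")

    for col in [c for c in df.columns if c.startswith(("beta_", "se_", "cov_"))]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(np.where(vals.isna())[0][0]) + 2
            raise ValidationError(f"{path}: non-numeric value in column '{col}' at line {line}")
        df[col] = vals
    for col in [c for c in df.columns if c.startswith("se_")]:
        if (df[col] < 0).any():
            line = int(np.where(df[col] < 0)[0][0]) + 2
            raise ValidationError(f"{path}: negative standard error in '{col}' at line {line}")

    pi_hat = df[[f"beta_exp{k + 1}" for k in range(K)]].to_numpy(float)
    var_pi = df[[f"se_exp{k + 1}" for k in range(K)]].to_numpy(float) ** 2
    pairs = _pair_index(K)
    cov_cols = [f"cov_exp{k + 1}_exp{l + 1}" for k, l in pairs]
    if pairs and all(c in df.columns for c in cov_cols):
        cov_pi = df[cov_cols].to_numpy(float)
    else:
        cov_pi = None
        if pairs:
            logger.warning(
                "%s: no cross-exposure covariance columns; covariance is UNKNOWN. "
                "It can be estimated from individual data, assumed to be zero, or "
                "fixed at zero by using non-overlapping samples per association source.",
                path,
            )
    snp = df["snp"].astype(str).tolist() if "snp" in df.columns else None
    return SummaryDataset(
        pi_hat=pi_hat,
        gamma_hat=df["beta_out"].to_numpy(float),
        var_pi=var_pi,
        var_gamma=df["se_out"].to_numpy(float) ** 2,
        cov_pi=cov_pi,
        snp_ids=snp,
        mode=SummarySource.EXTERNAL,
    )


def save_config(config: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def load_config(path) -> ScenarioConfig:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    try:
        return ScenarioConfig.from_dict(d)
    except TypeError as exc:
        raise ValidationError(f"{path}: invalid config ({exc})") from exc
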