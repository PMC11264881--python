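"""Missingness-based feature triage, binarization and coding.

Features detected in less than 25% of analytical samples are dropped;
features detected in fewer than 75% are treated as binary present/absent
indicators; the rest are continuous, imputed, batch-corrected and
standardized (natural log, then mean 0 / SD 1 over analytical samples).
Boundary semantics are literal: a presence fraction of exactly 0.25 is
binary, exactly 0.75 is continuous.

The partition depends only on the missingness mask, never on intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ConfigError, FeatureTable
from .qc_normalization import correct_batch, impute_continuous

__all__ = [
    "PartitionConfig",
    "ProcessedFeatures",
    "presence_fraction",
    "partition_features",
    "binarize",
    "quartile_bins",
    "standardize",
    "process_features",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PartitionConfig:
    low_threshold: float = 0.25
    high_threshold: float = 0.75

    def __post_init__(self) -> None:
        if not (0 < self.low_threshold < self.high_threshold <= 1):
            raise ConfigError("need 0 < low < high <= 1")


@dataclass
class ProcessedFeatures:
    """Analysis-ready blocks: standardized continuous and 0/1 binary features."""

    continuous: pd.DataFrame
    binary: pd.DataFrame
    dropped: list[str]
    stratum: pd.Series  # feature_id -> {"dropped", "binary", "continuous"}
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = self.stratum.value_counts()
        total = int(counts.sum())
        if total != len(self.stratum):
            raise ValueError("stratum labels inconsistent")


def presence_fraction(table: FeatureTable) -> pd.Series:
    """Fraction of analytical samples in which each feature is detected."""
    analytical = table.analytical()
    if len(analytical.sample_ids) == 0:
        raise ValueError("no analytical samples")
    return analytical.intensities.notna().mean(axis=0)


def partition_features(fractions: pd.Series, config: PartitionConfig = PartitionConfig()) -> pd.Series:
    """Assign each feature to dropped / binary / continuous by presence."""
    frac = pd.Series(fractions, dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("presence fractions must lie in [0, 1]")
    out = pd.Series(
        np.where(
            frac.to_numpy() < config.low_threshold,
            "dropped",
            np.where(frac.to_numpy() < config.high_threshold, "binary", "continuous"),
        ),
        index=frac.index,
        name="stratum",
    )
    return out


def binarize(values) -> np.ndarray:
    """Presence indicator: 1 where detected (non-missing, zero included), else 0."""
    v = np.asarray(values, dtype=float)
    return (~np.isnan(v)).astype(int)


def quartile_bins(values) -> np.ndarray:
    """Rank-based quartile labels 1-4 (Q1 low); NaN cells stay NaN.

    Ties get the average rank, so tied values always land in the same bin;
    ranks on a bin boundary go to the lower bin.  Without ties, bin sizes
    differ by at most one.
    """
    v = np.asarray(values, dtype=float)
    obs = ~np.isnan(v)
    x = v[obs]
    if x.size < 8:
        raise ValueError("quartiles need >= 8 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("quartiles undefined for a constant vector")
    ranks = stats.rankdata(x, method="average")
    bins = np.ceil(4.0 * ranks / x.size).astype(float)
    bins = np.clip(bins, 1, 4)
    out = np.full(v.shape, np.nan)
    out[obs] = bins
    return out


def standardize(values, log_transform: bool = True) -> np.ndarray:
    """Natural-log (optional) then center/scale to mean 0, SD 1 (ddof=1)."""
    v = np.asarray(values, dtype=float)
    if log_transform:
        if np.nanmin(v) <= 0:
            raise ValueError("log transform requires strictly positive values")
        v = np.log(v)
    sd = np.nanstd(v, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a constant feature")
    return (v - np.nanmean(v)) / sd


def process_features(
    table: FeatureTable,
    config: PartitionConfig = PartitionConfig(),
    impute_method: str = "tree",
    batch_method: str = "plate_median",
    log_transform: bool = True,
    seed: int = 0,
) -> ProcessedFeatures:
    """Triage features by missingness and build analysis-ready blocks.

    Continuous features are imputed (missing cells only), batch-corrected,
    then standardized over analytical samples.  Binary features become 0/1
    presence indicators.  QC rows are excluded from the output blocks.
    """
    frac = presence_fraction(table)
    stratum = partition_features(frac, config)
    analytical = table.analytical()

    binary_ids = list(stratum.index[stratum == "binary"])
    cont_ids = list(stratum.index[stratum == "continuous"])
    dropped = list(stratum.index[stratum == "dropped"])

    binary = pd.DataFrame(
        {fid: binarize(analytical.intensities[fid]) for fid in binary_ids},
        index=analytical.intensities.index,
    )

    cont_table = analytical.subset(analytical.sample_ids)
    if cont_ids:
        cont_table = impute_continuous(cont_table, feature_ids=cont_ids, method=impute_method, seed=seed)
        cont_table = correct_batch(cont_table, method=batch_method) if batch_method != "none" else cont_table
    cont_cols = {}
    for fid in cont_ids:
        try:
            cont_cols[fid] = standardize(cont_table.intensities[fid].to_numpy(), log_transform=log_transform)
        except ValueError as exc:
            logger.info("feature %s dropped at standardization: %s", fid, exc)
            stratum.loc[fid] = "dropped"
            dropped.append(fid)
    continuous = pd.DataFrame(cont_cols, index=analytical.intensities.index)

    return ProcessedFeatures(
        continuous=continuous,
        binary=binary,
        dropped=dropped,
        stratum=stratum,
        metadata={
            "impute_method": impute_method,
            "batch_method": batch_method,
            "log_transform": log_transform,
            "standardize_population": "all analytical samples (cases + controls), ddof=1",
            "low_threshold": config.low_threshold,
            "high_threshold": config.high_threshold,
        },
    )
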