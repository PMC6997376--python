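"""Count filtering, median-of-ratios size factors, log2 normalisation.

Tables are gene-major throughout: rows are genes, columns are samples, the
orientation the count TSVs are written in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "filter_low_expression",
    "median_of_ratios_size_factors",
    "log2_normalize",
    "CountFilter",
    "MedianRatioNormalizer",
]


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    if counts.isna().any().any():
        raise ValueError("count matrix contains missing values")
    if (counts.values < 0).any():
        raise ValueError("count matrix contains negative values")
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    return counts


def filter_low_expression(
    counts: pd.DataFrame, min_count: int = 10, min_samples: int = 16
) -> pd.DataFrame:
    """Keep genes with at least ``min_count`` reads in at least
    ``min_samples`` samples (default: the exposure group size). Both
    thresholds are inclusive; gene order is preserved."""
    _validate_counts(counts)
    if min_samples > counts.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds the number of samples ({counts.shape[1]})"
        )
    keep = (counts >= min_count).sum(axis=1) >= min_samples
    return counts.loc[keep]


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with strictly positive counts in every sample;
    for each sample, the size factor is the median ratio of its counts to the
    per-gene geometric mean across samples (median ties resolved by the
    midpoint of the two central ratios).
    """
    _validate_counts(counts)
    positive = (counts.values > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has all-positive counts; size factors are undefined "
            "(consider a pseudo-reference: add a pseudocount or filter samples)"
        )
    ref = counts.values[positive].astype(float)
    log_geo_mean = np.mean(np.log(ref), axis=1)
    ratios = ref / np.exp(log_geo_mean)[:, None]
    s = np.median(ratios, axis=0)
    return pd.Series(s, index=counts.columns, name="size_factor")


def log2_normalize(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1) expression matrix."""
    _validate_counts(counts)
    s = size_factors.reindex(counts.columns)
    if s.isna().any():
        raise ValueError("size factors missing for some samples")
    if (s <= 0).any():
        raise ValueError("size factors must be positive")
    return np.log2(counts / s + 1.0)


class CountFilter(BaseEstimator, TransformerMixin):
    """Low-expression gene filter as a transformer on gene-major tables.

    ``fit`` records the surviving genes (``genes_to_keep_``); ``transform``
    subsets any gene-major table to them, so the gene universe chosen on one
    sample set can be reused on another (e.g. the water-vs-vehicle contrast
    reuses the gene list chosen on the dosed sample set).
    """

    def __init__(self, min_count: int = 10, min_samples: int = 16):
        self.min_count = min_count
        self.min_samples = min_samples

    def fit(self, X: pd.DataFrame, y=None):
        kept = filter_low_expression(X, self.min_count, self.min_samples)
        self.genes_to_keep_ = kept.index
        self.n_genes_in_ = X.shape[0]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = self.genes_to_keep_.difference(X.index)
        if len(missing):
            raise ValueError(f"{len(missing)} retained genes absent from input")
        return X.loc[self.genes_to_keep_]


class MedianRatioNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios size factors + log2(normalised + 1) transform."""

    def fit(self, X: pd.DataFrame, y=None):
        self.size_factors_ = median_of_ratios_size_factors(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return log2_normalize(X, self.size_factors_)
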