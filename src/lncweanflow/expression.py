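"""Count matrices, median-of-ratios normalization, expression filter.

Normalization follows the median-of-ratios scheme: each sample's size
factor is the median, over features with a positive geometric mean
across samples, of that sample's count divided by the feature's
geometric mean. Dividing counts by the size factors corrects for
library size and RNA composition.

A feature counts as truly expressed when its normalized count exceeds
5 in at least 10% of libraries (ceiling), evaluated per tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

TISSUES = ("ileum", "rumen")
TIMEPOINTS = ("D33", "D96")


@dataclass
class CountMatrix:
    """Raw gene-level counts (features x samples) plus the sample sheet.

    ``sample_sheet`` is indexed by sample id with columns ``tissue``
    and ``timepoint``.
    """

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_sheet.index)
        if missing:
            raise ValueError(f"samples absent from sample sheet: {sorted(missing)}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_tissue(self, tissue: str) -> "CountMatrix":
        keep = [s for s in self.counts.columns if self.sample_sheet.loc[s, "tissue"] == tissue]
        return CountMatrix(self.counts[keep], self.sample_sheet.loc[keep])

    def groups(self) -> pd.Series:
        """Timepoint label per sample, aligned to the count columns."""
        return self.sample_sheet.loc[self.counts.columns, "timepoint"]

    @classmethod
    def from_tsv(cls, counts_path, sample_sheet_path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        sheet = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
        return cls(counts, sheet)

    def to_tsv(self, counts_path, sample_sheet_path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        self.sample_sheet.to_csv(sample_sheet_path, sep="\t")


@dataclass
class SizeFactors:
    factors: pd.Series  # sample_id -> s_j > 0

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValueError("size factors must be positive")

    def __getitem__(self, sample_id: str) -> float:
        return float(self.factors[sample_id])


def size_factors(cm: CountMatrix) -> SizeFactors:
    """Median-of-ratios size factors.

    Requires at least one feature with positive counts in every sample;
    otherwise raises with a pointer to a pseudo-reference fallback
    (compute the geometric mean over positive counts only), which this
    implementation deliberately does not silently apply.
    """
    counts = cm.counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    log_geomean = log_counts.mean(axis=1)  # -inf for any feature with a zero
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError(
            "no feature has positive counts in every sample; "
            "median-of-ratios is undefined (a pseudo-reference fallback would be needed)"
        )
    ratios = np.exp(log_counts[usable] - log_geomean[usable, None])
    factors = np.median(ratios, axis=0)
    return SizeFactors(pd.Series(factors, index=cm.counts.columns, name="size_factor"))


def normalized_counts(cm: CountMatrix, sf: SizeFactors) -> pd.DataFrame:
    return cm.counts / sf.factors


def expression_filter(
    cm: CountMatrix,
    sf: SizeFactors,
    min_count: float = 5.0,
    min_fraction: float = 0.10,
) -> list[str]:
    """Feature ids passing the expressed-gene filter.

    Retains feature i iff its normalized count strictly exceeds
    ``min_count`` in at least ``ceil(min_fraction * n_samples)``
    libraries.
    """
    norm = normalized_counts(cm, sf).to_numpy()
    needed = ceil(min_fraction * norm.shape[1])
    passing = (norm > min_count).sum(axis=1) >= needed
    return [f for f, keep in zip(cm.feature_ids, passing) if keep]
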