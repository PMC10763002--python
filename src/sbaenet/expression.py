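"""Expression preparation: sample/gene filters and sex-aware normalization.

The normalization is a smoothed ("shrunken") quantile scheme: each quantile
of the output is a convex combination of the overall mean quantile curve and
the sample's own group curve, weighted by how much of the quantile's
variance across samples is explained by group. Where the groups look alike
(weight near 1) it reduces to standard quantile normalization; where they
differ strongly (weight near 0) each group keeps its own reference
distribution, preserving biological group signal such as sample sex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.stats import rankdata

from .io import ExpressionData

log = logging.getLogger(__name__)

__all__ = ["NormalizedExpression", "filter_samples", "filter_genes_cpm",
           "sex_aware_quantile_normalize", "split_by_group"]


@dataclass
class NormalizedExpression:
    """Normalized gene x sample matrix plus the normalization record."""

    matrix: pd.DataFrame
    samples: pd.DataFrame
    normalization: dict = field(default_factory=dict)

    def subset(self, sample_ids) -> "NormalizedExpression":
        sample_ids = list(sample_ids)
        return NormalizedExpression(self.matrix[sample_ids],
                                    self.samples.loc[sample_ids],
                                    self.normalization)


def filter_samples(data: ExpressionData, min_rin: float = 5.0,
                   min_per_sex: int = 5,
                   excluded_tissues=()) -> ExpressionData:
    """Sample-level quality and design filters.

    Removes samples with RIN <= `min_rin` (the rule is "less than or equal
    to"), samples from excluded tissues, and then whole tissues that retain
    fewer than `min_per_sex` samples in either sex.
    """
    meta = data.samples
    keep = (meta["rin"] > min_rin) & ~meta["tissue"].isin(set(excluded_tissues))
    meta = meta[keep]
    by = meta.groupby(["tissue", "sex"]).size().unstack(fill_value=0)
    for sex in ("male", "female"):
        if sex not in by.columns:
            by[sex] = 0
    ok_tissues = by.index[(by["male"] >= min_per_sex)
                          & (by["female"] >= min_per_sex)]
    dropped = sorted(set(by.index) - set(ok_tissues))
    if dropped:
        log.info("filter_samples: tissues removed for sex imbalance: %s", dropped)
    meta = meta[meta["tissue"].isin(ok_tissues)]
    return data.subset(meta.index)


def filter_genes_cpm(data: ExpressionData, min_cpm: float = 1.0,
                     rule: str = "any_sample") -> ExpressionData:
    """Remove genes below `min_cpm` counts-per-million.

    ``rule="any_sample"`` (default) keeps a gene if its CPM reaches the
    threshold in at least one sample, i.e. a gene is removed only when it is
    below threshold in every sample. ``rule="summed"`` applies the threshold
    to the CPM of counts summed across samples instead.
    """
    lib = data.counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    if rule == "any_sample":
        cpm = data.counts / lib * 1e6
        keep = (cpm >= min_cpm).any(axis=1)
    elif rule == "summed":
        total = data.counts.sum(axis=1)
        keep = total / lib.sum() * 1e6 >= min_cpm
    else:
        raise ValueError(f"unknown cpm rule {rule!r}")
    log.info("filter_genes_cpm: %d of %d genes retained",
             int(keep.sum()), len(keep))
    return ExpressionData(data.counts[keep], data.samples)


def _smooth_weights(w: np.ndarray, window: int | None) -> np.ndarray:
    if window is None:
        window = max(3, int(round(0.05 * w.size)) | 1)  # odd, ~5% of quantiles
    window = min(window | 1, w.size | 1)
    return median_filter(w, size=window, mode="nearest")


def sex_aware_quantile_normalize(data: ExpressionData, group: str = "sex",
                                 window: int | None = None
                                 ) -> NormalizedExpression:
    """Group-aware smoothed quantile normalization.

    Per quantile rank k, with sample quantile curves q_s(k), group mean
    curves m_g(k) and overall mean curve M(k):

        w(k) = 1 - SSB(k) / SST(k)          (clipped to [0, 1])
        F_g(k) = w(k) * M(k) + (1 - w(k)) * m_g(k)

    where SSB is the between-group and SST the total sum of squares of the
    curves at that rank; w is smoothed by a running median. Each sample's
    values are replaced by its group's reference curve evaluated at the
    sample's midranks (ties map to the mean of tied quantiles). The mapping
    is rank-preserving by construction.
    """
    meta = data.samples
    groups = meta[group]
    counts = data.counts.to_numpy(dtype=float)
    n_genes, n_samples = counts.shape
    sizes = groups.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"group(s) with a single sample: {list(small.index)}")

    order = np.sort(counts, axis=0)                    # quantile curves
    overall = order.mean(axis=1)
    levels = list(sizes.index)
    group_curves = {g: order[:, (groups == g).to_numpy()].mean(axis=1)
                    for g in levels}

    sst = ((order - overall[:, None]) ** 2).sum(axis=1)
    ssb = np.zeros(n_genes)
    for g in levels:
        ssb += sizes[g] * (group_curves[g] - overall) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        w = 1.0 - ssb / sst
    w[~np.isfinite(w)] = 1.0
    w = np.clip(w, 0.0, 1.0)
    w = _smooth_weights(w, window)

    refs = {g: np.maximum.accumulate(w * overall + (1.0 - w) * group_curves[g])
            for g in levels}

    out = np.empty_like(counts)
    ranks_pos = np.arange(1, n_genes + 1, dtype=float)
    for j in range(n_samples):
        ref = refs[groups.iloc[j]]
        r = rankdata(counts[:, j], method="average")
        out[:, j] = np.interp(r, ranks_pos, ref)

    matrix = pd.DataFrame(out, index=data.counts.index,
                          columns=data.counts.columns)
    return NormalizedExpression(
        matrix=matrix, samples=meta.copy(),
        normalization={"method": "smoothed-quantile", "group": group,
                       "weights": w})


def split_by_group(norm: NormalizedExpression, group: str = "sex") -> dict:
    """Split a normalized matrix into one NormalizedExpression per group level."""
    return {g: norm.subset(norm.samples.index[norm.samples[group] == g])
            for g in norm.samples[group].unique()}
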