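"""Matched-count permutation enrichment.

Used twice in the pipeline: (1) are particular drug targets / metabolism
enzymes over-represented among the drugs implicated in sex-biased adverse
events, compared to equally many randomly drawn drugs; (2) are particular
gene sets (sex-biased expression, community core genes) over-represented
among the implicated drug targets, compared to random draws from the
drug-target universe.

Both share one scheme: draw `n_perm` random sets of the same size as the
query, count the feature in each draw, and test with a one-sample Wilcoxon
signed-rank whether the null counts sit below the observed count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .stats import bh_adjust, wilcoxon_signed_rank_one_sample

log = logging.getLogger(__name__)

__all__ = ["EnrichmentResult", "count_drugs_with_feature",
           "permute_feature_enrichment", "permute_geneset_enrichment",
           "results_to_frame"]


@dataclass
class EnrichmentResult:
    """Permutation-enrichment outcome for one feature."""

    feature: str
    observed: int
    null_counts: np.ndarray
    p: float
    p_adj: float = np.nan
    passes: bool = False

    def __post_init__(self) -> None:
        if self.observed < 0:
            raise ValueError("observed count must be non-negative")


def count_drugs_with_feature(drugs, annotations: dict, feature: str,
                             field: str = "targets") -> int:
    """Number of drugs whose annotation `field` contains `feature`.

    Drugs missing from the annotation table count as lacking the feature.
    """
    missing = [d for d in drugs if d not in annotations]
    if missing:
        log.warning("%d drugs lack annotations and count as feature-negative",
                    len(missing))
    return sum(1 for d in drugs
               if feature in annotations.get(d, {}).get(field, ()))


def _signed_rank_p(null_counts: np.ndarray, observed: int) -> float:
    """One-sided p that null counts are smaller than the observed count."""
    res = wilcoxon_signed_rank_one_sample(null_counts, mu=float(observed),
                                          alternative="less")
    return 1.0 if res.degenerate else res.p_value


def permute_feature_enrichment(sbae_drugs, all_drugs, annotations: dict,
                               field: str = "targets", n_perm: int = 1000,
                               seed: int = 0, alpha_adj: float = 0.001,
                               min_support: int = 5) -> list:
    """Enrichment of annotation features among a drug set.

    For every feature observed in at least one query drug (the test family,
    fixed before testing), the null is the feature count in `n_perm`
    same-size draws of drugs without replacement from `all_drugs`. A feature
    passes when its BH-adjusted p is below `alpha_adj` (default 0.001) and
    at least `min_support` query drugs carry it (default 5).
    """
    sbae_drugs = sorted(set(sbae_drugs))
    all_drugs = sorted(set(all_drugs))
    if len(sbae_drugs) > len(all_drugs):
        raise ValueError("query drug set larger than the drug universe")
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = np.random.default_rng(seed)

    features = sorted({f for d in sbae_drugs
                       for f in annotations.get(d, {}).get(field, ())})
    if not features:
        return []
    feat_idx = {f: i for i, f in enumerate(features)}
    membership = np.zeros((len(features), len(all_drugs)), dtype=bool)
    for j, d in enumerate(all_drugs):
        for f in annotations.get(d, {}).get(field, ()):
            if f in feat_idx:
                membership[feat_idx[f], j] = True

    sbae_idx = [j for j, d in enumerate(all_drugs) if d in set(sbae_drugs)]
    observed = membership[:, sbae_idx].sum(axis=1)

    k = len(sbae_drugs)
    null = np.empty((len(features), n_perm), dtype=np.int64)
    for b in range(n_perm):
        draw = rng.choice(len(all_drugs), size=k, replace=False)
        null[:, b] = membership[:, draw].sum(axis=1)

    raw_p = [_signed_rank_p(null[i], int(observed[i]))
             for i in range(len(features))]
    adj = bh_adjust(raw_p).values
    return [
        EnrichmentResult(feature=f, observed=int(observed[i]),
                         null_counts=null[i], p=raw_p[i], p_adj=float(adj[i]),
                         passes=bool(adj[i] < alpha_adj
                                     and observed[i] >= min_support))
        for i, f in enumerate(features)
    ]


def permute_geneset_enrichment(query_genes, gene_universe,
                               sets: GeneSetCollection, n_perm: int = 1000,
                               seed: int = 0, alpha_adj: float = 0.05) -> list:
    """Enrichment of gene sets among a query gene list.

    The observed statistic per set is the query/set overlap; nulls are
    overlaps of same-size random draws from `gene_universe` (by default the
    known drug-target universe). Query genes outside the universe are
    logged and dropped.
    """
    universe = sorted(set(gene_universe))
    query = sorted(set(query_genes))
    outside = [g for g in query if g not in set(universe)]
    if outside:
        log.warning("%d query genes outside the universe were dropped",
                    len(outside))
        query = [g for g in query if g not in set(outside)]
    if not query:
        raise ValueError("empty query after intersecting with the universe")
    rng = np.random.default_rng(seed)

    uni_idx = {g: i for i, g in enumerate(universe)}
    set_names = sorted(sets.sets)
    set_masks = np.zeros((len(set_names), len(universe)), dtype=bool)
    for i, name in enumerate(set_names):
        for g in sets.sets[name]:
            if g in uni_idx:
                set_masks[i, uni_idx[g]] = True

    query_mask = np.zeros(len(universe), dtype=bool)
    query_mask[[uni_idx[g] for g in query]] = True
    observed = (set_masks & query_mask).sum(axis=1)

    null = np.empty((len(set_names), n_perm), dtype=np.int64)
    for b in range(n_perm):
        draw = rng.choice(len(universe), size=len(query), replace=False)
        null[:, b] = set_masks[:, draw].sum(axis=1)

    raw_p = [_signed_rank_p(null[i], int(observed[i]))
             for i in range(len(set_names))]
    adj = bh_adjust(raw_p).values
    return [
        EnrichmentResult(feature=name, observed=int(observed[i]),
                         null_counts=null[i], p=raw_p[i], p_adj=float(adj[i]),
                         passes=bool(adj[i] < alpha_adj))
        for i, name in enumerate(set_names)
    ]


def results_to_frame(results: list) -> pd.DataFrame:
    """Flatten enrichment results for on-disk TSV output."""
    return pd.DataFrame({
        "feature": [r.feature for r in results],
        "observed": [r.observed for r in results],
        "null_mean": [float(np.mean(r.null_counts)) for r in results],
        "null_sd": [float(np.std(r.null_counts, ddof=1)) for r in results],
        "p": [r.p for r in results],
        "p_adj": [r.p_adj for r in results],
        "passes": [r.passes for r in results],
    })
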