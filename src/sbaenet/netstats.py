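"""Sex-comparison statistics on inferred regulatory networks.

Covers the network-level read-outs around a gene set of interest (typically
drug-metabolism enzymes): weighted in-degree differences between the sexes,
calling of sex-biased edges, proportion-based targeting classification,
correlation-based activator/repressor typing of present edges, and the
per-gene activator-repressor weight balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grn import Grn
from .stats import bh_adjust, pearson_cor_test, wilcoxon_rank_sum

log = logging.getLogger(__name__)

__all__ = ["weighted_in_degree", "degree_difference_test",
           "multi_tissue_degree_scan", "call_sex_biased_edges",
           "classify_targeting", "type_edge_regulation",
           "activator_repressor_balance", "compare_balances"]


def weighted_in_degree(grn: Grn) -> pd.Series:
    """Per gene, the sum of raw incoming edge weights over all TFs
    (weights untransformed and unfiltered)."""
    return grn.weights.sum(axis=0)


def _shared_genes(female: Grn, male: Grn) -> list:
    return sorted(set(female.gene_ids) & set(male.gene_ids))


def degree_difference_test(female: Grn, male: Grn, gene_set) -> dict:
    """Compare female-minus-male in-degree of a gene set against all other
    genes with a Wilcoxon rank-sum test (continuity corrected)."""
    genes = _shared_genes(female, male)
    diff = (weighted_in_degree(female)[genes]
            - weighted_in_degree(male)[genes])
    in_set = diff.index.isin(set(gene_set))
    if not in_set.any():
        raise ValueError("gene set has no overlap with the network genes")
    test = wilcoxon_rank_sum(diff[in_set], diff[~in_set], continuity=True) \
        if (~in_set).any() else None
    return {
        "differences": diff,
        "median_diff_in_set": float(diff[in_set].median()),
        "test": test,
        "n_in_set": int(in_set.sum()),
    }


def multi_tissue_degree_scan(pairs, gene_set) -> pd.DataFrame:
    """One degree-difference test per (tissue, female Grn, male Grn) triple,
    with Bonferroni-adjusted p-values and a direction label."""
    rows = []
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one tissue")
    for tissue, f, m in pairs:
        res = degree_difference_test(f, m, gene_set)
        rows.append({
            "tissue": tissue,
            "median_diff": res["median_diff_in_set"],
            "W": res["test"].statistic,
            "p": res["test"].p_value,
            "direction": "female" if res["median_diff_in_set"] > 0 else "male",
        })
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(pairs), 1.0)
    return out


def call_sex_biased_edges(female: Grn, male: Grn,
                          z_cut: float = 2.0) -> pd.DataFrame:
    """Classify every TF-gene pair by presence (weight > z_cut) per sex:
    female-only, male-only, shared, or absent."""
    tfs = sorted(set(female.tf_ids) & set(male.tf_ids))
    genes = _shared_genes(female, male)
    wf = female.weights.loc[tfs, genes].to_numpy()
    wm = male.weights.loc[tfs, genes].to_numpy()
    pf = wf > z_cut
    pm = wm > z_cut
    cls = np.select([pf & pm, pf & ~pm, ~pf & pm],
                    ["shared", "female-only", "male-only"], default="absent")
    ti, gj = np.meshgrid(np.arange(len(tfs)), np.arange(len(genes)),
                         indexing="ij")
    return pd.DataFrame({
        "tf": np.array(tfs)[ti.ravel()],
        "gene": np.array(genes)[gj.ravel()],
        "w_female": wf.ravel(),
        "w_male": wm.ravel(),
        "edge_class": cls.ravel(),
    })


def classify_targeting(edge_classes: pd.DataFrame, low: float = 0.4,
                       high: float = 0.6) -> pd.DataFrame:
    """Per gene, the proportion of its sex-biased edges in the female
    direction and the derived targeting class.

    female-biased when the proportion exceeds `high`; male-biased when the
    male-direction proportion exceeds `high` (i.e. female proportion below
    1 - high); sex-divergent when the proportion lies in [low, high]; genes
    with no sex-biased edges are reported as unclassified.
    """
    counts = (edge_classes[edge_classes["edge_class"]
                           .isin(["female-only", "male-only"])]
              .groupby(["gene", "edge_class"]).size().unstack(fill_value=0))
    for col in ("female-only", "male-only"):
        if col not in counts.columns:
            counts[col] = 0
    all_genes = pd.Index(sorted(edge_classes["gene"].unique()), name="gene")
    counts = counts.reindex(all_genes, fill_value=0)
    nf = counts["female-only"].to_numpy(float)
    nm = counts["male-only"].to_numpy(float)
    total = nf + nm
    with np.errstate(invalid="ignore"):
        prop = np.where(total > 0, nf / np.maximum(total, 1), np.nan)
    cls = np.select(
        [total == 0, prop > high, prop < 1.0 - high],
        ["unclassified", "female-biased", "male-biased"],
        default="sex-divergent")
    # with the default thresholds, [low, high] is exactly the divergent band
    divergent = (total > 0) & (prop >= low) & (prop <= high)
    cls = np.where(divergent, "sex-divergent", cls)
    return pd.DataFrame({
        "gene": all_genes,
        "n_sex_biased_edges_female": nf.astype(int),
        "n_sex_biased_edges_male": nm.astype(int),
        "prop_female": prop,
        "targeting_class": cls,
    })


def type_edge_regulation(edges: pd.DataFrame, expr, sex_context: str = "combined",
                         alpha: float = 0.05) -> pd.DataFrame:
    """Type present edges as activator / repressor / undefined.

    For each (tf, gene) edge, the Pearson correlation between TF and target
    expression over the context samples (one sex, or all samples for the
    combined context) is computed; BH adjustment is applied across all typed
    edges in the context. Significant positive -> activator, significant
    negative -> repressor, otherwise (or zero-variance input) -> undefined.
    """
    matrix = expr.matrix if hasattr(expr, "matrix") else expr
    samples = expr.samples if hasattr(expr, "samples") else None
    if sex_context in ("female", "male"):
        if samples is None:
            raise ValueError("sex-specific typing needs sample metadata")
        cols = samples.index[samples["sex"] == sex_context]
        matrix = matrix[list(cols)]
    rows = []
    for tf, gene in edges[["source", "target"]].itertuples(index=False):
        if tf not in matrix.index or gene not in matrix.index:
            rows.append((tf, gene, np.nan, np.nan, True))
            continue
        res = pearson_cor_test(matrix.loc[tf], matrix.loc[gene])
        rows.append((tf, gene, res.statistic, res.p_value, res.degenerate))
    out = pd.DataFrame(rows, columns=["tf", "gene", "rho", "p", "undefined"])
    out["sex_context"] = sex_context
    valid = ~out["p"].isna()
    out["p_adj"] = np.nan
    if valid.any():
        out.loc[valid, "p_adj"] = bh_adjust(out.loc[valid, "p"].tolist()).values
    sig = valid & (out["p_adj"] < alpha)
    out["reg_class"] = np.select(
        [sig & (out["rho"] > 0), sig & (out["rho"] < 0)],
        ["activator", "repressor"], default="undefined")
    return out


def activator_repressor_balance(typed: pd.DataFrame, grn: Grn) -> pd.Series:
    """Per gene: sum of activator edge weights minus sum of repressor edge
    weights (positive -> activator-targeted, negative -> repressor-targeted).
    Genes with no typed edges balance to 0."""
    w = grn.weights
    balance = pd.Series(0.0, index=sorted(set(typed["gene"])))
    for row in typed.itertuples(index=False):
        if row.reg_class == "undefined":
            continue
        if row.tf not in w.index or row.gene not in w.columns:
            continue
        sign = 1.0 if row.reg_class == "activator" else -1.0
        balance[row.gene] += sign * float(w.at[row.tf, row.gene])
    return balance


def compare_balances(balance_female: pd.Series, balance_male: pd.Series,
                     gene_set) -> dict:
    """Rank-sum comparison of per-gene activator-repressor balances between
    the sexes over a gene set."""
    genes = sorted((set(balance_female.index) & set(balance_male.index))
                   & set(gene_set))
    if not genes:
        raise ValueError("gene set has no overlap with the balances")
    test = wilcoxon_rank_sum(balance_female[genes], balance_male[genes],
                             continuity=True)
    return {"genes": genes, "test": test,
            "n_activator_female": int((balance_female[genes] > 0).sum()),
            "n_repressor_female": int((balance_female[genes] < 0).sum()),
            "n_activator_male": int((balance_male[genes] > 0).sum()),
            "n_repressor_male": int((balance_male[genes] < 0).sum())}
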