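"""Cross-stage summaries and end-to-end pipeline orchestration.

The summary operations compute the headline fractions of the analysis (what
share of implicated drug targets show sex-biased expression or community-core
membership; what share of typed regulatory edges are unique to one sex) with
the rounding conventions used when such fractions are printed: integer
percentages (half-up) for target-evidence fractions, two decimals for edge
fractions.

``run_pipeline`` executes the full synthetic-to-results run: simulate ->
sex-biased-pair calling -> target enrichment -> expression prep -> network
inference -> communities -> network statistics -> gene-set enrichment ->
summary, writing every artifact plus a hash manifest for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import (communities, enrichment, expression, grn, io, netstats,
               pharmacovigilance, simulate)
from .stats import bh_adjust, wilcoxon_rank_sum

log = logging.getLogger(__name__)

__all__ = ["SummaryFraction", "percent_round", "fraction",
           "summarize_target_evidence", "summarize_edge_uniqueness",
           "run_pipeline", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class SummaryFraction:
    """A printed-style numerator/denominator percentage."""

    label: str
    numerator: int
    denominator: int
    percent: float | None

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= max(self.denominator, 0):
            raise ValueError("numerator must lie in [0, denominator]")


def percent_round(numerator: int, denominator: int,
                  decimals: int = 0) -> float | None:
    """100 * num / den rounded half-up at the displayed precision;
    None when the denominator is zero."""
    if denominator == 0:
        return None
    q = Decimal(1).scaleb(-decimals)
    pct = (Decimal(100) * Decimal(numerator) / Decimal(denominator)
           ).quantize(q, rounding=ROUND_HALF_UP)
    return float(pct)


def fraction(label: str, numerator: int, denominator: int,
             decimals: int = 0) -> SummaryFraction:
    return SummaryFraction(label=label, numerator=numerator,
                           denominator=denominator,
                           percent=percent_round(numerator, denominator,
                                                 decimals))


def _gene_union(sets) -> set:
    if hasattr(sets, "sets"):
        sets = sets.sets
    if isinstance(sets, dict):
        sets = sets.values()
    out: set = set()
    for s in sets:
        out |= set(s)
    return out


def summarize_target_evidence(targets, sex_biased_sets, core_sets) -> list:
    """Fractions of implicated drug targets carrying sex-linked evidence.

    Counts targets that (a) appear in at least one sex-biased-expression
    gene set, (b) are a community core gene in at least one tissue,
    (c) either, (d) both. Percentages use integer half-up rounding.
    """
    targets = sorted(set(targets))
    expr_genes = _gene_union(sex_biased_sets)
    core_genes = _gene_union(core_sets)
    n = len(targets)
    in_expr = {t for t in targets if t in expr_genes}
    in_core = {t for t in targets if t in core_genes}
    return [
        fraction("sex_biased_expression", len(in_expr), n),
        fraction("core_gene", len(in_core), n),
        fraction("either", len(in_expr | in_core), n),
        fraction("both", len(in_expr & in_core), n),
    ]


def summarize_edge_uniqueness(typed_female: pd.DataFrame,
                              typed_male: pd.DataFrame) -> list:
    """Edge-sharing fractions between the sex-specific networks.

    `typed_female` / `typed_male` are regulation-typed edge tables for the
    edges present in each sex's network. Reports the percentage of typed
    edges unique to one sex and, among shared edges, the percentage with an
    opposite regulation class, both with two-decimal rounding (shared
    denominator of zero -> None).
    """
    fkey = {(r.tf, r.gene): r.reg_class for r in typed_female.itertuples()}
    mkey = {(r.tf, r.gene): r.reg_class for r in typed_male.itertuples()}
    all_edges = set(fkey) | set(mkey)
    shared = set(fkey) & set(mkey)
    unique = all_edges - shared
    opposite = {e for e in shared
                if {fkey[e], mkey[e]} == {"activator", "repressor"}}
    return [
        fraction("edges_unique_to_one_sex", len(unique), len(all_edges),
                 decimals=2),
        fraction("shared_edges_opposite_class", len(opposite), len(shared),
                 decimals=2),
    ]


# ---------------------------------------------------------------------------
# end-to-end synthetic pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "cases": {
        "n_cases": 50_000, "drug_catalog": 40, "event_catalog": 25,
        "baseline_rate": 0.04, "sex_ratio": 0.5,
        "planted": [
            {"drug": 0, "event": 0, "log2ror": 2.0},
            {"drug": 1, "event": 1, "log2ror": -2.0},
        ],
    },
    "annotations": {
        "n_features": 50, "background_freq": 0.05,
        "planted_fraction": 0.30, "n_planted": 3,
    },
    "expression": {
        "n_genes": 200, "n_tfs": 20, "samples_per_sex": 60,
        "nb_dispersion": 0.1, "motif_density": 0.10, "ppi_density": 0.20,
        "n_sex_biased": 20, "sex_log2fc": 1.0,
        "diff_block_tfs": 5, "diff_block_genes": 20, "diff_boost": 1.5,
        "diff_sex": "female",
    },
    "grn": {"alpha": 0.1, "tol": 1e-3, "max_iter": 200, "z_cut": 2.0},
    "enrichment": {"n_perm": 1000, "alpha_adj": 0.001, "min_support": 5},
}


def _merge_config(config: dict | None) -> dict:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for section, values in (config or {}).items():
        merged.setdefault(section, {}).update(values)
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def expression_inputs_from_config(cfg: dict, seed: int):
    """Build the expression simulation call (specs included) from config."""
    e = cfg["expression"]
    genes = [simulate.gene_id(i) for i in range(e["n_genes"])]
    tfs = [simulate.tf_id(i) for i in range(e["n_tfs"])]
    sex_spec = [{"gene": g, "log2fc": e["sex_log2fc"] * (1 if i % 2 == 0 else -1)}
                for i, g in enumerate(genes[:e["n_sex_biased"]])]
    block_genes = genes[e["n_sex_biased"]:e["n_sex_biased"] + e["diff_block_genes"]]
    diff_spec = [{"tf": t, "gene": g, "sex": e["diff_sex"], "boost": e["diff_boost"]}
                 for t in tfs[:e["diff_block_tfs"]] for g in block_genes]
    return simulate.simulate_expression(
        n_genes=e["n_genes"], n_tfs=e["n_tfs"],
        samples_per_sex=e["samples_per_sex"],
        nb_dispersion=e["nb_dispersion"], sex_biased_spec=sex_spec,
        diff_regulation_spec=diff_spec, motif_density=e["motif_density"],
        ppi_density=e["ppi_density"], seed=seed), block_genes


def sex_biased_genes_from_expression(norm: expression.NormalizedExpression,
                                     alpha: float = 0.05) -> set:
    """Genes with sex-differential normalized expression (rank-sum, BH)."""
    f_cols = norm.samples.index[norm.samples["sex"] == "female"]
    m_cols = norm.samples.index[norm.samples["sex"] == "male"]
    fm = norm.matrix[list(f_cols)].to_numpy()
    mm = norm.matrix[list(m_cols)].to_numpy()
    pvals = [wilcoxon_rank_sum(fm[i], mm[i]).p_value
             for i in range(fm.shape[0])]
    adj = bh_adjust(pvals).values
    return {g for g, p in zip(norm.matrix.index, adj) if p < alpha}


def run_pipeline(config: dict | None = None, seed: int = 0,
                 out_dir: str | Path = "results") -> dict:
    """Run the full synthetic-to-results pipeline and write a manifest.

    Stage order: simulate cases -> sex-biased pair calling -> drug-feature
    enrichment -> expression simulation/prep -> per-sex network inference ->
    differential-modularity communities -> network statistics -> gene-set
    enrichment -> summary report. Returns the in-memory results; every
    artifact is also written under `out_dir` and hashed into manifest.json.
    """
    cfg = _merge_config(config)
    out = io.ensure_dir(out_dir)
    rng = np.random.default_rng(seed)
    seeds = {k: int(s) for k, s in zip(
        ("cases", "annotations", "expression", "enrichment", "communities"),
        rng.integers(0, 2**31 - 1, size=5))}

    # stage 1: case reports -> sex-biased pairs
    cases, case_truth = simulate.simulate_cases(seed=seeds["cases"],
                                                **cfg["cases"])
    io.write_case_table(cases, out / "cases.tsv")
    events = sorted({e for es in cases["events"] for e in es})
    hierarchy = io.TermHierarchy(
        lower_to_preferred={e: e for e in events},
        preferred_to_soc={e: {"soc_general"} for e in events})
    filtered = pharmacovigilance.filter_cases(cases)
    mapped = pharmacovigilance.map_terms(filtered, hierarchy)
    tables = pharmacovigilance.build_contingency(mapped)
    tested = pharmacovigilance.apply_report_filters(tables)
    sbae = pharmacovigilance.score_pairs(tested)
    sbae.to_csv(out / "sbae_results.tsv", sep="\t", index=False)
    overlap = pharmacovigilance.overlap_summary(sbae)
    (out / "overlap_summary.json").write_text(json.dumps(overlap, indent=2))

    # stage 2: drug-feature enrichment among SBAE-associated drugs
    sbae_drugs = sorted(set(sbae.loc[sbae["bias"] != "none", "drug"]))
    all_drugs = sorted({d for ds in cases["drugs"] for d in ds})
    acfg = cfg["annotations"]
    ecfg = cfg["expression"]
    feature_names = [simulate.gene_id(i) for i in range(acfg["n_features"])]
    planted_features = {g: acfg["planted_fraction"]
                        for g in feature_names[:acfg["n_planted"]]}
    annotations, anno_truth = simulate.simulate_annotations(
        n_drugs=len(all_drugs), n_features=acfg["n_features"],
        background_freq=acfg["background_freq"],
        planted_features=planted_features if sbae_drugs else {},
        sbae_drug_ids=set(sbae_drugs) & {simulate.drug_id(i)
                                         for i in range(len(all_drugs))},
        seed=seeds["annotations"], feature_names=feature_names)
    io.write_drug_annotations(annotations, out / "drug_annotations.tsv")
    ncfg = cfg["enrichment"]
    target_enrichment = enrichment.permute_feature_enrichment(
        sbae_drugs, all_drugs, annotations, field="targets",
        n_perm=ncfg["n_perm"], seed=seeds["enrichment"],
        alpha_adj=ncfg["alpha_adj"], min_support=ncfg["min_support"]
    ) if sbae_drugs else []
    enrichment.results_to_frame(target_enrichment).to_csv(
        out / "enrichment_targets.tsv", sep="\t", index=False)
    enriched_targets = sorted(r.feature for r in target_enrichment if r.passes)

    # stage 3: expression -> per-sex networks
    (expr, motif, ppi, expr_truth), block_genes = \
        expression_inputs_from_config(cfg, seeds["expression"])
    io.write_expression(expr, out / "expression_counts.tsv",
                        out / "expression_samples.tsv")
    io.write_edge_list(motif, out / "motif_prior.tsv")
    io.write_edge_list(ppi, out / "ppi.tsv")
    prepped = expression.filter_genes_cpm(expression.filter_samples(expr))
    norm = expression.sex_aware_quantile_normalize(prepped)
    by_sex = expression.split_by_group(norm)
    gcfg = cfg["grn"]
    nets = {s: grn.build_grn(by_sex[s], motif, ppi, alpha=gcfg["alpha"],
                             tol=gcfg["tol"], max_iter=gcfg["max_iter"],
                             sex=s, tissue="liver")
            for s in ("female", "male")}
    for s, net in nets.items():
        io.write_matrix(net.weights, out / f"grn_{s}.tsv")

    # stage 4: communities and core genes
    assignments = communities.run_both_orientations(
        nets["female"], nets["male"], seed=seeds["communities"])
    core_sets = {}
    membership_rows = []
    for orientation, assign in assignments.items():
        core = communities.extract_core_genes(assign, k=100)
        for cid, genes_ in core.items():
            core_sets[f"liver_{orientation}_c{cid}"] = genes_
        membership_rows += [
            {"node": node, "community": cid, "orientation": orientation,
             "score": assign.score[node]}
            for node, cid in assign.membership.items()]
    pd.DataFrame(membership_rows).to_csv(out / "communities.tsv", sep="\t",
                                         index=False)
    core_coll = io.GeneSetCollection(
        sets={k: set(v) for k, v in core_sets.items()},
        descriptions={k: "community core genes" for k in core_sets})
    io.write_gmt(core_coll, out / "core_genes.gmt")

    # stage 5: network statistics around the boosted ("drug metabolism") set
    gene_set = set(block_genes)
    degree = netstats.degree_difference_test(nets["female"], nets["male"],
                                             gene_set)
    edge_classes = netstats.call_sex_biased_edges(nets["female"], nets["male"],
                                                  z_cut=gcfg["z_cut"])
    edge_classes[edge_classes["edge_class"] != "absent"].to_csv(
        out / "edge_classes.tsv", sep="\t", index=False)
    targeting = netstats.classify_targeting(edge_classes)
    targeting.to_csv(out / "targeting_classes.tsv", sep="\t", index=False)
    typed = {}
    for s in ("female", "male"):
        present = grn.grn_edges_above(nets[s], z_cut=gcfg["z_cut"])
        typed[s] = netstats.type_edge_regulation(present, norm, sex_context=s)
    pd.concat(typed.values()).to_csv(out / "edge_regulation.tsv", sep="\t",
                                     index=False)
    balances = {s: netstats.activator_repressor_balance(typed[s], nets[s])
                for s in ("female", "male")}
    pd.DataFrame(balances).fillna(0.0).to_csv(out / "balance.tsv", sep="\t")

    # stage 6: gene-set enrichment of enriched targets + summary
    sex_biased = sex_biased_genes_from_expression(norm)
    geneset_coll = io.GeneSetCollection(
        sets={"sex_biased_expression": sex_biased,
              **{k: set(v) for k, v in core_sets.items()}},
        descriptions={})
    geneset_enrichment = []
    if enriched_targets:
        geneset_enrichment = enrichment.permute_geneset_enrichment(
            [g for g in enriched_targets if g in set(feature_names)],
            feature_names, geneset_coll, n_perm=ncfg["n_perm"],
            seed=seeds["enrichment"] + 1)
        enrichment.results_to_frame(geneset_enrichment).to_csv(
            out / "enrichment_genesets.tsv", sep="\t", index=False)

    target_summary = summarize_target_evidence(
        enriched_targets, {"sex_biased": sex_biased}, core_sets) \
        if enriched_targets else []
    edge_summary = summarize_edge_uniqueness(typed["female"], typed["male"])
    summary = {
        "seed": seed,
        "n_pairs_tested": int(len(sbae)),
        "n_pairs_female": int((sbae["bias"] == "female").sum()),
        "n_pairs_male": int((sbae["bias"] == "male").sum()),
        "n_sbae_drugs": len(sbae_drugs),
        "n_enriched_targets": len(enriched_targets),
        "degree_median_diff": degree["median_diff_in_set"],
        "degree_p": degree["test"].p_value,
        "target_evidence": [dataclasses.asdict(f) for f in target_summary],
        "edge_uniqueness": [dataclasses.asdict(f) for f in edge_summary],
        "truth": {
            "planted_pairs": case_truth.planted_pairs,
            "planted_features": anno_truth.planted_features,
            "planted_sex_biased_genes": expr_truth.planted_sex_biased_genes,
            "n_planted_diff_edges": len(expr_truth.planted_diff_edges),
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    artifacts = sorted(p for p in out.iterdir()
                       if p.is_file() and p.name != "manifest.json")
    manifest = {"seed": seed, "config": cfg,
                "files": {p.name: _sha256(p) for p in artifacts}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"sbae": sbae, "overlap": overlap, "enrichment": target_enrichment,
            "networks": nets, "assignments": assignments,
            "degree": degree, "typed_edges": typed, "summary": summary,
            "truth": {"cases": case_truth, "annotations": anno_truth,
                      "expression": expr_truth}}
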