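"""Calibration and recovery studies on synthetic data with known truth.

Each study runs the relevant pipeline stages end-to-end on generated inputs
and measures how well planted effects are recovered (or how well false-
positive rates are controlled when nothing is planted). The studies are the
package's own validation surface; they are consumed both by the test suite
and by the results-reproduction script.

Problem sizes are chosen to represent the study conditions at desk scale:
50,000 case reports over a 40-drug / 25-term vocabulary for the
pharmacovigilance stages, a 400-drug universe with 100 implicated drugs and
1,000 permutations for enrichment, and 200 genes x 20 TFs x 60 samples per
sex for the network stages.
"""

from __future__ import annotations

import numpy as np

from . import communities as communities_mod
from . import enrichment, expression, grn, netstats, pharmacovigilance, simulate
from .io import GeneSetCollection

__all__ = ["run_sbae_stage", "null_bias_calibration", "planted_pair_recall",
           "feature_enrichment_study", "geneset_null_calibration",
           "network_recovery_study"]


def run_sbae_stage(cases, **score_kwargs):
    """Contingency build + report filters + pair scoring on filtered cases."""
    filtered = pharmacovigilance.filter_cases(cases)
    tables = pharmacovigilance.build_contingency(filtered)
    tested = pharmacovigilance.apply_report_filters(tables)
    return pharmacovigilance.score_pairs(tested, **score_kwargs)


def null_bias_calibration(n_seeds: int = 20, seed: int = 0,
                          **case_kwargs) -> list:
    """Fraction of tested pairs called sex-biased on null case data.

    No effects are planted, so any biased call is a false positive; with BH
    at 0.05 plus the |log2 ROR| > 1 effect-size gate the fraction should
    stay at or below the nominal level.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in rng.integers(0, 2**31 - 1, size=n_seeds):
        cases, _ = simulate.simulate_cases(seed=int(s), planted=[],
                                           **case_kwargs)
        results = run_sbae_stage(cases)
        n_biased = int((results["bias"] != "none").sum())
        out.append({"seed": int(s), "n_tested": int(len(results)),
                    "n_biased": n_biased,
                    "frac_biased": n_biased / max(len(results), 1)})
    return out


def planted_pair_recall(seed: int = 0, n_pairs: int = 12,
                        log2ror: float = 2.0, exposure: int = 1600,
                        **case_kwargs) -> dict:
    """Recovery of planted sex-biased pairs (and false calls elsewhere).

    Plants `n_pairs` pairs with |log2 ROR| = `log2ror` (alternating female/
    male direction) on drugs given enough exposure that the report filters
    are satisfiable, then measures the fraction recovered with the correct
    bias direction, and the number of unplanted pairs called biased.
    """
    planted = [{"drug": i, "event": i,
                "log2ror": log2ror if i % 2 == 0 else -log2ror,
                "exposure": exposure}
               for i in range(n_pairs)]
    cases, truth = simulate.simulate_cases(seed=seed, planted=planted,
                                           **case_kwargs)
    results = run_sbae_stage(cases)
    keyed = results.set_index(["drug", "event"])
    hits = 0
    for spec in truth.planted_pairs:
        key = (spec["drug"], spec["event"])
        want = "female" if spec["true_log2ror"] > 0 else "male"
        if key in keyed.index and keyed.loc[key, "bias"] == want:
            hits += 1
    planted_keys = {(p["drug"], p["event"]) for p in truth.planted_pairs}
    false_calls = int(sum(
        1 for r in results.itertuples()
        if r.bias != "none" and (r.drug, r.event) not in planted_keys))
    return {"recall": hits / n_pairs, "n_planted": n_pairs,
            "n_false_biased": false_calls, "n_tested": int(len(results))}


def feature_enrichment_study(n_seeds: int = 20, seed: int = 0,
                             n_drugs: int = 400, n_sbae: int = 100,
                             planted_fraction: float = 0.30,
                             background_freq: float = 0.05,
                             n_perm: int = 1000, alpha_adj: float = 0.001,
                             min_support: int = 5) -> list:
    """Does a feature planted in 30% of implicated drugs vs a 5% background
    pass the enrichment gate (BH < alpha_adj and support >= min_support)?"""
    rng = np.random.default_rng(seed)
    sbae_drugs = {simulate.drug_id(i) for i in range(n_sbae)}
    all_drugs = [simulate.drug_id(i) for i in range(n_drugs)]
    out = []
    for s in rng.integers(0, 2**31 - 1, size=n_seeds):
        annotations, _ = simulate.simulate_annotations(
            n_drugs=n_drugs, background_freq=background_freq,
            planted_features={"FEAT000": planted_fraction},
            sbae_drug_ids=sbae_drugs, seed=int(s))
        results = enrichment.permute_feature_enrichment(
            sbae_drugs, all_drugs, annotations, n_perm=n_perm, seed=int(s),
            alpha_adj=alpha_adj, min_support=min_support)
        planted = next(r for r in results if r.feature == "FEAT000")
        out.append({"seed": int(s), "passes": bool(planted.passes),
                    "observed": planted.observed, "p_adj": planted.p_adj})
    return out


def geneset_null_calibration(n_seeds: int = 20, seed: int = 0,
                             universe_size: int = 2000, n_sets: int = 20,
                             set_size: int = 200, query_size: int = 84,
                             n_perm: int = 500, alpha_adj: float = 0.05) -> list:
    """Pass rate of gene-set enrichment for random (null) query genes."""
    rng = np.random.default_rng(seed)
    universe = [simulate.gene_id(i) for i in range(universe_size)]
    out = []
    for s in rng.integers(0, 2**31 - 1, size=n_seeds):
        local = np.random.default_rng(int(s))
        sets = GeneSetCollection(sets={
            f"set{i:02d}": set(local.choice(universe, size=set_size,
                                            replace=False))
            for i in range(n_sets)})
        query = local.choice(universe, size=query_size, replace=False)
        results = enrichment.permute_geneset_enrichment(
            query, universe, sets, n_perm=n_perm, seed=int(s),
            alpha_adj=alpha_adj)
        n_pass = sum(r.passes for r in results)
        out.append({"seed": int(s), "n_sets": n_sets, "n_pass": int(n_pass),
                    "pass_rate": n_pass / n_sets})
    return out


def _simulate_and_infer(seed: int, n_genes: int, n_tfs: int,
                        samples_per_sex: int, block_tfs: int, block_genes: int,
                        boost: float, diff_sex: str, grn_kwargs: dict):
    genes = [simulate.gene_id(i) for i in range(n_genes)]
    tfs = [simulate.tf_id(i) for i in range(n_tfs)]
    block = genes[:block_genes]
    diff_spec = [{"tf": t, "gene": g, "sex": diff_sex, "boost": boost}
                 for t in tfs[:block_tfs] for g in block]
    expr, motif, ppi, truth = simulate.simulate_expression(
        n_genes=n_genes, n_tfs=n_tfs, samples_per_sex=samples_per_sex,
        diff_regulation_spec=diff_spec, seed=seed)
    prepped = expression.filter_genes_cpm(expr)
    norm = expression.sex_aware_quantile_normalize(prepped)
    by_sex = expression.split_by_group(norm)
    nets = {s: grn.build_grn(by_sex[s], motif, ppi, sex=s, **grn_kwargs)
            for s in ("female", "male")}
    return nets, truth, block


def network_recovery_study(n_seeds: int = 10, seed: int = 0,
                           n_genes: int = 200, n_tfs: int = 20,
                           samples_per_sex: int = 60, block_tfs: int = 5,
                           block_genes: int = 20, boost: float = 1.5,
                           grn_kwargs: dict | None = None) -> list:
    """Recovery of a planted female-only regulatory boost.

    Per seed, a dense block of `block_tfs` x `block_genes` TF->gene couplings
    is boosted in females only; the study records (i) whether those edges
    have higher female than male inferred weights on average, (ii) whether
    the female-perturbed differential-modularity run co-assigns the planted
    nodes to one community, and (iii) the degree-difference test on the
    boosted gene set.
    """
    grn_kwargs = grn_kwargs or {}
    rng = np.random.default_rng(seed)
    out = []
    for s in rng.integers(0, 2**31 - 1, size=n_seeds):
        nets, truth, block = _simulate_and_infer(
            int(s), n_genes, n_tfs, samples_per_sex, block_tfs, block_genes,
            boost, "female", grn_kwargs)
        wf, wm = nets["female"].weights, nets["male"].weights
        margins = np.array([
            wf.at[e["tf"], e["gene"]] - wm.at[e["tf"], e["gene"]]
            for e in truth.planted_diff_edges
            if e["gene"] in wf.columns and e["tf"] in wf.index])

        assign = communities_mod.run_both_orientations(
            nets["female"], nets["male"], seed=int(s))["female-perturbed"]
        planted_nodes = (
            {communities_mod.TF_PREFIX + e["tf"] for e in truth.planted_diff_edges}
            | {communities_mod.GENE_PREFIX + e["gene"]
               for e in truth.planted_diff_edges})
        planted_nodes &= set(assign.membership)
        counts: dict = {}
        for node in planted_nodes:
            cid = assign.membership[node]
            counts[cid] = counts.get(cid, 0) + 1
        coassigned = max(counts.values()) / len(planted_nodes)

        degree = netstats.degree_difference_test(nets["female"], nets["male"],
                                                 set(block))
        out.append({
            "seed": int(s),
            "mean_planted_margin": float(margins.mean()),
            "frac_planted_edges_positive": float((margins > 0).mean()),
            "coassigned_fraction": float(coassigned),
            "degree_median_diff": degree["median_diff_in_set"],
            "degree_p": degree["test"].p_value,
        })
    return out
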