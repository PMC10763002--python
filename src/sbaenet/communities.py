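"""Differential-modularity communities between two sex-specific networks.

Given a "perturbed" network and a "baseline" network over the same TF and
gene nodes, the differential modularity of an edge is the perturbed weight
minus the weight expected from the baseline's node strengths:

    D_ij = w_pert_ij - s_i * t_j / m

with s the TF out-strengths, t the gene in-strengths and m the total weight,
all in the baseline (weights clamped to be non-negative first, since the
inferred weights live on a standardized scale that admits negatives). Nodes
are partitioned by Louvain on the positive part of D; each node's
differential-modularity score is the positive D it contributes to edges
inside its own community. The comparison is run twice, once per orientation
(female perturbed vs male baseline, and the reverse), and the top scoring
nodes per community are that community's core genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .grn import Grn

log = logging.getLogger(__name__)

__all__ = ["CommunityAssignment", "differential_modularity",
           "detect_communities", "extract_core_genes", "run_both_orientations"]

TF_PREFIX = "tf:"
GENE_PREFIX = "gene:"


@dataclass
class CommunityAssignment:
    """Node -> community partition with differential-modularity scores."""

    orientation: str
    membership: dict                 # prefixed node -> community id (1-based)
    score: dict                      # prefixed node -> score
    communities: dict = field(default_factory=dict)  # id -> node set

    def __post_init__(self) -> None:
        if not self.communities:
            for node, cid in self.membership.items():
                self.communities.setdefault(cid, set()).add(node)


def _aligned_weights(perturbed: Grn, baseline: Grn) -> tuple:
    tfs = sorted(set(perturbed.tf_ids) & set(baseline.tf_ids))
    genes = sorted(set(perturbed.gene_ids) & set(baseline.gene_ids))
    if len(tfs) < len(perturbed.tf_ids) or len(genes) < len(perturbed.gene_ids):
        log.warning("differential_modularity: node sets intersected to "
                    "%d TFs x %d genes", len(tfs), len(genes))
    wp = perturbed.weights.loc[tfs, genes].to_numpy(dtype=float)
    wb = baseline.weights.loc[tfs, genes].to_numpy(dtype=float)
    return np.maximum(wp, 0.0), np.maximum(wb, 0.0), tfs, genes


def differential_modularity(perturbed: Grn, baseline: Grn) -> pd.DataFrame:
    """Perturbed weight minus the baseline-expected weight, per edge."""
    wp, wb, tfs, genes = _aligned_weights(perturbed, baseline)
    m = wb.sum()
    if m <= 0:
        raise ValueError("baseline network has zero total weight")
    s = wb.sum(axis=1)
    t = wb.sum(axis=0)
    d = wp - np.outer(s, t) / m
    return pd.DataFrame(d, index=tfs, columns=genes)


def detect_communities(D: pd.DataFrame, seed: int = 0,
                       resolution: float = 1.0,
                       n_restarts: int = 10) -> CommunityAssignment:
    """Louvain partition of the bipartite positive-differential graph.

    Edge weights are max(D_ij, 0); TF and gene namespaces are kept apart by
    node prefixes. Louvain is a greedy maximizer whose output depends on its
    sweep order, so `n_restarts` seeded runs are performed and the partition
    with the highest weighted modularity kept (restart seeds derive from
    `seed`, keeping the result deterministic). Node score = the node's summed
    positive D over edges inside its own community (so community score sums
    equal twice the community's internal positive D). With no positive D
    everywhere, all nodes form one community with zero scores.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    pos = np.maximum(D.to_numpy(dtype=float), 0.0)
    tf_nodes = [TF_PREFIX + t for t in D.index]
    gene_nodes = [GENE_PREFIX + g for g in D.columns]
    nodes = tf_nodes + gene_nodes

    graph = nx.Graph()
    graph.add_nodes_from(sorted(nodes))
    ti, gj = np.nonzero(pos)
    for i, j in zip(ti, gj):
        graph.add_edge(tf_nodes[i], gene_nodes[j], weight=float(pos[i, j]))

    if not graph.number_of_edges():
        membership = {n: 1 for n in nodes}
        return CommunityAssignment(orientation="", membership=membership,
                                   score={n: 0.0 for n in nodes})

    restart_seeds = np.random.default_rng(seed).integers(
        0, 2**31 - 1, size=n_restarts)
    best_q, parts = -np.inf, None
    for rs in restart_seeds:
        cand = nx.community.louvain_communities(graph, weight="weight",
                                                resolution=resolution,
                                                seed=int(rs))
        q = nx.community.modularity(graph, cand, weight="weight",
                                    resolution=resolution)
        if q > best_q:
            best_q, parts = q, cand
    parts = sorted(parts, key=lambda com: min(com))
    membership = {}
    for cid, com in enumerate(parts, start=1):
        for node in com:
            membership[node] = cid

    score = {n: 0.0 for n in nodes}
    for i, j in zip(ti, gj):
        u, v = tf_nodes[i], gene_nodes[j]
        if membership[u] == membership[v]:
            score[u] += float(pos[i, j])
            score[v] += float(pos[i, j])
    return CommunityAssignment(orientation="", membership=membership,
                               score=score)


def strip_prefix(node: str) -> str:
    for p in (TF_PREFIX, GENE_PREFIX):
        if node.startswith(p):
            return node[len(p):]
    return node


def extract_core_genes(assignment: CommunityAssignment, k: int = 100,
                       exclude_tfs: bool = False) -> dict:
    """Top-k nodes per community by descending score (ties: lexicographic).

    TF nodes are genes too and are eligible by default; set `exclude_tfs`
    to score only target-gene nodes. Returns community id -> ordered list of
    unprefixed node names (length min(k, community size)).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    core = {}
    for cid, com in sorted(assignment.communities.items()):
        members = [n for n in com
                   if not (exclude_tfs and n.startswith(TF_PREFIX))]
        ordered = sorted(members,
                         key=lambda n: (-assignment.score[n], strip_prefix(n)))
        core[cid] = [strip_prefix(n) for n in ordered[:k]]
    return core


def run_both_orientations(female: Grn, male: Grn, seed: int = 0,
                          resolution: float = 1.0) -> dict:
    """Differential-modularity runs in both perturbed/baseline orientations."""
    out = {}
    for orientation, pert, base in (("female-perturbed", female, male),
                                    ("male-perturbed", male, female)):
        d = differential_modularity(pert, base)
        assignment = detect_communities(d, seed=seed, resolution=resolution)
        assignment.orientation = orientation
        out[orientation] = assignment
    return out
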