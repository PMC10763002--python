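"""Message-passing inference of bipartite TF -> gene regulatory networks.

Three evidence sources are fused: a binary motif prior (where a TF could
bind), a TF-TF interaction network (which regulators cooperate), and gene
co-expression (which genes respond together). Each matrix is standardized,
then the edge-weight matrix W is refined iteratively: the "responsibility"
of TF i for gene j measures the agreement between TF i's interaction profile
and gene j's current regulator profile; the "availability" measures the
agreement between TF i's current target profile and gene j's co-expression
profile. W steps toward the mean of the two, and the interaction and
co-expression matrices are in turn pulled toward the self-similarity of W's
rows and columns, all with a common step size. Agreement is measured with a
continuous Tanimoto kernel. The final weights live on an unbounded
standardized scale, read downstream as z-scores (edge "present" when > 2).

There is no randomness anywhere in the procedure: given the same inputs the
same network is returned, and identical female/male inputs give identical
networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["Grn", "standardize_matrix", "continuous_tanimoto", "build_grn",
           "grn_edges_above"]

_EPS = 1e-10


@dataclass
class Grn:
    """Weighted bipartite TF x gene regulatory network."""

    weights: pd.DataFrame            # TFs as rows, genes as columns
    sex: str = ""
    tissue: str = ""
    convergence: dict = field(default_factory=dict)

    @property
    def tf_ids(self) -> list:
        return list(self.weights.index)

    @property
    def gene_ids(self) -> list:
        return list(self.weights.columns)


def standardize_matrix(m: np.ndarray) -> np.ndarray:
    """(row z-score + column z-score) / sqrt(2), with zero-variance rows or
    columns contributing 0 for their term."""
    m = np.asarray(m, dtype=float)

    def _z(axis: int) -> np.ndarray:
        mean = m.mean(axis=axis, keepdims=True)
        sd = m.std(axis=axis, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (m - mean) / sd
        return np.where(sd > 0, z, 0.0)

    return (_z(1) + _z(0)) / np.sqrt(2.0)


def continuous_tanimoto(x: np.ndarray, y: np.ndarray) -> float:
    """T(x, y) = x.y / sqrt(|x|^2 + |y|^2 - |x.y|)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    dot = float(x @ y)
    denom = np.sqrt(max(float(x @ x + y @ y) - abs(dot), _EPS))
    return dot / denom


def _tanimoto_rows_cols(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """T between every row of `rows` and every column of `cols`."""
    dot = rows @ cols
    rn = (rows ** 2).sum(axis=1)[:, None]
    cn = (cols ** 2).sum(axis=0)[None, :]
    denom = np.sqrt(np.maximum(rn + cn - np.abs(dot), _EPS))
    return dot / denom


def _inflate_diagonal(m: np.ndarray, alpha: float, step: int) -> np.ndarray:
    """Replace the diagonal of a square self-similarity matrix by the
    off-diagonal row spread scaled by the matrix dimension and exp(2*alpha*
    step). Large self-affinity terms enlarge every row/column norm in the
    Tanimoto kernel, shrinking subsequent similarity updates."""
    n = m.shape[0]
    np.fill_diagonal(m, np.nan)
    sd = np.nanstd(m, axis=1)
    np.fill_diagonal(m, sd * n * np.exp(2.0 * alpha * step))
    return m


def _motif_matrix(motif: pd.DataFrame, tfs: list, genes: list) -> np.ndarray:
    m = np.zeros((len(tfs), len(genes)))
    ti = {t: i for i, t in enumerate(tfs)}
    gi = {g: j for j, g in enumerate(genes)}
    for s, t, w in motif[["source", "target", "weight"]].itertuples(index=False):
        if s in ti and t in gi:
            m[ti[s], gi[t]] = w
    return m


def _ppi_matrix(ppi: pd.DataFrame, tfs: list) -> np.ndarray:
    m = np.eye(len(tfs))
    ti = {t: i for i, t in enumerate(tfs)}
    for s, t, w in ppi[["source", "target", "weight"]].itertuples(index=False):
        if s in ti and t in ti:
            m[ti[s], ti[t]] = w
            m[ti[t], ti[s]] = w
    return m


def build_grn(expr, motif: pd.DataFrame, ppi: pd.DataFrame,
              alpha: float = 0.1, tol: float = 1e-3, max_iter: int = 200,
              sex: str = "", tissue: str = "") -> Grn:
    """Infer a TF -> gene network from one sex and tissue's expression.

    `expr` is a NormalizedExpression (or anything with a gene x sample
    `.matrix` DataFrame). Motif-prior TFs absent from the expression matrix
    are dropped with a warning; if no TF or no target gene overlaps the
    expression space, an error lists the missing identifiers. At alpha = 0
    the returned weights equal the standardized motif prior.
    """
    matrix = expr.matrix if hasattr(expr, "matrix") else expr
    if matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    expr_genes = set(matrix.index)
    tfs = sorted(set(motif["source"]))
    missing_tfs = [t for t in tfs if t not in expr_genes]
    if missing_tfs:
        log.warning("build_grn: %d motif TFs absent from expression dropped: %s",
                    len(missing_tfs), missing_tfs[:5])
        tfs = [t for t in tfs if t in expr_genes]
    genes = sorted(set(motif["target"]) & expr_genes)
    if not tfs or not genes:
        raise ValueError(
            f"identifier spaces do not overlap; missing TFs {missing_tfs[:5]}, "
            f"missing targets {sorted(set(motif['target']) - expr_genes)[:5]}")

    W = standardize_matrix(_motif_matrix(motif, tfs, genes))
    P = standardize_matrix(_ppi_matrix(ppi, tfs))
    expr_gene = matrix.loc[genes].to_numpy(dtype=float)
    corr = np.corrcoef(expr_gene)  # co-expression over the target-gene space
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    C = standardize_matrix(corr)

    deltas = []
    converged = alpha == 0
    for it in range(max_iter if alpha > 0 else 0):
        R = _tanimoto_rows_cols(P, W)            # TF x gene responsibility
        A = _tanimoto_rows_cols(W, C)            # TF x gene availability
        target = 0.5 * (R + A)
        delta = float(alpha * np.mean(np.abs(W - target)))
        W = (1.0 - alpha) * W + alpha * target
        deltas.append(delta)
        if delta < tol:
            converged = True
            break

        # pull P and C toward the self-similarity of W rows / columns; the
        # diagonal is inflated (off-diagonal spread x dimension x a factor
        # growing with the step) which damps the Tanimoto feedback loop and
        # makes the iteration contract instead of diverging
        S_p = _tanimoto_rows_cols(W, W.T)
        P = (1.0 - alpha) * P + alpha * _inflate_diagonal(S_p, alpha, it)
        S_c = _tanimoto_rows_cols(W.T, W)
        C = (1.0 - alpha) * C + alpha * _inflate_diagonal(S_c, alpha, it)

    weights = pd.DataFrame(W, index=tfs, columns=genes)
    return Grn(weights=weights, sex=sex, tissue=tissue,
               convergence={"iterations": len(deltas),
                            "final_delta": deltas[-1] if deltas else 0.0,
                            "converged": converged,
                            "deltas": deltas})


def grn_edges_above(grn: Grn, z_cut: float = 2.0) -> pd.DataFrame:
    """Edge list of weights strictly above `z_cut` (edge-presence rule)."""
    ti, gj = np.nonzero(grn.weights.to_numpy() > z_cut)
    return pd.DataFrame({
        "source": [grn.tf_ids[i] for i in ti],
        "target": [grn.gene_ids[j] for j in gj],
        "weight": grn.weights.to_numpy()[ti, gj],
    })
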