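"""Single-sample gene-set enrichment (ssGSEA).

Per sample, genes are ranked by expression and the score is the sum over
ranked positions of the difference between a rank-weighted in-set ECDF and
the unweighted out-of-set ECDF (weight = rank^alpha, alpha = 0.25). Scores
depend only on within-sample ranks, so any strictly monotone transform of
a sample's expression leaves them unchanged.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import AdaptedSignature, ExpressionMatrix, GeneSet, LOG_CPM, as_gene_sets

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25
DEFAULT_MIN_SIZE = 2


def ssgsea_score(sample_expr: Mapping[str, float] | pd.Series,
                 signature: GeneSet | AdaptedSignature | Sequence[str],
                 alpha: float = DEFAULT_ALPHA) -> float:
    """ssGSEA score of one signature in one sample.

    Expression ties get average ranks and tied genes contribute as one
    block, so the score never depends on input gene order. Requires at
    least 2 signature genes among the expressed genes.
    """
    if isinstance(sample_expr, pd.Series):
        genes = sample_expr.index.to_numpy(dtype=object)
        values = sample_expr.to_numpy(dtype=float)
    else:
        genes = np.array(list(sample_expr), dtype=object)
        values = np.array([sample_expr[g] for g in genes], dtype=float)
    sig_genes = set(signature.genes) if hasattr(signature, "genes") else set(signature)
    in_set = np.array([g in sig_genes for g in genes])
    n_in = int(in_set.sum())
    if n_in < DEFAULT_MIN_SIZE:
        raise ValueError(f"signature has {n_in} gene(s) in the sample; need >= 2")
    if n_in == len(genes):
        raise ValueError("signature covers every expressed gene; no out-of-set ECDF")

    ranks = rankdata(values)  # 1 = lowest expression
    order = np.argsort(-ranks, kind="stable")
    return _running_sum(ranks[order], in_set[order], len(genes) - n_in, alpha)


def _running_sum(sorted_ranks: np.ndarray, in_ord: np.ndarray, n_out: int,
                 alpha: float) -> float:
    """Weighted ECDF-difference sum over descending ranked positions.

    Genes tied in expression form one block: both ECDFs advance over the
    whole block before it contributes, so the score is exactly invariant
    to input gene order and ~0 for a constant expression vector.
    """
    w_in = np.where(in_ord, sorted_ranks ** alpha, 0.0)
    ecdf_in = np.cumsum(w_in) / w_in.sum()
    ecdf_out = np.cumsum(~in_ord) / n_out
    # index of the last position of each tie block
    boundary = np.flatnonzero(np.diff(sorted_ranks) != 0)
    block_end = np.empty(len(sorted_ranks), dtype=int)
    start = 0
    for b in boundary:
        block_end[start:b + 1] = b
        start = b + 1
    block_end[start:] = len(sorted_ranks) - 1
    return float(np.sum(ecdf_in[block_end] - ecdf_out[block_end]))


def score_collection(m: ExpressionMatrix,
                     signatures: Iterable[GeneSet | AdaptedSignature],
                     alpha: float = DEFAULT_ALPHA,
                     min_size: int = DEFAULT_MIN_SIZE,
                     normalize: bool = False) -> pd.DataFrame:
    """Score every signature in every sample; returns signatures x samples.

    Signatures with fewer than ``min_size`` expressed genes are dropped
    with a logged message. ``normalize=True`` min-max rescales the whole
    matrix to [0, 1] (off by default: scores are compared across samples
    as-is).
    """
    m.require_stage(LOG_CPM)
    genes = m.genes.to_numpy(dtype=object)
    expressed = set(genes)
    kept: list[GeneSet] = []
    for sig in as_gene_sets(signatures):
        n_in = sum(g in expressed for g in sig.genes)
        if n_in < min_size:
            log.info("score_collection: dropping %s (%d expressed gene(s) < %d)",
                     sig.name, n_in, min_size)
            continue
        if n_in == len(expressed):
            log.warning("score_collection: dropping %s (covers every expressed gene)", sig.name)
            continue
        kept.append(sig)
    if not kept:
        return pd.DataFrame(index=pd.Index([], name="signature"), columns=m.samples)

    values = m.values.to_numpy(dtype=float)
    n_genes = len(genes)
    memberships = [np.array([g in set(sig.genes) for g in genes]) for sig in kept]

    out = np.empty((len(kept), m.shape[1]))
    for j in range(m.shape[1]):
        ranks = rankdata(values[:, j])
        order = np.argsort(-ranks, kind="stable")
        sorted_ranks = ranks[order]
        for i, in_set in enumerate(memberships):
            out[i, j] = _running_sum(sorted_ranks, in_set[order],
                                     n_genes - in_set.sum(), alpha)

    scores = pd.DataFrame(out, index=pd.Index([s.name for s in kept], name="signature"),
                          columns=m.samples)
    if normalize:
        lo, hi = out.min(), out.max()
        if hi > lo:
            scores = (scores - lo) / (hi - lo)
    scores.attrs.update({"alpha": alpha, "min_size": min_size, "normalized": normalize})
    return scores
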