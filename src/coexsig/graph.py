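"""Graph-based adaptation of gene sets into co-expressed signatures.

The pipeline per gene set: Spearman co-expression matrix on log-CPM →
threshold at the correlation cutoff (CCIM) → undirected graph → Louvain
communities (resolution 1) → eigenvector centrality → keep communities
holding at least ``min_fraction`` of the (expressed) set, name each after
its most central gene, and mark a core of members whose centrality is at
least ``core_ratio`` of the central gene's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import AdaptedSignature, ExpressionMatrix, GeneSet, LOG_CPM

log = logging.getLogger(__name__)

DEFAULT_CCIM = 0.4
DEFAULT_MIN_FRACTION = 0.20
DEFAULT_CORE_RATIO = 0.90
DEFAULT_SEED = 17


@dataclass
class CoexpressionDiagnostics:
    """Cohesion summaries of a gene set in one expression context.

    mggc: median of the off-diagonal pairwise Spearman correlations.
    mggv: median over gene pairs of the per-sample expression-difference
        variance Var(x_i - x_j) — low when members move together.
    """

    mggc: float
    mggv: float
    n_genes: int


def spearman_matrix(m: ExpressionMatrix, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman correlation (average ranks for ties) among
    ``genes`` over all samples; genes absent from the matrix are dropped
    with a logged count. Diagonal is exactly 1.
    """
    m.require_stage(LOG_CPM)
    if genes is None:
        present = list(m.genes)
    else:
        idx = set(m.genes)
        present = [g for g in genes if g in idx]
        missing = len(genes) - len(present)
        if missing:
            log.info("spearman_matrix: %d of %d genes absent from matrix", missing, len(genes))
    if len(present) < 2:
        raise ValueError("need at least 2 genes present in the matrix")
    x = m.values.loc[present].to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, x)
    sd = ranks.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(ranks)
    # constant genes have undefined correlation; define it as 0 off-diagonal
    if (sd == 0).any():
        const = np.flatnonzero(sd == 0)
        log.info("spearman_matrix: %d constant gene(s); correlations set to 0", const.size)
        corr[const, :] = 0.0
        corr[:, const] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=present, columns=present)


def threshold_graph(corr: pd.DataFrame, ccim: float = DEFAULT_CCIM) -> nx.Graph:
    """Build the undirected co-expression graph keeping edges with
    signed rho >= ccim (boundary inclusive). Every gene stays as a node;
    genes with no qualifying edge remain isolated.
    """
    if not 0.0 <= ccim <= 1.0:
        raise ValueError("ccim must be in [0, 1]")
    genes = list(corr.index)
    g = nx.Graph(ccim=ccim)
    g.add_nodes_from(genes)
    a = corr.to_numpy()
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = a[iu, ju] >= ccim
    g.add_weighted_edges_from(
        (genes[i], genes[j], float(a[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    )
    return g


def eigen_centrality(g: nx.Graph) -> dict[str, float]:
    """Eigenvector centrality from the principal eigenvector of the
    (unweighted) adjacency matrix, rescaled so the maximum is 1.

    Isolated nodes get exactly 0; an edgeless graph is all zeros. On a
    disconnected graph the centrality concentrates on the component with
    the largest adjacency eigenvalue; other components come out at ~0.
    """
    nodes = list(g.nodes)
    if g.number_of_edges() == 0:
        return {n: 0.0 for n in nodes}
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    w, v = np.linalg.eigh(a)
    vec = v[:, int(np.argmax(w))]
    # Perron vector of the dominant component is one-signed; make it >= 0
    if vec.sum() < 0:
        vec = -vec
    vec = np.clip(vec, 0.0, None)
    vec = vec / vec.max()
    out = {n: float(c) for n, c in zip(nodes, vec)}
    for n in nodes:  # exact zeros for isolates regardless of round-off
        if g.degree(n) == 0:
            out[n] = 0.0
    return out


def louvain_communities(g: nx.Graph, resolution: float = 1.0,
                        seed: int = DEFAULT_SEED) -> dict[str, int]:
    """Louvain partition (greedy modularity maximization) on the
    unweighted graph; the seed fixes the node-visit order. Returns a
    gene → community-id map; an edgeless graph yields singleton
    communities.
    """
    parts = nx.community.louvain_communities(g, weight=None,
                                             resolution=resolution, seed=seed)
    # deterministic community ids: order by (size desc, lexicographic min)
    parts = sorted(parts, key=lambda c: (-len(c), min(map(str, c))))
    return {n: i for i, comm in enumerate(parts) for n in comm}


def adapt_gene_set(gene_set: GeneSet, m: ExpressionMatrix,
                   ccim: float = DEFAULT_CCIM,
                   min_fraction: float = DEFAULT_MIN_FRACTION,
                   core_ratio: float = DEFAULT_CORE_RATIO,
                   resolution: float = 1.0,
                   seed: int = DEFAULT_SEED) -> list[AdaptedSignature]:
    """Adapt one public gene set into zero or more co-expressed signatures.

    Communities smaller than ``min_fraction`` of the expressed gene set
    are discarded; each retained community is named after its maximum-
    centrality member (ties broken lexicographically) and carries its
    members' eigencentralities, computed on the community subgraph and
    rescaled so the central gene has centrality 1.
    """
    present = [g for g in gene_set.genes if g in set(m.genes)]
    if len(present) < 2:
        raise ValueError(
            f"gene set {gene_set.name!r} has {len(present)} gene(s) in the matrix; need >= 2"
        )
    corr = spearman_matrix(m, present)
    graph = threshold_graph(corr, ccim=ccim)
    membership = louvain_communities(graph, resolution=resolution, seed=seed)
    n_present = len(present)

    by_comm: dict[int, list[str]] = {}
    for gene, comm in membership.items():
        by_comm.setdefault(comm, []).append(gene)

    signatures = []
    for comm_id in sorted(by_comm):
        members = sorted(by_comm[comm_id])
        fraction = len(members) / n_present
        if fraction < min_fraction:
            continue
        sub = graph.subgraph(members)
        cent = eigen_centrality(sub)
        # central gene = max centrality, ties broken lexicographically
        best = max(cent.values())
        central = min(g for g in members if cent[g] >= best - 1e-12)
        signatures.append(AdaptedSignature(
            name=central,
            origins=(gene_set.name,),
            members={g: cent[g] for g in members},
            ccim=ccim,
            community_fraction=fraction,
            core_ratio=core_ratio,
        ))
    signatures.sort(key=lambda s: (-len(s.members), s.name))
    return signatures


def adapt_collection(collection: Iterable[GeneSet], m: ExpressionMatrix,
                     ccim: float = DEFAULT_CCIM,
                     min_fraction: float = DEFAULT_MIN_FRACTION,
                     core_ratio: float = DEFAULT_CORE_RATIO,
                     resolution: float = 1.0,
                     seed: int = DEFAULT_SEED,
                     merge: bool = True) -> list[AdaptedSignature]:
    """Adapt every set in a collection; sets with fewer than 2 expressed
    genes are skipped with a logged warning. Same-central-gene signatures
    are merged unless ``merge=False``.
    """
    out: list[AdaptedSignature] = []
    expressed = set(m.genes)
    for gs in collection:
        if sum(g in expressed for g in gs.genes) < 2:
            log.warning("skipping %s: fewer than 2 genes expressed", gs.name)
            continue
        out.extend(adapt_gene_set(gs, m, ccim=ccim, min_fraction=min_fraction,
                                  core_ratio=core_ratio, resolution=resolution,
                                  seed=seed))
    return merge_by_central_gene(out) if merge else out


def merge_by_central_gene(signatures: Sequence[AdaptedSignature]) -> list[AdaptedSignature]:
    """Merge signatures sharing a central gene.

    Members are unioned keeping the maximum eigencentrality per gene,
    origins are concatenated, and the core is recomputed with the original
    core ratio on the merged eigenvalues.
    """
    grouped: dict[str, list[AdaptedSignature]] = {}
    order: list[str] = []
    for s in signatures:
        if s.name not in grouped:
            order.append(s.name)
        grouped.setdefault(s.name, []).append(s)

    merged = []
    for name in order:
        group = grouped[name]
        if len(group) == 1:
            merged.append(group[0])
            continue
        members: dict[str, float] = {}
        origins: list[str] = []
        for s in group:
            for g, v in s.members.items():
                members[g] = max(members.get(g, -np.inf), v)
            for o in s.origins:
                if o not in origins:
                    origins.append(o)
        merged.append(AdaptedSignature(
            name=name,
            origins=tuple(origins),
            members=members,
            ccim=group[0].ccim,
            community_fraction=max(s.community_fraction for s in group),
            core_ratio=group[0].core_ratio,
        ))
    return merged


def coexpression_diagnostics(gene_set: GeneSet | AdaptedSignature,
                             m: ExpressionMatrix) -> CoexpressionDiagnostics:
    """MGGC / MGGV of a gene set in an expression context."""
    genes = list(gene_set.genes)
    corr = spearman_matrix(m, genes)
    present = list(corr.index)
    a = corr.to_numpy()
    iu, ju = np.triu_indices(len(present), k=1)
    mggc = float(np.median(a[iu, ju]))
    x = m.values.loc[present].to_numpy(dtype=float)
    diffs_var = np.array([np.var(x[i] - x[j], ddof=1) for i, j in zip(iu, ju)])
    mggv = float(np.median(diffs_var))
    return CoexpressionDiagnostics(mggc=mggc, mggv=mggv, n_genes=len(present))


def ccim_sweep(collection: Iterable[GeneSet], m: ExpressionMatrix,
               grid: Sequence[float] = tuple(np.round(np.arange(0.05, 0.95, 0.05), 2)),
               min_fraction: float = DEFAULT_MIN_FRACTION,
               core_ratio: float = DEFAULT_CORE_RATIO,
               seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """Re-run the adaptation across a grid of correlation cutoffs.

    Returns one row per threshold with the number of retained communities,
    unique member / core / central genes, and the mean retained-size
    fraction, MGGC and MGGV of the adapted signatures — the diagnostics
    used to choose a working CCIM.
    """
    collection = list(collection)
    if any(not 0.0 <= c <= 1.0 for c in grid):
        raise ValueError("grid thresholds must lie in [0, 1]")
    rows = []
    for ccim in grid:
        sigs = adapt_collection(collection, m, ccim=ccim,
                                min_fraction=min_fraction,
                                core_ratio=core_ratio, seed=seed, merge=False)
        uniq_genes: set[str] = set()
        core_genes: set[str] = set()
        central: set[str] = set()
        mggcs, mggvs = [], []
        for s in sigs:
            uniq_genes.update(s.members)
            core_genes.update(s.core)
            central.add(s.name)
            d = coexpression_diagnostics(s, m)
            mggcs.append(d.mggc)
            mggvs.append(d.mggv)
        rows.append({
            "ccim": ccim,
            "n_communities": len(sigs),
            "n_unique_genes": len(uniq_genes),
            "n_core_genes": len(core_genes),
            "n_central_genes": len(central),
            "mean_size_retained_fraction": float(np.mean([s.community_fraction for s in sigs])) if sigs else 0.0,
            "mean_mggc": float(np.mean(mggcs)) if mggcs else np.nan,
            "mean_mggv": float(np.mean(mggvs)) if mggvs else np.nan,
        })
    return pd.DataFrame(rows).set_index("ccim")
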