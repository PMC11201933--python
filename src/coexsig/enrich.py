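"""Hypergeometric over-representation of adapted signatures.

Each adapted signature is tested against the full source collections; a
signature is kept for downstream analysis only if its best-ranked hit is
the set it was derived from (first-rank retention), which guards against
communities drifting away from their original biology.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import AdaptedSignature, GeneSet, GeneSetCollection

log = logging.getLogger(__name__)

DEFAULT_MIN_GS_SIZE = 5


@dataclass
class EnrichmentResult:
    """Ranked over-representation hits for one query gene set."""

    query: str
    hits: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: set_name, overlap, set_size, query_size, universe_size, p, p_adj

    @property
    def top_hit(self) -> str | None:
        return None if self.hits.empty else str(self.hits.iloc[0]["set_name"])

    def top_hits(self) -> list[str]:
        """All hits tied at the minimal (adjusted p, raw p)."""
        if self.hits.empty:
            return []
        best = self.hits.iloc[0]
        tied = self.hits[(self.hits["p_adj"] == best["p_adj"]) & (self.hits["p"] == best["p"])]
        return tied["set_name"].tolist()


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when drawing ``n`` genes from a universe of ``N``
    containing ``K`` members of the reference set.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent hypergeometric arguments k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_collection(query: GeneSet | AdaptedSignature,
                      reference: GeneSetCollection,
                      min_gs_size: int = DEFAULT_MIN_GS_SIZE,
                      universe: Iterable[str] | None = None) -> EnrichmentResult:
    """Over-representation of a query set against every reference set.

    The universe defaults to the union of all reference genes. Reference
    sets with fewer than ``min_gs_size`` genes in the universe are not
    tested. P-values are Benjamini–Hochberg adjusted over the tested sets
    and hits sorted by (adjusted p, raw p, -overlap, name).
    """
    uni = set(universe) if universe is not None else set(reference.universe)
    q_all = list(query.genes)
    q = [g for g in q_all if g in uni]
    dropped = len(q_all) - len(q)
    if dropped:
        log.info("enrich: %d query gene(s) outside the universe dropped", dropped)
    qs = set(q)
    rows = []
    for ref in reference:
        ref_in = set(ref.genes) & uni
        if len(ref_in) < min_gs_size:
            continue
        k = len(qs & ref_in)
        rows.append({
            "set_name": ref.name,
            "overlap": k,
            "set_size": len(ref_in),
            "query_size": len(qs),
            "universe_size": len(uni),
            "p": hypergeom_p(k, len(ref_in), len(qs), len(uni)),
        })
    if not rows:
        return EnrichmentResult(query=query.name, hits=pd.DataFrame(
            columns=["set_name", "overlap", "set_size", "query_size",
                     "universe_size", "p", "p_adj"]))
    hits = pd.DataFrame(rows)
    hits["p_adj"] = multipletests(hits["p"].to_numpy(), method="fdr_bh")[1]
    hits = hits.sort_values(
        by=["p_adj", "p", "overlap", "set_name"],
        ascending=[True, True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return EnrichmentResult(query=query.name, hits=hits)


def rank1_filter(signatures: Sequence[AdaptedSignature],
                 reference: GeneSetCollection,
                 min_gs_size: int = DEFAULT_MIN_GS_SIZE,
                 universe: Iterable[str] | None = None) -> list[AdaptedSignature]:
    """Keep only signatures whose top enrichment hit is their own origin.

    Ties at the minimal p count in the signature's favour: it survives if
    any origin set is among the minimal-(p_adj, p) hits.
    """
    retained = []
    for sig in signatures:
        res = enrich_collection(sig, reference, min_gs_size=min_gs_size, universe=universe)
        top = set(res.top_hits())
        if top & set(sig.origins):
            retained.append(sig)
        else:
            log.info("rank1_filter: dropping %s (top hit %s, origins %s)",
                     sig.name, res.top_hit, sig.origins)
    return retained
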