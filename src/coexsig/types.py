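"""Core in-memory containers shared across the pipeline.

Expression data travels as a thin wrapper around a pandas DataFrame so that
every stage can assert what it receives (raw counts vs. normalized log-CPM)
instead of silently mixing scales. Gene sets and adapted signatures are
frozen-ish dataclasses with explicit invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

RAW_COUNTS = "raw_counts"
LOG_CPM = "log_cpm"

_SOURCES = {"MSigDB", "MetAtlas", "user", "adapted"}


@dataclass
class GeneSet:
    """A named, ordered collection of unique gene symbols.

    Gene symbols are opaque, case-sensitive identifiers; duplicates are
    removed preserving first occurrence.
    """

    name: str
    description: str = ""
    genes: tuple[str, ...] = ()
    source: str = "user"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("GeneSet name must be non-empty")
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {sorted(_SOURCES)}")
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g)
        self.genes = tuple(seen)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass
class GeneSetCollection:
    """A list of gene sets with unique names; ``universe`` is their union."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate set names in collection: {dupes}")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sets:
            out.update(s.genes)
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix tagged with its processing stage."""

    values: pd.DataFrame
    stage: str = RAW_COUNTS

    def __post_init__(self) -> None:
        if self.stage not in (RAW_COUNTS, LOG_CPM):
            raise ValueError(f"unknown stage {self.stage!r}")
        v = self.values
        if v.index.has_duplicates:
            dupes = sorted(v.index[v.index.duplicated()].unique().tolist())
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if v.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.stage == RAW_COUNTS and (v.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise ValueError(f"expected a {stage} matrix, got {self.stage}")


@dataclass
class NormalizationResult:
    """Per-sample library sizes and TMM scaling factors.

    ``effective_lib`` (= lib_size * factor) is what log-CPM divides by.
    Factors are rescaled so their geometric mean is 1.
    """

    lib_sizes: pd.Series
    tmm_factors: pd.Series

    def __post_init__(self) -> None:
        if (self.tmm_factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        if not np.allclose(np.exp(np.mean(np.log(self.tmm_factors))), 1.0, atol=1e-9):
            raise ValueError("TMM factors must have geometric mean 1")

    @property
    def effective_lib(self) -> pd.Series:
        return self.lib_sizes * self.tmm_factors


@dataclass
class AdaptedSignature:
    """A co-expression community promoted to a gene set.

    Named after its central gene (the maximum-eigencentrality member);
    ``core`` is the subset with eigencentrality >= core_ratio times the
    central gene's; ``community_fraction`` is |members| over the size of the
    originating set after intersection with the expressed genes.
    """

    name: str
    origins: tuple[str, ...]
    members: dict[str, float]  # gene -> eigencentrality
    ccim: float
    community_fraction: float
    core_ratio: float = 0.90

    def __post_init__(self) -> None:
        if self.name not in self.members:
            raise ValueError("central gene must be a member")
        central = self.members[self.name]
        if any(v > central + 1e-12 for v in self.members.values()):
            raise ValueError("central gene must have the maximum eigencentrality")

    @property
    def central_eigenvalue(self) -> float:
        return self.members[self.name]

    @property
    def core(self) -> tuple[str, ...]:
        cutoff = self.core_ratio * self.central_eigenvalue
        return tuple(g for g, v in self.members.items() if v >= cutoff - 1e-12)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.members)

    def as_gene_set(self) -> GeneSet:
        return GeneSet(name=self.name, description=";".join(self.origins),
                       genes=tuple(self.members), source="adapted")

    def __len__(self) -> int:
        return len(self.members)


def as_gene_sets(items: Iterable[GeneSet | AdaptedSignature]) -> list[GeneSet]:
    """Coerce a mixed iterable of gene sets / adapted signatures to GeneSet."""
    out = []
    for it in items:
        out.append(it.as_gene_set() if isinstance(it, AdaptedSignature) else it)
    return out
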