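"""Readers and writers for the formats the pipeline touches.

GMT (Broad dialect), dense TSV count/clinical matrices, wide DepMap-style
CSV score matrices, and a JSON serialization of adapted-signature
collections. All readers validate and fail with located errors; none of
them guess.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path
from typing import Iterable

import pandas as pd

from .types import AdaptedSignature, ExpressionMatrix, GeneSet, GeneSetCollection, RAW_COUNTS

log = logging.getLogger(__name__)

_DEPMAP_COL = re.compile(r"^\s*(?P<symbol>\S+)\s*(?:\((?P<entrez>[^)]*)\))?\s*$")


class ParseError(ValueError):
    """A malformed input file; the message carries file/line coordinates."""


def read_gmt(path: str | Path, source: str = "user") -> GeneSetCollection:
    """Read a GMT file (one set per line: name TAB description TAB genes...).

    Within-line duplicate genes are dropped preserving first occurrence.
    An empty file yields an empty collection.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    names: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s); "
                    "expected name, description and at least one gene"
                )
            name, description, *genes = fields
            genes = [g for g in genes if g]  # trailing tabs are tolerated
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in names:
                raise ParseError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            names.add(name)
            sets.append(GeneSet(name=name, description=description,
                                genes=tuple(genes), source=source))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection | Iterable[GeneSet], path: str | Path) -> Path:
    """Write a collection to GMT. Tabs inside descriptions become spaces."""
    path = Path(path)
    sets = list(collection)
    with path.open("w", encoding="utf-8") as fh:
        for s in sets:
            desc = s.description
            if "\t" in desc:
                log.warning("tab in description of %s replaced by space", s.name)
                desc = desc.replace("\t", " ")
            fh.write("\t".join([s.name, desc, *s.genes]) + "\n")
    return path


def read_counts_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a dense TSV of raw counts: header row of sample ids, first
    column gene ids. Rejects non-numeric cells, missing values, duplicate
    gene ids and negative counts.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ParseError(f"{path}: duplicate gene id(s): {dupes[:5]}")
    bad = df.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        gene = bad.index[bad.isna().any(axis=1)][0]
        sample = bad.columns[bad.loc[gene].isna()][0]
        raise ParseError(f"{path}: non-numeric or missing value at gene {gene!r}, sample {sample!r}")
    if (bad.to_numpy() < 0).any():
        gene = bad.index[(bad < 0).any(axis=1)][0]
        raise ParseError(f"{path}: negative count in gene {gene!r}")
    return ExpressionMatrix(values=bad, stage=RAW_COUNTS)


def read_expression_tsv(path: str | Path, stage: str) -> ExpressionMatrix:
    """Read a genes x samples TSV at an arbitrary stage (e.g. log_cpm)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df.astype(float), stage=stage)


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    m.values.to_csv(path, sep="\t")
    return path


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV keyed by ``sample_id``.

    Recognized columns: ``survival_time`` (days, > 0), ``event`` (0/1) and
    optional ``paired_nontumor_id``; any other columns ride along as group
    labels.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: clinical table must have a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids in clinical table")
    if "event" in df.columns:
        ev = df["event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ParseError(f"{path}: 'event' must be 0 or 1")
        if "survival_time" not in df.columns:
            raise ParseError(f"{path}: 'event' present without 'survival_time'")
        has_event = df["event"].notna()
        if df.loc[has_event, "survival_time"].isna().any():
            raise ParseError(f"{path}: survival_time missing for samples with an event status")
        t = df.loc[has_event, "survival_time"]
        if (t <= 0).any():
            raise ParseError(f"{path}: survival_time must be > 0")
    return df.set_index("sample_id", drop=False)


def write_adapted_collection(signatures: Iterable[AdaptedSignature], path: str | Path) -> Path:
    """Serialize adapted signatures to JSON with deterministic key order."""
    path = Path(path)
    payload = []
    for s in signatures:
        payload.append({
            "name": s.name,
            "origins": list(s.origins),
            "ccim": s.ccim,
            "community_fraction": s.community_fraction,
            "core_ratio": s.core_ratio,
            "members": {g: round(v, 12) for g, v in s.members.items()},
            "core": list(s.core),
        })
    with path.open("w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")
    return path


def read_adapted_collection(path: str | Path) -> list[AdaptedSignature]:
    with Path(path).open("r", encoding="utf-8") as fh:
        payload = json.load(fh)
    out = []
    for d in payload:
        out.append(AdaptedSignature(
            name=d["name"],
            origins=tuple(d["origins"]),
            members={g: float(v) for g, v in d["members"].items()},
            ccim=float(d["ccim"]),
            community_fraction=float(d["community_fraction"]),
            core_ratio=float(d.get("core_ratio", 0.90)),
        ))
    return out


def read_depmap_matrix(path: str | Path) -> pd.DataFrame:
    """Read a DepMap-style wide CSV (cell lines x genes).

    Gene columns are labeled ``"SYMBOL (entrez)"``; the parenthetical is
    stripped so downstream code works in plain symbols.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    renamed = {}
    for col in df.columns:
        m = _DEPMAP_COL.match(str(col))
        renamed[col] = m.group("symbol") if m else str(col)
    df = df.rename(columns=renamed)
    if df.columns.has_duplicates:
        dupes = sorted(df.columns[df.columns.duplicated()].unique().tolist())
        raise ParseError(f"{path}: duplicate gene symbols after stripping ids: {dupes[:5]}")
    return df.astype(float)


def write_score_matrix(scores: pd.DataFrame, path: str | Path) -> Path:
    """Write a signatures x samples score matrix as TSV."""
    path = Path(path)
    scores.to_csv(path, sep="\t")
    return path


def read_score_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
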