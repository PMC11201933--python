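"""CRISPR-screen vulnerability summaries for adapted signatures.

Gene dependency scores live in [0, 1] (0 = the cell line does not need the
gene, 1 = fully dependent); gene effect scores are unbounded with 0 = no
effect of the knockout, negative = deleterious for the cell, positive =
protective. Per signature, each member gene is summarized across cell
lines and ranked by median dependency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import AdaptedSignature, GeneSet

log = logging.getLogger(__name__)

DELETERIOUS_BELOW = -0.5

DELETERIOUS = "deleterious"
NEUTRAL = "neutral"
PROTECTIVE = "protective"


@dataclass
class PerturbationScores:
    """Parallel cell-line x gene matrices of dependency and effect."""

    dependency: pd.DataFrame
    effect: pd.DataFrame

    def __post_init__(self) -> None:
        dep = self.dependency.to_numpy(dtype=float)
        if np.nanmin(dep) < 0 or np.nanmax(dep) > 1:
            raise ValueError("dependency scores must lie in [0, 1]")
        if not self.dependency.index.equals(self.effect.index) or \
           not self.dependency.columns.equals(self.effect.columns):
            raise ValueError("dependency and effect matrices must share axes")

    def subset_lines(self, lines) -> "PerturbationScores":
        return PerturbationScores(dependency=self.dependency.loc[lines],
                                  effect=self.effect.loc[lines])


def classify_effect(median_effect: float,
                    deleterious_below: float = DELETERIOUS_BELOW) -> str:
    """Label a median gene-effect score.

    Below the (negative) threshold the knockout is deleterious; above its
    magnitude the gene is protective; otherwise neutral. The threshold is
    a convention, not a measured constant, and is surfaced in output
    metadata.
    """
    if not np.isfinite(median_effect):
        raise ValueError("median effect must be finite")
    if median_effect < deleterious_below:
        return DELETERIOUS
    if median_effect > abs(deleterious_below):
        return PROTECTIVE
    return NEUTRAL


def signature_vulnerability(scores: PerturbationScores,
                            signature: AdaptedSignature | GeneSet,
                            deleterious_below: float = DELETERIOUS_BELOW
                            ) -> pd.DataFrame:
    """Per-gene dependency/effect summary for one signature.

    Rows are the signature genes found in the matrices, ranked by median
    dependency descending; genes absent from the screen are omitted with a
    logged count. Raises if no signature gene is screened.
    """
    genes = [g for g in signature.genes if g in scores.dependency.columns]
    missing = len(signature.genes) - len(genes)
    if missing:
        log.info("signature_vulnerability: %d gene(s) of %s absent from the screen",
                 missing, signature.name)
    if not genes:
        raise ValueError(f"no gene of {signature.name!r} is present in the screen")
    rows = []
    for g in genes:
        dep = scores.dependency[g].dropna().to_numpy()
        eff = scores.effect[g].dropna().to_numpy()
        med_eff = float(np.median(eff))
        rows.append({
            "gene": g,
            "n_lines": len(dep),
            "median_dependency": float(np.median(dep)),
            "iqr_dependency": float(np.subtract(*np.percentile(dep, [75, 25]))),
            "median_effect": med_eff,
            "iqr_effect": float(np.subtract(*np.percentile(eff, [75, 25]))),
            "effect_class": classify_effect(med_eff, deleterious_below),
        })
    out = pd.DataFrame(rows).sort_values(
        by=["median_dependency", "gene"], ascending=[False, True],
        kind="mergesort").set_index("gene")
    out.attrs["deleterious_below"] = deleterious_below
    out.attrs["signature"] = signature.name
    return out
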