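"""CRISPR-screen vulnerability summary for an adapted signature.

Builds a small synthetic DepMap-style screen (cell lines x genes) with
gene dependency in [0, 1] and unbounded gene effect, then ranks a
signature's genes by how essential they are across the cell lines.
"""

import numpy as np
import pandas as pd

import coexsig as cx

rng = np.random.default_rng(3)
lines = [f"LIVER-{i:02d}" for i in range(12)]
genes = ["HMGCR", "FDPS", "MVD", "IDI1", "NSDHL", "SQLE"]
# essential genes: high dependency, strongly negative effect
dep_center = {"HMGCR": 0.95, "FDPS": 0.9, "MVD": 0.85, "IDI1": 0.4,
              "NSDHL": 0.05, "SQLE": 0.3}
eff_center = {"HMGCR": -1.8, "FDPS": -1.5, "MVD": -1.2, "IDI1": -0.3,
              "NSDHL": 0.7, "SQLE": -0.2}
dependency = pd.DataFrame(
    {g: np.clip(dep_center[g] + rng.normal(0, 0.05, len(lines)), 0, 1) for g in genes},
    index=lines)
effect = pd.DataFrame(
    {g: eff_center[g] + rng.normal(0, 0.15, len(lines)) for g in genes},
    index=lines)
screen = cx.PerturbationScores(dependency=dependency, effect=effect)

signature = cx.AdaptedSignature(
    name="IDI1", origins=("MEVALONATE_PATHWAY",),
    members={"IDI1": 1.0, "HMGCR": 0.97, "FDPS": 0.95, "MVD": 0.93,
             "NSDHL": 0.6, "SQLE": 0.91},
    ccim=0.4, community_fraction=0.6)

table = cx.signature_vulnerability(screen, signature)
print(table.round(3).to_string())
print("\nGenes at the top (dependency near 1, strongly negative effect) are")
print("the ones the cell lines cannot survive losing - candidate targets.")
print("A positive median effect (e.g. NSDHL) means the knockout protects the cell.")
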