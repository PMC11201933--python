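"""Adapt a poorly co-expressed gene set into a co-expressed signature.

Simulates a cohort with a planted co-expressed module, normalizes it
(filter / TMM / log-CPM), and adapts a gene set that is 70% module genes
and 30% unrelated genes. The adapted signature should keep the module and
shed the noise, raising the median gene-to-gene correlation (MGGC).
"""

import coexsig as cx

plan = cx.ModulePlan(seed=7)
counts, truth = cx.simulate_counts(plan)
logcpm, norm = cx.normalize_pipeline(counts)
print(f"simulated {counts.shape[0]} genes x {counts.shape[1]} samples; "
      f"{logcpm.shape[0]} genes pass the low-expression filter")

sets = cx.simulate_gene_sets(
    truth, [cx.GeneSetSpec("MIXED_SET", size=40, module="module_1",
                           module_fraction=0.7)], seed=7)
origin = sets["MIXED_SET"]

signatures = cx.adapt_gene_set(origin, logcpm, ccim=0.4, seed=17)
sig = signatures[0]
d_origin = cx.coexpression_diagnostics(origin, logcpm)
d_adapted = cx.coexpression_diagnostics(sig, logcpm)

print(f"\norigin set: {len(origin)} genes, MGGC = {d_origin.mggc:.3f}")
print(f"adapted signature '{sig.name}': {len(sig)} genes "
      f"({sig.community_fraction:.0%} of the expressed set), "
      f"MGGC = {d_adapted.mggc:.3f}")
print(f"core genes (eigencentrality >= 90% of the central gene's): {len(sig.core)}")
truth_frac = sum(truth[g] == 'module_1' for g in sig.genes) / len(sig)
print(f"{truth_frac:.0%} of the adapted members are true planted-module genes")
print("\nMGGC rising from ~0.2 to ~0.75 means the community moves together —")
print("the adapted signature is far more co-expressed than its public origin.")
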