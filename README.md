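# coexsig

**Context-specific adaptation of public gene signatures via co-expression
graphs**, with single-sample enrichment scoring, survival stratification and
CRISPR-vulnerability summaries downstream.

## The problem

Public gene-set collections (MSigDB Hallmark/C2-CP, Metabolic Atlas
pathways, ...) are written for the average transcriptome. In a specific
disease context — a tumor cohort, say — the members of such a set are often
only weakly co-expressed, so enrichment scores built on them mix signal
with noise. `coexsig` rebuilds each public set into one or more compact,
highly co-expressed *adapted signatures* that reflect how the pathway is
actually wired in the cohort at hand, then quantifies those signatures per
sample and links them to outcome and to genetic vulnerability.

## The method

Starting from a raw count matrix (genes × samples):

1. **Preprocess** — drop genes with < 1 count in more than 30% of samples;
   compute TMM normalization factors (trimmed mean of M-values, 30%/5%
   double trim, precision weights); transform to log2-CPM with voom offsets:
   `log2((count + 0.5) / (lib·TMM + 1) · 1e6)`.
2. **Graph adaptation** — per gene set, compute the pairwise Spearman
   correlation matrix ρ on log-CPM; keep edges with ρ ≥ CCIM (correlation
   cutoff of the input matrix, default 0.4); detect Louvain communities at
   resolution 1; keep communities holding ≥ 20% of the expressed set; name
   each retained community after its maximum eigenvector-centrality member
   (the *central gene*, centrality 1 after rescaling); mark the *core* as
   members with centrality ≥ 0.9 × the central gene's; merge same-central-
   gene signatures across origins.
3. **Validation** — hypergeometric over-representation of each adapted
   signature against the full reference collections (minGSSize 5, BH
   adjustment); a signature survives only if its top-ranked hit is its own
   origin set (first-rank rule).
4. **Scoring** — single-sample GSEA per sample: genes ranked by expression,
   score = Σ over ranked positions of (rank^0.25-weighted in-set ECDF −
   out-of-set ECDF); signatures with < 2 expressed genes are dropped.
5. **Downstream statistics** — Shapiro–Wilk-gated group comparisons
   (t / Wilcoxon for 2 groups, ANOVA / Kruskal–Wallis + pairwise for ≥ 3);
   50:50 cohort splitting; median-split Kaplan–Meier survival with the
   log-rank test and the median survival difference MSD = median(high) −
   median(low); paired tumor/non-tumor signed-rank comparisons.
6. **Vulnerability** — per-gene median/IQR of DepMap-style CRISPR gene
   dependency (∈ [0,1]) and gene effect (< 0 deleterious) across cell
   lines, ranked by median dependency.

A first-class synthetic-data module generates count matrices with planted
co-expressed modules (negative-binomial counts over calibrated latent
factors), gene sets spanning them, score-linked exponential survival and
dependency screens, so the whole pipeline is testable without downloads.

## Worked example

`python examples/01_adapt_signatures.py` simulates a 160-gene × 200-sample
cohort with a planted 30-gene co-expressed module (target within-module
Spearman 0.8), normalizes it, and adapts a 40-gene set that is 70% module
genes / 30% unrelated genes:

```
simulated 160 genes x 200 samples; 160 genes pass the low-expression filter

origin set: 40 genes, MGGC = 0.177
adapted signature 'M1_G000': 28 genes (70% of the expressed set), MGGC = 0.770
core genes (eigencentrality >= 90% of the central gene's): 28
100% of the adapted members are true planted-module genes
```

MGGC (median gene-to-gene correlation) jumps from 0.18 to 0.77: the
adaptation keeps exactly the planted module and sheds the 12 unrelated
genes, at the cost of a 30% reduction in set size. The other examples walk
through first-rank validation + ssGSEA scoring (`02`), median-split
survival (`03`, printing KM medians, log-rank p and MSD) and CRISPR
vulnerability ranking (`04`).

A thin CLI mirrors the library:

```bash
coexsig simulate --seed 1 --out data/
coexsig normalize --counts data/counts.tsv --out data/logcpm.tsv
coexsig adapt --logcpm data/logcpm.tsv --gmt data/sets.gmt --ccim 0.4 --out data/adapted.json
coexsig validate --adapted data/adapted.json --gmt data/sets.gmt --out data/validated.json
coexsig score --logcpm data/logcpm.tsv --adapted data/validated.json --out data/scores.tsv
coexsig survival --scores data/scores.tsv --clinical data/clinical.tsv --out data/survival.tsv
```

## Layout

- `src/coexsig/` — library (`io`, `simulate`, `preprocess`, `graph`,
  `enrich`, `ssgsea`, `survival`, `depmap`, `cli`)
- `examples/` — one narrative script per capability
- `tests/` — pytest suite with independent oracles (exact hypergeometric
  enumeration, power-iteration centrality, exhaustive modularity search,
  hand-computed log-rank tables, a reference TMM implementation and an
  edgeR cross-check)
- `docs/methods.md` — modeling and design notes
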