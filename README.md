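# coexmod

Co-expression module discovery and promoter chromatin-state enrichment for
genotype × differentiation-time expression studies.

## The problem

When a chromatin repressor (e.g. the PRC2 methyltransferase EZH2, which
deposits H3K27me3) is knocked out in neural stem cells, genes that depend on
it for silencing become *derepressed* — they rise in knockout cultures early
in a differentiation time course while staying flat in controls. `coexmod`
finds such genes as co-expression **modules**: clusters of probes with
correlated expression across samples, summarized by an **eigengene** (the
module's first principal component), screened for knockout-specific early
elevation, and cross-referenced against H3K27me3/H3K4me3 ChIP-seq peaks at
their promoters to ask whether they are plausible direct targets.

The pipeline is aimed at bulk expression matrices (microarray or RNA-seq
intensities) with a two-genotype × multi-day design, plus peak interval
files (BED) and a TSS annotation (BED or GFF).

## Method

1. **Preprocess** — quantile-normalize all samples to the common
   mean-of-sorted-vectors distribution; remove sample outliers whose
   standardized connectivity `z.K_i = (K_i − mean K)/sd K`,
   `K_i = Σ_{j≠i} cor(s_i, s_j)`, falls below a cut (default −2).
2. **Cluster** — Pearson correlation for all probe pairs; complete-linkage
   hierarchical clustering with `d = 1 − cor`; cut the dendrogram at a
   *static* height `1 − q`, where `q` is the quantile keeping the top 2% of
   pairwise correlations; clusters with ≥ 10 members become modules.
3. **Summarize & merge** — each module's eigengene is the unit-variance PC1
   of its standardized submatrix; modules whose eigengenes correlate above
   0.85 are merged greedily in order of highest correlation, recomputing
   eigengenes after every merge.
4. **Assign** — every probe's module membership kME is its correlation with
   each eigengene; a probe joins the module of its strongest *positive* kME
   if the correlation is significant after Bonferroni correction over
   (probes × modules).
5. **Screen** — per module, the contrast `mean eigengene(KO, early days) −
   mean eigengene(control, early days)` with a one-sided permutation p
   (genotype labels shuffled within each day); positive, significant modules
   are flagged and their top members ranked by kME.
6. **Chromatin** — a gene is H3K27me3/H3K4me3-marked if any peak overlaps
   the half-open ±1 kb window around its TSS; promoters are classed
   bivalent / K27-only / K4-only / unmarked, and marking of a gene set vs a
   universe is tested with a one-sided hypergeometric p.

A synthetic-data generator plants modules driven by smooth latent day
profiles (plus a knockout-early derepression offset) in Gaussian background
noise, with matched TSS/peak fixtures, so every stage is verifiable by
planted-structure recovery without external data.

## Worked example

```python
from coexmod import (SimulationDesign, simulate_expression, simulate_intervals,
                     correlation_model, static_cut_height, cluster_and_cut,
                     attach_eigengenes, merge_modules, assign_membership,
                     derepression_screen, classify_promoters, set_enrichment)

data, truth = simulate_expression(SimulationDesign(seed=1))   # 2000 probes, 30 samples
model = correlation_model(data)
height = static_cut_height(model, top_fraction=0.02)
modules = merge_modules(data, attach_eigengenes(
    data, cluster_and_cut(model, height, min_size=10)), threshold=0.85)
membership = assign_membership(data, modules, alpha=0.05)
screen = derepression_screen(modules.eigengenes, data.sample_meta, seed=1)
print(f"cut height {height:.3f}, {len(modules.eigengenes)} modules, "
      f"flagged: {screen.flagged}")

iv = simulate_intervals(truth, seed=2, marked_modules=truth.derepressed_modules)
states = classify_promoters(iv.tss, iv.k27_peaks, iv.k4_peaks, window_bp=1000)
flagged_genes = [g for g in membership.assigned.dropna().index
                 if membership.assigned[g] in screen.flagged]
enr = set_enrichment(states, flagged_genes, list(membership.assigned.dropna().index))
print(f"K27 near TSS: {enr.marked_in_set}/{enr.set_size} "
      f"({100*enr.set_fraction:.0f}%) vs {enr.marked_in_universe}/{enr.universe_size} "
      f"({100*enr.universe_fraction:.0f}%), p={enr.p_value:.1e}")
```

Output:

```
cut height 0.613, 5 modules, flagged: ['M1']
K27 near TSS: 13/20 (65%) vs 22/158 (14%), p=6.8e-09
```

The cut height ~0.61 is the 98th-percentile correlation distance of this
matrix; the five planted modules are recovered and the one planted
derepressed module (M1) is flagged. M1's genes are strongly H3K27me3-marked
near their TSS relative to all module genes (65% vs 14%, hypergeometric
p ≈ 7e-09) — the signature of direct repressor targets.

The same stages are exposed as a CLI:
`coexmod simulate|preprocess|modules|screen|enrich|run` (see `--help`);
`coexmod run --config config.yaml --out DIR` executes the whole pipeline
and writes a manifest capturing parameters, seeds and input checksums.

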