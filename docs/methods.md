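# Methods

## Model and procedure

`coexmod` treats a probe × sample expression matrix as a correlation
network. The analysis assumes (i) module structure is expressed as positive
pairwise Pearson correlation across samples, (ii) a module's activity is
well summarized by one latent per-sample score (its eigengene, the first
principal component of the standardized member submatrix), and (iii)
derepression manifests as an additive shift of that latent score in
knockout samples at early differentiation days. No soft-thresholding,
adjacency powers or topological-overlap transforms are applied: clustering
acts directly on the unweighted `1 − cor` distance, and the dendrogram is
cut at one fixed height (a *static* cut), not by dynamic branch cutting.

Stages and their contracts:

- **Quantile normalization.** Every sample is mapped onto the across-sample
  mean of sorted value vectors. Ties within a sample receive the mean of
  the reference values at their tied ranks; this keeps equal inputs equal
  at the cost of strict idempotence when samples differ in tie structure
  (a second pass can shift untied samples by the tie-collapse distortion;
  with continuous intensities this is immaterial).
- **Sample QC.** Connectivity `K_i = Σ_{j≠i} cor(s_i, s_j)` over probes,
  standardized within the retained set; samples with `z < z_cut` are
  removed and the procedure iterates (default `z_cut = −2`, ≤ 5 rounds).
  If all profiles are identical (`sd K = 0`) every z is defined as 0 and
  nothing is removed. An explicit a-priori exclusion list is honoured
  first, for samples removed on technical grounds (e.g. hybridized on a
  different day). Default order is normalize → QC → re-normalize the
  retained samples (the re-normalization is flag-controlled).
- **Static cut height.** `1 − q`, with `q` the `(1 − top_fraction)`
  linear-interpolation quantile of the signed upper-triangle correlations
  (default top 2%). Negative correlations count as small, consistent with
  membership being defined by *positive* kME. An explicit height override
  is accepted for reproducing a published cut exactly.
- **Clustering.** Complete linkage via `scipy.cluster.hierarchy.linkage`
  on the condensed `1 − cor` matrix; flat clusters from
  `fcluster(..., criterion="distance")`, which realizes the
  maximal-subtree-below-height semantics. Clusters with fewer than
  `min_size = 10` members are left unassigned at this stage. scipy's
  NN-chain algorithm is deterministic; exact distance ties (measure-zero
  for continuous data) resolve by its internal order.
- **Eigengene.** Rows standardized to zero mean / unit variance (ddof = 1)
  before SVD; per-sample PC1 scores rescaled to unit variance. Sign
  convention: non-negative correlation with the mean standardized member
  profile; if that correlation is exactly 0 (e.g. a module of `x` and `−x`
  in equal numbers), the sign making the first nonzero probe loading
  positive is used. Variance explained is `S₁²/ΣSᵢ²`.
- **Merging.** Greedy: repeatedly merge the pair of modules with the
  highest eigengene correlation while it *strictly exceeds* the threshold
  (default 0.85), recomputing the merged eigengene before the next
  decision; every merge is logged with its correlation. On termination no
  pair exceeds the threshold by construction.
- **Membership (kME).** Every probe — clustered or not — is correlated
  with every eigengene; two-sided p-values use the exact t transform
  `t = r√((n−2)/(1−r²))` with `n − 2` df. A probe is assigned to its
  strongest positive kME module iff that p beats
  `alpha / (n_probes × n_modules)` (Bonferroni over the full test family).
  Probes whose best kME is negative are never assigned.
- **Derepression screen.** Statistic: mean eigengene over knockout samples
  at early days minus the control mean at the same days (early days
  default {0, 1, 2} of the {0, 1, 2, 4, 7} design — "early" is a free
  choice made once and kept configurable). Null: genotype labels permuted
  within each day, preserving the time-course blocking;
  `p = (1 + #{permuted ≥ observed}) / (1 + n_permutations)` (never zero).
  Flag rule: statistic > 0 and p < 0.05. This formalizes what is otherwise
  a visual judgement of eigengene plots; the threshold is configurable.
- **Promoter states.** A gene is marked for a histone modification iff ≥ 1
  base of any peak of that mark overlaps the half-open symmetric window
  `[tss − window, tss + window)` (default 1 kb each side;
  strand-independent, the least-assuming reading of a plain distance).
  Both marks → bivalent; K27-only; K4-only; unmarked. Coordinates are BED
  dialect (0-based half-open) throughout; GFF input is converted on read
  with the strand-aware 5′ end as the TSS. The hypergeometric
  over-representation p on set-vs-universe marking counts is an extension
  for usability — the classification itself is the primary output, and the
  universe is always supplied explicitly because "all module genes" and
  "all expressed genes" are both defensible universes.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical design* of a two-genotype
(control / repressor-knockout) differentiation time course: days
{0, 1, 2, 4, 7} × 3 replicates per genotype = 30 samples, ~2,000 probes of
which five planted modules (sizes 20–60) ride smooth latent day-profiles
and the rest are i.i.d. Gaussian noise. Latent profiles are random cubic
polynomials in rescaled day, standardized to zero mean / unit variance
across samples — slowly varying trajectories, drawn with rejection so no
two latents correlate above 0.7 (planted modules are distinct by
construction). Module members are `latent + N(0, σ_w)` with
`σ_w = 0.8165`, giving a population within-module correlation
`1/(1 + σ_w²) ≈ 0.6`; one module additionally receives a `+2.0` offset in
knockout samples at days ≤ 2 (the planted derepression). Replicate count
(3) is a free design choice giving dimensionality comparable to a
typical retained microarray set of ~24 samples.

Matched interval fixtures put one TSS per gene on a single synthetic
chromosome, spaced 10 × window apart so promoter windows never overlap
(isolating the overlap logic), and draw per-gene Bernoulli marks: H3K27me3
at 0.74 for module-class genes vs 0.07 for background, H3K4me3 at 0.70 vs
0.50 — so bivalent promoters concentrate in modules. The module class
defaults to all planted-module genes and can be restricted (e.g. to the
derepressed modules) to emulate repressor targets specifically. Unmarked
genes may receive decoy peaks well outside every window.

Passing tests on these data show the *pipeline machinery* is correct —
clustering agrees with an independent agglomeration oracle, eigengenes
with a dense decomposition, permutation p-values with exhaustive
enumeration, interval overlap with a quadratic scan, and planted structure
is recovered under realistic noise. They do not show robustness to what
the generator omits: probe-level microarray artifacts, batch effects,
heavy-tailed or correlated noise, overlapping/nested modules, negative
within-module correlation, or read-level ChIP-seq noise (peaks are
consumed as given).

## Numerical choices and degenerate inputs

- Correlations are clipped to [−1, 1] and symmetrized before clustering;
  zero-variance probes are rejected or dropped explicitly, never silently.
- Missing expression values are refused at load rather than imputed.
- `p = 0` is reported for |r| = 1 (the t transform overflows gracefully).
- Degenerate cut (all pairwise correlations equal) warns and returns
  `1 − that value`; quantile convention is linear interpolation, pinned so
  the height is bit-reproducible.
- kME tie between modules resolves to the first module in index order via
  argmax; top-member kME ties break by probe ID (stable sort).
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical
  matrices, truths, intervals, and pipeline output files.

## Problem sizes

Default verification runs use 2,000 probes × 30 samples for recovery
benchmarks (50 seeds), 100-instance oracle sweeps at ≤ 60 probes, 100-seed
screens and marking-recovery sweeps at ~2,000 genes, and a 5,566-gene
universe with a 46-gene set for the flagged-set marking fraction — sizes
chosen to exercise every code path at desk scale.

## Known limitations

- The static cut and minimum module size make small or weakly separated
  modules invisible by design; the Bonferroni kME gate intentionally
  leaves weakly correlated members unassigned (~20% of members at
  within-module correlation 0.6 with 30 samples), so module recovery is
  precise rather than exhaustive.
- The merge step's greedy order can depend on sample noise when two pairs
  correlate almost identically; the merge log records the realized order.
- The screen assumes exchangeability of genotype labels within a day;
  confounding between genotype and batch within a day is not modelled.
- Enrichment p-values assume genes are exchangeable draws, ignoring
  correlated chromatin domains between neighbouring genes.
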