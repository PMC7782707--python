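# Methods

This note documents the models, rules and numerical choices behind each
stage of `popsc`, the assumptions they make, and what the synthetic-data
generator does and does not emulate.

## Data model and formats

The pipeline's unit is a sparse genes × cells integer UMI matrix
(`UmiMatrix`) whose per-cell metadata carries a sample identifier, a
condition (`control` or `POP`) and, for the downstream stages, a cell-type
label. On disk this is the 10x-style MTX triplet (MatrixMarket coordinate
integer matrix, feature TSV, barcode TSV) plus a `metadata.tsv`. The reader
detects on-disk orientation from the id-table lengths and normalizes to
genes × cells; a square matrix is taken as rows = genes by convention.
Matrices are 0-based in memory and 1-based on disk per the MatrixMarket
standard. Mitochondrial genes are identified by the case-insensitive `MT-`
symbol prefix — the human genome-annotation convention — because no explicit
mitochondrial gene list travels with the data. Gene identifiers are symbols
throughout; ligand–receptor tables and GMT gene sets are matched by symbol.

## Quality control, normalization, HVGs

Cells are kept when (a) they detect between 500 and 3500 genes, inclusive at
both ends (a gene is "detected" at count ≥ 1), and (b) their mitochondrial
count fraction is strictly below 0.10, computed on raw counts before any
filtering. The QC report counts failures per rule; cells can fail several
rules at once, so rule counts can exceed removals. Filtering is idempotent
and never touches the gene set.

Normalization is ln(1 + count / cell_total × 10,000): each cell is scaled
to a common size factor of 10⁴ molecules and log-transformed with natural
log. Natural log is the convention of the standard single-cell toolchain;
changing the base would only rescale log-space statistics, and the choice is
recorded in the matrix provenance string.

Highly variable genes are scored by standardized variance: per-gene raw
count variance is regressed on mean (log10–log10) with a degree-2
polynomial, each count is standardized by the trend-expected SD and clipped
at √N, and the variance of the clipped values is the score. The degree-2
polynomial is a smooth, deterministic stand-in for a local regression and
behaves equivalently on the generator's mean range; ties are broken by gene
id so selection is fully deterministic. Constant genes are never selected;
if fewer than `n_hvg` genes vary, all varying genes are returned.

## Marker detection

One-vs-rest per cell type, two-sided Wilcoxon rank-sum. Genes are
pre-filtered at detection fraction ≥ 0.10 (in either group) and
|log2FC| ≥ 0.25, where the fold change is computed on de-logged means with a
+1 pseudocount — the defaults and fold-change convention of the familiar
`FindAllMarkers` contract. The rank-sum p-value uses exact enumeration when
n₁ + n₂ ≤ 12 without ties, and the tie-corrected normal approximation with
continuity correction otherwise; the approximation is conservative in the
far tail (verified against full enumeration). A marker is significant at
p < 0.05 with positive fold change. Label levels with fewer than 3 cells
(configurable) are skipped with a warning rather than guessed at.

## Pseudobulk NB differential expression

Within each (cell type, condition, sample) stratum, cells are randomly
partitioned (seeded) into chunks of 20. The remainder rule is ours, since
only the group size is prescribed: a remainder of ≥ 10 cells becomes its own
replicate; a smaller remainder is merged into the last full chunk; strata
under 10 cells are dropped with a warning. Every cell of a retained stratum
is summed exactly once, so gene-wise stratum totals are conserved as exact
integers — a tested invariant.

The count model per gene g and replicate i is NB(μ_gi, φ_g) with
log μ_gi = β₀g + β₁g·POP_i + log N_i, N_i the replicate's total count.
Offsets are plain log column totals rather than TMM: pseudobulks within a
stratum share cell-type composition, making compositional normalization a
second-order refinement (a config switch reserves the option). Dispersion
estimation follows the Cox–Reid adjusted-profile-likelihood approach: for a
grid of 47 φ values (1e-6 and log-spaced 1e-4…10), every gene's GLM is
refit by vectorized Fisher scoring and its APL = loglik − ½·log det(XᵀWX)
recorded; the common dispersion maximizes the gene-summed APL with parabolic
refinement in log φ, and tagwise dispersions maximize each gene's APL plus
the gene-averaged APL weighted by prior_reps/R (default prior weight
equivalent to 10 replicates), shrinking noisy per-gene estimates toward the
common value. The condition effect is then tested with the tagwise φ fixed:
twice the log-likelihood difference between the full and intercept-only fits
against χ²(1); log2FC = β₁/ln 2. Non-converged genes are flagged and
assigned p = 1, never dropped. At φ = 0 the machinery reduces exactly to a
Poisson deviance test (tested against statsmodels to 1e-6), and at fixed φ
it reproduces edgeR `glmLRT` p-values to ~1e-9 (tested via Rscript).

Treating pseudobulks as technical replicates understates biological
between-sample variance and is anti-conservative; this is a deliberate,
faithful reproduction of the design the pipeline implements, not an
oversight. The worked example shows the consequence: null genes are called
alongside planted ones. Calls are made at |log2FC| > 0.5 and p < 0.05; the
same thresholds apply to bulk count tables.

Whether cells should be randomized before chunking was unspecified; we
randomize with a logged seed, which makes replicates exchangeable within a
stratum and the whole stage reproducible.

## Ligand–receptor communication

Conditions are analyzed separately. Within a condition, the statistic for
(pair, sender, receiver) is ½·(mean ligand log-normalized expression in the
sender type + mean receptor expression in the receiver type) — the
arithmetic mean is the convention of the permutation framework this
reproduces. A pair is tested only if ligand and receptor are each expressed
(nonzero) in at least 10% of the sender and receiver populations
respectively, with the filter applied per type within each condition.
Significance comes from shuffling cell-type labels over all of the
condition's cells: 1,000 shared shuffles (each reused for every pair and
type pair), p = (1 + #{permuted ≥ observed}) / (P + 1), significant at
p < 0.01. The add-one estimator bounds p below by 1/(P+1) and avoids zero
p-values; a tolerance of 1e-9 relative on the ≥ comparison makes
permutation-invariant statistics count as ties (p = 1 for constant genes).
Fewer than 100 permutations are rejected as under-resolved. Pairs with
missing genes are skipped with a warning; multi-subunit complexes are out of
scope — pairs are single genes.

Graphs per condition weight each ordered type edge by its count of
significant pairs; the POP−control comparison reports per-edge weight
changes and gained (significant in POP only) / lost (control only) pair
sets, disjoint by construction. Note that elevating a ligand in one sender
type raises the statistic for every receiver whose receptor passes the
filter, so a planted interaction typically gains on several edges sharing
its sender — a structural property of mean-based scoring, visible in the
recovery tests.

## Proportions

Per cell type, fractions are cell counts over the pooled total of each
condition ("pooled" mode; a per-sample mode exists), and
log2FC = log2((f_POP + ε)/(f_control + ε)) with ε = 1/(2·smaller condition
total) — half a cell's worth — so types absent from one condition stay
finite and are flagged one-sided. Change is called at |log2FC| > 0.5; no
compositional-statistics correction is applied, matching the threshold-rule
design.

## Enrichment

Over-representation: per set, the 2×2 membership table of a query gene list
against a declared universe, two-sided Fisher exact (point-probability
rule), sets intersected with the universe first. Preranked GSEA: genes
sorted by descending score (deterministic gene-id tie-break), weighted KS
running sum with weight exponent 1 (hit steps ∝ |score|, uniform miss
steps), ES = the signed maximum deviation; the null re-draws random gene
sets of the same size, and p is the add-one fraction of same-sign
permutations at least as extreme — the sign-conditional denominator is what
makes null p-values uniform (tested by KS over repeated random sets). The
default ranking metric fed from a DE table is sign(log2FC) × −log10 p. No
multiple-testing correction is applied by default, matching the raw
p < 0.05 usage it reproduces; a BH option can be layered on by the caller.

## Clinical table statistics

Pooled-variance two-tailed Student t (df = n₁+n₂−2) accepting published
n/mean/SD summaries directly — SDs are sample (n−1) SDs, the SPSS
convention, which is required for the published p-values to reproduce.
Mann–Whitney U is exact by enumeration for n₁+n₂ ≤ 12 without ties, else
tie-corrected normal with continuity correction. For 2×2 tables both the
Fisher exact test (two-sided, point-probability rule) and the Pearson χ²
(optional Yates) are provided; the dispatcher prefers Fisher when any
expected cell is below 5, mirroring common crosstabs practice. The published
cohort table's categorical p-values (0.228, 0.553, 1.000) are reproduced by
the exact test, although its footnote names a χ² test; both are implemented
and the dispatcher documents which reproduces the table.

## The synthetic-data generator

Counts are gamma-Poisson: y ~ NB(mean = baseline_g × type_effect_gt ×
condition_effect_gtd × library_factor_c, dispersion φ_g), chosen because it
matches the NB model the DE stage assumes and has closed-form moments for
tests. Defaults (the desk-scale preset):

| parameter | default | rationale |
|---|---|---|
| genes | 1,500 (10 mitochondrial) | minutes-scale tests, full pipeline shape |
| cell types | 5 (epithelial, fibroblast, smooth muscle, endothelial, macrophage) | the dominant vaginal-wall populations |
| samples | 3 control + 3 POP, 400 cells each | smallest design with per-sample strata |
| proportions | epithelial 0.10→0.22, smooth muscle 0.25→0.13, others stable | the qualitative composition shift in prolapse, both planted shifts past the 0.5 log2FC threshold |
| baseline means | log-normal σ=1.2, scaled to 4,000 UMIs/cell | long-tailed expression; typical cells detect 650–1,250 of 1,500 genes, inside the QC window |
| dispersion | log-normal, median 0.2, σ=0.5 | typical single-cell NB dispersions |
| library factors | log-normal σ=0.3 | typical droplet depth spread |
| mitochondrial fraction | 5% of counts | healthy-cell level, half the QC cap |
| markers | 10 genes/type at +3 log2FC | drive marker recovery and realistic type structure |
| planted DEGs | 20 fibroblast genes at ±1.5 log2FC | recovery targets for the DE stage |
| planted LR | TGFB1→TGFBR2 (SMC→fibroblast), IL1B→IL1R1 (macrophage→SMC), POP-only, ×4 | the interactions highlighted in the tissue, as recovery targets |
| QC outliers | 10 low-library + 10 high-mito cells | violate exactly one rule each, by margin (×0.05 library; ×8 mitochondrial means) |

With 1,500 genes no cell can exceed the 3,500-gene ceiling, so
high-detected-gene violators are only meaningful when the simulated gene
count exceeds the cap; the preset plants none. `plant_baseline` pins planted
genes' per-cell baseline exactly (e.g. 2.5 per cell → pseudobulk mean 50
over 20 summed cells), used by the calibration studies.

The bulk companion draws gene × replicate NB counts with condition effects
applied to planted genes (baseline pinned at `bulk_mean`, default 50;
dispersion fixed at 0.2 by default so calibration conditions are exact).

What the generator does **not** emulate: doublets, batch/integration
effects, sample-level biological variability beyond library size (cells of
a type are exchangeable across samples within a condition), gene–gene
correlation beyond the planted structure, zero-inflation beyond NB, and
realistic gene-length or GC effects. Consequently, passing recovery tests
demonstrates correctness of the statistical machinery under its own model
assumptions — not robustness to the full messiness of real droplet data; in
particular the technical-replicate pseudobulk design will be more
anti-conservative on real data, where samples differ biologically.

## Problem sizes and numerical choices

Test and acceptance runs use the desk-scale preset (seconds per stage,
~15 s for the full acceptance sweep): NB-LRT null calibration on 1,000
genes × 3v3 replicates at φ = 0.2; planted-effect recovery on 3v3
pseudobulks of 20 summed cells at pseudobulk mean 50 (the dispersion of a
20-cell sum is ~φ_cell/20, which is what gives the stage its power at this
design size); LR null calibration pooled over three independent simulations
(~4,500 tested slots) against a 2-binomial-SE band around 0.01, noting that
slots sharing a gene are positively correlated so the binomial band is
approximate. GLM fitting clips the linear predictor at ±50, adds 1e-10
ridge jitter to XᵀWX, iterates Fisher scoring to a 1e-10 step tolerance
(60 iteration cap), and initializes from offset-adjusted log means.
P-values are clipped into (0, 1]. All randomness flows from explicit seeds
through `numpy.random.default_rng`; every stage is bit-reproducible given
its seed.

## Known limitations

- The pseudobulk design intentionally reproduces an anti-conservative
  testing scheme; interpret absolute DEG counts accordingly.
- The LR permutation test calibrates against label exchangeability; real
  cell-type structure (e.g. marker-driven library differences) makes
  unrelated genes deviate from that null, as the calibration study shows
  when markers are present.
- The HVG trend is a global polynomial; extreme mean ranges outside the
  generator's regime may need a local-regression trend.
- 2×2 tests beyond the published table's families (stratification,
  regression adjustment) are out of scope.
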