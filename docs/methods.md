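# Methods

`coexcons` implements a comparative coexpression workflow in three parts:
query-gene coexpression networks within one species, ortholog pairing
between two species, and an iterative expression-conservation (EC) score
for the paired genes. A synthetic-data generator with planted ground truth
stands in for RNA-seq data, so every stage is testable offline.

## Expression filtering and transformation

Input is a gene × sample FPKM matrix. Two filters run on the raw FPKM rows
before anything else:

- *non-expressed*: mean FPKM < 0.1 (strict; boundary retained);
- *constitutive*: coefficient of variation CV = sd/mean < 0.5, with the
  sample standard deviation (n−1 denominator).

Surviving rows are transformed cell-wise by `log2(x + 1)`. The pseudocount
is a deliberate choice: filtered matrices can still contain zero-FPKM cells
and `−inf` must never reach a correlation; the map is strictly monotone, so
rank-based statistics downstream are unaffected by it. The filter is
idempotent, and a removal report records every removed gene with its
reason(s) (`low_mean`, `low_cv`, or both).

Replicate columns are used as independent samples by default; an opt-in
`average_replicates` collapses them to per-tissue means. The pipeline log
states which convention a run used.

## Coexpression networks

For a set of query genes (e.g. one phylogenetic group of a gene family),
Spearman's ρ is computed between each query and every other gene, with
average ranks on ties and a two-sided p-value from the t approximation
`t = ρ·√((n−2)/(1−ρ²))`; an exact permutation p-value is available for
n ≤ 9. Edges require `|ρ| > 0.95` and `p < 1e−5` (both strict) and carry a
sign; negative coexpression is retained as its own edge class.

Edges are then rescored with the mutual rank,

    MR(ab) = √(Rank(a→b) · Rank(b→a)),

where `Rank(a→b)` is the position of b among **all** scored partners of a,
ordered by decreasing |ρ| (rank 1 = strongest, fractional average ranks on
ties). Spearman ρ on small panels is rank-based and takes rational values,
so exact ties are common; correlations are rounded to 12 decimals before
ranking so that mathematically equal values tie regardless of
floating-point summation order. An edge is flagged *reliable* when its MR
is among the smallest `k = ceil(0.01·N)` of the N scored pairs (ties at the
cutoff included). Smaller MR means stronger mutual coexpression; ranking by
|ρ| (not signed ρ) is the default so that strong negative partners rank
highly, with a signed option exposed. The top-1% cutoff is global over all
scored pairs by default.

Network-level summaries count, per query pair, the partners coexpressed
with both (shared neighbors), and per partner the number of queries it
connects to. Cross-species comparison maps a network through an ortholog
pairing and counts edges present in both species with the same sign.

## Ortholog pairing

"Highly similar orthologs" between species A and B satisfy two independent
criteria: (1) reciprocal best BLASTP hits, where hits with e-value ≥ 1e−5
are discarded *before* best-hit selection (a query whose best raw hit fails
the gate gets no ortholog, not its second-best), with ties broken by higher
bitscore and then lexicographically smallest subject id; and (2) both genes
belong to the same orthogroup. The e-value gate applies in both directions.
Multiple HSPs per (query, subject) are collapsed at load time to the
minimal-e-value/maximal-bitscore row.

Gene-family candidates are additionally screened for conserved domains: a
candidate must carry every required domain (default `DPBB_1` and
`Expansin_C`, the two domains characteristic of expansins). Domain names
are matched case-insensitively with `-` and `_` equivalent.

## Expression conservation (EC)

Species rarely share a tissue panel, so the two expression matrices cannot
be compared column-wise. EC instead compares correlation *structure*: align
n ortholog pairs as rows of a species-A and a species-B matrix, convert
each to an n × n Pearson correlation matrix R^A, R^B, and score pair i as
the correlation of row i of R^A with row i of R^B. The self position i is
excluded from both rows — it is 1 in both matrices and would add a constant
upward artifact (configurable).

The initial score EC₀ uses all partner positions equally. Each iteration
then focuses on positions that already look conserved:

    EC_k(i) = PCCw(R^A[i, g′], R^B[i, g′]),
    g′ = { l ≠ i : EC_{k−1}(l) > 0 },  w_l = EC_{k−1}(l)

where PCCw is a weighted Pearson correlation with weighted means and the
symmetric denominator `√(Σw(x−x̄)²)·√(Σw(y−ȳ)²)` — the only form bounded in
[−1, 1]. EC is recomputed for *every* pair each iteration; the positivity
rule governs only which pairs contribute as weights. Iteration stops when
`Σᵢ (EC_k(i) − EC_{k−1}(i))² < 0.1` (default tolerance), with a hard cap of
100 iterations and a `converged` flag. Pairs whose EC₀ is undefined
(degenerate rows) are dropped with a logged warning, and fewer than 3
positive-weight pairs raises a "weight support collapsed" error rather than
returning a meaningless statistic.

Distribution-level comparisons use the two-sided Mann-Whitney U test
(normal approximation with tie correction), and gene-set placement reports
the fraction of a subset at or above the genome-wide 95th-percentile EC
(nearest-rank quantile, with 1e−12 slack so values equal to the cutoff
count).

### Known small-sample bias of the iteration

EC₀ is unbiased under the null (independent species), but the iterative
reweighting is not: choosing weight genes by their own EC selects
correlation-matrix entries that are shared with every other row, which
drags all scores slightly positive. At 100 pairs the mean null EC is about
+0.07 even for completely structureless data, independent of the number of
conditions; the bias decays roughly as the pair count grows (≈ +0.04 at 400
pairs) and is negligible at genome scale (thousands of pairs). Analyses on
small pair sets should therefore compare EC distributions against a
matched null rather than against zero.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
tissue-driven coexpression and partially conserved ortholog expression —
not read-level data. It is a linear latent-factor model on the log2 scale:

    signal(g, s) = baseline + loading · activity(module(g), condition(s)) + ε,
    FPKM = 2^signal − 1 (floored at 0),   ε ~ N(0, noise_sd²)

Module activities are drawn standard-normal per condition, then
mean-centred and orthogonalized across modules (QR) within each species, so
the planted programs are exactly uncorrelated over the panel — the
idealization of distinct tissue programs. This matters at desk scale: with
raw i.i.d. activities on a 10-condition panel, chance program–program
sample correlations (sd ≈ 1/3) dominate the correlation matrix and the
planted structure is not recoverable at the accuracy the tests demand.
Because centred programs span at most n_conditions − 1 dimensions, the
module count defaults to `min(n_conditions_A, n_conditions_B) − 1`, the
maximal program diversity the smaller panel supports; it can be set
explicitly.

Defaults mirror the study design scaled down: species A profiled over 5
tissue conditions × 2 biological replicates (replicates share the
condition's activity and differ only in noise), species B over 6 conditions;
baseline 3 (FPKM ≈ 7), loading 2, noise 0.25. A `flat_fraction` of genes
(10%) receives no module loading to exercise the CV filter. For a species
pair, condition panels are drawn independently per species — deliberately
unmatched, since coping with unmatched panels is the reason EC exists. A
`conserved_fraction` of pairs keeps its module identity in species B; the
rest get an independently, uniformly drawn module, so module co-membership
carries no cross-species information under the null (a scrambled pair may
land on its own module by chance — its label remains "scrambled", which
bounds achievable recovery accuracy by 1 − 0.5/n_modules).

Orthology tables are generated so that each decoy class is defeated by
exactly one rule of the pairing procedure: one-directional hits to wrong
partners (reciprocity), high-bitscore hits at e-value ≥ 1e−4 (the gate),
and extra reciprocal-best-hit gene pairs placed in different orthogroups
(the orthogroup constraint). Decoy e-values are strictly worse than every
true hit, so the planted map remains recoverable exactly. Domain tables
plant both expansin domains on the designated family subset.

What the generator does **not** emulate: count noise and library-size
effects (FPKM is treated as given), correlated residuals between genes
outside modules, gene-specific loading heterogeneity, many-to-many
orthology, and genome-scale pair counts. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
model, not performance on real RNA-seq data.

## Benchmark conditions and problem sizes

The EC benchmark used throughout the tests and the acceptance script is
100 ortholog pairs profiled over 10 conditions per species (9 planted
programs), per-cell noise 0.25: recovery at conserved fraction 0.5 is
summarized as the area under the conserved-vs-scrambled ranking (mean ≈
0.94 over 20 seeds), and the null (conserved fraction 0) as the grand mean
EC over repeated runs (≈ +0.14 at this size, reflecting the small-sample
bias and the ~1/9 chance-co-modular scrambled pairs described above).
Network experiments run at 120–200 genes with 10–16 samples. These sizes
keep the full suite in the tens of seconds while leaving every statistic
far from its decision boundary.

## Numerical and design choices

- Correlations are clipped to [−1, 1] after computation; |ρ| = 1 yields
  p = 0 under the t approximation and passes any p threshold.
- Best-hit tie-breaking (bitscore, then lexicographic subject id) and the
  fractional-rank tie rule exist for determinism; neither changes results
  on continuous data.
- The pipeline embeds a version string, a hash of the scientific
  configuration (output paths excluded), and the seed in every output file;
  identical (inputs, config, seed) produce byte-identical outputs.
- Exit codes: 0 success, 2 validation error, 3 numeric failure (e.g.
  non-convergence under `--strict`).
- The `paper-small` pipeline preset lowers the generator noise to 0.15:
  with only 10 samples in species A, the `|ρ| > 0.95` and `p < 1e−5` gates
  are near their power limit, and the preset is meant to produce non-trivial
  per-group networks for demonstration and determinism checks.

## Limitations

- EC values from small pair sets carry the positive bias described above;
  the package reports it rather than correcting it, matching the published
  procedure.
- The MR reliability rule needs the full gene–gene Spearman matrix; the
  implementation is dense and intended for matrices up to a few thousand
  genes.
- One-to-one ortholog pairing only; paralog-aware conservation scoring is
  out of scope.
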