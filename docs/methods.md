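# Methods

This note documents the models, parameter choices and numerical conventions
behind `spermatocap`, and what the synthetic benchmark does and does not
establish about real data.

## Expression model and normalization

Input counts are 3′-end tag counts (UMI-collapsed reads), so "TPM" is
counts-per-million per cell with **no gene-length normalization** — a length
term is meaningless when each transcript contributes one 3′ tag. Values are
`log2(TPM/10 + 1)`; the `/10` keeps single-tag observations from dominating
at typical library depths, and the `+1` maps zero counts to exactly 0.
Ribosomal genes (symbols matching `^RP[SL]`) and mitochondrial genes
(`^MT-`, both case-insensitive) are removed *before* the per-cell rescaling,
so retained genes sum to exactly 10^6 TPM in every cell. The prefix rule is
a convention: supply your own flags if your annotation disagrees.

QC retains cells with strictly more than `min_genes` detected genes
(default 2 000) and strictly more than `min_transcripts` total counts
(default 10 000). Strict inequalities are deliberate and tested; the filter
is idempotent.

## Shared statistics

*Wilcoxon rank-sum* (two-sided): exact null enumeration when
`n1 + n2 ≤ 12` and the pooled sample is tie-free; otherwise the
tie-corrected normal approximation with continuity correction. The exact
branch is verified against a full enumeration oracle in the tests. *Pearson
chi-square* on r × c tables uses no continuity correction (these are
composition tables, not 2 × 2 designs); zero marginals are an error naming
the offending row/column.

*Gene-set score*: per gene, z-scores across the cell subset with the sample
(n − 1) standard deviation; zero-variance genes are dropped with a logged
warning rather than scored 0 (their z is undefined); the cell's score is
the mean z over surviving genes. When the set spans the whole gene universe
the per-cell scores average to zero by construction.

## Donor stratification

Pseudobulk = per-gene mean of normalized values over a donor's cells.
Distance between donors is `1 − Pearson` over the top 2 000 genes by
pseudobulk variance; linkage is average; the tree is cut into `k` flat
clusters (default `k = 5` over controls + patients jointly). Donors are
sorted by id before clustering so results are input-order invariant. Only
expression enters the clustering — histopathology, which real studies also
consult, is outside the package's scope — and the non-reference clusters
carry provisional labels because a dendrogram has no severity order; the
capacity ranking supplies it.

## Cell typing

Cell-level panel scoring (argmax of per-panel average-z, `min_margin = 0.1`
in z units to suppress coin-flip labels) replaces cluster-then-annotate
workflows on purpose: it has no stochastic embedding, and its contract —
marker-consistent labels — is directly testable against planted truth.
Bundled panels cover the 12 testis types with standard literature markers
and are user-replaceable TSVs; any serious application should supply its
own panels.

## Cell-cycle activity

Phase scores use bundled 43-gene G1/S and 54-gene G2/M lists (the canonical
single-cell phase programs; replaceable). "Cycling" is not defined by a
fixed score cutoff: the threshold is the 0.99 quantile of scores of random
gene sets matched in size to each phase set (200 draws, pooled), and a cell
cycles iff `max(s, g2m)` strictly exceeds it. This makes the call
self-calibrating — on data with no cycle structure the expected cycling
fraction is about `2 × (1 − quantile)` — and degenerate all-equal inputs
yield zero cycling cells. Threshold quantile and draw count are exposed.

## DEG screen and frequency tally

For each (class, cell type) vs the same type in the reference group, a gene
is tested only if expressed (value > 0) in ≥ 25% of cells on at least one
side and its mean log-scale difference reaches 2.0 in absolute value. The
mean-difference gate is the analysis-scale reading of the legacy
`thresh.use = 2` parameter; both gates are configurable. P-values are
Bonferroni-adjusted over the genes actually tested within that comparison
(matching how the legacy wrapper only tests gate-passing genes); BH is a
flag away in the trend stage, where the framing is discovery rather than
confirmation. Comparisons with fewer than 3 cells on either side are
skipped with a notice, not an error.

The frequency screen requires a gene to be differential in **every** germ
stage of a class to count for that class. Two stage-list policies exist:
`germ_types_for_classes` (all nine germ stages for unarrested classes,
truncation at pachytene for arrested ones — the documented contract used in
the hand-tally tests) and `observed_germ_types` (stages with ≥ 3 cells in
both class and reference), which the pipeline uses because a stage that is
absent — by arrest or by sampling — cannot carry a differential call and
would make the all-stage quantifier vacuously unsatisfiable.

## Capacity score, trend genes, modules

The spermatogenesis score is the average z over a spermatogenesis gene set,
computed over **pooled** germ cells (per-group z-scoring is available as an
option; pooling is the default because the score is compared across
groups). Groups are ranked by median (score distributions are skewed);
pairwise Wilcoxon tests accompany the ranking, and median ties still yield
a total order (alphabetical) with the tie recorded.

Trend correlation is Spearman between **per-donor** germ-cell mean
expression and the donor's group severity rank — donor-level on purpose, to
avoid pseudoreplication from correlated cells of one donor; a per-cell
variant exists behind a flag. BH controls the gene-level FDR. Spearman makes
the result invariant to any strictly monotone relabeling of the ranks.
Significant trend genes are clustered by seeded k-means (25 restarts) on
their group-mean profiles standardized per gene over the severity-ordered
groups; `m = 5` modules by default. Modules are renumbered by mean ρ, so
Module 1 always rises as capacity falls and Module m always falls; end
modules are the predictor candidates. External-list overlap is set
arithmetic only — no enrichment inference.

## Ligand–receptor inference

Statistic: mean of (ligand mean in sender, receptor mean in receiver) on
the normalized scale including zeros. Gates: strictly more than 10%
expressing cells on both ends; an absent gene is "no interaction", not an
error. The null permutes the type labels of all cells jointly, one
permutation shared by every pair within an iteration — this preserves
marginal type sizes and the between-pair dependence structure. `p` is the
fraction of permuted statistics ≥ observed, so `p = 0` occurs; a
`+1/(n+1)` smoothed variant is available for downstream FDR. Types with
fewer than 3 cells are flagged low-confidence rather than dropped. Node
"strength" in the network is the total incident significant-interaction
count (the underlying notion is not numerically standardized in the field;
this definition is explicit and additive).

## Synthetic study conditions

The generator's defaults define the reference conditions used throughout
the tests and the acceptance script:

| parameter | default | rationale |
|---|---|---|
| donors | 9 NC + 4/6/3/4 (Classes I–IV) = 26 | the study design's donor structure |
| cells/donor | 80 | desk-scale problem size; keeps all stages testable |
| genes | 2 000 | ~320 named program genes + anonymous background |
| library mean | 20 000 tags, lognormal σ = 0.35 per cell | typical 3′ protocol depth with realistic spread |
| NB dispersion | 0.25 (gamma–Poisson) | overdispersion typical of UMI counts |
| donor effect | lognormal σ = 0.05 per gene | donors similar but separable |
| arrest | pachytene for Classes II–IV | no D/SPC7/RS cells in those groups |
| composition | class-specific shifts (excess L in II, excess Z in III, depleted SPG in IV) | qualitative arrest phenotypes |
| capacity factor | 0.6^(rank−1) on the score set in germ cells | log-linear severity along NC < I < III < IV < II |
| planted downs | log2FC −3 in germ cells; named genes at frequencies 4/3/1 plus an anonymous Class-IV block | benchmark for the frequency screen |
| trend genes | 50 genes at ±0.5 log2 per rank step | benchmark for trend discovery |
| cycling | 4% (NC) vs 20% (classes), cycle genes ×4 in cycling cells | benchmark for activity calling |
| LR plants | e.g. RSPO3→LGR4 ST→SSC at ×8 in NC, attenuated in classes | benchmark for interaction power |

One seeded generator drives every draw; identical config + seed reproduces
the dataset byte for byte, and the config hash in the fixture manifest
changes whenever any field changes.

Two design consequences are worth stating plainly. First, planting capacity
as a multiplicative factor on the score-set genes makes those genes
*genuinely* monotone in severity; the ground truth therefore records every
gene given group structure (trend, capacity, down, cycle), and benchmark
metrics that need "clean" negatives (trend AUROC, DEG false-discovery
proportion) exclude structured genes from the negative class rather than
miscounting real planted signal as error. Second, because per-cell library
size is fixed in expectation, removing expression mass from germ cells of
severe classes (capacity + downs) slightly inflates every other gene's
relative abundance in those classes — a real compositional effect of
depth normalization, partially offset here by the planted upward trend
genes; it is visible as a mild severity-correlated drift in background
genes and is why trend discovery is evaluated as a ranking (AUROC) rather
than by a fixed ρ cutoff.

## What the benchmark does not show

The generator emulates group/donor/type structure, overdispersed counts and
the planted effects above; it does not emulate doublets, ambient RNA, batch
effects, stage-continuous expression gradients within a cell type, gene–gene
correlation beyond the planted programs, or dropout beyond what the
gamma–Poisson implies. Passing the synthetic benchmarks therefore
demonstrates correctness and calibration of the methods under the stated
generative model, not robustness to every artifact of real testis data. The
bundled spermatogenesis list and marker panels are curated defaults, not
any study's exact supplementary tables; analyses of real data should swap
in study-specific lists via the same TSV loaders.

## Problem sizes and determinism

Default test/acceptance sizes: 2 080 cells × 2 000 genes per dataset;
capacity-ranking recovery over 20 (tests) or 10 (acceptance script)
generator replicates; 200 permutations for null-calibration runs and 1 000
for planted-pair power; 200 random draws for the cycle null. Every
stochastic step takes an explicit seed, and the acceptance script derives
all sub-seeds from its single `--seed` argument.
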