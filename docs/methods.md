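# Methods

This note documents the models, parameter choices, numerical details and
known limitations of `haploquartet`, in the order the pipeline runs.

## Quartet construction and filtering

Haplotype assignment is purely lexical: the trailing letter a–d of a
chromosome identifier (case-insensitive) names the haplotype; identifiers
ending in "un" (unanchored sequence) and anything unparseable are UNPLACED
and excluded from quartet construction. Allelic retention classifies each
orthogroup by the number of haplotypes with at least one member; the
*strict* mode additionally discards any orthogroup with a within-haplotype
duplicate, while *lenient* tolerates duplicates. Empty orthogroups are
excluded from both denominators.

Read-support filtering is evaluated **per contrast** (control vs one
stress), so a quartet may pass for one stress and fail for another. The
four rules — ≥ 50 reads over the quartet, ≥ 20 per condition, ≥ 10 per
gene, ≥ 2 detected replicates per condition — are deliberately literal;
two readings were genuinely open and both are implemented:

- *per-gene scope*: the ≥ 10-read rule defaults to the gene's total over
  all contrast samples (`overall`), paralleling the other per-entity
  totals; `per-condition` applies it within each condition instead.
- *detectable replicate*: a replicate counts as detected when the
  quartet-level sum reaches `detect_count` (default 1 read) — the weakest
  defensible definition, configurable upward.

## ASE statistics

Replicates are **pooled (summed)** within a condition before proportions
and testing; a replicate-mean mode exists (`proportion_mode` analog via
`condition_proportions` on per-replicate slices) but pooling is the default
because the chi-square operates on read counts, and pooled counts are the
counts the test sees. The contrast test is a plain Pearson chi-square on
the 2×4 condition-by-haplotype table without continuity correction or
pseudo-counts; haplotype columns with zero reads in both conditions are
dropped with the degrees of freedom reduced, and tables with fewer than two
informative columns are flagged undefined and excluded from the BH
adjustment (reinserted as NaN). Quartets with any expected cell below 1 are
flagged (`low_expected`) but still tested, preserving auditability.

Dominance boundaries are asymmetric on purpose: bias exactly 0.25 or 0.5 is
*mild*; *strong* requires bias strictly above 0.5. Δ is the **absolute**
difference of the two conditions' maximum proportions, even when the top
haplotype switches; argmax ties are broken alphabetically and flagged, and
tied-top quartets count as switches unless `strict_ties` is set. FDR is
computed within each contrast separately.

## The NB GLM engine

The engine is a transparent gene-wise NB2 fit, written to be auditable
rather than fast-path clever:

- **Normalisation**: median-of-ratios size factors against the geometric
  mean of all-positive genes, rescaled to median 1. When no gene is
  positive everywhere (small simulated matrices), the reference falls back
  to genes positive in ≥ 90% of samples with zero cells masked.
- **Coefficients**: log-link IRLS, convergence when the largest coefficient
  change drops below 1e-8 or 100 iterations; linear predictors are clipped
  at ±30 to survive degenerate genes (e.g. an all-zero factor level).
  Non-converging genes are flagged, excluded from testing and counted in
  the log.
- **Dispersion**: method-of-moments initialisation from the Poisson fit,
  refined by maximising the **Cox–Reid adjusted** profile likelihood
  (penalty −½ log det XᵀWX) over log α ∈ [log 1e-8, log 50] with a bounded
  scalar search. The CR adjustment is the standard small-sample correction
  for the downward bias of plain profile ML; without it the dispersion at
  24 samples is visibly underestimated. There is **no** empirical-Bayes
  shrinkage across genes, no dispersion trend, and no fold-change
  shrinkage — every gene stands alone, which keeps the engine a documented,
  inspectable stand-in for heavier DE frameworks rather than a numerical
  clone of any of them.
- **Testing**: nested models share the full model's dispersion. The LRT
  statistic 2Δℓ (clipped at 0) is referred by default to
  **F(df, n − p_full)** on stat/df rather than χ²_df. With a gene-wise
  estimated dispersion the χ² reference is anticonservative in exactly the
  way a z-test is against a t-test: on null simulations at 6 tissues × 4
  replicates the χ² tail gave 3.7–4% of p-values below 0.01 (1.2% when the
  true dispersion was supplied), while the F reference gives 0.9% and an
  approximately uniform p distribution. The χ² reference remains available
  by calling `lrt_test` without a residual df.
- **Fold changes**: log2 of the ratio of size-factor-normalised group
  means, with a moderation constant of 0.5 normalised counts added to both
  means to avoid infinities at zero; configurable.
- **Pre-filter**: genes with CPM ≥ 1 in fewer than 2 libraries are removed
  before testing, and the BH adjustment runs over tested genes only. The
  same expressed rule is reused by the atlas for consistency.

## Tissue atlas

Raw tissue labels are collapsed before modelling (default: developing +
emerging leaves → young leaves; first + third fully expanded leaves →
mature leaves; root crown + root tips → roots; stem, floral buds and open
flowers map to themselves), turning the nine-tissue design into six
categories with eight, eight, eight, four, four and four replicates. The
variance-stabilising transform is the parameter-free stand-in
log2(count/size_factor + 1) — monotone, non-negative, and invariant to
jointly scaling a sample and its factor — not a fitted-dispersion VST; the
top-vs-second margin and the stability CV are both computed on this scale
(raw-normalised CV available by flag). Stability tiers preserve the mixed
boundary operators ≤ 0.20, < 0.15, < 0.10 exactly, reporting the strictest
satisfied tier. "Highest expression" means the highest mean transformed
value within a collapsed category, not the maximum single sample.

## Enrichment

One-sided Fisher's exact test (hypergeometric upper tail) per term with at
least one study gene, BH over tested terms, rows sorted by (q, p, term) for
determinism. The sample odds ratio uses the k(N−n−K+k)/((n−k)(K−k))
convention and reports infinity when a denominator cell is zero. The
default background is the gene set surviving the relevant module's
expression filter, not the whole annotation — the standard guard against
detection bias. Terms are flat opaque labels; no ontology-graph propagation
is performed.

## The simulator

The quartet generator draws, per quartet and condition, **one** true
haplotype-proportion vector, and splits an overdispersed NB total
(mean 500 reads/quartet/replicate, dispersion 0.1, 4 replicates per
condition) multinomially across the four genes in every replicate. Truth
is fixed within a quartet, so allele counts are Dirichlet-multinomial
*across* quartets and multinomial *within* one — the construction under
which pooled null 2×4 tables have exactly uniform chi-square p-values,
which is what a type-I-error harness must provide. Balanced quartets draw
from a symmetric Dirichlet with concentration 30 (typical bias ≈ 0.1);
planted effects are defined on true proportions so recovery is well-posed:
*strong* rejects samples until max − min ≥ 0.55 (dominant share uniform on
0.65–0.90), *mild* until bias lies in [0.25, 0.5], and *switch* sets a new
top haplotype's stress share to max(control) + Δ exactly, rescaling the
rest — guaranteeing an argmax change and a true Δ equal to the planted
value. Optional arity noise converts stated fractions of orthogroups to
tri/bi/mono-allelic or duplicate-bearing groups for retention tests.

The atlas generator draws per-gene baselines lognormally (log-sd 0.6)
around a median of 100 counts so the matrix spans a realistic expression
range, multiplies one random tissue's mean by 2^planted_lfc for enriched
genes, and gives "stable" genes a tenfold smaller dispersion.

What the simulator does **not** emulate: read-level mapping bias between
near-identical haplotype copies, replicate-level wobble of allele
proportions (truth is fixed within a quartet), library-size imbalance
beyond NB depth variation, correlated gene programs, and — in the null
atlas — the pervasive between-tissue variation of real transcriptomes
(which is why nearly all simulated null genes look "stable" by CV, unlike
real multi-tissue data where stable genes are rare). Passing tests
therefore certify the statistical machinery under its stated model, not
biological realism of any particular dataset.

## Problem sizes and runtime

The validation suite uses 2,000 quartets for null calibration, 5 × 2,000
for FDR control, 400/200 for dominance and switch recovery, and 1,000
genes × 6 categories × 4 replicates for the atlas checks — sizes at which
every Monte-Carlo bound in the tests has comfortable margin while the whole
suite runs in well under a minute of simulation time. All randomness flows
from explicit seeds through `numpy.random.default_rng`; identical seeds
give byte-identical outputs, including CLI-written files.

## Known limitations

- The chi-square contrast inherits the usual asymptotics; very shallow
  quartets are flagged (`low_expected`) rather than excluded or exact-tested.
- Gene-wise dispersions are noisy at 4 replicates; the F reference absorbs
  this for testing, but per-gene α estimates themselves should not be
  over-interpreted.
- The VST stand-in under-stabilises very low counts relative to a
  fitted-dispersion VST, slightly compressing top-vs-second margins for
  weakly expressed genes.
- Counts must be integers; fractional upstream estimates (e.g. multi-mapper
  fractions) are rejected rather than rounded, by design.
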