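# Methods

## The evaluation problem

A structure predictor maps a sequence to a model with a per-residue
confidence score (pLDDT, 0–100). For a single substitution, two scalar
summaries of the wild-type/mutant model pair are candidates for predicting
the mutation's measured effect:

    ΔpLDDT   = pLDDT_mut(i) − pLDDT_wt(i)        (i = mutated position)
    Δ⟨pLDDT⟩ = mean(pLDDT_mut) − mean(pLDDT_wt)

Deltas are oriented mutant − wild type, so a confidence drop upon mutation
is negative. The response variable is either ΔΔG (kcal/mol; this package's
convention is stabilizing < 0 < destabilizing, hence the optional sign flip
when importing databases that store the opposite) or a functional readout
such as fluorescence. The evaluation asks how strongly the deltas correlate
with the response, globally and within physicochemical strata, and how a
two-predictor linear model transfers across a homology split.

## Pipeline stages and their rules

**Curation.** Records are single-point mutations with assay pH in [3, 9]
and temperature in [293, 300] K (both inclusive; records missing either
condition are excluded while the bound is active, since the conditions are
part of the selection), in proteins strictly shorter than 250 residues.
Positions are 1-based everywhere, matching mutation-code notation; arrays
convert at the boundary. Random subsampling of an analysis set is an
explicit, seeded operation so that a draw can be reproduced.

**Model handling.** Predictors typically emit five models per sequence; the
analysis keeps only the most confident one (highest ⟨pLDDT⟩; ties go to the
lowest model index). Scores are read from the B-factor column of the
alpha-carbon record (predictors write one value per residue on every atom,
so intra-residue disagreement is a warning, not an error); multi-chain
files and insertion codes are rejected because only single-sequence models
are meaningful here. Plain score arrays (JSON or one value per line) are
accepted as an alternative to coordinates; binary pickle files are not read.

**Annotation.** RSA = ASA/maxASA, with ASA supplied by an external
Stride-like tool — this package never computes surface areas or secondary
structure from coordinates. maxASA defaults to the theoretical scale
bundled in `confdelta/data/max_asa_tien2013.tsv`; any two-column TSV can be
swapped in. RSA exactly at the 25% threshold is classified *exposed*
(buried is strictly below 25%; one convention fixed and documented).
RSA above 1 is possible with theoretical maxASA values and is kept with a
warning. Side-chain volume classes (1–5), hydropathy, polarity and charge
follow the IMGT aide-mémoire, shipped as `imgt_classes.tsv`; the size-change
category is |class(wt) − class(mut)|: 0 → none, 1–2 → small, 3–4 → large.
The mutation's effect direction (stabilizing/neutral/destabilizing) is the
sign of the curated effect value, with zero as its own category.

**Homology split.** Identity is computed by global Needleman–Wunsch
alignment with affine gaps (match +1, mismatch −1, open −10, extend −0.5)
as identical matched positions over alignment length. A protein joins the
training set iff its maximum identity to any *other* dataset protein
exceeds 50%; the rest — including proteins at exactly 50%, and proteins
with no partner — are test (a flag flips the boundary convention).
Externally computed identity matrices can be imported instead. No
clustering is performed: the rule is per-protein thresholding only.

**Statistics.** Pearson and Spearman correlations use the t-transform
p-value (on ranks for Spearman); a p-value that underflows to exactly zero
for |r| = 1 is floored at the smallest positive float to preserve the
(0, 1] contract. The quoted uncertainty is the SD over B = 1000 seeded
nonparametric bootstrap resamples (pairs resampled together; degenerate
constant resamples are dropped); the closed-form Fisher-z standard error
(1 − r²)/√(n − 3) is available as an alternative and agrees with the
bootstrap to ~20% on bivariate normal data at n = 1000. The two-predictor
regression is plain OLS (no regularization or cross-validation), fit on the
training split by default (a scope switch fits on everything when no split
exists), and scored by Pearson correlation between predicted and observed
effects on both splits. Sign enrichment is the fraction of destabilizing
mutations (effect strictly > 0; zeros excluded) with ΔpLDDT < 0, tested by
a two-sided exact binomial against 0.5. Kruskal–Wallis (tie-corrected,
chi-square p) compares site-delta distributions across category levels;
all-identical input returns H = 0, p = 1 rather than an error.
Benjamini–Hochberg adjustment is applied to each stratified report as a
single family spanning every PCC and SCC p-value in it; levels with n < 3
are emitted unfitted and flagged rather than dropped, so per-level counts
always sum to the dataset size.

## The synthetic-data generator

`generate_cohort` emulates the statistical structure the analysis assumes,
not the physics of any predictor. Wild-type profiles are a per-protein base
quality (uniform in [70, 95] pLDDT units) plus first-order autoregressive
noise along the chain (ρ = 0.8, SD 3), because real confidence profiles are
spatially correlated. A mutation with effect G perturbs the site by
−β_site·G + N(0, σ_site), spread to neighbours with exponential decay
(length scale 2 residues), plus a uniform chain shift −β_glob·G/L; five
models per variant are produced by re-noising (SD 0.2) and clipping to
[0, 100] (clipping touches < 1% of residues under the defaults, asserted by
a test). Effects follow a two-component Gaussian mixture, by default 20%
stabilizing (−0.5 ± 0.5 kcal/mol) and 80% destabilizing (+1.5 ± 1.0),
reflecting the destabilizing-dominated composition of curated stability
databases.

The planted site-delta/effect correlation has the closed form
−β_site·σ_G / √(β_site²σ_G² + σ_site²), with σ_G the mixture SD.
The defaults (β_site = 0.5, σ_site = 3.52) put this at ≈ −0.17, the
weak-signal regime the pipeline is designed to resolve;
`site_noise_for_expected_correlation` inverts the formula to target any
regime (the fluorescence regime uses a negative coupling, giving a positive
correlation). Model re-noising adds ~2·(0.2)² of variance not in the closed
form — a relative error below 1% at the defaults.

What the generator does *not* emulate: a coupling-independent overall
confidence drop upon mutation (real mutant models tend to lose confidence
regardless of ΔΔG, which is what drives very high sign-enrichment fractions
in real data), predictor-specific error structure, or MSA-depth effects.
Passing parameter-recovery tests therefore shows the pipeline measures what
was planted — not that real confidence deltas behave this way.

Two deterministic factories complement the cohort generator.
`synthetic_metrics_table` imposes an exact *sample* correlation matrix on
(effect, ΔpLDDT, Δ⟨pLDDT⟩) by Gram–Schmidt construction and shifts the site
column so an exact target fraction of destabilizing rows is negative; it is
a synthetic stand-in for a published per-mutation metrics table, useful for
validating the statistics stage against known moments (it reproduces
summary statistics by construction, not the underlying measurements).
`synthetic_curation_table` writes a raw source-convention table with a
controlled number of in-filter records and single-violation records, so the
curation funnel's counts are exactly predictable.

## Numerical and design choices

- Delta sign convention (mutant − wild type) makes destabilization-driven
  confidence drops negative; the ΔΔG–ΔpLDDT correlation is then negative.
- Best-model ties broken by lowest model index; unindexed profiles sort
  after indexed ones in input order, keeping selection order-invariant.
- Problem sizes in the test suite and acceptance script (cohorts of 1000
  mutations across 100 proteins, three seeds; 1154-row metrics tables) are
  the smallest at which the recovery tolerances (±0.05 on a correlation)
  are comfortably resolvable; larger cohorts only shrink the Monte-Carlo
  error.
- Seeds propagate through `numpy.random.default_rng`; every stochastic
  routine (bootstrap, subsampling, generation) takes an explicit seed and
  is bit-reproducible under it.
- The two-predictor OLS is exposed as a scikit-learn estimator
  (`DeltaRegressor`) so it composes with sklearn model selection; the rest
  of the pipeline is deliberately function-shaped, since curation, file
  parsing and report generation are not fit/transform operations.

## Known limitations

- The homology split replaces a local-alignment search with global-alignment
  identity; absolute identity values (hence exact train/test counts on a
  given real dataset) can differ from search-tool output, though the
  splitting semantics are preserved. Import an external identity matrix for
  exact replication of a search-based split.
- ASA and secondary structure must come from external tools; no structural
  computation is done here.
- The bootstrap SE is undefined for tiny strata; levels with n < 3 are
  flagged rather than estimated.
- Fixed-width PDB B-factors round scores to two decimals; use score-array
  files where that matters.
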