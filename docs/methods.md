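# Methods

## The measurement model

Fecal DNA is modelled as a two-component mixture: a human fraction
(percent of total DNA mass) and a microbial remainder. The human fraction
is itself a mixture over cell types (neutrophil, monocyte, B cell, T cell,
colon epithelium, small-intestine epithelium by default). Three assays
observe this object:

1. **Targeted bisulfite amplicon sequencing.** Each marker is an amplicon
   locus whose CpG sites are unmethylated exclusively in one cell type.
   Methylation is treated as all-or-none per molecule: a molecule from the
   marker's own cell type is fully unmethylated at that marker's CpGs,
   any other molecule fully methylated. Only conversion noise and
   sequencing error produce intermediate patterns. This matches the
   fully-unmethylated-fraction readout, which scores a molecule only when
   *every* CpG reads `TG`; partial patterns carry no signal under the
   scoring rule, so modelling them would add parameters without changing
   any estimand.
2. **Droplet digital PCR.** Template molecules partition into droplets
   under Poisson loading; a droplet is negative with probability
   exp(−λ). The estimator λ̂ = −ln(N_neg/N_tot) and copies = λ̂·N_tot are
   the defining arithmetic of the method; droplet volume is not modelled
   because the downstream quantity is a mass percentage, obtained via the
   3.3 pg genome-equivalent constant and the 5 ng input. Saturated
   percentages (>100%) are capped and flagged rather than propagated.
3. **Shotgun metagenomics.** Only counts are modelled: human reads are
   binomial in the human mass fraction; the non-human remainder feeds the
   species table. Alignment and taxonomic classification are upstream
   tools, not reimplemented — their outputs are the package's inputs.

## Bisulfite-space matching

Reads are compared ungapped and anchored at the 5' end; a reference C
(CpG or not) matches read C or T, all other positions literally. The
similarity is percent identity over the overlap, reads under half the
reference length are unassignable, ties keep the first marker in panel
order. Amplicons are fixed-locus and indel-free by construction, so a
gapped aligner would add a dependency without changing assignments; the
ungapped rule is also exactly reproducible by a brute-force loop, which
the test suite uses as an oracle.

Conversion QC discards reads whose non-CpG cytosines remained cytosine at
more than 10% of positions (threshold configurable; the assay literature
checks conversion without printing a number). Molecules with any
ambiguous CpG readout (neither `CG` nor `TG`, or a site beyond the read
end) are excluded from numerator and denominator — the readout defines
only two valid states, and exclusion is the closure that biases neither
direction. Cell-type fractions are the unweighted mean over the cell
type's markers (depth-weighted available); raw fractions are deliberately
not renormalized to 100% — the 5–150% QC window is defined on raw sums,
and is checked before any ddPCR renormalization. The 1000-read sample
threshold counts reads retained after the similarity and conversion
filters.

## Ecology

The robust Aitchison convention: per sample, nonzero abundances map to
ln(x/g) with g the geometric mean of that sample's nonzero parts; zeros
stay 0. Principal coordinates under Euclidean distance on this matrix
coincide with principal components of the sample-by-species rclr matrix
after column centering, which is how the ordination is computed (SVD;
component signs fixed by making each component's largest loading
positive). Zeros contribute 0 to distances (matched-zero convention).

The species classifier restricts to species with median abundance > 0 in
at least one group, runs four one-sided Mann–Whitney tests per species
(CD and UC vs Control, loss = "less", expansion = "greater"), exact
distributions for group sizes ≤ 12 and the tie-corrected normal
approximation otherwise. Benjamini–Hochberg correction is applied within
the loss family and within the expansion family, each pooled across all
species and both group contrasts (per-comparison correction available).
Significance in both CD and UC yields the IBD-prefixed category — there is
no pooled IBD-vs-Control test, since the underlying hypotheses are
pairwise. When loss and expansion categories both apply, the family with
the smaller minimal adjusted p wins.

Spearman correlation uses average ranks; p-values come from the exact
permutation distribution for n ≤ 10 (enumerated in chunks) and the t
approximation above.

## Models

The calprotectin mixed model is fitted by REML (statsmodels MixedLM);
records at the 2100 µg/g assay cap are excluded as right-censored rather
than modelled. Both Nakagawa R² flavors are reported — marginal
var(Xβ)/(var(Xβ)+σ²_re+σ²_ε) and conditional with the random-intercept
variance in the numerator — because single published R² values rarely
state their flavor. Crossed random intercepts (subject and integer age
year) are expressed as variance components over a single grouping; when
every group has one observation the random intercept is unidentifiable
and the fit falls back to OLS with a warning.

The classifiers are gradient-boosted trees with a logistic objective and
fixed hyperparameters (η 0.05, γ 1, λ 3, max depth 10, min child weight 1,
subsample 0.8, colsample_bytree 0.8, 200 rounds, 5 stratified folds).
Fold assignment hashes sample IDs (md5 of seed:id, round-robin within
class), making the protocol invariant to input order. Per-round
validation AUC is averaged over folds; the best round maximizes that
mean, out-of-fold predictions are pooled at the best round for the
reported AUC, and the final model refits all data at that round.
External validation reconciles features by name — species missing from
the validation cohort are imputed absent, novel species dropped, with a
hard warning below 50% overlap. Age and sex are never predictors.
Shapley values come from TreeSHAP as implemented inside XGBoost
(`pred_contribs`), on the log-odds scale, satisfying per-sample
additivity to machine precision.

## The synthetic cohort generator

The generator's defaults are the study conditions the analyses assume:

| parameter | default | meaning |
|---|---|---|
| richness means | Control 275, CD 130, UC 170 | expected species count per group |
| activity probability | 0.5 in CD/UC, 0 in Control | P(active disease) |
| human % (log10 mean, sd) | Control (−1.0, 0.45); remission (−0.7, 0.55); active (0.0, 0.65) | human DNA percent strata |
| calprotectin coefficients | intercept 1200; human% +40; active +250; treatment −159.04; age −1.5 | µg/g linear predictor |
| subject / residual SD | 100 / 120 µg/g | random intercept and noise |
| panel | 6 cell types × 2 markers, 150 bp, 5 CpGs | marker panel shape |
| sequencing | conversion 0.99, substitution error 0.001 | read noise |
| droplets | 20 000 per reaction | ddPCR partitions |
| metagenome | 8 M reads/sample (Poisson) | read depth |

Species presence is Bernoulli per group with per-species weights scaled by
bisection so expected richness hits each group's mean; abundance within
presence is log-normal (per-species location ~ N(0, 1.8), shape 1.0),
renormalized to percent. Planted effects multiply abundance by a fold
change and presence probability by a (default equal, clipped) factor in
the affected groups, giving the presence-driven signal the classifiers
exploit. Species-pool parameters can be pinned with a separate
`species_seed`, so independent cohorts can share one species universe —
required for meaningful external validation. Calprotectin noise is
Gaussian on the linear-predictor scale, truncated at zero; the default
intercept (1200 µg/g) keeps truncation negligible so the planted
coefficients hold on the observed scale. That choice trades realism of
the Control group's absolute calprotectin level for exactness of the
planted linear structure; group *contrasts* (activity, treatment) are
unaffected. Activity scores are drawn directly in the remission/active
score ranges of the group's index (pCDAI for CD, pUCAI for UC), so
harmonization can be cross-checked against the generator's labels.

What the generator does **not** emulate: overdispersed or correlated
species co-occurrence, compositional interactions, PCR/primer bias,
indels or quality-score structure in reads, batch effects between
cohorts, age-dependent microbiome maturation, and any real taxon
identities. Passing tests therefore demonstrate that the pipeline
recovers the structures it claims to measure when those structures are
present — not that real cohorts contain them.

## Numerical choices and problem sizes

Deconvolution benchmarks run 50 replicates of a 3-type (0.5/0.3/0.2)
mixture at 10 000 reads/marker; ddPCR round-trips 100 reactions at
20 000 droplets and 100–10 000 copies; classifier calibration uses 1000
null species (n = 20/group) and 20 planted-effect seeds at n = 50/group
with 20-fold effects; mixed-model coverage runs 100 replicates of 400
samples over 100 subjects; classifier parity uses 90 samples × 200
species for the signal cohorts and 400 × 100 for the null; the
subsampling control draws 10⁶ reads per sample. These sizes keep every
evaluation on one CPU in minutes while leaving Monte-Carlo error well
inside the asserted margins.

Degenerate inputs are errors, not silent results: empty panels,
all-positive droplet reactions (unbounded copies), all-zero abundance
samples in rclr, constant vectors in Spearman, unknown activity scales or
treatment names, single-class labels. Ratio denominators use an ε
pseudocount (default 0.01 percentage points) rather than returning
infinity; ε = 0 surfaces the division error with guidance.

## Known limitations

- The subsampling control acts on abundance tables (counts reconstructed
  as abundance × non-human reads, rounded), not on raw reads; it is an
  approximation of re-classifying subsampled reads.
- The ungapped matcher cannot rescue reads with indels; such reads fail
  the similarity filter rather than being realigned.
- Mixed-model R² values depend on the R² definition; both Nakagawa
  flavors are reported and neither is asserted to equal any external
  single-number R².
- The remission-vs-active classification task is implemented but known to
  be the hardest of the three; no tuning beyond the fixed hyperparameters
  is attempted.
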