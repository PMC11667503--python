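# Methods

`tmtpipe` implements the analysis stack used for large multi-center TMT
(tandem mass tag) brain-proteome cohorts: quality control and batch
harmonization of reporter-ion abundance matrices, per-protein variance
partitioning by donor traits, robust correlation screens and race-stratified
differential abundance, and targeted protein-level analyses (APOE ε4
proteotyping, tau-domain and amyloid-β species quantification). Because such
cohorts are access-restricted, every stage is exercised against a synthetic
cohort generator with fully recorded ground truth; this note documents the
models, the estimators, the numerical choices, and what the synthetic tests
do and do not establish about real data.

## Data model

An `AbundanceMatrix` is a dense proteins × samples grid, either linear-scale
reporter intensities (strictly positive where observed) or log2 abundances,
with `NaN` as the explicit missing marker. A `TraitTable` carries one row per
sample: TMT design (site, batch, channel, GIS flag) and donor traits (sex,
race, diagnosis, age, CERAD, Braak, APOE genotype). At cohort scale
(≤ ~12k proteins × ~1.2k samples) dense arrays fit comfortably in memory, so
no sparse representation is used. GIS channels — per-batch pooled internal
standards — are flagged in the traits and excluded from all donor-level
statistics; they are consumed only by the harmonization anchor.

## Quality control

QC runs in the classical three steps, in this order:

1. **Missingness filter.** A protein is retained iff its missing fraction is
   *strictly* below `missing_max_frac` (default 0.5): a protein missing in
   exactly half the samples is dropped. **Loading normalization** divides
   each sample column by its total observed abundance, then values are
   **log2-transformed**.
2. **Iterative PCA outlier removal.** Missing cells are mean-imputed per
   protein (inside the detector only), proteins are centered but not scaled
   (covariance PCA), and any sample whose score on PC1 or PC2 lies more than
   `outlier_sd` (default 4) sample standard deviations from the component
   mean is removed; PCA is recomputed on the survivors until an iteration
   removes nobody. Iteration matters: an extreme outlier inflates the score
   SD and can mask milder outliers that only become detectable once it is
   gone (covered by a dedicated masking fixture). The kept set is a fixed
   point of the procedure.
3. **Batch regression.** Per protein, least squares on batch indicator
   variables over complete observations; the delivered values are the
   residuals plus the protein grand mean, so batch-level means are equalized
   exactly while within-batch deviations and the protein's location are
   preserved. Batch labels already encode site, and the regression is fit
   globally across sites (a per-site mode is a grouping away since batches
   are nested in sites).

Note that loading normalization exactly cancels any uniform per-sample
scaling; a sample that is "shifted by a constant in log2" is therefore
invisible to the downstream detector by construction. Real whole-sample
failures distort the *profile*, not just the level, which is how the
synthetic generator plants them (below).

## GIS-anchored median polish (harmonization)

For the targeted analyses the package provides a two-way median-polish
harmonization anchored on the pooled internal standard: each protein's
values are divided by the batch's GIS median profile (batch median as
fallback), log2-transformed, and then row (protein) and column (sample)
medians are alternately subtracted until every median is within `tol`
(default 1e-4, `max_iter` 250). The output lives on a centered log2 ratio
scale; this makes the result *strictly invariant* to multiplying any batch
(including its GIS channel) by a positive constant — the defining property
of reference-channel harmonization. An optional `restore_central=True` adds
back each protein's median-across-batches log2 anchor for display on an
abundance-like scale; that offset is estimated from the data and is not
batch-rescaling invariant, which is why it is off by default.

Anchor quality bounds what the polish can remove: the ratio step cancels
protein×batch effects exactly only insofar as the GIS measures the batch's
systematic profile. Pool-composition noise (finite donors per pool) and GIS
channel noise remain as genuine batch-level variance that no row/column
median operation can touch.

**Covariate adjustment.** Age and sex are removed by per-protein
residualization where the coefficients are the mean over `n_boot` (default
200) bootstrap OLS refits (samples resampled with replacement, seeded); a
plain single fit is available via `bootstrap=False`. With noiseless data the
bootstrap is degenerate and both paths agree to machine precision. Race and
diagnosis are never adjustable — they are the inferential targets.

## Variance partitioning

Per protein, log2 abundance is modeled with every categorical factor (sex,
race, diagnosis, optionally batch) as a random intercept:

    y = μ + Σ_f Z_f b_f + ε,   b_f ~ N(0, σ_f² I),   ε ~ N(0, σ_e² I)

Components are estimated by REML. The implementation profiles σ_e², rewrites
every likelihood evaluation with the Woodbury identity so the cost per
evaluation is one q×q Cholesky (q = total factor levels, ≤ ~80 with batch),
and optimizes the log variance ratios with L-BFGS-B. Reported fractions are
σ_f² / (Σσ_f² + σ_e²). On balanced one-way designs the fit reproduces the
classical closed-form ANOVA estimator to 1e-4, which serves as the
independent oracle in the tests. Race is dichotomized African American vs
all others and diagnosis AD vs all others by default (multi-level coding by
flag); proteins with fewer than 10 complete observations are skipped, and
non-converged fits fall back to the sums-of-squares mode with a flag.

A fixed-effects mode (`method="anova"`) computes sequential type-I sums of
squares (batch first, then traits, with reference-coded dummies so the
cumulative design stays full rank) normalized by the total SS; fractions add
to one exactly. Two conventions are worth keeping straight: for a two-level
factor with fixed level offsets ±d/2, the mixed-model component is d²/2
(level variance with q−1 in the denominator, as in lme4), while the SS share
is governed by the population mixture variance d²/4. The recovery tests
plant effects in the mixed-model parameterization. Note also that the SS
mode cannot report batch fractions below the chance level (k−1)/(n−1) —
batch dummies absorb that much noise by construction — whereas REML
estimates a zero component at the boundary; the pre/post batch audits
therefore use REML.

## Association analyses

**bicor.** The biweight midcorrelation downweights outlying observations
with median/MAD-based biweights: u = (x − med x)/(c·mad x) with c = 9,
weights (1−u²)² for |u| < 1 else 0, and the correlation of the weighted
deviations. Zero MAD triggers a Pearson fallback with a logged flag.
p-values use the t approximation t = r·√((n−2)/(1−r²)) on n−2 df. Proteome
screens against an anchor protein run on pairwise-complete donor samples;
results with n < 30 pairs are flagged low-confidence.

**Differential abundance.** The default model is one four-level one-way
ANOVA over the race×diagnosis groups (White-CT, White-AD, AA-CT, AA-AD) with
Tukey-Kramer HSD over all pairwise contrasts, reporting the two within-race
AD-vs-control contrasts; `separate=True` instead fits each contrast as its
own two-group model, where the Tukey statistic reduces exactly to the pooled
t test (q = t·√2). The log2 fold change is the difference of group means in
log2 space. Under a global null the two-group mode rejects at the nominal
level, while the four-group Tukey contrast is family-wise conservative
(~0.01 per contrast at α = 0.05) — both behaviours are asserted in tests.
No additional across-protein FDR is applied by default, mirroring
Tukey-only correction; the per-contrast raw p is also reported.

**DAP classes.** Proteins are partitioned by the two within-race contrasts:
down in both races (G1), significant only in White (G2), only in African
American (G3), up in both (G4), opposite signs (mixed), else nonsig.
**Fold-change concordance** is the bicor of the two contrasts' log2 fold
changes over the union of race-significant proteins. **Stage trends**
summarize a protein per CERAD/Braak level (n, median, quartiles) plus a
Spearman rank correlation.

## Targeted quantification

**APOE ε4 proteotype.** The apoE4 variant's allele-specific tryptic peptide
(LGADMEDVR) gives a protein-level carrier readout. Calling is a
one-dimensional two-class split — the exact 1-D 2-means over all sorted
split points, deterministic, no iterative seeding — with the decision
threshold at the midpoint of the class means; if the classes are closer
than 1 log2 unit the caller aborts ("no bimodality") instead of emitting
arbitrary labels, because non-carriers do show detectable background
signal. Only carrier status is called, not ε4 dosage. The concordance
report compares calls with recorded genotypes and quantifies the
carrier/non-carrier mean linear ratio. Batch-mean regression smears carrier
composition into the peptide's batch means, so proteotyping is best done on
pre-regression or ratio-harmonized values; on batch-regressed data a ~1%
extra miscall rate is expected at realistic separations.

**Tau domains and Aβ species.** Peptides are mapped onto tau (MAPT isoform
P10636-8, 441 aa) regions — N-terminal 1–126, proline-rich domain 127–242,
microtubule binding region 243–369, C-terminal 370–441 — by full
containment, majority residue count for spanning peptides, and the more
N-terminal region on exact ties; assignment is total and deterministic.
Region abundance is the mean (not sum) of log2 peptide values so regions
with different peptide counts stay comparable; the contributing peptide
count is reported per cell for users who want to reweight. Aβ species are
C-terminally defined: a peptide counts toward Abeta40 or Abeta42 only if its
C-terminus matches the species-defining tryptic position (APP P05067
numbering: 711 and 713), shipped as editable YAML rather than hard-coded.

## Synthetic cohort generator

The generator emulates a multi-center TMT study: donors are randomized
round-robin into 16-channel batches (one GIS channel per batch by default),
batches are spread over four contributing sites, and the linear-scale
abundance of protein p in sample s is 2^(μ_p + β_{p,b(s)} + trait effects +
ε_ps) with μ_p ~ N(16, 1.5), ε ~ N(0, 0.5) and all effects additive in
log2 space. Key structural choices:

- **Batch effects** β have two parts: a site-shared profile (sd 1.0 log2,
  common to all batches from a site) plus an iid per-(protein, batch)
  component (sd 1.5). The site component reproduces the distinct site
  clusters that multi-center cohorts show in leading-PC/MDS space and makes
  batch the dominant variance source (median batch fraction ~0.91 on raw
  normalized data, collapsing below 0.01 after batch regression).
- **Trait effects** are planted on proteins below the 90th abundance
  percentile. Constant-sum loading normalization ties every protein to the
  column total, which is dominated by the few most abundant proteins;
  planting effects there would leak a compositional offset into every null
  protein. Disease-responsive proteins are mid-abundance in practice, so
  this restriction is realistic rather than cosmetic. Sex effects are large
  (3 log2) on a small sex-chromosome-like set, half female-high and half
  male-high; a dozen proteins carry race effects; AD effects (default 200
  proteins, sd 0.75 log2) are drawn with cross-race correlation 0.9 —
  matrisome-like proteins up, synaptic-like down by sign.
- **Outliers** are whole-sample failures sharing a degradation profile: a
  per-protein log2 perturbation with RMS `outlier_shift` (default 8),
  applied at the channel level (after pooling, so the GIS is not
  contaminated). A uniform column scaling would be exactly cancelled by
  loading normalization; and with the site subspace occupying the leading
  PCs, only gross profile distortions are detectable by the 4-SD/2-PC rule —
  the generator plants the kind of failure the detector is designed for.
- **GIS channels** are the batch pool of the members' *systematic*
  (noise-free) profiles, measured with a small channel noise (sd 0.03 log2).
  This idealizes a real pooled standard, whose composition also carries
  ~1/√m of the donors' biological spread; with that composition noise
  included, no median polish could push batch variance below ~0.02 log2²
  at 15 donors per pool. Passing polish tests therefore demonstrate
  correctness of the algorithm, not that real pooled standards are this
  clean.
- **APOE.** Alleles are drawn with ε4 enriched in AD donors; the
  allele-specific peptide sits at a background floor of log2 = 10 with
  +apoe_delta (default 3) for carriers and one extra log2 unit for ε4
  homozygotes (allele dosage), measured with sd 0.25 — a strong targeted
  peptide. A fraction `apoe_error_rate` (default 0.02) of donors get a
  recorded genotype contradicting their true carrier status, with the
  planted list kept in the ground truth. The dosage term makes the
  carrier/non-carrier linear mean ratio strictly exceed 2^3 = 8.
- **Missingness** is MCAR (default 1%) plus MNAR: a logistic drop
  probability increasing as log2 abundance falls below the matrix's 2nd
  percentile, scaled by `mnar_strength` (default 0.5). The MNAR form is a
  fixture choice, not a claim about real censoring. MNAR truncation
  measurably shrinks large planted fold changes by a few percent — a real
  phenomenon the recovery tolerances accommodate.
- CERAD and Braak are drawn conditionally on diagnosis (AD stochastically
  higher), so stage trends arise through the diagnosis effects.

Default sizes are 1,000 proteins × 600 donors in 40 batches of 15 donors +
1 GIS channel; recovery studies use the sizes stated in their tests (e.g.
50 cohorts of 200 samples for outlier recovery, 1,000 samples for
variance-ratio recovery). These sizes keep the full suite and the
acceptance script within a few minutes while leaving every per-test margin
several standard errors wide.

**What the synthetic tests do not show.** The generator has no peptide-level
spectral structure, no isotope-impurity or co-isolation interference, no
correlated protein modules beyond the planted effects, Gaussian log-scale
noise, and an idealized GIS. Passing tests establish that the estimators
recover what was planted under the stated model — not that real cohorts
satisfy that model.

## Numerical details and edge cases

- Missing markers: "" or "NA" on input, "NA" on output; round trips are
  lossless, including NaN placement.
- Replicate donor samples are kept; donor-level deduplication is left to the
  caller (the `donor_id` column supports it) rather than asserting a
  collapsing rule.
- PCA outlier detection requires ≥ 3 samples and errors if fewer than 3
  survive; a zero score SD is treated as "no spread", never a division.
- Tukey p-values use `scipy.stats.studentized_range` for k > 2 and the exact
  t-identity for k = 2; −log10 p is capped at 300 with an underflow flag.
- REML optimizer bounds the log variance ratios in [−18, 12]; components at
  the lower bound are reported as exactly zero.
- `rank_by_factor` breaks fraction ties lexicographically by protein id, so
  rankings are reproducible.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the configuration objects; identical seeds give bit-identical cohorts.

## Known limitations

- The bootstrap interpretation of covariate adjustment (coefficient
  averaging) is one of two defensible readings; plain residualization is the
  other and is exposed as a flag. With realistic n they differ negligibly.
- Variance partitioning treats donors as exchangeable; repeated samples from
  one donor are not modeled with a donor random effect.
- The SS decomposition is sequential (type I) with batch first; for the
  randomized designs generated here the factors are near-orthogonal and
  order barely matters, but heavily confounded designs would need care.
- ComBat-style empirical-Bayes batch correction and WGCNA-style network
  analysis are out of scope.
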