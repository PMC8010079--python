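# Methods

`refeedomics` re-implements, as a tested library, the statistical machinery
of a three-visit (baseline V1, one-week V2, three-month V3) two-arm dietary
intervention study in hypertensive metabolic-syndrome patients: preprocessing
of multi-space feature tables, medication-deconfounded longitudinal
screening, cross-space correlation networks with a repeated-measures guard,
responder stratification, and leakage-safe subject-level response
prediction. Because the study's per-patient tables are not public, every
stage is exercised end-to-end on a synthetic cohort generator whose planted
signals are known exactly; the package's empirical claims are therefore
operating characteristics (calibration, power, precision/recall, chance-level
nulls), not reproductions of the study's cohort-specific numbers.

## Preprocessing

**Rarefaction.** Count tables are subsampled without replacement
(multivariate hypergeometric) to a common depth; `depth="auto"` uses
`floor(0.95 × smallest library)`. Row sums equal the depth exactly and every
rarefied count is bounded by the original. Samples below the target depth
are dropped with a warning (configurable to a hard error).

**Binning.** Gene families (KOs) are binned into functional modules by
averaging over *all* module members — members absent from the table
contribute zero — matching the convention of module-abundance profilers.
Taxonomic rollup sums the members present.

**Medication normalization.** Each (subject, drug) dose trajectory is
divided by its reference dose: the baseline dose when nonzero, otherwise the
lowest nonzero dose across visits (this covers drugs initiated mid-study; an
unchanged regimen is exactly 1, a discontinued drug exactly 0). The
per-visit *agent sum* is by default the sum of normalized doses over drugs
("dose-sum" mode), because the contrast models consume dosage as a
continuous covariate; an "agent-count" mode (number of drugs taken) is
provided since the source description admits either reading.

**Derived indices.** BMI = weight [kg] / height [m]²; HOMA = insulin
[µU/ml] × glucose [mmol/l] / 22.5.

## Longitudinal screening with medication deconfounding

Each feature is tested in two gated steps:

1. **Nested linear-model comparison.** Null model: feature ~ age + sex +
   patient identity (fixed effects) + normalized dose of every tracked
   antihypertensive agent (one column per drug class), optionally + BMI.
   Full model: null + visit (categorical). Models are fitted on raw
   (rarefied) abundances by Gaussian maximum likelihood; an optional
   rank-transform mode exists but is off by default. Age and sex are
   constant within patient and therefore exactly aliased with the patient
   dummies; the pivoted-QR factorization drops aliased columns, which leaves
   both models' fitted subspaces (hence the likelihood ratio) unchanged.
   Degrees of freedom come from the rank difference of the two designs.
   The reported statistic is the likelihood ratio `n·ln(RSS0/RSS1) =
   2Δloglik`. Its **p-value is taken through the exact finite-sample F
   transform of the same ratio**, not the χ² limit: with one fixed effect
   per patient the residual degrees of freedom are far below `n`
   (≈ 210 − 78 here) and the χ² reference is anticonservative by roughly
   `n/(n−p)` ≈ 1.6 — measured as 17 % of pure-null features at p < 0.05.
   The F form is exact under Gaussian errors and orders features
   identically. p-values are BH-adjusted within each measurement space and
   gated at FDR < 0.1.
2. **Post-hoc contrasts.** Unpaired two-sided Mann–Whitney U tests between
   each pair of visits (the source pipeline's choice, kept for fidelity even
   though the data are paired), BH-adjusted across the three visit contrasts
   of each feature and gated at FDR < 0.05. Exact enumeration p-values are
   used when the pooled sample is tie-free with ≤ 16 observations, otherwise
   the normal approximation with tie and continuity corrections.

Signed Cliff's delta is reported for every contrast regardless of
significance. The **BMI sensitivity analysis** re-runs the whole screen with
BMI as an additional covariate in both nested models and reports the
fraction of originally significant features that remain significant.

Complete-case analysis is used per feature; rows with a missing value are
dropped before the design is built.

## Diversity and ordination

Alpha metrics follow the standard definitions (Shannon with natural log;
evenness = Shannon/ln richness; Simpson 1−Σp²; inverse Simpson; Chao1 always
in the bias-corrected form `S + F1(F1−1)/(2(F2+1))`, defined even without
doubletons). Bray–Curtis (a semimetric; no triangle inequality is claimed)
serves the microbiome tables and Euclidean distance the immune tables. PCoA
Gower-centers −D²/2 and eigendecomposes; axes with non-positive eigenvalues
are reported but excluded from the coordinates, and on Euclidean-embeddable
input the coordinates reproduce all pairwise distances to numerical
precision.

**Donor-stratified PERMANOVA.** The pseudo-F partitions the squared-distance
matrix into between- and within-group sums of squares. Permutations shuffle
group (visit) labels only *within* each donor's block of repeated samples,
preserving the repeated-measures structure; the p-value includes the
observed statistic, `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, so p = 0 is
impossible. Blocks whose samples share one label are unpermutable; if every
block is degenerate the test reports p = 1 with a warning. The default
permutation count is 999 (configurable; the source does not state one).

## Cross-space correlation networks and triplets

Pairs of features from two spaces are screened by Spearman correlation over
samples pooled across visits (average ranks for ties, t-approximation
p-values), BH-adjusted within each unordered space-pair family at FDR < 0.05
(the source states 0.05 in one place and 0.1 in another; 0.05 is the default
and the threshold is a config switch). Surviving pairs face a
**same-donor post-hoc**: rank(y) ~ rank(x) and rank(x) ~ rank(y), each with
a per-patient random intercept fitted by ML (so the likelihood-ratio
comparison against the intercept-plus-random-effect null is valid), and the
*larger* of the two p-values must fall below 0.05. This guards against
pseudo-replication: a correlation carried purely by between-subject level
differences inflates the pooled sample size from ~30 subjects to ~90 samples
but contributes no within-subject evidence, and the mixed model discounts
it. Variance-estimation failures yield p = 1 (conservative); boundary fits
with zero random-effect variance fall back to the effectively-fixed model,
which is slightly conservative.

Triplets (clinical, immune, microbiome) are retained when at least two of
the three pairwise edges are robust and at least one member passed the
intervention contrast screen.

## Responder stratification and prediction

**Stratification.** A subject is a responder iff their 24 h ambulatory SBP
fell by at least 2 mmHg from V1 to V3 without a medication increase, or
their medication was reduced while SBP did not rise. The branches and
thresholds are configurable so a different decision tree can be transcribed.

**LOSO prediction.** One row per subject (baseline features or V3−V1
deltas). For each fold, the held-out subject is removed before anything is
estimated: z-scaling statistics, the forward-stepwise selection path, and
the final ridge-logistic fit all use the n−1 training subjects only.
Selection greedily adds the candidate with the smallest likelihood-ratio
p-value (χ², 1 df; ties broken by feature order), runs to k features
(k = 10 for immunome-style analyses, k = 5 for microbiome transfer) and
flags steps with p ≥ 0.05. The final classifier minimizes
`½‖w‖² + C·Σ log(1 + exp(−ỹ xw))` with no intercept and C = 1, solved by
damped Newton iterations to gradient norm ≤ 1e−8; prediction thresholds the
decision score at 0.

Inside the LOSO and transfer pipelines, candidate models during selection
are fitted under the same L2 penalty as the final model (α = 1/C) rather
than a vanishing stabilizer: with ~31 training subjects, a near-zero penalty
lets the model separate the training labels after two or three selections,
the unpenalized log-likelihood saturates at zero, and every later step is an
uninformative p ≈ 1 tie that admits arbitrary noise features. Measured on
the planted-signal benchmark this costs about 7 accuracy points. The
standalone `forward_stepwise_select` keeps a 1e−6 micro-ridge default for
use outside the pipelines.

**Transfer.** A single model (scaler, stepwise path, ridge fit) is trained
on the full training cohort, optionally restricted to a feature filter
(e.g. responder-specific taxa), and applied to an external cohort; selected
features missing externally are imputed at the training mean (zero after
scaling) with a warning.

## Synthetic cohort generator

The generator emulates the *statistical structure* the analyses assume, not
any real microbiome: no phylogeny, no immune gating hierarchy, no drift
beyond three visits.

* **Latent model.** Each feature carries a latent log-abundance
  `μ_f + b_sf + ε_sfv` with subject intercept `b` (variance ρσ²) and sample
  noise ε (variance (1−ρ)σ²); ρ = `within_subject_corr` (default 0.5 — the
  source reports no estimate, this is a free parameter) and σ =
  `latent_sigma` (default 0.7 log-units). Taxa counts are multinomial draws
  of the softmax-closed latent field at log-normally distributed library
  sizes (mean 20,000 reads, spread 0.3), so rarefaction downstream operates
  on genuine compositional counts and row sums equal sampled depths exactly.
* **Planted effects** enter as latent shifts `√2·σ·Φ⁻¹((δ+1)/2)`, the exact
  inverse of the unpaired Cliff's delta of two equal-variance normal
  samples; reversible effects act at the onset visit only, sustained effects
  persist. Planted and confounded taxa are given a fixed moderate baseline
  (μ = 1) so multinomial counting noise does not attenuate the calibration;
  measured recovery is within ±0.15 of targets 0.3/0.6/0.9 at 35
  subjects/arm.
* **Medication.** 80 % of subjects take 1–2 antihypertensive agents; half of
  the medicated have one agent halved at V2 (persisting), and responders
  additionally reduce one agent at V3 with probability 0.5. Confounded
  features receive a latent shift of `confounder_strength·σ` per unit change
  of the normalized agent sum (default 3.0), calibrated so the naive
  marginal MWU flags essentially every confounded feature while the
  dose-adjusted screen stays at its nominal null level.
* **Responders.** A latent binary class (default fraction 22/32) receives a
  sustained V3 ambulatory-SBP drop of 8 mmHg (non-responders 0.3 mmHg),
  with noise, plus the possible medication reduction above — the
  constellation the stratification rule recognizes.
* **Triplet planting** replaces three features (one per space) with
  equicorrelated constructs built from a shared factor. Three mutually
  negative correlations are bounded by the 3×3 equicorrelation limit of
  −1/2, so negative targets are clipped to −0.49 (signs propagate; the
  magnitude cannot). The planted taxon is rebuilt at a moderate relative
  abundance (median 0.5 % of the library, capped at 5 %) and the remaining
  taxa re-closed by largest-remainder rounding so depths are preserved
  exactly; without the cap, an abundant planted taxon induces
  community-wide anticorrelation through compositional closure.
* **Prediction testbeds** (`simulate_prediction_dataset`) assign exactly
  `round(fraction·n)` positive labels in shuffled order — a designed
  benchmark should not confound power with random class-imbalance variation
  — and give the first `n_informative` features a between-class mean
  separation of `separation` within-class SDs.

What passing tests on this generator do **not** show: behavior under real
zero-inflation and phylogenetic correlation among taxa, batch effects,
informative missingness, or model misspecification beyond the
lognormal-multinomial family.

## Benchmark problem sizes

The validation suite (also run by `scripts/acceptance.py`) uses: generator
calibration over 20 seeds at 35 subjects/arm; deconfounding over 25 null
cohorts of 70 subjects × 200 taxa with 20 confounded features; screen power
over 5 cohorts × 20 planted reversible effects (|δ| = 0.6); PCoA recovery on
20 random 5-D configurations; stratified-PERMANOVA type-I over 500–1,000
within-strata null replicates at 999 permutations; triplet recovery over 10
cohorts with 5 planted triplets among 12,500 candidates; the LOSO leakage
null over 50 label-randomized 32 × 494 datasets and planted power over 25;
transfer over 25 train/external pairs. These sizes keep each benchmark's
Monte-Carlo error well inside the asserted margins.

## Known limitations

* The Gaussian linear screen on raw abundances (kept for fidelity) is not
  compositionally aware; CLR-style analyses are an explicit non-goal.
* The unpaired post-hoc MWU discards the pairing, costing power on
  within-subject effects — fidelity over optimality.
* MixedLM boundary fits (zero random-effect variance) make the same-donor
  post-hoc slightly conservative.
* Forward-stepwise selection at n ≈ 31 with hundreds of noise candidates is
  intrinsically noisy: it recovers ~3 of 5 planted informative features per
  fold, leaving held-out accuracy ≈ 0.83 against an oracle-selection ceiling
  of ≈ 0.94 on the same data.
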