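# Methods

## Synthetic cohort model

The generator stands in for a private multi-hospital PTE registry and
emulates only its *marginal* printed structure; it makes no claim about the
real joint distribution.

**Features.** 19 indicators: 7 continuous vitals/labs, each paired with a
binary discretization at its clinical threshold (age > 80 y, systolic BP
< 100 mm Hg, pulse ≥ 110 bpm, temperature < 36 °C, respiratory rate > 30,
serum calcium ≤ 2.13 mmol/L, SaO₂ < 90%), plus 5 standalone flags (male
sex, altered mental status, chronic heart failure, chronic pulmonary
disease, cancer). Continuous features are independent Gaussians per
hospital; means sit at the registry's central values and standard
deviations were chosen so that each Gaussian tail reproduces the published
prevalence of its paired indicator (e.g. age 68 ± 12 y gives
P(age > 80) ≈ 15.9% against a printed 15.01%; temperature 36.5 ± 0.23 °C
gives P(< 36 °C) ≈ 1.5% against 1.6%). Standalone flags are Bernoulli at
their published prevalences. Derived indicators are exact functions of
their continuous partner *before* masking, so the paired structure is
internally consistent.

**Hospitals.** 12 hospitals with fixed heterogeneous size fractions
(0.17 … 0.025). Heterogeneity across hospitals is controlled by one scale
parameter (default 0.15): each hospital's continuous means shift by
N(0, (0.15 σ)²) and each flag's log-odds by N(0, 0.3²), drawn once from a
fixed entropy source so the default hospital profile is part of the study
conditions, not of the per-run seed.

**Outcome.** A logistic model on the feature vector with coefficients
proportional (× 0.35) to the PUMCH point weights — giving clinically shaped
effects such as cancer OR ≈ 5.8 — and intercept −4.6. Labels are assigned
by adding standard-logistic noise to the linear predictor and thresholding
at the empirical quantile that yields *exactly* the requested event count
(default 176/3997 = 4.40%). This is a logistic data-generating process
conditioned on the total count: calibration is exact for every seed while
slopes remain recoverable by a logistic fit (verified at n = 50 000 to max
coefficient error < 0.1; at that size the conditioning bias is negligible
against sampling noise).

**Missingness** is completely at random per column at the published rates
(0.5%–16.11% on six continuous columns and 12.33% on chronic heart
failure; the table prints ratios for no other column, so all others are
complete). MCAR is the regime under which the pipeline's mean imputation
is unbiased.

**What the generator does not emulate** — and therefore what passing tests
cannot show about real data: inter-feature correlation beyond the
continuous→indicator pairings (pulse and temperature are independent here),
non-Gaussian marginals, informative missingness, site-specific measurement
practices, and any real-cohort coefficient values. Absolute AUCs on
synthetic cohorts are set by the chosen signal strength; only *relative*
statements (federated vs centralized vs scores) transfer qualitatively.

## Preprocessing

Missing cells are filled with the per-column mean of observed values; a
fully missing column is an error, never a silent zero. Standardization uses
the population form μ = (1/n)Σxᵢ, σ = √((1/n)Σ(xᵢ−μ)²) — deliberately not
the n−1 form — and maps constant columns to zero. By default both are
fitted on the *full* dataset before splitting, reproducing the upstream
experimental protocol; `fit_on_train_only=True` gives the leakage-free
variant. Binary columns are imputed and standardized like any other column
(an exemption flag exists, default off). The feature-group operation
restricts doubly-represented indicators to discrete-only (A),
continuous-only (B) or both (C, the default, which performed best upstream).

## Splitting and client partitioning

The test set is whole held-out hospitals — the `n_test_hospitals` (default
2) smallest by row count, ties by id — so generalization is measured across
sites. Validation draws a seeded 10% simple random sample from each
remaining hospital (round-half-away-from-zero); the rest is training data.

Three partitioning regimes allocate training rows to K clients (default 5):

* **IID** — positives and negatives are dealt separately, as evenly as
  possible; the remainder goes round-robin over a seeded client
  permutation, so every client's prevalence is within one sample of global.
* **Non-IID** — per label class, client shares are drawn from a symmetric
  Dirichlet(α) (default α = 0.5, a standard label-skew construction;
  explicit proportion matrices are accepted for exact reproducibility),
  with largest-remainder rounding and empty-client repair by moving one row
  from the largest client.
* **Real-world** — rows follow their hospital; the default hospital→client
  mapping groups training hospitals greedily, largest first onto the
  currently smallest client, since no canonical mapping is published.

Largest-remainder rounding (ties to the earlier index) is used everywhere
an integer allocation is needed.

## Training

Logistic regression trained with minibatch SGD on unweighted mean binary
cross-entropy (a positive-class weight exists but defaults to 1, since the
upstream protocol reports none despite the 4.4% prevalence). Defaults
T = 200 rounds, E = 1 local epoch, B = 32, η = 0.05, full client
participation, early stop when the max-norm round-to-round parameter change
falls below 1e−6. These hyperparameters are design choices — the upstream
values are unreported — and all are exposed in `FedConfig`. Initialization
is uniform [−0.01, 0.01] weights and zero bias. Probabilities are clipped
to [1e−12, 1−1e−12] inside the loss only, never in reported predictions.
The final-round parameters are reported (no early-stopping model
selection); the trace retains per-round validation AUC so best-round
selection remains available to callers.

Every shuffle is keyed by an explicit seed tuple (seed, round, client,
epoch): runs are bit-reproducible, FedAvg with K = 1 and B = n is exactly
full-batch gradient descent (tested to 1e−12 per round), and a multi-epoch
local update decomposes into single-epoch updates.

## Clinical scores

PESI, sPESI and PUMCH are computed from raw-unit records with per-component
breakdowns (the total is asserted to equal the component sum on every
call). Scores operate on imputed, *unstandardized* data; a cohort whose age
column looks standardized is rejected. Mean-imputed binary cells are
fractional and round at 0.5, i.e. a missing factor scores as its majority
class — one documented choice among several defensible ones. For ROC/AUC
the integer totals are used directly as ranking statistics (no
calibration); for thresholded metrics the conventional not-low-risk cutoffs
are used: PESI ≥ 86 (class III+), sPESI ≥ 1, PUMCH ≥ 2.

## Evaluation

AUC uses the rank (Mann–Whitney) formulation with midranks, so ties earn
half credit. AUPRC is the area under the step precision–recall curve swept
over descending thresholds; the step convention (not trapezoids) avoids
optimistic interpolation and is tested against hand-enumerated small cases.
Thresholded metrics predict positive at score ≥ threshold (boundary
inclusive, tested); the default threshold 0.3 reflects the class imbalance.
Precision and F1 are defined as 0 — and flagged — when no positives are
predicted.

The DeLong test for two correlated AUCs uses the structural-components
(placement-value) covariance estimator with a two-sided normal p-value; its
variance is validated against a 2000-replicate paired bootstrap (within
25%) and its null calibration against label permutations (≈ 5% rejection).
The replicate-level comparison uses Welch's two-sided t-test (the pooled
form is available by flag; which form the upstream analysis used is
unstated). Replicate summaries report mean ± sample (n−1) standard
deviation, formatted to three decimals.

## Experiment runner

A replicate r uses seed base_seed + r, split into fixed per-stage
substreams (generation, validation sampling, client assignment, model
initialization/shuffles) via `SeedSequence([seed, stage])`; everything
downstream of the deterministic test-hospital selection is re-drawn each
replicate. The default design is 10 replicates on the default cohort
(3997 patients, 176 events, 12 hospitals), K = 5 clients — small enough
that a full ten-replicate experiment with all baselines runs in seconds on
one core, which is also the problem size the acceptance-style tests use.
Bundles are plain JSON with sorted keys, so identical configs produce
byte-identical outputs and single replicates can be reproduced in
isolation.

## Known limitations

* Feature independence within hospitals (see above); no covariate-shift
  Non-IID variant — the Non-IID regime skews labels and sizes only.
* Clients are simulated in-process; there is no transport layer, secure
  aggregation or differential privacy.
* Single imputation only (no MICE, no missingness indicators).
* FedAvg only — no proximal (FedProx-style) or normalization-aware
  aggregation variants.
* The generator's defaults are calibrated to printed marginals of one
  registry; they are a test bed, not a validated simulator of PTE
  epidemiology.
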