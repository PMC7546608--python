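# Methods

This note documents the models, estimators and design choices behind
`facersa`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The analysis model

RSA treats the geometry of a representation — the pattern of pairwise
dissimilarities between conditions — as the object of inference. For
time-resolved EEG the pipeline estimates one neural representational
dissimilarity matrix (RDM) per time bin and asks how well candidate
predictor RDMs explain it, per participant, then aggregates across
participants. Inference is deliberately rank-based (Spearman): neural
and predictor dissimilarities live on different, monotonically related
scales, and no calibration between them is assumed.

## Cross-validated split-half PCA RDM estimation

Per time bin, trials are unfolded into channel-major pattern vectors of
`n_channels × samples_per_bin` features. One estimation repetition:

1. Every condition's trials are split into two random halves. For odd
   counts the surplus trial joins a random half, so each half receives
   at least ⌊n/2⌋ trials per condition.
2. PCA (thin SVD) is fitted on the trial matrix of half A, centred by
   half A's feature means. The leading k components are kept, with k
   the smallest number whose cumulative explained variance in half A
   reaches `variance_threshold` (default 0.99).
3. Half B's condition means are centred by half A's means, projected
   onto the k components, and *reconstructed back in sensor space*
   (denoising is linear, so denoising trials and averaging equals
   denoising the means — the implementation uses the cheaper form).
4. Condition pairs are scored as 1 − Pearson r between denoised means;
   roles swap and the two RDMs are averaged.

Repetitions (default 50) are averaged into the final RDM. Diagonals are
never estimated (NaN); entries involving a zero-variance mean are
flagged NaN and removed pairwise downstream.

**Why reconstruction rather than correlating the PCA scores.** Pearson
correlation re-centres each vector by its own mean and is therefore not
invariant under orthogonal projection: correlating k-dimensional score
vectors measures a different quantity than correlating sensor-space
patterns, and the difference does not vanish as k grows. Computing the
correlation on the truncated reconstruction keeps the estimator in
sensor space, where it has a clean limiting behaviour: with
`variance_threshold = 1` the reconstruction is exact on data in the
fitting span and the estimator reduces to plain split-half correlation
(a property the test suite asserts at 1e-6, and an independent
straight-line oracle asserts at 1e-10 on random data).

**Bin layout.** `samples_per_bin = ⌊width · fs / 1000⌋` and bins advance
by exactly that many samples from the epoch start. At 250 Hz a 50 ms bin
is nominally 12.5 samples; 12 are used, so nominal windows and sample
windows drift slowly apart across the epoch. This keeps bins
non-overlapping with the standard 34 × 12-sample layout; no alternative
alignment is offered.

**Randomness.** Each bin's generator derives from
`SeedSequence([seed, bin_index])`; within a repetition randomness is
consumed in a documented order (one permutation per condition in sorted
label order, one uniform draw per odd-count condition). This makes whole
timecourses reproducible from one integer and lets an independently
coded oracle replay the exact splits.

## Predictor RDMs

Attractiveness predictors are absolute differences of per-face scalars:
the database rating (shared across participants) and each participant's
mean yes/no code (1 = yes, 2 = no) and mean 1–7 rating. Responses vary
across the (up to 7) repetitions of a face; they are **averaged** per
face before differencing — the mean preserves graded preference
information that a modal response would discard. Attribute predictors
are 0/1 same/different RDMs for sex and for ethnicity binarised to
{reference, other} (reference category configurable, default
"caucasian"), and absolute age differences. Activation predictors are
1 − Pearson r between faces' feature vectors in one model layer;
computing the activations themselves (e.g. running a face-recognition
network) is out of scope — matrices are consumed as given.

## Model comparison

Only the lower off-diagonal triangle enters, in fixed row-major order.
Partial Spearman is implemented as **Pearson on residualised average
ranks**: rank-transform all vectors, residualise the neural and
predictor ranks on an intercept plus the control ranks by least squares,
correlate the residuals. With zero controls this is exactly Spearman
with average-rank ties (the convention matters: category and 1–7 rating
RDMs are heavily tied). Flagged entries are deleted pairwise,
identically across all vectors of a fit, before ranking. Collinear
controls are harmless (the projection is onto their column space) and
trigger a warning. Edge conventions: a constant vector → NaN
(undefined); a vector fully explained by its controls (residual norm
below 1e-8 of the pre-regression norm, e.g. a predictor controlled by
itself) → ρ = 0 exactly. Fisher z = atanh(ρ) with ρ clipped to
±(1 − 1e-12) to stay finite on degenerate inputs.

## Group statistics

Per bin, a one-sample t-test of the participants' z values, one-sided
for positive correlation (the hypothesised direction in RSA);
Benjamini–Hochberg across **all** bins including pre-stimulus ones (the
correction family is "time", with no principled reason to exempt
baseline bins; restricting the family is a caller-side choice of epoch
window). Cohen's d = t/√n, rounded to two decimals only at reporting.
The **peak** is the maximal-t bin among FDR-significant bins — t, not
mean ρ, because peak effects are reported as t statistics; when nothing
survives, the global maximum is returned flagged non-significant. The
**earliest significant bin** is the onset summary.

## The synthetic-data generator

The generator emulates the emulated study's structure — 23 participants,
100 faces × 7 blocks (700 trials), 63 channels at 250 Hz, −250…1450 ms
epochs — with a known generative process:

* **Faces**: sex ~ Bernoulli(0.5); ethnicity ~ Bernoulli(0.7) over
  {caucasian, other}; age ~ U(18, 50) years; database rating ~
  N(3.5, 0.8) clipped to [1, 7].
* **Behaviour**: latent preference u = λ·z(db_rating) + (1−λ)·ε with
  ε ~ N(0,1) fixed per participant/face; trial ratings
  clip(round(3.5 + 1.5·u + noise), 1, 7) with noise sd 1.0; yes/no = 1
  when u + noise > 0. λ = 0.5 by default, calibrated so that a
  participant's rating RDM correlates only moderately (r ≈ 0.35; yes/no
  RDM r ≈ 0.27) with the database-rating RDM — the regime of substantial
  but incomplete taste sharing that motivates the idiosyncrasy analyses.
  λ = 1 makes responses a monotone function of the database rating
  (exactly monotone, not rank-perfect: rounding to the integer scale
  ties neighbouring faces).
* **EEG**: each injected geometry is an RDM (or the name of a predictor
  built per participant, so `"rating"` injects idiosyncratic geometry).
  It is embedded as *correlation structure*: dissimilarities are mapped
  affinely onto [0, 2], the target Gram G = 1 − 2·D/max(D) is projected
  onto the PSD cone and factorised, and the top-q factor (q = 5 by
  default) gives latent coordinates whose pairwise cosines reproduce the
  scaled dissimilarities. This matches the measure the estimator
  computes (1 − Pearson); a classical-MDS embedding
  (`rdm_to_coordinates`, also exported, negative eigenvalues truncated)
  reproduces *Euclidean* geometry instead and would collapse any
  line-embeddable (rating-difference) RDM to ±1 cosines. Coordinates are
  normalised to unit mean squared norm, mixed into channels by a random
  per-participant channels × q matrix (entries N(0, 1/q)), weighted by a
  piecewise-linear onset/peak/offset envelope, and summed with i.i.d.
  N(0, noise_sd) sensor noise.

Defaults — amplitude 1.0 against noise sd 1.0, envelope 150/400/900 ms —
define a moderate-SNR regime: per-trial signal and noise have comparable
channel variance at the envelope peak, so single trials are useless but
cross-validated averaging over ~7 repetitions recovers the geometry.
What the generator does **not** emulate: 1/f spectra, spatial noise
correlations, ERP waveform shapes, artefacts, trial rejection. Passing
recovery tests therefore demonstrates the correctness of the estimation
chain under a known forward model, not its robustness to every property
of real EEG.

All randomness flows from one master seed through spawn-keyed
`SeedSequence` substreams (faces: spawn key (0,); participant i
behaviour: (1, i); EEG: (2, i)), so datasets are bit-reproducible and
single participants can be materialised lazily — a full default-size
dataset held at once would be ~4 GiB, so `generate_dataset` returns a
handle that builds bundles on demand. Spawn keys, numpy's documented
mechanism for independent child streams, matter here: an earlier
hand-rolled keying (entropy lists differing in one word) produced
subtly cross-correlated behaviour and EEG streams, consistent across
participants, which manufactured spurious group-level "effects" at
specific time bins — a failure mode the validation battery caught and
one reason it exists.

## Validation studies and problem sizes

`facersa.studies` defines the canonical validation battery used by the
test suite and `scripts/acceptance.py`, at a scale chosen so a
multi-seed battery runs in minutes on one CPU: 10 participants, 40
faces, 16 channels, 6 estimator repetitions (the null study smaller
still: 30 faces, 12 channels, 3 repetitions). The studies:

* **Onset recovery** — inject per-participant rating geometry switching
  on at 150 ms; score whether the earliest FDR-significant bin of the
  rating predictor starts within one bin of 150–200 ms.
* **Null specificity** — no geometry; no bin may survive FDR.
* **Shared-taste partialing** — inject only database-rating geometry;
  the individual-rating predictor must correlate plainly but lose all
  significant bins when the database rating is partialed out.
* **Attribute partialing** — inject only sex geometry; the rating
  predictor must show no significant bin after partialing sex,
  ethnicity and age. (The generator draws ratings independently of sex,
  so this study checks the absence of leakage; a *plain* attractiveness
  effect from a sex geometry would require building taste–attribute
  correlations into the generator, which the defaults deliberately do
  not.)

## Known limitations

* The estimator offers only correlation distance (no Euclidean or
  cross-validated Mahalanobis variants) and no noise-ceiling estimate.
* Epochs are consumed from the package's own `.npz` container; importers
  for vendor epoch formats are not provided.
* Group inference is a fixed-effects-across-bins, random-across-
  participants t-test with BH-FDR; no cluster-based permutation or
  Bayesian alternatives.
* The generator's idiosyncratic preferences are Gaussian and
  feature-free; it cannot speak to *why* a face is preferred.
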