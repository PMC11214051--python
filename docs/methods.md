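# Methods

`voicersa` implements a time-resolved representational similarity analysis
(RSA) linking EEG responses to voice recordings with subjective ratings of
person characteristics. This note documents the models, the synthetic data
the package is validated on, the numerical choices, and the limitations of
what the tests demonstrate.

## The analysis chain

**Stimulus space.** 32 speakers x 3 vowels (/a/, /i/, /u/) = 96 voice
recordings, balanced for speaker gender and age group. Listeners rate each
recording on nine person-characteristic scales (gender, age, health,
attractiveness, dominance, trustworthiness, educatedness, professionalism,
sexual orientation) from 1 to 9.

**Behavioral stage.** Raters who give the same response on more than 80% of
trials for a scale are excluded for that scale (strict inequality; exactly
80% is retained). Inter-rater agreement per scale is ICC(2,k), the Shrout &
Fleiss two-way random-effects reliability of the k-rater mean, computed from
ANOVA mean squares:

    ICC(2,k) = (MS_items − MS_err) / (MS_items + (MS_raters − MS_err) / n_items)

Scales below the agreement threshold (default 0.5) are dropped from every
downstream analysis; with the synthetic generator this reliably removes the
sexual-orientation scale, which is generated with essentially no
stimulus-level signal. The behavioral RDM of a characteristic is the matrix
of absolute differences in mean rating between all stimulus pairs.

**Neural RDMs.** Per participant, trials of each stimulus are randomly
assigned to 5 splits and subaveraged into pseudo-trials. Folds hold out one
split; the channel covariance of pseudo-trial residuals in the training
splits (the "epoch method": per-time-point covariances averaged over time,
mean-centered per stimulus) is shrunk toward a scaled identity — analytic
Ledoit–Wolf intensity by default — and inverted through its symmetric
inverse square root to whiten both training and test data. For every
unordered stimulus pair and every 1-ms sample, a linear SVM (C = 1) is
trained on the whitened training pseudo-trials using the channel amplitudes
at that sample as features, and scored on the two held-out pseudo-trials
(a zero decision value scores 0.5, so degenerate identical-class data yield
chance rather than an error). Accuracies are averaged over the 5 folds and
over 50 independent split assignments ("permutations"), producing a
time x 96 x 96 RDM of decoding accuracies per participant; the diagonal is
stored as NaN and excluded from every summary.

The SVM dual problem is solved in-package with an SMO solver using
maximal-violating-pair working-set selection (the libsvm strategy), because
the pipeline requires millions of 8-sample fits and general-purpose wrappers
spend orders of magnitude more time on input validation than on the
optimization. The solver is verified against sklearn's libsvm backend in the
test suite (identical dual objectives; sign agreement of decision values on
decisive cases; max decision-value difference below 1e-2 at matched
tolerance). After each two-variable update, alphas are snapped to the box
bounds within 1e-12 so the bound/free classification used for the bias
remains exact; with no free support vectors the bias is the midpoint of the
KKT interval, as in libsvm.

**Acoustic RDMs.** The long-term average spectrum (LTAS) of each recording
is a Welch-averaged periodogram in 100-Hz bins up to 8 kHz; the LTAS RDM is
the pairwise cosine dissimilarity of the *linear-power* spectra (cosine on
dB values would be distorted by additive offsets). The 13 perceptually
salient acoustic measures (F0 mean, F1–F4, formant dispersion DF, H1–H2,
H2–H4, H4–H2k, H2k–H5k, CPP, energy, HNR) are consumed as a table —
extracting them from audio is delegated to external voice-analysis tools —
standardized, and reduced by PCA with direct oblimin rotation; components
with eigenvalue > 1 (four, on both real-world-like and synthetic tables)
each yield an RDM of absolute component-score differences. Formant
dispersion uses the regression formulation (slope of formant frequency
against the odd-quarter-wavelength positions (2i−1)/2); the mean-spacing
alternative (F4 − F1)/3 is exposed and agrees exactly for arithmetic
progressions.

**PCA with oblimin.** One implementation serves the rating PCA and the
acoustic PCA: standardize, eigendecompose the correlation matrix, retain
eigenvalue > 1, rotate obliquely by direct quartimin (oblimin with
gamma = 0) using the gradient-projection algorithm. The rotation cannot
change the retained components' contribution to the reconstructed
correlation matrix (Lambda Phi Lambda' is invariant), which is asserted in
the tests, and a known oblique two-factor model is recovered with the factor
correlation within 0.1. Component scores use the regression method
(R⁻¹ times the structure matrix).

**RSA models.** RDMs are vectorized as the strict lower triangle in
row-major order (row i, columns j < i; length n(n−1)/2 — 4,560 of the 9,216
cells of a 96 x 96 matrix are informative). The statistic is the partial
Spearman rank correlation: every vector is rank-transformed with average
ranks; the ranked neural and target vectors are residualized on the ranked
covariates plus an intercept by least squares; the Pearson correlation of
the residuals is returned. With no covariates this reduces exactly to
Spearman's rho, and with one covariate it equals the closed-form recursion —
both are test oracles, alongside the equivalent route through the inverse
rank-correlation matrix. Degenerate inputs (constant vectors, covariates
collinear with an input) return NaN with a warning, never a silent number.
Covariate sets per model, for target characteristic c:

* Model 0 — none (plain Spearman; optional diagnostic),
* Model 1 — LTAS cosine RDM,
* Model 2 — LTAS + the four acoustic principal-component RDMs,
* Model 3 — Model 2 covariates + the behavioral RDMs of all other retained
  characteristics.

Covariates are time-invariant and pre-ranked once per model.

**Group inference.** Per time point, a one-sample t statistic (df = n−1)
against zero is mapped to a z value through the probability-integral
transform (computed tail-wise for numerical stability). Contiguous runs with
z > 1.64 (one-sided, model vs zero) or |z| > 1.96 (two-sided, model vs
model on paired differences) — strict inequalities — form clusters scored
by their size in samples (cluster mass is available as an option). The null
distribution of the maximum cluster score comes from sign-flipping whole
participant time courses (the exact randomization under a symmetric null);
corrected p values use the add-one estimator (1 + #{null ≥ observed}) /
(1 + iterations), which is monotone in cluster size. Zero-variance time
points are excluded from clusters with a warning. The peak statistic reports
the time of the maximum group mean (restricted to significant clusters when
any exist; exact ties resolve to the earliest sample), its one-sample t
against the relevant null level (0 for correlations, 0.5 for accuracies)
and Cohen's d = mean difference / SD.

**Preprocessing.** The cleaning chain, in canonical order: joint-probability
bad-channel detection in the frequency domain (per-channel Welch log-power
spectra scored bin-wise against the robust across-channel distribution;
channels whose mean squared robust z deviates more than 4 robust SDs from
the channel median are flagged; flagging every channel is an error),
spherical-spline interpolation of flagged channels (Perrin-style, order-4
Legendre weighting with 50 series terms and 1e-5 regularization, matching
MNE's interpolation operator to 1e-8), an optional 100-Hz low-pass
(a no-op at reduced synthetic rates), muscle-artifact flagging (trials with
log high-frequency power, >30 Hz, more than 4 SD above the mean),
peak-to-peak rejection at 150 uV applied per channel (the stricter of the
two possible readings; rejection only flags trials and never alters
samples), a zero-phase 4th-order Butterworth band-pass at 0.1–30 Hz with
1 s of reflection padding per epoch edge (epochs are short relative to the
0.1-Hz cutoff), baseline correction by the mean of the 100 ms prestimulus
window, and re-referencing to the TP9/TP10 average.

## The synthetic world

The generator emulates the experiment so every stage can be tested against
known ground truth.

* **Design.** Experimental trials are n_stimuli x n_repetitions
  (96 x 40 = 3,840 at full scale), plus vigilance probes
  (24 stimuli x 16 repetitions = 384) split 50/50 into identical-pair and
  different-pair probes — the split that makes 384 probes produce 576
  vigilance-stimulus presentations. Trials divide evenly over 6 blocks
  (704 each); probes are placed one per equal-length segment at a random
  non-initial position, so they are never first in a block and never
  consecutive. Onset asynchronies are uniform in 800–1,000 ms.
* **Trait space.** Speaker-level latent scores (exactly standardized) map
  to the eight analyzable characteristics through a loading matrix; the
  default two-dimensional structure loads the valenced traits
  (trustworthiness, dominance, health, educatedness, professionalism) on one
  latent and the physical characteristics (gender, attractiveness, age) on
  the other, reproducing the halo-effect intercorrelation pattern of real
  rating data. The implied characteristic correlation matrix is available in
  closed form and is verified against Monte-Carlo rating correlations.
* **Ratings.** Latent-driven characteristic values receive stimulus-level
  jitter (the three vowels of a speaker share the speaker latent but are
  not rated identically; default SD 0.2), are mapped to the 1–9 scale with
  mean 5 and SD 1.5, perturbed per rater (default SD 1.0), rounded and
  clipped. The ninth scale carries no latent signal and heavy rater noise
  (SD 3), emulating a scale that fails the agreement screen.
* **Acoustics.** A 13 x n_latent mixing matrix states how strongly each
  measure tracks each latent (default: F0 and formants track the physical
  latent; voice-quality measures weakly track the trait latent). Formants
  come from vowel targets scaled by a speaker vocal-tract factor, and DF is
  computed from them, keeping the table internally consistent. The LTAS is
  parametric: a speaker-specific spectral tilt plus Gaussian formant bumps
  in linear power.
* **EEG.** Each experimental trial is the deterministic stimulus response —
  per latent, latent score x fixed scalp pattern x raised-cosine temporal
  window — plus an optional acoustic-confound term (stimulus-level drivers x
  scalp pattern x early window), scaled to `snr` times the noise SD, plus
  noise that is spatially correlated (exponential falloff calibrated to
  r ≈ 0.6 between neighboring channels) with a 1/f-shaped temporal spectrum.
  Channel positions come from the standard 10-05 montage (32-channel cap
  including TP9/TP10). Trials of the same stimulus share the deterministic
  part exactly; `snr = 0` gives pure noise; everything is bit-reproducible
  from the seed.

**What the generator does not emulate:** real auditory evoked components
(the deterministic signal is an abstract window kernel, not an AEP),
eye-blink/muscle artifact morphology (only amplitude outliers are
available), non-stationary noise, inter-individual differences in scalp
patterns (participants share patterns and differ only in noise), and any
acoustically realistic vowel synthesis. Passing tests therefore demonstrate
that the statistical machinery recovers the structures it assumes — not
that those structures are what real EEG contains.

## Problem sizes and the desk scale

The full published-scale analysis (96 stimuli, 40 repetitions, 32
participants, 1 kHz, 50 permutations, 10,000 permutation iterations) is
expressible through the `paper` configuration preset, but the package's own
validation runs at a reduced "desk" scale chosen to keep the whole suite in
the minutes range: 16 stimuli (8 speakers x 2 vowels), 20 repetitions,
8 participants, a 10-ms time grid (−100..700 ms), 5 subaveraging
permutations for recovery simulations (20 where chance calibration is the
point), and 500–1,000 sign-flip iterations. Every *analysis* parameter that
defines the method — split count, classifier, thresholds, filter band,
rejection criterion — is identical across presets.

## Simulation scenarios and their rationale

Four packaged scenarios (module `voicersa.scenarios`) probe the model
logic; signal-to-noise values are free parameters of the synthetic world
and were fixed as follows.

* **Recovery** (`snr = 1.5`, window 100–300 ms): Model 1 must find a
  cluster where the latent drives the scalp. Because the temporal kernel is
  a raised cosine, the embedded signal is exactly zero at the window edges;
  the recovery criterion is therefore coverage of the kernel's half-maximum
  support (the middle half of the window) rather than of the nominal window,
  plus the requirement that clusters lie within the nominal window.
* **Acoustic confound** (`acoustic snr = 2.5`, window 60–160 ms): the
  physical latent reaches the scalp only through an acoustic pathway that
  the feature table also tracks, so partialling the acoustic PC RDMs
  (Model 2) removes what Model 1 sees; the paired two-sided cluster test
  localizes M1 > M2 to the confound window.
* **Mixture** (`snr = 0.8`): the health scale is constructed, rater by
  rater, as the rounded average of trustworthiness and dominance, which are
  themselves noise-free expressions of the single latent allowed to reach
  the scalp. Model 1 detects health; Model 3, which partials the parent
  scales, should find nothing. Two design points matter here. First, the
  parents must have no unique speaker-level variance — partialling *noisy*
  proxies of a shared latent leaves a residual correlation (classic
  incomplete adjustment) that the group test will find, because the
  stimulus set is fixed across participants and any seed-level residual is
  a common bias. Second, the signal-to-noise is moderate: with a fixed
  stimulus set, chance rank correlations between 120-pair RDM vectors are
  of order 0.1, and a sufficiently clean neural estimate would resolve even
  those; the per-participant rho noise must stay above that floor.
* **Latency ordering** (`snr = 1.5`, windows 80–200 vs 350–500 ms): a
  physical-like characteristic with an early unique latent versus a
  trait-like characteristic with a late one; Model 3 onset order must match.
  Acoustics are generated with zero latent mixing here so the acoustic
  covariates do not absorb the unique latents.

The cluster-inference null calibration uses temporally smoothed Gaussian
noise (Gaussian kernel, SD 2 samples) rather than white noise: the
pipeline's rho time courses are temporally smooth because the EEG is
band-limited, and on white noise the cluster-*size* statistic is markedly
conservative (small cluster sizes are coarsely discrete), which would
misrepresent the pipeline's operating characteristics.

## Numerical choices

* SMO tolerance 1e-3 (libsvm's default) in production, 1e-4 in oracle
  comparisons; C = 1 throughout; no feature scaling beyond noise
  normalization.
* Ledoit–Wolf shrinkage is computed on the stacked residual samples with
  `assume_centered=True` (residuals are mean-zero per stimulus by
  construction); fixed-intensity shrinkage is available, and zero shrinkage
  on singular covariances raises with a pointer to shrinkage.
* Split assignment, noise draws, sign flips and all other randomness derive
  from `numpy` `SeedSequence` streams keyed by (seed, stage tag, index), so
  every stage is independently reproducible and participant streams are
  stable across processes.
* Baseline windows, filter bands and epoch limits are validated before any
  computation; item-order mismatches between RDMs abort before statistics.
* Ties: average ranks everywhere; exact peak ties resolve to the earliest
  time point; cluster membership at exactly the threshold is excluded
  (strict inequality).

## Known limitations

* The pairwise SVM stage at full 96-stimulus, 1-ms, 50-permutation scale is
  hours of single-core compute; the desk preset exists because of it.
* Partial correlation with noisy covariates under a fixed stimulus set
  cannot produce an exact null (see the mixture scenario); Model 3 effects
  in any fixed-stimulus design should be read with that caveat.
* The agreement threshold (ICC ≥ 0.5) is a policy default, not an estimated
  quantity.
* The joint-probability bad-channel statistic follows the spirit of the
  cited approach (log-probability of spectral values under the
  across-channel distribution); no exact reference implementation exists to
  compare against, so its tests are constructive (planted bad channels).
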