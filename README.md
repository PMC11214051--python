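# voicersa

Time-resolved representational similarity analysis (RSA) of EEG responses
to voices: when, after hearing a voice, does the brain carry information
about the person characteristics listeners perceive in it — gender, age,
health, attractiveness, dominance, trustworthiness, educatedness,
professionalism — and how much of that information is explained by the
sound itself?

The package is written for cognitive/auditory neuroscientists running
multivariate EEG experiments with rated stimuli. It provides the full
analysis chain as a tested library plus a `voicersa` command line, and a
synthetic-data generator with known embedded structure so that every stage
is verifiable end to end without access to any real recordings.

## The method

Three dissimilarity structures are built over one stimulus set
(32 speakers x 3 vowels = 96 recordings at full scale):

* **Neural RDMs** `D_neural(t)`: for each participant and each 1-ms sample,
  the cross-validated pairwise decoding accuracy between every pair of
  recordings — trials subaveraged into 5 splits, multivariate noise
  normalization fitted on training folds (epoch-method covariance, shrunk
  and inverted via its symmetric inverse square root), linear SVM (C = 1)
  on channel amplitudes, averaged over folds and 50 split assignments.
  0.5 means indistinguishable.
* **Behavioral RDMs** `D_c`: absolute differences in mean rating for each
  characteristic `c`, after excluding raters who gave the same response on
  more than 80% of trials and dropping scales with poor inter-rater
  agreement (ICC(2,k); the sexual-orientation scale falls here).
* **Acoustic RDMs**: the cosine dissimilarity of long-term average spectra
  (LTAS), and absolute score differences on the four eigenvalue > 1
  principal components (PCA with oblimin rotation) of 13 perceptually
  salient acoustic measures (F0, F1–F4, formant dispersion, harmonic
  source shape, CPP, energy, HNR).

The statistic is the time-resolved partial Spearman correlation between
vectorized RDM lower triangles,

    rho_c(t) = spearman( D_neural(t), D_c | covariates ),

with nested covariate sets: **Model 1** partials the LTAS RDM, **Model 2**
additionally the four acoustic PC RDMs, **Model 3** additionally the
behavioral RDMs of all other retained characteristics — so M3 asks for
representation unique to a characteristic beyond acoustics and beyond the
rest of the trait space. Group inference uses permutation-based
cluster-size statistics: per-sample t against zero converted to z,
thresholded at z > 1.64 (one-sided; |z| > 1.96 two-sided for model-vs-model
comparisons), contiguous suprathreshold runs scored by size against a
sign-flip null of the maximum cluster size, with peak times, t and Cohen's
d reported per cluster. See `docs/methods.md` for the complete account.

## Worked example

Run the whole chain on synthetic data at desk scale (16 stimuli,
8 participants, 10-ms grid, an embedded trait-space signal at
100–300 ms, seed 7):

```python
from voicersa.config import desk_config
from voicersa.pipeline import run_pipeline

cfg = desk_config(seed=7, n_permutations=3, n_iterations=500,
                  n_raters=12, snr=1.2)
run_pipeline(cfg, "results/demo")
```

or equivalently `voicersa run --out results/demo --seed 7`. The stage
outputs land in `results/demo/` (ratings and feature CSVs, per-participant
RDM archives, time-course CSV, `inference.json`, a manifest with the config
hash). From `inference.json` of that exact run:

```
voice_decoding:      cluster 130–320 ms (p = 0.006), peak 220 ms,
                     83.0% accuracy, t(7) = 38.9, d = 13.7
trustworthiness:M1   cluster 130–290 ms (p = 0.008), peak rho 0.67 at 180 ms
trustworthiness:M2   cluster 140–270 ms (p = 0.008), peak rho 0.61
trustworthiness:M3   cluster 150–200 ms (p = 0.024), peak rho 0.16
```

Reading: voice identity is decodable where the latent signal was embedded;
the trustworthiness rating RDM tracks the neural RDM there (M1); the effect
survives partialling acoustics (M2) and shrinks but persists against the
other characteristics (M3), because in this synthetic world the valenced
traits share one latent. The `sexual_orientation` scale is dropped by the
agreement screen before any model runs.

Every stage is also a standalone command operating on the stage files:
`voicersa simulate`, `preprocess`, `rdm`, `behavior`, `acoustics`, `rsa`,
`infer`, `run` (see `--help` of each).

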