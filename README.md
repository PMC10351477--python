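# neurotrack

Neural tracking of continuous natural speech from EEG, built around boosted
temporal response functions (TRFs).

When a listener follows running speech, cortical activity time-locks to
features of the signal. *Acoustic tracking* — responses to the spectrogram
and its onsets — survives even when the speech is not understood. *Language
tracking* — responses to linguistic quantities such as word surprisal —
requires comprehension: the hallmark is an N400-like negativity ~300–500 ms
after word onset that appears only when words can be integrated into their
context. This package implements the full analysis chain that measures both,
for researchers in auditory cognitive neuroscience who work with continuous
speech EEG:

- **Speech regressors** — a 256-channel gammatone spectrogram (ERB-spaced
  70–4000 Hz, 10 ms integration) averaged into 8 bands, half-wave-rectified
  acoustic edges, phoneme/word onset impulses, and four language features
  computed from a pronunciation lexicon and a 5-gram language model:

  - phoneme surprisal `−log₂( freq(cohortᵢ) / freq(cohortᵢ₋₁) )`
  - cohort entropy `−Σ_w p_w log₂ p_w` over the active cohort (normalized
    per fragment by its maximum)
  - word surprisal `−log₁₀ p(wᵢ | wᵢ₋₄ … wᵢ₋₁)`
  - word frequency `−log₁₀ p(wᵢ)`

  where the *active cohort* is the set of lexicon words consistent with the
  phonemes heard so far within the current word.

- **EEG preprocessing** — resampling, common-average reference, 0.5–25 Hz
  least-squares FIR bandpass (orders 5000/250, stopband edges 10 % outside
  the passband, pass/stop weights 100/1), z-scoring across conditions, 455 s
  truncation, and denoising source separation (DSS) with a 2–25 Hz evoked
  bias.

- **Boosted TRFs** (`BoostingTRF`, a scikit-learn-style estimator) — sparse
  kernels over lags −100…600 ms estimated by greedy coordinate descent with
  a 50 ms Hamming basis and validation-based early stopping, under 10-fold
  cross-validation with contiguous folds. Acoustic tracking is the held-out
  per-channel prediction accuracy (Pearson r) of the acoustic model;
  language tracking is the accuracy increase Δr of the complete model
  (acoustic + onsets + language features) over the baseline model
  (acoustic + onsets).

- **Peaks and group statistics** — signed extrema of selection-averaged TRFs
  inside a-priori windows (e.g. N250: 150–350 ms after phoneme onsets, N400:
  300–500 ms after word onsets; extrema on a window edge are discarded),
  paired Wilcoxon and Mann–Whitney U tests with Benjamini–Hochberg or Holm
  correction, and spatio-temporal cluster-based permutation tests
  (max-cluster-mass null from per-subject sign flips).

- **Synthetic study generator** — because no public data accompany this
  design, `neurotrack.simulate` builds a complete replica: Zipf lexicons
  with shared prefixes, Markov transcripts with Gamma-distributed phoneme
  durations, three conditions (comprehensible story, foreign story, shuffled
  word list), and 64-channel EEG as regressor ⊛ kernel convolutions plus
  spatially correlated 1/f noise. The N400-like word-surprisal kernel is
  planted only in the comprehensible condition.

## Worked example

```python
from neurotrack.simulate import SimConfig, simulate_study
from neurotrack.pipeline import StudyConfig, run_study, summarize

cfg = SimConfig(seed=3, n_subjects=6, duration_s=100.0, corpus_tokens=4000)
result = run_study(StudyConfig(sim=cfg, n_perm=200))
print(summarize(result)["language_tracking"])
```

prints (numbers from this exact run):

```
{'comprehensible': {'mean_delta_r':  0.0073, 'min_cluster_p': 0.0498},
 'foreign':        {'mean_delta_r': -0.0001, 'min_cluster_p': 0.3483},
 'word_list':      {'mean_delta_r': -0.0002, 'min_cluster_p': 0.5025}}
```

`mean_delta_r` is the channel-averaged increase in cross-validated
prediction accuracy attributable to the language features; `min_cluster_p`
is the smallest cluster-permutation p-value of that increase against zero.
Only the comprehensible condition shows language tracking — the planted
contrast, recovered by the full pipeline.

The command line mirrors the library:

```bash
neurotrack simulate --seed 1 --out simdata/
neurotrack trf --features simdata/features_comprehensible.h5 \
               --eeg simdata/eeg_comprehensible_s00.h5 \
               --model complete --out trf.h5
neurotrack run --seed 1 --out summary.json
```

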