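# Methods

This note documents the models, algorithms, defaults, and design choices of
`neurotrack`, and what the synthetic validation does and does not show.

## Speech regressors

**Gammatone spectrogram.** The waveform passes a bank of 256 4th-order
gammatone IIR filters (scipy's design) with center frequencies equally
spaced on the ERB-rate scale between 70 and 4000 Hz. Output power is
averaged over non-overlapping 10 ms windows (100 frames/s), square-rooted to
an amplitude-like scale, averaged over 32 consecutive channels into 8 broad
bands, and polyphase-resampled to the 128 Hz EEG grid. Tiny negative values
from resampling ringing are clipped to 0 because the feature represents
energy. The filter order (4th) is the standard auditory-model choice; the
intermediate frame rate (1/integration) and the order of operations
(derivative after band-averaging, before resampling) are configurable
because the pipeline definition leaves them open — `acoustic_feature_set`
exposes `edges_on_bands`.

**Acoustic edges** are the half-wave-rectified first difference of the
spectrogram along time; the first frame is defined as 0 so shapes are
preserved.

**Cohort model.** The lexicon is held in a prefix trie caching, per node,
the member words and their summed frequency, so every cohort query is O(
prefix length). Phoneme surprisal uses frequency *ratios* and is therefore
invariant to the count/probability distinction; cohort entropy uses
within-cohort normalized frequencies, as the entropy formula requires. The
cohort resets to the full lexicon at each word onset. Homophones remain
separate cohort members (frequencies not merged). Words whose label or
phoneme sequence is missing from the lexicon are skipped for phoneme-level
features with a logged message, leaving zero-amplitude impulses at their
onsets. Cohort entropy is normalized by its maximum over the fragment.

**n-gram model.** A trainable add-k (default k=1) model with backoff to the
longest seen shorter context stands in for the large pretrained models such
analyses normally use; with k=0 an unseen continuation yields `+inf`
surprisal or an error (`oov` switch). Log bases: 2 (bits) for phoneme-level
features, 10 for word-level features. Feature values for the word list are
computed with the shuffled order as 5-gram context, since the features
describe the token sequence as presented.

**Impulses.** Event onsets are rounded half-away-from-zero to the nearest
sample at 128 Hz; collisions are summed with a warning. (Pre)lexical
features carry unit amplitudes; language features carry the per-event
values.

## EEG preprocessing

The chain is resample→256 Hz, artifact hook, common-average reference,
0.5–25 Hz least-squares FIR bandpass (high-pass order 5000, low-pass order
250, stopband edges 10 % outside the passband, pass/stop weights 100/1),
resample→128 Hz, z-scoring across conditions per channel, truncation to the
first 455 s. The filters are linear-phase; they are applied center-aligned
via FFT convolution, which compensates the group delay exactly (zero phase)
while keeping the designed magnitude response — peak latencies are
unaffected. The artifact hook is an identity by default: a trained
eye-blink filter requires recorded blink artifacts, which synthetic data do
not contain; any channels×time → channels×time transform can be plugged in.

**DSS.** Spatial filters are estimated across recordings of the same
stimulus: whiten on the mean within-recording broadband covariance
(relative ridge 1e-9, warning when rank-deficient), then rotate to the
eigenvectors of the covariance of the 2–25 Hz filtered cross-recording
average (least-squares FIR, order 400). Components are ranked by a
repeatability ratio — N·(power of the filtered average)/(mean power of
filtered individual recordings), per component — which is ~1 for
independent noise, ~N for perfectly reproducible activity. With fully
identical recordings every ratio equals N exactly and the component order
is degenerate, so the implementation is validated through that ratio
property rather than a particular component ordering. Reconstruction keeps
the top k=6 components and projects back to sensor space (a rank-k
projection, idempotent by construction). The bias average is taken across
participants; filters should be trained on data excluded from TRF
evaluation.

## Boosted TRFs

The encoding model is `pred[c,t] = Σ_p Σ_l h[p,l,c]·x_p[t−l]` with lags
−100…600 ms (samples −12…76 at 128 Hz; fractional endpoints truncate toward
zero). Estimation is greedy coordinate descent: starting from zero kernels,
each iteration applies the single ±Δ update over (predictor, lag) that most
reduces training squared error, per channel. Early stopping monitors the
validation-segment ℓ2 error; each channel returns the kernels at its
running validation optimum after `patience` (default 10) consecutive
non-improving iterations, or stops immediately when no update reduces
training error. Defaults: Δ = 0.005 × the channel's training SD,
max_iter = 10 000, per-channel stopping (a `global` mode pools the summed
validation error). Predictors are divided by their training-fold SD before
fitting (inverted on the returned kernels) so Δ is commensurate between
dense bands and sparse impulses. Scaling the EEG by c scales the kernels by
c exactly, because Δ is proportional to the channel SD.

**Basis smoothing.** A 50 ms Hamming window (6 samples at 128 Hz) smooths
the kernels. By default it acts *in the loop*: candidate updates are
smoothed bumps rather than single-lag deltas, implemented by mapping the
design through a column-stochastic smoothing matrix (each column a
truncated, renormalized window, so kernel mass is preserved exactly). A
post-hoc mode (`basis_mode="post"`) smooths only the final kernel.

**Implementation.** Fitting runs entirely in sufficient-statistic space:
per-segment Gram matrices of the lagged design and FFT-based feature–EEG
cross-covariances. Residual correlations are updated incrementally
(O(channels × predictors × lags) per iteration), the validation ℓ2 error
is tracked in closed form, and for a fixed stimulus the Grams are shared
across subjects and nested models. Lagged values that would cross a fold
boundary are treated as zero (zero-padded segments), consistently in
training, validation and scoring.

**Cross-validation.** 10 contiguous equal-length folds (the remainder goes
to the first folds); each rotation trains on 8, early-stops on 1, scores on
1; test segments tile the recording exactly once. Reported kernels are the
fold average; accuracies are per-channel Pearson r on the test segments. A
channel whose kernel stays all-zero predicts a constant and scores r = 0.
Contiguous (rather than interleaved) folds avoid autocorrelation leakage
between train and test.

## Tracking measures and peaks

Acoustic tracking = accuracy of the acoustic model (spectrogram + edges).
Language tracking = per-channel Δr of the complete model (acoustic +
onsets + 4 language features) over the baseline (acoustic + onsets).
Channel selections are fixed a priori: a 21-channel fronto-central set for
acoustic/lexical responses and the 6-channel centro-parietal set
{P1, Pz, P2, CP1, CPz, CP2} for language responses. Peak windows
(ms): spectrogram P1 0–65, N1 70–110, P2 115–200; edges P1 0–90, N1 95–140;
phoneme surprisal & cohort entropy N250 150–350; word surprisal & word
frequency N400 300–500. The signed extremum matching the expected polarity
is located within the window; an extremum on the first or last window
sample is discarded (`found=False`); ties resolve to the earliest lag; a
"negative" peak with positive amplitude is reported but flagged
`wrong_sign`.

## Group statistics

Paired Wilcoxon signed-rank tests drop zero differences and use the exact
null up to 25 remaining pairs (normal approximation beyond; all-zero
differences return p=1 with a warning). Mann–Whitney U uses the
tie-corrected normal approximation and serves where missing peaks break the
pairing. BH and Holm adjustments delegate to statsmodels. The cluster-based
permutation test thresholds per-cell one-sample t-statistics at the
two-sided p<0.05 quantile, groups suprathreshold cells of equal sign by
adjacency (Delaunay triangulation of the flattened standard montage for
channels, chain adjacency along lags, both combined for channel×lag maps),
scores clusters by mass (sum of t), and compares against the maximum
absolute cluster mass over `n_perm` random per-subject sign flips
(p = (1 + #{null ≥ obs}) / (1 + n_perm), default n_perm=1000, seeded).
Both lag-only (selection-averaged TRFs) and channel×lag modes are
available; the pipeline uses channel maps for Δr and lag-only maps for
TRFs.

## Synthetic study

The generator emulates the study conditions the analysis assumes: 19
subjects, 64 channels on the standard montage, 128 Hz, 455 s per condition,
three conditions. Defaults: a 500-word lexicon over 20 phonemes with
prefix-shared pronunciations of length 2–8 and exact Zipf frequencies
(s=1.1); a 20 000-token Markov corpus training the 5-gram; transcripts at
3.5 words/s with Gamma-distributed phoneme durations (shape 2) and short
exponential gaps. The word list permutes the story's word slots while
keeping the gap sequence, preserving the word multiset and the timing
envelope exactly; the foreign condition uses an independent lexicon with
matched timing statistics.

Ground-truth kernels are sums of Gaussian lag components times smooth scalp
topographies (fronto-central for acoustic/lexical, centro-parietal for
language features; unit maximum). Acoustic and lexical kernels are
identical across conditions. All four language kernels are zeroed outside
the comprehensible condition — this plants the headline contrast the
pipeline must recover (language tracking and the N400-window trough only
with comprehension, acoustic tracking unchanged). Spectrogram/edges are
simulated as 2 bands each of slow rectified noise (the forward model plants
kernels per feature family, so the band count is a simulation parameter,
not an analysis one); edges derive from the simulated spectrogram through
the actual edge code, and the language impulses are computed by the actual
cohort/n-gram code, so regressor collinearity (shared onset times) matches
the analysis assumptions by construction.

Noise is 1/f (exponent 1) Gaussian noise mixed through a spatially smooth
random matrix, unit variance per channel. Each feature family's summed
contribution is scaled to a per-family SNR (defaults: acoustic −8 dB,
lexical −13 dB, language −13 dB, chosen so kernel recovery succeeds at
455 s while the language Δr stays small, ~0.01 correlation units);
per-subject lognormal amplitude jitter (σ=0.2, shared across conditions so
subjects remain paired) multiplies the family gains. A family whose kernels
are zeroed in a condition contributes its power to the noise instead:
ongoing brain activity does not vanish when speech is incomprehensible, it
merely stops being stimulus-locked. This keeps total variance — and hence
the acoustic model's expected accuracy — equal across conditions, which is
the planted acoustic null. The null is statistical rather than exact: the
language signal shares onset times with the acoustic regressors (the
collinearity is intentional, it is what the model-differencing design must
cope with), which biases the comprehensible condition's acoustic accuracy
down by a few percent relative — small against the between-subject spread,
so the paired comparisons stay non-significant apart from the test's
designed ~5 % family false-positive rate.

**What passing tests show and do not show.** The simulation validates the
estimator chain (recovery, calibration, bookkeeping) under its own forward
model: linear, stationary responses, Gaussian 1/f noise, perfectly known
segmentations, no artifacts, no inter-subject latency differences. Real EEG
violates all of these to some degree; passing here demonstrates
correctness of the implementation, not robustness to real-data pathology.

## Problem sizes and numerical choices

The packaged validation runs the single-subject kernel-recovery check at
the full 455 s and the 19-subject replica at 455 s in the acceptance
script; the test suite runs the same replica on 250 s fragments, which
leaves the planted effects far from threshold while keeping the default
suite quick. Cluster-test calibration uses 200 null cohorts at n_perm=500.
Gram matrices are float64; cached lagged designs for scoring are float32.
Degenerate inputs: constant EEG channels yield zero kernels with a warning;
zero-variance channels make z-scoring fail loudly with the channel named;
rank-deficient DSS covariances are ridge-regularized with a warning.

## Known limitations

- The boosting step, patience and iteration cap are package defaults, not
  canonical values; different choices trade sparsity against fit.
- The n-gram stand-in is far smaller than production language models;
  absolute surprisal scales differ from those obtained with large corpora.
- The DSS variant (evoked bias, cross-participant average) is one member of
  a family; other bias functions reorder components.
- TextGrid parsing covers interval tiers in the common long/short text
  formats only.
- No artifact rejection beyond the identity hook; no source localization;
  no decoding (backward) models; ridge/Tikhonov TRF estimation is
  deliberately out of scope (boosting only).
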