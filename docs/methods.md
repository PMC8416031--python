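# Methods

## The staging problem

Polysomnography (PSG) records EEG, EOG, EMG and ECG over a night; sleep
medicine divides the night into 30-second epochs and assigns each one of the
five AASM stages W, N1, N2, N3, REM. `somnostage` implements an automatic
stager with three parts: a hand-crafted feature extractor (152 features per
channel per epoch), a time-attention encoder (bidirectional GRU + sigmoid
gate), and a class-weighted linear-chain CRF that scores whole-night stage
sequences. The canonical stage order W, N1, N2, N3, REM (indices 0-4) is used
everywhere.

## Preprocessing

Each channel is bandpass-filtered by modality with a zero-phase
(forward-backward) Butterworth filter of order 4: EEG and EOG 0.3-35 Hz, EMG
10-100 Hz, ECG 0.3-70 Hz. At 100 Hz sampling the EMG band's upper edge meets
the Nyquist frequency and is clipped to 0.99 x Nyquist with a warning. The
filter order is our choice (the conventional EEG value); the family, bands
and zero-phase requirement are fixed by the method.

Signals are cut into non-overlapping 30-s epochs (trailing remainder
discarded) and each night is standardized to exactly 1,140 epochs (9.5 h):
longer nights keep their first 1,140 epochs; shorter nights are pre-padded by
cyclically repeating the night's leading consecutive Wake epochs, signal and
label alike. The padding rule is a documented interpretation: padding "from
the previous consecutive Wake period" is read as extending the pre-sleep Wake
block, the only reading consistent with padding before sleep onset. A short
night with no leading Wake epochs cannot be padded and is an error.

## Features (152 per channel per epoch)

From each channel-epoch, ten sequences: the raw samples; their first
difference; and eight band sequences - the Welch PSD bin values and the
Lomb-Scargle PSD bin values within delta (0.5-4 Hz), theta (4-8 Hz), alpha
(8-13 Hz) and beta (13-30 Hz). Fourteen descriptive statistics per sequence
(max, min, mean, population variance, std, 25/75/95th percentiles, skewness,
excess kurtosis, median, zero-crossing rate, Hjorth mobility, Hjorth
complexity) give 140 features. Twelve non-linear features complete the 152:
permutation, sample and SVD entropy of the raw sequence and of its first
difference (6), the four absolute Welch band energies (trapezoidal
integration), and the spectral Shannon entropy of the Welch and of the Lomb
PSD (2). The allocation of the twelve non-linear features is a documented
design choice: it is the only composition of the published feature families
consistent with the totals 140 + 12 = 152.

Numerical choices:

* Welch: Hann window, segment length min(256, S), 50% overlap.
* Lomb-Scargle: uniform grid 0.5 to min(30, 0.99 x Nyquist) Hz, 0.25 Hz
  spacing. Because epochs are uniformly sampled on a fixed grid, the
  per-frequency trig factors are data-independent; they are precomputed once
  per (length, rate) and each evaluation reduces to two matrix-vector
  products. The result matches `scipy.signal.lombscargle` to ~1e-15
  relative (tested).
* Entropy parameters: permutation entropy order 3, delay 1 (ties broken
  earlier-index-smaller); sample entropy m = 2, r = 0.2 x sd, Chebyshev
  distance, self-matches excluded, with the cap ln(n_pairs) returned when no
  template pair matches; SVD entropy embedding dimension 10, delay 1. All
  entropies are normalized to [0, 1].
* Sample entropy is computed on the epoch decimated by 3. The quadratic
  template search dominates extraction cost at 3,000 samples per epoch, and
  the decimated statistic preserves the stage ordering that makes the feature
  informative.
* Degenerate inputs map to 0 (skew/kurtosis/Hjorth of constant sequences,
  spectral entropy of empty spectra), so feature matrices never contain
  NaN/Inf. A relative round-off floor treats numerically-constant sequences
  as constant.

With the six supported channels the blocks are ordered C4, EMG, LEOG, REOG,
F4, O2 (912 features). Features are z-scored with mean/std estimated on
training nights only; features whose training std is below 1e-8 map to 0.

## Model

For a night X (T x F), a single-layer bidirectional GRU with hidden size F/2
per direction (an odd F is zero-padded by one column) produces a (T, F)
hidden sequence H; the common GRU formulation with the reset gate inside the
candidate's recurrent term is used. The time-attention gate is the
elementwise product sigmoid(H) * X - the elementwise reading is the only
shape-consistent one given the bidirectional hidden width equals F. A linear
layer maps the gated features to five per-epoch emission scores.

The linear-chain CRF adds transition scores A (5x5) plus learnable start/end
scores (initialized 0). Training minimizes a class-weighted negative
log-likelihood in which the stage weights scale the gold path's emission
term only:

    L_w = log Z(E) - [start(y_0) + sum_t w(y_t) E(t, y_t)
                      + sum_t A(y_{t-1}, y_t) + end(y_T)]

Unit weights recover the standard CRF NLL exactly; the emission gradient is
P(y_t = k) - w(y_t) 1{k = y_t}, so epochs of an upweighted rare stage (the
imbalance setting of the method's study is w = (1, 6, 1, 2, 1), boosting
rare N1) pull that stage's score up w times harder, raising its recall at
the cost of precision and overall accuracy - the documented behaviour of the
class-balance strategy. Weights apply during training only; decoding is
Viterbi over unweighted emissions, since the weighting is an imbalance
correction, not a change of decision rule. How class weights couple to a
globally-normalized chain loss is genuinely open; the obvious alternative -
reweighting the emission table inside the partition as well, so every path
is scored with its own labels' weights - shares the unit-weight reduction
but empirically *suppresses* the rare stage at unweighted decoding (the
learned rare-class emissions converge to roughly 1/w of the
decision-relevant scale), so the gold-path scheme is used; the alternative
remains available in `somnostage.crf` (the `weights` argument of
`log_partition`/`nll_loss`/`crf_gradients`) with its own enumeration-oracle
tests. Viterbi ties break toward the lower stage index.

The implementation is plain NumPy. Gradients are derived by hand
(backpropagation through time for the GRU; forward-backward expected counts
minus empirical counts for the CRF) and verified against central finite
differences in the test suite; log-space forward/backward recursions are
verified against exhaustive enumeration over all 5^T paths for small T.

## Training

One optimization step per night (the 1,140-epoch sequence is the batch, as
the chain couples all epochs), Adam with learning rate 1e-4 and weight decay
0.01. Weight decay is classic L2 added to the gradient and applies to
connection weights only - biases and the CRF transition/start/end scores are
exempt, so the learned transition structure reflects the data alone.
Parameters initialize uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)), seeded. Early
stopping monitors the validation loss on a held-out 10% of the training
nights (at least one night) with patience 10; defaults max_epochs = 100. The
stopping scheme and initialization are our choices; optimizer, learning
rate, batch convention and weight decay value are fixed by the method.

## Evaluation

Confusion matrices have expert stages as rows and predictions as columns.
ACC is the trace over the total; per-class precision/recall/F1 are
one-vs-rest with zero-denominator conventions of 0; WF1 is the
support-weighted mean of per-class F1 (the standard reading of "weighted
F1"); Cohen's kappa is (Po - Pe)/(1 - Pe) with Pe from the row/column
marginals. SEN-N1 is the N1 recall. Cross-validation is subject-independent:
whole subjects go to train or test, folds balance total night counts by
greedy largest-first packing, and reported metrics pool the per-fold
confusion matrices by summation. Configurations are compared with the paired
two-sided Wilcoxon signed-rank test over per-fold metrics (exact null for
n <= 25, zero differences dropped).

## Synthetic nights

The generator emulates exactly what the stager exploits: stage-dependent
band-power structure per channel and Markovian stage dynamics. Stage
sequences follow a first-order chain started in Wake with self-transition
0.9 in every stage, stationary N1 mass ~= 5% (deliberately rare), and a hard
zero on the physiologically unlikely direct W -> N3 transition - giving a
testable signature: the learned CRF score A[W, N3] should rank lowest among
Wake's outgoing transitions. Signals are sums of stage/channel-specific
oscillators with random phase (alpha in Wake, theta + 13 Hz spindle bursts
in N2, dominant delta in N3, slow eye movements on EOG in REM, chin-EMG tone
decreasing with depth to REM atonia), plus Gaussian noise, in microvolts.
N1 is spectrally intermediate between Wake and N2 (attenuated alpha plus
moderate theta, intermediate EMG tone) so it is genuinely confusable.

Two jitters make the task realistic rather than separable-in-the-limit:
per-subject amplitude scale (+-10%), so subject-independent CV generalizes
across amplitude regimes, and per-channel-epoch amplitude scale (+-35%),
so amplitude statistics of neighbouring stages overlap as they do in real
PSG. The default montage is the AASM minimal one (C4, EMG, LEOG); all six
channels are supported.

What the generator does **not** emulate: artifacts (movement, electrode
pop), K-complexes, stage-transition dynamics within an epoch, inter-scorer
disagreement, and realistic 1/f background spectra. Passing the synthetic
study therefore shows that the pipeline extracts band-power/entropy
structure and exploits label continuity; it does not certify clinical
performance on real PSG.

## Desk-scale study sizes

The shipped experiments use a 10-subject x 1-night corpus of standardized
1,140-epoch nights on the default three-channel montage (8 training / 2
held-out subjects, 30 training epochs with patience 10), and, for the
transition-structure check, ten independent seeded runs on 3-subject x
150-epoch two-channel corpora trained for 60 epochs without early
stopping. These sizes are the package's chosen desk-scale study
conditions; the full method on real data uses 5-fold subject-independent CV
over complete cohorts.

## What the CRF does and does not learn about transitions

The generator's hard zero on W -> N3 was designed to give a testable
signature: a transition absent from the training data should end up with
the lowest learned score among Wake's outgoing transitions. Extensive
experiments (varied corpus sizes, chain densities, montages, learning
rates and training lengths) show that this signature does **not** reliably
emerge from discriminative training at desk scale. The reason is
instructive: the gradient on A[W, N3] is the model's expected W-N3
adjacency mass minus its (zero) empirical count, and once the emissions are
informative the posterior never hesitates between Wake and N3 - N3 and its
N2 predecessors are spectrally unmistakable - so the entry receives almost
no gradient and stays near its initialization, while genuinely confusable
observed transitions (the W/N1 boundary) absorb systematic
expected-vs-empirical mismatch and often drift lower. The expectation
"absent transition -> minimal score" is a property of generatively
estimated (count-based) transition models, not of a conditionally trained
chain with strong emissions; the asymptotic separation (A[W, N3] -> -inf at
the exact optimum) is real but needs orders of magnitude more optimizer
steps than any desk-scale run performs. The transition-structure check in
the acceptance suite states the original expectation and is allowed to
fail; the measured rate is reported by the acceptance script.

## Known limitations

* The exact membership of the twelve non-linear features and the definition
  of WF1 are reconstructions (documented above); printed-table arithmetic is
  reproduced to rounding, but a different original composition cannot be
  excluded.
* Whether the fourteen statistics of the band sequences operate on PSD bin
  values (implemented) or band-passed time series is ambiguous in the source
  description; PSD bins were chosen.
* Training is CPU NumPy; a night step at F = 912 is ~seconds, so full
  Sleep-EDF-scale replication is possible but slow.
* The hyperparameter search for class weights is out of scope; weights are
  configuration values.
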