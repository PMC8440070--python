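# Methods

## Problem and model

Every heartbeat in a single-lead ECG is assigned one of five classes
(N, L, R, V, A; fixed canonical order for all vectorised outputs). Two
independent classifiers score each 250-sample beat window:

* a **time-domain stream**: a small 1-D CNN on the raw beat
  (conv 5×1×4 → pool → conv 4×1×4 → pool → conv 5×1×4 → pool →
  conv 5×1×8 → pool → FC 10 ReLU → softmax 5; valid convolutions, stride 1;
  max-pooling window 2, stride 2, odd lengths floored). The shape trace from
  a 250-sample input is 246×4, 123×4, 120×4, 60×4, 56×4, 28×4, 24×8, 12×8,
  10, 5.
* a **frequency-domain stream**: a full 5-level db6 wavelet-packet tree
  (32 terminal subbands in natural filter-bank order), per-subband
  population variance, mean and signed maximum → 96 features, z-scored with
  a transform fitted on training rows only, classified by five one-vs-rest
  epsilon-SVRs (targets 1/0, RBF kernel, g = 3.2, c = 2.9, ε = 0.1).

Both outputs are basic probability assignments with singleton focal
elements over the five-class frame; Dempster's rule reduces to
m(k) ∝ m₁(k)·m₂(k), renormalised by 1−K where K = 1 − Σⱼ m₁(j)m₂(j) is the
conflict. Total conflict (disjoint supports, K = 1) raises an explicit
error; the pipeline then falls back to the CNN mass, the stronger single
stream. The decision is the fused argmax, ties broken toward the earlier
canonical class.

## Preprocessing

Baseline wander is the output of a two-stage median filter
(median₁₅₁ ∘ median₅₁, reflect padding; window widths are the stated 50 and
150 samples bumped to the next odd integer), subtracted from the signal.
A centred median of width w is transparent to isolated waves shorter than
about w/2 samples and suppresses wider structure into the baseline
estimate; with the 151-sample second stage this bounds wave durations near
210 ms at 360 Hz. This constraint informed the simulator's wave durations
(below); on clean synthetic records the full preprocessing chain changes
the signal by ~2 % relative L2.

Wavelet denoising: db6, level 4, soft thresholding at the universal
threshold σ·√(2 ln n). The two finest detail bands (≥ 45 Hz at 360 Hz),
which carry powerline-type interference and only sparse QRS energy, are
each thresholded with their own robust noise estimate (MAD/0.6745), so an
in-band interference line inflates its own band's threshold and is removed
(≥ 95 % of 50 Hz line power in tests). Deeper bands reuse the finest band's
estimate so genuine morphology is not shrunk. The approximation band is
untouched. The operator is idempotent to machine precision on already
denoised signals.

Order of operations: baseline removal first, then denoising.

## QRS detection

Derivative → square → causal moving-window mean (default width 150 ms
= 54 samples). Candidate local maxima of the integrated signal are accepted
above TH1; SPKI/NPKI track accepted/rejected peak levels with 1/8–7/8
exponential updates, initialised from the first 2 s (SPKI = max,
NPKI = mean of the integrated signal). When a gap exceeds 1.66× the running
RR average (last 8 intervals), a search-back pass re-examines rejected
candidates in the gap against TH2 = 0.5·TH1. Accepted candidates are
refined to the maximum of the input signal in a window spanning the
integrator's group delay plus ±50 ms, with a 200 ms refractory rule.
Because both thresholds are data-driven ratios, detection is invariant to
positive amplitude scaling. Detection and refinement both run on the
preprocessed signal. Negative (inverted) R peaks are not handled — a known
limitation of this detector family.

Beats are windows [r−99, r+150] (250 samples, R at 0-based index 99);
peaks too close to the record edges are skipped and counted.

## Synthetic data

Beats are sums of Gaussian bumps (P, Q, R, S, T); asymmetric bumps use
different left/right widths. Class signatures: V — widened dominant
deflection (~150 ms), absent P, discordant T; L/R — opposite-skew slurred
QRS (~125 ms); A — reduced P and a 20 % shortened preceding RR; N —
canonical. Wave durations sit at physiological midpoints chosen to respect
the median-filter transparency bound above (T ~170 ms, normal QRS ~95 ms).
Amplitudes and widths get 5 % relative jitter per beat; all randomness
flows from one explicit seed.

Records concatenate jittered beats at truncated-normal RR intervals
(sd 5 %, clipped at 2 sd, floor 0.3 s; the floor rises to the 250-sample
window length when the mean interval allows, so windows stay disjoint).
Noise defaults: 0.15 mV baseline wander at 0.3 Hz, 0.05 mV powerline hum at
50 Hz, 0.02 mV white noise — moderate recording conditions.

What the simulator does **not** emulate: rhythm-level phenomena (AF,
bigeminy), respiration modulation, electrode motion artefacts, inverted
QRS, inter-patient variability, multi-lead structure. Passing tests on this
benchmark demonstrate the pipeline's internal correctness and the value of
fusion under controlled separability — not clinical performance on real
recordings, which is measured on annotated databases via the WFDB reader.

## Training and evaluation

CNN: categorical cross-entropy, Adam (lr 0.01, batch 64), seeded uniform
fan-in initialisation; the full-run default is 600 epochs, while the
benchmark and tests use 30 epochs with 50 beats per class — enough for the
separable synthetic templates and small enough that the whole suite runs in
well under a minute on one CPU. SVR fits use solver tolerance 1e-10, which
makes the SMO solution order-independent to ~1e-10 so training-row
permutations cannot move predictions.

Cross-validation is stratified k-fold (default 10; the desk-scale
benchmark uses 5), per-fold metrics averaged by plain means. Per-class
one-vs-rest metrics in percent: PPV, SE, SP, Acc and F1 = 2TP/(2TP+FP+FN)
(the harmonic mean of PPV and SE — asserted as an identity in tests).
Zero-denominator metrics return 0 with a degenerate flag so reports stay
total.

## Numerical and design choices

* **Wavelet-packet boundary handling**: beats are zero-padded from 250 to
  256 samples so the periodised transform is orthonormal — coefficient
  energy equals signal energy to 1e-8 and every leaf holds exactly 8
  coefficients. Zero-padding adds no energy; leaf order is the natural
  filter-bank order.
* **Per-leaf statistics**: population variance (divide by n) and signed
  maximum; both documented rather than configurable-by-accident.
* **SVR kernel parameter**: read as the RBF bandwidth,
  K = exp(−‖u−v‖²/(2g²)). Over z-scored 96-dimensional features the median
  squared distance is ≈ 200, so the alternative reading exp(−g‖u−v‖²)
  with g = 3.2 underflows every kernel value and all predictions collapse
  to the regression intercept (measured: held-out accuracy drops to
  chance). The gamma reading stays available via `g_is_gamma=True`.
* **SVR output → mass**: raw outputs clipped at 0 and renormalised;
  all-zero rows become uniform. Alternative mappings (e.g. softmax) could
  be swapped in at the `outputs_to_mass` seam.
* **Pooling**: plain max (no multiplicative/additive pooling biases).
* **Fusion representation**: only singleton focal elements are carried,
  since both streams emit per-class probabilities; the general power-set
  rule lives in the test oracle and is checked to 1e-12 agreement.
* **Thresholds TH1/TH2**: TH1 is the primary (higher) acceptance
  threshold; TH2 = 0.5·TH1 serves search-back only.

## Limitations

* The CNN is a compact reference implementation in numpy — adequate for
  these beat lengths and dataset sizes, not a platform for large-scale
  training.
* Only single-channel format-16 WFDB records and MIT-style annotations are
  read; multi-lead fusion and other annotation dialects are out of scope.
* Synthetic results quantify internal consistency, not clinical accuracy.
* The detector does not handle inverted QRS complexes or discriminate tall
  T waves beyond the refractory rule.
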