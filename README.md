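# ecgfuse

Two-stream heartbeat classification for single-lead ECG with
Dempster–Shafer evidence fusion.

Automatic arrhythmia screening assigns every heartbeat one of five classes —
normal (N), left/right bundle branch block (L, R), premature ventricular
contraction (V) and atrial premature beat (A), the canonical MIT-BIH beat
codes. `ecgfuse` implements a complete pipeline for this task, aimed at
biomedical-signal researchers who want a reproducible, dependency-light
reference:

1. **Conditioning** — baseline wander is estimated by a two-stage median
   filter (windows of 50 and 150 samples at 360 Hz) and subtracted;
   high-frequency interference is removed by db6 wavelet soft-threshold
   denoising with the universal threshold σ·√(2 ln n).
2. **QRS detection** — the difference-threshold detector: derivative filter
   y(n) = ⅛[2(x(n+1)−x(n−1)) + x(n+2)−x(n−2)], squaring, causal
   moving-window integration, then an adaptive dual threshold
   TH1 = NPKI + 0.25(SPKI − NPKI), TH2 = 0.5·TH1 with search-back over long
   RR gaps. Beats are cut as 250-sample windows, 99 samples before the R
   peak and 150 after.
3. **Time-domain stream** — a 1-D CNN (four conv/max-pool pairs, a
   10-unit fully connected layer and a 5-way softmax) over the raw beat,
   trained with Adam on cross-entropy.
4. **Frequency-domain stream** — a full 5-level db6 wavelet-packet
   decomposition gives 32 subbands; per subband the variance, mean and
   maximum form a 96-feature vector, z-scored and classified by five
   one-vs-rest RBF support vector regressors (kernel parameter g = 3.2,
   penalty c = 2.9).
5. **Fusion** — each stream's class probabilities are treated as a basic
   probability assignment m over the frame Ω = {N, L, R, V, A} and combined
   by Dempster's rule, m(A) = m₁(A)m₂(A)/(1−K) with conflict
   K = 1 − Σⱼ m₁(Aⱼ)m₂(Aⱼ); the fused argmax is the decision.
6. **Evaluation** — stratified k-fold cross-validation with per-class PPV,
   SE, SP, Acc and F1 (percent), comparing CNN-only, SVR-only and fused
   systems.

A built-in simulator generates 360 Hz single-lead records with
class-distinct Gaussian-bump morphologies, baseline wander, powerline hum
and white noise, plus ground-truth R positions and labels, so the whole
pipeline is testable without downloading any database. A minimal WFDB-style
reader/writer (format-16 signals, MIT annotations) handles real records.

## Worked example

```bash
python examples/03_cross_validated_comparison.py
```

```
system   Acc %  per-class F1 %
   cnn   91.20  N:60.0  L:98.2  R:99.0  V:100.0  A:85.2
   svr   98.00  N:95.0  L:100.0  R:100.0  V:100.0  A:94.9
 fused   98.80  N:96.9  L:100.0  R:100.0  V:100.0  A:97.0
```

On the balanced synthetic benchmark (50 beats per class, 5 stratified
folds, 30 training epochs) the fused system reaches 98.8 % overall
accuracy, above both single streams — the evidence combination recovers the
N/A confusions where the two streams disagree. The other examples cover
simulation + detection, manual two-stream training, and Dempster
combination by hand; each prints what its numbers mean.

A thin CLI wraps the same library calls:

```bash
ecgfuse run --n-beats 200 --folds 5 --epochs 30 --seed 0 --out run/
ecgfuse synth --per-class 50 --seed 0 --out data/
```

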