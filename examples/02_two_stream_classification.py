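"""Train both classifier streams on synthetic beats and fuse their evidence.

Uses a balanced benchmark (50 beats per class), trains the 1-D CNN on raw
beats and the one-vs-rest SVR ensemble on 96 wavelet-packet features, then
combines per-beat class probabilities with Dempster's rule.
"""

import numpy as np

import ecgfuse as ef
from ecgfuse.svr import predict_mass_svr, train_svr_ensemble

beats, labels = ef.make_benchmark_dataset(per_class=50, rng_seed=0)
X = np.vstack([b.samples for b in beats])
F = ef.feature_matrix(beats)

train, test = slice(0, 200), slice(200, 250)
cnn = ef.train_cnn(X[train], labels[:200], ef.TrainingConfig(epochs=30, rng_seed=0))
svr = train_svr_ensemble(F[train], labels[:200])

cnn_mass = ef.predict_mass_cnn(cnn, X[test])
svr_mass = predict_mass_svr(svr, F[test])
fused_mass, fused_labels, _ = ef.fuse_streams(cnn_mass, svr_mass)

truth = labels[200:]
for name, mass in [("CNN", cnn_mass), ("SVR", svr_mass)]:
    pred = [ef.CLASSES[m.argmax()] for m in mass]
    print(f"{name} accuracy  : {np.mean([p == t for p, t in zip(pred, truth)]):.3f}")
print(f"fused accuracy: {np.mean([p == t for p, t in zip(fused_labels, truth)]):.3f}")
# each number is the fraction of 50 held-out beats assigned the correct
# class; fusion combines time-domain and frequency-domain evidence.
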