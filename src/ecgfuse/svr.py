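"""Frequency-domain stream: one-vs-rest support vector regression.

Five epsilon-SVR machines with a radial basis kernel (kernel parameter
g = 3.2, penalty C = 2.9, found by cross-validation) are fitted over the
96 wavelet-packet features, one per class with targets 1 (that class) / 0
(the rest), sharing a single z-scoring normaliser fitted on the training
rows. The kernel parameter is read as the RBF bandwidth,
K(u, v) = exp(-||u - v||^2 / (2 g^2)): over z-scored 96-dimensional feature
vectors the squared distances are of order 2 x 96, so the alternative gamma
reading exp(-g ||u - v||^2) underflows the kernel to zero and every
prediction collapses to the regression intercept. The gamma reading remains
available via ``g_is_gamma=True``. At prediction time the five raw regression outputs are clipped below
at zero and normalised to sum to one, giving a basic probability assignment
over the five-class frame; if all five outputs clip to zero the assignment
falls back to uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVR

from .features import N_FEATURES, Normalizer, fit_normalizer
from .types import CLASSES


@dataclass
class SvrEnsemble:
    """Five fitted one-vs-rest regressors in canonical class order, plus the
    shared feature normaliser and the kernel settings used."""

    machines: list[SVR]
    normalizer: Normalizer
    g: float
    c: float
    epsilon: float
    g_is_gamma: bool = False

    def __post_init__(self) -> None:
        if len(self.machines) != len(CLASSES):
            raise ValueError(f"expected {len(CLASSES)} machines")


def train_svr_ensemble(
    features: np.ndarray,
    labels,
    g: float = 3.2,
    c: float = 2.9,
    epsilon: float = 0.1,
    rng_seed: int | None = None,
    g_is_gamma: bool = False,
) -> SvrEnsemble:
    """Fit the five one-vs-rest machines.

    ``g`` is the RBF bandwidth by default; pass ``g_is_gamma=True`` to read it
    as the exponent coefficient instead. ``rng_seed`` is accepted for
    interface uniformity with the CNN stream but unused: the epsilon-SVR fit
    is deterministic given the data.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_FEATURES:
        raise ValueError(f"features must be (n, {N_FEATURES}), got {X.shape}")
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("training needs at least 2 distinct classes")
    normalizer = fit_normalizer(X)
    Xn = normalizer.transform(X)
    gamma = g if g_is_gamma else 1.0 / (2.0 * g * g)
    machines = []
    for cls in CLASSES:
        y = np.asarray([1.0 if l == cls else 0.0 for l in labels])
        # tight solver tolerance: the SMO solution is then order-independent
        # to ~1e-10, so training-row permutations cannot move predictions
        machines.append(
            SVR(kernel="rbf", gamma=gamma, C=c, epsilon=epsilon, tol=1e-10).fit(Xn, y)
        )
    return SvrEnsemble(machines=machines, normalizer=normalizer,
                       g=g, c=c, epsilon=epsilon, g_is_gamma=g_is_gamma)


def raw_outputs(ensemble: SvrEnsemble, features: np.ndarray) -> np.ndarray:
    """Unnormalised per-class regression outputs, shape (n, 5)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"features must have {N_FEATURES} columns, got {X.shape[1]}")
    Xn = ensemble.normalizer.transform(X)
    return np.column_stack([m.predict(Xn) for m in ensemble.machines])


def outputs_to_mass(raw: np.ndarray) -> np.ndarray:
    """Clip raw regression outputs at zero and normalise rows to sum to 1;
    an all-zero row becomes the uniform assignment."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    clipped = np.clip(raw, 0.0, None)
    sums = clipped.sum(axis=1, keepdims=True)
    uniform = np.full(raw.shape[1], 1.0 / raw.shape[1])
    out = np.where(sums > 0, clipped / np.where(sums > 0, sums, 1.0), uniform)
    return out


def predict_mass_svr(ensemble: SvrEnsemble, features: np.ndarray) -> np.ndarray:
    """Per-beat mass functions (n, 5) from the SVR stream."""
    return outputs_to_mass(raw_outputs(ensemble, features))
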