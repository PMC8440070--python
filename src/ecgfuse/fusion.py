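"""Dempster-Shafer evidence combination of the two classifier streams.

Both streams emit per-beat class probabilities, i.e. basic probability
assignments whose focal elements are the five singletons of the frame of
discernment Omega = {N, L, R, V, A}. For two such assignments m1, m2,
Dempster's rule reduces to::

    fused(k) = m1(k) * m2(k) / (1 - K),   K = 1 - sum_j m1(j) * m2(j)

where K is the conflict mass. K = 1 (total conflict) is possible only when
the two supports are disjoint; `combine` raises then, and the pipeline falls
back to the CNN mass alone (the stronger single stream). The final decision
is the argmax of the fused assignment, ties broken toward the earlier class
in canonical order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import CLASSES, validate_mass


class TotalConflictError(ValueError):
    """Raised when two assignments have disjoint support (K = 1)."""


@dataclass
class FusionResult:
    fused: np.ndarray  # valid mass function over the 5-class frame
    conflict: float  # K in [0, 1)
    decided: str  # argmax class label


def combine(m1: np.ndarray, m2: np.ndarray) -> FusionResult:
    """Dempster's rule for two singleton-focused assignments."""
    m1 = validate_mass(m1)
    m2 = validate_mass(m2)
    products = m1 * m2
    agreement = products.sum()
    K = 1.0 - agreement
    if agreement <= 0.0:
        raise TotalConflictError(
            f"total conflict (K=1) between m1={m1.tolist()} and m2={m2.tolist()}"
        )
    fused = products / agreement
    return FusionResult(fused=fused, conflict=float(K), decided=decide(fused))


def bel_pls(m: np.ndarray, subset) -> tuple[float, float]:
    """Belief and plausibility of a subset of the frame.

    With only singleton focal elements, Bel(A) = sum of masses in A and
    Pls(A) = 1 - Bel(complement of A) = Bel(A); the trust interval collapses.
    """
    m = validate_mass(m)
    idx = [CLASSES.index(c) for c in subset]
    bel = float(m[idx].sum()) if idx else 0.0
    comp = [i for i in range(len(CLASSES)) if i not in idx]
    pls = 1.0 - (float(m[comp].sum()) if comp else 0.0)
    return bel, pls


def decide(m: np.ndarray) -> str:
    """Argmax decision; ties break toward the earlier canonical class."""
    m = validate_mass(m)
    return CLASSES[int(np.argmax(m))]


def fuse_streams(cnn_mass: np.ndarray, svr_mass: np.ndarray) -> tuple[np.ndarray, list[str], int]:
    """Row-wise fusion of two (n, 5) mass matrices.

    Returns (fused masses, decided labels, number of total-conflict fallbacks
    to the CNN mass).
    """
    cnn_mass = np.atleast_2d(cnn_mass)
    svr_mass = np.atleast_2d(svr_mass)
    if cnn_mass.shape != svr_mass.shape:
        raise ValueError("mass matrices must have equal shape")
    fused = np.empty_like(cnn_mass)
    labels: list[str] = []
    fallbacks = 0
    for i in range(cnn_mass.shape[0]):
        try:
            res = combine(cnn_mass[i], svr_mass[i])
            fused[i] = res.fused
        except TotalConflictError:
            fused[i] = cnn_mass[i]
            fallbacks += 1
        labels.append(decide(fused[i]))
    return fused, labels, fallbacks
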