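"""Frequency-domain features: wavelet-packet statistics per beat.

Each 250-sample beat is decomposed with a full 5-level db6 wavelet-packet tree
into 2^5 = 32 terminal subbands; the beat is zero-padded to 256 samples so the
periodised transform is orthonormal (coefficient energy equals signal energy)
and every leaf holds exactly 8 coefficients. For each leaf, in the natural
(filter-bank) order, three statistics are taken — population variance,
arithmetic mean and maximum — giving a 96-long feature vector per beat in the
fixed (var, mean, max) slot order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from sklearn.preprocessing import StandardScaler

from .types import BEAT_LENGTH, BeatSegment

N_LEAVES = 32
N_FEATURES = 96


@dataclass
class WaveletPacketLeaves:
    """Terminal subband coefficients of a full wavelet-packet tree."""

    leaves: list[np.ndarray]
    wavelet_name: str
    level: int

    def __post_init__(self) -> None:
        if len(self.leaves) != 2**self.level:
            raise ValueError(
                f"expected {2**self.level} leaves at level {self.level}, "
                f"got {len(self.leaves)}"
            )


def wp_decompose(
    beat: BeatSegment | np.ndarray, wavelet: str = "db6", level: int = 5
) -> WaveletPacketLeaves:
    """Full wavelet-packet decomposition of one beat.

    Returns the ``2**level`` terminal-node coefficient sequences in natural
    (filter-bank) order. The beat is zero-padded to the next multiple of
    ``2**level`` so the periodised transform conserves energy exactly.
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    x = beat.samples if isinstance(beat, BeatSegment) else np.asarray(beat, float)
    if x.size != BEAT_LENGTH:
        raise ValueError(f"beat must have {BEAT_LENGTH} samples, got {x.size}")
    block = 2**level
    padded = int(np.ceil(x.size / block)) * block
    if padded > x.size:
        x = np.concatenate([x, np.zeros(padded - x.size)])
    wp = pywt.WaveletPacket(x, wavelet, mode="periodization", maxlevel=level)
    nodes = wp.get_level(level, order="natural")
    return WaveletPacketLeaves(
        leaves=[np.asarray(n.data, dtype=float) for n in nodes],
        wavelet_name=wavelet,
        level=level,
    )


def extract_features(leaves: WaveletPacketLeaves) -> np.ndarray:
    """Per-leaf (population variance, mean, max), concatenated over 32 leaves.

    The maximum is of the signed coefficients; variance divides by n.
    """
    if len(leaves.leaves) != N_LEAVES:
        raise ValueError(f"expected {N_LEAVES} leaves, got {len(leaves.leaves)}")
    out = np.empty(N_FEATURES)
    for i, leaf in enumerate(leaves.leaves):
        out[3 * i] = np.var(leaf)
        out[3 * i + 1] = np.mean(leaf)
        out[3 * i + 2] = np.max(leaf)
    return out


def beat_features(beat: BeatSegment | np.ndarray) -> np.ndarray:
    """Convenience: decompose a beat and extract its 96 features."""
    return extract_features(wp_decompose(beat))


def feature_matrix(beats: list[BeatSegment] | np.ndarray) -> np.ndarray:
    """Stack per-beat feature vectors into an (n_beats, 96) matrix."""
    return np.vstack([beat_features(b) for b in beats])


@dataclass
class Normalizer:
    """Per-feature affine transform (z-scoring) fitted on training data only.

    Constant features map to zero rather than dividing by zero.
    """

    scaler: StandardScaler

    def transform(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        return self.scaler.transform(features)


def fit_normalizer(train_features: np.ndarray) -> Normalizer:
    """Fit a z-scoring transform on the training feature matrix."""
    train_features = np.asarray(train_features, dtype=float)
    if train_features.ndim != 2 or train_features.shape[0] < 2:
        raise ValueError("need at least 2 training rows to fit a normalizer")
    scaler = StandardScaler().fit(train_features)
    return Normalizer(scaler=scaler)


def apply_normalizer(normalizer: Normalizer, features: np.ndarray) -> np.ndarray:
    """Apply a fitted transform to (new) feature rows."""
    return normalizer.transform(features)
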