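"""Shared domain types for the heartbeat-classification pipeline.

The canonical class order used for every vectorised output (probability
vectors, mass functions, confusion matrices) is ``CLASSES = (N, L, R, V, A)``:
normal, left bundle branch block, right bundle branch block, premature
ventricular contraction, atrial premature beat. It is fixed here and nowhere
else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical beat-class order for all vectorised outputs.
CLASSES: tuple[str, ...] = ("N", "L", "R", "V", "A")

#: Index of a class label in the canonical order.
CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}

#: Samples in one beat window.
BEAT_LENGTH: int = 250

#: 0-based index of the R sample inside a beat window: 99 samples precede the
#: R peak and 150 follow it.
R_OFFSET: int = 99


@dataclass
class RawECG:
    """A single-lead sampled voltage sequence.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in millivolts.
    fs : float
        Sampling rate in Hz (MIT-BIH records use 360).
    """

    samples: np.ndarray
    fs: float = 360.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("signal must be 1-D with at least 2 samples")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class BeatSegment:
    """A fixed 250-sample beat window with the R peak at index 99."""

    samples: np.ndarray
    r_offset: int = R_OFFSET
    label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (BEAT_LENGTH,):
            raise ValueError(
                f"beat must have exactly {BEAT_LENGTH} samples, "
                f"got shape {self.samples.shape}"
            )
        if self.r_offset != R_OFFSET:
            raise ValueError(f"r_offset must be {R_OFFSET}, got {self.r_offset}")
        if self.label is not None and self.label not in CLASS_INDEX:
            raise ValueError(
                f"unknown label {self.label!r}; valid labels are {CLASSES}"
            )


@dataclass
class SyntheticRecord:
    """A simulated record with ground-truth R positions and beat labels."""

    signal: RawECG
    true_r_indices: np.ndarray
    true_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.true_r_indices = np.asarray(self.true_r_indices, dtype=int)
        if len(self.true_labels) != self.true_r_indices.size:
            raise ValueError("one label per R index required")
        if np.any(np.diff(self.true_r_indices) <= 0):
            raise ValueError("true R indices must be strictly increasing")


def validate_mass(m: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Check that ``m`` is a basic probability assignment over the 5-class
    frame of discernment (nonnegative, sums to 1) and return it as ndarray."""
    m = np.asarray(m, dtype=float)
    if m.shape != (len(CLASSES),):
        raise ValueError(f"mass function must have {len(CLASSES)} entries")
    if np.any(m < -tol):
        raise ValueError("mass function entries must be nonnegative")
    if abs(m.sum() - 1.0) > tol:
        raise ValueError(f"mass function must sum to 1, got {m.sum()!r}")
    return m
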