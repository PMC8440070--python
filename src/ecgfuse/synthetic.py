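"""Synthetic single-lead ECG generator.

Beats are sums of Gaussian bumps for the P, Q, R, S and T waves; the five
arrhythmia classes differ in morphology:

* ``N`` — canonical template.
* ``L`` / ``R`` (bundle branch blocks) — slurred, asymmetric QRS with opposite
  skew (the dominant deflection decays slowly to the right for L, to the left
  for R).
* ``V`` (premature ventricular contraction) — widened, large dominant
  deflection with no P wave and a discordant (inverted) T wave.
* ``A`` (atrial premature beat) — near-normal QRS with a reduced P wave and a
  shortened preceding RR interval at the record level.

Records are built by summing jittered beat templates at randomised RR
intervals and adding three noise components: low-frequency baseline wander,
powerline-type sinusoidal interference, and white noise. All randomness flows
from one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import BEAT_LENGTH, CLASSES, R_OFFSET, BeatSegment, RawECG, SyntheticRecord

#: (name, center offset from R in samples, std in samples, amplitude in mV)
#: for each class. Asymmetric bumps carry separate left/right widths.
_TEMPLATES: dict[str, list[tuple[str, float, float, float, float]]] = {
    # name, center, sd_left, sd_right, amplitude
    "N": [
        ("P", -50.0, 6.0, 6.0, 0.15),
        ("Q", -9.0, 2.5, 2.5, -0.10),
        ("R", 0.0, 4.0, 4.0, 1.00),
        ("S", 9.0, 3.0, 3.0, -0.20),
        ("T", 60.0, 9.0, 9.0, 0.30),
    ],
    "L": [  # slurred QRS, slow rightward decay
        ("P", -50.0, 6.0, 6.0, 0.12),
        ("Q", -12.0, 3.0, 3.0, -0.08),
        ("R", 0.0, 4.0, 7.0, 0.85),
        ("S", 14.0, 4.0, 4.0, -0.15),
        ("T", 62.0, 9.0, 9.0, 0.25),
    ],
    "R": [  # slurred QRS, slow leftward onset
        ("P", -50.0, 6.0, 6.0, 0.12),
        ("Q", -14.0, 4.0, 4.0, -0.15),
        ("R", 0.0, 7.0, 4.0, 0.85),
        ("S", 10.0, 3.0, 3.0, -0.25),
        ("T", 60.0, 9.0, 9.0, 0.28),
    ],
    "V": [  # wide dominant deflection, absent P, discordant T
        ("Q", -12.0, 3.5, 3.5, -0.10),
        ("R", 0.0, 8.0, 8.0, 0.90),
        ("S", 16.0, 6.0, 6.0, -0.35),
        ("T", 64.0, 9.0, 9.0, -0.30),
    ],
    "A": [  # reduced P, otherwise near-normal QRS
        ("P", -45.0, 5.0, 5.0, 0.05),
        ("Q", -9.0, 2.5, 2.5, -0.10),
        ("R", 0.0, 4.0, 4.0, 0.95),
        ("S", 9.0, 3.0, 3.0, -0.20),
        ("T", 56.0, 9.0, 9.0, 0.28),
    ],
}

#: Relative jitter (std) applied to amplitudes and widths per beat.
_JITTER = 0.05


@dataclass
class NoiseSpec:
    """Additive noise components for a simulated record.

    Defaults emulate moderate recording conditions: slow baseline wander,
    50 Hz powerline interference and broadband white noise.
    """

    baseline_amplitude: float = 0.15  # mV
    baseline_frequency: float = 0.3  # Hz, < 1 Hz
    powerline_amplitude: float = 0.05  # mV
    powerline_frequency: float = 50.0  # Hz
    white_sigma: float = 0.02  # mV

    def __post_init__(self) -> None:
        for name in ("baseline_amplitude", "powerline_amplitude", "white_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 < self.baseline_frequency < 1:
            raise ValueError("baseline_frequency must be in (0, 1) Hz")

    @classmethod
    def none(cls) -> "NoiseSpec":
        """A zero-noise specification (clean signal)."""
        return cls(0.0, 0.3, 0.0, 50.0, 0.0)


def _render_template(label: str, rng: np.random.Generator, length: int,
                     r_at: int) -> np.ndarray:
    """Render one jittered beat template into a ``length``-sample buffer with
    the R peak at index ``r_at``."""
    n = np.arange(length, dtype=float) - r_at
    beat = np.zeros(length)
    for _, center, sd_l, sd_r, amp in _TEMPLATES[label]:
        a = amp * (1.0 + _JITTER * rng.standard_normal())
        wl = sd_l * (1.0 + _JITTER * rng.standard_normal())
        wr = sd_r * (1.0 + _JITTER * rng.standard_normal())
        wl, wr = max(wl, 0.5), max(wr, 0.5)
        t = n - center
        sd = np.where(t < 0, wl, wr)
        beat += a * np.exp(-0.5 * (t / sd) ** 2)
    return beat


def generate_beat(class_label: str, rng_seed: int = 0) -> BeatSegment:
    """Generate one labelled 250-sample beat.

    The dominant deflection sits at the standard R offset (index 99);
    amplitudes and widths receive small seeded jitter.
    """
    if class_label not in _TEMPLATES:
        raise ValueError(
            f"unknown label {class_label!r}; valid labels are {CLASSES}"
        )
    rng = np.random.default_rng(rng_seed)
    samples = _render_template(class_label, rng, BEAT_LENGTH, R_OFFSET)
    return BeatSegment(samples=samples, label=class_label)


def generate_record(
    n_beats: int,
    class_mix: dict[str, float] | None = None,
    mean_rr_s: float = 0.8,
    noise: NoiseSpec | None = None,
    fs: float = 360.0,
    rng_seed: int = 0,
) -> SyntheticRecord:
    """Generate a synthetic single-lead record with ground truth.

    Parameters
    ----------
    n_beats : int
        Number of beats (>= 1).
    class_mix : dict, optional
        Label -> proportion; must sum to 1. Default: all normal beats.
    mean_rr_s : float
        Mean RR interval in seconds (>= 0.3). RR intervals are jittered with a
        truncated normal (sd 5 %, floor 0.3 s); beats of class A shorten their
        preceding interval by 20 %.
    noise : NoiseSpec, optional
        Noise components; default :class:`NoiseSpec` defaults.
    fs : float
        Sampling rate in Hz.
    rng_seed : int
        Seed for all randomness in the record.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if mean_rr_s < 0.3:
        raise ValueError("mean_rr_s must be >= 0.3 s")
    if class_mix is None:
        class_mix = {"N": 1.0}
    unknown = set(class_mix) - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown labels in class_mix: {sorted(unknown)}")
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class_mix proportions must sum to 1, got {total!r}")
    if noise is None:
        noise = NoiseSpec()

    rng = np.random.default_rng(rng_seed)
    labels_pool = list(class_mix)
    probs = np.array([class_mix[c] for c in labels_pool])
    labels = [str(c) for c in rng.choice(labels_pool, size=n_beats, p=probs)]

    # RR intervals: truncated normal (sd 5 %, clipped at 2 sd), floored at
    # 0.3 s; when the mean interval spans a full beat window the floor rises
    # to the window length so consecutive windows stay disjoint. Class A
    # shortens its preceding interval by 20 % (down to the floor).
    floor_s = 0.3
    if mean_rr_s * fs >= BEAT_LENGTH:
        floor_s = max(floor_s, BEAT_LENGTH / fs)
    rr = np.empty(n_beats)
    for i, lab in enumerate(labels):
        mu = mean_rr_s * (0.8 if lab == "A" else 1.0)
        z = float(np.clip(rng.standard_normal(), -2.0, 2.0))
        rr[i] = max(floor_s, mu * (1.0 + 0.05 * z))
    r_indices = (R_OFFSET + np.concatenate(([0.0], np.cumsum(rr[1:] * fs)))).astype(int)

    length = int(r_indices[-1] + BEAT_LENGTH - R_OFFSET + 1)
    sig = np.zeros(length)
    for r, lab in zip(r_indices, labels):
        start = r - R_OFFSET
        sig[start:start + BEAT_LENGTH] += _render_template(
            lab, rng, BEAT_LENGTH, R_OFFSET
        )

    t = np.arange(length) / fs
    if noise.baseline_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig = sig + noise.baseline_amplitude * np.sin(
            2 * np.pi * noise.baseline_frequency * t + phase
        )
    if noise.powerline_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        sig = sig + noise.powerline_amplitude * np.sin(
            2 * np.pi * noise.powerline_frequency * t + phase
        )
    if noise.white_sigma > 0:
        sig = sig + noise.white_sigma * rng.standard_normal(length)

    return SyntheticRecord(
        signal=RawECG(samples=sig, fs=fs),
        true_r_indices=r_indices,
        true_labels=labels,
    )


def make_benchmark_dataset(
    per_class: int, rng_seed: int = 0
) -> tuple[list[BeatSegment], list[str]]:
    """Build a balanced, shuffled beat dataset: ``per_class`` beats per label.

    Emulates drawing an equal-sized sample per arrhythmia type; per-beat
    morphological jitter comes from seeds derived from ``rng_seed``.
    """
    if per_class < 10:
        raise ValueError("per_class must be >= 10")
    rng = np.random.default_rng(rng_seed)
    beats: list[BeatSegment] = []
    for label in CLASSES:
        for _ in range(per_class):
            beats.append(generate_beat(label, rng_seed=int(rng.integers(2**31))))
    order = rng.permutation(len(beats))
    beats = [beats[i] for i in order]
    return beats, [b.label for b in beats]
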