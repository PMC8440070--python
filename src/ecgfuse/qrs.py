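"""QRS detection by the difference-threshold algorithm and beat segmentation.

The detector follows the classical derivative / square / moving-window-
integration chain. Candidate peaks of the integrated signal are accepted
against an adaptive dual threshold::

    TH1 = NPKI + 0.25 * (SPKI - NPKI)
    TH2 = 0.5 * TH1

where SPKI tracks the QRS-peak level and NPKI the noise-peak level with
exponential running updates (1/8 new, 7/8 old). A search-back pass re-examines
long inter-beat gaps against the lower threshold TH2. Accepted candidates are
refined to the local maximum of the input signal within +/-50 ms, and a 200 ms
refractory period is enforced.

Beats are cut as fixed 250-sample windows: 99 samples before the R peak and
150 after it (R at 0-based offset 99).
"""

from __future__ import annotations

import numpy as np

from .types import BEAT_LENGTH, R_OFFSET, BeatSegment, RawECG


def derivative_filter(x: np.ndarray) -> np.ndarray:
    """Five-point derivative: y(n) = (1/8)[2(x(n+1)-x(n-1)) + x(n+2)-x(n-2)].

    Boundary samples are handled by edge replication; output length equals
    input length.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("derivative filter needs at least 5 samples")
    xp = np.pad(x, 2, mode="edge")
    return (2.0 * (xp[3:-1] - xp[1:-3]) + (xp[4:] - xp[:-4])) / 8.0


def square(x: np.ndarray) -> np.ndarray:
    """Elementwise square, y(n) = x(n)^2."""
    x = np.asarray(x, dtype=float)
    return x * x


def moving_window_integrate(x: np.ndarray, N: int) -> np.ndarray:
    """Causal moving mean over the N most recent samples.

    The warm-up region (first N-1 samples) averages over the samples available
    so far.
    """
    x = np.asarray(x, dtype=float)
    if not 1 <= N <= x.size:
        raise ValueError(f"window width N={N} out of range [1, {x.size}]")
    c = np.concatenate(([0.0], np.cumsum(x)))
    counts = np.minimum(np.arange(1, x.size + 1), N)
    starts = np.arange(1, x.size + 1) - counts
    return (c[1:] - c[starts]) / counts


def compute_thresholds(SPKI: float, NPKI: float) -> tuple[float, float]:
    """Dual thresholds from the running peak levels."""
    if not (SPKI >= NPKI >= 0):
        raise ValueError(
            f"detector state corrupt: need SPKI >= NPKI >= 0, got {SPKI}, {NPKI}"
        )
    th1 = NPKI + 0.25 * (SPKI - NPKI)
    return th1, 0.5 * th1


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of y (plateaus take the first sample)."""
    idx = []
    n = y.size
    i = 1
    while i < n - 1:
        if y[i] > y[i - 1] and y[i] >= y[i + 1]:
            idx.append(i)
            # skip plateau
            j = i + 1
            while j < n - 1 and y[j] == y[i]:
                j += 1
            i = j
        else:
            i += 1
    return np.asarray(idx, dtype=int)


def detect_r_peaks(
    sig: RawECG,
    mwi_ms: float = 150.0,
    refractory_ms: float = 200.0,
) -> np.ndarray:
    """Detect R-peak sample indices on a preprocessed signal.

    Returns strictly increasing indices into ``sig.samples``. Candidates come
    from the integrated derivative-squared signal; the adaptive dual threshold
    accepts them, a search-back pass over long RR gaps recovers misses using
    the lower threshold, and each accepted peak is refined to the maximum of
    the input signal within +/-50 ms.
    """
    fs = sig.fs
    x = sig.samples
    if x.size < int(2 * fs):
        raise ValueError("signal must be at least 2 s long")

    N = max(1, int(round(mwi_ms / 1000.0 * fs)))
    refractory = int(round(refractory_ms / 1000.0 * fs))
    refine_w = int(round(0.05 * fs))

    mwi = moving_window_integrate(square(derivative_filter(x)), N)

    cand = _local_maxima(mwi)
    if cand.size == 0:
        return np.asarray([], dtype=int)

    # Initialise running levels from the first 2 s.
    init = mwi[: int(2 * fs)]
    SPKI = float(init.max())
    NPKI = float(init.mean())
    if SPKI < NPKI:  # degenerate flat signal
        SPKI = NPKI

    accepted_mwi: list[int] = []  # candidate indices (into mwi) accepted
    rejected: list[int] = []
    rr_history: list[float] = []

    def th() -> tuple[float, float]:
        return compute_thresholds(SPKI, NPKI)

    for c in cand:
        peak = mwi[c]
        th1, _ = th()
        if accepted_mwi and c - accepted_mwi[-1] < refractory:
            continue
        if peak > th1:
            # search-back first: if the gap since the last beat is long,
            # look for a missed peak above TH2 inside the gap
            if accepted_mwi and rr_history:
                rr_avg = float(np.mean(rr_history[-8:]))
                gap = c - accepted_mwi[-1]
                if gap > 1.66 * rr_avg:
                    _, th2 = th()
                    lo = accepted_mwi[-1] + refractory
                    inside = [r for r in rejected if lo <= r <= c - refractory]
                    if inside:
                        best = max(inside, key=lambda r: mwi[r])
                        if mwi[best] > th2:
                            rr_history.append(best - accepted_mwi[-1])
                            accepted_mwi.append(best)
                            SPKI = 0.125 * float(mwi[best]) + 0.875 * SPKI
            if accepted_mwi:
                rr_history.append(c - accepted_mwi[-1])
            accepted_mwi.append(c)
            SPKI = 0.125 * float(peak) + 0.875 * SPKI
        else:
            rejected.append(c)
            NPKI = 0.125 * float(peak) + 0.875 * NPKI
            NPKI = min(NPKI, SPKI)

    accepted_mwi.sort()

    # Refine to the maximum of the input signal within +/-50 ms. The MWI peak
    # lags the R wave by roughly the window width, so search a window ending
    # at the candidate.
    refined: list[int] = []
    for c in accepted_mwi:
        lo = max(0, c - N - refine_w)
        hi = min(x.size, c + refine_w + 1)
        r = lo + int(np.argmax(x[lo:hi]))
        if refined and r - refined[-1] < refractory:
            # keep the larger of the two colliding refinements
            if x[r] > x[refined[-1]]:
                refined[-1] = r
            continue
        refined.append(r)
    return np.asarray(refined, dtype=int)


def segment_beats(
    sig: RawECG, r_indices: np.ndarray
) -> tuple[list[BeatSegment], int]:
    """Cut 250-sample windows around each R index.

    Windows are ``[r-99, r+150]`` inclusive. R peaks too close to the record
    edges are skipped; the skip count is returned alongside the segments.
    """
    x = sig.samples
    segments: list[BeatSegment] = []
    skipped = 0
    for r in np.asarray(r_indices, dtype=int):
        if r < R_OFFSET or r + (BEAT_LENGTH - R_OFFSET) > x.size:
            skipped += 1
            continue
        segments.append(BeatSegment(samples=x[r - R_OFFSET: r - R_OFFSET + BEAT_LENGTH]))
    return segments, skipped
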