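"""Record and dataset I/O.

Reads and writes single-lead records in the WFDB conventions used by the
MIT-BIH arrhythmia database: a text header (``.hea``), 16-bit little-endian
signal samples (``.dat``, format 16) and MIT-format beat annotations
(``.atr``). Amplitudes are converted to millivolts on read using the header
gain, so all downstream processing is unit-agnostic. Beat datasets travel as
plain CSV: 250 amplitude columns plus a label column.

Only the subset of the WFDB spec needed for single-channel format-16 records
is implemented; the reader is exercised on fixtures this package writes.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BEAT_LENGTH, CLASSES, BeatSegment, RawECG

# MIT annotation type codes <-> display symbols (beat subset + common others).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 8: "A", 9: "S",
    12: "/", 13: "Q", 38: "f", 31: "!", 34: "j", 11: "J", 10: "e",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}
_SKIP = 59  # long-interval escape code
_BEAT_SYMBOLS = frozenset(CLASSES)


# --------------------------------------------------------------------------
# WFDB-style records
# --------------------------------------------------------------------------

def write_record(
    path, sig: RawECG, lead_name: str = "MLII", gain: float = 200.0
) -> None:
    """Write ``path.hea`` and ``path.dat`` (format 16, one channel)."""
    path = Path(path)
    adc = np.round(sig.samples * gain).astype("<i2")
    record = path.name
    checksum = int(adc.astype(np.int64).sum() % 65536)
    header = (
        f"{record} 1 {sig.fs:g} {adc.size}\n"
        f"{record}.dat 16 {gain:g} 16 0 {int(adc[0])} {checksum} 0 {lead_name}\n"
    )
    path.with_suffix(".hea").write_text(header)
    path.with_suffix(".dat").write_bytes(adc.tobytes())


def read_record(path, lead_name: str = "MLII") -> RawECG:
    """Read a single-channel format-16 record; amplitudes in mV per the
    header gain."""
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"no header file at {hea}")
    lines = [l for l in hea.read_text().splitlines()
             if l.strip() and not l.startswith("#")]
    rec_fields = lines[0].split()
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    leads = []
    for ln in lines[1: 1 + n_sig]:
        f = ln.split()
        leads.append({
            "file": f[0], "fmt": f[1],
            "gain": float(f[2].split("(")[0].split("/")[0]) or 200.0,
            "name": f[-1],
        })
    names = [l["name"] for l in leads]
    if lead_name not in names:
        raise ValueError(f"lead {lead_name!r} not present; available leads: {names}")
    ch = names.index(lead_name)
    spec = leads[ch]
    if spec["fmt"] != "16":
        raise ValueError(f"only format 16 is supported, got format {spec['fmt']}")
    dat = path.parent / spec["file"]
    if not dat.exists():
        raise FileNotFoundError(f"no signal file at {dat}")
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2").astype(float)
    samples = raw.reshape(-1, n_sig)[:, ch] / spec["gain"]
    return RawECG(samples=samples, fs=fs)


def write_annotations(path, ann: list[tuple[int, str]]) -> None:
    """Write MIT-format annotations: (sample_index, symbol) pairs."""
    path = Path(path)
    out = bytearray()
    prev = 0
    for idx, symbol in ann:
        code = _SYMBOL_TO_CODE.get(symbol)
        if code is None:
            raise ValueError(f"no MIT annotation code for symbol {symbol!r}")
        delta = idx - prev
        if delta < 0:
            raise ValueError("annotation indices must be nondecreasing")
        if delta > 1023:
            out += struct.pack("<H", _SKIP << 10)
            out += struct.pack("<H", (delta >> 16) & 0xFFFF)
            out += struct.pack("<H", delta & 0xFFFF)
            delta = 0
        out += struct.pack("<H", (code << 10) | delta)
        prev = idx
    out += struct.pack("<H", 0)  # EOF
    path.write_bytes(bytes(out))


def read_annotations(path) -> list[tuple[int, str]]:
    """Read MIT-format annotations to (sample_index, symbol) pairs."""
    data = Path(path).read_bytes()
    ann: list[tuple[int, str]] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(data) or (i + 2 <= len(data)):
        (word,) = struct.unpack_from("<H", data, i)
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if word == 0:
            break
        if code == _SKIP:
            (hi,) = struct.unpack_from("<H", data, i)
            (lo,) = struct.unpack_from("<H", data, i + 2)
            i += 4
            pending_skip = (hi << 16) | lo
            continue
        t += delta + pending_skip
        pending_skip = 0
        symbol = _CODE_TO_SYMBOL.get(code, "?")
        ann.append((t, symbol))
    return ann


def map_symbols(ann: list[tuple[int, str]]) -> list[tuple[int, str]]:
    """Keep only the five beat classes {N, L, R, V, A}; order preserved."""
    return [(idx, sym) for idx, sym in ann if sym in _BEAT_SYMBOLS]


# --------------------------------------------------------------------------
# beat datasets (CSV)
# --------------------------------------------------------------------------

def save_dataset(beats, labels, path) -> None:
    """Write beats as CSV: 250 amplitude columns (s0..s249) + label column."""
    rows = []
    for i, b in enumerate(beats):
        x = b.samples if isinstance(b, BeatSegment) else np.asarray(b, float)
        if x.shape != (BEAT_LENGTH,):
            raise ValueError(f"beat {i} has length {x.size}, expected {BEAT_LENGTH}")
        rows.append(x)
    df = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, BEAT_LENGTH)),
                      columns=[f"s{i}" for i in range(BEAT_LENGTH)])
    df["label"] = list(labels)
    df.to_csv(path, index=False)


def load_dataset(path) -> tuple[list[BeatSegment], list[str]]:
    """Read a beat dataset written by :func:`save_dataset`."""
    df = pd.read_csv(path)
    expected = [f"s{i}" for i in range(BEAT_LENGTH)] + ["label"]
    if list(df.columns) != expected:
        raise ValueError(
            f"malformed dataset at {path}: expected {BEAT_LENGTH} sample "
            "columns plus a label column"
        )
    labels = df["label"].astype(str).tolist()
    X = df[expected[:-1]].to_numpy(dtype=float)
    beats = [BeatSegment(samples=X[i], label=labels[i]) for i in range(len(df))]
    return beats, labels
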