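"""Minimal codec for the MIT-BIH (WFDB) record format.

Reads and writes the header / signal / annotation file triplet used by the
PhysioNet arrhythmia databases: a text ``.hea`` header, a binary signal
file (format 16 = little-endian int16; format 212 = packed 12-bit, the
MIT-BIH native layout, read-only here), and a ``.atr`` annotation file in
the MIT annotation byte-pair encoding. Only the subset needed to exchange
single-channel ECG with beat annotations is covered.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np

from .record import ECGRecord

# MIT annotation codes (ecgcodes): symbol <-> numeric annotation type.
_SYMBOL_TO_CODE = {
    "N": 1, "L": 2, "R": 3, "a": 4, "V": 5, "F": 6, "J": 7, "A": 8, "S": 9,
    "E": 10, "j": 11, "/": 12, "Q": 13, "~": 14, "|": 16, "s": 18, "T": 19,
    "*": 20, "D": 21, '"': 22, "=": 23, "p": 24, "B": 25, "^": 26, "t": 27,
    "+": 28, "u": 29, "?": 30, "!": 31, "[": 32, "]": 33, "e": 34, "n": 35,
    "@": 36, "x": 37, "f": 38, "(": 39, ")": 40, "r": 41,
}
_CODE_TO_SYMBOL = {v: k for k, v in _SYMBOL_TO_CODE.items()}
#: annotation codes that mark a beat (QRS) rather than rhythm/noise/etc.
_BEAT_CODES = frozenset({1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 25, 34, 35, 38, 41})

_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


def _parse_gain(field: str) -> tuple[float, int, str]:
    """Parse an ``adcgain(baseline)/units`` header field."""
    m = re.match(r"^([-\d.eE+]+)(?:\(([-\d]+)\))?(?:/(\S+))?$", field)
    if not m:
        raise ValueError(f"cannot parse gain field {field!r}")
    gain = float(m.group(1)) or 200.0
    baseline = int(m.group(2)) if m.group(2) else 0
    units = m.group(3) or "mV"
    return gain, baseline, units


def read_annotations(path: Path) -> tuple[np.ndarray, list[str]]:
    """Decode an MIT-format annotation file into (sample_times, symbols)."""
    data = Path(path).read_bytes()
    times, symbols = [], []
    t = 0
    i = 0
    n = len(data)
    while i + 1 < n:
        word = data[i] | (data[i + 1] << 8)
        i += 2
        code = word >> 10
        amount = word & 0x3FF
        if code == 0 and amount == 0:
            break
        if code == _SKIP:
            if i + 3 >= n:
                break
            high = data[i] | (data[i + 1] << 8)
            low = data[i + 2] | (data[i + 3] << 8)
            i += 4
            t += (high << 16) | low
        elif code == _AUX:
            i += amount + (amount & 1)  # aux string, padded to even length
        elif code in (_NUM, _SUB, _CHN):
            pass  # modifier of the previous annotation; no time advance
        else:
            t += amount
            times.append(t)
            symbols.append(_CODE_TO_SYMBOL.get(code, "Q"))
    return np.asarray(times, dtype=np.int64), symbols


def write_annotations(path: Path, times: np.ndarray, symbols: list[str]) -> None:
    out = bytearray()
    prev = 0
    for t, sym in zip(times, symbols):
        code = _SYMBOL_TO_CODE.get(sym, _SYMBOL_TO_CODE["Q"])
        delta = int(t) - prev
        prev = int(t)
        if delta > 1023:
            out += (_SKIP << 10).to_bytes(2, "little")
            out += ((delta >> 16) & 0xFFFF).to_bytes(2, "little")
            out += (delta & 0xFFFF).to_bytes(2, "little")
            delta = 0
        out += ((code << 10) | delta).to_bytes(2, "little")
    out += b"\x00\x00"  # end of annotations
    Path(path).write_bytes(bytes(out))


def _read_dat(path: Path, n_sig: int, fmt: int) -> np.ndarray:
    raw = Path(path).read_bytes()
    if fmt == 16:
        flat = np.frombuffer(raw, dtype="<i2").astype(np.int64)
    elif fmt == 212:
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: 3 * (b.size // 3)].reshape(-1, 3).astype(np.int64)
        s1 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        s2 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        s1[s1 > 2047] -= 4096
        s2[s2 > 2047] -= 4096
        flat = np.empty(2 * b.shape[0], dtype=np.int64)
        flat[0::2], flat[1::2] = s1, s2
    else:
        raise ValueError(f"unsupported signal format {fmt}")
    usable = n_sig * (flat.size // n_sig)
    return flat[:usable].reshape(-1, n_sig)


def read_record(path, channel: int = 0, physical: bool = True) -> ECGRecord:
    """Read a WFDB-style record (header + signal + optional annotations).

    ``path`` is the record prefix (with or without ``.hea``). Only beat
    annotations populate ``r_peaks``; rhythm and noise markers are dropped.
    With ``physical`` false the raw ADC integers are returned.
    """
    prefix = Path(str(path).removesuffix(".hea"))
    header = prefix.with_suffix(".hea").read_text().splitlines()
    lines = [ln for ln in header if ln.strip() and not ln.startswith("#")]
    first = lines[0].split()
    name, n_sig = first[0], int(first[1])
    fs = float(first[2]) if len(first) > 2 else 250.0
    if channel >= n_sig:
        raise ValueError(f"channel {channel} out of range ({n_sig} signals)")

    sig_line = lines[1 + channel].split()
    dat_name, fmt_field = sig_line[0], sig_line[1]
    fmt = int(re.match(r"(\d+)", fmt_field).group(1))
    gain, baseline, _units = _parse_gain(sig_line[2]) if len(sig_line) > 2 else (200.0, 0, "mV")

    digital = _read_dat(prefix.parent / dat_name, n_sig, fmt)[:, channel]
    samples = (digital - baseline) / gain if physical else digital.astype(float)

    atr = prefix.with_suffix(".atr")
    if atr.exists():
        times, symbols = read_annotations(atr)
        beat = [k for k, s in enumerate(symbols)
                if _SYMBOL_TO_CODE.get(s, 13) in _BEAT_CODES]
        in_range = [k for k in beat if 0 <= times[k] < samples.size]
        r_peaks = times[in_range]
        labels = [symbols[k] for k in in_range]
    else:
        warnings.warn(f"no annotation file for {prefix.name}: record has no R peaks",
                      stacklevel=2)
        r_peaks, labels = np.empty(0, dtype=np.int64), None
    return ECGRecord(samples=samples, fs=fs, r_peaks=r_peaks,
                     beat_labels=labels, record_id=name)


def write_record(
    rec: ECGRecord,
    directory,
    record_name: str | None = None,
    gain: float = 200.0,
    adc_res: int = 11,
    units: str = "mV",
) -> Path:
    """Write a record as header + format-16 signal + annotation triplet.

    Samples are quantized to integers with the given gain; the annotation
    file carries one beat symbol per R peak. Returns the header path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = record_name or (rec.record_id or "record")
    digital = np.clip(
        np.round(rec.samples * gain), np.iinfo(np.int16).min, np.iinfo(np.int16).max
    ).astype("<i2")
    (directory / f"{name}.dat").write_bytes(digital.tobytes())
    header = (
        f"{name} 1 {rec.fs:g} {rec.samples.size}\n"
        f"{name}.dat 16 {gain:g}(0)/{units} {adc_res} 0 {int(digital[0])} 0 0 ECG\n"
    )
    (directory / f"{name}.hea").write_text(header)
    labels = rec.beat_labels or ["N"] * rec.r_peaks.size
    write_annotations(directory / f"{name}.atr", rec.r_peaks, labels)
    return directory / f"{name}.hea"
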