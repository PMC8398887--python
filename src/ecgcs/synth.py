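"""Synthetic single-lead ECG with known R-peak ground truth.

Each heartbeat is a sum of five Gaussian bumps (P, Q, R, S, T), a standard
desk-scale phantom of the ECG morphology. The generator places R peaks on
exact sample indices so that downstream R-peak-aligned framing can be tested
against ground truth, and a separate stage adds the disturbances a wearable
front end would see: powerline interference (fundamental plus 2nd and 3rd
harmonic), low-frequency baseline wander and white noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .record import ECGRecord

#: (amplitude [rel. units], width sigma [s], offset from the R peak [s])
_DEFAULT_WAVES = {
    "P": (0.15, 0.025, -0.17),
    "Q": (-0.10, 0.010, -0.025),
    "R": (1.00, 0.012, 0.0),
    "S": (-0.20, 0.010, 0.025),
    "T": (0.30, 0.060, 0.30),
}


@dataclass
class MorphologyParams:
    """Per-wave Gaussian parameters plus heart-rate settings.

    ``waves`` maps wave name -> (amplitude, width_s, offset_s). Offsets are
    relative to the R peak; widths are Gaussian sigmas in seconds.
    ``hr_jitter`` is the relative standard deviation of the beat-to-beat
    interval (0 = perfectly periodic).
    """

    waves: dict = field(default_factory=lambda: dict(_DEFAULT_WAVES))
    heart_rate_bpm: float = 60.0
    hr_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not 20.0 < self.heart_rate_bpm < 300.0:
            raise ValueError("heart_rate_bpm must be in (20, 300)")
        if self.hr_jitter < 0:
            raise ValueError("hr_jitter must be >= 0")
        for name, (_, width, _) in self.waves.items():
            if width <= 0:
                raise ValueError(f"wave {name!r} width must be > 0")


def generate_ecg(
    duration_s: float,
    fs: float = 360.0,
    morph: MorphologyParams | None = None,
    seed: int = 0,
    quantize_bits: int | None = None,
) -> ECGRecord:
    """Generate a clean quasi-periodic P-QRS-T record.

    R-peak times are laid on exact sample indices (the R Gaussian is centred
    on a grid point), so each annotated peak is the argmax of its beat.
    With ``quantize_bits`` set, samples are rounded to that many bits over
    [-2, 2] (off by default; the pipeline operates on real-valued samples).
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    morph = morph or MorphologyParams()
    period_s = 60.0 / morph.heart_rate_bpm
    if duration_s < 2 * period_s:
        raise ValueError("duration must cover at least two beats")

    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * fs))

    # Beat-to-beat intervals in integer samples; first R at 0.5 s.
    r_idx = []
    pos = int(round(0.5 * fs))
    margin = int(round(0.45 * fs))  # keep full T wave inside the record
    while pos < n_samples - margin:
        r_idx.append(pos)
        interval = period_s * (1.0 + morph.hr_jitter * rng.standard_normal())
        interval = max(interval, 0.25 * period_s)
        pos += int(round(interval * fs))
    r_peaks = np.asarray(r_idx, dtype=np.int64)

    t = np.arange(n_samples) / fs
    x = np.zeros(n_samples)
    for r in r_peaks:
        t_r = r / fs
        for amp, width, offset in morph.waves.values():
            centre = t_r + offset
            lo = max(0, int((centre - 6 * width) * fs))
            hi = min(n_samples, int((centre + 6 * width) * fs) + 1)
            if hi > lo:
                d = (t[lo:hi] - centre) / width
                x[lo:hi] += amp * np.exp(-0.5 * d * d)

    if quantize_bits is not None:
        full_scale = 2.0
        levels = 2 ** (quantize_bits - 1)
        x = np.round(x / full_scale * levels) / levels * full_scale

    return ECGRecord(
        samples=x,
        fs=fs,
        r_peaks=r_peaks,
        beat_labels=["N"] * r_peaks.size,
        record_id=f"synth-{seed}",
    )


def add_interference(
    rec: ECGRecord,
    powerline_amp: float = 0.0,
    powerline_f0: float = 60.0,
    baseline_amp: float = 0.0,
    baseline_f: float = 0.3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ECGRecord:
    """Add powerline harmonics, baseline wander and white Gaussian noise.

    The powerline component is ``amp * (sin(2pi f0 t + phi) +
    0.5 sin(2pi 2 f0 t + phi) + 0.25 sin(2pi 3 f0 t + phi))`` -- the first
    three harmonics a mains-coupled front end picks up. R peaks are left
    untouched: interference is additive and the ground truth still refers
    to the clean morphology.
    """
    if min(powerline_amp, baseline_amp, noise_sd) < 0:
        raise ValueError("amplitudes and noise_sd must be >= 0")
    nyquist = rec.fs / 2.0
    if powerline_amp > 0 and 3 * powerline_f0 > nyquist:
        raise ValueError("third powerline harmonic exceeds the Nyquist rate")
    if baseline_amp > 0 and baseline_f >= nyquist:
        raise ValueError("baseline frequency exceeds the Nyquist rate")

    rng = np.random.default_rng(seed)
    t = np.arange(rec.samples.size) / rec.fs
    out = rec.samples.copy()
    if powerline_amp > 0:
        phi = np.pi / 4  # nonzero phase keeps an exactly-Nyquist harmonic visible
        for k, rel in enumerate((1.0, 0.5, 0.25), start=1):
            out += powerline_amp * rel * np.sin(2 * np.pi * k * powerline_f0 * t + phi)
    if baseline_amp > 0:
        out += baseline_amp * np.sin(2 * np.pi * baseline_f * t)
    if noise_sd > 0:
        out += noise_sd * rng.standard_normal(out.size)
    return rec.with_samples(out)
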