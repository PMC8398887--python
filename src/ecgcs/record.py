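"""Core ECG record container shared by the synthesis, I/O and framing stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ECGRecord:
    """A single-lead ECG trace with R-peak ground truth.

    Parameters
    ----------
    samples : ndarray
        Amplitude samples (arbitrary units, typically mV).
    fs : float
        Sampling rate in Hz. MIT-BIH ambulatory recordings use 360 Hz.
    r_peaks : ndarray of int
        Strictly increasing sample indices of the R peaks. These come from
        beat annotations (real records) or from generator ground truth
        (synthetic records) -- never from an in-package detector.
    beat_labels : list of str, optional
        One annotation symbol per R peak ('N', 'V', '/', ...).
    record_id : str
        Free-form identifier.
    """

    samples: np.ndarray
    fs: float = 360.0
    r_peaks: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    beat_labels: list | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-D vector with at least 2 entries")
        if self.r_peaks.size:
            if np.any(np.diff(self.r_peaks) <= 0):
                raise ValueError("r_peaks must be strictly increasing")
            if self.r_peaks[0] < 0 or self.r_peaks[-1] >= self.samples.size:
                raise ValueError("r_peaks must lie inside the record")
        if self.beat_labels is not None and len(self.beat_labels) != self.r_peaks.size:
            raise ValueError("beat_labels must match r_peaks in length")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray) -> "ECGRecord":
        """Copy of the record with replaced sample vector (peaks unchanged)."""
        return ECGRecord(
            samples=np.asarray(samples, dtype=float),
            fs=self.fs,
            r_peaks=self.r_peaks.copy(),
            beat_labels=None if self.beat_labels is None else list(self.beat_labels),
            record_id=self.record_id,
        )
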