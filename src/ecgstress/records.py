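"""Core record container shared by every pipeline stage.

All in-memory amplitudes are millivolts; converters in :mod:`ecgstress.io`
are the only place analog-to-digital gains are applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Valid class labels. ``without_stress`` is the positive class throughout
#: the evaluation module.
LABELS = ("without_stress", "under_stress", "unknown")


@dataclass
class ECGRecord:
    """A single-lead ECG waveform.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in mV.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        One of ``without_stress``, ``under_stress``, ``unknown``.
    record_id : str
        Identifier used in manifests and file names.
    source : str
        ``"synthetic"`` or the path the record was read from.
    """

    samples: np.ndarray
    fs: float
    label: str = "unknown"
    record_id: str = ""
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.label:
            self.label = "unknown"
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def copy_with(self, **kwargs) -> "ECGRecord":
        """Return a copy with selected fields replaced."""
        params = dict(
            samples=self.samples.copy(),
            fs=self.fs,
            label=self.label,
            record_id=self.record_id,
            source=self.source,
        )
        params.update(kwargs)
        return ECGRecord(**params)
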