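"""Denoising, R/S-peak feature extraction, and spectrogram imaging.

The pipeline mirrors common single-lead ECG practice: a zero-phase
low-pass (360 Hz sampling, 150 Hz cutoff by default) removes
high-frequency noise without shifting peak times, R and S peaks are then
found by simple amplitude thresholding (+0.2 mV / −0.54 mV) with a
refractory window standing in for "one period", and each record is
rendered as a log-magnitude STFT image.  A frequency-domain counterpart
of every record — the magnitude spectrum pushed through the same imaging
path — doubles the dataset.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy.fft import rfft, rfftfreq
from skimage.transform import resize

from .records import ECGRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Filtering / resampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterSpec:
    """Low-pass design: Butterworth of ``order``, applied forward-backward."""

    fs: float = 360.0
    cutoff: float = 150.0
    order: int = 4
    family: str = "butterworth"

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not 0 < self.cutoff < self.fs / 2:
            raise ValueError(
                f"cutoff must lie in (0, fs/2) = (0, {self.fs / 2:g}), got {self.cutoff}"
            )
        if self.order < 1:
            raise ValueError("order must be >= 1")

    def sos(self) -> np.ndarray:
        self.validate()
        if self.family != "butterworth":
            raise ValueError(f"unknown filter family {self.family!r}")
        return sps.butter(self.order, self.cutoff, btype="low", fs=self.fs, output="sos")


def apply_lowpass(record: ECGRecord, spec: FilterSpec = FilterSpec()) -> ECGRecord:
    """Zero-phase low-pass; output length equals input length.

    Forward-backward application squares the magnitude response and
    cancels the phase, so detected peak indices are directly comparable
    before and after filtering.
    """
    spec.validate()
    if record.fs != spec.fs:
        raise ValueError(
            f"record fs {record.fs:g} != filter fs {spec.fs:g}; resample first"
        )
    filtered = sps.sosfiltfilt(spec.sos(), record.samples)
    return record.copy_with(samples=filtered)


def resample(record: ECGRecord, target_fs: float) -> ECGRecord:
    """Band-limited (polyphase) resampling; duration preserved within one sample."""
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if target_fs == record.fs:
        return record.copy_with()
    frac = Fraction(target_fs / record.fs).limit_denominator(1000)
    out = sps.resample_poly(record.samples, frac.numerator, frac.denominator)
    return record.copy_with(samples=out, fs=target_fs)


def noise_reduction_percent(
    raw: ECGRecord, filtered: ECGRecord, spec: FilterSpec = FilterSpec()
) -> float:
    """Percentage of above-cutoff spectral power removed by the filter.

    ``100 * (P_raw - P_filt) / P_raw`` where P is the summed power in
    frequency bins strictly above the cutoff.  Returns NaN when the raw
    record carries no out-of-band power (the ratio is undefined).

    This is one concrete definition of "noise eliminated"; any figure it
    produces depends on the noise actually present out of band.
    """
    if raw.n_samples != filtered.n_samples or raw.fs != filtered.fs:
        raise ValueError("raw and filtered records must share length and fs")
    freqs = rfftfreq(raw.n_samples, d=1.0 / raw.fs)
    band = freqs > spec.cutoff
    spectrum = np.abs(rfft(raw.samples)) ** 2
    p_total = float(np.sum(spectrum))
    p_raw = float(np.sum(spectrum[band]))
    p_filt = float(np.sum(np.abs(rfft(filtered.samples))[band] ** 2))
    if p_raw <= 1e-12 * p_total or p_total == 0.0:
        return float("nan")
    return 100.0 * (p_raw - p_filt) / p_raw


# ---------------------------------------------------------------------------
# Peak detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakThresholds:
    """Amplitude thresholds (mV) and the refractory window (s).

    The refractory window plays the role of "one period": at most one R
    and one S peak are kept per window, the largest-amplitude candidate
    winning.  0.35 s caps repetition at ~170 beats/min.
    """

    r_threshold: float = 0.2
    s_threshold: float = -0.54
    refractory: float = 0.35

    def validate(self) -> None:
        if not (self.r_threshold > 0 > self.s_threshold):
            raise ValueError("need r_threshold > 0 > s_threshold")
        if self.refractory <= 0:
            raise ValueError("refractory window must be positive")


@dataclass
class BeatFeatures:
    """Detected peaks and the derived per-beat features.

    ``rs_amplitudes`` holds R − S (mV) for each R peak paired with the
    nearest following S peak inside the refractory window; unpaired peaks
    contribute nothing.  ``rr_intervals`` are successive R-to-R gaps (s).
    """

    r_indices: np.ndarray
    s_indices: np.ndarray
    rr_intervals: np.ndarray
    rs_amplitudes: np.ndarray
    fs: float

    @property
    def n_beats(self) -> int:
        return int(self.r_indices.size)


def detect_peaks(record: ECGRecord, thresholds: PeakThresholds = PeakThresholds()) -> BeatFeatures:
    """Threshold-based R/S-peak detection.

    An R peak is a local maximum exceeding ``r_threshold``; an S peak a
    local minimum below ``s_threshold``; spacing between same-type peaks
    is enforced to be at least the refractory window, keeping the
    greatest amplitude when candidates collide.
    """
    thresholds.validate()
    x = record.samples
    distance = max(1, int(round(thresholds.refractory * record.fs)))
    if x.size <= distance:
        raise ValueError(
            f"record of {x.size} samples is shorter than one refractory window "
            f"({distance} samples)"
        )
    r_idx, _ = sps.find_peaks(x, height=thresholds.r_threshold, distance=distance)
    s_idx, _ = sps.find_peaks(-x, height=-thresholds.s_threshold, distance=distance)

    rr = np.diff(r_idx) / record.fs
    rs = []
    used = np.zeros(s_idx.size, dtype=bool)
    for r in r_idx:
        after = np.nonzero((s_idx > r) & (s_idx <= r + distance) & ~used)[0]
        if after.size:
            j = after[0]
            used[j] = True
            rs.append(x[r] - x[s_idx[j]])
    return BeatFeatures(
        r_indices=r_idx,
        s_indices=s_idx,
        rr_intervals=rr,
        rs_amplitudes=np.asarray(rs, dtype=float),
        fs=record.fs,
    )


def summarize_rs(features: BeatFeatures) -> float:
    """Mean R−S amplitude (mV); NaN when no beat could be paired."""
    if features.rs_amplitudes.size == 0:
        return float("nan")
    return float(np.mean(features.rs_amplitudes))


def summarize_rr(features: BeatFeatures) -> float:
    """Mean R–R interval (s); NaN with fewer than two R peaks."""
    if features.rr_intervals.size == 0:
        return float("nan")
    return float(np.mean(features.rr_intervals))


# ---------------------------------------------------------------------------
# Frequency transform / spectrogram imaging
# ---------------------------------------------------------------------------

def to_frequency_domain(record: ECGRecord, detrend: bool = False) -> np.ndarray:
    """One-sided magnitude spectrum, length ``floor(n/2) + 1``."""
    x = record.samples
    if detrend:
        x = x - np.mean(x)
    return np.abs(rfft(x))


@dataclass(frozen=True)
class STFTParams:
    """STFT imaging settings.

    A 1 s Hann window with 50% overlap at the record's sampling rate; for
    unitless series (e.g. a magnitude spectrum) the window defaults to
    1/8 of the series length.  Log magnitudes are min–max normalized to
    [0, 1] and resized bilinearly to ``image_size`` square.
    """

    window_seconds: float = 1.0
    overlap: float = 0.5
    image_size: int = 124
    log_floor: float = 1e-10

    def validate(self) -> None:
        if self.window_seconds <= 0 or not 0 <= self.overlap < 1:
            raise ValueError("need window_seconds > 0 and overlap in [0, 1)")
        if self.image_size < 2:
            raise ValueError("image_size must be >= 2")


@dataclass
class SpectrogramImage:
    """124 × 124 × 3 image (values in [0, 1]) with domain tag and label."""

    pixels: np.ndarray
    domain: str  # "time" | "frequency"
    label: str
    record_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] != p.shape[1]:
            raise ValueError(f"pixels must be square (N, N, 3), got {p.shape}")
        if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
            raise ValueError("pixel values must be finite and in [0, 1]")
        if self.domain not in ("time", "frequency"):
            raise ValueError(f"domain must be 'time' or 'frequency', got {self.domain!r}")
        self.pixels = p


def to_spectrogram(
    series: np.ndarray,
    params: STFTParams = STFTParams(),
    fs: float | None = None,
    domain: str = "time",
    label: str = "unknown",
    record_id: str = "",
) -> SpectrogramImage:
    """Render a 1-D series as a normalized log-magnitude STFT image.

    Deterministic for fixed inputs.  An all-zero (or constant) series
    yields an all-zero image: the degenerate min–max normalization maps
    everything to 0.
    """
    params.validate()
    series = np.asarray(series, dtype=float)
    if fs is not None:
        nperseg = int(round(params.window_seconds * fs))
    else:
        nperseg = max(8, series.size // 8)
    nperseg = min(nperseg, series.size)
    if series.size < 2 or nperseg < 2:
        raise ValueError("series shorter than one STFT window")
    hop = max(1, int(round(nperseg * (1.0 - params.overlap))))
    stf = sps.ShortTimeFFT(
        sps.windows.hann(nperseg, sym=False), hop=hop, fs=1.0, mfft=nperseg
    )
    mag = np.abs(stf.stft(series))
    logmag = np.log10(mag + params.log_floor)
    lo, hi = float(logmag.min()), float(logmag.max())
    if hi - lo < 1e-12:
        norm = np.zeros_like(logmag)
    else:
        norm = (logmag - lo) / (hi - lo)
    img = resize(norm, (params.image_size, params.image_size), order=1, anti_aliasing=False)
    img = np.clip(img, 0.0, 1.0)
    pixels = np.repeat(img[:, :, None], 3, axis=2)
    return SpectrogramImage(pixels=pixels, domain=domain, label=label, record_id=record_id)


def build_dataset(
    records: list[ECGRecord],
    thresholds: PeakThresholds = PeakThresholds(),
    filter_spec: FilterSpec = FilterSpec(),
    stft_params: STFTParams = STFTParams(),
) -> tuple[list[SpectrogramImage], list[SpectrogramImage]]:
    """Filter each record and render its time- and frequency-domain images.

    Records at a different sampling rate are resampled to the filter's
    rate first.  For n successfully processed records the output is
    exactly n time-domain plus n frequency-domain images with labels
    carried through; a record that fails is logged and skipped.
    """
    if not records:
        raise ValueError("need at least one record")
    time_images: list[SpectrogramImage] = []
    freq_images: list[SpectrogramImage] = []
    skipped = 0
    for rec in records:
        try:
            if rec.fs != filter_spec.fs:
                rec = resample(rec, filter_spec.fs)
            filtered = apply_lowpass(rec, filter_spec)
            time_images.append(
                to_spectrogram(
                    filtered.samples, stft_params, fs=filtered.fs,
                    domain="time", label=rec.label, record_id=rec.record_id,
                )
            )
            spectrum = to_frequency_domain(filtered)
            freq_images.append(
                to_spectrogram(
                    spectrum, stft_params, fs=None,
                    domain="frequency", label=rec.label, record_id=rec.record_id,
                )
            )
        except Exception:  # noqa: BLE001 - per-record isolation is the contract
            skipped += 1
            logger.exception("skipping record %s", rec.record_id)
    if skipped:
        logger.warning("skipped %d of %d records", skipped, len(records))
    return time_images, freq_images


def images_to_arrays(images: list[SpectrogramImage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack images into (n, H, W, 3) float32 X and a label array y."""
    X = np.stack([im.pixels for im in images]).astype(np.float32)
    y = np.array([im.label for im in images])
    return X, y
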