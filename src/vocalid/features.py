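"""Call segmentation and acoustic descriptor extraction.

Segments calls from an amplitude envelope and computes, per call, the eight
descriptors used throughout the package: duration, mean per-frame RMS
amplitude, peak frequency, the 25/50/75% spectral energy quantiles, the
spectral centroid, and the spectral slope (dB/kHz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.io import wavfile
from scipy.signal.windows import hann

logger = logging.getLogger(__name__)

__all__ = [
    "AcousticParameters",
    "Segment",
    "detect_call_boundaries",
    "extract_features",
    "read_wav",
    "write_wav",
]


@dataclass(frozen=True)
class AcousticParameters:
    """The eight-descriptor feature vector of one call.

    Frequencies are in Hz, duration in seconds, mean_amplitude is linear
    full-scale-relative RMS, spectral_slope in dB/kHz.
    """

    duration: float
    mean_amplitude: float
    peak_frequency: float
    q25: float
    q50: float
    q75: float
    spectral_centroid: float
    spectral_slope: float

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not (self.q25 <= self.q50 <= self.q75):
            raise ValueError(
                f"spectral quantiles must be ordered, got {self.q25}, {self.q50}, {self.q75}"
            )
        if self.mean_amplitude < 0:
            raise ValueError("mean_amplitude must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.duration,
                self.mean_amplitude,
                self.peak_frequency,
                self.q25,
                self.q50,
                self.q75,
                self.spectral_centroid,
                self.spectral_slope,
            ]
        )


@dataclass(frozen=True)
class Segment:
    """A half-open time interval [start, end) within a source recording."""

    start: float
    end: float
    source: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"need 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start


def read_wav(path, channel: int | None = None) -> tuple[np.ndarray, int]:
    """Read a RIFF PCM WAV file as float64 in [-1, 1].

    Parameters
    ----------
    path : path-like
    channel : which channel of a multi-channel file to keep; ``None`` keeps
        channel 0 of multi-channel input (with a log note).

    Returns
    -------
    (waveform, sample_rate)
    """
    sample_rate, data = wavfile.read(path)
    if data.dtype.kind == "i":
        scale = float(np.iinfo(data.dtype).max) + 1.0
        x = data.astype(np.float64) / scale
    elif data.dtype.kind == "u":  # 8-bit unsigned
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:
        x = data.astype(np.float64)
    if x.ndim == 2:
        if channel is None:
            logger.info("multi-channel WAV %s: keeping channel 0", path)
            channel = 0
        x = x[:, channel]
    return x, int(sample_rate)


def write_wav(path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write a mono waveform in [-1, 1] as 16-bit PCM WAV."""
    x = np.clip(np.asarray(waveform, dtype=np.float64), -1.0, 1.0)
    wavfile.write(path, sample_rate, (x * 32767.0).astype(np.int16))


def _smooth_envelope(x: np.ndarray, sample_rate: int, smooth_s: float) -> np.ndarray:
    win = max(1, int(round(smooth_s * sample_rate)))
    kernel = np.full(win, 1.0 / win)
    return np.convolve(np.abs(x), kernel, mode="same")


def detect_call_boundaries(
    waveform: np.ndarray,
    sample_rate: int,
    threshold_fraction: float = 0.1,
    min_duration: float = 0.02,
    min_gap: float = 0.05,
    smooth_s: float = 0.005,
    source: str | None = None,
) -> list[Segment]:
    """Segment calls where the smoothed amplitude envelope exceeds a
    fraction of its maximum.

    Above-threshold runs separated by gaps shorter than ``min_gap`` are
    merged; runs shorter than ``min_duration`` are discarded. A silent
    (all-zero) waveform yields an empty list.

    Returns non-overlapping segments sorted by onset.
    """
    x = np.asarray(waveform, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains non-finite samples")
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    if x.size == 0 or np.max(np.abs(x)) == 0:
        return []

    env = _smooth_envelope(x, sample_rate, smooth_s)
    mask = env > threshold_fraction * env.max()
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1)  # exclusive

    # merge across short gaps
    merged: list[list[int]] = []
    gap_samples = int(round(min_gap * sample_rate))
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] < gap_samples:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])

    min_samples = int(round(min_duration * sample_rate))
    out = [
        Segment(start=s / sample_rate, end=e / sample_rate, source=source)
        for s, e in merged
        if e - s >= min_samples
    ]
    return out


def extract_features(
    waveform: np.ndarray,
    sample_rate: int,
    frame_length: int = 512,
    step: float = 0.001,
    quantile_mode: Literal["per_frame", "mean_spectrum"] = "per_frame",
) -> AcousticParameters:
    """Compute the eight-descriptor vector for one segmented call.

    The signal is framed (Hann window of ``frame_length`` samples, hop of
    ``step`` seconds); per-frame power spectra give the spectral statistics.

    * duration — segment length in seconds
    * mean_amplitude — mean per-frame RMS of the raw (unwindowed) frames
    * q25/q50/q75 — frequencies below which 25/50/75% of cumulative spectral
      energy lies; by default computed per frame and averaged over frames
      (``quantile_mode="mean_spectrum"`` computes them on the mean spectrum)
    * spectral_centroid — energy-weighted mean frequency, averaged over frames
    * peak_frequency — frequency of maximum power in the mean spectrum
    * spectral_slope — OLS slope of the mean spectrum level (dB) on
      frequency (kHz)

    Raises
    ------
    ValueError
        if the segment is shorter than one frame, all-zero (spectrum
        undefined), or contains non-finite samples.
    """
    x = np.asarray(waveform, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if x.size == 0:
        raise ValueError("empty segment")
    if not np.all(np.isfinite(x)):
        raise ValueError("waveform contains non-finite samples")
    if step <= 0:
        raise ValueError("step must be > 0")
    if x.size < frame_length:
        raise ValueError(
            f"segment of {x.size} samples is shorter than one frame ({frame_length})"
        )
    if not np.any(x != 0):
        raise ValueError("silent segment: spectrum undefined")

    hop = max(1, int(round(step * sample_rate)))
    n_frames = 1 + (x.size - frame_length) // hop
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]

    mean_amplitude = float(np.mean(np.sqrt(np.mean(frames**2, axis=1))))

    window = hann(frame_length, sym=False)
    spectra = np.abs(np.fft.rfft(frames * window, axis=1)) ** 2
    freqs = np.fft.rfftfreq(frame_length, d=1.0 / sample_rate)

    frame_energy = spectra.sum(axis=1)
    live = frame_energy > 0
    if not np.any(live):
        raise ValueError("no frame with spectral energy")
    spectra_live = spectra[live]
    energy_live = frame_energy[live]

    centroid = float(np.mean((spectra_live @ freqs) / energy_live))

    cum = np.cumsum(spectra_live, axis=1) / energy_live[:, None]
    if quantile_mode == "per_frame":
        q = [
            float(np.mean(freqs[np.argmax(cum >= p, axis=1)]))
            for p in (0.25, 0.50, 0.75)
        ]
    elif quantile_mode == "mean_spectrum":
        mean_cum = np.cumsum(spectra_live.mean(axis=0))
        mean_cum /= mean_cum[-1]
        q = [float(freqs[np.searchsorted(mean_cum, p)]) for p in (0.25, 0.50, 0.75)]
    else:
        raise ValueError(f"unknown quantile_mode {quantile_mode!r}")

    mean_spectrum = spectra_live.mean(axis=0)
    peak_frequency = float(freqs[int(np.argmax(mean_spectrum))])

    # slope of spectrum level (dB) on frequency (kHz); floor relative to the
    # peak so that pure amplitude scaling shifts the intercept, not the slope
    level_db = 10.0 * np.log10(np.maximum(mean_spectrum, mean_spectrum.max() * 1e-12))
    f_khz = freqs / 1000.0
    slope = float(np.polyfit(f_khz, level_db, 1)[0])

    q25, q50, q75 = sorted(q)
    return AcousticParameters(
        duration=x.size / sample_rate,
        mean_amplitude=mean_amplitude,
        peak_frequency=peak_frequency,
        q25=q25,
        q50=q50,
        q75=q75,
        spectral_centroid=centroid,
        spectral_slope=slope,
    )
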