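"""Seeded synthetic call datasets with known individual signatures.

Feature vectors are built additively: baseline + individual offset +
age drift x (age - age_min) + context effect + Gaussian within-individual
noise, truncated to valid ranges by resampling. Optionally, a call can be
rendered as a band-shaped noise waveform whose extracted spectral statistics
approximate a target descriptor vector, enabling round-trip tests of the
feature extractor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import FEATURE_COLUMNS, METADATA_COLUMNS
from .features import AcousticParameters

logger = logging.getLogger(__name__)

__all__ = [
    "IndividualProfile",
    "GeneratorConfig",
    "generate_dataset",
    "synthesize_call_waveform",
    "default_baseline",
    "default_within_sd",
]

_FREQ_FIELDS = ["peak_frequency", "q25", "q50", "q75", "spectral_centroid"]
_FREQ_IDX = [FEATURE_COLUMNS.index(f) for f in _FREQ_FIELDS]
_DUR_IDX = FEATURE_COLUMNS.index("duration")
_AMP_IDX = FEATURE_COLUMNS.index("mean_amplitude")


def default_baseline() -> np.ndarray:
    """Plausible descriptor means for a juvenile corvid-like call."""
    return np.array([0.25, 0.08, 1600.0, 1100.0, 1900.0, 3000.0, 2100.0, -6.0])


def default_within_sd() -> np.ndarray:
    """Call-to-call noise SDs, roughly 10-20% of the baseline scale."""
    return np.array([0.05, 0.015, 250.0, 180.0, 220.0, 320.0, 230.0, 1.2])


@dataclass
class IndividualProfile:
    """Generative parameters of one individual's calls (descriptor units)."""

    individual_id: str
    nest_id: str
    baseline: np.ndarray
    individual_offset: np.ndarray
    age_drift: np.ndarray
    within_sd: np.ndarray

    def __post_init__(self) -> None:
        for name in ("baseline", "individual_offset", "age_drift", "within_sd"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.shape != (8,):
                raise ValueError(f"{name} must be an 8-vector, got shape {v.shape}")
            setattr(self, name, v)
        if np.any(self.within_sd < 0):
            raise ValueError("within_sd must be >= 0 elementwise")
        if self.baseline[_DUR_IDX] <= 0:
            raise ValueError("baseline duration must be > 0")


_DEFAULT_CONTEXT_WEIGHTS: dict[str, tuple[float, float]] = {
    # (weight at age_min, weight at age_max); begging dominates early
    "beg": (0.60, 0.15),
    "rest": (0.10, 0.25),
    "touch-affiliative": (0.08, 0.15),
    "touch-aversive": (0.05, 0.10),
    "fed": (0.10, 0.10),
    "move": (0.02, 0.15),
    "unknown": (0.05, 0.10),
}


@dataclass
class GeneratorConfig:
    """Configuration of a synthetic call dataset.

    ``contexts`` maps each context label to a pair of mixture weights at the
    youngest and oldest age; weights are linearly interpolated across the age
    range and renormalised per day. ``offset_sd``/``drift_sd`` control the
    SDs from which per-individual offsets and age drifts are drawn when
    explicit ``profiles`` are not supplied.
    """

    n_individuals: int = 5
    n_nests: int = 2
    age_range_days: tuple[int, int] = (11, 45)
    contexts: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CONTEXT_WEIGHTS)
    )
    calls_per_individual_day: int = 2
    context_effects: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0
    baseline: np.ndarray = field(default_factory=default_baseline)
    within_sd: np.ndarray = field(default_factory=default_within_sd)
    offset_sd: np.ndarray = field(default_factory=lambda: np.zeros(8))
    drift_sd: np.ndarray = field(default_factory=lambda: np.zeros(8))
    profiles: list[IndividualProfile] | None = None
    fledge_age: int = 25  # first day counted as phase 2

    def __post_init__(self) -> None:
        if not self.contexts:
            raise ValueError("contexts list must not be empty")
        lo, hi = self.age_range_days
        if not (lo <= hi):
            raise ValueError("age_range_days must be (min, max) with min <= max")
        for name in ("baseline", "within_sd", "offset_sd", "drift_sd"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if v.shape != (8,):
                raise ValueError(f"{name} must be an 8-vector")
            setattr(self, name, v)
        for ctx, w in self.contexts.items():
            w0, w1 = (w, w) if np.isscalar(w) else tuple(w)
            if w0 < 0 or w1 < 0:
                raise ValueError(f"negative mixture weight for context {ctx!r}")
            self.contexts[ctx] = (float(w0), float(w1))
        if sum(w0 + w1 for w0, w1 in self.contexts.values()) <= 0:
            raise ValueError("context mixture weights must not all be zero")


def _mean_feasible(mean: np.ndarray, within_sd: np.ndarray, nyquist: float) -> bool:
    """Generative mean leaves ~2 SD of headroom inside the valid range."""
    lo = mean - 2 * within_sd
    hi = mean + 2 * within_sd
    if lo[_DUR_IDX] <= 0 or lo[_AMP_IDX] <= 0:
        return False
    return bool(np.all(lo[_FREQ_IDX] > 0) and np.all(hi[_FREQ_IDX] < nyquist))


def _make_profiles(
    config: GeneratorConfig, rng: np.random.Generator, nyquist: float
) -> list[IndividualProfile]:
    if config.profiles is not None:
        if len(config.profiles) != config.n_individuals:
            raise ValueError("profiles length must equal n_individuals")
        return config.profiles
    profiles = []
    for i in range(config.n_individuals):
        nest = f"N{i % config.n_nests + 1}"
        for _ in range(_MAX_REDRAWS):
            offset = rng.normal(0.0, 1.0, 8) * config.offset_sd
            if _mean_feasible(config.baseline + offset, config.within_sd, nyquist):
                break
        else:
            raise RuntimeError(
                "could not draw a feasible individual offset; offset_sd too large "
                "relative to the baseline"
            )
        drift = rng.normal(0.0, 1.0, 8) * config.drift_sd
        profiles.append(
            IndividualProfile(
                individual_id=f"ind{i + 1:02d}",
                nest_id=nest,
                baseline=config.baseline.copy(),
                individual_offset=offset,
                age_drift=drift,
                within_sd=config.within_sd.copy(),
            )
        )
    return profiles


def _context_weights_for_age(config: GeneratorConfig, age: int) -> tuple[list[str], np.ndarray]:
    lo, hi = config.age_range_days
    t = 0.0 if hi == lo else (age - lo) / (hi - lo)
    labels = list(config.contexts)
    w = np.array([(1 - t) * w0 + t * w1 for w0, w1 in config.contexts.values()])
    total = w.sum()
    if total <= 0:
        raise ValueError(f"context mixture weights sum to zero at age {age}")
    return labels, w / total

_MAX_REDRAWS = 200


def _draw_valid(
    mean: np.ndarray, sd: np.ndarray, nyquist: float, rng: np.random.Generator
) -> np.ndarray:
    """One feature vector; invalid draws are rejected and redrawn (no clipping)."""
    for _ in range(_MAX_REDRAWS):
        v = mean + rng.normal(0.0, 1.0, 8) * sd
        freqs = v[_FREQ_IDX]
        if v[_DUR_IDX] > 0 and v[_AMP_IDX] > 0 and np.all((freqs > 0) & (freqs < nyquist)):
            return v
    raise RuntimeError(
        "could not draw a valid feature vector; generative means likely out of range"
    )


def generate_dataset(
    config: GeneratorConfig, sample_rate: int = 48_000
) -> pd.DataFrame:
    """Generate a synthetic call table, deterministic given ``config.seed``.

    Returns a DataFrame with the standard metadata and feature columns, one
    row per call, ordered by individual, day and call index.
    """
    rng = np.random.default_rng(config.seed)
    nyquist = sample_rate / 2.0
    profiles = _make_profiles(config, rng, nyquist)
    lo, hi = config.age_range_days

    unknown_ctx = set(config.context_effects) - set(config.contexts)
    if unknown_ctx:
        raise ValueError(f"context_effects for unknown contexts: {sorted(unknown_ctx)}")

    rows = []
    call_counter = 0
    for prof in profiles:
        for age in range(lo, hi + 1):
            labels, weights = _context_weights_for_age(config, age)
            for _ in range(config.calls_per_individual_day):
                ctx = labels[rng.choice(len(labels), p=weights)]
                effect = config.context_effects.get(ctx, np.zeros(8))
                mean = (
                    prof.baseline
                    + prof.individual_offset
                    + prof.age_drift * (age - lo)
                    + np.asarray(effect, dtype=np.float64)
                )
                v = _draw_valid(mean, prof.within_sd, nyquist, rng)
                call_counter += 1
                rows.append(
                    {
                        "call_id": f"call{call_counter:06d}",
                        "individual": prof.individual_id,
                        "nest": prof.nest_id,
                        "context": ctx,
                        "age_days": age,
                        "phase": 1 if age < config.fledge_age else 2,
                        **dict(zip(FEATURE_COLUMNS, v)),
                    }
                )
    df = pd.DataFrame(rows, columns=METADATA_COLUMNS + FEATURE_COLUMNS)
    logger.info(
        "generated %d calls for %d individuals (seed=%d)",
        len(df),
        config.n_individuals,
        config.seed,
    )
    return df


def synthesize_call_waveform(
    target: AcousticParameters,
    sample_rate: int = 48_000,
    rng: np.random.Generator | None = None,
    harmonic_weight: float = 0.0,
    ramp_s: float = 0.005,
) -> np.ndarray:
    """Render a mono waveform approximating a target descriptor vector.

    The spectrum is band-shaped noise with equal energy between the
    quartile breakpoints, so extracted spectral quantiles land near the
    targets by construction; ``harmonic_weight`` mixes in a decaying
    harmonic stack rooted at the target q50. Waveform RMS is scaled to the
    target mean amplitude and short cosine ramps avoid onset clicks.

    Raises
    ------
    ValueError
        if the target quantiles are unordered or the sample rate is too low
        for the requested q75.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    nyquist = sample_rate / 2.0
    q25, q50, q75 = target.q25, target.q50, target.q75
    if not (0 < q25 <= q50 <= q75):
        raise ValueError("target quantiles must satisfy 0 < q25 <= q50 <= q75")
    if q75 >= 0.98 * nyquist:
        raise ValueError(
            f"sample rate {sample_rate} too low for target q75={q75} Hz"
        )

    n = int(round(target.duration * sample_rate))
    if n < 32:
        raise ValueError("target duration too short at this sample rate")

    lo = 0.5 * q25
    hi = min(0.98 * nyquist, q75 + max(0.5 * (q75 - q25), 0.25 * q75))
    edges = np.array([lo, q25, q50, q75, hi])
    widths = np.maximum(np.diff(edges), 1e-9)

    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    density = np.zeros_like(freqs)
    for k in range(4):
        band = (freqs >= edges[k]) & (freqs < edges[k + 1])
        density[band] = 0.25 / widths[k]

    spectrum = np.sqrt(density) * (rng.normal(size=freqs.size) + 1j * rng.normal(size=freqs.size))
    x = np.fft.irfft(spectrum, n=n)

    if harmonic_weight > 0:
        f0 = q50
        t = np.arange(n) / sample_rate
        stack = np.zeros(n)
        k = 1
        while k * f0 < hi:
            stack += np.sin(2 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi)) / k
            k += 1
        stack /= max(np.sqrt(np.mean(stack**2)), 1e-12)
        x = (1 - harmonic_weight) * x / max(np.sqrt(np.mean(x**2)), 1e-12) + harmonic_weight * stack

    ramp = min(int(round(ramp_s * sample_rate)), n // 4)
    if ramp > 0:
        env = np.ones(n)
        fade = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = fade
        env[-ramp:] = fade[::-1]
        x = x * env

    rms = np.sqrt(np.mean(x**2))
    if rms > 0 and target.mean_amplitude > 0:
        x = x * (target.mean_amplitude / rms)
    return x
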