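"""Jeffress-style binaural cross-correlator used as a mechanistic reference.

The model is deliberately simple and fixed (it is never fitted): each ear's
waveform is band-pass filtered by a 4th-order gammatone centered at the
tone frequency, passed through a rough model of neural transduction
(half-wave rectification followed by power-law compression), and the two
transduced signals are multiplied point-by-point at a range of internal
delays and summed.  The resulting delay profile peaks at internal delays
matching the interaural configuration of the dominant (noise) component:
diotic noise peaks at 0 us, phase-inverted noise has a trough there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import gammatone, lfilter

from binauralnet import stimuli

__all__ = [
    "CrossCorrConfig",
    "DelayProfile",
    "gammatone_filter",
    "transduce",
    "delay_profile",
    "lab_profiles",
]


def _default_delays() -> np.ndarray:
    return np.arange(-2000.0, 2000.0 + 1, 100.0)


@dataclass(frozen=True)
class CrossCorrConfig:
    cf_hz: float = 500.0
    sample_rate_hz: int = 20_000
    duration_s: float = 1.0
    delays_us: np.ndarray = field(default_factory=_default_delays)
    #: transduction variant: "rectify_compress" (exponent below) or "rectify_square"
    transduction: str = "rectify_compress"
    compression_exponent: float = 0.23

    def __post_init__(self) -> None:
        d = np.asarray(self.delays_us, dtype=float)
        if not np.allclose(d, -d[::-1]):
            raise ValueError("delay grid must be symmetric about zero")
        if self.cf_hz >= self.sample_rate_hz / 2:
            raise ValueError("center frequency must be below Nyquist")
        object.__setattr__(self, "delays_us", d)


@dataclass(frozen=True)
class DelayProfile:
    """Summed interaural cross-products vs internal delay (arbitrary units)."""

    delays_us: np.ndarray
    values: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.delays_us) != len(self.values):
            raise ValueError("delay grid and values must align")


def gammatone_filter(x: np.ndarray, cf_hz: float, sample_rate_hz: int) -> np.ndarray:
    """4th-order gammatone band-pass response centered at ``cf_hz``."""
    if cf_hz >= sample_rate_hz / 2:
        raise ValueError("center frequency must be below Nyquist")
    b, a = gammatone(cf_hz, "iir", fs=sample_rate_hz)
    return lfilter(b, a, np.asarray(x, dtype=float))


def transduce(x: np.ndarray, config: CrossCorrConfig = CrossCorrConfig()) -> np.ndarray:
    """Nonnegative, monotone-in-amplitude model of neural transduction."""
    rect = np.maximum(np.asarray(x, dtype=float), 0.0)
    if config.transduction == "rectify_compress":
        return rect**config.compression_exponent
    if config.transduction == "rectify_square":
        return rect**2
    raise ValueError(f"unknown transduction {config.transduction!r}")


def delay_profile(
    left: np.ndarray,
    right: np.ndarray,
    config: CrossCorrConfig = CrossCorrConfig(),
    condition: str = "",
) -> DelayProfile:
    """Summed cross-products of transduced signals over the delay grid.

    For internal delay d (in samples), sums L(t) * R(t + d) over the valid
    overlap and normalizes by the overlap length, avoiding wrap-around
    bias.  Positive internal delay advances the right-ear signal, so a
    right-ear lag of x us produces a profile peak at +x us.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("ear signals must have equal length")
    n = len(left)
    values = np.empty(len(config.delays_us))
    for j, d_us in enumerate(config.delays_us):
        d = int(round(d_us * 1e-6 * config.sample_rate_hz))
        if abs(d) >= n:
            raise ValueError(f"delay {d_us} us exceeds signal length")
        if d >= 0:
            seg_l, seg_r = left[: n - d], right[d:]
        else:
            seg_l, seg_r = left[-d:], right[: n + d]
        values[j] = np.dot(seg_l, seg_r) / len(seg_l)
    return DelayProfile(config.delays_us.copy(), values, condition)


def _peripheral(x: np.ndarray, config: CrossCorrConfig) -> np.ndarray:
    return transduce(gammatone_filter(x, config.cf_hz, config.sample_rate_hz), config)


def lab_profiles(
    tone_level_db_spl: float = 35.0,
    noise_level_db_spl: float = stimuli.NOISE_LEVEL_DB_SPL,
    seed: int = 0,
    n_reps: int = 10,
    config: CrossCorrConfig = CrossCorrConfig(),
    conditions: tuple[str, ...] = stimuli.LAB_CONDITIONS,
) -> dict[str, DelayProfile]:
    """Delay profiles for the laboratory conditions, averaged over noise seeds.

    Stimuli are 1-s tone-in-noise waveforms generated by
    :mod:`binauralnet.stimuli` with the interaural phase configuration of
    each condition; the same seeds are reused across conditions so
    profile differences reflect the configuration, not the noise draw.
    """
    n_samples = int(round(config.duration_s * config.sample_rate_hz))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    out: dict[str, DelayProfile] = {}
    for cond in conditions:
        acc = np.zeros(len(config.delays_us))
        for rs in rep_seeds:
            spec = stimuli.lab_condition_spec(
                cond,
                tone_level_db_spl=tone_level_db_spl,
                seed=int(rs),
                n_samples_per_ear=n_samples,
            )
            spec = stimuli.StimulusSpec(
                **{**spec.__dict__, "noise_level_db_spl": noise_level_db_spl}
            )
            pair = stimuli.make_tone(spec) + stimuli.make_noise(spec)
            prof = delay_profile(
                _peripheral(pair.left, config),
                _peripheral(pair.right, config),
                config,
                cond,
            )
            acc += prof.values
        out[cond] = DelayProfile(config.delays_us.copy(), acc / n_reps, cond)
    return out
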