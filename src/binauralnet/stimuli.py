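"""Dichotic tone-in-noise stimulus synthesis and labeled datasets.

All stimuli are fully synthetic.  A trial is a 500 Hz pure tone (0--50 dB
SPL, random starting phase) masked by band-limited Gaussian noise (50--5000
Hz, 6th-order Butterworth, 60 dB SPL overall), sampled at 20 kHz with 400
samples per ear (ten tone periods).  Interaural time differences (ITDs) are
realized as integer-sample delays of the source (one sample = 50 us) and
are mapped from azimuth with Woodworth's spherical-head formula

    ITD = r * (theta + sin(theta)) / c,

which for r = 0.0875 m and c = 343 m/s gives the familiar +-655 us range at
+-90 degrees.  Ground-truth detection rates for labeled examples come from
the EC equations in :mod:`binauralnet.ec`.

Amplitude convention: waveforms are in pascals, with RMS = 20 uPa *
10^(L/20) for a level of L dB SPL.  Sign convention (package-wide, matching
:class:`binauralnet.ec.LagPair`): positive ITD means the right-ear channel
is the source delayed by the ITD, i.e. the right ear lags the left.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.signal import butter, sosfilt

from binauralnet import ec
from binauralnet.ec import ECParams, LagPair, PsychoParams, P_REF_PA

__all__ = [
    "StimulusSpec",
    "WaveformPair",
    "LabeledExample",
    "LabDataset",
    "LAB_CONDITIONS",
    "woodworth_itd",
    "ipd_to_itd",
    "azimuth_grid",
    "make_tone",
    "make_noise",
    "make_example",
    "make_lab_stimulus",
    "lab_condition_spec",
    "make_dataset",
    "parametric_dataset",
    "save_dataset",
    "load_dataset",
    "spl_to_rms",
]

SAMPLE_RATE_HZ = 20_000
N_SAMPLES_PER_EAR = 400
US_PER_SAMPLE = 1e6 / SAMPLE_RATE_HZ  # 50 us
HEAD_RADIUS_M = 0.0875
SPEED_OF_SOUND_M_S = 343.0
NOISE_BAND_HZ = (50.0, 5000.0)
BUTTERWORTH_ORDER = 6
NOISE_LEVEL_DB_SPL = 60.0
MAX_ITD_US = 2000.0  # largest ITD any probe stimulus may request

#: The four laboratory interaural-phase configurations.  "o" = in phase
#: across ears, "pi" = phase inverted (tone: carrier shift of pi; noise:
#: polarity inversion of one ear).
LAB_CONDITIONS = ("NoSo", "NoSpi", "NpiSpi", "NpiSo")

# Samples discarded to let the Butterworth transient die out; the slow edge
# of the band is 50 Hz, so this is several ringing time constants.
_FILTER_WARMUP = 1500


def spl_to_rms(level_db_spl: float) -> float:
    """RMS pressure (Pa) of a signal at the given dB SPL."""
    return P_REF_PA * 10.0 ** (level_db_spl / 20.0)


def woodworth_itd(
    azimuth_deg,
    head_radius_m: float = HEAD_RADIUS_M,
    speed_of_sound_m_s: float = SPEED_OF_SOUND_M_S,
):
    """Woodworth spherical-head ITD in microseconds, signed by side."""
    az = np.asarray(azimuth_deg, dtype=float)
    if np.any(np.abs(az) > 90.0):
        raise ValueError("azimuth must lie within +-90 degrees")
    theta = np.deg2rad(np.abs(az))
    itd_us = head_radius_m * (theta + np.sin(theta)) / speed_of_sound_m_s * 1e6
    signed = np.sign(az) * itd_us
    return float(signed) if np.isscalar(azimuth_deg) else signed


def ipd_to_itd(f_hz: float, ipd_rad: float) -> float:
    """Convert interaural phase difference (radians) to ITD in microseconds."""
    if f_hz <= 0:
        raise ValueError("frequency must be positive")
    return ipd_rad / (2.0 * np.pi * f_hz) * 1e6


def _itd_to_samples(itd_us) -> np.ndarray | int:
    d = np.round(np.asarray(itd_us) / US_PER_SAMPLE).astype(int)
    return int(d) if np.isscalar(itd_us) else d


def azimuth_grid(
    head_radius_m: float = HEAD_RADIUS_M,
    speed_of_sound_m_s: float = SPEED_OF_SOUND_M_S,
) -> np.ndarray:
    """Azimuths (deg) whose Woodworth ITDs fall on the 50-us sample grid.

    Inverting the Woodworth formula at one-sample ITD steps gives the
    effective azimuthal resolution of the simulation: ~5.6 deg near the
    midline, widening to ~10.3 deg at the far lateral positions.
    """
    max_itd = woodworth_itd(90.0, head_radius_m, speed_of_sound_m_s)
    n_steps = int(max_itd // US_PER_SAMPLE)
    itds = np.arange(1, n_steps + 1) * US_PER_SAMPLE

    def invert(itd_us: float) -> float:
        target = itd_us * 1e-6 * speed_of_sound_m_s / head_radius_m
        lo, hi = 0.0, np.pi / 2
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if mid + np.sin(mid) < target:
                lo = mid
            else:
                hi = mid
        return np.rad2deg(0.5 * (lo + hi))

    pos = np.array([invert(i) for i in itds])
    return np.concatenate([-pos[::-1], [0.0], pos])


@dataclass(frozen=True)
class StimulusSpec:
    """Full parametric description of one dichotic trial."""

    tone_level_db_spl: float = 35.0
    tone_phase: float = 0.0
    tone_itd_us: float = 0.0
    noise_itd_us: float = 0.0
    noise_level_db_spl: float = NOISE_LEVEL_DB_SPL
    f0_hz: float = 500.0
    sample_rate_hz: int = SAMPLE_RATE_HZ
    n_samples_per_ear: int = N_SAMPLES_PER_EAR
    seed: int = 0
    tone_ipd_rad: float = 0.0  # extra carrier phase shift (pi for S_pi)
    noise_inverted: bool = False  # polarity inversion of right ear (N_pi)

    @property
    def realized_tone_itd_us(self) -> float:
        """Tone ITD after quantization to the 50-us sample grid."""
        return _itd_to_samples(self.tone_itd_us) * US_PER_SAMPLE

    @property
    def realized_noise_itd_us(self) -> float:
        return _itd_to_samples(self.noise_itd_us) * US_PER_SAMPLE

    def ec_lags(self) -> LagPair:
        """Interaural lags (seconds) this trial presents to the EC model.

        A carrier IPD adds -ipd/omega0 to the tone lag; an inverted-noise
        ear is a pi IPD at the tone frequency, i.e. a half-period noise
        lag.  Monaural tone phase does not enter.
        """
        tau_s = self.realized_tone_itd_us * 1e-6 - self.tone_ipd_rad / (
            2.0 * np.pi * self.f0_hz
        )
        tau_n = self.realized_noise_itd_us * 1e-6
        if self.noise_inverted:
            tau_n -= 0.5 / self.f0_hz
        return LagPair(tau_s, tau_n)


@dataclass(frozen=True)
class WaveformPair:
    """Left/right ear pressure waveforms (Pa)."""

    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        if self.left.shape != self.right.shape:
            raise ValueError("ear channels must have equal length")

    def concat(self) -> np.ndarray:
        """Network input layout: left followed by right."""
        return np.concatenate([self.left, self.right])

    def __add__(self, other: "WaveformPair") -> "WaveformPair":
        return WaveformPair(self.left + other.left, self.right + other.right)


@dataclass(frozen=True)
class LabeledExample:
    input: np.ndarray  # 2*n_samples_per_ear values, left || right
    target_rate: float  # percent, ground truth from the EC equations
    spec: StimulusSpec


def make_tone(spec: StimulusSpec) -> WaveformPair:
    """Pure tone with an integer-sample interaural delay.

    Positive ITD delays the right ear.  For a pure tone the sample shift is
    applied analytically as a carrier phase offset, which is exact and free
    of edge effects; ``tone_ipd_rad`` adds a further carrier phase shift to
    the right ear for antiphasic (S_pi) configurations.
    """
    d = _itd_to_samples(spec.tone_itd_us)
    if abs(d) > _itd_to_samples(MAX_ITD_US):
        raise ValueError(f"tone ITD {spec.tone_itd_us} us outside representable range")
    n = spec.n_samples_per_ear
    t = np.arange(n) / spec.sample_rate_hz
    amp = spl_to_rms(spec.tone_level_db_spl) * np.sqrt(2.0)
    w0 = 2.0 * np.pi * spec.f0_hz
    delay_s = d / spec.sample_rate_hz
    left = amp * np.sin(w0 * t + spec.tone_phase)
    right = amp * np.sin(w0 * (t - delay_s) + spec.tone_phase + spec.tone_ipd_rad)
    return WaveformPair(left, right)


@lru_cache(maxsize=8)
def _bandpass_sos(sample_rate_hz: int) -> np.ndarray:
    return butter(
        BUTTERWORTH_ORDER,
        NOISE_BAND_HZ,
        btype="bandpass",
        fs=sample_rate_hz,
        output="sos",
    )


def make_noise(spec: StimulusSpec) -> WaveformPair:
    """Masking noise token delayed across ears by an integer-sample ITD.

    Both ears receive the *same* frozen Gaussian token, band-pass filtered
    and scaled so the token's overall RMS sits at ``noise_level_db_spl``.
    Positive ITD delays the right ear.  Deterministic per ``spec.seed``.
    """
    d = _itd_to_samples(spec.noise_itd_us)
    max_d = _itd_to_samples(MAX_ITD_US)
    if abs(d) > max_d:
        raise ValueError(f"noise ITD {spec.noise_itd_us} us outside representable range")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples_per_ear
    raw = rng.standard_normal(_FILTER_WARMUP + n + 2 * max_d)
    token = sosfilt(_bandpass_sos(spec.sample_rate_hz), raw)[_FILTER_WARMUP:]
    token *= spl_to_rms(spec.noise_level_db_spl) / np.sqrt(np.mean(token**2))
    start = max_d
    left = token[start : start + n].copy()
    right = token[start - d : start - d + n].copy()
    if spec.noise_inverted:
        right = -right
    return WaveformPair(left, right)


def make_example(
    spec: StimulusSpec,
    ec_params: ECParams = ECParams(),
    psycho: PsychoParams = PsychoParams(),
) -> LabeledExample:
    """Tone+noise mixture with its EC ground-truth detection rate.

    The target depends on the spec only through the tone level and the
    *realized* (sample-quantized) interaural lags; monaural tone phase is
    an irrelevant stimulus property and does not enter the EC equations.
    """
    pair = make_tone(spec) + make_noise(spec)
    bmld = ec.bmld_db(spec.ec_lags(), ec_params)
    rate = float(ec.detection_rate(bmld, spec.tone_level_db_spl, psycho))
    return LabeledExample(pair.concat(), rate, spec)


def lab_condition_spec(
    condition: str,
    tone_level_db_spl: float = 35.0,
    seed: int = 0,
    tone_phase: float | None = None,
    n_samples_per_ear: int = N_SAMPLES_PER_EAR,
) -> StimulusSpec:
    """StimulusSpec for one of NoSo, NoSpi, NpiSpi, NpiSo."""
    if condition not in LAB_CONDITIONS:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {LAB_CONDITIONS}"
        )
    if tone_phase is None:
        tone_phase = float(
            np.random.default_rng(np.random.SeedSequence([seed, 7])).uniform(
                0, 2 * np.pi
            )
        )
    return StimulusSpec(
        tone_level_db_spl=tone_level_db_spl,
        tone_phase=tone_phase,
        seed=seed,
        tone_ipd_rad=np.pi if condition.endswith("Spi") else 0.0,
        noise_inverted=condition.startswith("Npi"),
        n_samples_per_ear=n_samples_per_ear,
    )


def make_lab_stimulus(
    condition: str,
    tone_level_db_spl: float = 35.0,
    seed: int = 0,
    tone_phase: float | None = None,
    n_samples_per_ear: int = N_SAMPLES_PER_EAR,
) -> WaveformPair:
    """One of the laboratory configurations NoSo, NoSpi, NpiSpi, NpiSo.

    ``o`` components are identical across ears; an ``Spi`` tone carries a
    carrier phase shift of pi (equivalently 1000 us at 500 Hz) and an
    ``Npi`` noise is a polarity-inverted copy in one ear (a true pi IPD at
    every frequency).  Tone phase is randomized per seed unless given.
    """
    spec = lab_condition_spec(
        condition, tone_level_db_spl, seed, tone_phase, n_samples_per_ear
    )
    return make_tone(spec) + make_noise(spec)


@dataclass
class LabDataset:
    """Training/validation arrays plus a manifest of the drawn parameters."""

    inputs: np.ndarray  # float32 [n, input_width]
    targets: np.ndarray  # float32 [n]
    manifest: dict
    n_train: int

    @property
    def train(self):
        return self.inputs[: self.n_train], self.targets[: self.n_train]

    @property
    def validation(self):
        return self.inputs[self.n_train :], self.targets[self.n_train :]


def make_dataset(
    n: int,
    seed: int,
    tone_level_range_db: tuple[float, float] = (0.0, 50.0),
    azimuth_range_deg: tuple[float, float] = (-90.0, 90.0),
    train_fraction: float = 0.95,
    ec_params: ECParams = ECParams(),
    psycho: PsychoParams = PsychoParams(),
    chunk: int = 4096,
) -> LabDataset:
    """Labeled waveform dataset for network training.

    Tone and noise azimuths are drawn independently and uniformly, tone
    level uniformly over ``tone_level_range_db``, tone phase uniformly over
    [0, 2pi).  Generation is vectorized (noise tokens are filtered in
    chunks) but statistically identical to stacking
    :func:`make_example` outputs; the whole dataset is reproducible from
    its single seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    az = rng.uniform(*azimuth_range_deg, size=(n, 2))
    levels = rng.uniform(*tone_level_range_db, size=n)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n)

    d_tone = _itd_to_samples(woodworth_itd(az[:, 0]))
    d_noise = _itd_to_samples(woodworth_itd(az[:, 1]))
    tau_s = d_tone * US_PER_SAMPLE * 1e-6
    tau_n = d_noise * US_PER_SAMPLE * 1e-6
    targets = ec.detection_rate(
        ec.bmld_db_array(tau_s, tau_n, ec_params), levels, psycho
    ).astype(np.float32)

    ns = N_SAMPLES_PER_EAR
    sr = SAMPLE_RATE_HZ
    max_d = int(np.max(np.abs(np.concatenate([d_tone, d_noise]))) or 1)
    t = np.arange(ns) / sr
    w0 = 2.0 * np.pi * 500.0
    sos = _bandpass_sos(sr)
    noise_rms = spl_to_rms(NOISE_LEVEL_DB_SPL)

    inputs = np.empty((n, 2 * ns), dtype=np.float32)
    idx = np.arange(ns)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m = hi - lo
        raw = rng.standard_normal((m, _FILTER_WARMUP + ns + 2 * max_d))
        tokens = sosfilt(sos, raw, axis=-1)[:, _FILTER_WARMUP:]
        tokens *= (
            noise_rms / np.sqrt(np.mean(tokens**2, axis=-1, keepdims=True))
        )
        rows = np.arange(m)[:, None]
        left_n = tokens[rows, max_d + idx]
        right_n = tokens[rows, max_d - d_noise[lo:hi, None] + idx]
        amp = (spl_to_rms(levels[lo:hi]) * np.sqrt(2.0))[:, None]
        ph = phases[lo:hi, None]
        delay = (d_tone[lo:hi] / sr)[:, None]
        left_t = amp * np.sin(w0 * t[None, :] + ph)
        right_t = amp * np.sin(w0 * (t[None, :] - delay) + ph)
        inputs[lo:hi, :ns] = left_n + left_t
        inputs[lo:hi, ns:] = right_n + right_t

    manifest = {
        "seed": seed,
        "n": n,
        "tone_azimuth_deg": az[:, 0],
        "noise_azimuth_deg": az[:, 1],
        "tone_level_db_spl": levels,
        "tone_phase_rad": phases,
        "tone_itd_us": d_tone * US_PER_SAMPLE,
        "noise_itd_us": d_noise * US_PER_SAMPLE,
    }
    return LabDataset(inputs, targets, manifest, n_train=int(round(n * train_fraction)))


def parametric_dataset(
    n: int,
    seed: int,
    arrival_range_us: tuple[float, float] = (0.0, 2000.0),
    train_fraction: float = 0.95,
    ec_params: ECParams = ECParams(),
) -> LabDataset:
    """Proof-of-principle dataset: four monaural arrival times -> BMLD.

    Inputs are the arrival times (us) of the tone and the noise at each
    ear, drawn uniformly; the target is the EC BMLD for the implied lags
    tau_s = tone_R - tone_L, tau_n = noise_R - noise_L.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    times = rng.uniform(*arrival_range_us, size=(n, 4))  # [sL, sR, nL, nR]
    tau_s = (times[:, 1] - times[:, 0]) * 1e-6
    tau_n = (times[:, 3] - times[:, 2]) * 1e-6
    targets = ec.bmld_db_array(tau_s, tau_n, ec_params).astype(np.float32)
    manifest = {"seed": seed, "n": n, "phi_us": (tau_s - tau_n) * 1e6}
    return LabDataset(
        times.astype(np.float32), targets, manifest, int(round(n * train_fraction))
    )


def save_dataset(ds: LabDataset, path) -> None:
    """NPZ writer: float32 inputs/targets plus the train split size."""
    np.savez(path, inputs=ds.inputs, targets=ds.targets, n_train=ds.n_train)


def load_dataset(path) -> LabDataset:
    with np.load(path) as z:
        return LabDataset(z["inputs"], z["targets"], {}, int(z["n_train"]))
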