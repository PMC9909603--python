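"""Equalization--cancelation (EC) psychophysics in closed form.

The EC framework models binaural unmasking as an internal two-stage
operation: the waveform at one ear is time-shifted to *equalize* the
masker's interaural delay and then subtracted (*canceled*) from the other
ear's waveform.  Internal amplitude jitter ``sigma_eps`` and time jitter
``sigma_delta`` limit how completely the masker can be canceled; they enter
through the factor

    k = (1 + sigma_eps**2) * exp((2*pi*f0)**2 * sigma_delta**2)  >= 1.

The binaural masking level difference (BMLD) predicted for a tone with
interaural lag ``tau_s`` masked by noise with lag ``tau_n`` is

    BMLD = 10*log10( max{ (k - cos(w0*phi)) / (k - gamma(tau_n - tau0)), 1 } )

where ``phi = tau_s - tau_n`` is the residual tone delay after
equalization, ``gamma`` is the normalized autocorrelation envelope of the
filtered masker and ``tau0`` the internal equalization delay.  Detection
rates follow from the BMLD through a fixed-slope psychometric function with
threshold defined at d' = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

__all__ = [
    "ECParams",
    "PsychoParams",
    "LagPair",
    "k_factor",
    "gamma_envelope",
    "bmld_db",
    "bmld_db_array",
    "solve_m0",
    "dprime",
    "detection_rate",
]

#: Reference sound pressure (Pa) for dB SPL.
P_REF_PA = 20e-6

#: Largest head-limited ITD represented in training stimuli, seconds.
HEAD_ITD_LIMIT_S = 655e-6


@dataclass(frozen=True)
class ECParams:
    """Parameters of the EC-model BMLD equation.

    Attributes
    ----------
    f0:
        Tone frequency in Hz.
    sigma_eps:
        Internal amplitude-jitter parameter (dimensionless, Durlach value
        0.25).
    sigma_delta:
        Internal time-jitter parameter in seconds (Durlach value 105 us).
    gamma_bandwidth:
        Bandwidth (Hz) of the triangular-gain filter whose output
        autocorrelation envelope defines ``gamma``; default 115 Hz, a
        critical bandwidth near 500 Hz.
    equalization_policy:
        ``"optimal"`` sets the internal delay tau0 equal to the noise lag
        (perfect equalization); ``"bounded"`` clips tau0 to the
        head-limited range of +-655 us.
    """

    f0: float = 500.0
    sigma_eps: float = 0.25
    sigma_delta: float = 105e-6
    gamma_bandwidth: float = 115.0
    equalization_policy: str = "optimal"

    def __post_init__(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if self.sigma_eps < 0 or self.sigma_delta < 0:
            raise ValueError("jitter parameters must be non-negative")
        if self.equalization_policy not in ("optimal", "bounded"):
            raise ValueError(
                f"unknown equalization policy {self.equalization_policy!r}"
            )

    @property
    def omega0(self) -> float:
        return 2.0 * np.pi * self.f0


@dataclass(frozen=True)
class PsychoParams:
    """Psychometric-scale parameters anchoring detection rate to dB SPL.

    ``m0`` is solved from the nominal diotic threshold: a tone at
    ``ref_threshold_db`` dB SPL in diotic noise (BMLD = 0) is detected at
    ``ref_rate`` (fraction), which pins d' near 1 there.
    """

    ref_threshold_db: float = 31.0
    ref_rate: float = 0.69
    m0: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.5 < self.ref_rate < 1.0:
            raise ValueError("ref_rate must lie strictly between 0.5 and 1")
        if self.m0 is None:
            object.__setattr__(
                self, "m0", solve_m0(self.ref_threshold_db, self.ref_rate)
            )
        if self.m0 <= 0:
            raise ValueError("m0 must be positive")


@dataclass(frozen=True)
class LagPair:
    """Interaural time lags (seconds) of signal and noise.

    Sign convention, package-wide: positive lag means the right ear
    receives the source later than the left.
    """

    tau_s: float
    tau_n: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.tau_s) and np.isfinite(self.tau_n)):
            raise ValueError("lags must be finite")

    @property
    def phi(self) -> float:
        """Residual tone delay after optimal equalization, tau_s - tau_n."""
        return self.tau_s - self.tau_n


def k_factor(params: ECParams = ECParams()) -> float:
    """Internal-jitter factor k = (1 + sigma_eps^2) exp(omega0^2 sigma_delta^2)."""
    w0 = params.omega0
    return (1.0 + params.sigma_eps**2) * np.exp((w0 * params.sigma_delta) ** 2)


def gamma_envelope(delta_tau, params: ECParams = ECParams()):
    """Normalized autocorrelation envelope of the filtered masker.

    A triangular power spectrum of bandwidth ``W`` has autocorrelation
    envelope sinc^2, so gamma(dt) = sinc(W*dt)^2 with numpy's normalized
    sinc.  gamma(0) = 1, symmetric, |gamma| <= 1.
    """
    return np.sinc(params.gamma_bandwidth * np.asarray(delta_tau)) ** 2


def _tau0(tau_n, params: ECParams):
    if params.equalization_policy == "optimal":
        return tau_n
    return np.clip(tau_n, -HEAD_ITD_LIMIT_S, HEAD_ITD_LIMIT_S)


def bmld_db(lags: LagPair, params: ECParams = ECParams()) -> float:
    """EC-predicted binaural masking level difference in dB (>= 0)."""
    return float(bmld_db_array(lags.tau_s, lags.tau_n, params))


def bmld_db_array(tau_s, tau_n, params: ECParams = ECParams()):
    """Vectorized :func:`bmld_db` over arrays of signal/noise lags (seconds)."""
    tau_s = np.asarray(tau_s, dtype=float)
    tau_n = np.asarray(tau_n, dtype=float)
    k = k_factor(params)
    numerator = k - np.cos(params.omega0 * (tau_s - tau_n))
    denominator = k - gamma_envelope(tau_n - _tau0(tau_n, params), params)
    if np.any(denominator <= 0):
        raise ValueError(
            "degenerate EC denominator: k - gamma(tau_n - tau0) <= 0 "
            f"(k={k:.6g})"
        )
    return 10.0 * np.log10(np.maximum(numerator / denominator, 1.0))


def solve_m0(ref_threshold_db: float = 31.0, ref_rate: float = 0.69) -> float:
    """Solve the psychometric scale constant from the diotic anchor.

    Inverts ``detection_rate`` at BMLD = 0 and tone level
    ``ref_threshold_db``:  m0 = 2 * PhiInv(ref_rate) / 10^{0.1*(a - 23)}.
    """
    if not 0.5 < ref_rate < 1.0:
        raise ValueError("ref_rate must lie strictly between 0.5 and 1")
    return float(2.0 * norm.ppf(ref_rate) / 10.0 ** (0.1 * (ref_threshold_db - 23.0)))


def dprime(bmld: float, a: float, psycho: PsychoParams = PsychoParams()):
    """Sensitivity index d' = m0 * 10^{0.1*(BMLD + a - 23)}.

    ``a`` is the tone level in dB SPL; increasing either argument by 10 dB
    multiplies d' by 10.
    """
    return psycho.m0 * 10.0 ** (0.1 * (np.asarray(bmld) + np.asarray(a) - 23.0))


def detection_rate(bmld, a, psycho: PsychoParams = PsychoParams()):
    """Detection rate in percent: 100 * Phi(d'/2), bounded in [50, 100)."""
    return 100.0 * norm.cdf(dprime(bmld, a, psycho) / 2.0)
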