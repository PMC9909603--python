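"""Probing trained networks: psychophysics, ITD tuning, latent dynamics.

This module contains everything done *to* a trained network:

* psychometric regression of predicted detection rates over tone level and
  the BMLDs derived from the fitted thresholds (d' = 1 points);
* noise-delay functions -- a node's mean activation versus the ITD of a
  noise-only stimulus -- and their Gabor fits, whose central peak defines
  the node's best ITD;
* population delay profiles (activation of all layer nodes ordered by best
  ITD) and their Pearson comparison with the reference cross-correlator;
* the dynamics of operational latent nodes across the laboratory
  homophasic/antiphasic stimulus pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps
from scipy.optimize import curve_fit
from scipy.stats import norm

from binauralnet import autoencoder as ae
from binauralnet import stimuli
from binauralnet.crosscorr import DelayProfile

__all__ = [
    "PsychometricFit",
    "NoiseDelayFunction",
    "GaborFit",
    "LatentDynamicsReport",
    "psychometric_curve",
    "fit_psychometric",
    "compute_bmld",
    "predict_rate_curve",
    "noise_delay_function",
    "noise_delay_functions",
    "gabor",
    "fit_gabor",
    "population_delay_profile",
    "compare_to_crosscorr",
    "latent_dynamics",
    "residualize_node",
    "min_rmse_curve",
]

DEFAULT_LEVELS_DB = np.arange(0.0, 50.0 + 1e-9, 2.5)
NOISE_DELAY_GRID_US = np.arange(-2000.0, 2000.0 + 1, 100.0)


# ----------------------------------------------------------- psychometrics


def psychometric_curve(levels_db, threshold_db):
    """Fixed-slope psychometric function: rate = 100*Phi(10^{0.1(a-theta)}/2).

    ``threshold_db`` is the tone level at which d' = 1; the slope is fixed
    by the detection-rate equation, leaving the horizontal position as the
    only free parameter.
    """
    dprime = 10.0 ** (0.1 * (np.asarray(levels_db) - threshold_db))
    return 100.0 * norm.cdf(dprime / 2.0)


@dataclass(frozen=True)
class PsychometricFit:
    threshold_db_spl: float
    rss: float
    levels_db: np.ndarray
    mean_rates: np.ndarray
    reliable: bool = True


def fit_psychometric(levels_db, mean_rates) -> PsychometricFit:
    """Least-squares fit of the one-parameter psychometric curve.

    The fit is flagged unreliable when the rates barely rise above the 50%
    floor (threshold beyond the sampled levels) -- the threshold is then an
    extrapolation.
    """
    levels_db = np.asarray(levels_db, dtype=float)
    mean_rates = np.asarray(mean_rates, dtype=float)
    if len(levels_db) < 3:
        raise ValueError("need at least 3 level points")
    grid = np.linspace(levels_db.min() - 20.0, levels_db.max() + 20.0, 121)
    rss_grid = [
        np.sum((psychometric_curve(levels_db, th) - mean_rates) ** 2) for th in grid
    ]
    th0 = grid[int(np.argmin(rss_grid))]
    (theta,), _ = curve_fit(
        psychometric_curve, levels_db, mean_rates, p0=[th0], maxfev=10_000
    )
    rss = float(np.sum((psychometric_curve(levels_db, theta) - mean_rates) ** 2))
    reliable = bool(np.max(mean_rates) > 55.0 and theta < levels_db.max())
    return PsychometricFit(float(theta), rss, levels_db, mean_rates, reliable)


def compute_bmld(ref: PsychometricFit, cond: PsychometricFit) -> float:
    """BMLD in dB: reference (co-located/homophasic) threshold minus condition's."""
    if not (ref.reliable and cond.reliable):
        warnings.warn("BMLD computed from an unreliable psychometric fit")
    return ref.threshold_db_spl - cond.threshold_db_spl


def predict_rate_curve(
    net: ae.ModifiedAutoencoder,
    spec: stimuli.StimulusSpec,
    levels_db=DEFAULT_LEVELS_DB,
    n_repeats: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Mean predicted rate at each tone level for a fixed interaural geometry."""
    return np.array(
        [
            ae.predict_rate(
                net,
                replace(spec, tone_level_db_spl=float(a)),
                n_repeats=n_repeats,
                seed=seed + i,
            )
            for i, a in enumerate(np.asarray(levels_db, dtype=float))
        ]
    )


# -------------------------------------------------------------- ITD tuning


@dataclass(frozen=True)
class NoiseDelayFunction:
    """Mean node activation versus noise ITD (noise-only stimuli)."""

    itds_us: np.ndarray
    activation: np.ndarray
    node: int
    layer: int


def _noise_only_batch(itd_us: float, n_reps: int, seed: int, n_samples: int):
    seeds = np.random.default_rng(np.random.SeedSequence([seed, 31])).integers(
        0, 2**31 - 1, size=n_reps
    )
    return np.stack(
        [
            stimuli.make_noise(
                stimuli.StimulusSpec(
                    noise_itd_us=itd_us, seed=int(s), n_samples_per_ear=n_samples
                )
            ).concat()
            for s in seeds
        ]
    )


def noise_delay_functions(
    net: ae.ModifiedAutoencoder,
    layer: int,
    n_reps: int = 50,
    seed: int = 0,
    itds_us=NOISE_DELAY_GRID_US,
) -> list[NoiseDelayFunction]:
    """Noise-delay functions for every node of an encoder layer.

    ``layer`` is 0-based over encoder ELU layers; ``layer ==
    n_encoder_layers`` probes the latent means.  The same noise seeds are
    reused at every grid ITD so the curves differ only through the delay.
    ITDs beyond the +-655 us training range deliberately probe
    extrapolation.
    """
    n_samples = net.config.input_width // 2
    itds_us = np.asarray(itds_us, dtype=float)
    acts = []
    for itd in itds_us:
        batch = _noise_only_batch(float(itd), n_reps, seed, n_samples)
        acts.append(net.encoder_activations(batch, layer).mean(axis=0))
    acts = np.asarray(acts)  # [n_itd, n_nodes]
    return [
        NoiseDelayFunction(itds_us.copy(), acts[:, j], node=j, layer=layer)
        for j in range(acts.shape[1])
    ]


def noise_delay_function(
    net: ae.ModifiedAutoencoder,
    layer: int,
    node: int,
    n_reps: int = 50,
    seed: int = 0,
    itds_us=NOISE_DELAY_GRID_US,
) -> NoiseDelayFunction:
    ndfs = noise_delay_functions(net, layer, n_reps, seed, itds_us)
    if not 0 <= node < len(ndfs):
        raise ValueError(f"node {node} out of range for layer {layer}")
    return ndfs[node]


def gabor(itd_us, A, b_itd_us, s_us, F_hz, C):
    """Gabor tuning curve: Gaussian-windowed cosine of the noise ITD."""
    itd_us = np.asarray(itd_us, dtype=float)
    return (
        A
        * np.exp(-((itd_us - b_itd_us) ** 2) / (2.0 * s_us**2))
        * np.cos(2.0 * np.pi * F_hz * 1e-6 * (itd_us - b_itd_us))
        + C
    )


@dataclass(frozen=True)
class GaborFit:
    A: float
    b_itd_us: float
    s_us: float
    F_hz: float
    C: float
    r_squared: float
    f_test_p: float
    best_itd_us: float  # most central tuning peak of the fitted Gabor
    converged: bool = True


def _central_peak(A, b, s, F, lo=-2000.0, hi=2000.0) -> float:
    """Local maximum of the Gabor nearest 0 us within one Gaussian s of b.

    Ties (symmetric peaks) break toward negative delay.
    """
    t = np.linspace(lo, hi, 4001)
    g = gabor(t, A, b, s, F, 0.0)
    interior = np.flatnonzero((g[1:-1] >= g[:-2]) & (g[1:-1] >= g[2:])) + 1
    peaks = t[interior]
    windowed = peaks[np.abs(peaks - b) <= s]
    if len(windowed) == 0:
        windowed = peaks if len(peaks) else np.array([b])
    dist = np.abs(windowed)
    best = windowed[dist == dist.min()]
    return float(best.min())  # toward negative delay on ties


def fit_gabor(
    ndf: NoiseDelayFunction,
    f_grid_hz=(250.0, 400.0, 500.0, 650.0, 800.0),
    b_step_us: float = 200.0,
) -> GaborFit:
    """Multi-start nonlinear least-squares Gabor fit plus F-test vs linear.

    The scale A is constrained positive.  The F-test compares the 5-param
    Gabor against a 2-param linear regression on ITD; a small p-value
    means the tuning structure is real rather than a trend.
    """
    x, y = ndf.itds_us, ndf.activation
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 grid points")
    yr = float(np.ptp(y))
    span = float(x.max() - x.min())
    # linear benchmark
    lin = np.polyfit(x, y, 1)
    rss_lin = float(np.sum((np.polyval(lin, x) - y) ** 2))
    if yr == 0.0:  # flat node: nothing to fit
        return GaborFit(0.0, 0.0, span, 0.0, float(y[0]), 0.0, 1.0, 0.0, False)

    best, best_rss = None, np.inf
    tss0 = float(np.sum((y - np.mean(y)) ** 2))
    b_grid = np.arange(x.min(), x.max() + 1e-9, b_step_us)
    bounds = (
        [0.0, x.min() - span, 10.0, 1.0, -np.inf],
        [np.inf, x.max() + span, 10.0 * span, 5000.0, np.inf],
    )
    for F0 in f_grid_hz:
        for b0 in b_grid:
            p0 = [yr / 2.0, b0, span / 2.0, F0, float(np.mean(y))]
            try:
                popt, _ = curve_fit(
                    gabor, x, y, p0=p0, bounds=bounds,
                    maxfev=300, xtol=1e-6, ftol=1e-6,
                )
            except RuntimeError:
                continue
            rss = float(np.sum((gabor(x, *popt) - y) ** 2))
            if rss < best_rss:
                best, best_rss = popt, rss
        if best_rss < 1e-6 * tss0:  # already an essentially perfect fit
            break
    if best is None:
        return GaborFit(
            np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, 1.0, np.nan, False
        )
    A, b, s, F, C = (float(v) for v in best)
    tss = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - best_rss / tss if tss > 0 else 0.0
    # F-test: nested in the sense of model complexity (2 vs 5 params)
    df1, df2 = 3, n - 5
    if best_rss <= 0:
        p_val = 0.0
    else:
        f_stat = ((rss_lin - best_rss) / df1) / (best_rss / df2)
        p_val = float(sps.f.sf(max(f_stat, 0.0), df1, df2))
    return GaborFit(A, b, s, F, C, r2, p_val, _central_peak(A, b, s, F))


# ------------------------------------------------- population delay profiles


def population_delay_profile(
    net: ae.ModifiedAutoencoder,
    layer: int,
    condition: str,
    gabor_fits: list[GaborFit],
    tone_level_db_spl: float = 35.0,
    n_reps: int = 50,
    seed: int = 0,
    significant_only: bool = True,
) -> DelayProfile:
    """Mean node activations for a lab condition, ordered by best ITD.

    Only nodes whose Gabor fit beat the linear model (p < 0.05) carry a
    meaningful best ITD; others are dropped unless ``significant_only`` is
    False.
    """
    n_samples = net.config.input_width // 2
    rng = np.random.default_rng(np.random.SeedSequence([seed, 37]))
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_reps)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_reps)
    batch = []
    for rs, ph in zip(rep_seeds, phases):
        spec = stimuli.lab_condition_spec(
            condition, tone_level_db_spl, int(rs), float(ph), n_samples
        )
        batch.append((stimuli.make_tone(spec) + stimuli.make_noise(spec)).concat())
    acts = net.encoder_activations(np.stack(batch), layer).mean(axis=0)
    keep = [
        j
        for j, g in enumerate(gabor_fits)
        if g.converged and (not significant_only or g.f_test_p < 0.05)
    ]
    b_itds = np.array([gabor_fits[j].best_itd_us for j in keep])
    order = np.argsort(b_itds, kind="stable")
    return DelayProfile(b_itds[order], acts[keep][order], condition)


def smooth_by_delay(profile: DelayProfile, window_us: float = 600.0) -> DelayProfile:
    """Moving average over the delay axis with a +-window/2 box."""
    d, v = profile.delays_us, profile.values
    sm = np.array(
        [np.mean(v[np.abs(d - di) <= window_us / 2.0]) for di in d]
    )
    return DelayProfile(d.copy(), sm, profile.condition)


def compare_to_crosscorr(
    profiles: dict[str, DelayProfile],
    crosscorr_profiles: dict[str, DelayProfile],
    smooth_us: float = 600.0,
) -> dict[str, float]:
    """Pearson r between network and cross-correlator profiles.

    Profiles for each condition are matched by nearest delay (each node's
    best ITD to the nearest cross-correlator internal delay), concatenated
    across conditions, and correlated twice: once after local averaging of
    both profiles within ``smooth_us`` and once raw.
    """
    net_vals, ref_vals, net_sm, ref_sm = [], [], [], []
    for cond, prof in profiles.items():
        ref = crosscorr_profiles[cond]
        idx = np.abs(ref.delays_us[None, :] - prof.delays_us[:, None]).argmin(axis=1)
        net_vals.append(prof.values)
        ref_vals.append(ref.values[idx])
        sm_p = smooth_by_delay(prof, smooth_us)
        sm_r = smooth_by_delay(ref, smooth_us)
        net_sm.append(sm_p.values)
        ref_sm.append(sm_r.values[idx])
    a, b = np.concatenate(net_vals), np.concatenate(ref_vals)
    if len(a) < 3:
        raise ValueError("need at least 3 matched points")
    r_raw = float(sps.pearsonr(a, b).statistic)
    r_smooth = float(
        sps.pearsonr(np.concatenate(net_sm), np.concatenate(ref_sm)).statistic
    )
    return {"r_smoothed": r_smooth, "r_raw": r_raw}


# ------------------------------------------------------------ latent dynamics


@dataclass(frozen=True)
class LatentDynamicsReport:
    """Per-operational-node activation changes for the two lab transitions.

    ``delta_no`` is the mean activation change NoSo -> NoSpi and
    ``delta_npi`` the change NpiSpi -> NpiSo; under a cross-correlation
    mechanism the two transitions move node activations in *opposite*
    directions even though detection improves in both.
    """

    nodes: np.ndarray
    delta_no: np.ndarray
    delta_npi: np.ndarray
    t_p_no: np.ndarray
    t_p_npi: np.ndarray
    ks_d: np.ndarray
    ks_p: np.ndarray
    sign_opposed: np.ndarray


def _condition_batch(net, condition, tone_level, n_trials, seed):
    n_samples = net.config.input_width // 2
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_trials)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
    batch = []
    for rs, ph in zip(rep_seeds, phases):
        spec = stimuli.lab_condition_spec(
            condition, tone_level, int(rs), float(ph), n_samples
        )
        batch.append((stimuli.make_tone(spec) + stimuli.make_noise(spec)).concat())
    return np.stack(batch)


def latent_dynamics(
    net: ae.ModifiedAutoencoder,
    tone_level_db_spl: float = 35.0,
    n_trials: int = 200,
    seed: int = 0,
) -> LatentDynamicsReport:
    """Activation changes of operational latent nodes across lab pairs.

    Welch two-sided t-tests compare the per-trial activations of the two
    members of each pair; the two-sample KS test compares the
    *distributions of changes* between pairs (NoSo->NoSpi vs
    NpiSpi->NpiSo deltas across matched trials).  Operational nodes are
    determined by the exact KL criterion on the pooled probe stimuli.
    """
    batches = {
        c: _condition_batch(net, c, tone_level_db_spl, n_trials, seed + i)
        for i, c in enumerate(stimuli.LAB_CONDITIONS)
    }
    lat = {c: net.encode(b)[0] for c, b in batches.items()}
    ops = ae.operational_nodes(net, np.vstack(list(batches.values())))
    d1 = lat["NoSpi"][:, ops] - lat["NoSo"][:, ops]
    d2 = lat["NpiSo"][:, ops] - lat["NpiSpi"][:, ops]
    t_p_no = np.array(
        [
            sps.ttest_ind(lat["NoSo"][:, j], lat["NoSpi"][:, j], equal_var=False).pvalue
            for j in ops
        ]
    )
    t_p_npi = np.array(
        [
            sps.ttest_ind(
                lat["NpiSpi"][:, j], lat["NpiSo"][:, j], equal_var=False
            ).pvalue
            for j in ops
        ]
    )
    ks = [sps.ks_2samp(d1[:, i], d2[:, i]) for i in range(len(ops))]
    delta_no = d1.mean(axis=0)
    delta_npi = d2.mean(axis=0)
    return LatentDynamicsReport(
        nodes=ops,
        delta_no=delta_no,
        delta_npi=delta_npi,
        t_p_no=t_p_no,
        t_p_npi=t_p_npi,
        ks_d=np.array([k.statistic for k in ks]),
        ks_p=np.array([k.pvalue for k in ks]),
        sign_opposed=delta_no * delta_npi < 0,
    )


def residualize_node(node_activations, other_node_activations):
    """Residual of a node after linear regression on the other nodes.

    Returns ``(residuals, variance_explained)``; rank deficiency is
    handled by the least-norm solution of ``lstsq``.
    """
    y = np.asarray(node_activations, dtype=float)
    X = np.atleast_2d(np.asarray(other_node_activations, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    Xc = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ coef
    tot = np.sum((y - y.mean()) ** 2)
    var_explained = 1.0 - np.sum(resid**2) / tot if tot > 0 else 0.0
    return resid, float(var_explained)


def min_rmse_curve(report) -> tuple[np.ndarray, np.ndarray, float]:
    """Minimum validation RMSE per beta and the global optimum.

    Mirrors the grid-selection envelope: returns (betas, min_rmse,
    best_beta) with betas sorted ascending.
    """
    env = ae.min_rmse_per_beta(report)
    betas = np.array(sorted(env))
    curve = np.array([env[b] for b in betas])
    best_beta = betas[int(np.argmin(curve))]
    return betas, curve, float(best_beta)
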