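# Methods

This note documents the models, conventions and design choices of
`binauralnet`, in the spirit of a model-description appendix. Everything
quantitative stated here is computed by the package's tests or scripts;
nothing is asserted from memory of external data.

## EC psychophysics (`binauralnet.ec`)

The closed-form BMLD is

    BMLD(τS, τN) = 10 log10 max{ (k − cos ω0 φ) / (k − γ(τN − τ0)), 1 },
    k = (1 + σε²) · exp(ω0² σδ²),   φ = τS − τN,

with defaults f0 = 500 Hz, σε = 0.25, σδ = 105 μs. Two readings of the
jitter parameters are possible from the way they are usually quoted
("σε² = 0.25, σδ² = 105 μs"); the μs unit shows the time jitter is quoted
unsquared, and only the unsquared pair reproduces the canonical 10.7 dB
antiphasic-tone BMLD, so both are implemented unsquared.

γ is the normalized autocorrelation envelope of noise filtered by a
triangular-gain filter: γ(Δτ) = sinc²(W·Δτ) with W configurable
(default 115 Hz, a critical bandwidth near 500 Hz). Under the default
optimal-equalization policy τ0 = τN, the denominator is always k − 1 and
γ never matters; a bounded policy clipping τ0 to ±655 μs is provided for
constrained-equalization studies. The bounded policy does **not**
reproduce the sometimes-quoted 10.3 dB for the NπSπ/NπSo pair — under
ideal equalization that pair has exactly the same 10.7 dB prediction as
NoSo/NoSπ, and no documented τ0 constraint or γ bandwidth is available
that yields 10.3 — so no such claim is encoded in tests.

Detection rate is 100·Φ(d′/2) with d′ = m0·10^{0.1(BMLD + a − 23)}. The
scale constant m0 = 2Φ⁻¹(0.69)/10^{0.8} ≈ 0.15717 is stored at full
precision; the threshold definition (d′ = 1) and the 69%-at-31-dB anchor
are mutually consistent by construction. The divide-by-two inside Φ is
fixed by that anchor.

## Stimuli (`binauralnet.stimuli`)

Waveforms are in pascals with RMS = 20 μPa·10^{L/20} at L dB SPL; the
reference is arbitrary for the networks (they see consistent scales) but
pascals keep levels auditable. A trial is 400 samples per ear at 20 kHz
(10 periods of the 500 Hz tone), tone level uniform 0–50 dB SPL, tone
phase uniform, masker 60 dB SPL Gaussian noise band-passed 50–5000 Hz by
a 6th-order Butterworth (the −3 dB skirts leave ≈3–4% of power outside
the nominal band; the test suite checks the measured fraction against
the filter's analytic magnitude response).

ITDs are realized as integer-sample delays (1 sample = 50 μs) of a
single source token: the noise token is generated longer than the trial
and both ears are cropped from it at an offset, so no wrap-around occurs;
the pure tone's shift is applied analytically as a carrier phase offset
(exact, and identical to a sample shift for a pure tone). Azimuth maps
to ITD through Woodworth's spherical head, ITD = r(θ + sin θ)/c with
r = 0.0875 m, c = 343 m/s (655 μs at ±90°); quantization to the sample
grid gives an effective azimuthal resolution of ≈5.6°–10.3°.

Sign convention, package wide: positive ITD ⇔ the right-ear channel is
the source delayed by the ITD (right lags left). Laboratory conditions:
an Sπ tone is a carrier phase shift of π (≡1000 μs at 500 Hz); an Nπ
noise is a polarity inversion of one ear (a true π IPD at all
frequencies, the standard laboratory manipulation) — in the EC equations
it enters as a half-period noise lag. Ground-truth targets use only the
realized (quantized) interaural lags and the tone level; monaural tone
phase is irrelevant to the EC equations and is excluded deliberately.
Tone and noise are gated simultaneously with rectangular gating (no
onset ramps — gating is unstated in the protocol this emulates, and
rectangular is the simplest consistent choice).

Noise tokens are normalized per token (each token's RMS is set to the
nominal masker level over the generation window, shared by both ears),
so the masker carries no trial-to-trial level cue.

Dataset generation is vectorized (noise filtered in chunks, tones
analytic) but statistically identical to stacking single-trial calls;
the whole dataset derives from one seed. What the generator does *not*
emulate: head-related filtering (ILDs, spectral cues), reverberation,
onset asynchronies, and ITDs beyond ±2000 μs. Passing tests therefore
speak to the idealized dichotic laboratory situation, not to free-field
listening.

## The modified autoencoder (`binauralnet.autoencoder`)

Architecture: fully connected ELU layers (encoder), a central layer of
Gaussian nodes with linear heads for per-node mean and log-variance
(σ = exp(½ log σ²) > 0 by construction), reparameterized sampling
z = μ + σε during training, mirrored ELU decoder, single linear output.
Readout (all interpretation code) uses ε = 0, the deterministic mode;
training history records validation RMSE in that mode.

The cost is the squared reconstruction error plus the β-weighted
bottleneck penalty −(β/2)Σᵢ(log σᵢ² − μᵢ² − σᵢ²), the Gaussian KL to the
unit normal up to an additive β·n_latent/2. Training uses Adam
(lr 5·10⁻⁴, batch 256), weights Glorot-uniform from the run seed, and is
bitwise reproducible per config. Gradients are hand-derived and checked
against numerical differentiation in the tests.

Numerical choices:

* `sigma_init` (default 0.1): the log-variance head bias starts at
  2·ln(0.1). Starting σ near 1 makes early latent samples pure noise and
  reliably triggers posterior collapse (the decoder learns to ignore the
  bottleneck before the encoder transmits anything); a small initial σ
  avoids the trap while the β penalty remains free to push unused nodes
  back to σ = 1.
* Fixed affine input/target normalization (never per-batch, which would
  leak level information): waveforms are divided by the nominal masker
  RMS (0.02 Pa); parametric arrival times by 1000 μs; detection-rate
  targets map [50, 100)% to [0, 1); BMLD targets are divided by 10.
  The constants are part of the model archive.
* log σ² is clipped to ±30 before exponentiation to keep early training
  finite; the clip is inactive after the first epochs.
* Early stopping (optional `patience`) monitors validation RMSE and
  restores the best-epoch weights; the published protocol's fixed
  1000-epoch budget is the default upper bound.

A latent node is *operational* when its mean KL from the unit Gaussian
over a stimulus probe exceeds 0.1 bits; grid selection over β and seeds
minimizes deterministic-readout validation RMSE, breaking exact ties
toward the lower β, then the lower seed.

Adam on this cost has a prominent bad local optimum for the
proof-of-principle configuration — both latent nodes converge onto the
*signed* variable φ, leaving the decoder unable to form the even BMLD
surface and stalling validation RMSE near 0.8 dB — which catches a
sizable fraction of weight-initialization seeds. The proof-of-principle
runner therefore trains a small number of restarts (`pop_restarts`,
default 3) on the same data and keeps the best network by validation
RMSE, the same global-minimum selection rationale the β-grid applies to
the waveform study.

## Interpretation (`binauralnet.interpretation`)

The psychometric fit has exactly one free parameter, the horizontal
threshold shift θ in rate = 100·Φ(10^{0.1(a−θ)}/2); the slope is owned
by the detection-rate equation, which makes the d′ = 1 threshold
well-defined and the fit robust at 21 level points. Fits with rates
pinned near the 50% floor are flagged unreliable (the threshold is then
an extrapolation). BMLDs are differences of fitted thresholds against
the co-located (azimuth sweeps) or homophasic (lab pairs) reference.

Noise-delay functions probe each node's mean activation (post-ELU for
hidden nodes, μ for latent nodes) over noise-only stimuli at ITDs
−2000…2000 μs in 100 μs steps, reusing the same noise seeds at every
ITD. Gabor fits G = A·exp(−(ITD−b)²/2s²)·cos(2πF(ITD−b)) + C use
bounded nonlinear least squares with a multi-start grid
(F ∈ {250, 400, 500, 650, 800} Hz × b in 200 μs steps; best RSS wins,
with an early exit once a start is essentially perfect). Significance
of tuning is an F-test of the 5-parameter Gabor against a 2-parameter
linear trend; per-node p-values are reported uncorrected (raw counts
are the quantity of interest), with Benjamini–Hochberg available but
off by default. A node's best ITD is the local maximum of the fitted
Gabor nearest 0 μs within ±1 Gaussian s of b (ties toward negative
delay) — the "most central peak" rule for cyclic tuning curves.

Population profiles order nodes by best ITD and can be smoothed by a
600 μs moving average along the best-ITD axis; comparison with the
cross-correlator matches each node to the nearest internal delay and
reports Pearson r both raw and smoothed (both series smoothed with the
same window). Latent dynamics compare per-trial node activations across
NoSo→NoSπ and NπSπ→NπSo (Welch t-tests, two-sample KS on the deltas)
and flag sign opposition Δ₁·Δ₂ < 0 per node; covariation with other
central nodes can be removed by ordinary linear regression
(`residualize_node`).

## Cross-correlator reference (`binauralnet.crosscorr`)

Fixed, never fitted: 4th-order gammatone at 500 Hz (ERB bandwidth),
half-wave rectification followed by power-law compression (exponent
0.23; a rectify-and-square variant is available — the qualitative
profile pattern is robust to this choice and the variant is recorded in
output metadata), then summed cross-products over internal delays with
truncation to the valid overlap and normalization by overlap length
(no wrap-around). 1-s stimuli at 20 kHz. Positive internal delay
advances the right ear, so a right-ear lag of x μs peaks at +x μs.

## Scales and problem sizes

The `paper` preset mirrors the published protocol (10⁶ waveform
instances, 6 β × 10 seeds, 1000 epochs; 10⁵ parametric instances). At
~4 ms per optimizer step for the waveform architecture in this numpy
implementation, one paper-scale network is ≈5 CPU-hours and the full
grid ≈2 CPU-weeks, so the waveform study's published numbers are not
recomputed here. The `desk` preset — used by the test suite — reduces
the waveform study to 60k instances, β ∈ {0, 10⁻⁵, 10⁻³} × 1 seed and
120 epochs, with probe counts scaled accordingly.

What desk scale does and does not show: the optimization of the
waveform networks is step-limited — the essential features (band
energies and interaural cross-products) are quadratic in the inputs,
which near-linear ELU stacks acquire slowly. A desk-scale network
(~10⁵ steps vs ~4·10⁶ at paper scale) reaches a prediction–target
correlation of only ≈0.2, while a linear regression on hand-built
500 Hz quadrature features reaches ≈0.47 on the same data — the
information is present; the network has not yet extracted it. The
encoder-side signatures emerge early and are exercised by the tests
(widespread significant layer-2 ITD tuning, positive smoothed
similarity to the cross-correlator that grows with training), whereas
quantities that require accurate detection-rate prediction (lab-pair
BMLDs from psychometric fits, latent sign opposition, the No-peak/
Nπ-trough contrast) are dominated by fit noise at this scale and are
not reliably reproduced; the corresponding study-level checks document
this rather than relax their thresholds.

## Known limitations

* The proof-of-principle network in this implementation consistently
  converges to a *two*-node latent code — one node linear in φ
  (|Pearson R| ≈ 0.92–0.996 depending on run length and seed) and one
  encoding an even companion (≈|φ|) —
  rather than a single operational node with its twin fully suppressed.
  The two-node code reconstructs slightly better than the one-node code
  and is stable across seeds, initial σ, input/target scalings and
  2000-epoch training; with the β penalty read per-example as written,
  the pruning pressure at β = 10⁻⁵ is orders of magnitude below the
  reconstruction term. See the bottleneck discussion above.
* Predictions concern the average listener; individual differences are
  out of scope, as are ILDs, frequencies other than the configured f0,
  and dynamically varying ("sluggish") stimuli.
* The transduction stage of the cross-correlator is a generic
  rectify-compress model; similarity numbers depend quantitatively (not
  qualitatively) on that choice.
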