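"""The modified autoencoder: ELU encoder, Gaussian bottleneck, ELU decoder.

The network maps a stimulus vector ``x`` through fully connected ELU
layers to a central layer of ``n_latent`` Gaussian nodes.  Two linear
heads emit per-node means ``mu_i`` and log-variances; a latent sample is
``z_i = mu_i + sigma_i * eps`` with ``eps ~ N(0, 1)``.  The decoder maps
the sampled latents through mirrored ELU layers to a single linear output
(predicted detection rate in percent, or predicted BMLD in dB for the
parameter-based configuration).  Training minimizes

    C_beta = ||x_hat - y||_2^2  -  (beta/2) * sum_i [log sigma_i^2 - mu_i^2 - sigma_i^2]

averaged over the batch, with Adam.  The beta term is the standard
Gaussian KL penalty up to an additive constant: it drives latent nodes
that the decoder does not use toward the unit Gaussian (mu = 0, sigma = 1),
"suppressing" them, so that an intermediate beta yields a small set of
operational, interpretable latent variables.

Everything here is plain numpy: forward pass, analytic backward pass
(verified against numerical differentiation in the test suite), and the
Adam update.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np

__all__ = [
    "NetworkConfig",
    "ModifiedAutoencoder",
    "TrainingHistory",
    "TrainingDiverged",
    "elu",
    "sample_latent",
    "cost",
    "train",
    "kl_bits_per_node",
    "operational_nodes",
    "beta_grid_train_and_select",
    "save_model",
    "load_model",
]

LN2 = float(np.log(2.0))

#: KL threshold (bits) above which a latent node counts as operational.
OPERATIONAL_KL_BITS = 0.1


class TrainingDiverged(RuntimeError):
    """Raised when the training cost becomes non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"training cost became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture plus training hyperparameters; fully determines a run.

    ``input_offset``/``input_scale`` define a *fixed* affine normalization
    of the raw inputs (e.g. dividing waveforms by the nominal masker RMS
    in pascals).  Using constants rather than per-batch statistics keeps
    level information in the inputs.
    """

    input_width: int
    encoder_layers: tuple[int, ...] = (100, 100)
    n_latent: int = 10
    decoder_layers: tuple[int, ...] | None = None  # mirror of encoder if None
    beta: float = 1e-5
    lr: float = 5e-4
    batch_size: int = 256
    epochs: int = 1000
    seed: int = 0
    input_offset: float = 0.0
    input_scale: float = 1.0
    target_offset: float = 0.0
    target_scale: float = 1.0
    dtype: str = "float32"
    init: str = "glorot_uniform"
    #: initial per-node sigma (via the log-variance head bias).  Starting
    #: well below 1 keeps early latent samples nearly deterministic, which
    #: avoids the posterior-collapse trap where the decoder learns to
    #: ignore the bottleneck before the encoder carries any information.
    sigma_init: float = 0.1
    patience: int | None = None  # epochs of no val improvement before stopping

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if min(self.encoder_layers) < 1 or self.n_latent < 1:
            raise ValueError("all layer widths must be >= 1")
        if self.decoder_layers is None:
            object.__setattr__(self, "decoder_layers", self.encoder_layers[::-1])
        object.__setattr__(self, "encoder_layers", tuple(self.encoder_layers))
        object.__setattr__(self, "decoder_layers", tuple(self.decoder_layers))


@dataclass
class TrainingHistory:
    train_cost: list = field(default_factory=list)
    val_rmse: list = field(default_factory=list)
    stopped_epoch: int | None = None


def elu(z):
    """Exponential linear unit: z for z >= 0, exp(z) - 1 otherwise."""
    z = np.asarray(z)
    return np.where(z >= 0, z, np.expm1(np.minimum(z, 0.0)))


def _elu_grad_from_output(a):
    # For z < 0 the output is exp(z) - 1, so d/dz = exp(z) = a + 1.
    return np.where(a >= 0, 1.0, a + 1.0)


def sample_latent(mu, sigma, eps):
    """Reparameterized latent sample z = mu + sigma * eps."""
    return np.asarray(mu) + np.asarray(sigma) * np.asarray(eps)


def cost(x_hat, y, mu, sigma, beta):
    """Per-batch mean of the beta-weighted cost.

    Squared reconstruction error minus (beta/2) * sum_i [log sigma_i^2 -
    mu_i^2 - sigma_i^2].  With beta = 0 this is the mean squared error;
    the penalty's minimum over (mu, sigma) is beta * n_latent / 2 at
    mu = 0, sigma = 1.
    """
    sigma = np.asarray(sigma)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be strictly positive")
    err = np.mean((np.asarray(x_hat) - np.asarray(y)) ** 2)
    mu = np.atleast_2d(mu)
    sigma = np.atleast_2d(sigma)
    penalty = -0.5 * beta * np.mean(
        np.sum(np.log(sigma**2) - mu**2 - sigma**2, axis=-1)
    )
    return float(err + penalty)


class ModifiedAutoencoder:
    """Weights and forward/backward machinery for one network.

    Parameters are stored in ``self.params`` (dict of numpy arrays).
    The forward pass with ``eps = 0`` is deterministic and is the readout
    mode used by all interpretation code.
    """

    def __init__(self, config: NetworkConfig):
        self.config = config
        self.dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        enc = [config.input_width, *config.encoder_layers]
        for i in range(len(enc) - 1):
            self._init_layer(rng, f"enc{i}", enc[i], enc[i + 1])
        h = config.encoder_layers[-1]
        self._init_layer(rng, "mu", h, config.n_latent)
        self._init_layer(rng, "lv", h, config.n_latent)
        self.params["lv_b"] += self.dtype.type(2.0 * np.log(config.sigma_init))
        dec = [config.n_latent, *config.decoder_layers]
        for i in range(len(dec) - 1):
            self._init_layer(rng, f"dec{i}", dec[i], dec[i + 1])
        self._init_layer(rng, "out", dec[-1], 1)
        self.trained = False

    def _init_layer(self, rng, name, fan_in, fan_out):
        if self.config.init != "glorot_uniform":
            raise ValueError(f"unknown init scheme {self.config.init!r}")
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.params[f"{name}_W"] = rng.uniform(
            -limit, limit, size=(fan_in, fan_out)
        ).astype(self.dtype)
        self.params[f"{name}_b"] = np.zeros(fan_out, dtype=self.dtype)

    # ---------------------------------------------------------------- forward

    def encode(self, x: np.ndarray):
        """Per-node (mu, sigma) for a batch of inputs; sigma > 0 by construction."""
        _, mu, sigma, _ = self._forward_encoder(self._prep(x))
        return mu, sigma

    def _prep(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=self.dtype))
        if x.shape[1] != self.config.input_width:
            raise ValueError(
                f"input width {x.shape[1]} != configured {self.config.input_width}"
            )
        return (x - self.dtype.type(self.config.input_offset)) / self.dtype.type(
            self.config.input_scale
        )

    def _forward_encoder(self, x0):
        h = x0
        hidden = []
        for i in range(len(self.config.encoder_layers)):
            h = elu(h @ self.params[f"enc{i}_W"] + self.params[f"enc{i}_b"])
            hidden.append(h)
        mu = h @ self.params["mu_W"] + self.params["mu_b"]
        lv = h @ self.params["lv_W"] + self.params["lv_b"]
        lv = np.clip(lv, -30.0, 30.0)  # keeps exp() finite early in training
        return hidden, mu, np.exp(0.5 * lv), lv

    def _forward_decoder(self, z):
        g = z
        hidden = []
        for i in range(len(self.config.decoder_layers)):
            g = elu(g @ self.params[f"dec{i}_W"] + self.params[f"dec{i}_b"])
            hidden.append(g)
        out = g @ self.params["out_W"] + self.params["out_b"]
        return hidden, out[:, 0]

    def predict(self, x: np.ndarray, eps: np.ndarray | None = None) -> np.ndarray:
        """Decoder output; deterministic (z = mu) unless ``eps`` is given."""
        _, mu, sigma, _ = self._forward_encoder(self._prep(x))
        z = mu if eps is None else sample_latent(mu, sigma, eps.astype(self.dtype))
        raw = self._forward_decoder(z)[1].astype(float)
        return raw * self.config.target_scale + self.config.target_offset

    def encoder_activations(self, x: np.ndarray, layer: int) -> np.ndarray:
        """Post-ELU activations of encoder layer ``layer`` (0-based).

        ``layer == n_encoder_layers`` returns the latent means, the
        activation readout for central nodes.
        """
        hidden, mu, _, _ = self._forward_encoder(self._prep(x))
        if layer == len(hidden):
            return mu
        return hidden[layer]

    # --------------------------------------------------------------- backward

    def _forward_backward(self, x, y, eps, beta):
        """Batch cost and parameter gradients (mean-over-batch convention)."""
        p = self.params
        cfg = self.config
        B = x.shape[0]
        x0 = self._prep(x)
        enc_hidden, mu, sigma, lv = self._forward_encoder(x0)
        z = mu + sigma * eps
        dec_hidden, out = self._forward_decoder(z)

        err = out - y
        penalty_term = np.sum(np.log(sigma**2) - mu**2 - sigma**2, axis=-1)
        total = float(np.mean(err**2) - 0.5 * beta * np.mean(penalty_term))

        grads = {}
        # output layer
        dout = (2.0 / B) * err[:, None]  # [B,1]
        g_last = dec_hidden[-1]
        grads["out_W"] = g_last.T @ dout
        grads["out_b"] = dout.sum(axis=0)
        dg = dout @ p["out_W"].T
        # decoder ELU stack
        for i in range(len(cfg.decoder_layers) - 1, -1, -1):
            dpre = dg * _elu_grad_from_output(dec_hidden[i])
            below = z if i == 0 else dec_hidden[i - 1]
            grads[f"dec{i}_W"] = below.T @ dpre
            grads[f"dec{i}_b"] = dpre.sum(axis=0)
            dg = dpre @ p[f"dec{i}_W"].T
        dz = dg
        # bottleneck heads
        dmu = dz + (beta / B) * mu
        dlv = dz * (0.5 * sigma * eps) + (0.5 * beta / B) * (sigma**2 - 1.0)
        h_last = enc_hidden[-1]
        grads["mu_W"] = h_last.T @ dmu
        grads["mu_b"] = dmu.sum(axis=0)
        grads["lv_W"] = h_last.T @ dlv
        grads["lv_b"] = dlv.sum(axis=0)
        dh = dmu @ p["mu_W"].T + dlv @ p["lv_W"].T
        # encoder ELU stack
        for i in range(len(cfg.encoder_layers) - 1, -1, -1):
            dpre = dh * _elu_grad_from_output(enc_hidden[i])
            below = x0 if i == 0 else enc_hidden[i - 1]
            grads[f"enc{i}_W"] = below.T @ dpre
            grads[f"enc{i}_b"] = dpre.sum(axis=0)
            dh = dpre @ p[f"enc{i}_W"].T
        return total, grads


def train(
    config: NetworkConfig,
    dataset,
    eval_every: int = 1,
    initial: ModifiedAutoencoder | None = None,
) -> tuple[ModifiedAutoencoder, TrainingHistory]:
    """Train a network with Adam (lr, batch size and epochs from config).

    Latent sampling is active during training; validation RMSE is computed
    in deterministic readout mode (eps = 0).  Reproducible: the same config
    (including seed) yields bitwise-identical weights.  If
    ``config.patience`` is set, training stops once validation RMSE has not
    improved for that many epochs and the best-epoch weights are restored.
    ``initial`` warm-starts from an existing network's weights (Adam
    moments start fresh).
    """
    net = ModifiedAutoencoder(config)
    if initial is not None:
        if initial.config.input_width != config.input_width:
            raise ValueError("warm-start network has a different input width")
        net.params = {k: v.copy() for k, v in initial.params.items()}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    x_train, y_train = dataset.train
    x_val, y_val = dataset.validation
    y_train = (
        (y_train.astype(net.dtype) - net.dtype.type(config.target_offset))
        / net.dtype.type(config.target_scale)
    )
    n = x_train.shape[0]
    history = TrainingHistory()

    adam_m = {k: np.zeros_like(v) for k, v in net.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in net.params.items()}
    b1, b2, eps_adam = 0.9, 0.999, 1e-8
    step = 0

    best_rmse = np.inf
    best_params = None
    stale = 0

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_cost = 0.0
        n_batches = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            eps = rng.standard_normal(
                (xb.shape[0], config.n_latent), dtype=net.dtype
            )
            c, grads = net._forward_backward(xb, yb, eps, config.beta)
            if not np.isfinite(c):
                raise TrainingDiverged(epoch)
            step += 1
            lr_t = config.lr * np.sqrt(1 - b2**step) / (1 - b1**step)
            for k, g in grads.items():
                adam_m[k] = b1 * adam_m[k] + (1 - b1) * g
                adam_v[k] = b2 * adam_v[k] + (1 - b2) * g * g
                net.params[k] -= (
                    lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + eps_adam)
                ).astype(net.dtype)
            epoch_cost += c
            n_batches += 1
        history.train_cost.append(epoch_cost / max(n_batches, 1))

        if len(x_val) and (epoch % eval_every == 0 or epoch == config.epochs - 1):
            rmse = float(np.sqrt(np.mean((net.predict(x_val) - y_val) ** 2)))
            history.val_rmse.append(rmse)
            if rmse < best_rmse - 1e-12:
                best_rmse = rmse
                stale = 0
                if config.patience is not None:
                    best_params = {k: v.copy() for k, v in net.params.items()}
            else:
                stale += eval_every
            if config.patience is not None and stale >= config.patience:
                history.stopped_epoch = epoch
                break

    if best_params is not None:
        net.params = best_params
    net.trained = True
    return net, history


def validation_rmse(net: ModifiedAutoencoder, dataset) -> float:
    x_val, y_val = dataset.validation
    return float(np.sqrt(np.mean((net.predict(x_val) - y_val) ** 2)))


def kl_bits_per_node(net: ModifiedAutoencoder, probe_stimuli: np.ndarray) -> np.ndarray:
    """Mean KL divergence (bits) of each latent node from the unit Gaussian.

    KL(N(mu, sigma^2) || N(0, 1)) = (mu^2 + sigma^2 - 1 - log sigma^2) / 2
    nats, averaged over the probe stimuli and converted to bits.  A node is
    operational if this exceeds 0.1 bits.
    """
    mu, sigma = net.encode(probe_stimuli)
    kl_nats = 0.5 * (mu**2 + sigma**2 - 1.0 - np.log(sigma**2))
    return np.asarray(kl_nats.mean(axis=0), dtype=float) / LN2


def operational_nodes(
    net: ModifiedAutoencoder,
    probe_stimuli: np.ndarray,
    threshold_bits: float = OPERATIONAL_KL_BITS,
) -> np.ndarray:
    """Indices of latent nodes transmitting information (KL > threshold)."""
    return np.flatnonzero(kl_bits_per_node(net, probe_stimuli) > threshold_bits)


def predict_rate(
    net: ModifiedAutoencoder,
    spec,
    n_repeats: int = 10,
    seed: int = 0,
) -> float:
    """Mean predicted detection rate over stimulus regenerations.

    The interaural configuration and tone level of ``spec`` are held
    fixed while the tone phase and the noise token are re-randomized on
    each of ``n_repeats`` regenerations; latent readout is deterministic
    (eps = 0).  Averaging reduces the trial-to-trial variance introduced
    by the frozen noise tokens.
    """
    from binauralnet import stimuli  # deferred: stimuli does not import us
    from dataclasses import replace as _replace

    if not net.trained:
        raise RuntimeError("predict_rate requires a trained network")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_repeats)
    noise_seeds = rng.integers(0, 2**31 - 1, size=n_repeats)
    batch = []
    for ph, ns in zip(phases, noise_seeds):
        s = _replace(spec, tone_phase=float(ph), seed=int(ns))
        batch.append((stimuli.make_tone(s) + stimuli.make_noise(s)).concat())
    return float(np.mean(net.predict(np.stack(batch))))


def beta_grid_train_and_select(
    dataset,
    betas: Sequence[float] = (0.0, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2),
    n_seeds: int = 10,
    base_config: NetworkConfig | None = None,
    eval_every: int = 1,
):
    """Train ``len(betas) * n_seeds`` networks and select the best.

    Selection minimizes validation RMSE in deterministic readout mode;
    exact ties break toward the lowest beta, then the lowest seed.  Returns
    ``(selected_net, report)`` where the report is a list of dicts
    (beta, seed, val_rmse, net) ordered by (beta, seed).
    """
    if base_config is None:
        base_config = NetworkConfig(input_width=dataset.inputs.shape[1])
    report = []
    for beta in betas:
        for s in range(n_seeds):
            cfg = replace(base_config, beta=float(beta), seed=base_config.seed + s)
            net, hist = train(cfg, dataset, eval_every=eval_every)
            report.append(
                {
                    "beta": float(beta),
                    "seed": cfg.seed,
                    "val_rmse": validation_rmse(net, dataset),
                    "net": net,
                    "history": hist,
                }
            )
    best = min(report, key=lambda r: (r["val_rmse"], r["beta"], r["seed"]))
    return best["net"], report


def min_rmse_per_beta(report) -> dict[float, float]:
    """Minimum validation RMSE for each beta (the envelope of a grid run)."""
    out: dict[float, float] = {}
    for r in report:
        b = r["beta"]
        out[b] = min(out.get(b, np.inf), r["val_rmse"])
    return out


# ------------------------------------------------------------- serialization

FORMAT_VERSION = 1


def save_model(net: ModifiedAutoencoder, path) -> None:
    """Single-file NPZ archive: weights + config + format version."""
    cfg = asdict(net.config)
    np.savez(
        path,
        __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
        __version__=np.array([FORMAT_VERSION]),
        **net.params,
    )


def load_model(path) -> ModifiedAutoencoder:
    with np.load(path) as z:
        cfg_dict = json.loads(bytes(z["__config__"]).decode())
        for key in ("encoder_layers", "decoder_layers"):
            cfg_dict[key] = tuple(cfg_dict[key])
        net = ModifiedAutoencoder(NetworkConfig(**cfg_dict))
        for k in net.params:
            net.params[k] = z[k]
    net.trained = True
    return net
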