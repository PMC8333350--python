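"""Conditioned adversarial autoencoder (AAE) normative model.

The model learns the healthy-control distribution of 101 normalised regional
brain volumes.  An encoder maps the input to a 20-dimensional latent code; a
decoder reconstructs the input from the latent code concatenated with one-hot
age (27) and sex (2) conditioning vectors; a discriminator pushes the latent
distribution towards a standard-normal prior via adversarial training.  A
subject's deviation from the norm is the mean squared reconstruction error.

Architecture (hidden layers use leaky ReLU; latent and decoder outputs are
linear; the discriminator output is a probability):

    encoder        101 -> 100 -> 100 -> 20
    decoder   20+27+2  -> 100 -> 100 -> 101
    discriminator  20  -> 100 -> 100 -> 1

Training alternates three phases per minibatch — reconstruction (encoder +
decoder, mean squared error), discriminator (binary cross-entropy separating
prior draws from latent codes), and generator (encoder updated to fool the
discriminator) — each with its own Adam state, all sharing one decaying
triangular cyclical learning-rate schedule.  Everything is implemented in
numpy with explicit backpropagation; forward passes and training are
deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .cohort import Cohort, N_REGIONS, SubjectRecord
from .preprocess import (
    N_CONDITION,
    ScalerParams,
    apply_scaler,
    cohort_condition_matrix,
    cohort_relative_volumes,
    condition_vector,
    fit_scaler,
    relative_volumes,
)

MODEL_SCHEMA_VERSION = 1


@dataclass
class AAEConfig:
    """Hyperparameters of the adversarial autoencoder."""

    input_dim: int = N_REGIONS
    encoder_hidden: tuple[int, ...] = (100, 100)
    latent_dim: int = 20
    decoder_hidden: tuple[int, ...] = (100, 100)
    discriminator_hidden: tuple[int, ...] = (100, 100)
    leaky_slope: float = 0.01
    epochs: int = 200
    batch_size: int = 256
    base_lr: float = 0.0001
    max_lr: float = 0.005
    lr_gamma: float = 0.98
    # half-period of the triangular wave, in minibatches; None = 4 epochs' worth
    cycle_step_batches: int | None = None
    adv_weight: float = 0.5
    disc_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (self.input_dim, self.latent_dim, *self.encoder_hidden,
                *self.decoder_hidden, *self.discriminator_hidden)
        if any(d <= 0 for d in dims):
            raise ValueError("all layer dimensions must be positive")
        if not self.base_lr < self.max_lr:
            raise ValueError("base_lr must be smaller than max_lr")
        if not 0.0 < self.lr_gamma <= 1.0:
            raise ValueError("lr_gamma must lie in (0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def cyclical_learning_rate(step: int, config: AAEConfig,
                           step_size: int | None = None) -> float:
    """Decaying triangular cyclical learning rate.

    The rate oscillates between ``base_lr`` and ``base_lr + amplitude``
    with period ``2 * step_size`` minibatches; the amplitude starts at
    ``max_lr - base_lr`` and decays by ``gamma`` each full cycle, so the
    first peak hits ``max_lr`` exactly and the k-th peak
    ``base_lr + gamma^(k-1) * (max_lr - base_lr)``.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    if step_size is None:
        step_size = config.cycle_step_batches or 1
    cycle = step // (2 * step_size)
    x = abs(step / step_size - 2 * cycle - 1)  # 1 at cycle edges, 0 at peak
    amplitude = (config.max_lr - config.base_lr) * config.lr_gamma ** cycle
    return config.base_lr + amplitude * max(0.0, 1.0 - x)


class MLP:
    """Fully connected network, leaky-ReLU hidden layers, linear output."""

    def __init__(self, dims: tuple[int, ...], slope: float,
                 rng: np.random.Generator | None = None):
        self.dims = tuple(int(d) for d in dims)
        self.slope = float(slope)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for d_in, d_out in zip(self.dims[:-1], self.dims[1:]):
            if rng is None:
                W = np.zeros((d_in, d_out))
            else:
                bound = 1.0 / np.sqrt(d_in)  # fan-in-scaled uniform init
                W = rng.uniform(-bound, bound, size=(d_in, d_out))
            self.W.append(W)
            self.b.append(np.zeros(d_out))

    @property
    def n_parameters(self) -> int:
        return sum(W.size + b.size for W, b in zip(self.W, self.b))

    def forward(self, X: np.ndarray, keep_cache: bool = False):
        """Forward pass; returns output (and layer caches when training)."""
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.dims[0]:
            raise ValueError(f"expected input width {self.dims[0]}, got {X.shape[-1]}")
        caches = []
        a = X
        last = len(self.W) - 1
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if i < last:
                out = np.where(z > 0, z, self.slope * z)
            else:
                out = z
            if keep_cache:
                caches.append((a, z))
            a = out
        return (a, caches) if keep_cache else a

    def backward(self, d_out: np.ndarray, caches):
        """Backpropagate ``d_out`` (gradient w.r.t. linear output).

        Returns (gradient w.r.t. input, [(dW, db), ...] per layer).
        """
        grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.W)
        last = len(self.W) - 1
        grad = d_out
        for i in range(last, -1, -1):
            a_in, z = caches[i]
            if i < last:
                grad = grad * np.where(z > 0, 1.0, self.slope)
            grads[i] = (a_in.T @ grad, grad.sum(axis=0))
            grad = grad @ self.W[i].T
        return grad, grads

    def params(self) -> list[np.ndarray]:
        out = []
        for W, b in zip(self.W, self.b):
            out.extend((W, b))
        return out

    def flat_grads(self, grads) -> list[np.ndarray]:
        out = []
        for dW, db in grads:
            out.extend((dW, db))
        return out


class Adam:
    """Adam optimiser with standard moment defaults (0.9, 0.999, 1e-8)."""

    def __init__(self, params: list[np.ndarray], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


@dataclass
class AAEParams:
    """A built (possibly trained) model: networks, config, scaler, log."""

    config: AAEConfig
    encoder: MLP
    decoder: MLP
    discriminator: MLP
    scaler: ScalerParams | None = None
    training_log: list[dict] = field(default_factory=list)

    @property
    def is_trained(self) -> bool:
        return self.scaler is not None


def build_model(config: AAEConfig) -> AAEParams:
    """Build the three networks with seeded fan-in-scaled uniform weights."""
    ss = np.random.SeedSequence([int(config.seed), 0])
    r_enc, r_dec, r_disc = (np.random.default_rng(s) for s in ss.spawn(3))
    enc = MLP((config.input_dim, *config.encoder_hidden, config.latent_dim),
              config.leaky_slope, r_enc)
    dec = MLP((config.latent_dim + N_CONDITION, *config.decoder_hidden,
               config.input_dim), config.leaky_slope, r_dec)
    disc = MLP((config.latent_dim, *config.discriminator_hidden, 1),
               config.leaky_slope, r_disc)
    return AAEParams(config=config, encoder=enc, decoder=dec, discriminator=disc)


def encode(x: np.ndarray, params: AAEParams) -> np.ndarray:
    """Deterministic forward pass to the (linear) 20-d latent code."""
    return params.encoder.forward(np.asarray(x, dtype=float))


def decode(h: np.ndarray, c: np.ndarray, params: AAEParams) -> np.ndarray:
    """Reconstruct from latent code + condition vector (linear output)."""
    h = np.asarray(h, dtype=float)
    c = np.asarray(c, dtype=float)
    single = h.ndim == 1
    h2, c2 = np.atleast_2d(h), np.atleast_2d(c)
    if c2.shape[-1] != N_CONDITION:
        raise ValueError(f"condition vector must have {N_CONDITION} entries")
    out = params.decoder.forward(np.concatenate([h2, c2], axis=-1))
    return out[0] if single else out


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * a))


def discriminate(z: np.ndarray, params: AAEParams) -> np.ndarray:
    """Probability that ``z`` came from the prior rather than the encoder."""
    a = params.discriminator.forward(np.asarray(z, dtype=float))
    return np.squeeze(_sigmoid(a), axis=-1)


def _softplus(a: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, a)


def train(cohort: Cohort, config: AAEConfig, hc_label: str = "HC",
          scaler: ScalerParams | None = None) -> AAEParams:
    """Train the AAE on a healthy-control cohort.

    Fits the robust scaler on the training cohort (unless one is supplied),
    then runs ``config.epochs`` epochs of minibatch training with the three
    adversarial phases.  Raises if any subject is not labelled ``hc_label``:
    the normative model is defined on controls only.
    """
    labels = set(cohort.group_labels().tolist())
    if labels - {hc_label}:
        raise ValueError(
            f"normative training requires {hc_label!r} subjects only; "
            f"found {sorted(labels - {hc_label})}"
        )
    n = len(cohort)
    if n < 4:
        raise ValueError("need at least 4 training subjects")

    rel = cohort_relative_volumes(cohort)
    if scaler is None:
        scaler = fit_scaler(rel, region_names=cohort.atlas.names)
    Z = apply_scaler(rel, scaler)
    C = cohort_condition_matrix(cohort)

    params = build_model(config)
    enc, dec, disc = params.encoder, params.decoder, params.discriminator
    opt_rec = Adam(enc.params() + dec.params())
    opt_disc = Adam(disc.params())
    opt_gen = Adam(enc.params())

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1]))
    batches_per_epoch = max(1, int(np.ceil(n / config.batch_size)))
    step_size = config.cycle_step_batches or 4 * batches_per_epoch
    latent = config.latent_dim

    step = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        rec_losses, disc_losses, gen_losses = [], [], []
        lr = config.base_lr
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb, cb = Z[idx], C[idx]
            m = len(idx)
            lr = cyclical_learning_rate(step, config, step_size)

            # -- phase 1: reconstruction (encoder + decoder, MSE)
            h, cache_e = enc.forward(xb, keep_cache=True)
            xhat, cache_d = dec.forward(np.concatenate([h, cb], axis=1),
                                        keep_cache=True)
            resid = xhat - xb
            rec_losses.append(float(np.mean(resid ** 2)))
            d_xhat = 2.0 * resid / resid.size
            d_in_dec, g_dec = dec.backward(d_xhat, cache_d)
            _, g_enc = enc.backward(d_in_dec[:, :latent], cache_e)
            opt_rec.step(enc.flat_grads(g_enc) + dec.flat_grads(g_dec), lr)

            # -- phase 2: discriminator (prior -> 1, encoded -> 0)
            z_prior = rng.standard_normal((m, latent))
            h_fixed = enc.forward(xb)
            z_all = np.concatenate([z_prior, h_fixed], axis=0)
            t_all = np.concatenate([np.ones(m), np.zeros(m)])[:, None]
            a, cache_disc = disc.forward(z_all, keep_cache=True)
            disc_losses.append(float(np.mean(
                _softplus(a) - t_all * a)))  # BCE with logits
            d_a = (_sigmoid(a) - t_all) / a.size
            _, g_disc = disc.backward(d_a, cache_disc)
            opt_disc.step(disc.flat_grads(g_disc), lr * config.disc_weight)

            # -- phase 3: generator (encoder fools the discriminator)
            h, cache_e = enc.forward(xb, keep_cache=True)
            a, cache_disc = disc.forward(h, keep_cache=True)
            gen_losses.append(float(np.mean(_softplus(-a))))
            d_a = (_sigmoid(a) - 1.0) / a.size
            d_h, _ = disc.backward(d_a, cache_disc)
            _, g_enc = enc.backward(d_h, cache_e)
            # Adam is invariant to constant gradient scaling, so the
            # adversarial weight acts on the generator step size instead
            opt_gen.step(enc.flat_grads(g_enc), lr * config.adv_weight)

            step += 1

        params.training_log.append({
            "epoch": epoch,
            "reconstruction_loss": float(np.mean(rec_losses)),
            "discriminator_loss": float(np.mean(disc_losses)),
            "generator_loss": float(np.mean(gen_losses)),
            "learning_rate": float(lr),
        })

    params.scaler = scaler
    return params


def reconstruct(record: SubjectRecord, params: AAEParams) -> tuple[np.ndarray, np.ndarray]:
    """Normalise one subject and run it through the trained model.

    Returns ``(z, z_hat)``: the scaled feature vector and its reconstruction
    under the subject's age/sex conditioning.
    """
    if not params.is_trained:
        raise ValueError("model has no fitted scaler; train it first")
    record.validate()
    x = apply_scaler(relative_volumes(record), params.scaler)
    h = encode(x[None, :], params)
    c = condition_vector(record.age, record.sex)[None, :]
    xhat = params.decoder.forward(np.concatenate([h, c], axis=1))
    return x, xhat[0]


def reconstruct_cohort(cohort: Cohort, params: AAEParams) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`reconstruct` over a cohort: (Z, Z_hat) matrices."""
    if not params.is_trained:
        raise ValueError("model has no fitted scaler; train it first")
    X = apply_scaler(cohort_relative_volumes(cohort), params.scaler)
    H = encode(X, params)
    C = cohort_condition_matrix(cohort)
    Xhat = params.decoder.forward(np.concatenate([H, C], axis=1))
    return X, Xhat


# ---------------------------------------------------------------------------
# model artefact serialisation (single .npz bundling config, scaler, weights)

def _weights_checksum(arrays: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for k in sorted(arrays):
        h.update(k.encode())
        h.update(np.ascontiguousarray(arrays[k]).tobytes())
    return h.hexdigest()


def save_model(params: AAEParams, path: str | Path) -> None:
    """Serialise the full model artefact; load/save round-trips bit-exactly."""
    arrays: dict[str, np.ndarray] = {}
    for net_name, net in (("encoder", params.encoder),
                          ("decoder", params.decoder),
                          ("discriminator", params.discriminator)):
        for i, (W, b) in enumerate(zip(net.W, net.b)):
            arrays[f"{net_name}_W{i}"] = W
            arrays[f"{net_name}_b{i}"] = b
    if params.scaler is not None:
        arrays["scaler_median"] = params.scaler.median
        arrays["scaler_iqr"] = params.scaler.iqr
    header = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "config": asdict(params.config),
        "training_log": params.training_log,
        "checksum": _weights_checksum(arrays),
    }
    arrays["header_json"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str | Path, verify_checksum: bool = True) -> AAEParams:
    """Load a model artefact, verifying the stored weight checksum."""
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    header = json.loads(bytes(arrays.pop("header_json")).decode())
    if header.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema {header.get('schema_version')}")
    if verify_checksum and _weights_checksum(arrays) != header["checksum"]:
        raise ValueError("model artefact checksum mismatch: file corrupted or tampered")
    cfg_dict = dict(header["config"])
    for key in ("encoder_hidden", "decoder_hidden", "discriminator_hidden"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = AAEConfig(**cfg_dict)
    params = build_model(config)
    for net_name, net in (("encoder", params.encoder),
                          ("decoder", params.decoder),
                          ("discriminator", params.discriminator)):
        for i in range(len(net.W)):
            net.W[i] = arrays[f"{net_name}_W{i}"]
            net.b[i] = arrays[f"{net_name}_b{i}"]
    if "scaler_median" in arrays:
        params.scaler = ScalerParams(median=arrays["scaler_median"],
                                     iqr=arrays["scaler_iqr"])
    params.training_log = header["training_log"]
    return params
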