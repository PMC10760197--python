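"""Encoder/decoder networks and the training objective.

The model is a fully connected VAE with a diagonal-Gaussian posterior and a
standard-normal prior. Two variants share the architecture and differ only in
the prediction target:

* ``predictive=False`` — classic VAE, reconstructs the input row ``x_t``;
* ``predictive=True``  — next-step variant, the encoder of ``x_t``
  parameterizes the posterior over the *next* latent and the decoder
  predicts ``x_{t+1}``.

The likelihood is Gaussian with fixed unit variance, so the reconstruction
term is half the squared error averaged over features and over the batch; the
KL term uses the closed diagonal-Gaussian form, summed over latent dimensions
and averaged over the batch. ``total = reconstruction + beta * kl``. (With a
summed-over-features reduction the conventional small KL weights would leave
the KL term at a negligible fraction of the objective; the per-feature mean
keeps ``beta`` a meaningful knob at those magnitudes.)

Networks are plain NumPy with hand-written backpropagation (ReLU hidden
layers, linear output heads), which keeps the package dependency-free and is
ample for the network sizes used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .datasets import LabeledTimeSeries
from .exceptions import ShapeError, ValidationError

__all__ = [
    "VAEConfig",
    "PosteriorParams",
    "LossComponents",
    "VAE",
    "kl_divergence",
    "reparameterize",
    "make_pairs",
]


@dataclass(frozen=True)
class VAEConfig:
    """One hyperparameter point: architecture, objective weight, optimizer, seed."""

    n_layers: int = 2
    layer_dim: int = 100
    latent_dim: int = 2
    beta: float = 3e-4
    batch_size: int = 2048
    learning_rate: float = 1e-3
    seed: int = 0
    predictive: bool = True
    mc_samples: int = 1

    def __post_init__(self):
        for name in ("n_layers", "layer_dim", "latent_dim", "batch_size", "mc_samples"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.beta <= 0:
            raise ValidationError(f"beta must be > 0, got {self.beta}")
        if self.learning_rate <= 0:
            raise ValidationError(f"learning_rate must be > 0, got {self.learning_rate}")

    def key(self) -> tuple:
        """Hyperparameter identity ignoring the seed (groups model instances)."""
        d = asdict(self)
        d.pop("seed")
        return tuple(sorted(d.items()))


@dataclass
class PosteriorParams:
    """Per-sample posterior mean and log-variance (diagonal Gaussian)."""

    mean: np.ndarray  # (N, latent_dim)
    log_variance: np.ndarray  # (N, latent_dim)

    def __post_init__(self):
        if self.mean.shape != self.log_variance.shape:
            raise ShapeError(
                f"mean {self.mean.shape} and log_variance {self.log_variance.shape} differ"
            )


@dataclass
class LossComponents:
    reconstruction: float
    kl: float
    beta: float

    @property
    def total(self) -> float:
        return self.reconstruction + self.beta * self.kl


def kl_divergence(mean: np.ndarray, log_variance: np.ndarray) -> float:
    """KL(q || N(0, I)) for a diagonal Gaussian, summed over dims, batch mean."""
    per = 0.5 * np.sum(mean**2 + np.exp(log_variance) - log_variance - 1.0, axis=-1)
    return float(np.mean(per))


def reparameterize(q: PosteriorParams, noise: np.ndarray) -> np.ndarray:
    """z = mean + exp(log_variance / 2) * noise."""
    noise = np.asarray(noise, dtype=float)
    if noise.shape != q.mean.shape:
        raise ShapeError(f"noise shape {noise.shape} != posterior shape {q.mean.shape}")
    return q.mean + np.exp(0.5 * q.log_variance) * noise


def _relu(a):
    return np.maximum(a, 0.0)


class VAE:
    """Fully connected VAE with manual gradients.

    Parameters live in ``self.params`` (dict of arrays) so they can be
    serialized, copied, and hand-set in tests.
    """

    def __init__(self, config: VAEConfig, input_dim: int, rng: np.random.Generator | None = None):
        self.config = config
        self.input_dim = int(input_dim)
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.params = self._init_params(rng)

    # -- initialization ----------------------------------------------------
    def _init_params(self, rng) -> dict:
        c = self.config
        p = {}

        def he(fan_in, fan_out):
            return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)

        dims_enc = [self.input_dim] + [c.layer_dim] * c.n_layers
        for i in range(c.n_layers):
            p[f"enc_W{i}"] = he(dims_enc[i], dims_enc[i + 1])
            p[f"enc_b{i}"] = np.zeros(dims_enc[i + 1])
        p["W_mu"] = he(c.layer_dim, c.latent_dim) * 0.1
        p["b_mu"] = np.zeros(c.latent_dim)
        p["W_lv"] = he(c.layer_dim, c.latent_dim) * 0.1
        p["b_lv"] = np.zeros(c.latent_dim)

        dims_dec = [c.latent_dim] + [c.layer_dim] * c.n_layers
        for i in range(c.n_layers):
            p[f"dec_W{i}"] = he(dims_dec[i], dims_dec[i + 1])
            p[f"dec_b{i}"] = np.zeros(dims_dec[i + 1])
        p["W_out"] = he(c.layer_dim, self.input_dim)
        p["b_out"] = np.zeros(self.input_dim)
        return p

    # -- forward passes ----------------------------------------------------
    def _encode_forward(self, X):
        c, p = self.config, self.params
        h = X
        hs = [h]
        for i in range(c.n_layers):
            pre = h @ p[f"enc_W{i}"] + p[f"enc_b{i}"]
            h = _relu(pre)
            hs.append(h)
        mu = h @ p["W_mu"] + p["b_mu"]
        lv = h @ p["W_lv"] + p["b_lv"]
        return mu, lv, hs

    def encode(self, X: np.ndarray) -> PosteriorParams:
        """Posterior parameters for each row of X (deterministic)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ShapeError(
                f"expected {self.input_dim} features, got {X.shape[1]}"
            )
        mu, lv, _ = self._encode_forward(X)
        return PosteriorParams(mean=mu, log_variance=lv)

    def _decode_forward(self, Z):
        c, p = self.config, self.params
        g = Z
        gs = [g]
        for i in range(c.n_layers):
            pre = g @ p[f"dec_W{i}"] + p[f"dec_b{i}"]
            g = _relu(pre)
            gs.append(g)
        xhat = g @ p["W_out"] + p["b_out"]
        return xhat, gs

    def decode(self, Z: np.ndarray) -> np.ndarray:
        """Reconstruction mean for each latent row (deterministic)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.config.latent_dim:
            raise ShapeError(
                f"expected latent_dim {self.config.latent_dim}, got {Z.shape[1]}"
            )
        xhat, _ = self._decode_forward(Z)
        return xhat

    # -- objective ---------------------------------------------------------
    def loss(self, x_in, x_target, beta=None, noise=None) -> LossComponents:
        comps, _ = self.loss_and_grads(x_in, x_target, beta=beta, noise=noise, want_grads=False)
        return comps

    def loss_and_grads(self, x_in, x_target, beta=None, noise=None, want_grads=True):
        """Objective value and parameter gradients for one batch.

        ``noise`` (same shape as the posterior) supplies the reparameterization
        draw; zeros make the pass deterministic. Returns
        ``(LossComponents, grads_dict_or_None)``.
        """
        c, p = self.config, self.params
        beta = c.beta if beta is None else float(beta)
        x_in = np.atleast_2d(np.asarray(x_in, dtype=float))
        x_target = np.atleast_2d(np.asarray(x_target, dtype=float))
        if x_in.shape[0] != x_target.shape[0]:
            raise ShapeError(
                f"x_in rows {x_in.shape[0]} != x_target rows {x_target.shape[0]}"
            )
        if x_in.shape[1] != self.input_dim:
            raise ShapeError(f"expected {self.input_dim} features, got {x_in.shape[1]}")
        B = x_in.shape[0]

        mu, lv, hs = self._encode_forward(x_in)
        if noise is None:
            noise = np.zeros_like(mu)
        noise = np.asarray(noise, dtype=float)
        if noise.shape != mu.shape:
            raise ShapeError(f"noise shape {noise.shape} != posterior shape {mu.shape}")
        sd = np.exp(0.5 * lv)
        z = mu + sd * noise
        xhat, gs = self._decode_forward(z)

        recon = float(0.5 * np.sum((xhat - x_target) ** 2) / (B * self.input_dim))
        kl = kl_divergence(mu, lv)
        comps = LossComponents(reconstruction=recon, kl=kl, beta=beta)
        if not want_grads:
            return comps, None

        grads = {k: np.zeros_like(v) for k, v in p.items()}

        # decoder backward
        d = (xhat - x_target) / (B * self.input_dim)
        grads["W_out"] = gs[-1].T @ d
        grads["b_out"] = d.sum(axis=0)
        dg = d @ p["W_out"].T
        for i in reversed(range(c.n_layers)):
            dpre = dg * (gs[i + 1] > 0)
            grads[f"dec_W{i}"] = gs[i].T @ dpre
            grads[f"dec_b{i}"] = dpre.sum(axis=0)
            dg = dpre @ p[f"dec_W{i}"].T
        dz = dg

        # through reparameterization + KL
        dmu = dz + beta * mu / B
        dlv = dz * noise * 0.5 * sd + beta * 0.5 * (np.exp(lv) - 1.0) / B

        # encoder heads and hidden stack
        grads["W_mu"] = hs[-1].T @ dmu
        grads["b_mu"] = dmu.sum(axis=0)
        grads["W_lv"] = hs[-1].T @ dlv
        grads["b_lv"] = dlv.sum(axis=0)
        dh = dmu @ p["W_mu"].T + dlv @ p["W_lv"].T
        for i in reversed(range(c.n_layers)):
            dpre = dh * (hs[i + 1] > 0)
            grads[f"enc_W{i}"] = hs[i].T @ dpre
            grads[f"enc_b{i}"] = dpre.sum(axis=0)
            dh = dpre @ p[f"enc_W{i}"].T
        return comps, grads

    def copy(self) -> "VAE":
        clone = VAE.__new__(VAE)
        clone.config = self.config
        clone.input_dim = self.input_dim
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone


def make_pairs(ts: LabeledTimeSeries, predictive: bool, transitions: np.ndarray | None = None):
    """Aligned (x_in, x_target) batches plus the transition indices used.

    Predictive pairing emits ``(x_t, x_{t+1})`` for every valid transition
    (never spanning a recorded gap): N-1 pairs per contiguous segment.
    Non-predictive pairing targets the input itself; when ``transitions`` is
    given it is restricted to the same transition slots so that data splits
    defined over transitions apply identically to both model kinds, otherwise
    every row becomes a pair.
    """
    if predictive:
        if ts.n < 2:
            raise ValidationError("no transitions available (need N >= 2)")
        idx = ts.transitions() if transitions is None else np.asarray(transitions, dtype=int)
        if len(idx) == 0:
            raise ValidationError("no transitions available")
        return ts.X[idx], ts.X[idx + 1], idx
    if transitions is None:
        idx = np.arange(ts.n)
        return ts.X[idx], ts.X[idx], idx
    idx = np.asarray(transitions, dtype=int)
    return ts.X[idx], ts.X[idx], idx
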