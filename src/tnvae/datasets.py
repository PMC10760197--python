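"""Synthetic time-series generators with known ground truth.

Three dataset families are provided:

* a small-state-count hidden Markov chain with diagonal-Gaussian emissions in
  a high-dimensional feature space, mimicking slow brain-state dynamics
  (long dwell times, partially overlapping clusters);
* points sampled uniformly by arc length along a 2-D Archimedean spiral,
  lifted into a higher-dimensional space through a fixed random smooth map,
  with additive white noise;
* an i.i.d. variant of any series obtained by uniformly permuting its rows
  (destroys temporal structure while preserving the marginal distribution).

Every generator returns a :class:`LabeledTimeSeries` so downstream training
and evaluation never need external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError

__all__ = [
    "LabeledTimeSeries",
    "HMMParams",
    "SpiralParams",
    "simulate_hmm",
    "simulate_spiral",
    "shuffle_time",
    "block_labels",
    "stationary_distribution",
    "archimedean_spiral",
    "load_preset",
    "read_csv",
    "write_csv",
]

DEFAULT_DIM = 31


@dataclass
class LabeledTimeSeries:
    """Time-ordered observation matrix with optional ground truth.

    Attributes
    ----------
    X : (N, D) float array
        One observation row per time bin.
    t : (N,) int array
        Time index per row, strictly increasing with unit steps.
    labels : (N,) int array or None
        Ground-truth discrete state per row, if known.
    latent_truth : (N,) float array or None
        Generative latent coordinate per row (state id for the chain,
        arc-length position for the spiral).
    gaps : frozenset of int
        Transition indices ``t`` for which ``t -> t+1`` is *not* a valid
        temporal transition (recorded by split operations).
    """

    X: np.ndarray
    t: np.ndarray
    labels: np.ndarray | None = None
    latent_truth: np.ndarray | None = None
    gaps: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValidationError(f"X must be 2-D, got shape {self.X.shape}")
        n = self.X.shape[0]
        self.t = np.asarray(self.t, dtype=int)
        if self.t.shape != (n,):
            raise ValidationError(f"t has length {self.t.shape}, expected ({n},)")
        if n > 1 and not np.all(np.diff(self.t) == 1) and not self.gaps:
            raise ValidationError("t must increase with unit steps unless gaps are recorded")
        for name in ("labels", "latent_truth"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (n,):
                    raise ValidationError(f"{name} has shape {v.shape}, expected ({n},)")
                setattr(self, name, v)
        self.gaps = frozenset(int(g) for g in self.gaps)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def transitions(self) -> np.ndarray:
        """Indices t with a valid temporal transition t -> t+1."""
        all_t = np.arange(self.n - 1)
        if not self.gaps:
            return all_t
        mask = ~np.isin(all_t, sorted(self.gaps))
        return all_t[mask]

    def slice(self, rows: slice) -> "LabeledTimeSeries":
        """Contiguous row slice, preserving alignment and in-range gaps."""
        idx = np.arange(self.n)[rows]
        lo, hi = int(idx[0]), int(idx[-1])
        gaps = frozenset(g - lo for g in self.gaps if lo <= g < hi)
        return LabeledTimeSeries(
            X=self.X[rows],
            t=np.arange(len(idx)),
            labels=None if self.labels is None else self.labels[rows],
            latent_truth=None if self.latent_truth is None else self.latent_truth[rows],
            gaps=gaps,
        )


# ---------------------------------------------------------------------------
# Hidden Markov chain with diagonal-Gaussian emissions
# ---------------------------------------------------------------------------


@dataclass
class HMMParams:
    n_states: int
    transition: np.ndarray  # (K, K) row-stochastic
    means: np.ndarray  # (K, D)
    scales: np.ndarray  # (K, D) per-dimension emission SDs

    def __post_init__(self):
        self.transition = np.asarray(self.transition, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        k = self.n_states
        if self.transition.shape != (k, k):
            raise ValidationError(
                f"transition must be ({k},{k}), got {self.transition.shape}"
            )
        if np.any(self.transition < 0):
            raise ValidationError(f"transition has negative entries:\n{self.transition}")
        rowsums = self.transition.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-12):
            raise ValidationError(
                f"transition rows must sum to 1 (got {rowsums}):\n{self.transition}"
            )
        if self.means.shape[0] != k or self.scales.shape != self.means.shape:
            raise ValidationError("means/scales must both be (n_states, D)")
        if np.any(self.scales <= 0):
            raise ValidationError("emission scales must be strictly positive")

    @property
    def dim(self) -> int:
        return self.means.shape[1]


def stationary_distribution(transition: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Unique stationary distribution of a row-stochastic matrix.

    Uses the left eigenvector of eigenvalue 1. Raises :class:`ValidationError`
    when the chain has no unique stationary distribution (reducible chain).
    """
    transition = np.asarray(transition, dtype=float)
    vals, vecs = np.linalg.eig(transition.T)
    close = np.isclose(vals, 1.0, atol=1e-8)
    if close.sum() != 1:
        raise ValidationError(
            "transition matrix has no unique stationary distribution "
            f"(eigenvalue-1 multiplicity {int(close.sum())}):\n{transition}"
        )
    pi = np.real(vecs[:, close].ravel())
    pi = pi / pi.sum()
    if np.any(pi < -tol):
        raise ValidationError(
            f"stationary vector has negative mass:\n{transition}"
        )
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def simulate_hmm(params: HMMParams, n_points: int, seed: int) -> LabeledTimeSeries:
    """Sample a hidden-state path and diagonal-Gaussian emissions.

    The initial state is drawn from the stationary distribution of the
    transition matrix; identical seeds yield identical output.
    """
    if n_points < 1:
        raise ValidationError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    k = params.n_states

    if np.allclose(params.transition, np.eye(k)):
        # Absorbing everywhere: stationary distribution is not unique, but the
        # chain is still well defined; start uniformly at random.
        pi0 = np.full(k, 1.0 / k)
    else:
        pi0 = stationary_distribution(params.transition)

    states = np.empty(n_points, dtype=int)
    states[0] = rng.choice(k, p=pi0)
    # cumulative rows let us sample each step with one uniform draw
    cum = np.cumsum(params.transition, axis=1)
    u = rng.random(n_points - 1)
    for i in range(1, n_points):
        states[i] = np.searchsorted(cum[states[i - 1]], u[i - 1], side="right")
    states = np.minimum(states, k - 1)

    noise = rng.standard_normal((n_points, params.dim))
    X = params.means[states] + params.scales[states] * noise
    return LabeledTimeSeries(
        X=X,
        t=np.arange(n_points),
        labels=states,
        latent_truth=states.astype(float),
    )


# ---------------------------------------------------------------------------
# Spiral sampled uniformly in arc length, lifted to higher dimension
# ---------------------------------------------------------------------------


@dataclass
class SpiralParams:
    n_points: int
    turns: float = 3.0
    noise_sd: float = 0.1
    embed_dim: int = DEFAULT_DIM
    embed_seed: int = 0

    def __post_init__(self):
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")
        if self.turns <= 0:
            raise ValidationError("turns must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.embed_dim < 2:
            raise ValidationError("embed_dim must be >= 2")


_SPIRAL_A = 1.0  # inner radius; keeps the curve away from the origin
_SPIRAL_B = 0.5  # radial growth per radian


def archimedean_spiral(params: SpiralParams, n_points: int | None = None):
    """2-D Archimedean spiral r = a + b*theta sampled uniformly in arc length.

    Returns ``(theta, points, arc)`` where ``arc`` is the arc-length position
    of each point from the innermost end. The arc-length integral is inverted
    numerically on a dense grid.
    """
    n = params.n_points if n_points is None else n_points
    theta_max = 2.0 * np.pi * params.turns
    grid = np.linspace(0.0, theta_max, max(200 * n, 20000))
    r = _SPIRAL_A + _SPIRAL_B * grid
    speed = np.sqrt(r**2 + _SPIRAL_B**2)  # |d(curve)/d theta|
    arc_grid = np.concatenate(
        [[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(grid))]
    )
    targets = np.linspace(0.0, arc_grid[-1], n)
    theta = np.interp(targets, arc_grid, grid)
    radii = _SPIRAL_A + _SPIRAL_B * theta
    points = np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
    return theta, points, targets


def _embedding_map(params: SpiralParams):
    """Fixed random smooth lift R^2 -> R^embed_dim (injective a.s.)."""
    rng = np.random.default_rng(params.embed_seed)
    W = rng.standard_normal((2, params.embed_dim))
    b = 0.5 * rng.standard_normal(params.embed_dim)
    r_max = _SPIRAL_A + _SPIRAL_B * 2.0 * np.pi * params.turns

    def lift(points2d: np.ndarray) -> np.ndarray:
        u = (points2d / r_max) @ W + b
        return np.tanh(u)

    return lift


def simulate_spiral(params: SpiralParams, seed: int) -> LabeledTimeSeries:
    """Uniform-arc-length spiral points, nonlinearly lifted, plus white noise.

    ``latent_truth`` holds the arc-length position (strictly increasing from
    the innermost point). The lift is fully determined by ``embed_seed``; the
    observation noise by ``seed``.
    """
    _, points2d, arc = archimedean_spiral(params)
    lift = _embedding_map(params)
    X = lift(points2d)
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        X = X + params.noise_sd * rng.standard_normal(X.shape)
    return LabeledTimeSeries(
        X=X, t=np.arange(params.n_points), latent_truth=arc
    )


# ---------------------------------------------------------------------------
# Row shuffling and block labels
# ---------------------------------------------------------------------------


def shuffle_time(ts: LabeledTimeSeries, seed: int) -> LabeledTimeSeries:
    """Uniformly permute rows, making the series look i.i.d. in time.

    Labels and latent truth are permuted in lockstep; the time index is reset
    to ``0..N-1``.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ts.n)
    return LabeledTimeSeries(
        X=ts.X[perm],
        t=np.arange(ts.n),
        labels=None if ts.labels is None else ts.labels[perm],
        latent_truth=None if ts.latent_truth is None else ts.latent_truth[perm],
    )


def block_labels(ts: LabeledTimeSeries, block: int) -> np.ndarray:
    """Label row i with floor(i / block); cluster truth for curve-like data."""
    if block < 1:
        raise ValidationError("block must be >= 1")
    return np.arange(ts.n) // block


# ---------------------------------------------------------------------------
# Presets and columnar I/O
# ---------------------------------------------------------------------------


def load_preset(name_or_path: str):
    """Load HMM or spiral parameters from a YAML preset.

    ``name_or_path`` is either a path to a YAML file or the name of a bundled
    preset (``hmm_sleep``, ``spiral_default``).
    """
    p = Path(name_or_path)
    if p.exists():
        text = p.read_text()
    else:
        ref = resources.files("tnvae").joinpath(f"presets/{name_or_path}.yaml")
        if not ref.is_file():
            raise ValidationError(f"unknown preset {name_or_path!r}")
        text = ref.read_text()
    raw = yaml.safe_load(text)
    kind = raw.pop("kind")
    if kind == "hmm":
        return HMMParams(**raw)
    if kind == "spiral":
        return SpiralParams(**raw)
    raise ValidationError(f"unknown preset kind {kind!r}")


def write_csv(ts: LabeledTimeSeries, path) -> None:
    """Write a series as `t, label, f0..f{D-1}` columnar text."""
    d = ts.dim
    df = pd.DataFrame(ts.X, columns=[f"f{i}" for i in range(d)])
    df.insert(0, "label", ts.labels if ts.labels is not None else pd.NA)
    df.insert(0, "t", ts.t)
    df.to_csv(path, index=False)


def read_csv(path) -> LabeledTimeSeries:
    """Read a series written by :func:`write_csv` (label column may be empty)."""
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise ValidationError("dataset CSV must have a 't' column")
    feat = [c for c in df.columns if c.startswith("f")]
    labels = None
    if "label" in df.columns and df["label"].notna().all():
        labels = df["label"].to_numpy(dtype=int)
    return LabeledTimeSeries(
        X=df[feat].to_numpy(dtype=float),
        t=df["t"].to_numpy(dtype=int),
        labels=labels,
    )
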