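"""Evaluation statistics for latent representations.

* neighbor loss — summed Euclidean distance between temporally adjacent
  latent encodings, normalized by the mean latent norm (the model-selection
  signal; scale/rotation invariant by construction);
* silhouette score — correspondence of encodings to ground-truth clusters;
* shape (Procrustes) distance — residual between two point sets after the
  best translation + rotation + reflection + scaling, used to compare two
  models' encodings of the same test data;
* per-cluster skew/kurtosis — diagnostic for non-Gaussian "feathering" of
  cluster encodings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import cdist

from .exceptions import ShapeError, UndefinedMetricError, ValidationError

__all__ = [
    "LatentTrajectory",
    "SilhouettePerSample",
    "neighbor_loss",
    "neighbor_loss_normalized",
    "silhouette",
    "procrustes_distance",
    "encoding_distance",
    "cluster_moments",
]


@dataclass
class LatentTrajectory:
    """Posterior-mean encodings in time order, with excluded transitions."""

    Z: np.ndarray  # (N, latent_dim)
    t: np.ndarray | None = None
    gaps: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if not np.all(np.isfinite(self.Z)):
            raise ValidationError("latent trajectory contains non-finite entries")
        if self.t is None:
            self.t = np.arange(self.Z.shape[0])
        self.t = np.asarray(self.t, dtype=int)
        if self.t.shape[0] != self.Z.shape[0]:
            raise ShapeError("t and Z are misaligned")
        self.gaps = frozenset(int(g) for g in self.gaps)

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    def transition_indices(self) -> np.ndarray:
        idx = np.arange(self.n - 1)
        if not self.gaps:
            return idx
        return idx[~np.isin(idx, sorted(self.gaps))]


@dataclass
class SilhouettePerSample:
    a: np.ndarray  # mean intra-cluster distance per point
    b: np.ndarray  # mean distance to the nearest other cluster per point
    s: np.ndarray  # (b - a) / max(a, b) per point


def _mean_norm(Z: np.ndarray) -> float:
    return float(np.mean(np.linalg.norm(Z, axis=1)))


def neighbor_loss(traj: LatentTrajectory) -> float:
    """Sum of ||z_{t+1} - z_t|| over included transitions, divided by the
    mean latent norm over all points. Raises when the trajectory is all-zero
    (the normalizer vanishes)."""
    if traj.n < 2:
        raise ValidationError("neighbor loss needs at least 2 points")
    idx = traj.transition_indices()
    if len(idx) == 0:
        raise ValidationError("no transitions included")
    zbar = _mean_norm(traj.Z)
    if zbar == 0.0:
        raise UndefinedMetricError("all-zero trajectory: mean latent norm is 0")
    steps = np.linalg.norm(traj.Z[idx + 1] - traj.Z[idx], axis=1)
    return float(steps.sum() / zbar)


def neighbor_loss_normalized(traj: LatentTrajectory) -> float:
    """Neighbor loss divided by the number of included transitions, so values
    are comparable across datasets of different length."""
    idx = traj.transition_indices()
    return neighbor_loss(traj) / len(idx)


def silhouette(Z: np.ndarray, labels: np.ndarray) -> tuple[float, SilhouettePerSample]:
    """Mean silhouette score plus the per-sample breakdown.

    For point i, a(i) is the mean distance to the other members of its own
    cluster and b(i) the mean distance to the members of the nearest other
    cluster; s(i) = (b - a) / max(a, b). Singleton clusters score 0 by
    convention. Requires at least two distinct labels.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    labels = np.asarray(labels)
    if labels.shape[0] != Z.shape[0]:
        raise ShapeError("labels and Z are misaligned")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("silhouette undefined for one cluster")

    D = cdist(Z, Z)
    n = Z.shape[0]
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(masks[c].sum()) for c in uniq}

    a = np.zeros(n)
    b = np.full(n, np.inf)
    for c in uniq:
        m = masks[c]
        sums_to_c = D[:, m].sum(axis=1)
        if sizes[c] > 1:
            # own cluster: the self-distance (zero) is excluded from the mean
            a[m] = sums_to_c[m] / (sizes[c] - 1)
        other = ~m
        b[other] = np.minimum(b[other], sums_to_c[other] / sizes[c])

    s = np.zeros(n)
    valid = np.array([sizes[l] > 1 for l in labels])
    denom = np.maximum(a, b)
    s[valid] = (b[valid] - a[valid]) / denom[valid]
    per = SilhouettePerSample(a=a, b=b, s=s)
    return float(s.mean()), per


def procrustes_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Shape discrepancy between two point sets.

    Both matrices are centered and scaled to unit Frobenius norm, the optimal
    orthogonal alignment (rotation + reflection) and scaling are applied, and
    the residual Euclidean distance is returned. Symmetric; zero iff B is a
    similarity transform of A.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape != B.shape:
        raise ShapeError(f"shape mismatch: {A.shape} vs {B.shape}")
    if A.shape[0] < A.shape[1]:
        raise ValidationError("need at least as many points as dimensions")
    try:
        _, _, disparity = _scipy_procrustes(A, B)
    except ValueError as e:  # zero-variance input
        raise UndefinedMetricError(f"degenerate input for shape distance: {e}") from None
    return float(np.sqrt(max(disparity, 0.0)))


def encoding_distance(model_a, model_b, test) -> float:
    """Shape distance between two models' posterior-mean encodings of the
    same test data. Models must expose ``encode_series`` (trained models) or
    ``encode`` over raw rows."""
    Za = _encodings(model_a, test)
    Zb = _encodings(model_b, test)
    return procrustes_distance(Za, Zb)


def _encodings(model, test) -> np.ndarray:
    if hasattr(model, "encode_series"):
        return model.encode_series(test).mean
    return model.encode(test.X if hasattr(test, "X") else test).mean


def cluster_moments(Z: np.ndarray, labels: np.ndarray):
    """Per-cluster, per-dimension sample skewness and excess kurtosis.

    Returns ``(summary, table)`` where ``table`` maps cluster label to a dict
    with 'skew' and 'kurtosis' arrays (one entry per latent dimension), and
    ``summary`` is the mean absolute value across clusters and dimensions —
    the scalar deviation-from-Gaussianity diagnostic. Clusters with fewer
    than 3 points are reported as missing (None), not fatal.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    labels = np.asarray(labels)
    table = {}
    sk_all, ku_all = [], []
    for c in np.unique(labels):
        pts = Z[labels == c]
        if pts.shape[0] < 3:
            table[c] = None
            continue
        sk = stats.skew(pts, axis=0, bias=False)
        ku = stats.kurtosis(pts, axis=0, fisher=True, bias=False)
        table[c] = {"skew": sk, "kurtosis": ku}
        sk_all.append(np.abs(sk))
        ku_all.append(np.abs(ku))
    summary = {
        "abs_skew": float(np.mean(sk_all)) if sk_all else float("nan"),
        "abs_kurtosis": float(np.mean(ku_all)) if ku_all else float("nan"),
    }
    return summary, table
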