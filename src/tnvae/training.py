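"""Single-model training and grid ensembles.

Data splits are defined over *transitions* (index t covers rows t and t+1):
a contiguous terminal block is held out as the test set — identical for every
seed, so encoding distances between model instances compare like with like —
and the remaining transitions are partitioned into train/validation uniformly
at random by seed. Features are z-scored with statistics fitted on the
training rows only.

Optimization is Adam on the objective from :mod:`tnvae.model`; after every
epoch the validation loss and validation neighbor loss are appended to the
history. The run is fully reproducible from ``(config.seed, split.seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import LabeledTimeSeries
from .exceptions import TrainingDivergedError, ValidationError
from .metrics import LatentTrajectory, neighbor_loss
from .model import VAE, VAEConfig, PosteriorParams, make_pairs

__all__ = [
    "SplitSpec",
    "SplitResult",
    "Normalizer",
    "TrainedModel",
    "split",
    "train",
    "expand_grid",
    "run_ensemble",
    "save_model",
    "load_model",
]

GRID_AXES = ("n_layers", "layer_dim", "latent_dim", "beta", "batch_size",
             "learning_rate", "seed", "predictive", "mc_samples")


@dataclass(frozen=True)
class SplitSpec:
    seed: int = 0
    val_fraction: float = 0.2
    test_fraction: float = 0.2

    def __post_init__(self):
        for name in ("val_fraction", "test_fraction"):
            f = getattr(self, name)
            if not 0.0 < f < 1.0:
                raise ValidationError(f"{name} must be in (0,1), got {f}")
        if self.val_fraction + self.test_fraction >= 1.0:
            raise ValidationError("val_fraction + test_fraction must be < 1")


@dataclass
class SplitResult:
    train: np.ndarray  # transition indices
    val: np.ndarray
    test: np.ndarray
    n_rows: int

    @property
    def test_row_start(self) -> int:
        """First row belonging exclusively to the terminal test block."""
        return int(self.test[0]) if len(self.test) else self.n_rows


@dataclass
class Normalizer:
    """Per-feature affine standardization fitted on training rows."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, rows: np.ndarray) -> "Normalizer":
        mean = rows.mean(axis=0)
        sd = rows.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return cls(mean=mean, sd=sd)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def split(ts: LabeledTimeSeries, spec: SplitSpec) -> SplitResult:
    """Partition the series' transitions into train/val/test index sets.

    The test set is the contiguous terminal block of transitions (size
    ``round(test_fraction * n_transitions)``); of the remainder,
    ``round(val_fraction * n_remaining)`` are drawn at random by seed for
    validation and the rest train the model.
    """
    trans = ts.transitions()
    n_trans = len(trans)
    n_test = int(round(spec.test_fraction * n_trans))
    n_test = max(n_test, 1)
    test = trans[n_trans - n_test:]
    rest = trans[: n_trans - n_test]
    n_val = max(int(round(spec.val_fraction * len(rest))), 1)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(len(rest))
    val = np.sort(rest[perm[:n_val]])
    tr = np.sort(rest[perm[n_val:]])
    if min(len(tr), len(val), len(test)) == 0:
        raise ValidationError(
            f"empty split part: train={len(tr)}, val={len(val)}, test={len(test)}"
        )
    return SplitResult(train=tr, val=val, test=test, n_rows=ts.n)


@dataclass
class TrainedModel:
    """A fitted network plus everything needed to reuse and audit it."""

    config: VAEConfig
    vae: VAE
    normalizer: Normalizer
    history: pd.DataFrame  # columns: epoch, train_loss, val_loss, val_nl
    split: SplitResult | None = None
    split_spec: SplitSpec | None = None

    def encode_series(self, ts: LabeledTimeSeries) -> PosteriorParams:
        """Posterior parameters for every row, in the model's feature scale."""
        return self.vae.encode(self.normalizer.apply(ts.X))

    def latent_trajectory(self, ts: LabeledTimeSeries) -> LatentTrajectory:
        """Posterior-mean trajectory over the series, honoring recorded gaps."""
        q = self.encode_series(ts)
        return LatentTrajectory(Z=q.mean, gaps=ts.gaps)

    def final(self, column: str) -> float:
        if len(self.history) == 0:
            raise ValidationError("model has no training history")
        return float(self.history[column].iloc[-1])


class _Adam:
    def __init__(self, params: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _validation_nl(vae: VAE, Xn: np.ndarray, split_res: SplitResult) -> float:
    """Neighbor loss over validation transitions.

    The trajectory covers every non-test row; transitions not in the
    validation set are recorded as gaps so only held-out steps contribute,
    while the normalizer (mean latent norm) reflects the whole manifold.
    For the predictive model the encoder output for row s is the latent
    attributed to s+1 — a uniform index shift that leaves step distances
    unchanged, so rows are encoded directly.
    """
    n_rows = split_res.test_row_start + 1  # rows 0 .. first test transition
    Z = vae.encode(Xn[:n_rows]).mean
    val = set(int(v) for v in split_res.val)
    gaps = frozenset(t for t in range(n_rows - 1) if t not in val)
    traj = LatentTrajectory(Z=Z, gaps=gaps)
    return neighbor_loss(traj)


def train(
    config: VAEConfig,
    ts: LabeledTimeSeries,
    spec: SplitSpec,
    epochs: int,
) -> TrainedModel:
    """Fit one model; returns parameters, normalizer, and per-epoch history."""
    split_res = split(ts, spec)
    x_in_rows = np.unique(split_res.train)
    normalizer = Normalizer.fit(ts.X[x_in_rows])
    Xn = normalizer.apply(ts.X)
    ts_n = LabeledTimeSeries(
        X=Xn, t=ts.t, labels=ts.labels, latent_truth=ts.latent_truth, gaps=ts.gaps
    )

    rng = np.random.default_rng([config.seed, spec.seed])
    vae = VAE(config, input_dim=ts.dim, rng=rng)
    opt = _Adam(vae.params, lr=config.learning_rate)

    tr_in, tr_tg, _ = make_pairs(ts_n, config.predictive, transitions=split_res.train)
    va_in, va_tg, _ = make_pairs(ts_n, config.predictive, transitions=split_res.val)

    records = []
    n_train = tr_in.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n_train)
        losses = []
        for start in range(0, n_train, config.batch_size):
            sel = order[start : start + config.batch_size]
            noise = rng.standard_normal((len(sel), config.latent_dim))
            comps, grads = vae.loss_and_grads(tr_in[sel], tr_tg[sel], noise=noise)
            if not np.isfinite(comps.total):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} (config={config})"
                )
            opt.step(vae.params, grads)
            losses.append(comps.total)
        val_noise = rng.standard_normal((va_in.shape[0], config.latent_dim))
        val_comps = vae.loss(va_in, va_tg, noise=val_noise)
        if not np.isfinite(val_comps.total):
            raise TrainingDivergedError(
                f"non-finite validation loss at epoch {epoch} (config={config})"
            )
        records.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_comps.total,
                "val_nl": _validation_nl(vae, Xn, split_res),
            }
        )

    history = pd.DataFrame(records, columns=["epoch", "train_loss", "val_loss", "val_nl"])
    return TrainedModel(
        config=config,
        vae=vae,
        normalizer=normalizer,
        history=history,
        split=split_res,
        split_spec=spec,
    )


def expand_grid(axes: dict) -> list[VAEConfig]:
    """Full Cartesian product of named hyperparameter axes, in deterministic
    lexicographic order (axis order as given, values in listed order)."""
    for name, values in axes.items():
        if name not in GRID_AXES:
            raise ValidationError(
                f"unknown axis {name!r}; valid axes: {', '.join(GRID_AXES)}"
            )
        if not values:
            raise ValidationError(f"axis {name!r} is empty")
    names = list(axes)
    configs = []
    for combo in product(*(axes[n] for n in names)):
        configs.append(VAEConfig(**dict(zip(names, combo))))
    return configs


# ---------------------------------------------------------------------------
# Ensembles with incremental checkpointing
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model to a single .npz archive (versioned)."""
    payload = {f"param_{k}": v for k, v in model.vae.params.items()}
    payload["norm_mean"] = model.normalizer.mean
    payload["norm_sd"] = model.normalizer.sd
    payload["history"] = model.history.to_numpy()
    meta = {
        "format_version": 1,
        "config": dataclasses.asdict(model.config),
        "input_dim": model.vae.input_dim,
        "history_columns": list(model.history.columns),
        "split_spec": dataclasses.asdict(model.split_spec) if model.split_spec else None,
    }
    payload["meta_json"] = np.array(json.dumps(meta))
    np.savez_compressed(path, **payload)


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta_json"]))
        config = VAEConfig(**meta["config"])
        vae = VAE(config, input_dim=meta["input_dim"])
        vae.params = {
            k[len("param_"):]: z[k] for k in z.files if k.startswith("param_")
        }
        normalizer = Normalizer(mean=z["norm_mean"], sd=z["norm_sd"])
        history = pd.DataFrame(z["history"], columns=meta["history_columns"])
    spec = SplitSpec(**meta["split_spec"]) if meta["split_spec"] else None
    return TrainedModel(
        config=config, vae=vae, normalizer=normalizer, history=history, split_spec=spec
    )


def run_ensemble(
    grid: list[VAEConfig],
    ts: LabeledTimeSeries,
    spec_template: SplitSpec,
    epochs: int,
    out_dir=None,
    resume: bool = False,
    progress=None,
) -> list[TrainedModel]:
    """Train one model per grid cell (the cell's seed drives both the data
    partition and the initialization). With ``out_dir`` set, each cell is
    checkpointed as ``cell_XXXX.npz`` and a ``manifest.json`` records status;
    interrupted runs resume by completing only the missing cells. A failing
    cell is recorded in the manifest and the run continues.
    """
    if not grid:
        raise ValidationError("empty hyperparameter grid")
    out = Path(out_dir) if out_dir is not None else None
    manifest_path = out / "manifest.json" if out else None
    manifest = []
    if out:
        out.mkdir(parents=True, exist_ok=True)
        if resume and manifest_path.exists():
            manifest = json.loads(manifest_path.read_text())
    done = {
        m["cell"]
        for m in manifest
        if m["status"] == "done" and (out / m["path"]).exists()
    }

    models: list[TrainedModel] = []
    for i, config in enumerate(grid):
        spec = dataclasses.replace(spec_template, seed=config.seed)
        cell_name = f"cell_{i:04d}.npz"
        if i in done:
            models.append(load_model(out / cell_name))
            continue
        entry = {"cell": i, "config": dataclasses.asdict(config), "path": cell_name}
        try:
            model = train(config, ts, spec, epochs)
        except Exception as e:  # noqa: BLE001 - single-cell failure is data
            entry.update(status="failed", error=f"{type(e).__name__}: {e}")
            models.append(None)
        else:
            if out:
                save_model(model, out / cell_name)
            entry["status"] = "done"
            models.append(model)
        manifest = [m for m in manifest if m["cell"] != i] + [entry]
        if out:
            manifest.sort(key=lambda m: m["cell"])
            manifest_path.write_text(json.dumps(manifest, indent=1))
        if progress is not None:
            progress(i, len(grid))
    return models
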