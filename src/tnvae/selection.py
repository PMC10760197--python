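"""Model selection and ensemble-level analyses.

Two selection criteria are compared throughout: final validation loss (the
conventional choice) and final validation neighbor loss (the temporal-
smoothness criterion). The ensemble report gathers, per trained model, the
final criteria and the silhouette of its test-set encodings against ground
truth, plus pairwise encoding distances between model instances, and the rank
correlations that link criteria to representation quality and robustness.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import LabeledTimeSeries
from .exceptions import ValidationError
from .metrics import cluster_moments, encoding_distance, procrustes_distance, silhouette
from .training import TrainedModel

__all__ = ["EnsembleReport", "select", "ensemble_analysis", "selection_comparison"]

_CRITERIA = {"val_loss": "val_loss", "neighbor_loss": "val_nl", "nl": "val_nl"}


def _final(model, column: str) -> float:
    return float(model.history[column].iloc[-1])


def select(models: list, criterion: str) -> int:
    """Index of the model minimizing the final-epoch criterion.

    Ties are broken by the other criterion, then by position in the ensemble,
    so the result is deterministic and order-invariant up to exact ties.
    """
    if criterion not in _CRITERIA:
        raise ValidationError(f"criterion must be one of {sorted(_CRITERIA)}")
    models = [m for m in models]
    if not models:
        raise ValidationError("empty ensemble")
    col = _CRITERIA[criterion]
    other = "val_nl" if col == "val_loss" else "val_loss"
    keys = []
    for i, m in enumerate(models):
        v = _final(m, col)
        if not np.isfinite(v):
            raise ValidationError(f"non-finite {col} for model {i}")
        keys.append((v, _final(m, other), i))
    return min(keys)[2]


def _spearman(x, y):
    """Spearman rho with n; undefined (None) for constant input, never 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": None, "p": None, "n": n, "reason": "constant or tiny sample"}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": n}


def _pearson(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or np.all(x == x[0]) or np.all(y == y[0]):
        return {"rho": None, "p": None, "n": n, "reason": "constant or tiny sample"}
    r, p = stats.pearsonr(x, y)
    return {"rho": float(r), "p": float(p), "n": n}


@dataclass
class EnsembleReport:
    rows: pd.DataFrame  # one record per model
    pairs: pd.DataFrame  # one record per model pair
    correlations: dict
    pairing: str
    excluded: list = field(default_factory=list)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "pairing": self.pairing,
            "correlations": self.correlations,
            "rows": self.rows.to_dict(orient="records"),
            "pairs": self.pairs.to_dict(orient="records"),
            "excluded": self.excluded,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


def _test_encodings(model, test: LabeledTimeSeries):
    """Posterior-mean test encodings and aligned truth-label slice.

    For predictive models the encoder output for row t parameterizes the
    latent of t+1, so encodings of rows[:-1] are paired with labels[1:].
    """
    Z = model.encode_series(test).mean
    if getattr(model.config, "predictive", False):
        return Z[:-1], slice(1, None)
    return Z, slice(None)


def ensemble_analysis(
    models: list,
    test: LabeledTimeSeries,
    truth_labels: np.ndarray,
    pairing: str = "within_config",
    correlation: str = "spearman",
    max_pairs: int = 500,
    seed: int = 0,
) -> EnsembleReport:
    """Per-model metrics, pairwise encoding distances, and rank correlations.

    ``pairing`` is either ``"within_config"`` (pairs of model instances
    sharing hyperparameters, differing only in seed) or ``"all"``; when the
    pair count exceeds ``max_pairs``, a uniform subsample (fixed by ``seed``)
    is analyzed. Models that fail to encode the test set are excluded with a
    logged reason.
    """
    if pairing not in ("within_config", "all"):
        raise ValidationError("pairing must be 'within_config' or 'all'")
    corr = {"spearman": _spearman, "pearson": _pearson}[correlation]
    truth_labels = np.asarray(truth_labels)

    rows, encs, excluded = [], {}, []
    for i, m in enumerate(models):
        if m is None:
            excluded.append({"model": i, "reason": "training failed"})
            continue
        try:
            Z, lab_slice = _test_encodings(m, test)
            score, _ = silhouette(Z, truth_labels[lab_slice])
            moments, _ = cluster_moments(Z, truth_labels[lab_slice])
        except Exception as e:  # noqa: BLE001 - exclusion is part of the report
            excluded.append({"model": i, "reason": f"{type(e).__name__}: {e}"})
            continue
        encs[i] = Z
        rows.append(
            {
                "model": i,
                "config_key": str(m.config.key()),
                "seed": m.config.seed,
                "val_loss": _final(m, "val_loss"),
                "val_nl": _final(m, "val_nl"),
                "silhouette": score,
                "abs_skew": moments["abs_skew"],
                "abs_kurtosis": moments["abs_kurtosis"],
            }
        )
    rows = pd.DataFrame(rows)
    if rows.empty:
        raise ValidationError("no model could encode the test set")

    if pairing == "within_config":
        pair_idx = [
            (int(a), int(b))
            for _, grp in rows.groupby("config_key", sort=True)
            for a, b in combinations(sorted(grp["model"]), 2)
        ]
    else:
        pair_idx = list(combinations(sorted(rows["model"]), 2))
    if len(pair_idx) > max_pairs:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(pair_idx), size=max_pairs, replace=False)
        pair_idx = [pair_idx[k] for k in sorted(keep)]

    by_model = rows.set_index("model")
    pair_records = []
    for a, b in pair_idx:
        # encodings share the test block, so shapes agree within a pairing
        d = procrustes_distance(encs[a], encs[b])
        pair_records.append(
            {
                "model_a": a,
                "model_b": b,
                "encoding_distance": d,
                "mean_val_loss": (by_model.loc[a, "val_loss"] + by_model.loc[b, "val_loss"]) / 2,
                "mean_val_nl": (by_model.loc[a, "val_nl"] + by_model.loc[b, "val_nl"]) / 2,
            }
        )
    pairs = pd.DataFrame(
        pair_records,
        columns=["model_a", "model_b", "encoding_distance", "mean_val_loss", "mean_val_nl"],
    )

    correlations = {
        "val_nl_vs_silhouette": corr(rows["val_nl"], rows["silhouette"]),
        "val_loss_vs_silhouette": corr(rows["val_loss"], rows["silhouette"]),
    }
    if len(pairs) >= 2:
        correlations["val_nl_vs_encoding_distance"] = corr(
            pairs["mean_val_nl"], pairs["encoding_distance"]
        )
        correlations["val_loss_vs_encoding_distance"] = corr(
            pairs["mean_val_loss"], pairs["encoding_distance"]
        )
    return EnsembleReport(
        rows=rows, pairs=pairs, correlations=correlations, pairing=pairing, excluded=excluded
    )


def selection_comparison(
    vae_models: list,
    tnvae_models: list,
    test: LabeledTimeSeries,
    truth_labels: np.ndarray,
    k: int = 5,
) -> pd.DataFrame:
    """Three-arm comparison table.

    Arms: (standard, val-loss selection), (predictive, val-loss selection),
    (predictive, neighbor-loss selection). Each arm reports the selected
    model's test silhouette and the mean pairwise encoding distance among the
    arm's top-k models (missing when k < 2 applies).
    """
    truth_labels = np.asarray(truth_labels)
    arms = [
        ("vae", "val_loss", vae_models),
        ("tnvae", "val_loss", tnvae_models),
        ("tnvae", "neighbor_loss", tnvae_models),
    ]
    records = []
    for arch, criterion, models in arms:
        models = [m for m in models if m is not None]
        best = select(models, criterion)
        Z, lab_slice = _test_encodings(models[best], test)
        score, _ = silhouette(Z, truth_labels[lab_slice])
        col = _CRITERIA[criterion]
        order = np.argsort([_final(m, col) for m in models], kind="stable")
        top = [models[i] for i in order[: min(k, len(models))]]
        if len(top) >= 2:
            dists = [
                encoding_distance(a, b, test) for a, b in combinations(top, 2)
            ]
            spread = float(np.mean(dists))
        else:
            spread = None
        records.append(
            {
                "architecture": arch,
                "criterion": criterion,
                "selected": best,
                "selected_silhouette": score,
                "top_k": len(top),
                "encoding_distance_spread": spread,
            }
        )
    return pd.DataFrame(records)
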