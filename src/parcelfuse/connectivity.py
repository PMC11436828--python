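"""Cortico-cerebellar connectivity by ridge regression.

For each subject, cortical parcel activity ``X`` (conditions x Q) predicts
cerebellar voxel activity ``Y`` (conditions x P) through ``Y = X W``; ``W``
is fit by ridge regression with a per-dataset penalty tuned to maximize
cross-dataset prediction. Evaluation averages ``W`` across training
subjects (leave-one-subject-out when training and evaluation datasets
coincide), predicts the held-out subject's cerebellar patterns, and scores
with cosine similarity. Fusing models from several datasets is a plain
average of their weights — again always excluding the evaluated subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin


@dataclass
class ConnectivityModel:
    """A fitted weight matrix with its provenance."""

    W: np.ndarray  # (Q, P)
    lam: float
    train_dataset: str = ""
    subject: str | None = None  # None = average over subjects

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if not np.all(np.isfinite(self.W)):
            raise ValueError("W must be finite")


@dataclass
class ConnectivityData:
    """Matched cortical/cerebellar matrices for one dataset's subjects."""

    dataset_id: str
    subjects: list
    X: np.ndarray  # (S, N, Q)
    Y: np.ndarray  # (S, N, P)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.shape[:2] != self.Y.shape[:2]:
            raise ValueError("X and Y must match in subjects and conditions")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]


def fit_ridge(X: np.ndarray, Y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge solution ``W = (X'X + lam I)^-1 X'Y``."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    G = X.T @ X
    if lam == 0.0:
        if np.linalg.matrix_rank(G) < G.shape[0]:
            raise ValueError("rank-deficient X requires lambda > 0")
        return linalg.solve(G, X.T @ Y, assume_a="sym")
    return linalg.solve(G + lam * np.eye(G.shape[0]), X.T @ Y, assume_a="pos")


def fit_subject_models(data: ConnectivityData, lam: float) -> list[ConnectivityModel]:
    return [
        ConnectivityModel(
            W=fit_ridge(data.X[s], data.Y[s], lam),
            lam=lam,
            train_dataset=data.dataset_id,
            subject=data.subjects[s],
        )
        for s in range(data.n_subjects)
    ]


def evaluate_connectivity(
    models: list[ConnectivityModel],
    eval_data: ConnectivityData,
    same_dataset: bool | None = None,
) -> np.ndarray:
    """Per-subject cosine similarity of predicted vs observed patterns.

    For each evaluation subject the weights are averaged over all supplied
    models except any trained on that same subject of the same dataset
    (the leave-one-subject-out rule; ``same_dataset`` merely asserts the
    expectation). A zero prediction scores 0 by convention.
    """
    if not models:
        raise ValueError("no models to evaluate")
    scores = np.zeros(eval_data.n_subjects)
    for s in range(eval_data.n_subjects):
        usable = [
            m
            for m in models
            if not (
                m.train_dataset == eval_data.dataset_id
                and m.subject == eval_data.subjects[s]
            )
        ]
        if not usable:
            raise ValueError("no training model left after leave-one-subject-out")
        if same_dataset and len(usable) == len(models):
            raise ValueError("same-dataset evaluation requires a left-out subject model")
        W = np.mean([m.W for m in usable], axis=0)
        pred = eval_data.X[s] @ W
        scores[s] = cosine_score(pred, eval_data.Y[s])
    return scores


def cosine_score(pred: np.ndarray, obs: np.ndarray) -> float:
    """Cosine similarity of the concatenated voxel patterns; 0 if degenerate."""
    p = pred.ravel()
    o = obs.ravel()
    denom = np.linalg.norm(p) * np.linalg.norm(o)
    if denom == 0:
        return 0.0
    return float(p @ o / denom)


def tune_lambda(datasets: list[ConnectivityData], grid: list[float]) -> dict[str, float]:
    """Per-dataset ridge penalty maximizing mean cross-dataset score.

    For each training dataset, candidate penalties are scored by fitting
    per-subject models and evaluating their average on every *other*
    dataset; ties break to the smallest penalty. Needs >= 2 datasets.
    """
    if len(grid) == 0:
        raise ValueError("empty lambda grid")
    if len(datasets) < 2:
        raise ValueError("cross-dataset tuning needs at least 2 datasets")
    out: dict[str, float] = {}
    for train in datasets:
        best_lam, best_score = None, -np.inf
        for lam in sorted(grid):
            models = fit_subject_models(train, lam)
            score = np.mean(
                [
                    evaluate_connectivity(models, other).mean()
                    for other in datasets
                    if other.dataset_id != train.dataset_id
                ]
            )
            if score > best_score:
                best_lam, best_score = lam, score
        out[train.dataset_id] = float(best_lam)
    return out


def fuse_connectivity(models: list[ConnectivityModel]) -> ConnectivityModel:
    """Elementwise mean of the weight matrices across models."""
    if not models:
        raise ValueError("nothing to fuse")
    shapes = {m.W.shape for m in models}
    if len(shapes) > 1:
        raise ValueError("weight shape mismatch across models")
    W = np.mean([m.W for m in models], axis=0)
    return ConnectivityModel(
        W=W, lam=float(np.mean([m.lam for m in models])), train_dataset="fused"
    )


def noise_ceiling_adjust(score: float, rel_cereb: float, rel_pred: float) -> float:
    """Score divided by the noise ceiling sqrt(rel_cereb * rel_pred);
    reliabilities come from split-half correlations and must be in (0, 1]."""
    if rel_cereb <= 0 or rel_pred <= 0:
        raise ValueError("reliabilities must be positive")
    return float(score / np.sqrt(rel_cereb * rel_pred))


def network_summary(
    model: ConnectivityModel,
    network_labels: np.ndarray,
    region_labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean connectivity weight per (cerebellar region, cortical network).

    ``network_labels`` assigns each of the Q cortical parcels to a network
    (all must be labeled); ``region_labels`` groups the P cerebellar voxels
    (default: one global region). Rows are regions, columns networks.
    """
    network_labels = np.asarray(network_labels)
    Q, P = model.W.shape
    if network_labels.shape != (Q,) or pd.isnull(network_labels).any():
        raise ValueError("every cortical parcel needs a network label")
    if region_labels is None:
        region_labels = np.zeros(P, dtype=int)
    region_labels = np.asarray(region_labels)
    networks = np.unique(network_labels)
    regions = np.unique(region_labels)
    table = np.zeros((regions.size, networks.size))
    for i, r in enumerate(regions):
        cols = region_labels == r
        for j, nw in enumerate(networks):
            rows = network_labels == nw
            table[i, j] = model.W[np.ix_(rows, cols)].mean()
    return pd.DataFrame(table, index=regions, columns=networks)


class RidgeConnectivity(BaseEstimator, RegressorMixin):
    """Closed-form multi-output ridge, estimator-style.

    ``fit(X, Y)`` with X (N, Q) and Y (N, P) sets ``W_`` to
    ``(X'X + alpha I)^-1 X'Y``; ``predict`` maps cortical patterns to
    cerebellar ones and ``score`` is the cosine similarity of prediction
    and observation.
    """

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def fit(self, X, y):
        self.W_ = fit_ridge(X, y, self.alpha)
        return self

    def predict(self, X):
        if not hasattr(self, "W_"):
            raise AttributeError("estimator is not fitted")
        return np.asarray(X, dtype=float) @ self.W_

    def score(self, X, y):
        return cosine_score(self.predict(X), np.asarray(y, dtype=float))


DEFAULT_LAMBDA_GRID = list(np.logspace(-2, 4, 7))


def make_connectivity_world(
    n_datasets: int = 3,
    n_subjects: int = 5,
    n_conditions: int = 40,
    Q: int = 20,
    P: int = 30,
    dataset_sd: float = 0.1,
    noise_sd: float = 1.0,
    seed=None,
) -> tuple[np.ndarray, list[ConnectivityData]]:
    """Synthetic multi-dataset connectivity world with a shared true W.

    All datasets share a ground-truth weight matrix plus a small
    dataset-level perturbation (functional organization is similar but not
    identical across studies); each subject observes ``Y = X W_d + noise``
    with its own design and measurement noise. Returns the shared truth and
    the per-dataset data.
    """
    rng = np.random.default_rng(seed)
    W_true = rng.standard_normal((Q, P))
    datasets = []
    for d in range(n_datasets):
        W_d = W_true + dataset_sd * rng.standard_normal((Q, P))
        X = rng.standard_normal((n_subjects, n_conditions, Q))
        noise = noise_sd * rng.standard_normal((n_subjects, n_conditions, P))
        Y = np.einsum("snq,qp->snp", X, W_d) + noise
        datasets.append(
            ConnectivityData(
                dataset_id=f"conn{d}",
                subjects=[f"conn{d}-s{s:02d}" for s in range(n_subjects)],
                X=X,
                Y=Y,
            )
        )
    return W_true, datasets
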