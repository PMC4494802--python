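"""Nearest-shrunken-centroid (PAM-style) classification on log expression.

The classifier standardizes class-centroid deviations from the overall
centroid, soft-thresholds them by a shrinkage amount delta (which performs
gene selection), and classifies a new profile by the standardized squared
distance to each shrunken centroid with a prior-correction term.  It is the
model used here for breast-cancer receptor status (binary) and intrinsic
molecular subtype (Basal / HER2 / Luminal A / Luminal B).

Notation: for gene j and class k with n_k of n training samples,

    d_kj  = (xbar_kj - xbar_j) / (m_k (s_j + s0)),   m_k = sqrt(1/n_k + 1/n)
    d'_kj = sign(d_kj) max(|d_kj| - delta, 0)
    xbar'_kj = xbar_j + m_k (s_j + s0) d'_kj

with s_j the pooled within-class standard deviation, s0 the median of s_j,
and priors pi_k = n_k / n.  Discriminant score for profile x:

    delta_k(x) = sum_{j selected} (x_j - xbar'_kj)^2 / (s_j + s0)^2 - 2 ln pi_k

The predicted label is argmin delta_k; class probabilities are proportional
to exp(-delta_k / 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .errors import TrainingError

__all__ = [
    "CentroidStats",
    "CentroidModel",
    "Prediction",
    "fit_centroids",
    "shrink",
    "predict",
    "cross_validate",
    "train",
]


@dataclass
class CentroidStats:
    """Unshrunk training statistics, the input to :func:`shrink`."""

    classes: list[str]
    gene_ids: list[str]
    overall_centroid: np.ndarray  # (G,)
    class_centroids: np.ndarray  # (K, G)
    pooled_sd: np.ndarray  # (G,)
    s0: float
    m_k: np.ndarray  # (K,)
    priors: np.ndarray  # (K,)
    class_sizes: np.ndarray  # (K,)

    @property
    def d(self) -> np.ndarray:
        """Standardized centroid deviations d_kj (zero where s_j + s0 = 0)."""
        denom = self.m_k[:, None] * (self.pooled_sd + self.s0)[None, :]
        d = np.zeros_like(self.class_centroids)
        ok = denom > 0
        diff = self.class_centroids - self.overall_centroid[None, :]
        d[ok] = diff[ok] / denom[ok]
        return d


@dataclass
class CentroidModel:
    """A shrunken-centroid classifier at a fixed shrinkage delta."""

    name: str
    classes: list[str]
    gene_ids: list[str]
    overall_centroid: np.ndarray
    shrunk_centroids: np.ndarray  # (K, G)
    pooled_sd: np.ndarray
    s0: float
    m_k: np.ndarray
    priors: np.ndarray
    delta: float
    selected: np.ndarray  # (G,) bool
    cv_errors: dict | None = field(default=None, repr=False)

    @property
    def selected_genes(self) -> list[str]:
        return [g for g, s in zip(self.gene_ids, self.selected) if s]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "classes": list(self.classes),
            "gene_ids": list(self.gene_ids),
            "overall_centroid": self.overall_centroid.tolist(),
            "shrunk_centroids": self.shrunk_centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "m_k": self.m_k.tolist(),
            "priors": self.priors.tolist(),
            "delta": self.delta,
            "selected": [bool(s) for s in self.selected],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CentroidModel":
        return cls(
            name=d["name"],
            classes=list(d["classes"]),
            gene_ids=list(d["gene_ids"]),
            overall_centroid=np.asarray(d["overall_centroid"], dtype=float),
            shrunk_centroids=np.asarray(d["shrunk_centroids"], dtype=float),
            pooled_sd=np.asarray(d["pooled_sd"], dtype=float),
            s0=float(d["s0"]),
            m_k=np.asarray(d["m_k"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float),
            delta=float(d["delta"]),
            selected=np.asarray(d["selected"], dtype=bool),
        )


@dataclass
class Prediction:
    label: str
    probabilities: dict[str, float]
    discriminants: dict[str, float]
    uninformative: bool = False


def fit_centroids(X: np.ndarray, y, gene_ids=None) -> CentroidStats:
    """Compute unshrunk centroid statistics from log expression.

    Parameters
    ----------
    X : (n_samples, n_genes) array of log2 expression.
    y : per-sample class labels; every class needs >= 2 samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise TrainingError("X and y dimensions disagree")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TrainingError("need at least 2 classes")
    if (counts < 2).any():
        small = classes[counts < 2].tolist()
        raise TrainingError(f"classes with fewer than 2 samples: {small}")
    n, n_genes = X.shape
    if gene_ids is None:
        gene_ids = [f"g{j}" for j in range(n_genes)]

    overall = X.mean(axis=0)
    class_centroids = np.vstack([X[y == c].mean(axis=0) for c in classes])
    ss = np.zeros(n_genes)
    for idx, c in enumerate(classes):
        resid = X[y == c] - class_centroids[idx]
        ss += (resid**2).sum(axis=0)
    pooled_sd = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(pooled_sd))
    m_k = np.sqrt(1.0 / counts + 1.0 / n)
    priors = counts / n
    return CentroidStats(
        classes=[str(c) for c in classes],
        gene_ids=list(gene_ids),
        overall_centroid=overall,
        class_centroids=class_centroids,
        pooled_sd=pooled_sd,
        s0=s0,
        m_k=m_k,
        priors=priors,
        class_sizes=counts,
    )


def shrink(stats: CentroidStats, delta: float, name: str = "classifier") -> CentroidModel:
    """Soft-threshold the standardized deviations by ``delta``.

    At delta = 0 the shrunken centroids equal the class centroids exactly and
    every gene with positive standardized scale is selected.
    """
    if delta < 0:
        raise TrainingError("delta must be >= 0")
    d = stats.d
    d_shrunk = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    scale = stats.m_k[:, None] * (stats.pooled_sd + stats.s0)[None, :]
    shrunk = stats.overall_centroid[None, :] + scale * d_shrunk
    if delta == 0:
        selected = (stats.pooled_sd + stats.s0) > 0
    else:
        selected = (d_shrunk != 0).any(axis=0)
    return CentroidModel(
        name=name,
        classes=list(stats.classes),
        gene_ids=list(stats.gene_ids),
        overall_centroid=stats.overall_centroid.copy(),
        shrunk_centroids=shrunk,
        pooled_sd=stats.pooled_sd.copy(),
        s0=stats.s0,
        m_k=stats.m_k.copy(),
        priors=stats.priors.copy(),
        delta=float(delta),
        selected=selected,
    )


def predict(model: CentroidModel, x: np.ndarray) -> Prediction:
    """Classify one log-expression profile aligned to ``model.gene_ids``.

    Missing values (NaN) are imputed with the overall centroid, with a
    warning.  With no selected genes the call falls back to the priors and is
    flagged uninformative.
    """
    x = np.asarray(x, dtype=float).copy()
    if x.shape != model.overall_centroid.shape:
        raise TrainingError(
            f"profile has {x.shape} genes, model expects {model.overall_centroid.shape}"
        )
    missing = np.isnan(x)
    if missing.any():
        warnings.warn(
            f"{model.name}: imputed {int(missing.sum())} missing genes with "
            "the overall centroid",
            stacklevel=2,
        )
        x[missing] = model.overall_centroid[missing]

    uninformative = not model.selected.any()
    if uninformative:
        disc = -2.0 * np.log(model.priors)
    else:
        sel = model.selected
        denom = (model.pooled_sd[sel] + model.s0) ** 2
        diff = x[sel][None, :] - model.shrunk_centroids[:, sel]
        disc = (diff**2 / denom[None, :]).sum(axis=1) - 2.0 * np.log(model.priors)
    shifted = -(disc - disc.min()) / 2.0
    w = np.exp(shifted)
    probs = w / w.sum()
    label = model.classes[int(np.argmin(disc))]
    return Prediction(
        label=label,
        probabilities={c: float(p) for c, p in zip(model.classes, probs)},
        discriminants={c: float(v) for c, v in zip(model.classes, disc)},
        uninformative=uninformative,
    )


def _fold_splitter(y: np.ndarray, k_folds: int, seed: int) -> StratifiedKFold:
    _, counts = np.unique(y, return_counts=True)
    min_class = int(counts.min())
    if min_class < 2:
        raise TrainingError("stratified CV needs >= 2 samples per class")
    k = min(k_folds, min_class)
    if k < k_folds:
        warnings.warn(
            f"reduced CV folds from {k_folds} to {k}: smallest class has "
            f"{min_class} samples",
            stacklevel=3,
        )
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)


def cross_validate(X, y, delta_grid, k_folds: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified k-fold CV error rate for every delta in ``delta_grid``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    delta_grid = np.asarray(delta_grid, dtype=float)
    splitter = _fold_splitter(y, k_folds, seed)
    errors = np.zeros(len(delta_grid))
    n_total = 0
    for train_idx, test_idx in splitter.split(X, y):
        stats = fit_centroids(X[train_idx], y[train_idx])
        n_total += len(test_idx)
        for di, delta in enumerate(delta_grid):
            model = shrink(stats, delta)
            preds = [predict(model, x).label for x in X[test_idx]]
            errors[di] += sum(p != str(t) for p, t in zip(preds, y[test_idx]))
    return errors / n_total


def train(
    X,
    y,
    name: str = "classifier",
    gene_ids=None,
    delta_grid=None,
    k_folds: int = 10,
    seed: int = 0,
) -> CentroidModel:
    """Fit, cross-validate over a delta grid, and return the selected model.

    The grid defaults to 30 points from 0 to max|d_kj|.  The selected delta
    minimizes CV error; ties break toward the largest delta (fewest genes).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    stats = fit_centroids(X, y, gene_ids=gene_ids)
    if delta_grid is None:
        dmax = float(np.abs(stats.d).max())
        delta_grid = np.linspace(0.0, dmax, 30)
    delta_grid = np.asarray(delta_grid, dtype=float)
    cv_err = cross_validate(X, y, delta_grid, k_folds=k_folds, seed=seed)
    best_err = cv_err.min()
    # ties break toward the largest delta (fewest genes)
    best_idx = int(np.flatnonzero(cv_err == best_err)[-1])
    model = shrink(stats, float(delta_grid[best_idx]), name=name)
    model.cv_errors = {
        "delta_grid": delta_grid.tolist(),
        "cv_error": cv_err.tolist(),
        "selected_delta": float(delta_grid[best_idx]),
        "selected_error": float(best_err),
        "k_folds": k_folds,
        "seed": seed,
    }
    return model
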