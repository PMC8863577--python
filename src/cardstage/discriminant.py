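"""O-PLS-DA classification with repeated 70/30 split evaluation.

Orthogonal projections to latent structures discriminant analysis:
predictor variation orthogonal to the class contrast is removed by a
small number of orthogonal components before a single predictive PLS
component is fitted.  Marker panels are benchmarked by stratified
70%/30% train/test splits, iterated (1,000 times in the reference
protocol), scoring each held-out set by AUROC; the split indices are
shared across panels within an iteration so panel comparisons are
paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ValidationError

__all__ = [
    "OplsModel",
    "SplitEvaluation",
    "fit_oplsda",
    "predict_scores",
    "auroc",
    "repeated_split_evaluate",
    "external_validate",
]


@dataclass
class OplsModel:
    """A fitted O-PLS-DA model (one predictive component).

    Scores of new data are obtained by standardizing with the training
    center/scale, sequentially removing the orthogonal components, and
    projecting on the predictive weights.
    """

    feature_names: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    w_pred: np.ndarray  # unit-norm predictive weights
    q_pred: float  # inner y-loading
    w_orth: np.ndarray  # (p, k) unit-norm orthogonal weights
    p_orth: np.ndarray  # (p, k) orthogonal loadings
    y_mean: float
    scores_train: np.ndarray = field(repr=False, default=None)
    orth_scores_train: np.ndarray = field(repr=False, default=None)

    @property
    def n_orth(self) -> int:
        return self.w_orth.shape[1]


def _standardize(x: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    return (x - mean) / scale


def fit_oplsda(x, y, n_orth: int = 1, scaling: str = "uv") -> OplsModel:
    """Fit an O-PLS-DA model with ``n_orth`` orthogonal components.

    ``x`` is subjects x features (DataFrame or array), ``y`` binary
    labels.  Features are mean-centered and scaled to unit variance
    (``scaling="uv"``) or by the square root of the standard deviation
    (``scaling="pareto"``); constant columns are dropped.  The fit is
    fully deterministic.
    """
    names = list(x.columns) if isinstance(x, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(x).shape[1])
    ]
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float).ravel()
    if xa.shape[0] != ya.size:
        raise ValidationError("fit_oplsda: X and y length mismatch")
    if xa.shape[0] < 10:
        raise ValidationError("fit_oplsda: need at least 10 subjects")
    classes = np.unique(ya)
    if classes.size != 2:
        raise ValidationError(f"fit_oplsda: need 2 classes, got {classes.size}")

    sd = xa.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValidationError("fit_oplsda: all feature columns constant")
    xa = xa[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    mean = xa.mean(axis=0)
    if scaling == "uv":
        scale = sd[keep]
    elif scaling == "pareto":
        scale = np.sqrt(sd[keep])
    else:
        raise ValidationError(f"unknown scaling {scaling!r}")
    xc = _standardize(xa, mean, scale)
    y_mean = float(ya.mean())
    yc = ya - y_mean

    max_orth = min(xc.shape) - 1
    if n_orth < 0 or n_orth > max_orth:
        raise ValidationError(
            f"n_orth={n_orth} out of range for rank (max {max_orth})"
        )

    w_orths, p_orths, t_orths = [], [], []
    for _ in range(n_orth):
        w = xc.T @ yc / (yc @ yc)
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = xc @ w
        p = xc.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:  # no y-orthogonal variation left
            break
        w_o /= n_o
        t_o = xc @ w_o
        p_o = xc.T @ t_o / (t_o @ t_o)
        xc = xc - np.outer(t_o, p_o)
        w_orths.append(w_o)
        p_orths.append(p_o)
        t_orths.append(t_o)

    w = xc.T @ yc / (yc @ yc)
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValidationError("fit_oplsda: predictor/class covariance is zero")
    w /= nw
    t = xc @ w
    q = float(yc @ t / (t @ t))

    return OplsModel(
        feature_names=names,
        x_mean=mean,
        x_scale=scale,
        w_pred=w,
        q_pred=q,
        w_orth=(
            np.column_stack(w_orths) if w_orths else np.empty((xc.shape[1], 0))
        ),
        p_orth=(
            np.column_stack(p_orths) if p_orths else np.empty((xc.shape[1], 0))
        ),
        y_mean=y_mean,
        scores_train=t,
        orth_scores_train=(
            np.column_stack(t_orths) if t_orths else np.empty((xc.shape[0], 0))
        ),
    )


def predict_scores(model: OplsModel, x) -> np.ndarray:
    """Continuous class scores for new data (higher = class 1)."""
    if isinstance(x, pd.DataFrame):
        xa = x.reindex(columns=model.feature_names).to_numpy(dtype=float)
        # features absent from the new table are imputed at the training
        # mean, i.e. zero after centering
        xa = np.where(np.isnan(xa), model.x_mean, xa)
    else:
        xa = np.asarray(x, dtype=float)
        if xa.shape[1] != len(model.feature_names):
            raise ValidationError("predict_scores: column count mismatch")
    xc = _standardize(xa, model.x_mean, model.x_scale)
    for k in range(model.n_orth):
        t_o = xc @ model.w_orth[:, k]
        xc = xc - np.outer(t_o, model.p_orth[:, k])
    return (xc @ model.w_pred) * model.q_pred + model.y_mean


def auroc(scores, labels) -> float:
    """Area under the ROC curve: the probability that a random positive
    outranks a random negative, with half credit for score ties."""
    s = np.asarray(scores, dtype=float).ravel()
    lab = np.asarray(labels).ravel()
    classes = np.unique(lab)
    if classes.size != 2:
        raise ValidationError(f"auroc: need both classes, got {classes.size}")
    pos = lab == classes.max()
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = sps.rankdata(s)
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class SplitEvaluation:
    """Held-out AUROC distribution over repeated stratified splits."""

    name: str
    aurocs: np.ndarray
    n_iterations: int
    seed: int
    train_frac: float

    @property
    def median(self) -> float:
        return float(np.median(self.aurocs))

    @property
    def iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.aurocs, [25, 75])
        return float(lo), float(hi)

    def summary(self) -> dict:
        lo, hi = self.iqr
        return {
            "name": self.name,
            "median_auroc": self.median,
            "iqr": [lo, hi],
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }


def _stratified_split(
    y: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        n_train = max(2, int(round(train_frac * idx.size)))
        n_train = min(n_train, idx.size - 2)  # keep >= 2 per class held out
        if n_train < 2:
            raise ValidationError(
                "repeated_split_evaluate: class too small to stratify"
            )
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def repeated_split_evaluate(
    x: pd.DataFrame,
    y,
    feature_sets: dict[str, list[str]],
    train_frac: float = 0.7,
    n_iter: int = 1000,
    n_orth: int = 1,
    seed: int = 0,
    return_split_indices: bool = False,
):
    """Benchmark marker panels by repeated stratified 70/30 splits.

    Every panel in ``feature_sets`` (name -> list of columns of ``x``)
    is fitted on the same training subjects in each iteration so that
    per-iteration AUROC differences between panels are paired.  Returns
    a dict name -> :class:`SplitEvaluation` (plus the per-iteration
    split indices if requested).
    """
    ya = np.asarray(y, dtype=float).ravel()
    for name, cols in feature_sets.items():
        missing = [c for c in cols if c not in x.columns]
        if missing:
            raise ValidationError(
                f"feature set {name!r}: unknown columns {missing[:5]}"
            )
    rng = np.random.default_rng(seed)
    results = {name: np.empty(n_iter) for name in feature_sets}
    splits = []
    for it in range(n_iter):
        train_idx, test_idx = _stratified_split(ya, train_frac, rng)
        splits.append((train_idx, test_idx))
        for name, cols in feature_sets.items():
            sub = x[cols]
            model = fit_oplsda(sub.iloc[train_idx], ya[train_idx], n_orth=n_orth)
            scores = predict_scores(model, sub.iloc[test_idx])
            results[name][it] = auroc(scores, ya[test_idx])
    evals = {
        name: SplitEvaluation(
            name=name,
            aurocs=results[name],
            n_iterations=n_iter,
            seed=seed,
            train_frac=train_frac,
        )
        for name in feature_sets
    }
    if return_split_indices:
        return evals, splits
    return evals


def external_validate(model: OplsModel, x_ext: pd.DataFrame, y_ext) -> float:
    """Score a model trained in one cohort on an external cohort.

    Columns are aligned by feature ID; features missing from the
    external table are imputed at their training means.  Fewer than 50%
    overlapping features is an error.
    """
    overlap = [c for c in model.feature_names if c in x_ext.columns]
    if len(overlap) < 0.5 * len(model.feature_names):
        raise ValidationError(
            f"external table shares only {len(overlap)}/{len(model.feature_names)} "
            "model features (< 50%)"
        )
    scores = predict_scores(model, x_ext)
    return auroc(scores, np.asarray(y_ext))
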