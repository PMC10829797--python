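"""Proteome/phosphoproteome multinomial elastic-net subtype classifier.

Reproduces NMF-derived subtypes from protein-level features alone so
that samples lacking transcriptomics (or external cell lines) can be
assigned a subtype. The model minimizes the multinomial negative
log-likelihood plus lambda * [(1 - alpha)/2 ||b||_2^2 + alpha ||b||_1];
alpha is chosen on a grid by stratified repeated cross-validation to
maximize the recall of the hardest subtype, lambda by minimum mean CV
multinomial deviance along a log-spaced path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .types import OmicsMatrix

_EPS = 1e-12


@dataclass
class ClassifierModel:
    """Fitted multinomial elastic-net model with its scaling statistics."""

    classes: np.ndarray
    coef: np.ndarray  # n_classes x n_features
    intercept: np.ndarray  # n_classes
    alpha: float
    lam: float
    feature_ids: pd.Index
    feature_means: np.ndarray
    feature_sds: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": self.classes.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "alpha": self.alpha,
            "lam": self.lam,
            "feature_ids": list(self.feature_ids),
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierModel":
        return cls(
            classes=np.asarray(d["classes"]),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=np.asarray(d["intercept"], dtype=float),
            alpha=float(d["alpha"]),
            lam=float(d["lam"]),
            feature_ids=pd.Index(d["feature_ids"]),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            metadata=d.get("metadata", {}),
        )


def _design(X: OmicsMatrix, labels: pd.Series | None = None):
    """samples x features array (+ aligned labels), from features x samples."""
    Z = X.values.T
    if Z.isna().any().any():
        raise ValueError("classifier input must be imputed (no NA)")
    if labels is not None:
        labels = labels.loc[Z.index]
        return Z.to_numpy(dtype=float), Z.columns, labels.to_numpy()
    return Z.to_numpy(dtype=float), Z.columns, None


def _standardize_fit(x: np.ndarray):
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    return (x - means) / sds, means, sds


def _sk_fit(z, y, alpha: float, lam: float, seed: int = 0, warm=None):
    """One penalized fit; lambda is on the mean-NLL scale (C = 1/(n*lam))."""
    n = z.shape[0]
    est = warm or LogisticRegression(
        solver="saga",
        l1_ratio=float(alpha),
        max_iter=2000,
        tol=1e-5,
        warm_start=True,
        random_state=seed,
    )
    est.set_params(C=1.0 / (n * max(lam, _EPS)), l1_ratio=float(alpha))
    est.fit(z, y)
    return est


def lambda_path(
    z: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int = 30
) -> np.ndarray:
    """Log-spaced penalty path from near-total sparsity down 3 decades.

    lambda_max is the glmnet-style bound max_j |x_j . (y_c - pbar_c)| / (n*alpha)
    (alpha floored at 0.05 so the ridge end still gets a finite path).
    """
    n = len(y)
    classes = np.unique(y)
    Y = (y[:, None] == classes[None, :]).astype(float)
    resid = Y - Y.mean(axis=0, keepdims=True)
    grad = np.abs(z.T @ resid) / n
    lam_max = grad.max() / max(alpha, 0.05)
    return np.geomspace(lam_max, lam_max * 1e-3, n_lambda)


def multinomial_deviance(model_est, z: np.ndarray, y: np.ndarray) -> float:
    p = model_est.predict_proba(z)
    idx = np.searchsorted(model_est.classes_, y)
    return float(-2.0 * np.log(p[np.arange(len(y)), idx] + _EPS).mean())


def fit_multinomial_elasticnet(
    X: OmicsMatrix,
    labels: pd.Series,
    alpha: float = 0.9,
    lam: float | None = None,
    n_lambda: int = 30,
    cv_folds: int = 5,
    seed: int = 0,
) -> ClassifierModel:
    """Fit the multinomial elastic net, selecting lambda by CV if unset.

    Features are standardized internally (statistics stored on the
    model). When ``lam`` is None the penalty is chosen as the minimizer
    of mean CV multinomial deviance along a warm-started log-spaced
    path.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    x, feats, y = _design(X, labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if (counts == 0).any():
        raise ValueError("degenerate class with zero samples")
    z, means, sds = _standardize_fit(x)

    meta = {"n_lambda": n_lambda, "lambda_selection": "fixed"}
    if lam is None:
        path = lambda_path(z, y, alpha, n_lambda)
        lam = _select_lambda_cv(z, y, alpha, path, cv_folds, seed)
        meta["lambda_selection"] = f"min mean CV deviance, {cv_folds}-fold"
    est = _sk_fit(z, y, alpha, lam, seed=seed)
    coef, intercept = est.coef_.copy(), est.intercept_.copy()
    if coef.shape[0] == 1 and len(est.classes_) == 2:
        # binary solver parameterization -> symmetric two-row softmax form
        coef = np.vstack([np.zeros_like(coef), coef])
        intercept = np.array([0.0, intercept[0]])
    return ClassifierModel(
        classes=est.classes_,
        coef=coef,
        intercept=intercept,
        alpha=float(alpha),
        lam=float(lam),
        feature_ids=feats,
        feature_means=means,
        feature_sds=sds,
        metadata=meta,
    )


def _select_lambda_cv(z, y, alpha, path, folds, seed) -> float:
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(path)))
    for f, (tr, va) in enumerate(skf.split(z, y)):
        warm = None
        for j, lam in enumerate(path):
            warm = _sk_fit(z[tr], y[tr], alpha, lam, seed=seed, warm=warm)
            dev[f, j] = multinomial_deviance(warm, z[va], y[va])
    return float(path[int(dev.mean(axis=0).argmin())])


def cross_validate(
    X: OmicsMatrix,
    labels: pd.Series,
    alpha_grid=tuple(np.round(np.arange(0.0, 1.01, 0.1), 1)),
    folds: int = 5,
    repeats: int = 5,
    lam: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified repeated k-fold CV over the alpha grid.

    For each alpha, lambda is fixed once (by CV deviance on the full
    data if ``lam`` is None), then every (repeat, fold) fit is evaluated
    on its held-out fold. Returns one row per (alpha, repeat, fold) with
    overall error, per-class recall/precision, and the nonzero-feature
    count of the fold model.
    """
    x, _, y = _design(X, labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` members")
    rows = []
    for alpha in alpha_grid:
        z, _, _ = _standardize_fit(x)
        lam_a = lam
        if lam_a is None:
            path = lambda_path(z, y, alpha, 30)
            lam_a = _select_lambda_cv(z, y, alpha, path, folds, seed)
        for rep in range(repeats):
            skf = StratifiedKFold(
                n_splits=folds, shuffle=True, random_state=seed + 7919 * rep
            )
            for fold, (tr, va) in enumerate(skf.split(x, y)):
                ztr, mu, sd = _standardize_fit(x[tr])
                zva = (x[va] - mu) / sd
                est = _sk_fit(ztr, y[tr], alpha, lam_a, seed=seed)
                pred = est.predict(zva)
                row = {
                    "alpha": alpha,
                    "lam": lam_a,
                    "repeat": rep,
                    "fold": fold,
                    "error": float((pred != y[va]).mean()),
                    "n_nonzero": int((np.abs(est.coef_) > 1e-10).any(axis=0).sum()),
                }
                for c in classes:
                    is_c = y[va] == c
                    pred_c = pred == c
                    row[f"recall_{c}"] = (
                        float(pred_c[is_c].mean()) if is_c.any() else np.nan
                    )
                    row[f"precision_{c}"] = (
                        float(is_c[pred_c].mean()) if pred_c.any() else np.nan
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def select_alpha(report: pd.DataFrame) -> float:
    """Alpha maximizing mean recall of the hardest class; ties -> larger.

    The hardest class has the lowest recall averaged over the whole
    report; its per-alpha mean recall then ranks the candidates (the
    sparser, larger alpha wins ties).
    """
    if report.empty:
        raise ValueError("empty CV report")
    recall_cols = [c for c in report.columns if c.startswith("recall_")]
    hardest = report[recall_cols].mean().idxmin()
    by_alpha = report.groupby("alpha")[hardest].mean()
    best = by_alpha.max()
    return float(max(a for a, v in by_alpha.items() if np.isclose(v, best)))


def extract_signature(model: ClassifierModel) -> pd.DataFrame:
    """Features with a nonzero coefficient in at least one class.

    Returns a tidy frame with one row per selected feature, the list of
    classes it is predictive of, and a multi-class flag.
    """
    nz = np.abs(model.coef) > 1e-10
    rows = []
    for j, feat in enumerate(model.feature_ids):
        cls = [model.classes[i] for i in np.flatnonzero(nz[:, j])]
        if cls:
            rows.append(
                {
                    "feature": feat,
                    "classes": cls,
                    "n_classes": len(cls),
                    "multi_class": len(cls) > 1,
                }
            )
    return pd.DataFrame(rows, columns=["feature", "classes", "n_classes", "multi_class"])


def predict_proba(
    model: ClassifierModel, new_matrix: OmicsMatrix, stats: str = "training"
) -> tuple[pd.DataFrame, pd.Series]:
    """Class probabilities (softmax of linear scores) for new samples.

    Features are aligned to the model; with ``stats="training"`` they
    are standardized with the stored training statistics, with
    ``stats="self"`` with the new cohort's own mean/sd (the cell-line
    application mode). Model features absent from the new matrix, and
    NA entries, are mean-imputed -- i.e. contribute 0 after centering.
    Probabilities sum to 1 per sample; the label is the argmax class.
    """
    if stats not in {"training", "self"}:
        raise ValueError("stats must be 'training' or 'self'")
    present = model.feature_ids.intersection(new_matrix.features)
    if len(present) == 0:
        raise ValueError("no overlap between model features and new matrix")
    x = new_matrix.values.reindex(model.feature_ids).T  # samples x features
    if stats == "training":
        mu, sd = model.feature_means, model.feature_sds
    else:
        mu = x.mean(axis=0, skipna=True).to_numpy()
        sd = x.std(axis=0, ddof=0, skipna=True).to_numpy()
        mu = np.where(np.isfinite(mu), mu, 0.0)
        sd = np.where(np.isfinite(sd) & (sd > 0), sd, 1.0)
    z = (x.to_numpy(dtype=float) - mu) / sd
    z[~np.isfinite(z)] = 0.0  # missing feature/value -> mean -> 0 after centering

    scores = z @ model.coef.T + model.intercept
    scores -= scores.max(axis=1, keepdims=True)
    p = np.exp(scores)
    p /= p.sum(axis=1, keepdims=True)
    probs = pd.DataFrame(p, index=new_matrix.samples, columns=model.classes)
    labels = pd.Series(
        model.classes[p.argmax(axis=1)], index=new_matrix.samples, name="subtype"
    )
    return probs, labels
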