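"""Late-fusion classifier augmentation.

Three-stage pipeline: a binary linear-discriminant classifier on base
(extractor) features, a second on multi-axis symmetry scores, and a third
trained on the two posterior scores. The fusion stage only ever sees
out-of-fold posteriors, and all three stages are evaluated on an outer
held-out split that no training stage touches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "LinearPosteriorClassifier",
    "FusionModel",
    "train_linear_posterior",
    "train_fusion",
    "fit_fusion_pipeline",
    "evaluate_fusion",
    "feature_concat_baseline",
    "category_benchmark",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LinearPosteriorClassifier:
    """Binary linear discriminant: shared-covariance Gaussian classes, equal priors.

    Emits the posterior probability of the positive class. A singular pooled
    covariance is ridge-regularized (lambda = 1e-6 * trace / d) with a warning.
    """

    coef_: np.ndarray | None = None
    intercept_: float | None = None

    def fit(self, X, y) -> "LinearPosteriorClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("need exactly two classes")
        X0, X1 = X[y == classes[0]], X[y == classes[1]]
        mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
        n, d = X.shape
        pooled = (
            (X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)
        ) / max(n - 2, 1)
        if np.linalg.matrix_rank(pooled) < d:
            lam = 1e-6 * np.trace(pooled) / d
            lam = lam if lam > 0 else 1e-12
            warnings.warn("singular pooled covariance; applying ridge regularization")
            pooled = pooled + lam * np.eye(d)
        w = np.linalg.solve(pooled, mu1 - mu0)
        self.coef_ = w
        self.intercept_ = float(-0.5 * (mu0 + mu1) @ w)  # equal priors
        return self

    def decision_function(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_

    def posterior(self, X) -> np.ndarray:
        return _sigmoid(self.decision_function(X))

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


@dataclass
class FusionModel:
    """Fitted three-stage fusion pipeline (base, symmetry, fusion classifiers)."""

    base_clf: LinearPosteriorClassifier
    sym_clf: LinearPosteriorClassifier
    fusion_clf: LinearPosteriorClassifier
    folds: int
    seed: int
    fold_assignments: np.ndarray | None = None

    def posteriors(self, base_X, sym_X) -> np.ndarray:
        """Stacked (base, symmetry) posterior scores for new examples."""
        return np.column_stack(
            [self.base_clf.posterior(base_X), self.sym_clf.posterior(sym_X)]
        )

    def predict(self, base_X, sym_X) -> np.ndarray:
        return self.fusion_clf.predict(self.posteriors(base_X, sym_X))


def train_linear_posterior(
    X, y, folds: int = 10, seed: int = 0
) -> tuple[LinearPosteriorClassifier, np.ndarray, np.ndarray]:
    """Train a linear discriminant with K-fold CV and out-of-fold posteriors.

    Returns (classifier fit on all data, out-of-fold posterior per example,
    fold assignment per example). Each example's posterior comes from the fold
    in which it was held out.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y)
    if len(np.unique(y)) != 2:
        raise ValueError("need exactly two classes")
    if counts[counts > 0].min() < folds:
        raise ValueError("each class needs at least `folds` examples")
    oof = np.empty(len(y))
    assign = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for k, (train, test) in enumerate(skf.split(X, y)):
        clf = LinearPosteriorClassifier().fit(X[train], y[train])
        oof[test] = clf.posterior(X[test])
        assign[test] = k
    full = LinearPosteriorClassifier().fit(X, y)
    return full, oof, assign


def train_fusion(
    base_posteriors, symmetry_posteriors, labels, folds: int = 10, seed: int = 0
) -> LinearPosteriorClassifier:
    """Train the stacking classifier on the 2-D (base, symmetry) posterior space."""
    base_posteriors = np.asarray(base_posteriors, dtype=float)
    symmetry_posteriors = np.asarray(symmetry_posteriors, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (len(base_posteriors) == len(symmetry_posteriors) == len(labels)):
        raise ValueError("posterior scores and labels must be aligned")
    if len(np.unique(labels)) != 2:
        raise ValueError("need exactly two classes")
    Z = np.column_stack([base_posteriors, symmetry_posteriors])
    return LinearPosteriorClassifier().fit(Z, labels)


def fit_fusion_pipeline(
    base_X, sym_X, y, folds: int = 10, holdout: float = 0.2, seed: int = 0
) -> tuple[FusionModel, np.ndarray, np.ndarray]:
    """Fit all three stages with an outer held-out split none of them sees.

    Returns (model, train indices, held-out indices).
    """
    base_X = np.asarray(base_X, dtype=float)
    sym_X = np.asarray(sym_X, dtype=float)
    y = np.asarray(y).astype(int)
    if not (len(base_X) == len(sym_X) == len(y)):
        raise ValueError("feature tables and labels must be aligned")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=holdout, random_state=seed, stratify=y
    )
    base_clf, base_oof, assign = train_linear_posterior(
        base_X[train_idx], y[train_idx], folds=folds, seed=seed
    )
    sym_clf, sym_oof, _ = train_linear_posterior(
        sym_X[train_idx], y[train_idx], folds=folds, seed=seed
    )
    fusion = train_fusion(base_oof, sym_oof, y[train_idx], folds=folds, seed=seed)
    model = FusionModel(base_clf, sym_clf, fusion, folds, seed, assign)
    return model, train_idx, test_idx


def evaluate_fusion(model: FusionModel, base_X, sym_X, y) -> dict:
    """Held-out accuracies (percent) of the three stages and the fusion gain."""
    y = np.asarray(y).astype(int)
    if len(y) == 0:
        raise ValueError("held-out set is empty")
    base_acc = 100.0 * np.mean(model.base_clf.predict(base_X) == y)
    sym_acc = 100.0 * np.mean(model.sym_clf.predict(sym_X) == y)
    fused_acc = 100.0 * np.mean(model.predict(base_X, sym_X) == y)
    return {
        "base_accuracy": float(base_acc),
        "symmetry_accuracy": float(sym_acc),
        "fused_accuracy": float(fused_acc),
        "improvement": float(fused_acc - base_acc),
    }


def feature_concat_baseline(
    base_X, sym_X, y, holdout: float = 0.2, seed: int = 0
) -> dict:
    """Early-fusion control: one classifier on z-scored concatenated features."""
    base_X = np.asarray(base_X, dtype=float)
    sym_X = np.asarray(sym_X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(base_X) != len(sym_X) or len(base_X) != len(y):
        raise ValueError("feature tables and labels must be aligned")
    Z = np.hstack([base_X, sym_X])
    sd = Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Z - Z.mean(axis=0)) / sd
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=holdout, random_state=seed, stratify=y
    )
    clf = LinearPosteriorClassifier().fit(Z[train_idx], y[train_idx])
    acc = 100.0 * np.mean(clf.predict(Z[test_idx]) == y[test_idx])
    return {"concat_accuracy": float(acc)}


def category_benchmark(
    base_features: np.ndarray,
    sym_features: np.ndarray,
    categories: np.ndarray,
    folds: int = 10,
    holdout: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """One-vs-rest fusion benchmark over all categories.

    For each category, positives are its examples and an equal number of
    negatives is sampled (seeded) from the remaining categories. Reports
    per-category accuracies, the fusion improvement, and the category's mean
    symmetry score, plus a two-sided rank-sum test comparing fused vs base
    accuracies across categories.
    """
    base_features = np.asarray(base_features, dtype=float)
    sym_features = np.asarray(sym_features, dtype=float)
    categories = np.asarray(categories)
    rng = np.random.default_rng(seed)
    rows = []
    for cat in pd.unique(categories):
        pos = np.flatnonzero(categories == cat)
        others = np.flatnonzero(categories != cat)
        neg = rng.choice(others, size=min(len(pos), len(others)), replace=False)
        sel = np.concatenate([pos, neg])
        y = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
        model, _, test_idx = fit_fusion_pipeline(
            base_features[sel], sym_features[sel], y, folds=folds, holdout=holdout, seed=seed
        )
        report = evaluate_fusion(
            model, base_features[sel][test_idx], sym_features[sel][test_idx], y[test_idx]
        )
        report["category"] = cat
        report["mean_symmetry"] = float(sym_features[pos].mean())
        rows.append(report)
    df = pd.DataFrame(rows)
    stat, p = stats.ranksums(df["fused_accuracy"], df["base_accuracy"])
    summary = {
        "mean_improvement": float(df["improvement"].mean()),
        "ranksum_stat": float(stat),
        "ranksum_p": float(p),
        "improvement_vs_base_r": float(
            stats.pearsonr(df["improvement"], df["base_accuracy"])[0]
        )
        if df["base_accuracy"].std() > 0
        else np.nan,
        "improvement_vs_symmetry_r": float(
            stats.pearsonr(df["improvement"], df["mean_symmetry"])[0]
        )
        if df["mean_symmetry"].std() > 0
        else np.nan,
    }
    return df, summary
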