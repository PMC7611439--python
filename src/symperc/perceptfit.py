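"""Behavior-to-dissimilarity conversion, reliability estimation, and
perceptual-distance model fitting.

The central model predicts an observed pair dissimilarity as a weighted sum of
per-component absolute feature differences,

    y_ij = sum_k w_k |x_ik - x_jk|,

fit by least squares under repeated random 80/20 cross-validation. Model
quality is summarized as percent explainable variance: the squared ratio of
the model-data correlation to the Spearman-Brown-corrected split-half
reliability of the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import PCA

__all__ = [
    "FeatureTable",
    "ReliabilityEstimate",
    "FitResult",
    "rt_to_dissimilarity",
    "split_half_reliability",
    "spearman_brown",
    "pca_reduce",
    "fit_weighted_pc_distances",
    "fit_comb2",
    "variance_explained",
    "comb1_concat",
    "leave_one_group_out",
]


@dataclass
class FeatureTable:
    """Images-by-features matrix with resolvable image ids."""

    ids: list[str]
    values: np.ndarray
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = [str(i) for i in self.ids]
        if self.values.ndim != 2 or self.values.shape[0] != len(self.ids):
            raise ValueError("values must be an (n_images, d) matrix aligned with ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("image ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def row_index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}

    @classmethod
    def from_csv(cls, path, provenance: str = "raw") -> "FeatureTable":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1:].to_numpy(float), provenance)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=[f"f{k}" for k in range(self.n_features)])
        df.insert(0, "image_id", self.ids)
        df.to_csv(path, index=False, float_format="%.9g")


@dataclass(frozen=True)
class ReliabilityEstimate:
    split_half_r: float
    corrected_rc: float
    n_splits: int
    seed: int


@dataclass
class FitResult:
    """Fitted distance-model weights and cross-validated performance."""

    weights: np.ndarray
    fold_r: np.ndarray            # test correlation per CV fold
    mean_test_r: float
    sd_test_r: float
    percent_variance_explained: float | None = None
    folds: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights


def rt_to_dissimilarity(reaction_times) -> float:
    """Dissimilarity (1/s) as the reciprocal of the mean reaction time (s)."""
    rts = np.asarray(reaction_times, dtype=float)
    if rts.size == 0:
        raise ValueError("need at least one reaction time")
    if np.any(rts <= 0) or not np.all(np.isfinite(rts)):
        raise ValueError("reaction times must be finite and > 0")
    return float(1.0 / rts.mean())


def spearman_brown(r: float) -> float:
    """Correct a split-half correlation for full-length reliability: 2r/(1+r)."""
    return 2.0 * r / (1.0 + r)


def split_half_reliability(
    per_subject: pd.DataFrame,
    n_splits: int = 20,
    seed: int = 0,
    value_column: str = "dissimilarity",
) -> ReliabilityEstimate:
    """Split-half reliability of per-subject pair dissimilarities.

    For each random split the subjects contributing to each pair are divided
    into two halves; per-pair half-means are correlated across pairs. The mean
    Pearson r over splits is Spearman-Brown corrected.

    ``per_subject`` needs columns image_a, image_b, subject_id and either
    ``value_column`` or rt_seconds (converted via :func:`rt_to_dissimilarity`).
    """
    df = per_subject.copy()
    if value_column not in df.columns:
        if "rt_seconds" not in df.columns:
            raise ValueError("need a dissimilarity or rt_seconds column")
        df[value_column] = 1.0 / df["rt_seconds"]
    df["_pair"] = list(zip(df["image_a"], df["image_b"]))
    groups = {pair: g[value_column].to_numpy(float) for pair, g in df.groupby("_pair")}
    usable = {p: v for p, v in groups.items() if v.size >= 2}
    n_dropped = len(groups) - len(usable)
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} pairs with < 2 subjects")
    if not usable:
        raise ValueError("no pair has >= 2 subjects")
    rng = np.random.default_rng(seed)
    rs = []
    pair_values = list(usable.values())
    for _ in range(n_splits):
        half_a = np.empty(len(pair_values))
        half_b = np.empty(len(pair_values))
        for k, vals in enumerate(pair_values):
            perm = rng.permutation(vals.size)
            cut = vals.size // 2
            half_a[k] = vals[perm[:cut]].mean()
            half_b[k] = vals[perm[cut:]].mean()
        rs.append(stats.pearsonr(half_a, half_b)[0])
    r = float(np.mean(rs))
    return ReliabilityEstimate(r, spearman_brown(r), n_splits, seed)


def variance_explained(r_m: float, rc: float) -> float:
    """Percent explainable variance: 100 * (r_m / rc)**2."""
    if rc <= 0:
        raise ValueError("corrected reliability rc must be > 0")
    return 100.0 * (r_m / rc) ** 2


def pca_reduce(features: FeatureTable, d: int = 100) -> FeatureTable:
    """Project centered features onto the top ``d`` principal components.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive, making the output deterministic.
    """
    n, p = features.values.shape
    if d > min(n, p):
        raise ValueError(f"d={d} exceeds min(n_images, n_features)={min(n, p)}")
    pca = PCA(n_components=d, svd_solver="full")
    Z = pca.fit_transform(features.values)
    signs = np.sign(pca.components_[np.arange(d), np.abs(pca.components_).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return FeatureTable(features.ids, Z * signs, provenance=f"pca:{d}")


def pair_design_matrix(features: FeatureTable, pairs: pd.DataFrame) -> np.ndarray:
    """Per-pair absolute component differences |x_i,k - x_j,k|."""
    idx = features.row_index()
    try:
        ia = [idx[str(a)] for a in pairs["image_a"]]
        ib = [idx[str(b)] for b in pairs["image_b"]]
    except KeyError as exc:
        raise ValueError(f"pair references unknown image id {exc.args[0]!r}") from exc
    return np.abs(features.values[ia] - features.values[ib])


def _solve_ls(X: np.ndarray, y: np.ndarray, nonneg: bool) -> np.ndarray:
    if nonneg:
        w, _ = optimize.nnls(X, y)
        return w
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("singular design matrix; using least-norm solution")
    w, *_ = np.linalg.lstsq(X, y, rcond=None)
    return w


def _cv_splits(n: int, n_repeats: int, test_frac: float, seed: int):
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(n * test_frac)))
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        yield perm[n_test:], perm[:n_test]


def _fit_linear_distance_model(
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int,
    test_frac: float,
    seed: int,
    nonneg: bool,
) -> FitResult:
    folds, fold_r = [], []
    for train, test in _cv_splits(len(y), n_repeats, test_frac, seed):
        w = _solve_ls(X[train], y[train], nonneg)
        pred = X[test] @ w
        r = stats.pearsonr(pred, y[test])[0] if np.std(pred) > 0 else 0.0
        fold_r.append(r)
        folds.append((train, test))
    weights = _solve_ls(X, y, nonneg)
    fold_r = np.asarray(fold_r)
    return FitResult(weights, fold_r, float(fold_r.mean()), float(fold_r.std()), folds=folds)


def fit_weighted_pc_distances(
    features: FeatureTable,
    observed: pd.DataFrame,
    n_repeats: int = 10,
    test_frac: float = 0.2,
    seed: int = 0,
    nonneg: bool = False,
) -> FitResult:
    """Fit per-component distance weights to observed pair dissimilarities.

    Ordinary least squares on the |x_i - x_j| design matrix with repeated
    random train/test splits (default 10 repeats of 80/20); reports the test
    Pearson correlation per split and the full-data weights.
    """
    X = pair_design_matrix(features, observed)
    y = observed["dissimilarity"].to_numpy(float)
    if len(y) < X.shape[1] + 1:
        warnings.warn("fewer training pairs than recommended (d + 1)")
    return _fit_linear_distance_model(X, y, n_repeats, test_frac, seed, nonneg)


def fit_comb2(
    model_distances: np.ndarray,
    observed: pd.DataFrame,
    n_repeats: int = 10,
    test_frac: float = 0.2,
    seed: int = 0,
    nonneg: bool = False,
) -> FitResult:
    """Weighted sum of per-model distances: solve y = Xb by least squares.

    ``model_distances`` is a (pairs x models) matrix row-aligned with
    ``observed``; the fitted b gives each model's contribution.
    """
    X = np.asarray(model_distances, dtype=float)
    y = observed["dissimilarity"].to_numpy(float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("model_distances must be row-aligned with observed pairs")
    return _fit_linear_distance_model(X, y, n_repeats, test_frac, seed, nonneg)


def comb1_concat(tables: list[FeatureTable], d: int = 100) -> FeatureTable:
    """Concatenate z-scored feature tables and PCA-reduce to ``d`` dimensions."""
    if not tables:
        raise ValueError("need at least one feature table")
    ref_ids = tables[0].ids
    blocks = []
    for t in tables:
        if t.ids != ref_ids:
            raise ValueError("feature tables must cover identical image sets in the same order")
        sd = t.values.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {np.count_nonzero(~keep)} zero-variance features")
        z = (t.values[:, keep] - t.values[:, keep].mean(axis=0)) / sd[keep]
        blocks.append(z)
    concat = FeatureTable(ref_ids, np.hstack(blocks), provenance="concat")
    return pca_reduce(concat, d)


def leave_one_group_out(
    features: FeatureTable | None,
    observed: pd.DataFrame,
    rc: float | dict[str, float],
    model_distances: np.ndarray | None = None,
    seed: int = 0,
    nonneg: bool = False,
    min_test_pairs: int = 20,
) -> pd.DataFrame:
    """Generalization across experiments: train on all groups but one, test on it.

    ``observed`` must carry an experiment_id column. ``rc`` is either a pooled
    corrected reliability or a per-group mapping. Returns one row per group
    with the test correlation and percent variance explained.
    """
    if "experiment_id" not in observed.columns:
        raise ValueError("observed table needs an experiment_id column")
    if model_distances is not None:
        X = np.asarray(model_distances, dtype=float)
    elif features is not None:
        X = pair_design_matrix(features, observed)
    else:
        raise ValueError("provide features or model_distances")
    y = observed["dissimilarity"].to_numpy(float)
    groups = observed["experiment_id"].to_numpy()
    unique = pd.unique(groups)
    if len(unique) < 2:
        raise ValueError("need at least 2 experiment groups")
    rows = []
    for g in unique:
        test = np.flatnonzero(groups == g)
        train = np.flatnonzero(groups != g)
        if len(test) < min_test_pairs:
            warnings.warn(f"group {g!r} has only {len(test)} test pairs")
        w = _solve_ls(X[train], y[train], nonneg)
        pred = X[test] @ w
        r = stats.pearsonr(pred, y[test])[0] if np.std(pred) > 0 else 0.0
        g_rc = rc[g] if isinstance(rc, dict) else rc
        rows.append(
            {
                "experiment_id": g,
                "n_test_pairs": len(test),
                "test_r": r,
                "percent_variance_explained": variance_explained(r, g_rc),
            }
        )
    return pd.DataFrame(rows)
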