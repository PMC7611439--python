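"""Probing feature-extractor-plus-linear-head networks.

Unit importance by outgoing-weight ablation, the symmetry modulation index
(SMI) with bootstrap resampling, and spatial-frequency modulation from Gabor
bank responses. Works against any object satisfying the ProbeNetwork contract;
a trainable toy network is provided for desk-scale experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .stimuli import StimulusSet, enumerate_pairs

__all__ = [
    "ProbeNetwork",
    "UnitImportanceReport",
    "make_toy_network",
    "unit_importance",
    "unit_set_distances",
    "smi",
    "bootstrap_smi",
    "sf_modulation",
]

#: High/low spatial-frequency groups (cycles/pixel) for the modulation index.
HSF_FREQUENCIES = (0.25, 0.33, 0.5)
LSF_FREQUENCIES = (0.06, 0.09, 0.17)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class ProbeNetwork:
    """Feature extractor + linear softmax head.

    ``extractor`` maps a list of images to an (n_images, n_units) activation
    matrix; the head is ``softmax(activations @ weights + bias)``. Ablating a
    unit zeroes its row of ``weights``; the extractor is untouched.
    """

    extractor: callable
    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.ndim != 2 or self.bias.shape != (self.weights.shape[1],):
            raise ValueError("weights must be (n_units, n_classes) with matching bias")

    @property
    def n_units(self) -> int:
        return self.weights.shape[0]

    @property
    def n_classes(self) -> int:
        return self.weights.shape[1]

    def activations(self, images) -> np.ndarray:
        acts = np.asarray(self.extractor(images), dtype=float)
        if acts.ndim != 2 or acts.shape[1] != self.n_units:
            raise ValueError("extractor output does not match the head's unit count")
        return acts

    def probabilities(self, images, ablate_unit: int | None = None) -> np.ndarray:
        acts = self.activations(images)
        W = self.weights
        if ablate_unit is not None:
            if not 0 <= ablate_unit < self.n_units:
                raise IndexError(f"unit index {ablate_unit} out of range")
            W = W.copy()
            W[ablate_unit, :] = 0.0
        return _softmax(acts @ W + self.bias)

    def predict(self, images) -> np.ndarray:
        return self.probabilities(images).argmax(axis=1)


@dataclass
class UnitImportanceReport:
    """Per-unit ablation importance with top-k / bottom-k index sets."""

    delta: np.ndarray
    ranking: np.ndarray          # unit indices, most important first
    top_k: np.ndarray
    bottom_k: np.ndarray
    k: int


def make_toy_network(
    n_units: int,
    n_classes: int,
    train_images,
    train_labels,
    seed: int = 0,
    l2: float = 1e-3,
    n_iter: int = 200,
    train_extractor: bool = False,
) -> ProbeNetwork:
    """Desk-scale stand-in for a CNN penultimate layer.

    By default the extractor is a fixed random projection of flattened pixels
    followed by rectification, and only the softmax head is trained (full-batch
    gradient descent). With ``train_extractor=True`` the projection itself is
    learned by backpropagation, so the penultimate representation reflects the
    training data (needed e.g. to study effects of mirror-flip augmentation).
    Deterministic per seed.
    """
    if n_units > 512:
        raise ValueError("toy network limited to <= 512 units")
    train_labels = np.asarray(train_labels).astype(int)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("training data must contain at least two classes")
    n_pixels = np.asarray(train_images[0]).size
    rng = np.random.default_rng(seed)

    def _flatten(images):
        return np.stack([np.asarray(im, dtype=float).ravel() for im in images])

    X = _flatten(train_images)
    n = len(X)
    Y = np.zeros((n, n_classes))
    Y[np.arange(n), train_labels] = 1.0

    if train_extractor:
        W1 = rng.standard_normal((n_pixels, n_units)) / np.sqrt(n_pixels)
        b1 = np.zeros(n_units)
        W2 = rng.standard_normal((n_units, n_classes)) * 0.01
        b2 = np.zeros(n_classes)
        lr, l2w = 0.1, 1e-4
        for _ in range(max(n_iter, 300)):
            H = np.maximum(X @ W1 + b1, 0.0)
            Pk = _softmax(H @ W2 + b2)
            dz2 = (Pk - Y) / n
            dW2 = H.T @ dz2 + l2w * W2
            db2 = dz2.sum(axis=0)
            dH = dz2 @ W2.T
            dH[H <= 0] = 0.0
            dW1 = X.T @ dH + l2w * W1
            db1 = dH.sum(axis=0)
            W2 -= lr * dW2
            b2 -= lr * db2
            W1 -= 5 * lr * dW1
            b1 -= 5 * lr * db1

        def extractor(images):
            return np.maximum(_flatten(images) @ W1 + b1, 0.0)

        return ProbeNetwork(extractor, W2, b2)

    P = rng.standard_normal((n_pixels, n_units)) / np.sqrt(n_pixels)
    acts = np.maximum(X @ P, 0.0)
    mu, sd = acts.mean(axis=0), acts.std(axis=0)
    sd[sd == 0] = 1.0

    def norm_extractor(images):
        raw = np.maximum(_flatten(images) @ P, 0.0)
        return (raw - mu) / sd + 1.0  # keep activations mostly >= 0

    A = norm_extractor(train_images)
    W = np.zeros((n_units, n_classes))
    b = np.zeros(n_classes)
    lr = 0.5
    for _ in range(n_iter):
        Pk = _softmax(A @ W + b)
        G = A.T @ (Pk - Y) / n + l2 * W
        W -= lr * G
        b -= lr * (Pk - Y).mean(axis=0)
    return ProbeNetwork(norm_extractor, W, b)


def unit_importance(
    net: ProbeNetwork,
    images,
    true_classes,
    k: int | None = None,
) -> UnitImportanceReport:
    """Ablation importance of every unit.

    delta(unit) = mean over images of |p_o(c) - p_m(c)| where c is the image's
    true class, p_o the original true-class probability and p_m the probability
    after zeroing the unit's outgoing weights. Only images the unmodified
    network classifies correctly are admitted.
    """
    true_classes = np.asarray(true_classes).astype(int)
    if len(images) == 0:
        raise ValueError("need at least one image")
    probs = net.probabilities(images)
    pred = probs.argmax(axis=1)
    if np.any(pred != true_classes):
        raise ValueError("all probe images must be correctly classified by the network")
    n = len(images)
    p_o = probs[np.arange(n), true_classes]
    delta = np.empty(net.n_units)
    for i in range(net.n_units):
        p_m = net.probabilities(images, ablate_unit=i)[np.arange(n), true_classes]
        delta[i] = np.abs(p_o - p_m).mean()
    ranking = np.argsort(-delta, kind="stable")
    if k is None:
        k = 100 if net.n_units >= 1000 else max(1, net.n_units // 10)
    return UnitImportanceReport(delta, ranking, ranking[:k], ranking[-k:], k)


def unit_set_distances(
    net: ProbeNetwork, sset: StimulusSet, unit_subset=None
) -> pd.DataFrame:
    """Euclidean pair distances over penultimate activations, optionally
    restricted to a unit subset; one row per unordered image pair."""
    acts = net.activations(sset.images)
    if unit_subset is not None:
        unit_subset = np.asarray(unit_subset, dtype=int)
        if unit_subset.size == 0:
            raise ValueError("unit subset must be nonempty")
        acts = acts[:, unit_subset]
    D = squareform(pdist(acts, metric="euclidean"))
    pairs = enumerate_pairs(sset, "all")
    labels = sset.labels.reset_index(drop=True)
    rows = []
    from .stimuli import pair_relation_tag

    has_parts = {"left_part", "right_part", "is_symmetric"}.issubset(labels.columns)
    for i, j in pairs:
        row = {
            "image_a": labels.at[i, "image_id"],
            "image_b": labels.at[j, "image_id"],
            "distance": float(D[i, j]),
        }
        if has_parts:
            row["relation"] = pair_relation_tag(labels, i, j)
        rows.append(row)
    return pd.DataFrame(rows)


def _sym_asym_distances(distances: pd.DataFrame, column: str) -> tuple[np.ndarray, np.ndarray]:
    if "relation" not in distances.columns:
        raise ValueError("distance table needs a relation column")
    d_sym = distances.loc[distances["relation"] == "symmetric_symmetric", column].to_numpy(float)
    d_asym = distances.loc[distances["relation"] == "disjoint_asymmetric", column].to_numpy(float)
    if d_sym.size == 0 or d_asym.size == 0:
        raise ValueError("need both symmetric_symmetric and disjoint_asymmetric pairs")
    return d_sym, d_asym


def smi(distances: pd.DataFrame, column: str = "distance") -> dict:
    """Symmetry modulation index (d_sym - d_asym)/(d_sym + d_asym).

    ``d_sym`` / ``d_asym`` are mean distances over symmetric-symmetric and
    disjoint-asymmetric pairs respectively.
    """
    d_sym_v, d_asym_v = _sym_asym_distances(distances, column)
    d_sym, d_asym = float(d_sym_v.mean()), float(d_asym_v.mean())
    if d_sym + d_asym == 0:
        raise ValueError("SMI undefined: d_sym + d_asym = 0")
    return {
        "smi": (d_sym - d_asym) / (d_sym + d_asym),
        "d_sym": d_sym,
        "d_asym": d_asym,
        "n_sym": int(d_sym_v.size),
        "n_asym": int(d_asym_v.size),
    }


def bootstrap_smi(
    distances: pd.DataFrame,
    n_boot: int = 10000,
    seed: int = 0,
    column: str = "distance",
) -> dict:
    """Bootstrap the SMI by resampling pairs with replacement.

    Each replicate resamples as many symmetric and asymmetric pairs as the
    input holds (21 and 420 for the full 7-part set).
    """
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable bootstrap estimates")
    d_sym, d_asym = _sym_asym_distances(distances, column)
    rng = np.random.default_rng(seed)
    sym_means = d_sym[rng.integers(0, d_sym.size, size=(n_boot, d_sym.size))].mean(axis=1)
    asym_means = d_asym[rng.integers(0, d_asym.size, size=(n_boot, d_asym.size))].mean(axis=1)
    reps = (sym_means - asym_means) / (sym_means + asym_means)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return {
        "mean": float(reps.mean()),
        "sd": float(reps.std()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "replicates": reps,
    }


def sf_modulation(
    net: ProbeNetwork,
    gabor_set: StimulusSet,
    hsf: tuple[float, ...] = HSF_FREQUENCIES,
    lsf: tuple[float, ...] = LSF_FREQUENCIES,
) -> pd.DataFrame:
    """Per-unit spatial-frequency modulation index from Gabor responses.

    Each unit's activation is averaged across orientations within each
    frequency; MI = (A_hsf - A_lsf)/(A_hsf + A_lsf) with A_hsf / A_lsf the
    means over the high / low frequency groups. Units with A_hsf + A_lsf = 0
    get NaN.
    """
    labels = gabor_set.labels.reset_index(drop=True)
    if "frequency" not in labels.columns:
        raise ValueError("gabor set needs a frequency column in its labels")
    freqs = labels["frequency"].to_numpy(float)
    present = set(np.unique(freqs).round(6))
    needed = {round(f, 6) for f in tuple(hsf) + tuple(lsf)}
    if not needed.issubset(present):
        raise ValueError(f"gabor bank missing frequencies: {sorted(needed - present)}")
    acts = net.activations(gabor_set.images)
    per_freq = {}
    for f in sorted(needed):
        per_freq[f] = acts[np.isclose(freqs, f)].mean(axis=0)
    A_hsf = np.mean([per_freq[round(f, 6)] for f in hsf], axis=0)
    A_lsf = np.mean([per_freq[round(f, 6)] for f in lsf], axis=0)
    denom = A_hsf + A_lsf
    with np.errstate(divide="ignore", invalid="ignore"):
        mi = np.where(denom != 0, (A_hsf - A_lsf) / denom, np.nan)
    return pd.DataFrame(
        {"unit": np.arange(net.n_units), "A_hsf": A_hsf, "A_lsf": A_lsf, "mi": mi}
    )
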