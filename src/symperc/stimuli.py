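"""Synthetic part-based stimuli, Gabor banks, and simulated dissimilarity tables.

Objects are built by attaching one of ``n`` parts to each end of a horizontal
stem; the right-end instance of a part is the horizontal mirror of its
canonical (left-end) form, so an object with the same part at both ends is
pixel-exact mirror symmetric about the vertical axis. A full composition of an
``n``-part library yields ``n**2`` objects of which exactly ``n`` are symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from .symmetry import pair_symmetry_strength, area_ratio

__all__ = [
    "PartLibrary",
    "StimulusSet",
    "GaborSpec",
    "SyntheticDissimModel",
    "make_part_library",
    "compose_two_part_objects",
    "rotate_set",
    "enumerate_pairs",
    "shared_part_count",
    "make_gabor",
    "gabor_bank",
    "simulate_dissimilarities",
    "write_images",
    "read_images",
]

PAIR_RELATIONS = (
    "all",
    "symmetric_symmetric",
    "disjoint_asymmetric",
    "share_one_part",
    "share_two_parts",
)

#: Spatial frequencies (cycles/pixel) of the default Gabor bank.
DEFAULT_FREQUENCIES = (0.06, 0.09, 0.17, 0.25, 0.33, 0.5)


@dataclass(frozen=True)
class PartLibrary:
    """Canonical (left-end) binary part masks plus the stem geometry."""

    parts: tuple[np.ndarray, ...]
    canvas: int
    margin: int
    part_width: int
    part_height: int
    stem_thickness: int
    seed: int

    @property
    def n_parts(self) -> int:
        return len(self.parts)


@dataclass
class StimulusSet:
    """A list of intensity images with a row-aligned metadata table.

    ``labels`` always carries an ``image_id`` column; composed two-part sets
    additionally carry ``left_part``, ``right_part``, ``orientation`` and
    ``is_symmetric``.
    """

    images: list[np.ndarray]
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must be row-aligned")
        if "image_id" not in self.labels.columns:
            raise ValueError("labels must contain an image_id column")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def image_ids(self) -> list[str]:
        return self.labels["image_id"].tolist()


@dataclass(frozen=True)
class GaborSpec:
    """Parameters of one Gabor patch.

    ``orientation`` in degrees in [0, 180): 0 gives a vertically striped
    grating; ``spatial_frequency`` in cycles/pixel; ``envelope_sigma`` defaults
    to size/5 when not given.
    """

    orientation: float
    spatial_frequency: float
    phase: float = 0.0
    size: int = 140
    envelope_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.spatial_frequency <= 0:
            raise ValueError("spatial_frequency must be > 0")
        if self.size <= 0:
            raise ValueError("size must be > 0")

    @property
    def sigma(self) -> float:
        return self.envelope_sigma if self.envelope_sigma is not None else self.size / 5.0


@dataclass(frozen=True)
class SyntheticDissimModel:
    """Generative model for simulated pair dissimilarities (units 1/s).

    dissim(i, j) = sum_k w_k |x_ik - x_jk| + beta_sym * pair_symmetry(i, j)
    + beta_area * log(area_ratio(i, j)) + N(0, noise_sd), clipped to ``floor``.
    """

    weights: np.ndarray
    beta_sym: float = 0.0
    beta_area: float = 0.0
    noise_sd: float = 0.1
    floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# Part libraries and two-part objects
# ---------------------------------------------------------------------------

def _part_geometry(canvas: int) -> tuple[int, int, int, int]:
    margin = max(2, canvas // 16)
    part_width = max(4, (canvas - 2 * margin) // 4)
    part_height = max(6, canvas // 2)
    stem_thickness = max(2, canvas // 24)
    return margin, part_width, part_height, stem_thickness


def _draw_part(rng: np.random.Generator, height: int, width: int, thickness: int) -> np.ndarray:
    """One random smooth blob touching the right (stem-facing) edge of its box."""
    bar = np.zeros((height, width), dtype=bool)
    r0 = (height - thickness) // 2
    bar[r0 : r0 + thickness, :] = True
    for _ in range(50):
        field_ = ndimage.gaussian_filter(
            rng.standard_normal((height, width)), sigma=min(height, width) / 4.0
        )
        blob = field_ > np.quantile(field_, 0.6)
        lab, n = ndimage.label(blob)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(blob, lab, index=np.arange(1, n + 1))
        mask = (lab == (1 + int(np.argmax(sizes)))) | bar
        # require distinctive pixels beyond the shared connector bar
        if np.count_nonzero(mask & ~bar) >= height * width // 20:
            return mask
    raise RuntimeError("failed to draw a part blob")


def make_part_library(n_parts: int, canvas: int = 140, seed: int = 0) -> PartLibrary:
    """Generate ``n_parts`` pairwise-distinct part masks for a given canvas size."""
    if n_parts < 2:
        raise ValueError("n_parts must be >= 2")
    if canvas < 32:
        raise ValueError("canvas must be >= 32 pixels to hold a part")
    margin, pw, ph, thick = _part_geometry(canvas)
    if margin + pw > canvas // 2:
        raise ValueError("canvas too small to hold a part in its half-frame")
    rng = np.random.default_rng(seed)
    parts: list[np.ndarray] = []
    while len(parts) < n_parts:
        cand = _draw_part(rng, ph, pw, thick)
        if any(np.array_equal(cand, p) for p in parts):
            continue
        parts.append(cand)
    return PartLibrary(tuple(parts), canvas, margin, pw, ph, thick, seed)


def _render_object(lib: PartLibrary, left: int, right: int) -> np.ndarray:
    c = lib.canvas
    img = np.zeros((c, c), dtype=float)
    r0 = (c - lib.stem_thickness) // 2
    # stem spans the gap between the two part boxes; symmetric under c -> C-1-c
    img[r0 : r0 + lib.stem_thickness, lib.margin + lib.part_width : c - lib.margin - lib.part_width] = 1.0
    pr0 = (c - lib.part_height) // 2
    img[pr0 : pr0 + lib.part_height, lib.margin : lib.margin + lib.part_width][lib.parts[left]] = 1.0
    right_mask = lib.parts[right][:, ::-1]
    img[pr0 : pr0 + lib.part_height, c - lib.margin - lib.part_width : c - lib.margin][right_mask] = 1.0
    return img


def compose_two_part_objects(library: PartLibrary) -> StimulusSet:
    """All ``n**2`` two-part objects of a library, flagged symmetric when left == right."""
    images, rows = [], []
    for left in range(library.n_parts):
        for right in range(library.n_parts):
            images.append(_render_object(library, left, right))
            rows.append(
                {
                    "image_id": f"obj-{left}-{right}",
                    "left_part": left,
                    "right_part": right,
                    "orientation": "horizontal",
                    "is_symmetric": left == right,
                }
            )
    return StimulusSet(images, pd.DataFrame(rows))


def rotate_set(sset: StimulusSet, angle: int) -> StimulusSet:
    """Lossless counter-clockwise rotation of every image by a right angle."""
    if angle not in (90, 180, 270):
        raise ValueError("angle must be one of 90, 180, 270 degrees")
    k = angle // 90
    images = [np.rot90(img, k).copy() for img in sset.images]
    labels = sset.labels.copy()
    if "orientation" in labels.columns and angle in (90, 270):
        flip = {"horizontal": "vertical", "vertical": "horizontal"}
        labels["orientation"] = labels["orientation"].map(flip)
    return StimulusSet(images, labels)


def shared_part_count(labels: pd.DataFrame, i: int, j: int) -> int:
    """Multiset overlap of the two end-parts of objects ``i`` and ``j``."""
    a = [labels.at[i, "left_part"], labels.at[i, "right_part"]]
    b = [labels.at[j, "left_part"], labels.at[j, "right_part"]]
    shared = 0
    b = list(b)
    for part in a:
        if part in b:
            b.remove(part)
            shared += 1
    return shared


def enumerate_pairs(sset: StimulusSet, relation: str = "all") -> list[tuple[int, int]]:
    """Unordered index pairs (i < j) filtered by a pair-relation tag.

    ``symmetric_symmetric``: both objects symmetric; ``disjoint_asymmetric``:
    both asymmetric sharing no part (AB-CD pairs); ``share_one_part`` /
    ``share_two_parts``: multiset part overlap of exactly 1 / 2.
    """
    if relation not in PAIR_RELATIONS:
        raise ValueError(f"unknown pair relation {relation!r}; expected one of {PAIR_RELATIONS}")
    labels = sset.labels.reset_index(drop=True)
    n = len(sset)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if relation == "all":
        return pairs
    sym = labels["is_symmetric"].to_numpy()
    out = []
    for i, j in pairs:
        shared = shared_part_count(labels, i, j)
        if relation == "symmetric_symmetric":
            keep = sym[i] and sym[j]
        elif relation == "disjoint_asymmetric":
            keep = (not sym[i]) and (not sym[j]) and shared == 0
        elif relation == "share_one_part":
            keep = shared == 1
        else:  # share_two_parts
            keep = shared == 2
        if keep:
            out.append((i, j))
    return out


def pair_relation_tag(labels: pd.DataFrame, i: int, j: int) -> str:
    """Single relation tag for a pair (used to annotate simulated tables)."""
    sym = labels["is_symmetric"]
    if sym[i] and sym[j]:
        return "symmetric_symmetric"
    shared = shared_part_count(labels, i, j)
    if shared == 2:
        return "share_two_parts"
    if shared == 1:
        return "share_one_part"
    if not sym[i] and not sym[j]:
        return "disjoint_asymmetric"
    return "none"


# ---------------------------------------------------------------------------
# Gabor patches
# ---------------------------------------------------------------------------

def make_gabor(spec: GaborSpec) -> np.ndarray:
    """Sinusoidal grating under a Gaussian envelope, rescaled to [0, 1]."""
    s = spec.size
    half = (s - 1) / 2.0
    y, x = np.mgrid[0:s, 0:s].astype(float)
    x -= half
    y -= half
    theta = math.radians(spec.orientation)
    xt = x * math.cos(theta) + y * math.sin(theta)
    carrier = np.cos(2.0 * math.pi * spec.spatial_frequency * xt + math.radians(spec.phase))
    envelope = np.exp(-(x**2 + y**2) / (2.0 * spec.sigma**2))
    g = envelope * carrier
    lo, hi = g.min(), g.max()
    return (g - lo) / (hi - lo)


def gabor_bank(
    n_orientations: int = 8,
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES,
    size: int = 140,
    phase: float = 0.0,
) -> StimulusSet:
    """Bank of Gabors over uniformly sampled orientations x given frequencies."""
    images, rows = [], []
    for k in range(n_orientations):
        ori = k * 180.0 / n_orientations
        for f in frequencies:
            spec = GaborSpec(orientation=ori, spatial_frequency=f, phase=phase, size=size)
            images.append(make_gabor(spec))
            rows.append(
                {"image_id": f"gabor-o{ori:g}-f{f:g}", "orientation_deg": ori, "frequency": f}
            )
    return StimulusSet(images, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Simulated dissimilarities
# ---------------------------------------------------------------------------

def simulate_dissimilarities(
    sset: StimulusSet,
    features,
    model: SyntheticDissimModel,
    experiment_id: str | None = None,
) -> pd.DataFrame:
    """Simulate a pair-dissimilarity table over all pairs of a stimulus set.

    ``features`` is an (n_images, d) array or FeatureTable row-aligned with the
    set. Returns a table with columns image_a, image_b, dissimilarity plus the
    pair covariates (pair_symmetry, area_ratio, n_shared_parts, relation).
    """
    X = np.asarray(getattr(features, "values", features), dtype=float)
    if X.ndim != 2 or X.shape[0] != len(sset):
        raise ValueError("features must be a 2-D matrix row-aligned with the stimulus set")
    if X.shape[1] != model.weights.size:
        raise ValueError("model weights do not match feature dimensionality")
    labels = sset.labels.reset_index(drop=True)
    has_parts = {"left_part", "right_part", "is_symmetric"}.issubset(labels.columns)
    rng = np.random.default_rng(model.seed)
    pairs = enumerate_pairs(sset, "all")
    sym_strength = [pair_symmetry_strength(sset.images[i], sset.images[j]) for i, j in pairs]
    ratios = [area_ratio(sset.images[i], sset.images[j]) for i, j in pairs]
    rows = []
    noise = rng.normal(0.0, model.noise_sd, size=len(pairs)) if model.noise_sd > 0 else np.zeros(len(pairs))
    for idx, (i, j) in enumerate(pairs):
        base = float(model.weights @ np.abs(X[i] - X[j]))
        d = base + model.beta_sym * sym_strength[idx] + model.beta_area * math.log(ratios[idx])
        d = max(d + noise[idx], model.floor)
        row = {
            "image_a": labels.at[i, "image_id"],
            "image_b": labels.at[j, "image_id"],
            "dissimilarity": d,
            "n_trials": 1,
            "pair_symmetry": sym_strength[idx],
            "area_ratio": ratios[idx],
        }
        if has_parts:
            row["n_shared_parts"] = shared_part_count(labels, i, j)
            row["relation"] = pair_relation_tag(labels, i, j)
        if experiment_id is not None:
            row["experiment_id"] = experiment_id
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Image I/O (8-bit grayscale PNG + CSV manifest)
# ---------------------------------------------------------------------------

def write_images(sset: StimulusSet, directory) -> None:
    """Write a stimulus set as 8-bit grayscale PNGs plus a manifest.csv sidecar."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for img, image_id in zip(sset.images, sset.image_ids):
        quantized = np.clip(np.rint(np.asarray(img) * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(quantized, mode="L").save(directory / f"{image_id}.png")
    sset.labels.to_csv(directory / "manifest.csv", index=False)


def read_images(directory) -> StimulusSet:
    """Read a stimulus set written by :func:`write_images`; pixel-exact round trip."""
    from pathlib import Path

    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise OSError(f"missing manifest: {manifest}")
    labels = pd.read_csv(manifest)
    images = []
    for image_id in labels["image_id"]:
        path = directory / f"{image_id}.png"
        if not path.exists():
            raise OSError(f"missing image file: {path}")
        try:
            with Image.open(path) as im:
                if im.mode != "L":
                    raise OSError(f"not an 8-bit grayscale image: {path}")
                images.append(np.asarray(im, dtype=float) / 255.0)
        except (UnidentifiedImageError, SyntaxError, ValueError) as exc:
            raise OSError(f"cannot read image file {path}: {exc}") from exc
    return StimulusSet(images, labels)
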