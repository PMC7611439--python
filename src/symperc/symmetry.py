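"""Planar reflection-symmetry scoring about in-plane axes through the image center.

The score of an image ``A`` about an axis is ``1 - sum|A - R| / sum(A + R)``
where ``R`` is the reflection of ``A`` about that axis: 1 when the image equals
its mirror image in every pixel, 0 when image and reflection share no support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "SymmetryProfile",
    "reflect",
    "symmetry_score",
    "symmetry_profile",
    "pair_symmetry_strength",
    "area_ratio",
]

#: Fraction of the max intensity above which a pixel counts toward object area.
AREA_THRESHOLD = 0.5


def _as_image(image) -> np.ndarray:
    a = np.asarray(image, dtype=float)
    if a.ndim != 2 or a.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(a)):
        raise ValueError("image contains non-finite values")
    if np.any(a < 0):
        raise ValueError("image intensities must be non-negative")
    return a


def reflect(image, axis_angle: float) -> np.ndarray:
    """Reflect ``image`` about a center axis at ``axis_angle`` degrees.

    Angle 0 is the vertical axis (columns map ``c -> W-1-c``, exact); 90 is the
    horizontal axis (rows reversed, exact). Oblique angles use rotate-flip-rotate
    with bilinear interpolation and zero fill.
    """
    a = _as_image(image)
    angle = float(axis_angle) % 180.0
    if angle == 0.0:
        return a[:, ::-1].copy()
    if angle == 90.0:
        return a[::-1, :].copy()
    # Rotate the axis onto the vertical, flip columns, rotate back.
    back = _sk_rotate(a, angle, order=1, mode="constant", cval=0.0, preserve_range=True)
    back = back[:, ::-1]
    out = _sk_rotate(back, -angle, order=1, mode="constant", cval=0.0, preserve_range=True)
    return np.clip(out, 0.0, None)


def symmetry_score(image, axis_angle: float = 0.0) -> float:
    """Strength of reflection symmetry about a center axis; value in [0, 1]."""
    a = _as_image(image)
    total = a.sum()
    if total <= 0:
        raise ValueError("symmetry score undefined for an all-zero image")
    r = reflect(a, axis_angle)
    num = np.abs(a - r).sum()
    den = (a + r).sum()
    return float(1.0 - num / den)


@dataclass(frozen=True)
class SymmetryProfile:
    """Symmetry scores of one image over a fan of axes.

    ``axis_angles[k] = k * 180 / n`` degrees with 0 = vertical; ``s_v`` and
    ``s_h`` are the vertical- and horizontal-axis scores.
    """

    axis_angles: tuple[float, ...]
    scores: tuple[float, ...]
    s_v: float
    s_h: float
    image_id: str | None = None

    def as_array(self) -> np.ndarray:
        return np.asarray(self.scores, dtype=float)


def symmetry_profile(image, n_axes: int = 8, image_id: str | None = None) -> SymmetryProfile:
    """Score ``image`` about ``n_axes`` axes uniformly spanning [0, 180) degrees."""
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    angles = tuple(k * 180.0 / n_axes for k in range(n_axes))
    scores = tuple(symmetry_score(image, ang) for ang in angles)
    s_v = scores[0] if 0.0 in angles else symmetry_score(image, 0.0)
    s_h = scores[angles.index(90.0)] if 90.0 in angles else symmetry_score(image, 90.0)
    return SymmetryProfile(angles, scores, s_v, s_h, image_id)


def pair_symmetry_strength(a, b) -> float:
    """Pair-level symmetry: max of the two per-axis means over the pair.

    Vertical scores of both images are averaged, likewise horizontal; the
    larger of the two means is returned.
    """
    sv = 0.5 * (symmetry_score(a, 0.0) + symmetry_score(b, 0.0))
    sh = 0.5 * (symmetry_score(a, 90.0) + symmetry_score(b, 90.0))
    return float(max(sv, sh))


def object_area(image, threshold: float = AREA_THRESHOLD) -> int:
    """Pixel count above ``threshold`` times the max intensity."""
    a = _as_image(image)
    peak = a.max()
    if peak <= 0:
        raise ValueError("area undefined for an all-zero image")
    return int(np.count_nonzero(a > threshold * peak))


def area_ratio(a, b, threshold: float = AREA_THRESHOLD) -> float:
    """Area of the larger object over area of the smaller; symmetric, >= 1."""
    area_a = object_area(a, threshold)
    area_b = object_area(b, threshold)
    if area_a == 0 or area_b == 0:
        raise ValueError("area ratio undefined for empty objects")
    return float(max(area_a, area_b) / min(area_a, area_b))
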