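"""Image-pair statistics: changed-region size and location, Weibull contrast
scale, and synthetic fixture pairs with known ground truth.

The changed region between the two versions of a scene is detected from the
per-pixel absolute RGB difference: a pixel is flagged when the difference
(max over channels by default, on the 0-255 scale) exceeds a threshold
(default 10).  The image "clutter" axis is summarized by the scale parameter
of a two-parameter Weibull distribution fitted by maximum likelihood to the
strictly positive gradient magnitudes of the grayscale image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .design import split_grid
from .exceptions import DegenerateInputError, NoObjectError

# ITU-R 601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def _diff_mask(img_a, img_b, threshold, aggregate):
    a = np.asarray(img_a, dtype=np.int64)
    b = np.asarray(img_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError(f"image dimensions differ: {a.shape} vs {b.shape}")
    diff = np.abs(a - b)
    if diff.ndim == 3:
        diff = diff.max(axis=-1) if aggregate == "max" else diff.mean(axis=-1)
    return diff > threshold


def object_size(img_a, img_b, threshold: float = 10,
                aggregate: str = "max") -> float:
    """Fraction of pixels whose RGB difference exceeds ``threshold``.

    ``aggregate`` is "max" (default) or "mean" over the colour channels.
    """
    if aggregate not in ("max", "mean"):
        raise ValueError(f"aggregate must be 'max' or 'mean', got {aggregate!r}")
    return float(_diff_mask(img_a, img_b, threshold, aggregate).mean())


def critical_object_patch(img_a, img_b, threshold: float = 10,
                          aggregate: str = "max") -> int:
    """Grid location (1-9) of the patch holding most changed pixels.

    Ties break toward the lowest location number; identical images raise
    :class:`NoObjectError`.
    """
    mask = _diff_mask(img_a, img_b, threshold, aggregate)
    if not mask.any():
        raise NoObjectError("no pixel exceeds the difference threshold")
    counts = {loc: int(patch.sum()) for loc, patch in split_grid(mask).items()}
    return max(sorted(counts), key=lambda loc: counts[loc])


def to_grayscale(img) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:
        return img @ _LUMA
    return img


def gradient_magnitude(img, filter_scale: float = 1.0,
                       method: str = "gaussian") -> np.ndarray:
    """Gradient magnitude of the grayscale image.

    "gaussian" uses Gaussian-derivative filters at sigma=``filter_scale``
    pixels; "sobel" is available as a dialect (``filter_scale`` ignored).
    """
    gray = to_grayscale(img)
    if method == "gaussian":
        gx = ndimage.gaussian_filter(gray, filter_scale, order=(0, 1))
        gy = ndimage.gaussian_filter(gray, filter_scale, order=(1, 0))
    elif method == "sobel":
        gx = ndimage.sobel(gray, axis=1)
        gy = ndimage.sobel(gray, axis=0)
    else:
        raise ValueError(f"unknown gradient method {method!r}")
    return np.hypot(gx, gy)


def fit_weibull(samples, min_samples: int = 100) -> tuple[float, float]:
    """Two-parameter Weibull MLE on strictly positive samples -> (beta, gamma).

    beta is the scale, gamma the shape.  Zeros (and negatives) are excluded
    since the support is the positive reals.
    """
    x = np.asarray(samples, dtype=float)
    x = x[x > 0]
    if x.size < min_samples:
        raise DegenerateInputError(
            f"need >= {min_samples} positive samples, got {x.size}")
    gamma, _loc, beta = stats.weibull_min.fit(x, floc=0)
    return float(beta), float(gamma)


def weibull_scale(img, filter_scale: float = 1.0, method: str = "gaussian",
                  min_samples: int = 100) -> tuple[float, float]:
    """Weibull (beta, gamma) of an image's gradient-magnitude distribution."""
    mag = gradient_magnitude(img, filter_scale, method)
    if not (mag > 0).any():
        raise DegenerateInputError("constant image: all gradient magnitudes are zero")
    return fit_weibull(mag.ravel(), min_samples=min_samples)


@dataclass(frozen=True)
class FixtureTruth:
    object_proportion: float
    critical_location: int
    object_rect: tuple[int, int, int, int]   # (row, col, height, width)
    delta: int


def _background(canvas_size, rng, preset, delta):
    h, w = canvas_size
    hi = 255 - delta  # headroom so adding delta never clips
    if preset == "smooth":
        coarse = rng.uniform(0, hi, size=(max(h // 32, 1), max(w // 32, 1), 3))
        img = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1], 1),
                           order=1)
        img = ndimage.gaussian_filter(img, (3, 3, 0))
    elif preset == "cluttered":
        img = rng.uniform(0, hi, size=(h, w, 3))
    else:
        raise ValueError(f"unknown texture preset {preset!r}")
    return np.clip(img, 0, hi).astype(np.uint8)


def make_fixture_pair(canvas_size, object_rect, delta: int = 50,
                      texture_seed: int = 0, preset: str = "smooth"):
    """Build an image pair differing by exactly ``delta`` inside a rectangle.

    ``canvas_size`` is (height, width); ``object_rect`` is
    (row, col, height, width).  Returns (img_a, img_b, FixtureTruth) where
    the truth records the planted change proportion and the grid location
    holding most changed pixels.
    """
    h, w = canvas_size
    r, c, rh, rw = object_rect
    if r < 0 or c < 0 or r + rh > h or c + rw > w:
        raise ValueError(f"object_rect {object_rect} outside canvas {canvas_size}")
    if not 1 <= delta <= 255:
        raise ValueError("delta must be in 1..255")
    rng = np.random.default_rng(texture_seed)
    img_a = _background((h, w), rng, preset, delta)
    img_b = img_a.copy()
    img_b[r:r + rh, c:c + rw] = img_b[r:r + rh, c:c + rw].astype(int) + delta

    mask = np.zeros((h, w), dtype=bool)
    mask[r:r + rh, c:c + rw] = True
    counts = {loc: int(p.sum()) for loc, p in split_grid(mask).items()}
    loc = max(sorted(counts), key=lambda k: counts[k])
    truth = FixtureTruth(rh * rw / (h * w), loc, tuple(object_rect), delta)
    return img_a, img_b, truth


@dataclass(frozen=True)
class ImagePairStats:
    pair_id: str
    critical_location: int
    object_size: float
    log_object_size: float
    weibull_scale_congruent: float
    weibull_shape_congruent: float
    weibull_scale_incongruent: float
    weibull_shape_incongruent: float


def image_pair_stats(pair_id: str, img_congruent, img_incongruent,
                     threshold: float = 10, filter_scale: float = 1.0,
                     aggregate: str = "max") -> ImagePairStats:
    """All per-pair image statistics in one record."""
    size = object_size(img_congruent, img_incongruent, threshold, aggregate)
    loc = critical_object_patch(img_congruent, img_incongruent, threshold, aggregate)
    bc, gc = weibull_scale(img_congruent, filter_scale)
    bi, gi = weibull_scale(img_incongruent, filter_scale)
    return ImagePairStats(pair_id, loc, size,
                          float(np.log(size)) if size > 0 else float("nan"),
                          bc, gc, bi, gi)
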