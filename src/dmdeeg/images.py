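"""Fixed-size feature images and CNN input tensors.

Per-segment matrices (DMD mode maps or band-restricted PSDs) have a variable
number of columns, so each is bilinearly interpolated on a corner-aligned grid
to a 50x50 raster and min-max rescaled to [0, 1].  Twelve consecutive segment
images stack into the 50x50x12 tensor that is the unit of CNN input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .dmd import ModeMap
from .spectral import PSDMatrix

IMAGE_SIZE = 50
TENSOR_DEPTH = 12


@dataclass
class FeatureTensor:
    """50x50x12 stack of per-segment images in [0, 1] plus its provenance."""

    values: np.ndarray
    meta: dict = field(default_factory=dict)


def _as_matrix(m) -> np.ndarray:
    if isinstance(m, ModeMap):
        return m.magnitudes
    if isinstance(m, PSDMatrix):
        return m.values
    return np.asarray(m, dtype=float)


def to_image(matrix, size: int = IMAGE_SIZE) -> np.ndarray:
    """Resize an M x K matrix to ``size x size`` by corner-aligned bilinear
    interpolation, then rescale to [0, 1].

    Constant (or empty, K = 0) input maps to an all-zero image, making the
    transform invariant to positive affine changes of scale: ``to_image(a*X + b)
    == to_image(X)`` for ``a > 0``.
    """
    matrix = _as_matrix(matrix)
    if matrix.ndim != 2:
        raise ValueError("input must be a 2-D matrix")
    if matrix.size and not np.all(np.isfinite(matrix)):
        raise ValueError("input contains non-finite values")
    m, k = matrix.shape
    if m == 0 or k == 0:
        warnings.warn("empty feature matrix; emitting an all-zero image")
        return np.zeros((size, size))
    # corner-aligned grid: endpoints of the source map to endpoints of the raster
    if m == 1 or k == 1:
        matrix = np.broadcast_to(
            matrix, (max(m, 2) if m == 1 else m, max(k, 2) if k == 1 else k))
        m, k = matrix.shape
    interp = RegularGridInterpolator(
        (np.linspace(0, 1, m), np.linspace(0, 1, k)), matrix, method="linear")
    grid = np.linspace(0, 1, size)
    gy, gx = np.meshgrid(grid, grid, indexing="ij")
    img = interp(np.stack([gy.ravel(), gx.ravel()], axis=1)).reshape(size, size)
    lo, hi = img.min(), img.max()
    # constant up to interpolation round-off maps to all-zeros
    if hi - lo <= 1e-12 * max(abs(hi), abs(lo), 1.0):
        return np.zeros((size, size))
    return (img - lo) / (hi - lo)


def stack_tensor(images, meta: dict | None = None,
                 depth: int = TENSOR_DEPTH) -> FeatureTensor:
    """Stack exactly ``depth`` ordered 50x50 images into a feature tensor;
    depth index i holds segment i's image."""
    images = list(images)
    if len(images) != depth:
        raise ValueError(f"expected {depth} images, got {len(images)}")
    arrs = []
    for i, img in enumerate(images):
        img = np.asarray(img)
        if img.shape != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(f"image {i} has shape {img.shape}, "
                             f"expected ({IMAGE_SIZE}, {IMAGE_SIZE})")
        arrs.append(img)
    values = np.stack(arrs, axis=-1)
    return FeatureTensor(values, dict(meta or {}))


def average_class_heatmap(maps, labels, classes=None) -> dict:
    """Per-class mean feature image, re-normalized to [0, 1].

    ``maps`` are ModeMaps, PSDMatrices, or raw matrices; each is rastered with
    :func:`to_image` before averaging so heterogeneous mode counts share a
    geometry.  Returns ``{label: 50x50 array}``.  If ``classes`` is given,
    labels outside it are rejected.
    """
    maps, labels = list(maps), list(labels)
    if len(maps) != len(labels):
        raise ValueError("maps and labels must have equal length")
    if classes is None:
        classes = sorted(set(labels))
    else:
        unknown = set(labels) - set(classes)
        if unknown:
            raise ValueError(f"unknown label(s) {sorted(unknown)}")
    out = {}
    for cls in classes:
        members = [to_image(m) for m, lbl in zip(maps, labels) if lbl == cls]
        mean = np.mean(members, axis=0)
        lo, hi = mean.min(), mean.max()
        out[cls] = np.zeros_like(mean) if hi == lo else (mean - lo) / (hi - lo)
    return out
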