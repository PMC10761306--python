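"""Binary needle ground truth from photoacoustic envelope images.

The chain is: threshold -> binarize -> connected-component labeling -> keep
the large component(s). The needle is by far the strongest absorber, so the
surviving component is the needle band; small absorber blobs are discarded.
Frames where nothing survives are flagged rather than raised on, so callers
can exclude them from training pairs.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from skimage import measure

from .imgform import BScanImage, EnvelopeImage

__all__ = [
    "BinaryNeedleMask",
    "PreprocessConfig",
    "threshold_binarize",
    "label_components",
    "select_large_components",
    "preprocess_pa",
    "otsu_threshold",
]


@dataclasses.dataclass
class BinaryNeedleMask:
    """Boolean foreground mask for the needle, with an empty-result flag."""

    pixels: np.ndarray
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.n_foreground == 0:
            self.flagged_empty = True

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())

    def points(self) -> np.ndarray:
        """Foreground pixel coordinates as an (n, 2) array of (row, col)."""
        return np.argwhere(self.pixels)

    def save(self, path) -> None:
        import imageio.v3 as iio

        iio.imwrite(path, (self.pixels.astype(np.uint8) * 255))

    @classmethod
    def load(cls, path) -> "BinaryNeedleMask":
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = arr.max(axis=2)
        return cls(arr > 127)


@dataclasses.dataclass
class PreprocessConfig:
    """Configuration of the PA-to-mask chain."""

    method: Literal["otsu", "fixed_fraction"] = "otsu"
    fixed_fraction: float = 0.5
    connectivity: Literal[4, 8] = 8
    policy: Literal["largest", "area_fraction"] = "largest"
    area_fraction: float = 0.5


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's threshold over ``nbins`` histogram bins.

    Returns the lower edge of the first foreground bin, so foreground is
    ``values >= threshold``. Implemented directly (cumulative moments over the
    histogram) so tests can check it against an exhaustive threshold search.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = values.min(), values.max()
    if lo == hi:
        return hi  # degenerate: single level
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    w = hist.astype(np.float64)
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(w)[:-1]
    w1 = w.sum() - w0
    m = np.cumsum(w * centers)
    mu0 = m[:-1] / np.where(w0 > 0, w0, 1.0)
    mu1 = (m[-1] - m[:-1]) / np.where(w1 > 0, w1, 1.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(between))  # split after bin k; foreground starts at bin k+1
    return float(edges[k + 1])


def _as_values(img) -> np.ndarray:
    if isinstance(img, (BScanImage, EnvelopeImage)):
        return img.values
    return np.asarray(img, dtype=np.float64)


def threshold_binarize(
    img, method: str = "otsu", fraction: float = 0.5
) -> BinaryNeedleMask:
    """Binarize an image: pixel true iff value >= threshold.

    ``method`` is either ``"otsu"`` or ``"fixed_fraction"`` (threshold =
    ``fraction`` x max value). An all-zero image yields an empty, flagged mask.
    """
    values = _as_values(img)
    if not np.all(np.isfinite(values)) or np.any(values < 0):
        raise ValueError("image must be finite and non-negative")
    if values.max() == 0:
        return BinaryNeedleMask(np.zeros(values.shape, dtype=bool), flagged_empty=True)
    if method == "otsu":
        thr = otsu_threshold(values)
    elif method == "fixed_fraction":
        if not (0 < fraction <= 1):
            raise ValueError("fraction must lie in (0, 1]")
        thr = fraction * values.max()
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return BinaryNeedleMask(values >= thr)


def label_components(
    mask: BinaryNeedleMask | np.ndarray, connectivity: int = 8
) -> tuple[np.ndarray, np.ndarray]:
    """Label connected foreground regions.

    Returns ``(labeled, areas)`` where ``labeled`` assigns each maximal
    connected region a distinct positive label (background 0, labels in raster
    order of first pixel) and ``areas[i]`` is the pixel count of label ``i+1``.
    """
    pixels = mask.pixels if isinstance(mask, BinaryNeedleMask) else np.asarray(mask, dtype=bool)
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labeled = measure.label(pixels, connectivity=1 if connectivity == 4 else 2)
    n = labeled.max()
    areas = np.bincount(labeled.ravel(), minlength=n + 1)[1:].astype(np.int64)
    return labeled, areas


def select_large_components(
    labeled: np.ndarray,
    areas: np.ndarray | None = None,
    policy: str = "largest",
    area_fraction: float = 0.5,
) -> BinaryNeedleMask:
    """Keep the large component(s) of a labeled map.

    ``largest`` keeps only the single maximum-area component (ties broken by
    the smallest label, i.e. first in raster order); ``area_fraction`` keeps
    every component with area >= ``area_fraction`` x the maximum area.
    An empty map yields an empty, flagged mask.
    """
    labeled = np.asarray(labeled)
    if areas is None:
        n = labeled.max()
        areas = np.bincount(labeled.ravel(), minlength=n + 1)[1:].astype(np.int64)
    if len(areas) == 0 or areas.max() == 0:
        return BinaryNeedleMask(np.zeros(labeled.shape, dtype=bool), flagged_empty=True)
    if policy == "largest":
        keep = int(np.argmax(areas)) + 1  # argmax returns the first maximum
        return BinaryNeedleMask(labeled == keep)
    if policy == "area_fraction":
        if not (0 < area_fraction <= 1):
            raise ValueError("area_fraction must lie in (0, 1]")
        keep_labels = np.flatnonzero(areas >= area_fraction * areas.max()) + 1
        return BinaryNeedleMask(np.isin(labeled, keep_labels))
    raise ValueError(f"unknown policy {policy!r}")


def preprocess_pa(img, config: PreprocessConfig | None = None) -> BinaryNeedleMask:
    """Full PA-to-ground-truth chain: binarize, label, keep large components."""
    cfg = config or PreprocessConfig()
    binary = threshold_binarize(img, method=cfg.method, fraction=cfg.fixed_fraction)
    if binary.flagged_empty:
        return binary
    labeled, areas = label_components(binary, connectivity=cfg.connectivity)
    return select_large_components(labeled, areas, policy=cfg.policy, area_fraction=cfg.area_fraction)
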