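"""Needle localization metrics.

Implements the evaluation chain used for scoring predicted needle masks
against ground-truth masks: straight-line estimation from a mask, the
modified Hausdorff distance (MHD) between pixel sets, the two-criterion
localization-success rule (NLSR), targeting error relative to the image
center, the tip-to-base needle length ratio, and success-only aggregation
into a report.

Conventions (documented, not inferred): coordinates are 0-based (row, col);
the image center is ((H-1)/2, (W-1)/2); targeting error is the absolute
difference of center-to-line distances; summary standard deviations use the
sample (n-1) form.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .pagt import BinaryNeedleMask

__all__ = [
    "NeedleLine",
    "MetricsConfig",
    "ImageRecord",
    "MetricsReport",
    "estimate_needle_line",
    "directed_mean_distance",
    "mhd",
    "localization_success",
    "targeting_error",
    "needle_length_ratio",
    "evaluate_dataset",
    "edge_points",
]

DEFAULT_OVERLAP_THRESHOLD = 0.3
DEFAULT_PASS_THROUGH_TOL = 1.0  # px perpendicular distance


@dataclasses.dataclass(frozen=True)
class NeedleLine:
    """Tip/base endpoints (row, col) and the infinite line through them.

    The tip is the deeper endpoint (larger row).
    """

    tip: tuple[float, float]
    base: tuple[float, float]

    def __post_init__(self) -> None:
        if np.allclose(self.tip, self.base):
            raise ValueError("tip and base must differ")
        if self.tip[0] < self.base[0]:
            raise ValueError("tip must have the larger axial (row) coordinate")

    @property
    def direction(self) -> np.ndarray:
        """Unit vector from base to tip."""
        d = np.asarray(self.tip, dtype=np.float64) - np.asarray(self.base, dtype=np.float64)
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        """Tip-to-base 2-D Euclidean distance."""
        return float(
            np.linalg.norm(np.asarray(self.tip, dtype=np.float64) - np.asarray(self.base))
        )

    def distance_to_point(self, point: Sequence[float]) -> float:
        """Perpendicular distance from a point to the infinite line."""
        p = np.asarray(point, dtype=np.float64) - np.asarray(self.base, dtype=np.float64)
        d = self.direction
        return float(abs(p[0] * d[1] - p[1] * d[0]))

    def distances_to_points(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64) - np.asarray(self.base, dtype=np.float64)
        d = self.direction
        return np.abs(p[:, 0] * d[1] - p[:, 1] * d[0])


def _order_endpoints(p: np.ndarray, q: np.ndarray) -> NeedleLine:
    # tip = deeper point; break row ties by the larger column
    if (p[0], p[1]) >= (q[0], q[1]):
        tip, base = p, q
    else:
        tip, base = q, p
    return NeedleLine(tip=(float(tip[0]), float(tip[1])), base=(float(base[0]), float(base[1])))


def estimate_needle_line(mask: BinaryNeedleMask | np.ndarray) -> NeedleLine | None:
    """Fit a straight needle line to the foreground of a mask.

    Total least squares: the line through the centroid along the principal
    axis of the foreground pixel coordinates. Endpoints are the extreme
    orthogonal projections of foreground pixels onto that axis; the tip is
    the deeper endpoint. Returns ``None`` for an empty mask or a mask with a
    single pixel (no orientation defined), which callers record as a
    localization failure.
    """
    pts = (
        mask.points()
        if isinstance(mask, BinaryNeedleMask)
        else np.argwhere(np.asarray(mask, dtype=bool))
    ).astype(np.float64)
    if len(pts) < 2:
        return None
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # principal axis via SVD of the centered coordinates (TLS direction)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    proj = centered @ direction
    if np.isclose(proj.min(), proj.max()):
        return None  # all pixels project to one point (degenerate)
    p = centroid + proj.min() * direction
    q = centroid + proj.max() * direction
    return _order_endpoints(p, q)


def _as_points(a) -> np.ndarray:
    if isinstance(a, BinaryNeedleMask):
        return a.points().astype(np.float64)
    arr = np.asarray(a, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("point set must be an (n, 2) array")
    return arr


def directed_mean_distance(a, b) -> float:
    """Mean over points of A of the nearest-neighbor distance to B."""
    pa, pb = _as_points(a), _as_points(b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("point sets must be non-empty")
    d, _ = cKDTree(pb).query(pa, k=1)
    return float(np.mean(d))


def mhd(a, b) -> float:
    """Modified Hausdorff distance: max of the two directed mean distances."""
    return max(directed_mean_distance(a, b), directed_mean_distance(b, a))


def edge_points(mask: BinaryNeedleMask | np.ndarray) -> np.ndarray:
    """Boundary pixels of a mask (foreground pixels with a 4-neighbor outside)."""
    from scipy import ndimage

    pixels = mask.pixels if isinstance(mask, BinaryNeedleMask) else np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(pixels, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return np.argwhere(pixels & ~eroded).astype(np.float64)


def localization_success(
    gt_mask: BinaryNeedleMask | np.ndarray,
    pred_mask: BinaryNeedleMask | np.ndarray,
    pred_line: NeedleLine | None,
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    pass_through_tol: float = DEFAULT_PASS_THROUGH_TOL,
) -> bool:
    """Two-criterion success rule for one image.

    Success iff (1) the predicted line passes through the ground truth — at
    least one ground-truth pixel lies within ``pass_through_tol`` px of the
    infinite predicted line — and (2) the ground-truth/prediction pixel
    overlap reaches ``overlap_threshold`` x the ground-truth area. An empty
    prediction or missing line fails.
    """
    gt = gt_mask.pixels if isinstance(gt_mask, BinaryNeedleMask) else np.asarray(gt_mask, dtype=bool)
    pred = (
        pred_mask.pixels
        if isinstance(pred_mask, BinaryNeedleMask)
        else np.asarray(pred_mask, dtype=bool)
    )
    n_gt = int(gt.sum())
    if n_gt == 0:
        raise ValueError("ground-truth mask must be non-empty")
    if pred_line is None or not pred.any():
        return False
    gt_pts = np.argwhere(gt).astype(np.float64)
    if not np.any(pred_line.distances_to_points(gt_pts) <= pass_through_tol):
        return False
    overlap = int(np.logical_and(gt, pred).sum())
    return overlap >= overlap_threshold * n_gt


def _image_center(image_size: tuple[int, int]) -> np.ndarray:
    h, w = image_size
    return np.array([(h - 1) / 2.0, (w - 1) / 2.0])


def targeting_error(
    true_line: NeedleLine, pred_line: NeedleLine, image_size: tuple[int, int]
) -> float:
    """|d_true - d_pred|, the d's being center-to-infinite-line distances."""
    center = _image_center(image_size)
    return abs(true_line.distance_to_point(center) - pred_line.distance_to_point(center))


def needle_length_ratio(pred_line: NeedleLine, true_line: NeedleLine) -> float:
    """Predicted tip-to-base length divided by the true tip-to-base length."""
    if true_line.length <= 0:
        raise ValueError("true needle length must be > 0")
    return pred_line.length / true_line.length


@dataclasses.dataclass
class MetricsConfig:
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD
    pass_through_tol: float = DEFAULT_PASS_THROUGH_TOL
    use_edges: bool = False  # MHD on boundary pixels instead of full masks


@dataclasses.dataclass
class ImageRecord:
    index: int
    success: bool
    mhd: float | None = None
    te: float | None = None
    length_ratio: float | None = None


@dataclasses.dataclass
class MetricsReport:
    """NLSR over all images plus success-only mean +/- sample std per metric."""

    n_images: int
    records: list[ImageRecord]

    @property
    def n_success(self) -> int:
        return sum(r.success for r in self.records)

    @property
    def nlsr(self) -> float:
        """Needle localization success rate as a percentage."""
        return 100.0 * self.n_success / self.n_images

    def _summary(self, field: str) -> tuple[float, float]:
        vals = np.array([getattr(r, field) for r in self.records if r.success], dtype=np.float64)
        if len(vals) == 0:
            return float("nan"), float("nan")
        std = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        return float(vals.mean()), std

    @property
    def mhd_mean_std(self) -> tuple[float, float]:
        return self._summary("mhd")

    @property
    def te_mean_std(self) -> tuple[float, float]:
        return self._summary("te")

    @property
    def length_ratio_mean_std(self) -> tuple[float, float]:
        return self._summary("length_ratio")

    def to_frame(self):
        """Per-image rows plus a summary row (columns match the report layout)."""
        import pandas as pd

        rows = [
            {
                "index": r.index,
                "success": r.success,
                "mhd": r.mhd,
                "te": r.te,
                "length_ratio": r.length_ratio,
            }
            for r in self.records
        ]
        m, ms = self.mhd_mean_std
        t, ts = self.te_mean_std
        lr, lrs = self.length_ratio_mean_std
        rows.append(
            {
                "index": "summary",
                "success": f"NLSR={self.nlsr:.2f}%",
                "mhd": f"{m:.3f} +/- {ms:.3f}",
                "te": f"{t:.3f} +/- {ts:.3f}",
                "length_ratio": f"{lr:.4f} +/- {lrs:.4f}",
            }
        )
        return pd.DataFrame(rows)


def evaluate_dataset(
    pred_masks: Sequence,
    gt_masks: Sequence,
    config: MetricsConfig | None = None,
) -> MetricsReport:
    """Score paired prediction/ground-truth masks.

    Per image: apply the success rule; for successes only, compute MHD between
    the foreground pixel sets (or boundary sets if configured), targeting
    error and length ratio between the estimated lines. NLSR counts successes
    over all images.
    """
    cfg = config or MetricsConfig()
    if len(pred_masks) != len(gt_masks):
        raise ValueError("prediction and ground-truth lists must have equal length")
    if len(pred_masks) == 0:
        raise ValueError("at least one image pair is required")

    records: list[ImageRecord] = []
    for i, (pred, gt) in enumerate(zip(pred_masks, gt_masks)):
        pred_m = pred if isinstance(pred, BinaryNeedleMask) else BinaryNeedleMask(pred)
        gt_m = gt if isinstance(gt, BinaryNeedleMask) else BinaryNeedleMask(gt)
        if pred_m.pixels.shape != gt_m.pixels.shape:
            raise ValueError(f"image {i}: shape mismatch {pred_m.pixels.shape} vs {gt_m.pixels.shape}")
        pred_line = estimate_needle_line(pred_m)
        gt_line = estimate_needle_line(gt_m)
        ok = gt_line is not None and localization_success(
            gt_m, pred_m, pred_line, cfg.overlap_threshold, cfg.pass_through_tol
        )
        if not ok:
            records.append(ImageRecord(index=i, success=False))
            continue
        if cfg.use_edges:
            a, b = edge_points(pred_m), edge_points(gt_m)
        else:
            a, b = pred_m.points().astype(np.float64), gt_m.points().astype(np.float64)
        records.append(
            ImageRecord(
                index=i,
                success=True,
                mhd=mhd(a, b),
                te=targeting_error(gt_line, pred_line, gt_m.pixels.shape),
                length_ratio=needle_length_ratio(pred_line, gt_line),
            )
        )
    return MetricsReport(n_images=len(records), records=records)
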