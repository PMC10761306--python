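"""Synthetic paired US/PA frames of in-plane needle insertion.

The US image is log-compressed Rayleigh speckle plus a needle echo whose
intensity falls off with insertion angle (cos-power) and depth (exponential),
with Bernoulli segment dropout and optional dimmer parallel ghost lines. The
PA image is a clean high-intensity needle band plus bright absorber blobs;
the ground-truth mask is the exact (hard, un-anti-aliased) band with the
blobs excluded, mirroring the high-contrast PA rationale. Not a physical
acoustic simulation — a controllable test bed.

All randomness flows from a single seed; the same seed reproduces the same
pair bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .imgform import BScanImage, EnvelopeImage, log_compress, save_image
from .metrics import NeedleLine
from .pagt import BinaryNeedleMask

__all__ = [
    "SimConfig",
    "SimPair",
    "simulate_pair",
    "simulate_pairs",
    "simulate_dataset",
    "make_fixture_suite",
]

GAUGE_THICKNESS = {18: 3, 23: 2}  # needle gauge -> band thickness in px


@dataclasses.dataclass(frozen=True)
class SimConfig:
    image_size: tuple[int, int] = (256, 256)  # (H, W)
    angle_range: tuple[float, float] = (10.0, 45.0)  # insertion angle, degrees
    depth_range: tuple[float, float] = (0.4, 0.85)  # tip depth as fraction of H
    needle_length_range: tuple[float, float] = (0.35, 0.7)  # fraction of W
    gauges: tuple[int, ...] = (18, 23)
    needle_dropout: float = 0.15  # per-segment Bernoulli drop probability
    dropout_segment_px: int = 8
    needle_amplitude: float = 6.0  # echo amplitude before angle/depth falloff
    echo_angle_power: float = 1.5
    depth_attenuation: float = 0.8  # e-folding over the full image height
    speckle_scale: float = 1.0  # Rayleigh scale of the background envelope
    echo_ghost_count: int = 1
    echo_ghost_offset: int = 6  # px perpendicular offset per ghost
    echo_ghost_gain: float = 0.35
    pa_artifact_count: int = 3
    pa_artifact_radius: int = 3
    pa_artifact_amplitude: float = 0.6  # relative to the needle band's 1.0
    dynamic_range: float = 45.0  # dB for US log compression
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size[0] < 32 or self.image_size[1] < 32:
            raise ValueError("image_size must be at least 32x32")
        for name in ("angle_range", "depth_range", "needle_length_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be a non-empty (lo, hi) range")
        if not 0 <= self.needle_dropout <= 1:
            raise ValueError("needle_dropout must lie in [0, 1]")
        for g in self.gauges:
            if g not in GAUGE_THICKNESS:
                raise ValueError(f"unsupported gauge {g}; known: {sorted(GAUGE_THICKNESS)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SimPair:
    """One synthetic training example with its exact ground truth."""

    us_image: BScanImage
    pa_image: EnvelopeImage
    pa_mask: BinaryNeedleMask
    true_line: NeedleLine
    meta: dict


def _segment_geometry(cfg: SimConfig, rng: np.random.Generator):
    """Sample a needle segment fully inside the frame; bounded retries."""
    h, w = cfg.image_size
    margin = 4 + max(GAUGE_THICKNESS.values())
    for _ in range(200):
        angle = rng.uniform(*cfg.angle_range)
        depth = rng.uniform(*cfg.depth_range)
        length = rng.uniform(*cfg.needle_length_range) * w
        going_right = bool(rng.integers(0, 2))
        a = np.deg2rad(angle)
        tip_row = depth * (h - 1)
        base_row = tip_row - length * np.sin(a)
        dcol = length * np.cos(a) * (1 if going_right else -1)
        tip_col = rng.uniform(margin, w - 1 - margin)
        base_col = tip_col - dcol
        if (
            margin <= base_row < tip_row < h - margin
            and margin <= min(base_col, tip_col)
            and max(base_col, tip_col) <= w - 1 - margin
            and tip_row - base_row >= 2
        ):
            gauge = int(rng.choice(np.array(cfg.gauges)))
            return (base_row, base_col), (tip_row, tip_col), angle, depth, gauge
    raise ValueError("could not place a needle inside the frame; config geometry too tight")


def _band_fields(shape, base, tip):
    """Perpendicular distance to the segment and along-axis projection (px)."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    b = np.asarray(base, dtype=np.float64)
    t = np.asarray(tip, dtype=np.float64)
    d = t - b
    length = np.linalg.norm(d)
    u = d / length
    pr, pc = rr - b[0], cc - b[1]
    along = pr * u[0] + pc * u[1]
    perp = np.abs(pr * u[1] - pc * u[0])
    # distance to the *segment*: beyond the endpoints use the endpoint distance
    clamped = np.clip(along, 0.0, length)
    dr = pr - clamped * u[0]
    dc = pc - clamped * u[1]
    seg_dist = np.hypot(dr, dc)
    return seg_dist, along, perp, length


def simulate_pair(cfg: SimConfig, rng: np.random.Generator | int | None = None) -> SimPair:
    """Generate one paired US/PA frame with exact needle ground truth."""
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(cfg.seed if rng is None else int(rng))
    h, w = cfg.image_size
    base, tip, angle, depth, gauge = _segment_geometry(cfg, rng)
    thickness = GAUGE_THICKNESS[gauge]
    seg_dist, along, _, length = _band_fields((h, w), base, tip)

    hard_band = seg_dist <= thickness / 2.0
    # anti-aliased echo profile: soft 1-px roll-off beyond the hard band
    profile = np.clip(thickness / 2.0 + 1.0 - seg_dist, 0.0, 1.0)

    # angle- and depth-dependent echo strength (visibility mechanisms)
    rows = np.arange(h)[:, None] / max(h - 1, 1)
    depth_gain = np.exp(-cfg.depth_attenuation * rows)
    angle_gain = np.cos(np.deg2rad(angle)) ** cfg.echo_angle_power
    echo_amp = cfg.needle_amplitude * angle_gain

    # Bernoulli dropout over fixed-length segments along the shaft
    n_segments = max(int(np.ceil(length / cfg.dropout_segment_px)), 1)
    kept = rng.random(n_segments) >= cfg.needle_dropout
    seg_index = np.clip((along / cfg.dropout_segment_px).astype(int), 0, n_segments - 1)
    dropout_mask = kept[seg_index]

    needle_echo = echo_amp * profile * dropout_mask * depth_gain

    # ghost reverberation: dimmer parallel bands below the needle
    ghosts = np.zeros((h, w))
    for k in range(1, cfg.echo_ghost_count + 1):
        offset = k * cfg.echo_ghost_offset
        g_base = (base[0] + offset, base[1])
        g_tip = (tip[0] + offset, tip[1])
        if g_tip[0] >= h:
            continue
        g_dist, _, _, _ = _band_fields((h, w), g_base, g_tip)
        g_profile = np.clip(thickness / 2.0 + 1.0 - g_dist, 0.0, 1.0)
        ghosts += echo_amp * (cfg.echo_ghost_gain**k) * g_profile * depth_gain

    speckle = rng.rayleigh(scale=max(cfg.speckle_scale, 1e-12), size=(h, w))
    if cfg.speckle_scale == 0:
        speckle[:] = 0.0
    us_env = speckle + needle_echo + ghosts
    us_image = log_compress(EnvelopeImage(us_env), cfg.dynamic_range)

    # PA frame: clean unit-amplitude band plus absorber blobs kept off the needle
    pa = np.zeros((h, w))
    pa[hard_band] = 1.0
    min_sep = cfg.pa_artifact_radius + thickness + 4.0
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    for _ in range(cfg.pa_artifact_count):
        for _attempt in range(50):
            r0 = rng.uniform(0, h - 1)
            c0 = rng.uniform(0, w - 1)
            center_dist = seg_dist[int(round(r0)), int(round(c0))]
            if center_dist >= min_sep:
                radius = rng.uniform(1.0, cfg.pa_artifact_radius)
                amp = cfg.pa_artifact_amplitude * rng.uniform(0.5, 1.0)
                blob = amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * radius**2))
                pa += blob
                break
    pa_image = EnvelopeImage(pa)
    pa_mask = BinaryNeedleMask(hard_band)

    true_line = NeedleLine(tip=(float(tip[0]), float(tip[1])), base=(float(base[0]), float(base[1])))
    meta = {"angle": float(angle), "depth": float(depth), "gauge": gauge, "seed": cfg.seed}
    return SimPair(us_image, pa_image, pa_mask, true_line, meta)


def simulate_pairs(cfg: SimConfig, n: int) -> Iterator[SimPair]:
    """Stream ``n`` independent pairs, all derived from ``cfg.seed``."""
    children = np.random.SeedSequence(cfg.seed).spawn(n)
    for i, ss in enumerate(children):
        pair = simulate_pair(cfg, np.random.default_rng(ss))
        pair.meta["index"] = i
        yield pair


def split_sizes(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """Floor-based split sizes with the remainder assigned to train."""
    if abs(sum(ratios) - 1.0) > 1e-9 or any(r < 0 for r in ratios):
        raise ValueError("split ratios must be non-negative and sum to 1")
    n_val = int(n * ratios[1])
    n_test = int(n * ratios[2])
    return n - n_val - n_test, n_val, n_test


def simulate_dataset(
    cfg: SimConfig,
    n: int,
    outdir: str | Path,
    split: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> pd.DataFrame:
    """Write ``n`` pairs and a manifest assigning each to a split.

    Returns the manifest (also written to ``outdir/manifest.csv``) with
    columns path_us, path_mask, path_pa, split, angle, depth, gauge, seed,
    flag_empty.
    """
    if n < 10:
        raise ValueError("need at least 10 pairs to split")
    n_train, n_val, n_test = split_sizes(n, split)
    labels = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, pair in enumerate(simulate_pairs(cfg, n)):
        us_path = outdir / f"us_{i:05d}.png"
        mask_path = outdir / f"mask_{i:05d}.png"
        pa_path = outdir / f"pa_{i:05d}.tiff"
        save_image(pair.us_image, us_path)
        pair.pa_mask.save(mask_path)
        save_image(pair.pa_image, pa_path)
        rows.append(
            {
                "path_us": str(us_path),
                "path_mask": str(mask_path),
                "path_pa": str(pa_path),
                "split": labels[i],
                "angle": pair.meta["angle"],
                "depth": pair.meta["depth"],
                "gauge": pair.meta["gauge"],
                "seed": cfg.seed,
                "flag_empty": pair.pa_mask.flagged_empty,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def make_fixture_suite(outdir: str | Path) -> dict[str, str]:
    """Write the small canonical fixtures used by unit tests.

    Returns a name -> path mapping; a ``checksums.json`` records the sha256 of
    every written file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # noiseless pair: no speckle, no dropout, no ghosts
    clean_cfg = SimConfig(
        image_size=(64, 64),
        speckle_scale=0.0,
        needle_dropout=0.0,
        echo_ghost_count=0,
        pa_artifact_count=0,
        seed=7,
    )
    pair = simulate_pair(clean_cfg)
    paths["noiseless_us"] = outdir / "noiseless_us.png"
    paths["noiseless_mask"] = outdir / "noiseless_mask.png"
    save_image(pair.us_image, paths["noiseless_us"])
    pair.pa_mask.save(paths["noiseless_mask"])

    # blob-only PA frame: absorber artifacts but no needle
    rng = np.random.default_rng(11)
    blob = np.zeros((64, 64))
    rr, cc = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
    for _ in range(3):
        r0, c0 = rng.uniform(8, 56, size=2)
        blob += 0.8 * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * 2.5**2))
    paths["blob_only_pa"] = outdir / "blob_only_pa.tiff"
    save_image(EnvelopeImage(blob), paths["blob_only_pa"])

    # tie-area components: two 10-px bars with equal area
    tie = np.zeros((32, 32), dtype=bool)
    tie[5, 2:12] = True
    tie[20, 2:12] = True
    paths["tie_components"] = outdir / "tie_components.png"
    BinaryNeedleMask(tie).save(paths["tie_components"])

    # empty frame
    paths["empty_frame"] = outdir / "empty_frame.png"
    BinaryNeedleMask(np.zeros((32, 32), dtype=bool)).save(paths["empty_frame"])

    checksums = {
        name: hashlib.sha256(Path(p).read_bytes()).hexdigest() for name, p in paths.items()
    }
    (outdir / "checksums.json").write_text(json.dumps(checksums, indent=2, sort_keys=True))
    return {name: str(p) for name, p in paths.items()}
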