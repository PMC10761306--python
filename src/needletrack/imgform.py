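"""From beamformed RF to display-ready images.

US B-mode: quadrature (IQ) demodulation at the carrier, low-pass filtering,
envelope magnitude, then log compression. PA: per-line Hilbert envelope.
All processing runs per scan line along the axial (row) axis; the lateral
axis is untouched.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy import signal

__all__ = [
    "RFFrame",
    "EnvelopeImage",
    "BScanImage",
    "quadrature_demodulate",
    "hilbert_envelope",
    "log_compress",
    "save_image",
    "load_image",
]

DEFAULT_DYNAMIC_RANGE_DB = 50.0


@dataclasses.dataclass
class RFFrame:
    """One beamformed RF frame: axial samples (rows) by lateral lines (cols)."""

    samples: np.ndarray
    sampling_rate: float  # MHz
    carrier_frequency: float  # MHz

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError(f"samples must be 2-D, got shape {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")
        if not self.sampling_rate > 2 * self.carrier_frequency:
            raise ValueError(
                f"Nyquist violated: sampling_rate {self.sampling_rate} MHz must exceed "
                f"2 x carrier ({2 * self.carrier_frequency} MHz)"
            )

    @classmethod
    def load(cls, path: str | Path) -> "RFFrame":
        """Read a frame saved by :meth:`save` (``.npy`` array + JSON sidecar)."""
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(np.load(path), meta["sampling_rate"], meta["carrier_frequency"])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.save(path, self.samples)
        path.with_suffix(".json").write_text(
            json.dumps(
                {"sampling_rate": self.sampling_rate, "carrier_frequency": self.carrier_frequency}
            )
        )


@dataclasses.dataclass
class EnvelopeImage:
    """Non-negative detected envelope, prior to display mapping."""

    values: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)  # (axial cm, lateral cm)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("envelope must be 2-D")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("envelope values must be finite and >= 0")


@dataclasses.dataclass
class BScanImage:
    """Log-compressed display image with values in [0, 1]."""

    values: np.ndarray
    dynamic_range: float = DEFAULT_DYNAMIC_RANGE_DB

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("B-scan must be 2-D")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("B-scan values must lie in [0, 1]")


def quadrature_demodulate(
    rf: RFFrame, lpf_cutoff: float | None = None, filter_order: int = 4
) -> EnvelopeImage:
    """IQ-demodulate each scan line and return the baseband envelope magnitude.

    Each line is mixed with in-phase and quadrature references at the carrier
    frequency, low-pass filtered with a zero-phase Butterworth filter, and the
    magnitude of the complex baseband (scaled by 2 to restore the carrier
    amplitude) is returned. Output shape equals input shape.

    Parameters
    ----------
    rf:
        Beamformed RF frame; the axial axis is axis 0.
    lpf_cutoff:
        Low-pass cutoff in MHz. Defaults to half the carrier frequency.
        Must be below the Nyquist frequency.
    """
    if lpf_cutoff is None:
        lpf_cutoff = rf.carrier_frequency / 2.0
    nyquist = rf.sampling_rate / 2.0
    if not (0 < lpf_cutoff < nyquist):
        raise ValueError(f"lpf_cutoff must lie in (0, {nyquist}) MHz, got {lpf_cutoff}")

    n = rf.samples.shape[0]
    t = np.arange(n) / rf.sampling_rate  # microseconds; frequencies in MHz
    phase = 2.0 * np.pi * rf.carrier_frequency * t
    i_ref = np.cos(phase)[:, None]
    q_ref = -np.sin(phase)[:, None]

    sos = signal.butter(filter_order, lpf_cutoff / nyquist, btype="low", output="sos")
    i_bb = signal.sosfiltfilt(sos, rf.samples * i_ref, axis=0)
    q_bb = signal.sosfiltfilt(sos, rf.samples * q_ref, axis=0)
    env = 2.0 * np.hypot(i_bb, q_bb)
    return EnvelopeImage(env)


def hilbert_envelope(rf: RFFrame) -> EnvelopeImage:
    """Per-line magnitude of the analytic signal; shape preserved."""
    if rf.samples.shape[0] < 8:
        raise ValueError("each line must have at least 8 samples")
    analytic = signal.hilbert(rf.samples, axis=0)
    return EnvelopeImage(np.abs(analytic))


def log_compress(
    env: EnvelopeImage | np.ndarray, dynamic_range: float = DEFAULT_DYNAMIC_RANGE_DB
) -> BScanImage:
    """Map an envelope into [0, 1] over the given dynamic range in dB.

    Values are converted to dB relative to the image maximum, clipped at
    ``-dynamic_range``, and rescaled linearly so the maximum maps to 1 and the
    clip level to 0. An all-zero envelope maps to an all-zero image.
    """
    if not dynamic_range > 0:
        raise ValueError("dynamic_range must be > 0")
    values = env.values if isinstance(env, EnvelopeImage) else np.asarray(env, dtype=np.float64)
    peak = values.max() if values.size else 0.0
    if peak == 0.0:
        return BScanImage(np.zeros_like(values, dtype=np.float64), dynamic_range)
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(values / peak)
    out = np.clip(db, -dynamic_range, 0.0) / dynamic_range + 1.0
    return BScanImage(out, dynamic_range)


def save_image(img: BScanImage | EnvelopeImage | np.ndarray, path: str | Path) -> None:
    """Write an image as 8-bit PNG or 16-bit TIFF depending on the extension."""
    import imageio.v3 as iio
    import tifffile

    values = img.values if hasattr(img, "values") else np.asarray(img, dtype=np.float64)
    peak = values.max() if values.size else 0.0
    # images already in [0,1] are stored as-is; raw envelopes are peak-normalized
    norm = values / peak if peak > 1.0 else values
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, (norm * 65535).round().astype(np.uint16))
    else:
        iio.imwrite(path, (norm * 255).round().astype(np.uint8))


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF written by :func:`save_image` back to float in [0, 1]."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path)).astype(np.float64)
    if arr.ndim == 3:  # collapse any color channels
        arr = arr.mean(axis=2)
    denom = 65535.0 if arr.max() > 255 else 255.0
    return arr / denom
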