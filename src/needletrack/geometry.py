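"""Acquisition parameters of the dual-modal US/PA system and derived quantities.

The defaults describe a 128-element 8 MHz linear array driven in dual mode by
a 10 Hz pulsed laser, with 64 parallel receive channels, so that one combined
US+PA frame needs two laser shots.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "AcquisitionGeometry",
    "frame_rate",
    "surface_fluence",
    "max_recording_seconds",
    "lateral_fov",
]


@dataclasses.dataclass(frozen=True)
class AcquisitionGeometry:
    """Scanner, transducer and laser parameters of the acquisition setup.

    Lengths are in cm, frequencies in the unit given per field, energy in mJ.
    """

    n_elements: int = 128
    element_width: float = 0.03  # cm
    center_frequency: float = 8.0  # MHz
    fractional_bandwidth: float = 0.95
    imaging_depth: float = 2.0  # cm
    sound_speed: float = 1540.0  # m/s
    laser_prf: float = 10.0  # Hz
    n_channels: int = 128
    n_parallel_rx: int = 64
    pulse_energy: float = 100.0  # mJ
    coupling_efficiency: float = 0.25
    illumination_area: float = 3.0  # cm^2
    max_frames: int = 500

    def __post_init__(self) -> None:
        for name in ("n_elements", "n_channels", "n_parallel_rx"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        if not isinstance(self.max_frames, int) or self.max_frames < 0:
            raise ValueError(f"max_frames must be a non-negative integer, got {self.max_frames!r}")
        for name in (
            "element_width",
            "center_frequency",
            "imaging_depth",
            "sound_speed",
            "laser_prf",
            "pulse_energy",
            "illumination_area",
        ):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be > 0, got {v!r}")
        for name in ("fractional_bandwidth", "coupling_efficiency"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v!r}")
        if self.n_parallel_rx > self.n_channels:
            raise ValueError(
                f"n_parallel_rx ({self.n_parallel_rx}) cannot exceed n_channels ({self.n_channels})"
            )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AcquisitionGeometry":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path: str | Path) -> "AcquisitionGeometry":
        """Load from a YAML or JSON config file (or a ``geometry:`` block in one)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
        if isinstance(data, Mapping) and "geometry" in data:
            data = data["geometry"]
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    # -- derived quantities ------------------------------------------------

    @property
    def pulses_per_frame(self) -> int:
        """Laser shots needed to fill all receive channels."""
        return math.ceil(self.n_channels / self.n_parallel_rx)

    def frame_rate(self) -> float:
        """Dual-mode frame rate in Hz: the laser PRF divided by shots per frame."""
        return self.laser_prf / self.pulses_per_frame

    def surface_fluence(self) -> float:
        """Laser fluence at the sample surface in mJ/cm^2."""
        return self.pulse_energy * self.coupling_efficiency / self.illumination_area

    def max_recording_seconds(self) -> float:
        """Longest continuous recording in seconds given the frame buffer size."""
        return self.max_frames / self.frame_rate()

    def lateral_fov(self) -> float:
        """Lateral field of view in cm, using the (N - 1) * pitch convention.

        This is the element-center span, not N * width; chosen as a documented
        convention rather than a physical claim.
        """
        if self.n_elements < 2:
            raise ValueError("lateral_fov requires at least 2 elements")
        return (self.n_elements - 1) * self.element_width


def frame_rate(geom: AcquisitionGeometry) -> float:
    return geom.frame_rate()


def surface_fluence(geom: AcquisitionGeometry) -> float:
    return geom.surface_fluence()


def max_recording_seconds(geom: AcquisitionGeometry) -> float:
    return geom.max_recording_seconds()


def lateral_fov(geom: AcquisitionGeometry) -> float:
    return geom.lateral_fov()
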