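"""Image-stack container and multi-page TIFF I/O."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_stack", "write_stack", "FormatError"]


class FormatError(ValueError):
    """Input file is not a readable grayscale stack."""


@dataclass
class ImageStack:
    """A T x H x W grayscale time-lapse stack with acquisition metadata.

    Attributes
    ----------
    data : (T, H, W) ndarray
        Frame intensities; any numeric dtype.
    pixel_size_um : float
        Lateral calibration, micrometres per pixel.
    frame_rate_fps : float
        Acquisition rate, frames per second.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_rate_fps: float
    source: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise FormatError(f"stack must be T x H x W, got shape {self.data.shape}")
        if self.pixel_size_um <= 0 or self.frame_rate_fps <= 0:
            raise ValueError("pixel_size_um and frame_rate_fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_fps

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_fps


def read_stack(path, pixel_size_um: float, frame_rate_fps: float) -> ImageStack:
    """Read a multi-page TIFF as an :class:`ImageStack`.

    Calibration comes from the caller (typically the analysis config); TIFF
    resolution tags, when present and conflicting, are ignored with the
    config taking precedence.  RGB pages are converted to grayscale by
    channel averaging, with a warning.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface as a format error
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim == 4 and data.shape[-1] in (3, 4):
        warnings.warn(f"{path.name}: RGB input converted to grayscale by averaging")
        data = data[..., :3].mean(axis=-1)
    if data.ndim != 3:
        raise FormatError(f"{path}: unsupported TIFF layout with shape {data.shape}")
    return ImageStack(data, pixel_size_um, frame_rate_fps, source=str(path))


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a grayscale 16-bit multi-page TIFF."""
    data = stack.data
    if data.dtype != np.uint16:
        data = np.clip(np.round(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(Path(path), data, photometric="minisblack")
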