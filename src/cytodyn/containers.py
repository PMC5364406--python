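"""Image-like data carriers: movie stacks and kymographs.

Both are thin wrappers around a numpy intensity array plus the physical
calibration (pixel size in µm, frame interval in s) that every downstream
measurement needs.  Arrays are saved as multi-page TIFF with the calibration
in a JSON sidecar so that round trips are lossless and text-free metadata
conventions of specific acquisition software do not leak into the analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "Kymograph"]


@dataclass
class ImageStack:
    """A grayscale movie: ``intensity`` has shape (frames, H, W)."""

    intensity: np.ndarray
    pixel_size: float  # µm per pixel
    dt: float  # s per frame

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (frames, H, W)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape[1:]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.intensity.astype(np.float32))
        sidecar = {"pixel_size_um": self.pixel_size, "dt_s": self.dt}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "ImageStack":
        path = Path(path)
        data = np.asarray(tifffile.imread(path), dtype=float)
        if data.ndim == 2:
            data = data[None]
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(data, pixel_size=meta["pixel_size_um"], dt=meta["dt_s"])


@dataclass
class Kymograph:
    """Space x time intensity matrix sampled along a line through a movie.

    ``intensity`` has shape (n_space, n_time); row index maps to distance
    along the source line, column index to frame number.
    """

    intensity: np.ndarray
    pixel_size: float  # µm per spatial sample
    dt: float  # s per column
    line: np.ndarray | None = field(default=None)  # source polyline, image coords (µm)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be (space, time)")
        if self.pixel_size <= 0 or self.dt <= 0:
            raise ValueError("pixel_size and dt must be > 0")
        if self.line is not None:
            self.line = np.asarray(self.line, dtype=float)

    @property
    def n_space(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_time(self) -> int:
        return self.intensity.shape[1]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        tifffile.imwrite(path, self.intensity.astype(np.float32))
        sidecar = {
            "pixel_size_um": self.pixel_size,
            "dt_s": self.dt,
            "line_um": None if self.line is None else self.line.tolist(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path: str | Path) -> "Kymograph":
        path = Path(path)
        data = np.asarray(tifffile.imread(path), dtype=float)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        line = meta.get("line_um")
        return cls(
            data,
            pixel_size=meta["pixel_size_um"],
            dt=meta["dt_s"],
            line=None if line is None else np.asarray(line),
        )
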