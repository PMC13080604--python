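"""Video cube container and TIFF I/O.

A :class:`VideoCube` is the canonical in-memory representation of a
grayscale head–neck video: a ``T × H × W`` array of non-negative pixel
intensities plus the acquisition frame rate.  Cubes round-trip through
multi-page TIFF files (one page per frame) with the frame rate stored in
the image description tag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class VideoCube:
    """A grayscale video as a T×H×W intensity array.

    Parameters
    ----------
    frames : ndarray of shape (T, H, W)
        Pixel intensities; must be non-negative and T >= 2.
    frame_rate : float
        Acquisition rate in Hz; must be positive.
    window_length : int, optional
        Analysis window length N in frames (defaults to T).
    """

    frames: np.ndarray
    frame_rate: float
    window_length: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T×H×W, got shape {self.frames.shape}")
        if self.frames.shape[0] < 2:
            raise ValueError("a video cube needs at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.window_length is None:
            self.window_length = self.frames.shape[0]
        if not (2 <= self.window_length <= self.frames.shape[0]):
            raise ValueError(
                f"window_length must be in [2, T={self.frames.shape[0]}], "
                f"got {self.window_length}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration(self) -> float:
        """Video duration in seconds."""
        return self.n_frames / self.frame_rate

    def pixel_series(self, row: int, col: int) -> np.ndarray:
        """Intensity time series s(t) of one pixel (0-based row, column)."""
        return self.frames[:, row, col]

    def to_tiff(self, path: str | Path) -> None:
        """Write as multi-page TIFF; frame rate goes into the description tag."""
        desc = json.dumps({"frame_rate": self.frame_rate, **self.metadata})
        tifffile.imwrite(str(path), self.frames.astype(np.float32), description=desc)

    @classmethod
    def from_tiff(cls, path: str | Path, frame_rate: float | None = None) -> "VideoCube":
        """Read a multi-page TIFF written by :meth:`to_tiff`.

        ``frame_rate`` overrides the stored value (required when reading
        third-party files without a description tag).
        """
        with tifffile.TiffFile(str(path)) as tif:
            frames = tif.asarray()
            meta: dict = {}
            desc = tif.pages[0].tags.get("ImageDescription")
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                except (json.JSONDecodeError, TypeError):
                    meta = {}
        fr = frame_rate if frame_rate is not None else meta.pop("frame_rate", None)
        if fr is None:
            raise ValueError(f"{path}: no frame rate stored; pass frame_rate=")
        meta.pop("frame_rate", None)
        return cls(frames=np.asarray(frames, dtype=np.float64), frame_rate=float(fr),
                   metadata=meta)
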