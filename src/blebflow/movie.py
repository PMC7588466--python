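"""Two-channel calibrated time-lapse container and TIFF I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class CellMovie:
    """Two-channel (membrane + marker) time-lapse with physical calibration.

    Attributes
    ----------
    membrane, actin : (T, H, W) float arrays
        Fluorescence intensity stacks; the "actin" slot holds whichever
        marker channel is analysed (LifeAct, E-cadherin, ...).
    pixel_size : float
        Lateral calibration in micrometres per pixel.
    frame_interval : float
        Time between frames in seconds.
    """

    membrane: np.ndarray
    actin: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        if self.membrane.shape != self.actin.shape:
            raise ValueError("channel stacks must share shape")
        if self.membrane.ndim != 3:
            raise ValueError("stacks must be (T, H, W)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("calibration must be positive")

    @property
    def n_frames(self) -> int:
        return self.membrane.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.membrane.shape[1:]

    @property
    def duration(self) -> float:
        """Movie duration in seconds (first to last frame)."""
        return (self.n_frames - 1) * self.frame_interval

    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds."""
        return np.arange(self.n_frames) * self.frame_interval

    def save(self, path: str | Path, interleaved: bool = True) -> None:
        """Write the movie as multi-page TIFF.

        interleaved=True writes one file with axes (T, C, H, W); otherwise
        two files ``<stem>_membrane.tif`` and ``<stem>_actin.tif``.
        Calibration is stored in the ImageDescription JSON metadata.
        """
        path = Path(path)
        meta = {
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
        }
        if interleaved:
            stack = np.stack([self.membrane, self.actin], axis=1)
            tifffile.imwrite(path, stack.astype(np.float32), metadata=meta)
        else:
            tifffile.imwrite(
                path.with_name(path.stem + "_membrane.tif"),
                self.membrane.astype(np.float32), metadata=meta)
            tifffile.imwrite(
                path.with_name(path.stem + "_actin.tif"),
                self.actin.astype(np.float32), metadata=meta)

    @classmethod
    def load(cls, path: str | Path, pixel_size: float | None = None,
             frame_interval: float | None = None) -> "CellMovie":
        """Read an interleaved (T, C, H, W) TIFF written by :meth:`save`.

        Calibration is taken from the embedded metadata unless overridden.
        """
        path = Path(path)
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
        if stack.ndim != 4 or stack.shape[1] != 2:
            raise ValueError("expected a (T, 2, H, W) stack")
        px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
        dt = (frame_interval if frame_interval is not None
              else meta.get("frame_interval_s"))
        if px is None or dt is None:
            raise ValueError("calibration missing from file and arguments")
        return cls(membrane=stack[:, 0], actin=stack[:, 1],
                   pixel_size=float(px), frame_interval=float(dt))
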