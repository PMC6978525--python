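"""Image-stack container with acquisition metadata and TIFF round-trip."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A time-lapse (T, H, W) image stack in physical units.

    Attributes
    ----------
    data : ndarray, shape (T, H, W)
        Pixel intensities (counts).
    pixel_size : float
        Pixel edge length in um.
    frame_interval : float
        Time between frames in seconds.
    origin : (float, float)
        Physical coordinate (um) of the top-left corner of pixel (0, 0);
        lets localizations in the image map back to trajectory coordinates.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float
    origin: tuple[float, float] = (0.0, 0.0)
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack data must be (T, H, W)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    def pixel_centers(self):
        """Physical x (per column) and y (per row) coordinates of pixel centres."""
        t, h, w = self.data.shape
        x = self.origin[0] + (np.arange(w) + 0.5) * self.pixel_size
        y = self.origin[1] + (np.arange(h) + 0.5) * self.pixel_size
        return x, y

    def save(self, path) -> None:
        meta = {
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            "origin_um": list(self.origin),
            **self.extras,
        }
        tifffile.imwrite(path, self.data, photometric="minisblack",
                         description=json.dumps(meta))

    @classmethod
    def load(cls, path) -> "ImageStack":
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description or "{}"
        if data.ndim == 2:
            data = data[None]
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
        return cls(
            data=data,
            pixel_size=float(meta.get("pixel_size_um", 1.0)),
            frame_interval=float(meta.get("frame_interval_s", 1.0)),
            origin=tuple(meta.get("origin_um", (0.0, 0.0))),
            extras={k: v for k, v in meta.items()
                    if k not in ("pixel_size_um", "frame_interval_s", "origin_um")},
        )
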