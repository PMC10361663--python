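"""Calibrated two-channel time-lapse container and TIFF round-trip.

The in-memory currency of the whole pipeline is an :class:`ImageStack`:
a ``T x C x Y x X`` float array plus physical calibration (pixel size in
micrometres, per-frame timestamps in seconds) and a mapping telling which
channel is the reporter (the tracked fluorophore) and which the spatial
reference (tubulin / H2B).  On disk a stack is a multi-page TIFF in
``TCYX`` order with the calibration in the TIFF ImageJ metadata, plus an
optional YAML sidecar that overrides it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

DEFAULT_CHANNEL_ROLES = {"reporter": 0, "reference": 1}


@dataclass
class ImageStack:
    """Two-channel time-lapse with physical calibration.

    Parameters
    ----------
    pixels : ndarray, shape (T, C, Y, X)
        Intensities in detector counts.
    pixel_size : float
        Lateral pixel size, micrometres per pixel.
    timestamps : ndarray, shape (T,)
        Acquisition time of each frame in seconds, strictly increasing.
    channel_roles : dict
        Maps ``"reporter"`` and ``"reference"`` to channel indices.
    """

    pixels: np.ndarray
    pixel_size: float
    timestamps: np.ndarray
    channel_roles: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"pixels must be a T x C x Y x X array, got shape {self.pixels.shape}"
            )
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.shape != (self.pixels.shape[0],):
            raise ValueError("timestamps length must equal the number of frames")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def channel(self, role: str) -> np.ndarray:
        """Return the (T, Y, X) sub-stack for ``role`` ('reporter'/'reference')."""
        return self.pixels[:, self.channel_roles[role]]

    def frame(self, t: int, role: str) -> np.ndarray:
        return self.pixels[t, self.channel_roles[role]]


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """Write a stack as a multi-page TIFF (TCYX) with calibration metadata."""
    path = Path(path)
    meta = {
        "pixel_size_um": stack.pixel_size,
        "timestamps_s": list(map(float, stack.timestamps)),
        "channel_roles": stack.channel_roles,
    }
    tifffile.imwrite(path, stack.pixels.astype(np.float32), metadata=meta)


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> ImageStack:
    """Read a TIFF stack written by :func:`write_stack` or with a YAML sidecar.

    The sidecar (``{"pixel_size_um": ..., "frame_interval_s": ...}`` or an
    explicit ``timestamps_s`` list, optional ``channel_roles``) overrides
    any metadata embedded in the TIFF.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pixels = tf.asarray()
        meta = dict(tf.shaped_metadata[0]) if tf.shaped_metadata else {}
    if sidecar is not None:
        with open(sidecar) as fh:
            meta.update(yaml.safe_load(fh) or {})

    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 3:  # single-channel stack: promote to T,1,Y,X
        pixels = pixels[:, None]
    if pixels.ndim != 4:
        raise ValueError(f"cannot interpret TIFF of shape {pixels.shape} as T,C,Y,X")

    pixel_size = float(meta.get("pixel_size_um", 1.0))
    if "timestamps_s" in meta:
        timestamps = np.asarray(meta["timestamps_s"], dtype=float)
    else:
        dt = float(meta.get("frame_interval_s", 1.0))
        timestamps = np.arange(pixels.shape[0]) * dt
    roles = meta.get("channel_roles", dict(DEFAULT_CHANNEL_ROLES))
    roles = {k: int(v) for k, v in roles.items()}
    return ImageStack(pixels, pixel_size, timestamps, roles)
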