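"""Multi-channel image container and TIFF I/O.

The canonical in-memory layout is a float array of shape ``(C, Y, X)`` for a
single plane or ``(C, Z, Y, X)`` for a Z-stack, together with the physical
pixel size in micrometres.  Files are written as OME-TIFF via :mod:`tifffile`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_image", "write_image"]


@dataclass
class ImageStack:
    """A multi-channel fluorescence image with physical pixel size.

    Parameters
    ----------
    data:
        Intensity array, ``(C, Y, X)`` or ``(C, Z, Y, X)``, arbitrary units.
    pixel_size_um:
        Lateral pixel size in µm/pixel.
    channel_names:
        One label per channel (e.g. ``("green", "red")``).
    """

    data: np.ndarray
    pixel_size_um: float = 1.0
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"data must be (C, Y, X) or (C, Z, Y, X); got shape {self.data.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i + 1}" for i in range(self.n_channels))
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def is_zstack(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_planes(self) -> int:
        return self.data.shape[1] if self.is_zstack else 1

    def plane(self, z: int = 0) -> np.ndarray:
        """Return one ``(C, Y, X)`` plane (the only plane for 2D images)."""
        if self.is_zstack:
            return self.data[:, z]
        if z != 0:
            raise IndexError("2D image has a single plane (z = 0)")
        return self.data


def write_image(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as OME-TIFF, preserving pixel size."""
    axes = "CZYX" if stack.is_zstack else "CYX"
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        metadata={
            "axes": axes,
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeY": stack.pixel_size_um,
            "Channel": {"Name": list(stack.channel_names)},
        },
        ome=True,
    )


def read_image(path, pixel_size_um: float | None = None) -> ImageStack:
    """Read a (OME-)TIFF written by :func:`write_image` (or compatible)."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        px = pixel_size_um
        if px is None:
            px = 1.0
            if tf.ome_metadata:
                import re

                m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', tf.ome_metadata)
                if m:
                    px = float(m.group(1))
    if data.ndim == 2:
        data = data[None]
    return ImageStack(np.asarray(data, dtype=float), pixel_size_um=px)
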