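"""Shared in-memory containers for image data.

All lengths are nanometres internally.  Image arrays are indexed
``[row, column]``; the continuous coordinate of pixel ``(i, j)`` is
``((j + 0.5) * pixel_size_nm, (i + 0.5) * pixel_size_nm)`` in ``(x, y)``,
so ``y`` grows with the row index.  For membrane geometries the package
convention is that +y points toward the gut lumen and -y toward the
cell cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class InvalidParameterError(ValueError):
    """A parameter violates an operation's preconditions."""


class GeometryError(ValueError):
    """A requested geometry does not fit inside the available image."""


@dataclass
class ImageStack:
    """Time-ordered frames of one imaging plane and one channel.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Intensity in detector counts.
    pixel_size_nm : float
        Lateral pixel size.
    channel_label : str
        Free-text channel identifier (e.g. a dye name).
    """

    frames: np.ndarray
    pixel_size_nm: float
    channel_label: str = ""
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise InvalidParameterError(
                "an image stack needs >= 2 frames of identical shape"
            )
        if not self.pixel_size_nm > 0:
            raise InvalidParameterError("pixel_size_nm must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class SuperResImage:
    """A single reconstructed or rendered intensity field.

    ``provenance`` records the parameters that produced the image,
    including simulation ground truth when the image is synthetic, so
    that downstream recovery tests never re-derive them from context.
    """

    values: np.ndarray
    pixel_size_nm: float
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError("SuperResImage values must be 2-D")
        if not self.pixel_size_nm > 0:
            raise InvalidParameterError("pixel_size_nm must be > 0")
        if np.any(self.values < 0):
            raise InvalidParameterError("SuperResImage values must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape
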