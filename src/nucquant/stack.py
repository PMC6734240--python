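"""The in-memory 3D (multi-channel) image container.

Axis conventions used throughout the package:

* arrays are ordered ``(channel, z, y, x)``; single-channel 3D input is
  promoted to a singleton channel axis;
* ``spacing`` is ``(dz, dy, dx)`` in micrometres;
* voxel ``(k, j, i)`` spans ``[i*dx, (i+1)*dx)`` etc., so its physical
  centre is at ``((k+0.5)*dz, (j+0.5)*dy, (i+0.5)*dx)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import StackFormatError

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """A voxel grid with physical sampling intervals.

    Parameters
    ----------
    data:
        ``(z, y, x)`` or ``(channel, z, y, x)`` array; stored as float32
        unless already an integer label map.
    spacing:
        ``(dz, dy, dx)`` voxel size in µm, all strictly positive.
    channel_names:
        One name per channel; auto-generated (``ch0`` ...) when omitted.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    channel_names: tuple[str, ...] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 3:
            arr = arr[None]
        if arr.ndim != 4:
            raise StackFormatError(
                f"expected a 3D or 4D array, got shape {arr.shape}"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            arr = np.ascontiguousarray(arr, dtype=np.float32)
        self.data = arr
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise StackFormatError(f"spacing must be 3 positive floats, got {self.spacing}")
        self.spacing = sp
        if self.channel_names is None:
            self.channel_names = tuple(f"ch{i}" for i in range(arr.shape[0]))
        else:
            self.channel_names = tuple(self.channel_names)
            if len(self.channel_names) != arr.shape[0]:
                raise StackFormatError(
                    f"{arr.shape[0]} channels but {len(self.channel_names)} names"
                )

    # -- geometry -----------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[1:])  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in µm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def depth_um(self) -> float:
        return self.data.shape[1] * self.spacing[0]

    def channel(self, which: int | str = 0) -> np.ndarray:
        """Return one channel as a ``(z, y, x)`` view."""
        if isinstance(which, str):
            try:
                which = self.channel_names.index(which)
            except ValueError:
                raise KeyError(f"no channel named {which!r}; have {self.channel_names}")
        return self.data[which]

    def with_data(self, data: np.ndarray, metadata: dict | None = None) -> "ImageStack":
        return ImageStack(
            data,
            self.spacing,
            self.channel_names,
            dict(self.metadata if metadata is None else metadata),
        )


def as_stack(obj, spacing: Sequence[float] | None = None) -> ImageStack:
    """Coerce an array (+ spacing) or pass an ImageStack through."""
    if isinstance(obj, ImageStack):
        return obj
    if spacing is None:
        raise StackFormatError("spacing required when passing a bare array")
    return ImageStack(np.asarray(obj), tuple(spacing))
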