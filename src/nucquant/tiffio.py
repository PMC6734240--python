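"""Multi-page TIFF reading/writing with voxel-size metadata.

Stacks are written one page per z-plane (channels as separate series along the
first axis), with the lateral voxel size in the TIFF resolution tags
(pixels/µm via ImageJ-style metadata) and a sidecar JSON (``<path>.json``)
recording the full ``(dz, dy, dx)`` spacing and channel names. Reading
prefers the sidecar, falls back to ImageJ metadata + resolution tags, and
errors if no voxel size can be determined and none is supplied.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from .errors import MissingVoxelSizeError, StackFormatError
from .stack import ImageStack

__all__ = ["read_stack", "write_stack"]


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a voxel-size sidecar JSON.

    Lossless for 16-bit integer and 32-bit float data.
    """
    path = Path(path)
    dz, dy, dx = stack.spacing
    data = stack.data
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.uint16 if data.max() < 2**16 else np.int32)
    # ImageJ hyperstack layout: one page per (z, channel) plane, ZCYX order
    pages = np.ascontiguousarray(np.swapaxes(data, 0, 1))
    tifffile.imwrite(
        path,
        pages,
        imagej=pages.dtype in (np.dtype(np.uint16), np.dtype(np.float32)),
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={
            "spacing": dz,
            "unit": "um",
            "axes": "ZCYX",
        },
    )
    sidecar = {
        "spacing_zyx_um": [dz, dy, dx],
        "channel_names": list(stack.channel_names),
        "axes": "ZCYX",
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def _spacing_from_tiff(tf: tifffile.TiffFile):
    try:
        page = tf.pages[0]
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        dx = xres[1] / xres[0]
        dy = yres[1] / yres[0]
        dz = None
        if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
            dz = float(tf.imagej_metadata["spacing"])
        if dz is None:
            return None
        return (dz, float(dy), float(dx))
    except (KeyError, ZeroDivisionError, TypeError):
        return None


def read_stack(
    path: str | Path,
    spacing: Sequence[float] | None = None,
    channel_names: Sequence[str] | None = None,
) -> ImageStack:
    """Read a multi-page TIFF stack.

    Voxel sizes come from the sidecar JSON, else ImageJ metadata/resolution
    tags, else the ``spacing`` argument; if all are absent a
    :class:`MissingVoxelSizeError` names the argument to supply
    (CLI flag ``--voxel-size``).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        shapes = {p.shape for p in tf.pages}
        if len(shapes) > 1:
            raise StackFormatError(f"ragged TIFF pages with shapes {sorted(shapes)}")
        data = tf.asarray()
        axes = tf.series[0].axes if tf.series else ""
        tiff_spacing = _spacing_from_tiff(tf)
    sidecar_path = Path(str(path) + ".json")
    names = tuple(channel_names) if channel_names else None
    sp = tuple(spacing) if spacing is not None else None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        if sp is None:
            sp = tuple(sidecar["spacing_zyx_um"])
        if names is None and "channel_names" in sidecar:
            names = tuple(sidecar["channel_names"])
        axes = sidecar.get("axes", axes)
    if sp is None:
        sp = tiff_spacing
    if sp is None:
        raise MissingVoxelSizeError(
            f"{path} carries no voxel-size metadata; pass spacing=(dz, dy, dx) "
            f"(CLI: --voxel-size DZ,DY,DX)"
        )
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 4:
        if axes.upper() == "ZCYX":  # hyperstack page order
            data = np.swapaxes(data, 0, 1)
        elif axes.upper() not in ("CZYX", ""):
            raise StackFormatError(f"unsupported TIFF axes order {axes!r}")
    if data.ndim not in (3, 4):
        raise StackFormatError(f"cannot interpret TIFF with shape {data.shape}")
    return ImageStack(np.ascontiguousarray(data), sp, names)
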