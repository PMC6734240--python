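"""Shared fixtures: tiny synthetic stacks built directly in memory."""

from __future__ import annotations

import numpy as np
import pytest

from nucquant import ImageStack

#: fine-but-affordable sampling used by most unit fixtures, (dz, dy, dx) µm
UNIT_SPACING = (0.2, 0.112, 0.112)


def make_ball_stack(
    centers_um,
    radii_um,
    values,
    field_um=(10.0, 20.0, 20.0),
    spacing=UNIT_SPACING,
    background=0.0,
    channel_names=("ch0",),
):
    """Voxelize uniform balls (by voxel-centre membership) into a stack."""
    shape = tuple(int(round(f / s)) for f, s in zip(field_um, spacing))
    data = np.full(shape, background, dtype=np.float32)
    zz = (np.arange(shape[0]) + 0.5) * spacing[0]
    yy = (np.arange(shape[1]) + 0.5) * spacing[1]
    xx = (np.arange(shape[2]) + 0.5) * spacing[2]
    for c, r, v in zip(centers_um, radii_um, values):
        d2 = (
            (zz[:, None, None] - c[0]) ** 2
            + (yy[None, :, None] - c[1]) ** 2
            + (xx[None, None, :] - c[2]) ** 2
        )
        data[d2 <= r**2] += v
    return ImageStack(data, spacing, channel_names)


@pytest.fixture(scope="session")
def two_ball_stack():
    """Two well-separated interior balls on zero background."""
    return make_ball_stack(
        centers_um=[(5.0, 5.0, 5.0), (5.0, 14.0, 14.0)],
        radii_um=[2.5, 2.0],
        values=[50.0, 30.0],
    )
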