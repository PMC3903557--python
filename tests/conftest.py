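"""Shared geometric fixtures: tiny rasters with known skeleton structure."""

from __future__ import annotations

import math

import numpy as np
import pytest
from skimage import draw, morphology


def stroke_mask(lines, shape=(80, 80), width=1):
    """Render straight strokes (r0, c0, r1, c1) into a boolean mask."""
    mask = np.zeros(shape, dtype=bool)
    for r0, c0, r1, c1 in lines:
        rr, cc = draw.line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[ok], cc[ok]] = True
    if width > 1:
        mask = morphology.dilation(mask, morphology.disk(width // 2))
    return mask


@pytest.fixture
def y_mask_and_disk():
    """A Y: stem entering a disk region at the bottom, two arms on top."""
    mask = np.zeros((40, 40), dtype=bool)
    mask[15:31, 10] = True
    for i in range(10):
        mask[14 - i, 10 + i] = True
        mask[14 - i, 10 - i] = True
    disk = np.zeros((40, 40), dtype=bool)
    disk[28:, :] = True
    return mask, disk


@pytest.fixture
def x_mask_and_disk():
    """An X of two 3-px-wide straight vessels; both left tips in the disk."""
    mask = stroke_mask([(20, 5, 60, 75), (60, 5, 20, 75)], shape=(80, 80), width=3)
    disk = np.zeros((80, 80), dtype=bool)
    disk[:, :12] = True
    return mask, disk


def x_scene(angle_deg, length=70, shape=(160, 160), width=3):
    """Two straight vessels crossing at ``angle_deg`` with disk roots.

    Returns (mask, disk, vessel_masks) where vessel_masks give the
    per-vessel ground truth.
    """
    h, w = shape
    c = np.array([h / 2, w / 2])
    mask = np.zeros(shape, dtype=bool)
    disk = np.zeros(shape, dtype=bool)
    vessel_masks = []
    for a in (angle_deg / 2, -angle_deg / 2):
        d = np.array([math.sin(math.radians(a)), math.cos(math.radians(a))])
        p0, p1 = c - length * d, c + length * d
        vm = stroke_mask(
            [(*np.rint(p0).astype(int), *np.rint(p1).astype(int))],
            shape=shape, width=width,
        )
        vessel_masks.append(vm)
        mask |= vm
        rr, cc = draw.disk(tuple(p0), 8, shape=shape)
        disk[rr, cc] = True
    return mask, disk, vessel_masks
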