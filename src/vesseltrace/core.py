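"""Core data containers shared by the tracing pipeline.

The pipeline converts a binary vessel mask into a one-pixel skeleton,
cuts the skeleton into *segments* (maximal pixel chains between terminal
and branching points), and treats segments as nodes of an undirected
graph whose edges come from junction cliques.  Everything downstream
(ordering, simplification, affinities, label propagation) operates on
these containers.

Coordinates are ``(row, col)``, 0-based; skeleton connectivity is
8-connected throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "PixelClass",
    "EndType",
    "SkeletonMap",
    "Segment",
    "Junction",
    "SegmentSet",
    "VesselTraceError",
    "EmptySkeletonError",
    "NoRootsError",
    "UnsupportedJunctionError",
    "OrderingDeadlockError",
    "validate_mask",
]


class VesselTraceError(RuntimeError):
    """Base class for tracing failures."""


class EmptySkeletonError(VesselTraceError):
    """Raised when a mask contains no foreground to skeletonize."""


class NoRootsError(VesselTraceError):
    """Raised when no terminal point falls inside the optic-disk region."""


class UnsupportedJunctionError(VesselTraceError):
    """Raised for a junction with more than six incident segments."""


class OrderingDeadlockError(VesselTraceError):
    """Raised when segment ordering cannot make progress."""


class PixelClass(Enum):
    """Skeleton pixel taxonomy by 8-neighbour count on the skeleton."""

    TERMINAL = 1   # exactly one skeleton neighbour (or isolated)
    BODY = 2       # exactly two
    BRANCHING = 3  # three or more


class EndType(Enum):
    ROOT = "root"      # terminal point inside the optic-disk region
    END = "end"        # terminal point elsewhere
    BRANCH = "branch"  # bounded by a junction


@dataclass
class SkeletonMap:
    """One-pixel-wide skeleton with per-pixel radius and class.

    ``radius`` holds the Euclidean distance to the nearest background
    pixel (valid only where ``skeleton`` is True); ``pixel_class`` holds
    ``PixelClass`` values encoded as their integer ``value`` (0 off the
    skeleton).
    """

    skeleton: np.ndarray          # bool, rows x cols
    radius: np.ndarray            # float, rows x cols
    pixel_class: np.ndarray       # uint8, PixelClass values, 0 = background

    @property
    def shape(self) -> tuple[int, int]:
        return self.skeleton.shape

    def class_of(self, pixel: tuple[int, int]) -> PixelClass:
        return PixelClass(int(self.pixel_class[pixel]))


@dataclass
class Segment:
    """Ordered pixel chain between terminal/branching points.

    ``end_types`` refers to ``(pixels[0], pixels[-1])``; for a one-pixel
    segment both entries describe the same pixel.  ``junctions`` holds
    the junction index attached at each end (None for terminal ends).
    """

    id: int
    pixels: list[tuple[int, int]]
    end_types: tuple[EndType, EndType]
    radii: list[float]
    junctions: tuple[int | None, int | None] = (None, None)

    @property
    def length(self) -> int:
        """Segment length ``C`` in pixels."""
        return len(self.pixels)

    @property
    def is_root(self) -> bool:
        return EndType.ROOT in self.end_types

    def end_pixel(self, which: str) -> tuple[int, int]:
        return self.pixels[0] if which == "first" else self.pixels[-1]

    def junction_end(self, junction_idx: int) -> str:
        """Which end ('first'/'last') of this segment meets ``junction_idx``."""
        if self.junctions[1] == junction_idx:
            # prefer 'last' when both ends meet the same junction (loop)
            return "last"
        if self.junctions[0] == junction_idx:
            return "first"
        raise KeyError(f"segment {self.id} does not meet junction {junction_idx}")


@dataclass
class Junction:
    """A branching locus: one or more mutually adjacent branching pixels.

    Thick junction blobs are merged into a single junction placed at the
    centroid of their branching pixels.
    """

    point: tuple[float, float]                  # centroid (row, col)
    pixels: list[tuple[int, int]]               # branching pixels merged here
    members: list[int] = field(default_factory=list)   # incident segment ids


@dataclass
class SegmentSet:
    """Segments plus junction bookkeeping and the root set."""

    segments: dict[int, Segment]
    junctions: list[Junction]
    root_ids: set[int]
    disk_region: np.ndarray | None = None       # bool raster, optic-disk area
    shape: tuple[int, int] | None = None

    def __iter__(self):
        return iter(self.segments.values())

    def __len__(self) -> int:
        return len(self.segments)


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Coerce a mask to boolean, checking it is 2-D and binary."""
    arr = np.asarray(mask)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("mask must be a nonempty 2-D array")
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, [0, 1, False, True, 255])):
        raise ValueError("mask values must be binary (0/1 or 0/255)")
    return arr > 0
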