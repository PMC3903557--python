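"""Segment-end orientations and the three affinity profile functions.

Every segment end carries a unit direction pointing *out of* the segment
into the junction it meets.  The angle between two such directions,
folded into [0°, 180°), measures how well two segments continue one
another: 180° is a perfectly straight continuation, 0° doubles back.

Three scalar profiles turn angles into affinities:

* ``f1`` — a piecewise profile used at branchings: flat-ish for acute
  angles, then ``k*cos(theta)`` for wide angles, so ``exp(-f1)`` grows
  monotonically with the junction angle.
* ``f2 = k*cos(theta)`` — used for the favourable (crossing) pairs of a
  4-clique.
* ``f3 = k + k*sin(theta)`` — used for the unfavourable pairs, always
  dominated by ``exp(-f2)`` at obtuse angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Segment

__all__ = [
    "WeightParams",
    "EndOrientation",
    "segment_end_orientation",
    "segment_orientations",
    "angle_between",
    "angle_between_segments",
    "eval_f1",
    "eval_f2",
    "eval_f3",
    "f1_upper_breakpoint",
    "MAX_ANGLE_DEG",
]

# Angles live on the half-open interval [0, 180); exactly antiparallel
# directions are capped just below 180 so the domain is respected.
MAX_ANGLE_DEG = 179.999


@dataclass
class WeightParams:
    """Tunable parameters of the affinity construction.

    k : contrast of the angular profiles (dimensionless).
    theta_c : degrees; end of the steep part of ``f1``.
    c_critical : pixels; length threshold separating skeletonization
        artefacts from genuine short segments.
    beta_critical : degrees; spur-removal angle threshold.
    orientation_window : number of skeleton points averaged per end.
    hessian_sigma : pixels; Gaussian scale of the Hessian when an
        intensity image supplies orientations.
    alpha / epsilon / max_iters : label-propagation settings.
    """

    k: float = 5.0
    theta_c: float = 80.0
    c_critical: int = 10
    beta_critical: float = 70.0
    orientation_window: int = 10
    hessian_sigma: float = 2.0
    alpha: float = 0.9
    epsilon: float = 1e-5
    max_iters: int = 10000
    theta_star: float | None = None  # override of f1's upper breakpoint

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if not 0 < self.theta_c < 90:
            raise ValueError("theta_c must lie in (0, 90) degrees")
        if self.orientation_window < 2:
            raise ValueError("orientation_window must be >= 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class EndOrientation:
    """Unit direction of one segment end, pointing into its junction."""

    segment_id: int
    which_end: str                 # 'first' | 'last'
    direction: np.ndarray          # unit (d_row, d_col)

    def angle_deg(self) -> float:
        """Direction angle in [0, 360) degrees (row-down convention)."""
        return math.degrees(math.atan2(self.direction[0], self.direction[1])) % 360.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.hypot(v[0], v[1]))
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def _endpoint_tangent(pts: np.ndarray, window: int) -> np.ndarray:
    """Tangent at ``pts[-1]`` from a quadratic fit over the last points.

    The tail is parametrized by chordal arc length and each coordinate
    fitted with a degree-2 polynomial; the derivative at the endpoint
    tracks curvature instead of lagging behind it the way an averaged
    secant does.  Falls back to a plain secant for very short chains.
    """
    m = min(window, len(pts))
    tail = pts[-m:]
    if m < 4:
        return _unit(tail[-1] - tail[0])
    s = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(tail, axis=0), axis=1))])
    if s[-1] == 0:
        return _unit(tail[-1] - tail[0])
    dr = np.polyfit(s, tail[:, 0], 2)
    dc = np.polyfit(s, tail[:, 1], 2)
    tangent = np.array([np.polyval(np.polyder(dr), s[-1]),
                        np.polyval(np.polyder(dc), s[-1])])
    if not np.isfinite(tangent).all() or np.allclose(tangent, 0):
        return _unit(tail[-1] - tail[0])
    return _unit(tangent)


def _hessian_directions(pts: np.ndarray, image: np.ndarray, sigma: float) -> np.ndarray:
    """Per-point vessel directions from the smoothed image Hessian.

    The direction along a ridge is the eigenvector of the Hessian whose
    eigenvalue is smallest in magnitude.
    """
    img = np.asarray(image, dtype=float)
    hrr = ndimage.gaussian_filter(img, sigma, order=(2, 0))
    hrc = ndimage.gaussian_filter(img, sigma, order=(1, 1))
    hcc = ndimage.gaussian_filter(img, sigma, order=(0, 2))
    dirs = np.empty((len(pts), 2))
    for i, (r, c) in enumerate(pts):
        h = np.array([[hrr[r, c], hrc[r, c]], [hrc[r, c], hcc[r, c]]])
        evals, evecs = np.linalg.eigh(h)
        dirs[i] = evecs[:, int(np.argmin(np.abs(evals)))]
    return dirs


def segment_end_orientation(
    seg: Segment,
    which_end: str,
    image: np.ndarray | None = None,
    params: WeightParams | None = None,
    junction_point: tuple[float, float] | None = None,
) -> EndOrientation:
    """Orientation of one end of a segment, pointing outward.

    With an intensity ``image``, per-point directions come from the
    Hessian eigenvector at scale ``hessian_sigma`` and the end
    orientation is their sign-aligned mean over the last
    ``orientation_window`` points.  Without an image (binary masks,
    synthetic scenes) the chain geometry itself supplies the tangent at
    the end pixel via a quadratic arc-length fit over the same window.
    Either way the result points out of the segment, through the end
    pixel into the junction.

    A one-pixel segment has no chain direction; its orientation is taken
    from the geometry of the junction it meets (``junction_point``).
    """
    params = params or WeightParams()
    pts = np.asarray(seg.pixels, dtype=float)

    if len(pts) < 2:
        if junction_point is None:
            raise ValueError(
                f"segment {seg.id} has a single pixel; junction_point required"
            )
        v = np.asarray(junction_point, dtype=float) - pts[0]
        return EndOrientation(seg.id, which_end, _unit(v))

    if which_end == "first":
        pts = pts[::-1]
    elif which_end != "last":
        raise ValueError("which_end must be 'first' or 'last'")

    if image is not None:
        point_dirs = _hessian_directions(pts.astype(int), image, params.hessian_sigma)
        m = min(params.orientation_window, len(pts))
        tail = point_dirs[-m:]
        # coarse outward reference: from an interior pixel toward the end
        ref = pts[-1] - pts[max(0, len(pts) - 1 - m)]
        if np.allclose(ref, 0):
            ref = pts[-1] - pts[0]
        signs = np.sign(tail @ ref)
        signs[signs == 0] = 1.0
        mean_dir = (tail * signs[:, None]).mean(axis=0)
        if np.allclose(mean_dir, 0):
            mean_dir = ref
        return EndOrientation(seg.id, which_end, _unit(mean_dir))

    tangent = _endpoint_tangent(pts, params.orientation_window)
    ref = pts[-1] - pts[max(0, len(pts) - 1 - params.orientation_window)]
    if np.allclose(ref, 0):
        ref = pts[-1] - pts[0]
    if float(tangent @ ref) < 0:
        tangent = -tangent
    return EndOrientation(seg.id, which_end, tangent)


def segment_orientations(
    segset,
    image: np.ndarray | None = None,
    params: WeightParams | None = None,
) -> dict[tuple[int, str], EndOrientation]:
    """All end orientations of a SegmentSet, keyed by (segment_id, end)."""
    params = params or WeightParams()
    out: dict[tuple[int, str], EndOrientation] = {}
    for seg in segset:
        for which, jidx in zip(("first", "last"), seg.junctions):
            jpt = segset.junctions[jidx].point if jidx is not None else None
            try:
                out[(seg.id, which)] = segment_end_orientation(
                    seg, which, image=image, params=params, junction_point=jpt
                )
            except ValueError:
                # single-pixel segment with a terminal end: reuse the
                # opposite end's junction if available
                other = seg.junctions[1] if which == "first" else seg.junctions[0]
                if other is None:
                    raise
                jpt = segset.junctions[other].point
                ori = segment_end_orientation(
                    seg, which, image=image, params=params, junction_point=jpt
                )
                # outward at the terminal end points away from that junction
                out[(seg.id, which)] = EndOrientation(seg.id, which, -ori.direction)
    return out


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two directions, folded into [0, 180) degrees."""
    cu, cv = _unit(np.asarray(u, float)), _unit(np.asarray(v, float))
    cosang = float(np.clip(cu @ cv, -1.0, 1.0))
    theta = math.degrees(math.acos(cosang))
    return min(theta, MAX_ANGLE_DEG)


def angle_between_segments(a: EndOrientation, b: EndOrientation) -> float:
    """Junction angle between two segment ends (both pointing inward).

    Equals the geometric angle between the two segments' rays leaving
    the junction: ~180° for a straight continuation, ~0° for a segment
    doubling back on its neighbour.
    """
    return angle_between(a.direction, b.direction)


def f1_upper_breakpoint(params: WeightParams) -> float:
    """Upper breakpoint θ* of ``f1`` in degrees.

    Chosen as ``arccos(-sin(theta_c)^k / k)`` — the unique angle at
    which the plateau value ``-sin(theta_c)^k`` meets ``k*cos(theta)``,
    making ``f1`` continuous.  ``params.theta_star`` overrides it.
    """
    if params.theta_star is not None:
        return params.theta_star
    plateau = -math.sin(math.radians(params.theta_c)) ** params.k
    ratio = plateau / params.k
    if ratio < -1.0:
        # very small k: k*cos(theta) never reaches the plateau value, so
        # the plateau extends over the whole upper range
        return 180.0
    return math.degrees(math.acos(ratio))


def _check_domain(theta: float) -> None:
    if not 0 <= theta < 180:
        raise ValueError(f"angle {theta} outside [0, 180) degrees")


def eval_f1(theta: float, params: WeightParams | None = None) -> float:
    """Piecewise branching profile; continuous and non-increasing."""
    params = params or WeightParams()
    _check_domain(theta)
    k, theta_c = params.k, params.theta_c
    if theta < theta_c:
        return -math.sin(math.radians(theta)) ** k
    if theta < f1_upper_breakpoint(params):
        return -math.sin(math.radians(theta_c)) ** k
    return k * math.cos(math.radians(theta))


def eval_f2(theta: float, params: WeightParams | None = None) -> float:
    params = params or WeightParams()
    _check_domain(theta)
    return params.k * math.cos(math.radians(theta))


def eval_f3(theta: float, params: WeightParams | None = None) -> float:
    params = params or WeightParams()
    _check_domain(theta)
    return params.k + params.k * math.sin(math.radians(theta))
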