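"""Pixel-exact geometry for wound-area bisection.

The halving procedure places the wound (a set of foreground pixels obtained
by rasterizing the annotated border polygon) inside the minimum-area oriented
bounding box of its pixel centers, sweeps 1-pixel-wide strips along the box's
long axis, and selects the strip boundary whose cumulative wound area is
closest to half of the total.  The selected boundary, drawn perpendicular to
the long axis across the box, is the objective halving line.  Arbitrary
(manually drawn) halving lines are evaluated by the same pixel-counting rule:
each foreground pixel is assigned to one side of the (extended) line and the
two side percentages are reported together with the absolute deviation from
the 50% ground truth.

Coordinate convention: 0-based, x to the right, y down; pixel (row i, col j)
covers [j, j+1) x [i, i+1) and has center (j + 0.5, i + 0.5).  This matches
the VGG Image Annotator convention used for the input polygons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import ConvexHull, QhullError

from .errors import (
    CannotHalveError,
    DegenerateMaskError,
    EmptyMaskError,
    InvalidOutlineError,
)

Array = np.ndarray

__all__ = [
    "WoundOutline",
    "BinaryMask",
    "OrientedBox",
    "StripProfile",
    "HalvingLine",
    "SplitResult",
    "HalvingOutcome",
    "polygon_area",
    "rasterize_outline",
    "rasterize_outlines",
    "min_area_box",
    "min_area_box_of_points",
    "strip_profile",
    "select_halving",
    "halving_line",
    "split_by_line",
    "halve",
]


def _as_points(a, name: str = "points") -> Array:
    pts = np.asarray(a, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"{name} must be an (n, 2) array of (x, y) coordinates")
    return pts


def polygon_area(vertices) -> float:
    """Unsigned shoelace area of an implicitly closed polygon."""
    v = _as_points(vertices, "vertices")
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass(frozen=True)
class WoundOutline:
    """Closed wound-border polygon in image pixel coordinates.

    Parameters
    ----------
    vertices
        Ordered (n, 2) array of (x, y) coordinates; the polygon is implicitly
        closed (last vertex connects back to the first).
    image_size
        (width, height) of the underlying image in pixels.  All vertices must
        lie within [0, width] x [0, height].
    """

    vertices: Array
    image_size: tuple[int, int]

    def __post_init__(self):
        v = _as_points(self.vertices, "vertices")
        object.__setattr__(self, "vertices", v)
        if len(v) < 3:
            raise InvalidOutlineError("outline needs at least 3 vertices")
        if polygon_area(v) <= 0:
            raise InvalidOutlineError("outline encloses zero area")
        w, h = self.image_size
        if (
            v[:, 0].min() < 0
            or v[:, 1].min() < 0
            or v[:, 0].max() > w
            or v[:, 1].max() > h
        ):
            raise InvalidOutlineError("outline vertices outside the image bounds")


@dataclass(frozen=True)
class BinaryMask:
    """Rasterized wound region on the image pixel lattice."""

    grid: Array  # boolean, shape (height, width)

    def __post_init__(self):
        g = np.asarray(self.grid)
        if g.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        object.__setattr__(self, "grid", g.astype(bool))

    @property
    def pixel_count(self) -> int:
        """Number of foreground pixels (the wound area A, in px)."""
        return int(self.grid.sum())

    @property
    def image_size(self) -> tuple[int, int]:
        h, w = self.grid.shape
        return (w, h)

    def foreground_centers(self) -> Array:
        """(N, 2) array of (x, y) centers of the foreground pixels."""
        rows, cols = np.nonzero(self.grid)
        return np.column_stack([cols + 0.5, rows + 0.5])


@dataclass(frozen=True)
class OrientedBox:
    """Minimum-area oriented rectangle enclosing the wound pixel centers.

    ``length_L`` and ``width_W`` are center-to-center extents along the long
    and short axes; ``area_B`` is the pixel-footprint area (L+1)(W+1) of the
    box, so the non-wound area B - A is never negative.
    """

    center: Array  # (2,) (x, y)
    long_axis: Array  # (2,) unit vector, canonical sign
    length_L: float
    width_W: float
    area_B: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        u = np.asarray(self.long_axis, float)
        object.__setattr__(self, "long_axis", u / np.hypot(*u))
        if not (self.length_L >= self.width_W > 0):
            raise DegenerateMaskError(
                "oriented box must satisfy length_L >= width_W > 0"
            )

    @property
    def short_axis(self) -> Array:
        u = self.long_axis
        return np.array([-u[1], u[0]])

    def long_offsets(self, points: Array) -> Array:
        """Offsets of points along the long axis from the box's low edge."""
        t0 = float(self.center @ self.long_axis) - self.length_L / 2.0
        return np.asarray(points, float) @ self.long_axis - t0

    def corners(self) -> Array:
        """The 4 box corners (center-extent box), counter-clockwise."""
        u, v = self.long_axis, self.short_axis
        hl, hw = self.length_L / 2.0, self.width_W / 2.0
        return np.array(
            [
                self.center - hl * u - hw * v,
                self.center + hl * u - hw * v,
                self.center + hl * u + hw * v,
                self.center - hl * u + hw * v,
            ]
        )


@dataclass(frozen=True)
class StripProfile:
    """Cumulative wound area of 1-pixel strips along the box's long axis.

    ``cumulative[n-1]`` is the number of wound pixels whose center projects
    into strips 1..n (long-axis offset < n).
    """

    cumulative: Array  # int, shape (n_strips,)
    total_A: int

    def __post_init__(self):
        c = np.asarray(self.cumulative, dtype=np.int64)
        object.__setattr__(self, "cumulative", c)
        if len(c) == 0:
            raise ValueError("strip profile must have at least one strip")
        if np.any(np.diff(c) < 0):
            raise ValueError("cumulative strip profile must be nondecreasing")
        if c[-1] != self.total_A:
            raise ValueError("cumulative profile must end at total_A")

    @property
    def n_strips(self) -> int:
        return len(self.cumulative)

    def strip_masses(self) -> Array:
        """Wound pixels per individual 1-px strip."""
        return np.diff(self.cumulative, prepend=0)


@dataclass(frozen=True)
class HalvingLine:
    """A halving line: two or more (x, y) points in image coordinates.

    Algorithmic lines are straight 2-point segments perpendicular to the box
    long axis; manual lines may be multi-segment polylines.
    """

    endpoints: Array
    source: str = "manual"

    def __post_init__(self):
        pts = _as_points(self.endpoints, "endpoints")
        object.__setattr__(self, "endpoints", pts)
        if len(pts) < 2:
            raise ValueError("a halving line needs at least 2 points")
        if not np.any(np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0):
            raise ValueError("halving line endpoints must be distinct")
        if self.source not in ("algorithm", "manual"):
            raise ValueError("source must be 'algorithm' or 'manual'")


@dataclass(frozen=True)
class SplitResult:
    """Two-side pixel split of a wound and its deviation from the 50% truth."""

    fraction_side1: float  # % of wound pixels on side 1, in [0, 100]
    fraction_side2: float
    abs_deviation: float  # |fraction_side1 - 50| in percentage points
    n_selected: int | None = None  # strip index, algorithmic splits only
    non_separating: bool = False

    def __post_init__(self):
        if not (0.0 <= self.fraction_side1 <= 100.0):
            raise ValueError("fraction_side1 must lie in [0, 100]")


@dataclass(frozen=True)
class HalvingOutcome:
    """Everything the algorithm derives for one wound mask."""

    box: OrientedBox
    profile: StripProfile
    split: SplitResult
    line: HalvingLine


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def _raster_polygon(vertices: Array, image_size: tuple[int, int]) -> Array:
    """Boolean grid: pixel centers strictly inside the polygon."""
    w, h = image_size
    poly = shapely.Polygon(vertices)
    if not poly.is_valid:
        raise InvalidOutlineError("self-intersecting outline")
    minx, miny, maxx, maxy = poly.bounds
    j0 = max(int(np.floor(minx)) - 1, 0)
    j1 = min(int(np.ceil(maxx)) + 1, w)
    i0 = max(int(np.floor(miny)) - 1, 0)
    i1 = min(int(np.ceil(maxy)) + 1, h)
    grid = np.zeros((h, w), dtype=bool)
    if j1 <= j0 or i1 <= i0:
        return grid
    xs = np.arange(j0, j1) + 0.5
    ys = np.arange(i0, i1) + 0.5
    X, Y = np.meshgrid(xs, ys)
    shapely.prepare(poly)
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel())
    grid[i0:i1, j0:j1] = inside.reshape(i1 - i0, j1 - j0)
    return grid


def rasterize_outline(outline: WoundOutline) -> BinaryMask:
    """Rasterize a wound outline: foreground iff the pixel center lies inside.

    Raises :class:`InvalidOutlineError` when no pixel center is enclosed
    (e.g. a polygon smaller than one pixel cell).
    """
    grid = _raster_polygon(outline.vertices, outline.image_size)
    if not grid.any():
        raise InvalidOutlineError("outline encloses no pixel center")
    return BinaryMask(grid)


def rasterize_outlines(outlines: list[WoundOutline]) -> BinaryMask:
    """Rasterize several outline regions of one wound under the even-odd rule.

    Overlapping regions cancel pairwise (XOR), so a region drawn inside
    another acts as a hole.
    """
    if not outlines:
        raise InvalidOutlineError("no outline regions given")
    size = outlines[0].image_size
    grid = np.zeros((size[1], size[0]), dtype=bool)
    for o in outlines:
        if o.image_size != size:
            raise InvalidOutlineError("outline regions disagree on image size")
        grid ^= _raster_polygon(o.vertices, size)
    if not grid.any():
        raise InvalidOutlineError("outlines enclose no pixel center")
    return BinaryMask(grid)


# ---------------------------------------------------------------------------
# minimum-area oriented bounding box
# ---------------------------------------------------------------------------


def _canonical_axis(u: Array) -> Array:
    """Fix the sign of an axis: positive x component, or positive y if x = 0."""
    eps = 1e-12
    if u[0] < -eps or (abs(u[0]) <= eps and u[1] < 0):
        return -u
    return u


def min_area_box_of_points(pts: Array) -> OrientedBox:
    """Minimum-area rectangle (any orientation) enclosing a point set.

    Rotating-calipers: the minimum-area enclosing rectangle has one side
    collinear with an edge of the convex hull, so it suffices to evaluate the
    extent product for every hull-edge direction.
    """
    pts = _as_points(pts)
    if len(pts) < 3:
        raise DegenerateMaskError("need at least 3 points for a 2-D box")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise DegenerateMaskError(f"points are collinear: {exc}") from exc
    hp = pts[hull.vertices]
    edges = np.roll(hp, -1, axis=0) - hp
    lens = np.hypot(edges[:, 0], edges[:, 1])
    u = edges[lens > 0] / lens[lens > 0, None]  # (m, 2) edge directions
    v = np.column_stack([-u[:, 1], u[:, 0]])
    pu = hp @ u.T  # (hull, m) projections
    pv = hp @ v.T
    eu = pu.max(axis=0) - pu.min(axis=0)
    ev = pv.max(axis=0) - pv.min(axis=0)
    i = int(np.argmin(eu * ev))
    cu = (pu[:, i].min() + pu[:, i].max()) / 2.0
    cv = (pv[:, i].min() + pv[:, i].max()) / 2.0
    center = cu * u[i] + cv * v[i]
    if eu[i] >= ev[i]:
        long_axis, length_L, width_W = u[i], eu[i], ev[i]
        alt = v[i]
    else:
        long_axis, length_L, width_W = v[i], ev[i], eu[i]
        alt = u[i]
    if np.isclose(length_L, width_W):
        # square box: sweep along the axis closer to the image x-axis
        if abs(alt[0]) > abs(long_axis[0]):
            long_axis = alt
    if width_W <= 0:
        raise DegenerateMaskError("zero-width bounding box")
    return OrientedBox(
        center=center,
        long_axis=_canonical_axis(long_axis),
        length_L=float(length_L),
        width_W=float(width_W),
        area_B=float((length_L + 1.0) * (width_W + 1.0)),
    )


def min_area_box(mask: BinaryMask) -> OrientedBox:
    """Minimum-area oriented rectangle enclosing all foreground pixel centers."""
    pts = mask.foreground_centers()
    if len(pts) == 0:
        raise EmptyMaskError("cannot box an empty mask")
    if len(pts) < 3:
        raise DegenerateMaskError("mask has fewer than 3 pixels; no 2-D box")
    return min_area_box_of_points(pts)


# ---------------------------------------------------------------------------
# strip sweep
# ---------------------------------------------------------------------------


def strip_profile(mask: BinaryMask, box: OrientedBox) -> StripProfile:
    """Cumulative wound area per 1-px strip along the box's long axis.

    A pixel whose center projects to long-axis offset t (from the box's low
    edge) belongs to strip floor(t) + 1.
    """
    pts = mask.foreground_centers()
    if len(pts) == 0:
        raise EmptyMaskError("cannot profile an empty mask")
    off = box.long_offsets(pts)
    if off.min() < -1e-6 or off.max() > box.length_L + 1e-6:
        raise ValueError("box does not enclose the mask")
    n_strips = int(np.floor(box.length_L)) + 1
    idx = np.floor(np.clip(off, 0.0, None)).astype(int) + 1
    idx = np.minimum(idx, n_strips)
    counts = np.bincount(idx, minlength=n_strips + 1)[1:]
    return StripProfile(cumulative=np.cumsum(counts), total_A=int(len(pts)))


def select_halving(profile: StripProfile) -> SplitResult:
    """Select the strip count n whose cumulative area is closest to A/2.

    Ties are broken toward the smallest n (the incremental search order,
    starting at n = 1).
    """
    A = profile.total_A
    if A < 2:
        raise CannotHalveError("wound has fewer than 2 pixels")
    c = profile.cumulative
    n = int(np.argmin(np.abs(c - A / 2.0))) + 1
    f1 = 100.0 * float(c[n - 1]) / A
    return SplitResult(
        fraction_side1=f1,
        fraction_side2=100.0 - f1,
        abs_deviation=abs(f1 - 50.0),
        n_selected=n,
    )


def halving_line(box: OrientedBox, split: SplitResult) -> HalvingLine:
    """The algorithmic halving line in image coordinates.

    Perpendicular to the box long axis at offset ``n_selected`` from the low
    edge, spanning the box's short sides.
    """
    if split.n_selected is None:
        raise ValueError("split carries no strip index (not an algorithmic split)")
    u, v = box.long_axis, box.short_axis
    t = min(float(split.n_selected), box.length_L)
    p = box.center - u * (box.length_L / 2.0) + u * t
    hw = box.width_W / 2.0
    return HalvingLine(
        endpoints=np.array([p - v * hw, p + v * hw]), source="algorithm"
    )


# ---------------------------------------------------------------------------
# evaluating arbitrary (manual) lines
# ---------------------------------------------------------------------------


def _extend_polyline(points: Array, image_size: tuple[int, int]) -> Array:
    """Prolong a polyline past the image border along its terminal segments."""
    pts = _as_points(points, "polyline")
    reach = float(np.hypot(*image_size)) + 2.0

    def _dir(a, b):
        d = a - b
        n = np.hypot(*d)
        return d / n if n > 0 else None

    first = None
    for k in range(1, len(pts)):  # first point with a nonzero lead segment
        first = _dir(pts[0], pts[k])
        if first is not None:
            break
    last = None
    for k in range(len(pts) - 2, -1, -1):
        last = _dir(pts[-1], pts[k])
        if last is not None:
            break
    return np.vstack([pts[0] + first * reach, pts, pts[-1] + last * reach])


def _side_of_chain(pts: Array, chain: Array) -> Array:
    """Side-1 membership: sign of the signed distance to the nearest segment.

    Pixels exactly on the chain (signed distance 0) go to side 1.
    """
    best_d2 = np.full(len(pts), np.inf)
    sign = np.zeros(len(pts))
    for a, b in zip(chain[:-1], chain[1:]):
        d = b - a
        L2 = float(d @ d)
        if L2 == 0.0:
            continue
        t = np.clip(((pts - a) @ d) / L2, 0.0, 1.0)
        proj = a + t[:, None] * d
        d2 = ((pts - proj) ** 2).sum(axis=1)
        cr = d[0] * (pts[:, 1] - a[1]) - d[1] * (pts[:, 0] - a[0])
        upd = d2 < best_d2 - 1e-12
        best_d2[upd] = d2[upd]
        sign[upd] = cr[upd]
    return sign >= 0


def split_by_line(mask: BinaryMask, line: HalvingLine) -> SplitResult:
    """Pixel split of a wound by an arbitrary (manual) halving line.

    The drawn polyline is extended at both ends to the image border along its
    terminal directions; every foreground pixel is assigned to a side by the
    sign of its center's signed distance to the extended chain.  A line that
    fails to separate the wound yields fractions {0, 100} with the
    ``non_separating`` flag set.
    """
    pts = mask.foreground_centers()
    if len(pts) == 0:
        raise EmptyMaskError("cannot split an empty mask")
    chain = _extend_polyline(line.endpoints, mask.image_size)
    side1 = _side_of_chain(pts, chain)
    c1 = int(side1.sum())
    A = len(pts)
    f1 = 100.0 * c1 / A
    return SplitResult(
        fraction_side1=f1,
        fraction_side2=100.0 - f1,
        abs_deviation=abs(f1 - 50.0),
        non_separating=(c1 == 0 or c1 == A),
    )


def halve(mask: BinaryMask) -> HalvingOutcome:
    """Run the full algorithm on a mask: box, strip sweep, selection, line."""
    box = min_area_box(mask)
    profile = strip_profile(mask, box)
    split = select_halving(profile)
    line = halving_line(box, split)
    return HalvingOutcome(box=box, profile=profile, split=split, line=line)
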