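"""Planar geometry of square RyR2 tetramers.

A tetramer is modelled as a square of side ~27 nm lying in the plane of the
junctional SR membrane, described by its centre, an in-plane orientation and
the tomogram it was mapped in.  Because the square has 4-fold symmetry the
orientation is only meaningful modulo 90 degrees.

This module provides the pairwise edge relations (gap between facing edges,
projected edge overlap, parallelism) that drive the arrangement classifier,
centre-to-centre nearest-neighbour distances, alpha-shape boundaries/areas
and the tetramer coverage fraction of an array.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    InvalidInputError,
)

#: Edge length of a RyR2 tetramer footprint in nm.
DEFAULT_SIDE = 27.0

#: Default angular tolerance (degrees) for calling two squares parallel.
DEFAULT_ANGLE_TOL = 10.0


def reduce_angle(theta_deg: float) -> float:
    """Reduce an in-plane orientation to [0, 90) by square symmetry."""
    return float(theta_deg) % 90.0


def angle_difference(theta_a: float, theta_b: float) -> float:
    """Minimal angular difference of two square orientations, in [0, 45].

    Square footprints repeat every 90 degrees, so the angular distance
    between two orientations is folded into [0, 45].
    """
    d = (float(theta_b) - float(theta_a) + 45.0) % 90.0 - 45.0
    return abs(d)


@dataclass(frozen=True)
class Tetramer:
    """One RyR2 channel footprint: a square with centre, orientation, metadata.

    Parameters
    ----------
    id : str
        Identifier, unique within a tomogram.
    x, y : float
        Centre coordinates in nm (arbitrary origin).
    theta : float
        In-plane orientation in degrees; stored reduced modulo 90.
    side : float
        Edge length in nm (default 27, the RyR2 cytoplasmic footprint).
    tomogram_id : str
        Identifier of the tomogram the tetramer was mapped in.
    group : str
        Treatment label.
    """

    id: str
    x: float
    y: float
    theta: float = 0.0
    side: float = DEFAULT_SIDE
    tomogram_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        for name in ("x", "y", "theta", "side"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise InvalidInputError(
                    f"tetramer {self.id!r}: field {name!r} is not finite ({v!r})"
                )
            object.__setattr__(self, name, float(v))
        if self.side <= 0:
            raise InvalidInputError(f"tetramer {self.id!r}: side must be > 0")
        object.__setattr__(self, "theta", reduce_angle(self.theta))

    @property
    def footprint_area(self) -> float:
        """Area of the square footprint in nm² (729 for the 27-nm default)."""
        return self.side * self.side

    def corners(self) -> np.ndarray:
        """The four corner coordinates, shape (4, 2), counter-clockwise."""
        h = self.side / 2.0
        local = np.array([[-h, -h], [h, -h], [h, h], [-h, h]])
        t = math.radians(self.theta)
        rot = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
        return local @ rot.T + np.array([self.x, self.y])

    def polygon(self) -> Polygon:
        """Shapely polygon of the footprint."""
        return Polygon(self.corners())


@dataclass(frozen=True)
class TetramerArray:
    """All tetramers mapped in one tomogram (one dyad).

    Validates that the collection is non-empty, shares a single tomogram id
    and that no two square footprints overlap in area by more than
    ``overlap_tol`` (nm²), the placement tolerance of the manual box fit.
    """

    tetramers: tuple[Tetramer, ...]
    group: str = ""
    overlap_tol: float = 1.0

    def __post_init__(self) -> None:
        tets = tuple(self.tetramers)
        object.__setattr__(self, "tetramers", tets)
        if not tets:
            raise InvalidInputError("TetramerArray must contain >= 1 tetramer")
        tomos = {t.tomogram_id for t in tets}
        if len(tomos) > 1:
            raise InvalidInputError(
                f"all tetramers must share one tomogram_id, got {sorted(tomos)}"
            )
        if not self.group:
            object.__setattr__(self, "group", tets[0].group)
        self._check_overlaps()

    def _check_overlaps(self) -> None:
        tets = self.tetramers
        if len(tets) < 2:
            return
        coords = np.array([[t.x, t.y] for t in tets])
        # Footprints can only intersect if centres are closer than side*sqrt(2).
        reach = max(t.side for t in tets) * math.sqrt(2.0) + 1e-9
        tree = cKDTree(coords)
        for i, j in sorted(tree.query_pairs(reach)):
            area = tets[i].polygon().intersection(tets[j].polygon()).area
            if area > self.overlap_tol:
                raise InvalidInputError(
                    f"tetramers {tets[i].id!r} and {tets[j].id!r} overlap by "
                    f"{area:.2f} nm² (> {self.overlap_tol} nm² tolerance)"
                )

    def __len__(self) -> int:
        return len(self.tetramers)

    def __iter__(self):
        return iter(self.tetramers)

    @property
    def tomogram_id(self) -> str:
        return self.tetramers[0].tomogram_id

    def centres(self) -> np.ndarray:
        return np.array([[t.x, t.y] for t in self.tetramers])


@dataclass(frozen=True)
class PairRelation:
    """Geometric relation between two equal-sided square tetramers.

    ``gap`` is the separation of the two nearest facing edges measured along
    their common (mean) normal; ``overlap`` is the length of the intersection
    of those edges' projections onto their shared axis.  Both are defined only
    when the squares are parallel within the angular tolerance.
    """

    centre_distance: float
    delta_theta: float
    parallel: bool
    gap: float | None = None
    overlap: float | None = None


def pair_relation(
    a: Tetramer, b: Tetramer, angle_tol: float = DEFAULT_ANGLE_TOL
) -> PairRelation:
    """Compute the :class:`PairRelation` between two tetramers.

    The two squares are considered parallel when their orientations differ by
    at most ``angle_tol`` degrees (modulo 90).  For parallel squares the pair
    of facing edges is selected by the separating axis: in the frame rotated
    by the mean orientation, the axis along which the squares are separated
    carries the gap, and the overlap is the projected edge intersection along
    the perpendicular axis.  For near-parallel pairs (delta_theta <= 10°) the
    mean-normal approximation deviates from either edge normal by < 1.5% and
    is ignored.
    """
    if a.side != b.side:
        raise InvalidInputError("pair_relation requires equal side lengths")
    if not (0.0 <= angle_tol <= 45.0):
        raise InvalidInputError("angle_tol must lie in [0, 45] degrees")
    dx = b.x - a.x
    dy = b.y - a.y
    centre_distance = math.hypot(dx, dy)
    signed = (b.theta - a.theta + 45.0) % 90.0 - 45.0
    delta_theta = abs(signed)
    parallel = delta_theta <= angle_tol
    if not parallel:
        return PairRelation(centre_distance, delta_theta, False)

    side = a.side
    # Rotate the centre displacement into the mean-orientation frame.
    mean_theta = math.radians(a.theta + signed / 2.0)
    cos_t, sin_t = math.cos(mean_theta), math.sin(mean_theta)
    u = cos_t * dx + sin_t * dy  # along the frame x axis
    v = -sin_t * dx + cos_t * dy  # along the frame y axis

    gap_u = abs(u) - side
    gap_v = abs(v) - side
    # Separating-axis choice of the facing-edge pair: prefer the smallest
    # non-negative axis gap; if the squares interpenetrate (both negative,
    # possible within the placement tolerance), take the least negative.
    if gap_u >= 0.0 and gap_v >= 0.0:
        axis = "u" if gap_u <= gap_v else "v"
    else:
        axis = "u" if gap_u >= gap_v else "v"
    gap = gap_u if axis == "u" else gap_v
    perp = abs(v) if axis == "u" else abs(u)
    overlap = float(np.clip(side - perp, 0.0, side))
    return PairRelation(centre_distance, delta_theta, True, gap, overlap)


def nearest_neighbour_distances(array: TetramerArray) -> list[tuple[str, float]]:
    """Centre-to-centre nearest-neighbour distance for every tetramer.

    Returns one ``(id, nnd)`` pair per tetramer, in array order.  Raises
    :class:`InsufficientDataError` for single-tetramer arrays, which have no
    neighbour.
    """
    if len(array) < 2:
        raise InsufficientDataError(
            "nearest-neighbour distances need >= 2 tetramers in the array"
        )
    coords = array.centres()
    tree = cKDTree(coords)
    dists, _ = tree.query(coords, k=2)
    return [(t.id, float(d)) for t, d in zip(array.tetramers, dists[:, 1])]


@dataclass(frozen=True)
class ShapeParams:
    """Alpha-shape parameters.

    ``alpha_radius`` is the disk radius of the Delaunay alpha complex in nm.
    The default of 50 nm matches the cluster linkage scale: point sets joined
    at up to 50 nm remain a single connected boundary.
    """

    alpha_radius: float = 50.0

    def __post_init__(self) -> None:
        if not (self.alpha_radius > 0):
            raise InvalidInputError("alpha_radius must be > 0")


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    """Circumradius of each Delaunay triangle; inf for degenerate ones."""
    pa = points[simplices[:, 0]]
    pb = points[simplices[:, 1]]
    pc = points[simplices[:, 2]]
    a = np.linalg.norm(pb - pc, axis=1)
    b = np.linalg.norm(pa - pc, axis=1)
    c = np.linalg.norm(pa - pb, axis=1)
    cross = (pb[:, 0] - pa[:, 0]) * (pc[:, 1] - pa[:, 1]) - (
        pb[:, 1] - pa[:, 1]
    ) * (pc[:, 0] - pa[:, 0])
    area2 = np.abs(cross)  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (2.0 * area2)
    r[area2 <= 0] = np.inf
    return r


def alpha_shape_area(
    points: Iterable[Sequence[float]], params: ShapeParams | None = None
) -> tuple[MultiPolygon | Polygon, float]:
    """Alpha-shape boundary and area of a planar point set.

    The alpha shape is the union of Delaunay triangles whose circumradius is
    at most ``params.alpha_radius``; its area is the summed area of those
    faces and never exceeds the convex-hull area.  Returns the boundary as a
    shapely (Multi)Polygon together with the area in nm².

    Raises :class:`DegenerateGeometryError` for fewer than three points or an
    all-collinear set.
    """
    params = params or ShapeParams()
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be an iterable of (x, y) pairs")
    if not np.isfinite(pts).all():
        raise InvalidInputError("points contain non-finite coordinates")
    if pts.shape[0] < 3:
        raise DegenerateGeometryError("alpha shape needs >= 3 points")
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(
            "alpha shape needs >= 3 non-collinear points"
        ) from exc
    radii = _circumradii(pts, tri.simplices)
    keep = tri.simplices[radii <= params.alpha_radius]
    if keep.size == 0:
        return MultiPolygon([]), 0.0
    triangles = [Polygon(pts[s]) for s in keep]
    boundary = unary_union(triangles)
    # Delaunay faces are interior-disjoint, so the union area equals the sum.
    pa = pts[keep[:, 0]]
    pb = pts[keep[:, 1]]
    pc = pts[keep[:, 2]]
    cross = (pb[:, 0] - pa[:, 0]) * (pc[:, 1] - pa[:, 1]) - (
        pb[:, 1] - pa[:, 1]
    ) * (pc[:, 0] - pa[:, 0])
    area = float(np.abs(cross).sum() / 2.0)
    return boundary, area


def convex_hull_area(points: Iterable[Sequence[float]]) -> float:
    """Convex-hull area of a planar point set (nm²)."""
    pts = np.asarray(list(points), dtype=float)
    try:
        return float(ConvexHull(pts).volume)  # 2D "volume" is the area
    except QhullError as exc:
        raise DegenerateGeometryError("convex hull is degenerate") from exc


def coverage_fraction(
    array: TetramerArray, params: ShapeParams | None = None
) -> float:
    """Fraction of an array's alpha-shape area occupied by tetramer footprints.

    The alpha shape is drawn around the four corners of every tetramer; the
    coverage is the total footprint area divided by the shape area.  A single
    tetramer covers its own footprint exactly, giving 1.0.  Values may exceed
    1 slightly when the alpha shape cuts footprint corners.
    """
    params = params or ShapeParams()
    if len(array) == 1:
        return 1.0
    corners = np.vstack([t.corners() for t in array])
    _, area = alpha_shape_area(corners, params)
    if area <= 0:
        raise DegenerateGeometryError(
            "alpha shape of the array has zero area; increase alpha_radius"
        )
    footprint = sum(t.footprint_area for t in array)
    return float(footprint / area)
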