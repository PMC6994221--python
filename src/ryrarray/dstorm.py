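"""dSTORM localization pipeline: QC, rasterization, clustering, tetramer counts.

The pipeline mirrors how RyR2 cluster sizes are measured on the myocyte
surface: blinks failing quality thresholds are excluded, the survivors are
mapped onto a 10-nm binary pixel grid, pixels are joined into clusters by a
50-nm single-linkage rule, each cluster gets an alpha-shape boundary and
area (clusters under 1600 nm² are treated as noise), and areas are converted
into tetramer counts using the coverage fraction measured on tomograms and
the 729-nm² footprint of a single tetramer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    InvalidInputError,
)
from .geometry import ShapeParams, alpha_shape_area


@dataclass(frozen=True)
class Localization:
    """One dSTORM blink.

    Coordinates in nm; ``sigma_xy``/``sigma_z`` are the estimated position
    errors, ``gof`` the fit quality in [0, 1].
    """

    x: float
    y: float
    z: float = 0.0
    sigma_xy: float = 0.0
    sigma_z: float = 0.0
    gof: float = 1.0
    frame: int = 0

    def __post_init__(self) -> None:
        if self.sigma_xy < 0 or self.sigma_z < 0:
            raise InvalidInputError("localization uncertainties must be >= 0")
        if not (0.0 <= self.gof <= 1.0):
            raise InvalidInputError("goodness of fit must lie in [0, 1]")


@dataclass(frozen=True)
class QCThresholds:
    """Blink quality thresholds.

    Blinks with XY error > 10 nm, Z error > 40 nm or goodness of fit < 0.9
    are excluded, as are quality survivors whose nearest surviving neighbour
    (3D) is more than 30 nm away.  ``z_slice`` keeps a 150-nm slab centred on
    the cell surface (z = 0 by convention); set any field to ``None`` to
    disable that stage.
    """

    max_sigma_xy: float | None = 10.0
    max_sigma_z: float | None = 40.0
    min_gof: float | None = 0.9
    max_nn: float | None = 30.0
    z_slice: tuple[float, float] | None = (-75.0, 75.0)

    def __post_init__(self) -> None:
        if self.z_slice is not None and not (self.z_slice[0] < self.z_slice[1]):
            raise InvalidInputError("z_slice must satisfy z_min < z_max")


def qc_filter(
    locs: Sequence[Localization], thr: QCThresholds | None = None
) -> list[Localization]:
    """Apply blink quality control, quality stages first.

    Stage 1 keeps blinks inside the z slice with ``sigma_xy <= max_sigma_xy``,
    ``sigma_z <= max_sigma_z`` and ``gof >= min_gof``.  Stage 2 removes
    survivors whose nearest surviving neighbour (3D distance) is farther than
    ``max_nn``; the neighbour test is applied once, not iterated.
    """
    thr = thr or QCThresholds()
    survivors = []
    for loc in locs:
        if thr.z_slice is not None and not (
            thr.z_slice[0] <= loc.z <= thr.z_slice[1]
        ):
            continue
        if thr.max_sigma_xy is not None and loc.sigma_xy > thr.max_sigma_xy:
            continue
        if thr.max_sigma_z is not None and loc.sigma_z > thr.max_sigma_z:
            continue
        if thr.min_gof is not None and loc.gof < thr.min_gof:
            continue
        survivors.append(loc)
    if thr.max_nn is None or not survivors:
        return survivors
    if len(survivors) == 1:
        return []  # a lone blink has no neighbour within any finite radius
    coords = np.array([[l.x, l.y, l.z] for l in survivors])
    tree = cKDTree(coords)
    dists, _ = tree.query(coords, k=2)
    keep = dists[:, 1] <= thr.max_nn
    return [loc for loc, k in zip(survivors, keep) if k]


@dataclass(frozen=True)
class PixelGrid:
    """Binary 10-nm pixel map of QC-passed blinks.

    ``counts`` maps integer pixel indices ``(ix, iy)`` to blink counts; a
    pixel is lit iff it is present.  Pixels are half-open:
    ``[x0 + ix*p, x0 + (ix+1)*p)``.
    """

    pixel_size: float
    origin: tuple[float, float]
    counts: dict[tuple[int, int], int]

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0):
            raise InvalidInputError("pixel_size must be > 0")
        if any(c < 1 for c in self.counts.values()):
            raise InvalidInputError("lit pixels must hold >= 1 blink")

    @property
    def lit(self) -> set[tuple[int, int]]:
        return set(self.counts)

    def pixel_centre(self, idx: tuple[int, int]) -> tuple[float, float]:
        return (
            self.origin[0] + (idx[0] + 0.5) * self.pixel_size,
            self.origin[1] + (idx[1] + 0.5) * self.pixel_size,
        )

    def centres(self, pixels: Iterable[tuple[int, int]] | None = None) -> np.ndarray:
        idx = np.array(sorted(pixels if pixels is not None else self.counts))
        if idx.size == 0:
            return np.empty((0, 2))
        return np.asarray(self.origin) + (idx + 0.5) * self.pixel_size


_NEIGHBOURS_8 = [
    (-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1),
]


def rasterize(
    locs: Sequence[Localization],
    pixel_size: float = 10.0,
    origin: tuple[float, float] | None = None,
) -> PixelGrid:
    """Map QC-filtered blinks onto a binary pixel grid.

    A pixel is lit when at least one blink falls inside it; afterwards any
    pixel holding exactly one blink with no lit pixel in its 8-neighbourhood
    is treated as empty (the lone-blink rule, applied simultaneously to the
    initial lit set).  The grid origin defaults to the minimum x, y of the
    input.
    """
    if not locs:
        return PixelGrid(pixel_size, origin or (0.0, 0.0), {})
    xy = np.array([[l.x, l.y] for l in locs])
    if origin is None:
        origin = (float(xy[:, 0].min()), float(xy[:, 1].min()))
    idx = np.floor((xy - np.asarray(origin)) / pixel_size).astype(int)
    counts: dict[tuple[int, int], int] = {}
    for ix, iy in idx:
        counts[(int(ix), int(iy))] = counts.get((int(ix), int(iy)), 0) + 1
    lit = set(counts)
    pruned = {
        pix: c
        for pix, c in counts.items()
        if c > 1
        or any((pix[0] + dx, pix[1] + dy) in lit for dx, dy in _NEIGHBOURS_8)
    }
    return PixelGrid(pixel_size, origin, pruned)


@dataclass
class Cluster:
    """A connected set of lit pixels with optional boundary and estimates."""

    pixels: frozenset[tuple[int, int]]
    n_blinks: int = 0
    boundary: object | None = None
    area: float | None = None
    n_tetramers: int | None = None

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class ClusterParams:
    """Cluster linkage, filtering and tetramer-count parameters.

    ``linkage`` is the maximum pixel-centre separation joining pixels into
    one cluster (50 nm); ``min_area`` the noise filter (clusters under
    1600 nm² are dropped); ``tetramer_area`` the single-tetramer footprint
    (729 nm²); ``coverage`` the group-level fraction of cluster area covered
    by tetramers, measured on tomograms.
    """

    linkage: float = 50.0
    min_area: float = 1600.0
    tetramer_area: float = 729.0
    coverage: float | None = None

    def __post_init__(self) -> None:
        if not (self.linkage > 0):
            raise InvalidInputError("linkage must be > 0")
        if self.min_area < 0:
            raise InvalidInputError("min_area must be >= 0")
        if not (self.tetramer_area > 0):
            raise InvalidInputError("tetramer_area must be > 0")
        if self.coverage is not None and not (0 < self.coverage <= 1):
            raise InvalidInputError("coverage must lie in (0, 1]")


def link_clusters(
    grid: PixelGrid, params: ClusterParams | None = None
) -> list[Cluster]:
    """Single-linkage clusters of lit pixels.

    Two pixels belong to the same cluster when a chain of lit pixels joins
    them with every step at most ``params.linkage`` apart (pixel-centre
    Euclidean distance).  Every lit pixel lands in exactly one cluster.
    Clusters are returned sorted by their minimum pixel index for
    deterministic ordering.
    """
    params = params or ClusterParams()
    pixels = sorted(grid.counts)
    if not pixels:
        return []
    centres = grid.centres(pixels)
    tree = cKDTree(centres)
    pairs = tree.query_pairs(params.linkage, output_type="ndarray")
    n = len(pixels)
    if pairs.size:
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    _, labels = connected_components(adj, directed=False)
    groups: dict[int, list[tuple[int, int]]] = {}
    for pix, lab in zip(pixels, labels):
        groups.setdefault(int(lab), []).append(pix)
    clusters = [
        Cluster(
            pixels=frozenset(members),
            n_blinks=sum(grid.counts[p] for p in members),
        )
        for members in groups.values()
    ]
    clusters.sort(key=lambda c: min(c.pixels))
    return clusters


#: Numerical slack on the strict `area < min_area` noise filter so that
#: clusters sitting exactly on the boundary (e.g. a 5x5 pixel block whose
#: hull is exactly 1600 nm²) are not lost to floating-point rounding.
_AREA_EPS = 1e-6


def cluster_areas(
    clusters: Sequence[Cluster],
    grid: PixelGrid,
    shape: ShapeParams | None = None,
    params: ClusterParams | None = None,
) -> list[Cluster]:
    """Attach alpha-shape boundaries and areas; drop noise clusters.

    Areas are computed over lit-pixel centres.  Clusters with fewer than
    three non-collinear pixel centres are degenerate and dropped; clusters
    with area below ``params.min_area`` are dropped as noise.
    """
    shape = shape or ShapeParams()
    params = params or ClusterParams()
    kept: list[Cluster] = []
    for cluster in clusters:
        if cluster.n_pixels < 3:
            continue
        centres = grid.centres(cluster.pixels)
        try:
            boundary, area = alpha_shape_area(centres, shape)
        except DegenerateGeometryError:
            continue
        if area < params.min_area - _AREA_EPS:
            continue
        kept.append(
            Cluster(
                pixels=cluster.pixels,
                n_blinks=cluster.n_blinks,
                boundary=boundary,
                area=area,
            )
        )
    return kept


def estimate_tetramers(area: float, params: ClusterParams) -> int:
    """Estimated number of tetramers in a cluster of the given area.

    The cluster area is scaled by the group coverage fraction and divided by
    the single-tetramer footprint; the result is rounded to the nearest
    integer, halves away from zero.
    """
    if params.coverage is None:
        raise ConfigurationError(
            "ClusterParams.coverage must be set to estimate tetramer counts"
        )
    if not (area > 0):
        raise InvalidInputError("cluster area must be > 0")
    value = area * params.coverage / params.tetramer_area
    return int(math.floor(value + 0.5))


def analyze_localizations(
    locs: Sequence[Localization],
    thr: QCThresholds | None = None,
    shape: ShapeParams | None = None,
    params: ClusterParams | None = None,
    pixel_size: float = 10.0,
) -> tuple[list[Cluster], PixelGrid]:
    """Run the full pipeline: QC -> rasterize -> link -> areas (-> counts).

    Tetramer counts are filled in when ``params.coverage`` is set.
    """
    params = params or ClusterParams()
    filtered = qc_filter(locs, thr)
    grid = rasterize(filtered, pixel_size=pixel_size)
    clusters = link_clusters(grid, params)
    clusters = cluster_areas(clusters, grid, shape, params)
    if params.coverage is not None:
        for cluster in clusters:
            cluster.n_tetramers = estimate_tetramers(cluster.area, params)
    return clusters, grid


def clusters_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Tabulate clusters as ``cluster_id, area_nm2, n_pixels, n_tetramers``."""
    rows = [
        {
            "cluster_id": i,
            "area_nm2": c.area,
            "n_pixels": c.n_pixels,
            "n_tetramers": c.n_tetramers,
        }
        for i, c in enumerate(clusters)
    ]
    return pd.DataFrame(
        rows, columns=["cluster_id", "area_nm2", "n_pixels", "n_tetramers"]
    )
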