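"""Independent brute-force oracles used to validate the implementation.

Every oracle here re-derives its quantity from first principles (explicit
polygon edge arithmetic, exhaustive enumeration, union-find) without calling
the code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

from ryrarray.geometry import Tetramer


def _edges_with_normals(t: Tetramer):
    """Edges of the square as (p1, p2, outward unit normal)."""
    corners = t.corners()  # counter-clockwise
    out = []
    for i in range(4):
        p1, p2 = corners[i], corners[(i + 1) % 4]
        d = p2 - p1
        n = np.array([d[1], -d[0]])
        out.append((p1, p2, n / np.linalg.norm(n)))
    return out


def pair_label_oracle(a: Tetramer, b: Tetramer, params) -> str | None:
    """Brute-force pair classification via explicit edge arithmetic.

    Enumerates all 16 edge pairs, keeps those that face each other
    (antiparallel outward normals, A's edge oriented toward B), measures the
    support-line separation along the mean normal and the intersection of
    the two edges' projections onto the shared tangent, selects the facing
    pair by the same separating-axis rule as the implementation, and applies
    the gap/overlap thresholds.
    """
    signed = (b.theta - a.theta + 45.0) % 90.0 - 45.0
    if abs(signed) > params.angle_tol:
        return None
    ca = np.array([a.x, a.y])
    cb = np.array([b.x, b.y])
    disp = cb - ca
    candidates = []
    for p1, p2, na in _edges_with_normals(a):
        if np.dot(na, disp) <= 0:
            continue  # edge of A does not face toward B
        for q1, q2, nb in _edges_with_normals(b):
            if np.dot(na, nb) > -0.7:
                continue  # not antiparallel
            nm = na - nb
            nm = nm / np.linalg.norm(nm)
            gap = float(np.dot((q1 + q2) / 2.0 - (p1 + p2) / 2.0, nm))
            tangent = np.array([-nm[1], nm[0]])
            ia = sorted([np.dot(p1, tangent), np.dot(p2, tangent)])
            ib = sorted([np.dot(q1, tangent), np.dot(q2, tangent)])
            ov = min(ia[1], ib[1]) - max(ia[0], ib[0])
            candidates.append((gap, float(np.clip(ov, 0.0, a.side))))
    if not candidates:
        return None
    nonneg = [c for c in candidates if c[0] >= 0.0]
    gap, overlap = min(nonneg) if nonneg else max(candidates)
    if not (gap < params.gap_max and overlap > params.overlap_min):
        return None
    return "checkerboard" if overlap < params.overlap_cb_max else "side_by_side"


def nnd_oracle(coords: np.ndarray) -> np.ndarray:
    """All-pairs O(n²) nearest-neighbour distances."""
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def _circumcircle(pa, pb, pc):
    ax, ay = pa
    bx, by = pb
    cx, cy = pc
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        return None, np.inf
    ux = (
        (ax**2 + ay**2) * (by - cy)
        + (bx**2 + by**2) * (cy - ay)
        + (cx**2 + cy**2) * (ay - by)
    ) / d
    uy = (
        (ax**2 + ay**2) * (cx - bx)
        + (bx**2 + by**2) * (ax - cx)
        + (cx**2 + cy**2) * (bx - ax)
    ) / d
    centre = np.array([ux, uy])
    return centre, float(np.linalg.norm(centre - pa))


def alpha_area_oracle(points: np.ndarray, alpha: float) -> float:
    """Brute-force alpha-complex area: enumerate all point triples, keep
    those with an empty circumcircle (a Delaunay face) whose circumradius
    is at most alpha, and sum their areas.  Assumes general position."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    area = 0.0
    for i, j, k in itertools.combinations(range(n), 3):
        centre, radius = _circumcircle(pts[i], pts[j], pts[k])
        if centre is None:
            continue
        others = np.delete(np.arange(n), [i, j, k])
        dists = np.linalg.norm(pts[others] - centre, axis=1)
        if (dists < radius - 1e-9).any():
            continue  # not a Delaunay face
        if radius > alpha:
            continue
        pa, pb, pc = pts[i], pts[j], pts[k]
        area += 0.5 * abs(
            (pb[0] - pa[0]) * (pc[1] - pa[1]) - (pb[1] - pa[1]) * (pc[0] - pa[0])
        )
    return area


def shoelace_hull_area(points: np.ndarray) -> float:
    """Convex-hull area via gift wrapping + the shoelace formula."""
    pts = np.asarray(points, dtype=float)
    start = min(range(len(pts)), key=lambda i: (pts[i, 0], pts[i, 1]))
    hull = [start]
    while True:
        cur = hull[-1]
        cand = (cur + 1) % len(pts)
        for j in range(len(pts)):
            if j == cur:
                continue
            u = pts[cand] - pts[cur]
            v = pts[j] - pts[cur]
            cross = u[0] * v[1] - u[1] * v[0]
            if cross < 0 or (cross == 0 and
                             np.linalg.norm(pts[j] - pts[cur])
                             > np.linalg.norm(pts[cand] - pts[cur])):
                cand = j
        if cand == start:
            break
        hull.append(cand)
    xy = pts[hull]
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def linkage_components_oracle(
    pixels: list[tuple[int, int]], centres: np.ndarray, linkage: float
) -> list[frozenset]:
    """Union-find over all pixel pairs with centre distance <= linkage."""
    parent = list(range(len(pixels)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(pixels)):
        for j in range(i + 1, len(pixels)):
            if np.linalg.norm(centres[i] - centres[j]) <= linkage:
                parent[find(i)] = find(j)
    comps: dict[int, set] = {}
    for i, pix in enumerate(pixels):
        comps.setdefault(find(i), set()).add(pix)
    return [frozenset(c) for c in comps.values()]


def histogram_modes(
    values: np.ndarray,
    lo: float = 20.0,
    hi: float = 45.0,
    min_separation_bins: int = 3,
) -> tuple[float, float]:
    """The two dominant 1-nm histogram peaks, sorted ascending.

    The second peak is the most populated bin at least ``min_separation_bins``
    away from the first, so a single broad peak is not reported twice.
    """
    hist, edges = np.histogram(values, bins=np.arange(lo - 0.5, hi + 0.5, 1.0))
    first = int(np.argmax(hist))
    masked = hist.copy()
    span = slice(
        max(first - min_separation_bins + 1, 0), first + min_separation_bins
    )
    masked[span] = -1
    second = int(np.argmax(masked))
    centres = sorted([edges[first] + 0.5, edges[second] + 0.5])
    return centres[0], centres[1]


def ad_permutation_p_oracle(a: np.ndarray, b: np.ndarray, statistic_fn) -> float:
    """Exact two-sample permutation p-value: the share of all splits of the
    pooled data (same sizes) whose statistic reaches the observed one."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    obs = statistic_fn([a, b])
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        if statistic_fn([pooled[mask], pooled[~mask]]) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total
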