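"""Arrangement classification of tetramers within a dyadic array.

Two parallel tetramers whose facing edges are separated by less than 3 nm
and whose projected edge overlap is positive are adjacent; the pair is
checkerboard when the overlap is below 18 nm (two thirds of the 27-nm edge)
and side-by-side when it reaches or exceeds it.  A tetramer is then labelled
by its qualifying neighbours: only checkerboard neighbours -> checkerboard,
only side-by-side -> side_by_side, a mixture -> both, none -> isolated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy.spatial import cKDTree

from .errors import InsufficientDataError, InvalidInputError
from .geometry import (
    DEFAULT_ANGLE_TOL,
    DEFAULT_SIDE,
    PairRelation,
    Tetramer,
    TetramerArray,
    pair_relation,
)


class ArrangementLabel(str, enum.Enum):
    """Mutually exclusive arrangement labels for one tetramer."""

    CHECKERBOARD = "checkerboard"
    SIDE_BY_SIDE = "side_by_side"
    BOTH = "both"
    ISOLATED = "isolated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class PairLabel(str, enum.Enum):
    """Classification of one qualifying neighbour pair."""

    CHECKERBOARD = "checkerboard"
    SIDE_BY_SIDE = "side_by_side"


@dataclass(frozen=True)
class ArrangementParams:
    """Thresholds of the arrangement classifier.

    ``gap_max`` (strict upper bound on the facing-edge gap, nm) and
    ``overlap_cb_max`` (strict upper bound on the projected overlap for a
    checkerboard call, nm; overlap >= this is side-by-side) carry the
    published 3-nm and 18-nm (= 2/3 x 27 nm) rules.  ``overlap_min`` is the
    exclusive lower overlap bound: a zero projected overlap (corner-to-corner
    contact) does not create adjacency.
    """

    gap_max: float = 3.0
    overlap_cb_max: float = 2.0 / 3.0 * DEFAULT_SIDE
    angle_tol: float = DEFAULT_ANGLE_TOL
    overlap_min: float = 0.0
    side: float = DEFAULT_SIDE

    def __post_init__(self) -> None:
        if not (self.gap_max > 0):
            raise InvalidInputError("gap_max must be > 0")
        if not (0 < self.overlap_cb_max < self.side):
            raise InvalidInputError("overlap_cb_max must lie in (0, side)")
        if not (0.0 <= self.angle_tol <= 45.0):
            raise InvalidInputError("angle_tol must lie in [0, 45]")


def classify_pair(
    rel: PairRelation, params: ArrangementParams | None = None
) -> Optional[PairLabel]:
    """Classify one pair relation as checkerboard, side-by-side or neither.

    Returns ``None`` unless the pair is parallel, the facing-edge gap is
    strictly below ``gap_max`` and the projected overlap strictly exceeds
    ``overlap_min``.  Otherwise the overlap decides: below ``overlap_cb_max``
    is checkerboard, at or above it side-by-side.
    """
    params = params or ArrangementParams()
    if not rel.parallel or rel.gap is None or rel.overlap is None:
        return None
    if not (rel.gap < params.gap_max):
        return None
    if not (rel.overlap > params.overlap_min):
        return None
    if rel.overlap < params.overlap_cb_max:
        return PairLabel.CHECKERBOARD
    return PairLabel.SIDE_BY_SIDE


def _neighbour_reach(params: ArrangementParams, side: float) -> float:
    # A qualifying pair satisfies |axial| < side + gap_max and
    # |transverse| < side, hence a hard centre-distance bound.
    return math.hypot(side + params.gap_max, side) + 1e-9


def _neighbour_counts(
    t_index: int,
    array: TetramerArray,
    params: ArrangementParams,
    candidates: Iterable[int],
) -> tuple[int, int]:
    t = array.tetramers[t_index]
    n_cb = n_ss = 0
    for j in candidates:
        if j == t_index:
            continue
        rel = pair_relation(t, array.tetramers[j], params.angle_tol)
        label = classify_pair(rel, params)
        if label is PairLabel.CHECKERBOARD:
            n_cb += 1
        elif label is PairLabel.SIDE_BY_SIDE:
            n_ss += 1
    return n_cb, n_ss


def _label_from_counts(n_cb: int, n_ss: int) -> ArrangementLabel:
    if n_cb and n_ss:
        return ArrangementLabel.BOTH
    if n_cb:
        return ArrangementLabel.CHECKERBOARD
    if n_ss:
        return ArrangementLabel.SIDE_BY_SIDE
    return ArrangementLabel.ISOLATED


def classify_tetramer(
    t: Tetramer, array: TetramerArray, params: ArrangementParams | None = None
) -> ArrangementLabel:
    """Arrangement label of one tetramer within its array."""
    params = params or ArrangementParams()
    try:
        idx = next(i for i, u in enumerate(array.tetramers) if u is t or u.id == t.id)
    except StopIteration:
        raise InvalidInputError(f"tetramer {t.id!r} is not a member of the array")
    n_cb, n_ss = _neighbour_counts(idx, array, params, range(len(array)))
    return _label_from_counts(n_cb, n_ss)


def classify_array(
    array: TetramerArray, params: ArrangementParams | None = None
) -> pd.DataFrame:
    """Per-tetramer labels for a whole array.

    Returns a DataFrame with columns ``id, label, n_cb_neighbours,
    n_ss_neighbours`` in array order.  Neighbour search is pruned with a
    KD-tree at the exact qualifying-pair reach, which cannot discard a
    qualifying neighbour.
    """
    params = params or ArrangementParams()
    n = len(array)
    sides = {t.side for t in array}
    reach = _neighbour_reach(params, max(sides))
    coords = array.centres()
    if n > 64:
        tree = cKDTree(coords)
        neighbour_lists = tree.query_ball_point(coords, reach)
    else:
        neighbour_lists = [range(n)] * n
    rows = []
    for i, t in enumerate(array.tetramers):
        n_cb, n_ss = _neighbour_counts(i, array, params, neighbour_lists[i])
        rows.append(
            {
                "id": t.id,
                "label": _label_from_counts(n_cb, n_ss).value,
                "n_cb_neighbours": n_cb,
                "n_ss_neighbours": n_ss,
            }
        )
    return pd.DataFrame(rows, columns=["id", "label", "n_cb_neighbours", "n_ss_neighbours"])


@dataclass(frozen=True)
class ArrangementSummary:
    """Per-group pooled arrangement counts and fractions."""

    group: str
    counts: Mapping[ArrangementLabel, int]
    n_tetramers: int
    n_arrays: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_tetramers:
            raise InvalidInputError("arrangement counts must sum to n_tetramers")

    @property
    def fractions(self) -> dict[ArrangementLabel, float]:
        return {
            label: self.counts.get(label, 0) / self.n_tetramers
            for label in ArrangementLabel
        }


def summarize_arrangements(
    arrays: Sequence[TetramerArray], params: ArrangementParams | None = None
) -> dict[str, ArrangementSummary]:
    """Pool per-tetramer labels across arrays within each treatment group."""
    if not arrays:
        raise InsufficientDataError("summarize_arrangements needs >= 1 array")
    params = params or ArrangementParams()
    counts: dict[str, dict[ArrangementLabel, int]] = {}
    n_arrays: dict[str, int] = {}
    for array in arrays:
        labels = classify_array(array, params)["label"]
        group = array.group
        bucket = counts.setdefault(group, {label: 0 for label in ArrangementLabel})
        n_arrays[group] = n_arrays.get(group, 0) + 1
        for value in labels:
            bucket[ArrangementLabel(value)] += 1
    return {
        group: ArrangementSummary(
            group=group,
            counts=bucket,
            n_tetramers=sum(bucket.values()),
            n_arrays=n_arrays[group],
        )
        for group, bucket in counts.items()
    }


def summary_frame(summaries: Mapping[str, ArrangementSummary]) -> pd.DataFrame:
    """Tabulate group summaries (fractions, counts, sample sizes)."""
    rows = []
    for group in sorted(summaries):
        s = summaries[group]
        row: dict[str, object] = {"group": group}
        for label in ArrangementLabel:
            row[f"frac_{label.value}"] = s.fractions[label]
        for label in ArrangementLabel:
            row[f"n_{label.value}"] = s.counts.get(label, 0)
        row["n_tetramers"] = s.n_tetramers
        row["n_arrays"] = s.n_arrays
        rows.append(row)
    return pd.DataFrame(rows)
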