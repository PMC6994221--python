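"""Synthetic generators emulating the study's data-generating structure.

Three generators cover the three data streams the analysis modules consume:

* ``gen_tetramer_array`` lays out 27-nm squares in side-by-side runs
  (centre-to-centre 28 nm), checkerboard motifs (34 nm, half-overlapping
  edges), mixed neighbourhoods and isolated singletons, with positional and
  angular jitter, and returns the intended arrangement label of every
  tetramer as ground truth.
* ``gen_localizations`` scatters per-tetramer blink clouds with realistic
  uncertainty/goodness-of-fit columns, adds uniform coverslip background and
  a configurable share of QC-failing blinks, and returns ground-truth
  cluster memberships.
* ``gen_spark_table`` draws log-normal spark parameters with additive rat-
  and cell-level random effects on the log scale, plus a per-cell frequency
  table with an SR-content covariate.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .arrangement import (
    ArrangementLabel,
    ArrangementParams,
    PairLabel,
    classify_pair,
)
from .dstorm import Localization
from .errors import GenerationError, InvalidInputError
from .geometry import DEFAULT_SIDE, Tetramer, TetramerArray, pair_relation


# ---------------------------------------------------------------------------
# tetramer arrays


@dataclass(frozen=True)
class ArrayGenConfig:
    """Layout parameters for a synthetic tetramer array.

    ``target_fractions`` are the desired shares of (checkerboard,
    side_by_side, both, isolated) tetramers; the default is the control-group
    arrangement.  ``ss_centre_distance`` (28 nm) sets the nominal 1-nm edge
    gap; ``cb_centre_distance`` (34 nm) combined with that axial separation
    fixes the checkerboard lateral offset at sqrt(34² - 28²) ≈ 19.3 nm and
    hence a projected edge overlap of ≈ 7.7 nm.  Jitter is Gaussian per
    tetramer; the defaults give a centre-to-centre NND spread comparable to
    the sub-nm side-by-side spread seen in tomograms.
    """

    n_tetramers: int = 200
    target_fractions: tuple[float, float, float, float] = (0.50, 0.28, 0.08, 0.14)
    side: float = DEFAULT_SIDE
    cb_centre_distance: float = 34.0
    ss_centre_distance: float = 28.0
    positional_jitter_sd: float = 0.6
    angular_jitter_sd: float = 2.0
    seed: int | None = None
    tomogram_id: str = "synthetic-0"
    group: str = "synthetic"
    motif_spacing: float = 250.0
    overlap_tol: float = 1.0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_tetramers < 1:
            raise InvalidInputError("n_tetramers must be >= 1")
        if abs(sum(self.target_fractions) - 1.0) > 1e-6:
            raise InvalidInputError("target_fractions must sum to 1")
        if min(self.target_fractions) < 0:
            raise InvalidInputError("target_fractions must be non-negative")
        if self.ss_centre_distance < self.side - 1e-9:
            raise InvalidInputError(
                "ss_centre_distance must be >= side (no interpenetration)"
            )
        if self.cb_centre_distance <= self.ss_centre_distance:
            raise InvalidInputError(
                "cb_centre_distance must exceed ss_centre_distance"
            )


def _motif_offsets(cfg: ArrayGenConfig) -> dict[str, list[tuple[np.ndarray, str]]]:
    """Base (offset, intended-label) layouts for each motif type."""
    d_ax = cfg.ss_centre_distance
    d_perp = math.sqrt(cfg.cb_centre_distance**2 - d_ax**2)
    cb = ArrangementLabel.CHECKERBOARD.value
    ss = ArrangementLabel.SIDE_BY_SIDE.value
    return {
        "ss_pair": [
            (np.array([0.0, 0.0]), ss),
            (np.array([d_ax, 0.0]), ss),
        ],
        "cb_pair": [
            (np.array([0.0, 0.0]), cb),
            (np.array([d_ax, d_perp]), cb),
        ],
        "both_triple": [
            (np.array([0.0, 0.0]), ArrangementLabel.BOTH.value),
            (np.array([-d_ax, 0.0]), ss),
            (np.array([d_ax, d_perp]), cb),
        ],
        "isolated": [(np.array([0.0, 0.0]), ArrangementLabel.ISOLATED.value)],
    }


def _motif_counts(cfg: ArrayGenConfig) -> dict[str, int]:
    """Solve motif multiplicities for the requested label fractions.

    A both-triple contributes one both, one side-by-side and one
    checkerboard tetramer, so pair counts are reduced accordingly.
    """
    n = cfg.n_tetramers
    f_cb, f_ss, f_both, f_iso = cfg.target_fractions
    n_both = round(f_both * n)
    ss_extra = f_ss * n - n_both
    cb_extra = f_cb * n - n_both
    if n_both and (ss_extra < -0.5 or cb_extra < -0.5):
        raise GenerationError(
            "infeasible fractions: 'both' tetramers need at least as many "
            "side-by-side and checkerboard tetramers as 'both' ones"
        )
    counts = {
        "both_triple": n_both,
        "ss_pair": max(round(ss_extra / 2.0), 0),
        "cb_pair": max(round(cb_extra / 2.0), 0),
    }
    used = 3 * counts["both_triple"] + 2 * counts["ss_pair"] + 2 * counts["cb_pair"]
    while used > n:
        for key in ("cb_pair", "ss_pair", "both_triple"):
            if used > n and counts[key] > 0:
                counts[key] -= 1
                used -= 3 if key == "both_triple" else 2
    counts["isolated"] = n - used
    return counts


def _labels_within_motif(
    tets: list[Tetramer], params: ArrangementParams
) -> list[str]:
    labels = []
    for i, t in enumerate(tets):
        n_cb = n_ss = 0
        for j, u in enumerate(tets):
            if i == j:
                continue
            pl = classify_pair(pair_relation(t, u, params.angle_tol), params)
            if pl is PairLabel.CHECKERBOARD:
                n_cb += 1
            elif pl is PairLabel.SIDE_BY_SIDE:
                n_ss += 1
        if n_cb and n_ss:
            labels.append(ArrangementLabel.BOTH.value)
        elif n_cb:
            labels.append(ArrangementLabel.CHECKERBOARD.value)
        elif n_ss:
            labels.append(ArrangementLabel.SIDE_BY_SIDE.value)
        else:
            labels.append(ArrangementLabel.ISOLATED.value)
    return labels


def _max_overlap_area(tets: list[Tetramer]) -> float:
    worst = 0.0
    for i in range(len(tets)):
        pi = tets[i].polygon()
        for j in range(i + 1, len(tets)):
            worst = max(worst, pi.intersection(tets[j].polygon()).area)
    return worst


def gen_tetramer_array(
    cfg: ArrayGenConfig | None = None,
) -> tuple[TetramerArray, dict[str, ArrangementLabel]]:
    """Generate one synthetic tetramer array with ground-truth labels.

    Motifs (side-by-side pairs, checkerboard pairs, mixed triples, isolated
    singletons) are placed on a coarse shuffled grid whose spacing keeps
    distinct motifs far beyond the adjacency reach (> 60 nm), each with a
    random rigid rotation.  Per-tetramer positional/angular jitter is drawn
    and redrawn (bounded retries) until the motif still satisfies the
    non-overlap invariant and every member still classifies to its intended
    label, so the returned labels are ground truth by construction; if the
    retries are exhausted the unjittered motif is used.
    """
    cfg = cfg or ArrayGenConfig()
    rng = np.random.default_rng(cfg.seed)
    params = ArrangementParams(side=cfg.side)
    offsets = _motif_offsets(cfg)
    counts = _motif_counts(cfg)
    motifs: list[str] = []
    for kind in ("ss_pair", "cb_pair", "both_triple", "isolated"):
        motifs.extend([kind] * counts[kind])
    rng.shuffle(motifs)
    n_cells = max(len(motifs), 1)
    grid_side = math.ceil(math.sqrt(n_cells))
    cells = [(i, j) for i in range(grid_side) for j in range(grid_side)]
    rng.shuffle(cells)

    tetramers: list[Tetramer] = []
    truth: dict[str, ArrangementLabel] = {}
    counter = 0
    for kind, cell in zip(motifs, cells):
        base = offsets[kind]
        centre = (
            np.array(cell, dtype=float) * cfg.motif_spacing
            + rng.uniform(-cfg.motif_spacing / 6.0, cfg.motif_spacing / 6.0, 2)
        )
        phi = rng.uniform(0.0, 360.0)
        rot = np.array(
            [
                [math.cos(math.radians(phi)), -math.sin(math.radians(phi))],
                [math.sin(math.radians(phi)), math.cos(math.radians(phi))],
            ]
        )
        placed = [(centre + rot @ off, label) for off, label in base]
        intended = [label for _, label in base]
        accepted: list[Tetramer] | None = None
        for attempt in range(cfg.max_retries + 1):
            jitter_p = (
                rng.normal(0.0, cfg.positional_jitter_sd, (len(placed), 2))
                if cfg.positional_jitter_sd > 0
                else np.zeros((len(placed), 2))
            )
            jitter_a = (
                rng.normal(0.0, cfg.angular_jitter_sd, len(placed))
                if cfg.angular_jitter_sd > 0
                else np.zeros(len(placed))
            )
            if attempt == cfg.max_retries:
                jitter_p[:] = 0.0
                jitter_a[:] = 0.0
            candidate = [
                Tetramer(
                    id=f"t{counter + m:05d}",
                    x=pos[0] + jitter_p[m, 0],
                    y=pos[1] + jitter_p[m, 1],
                    theta=phi + jitter_a[m],
                    side=cfg.side,
                    tomogram_id=cfg.tomogram_id,
                    group=cfg.group,
                )
                for m, (pos, _) in enumerate(placed)
            ]
            if len(candidate) > 1:
                if _max_overlap_area(candidate) > cfg.overlap_tol:
                    continue
                if _labels_within_motif(candidate, params) != intended:
                    continue
            accepted = candidate
            break
        assert accepted is not None  # the unjittered motif always passes
        tetramers.extend(accepted)
        for t, label in zip(accepted, intended):
            truth[t.id] = ArrangementLabel(label)
        counter += len(accepted)
    array = TetramerArray(
        tetramers=tuple(tetramers), group=cfg.group, overlap_tol=cfg.overlap_tol
    )
    return array, truth


# ---------------------------------------------------------------------------
# dSTORM blink clouds


@dataclass(frozen=True)
class BlinkGenConfig:
    """Blink-cloud parameters.

    Per footprint the blink count is Poisson with mean
    ``blinks_per_tetramer_mean``; blink positions are uniform over the
    footprint plus Gaussian localization noise of the drawn ``sigma_xy``.
    Quality columns for passing blinks are drawn uniformly from the given
    ranges (all inside the QC thresholds); a ``fail_fraction`` of blinks has
    one quality field pushed beyond its threshold.  ``background_density``
    adds uniform coverslip blinks per µm² over the padded field.
    """

    blinks_per_tetramer_mean: float = 50.0
    sigma_xy_range: tuple[float, float] = (2.0, 9.0)
    sigma_z_range: tuple[float, float] = (5.0, 35.0)
    gof_range: tuple[float, float] = (0.92, 0.999)
    z_sd: float = 25.0
    background_density: float = 2.0
    fail_fraction: float = 0.02
    field_pad: float = 200.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.blinks_per_tetramer_mean < 0 or self.background_density < 0:
            raise InvalidInputError("rates must be >= 0")
        if not (0.0 <= self.fail_fraction <= 1.0):
            raise InvalidInputError("fail_fraction must lie in [0, 1]")


def _as_polygons(layout) -> list[Polygon]:
    if isinstance(layout, TetramerArray):
        return [t.polygon() for t in layout]
    polys = []
    for item in layout:
        if isinstance(item, Polygon):
            polys.append(item)
        else:
            xmin, ymin, xmax, ymax = item
            polys.append(
                Polygon(
                    [(xmin, ymin), (xmax, ymin), (xmax, ymax), (xmin, ymax)]
                )
            )
    return polys


def _sample_in_polygon(
    poly: Polygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points in a polygon by bounding-box rejection."""
    xmin, ymin, xmax, ymax = poly.bounds
    chunks: list[np.ndarray] = []
    remaining = n
    while remaining > 0:
        cand = rng.uniform((xmin, ymin), (xmax, ymax), (max(remaining, 8) * 2, 2))
        inside = shapely.intersects_xy(poly, cand[:, 0], cand[:, 1])
        hits = cand[inside][:remaining]
        chunks.append(hits)
        remaining -= len(hits)
    return np.vstack(chunks)


def gen_localizations(
    layout, cfg: BlinkGenConfig | None = None
) -> tuple[list[Localization], list[int]]:
    """Generate dSTORM blinks for a layout of footprints.

    ``layout`` is a :class:`TetramerArray`, a list of shapely polygons or a
    list of ``(xmin, ymin, xmax, ymax)`` rectangles.  Returns the blink list
    and ground-truth memberships: the footprint index per blink, -1 for
    background.
    """
    cfg = cfg or BlinkGenConfig()
    rng = np.random.default_rng(cfg.seed)
    polys = _as_polygons(layout)
    locs: list[Localization] = []
    truth: list[int] = []

    def draw_quality(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s_xy = rng.uniform(*cfg.sigma_xy_range, n)
        s_z = rng.uniform(*cfg.sigma_z_range, n)
        gof = rng.uniform(*cfg.gof_range, n)
        fail = rng.random(n) < cfg.fail_fraction
        mode = rng.integers(0, 3, n)
        s_xy = np.where(fail & (mode == 0), rng.uniform(10.5, 25.0, n), s_xy)
        s_z = np.where(fail & (mode == 1), rng.uniform(41.0, 80.0, n), s_z)
        gof = np.where(fail & (mode == 2), rng.uniform(0.5, 0.89, n), gof)
        return s_xy, s_z, gof

    frame = 0
    for i, poly in enumerate(polys):
        n = int(rng.poisson(cfg.blinks_per_tetramer_mean))
        if n == 0:
            continue
        pts = _sample_in_polygon(poly, n, rng)
        s_xy, s_z, gof = draw_quality(n)
        noise = rng.normal(0.0, s_xy[:, None], (n, 2))
        z = rng.normal(0.0, cfg.z_sd, n)
        for m in range(n):
            locs.append(
                Localization(
                    x=float(pts[m, 0] + noise[m, 0]),
                    y=float(pts[m, 1] + noise[m, 1]),
                    z=float(z[m]),
                    sigma_xy=float(s_xy[m]),
                    sigma_z=float(s_z[m]),
                    gof=float(gof[m]),
                    frame=frame + m,
                )
            )
            truth.append(i)
        frame += n
    if cfg.background_density > 0 and polys:
        bounds = np.array([p.bounds for p in polys])
        xmin, ymin = bounds[:, :2].min(axis=0) - cfg.field_pad
        xmax, ymax = bounds[:, 2:].max(axis=0) + cfg.field_pad
        area_um2 = (xmax - xmin) * (ymax - ymin) / 1e6
        n_bg = int(rng.poisson(cfg.background_density * area_um2))
        if n_bg:
            pts = rng.uniform((xmin, ymin), (xmax, ymax), (n_bg, 2))
            s_xy, s_z, gof = draw_quality(n_bg)
            z = rng.uniform(-75.0, 75.0, n_bg)
            for m in range(n_bg):
                locs.append(
                    Localization(
                        x=float(pts[m, 0]),
                        y=float(pts[m, 1]),
                        z=float(z[m]),
                        sigma_xy=float(s_xy[m]),
                        sigma_z=float(s_z[m]),
                        gof=float(gof[m]),
                        frame=frame + m,
                    )
                )
                truth.append(-1)
    return locs, truth


# ---------------------------------------------------------------------------
# Ca²⁺ sparks


#: Default multiplicative treatment effects on the spark-parameter geometric
#: means, mimicking the direction of the six experimental conditions
#: (immunophilins suppress, phosphorylation enhances).
DEFAULT_GROUP_EFFECTS = {
    "Control": 1.0,
    "FKBP12": 0.7,
    "FKBP12.6": 0.6,
    "Phosphorylation": 1.3,
    "FKBP12+Phos": 1.1,
    "FKBP12.6+Phos": 1.4,
}


@dataclass(frozen=True)
class SparkGenConfig:
    """Nested spark-table parameters.

    Spark parameters are log-normal: per group, log-mean = base log-mean +
    log(effect multiplier), with additive rat- and cell-level random effects
    (log scale, sds ``rat_sd``/``cell_sd``) and spark-level log-sds per
    parameter.  Frequency is generated per cell on the natural scale
    (truncated normal) together with an SR-content covariate.
    """

    group_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    base_log_means: dict[str, float] = field(
        default_factory=lambda: {
            "amplitude": math.log(0.45),
            "fdhm": math.log(25.0),
            "fwhm": math.log(2.0),
        }
    )
    spark_log_sds: dict[str, float] = field(
        default_factory=lambda: {"amplitude": 0.5, "fdhm": 0.4, "fwhm": 0.3}
    )
    rat_sd: float = 0.10
    cell_sd: float = 0.15
    n_rats: int = 4
    cells_per_rat: int = 5
    sparks_per_cell: int = 30
    freq_mean: float = 5.0
    freq_sd: float = 1.0
    sr_mean: float = 3.0
    sr_sd: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.n_rats, self.cells_per_rat, self.sparks_per_cell) < 1:
            raise InvalidInputError("design counts must be >= 1")
        if self.rat_sd < 0 or self.cell_sd < 0:
            raise InvalidInputError("random-effect sds must be >= 0")
        if min(self.spark_log_sds.values()) < 0:
            raise InvalidInputError("spark log-sds must be >= 0")


def gen_spark_table(
    cfg: SparkGenConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate nested spark and per-cell frequency tables.

    Returns ``(sparks, frequencies)``: sparks with columns ``rat, cell,
    group, amplitude, fdhm_ms, fwhm_um``; frequencies with ``rat, cell,
    group, rate, sr_content``.  Rat ids are unique across groups (each group
    has its own animals).
    """
    cfg = cfg or SparkGenConfig()
    rng = np.random.default_rng(cfg.seed)
    params = sorted(cfg.base_log_means)
    spark_rows = []
    freq_rows = []
    for group in sorted(cfg.group_effects):
        effect = math.log(cfg.group_effects[group])
        for r in range(cfg.n_rats):
            rat_id = f"{group}-rat{r + 1}"
            rat_shift = rng.normal(0.0, cfg.rat_sd) if cfg.rat_sd > 0 else 0.0
            for c in range(cfg.cells_per_rat):
                cell_id = f"{rat_id}-cell{c + 1}"
                cell_shift = (
                    rng.normal(0.0, cfg.cell_sd) if cfg.cell_sd > 0 else 0.0
                )
                draws = {}
                for name in params:
                    mu = (
                        cfg.base_log_means[name] + effect + rat_shift + cell_shift
                    )
                    sd = cfg.spark_log_sds[name]
                    draws[name] = (
                        np.exp(rng.normal(mu, sd, cfg.sparks_per_cell))
                        if sd > 0
                        else np.full(cfg.sparks_per_cell, math.exp(mu))
                    )
                for s in range(cfg.sparks_per_cell):
                    spark_rows.append(
                        {
                            "rat": rat_id,
                            "cell": cell_id,
                            "group": group,
                            "amplitude": draws["amplitude"][s],
                            "fdhm_ms": draws["fdhm"][s],
                            "fwhm_um": draws["fwhm"][s],
                        }
                    )
                rate = max(
                    float(
                        rng.normal(
                            cfg.freq_mean * math.exp(effect + rat_shift + cell_shift),
                            cfg.freq_sd,
                        )
                    ),
                    0.0,
                )
                sr = max(float(rng.normal(cfg.sr_mean, cfg.sr_sd)), 0.1)
                freq_rows.append(
                    {
                        "rat": rat_id,
                        "cell": cell_id,
                        "group": group,
                        "rate": rate,
                        "sr_content": sr,
                    }
                )
    sparks = pd.DataFrame(
        spark_rows, columns=["rat", "cell", "group", "amplitude", "fdhm_ms", "fwhm_um"]
    )
    freqs = pd.DataFrame(
        freq_rows, columns=["rat", "cell", "group", "rate", "sr_content"]
    )
    return sparks, freqs
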