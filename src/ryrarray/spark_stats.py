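"""Ca²⁺-spark parameter statistics with a rat -> cell -> spark hierarchy.

Spark parameters (amplitude ΔF/F₀, FDHM ms, FWHM µm, spark mass, frequency
normalized to SR content) are compared between treatment groups while
respecting the nesting of sparks within cells within animals.  Group pairs
are compared with a hierarchical bootstrap of the group-mean difference:
rats are resampled with replacement, then cells within each drawn rat, then
sparks within each drawn cell, and the two-sided p-value is the tail share
of bootstrap differences crossing zero.  The family of pairwise p-values is
then screened with the Holm-Bonferroni step-down rule.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidInputError


@dataclass(frozen=True)
class SparkRecord:
    """One Ca²⁺ spark: amplitude (ΔF/F₀), FDHM (ms), FWHM (µm) and nesting."""

    amplitude: float
    fdhm: float
    fwhm: float
    rat_id: str
    cell_id: str
    group: str

    def __post_init__(self) -> None:
        for name in ("amplitude", "fdhm", "fwhm"):
            if not (getattr(self, name) > 0):
                raise InvalidInputError(f"spark {name} must be > 0")


@dataclass(frozen=True)
class CellFrequency:
    """Per-cell spark rate (sparks·s⁻¹·(100 µm)⁻¹) and SR content (ΔF/F₀)."""

    rat_id: str
    cell_id: str
    group: str
    spark_rate: float
    sr_content: float

    def __post_init__(self) -> None:
        if self.spark_rate < 0:
            raise InvalidInputError("spark_rate must be >= 0")
        if not (self.sr_content > 0):
            raise InvalidInputError("sr_content must be > 0")


def spark_mass(record: SparkRecord) -> float:
    """Spark mass: amplitude × FDHM × FWHM (ΔF/F₀·ms·µm)."""
    return record.amplitude * record.fdhm * record.fwhm


def normalize_frequency(cell: CellFrequency) -> float:
    """Spark rate normalized to SR content, isolating array effects from
    changes in SR filling."""
    return cell.spark_rate / cell.sr_content


# ---------------------------------------------------------------------------
# hierarchical bootstrap

Nested = dict[str, dict[str, np.ndarray]]


def _nest(
    df: pd.DataFrame, parameter: str, rat_col: str, cell_col: str
) -> Nested:
    nested: Nested = {}
    for (rat, cell), sub in df.groupby([rat_col, cell_col], sort=True):
        values = np.asarray(sub[parameter], dtype=float)
        if values.size == 0:
            continue
        nested.setdefault(str(rat), {})[str(cell)] = values
    return nested


def _validate_hierarchy(group: str, nested: Nested) -> None:
    if len(nested) < 2:
        raise InsufficientDataError(f"group {group!r} needs >= 2 rats")
    for rat, cells in nested.items():
        if len(cells) < 2:
            raise InsufficientDataError(
                f"group {group!r}, rat {rat!r} needs >= 2 cells"
            )


def _group_mean(nested: Nested) -> float:
    """Group mean as the mean of rat means of cell means (equal weights)."""
    rat_means = [
        np.mean([np.mean(v) for v in cells.values()]) for cells in nested.values()
    ]
    return float(np.mean(rat_means))


def _n_draw(n: int) -> int:
    # n-out-of-n resampling at every level of the hierarchy.
    return n


def _bootstrap_group_means(
    nested: Nested, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    """Hierarchical bootstrap replicates of the group mean."""
    rats = sorted(nested)
    cells_per_rat = [sorted(nested[r]) for r in rats]
    n_rats = len(rats)
    cell_counts = {len(c) for c in cells_per_rat}
    spark_counts = {v.size for r in rats for v in nested[r].values()}
    balanced = len(cell_counts) == 1 and len(spark_counts) == 1
    if balanced:
        n_cells = cell_counts.pop()
        n_sparks = spark_counts.pop()
        data = np.array(
            [[nested[r][c] for c in sorted(nested[r])] for r in rats]
        )  # (R, C, S)
        rr, cc, ss = _n_draw(n_rats), _n_draw(n_cells), _n_draw(n_sparks)
        rat_idx = rng.integers(0, n_rats, size=(n_boot, rr))
        cell_idx = rng.integers(0, n_cells, size=(n_boot, rr, cc))
        spark_idx = rng.integers(0, n_sparks, size=(n_boot, rr, cc, ss))
        drawn = data[
            rat_idx[:, :, None, None], cell_idx[:, :, :, None], spark_idx
        ]
        return drawn.mean(axis=3).mean(axis=2).mean(axis=1)
    means = np.empty(n_boot)
    for b in range(n_boot):
        rat_means = []
        for ri in rng.integers(0, n_rats, size=_n_draw(n_rats)):
            cells = cells_per_rat[ri]
            cell_means = []
            for ci in rng.integers(0, len(cells), size=_n_draw(len(cells))):
                v = nested[rats[ri]][cells[ci]]
                cell_means.append(v[rng.integers(0, v.size, size=_n_draw(v.size))].mean())
            rat_means.append(np.mean(cell_means))
        means[b] = np.mean(rat_means)
    return means


def hierarchical_pairwise(
    records: pd.DataFrame,
    parameter: str,
    log_transform: bool = True,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
    group_col: str = "group",
    rat_col: str = "rat",
    cell_col: str = "cell",
) -> pd.DataFrame:
    """Two-sided p-values for every unordered group pair.

    ``records`` is a long table with one row per observation and columns for
    the group, rat and cell labels plus the parameter.  When
    ``log_transform`` is set (appropriate for the log-normal spark
    parameters; normalized frequency is analysed untransformed) the values
    are log-transformed before comparison.  Each pair's p-value is the
    two-sided hierarchical-bootstrap tail probability that the group-mean
    difference has the opposite sign, with a (count+1)/(B+1) finite-sample
    correction.

    Returns a DataFrame with columns ``comparison, group_a, group_b,
    p_value``.
    """
    if parameter not in records.columns:
        raise InvalidInputError(f"column {parameter!r} not present in records")
    if n_boot < 2:
        raise InvalidInputError("n_boot must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    df = records.copy()
    values = np.asarray(df[parameter], dtype=float)
    if not np.isfinite(values).all():
        raise InvalidInputError(f"column {parameter!r} contains non-finite values")
    if log_transform:
        if (values <= 0).any():
            raise InvalidInputError(
                f"log transform requires strictly positive {parameter!r} values"
            )
        df[parameter] = np.log(values)
    groups = sorted(df[group_col].astype(str).unique())
    if len(groups) < 2:
        raise InsufficientDataError("hierarchical_pairwise needs >= 2 groups")
    nested_by_group: dict[str, Nested] = {}
    boot_by_group: dict[str, np.ndarray] = {}
    for group in groups:
        nested = _nest(
            df[df[group_col].astype(str) == group], parameter, rat_col, cell_col
        )
        _validate_hierarchy(group, nested)
        nested_by_group[group] = nested
        boot_by_group[group] = _bootstrap_group_means(nested, n_boot, rng)
    rows = []
    for a, b in itertools.combinations(groups, 2):
        delta = boot_by_group[a] - boot_by_group[b]
        n_le = int((delta <= 0).sum())
        n_ge = int((delta >= 0).sum())
        p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n_boot + 1))
        rows.append(
            {
                "comparison": f"{a} vs {b}",
                "group_a": a,
                "group_b": b,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows, columns=["comparison", "group_a", "group_b", "p_value"])


# ---------------------------------------------------------------------------
# Holm-Bonferroni


def holm_bonferroni(
    pvalues: Sequence[float],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Holm-Bonferroni step-down ledger.

    P-values are ranked ascending; the critical value at 1-based rank k of m
    is alpha / (m - k + 1).  Hypotheses are rejected sequentially while
    p < critical (strict); the first failure stops all later rejections.

    Returns a DataFrame sorted by ascending p with columns ``comparison,
    p_value, significant, holm_critical_p, reject`` (``significant`` flags
    the unadjusted p < alpha).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise InvalidInputError("holm_bonferroni needs >= 1 p-value")
    if not ((p >= 0) & (p <= 1)).all():
        raise InvalidInputError("p-values must lie in [0, 1]")
    if not (0 < alpha < 1):
        raise InvalidInputError("alpha must lie in (0, 1)")
    m = p.size
    if labels is None:
        labels = [f"comparison {i + 1}" for i in range(m)]
    if len(labels) != m:
        raise InvalidInputError("labels must match pvalues in length")
    order = np.argsort(p, kind="stable")
    criticals = alpha / (m - np.arange(1, m + 1) + 1)
    reject = np.zeros(m, dtype=bool)
    still_rejecting = True
    for rank, idx in enumerate(order):
        if still_rejecting and p[idx] < criticals[rank]:
            reject[rank] = True
        else:
            still_rejecting = False
    return pd.DataFrame(
        {
            "comparison": [labels[i] for i in order],
            "p_value": p[order],
            "significant": p[order] < alpha,
            "holm_critical_p": criticals,
            "reject": reject,
        }
    )


def compare_groups(
    records: pd.DataFrame,
    parameter: str,
    log_transform: bool = True,
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | np.random.Generator | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Hierarchical pairwise comparison plus the Holm-Bonferroni ledger."""
    pairs = hierarchical_pairwise(
        records,
        parameter,
        log_transform=log_transform,
        n_boot=n_boot,
        seed=seed,
        **kwargs,
    )
    return holm_bonferroni(
        pairs["p_value"].tolist(), alpha=alpha, labels=pairs["comparison"].tolist()
    )
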