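"""Microbial dysbiosis index with Mann-Whitney sensitivity pruning.

The index summarises community imbalance per sample as

    log10( sum of abundances of outcome-enriched taxa /
           sum of abundances of outcome-depleted taxa )

where the enriched/depleted sets come from covariate-adjusted differential
abundance and are pruned by a Mann-Whitney U sensitivity test: any candidate
taxon whose between-group MWU p-value exceeds 0.10 is removed before the
index is computed. A pseudocount (default: half the smallest nonzero
abundance in the table) keeps the index finite for samples with zero total
abundance in either set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .da import DirectionSets
from .io_core import AbundanceTable

__all__ = [
    "MWUResult",
    "DysbiosisResult",
    "mwu_test",
    "prune_sets",
    "dysbiosis_index",
    "compute_dysbiosis",
]

#: exact enumeration is used when n_x + n_y is at or below this
EXACT_THRESHOLD = 12


@dataclass
class MWUResult:
    u_statistic: float  # U for the x sample
    p_value: float
    n_x: int
    n_y: int
    exact: bool


def _u_stat(x: np.ndarray, y: np.ndarray) -> float:
    """U_x = #{x_i > y_j} + 0.5 #{x_i == y_j} (handles ties)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mwu_test(x, y) -> MWUResult:
    """Two-sided Mann-Whitney U test.

    Exact by enumeration of all label assignments of the pooled sample when
    ``n_x + n_y <= 12`` (valid under ties); otherwise the normal
    approximation with continuity and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n_x, n_y = x.size, y.size
    u_obs = _u_stat(x, y)
    if n_x + n_y <= EXACT_THRESHOLD:
        pooled = np.concatenate([x, y])
        mid = n_x * n_y / 2.0
        dev_obs = abs(u_obs - mid)
        count = total = 0
        idx = np.arange(n_x + n_y)
        for chosen in combinations(idx, n_x):
            mask = np.zeros(n_x + n_y, dtype=bool)
            mask[list(chosen)] = True
            u = _u_stat(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mid) >= dev_obs - 1e-12:
                count += 1
        return MWUResult(u_obs, count / total, n_x, n_y, exact=True)
    res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MWUResult(float(res.statistic), float(res.pvalue), n_x, n_y, exact=False)


@dataclass
class DysbiosisResult:
    increased: set[str]
    decreased: set[str]
    index: pd.Series
    pseudocount: float
    pruning_p: dict[str, float]


def prune_sets(
    table: AbundanceTable,
    outcome,
    sets: DirectionSets,
    p_threshold: float = 0.10,
) -> tuple[DirectionSets, dict[str, float]]:
    """Mann-Whitney sensitivity pruning of candidate index taxa.

    Each candidate taxon's abundances are compared between outcome groups;
    taxa with p-value strictly greater than ``p_threshold`` are removed
    (taxa at exactly the threshold are retained). Returns the pruned sets
    and the per-taxon pruning p-values.
    """
    outcome = pd.Series(np.asarray(outcome), index=table.data.index).astype(bool)
    pvals: dict[str, float] = {}
    kept_inc, kept_dec = set(), set()
    for taxon in sorted(sets.increased | sets.decreased):
        if taxon not in table.data.columns:
            raise KeyError(f"taxon {taxon!r} not in abundance table")
        vals = table.data[taxon]
        p = mwu_test(vals[outcome], vals[~outcome]).p_value
        pvals[taxon] = p
        if p <= p_threshold:
            (kept_inc if taxon in sets.increased else kept_dec).add(taxon)
    return DirectionSets(kept_inc, kept_dec, alpha=sets.alpha), pvals


def dysbiosis_index(
    table: AbundanceTable,
    sets: DirectionSets,
    pseudocount: float | None = None,
) -> pd.Series:
    """Per-sample log10 ratio of summed increased over decreased abundances.

    ``pseudocount`` defaults to half the smallest nonzero abundance in the
    table and is added to both numerator and denominator.
    """
    if not sets.increased or not sets.decreased:
        raise ValueError(
            "dysbiosis index undefined: both direction sets must be non-empty "
            f"(increased={len(sets.increased)}, decreased={len(sets.decreased)})"
        )
    missing = (sets.increased | sets.decreased) - set(table.data.columns)
    if missing:
        raise KeyError(f"taxa not in table: {sorted(missing)[:3]}")
    if pseudocount is None:
        vals = table.values
        nz = vals[vals > 0]
        if nz.size == 0:
            raise ValueError("table has no nonzero abundances")
        pseudocount = float(nz.min()) / 2.0
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    inc = table.data[sorted(sets.increased)].sum(axis=1)
    dec = table.data[sorted(sets.decreased)].sum(axis=1)
    # difference of logs (not log of ratio) so set exchange negates exactly
    idx = np.log10(inc + pseudocount) - np.log10(dec + pseudocount)
    return pd.Series(idx, index=table.data.index, name="dysbiosis_index")


def compute_dysbiosis(
    table: AbundanceTable,
    outcome,
    sets: DirectionSets,
    p_threshold: float = 0.10,
    pseudocount: float | None = None,
) -> DysbiosisResult:
    """Prune candidate sets, then compute the per-sample index."""
    pruned, pvals = prune_sets(table, outcome, sets, p_threshold)
    idx = dysbiosis_index(table, pruned, pseudocount)
    if pseudocount is None:
        nz = table.values[table.values > 0]
        pseudocount = float(nz.min()) / 2.0
    return DysbiosisResult(
        increased=pruned.increased,
        decreased=pruned.decreased,
        index=idx,
        pseudocount=float(pseudocount),
        pruning_p=pvals,
    )
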