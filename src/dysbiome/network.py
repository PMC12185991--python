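"""Spearman correlation structure and thresholded co-occurrence networks.

Edges connect taxa whose Spearman correlation exceeds a threshold (default
rho > 0.5, signed) at raw p < 0.05 within a sample subset (e.g. one outcome
group). No multiple-testing correction is applied to edges — a deliberately
liberal, descriptive rule. Rank-based correlations make the networks
invariant to any per-sample monotone rescaling of abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .io_core import AbundanceTable

__all__ = ["CorrelationNetwork", "spearman", "cooccurrence_network",
           "taxa_clinical_correlations"]

#: exact permutation p-value used at or below this sample size
EXACT_N = 9


@dataclass
class CorrelationNetwork:
    nodes: list[str]
    edges: pd.DataFrame  # columns: taxon_a, taxon_b, rho, p_value
    rho_threshold: float
    p_threshold: float

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.taxon_a, row.taxon_b, rho=float(row.rho),
                       p_value=float(row.p_value))
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


@lru_cache(maxsize=4)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(permutations(range(n))), dtype=np.intp)


def _rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    return float((rxc * ryc).sum() / denom)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties.

    Two-sided p from exact permutation enumeration when n <= 9, otherwise
    the t-distribution approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")
    n = x.size
    rx, ry = rankdata(x), rankdata(y)
    rho = _rho(rx, ry)
    if n <= EXACT_N:
        perms = _perm_matrix(n)
        ry_all = ry[perms]                       # n! x n
        rxc = rx - rx.mean()
        ryc = ry_all - ry.mean()
        denom = np.sqrt((rxc ** 2).sum() * (ryc[0] ** 2).sum())
        rho_all = ryc @ rxc / denom
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
        return rho, p
    return rho, float(spearmanr(x, y).pvalue)


def cooccurrence_network(
    table: AbundanceTable,
    subset=None,
    rho_threshold: float = 0.5,
    p_threshold: float = 0.05,
    top_n: int = 50,
    extra_taxa=(),
    absolute: bool = False,
) -> CorrelationNetwork:
    """Thresholded Spearman co-occurrence network for a sample subset.

    Nodes are the ``top_n`` most abundant taxa (mean relative abundance in
    the subset) plus ``extra_taxa`` (e.g. differentially abundant species).
    By default only positive correlations above ``rho_threshold`` form edges
    (the signed rule); set ``absolute=True`` for an |rho| rule. Constant
    taxa are kept as isolated nodes.
    """
    data = table.data if subset is None else table.data.loc[np.asarray(subset)]
    if len(data) < 4:
        raise ValueError("subset must select at least 4 samples")
    mean_ab = data.mean(axis=0).sort_values(ascending=False)
    nodes = list(mean_ab.index[:top_n])
    for t in extra_taxa:
        if t not in table.data.columns:
            raise KeyError(f"taxon {t!r} not in table")
        if t not in nodes:
            nodes.append(t)
    rows = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            xa, xb = data[a].to_numpy(), data[b].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                continue
            rho, p = spearman(xa, xb)
            stat = abs(rho) if absolute else rho
            if stat > rho_threshold and p < p_threshold:
                a_, b_ = sorted((a, b))
                rows.append({"taxon_a": a_, "taxon_b": b_, "rho": rho, "p_value": p})
    edges = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "p_value"])
    return CorrelationNetwork(nodes=nodes, edges=edges,
                              rho_threshold=rho_threshold, p_threshold=p_threshold)


def taxa_clinical_correlations(
    table: AbundanceTable, taxa, clinical: pd.DataFrame
) -> pd.DataFrame:
    """Long-form Spearman correlation table: taxa x clinical parameters."""
    rows = []
    for taxon in taxa:
        for param in clinical.columns:
            vals = pd.concat([table.data[taxon], clinical[param]], axis=1).dropna()
            if len(vals) < 3 or vals.iloc[:, 0].nunique() < 2 or vals.iloc[:, 1].nunique() < 2:
                continue
            rho, p = spearman(vals.iloc[:, 0], vals.iloc[:, 1])
            rows.append({"taxon": taxon, "parameter": param, "rho": rho, "p_value": p})
    return pd.DataFrame(rows, columns=["taxon", "parameter", "rho", "p_value"])
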