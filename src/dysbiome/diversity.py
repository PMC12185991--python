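"""Alpha/beta diversity: Shannon, inverse Simpson, Bray-Curtis, PCoA, PERMANOVA.

PERMANOVA follows the adonis2-style sequential (terms-in-order) partition of
the Gower-centred sum of squares, with covariates entered before the group
term and p-values from free permutation of sample identities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io_core import AbundanceTable

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "shannon",
    "inverse_simpson",
    "alpha_diversity",
    "bray_curtis_matrix",
    "pcoa",
    "permanova",
]


@dataclass
class DistanceMatrix:
    data: pd.DataFrame  # square, symmetric, zero diagonal

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if vals.shape[0] != vals.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(vals), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if vals.min() < -1e-12:
            raise ValueError("distances must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame       # samples x retained axes
    eigenvalues: np.ndarray         # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # over positive eigenvalues only


@dataclass
class PermanovaResult:
    term: str
    df: int
    sum_of_squares: float
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int


def _proportions(vec) -> np.ndarray:
    x = np.asarray(vec, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("abundance vector must be 1-D and non-empty")
    if (x < 0).any():
        raise ValueError("abundances must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    return x / total


def shannon(abund) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log)."""
    p = _proportions(abund)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def inverse_simpson(abund) -> float:
    """Inverse Simpson index 1 / sum p_i^2."""
    p = _proportions(abund)
    return float(1.0 / (p ** 2).sum())


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Shannon and inverse Simpson indices."""
    rows = {
        sid: (shannon(row), inverse_simpson(row))
        for sid, row in zip(table.sample_ids, table.values)
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["shannon", "inverse_simpson"]
    ).rename_axis("sample_id")


def bray_curtis_matrix(table: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity on the raw abundance values."""
    vals = table.values
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    totals = vals.sum(axis=1)
    if (totals <= 0).any():
        bad = table.sample_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample {bad!r} has zero total abundance")
    dm = squareform(pdist(vals, metric="braycurtis"))
    return DistanceMatrix(
        data=pd.DataFrame(dm, index=table.data.index, columns=table.data.index)
    )


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Negative eigenvalues are retained in the eigenvalue list but contribute
    no coordinates; proportion explained is over positive eigenvalues only.
    """
    g = _gower_center(d.values)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    idx = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[idx], eigvecs[:, idx]
    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    pos = eigvals > tol
    n_pos = int(pos.sum())
    k = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    prop = eigvals[pos] / eigvals[pos].sum() if n_pos else np.array([])
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=d.data.index, columns=[f"PC{i+1}" for i in range(k)]
        ),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


def _design_columns(series: pd.Series) -> pd.DataFrame:
    """Numeric columns pass through; categoricals are dummy-coded (drop first)."""
    if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
        return series.astype(float).to_frame()
    dummies = pd.get_dummies(series.astype(str), prefix=series.name, drop_first=True)
    return dummies.astype(float)


def permanova(
    d: DistanceMatrix,
    group,
    covariates: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> list[PermanovaResult]:
    """Sequential PERMANOVA with covariates entered before the group term.

    Pseudo-F per term from the Gower-centred sum-of-squares partition
    (McArdle & Anderson); p = (#{F_perm >= F_obs} + 1) / (n_perm + 1) under
    free permutation of sample identities (rows/columns of the distance
    matrix), covariate design held fixed.
    """
    n = len(d.sample_ids)
    group = pd.Series(np.asarray(group), index=d.data.index, name="group")
    if group.nunique() < 2:
        raise ValueError("group label is constant")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    terms: list[tuple[str, pd.DataFrame]] = []
    if covariates is not None:
        if len(covariates) != n:
            raise ValueError("covariates do not align with the distance matrix")
        cov = covariates.loc[d.data.index]
        for col in cov.columns:
            terms.append((col, _design_columns(cov[col])))
    terms.append(("group", _design_columns(group)))

    g = _gower_center(d.values)
    ss_total = float(np.trace(g))

    # cumulative hat matrices via QR of the growing design (intercept first)
    x = np.ones((n, 1))
    hats = []
    dfs = []
    q, _ = np.linalg.qr(x)
    h_prev = q @ q.T
    rank_prev = 1
    for _, cols in terms:
        x = np.hstack([x, cols.to_numpy(dtype=float)])
        q, r = np.linalg.qr(x)
        rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r[0, 0]))).sum())
        h = q[:, :rank] @ q[:, :rank].T
        hats.append((h_prev, h))
        dfs.append(rank - rank_prev)
        h_prev, rank_prev = h, rank
    df_res = n - rank_prev
    if df_res <= 0:
        raise ValueError("model saturates the samples; no residual df")

    deltas = [h - hp for hp, h in hats]          # projector onto each term
    resid = np.eye(n) - hats[-1][1]

    def partition(gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(m * gm)) for m in deltas])
        return ss, float(np.sum(resid * gm))

    ss_obs, ss_res = partition(g)
    dfs_arr = np.array(dfs, dtype=float)
    f_obs = (ss_obs / dfs_arr) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        p = rng.permutation(n)
        gp = g[np.ix_(p, p)]
        ss_p, ss_rp = partition(gp)
        f_p = (ss_p / dfs_arr) / (ss_rp / df_res)
        exceed += f_p >= f_obs - 1e-12
    pvals = (exceed + 1) / (n_perm + 1)

    return [
        PermanovaResult(
            term=name,
            df=int(dfs[i]),
            sum_of_squares=float(ss_obs[i]),
            pseudo_F=float(f_obs[i]),
            R2=float(ss_obs[i] / ss_total),
            p_value=float(pvals[i]),
            n_permutations=n_perm,
        )
        for i, (name, _) in enumerate(terms)
    ] + [
        PermanovaResult(
            term="residual",
            df=int(df_res),
            sum_of_squares=float(ss_res),
            pseudo_F=float("nan"),
            R2=float(ss_res / ss_total),
            p_value=float("nan"),
            n_permutations=n_perm,
        )
    ]
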