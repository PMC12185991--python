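"""Shared data model: abundance tables, pseudo-counts, metadata, multiple testing.

The pipeline starts from a MetaPhlAn-style merged relative-abundance table
(rows = pipe-delimited taxonomic lineages with rank prefixes ``k__ .. s__``,
columns = samples, values on a 0-100 percent scale) and a per-sample clinical
metadata table. This module houses the containers and the format plumbing
every downstream stage shares: lineage parsing, rank filtering and
aggregation, conversion of percent profiles to integer pseudo-counts for
negative-binomial modelling, prevalence filtering, and Benjamini-Hochberg
false-discovery-rate adjustment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "AbundanceTable",
    "CountTable",
    "MultipleTestingResult",
    "LineageError",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "aggregate_taxonomy",
    "to_counts",
    "prevalence_filter",
    "bh_adjust",
    "terminal_rank",
]

#: Taxonomic ranks from root to leaf, with their lineage prefixes.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_PREFIX = {
    "kingdom": ("k__", "d__"),  # MetaPhlAn3 uses k__, MetaPhlAn4 d__
    "phylum": ("p__",),
    "class": ("c__",),
    "order": ("o__",),
    "family": ("f__",),
    "genus": ("g__",),
    "species": ("s__",),
}
_PREFIX_TO_RANK = {p: r for r, ps in _PREFIX.items() for p in ps}

#: Metadata columns the pipeline knows about (sample id is the index).
METADATA_COLUMNS = (
    "fev1_baseline_ml",
    "fev1_followup_ml",
    "fvc_baseline_ml",
    "followup_years",
    "fev1_pct_predicted",
    "smoking",
    "age",
    "sex",
    "bmi",
    "ethnicity",
    "transmission_mode",
    "nadir_cd4_lt200",
    "hiv_duration",
    "cart_years",
    "il1b_pg_ml",
    "il10_pg_ml",
    "pneumonia_history",
    "spiro_grade",
)

SMOKING_LEVELS = ("never", "former", "current")
SPIRO_GRADES = ("A", "B", "C", "D", "E", "F")


class LineageError(ValueError):
    """Raised for lineage strings without recognised rank prefixes."""


def terminal_rank(lineage: str) -> str:
    """Rank of the last field of a pipe-delimited lineage string."""
    last = lineage.split("|")[-1]
    prefix = last[:3]
    if prefix not in _PREFIX_TO_RANK:
        raise LineageError(f"lineage {lineage!r} has no recognised rank prefix")
    return _PREFIX_TO_RANK[prefix]


@dataclass
class AbundanceTable:
    """Samples x taxa relative abundances (percent scale) at one rank.

    ``data`` is indexed by sample id with lineage-string columns. Values are
    nonnegative and each row sums to at most 100 (the unclassified fraction
    may be absent).
    """

    data: pd.DataFrame
    rank: str

    def __post_init__(self) -> None:
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate taxa: {dups[:3]}")
        vals = self.data.to_numpy(dtype=float)
        if vals.size and vals.min() < 0:
            raise ValueError("negative abundance values")
        if vals.size and (vals.sum(axis=1) > 100 + 1e-6).any():
            bad = self.data.index[vals.sum(axis=1) > 100 + 1e-6][0]
            raise ValueError(f"sample {bad!r} total exceeds 100%")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


@dataclass
class CountTable:
    """Integer pseudo-counts derived from an :class:`AbundanceTable`."""

    data: pd.DataFrame  # samples x taxa, integer
    scale_depth: int

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be integer")
        if vals.size and vals.min() < 0:
            raise ValueError("negative counts")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class MultipleTestingResult:
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    method: str = "benjamini-hochberg"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_abundance_table(path, rank: str = "species") -> AbundanceTable:
    """Read a MetaPhlAn merged-profile TSV, keeping only rows at ``rank``.

    Comment lines beginning ``#`` are skipped, except a commented header line
    containing ``clade_name`` which is used as the header (MetaPhlAn4 dialect).
    """
    with open(path) as fh:
        lines = fh.readlines()
    body: list[str] = []
    for ln in lines:
        if ln.startswith("#"):
            if "clade_name" in ln and not body:
                body.append(ln.lstrip("#"))
            continue
        body.append(ln)
    if not body:
        raise ValueError(f"{path}: no data lines")
    df = pd.read_csv(io.StringIO("".join(body)), sep="\t")
    lineage_col = df.columns[0]
    df = df.set_index(lineage_col)
    seen: set[str] = set()
    keep: list[str] = []
    for i, lineage in enumerate(df.index):
        r = terminal_rank(str(lineage))  # raises LineageError naming the row
        if lineage in seen:
            raise ValueError(f"duplicated taxon row {lineage!r}")
        seen.add(lineage)
        if r == rank:
            keep.append(lineage)
    sub = df.loc[keep].astype(float)
    return AbundanceTable(data=sub.T, rank=rank)


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write the canonical TSV (lineages as ``clade_name`` rows)."""
    out = table.data.T
    out.index.name = "clade_name"
    out.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read a metadata TSV; first column is the sample id."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    validate_metadata(meta)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def validate_metadata(meta: pd.DataFrame) -> None:
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    if "smoking" in meta:
        bad = set(meta["smoking"].dropna()) - set(SMOKING_LEVELS)
        if bad:
            raise ValueError(f"unknown smoking levels: {sorted(bad)}")
    if "spiro_grade" in meta:
        bad = set(meta["spiro_grade"].dropna()) - set(SPIRO_GRADES)
        if bad:
            raise ValueError(f"unknown spirometry grades: {sorted(bad)}")
    if "followup_years" in meta and "fev1_followup_ml" in meta:
        has_fu = meta["fev1_followup_ml"].notna()
        yrs = meta.loc[has_fu, "followup_years"]
        if (yrs.isna() | (yrs <= 0)).any():
            raise ValueError("followup_years must be > 0 when follow-up spirometry present")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def _truncate_lineage(lineage: str, rank: str) -> str:
    parts = lineage.split("|")
    for i, part in enumerate(parts):
        if _PREFIX_TO_RANK.get(part[:3]) == rank:
            return "|".join(parts[: i + 1])
    raise LineageError(f"lineage {lineage!r} has no {rank}-level field")


def aggregate_taxonomy(table: AbundanceTable, target_rank: str) -> AbundanceTable:
    """Sum abundances up the taxonomy to ``target_rank`` (an ancestor rank)."""
    if target_rank not in RANKS:
        raise ValueError(f"unknown rank {target_rank!r}")
    if RANKS.index(target_rank) > RANKS.index(table.rank):
        raise ValueError(f"{target_rank} is not an ancestor of {table.rank}")
    if target_rank == table.rank:
        return AbundanceTable(data=table.data.copy(), rank=table.rank)
    groups = [_truncate_lineage(t, target_rank) for t in table.taxa]
    agg = table.data.T.groupby(pd.Index(groups, name="clade_name"), sort=False).sum().T
    return AbundanceTable(data=agg, rank=target_rank)


def to_counts(table: AbundanceTable, scale_depth: int = 100_000) -> CountTable:
    """Convert percent abundances to pseudo-counts at a fixed per-sample depth."""
    if scale_depth < 1:
        raise ValueError("scale_depth must be >= 1")
    counts = np.rint(table.values / 100.0 * scale_depth).astype(np.int64)
    return CountTable(
        data=pd.DataFrame(counts, index=table.data.index, columns=table.data.columns),
        scale_depth=int(scale_depth),
    )


def prevalence_filter(table: AbundanceTable, min_fraction: float = 0.10) -> AbundanceTable:
    """Drop taxa present (>0) in fewer than ``min_fraction`` of samples."""
    prev = (table.values > 0).mean(axis=0)
    keep = table.data.columns[prev >= min_fraction]
    return AbundanceTable(data=table.data[keep], rank=table.rank)


def bh_adjust(p) -> MultipleTestingResult:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return MultipleTestingResult(raw_p=p, adjusted_p=out)
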