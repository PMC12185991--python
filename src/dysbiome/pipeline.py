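"""End-to-end orchestration: (simulate | ingest) -> diversity -> differential
abundance -> Mann-Whitney pruning -> dysbiosis index -> association -> network.

All randomness flows from one root seed: stage ``k`` uses
``(root_seed * 1009 + k) % 2**31`` (documented splitting scheme), so an
identical config + seed yields a byte-identical run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import run_models
from .da import classify_directions, wald_test
from .diversity import alpha_diversity, bray_curtis_matrix, pcoa, permanova
from .dysbiosis import compute_dysbiosis, mwu_test
from .io_core import (
    AbundanceTable,
    prevalence_filter,
    read_abundance_table,
    read_metadata,
    to_counts,
    write_abundance_table,
)
from .association import derive_outcomes
from .simulate import SimConfig, generate_cohort

__all__ = ["RunReport", "default_config", "run_pipeline", "UndefinedIndexError"]

log = logging.getLogger(__name__)

_STAGE_SEEDS = {"simulate": 0, "permanova": 1, "network": 2}


class UndefinedIndexError(RuntimeError):
    """Both direction sets must be non-empty for the index to exist."""


def default_config() -> dict:
    return {
        "simulate": True,
        "seed": 0,
        "abundance": None,
        "metadata": None,
        "rank": "species",
        "sim": {},
        "count_depth": 100_000,
        "prevalence_min_fraction": 0.10,
        "da_alpha": 0.05,
        "prune_p_threshold": 0.10,
        "permanova_n_perm": 999,
        "permanova_covariates": ["smoking"],
        "network_top_n": 50,
        "network_rho_threshold": 0.5,
        "network_p_threshold": 0.05,
        "run_network": True,
        "run_airflow_models": True,
    }


def _stage_seed(root: int, stage: str) -> int:
    return int((root * 1009 + _STAGE_SEEDS[stage]) % 2**31)


@dataclass
class RunReport:
    config: dict
    seeds: dict
    stages: list = field(default_factory=list)
    alpha_diversity_p: dict = field(default_factory=dict)
    permanova: list = field(default_factory=list)
    da_summary: dict = field(default_factory=dict)
    sets_before_pruning: dict = field(default_factory=dict)
    sets_after_pruning: dict = field(default_factory=dict)
    pruning_p: dict = field(default_factory=dict)
    pseudocount: float | None = None
    associations: list = field(default_factory=list)
    network: dict = field(default_factory=dict)
    truth_recovery: dict | None = None
    status: str = "ok"
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if k not in base:
            raise ValueError(f"unknown config key {k!r}")
        out[k] = v
    return out


def run_pipeline(config: dict | None = None, outdir: str | Path | None = None) -> RunReport:
    """Run every stage in order; see module docstring for the seed scheme."""
    cfg = _merge(default_config(), config)
    root_seed = int(cfg["seed"])
    seeds = {s: _stage_seed(root_seed, s) for s in _STAGE_SEEDS}
    report = RunReport(config=cfg, seeds=seeds)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- ingest or simulate -------------------------------------------------
    truth = None
    if cfg["simulate"]:
        sim_cfg = SimConfig(**{**cfg["sim"], "seed": seeds["simulate"]})
        table, meta, truth = generate_cohort(sim_cfg)
    else:
        if not cfg["abundance"] or not cfg["metadata"]:
            raise ValueError("abundance and metadata paths required when simulate=false")
        table = read_abundance_table(cfg["abundance"], rank=cfg["rank"])
        meta = read_metadata(cfg["metadata"])
        meta = meta.loc[table.data.index]
    report.stages.append({"stage": "ingest", "n_samples": len(table.sample_ids),
                          "n_taxa": len(table.taxa)})
    log.info("stage=ingest n_samples=%d n_taxa=%d", len(table.sample_ids), len(table.taxa))

    outcomes = derive_outcomes(meta)
    rapid = outcomes["rapid_decline"]
    observed = rapid.notna()
    report.stages.append({
        "stage": "outcomes",
        "n_with_followup": int(observed.sum()),
        "n_rapid": int((rapid == True).sum()),  # noqa: E712 (nullable boolean)
        "n_airflow": int(outcomes["airflow_limitation"].sum()),
    })

    # restrict the case/control contrast to samples with a defined outcome
    sub = table.data.index[observed]
    table_obs = AbundanceTable(data=table.data.loc[sub], rank=table.rank)
    labels = rapid[observed].astype(bool)

    # --- diversity ----------------------------------------------------------
    alpha = alpha_diversity(table_obs)
    for metric in alpha.columns:
        res = mwu_test(alpha.loc[labels, metric], alpha.loc[~labels, metric])
        report.alpha_diversity_p[metric] = res.p_value
    dm = bray_curtis_matrix(table_obs)
    ordination = pcoa(dm, n_axes=2)
    perm = permanova(
        dm,
        labels.to_numpy(),
        covariates=meta.loc[sub, cfg["permanova_covariates"]]
        if cfg["permanova_covariates"] else None,
        n_perm=int(cfg["permanova_n_perm"]),
        seed=seeds["permanova"],
    )
    report.permanova = [dataclasses.asdict(r) for r in perm]
    log.info("stage=diversity n_samples=%d", len(sub))

    # --- differential abundance --------------------------------------------
    filtered = prevalence_filter(table_obs, cfg["prevalence_min_fraction"])
    counts = to_counts(filtered, cfg["count_depth"])
    da = wald_test(counts, labels.to_numpy(),
                   covariates=meta.loc[sub, ["smoking"]],
                   alpha=cfg["da_alpha"], case_level=True)
    sets = classify_directions(da, alpha=cfg["da_alpha"])
    report.stages.append({"stage": "da", "n_taxa_in": len(table_obs.taxa),
                          "n_taxa_tested": int(da["converged"].sum())})
    report.da_summary = {
        "n_tested": int(da["converged"].sum()),
        "n_significant": int((da["p_adjusted"] < cfg["da_alpha"]).sum()),
    }
    report.sets_before_pruning = {"increased": sorted(sets.increased),
                                  "decreased": sorted(sets.decreased)}
    log.info("stage=da n_tested=%d n_sig=%d", report.da_summary["n_tested"],
             report.da_summary["n_significant"])

    # --- pruning + index ----------------------------------------------------
    if not sets.increased or not sets.decreased:
        report.status = "undefined-index: a direction set is empty before pruning"
        _write_outputs(out, table, meta, alpha, dm, ordination, da, None, None)
        return report
    dys = compute_dysbiosis(table_obs, labels.to_numpy(), sets,
                            p_threshold=cfg["prune_p_threshold"])
    report.sets_after_pruning = {"increased": sorted(dys.increased),
                                 "decreased": sorted(dys.decreased)}
    report.pruning_p = dict(sorted(dys.pruning_p.items()))
    report.pseudocount = dys.pseudocount
    if not dys.increased or not dys.decreased:
        report.status = "undefined-index: a direction set is empty after pruning"
        _write_outputs(out, table, meta, alpha, dm, ordination, da, None, None)
        return report
    log.info("stage=index n_increased=%d n_decreased=%d",
             len(dys.increased), len(dys.decreased))

    # index over the FULL cohort (applied unchanged to airflow limitation)
    from .da import DirectionSets
    from .dysbiosis import dysbiosis_index

    full_index = dysbiosis_index(
        table, DirectionSets(dys.increased, dys.decreased, alpha=sets.alpha),
        pseudocount=dys.pseudocount,
    )

    # --- association --------------------------------------------------------
    assoc = run_models(full_index, meta, outcome="rapid")
    if cfg["run_airflow_models"]:
        assoc = pd.concat([assoc, run_models(full_index, meta, outcome="airflow")],
                          ignore_index=True)
    report.associations = assoc.to_dict(orient="records")
    log.info("stage=association n_models=%d", assoc["model"].nunique())

    # --- network ------------------------------------------------------------
    if cfg["run_network"]:
        from .network import cooccurrence_network

        da_taxa = sorted(dys.increased | dys.decreased)
        for name, mask in (("rapid", labels), ("normal", ~labels)):
            net = cooccurrence_network(
                table_obs, subset=table_obs.data.index[mask.to_numpy()],
                rho_threshold=cfg["network_rho_threshold"],
                p_threshold=cfg["network_p_threshold"],
                top_n=cfg["network_top_n"], extra_taxa=da_taxa,
            )
            report.network[name] = {"n_nodes": len(net.nodes),
                                    "n_edges": len(net.edges)}
            if out is not None:
                net.edges.to_csv(out / f"network_{name}_edges.tsv", sep="\t", index=False)
                net.write_graphml(out / f"network_{name}.graphml")

    # --- truth recovery (simulated cohorts only) ----------------------------
    if truth is not None and (truth.enriched_taxa or truth.depleted_taxa):
        planted = set(truth.enriched_taxa) | set(truth.depleted_taxa)
        recovered = (dys.increased & set(truth.enriched_taxa)) | (
            dys.decreased & set(truth.depleted_taxa))
        planted_lfc = da.loc[da.index.intersection(sorted(planted)), "log2_fc"]
        signs = pd.Series({**truth.enriched_taxa, **truth.depleted_taxa})
        aligned = (planted_lfc * np.sign(signs.loc[planted_lfc.index])).dropna()
        report.truth_recovery = {
            "n_planted": len(planted),
            "n_recovered": len(recovered),
            "mean_abs_log2fc_planted": float(aligned.mean()) if len(aligned) else None,
        }

    _write_outputs(out, table, meta, alpha, dm, ordination, da, dys, full_index)
    if out is not None:
        (out / "report.json").write_text(report.to_json())
    return report


def _write_outputs(out, table, meta, alpha, dm, ordination, da, dys, full_index):
    if out is None:
        return
    write_abundance_table(table, out / "abundance.tsv")
    meta.to_csv(out / "metadata.tsv", sep="\t", index_label="sample_id")
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    dm.data.to_csv(out / "bray_curtis.tsv", sep="\t")
    ordination.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
    da.to_csv(out / "differential_abundance.tsv", sep="\t")
    if dys is not None:
        idx = full_index.to_frame()
        idx.to_csv(out / "dysbiosis_index.tsv", sep="\t")
        record = {
            "increased": sorted(dys.increased),
            "decreased": sorted(dys.decreased),
            "pruning_p": dict(sorted(dys.pruning_p.items())),
            "pseudocount": dys.pseudocount,
        }
        (out / "dysbiosis_sets.json").write_text(json.dumps(record, indent=2))
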