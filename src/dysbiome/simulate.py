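"""Synthetic cohort generator.

Emulates the data structure of a metagenomic cohort study of people with HIV
in which gut species profiles at baseline are related to two spirometry
outcomes: rapid lung-function decline (FEV1 loss > 40 mL/year between two
visits) and airflow limitation (FEV1/FVC < 0.70 with FEV1 < 80% predicted).

Generative model
----------------
Per-taxon baseline intensities are log-normal with a heavy right tail
(across-taxa sigma ``base_sigma``); each sample perturbs every taxon by an
independent mean-one gamma factor (overdispersion ``bio_dispersion``; a
log-normal mode is available via ``noise``), giving realistic species-level
overdispersion. A per-sample *true dysbiosis index* is the log10 ratio of
summed planted-enriched over planted-depleted intensities before any outcome
effect is applied. Outcome labels are drawn from a logistic model on current
smoking (odds ratio ``smoking_or``) and the centred true index (log-odds
slope ``beta_index``), with the intercept solved so the realised prevalence
matches the configured target. Planted taxa are then multiplied by
``2**(+/-effect_log2fc)`` in cases, a configurable set of non-planted taxa is
shifted in current smokers (so smoking adjustment downstream is non-trivial),
compositions are renormalised, and reads are drawn multinomially at ``depth``
and expressed on a 0-100 percent scale. Spirometry and clinical covariates
are drawn consistently with the labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .io_core import AbundanceTable

__all__ = ["SimConfig", "SyntheticTruth", "generate_cohort", "generate_null_cohort"]


@dataclass(frozen=True)
class SimConfig:
    """Cohort-simulation parameters (defaults mirror the emulated study)."""

    n_samples: int = 350
    n_taxa: int = 400
    n_enriched: int = 6
    n_depleted: int = 2
    effect_log2fc: float = 1.0
    outcome_prevalence: float = 0.447
    airflow_prevalence: float = 0.10
    smoking_or: float = 1.5
    beta_index: float = math.log(1.2)  # log-odds of outcome per unit true index
    depth: int = 100_000
    seed: int = 0
    # distributional policy
    base_sigma: float = 2.0      # across-taxa spread of baseline log-intensity
    noise: str = "gamma"         # between-subject noise family: gamma | lognormal
    bio_dispersion: float = 1.0  # gamma-noise overdispersion (shape = 1/value)
    bio_sigma: float = 1.0       # lognormal-noise sd (used when noise="lognormal")
    n_smoking_taxa: int = 10
    smoking_taxa_log2fc: float = 1.0
    missing_followup_frac: float = 0.10
    smoking_probs: tuple[float, float, float] = (0.35, 0.41, 0.24)  # never/former/current
    planted_percentile_range: tuple[float, float] = (50.0, 90.0)

    def __post_init__(self) -> None:
        if not (0 < self.outcome_prevalence < 1 and 0 < self.airflow_prevalence < 1):
            raise ValueError("prevalences must lie in (0, 1)")
        if self.n_enriched + self.n_depleted > self.n_taxa:
            raise ValueError("planted taxa exceed n_taxa")
        if self.depth < 1 or self.n_samples < 2:
            raise ValueError("infeasible cohort size or depth")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with each simulated cohort."""

    enriched_taxa: dict[str, float]  # taxon -> log2 effect (> 0)
    depleted_taxa: dict[str, float]  # taxon -> log2 effect (< 0)
    beta_index: float
    confounder_effects: dict[str, float]
    seed: int
    smoking_taxa: list[str] = field(default_factory=list)
    true_index: pd.Series | None = None  # pre-planting per-sample index

    def __post_init__(self) -> None:
        if set(self.enriched_taxa) & set(self.depleted_taxa):
            raise ValueError("enriched and depleted sets overlap")
        if any(v <= 0 for v in self.enriched_taxa.values()):
            raise ValueError("enriched effects must be > 0")
        if any(v >= 0 for v in self.depleted_taxa.values()):
            raise ValueError("depleted effects must be < 0")


def _lineages(n_taxa: int, rng: np.random.Generator) -> list[str]:
    """Synthetic but structurally realistic pipe-delimited species lineages."""
    n_phyla, n_classes, n_orders, n_families, n_genera = 8, 16, 24, 40, 120
    cls_of = rng.integers(0, n_phyla, n_classes)
    ord_of = rng.integers(0, n_classes, n_orders)
    fam_of = rng.integers(0, n_orders, n_families)
    gen_of = rng.integers(0, n_families, n_genera)
    sp_gen = rng.integers(0, n_genera, n_taxa)
    out = []
    for s in range(n_taxa):
        g = sp_gen[s]
        f = gen_of[g]
        o = fam_of[f]
        c = ord_of[o]
        p = cls_of[c]
        out.append(
            f"k__Bacteria|p__Phylum{p:02d}|c__Class{c:02d}|o__Order{o:02d}"
            f"|f__Family{f:02d}|g__Genus{g:03d}|s__Genus{g:03d}_species{s:04d}"
        )
    return out


def _solve_intercept(offset: np.ndarray, target: float) -> float:
    """Intercept making mean(expit(b0 + offset)) equal the target prevalence."""
    f = lambda b0: expit(b0 + offset).mean() - target
    return brentq(f, -30.0, 30.0)


def generate_cohort(config: SimConfig) -> tuple[AbundanceTable, pd.DataFrame, SyntheticTruth]:
    """Simulate one cohort; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, t = cfg.n_samples, cfg.n_taxa

    taxa = _lineages(t, rng)
    sample_ids = [f"S{i:04d}" for i in range(n)]

    # (1) heavy-tailed per-taxon baselines + per-sample biological noise.
    # Gamma multiplicative noise (mean 1, shape 1/bio_dispersion) is the
    # default: it spans orders of magnitude between subjects while keeping
    # the marginal counts negative-binomial-compatible; a log-normal mode
    # with even heavier tails is available via config.
    base_log = rng.normal(0.0, cfg.base_sigma, size=t)
    if cfg.noise == "gamma":
        shape = 1.0 / cfg.bio_dispersion
        log_intensity = base_log[None, :] + np.log(
            rng.gamma(shape, 1.0 / shape, size=(n, t))
        )
    elif cfg.noise == "lognormal":
        log_intensity = base_log[None, :] + rng.normal(0.0, cfg.bio_sigma, size=(n, t))
    else:
        raise ValueError("noise must be 'gamma' or 'lognormal'")

    # planted taxa from a mid-to-high abundance window (detectable, not dominant)
    planting = cfg.effect_log2fc != 0 and (cfg.n_enriched + cfg.n_depleted) > 0
    order = np.argsort(base_log)
    lo, hi = cfg.planted_percentile_range
    eligible = order[int(lo / 100 * t): int(hi / 100 * t)]
    if planting:
        picked = rng.choice(eligible, size=cfg.n_enriched + cfg.n_depleted, replace=False)
        enriched_idx = picked[: cfg.n_enriched]
        depleted_idx = picked[cfg.n_enriched:]
    else:
        picked = np.array([], dtype=int)
        enriched_idx = depleted_idx = picked
    remaining = np.setdiff1d(eligible, picked)
    smoking_idx = (
        rng.choice(remaining, size=min(cfg.n_smoking_taxa, remaining.size), replace=False)
        if cfg.smoking_taxa_log2fc != 0 and cfg.n_smoking_taxa > 0
        else np.array([], dtype=int)
    )

    # (2) covariates drawn first so they can confound the outcome
    smoking = rng.choice(np.array(["never", "former", "current"]),
                         size=n, p=cfg.smoking_probs)
    current = (smoking == "current").astype(float)

    # true (pre-planting) dysbiosis index; defined only when taxa are planted
    if planting:
        inc = np.exp(log_intensity[:, enriched_idx]).sum(axis=1)
        dec = np.exp(log_intensity[:, depleted_idx]).sum(axis=1)
        true_index = np.log10(inc / dec)
    else:
        true_index = np.zeros(n)
    t_centred = true_index - true_index.mean()

    # (3) outcome labels: logistic in smoking + true index
    off_rapid = math.log(cfg.smoking_or) * current + cfg.beta_index * t_centred
    b0 = _solve_intercept(off_rapid, cfg.outcome_prevalence)
    rapid = rng.random(n) < expit(b0 + off_rapid)

    off_afl = math.log(cfg.smoking_or) * current + cfg.beta_index * t_centred
    c0 = _solve_intercept(off_afl, cfg.airflow_prevalence)
    airflow = rng.random(n) < expit(c0 + off_afl)

    # (4) planted case effects + smoking-driven taxa, renormalise, sequence
    shifted = log_intensity.copy()
    if planting:
        shifted[np.ix_(rapid, enriched_idx)] += cfg.effect_log2fc * math.log(2)
        shifted[np.ix_(rapid, depleted_idx)] -= cfg.effect_log2fc * math.log(2)
    if smoking_idx.size:
        shifted[np.ix_(current.astype(bool), smoking_idx)] += (
            cfg.smoking_taxa_log2fc * math.log(2)
        )
    intensity = np.exp(shifted - shifted.max(axis=1, keepdims=True))
    probs = intensity / intensity.sum(axis=1, keepdims=True)
    counts = rng.multinomial(cfg.depth, probs)
    percent = counts / cfg.depth * 100.0

    # (5) spirometry consistent with the labels
    fvc = rng.normal(4200, 700, n).clip(2200, 7000)
    ratio = np.where(airflow, rng.uniform(0.52, 0.695, n), rng.uniform(0.72, 0.88, n))
    fev1_base = fvc * ratio
    pct_pred = np.where(airflow, rng.uniform(45, 79.5, n), rng.uniform(81, 118, n))
    slope = np.where(rapid, rng.uniform(41, 120, n), rng.uniform(-20, 39.5, n))
    fu_years = rng.normal(2.3, 0.3, n).clip(0.8, 4.0)
    fev1_fu = fev1_base - slope * fu_years
    missing = rng.random(n) < cfg.missing_followup_frac
    fev1_fu = np.where(missing, np.nan, fev1_fu)
    fu_years = np.where(missing, np.nan, fu_years)

    # (6) remaining covariates (outcome-independent by design)
    meta = pd.DataFrame(
        {
            "fev1_baseline_ml": np.round(fev1_base, 1),
            "fev1_followup_ml": np.round(fev1_fu, 1),
            "fvc_baseline_ml": np.round(fvc, 1),
            "followup_years": np.round(fu_years, 3),
            "fev1_pct_predicted": np.round(pct_pred, 1),
            "smoking": smoking,
            "age": np.round(rng.normal(53.3, 10.8, n).clip(25, 85), 1),
            "sex": rng.choice(["male", "female"], n, p=[0.85, 0.15]),
            "bmi": np.round(rng.normal(24.7, 3.7, n).clip(15, 45), 1),
            "ethnicity": rng.choice(["caucasian", "other"], n, p=[0.88, 0.12]),
            "transmission_mode": rng.choice(
                ["msm", "heterosexual", "other"], n, p=[0.6, 0.3, 0.1]
            ),
            "nadir_cd4_lt200": rng.random(n) < 0.38,
            "hiv_duration": np.round(rng.normal(15.8, 9.2, n).clip(0.5, 45), 1),
            "cart_years": np.round(rng.normal(11.9, 6.6, n).clip(0.2, 35), 1),
            "il1b_pg_ml": np.round(rng.lognormal(-1.9, 0.8, n), 3),
            "il10_pg_ml": np.round(rng.lognormal(-0.6, 0.9, n), 3),
            "pneumonia_history": rng.random(n) < 0.38,
            "spiro_grade": rng.choice(
                list("ABCDEF"), n, p=[0.40, 0.28, 0.182, 0.08, 0.04, 0.018]
            ),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    table = AbundanceTable(
        data=pd.DataFrame(percent, index=meta.index, columns=taxa), rank="species"
    )
    truth = SyntheticTruth(
        enriched_taxa={taxa[i]: cfg.effect_log2fc for i in enriched_idx},
        depleted_taxa={taxa[i]: -cfg.effect_log2fc for i in depleted_idx},
        beta_index=cfg.beta_index if planting else 0.0,
        confounder_effects={"smoking_current": math.log(cfg.smoking_or)},
        seed=cfg.seed,
        smoking_taxa=[taxa[i] for i in smoking_idx],
        true_index=pd.Series(true_index, index=meta.index, name="true_index"),
    )
    return table, meta, truth


def generate_null_cohort(config: SimConfig) -> tuple[AbundanceTable, pd.DataFrame, SyntheticTruth]:
    """A cohort with every planted/confounder effect zeroed (type-I suites)."""
    null_cfg = replace(
        config,
        effect_log2fc=0.0,
        smoking_or=1.0,
        beta_index=0.0,
        smoking_taxa_log2fc=0.0,
    )
    return generate_cohort(null_cfg)
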