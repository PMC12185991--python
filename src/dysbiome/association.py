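"""Outcome derivation and multivariable logistic association models.

Outcomes follow the clinical definitions: *rapid lung-function decline* is an
FEV1 loss strictly greater than 40 mL/year between two spirometry visits
(undefined when follow-up is missing), and *airflow limitation* is
FEV1/FVC < 0.70 together with FEV1 below 80% of the predicted value.

The dysbiosis index enters multivariable logistic regressions untransformed
(per unit of log10 ratio). For the rapid-decline outcome, model 1 adjusts
for smoking plus traditional (age, sex, BMI, ethnicity) and HIV-related
(transmission mode, nadir CD4 < 200, HIV duration) risk factors; model 2
adds IL-1beta and IL-10. Sensitivity fits repeat model 1 on the
pneumonia-history-free subset and on the high-quality-spirometry (grade A-C)
subset. For the lower-prevalence airflow outcome, a family of parsimonious
fits each adjusts for age, BMI, and one additional covariate at a time.
Confidence intervals are 95% Wald intervals on the log-odds scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SeparationError",
    "LogisticFit",
    "derive_outcomes",
    "logistic_fit",
    "run_models",
    "MODEL1_COVARIATES",
    "MODEL2_EXTRA",
    "AIRFLOW_THIRD_COVARIATES",
]

log = logging.getLogger(__name__)

Z_95 = 1.96

MODEL1_COVARIATES = (
    "smoking", "age", "sex", "bmi", "ethnicity",
    "transmission_mode", "nadir_cd4_lt200", "hiv_duration",
)
MODEL2_EXTRA = ("il1b_pg_ml", "il10_pg_ml")
AIRFLOW_THIRD_COVARIATES = ("smoking", "hiv_duration", "cart_years")


class SeparationError(RuntimeError):
    """Raised when a logistic fit is perfectly (quasi-)separated."""


@dataclass
class LogisticFit:
    params: pd.Series
    se: pd.Series
    loglik: float
    n: int


def derive_outcomes(meta: pd.DataFrame) -> pd.DataFrame:
    """Derive outcome flags and the FEV1 slope from spirometry columns.

    Returns a frame with ``fev1_decline_ml_per_year`` (NaN without
    follow-up), nullable-boolean ``rapid_decline`` (strictly > 40 mL/year)
    and boolean ``airflow_limitation``.
    """
    has_fu = meta["fev1_followup_ml"].notna()
    yrs = meta["followup_years"]
    if ((yrs <= 0) & has_fu).any():
        bad = meta.index[(yrs <= 0) & has_fu][0]
        raise ValueError(f"sample {bad!r}: followup_years must be > 0")
    decline = (meta["fev1_baseline_ml"] - meta["fev1_followup_ml"]) / yrs
    rapid = pd.array(decline > 40.0, dtype="boolean")
    rapid[~has_fu.to_numpy()] = pd.NA
    ratio = meta["fev1_baseline_ml"] / meta["fvc_baseline_ml"]
    airflow = (ratio < 0.70) & (meta["fev1_pct_predicted"] < 80.0)
    return pd.DataFrame(
        {
            "fev1_decline_ml_per_year": decline,
            "rapid_decline": rapid,
            "airflow_limitation": airflow.astype(bool),
        },
        index=meta.index,
    )


def logistic_fit(y, X: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic regression (IRLS) with Wald SEs.

    ``X`` must not contain an intercept column; one is prepended. Raises
    :class:`SeparationError` naming the worst term under perfect separation
    and ``ValueError`` for rank-deficient designs.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary")
    if y.min() == y.max():
        raise ValueError("y has a single class")
    exog = sm.add_constant(X.astype(float), has_constant="add")
    if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.GLM(y, exog, family=sm.families.Binomial()).fit(
        maxiter=200, tol=1e-10
    )
    params = res.params
    if (~np.isfinite(params)).any() or np.abs(params).max() > 25.0:
        worst = params.abs().idxmax()
        raise SeparationError(f"perfect separation suspected (term {worst!r})")
    mu = res.fittedvalues
    if np.minimum(mu, 1 - mu).max() < 1e-8:
        raise SeparationError("perfect separation: fitted probabilities degenerate")
    return LogisticFit(params=params, se=res.bse, loglik=float(res.llf), n=len(y))


def _dummy_frame(meta: pd.DataFrame, columns) -> pd.DataFrame:
    """Numeric/boolean passthrough; categoricals dummy-coded with field refs."""
    parts = []
    for col in columns:
        s = meta[col]
        if pd.api.types.is_bool_dtype(s):
            parts.append(s.astype(float).rename(col))
        elif pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).rename(col))
        elif col == "smoking":
            cats = [c for c in ("never", "former", "current") if c in set(s.dropna())]
            d = pd.get_dummies(pd.Categorical(s, categories=cats), prefix="smoking",
                               drop_first=True).astype(float)
            d.index = meta.index
            parts.append(d)
        else:
            d = pd.get_dummies(s.astype("string"), prefix=col, drop_first=True).astype(float)
            parts.append(d)
    return pd.concat(parts, axis=1)


def _fit_one(model: str, y: pd.Series, design: pd.DataFrame) -> list[dict]:
    mask = design.notna().all(axis=1) & y.notna()
    n_dropped = int((~mask).sum())
    if n_dropped:
        log.info("%s: dropped %d samples with missing data", model, n_dropped)
    yy = y[mask].astype(float)
    xx = design.loc[mask]
    fit = logistic_fit(yy.to_numpy(), xx)
    rows = []
    for term in fit.params.index:
        if term == "const":
            continue
        coef = float(fit.params[term])
        se = float(fit.se[term])
        rows.append(
            {
                "model": model,
                "term": term,
                "coefficient": coef,
                "aOR": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - Z_95 * se)),
                "ci_high": float(np.exp(coef + Z_95 * se)),
                "p_value": float(2 * _norm_sf(abs(coef / se))),
                "n_used": fit.n,
            }
        )
    return rows


def _norm_sf(z: float) -> float:
    from scipy.stats import norm

    return float(norm.sf(z))


def run_models(index: pd.Series, meta: pd.DataFrame, outcome: str = "rapid") -> pd.DataFrame:
    """Fit the association model family for one outcome.

    ``outcome='rapid'``: model 1, model 2, and the pneumonia-free and
    high-spirometry-quality sensitivity refits of model 1.
    ``outcome='airflow'``: one fit per third covariate (index + age + BMI +
    third). Samples missing any required column are dropped per model, never
    imputed; ``n_used`` records the analysed n.
    """
    outcomes = derive_outcomes(meta)
    idx = index.reindex(meta.index).rename("index")
    rows: list[dict] = []
    if outcome == "rapid":
        y = outcomes["rapid_decline"].astype("Float64")
        base = pd.concat([idx, _dummy_frame(meta, MODEL1_COVARIATES)], axis=1)
        rows += _fit_one("model1", y, base)
        model2 = pd.concat([base, meta[list(MODEL2_EXTRA)].astype(float)], axis=1)
        rows += _fit_one("model2", y, model2)
        no_pneumonia = ~meta["pneumonia_history"].astype(bool)
        rows += _fit_one("sensitivity-pneumonia", y[no_pneumonia], base.loc[no_pneumonia])
        high_quality = meta["spiro_grade"].isin(["A", "B", "C"])
        rows += _fit_one("sensitivity-quality", y[high_quality], base.loc[high_quality])
    elif outcome == "airflow":
        y = outcomes["airflow_limitation"].astype("Float64")
        for third in AIRFLOW_THIRD_COVARIATES:
            design = pd.concat(
                [idx, _dummy_frame(meta, ("age", "bmi", third))], axis=1
            )
            rows += _fit_one(f"airflow+{third}", y, design)
    else:
        raise ValueError("outcome must be 'rapid' or 'airflow'")
    return pd.DataFrame(rows)
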