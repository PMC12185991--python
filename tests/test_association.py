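import numpy as np
import pandas as pd
import pytest

from dysbiome.association import (
    SeparationError,
    derive_outcomes,
    logistic_fit,
    run_models,
)


def _meta(**over):
    base = dict(
        fev1_baseline_ml=3000.0,
        fev1_followup_ml=2880.0,
        fvc_baseline_ml=4200.0,
        followup_years=2.3,
        fev1_pct_predicted=95.0,
    )
    base.update(over)
    return pd.DataFrame([base], index=["S1"])


class TestDeriveOutcomes:
    def test_decline_arithmetic_and_rapid_flag(self):
        out = derive_outcomes(_meta())
        assert out["fev1_decline_ml_per_year"].iloc[0] == pytest.approx(52.17, abs=0.01)
        assert out["rapid_decline"].iloc[0] == True  # noqa: E712

    def test_exactly_forty_is_not_rapid(self):
        out = derive_outcomes(_meta(fev1_followup_ml=3000.0 - 40.0 * 2.5,
                                    followup_years=2.5))
        assert out["fev1_decline_ml_per_year"].iloc[0] == pytest.approx(40.0)
        assert out["rapid_decline"].iloc[0] == False  # noqa: E712

    def test_airflow_requires_both_ratio_and_percent(self):
        m1 = _meta(fev1_baseline_ml=0.65 * 4200.0, fev1_pct_predicted=75.0)
        m2 = _meta(fev1_baseline_ml=0.65 * 4200.0, fev1_pct_predicted=85.0)
        assert derive_outcomes(m1)["airflow_limitation"].iloc[0]
        assert not derive_outcomes(m2)["airflow_limitation"].iloc[0]

    def test_missing_followup_gives_missing_rapid(self):
        out = derive_outcomes(_meta(fev1_followup_ml=np.nan, followup_years=np.nan))
        assert pd.isna(out["rapid_decline"].iloc[0])
        assert not pd.isna(out["airflow_limitation"].iloc[0])

    def test_nonpositive_followup_years_rejected(self):
        with pytest.raises(ValueError, match="followup_years"):
            derive_outcomes(_meta(followup_years=0.0))


def _grid_mle(y, x, span=6.0, steps=4):
    """Brute-force 2-parameter logistic MLE by iterative grid refinement."""
    def ll(b0, b1):
        eta = b0 + b1 * x
        return float(np.sum(y * eta - np.log1p(np.exp(eta))))

    c0 = c1 = 0.0
    width = span
    for _ in range(steps):
        g0 = np.linspace(c0 - width, c0 + width, 61)
        g1 = np.linspace(c1 - width, c1 + width, 61)
        vals = np.array([[ll(a, b) for b in g1] for a in g0])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        c0, c1 = g0[i], g1[j]
        width /= 12.0
    return c0, c1


class TestLogisticFit:
    def test_two_by_two_table_odds_ratio(self):
        # exposed: 30 cases / 10 controls; unexposed: 10 cases / 30 controls
        y = np.array([1] * 30 + [0] * 10 + [1] * 10 + [0] * 30)
        x = pd.DataFrame({"exposed": [1.0] * 40 + [0.0] * 40})
        fit = logistic_fit(y, x)
        assert fit.params["exposed"] == pytest.approx(np.log(9.0), abs=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        for n in (20, 30, 40):
            x = rng.normal(size=n)
            y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
            if y.min() == y.max():
                continue
            fit = logistic_fit(y, pd.DataFrame({"x": x}))
            b0, b1 = _grid_mle(y, x)
            assert fit.params["const"] == pytest.approx(b0, abs=1e-4)
            assert fit.params["x"] == pytest.approx(b1, abs=1e-4)

    def test_intercept_only_is_logit_of_mean(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        fit = logistic_fit(y, pd.DataFrame(index=range(10)))
        assert fit.params["const"] == pytest.approx(np.log(0.3 / 0.7), abs=1e-8)

    def test_affine_invariance_of_other_terms(self, rng):
        n = 200
        x1 = rng.normal(size=n)
        x2 = rng.normal(50, 10, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * x1 + 0.02 * (x2 - 50))))).astype(float)
        f1 = logistic_fit(y, pd.DataFrame({"a": x1, "b": x2}))
        f2 = logistic_fit(y, pd.DataFrame({"a": x1, "b": (x2 - 50) / 10}))
        assert f1.params["a"] == pytest.approx(f2.params["a"], abs=1e-8)
        assert f2.params["b"] == pytest.approx(f1.params["b"] * 10, abs=1e-8)

    def test_perfect_separation_raises(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        x = pd.DataFrame({"x": [0, 1, 2, 3, 10, 11, 12, 13.0]})
        with pytest.raises(SeparationError):
            logistic_fit(y, x)

    def test_rank_deficiency_rejected(self, rng):
        y = (rng.random(30) < 0.5).astype(float)
        x = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank"):
            logistic_fit(y, pd.DataFrame({"a": x, "b": 2 * x}))


class TestRunModels:
    def test_model_family_and_n_used(self, default_cohort):
        _, meta, truth = default_cohort
        res = run_models(truth.true_index, meta, outcome="rapid")
        models = set(res["model"])
        assert models == {"model1", "model2", "sensitivity-pneumonia",
                          "sensitivity-quality"}
        idx = res[res.term == "index"].set_index("model")
        n_obs = derive_outcomes(meta)["rapid_decline"].notna().sum()
        assert idx.loc["model1", "n_used"] == n_obs
        assert idx.loc["sensitivity-pneumonia", "n_used"] < n_obs
        # Wald CI geometry
        row = idx.loc["model1"]
        assert row["ci_low"] < row["aOR"] < row["ci_high"]
        assert row["aOR"] == pytest.approx(np.exp(row["coefficient"]), rel=1e-12)

    def test_airflow_family(self, default_cohort):
        _, meta, truth = default_cohort
        res = run_models(truth.true_index, meta, outcome="airflow")
        assert set(res["model"]) == {"airflow+smoking", "airflow+hiv_duration",
                                     "airflow+cart_years"}
        assert (res[res.term == "index"]["n_used"] == len(meta)).all()

    def test_missing_covariates_dropped_not_imputed(self, default_cohort):
        _, meta, truth = default_cohort
        meta = meta.copy()
        meta.loc[meta.index[:7], "bmi"] = np.nan
        res = run_models(truth.true_index, meta, outcome="rapid")
        idx = res[res.term == "index"].set_index("model")
        full = derive_outcomes(meta)["rapid_decline"].notna()
        dropped = (full & meta["bmi"].isna()).sum()
        assert idx.loc["model1", "n_used"] == full.sum() - dropped

    def test_null_cohort_ci_covers_one(self):
        from dysbiome import SimConfig, generate_null_cohort

        covered = 0
        for seed in range(20):
            table, meta, _ = generate_null_cohort(
                SimConfig(seed=seed, n_samples=200, n_taxa=30))
            rng = np.random.default_rng(seed)
            fake_index = pd.Series(rng.normal(size=len(meta)), index=meta.index)
            res = run_models(fake_index, meta, outcome="rapid")
            row = res[(res.model == "model1") & (res.term == "index")].iloc[0]
            covered += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert covered >= 16  # ~95% coverage; exact band in acceptance suite
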