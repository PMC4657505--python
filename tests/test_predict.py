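"""Logistic prediction models, LOO evaluation, AUC and deviance tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from cbmfrax.errors import (
    InvalidArgumentError,
    NotNestedError,
    UndefinedAUCError,
)
from cbmfrax.predict import (
    ModelSpec,
    compare_deviance,
    fit_fracture_model,
    loo_predict,
    roc_auc,
)

from conftest import planted_case_control


def logistic_data(n=400, beta=0.0, seed=0, outcome="binary_any"):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    eta = -1.0 + beta * x
    p = 1 / (1 + np.exp(-eta))
    frac = rng.random(n) < p
    kind = np.where(rng.random(n) < 0.5, "trochanteric", "neck")
    return pd.DataFrame({
        "age": rng.normal(74, 6, n), "height": rng.normal(174, 7, n),
        "site": rng.integers(0, 3, n), "img": x,
        "fracture_type": pd.Categorical(np.where(frac, kind, "none"),
                                        categories=["none", "trochanteric",
                                                    "neck"]),
    })


class TestRocAuc:
    def test_toy_pair_counting_value(self):
        """Concordant pairs (0.9,0.6) (0.9,0.2) (0.4,0.2) of 4 -> 3/4."""
        auc, _, _ = roc_auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0], n_boot=0)
        assert auc == 0.75

    def test_trapezoid_agrees_with_mann_whitney(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=200) + np.repeat([0.0, 0.8], 100)
        y = np.repeat([0, 1], 100)
        auc, _, _, curve = roc_auc(scores, y, n_boot=0, return_curve=True)
        trap = float(np.trapezoid(curve[:, 1], curve[:, 0]))
        assert auc == pytest.approx(trap, abs=1e-10)

    def test_perfect_separation_auc_one(self):
        auc, _, _ = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], n_boot=0)
        assert auc == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=300)
        y = (rng.random(300) < 0.3).astype(int)
        a1, _, _ = roc_auc(scores, y, n_boot=0)
        a2, _, _ = roc_auc(np.exp(3 * scores) + 5, y, n_boot=0)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(2)
        auc, lo, hi = roc_auc(rng.normal(size=500),
                              (rng.random(500) < 0.4).astype(int),
                              n_boot=500, seed=3)
        assert 0.45 <= auc <= 0.55
        assert lo <= auc <= hi

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([0.1, 0.2], [1, 1], n_boot=0)


class TestFitFractureModel:
    def test_separation_flagged(self):
        df = logistic_data(n=80, seed=4)
        df["img"] = (df["fracture_type"] != "none").astype(float)  # perfect
        fit = fit_fracture_model(df, ModelSpec("sep", imaging=("img",)))
        assert fit.separation_flag

    def test_symmetric_trichotomous_probabilities(self):
        rng = np.random.default_rng(5)
        n = 600
        df = pd.DataFrame({
            "age": rng.normal(74, 6, n), "height": rng.normal(174, 7, n),
            "site": rng.integers(0, 3, n),
            "fracture_type": pd.Categorical(
                rng.choice(["none", "trochanteric", "neck"], n),
                categories=["none", "trochanteric", "neck"])})
        fit = fit_fracture_model(df, ModelSpec("m", outcome="trichotomous"))
        probs = fit.predict_proba(df)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-10)
        assert np.allclose(probs.mean(axis=0), 1 / 3, atol=0.05)

    def test_per_sd_odds_ratio_recovery(self):
        """Median per-SD OR across replicates near the generative e^1."""
        ors = []
        for rep in range(40):
            df = logistic_data(n=2000, beta=1.0, seed=100 + rep)
            fit = fit_fracture_model(df, ModelSpec("m+img", imaging=("img",)))
            row = fit.odds_ratios.query("variable == 'img'").iloc[0]
            ors.append(1.0 / row["odds_ratio"])  # reported per SD decrease
        assert 2.5 <= float(np.median(ors)) <= 3.0

    def test_reporting_only_patches_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ModelSpec("bad", imaging=("cth_troch_patch",))
        spec = ModelSpec("ok", imaging=("cth_troch_patch",),
                         allow_reporting_variables=True)
        assert spec.cbm_columns == ("cth_troch_patch",)

    def test_deviance_is_minus_two_loglik(self):
        df = logistic_data(n=300, beta=0.8, seed=6)
        fit = fit_fracture_model(df, ModelSpec("m+img", imaging=("img",)))
        assert fit.deviance == pytest.approx(-2 * fit.llf)
        assert fit.deviance >= 0


class TestLooPredict:
    def test_every_subject_predicted_out_of_fold(self):
        df = logistic_data(n=60, beta=1.0, seed=7)
        res = loo_predict(df, ModelSpec("m+img", imaging=("img",)))
        assert res.probabilities.shape == (60, 2)
        assert np.all((res.probabilities >= 0) & (res.probabilities <= 1))
        assert np.allclose(res.probabilities.sum(axis=1), 1.0)

    def test_spm_rerun_count_equals_n(self, mesh_1000):
        """Patch discovery runs once per left-out subject."""
        subjects, Y = planted_case_control(mesh_1000, n=60, n_cases=20,
                                           effect=-0.10, seed=70)
        spec = ModelSpec("m+CBM", imaging=("cm_troch_patch",),
                         outcome="binary_any")
        res = loo_predict(subjects, spec, fields={"CM": Y}, mesh=mesh_1000,
                          rederive_patches=True,
                          spm_settings={"n_perm": 500, "seed": 1}, seed=2)
        assert res.n_spm_runs == 60
        assert len(res.fold_provenance) == 60

    def test_loo_auc_not_optimistic(self):
        """Cross-validated AUC does not exceed in-sample AUC on average."""
        gaps = []
        for rep in range(15):
            df = logistic_data(n=120, beta=0.7, seed=200 + rep)
            spec = ModelSpec("m+img", imaging=("img",))
            res = loo_predict(df, spec)
            fit = fit_fracture_model(df, spec)
            y = (df["fracture_type"] != "none").astype(int)
            in_auc, _, _ = roc_auc(fit.predict_proba(df)[:, 1], y, n_boot=0)
            out_auc, _, _ = roc_auc(res.probabilities[:, 1], y, n_boot=0)
            gaps.append(in_auc - out_auc)
        assert np.mean(gaps) >= 0.0

    def test_too_small_sample_rejected(self):
        df = logistic_data(n=20, seed=8)
        with pytest.raises(InvalidArgumentError):
            loo_predict(df, ModelSpec("m"))


class TestCompareDeviance:
    def test_identical_specs_zero_statistic(self):
        df = logistic_data(n=200, beta=0.5, seed=9)
        f1 = fit_fracture_model(df, ModelSpec("m"))
        f2 = fit_fracture_model(df, ModelSpec("m"))
        stat, dof, p = compare_deviance(f1, f2)
        assert stat == 0.0 and p == 1.0

    def test_disjoint_additions_not_nested(self):
        df = logistic_data(n=200, seed=10)
        fa = fit_fracture_model(df, ModelSpec("m+A", imaging=("img",)))
        df["img2"] = df["img"] + 1
        fb = fit_fracture_model(df, ModelSpec("m+B", imaging=("img2",)))
        with pytest.raises(NotNestedError):
            compare_deviance(fa, fb)

    def test_null_statistic_distribution(self):
        """Adding k pure-noise covariates: deviance drop ~ chi-squared_k."""
        stats = []
        for rep in range(150):
            rng = np.random.default_rng(300 + rep)
            df = logistic_data(n=300, beta=0.0, seed=300 + rep)
            df["noise1"] = rng.normal(size=300)
            df["noise2"] = rng.normal(size=300)
            small = fit_fracture_model(df, ModelSpec("m"))
            large = fit_fracture_model(
                df, ModelSpec("m+noise", imaging=("noise1", "noise2")))
            stats.append(small.deviance - large.deviance)
        assert kstest(stats, "chi2", args=(2,)).pvalue > 0.01
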