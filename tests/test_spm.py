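"""Surface statistical parametric mapping: calibration and patch recovery."""

import numpy as np
import pandas as pd
import pytest

from cbmfrax.errors import (
    EmptyPatchError,
    InvalidArgumentError,
    InvalidDesignError,
)
from cbmfrax import synth
from cbmfrax.spm import (
    PatchDefinition,
    SpmDesign,
    build_cluster_mass_null,
    build_design_matrix,
    extract_significant_patches,
    fit_vertex_glm,
    patch_average,
)

from conftest import planted_case_control


class TestVertexGlm:
    def test_null_raw_p_calibrated(self, mesh_1000):
        """Random labels: ~5% of vertices reach raw p<0.05."""
        subjects, Y = planted_case_control(mesh_1000, n=300, n_cases=75,
                                           effect=0.0, seed=40)
        res = fit_vertex_glm(Y, subjects, SpmDesign("CM"))
        frac = (res.raw_p["trochanteric_vs_cohort"] < 0.05).mean()
        assert frac == pytest.approx(0.05, abs=0.02)

    def test_planted_deficit_concentrates_t(self, mesh_1000):
        subjects, Y = planted_case_control(mesh_1000, n=400, n_cases=100,
                                           effect=-0.10, seed=41)
        res = fit_vertex_glm(Y, subjects, SpmDesign("CM"))
        mask = mesh_1000.region_mask("trochanter_superolateral")
        t = np.abs(res.tstat["trochanteric_vs_cohort"])
        assert t[mask].mean() > 3 * t[~mask].mean()

    def test_confounder_fully_absorbs_response(self, mesh_1000):
        """Response exactly linear in age: fracture t is identically zero."""
        subjects, _ = planted_case_control(mesh_1000, n=200, n_cases=50,
                                           effect=0.0, seed=42)
        age = subjects["age"].to_numpy()
        Y = np.outer(2.0 + 0.05 * age, np.ones(mesh_1000.n_vertices))
        res = fit_vertex_glm(Y, subjects, SpmDesign("CM"))
        assert np.max(np.abs(res.tstat["trochanteric_vs_cohort"])) < 0.5
        assert np.max(np.abs(res.tstat["neck_vs_cohort"])) < 0.5

    def test_rank_deficient_design_names_columns(self, mesh_1000):
        subjects, Y = planted_case_control(mesh_1000, n=100, n_cases=20,
                                           effect=0.0, seed=43)
        subjects["shape2"] = subjects["shape1"]  # force collinearity
        with pytest.raises(InvalidDesignError) as err:
            fit_vertex_glm(Y, subjects, SpmDesign("CM"))
        assert any("shape" in c for c in err.value.columns)

    def test_effect_pct_matches_planted_magnitude(self, mesh_1000):
        subjects, Y = planted_case_control(mesh_1000, n=400, n_cases=100,
                                           effect=-0.10, seed=44)
        res = fit_vertex_glm(Y, subjects, SpmDesign("CM"))
        mask = mesh_1000.region_mask("trochanter_superolateral")
        mean_pct = np.nanmean(res.effect_pct["trochanteric_vs_cohort"][mask])
        assert mean_pct == pytest.approx(-10.0, abs=3.0)

    def test_design_matrix_contents(self, mesh_1000):
        subjects, _ = planted_case_control(mesh_1000, n=60, n_cases=15,
                                           effect=0.0, seed=45)
        X, names, frac_cols = build_design_matrix(subjects, SpmDesign("CM"))
        assert names[0] == "intercept"
        assert {"fracture[trochanteric]", "fracture[neck]"} <= set(names)
        ft = subjects["fracture_type"].astype(str)
        jt = frac_cols["trochanteric_vs_cohort"]
        assert np.array_equal(X[:, jt], (ft == "trochanteric").astype(float))


class TestPatchExtraction:
    def test_planted_patch_recovery_dice(self, mesh_1000):
        """Median Dice over replicates between the recovered patch and the
        planted deficit region."""
        dices = []
        for rep in range(5):
            subjects, Y = planted_case_control(mesh_1000, n=400, n_cases=100,
                                               effect=-0.10, seed=50 + rep)
            res = fit_vertex_glm(Y, subjects, SpmDesign("CM"))
            null = build_cluster_mass_null(res, mesh_1000, 500, seed=rep)
            patch = extract_significant_patches(
                res, mesh_1000, "trochanteric_vs_cohort", null_masses=null)
            planted = np.flatnonzero(
                mesh_1000.region_mask("trochanter_superolateral"))
            inter = len(np.intersect1d(patch.vertices, planted))
            dices.append(2 * inter / (len(patch.vertices) + len(planted)))
        assert np.median(dices) >= 0.5

    def test_union_of_disjoint_clusters(self, mesh_1000):
        """Deficits planted in two non-adjacent regions are united."""
        subjects, Y = planted_case_control(mesh_1000, n=400, n_cases=100,
                                           effect=-0.10, seed=60)
        Y = synth.plant_group_deficit(
            Y, subjects["fracture_type"].astype(str) == "trochanteric",
            mesh_1000.region_mask("head"), -0.10)
        res = fit_vertex_glm(Y, subjects, SpmDesign("CM"))
        null = build_cluster_mass_null(res, mesh_1000, 500, seed=3)
        patch = extract_significant_patches(
            res, mesh_1000, "trochanteric_vs_cohort", null_masses=null)
        assert patch.n_clusters >= 2
        troch = mesh_1000.region_mask("trochanter_superolateral")
        head = mesh_1000.region_mask("head")
        assert np.intersect1d(patch.vertices, np.flatnonzero(troch)).size > 0
        assert np.intersect1d(patch.vertices, np.flatnonzero(head)).size > 0

    def test_null_data_falls_back_flagged(self, mesh_1000):
        subjects, Y = planted_case_control(mesh_1000, n=300, n_cases=75,
                                           effect=0.0, seed=61)
        res = fit_vertex_glm(Y, subjects, SpmDesign("CM"))
        null = build_cluster_mass_null(res, mesh_1000, 500, seed=4)
        patch = extract_significant_patches(
            res, mesh_1000, "neck_vs_cohort", null_masses=null)
        assert patch.fallback in ("uncorrected", "top_fraction")
        assert not patch.empty  # never silently empty

    def test_small_n_perm_rejected_without_precomputed_null(self, mesh_1000):
        subjects, Y = planted_case_control(mesh_1000, n=300, n_cases=75,
                                           effect=0.0, seed=62)
        res = fit_vertex_glm(Y, subjects, SpmDesign("CM"))
        with pytest.raises(InvalidArgumentError):
            extract_significant_patches(res, mesh_1000,
                                        "trochanteric_vs_cohort", n_perm=100)

    def test_bonferroni_crosscheck_recovers_planted(self, mesh_1000):
        subjects, Y = planted_case_control(mesh_1000, n=400, n_cases=100,
                                           effect=-0.10, seed=63)
        res = fit_vertex_glm(Y, subjects, SpmDesign("CM"))
        patch = extract_significant_patches(
            res, mesh_1000, "trochanteric_vs_cohort", method="bonferroni")
        planted = mesh_1000.region_mask("trochanter_superolateral")
        inside = np.isin(patch.vertices, np.flatnonzero(planted)).mean()
        assert inside > 0.8


class TestPatchAverage:
    def test_uniform_field(self):
        patch = PatchDefinition("CM", "trochanteric_vs_cohort",
                                np.array([0, 3, 5]))
        assert patch_average(np.full(10, 7.0), patch) == 7.0

    def test_two_vertex_mean(self):
        patch = PatchDefinition("CM", "neck_vs_cohort", np.array([1, 2]))
        vals = np.array([9.0, 1.0, 3.0, 9.0])
        assert patch_average(vals, patch) == 2.0

    def test_stacked_fields(self):
        patch = PatchDefinition("CM", "neck_vs_cohort", np.array([0, 1]))
        out = patch_average(np.array([[1.0, 3.0, 9.0], [2.0, 4.0, 9.0]]), patch)
        assert np.array_equal(out, [2.0, 3.0])

    def test_empty_patch_raises(self):
        patch = PatchDefinition("CM", "neck_vs_cohort", np.array([], dtype=int))
        with pytest.raises(EmptyPatchError):
            patch_average(np.ones(5), patch)
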