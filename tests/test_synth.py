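"""Synthetic cohort generator: planted structure and sampling invariants."""

import numpy as np
import pytest
from scipy.stats import binomtest

from cbmfrax.errors import InvalidArgumentError
from cbmfrax.mesh import make_canonical_mesh
from cbmfrax.profiles import fit_profile
from cbmfrax import synth


def zero_noise_spec(**overrides):
    base = dict(
        effect_fraction={"CTh": 0.0, "CBMD": 0.0, "ECTD": 0.0},
        spatial_noise_sd={"CTh": 0.0, "CBMD": 0.0, "ECTD": 0.0},
        subject_sd=0.0, age_slope=0.0, weight_slope=0.0,
        site_offset_sd=0.0, side_noise_sd=0.0,
    )
    base.update(overrides)
    return synth.TrueEffectSpec(**base)


class TestSimulatePopulation:
    def test_empty_population(self, mesh_small):
        pop = synth.simulate_population(mesh_small, 0, seed=0)
        assert pop.n == 0 and len(pop.subjects) == 0

    def test_zero_noise_fields_equal_baseline(self, mesh_small):
        pop = synth.simulate_population(mesh_small, 5, spec=zero_noise_spec(),
                                        seed=1)
        for var in ("CTh", "CBMD", "ECTD", "CM"):
            assert np.allclose(pop.truth[var], pop.baseline[var][None, :])
            assert np.allclose(pop.fields["left"][var],
                               pop.baseline[var][None, :])

    def test_cm_identity_every_vertex_every_side(self, mesh_small):
        pop = synth.simulate_population(mesh_small, 40, seed=2)
        for side in ("left", "right"):
            f = pop.fields[side]
            assert np.allclose(f["CM"], 0.1 * f["CTh"] * f["CBMD"], rtol=1e-12)

    def test_decile_contrast_matches_planted_deficit(self, mesh_small):
        """Planted -10% CM deficit appears as ~10% between risk deciles.

        risk_correlation=0 isolates the regional deficit from the global
        bone-quality factor, so the top/bottom risk deciles differ only by
        the planted effect plus averaging noise."""
        spec = synth.TrueEffectSpec(risk_correlation=0.0)
        pop = synth.simulate_population(mesh_small, 500, spec=spec, seed=3)
        mask = mesh_small.region_mask("trochanter_superolateral")
        cm = pop.truth["CM"][:, mask].mean(axis=1)
        rho = pop.subjects["risk_troch"].to_numpy()
        lo, hi = np.quantile(rho, [0.1, 0.9])
        contrast = 1.0 - cm[rho >= hi].mean() / cm[rho <= lo].mean()
        assert contrast == pytest.approx(0.10, abs=0.02)

    def test_covariate_means_within_three_se(self):
        mesh = make_canonical_mesh(150, seed=0)
        spec = synth.TrueEffectSpec()
        pop = synth.simulate_population(mesh, 5000, spec=spec, seed=4)
        s = pop.subjects
        # truncated-normal age mean: mu + sd * phi(a)/(1-Phi(a))
        from scipy.stats import truncnorm

        a = (spec.age_min - spec.age_mean) / spec.age_sd
        age_mean = truncnorm.mean(a, np.inf, loc=spec.age_mean, scale=spec.age_sd)
        assert abs(s["age"].mean() - age_mean) < 3 * s["age"].std() / np.sqrt(5000)
        assert abs(s["weight"].mean() - spec.weight_mean) < 3 * spec.weight_sd / np.sqrt(5000)
        assert abs(s["height"].mean() - spec.height_mean) < 3 * spec.height_sd / np.sqrt(5000)

    def test_reproducible_and_seed_sensitive(self, mesh_small):
        a = synth.simulate_population(mesh_small, 30, seed=5)
        b = synth.simulate_population(mesh_small, 30, seed=5)
        c = synth.simulate_population(mesh_small, 30, seed=6)
        assert np.array_equal(a.truth["CTh"], b.truth["CTh"])
        assert a.subjects.equals(b.subjects)
        assert not np.array_equal(a.truth["CTh"], c.truth["CTh"])

    def test_bmd_surrogates_track_surface_means(self, mesh_small):
        pop = synth.simulate_population(mesh_small, 400, seed=7)
        m_cm = pop.truth["CM"].mean(axis=1)
        r = np.corrcoef(m_cm, pop.subjects["bmd_dxa_like"])[0, 1]
        assert r > 0.7  # noisy monotone surrogate


class TestFractureOutcomes:
    def test_symmetric_rates_split_evenly(self, mesh_small):
        """No covariate effects, equal baseline rates: competing exponential
        processes give each type probability 1/2 among fractured subjects."""
        pop = synth.simulate_population(mesh_small, 2000,
                                        spec=zero_noise_spec(), seed=8)
        hz = synth.HazardSpec(lambda_troch=0.02, lambda_neck=0.02,
                              beta_cm=0.0, beta_ectd=0.0, beta_age=0.0)
        pop = synth.simulate_fracture_outcomes(pop, hz, seed=9)
        ft = pop.subjects["fracture_type"].astype(str)
        n_troch = int((ft == "trochanteric").sum())
        n_frac = int((ft != "none").sum())
        assert n_frac > 200
        assert binomtest(n_troch, n_frac, 0.5).pvalue > 0.01

    def test_zero_rates_all_censored(self, mesh_small):
        pop = synth.simulate_population(mesh_small, 50, seed=10)
        hz = synth.HazardSpec(lambda_troch=0.0, lambda_neck=0.0)
        pop = synth.simulate_fracture_outcomes(pop, hz, horizon=10.0, seed=11)
        assert pop.subjects["censored"].all()
        assert (pop.subjects["event_time"] == 10.0).all()

    def test_negative_rate_rejected(self, mesh_small):
        pop = synth.simulate_population(mesh_small, 10, seed=0)
        with pytest.raises(InvalidArgumentError):
            synth.simulate_fracture_outcomes(
                pop, synth.HazardSpec(lambda_troch=-0.1), seed=0)

    def test_low_bone_means_higher_hazard(self, outcome_population):
        """Negative coefficients: neck-fracture cases have lower superior-neck
        ECTD than censored subjects."""
        pop = outcome_population
        mask = pop.mesh.region_mask("neck_superior")
        ectd = pop.truth["ECTD"][:, mask].mean(axis=1)
        ft = pop.subjects["fracture_type"].astype(str)
        assert ectd[ft == "neck"].mean() < ectd[ft == "none"].mean()


class TestCaseCohort:
    def test_alpha_one_takes_everyone(self, outcome_population):
        cc = synth.draw_case_cohort(outcome_population, 1.0, seed=1)
        assert cc.n_subcohort == outcome_population.n
        assert (cc.table["weight"] == 1.0).all()

    def test_no_fractures_gives_zero_cases(self, mesh_small):
        pop = synth.simulate_population(mesh_small, 60, seed=12)
        pop = synth.simulate_fracture_outcomes(
            pop, synth.HazardSpec(lambda_troch=0.0, lambda_neck=0.0), seed=13)
        cc = synth.draw_case_cohort(pop, 0.25, seed=14)
        assert cc.n_cases == 0 and cc.n_subcohort == 15

    def test_cases_unique_and_overlap_allowed(self, outcome_population):
        cc = synth.draw_case_cohort(outcome_population, 0.2, seed=15)
        t = cc.table
        assert t["id"].is_unique
        ft = outcome_population.subjects["fracture_type"].astype(str)
        assert (t["is_case"].to_numpy() == (ft != "none").to_numpy()).all()
        assert (t["is_case"] & t["in_subcohort"]).any()  # overlap permitted

    def test_invalid_alpha_rejected(self, outcome_population):
        for alpha in (0.0, -0.1, 1.2):
            with pytest.raises(InvalidArgumentError):
                synth.draw_case_cohort(outcome_population, alpha, seed=0)

    def test_subcohort_membership_probability(self, mesh_small):
        """P(subject in subcohort) equals alpha over repeated draws."""
        pop = synth.simulate_population(mesh_small, 200, seed=16)
        pop = synth.simulate_fracture_outcomes(pop, seed=17)
        alpha = 0.15
        hits = 0
        for k in range(500):
            cc = synth.draw_case_cohort(pop, alpha, seed=1000 + k)
            hits += bool(cc.table.loc[cc.table["id"] == 7,
                                      "in_subcohort"].iloc[0])
        assert binomtest(hits, 500, alpha).pvalue > 0.01


class TestRepeatScans:
    def test_zero_error_reproduces_truth(self, mesh_small):
        pop = synth.simulate_population(mesh_small, 30, seed=18)
        scans = synth.simulate_repeat_scans(pop, {"CTh": 0.0}, n_pairs=5,
                                            seed=19)
        s1, s2 = scans["CTh"]
        assert np.array_equal(s1, s2)
        assert np.array_equal(s1, pop.truth["CTh"][scans["ids"]])

    def test_same_seed_identical_pairs(self, mesh_small):
        pop = synth.simulate_population(mesh_small, 30, seed=20)
        a = synth.simulate_repeat_scans(pop, {"CTh": 0.1}, n_pairs=5, seed=21)
        b = synth.simulate_repeat_scans(pop, {"CTh": 0.1}, n_pairs=5, seed=21)
        assert np.array_equal(a["CTh"][0], b["CTh"][0])
        assert np.array_equal(a["ids"], b["ids"])

    def test_negative_sd_rejected(self, mesh_small):
        pop = synth.simulate_population(mesh_small, 30, seed=22)
        with pytest.raises(InvalidArgumentError):
            synth.simulate_repeat_scans(pop, {"CTh": -1.0}, n_pairs=5, seed=0)


class TestRenderProfiles:
    def test_noiseless_unquantized_matches_model(self):
        from cbmfrax.profiles import ProfileParams, model_profile

        grid = np.arange(-6, 10.01, 0.5)
        ps = synth.render_profiles(np.array([2.0]), np.array([1100.0]),
                                   np.array([170.0]), sigma_blur=1.0,
                                   grid=grid, quantization=0.0, seed=0)
        expected = model_profile(
            ProfileParams(30.0, 1100.0, 170.0, 0.0, 2.0, 1.0), grid)
        assert np.allclose(ps.intensities[0], expected, rtol=1e-12)

    def test_zero_thickness_is_single_step(self):
        """CTh=0 collapses to one blurred step soft-tissue -> trabecular."""
        from scipy.special import ndtr

        grid = np.arange(-6, 10.01, 0.5)
        ps = synth.render_profiles(np.array([0.0]), np.array([1100.0]),
                                   np.array([170.0]), sigma_blur=1.5,
                                   grid=grid, quantization=0.0, seed=0)
        step = 30.0 + (170.0 - 30.0) * ndtr(grid / 1.5)
        assert np.allclose(ps.intensities[0], step, rtol=1e-12)

    def test_fit_roundtrip_on_rendered_profile(self):
        ps = synth.render_profiles(np.array([3.0]), np.array([1100.0]),
                                   np.array([170.0]), sigma_blur=1.0,
                                   quantization=0.0, seed=0)
        _, m = fit_profile(ps.profile(0), mode="free")
        assert m.cth == pytest.approx(3.0, rel=0.01)

    def test_grid_must_cover_blur_support(self):
        with pytest.raises(InvalidArgumentError):
            synth.render_profiles(np.array([2.0]), np.array([1100.0]),
                                  np.array([170.0]), sigma_blur=1.5,
                                  grid=np.arange(-1.0, 3.0, 0.5), seed=0)
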