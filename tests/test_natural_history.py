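"""Disease onset, progression, diagnosis, and PSA observation models."""

import numpy as np
import pytest
from scipy.linalg import expm

from prostasim.natural_history import (
    ConfigError,
    NaturalHistoryParams,
    VariantFParams,
    VariantPParams,
    psa_at_state_P,
    psa_level,
    psa_level_F,
    sample_disease_course_F,
    sample_disease_course_P,
    simulate_courses,
)
from prostasim.synthetic_data import default_nh_params


def onset_at(age, width=0.002):
    """Onset hazard concentrated just after ``age`` (effectively a point mass)."""
    return dict(
        onset_edges=np.array([35.0, age, age + width, 120.0]) if age > 35 else np.array([35.0, 35.0 + width, 120.0]),
        onset_hazard=np.array([0.0, 5000.0, 0.0]) if age > 35 else np.array([5000.0, 0.0]),
    )


def variant_p_overrides(**kw):
    base = default_nh_params("P").variant_p.__dict__.copy()
    base.update(kw)
    return VariantPParams(**base)


def variant_f_overrides(**kw):
    base = default_nh_params("F").variant_f.__dict__.copy()
    base.update(kw)
    return VariantFParams(**base)


class TestOnset:
    def test_zero_hazard_means_no_onset(self):
        params = NaturalHistoryParams(
            onset_edges=[35.0, 120.0], onset_hazard=[0.0], variant_p=default_nh_params("P").variant_p
        )
        c = simulate_courses(params, "P", 100_000, np.random.default_rng(0))
        assert not np.isfinite(c.onset_age).any()

    def test_missing_variant_block_rejected(self):
        params = NaturalHistoryParams(onset_edges=[35.0, 120.0], onset_hazard=[0.01])
        with pytest.raises(ConfigError):
            simulate_courses(params, "P", 10, np.random.default_rng(0))
        with pytest.raises(ConfigError):
            simulate_courses(params, "F", 10, np.random.default_rng(0))


class TestVariantP:
    def test_single_state_diagnosis_time_is_exponential(self):
        # no competing transitions, dx rate 0.1/yr from onset at 35
        vp = variant_p_overrides(
            stage_rates=np.zeros(3), grade_rates=np.zeros(2), dx_rate=np.full((4, 3), 0.1)
        )
        params = NaturalHistoryParams(variant_p=vp, **onset_at(35))
        n = 100_000
        c = simulate_courses(params, "P", n, np.random.default_rng(1))
        delay = c.cdx_age[np.isfinite(c.cdx_age)] - c.onset_age[np.isfinite(c.cdx_age)]
        lam, T = 0.1, 65.0  # lives capped at age 100 => censoring horizon
        mean_trunc = 1 / lam - T * np.exp(-lam * T) / (1 - np.exp(-lam * T))
        assert abs(delay.mean() - mean_trunc) < 3 * (1 / lam) / np.sqrt(n)

    def test_grade_and_stage_paths_are_monotone(self):
        params = default_nh_params("P")
        c = simulate_courses(params, "P", 50_000, np.random.default_rng(2))
        fin = np.isfinite
        assert np.all(c.g7_age[fin(c.g8_age)] <= c.g8_age[fin(c.g8_age)])
        assert np.all(c.t2_age[fin(c.t3_age)] <= c.t3_age[fin(c.t3_age)])
        assert np.all(c.t3_age[fin(c.met_age)] <= c.met_age[fin(c.met_age)])
        # no event precedes onset
        for t in (c.g7_age, c.g8_age, c.t2_age, c.t3_age, c.met_age, c.cdx_age):
            assert np.all(t[fin(t)] >= c.onset_age[fin(t)] - 1e-9)

    def test_occupancy_solves_kolmogorov_forward_equations(self):
        """Empirical state occupancy matches the matrix-exponential solution."""
        params = default_nh_params("P")
        vp = params.variant_p
        params = NaturalHistoryParams(variant_p=vp, **onset_at(35))
        n = 100_000
        c = simulate_courses(params, "P", n, np.random.default_rng(3))

        # generator over states (stage, grade) + absorbing diagnosis
        idx = lambda s, g: 3 * s + g
        Q = np.zeros((13, 13))
        for s in range(4):
            for g in range(3):
                i = idx(s, g)
                if s < 3:
                    Q[i, idx(s + 1, g)] += vp.stage_rates[s]
                if g < 2:
                    Q[i, idx(s, g + 1)] += vp.grade_rates[g]
                Q[i, 12] += vp.dx_rate[s, g]
                Q[i, i] = -Q[i].sum()
        p0 = np.zeros(13)
        p0[[idx(0, g) for g in range(3)]] = vp.init_grade_probs
        t = 10.0  # ages 35-45 sit in one dx-multiplier band: homogeneous chain
        p_t = p0 @ expm(Q * t)

        age = c.onset_age + t
        undiag = c.cdx_age > age
        occ = np.zeros(13)
        stage = c.stage_at(age)
        grade = c.grade_at(age)
        for s in range(4):
            for g in range(3):
                occ[idx(s, g)] = (undiag & (stage == s) & (grade == g)).mean()
        occ[12] = (~undiag).mean()
        se = np.sqrt(p_t * (1 - p_t) / n)
        assert np.all(np.abs(occ - p_t) <= 3 * se + 1e-4)


class TestVariantF:
    def test_zero_link_coefficients_mean_no_diagnosis_or_metastasis(self):
        vf = variant_f_overrides(dx_coef=0.0, met_coef=0.0)
        params = NaturalHistoryParams(variant_f=vf, **onset_at(35))
        c = simulate_courses(params, "F", 50_000, np.random.default_rng(4))
        assert not np.isfinite(c.cdx_age).any()
        assert not np.isfinite(c.met_age).any()

    def test_constant_psa_reduces_to_constant_hazard(self):
        # flat PSA of 10 ng/mL and dx_coef 0.02 => diagnosis hazard 0.2/yr
        vf = variant_f_overrides(
            psa_log_intercept=float(np.log(10.0)), psa_pre_slope=0.0,
            psa_post_slope=np.zeros(3), psa_sigma=0.0, dx_coef=0.02, met_coef=0.0,
        )
        params = NaturalHistoryParams(variant_f=vf, **onset_at(35))
        n = 100_000
        c = simulate_courses(params, "F", n, np.random.default_rng(5))
        fin = np.isfinite(c.cdx_age)
        delay = c.cdx_age[fin] - c.onset_age[fin]
        lam, T = 0.2, 65.0
        mean_trunc = 1 / lam - T * np.exp(-lam * T) / (1 - np.exp(-lam * T))
        assert abs(delay.mean() - mean_trunc) < 3 * (1 / lam) / np.sqrt(n)

    def test_grade_mix_recovered_at_onset(self):
        mix_young, mix_old = np.array([0.7, 0.2, 0.1]), np.array([0.4, 0.3, 0.3])
        vf = variant_f_overrides(
            grade_mix_edges=np.array([35.0, 65.0, 120.0]), grade_mix=np.vstack([mix_young, mix_old])
        )
        n = 100_000
        for age, mix in ((50, mix_young), (75, mix_old)):
            params = NaturalHistoryParams(variant_f=vf, **onset_at(age))
            c = simulate_courses(params, "F", n, np.random.default_rng(6))
            has = np.isfinite(c.onset_age)
            freq = np.bincount(c.grade_onset[has], minlength=3) / has.sum()
            se = np.sqrt(mix * (1 - mix) / has.sum())
            assert np.all(np.abs(freq - mix) <= 3 * se)

    def test_higher_grade_diagnosed_earlier_given_same_onset(self):
        params = NaturalHistoryParams(variant_f=default_nh_params("F").variant_f, **onset_at(45))
        c = simulate_courses(params, "F", 100_000, np.random.default_rng(7))
        fin = np.isfinite(c.cdx_age)
        means = [c.cdx_age[fin & (c.grade_onset == g)].mean() for g in range(3)]
        assert means[0] > means[1] > means[2]


class TestPsaModels:
    def test_psa_level_closed_form(self):
        # onset at 55, level 2.0 at onset, grade >=8 slope 0.15 => 8.96 at 65
        vf = variant_f_overrides(
            psa_log_intercept=float(np.log(2.0)), psa_pre_slope=0.0,
            psa_post_slope=np.array([0.10, 0.12, 0.15]), psa_sigma=0.0,
        )
        val = psa_level_F(vf, 65.0, 55.0, 2, 0.0)
        assert np.isclose(val, 2.0 * np.exp(1.5), rtol=1e-12)

    def test_psa_constant_when_no_onset_and_zero_slopes(self):
        vf = variant_f_overrides(psa_log_intercept=0.0, psa_pre_slope=0.0, psa_sigma=0.0)
        for age in (40.0, 60.0, 80.0):
            assert np.isclose(psa_level_F(vf, age, np.inf, 0, 0.0), 1.0)

    def test_psa_ordered_by_grade_after_onset(self):
        vf = default_nh_params("F").variant_f
        vals = [psa_level_F(vf, 65.0, 55.0, g, 0.0) for g in range(3)]
        assert vals[0] < vals[1] < vals[2]

    def test_state_psa_degenerate_distribution(self):
        vp = variant_p_overrides(psa_log_median=np.full((4, 3), np.log(12.0)), psa_sigma=0.0)
        out = psa_at_state_P(vp, np.full(100, 70.0), np.ones(100, bool),
                             np.full(100, 2), np.full(100, 2), np.random.default_rng(0).standard_normal(100))
        assert np.allclose(out, 12.0)

    def test_benign_tail_matches_lognormal_formula(self):
        from scipy.stats import norm

        vp = variant_p_overrides(benign_log_median_at_35=0.0, benign_log_slope=0.0, benign_sigma=0.6)
        n = 200_000
        z = np.random.default_rng(8).standard_normal(n)
        out = psa_at_state_P(vp, np.full(n, 60.0), np.zeros(n, bool), np.zeros(n, int), np.zeros(n, int), z)
        p = norm.sf(np.log(10.0) / 0.6)
        p_hat = (out > 10.0).mean()
        assert abs(p_hat - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_state_psa_stochastically_ordered_by_stage(self):
        vp = default_nh_params("P").variant_p
        n = 100_000
        z = np.random.default_rng(9).standard_normal(n)
        hi = psa_at_state_P(vp, np.full(n, 70.0), np.ones(n, bool), np.full(n, 2), np.zeros(n, int), z)
        lo = psa_at_state_P(vp, np.full(n, 70.0), np.ones(n, bool), np.zeros(n, int), np.zeros(n, int), z)
        assert (hi > 10).mean() > (lo > 10).mean()


class TestMonotonicity:
    @pytest.mark.parametrize("variant", ["P", "F"])
    def test_incidence_monotone_in_diagnosis_hazard(self, variant):
        params = default_nh_params(variant)
        n = 50_000
        counts = []
        for mult in (1.0, 2.0):
            c = simulate_courses(params.with_dx_mult(np.full(3, mult)), variant, n,
                                 np.random.default_rng(10))
            counts.append(np.isfinite(c.cdx_age).sum())
        assert counts[1] > counts[0]


class TestScalarApi:
    def test_scalar_course_structure(self):
        params = default_nh_params("P")
        rng = np.random.default_rng(11)
        for _ in range(200):
            course = sample_disease_course_P(params, rng)
            if course.onset_age is None:
                assert course.clinical_dx_age is None and not course.grade_path
            else:
                grades = [g for _, g in course.grade_path]
                assert grades == sorted(grades)
                stages = [s for _, s in course.stage_path]
                assert stages == sorted(stages)
                if course.clinical_dx_age is not None:
                    assert course.clinical_dx_age >= course.onset_age

    def test_scalar_psa_level_matches_vector_form(self):
        params = default_nh_params("F")
        rng = np.random.default_rng(12)
        course = sample_disease_course_F(params, rng)
        f = params.variant_f
        onset = np.inf if course.onset_age is None else course.onset_age
        expected = psa_level_F(f, 60.0, onset, course.psa_params["grade"], course.psa_params["noise"])
        assert np.isclose(psa_level(params, course, 60.0), float(expected))


class TestValidation:
    def test_grade_mix_rows_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            variant_f_overrides(grade_mix=np.array([[0.5, 0.2, 0.2], [0.4, 0.3, 0.3]]))

    def test_negative_rates_rejected(self):
        with pytest.raises(ConfigError):
            variant_p_overrides(stage_rates=np.array([0.1, -0.1, 0.1]))

    def test_decreasing_post_slopes_rejected(self):
        with pytest.raises(ConfigError):
            variant_f_overrides(psa_post_slope=np.array([0.2, 0.15, 0.1]))
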