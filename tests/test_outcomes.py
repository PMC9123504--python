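"""Rate standardization, outcome tallying, harm-benefit, and validation."""

import numpy as np
import pandas as pd
import pytest

from prostasim.demographics import PersonStubs, build_population
from prostasim.engine import Lives, PairedArm, run_screening_arm, simulate_lives
from prostasim.natural_history import CourseArrays
from prostasim.outcomes import (
    OutcomeTable,
    RateError,
    StandardWeights,
    age_standardized_rate,
    harm_benefit,
    tally,
    validate_screening_profile,
)
from prostasim.screening import ScreenArm, Strategy
from prostasim.synthetic_data import default_model, make_pyramid, make_screening_cohort


class TestAgeStandardizedRate:
    def weights(self, w):
        w = np.asarray(w, dtype=float)
        return StandardWeights(ages=np.arange(40, 40 + w.size), weights=w / w.sum())

    def test_constant_crude_rate_is_invariant_to_weights(self):
        py = np.array([100.0, 300.0, 50.0])
        ev = 0.002 * py
        for w in ([1, 1, 1], [5, 1, 2]):
            assert np.isclose(age_standardized_rate(ev, py, self.weights(w)), 200.0)

    def test_hand_arithmetic_two_ages(self):
        out = age_standardized_rate([1.0, 3.0], [1000.0, 1000.0], self.weights([0.5, 0.5]))
        assert np.isclose(out, 200.0)

    def test_degenerate_weights_pick_one_age(self):
        out = age_standardized_rate([5.0, 3.0], [1000.0, 500.0], self.weights([1.0, 0.0]))
        assert np.isclose(out, 500.0)

    def test_events_without_person_years_rejected(self):
        with pytest.raises(RateError):
            age_standardized_rate([1.0, 1.0], [0.0, 100.0], self.weights([0.5, 0.5]))


def _toy_lives(birth_year, oc_death, cdx, pc_death):
    """One-man Lives with hand-set event times."""
    n = 1
    inf = np.full(n, np.inf)
    stubs = PersonStubs(
        birth_year=np.array([birth_year]),
        baseline_age=np.array([2020.0 - birth_year]),
        entry_year=np.array([2020]),
    )
    courses = CourseArrays(
        onset_age=np.array([50.0]), grade_onset=np.array([2]),
        g7_age=np.array([50.0]), g8_age=np.array([50.0]),
        t2_age=inf.copy(), t3_age=inf.copy(), met_age=inf.copy(),
        cdx_age=np.array([float(cdx)]),
    )
    pc = np.array([float(pc_death)])
    death = np.minimum(np.array([float(oc_death)]), pc)
    return Lives(
        stubs=stubs, courses=courses, oc_death_age=np.array([float(oc_death)]),
        u_surv=np.array([0.5]), diagnosed=np.array([np.isfinite(cdx)]),
        prevalent=np.array([False]), stage_class_cf=np.array([0]),
        grade_cf=np.array([2]), treated_cf=np.array([np.isfinite(cdx)]),
        pc_anchor=np.array([float(cdx)]), pc_death_cf=pc,
        death_cf=death, cause_pc_cf=pc < np.array([float(oc_death)]),
    )


def _toy_arm(lives, det_age, det_year, overdx, pc_death, oc_death):
    n = 1
    screen = ScreenArm(
        n=n,
        test_person=np.array([0]), test_age=np.array([float(det_age)]),
        test_year=np.array([det_year]), test_psa=np.array([15.0]),
        test_biopsied=np.array([True]), test_detected=np.array([True]),
        detected=np.array([True]), det_age=np.array([float(det_age)]),
        det_year=np.array([det_year]), det_stage=np.array([0]),
        det_stage_class=np.array([0]), det_grade=np.array([2]),
        overdiagnosed=np.array([overdx]),
        lead_time=np.array([np.nan if overdx else lives.courses.cdx_age[0] - det_age]),
    )
    pc = np.array([float(pc_death)])
    death = np.minimum(np.array([float(oc_death)]), pc)
    return PairedArm(
        strategy=Strategy(test_ages=(int(det_age),)), screen=screen,
        cured=np.array([not np.isfinite(pc_death)]), shifted=np.array([False]),
        pc_death=pc, death_age=death, cause_pc=pc < oc_death,
        treated_screen=np.array([True]),
    )


class TestTally:
    def test_null_strategy_leaves_arms_identical(self, calibrated_p):
        model, _ = calibrated_p
        # only old men at baseline: nobody reaches the test age inside the window
        from prostasim.demographics import PopulationPyramid

        pyr = PopulationPyramid(ages=np.arange(70, 85), counts=np.full(15, 200),
                                baseline_year=2020)
        stubs = build_population(pyr, 2020, 2040)
        lives = simulate_lives(model, stubs, seed=3)
        arm = run_screening_arm(model, lives, Strategy(test_ages=(45,)), seed=3)
        weights = StandardWeights.from_pyramid(make_pyramid())
        table = tally(lives, arm, weights)
        assert table.totals["tests"] == 0
        assert table.totals["lives_saved"] == 0
        assert table.totals["life_years_gained"] == 0
        assert np.allclose(table.years["mortality_screen"], table.years["mortality_noscreen"])

    def test_single_toy_man_cause_flip(self):
        # unscreened: cancer death at 70; screened (cured): other-cause at 82
        lives = _toy_lives(birth_year=1965, oc_death=82.25, cdx=65.5, pc_death=70.25)
        arm = _toy_arm(lives, det_age=60.0, det_year=2025, overdx=False,
                       pc_death=np.inf, oc_death=82.25)
        weights = StandardWeights.from_pyramid(make_pyramid())
        table = tally(lives, arm, weights)
        assert table.totals["lives_saved"] == 1
        assert np.isclose(table.totals["life_years_gained"], 12.0)

    def test_overdiagnosis_total_matches_classification(self, calibrated_p):
        model, _ = calibrated_p
        stubs = build_population(make_pyramid(), 2020, 2040, multiplier=0.25)
        lives = simulate_lives(model, stubs, seed=4)
        arm = run_screening_arm(model, lives, Strategy(test_ages=(60,)), seed=4)
        table = tally(lives, arm, StandardWeights.from_pyramid(make_pyramid()))
        assert table.totals["overdiagnoses"] == arm.screen.overdiagnosed.sum()

    def test_count_scale_divides_counts(self):
        lives = _toy_lives(1965, 82.25, 65.5, 70.25)
        arm = _toy_arm(lives, 60.0, 2025, False, np.inf, 82.25)
        weights = StandardWeights.from_pyramid(make_pyramid())
        t1 = tally(lives, arm, weights, count_scale=0.5)
        assert t1.totals["tests"] == 0.5


class TestHarmBenefit:
    def _table(self, **totals):
        base = dict(tests=40_000.0, biopsies=1000.0, overdiagnoses=0.0,
                    additional_treatments=200.0, lives_saved=500.0)
        base.update(totals)
        return OutcomeTable(strategy_label="x", years=pd.DataFrame({"year": []}), totals=base)

    def test_simple_division(self):
        hb = harm_benefit(self._table())
        assert hb["tests_per_life_saved"] == 80.0

    def test_zero_overdiagnoses_gives_zero_ratio(self):
        hb = harm_benefit(self._table(overdiagnoses=0.0))
        assert hb["overdiagnoses_per_life_saved"] == 0.0

    def test_zero_lives_saved_is_undefined_not_infinite(self):
        hb = harm_benefit(self._table(lives_saved=0.0))
        assert all(v == "undefined" for v in hb.values())


class TestValidationProfile:
    def test_model_reproduces_its_own_cohort(self):
        model = default_model("F")
        cohort = make_screening_cohort(n=4300, model=model, seed=77)
        report = validate_screening_profile(model, cohort, seed=99)
        big = report[report["n"] >= 300]
        assert len(big) >= 4
        assert big["psa_within_3se"].all()

    def test_infinite_threshold_kills_exceedance(self):
        model = default_model("F")
        cohort = make_screening_cohort(n=1000, model=model, seed=77)
        report = validate_screening_profile(model, cohort, seed=99, threshold=np.inf)
        assert (report["p_psa_gt_thresh_model"] == 0).all()
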