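"""Cohort simulation engine: paired with/without-screening life histories.

One master seed drives named child streams (disease history, other-cause
death, survival, cure, and per-test-slot screening draws), so that

* the no-screening arm is identical across strategies, and
* alternative strategies share every draw they have in common

— the common-random-numbers construction that makes paired differences
(lives saved, overdiagnoses, life-years gained) exact per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _rng, natural_history as nh, screening as scr
from .demographics import LifeTable, PersonStubs, PopulationPyramid, sample_death_ages
from .natural_history import CourseArrays, NaturalHistoryParams
from .screening import ScreenArm, Strategy
from .survival_benefit import (
    SurvivalParams,
    cure_probability,
    delay_from_uniform,
    stage_shift_applies,
    stage_shift_survival,
)

MAX_TEST_SLOTS = 6


@dataclass
class ModelSpec:
    """Everything needed to simulate: variant, parameters, population."""

    variant: str  # "P" or "F"
    nh_params: NaturalHistoryParams
    survival: SurvivalParams
    lifetable: LifeTable
    pyramid: PopulationPyramid


@dataclass
class Lives:
    """No-screening life histories for a cohort (structure of arrays)."""

    stubs: PersonStubs
    courses: CourseArrays
    oc_death_age: np.ndarray
    u_surv: np.ndarray
    # counterfactual diagnosis bookkeeping
    diagnosed: np.ndarray  # clinical dx occurs before other-cause death
    prevalent: np.ndarray  # diagnosed before cohort entry (not incident)
    stage_class_cf: np.ndarray
    grade_cf: np.ndarray
    treated_cf: np.ndarray
    pc_anchor: np.ndarray  # age from which the cancer-death delay runs
    # resolved with the current survival parameters
    pc_death_cf: np.ndarray
    death_cf: np.ndarray
    cause_pc_cf: np.ndarray

    @property
    def n(self) -> int:
        return self.stubs.n

    @property
    def birth_year(self) -> np.ndarray:
        return self.stubs.birth_year


def simulate_lives(model: ModelSpec, stubs: PersonStubs, seed: int) -> Lives:
    """Simulate every man's no-screening arm under the master ``seed``.

    Disease histories run from age 35 regardless of entry age, so baseline
    men can carry prevalent (already diagnosed) disease; such men are not
    incident cases and are never screened. Conditioning on being alive at
    entry uses the exponential memoryless property: a prevalent case's
    cancer-death clock restarts at entry with the same rate.
    """
    n = stubs.n
    courses = nh.simulate_courses(
        model.nh_params, model.variant, n, _rng.child_rng(seed, _rng.STREAM_NATURAL_HISTORY)
    )
    oc = sample_death_ages(
        stubs.baseline_age, model.lifetable, _rng.child_rng(seed, _rng.STREAM_OTHER_CAUSE)
    )
    u_surv = _rng.child_rng(seed, _rng.STREAM_SURVIVAL).random(n)

    cdx = courses.cdx_age
    diagnosed = np.isfinite(cdx) & (cdx < oc)
    prevalent = diagnosed & (cdx < stubs.baseline_age)
    cdx_safe = np.where(diagnosed, cdx, 0.0)
    stage_class_cf = courses.metastatic_at(cdx_safe).astype(int)
    grade_cf = courses.grade_at(cdx_safe)
    treated_cf = model.survival.is_treated(stage_class_cf, grade_cf) & diagnosed
    pc_anchor = np.maximum(cdx, stubs.baseline_age)

    lives = Lives(
        stubs=stubs,
        courses=courses,
        oc_death_age=oc,
        u_surv=u_surv,
        diagnosed=diagnosed,
        prevalent=prevalent,
        stage_class_cf=stage_class_cf,
        grade_cf=grade_cf,
        treated_cf=treated_cf,
        pc_anchor=pc_anchor,
        pc_death_cf=np.full(n, np.inf),
        death_cf=oc.copy(),
        cause_pc_cf=np.zeros(n, dtype=bool),
    )
    resolve_noscreen(lives, model.survival)
    return lives


def resolve_noscreen(lives: Lives, survival: SurvivalParams) -> None:
    """(Re)compute counterfactual cancer deaths under ``survival``.

    Cheap relative to re-simulating natural history: the mortality
    calibration calls this repeatedly with different scale factors while
    reusing every random draw.
    """
    n = lives.n
    pc = np.full(n, np.inf)
    d = lives.diagnosed
    if d.any():
        rate = survival.hazard(
            lives.stage_class_cf[d], lives.grade_cf[d], treated=lives.treated_cf[d]
        )
        pc[d] = lives.pc_anchor[d] + delay_from_uniform(lives.u_surv[d], rate)
    lives.pc_death_cf = pc
    lives.death_cf = np.minimum(lives.oc_death_age, pc)
    lives.cause_pc_cf = pc < lives.oc_death_age


@dataclass
class PairedArm:
    """Screening arm outcomes paired with a :class:`Lives` cohort."""

    strategy: Strategy
    screen: ScreenArm
    cured: np.ndarray
    shifted: np.ndarray
    pc_death: np.ndarray
    death_age: np.ndarray
    cause_pc: np.ndarray
    treated_screen: np.ndarray  # treatment received in the screening arm


def _psa_draws(seed: int, slot: int, n: int) -> np.ndarray:
    """Per-slot standard-normal draws for variant-P PSA observations."""
    return _rng.child_rng(seed, _rng.STREAM_SCREEN_BASE + 3 * slot).standard_normal(n)


def _screen_uniforms(seed: int, n_slots: int, n: int):
    u_attend = np.stack(
        [_rng.child_rng(seed, _rng.STREAM_SCREEN_BASE + 3 * s + 1).random(n) for s in range(n_slots)]
    )
    u_sens = np.stack(
        [_rng.child_rng(seed, _rng.STREAM_SCREEN_BASE + 3 * s + 2).random(n) for s in range(n_slots)]
    )
    return u_attend, u_sens


def run_screening_arm(model: ModelSpec, lives: Lives, strategy: Strategy, seed: int) -> PairedArm:
    """Apply ``strategy`` and resolve screening-arm deaths.

    All screening draws are keyed by test-slot index under the master seed,
    independent of the strategy, so arms and strategies stay coupled.
    """
    n = lives.n
    n_slots = len(strategy.test_ages)
    if n_slots > MAX_TEST_SLOTS:
        raise scr.StrategyError(f"at most {MAX_TEST_SLOTS} test ages supported")
    courses = lives.courses

    if model.variant == "F":
        f = model.nh_params.require("F")

        def psa_of(slot, idx, age):
            return nh.psa_level_F(
                f, age, courses.onset_age[idx], courses.grade_onset[idx], courses.psa_noise[idx]
            )

    else:
        p = model.nh_params.require("P")
        z_cache = {}

        def psa_of(slot, idx, age):
            if slot not in z_cache:
                z_cache[slot] = _psa_draws(seed, slot, n)
            has = courses.onset_age[idx] <= age
            return nh.psa_at_state_P(
                p,
                np.full(idx.size, age),
                has,
                np.minimum(courses.stage_at(age)[idx], 3),
                courses.grade_at(age)[idx],
                z_cache[slot][idx],
            )

    def state_of(idx, age):
        stage = courses.stage_at(age)[idx]
        stage_class = courses.metastatic_at(age)[idx].astype(int)
        grade = courses.grade_at(age)[idx]
        return stage, stage_class, grade

    u_attend, u_sens = _screen_uniforms(seed, n_slots, n)
    screen = scr.run_screening(
        strategy,
        lives.birth_year,
        lives.stubs.entry_year,
        lives.death_cf,
        courses.cdx_age,
        courses.onset_age,
        psa_of,
        state_of,
        u_attend,
        u_sens,
    )

    u_cure = _rng.child_rng(seed, _rng.STREAM_CURE).random(n)
    return _resolve_screen_arm(model.survival, lives, strategy, screen, u_cure)


def _resolve_screen_arm(
    survival: SurvivalParams,
    lives: Lives,
    strategy: Strategy,
    screen: ScreenArm,
    u_cure: np.ndarray,
) -> PairedArm:
    """Deaths and treatment in the screening arm given detections."""
    pc = lives.pc_death_cf.copy()
    det = screen.detected
    benefit_pool = det & ~screen.overdiagnosed

    cured = np.zeros(lives.n, dtype=bool)
    shifted = np.zeros(lives.n, dtype=bool)
    if benefit_pool.any():
        if survival.mechanism == "cure_rate":
            p_cure = cure_probability(screen.lead_time[benefit_pool], survival.cure_slope)
            cured[benefit_pool] = u_cure[benefit_pool] < p_cure
            pc[cured] = np.inf
        else:  # stage_shift
            applies = stage_shift_applies(
                lives.stage_class_cf[benefit_pool],
                lives.grade_cf[benefit_pool],
                screen.det_stage_class[benefit_pool],
                screen.det_grade[benefit_pool],
                survival.shift_scope,
            )
            pool_idx = np.where(benefit_pool)[0][applies]
            shifted[pool_idx] = True
            if pool_idx.size:
                pc[pool_idx] = stage_shift_survival(
                    lives.u_surv[pool_idx],
                    screen.det_stage_class[pool_idx],
                    screen.det_grade[pool_idx],
                    lives.courses.cdx_age[pool_idx],
                    survival,
                )

    death = np.minimum(lives.oc_death_age, pc)
    cause_pc = pc < lives.oc_death_age

    # treatment in the screening arm: detected men by their detected state,
    # everyone else by the clinical-diagnosis state as in the counterfactual
    treated_screen = np.where(
        det,
        survival.is_treated(screen.det_stage_class, screen.det_grade),
        lives.treated_cf,
    ).astype(bool)

    return PairedArm(
        strategy=strategy,
        screen=screen,
        cured=cured,
        shifted=shifted,
        pc_death=pc,
        death_age=death,
        cause_pc=cause_pc,
        treated_screen=treated_screen,
    )


def simulate_paired(model: ModelSpec, stubs: PersonStubs, strategy: Strategy, seed: int):
    """Convenience: no-screening arm plus one strategy arm."""
    lives = simulate_lives(model, stubs, seed)
    arm = run_screening_arm(model, lives, strategy, seed)
    return lives, arm
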