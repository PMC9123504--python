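"""Three-stage calibration to population targets.

Stages run in a fixed order, each conditioning on the previous:

1. **Incidence** — age-band multipliers on the clinical-diagnosis hazard are
   fitted (Nelder-Mead, common random numbers) so lifetime age-specific
   clinical incidence matches the 15-year age-group targets.
2. **Mortality** — a single scale factor on all cancer-death hazards is
   fitted so no-screening age-standardized prostate-cancer mortality among
   men 40-84 in 2040 hits the anchor (root-bracketing on the deterministic
   common-random-number response).
3. **Cure slope** — beta of the lead-time-dependent cure function is fitted
   so an ERSPC-like reference scenario (cohort aged 55, 4-yearly tests
   55-69, threshold 3 ng/mL) reproduces the reference cumulative
   prostate-cancer mortality rate ratio over 13 years of follow-up.

Every objective evaluation reuses the same master seed, so the response
surfaces are deterministic and the simplex/bisection searches are noise-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import _rng
from .demographics import PersonStubs, PopulationPyramid, build_population, sample_death_ages
from .engine import Lives, ModelSpec, resolve_noscreen, run_screening_arm, simulate_lives
from .natural_history import NaturalHistoryParams, simulate_courses
from .outcomes import StandardWeights, age_standardized_rate, person_years_by_year_age
from .screening import Strategy
from .survival_benefit import SurvivalParams, delay_from_uniform

AGE_GROUP_EDGES = np.array([40.0, 55.0, 70.0, 85.0])
MORTALITY_RATE_YEAR = 2040

# ERSPC-like reference scenario for the cure-slope calibration
REFERENCE_COHORT_AGE = 55
REFERENCE_TEST_AGES = (55, 59, 63, 67)
REFERENCE_THRESHOLD = 3.0
REFERENCE_FOLLOWUP_YEARS = 13.0


class TargetError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationTargets:
    """Population targets the calibration must reproduce."""

    incidence_per_100k: np.ndarray  # (3,) for age groups 40-54, 55-69, 70-84
    asr_mortality_target: float = 154.5
    reference_rr: float = 0.80

    def __post_init__(self):
        inc = np.asarray(self.incidence_per_100k, dtype=float)
        object.__setattr__(self, "incidence_per_100k", inc)
        if inc.shape != (3,) or np.any(inc <= 0):
            raise TargetError("need 3 positive incidence targets (40-54, 55-69, 70-84)")
        if self.asr_mortality_target <= 0 or not (0 < self.reference_rr <= 1):
            raise TargetError("invalid mortality or rate-ratio target")

    @classmethod
    def from_csv(cls, path, **kw) -> "CalibrationTargets":
        df = pd.read_csv(path).sort_values("age_low")
        return cls(incidence_per_100k=df["incidence_per_100k"].to_numpy(), **kw)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "age_low": AGE_GROUP_EDGES[:-1].astype(int),
                "age_high": (AGE_GROUP_EDGES[1:] - 1).astype(int),
                "incidence_per_100k": self.incidence_per_100k,
            }
        ).to_csv(path, index=False)


@dataclass
class FitReport:
    """Outcome of one calibration stage."""

    stage: str
    converged: bool
    achieved: dict
    targets: dict
    params: dict
    iterations: int
    seed: int
    notes: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(type(x))


# ---------------------------------------------------------------------------
# Stage 1: incidence


def draw_baseline_ages(pyramid: PopulationPyramid, n: int, seed: int) -> np.ndarray:
    """Baseline ages for the incidence-calibration cohort (pyramid-weighted).

    Drawn from a dedicated stream so the same (pyramid, n, seed) always gives
    the same cohort — the common-random-numbers contract of the objective.
    """
    sel = (pyramid.ages >= 40) & (pyramid.ages <= 84)
    w = pyramid.counts[sel] / pyramid.counts[sel].sum()
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(99,)))
    return rng.choice(pyramid.ages[sel], size=n, p=w).astype(float)


def measure_incidence(
    nh_params: NaturalHistoryParams,
    variant: str,
    model_lt,
    survival: SurvivalParams,
    baseline_ages: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Lifetime age-group clinical incidence per 100 000 person-years.

    Simulates the cohort from its baseline ages to death and accumulates
    diagnoses and person-years within each 15-year band; diagnoses that
    predate a man's baseline age (prevalent disease) are not events.
    """
    n = baseline_ages.shape[0]
    courses = simulate_courses(nh_params, variant, n, _rng.child_rng(seed, _rng.STREAM_NATURAL_HISTORY))
    oc = sample_death_ages(baseline_ages, model_lt, _rng.child_rng(seed, _rng.STREAM_OTHER_CAUSE))
    u_surv = _rng.child_rng(seed, _rng.STREAM_SURVIVAL).random(n)

    cdx = courses.cdx_age
    diagnosed = np.isfinite(cdx) & (cdx < oc)
    stage_class = courses.metastatic_at(np.where(diagnosed, cdx, 0.0)).astype(int)
    grade = courses.grade_at(np.where(diagnosed, cdx, 0.0))
    anchor = np.maximum(cdx, baseline_ages)
    rate = survival.hazard(stage_class, grade)
    pc_death = np.where(diagnosed, anchor + delay_from_uniform(u_surv, rate), np.inf)
    death = np.minimum(oc, pc_death)

    events = np.zeros(3)
    py = np.zeros(3)
    incident = diagnosed & (cdx >= baseline_ages)
    for g in range(3):
        lo, hi = AGE_GROUP_EDGES[g], AGE_GROUP_EDGES[g + 1]
        events[g] = (incident & (cdx >= lo) & (cdx < hi)).sum()
        py[g] = np.clip(np.minimum(death, hi) - np.maximum(baseline_ages, lo), 0.0, None).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(py > 0, events / py * 1e5, 0.0)


def calibrate_incidence(
    nh_params: NaturalHistoryParams,
    targets: CalibrationTargets,
    variant: str,
    lifetable,
    pyramid: PopulationPyramid,
    survival: SurvivalParams,
    sim_budget: int = 200_000,
    seed: int = 1,
    maxiter: int = 80,
    tol_rel: float = 0.10,
):
    """Fit the diagnosis-hazard age-band multipliers to incidence targets.

    Only the ``dx_mult`` block moves; every other parameter is frozen. The
    objective is the sum of squared relative errors over the three age
    groups, minimized by Nelder-Mead with common random numbers. Failure to
    bring every group within ``tol_rel`` is flagged in the report, not
    raised.
    """
    if np.any(targets.incidence_per_100k <= 0):
        raise TargetError("incidence targets must be positive")
    baseline_ages = draw_baseline_ages(pyramid, int(sim_budget), seed)

    tgt = targets.incidence_per_100k
    evals = {"count": 0}

    def objective(log_m):
        evals["count"] += 1
        params = nh_params.with_dx_mult(np.exp(log_m))
        rates = measure_incidence(params, variant, lifetable, survival, baseline_ages, seed)
        return float((((rates - tgt) / tgt) ** 2).sum())

    # warm start: independent per-band rescaling, then simplex refinement
    first = measure_incidence(nh_params, variant, lifetable, survival, baseline_ages, seed)
    if np.any(first <= 0):
        x0 = np.zeros(3)
    else:
        x0 = np.log(tgt / first)
    simplex = np.vstack([x0] + [x0 + 0.3 * e for e in np.eye(3)])
    res = optimize.minimize(
        objective,
        x0=x0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 5e-4, "fatol": 1e-9,
                 "initial_simplex": simplex},
    )
    mult = np.exp(res.x)
    fitted = nh_params.with_dx_mult(mult)
    achieved = measure_incidence(fitted, variant, lifetable, survival, baseline_ages, seed)
    rel_err = (achieved - tgt) / tgt
    report = FitReport(
        stage="incidence",
        converged=bool(np.all(np.abs(rel_err) < tol_rel)),
        achieved={"incidence_per_100k": achieved, "relative_errors": rel_err},
        targets={"incidence_per_100k": tgt},
        params={"dx_mult": mult},
        iterations=evals["count"],
        seed=seed,
    )
    return fitted, report


# ---------------------------------------------------------------------------
# Stage 2: mortality


def measure_asr_mortality(lives: Lives, weights: StandardWeights, year: int = MORTALITY_RATE_YEAR) -> float:
    """Realized no-screening age-standardized cancer mortality in ``year``."""
    years = np.arange(year, year + 1)
    ages = np.arange(40, 85)
    death = lives.death_cf
    cause = lives.cause_pc_cf
    ev = np.zeros(ages.size)
    yr_of_death = lives.birth_year + np.floor(death)
    age_of_death = np.floor(death)
    sel = cause & (yr_of_death == year) & (age_of_death >= 40) & (age_of_death <= 84)
    np.add.at(ev, age_of_death[sel].astype(int) - 40, 1.0)
    py = person_years_by_year_age(lives.birth_year, lives.stubs.entry_year, death, years)[0]
    return age_standardized_rate(ev, py, weights)


def expected_asr_mortality(
    lives: Lives, survival: SurvivalParams, weights: StandardWeights,
    year: int = MORTALITY_RATE_YEAR,
) -> float:
    """Expected ASR mortality in ``year`` given each man's diagnosis state.

    Conditional on the simulated natural history and other-cause death, the
    exponential cancer-death time is integrated out analytically (conditional
    Monte Carlo). The resulting statistic is a smooth, noise-free function of
    the survival scale — the response surface the scale calibration roots on.
    """
    n = lives.n
    birth = lives.birth_year
    age_in_year = year - birth  # integer age throughout the calendar year
    in_range = (age_in_year >= 40) & (age_in_year <= 84) & (year >= lives.stubs.entry_year)

    lam = np.zeros(n)
    d = lives.diagnosed
    lam[d] = survival.hazard(lives.stage_class_cf[d], lives.grade_cf[d],
                             treated=lives.treated_cf[d])
    # calendar-time anchors (birthdays fall on January 1)
    a = birth + lives.pc_anchor
    o = birth + lives.oc_death_age
    y0 = np.full(n, float(year))
    y1 = y0 + 1.0

    def surv_pc(u):
        """P(no cancer death by time u), piecewise exponential from anchor."""
        s = np.ones(n)
        late = d & (u > a)
        s[late] = np.exp(-lam[late] * (u[late] - a[late]))
        return s

    u_end = np.minimum(y1, o)
    # expected cancer deaths within the year, before other-cause death
    u1 = np.maximum(y0, a)
    p_death = np.where(
        d & in_range & (u_end > u1), surv_pc(u1) - surv_pc(u_end), 0.0
    )
    # expected person-years alive within the year
    lo = np.minimum(np.maximum(y0, a), u_end)
    pre = np.clip(np.minimum(u_end, np.maximum(y0, a)) - y0, 0.0, 1.0)  # before anchor
    with np.errstate(divide="ignore", invalid="ignore"):
        post = np.where(
            d & (u_end > lo) & (lam > 0),
            (surv_pc(lo) - surv_pc(u_end)) / np.where(lam > 0, lam, 1.0),
            np.clip(u_end - lo, 0.0, None),
        )
    py_i = np.where(in_range & (u_end > y0), pre + post, 0.0)

    ages = np.arange(40, 85)
    ev = np.zeros(ages.size)
    py = np.zeros(ages.size)
    sel = in_range & (u_end > y0)
    np.add.at(ev, age_in_year[sel] - 40, p_death[sel])
    np.add.at(py, age_in_year[sel] - 40, py_i[sel])
    return age_standardized_rate(ev, py, weights)


def _mortality_world(model: ModelSpec, survival: SurvivalParams, sim_budget: int,
                     seed: int, end_year: int):
    """The shared no-screening world the mortality calibration measures on."""
    base_pop = build_population(model.pyramid, model.pyramid.baseline_year, end_year)
    mult = max(1.0, sim_budget / max(base_pop.n, 1))
    stubs = build_population(model.pyramid, model.pyramid.baseline_year, end_year, multiplier=mult)
    model_scaled = ModelSpec(
        variant=model.variant,
        nh_params=model.nh_params,
        survival=survival.with_scale(1.0),
        lifetable=model.lifetable,
        pyramid=model.pyramid,
    )
    lives = simulate_lives(model_scaled, stubs, seed)
    return lives, StandardWeights.from_pyramid(model.pyramid)


def simulated_asr_mortality(
    model: ModelSpec,
    survival: SurvivalParams,
    sim_budget: int = 300_000,
    seed: int = 1,
    end_year: int = MORTALITY_RATE_YEAR,
) -> float:
    """The exact statistic calibrate_mortality controls, at a given scale."""
    lives, weights = _mortality_world(model, survival, sim_budget, seed, end_year)
    return expected_asr_mortality(lives, survival, weights, year=end_year)


def calibrate_mortality(
    survival: SurvivalParams,
    targets: CalibrationTargets,
    model: ModelSpec,
    sim_budget: int = 300_000,
    seed: int = 1,
    tol_rel: float = 0.01,
    end_year: int = MORTALITY_RATE_YEAR,
):
    """Fit the common survival-hazard scale to the mortality anchor.

    The natural history is simulated once; the scale search roots on the
    expected (analytically integrated) cancer-death statistic, which is a
    smooth deterministic function of the scale given the simulated histories.
    Orderings among state medians are scale-invariant and preserved.
    """
    lives, weights = _mortality_world(model, survival, sim_budget, seed, end_year)
    stubs = lives.stubs
    target = targets.asr_mortality_target

    def asr_at(scale):
        return expected_asr_mortality(lives, survival.with_scale(scale), weights, year=end_year)

    lo, hi = 0.05, 20.0
    f_lo, f_hi = asr_at(lo) - target, asr_at(hi) - target
    if f_lo > 0 or f_hi < 0:
        report = FitReport(
            stage="mortality", converged=False,
            achieved={"asr_mortality_2040": asr_at(1.0)},
            targets={"asr_mortality_target": target},
            params={"mortality_scale": 1.0}, iterations=2, seed=seed,
            notes="target outside the reachable bracket",
        )
        return survival, report
    scale = optimize.brentq(lambda s: asr_at(s) - target, lo, hi, xtol=1e-4, rtol=1e-5)
    achieved = asr_at(scale)
    fitted = survival.with_scale(scale)
    report = FitReport(
        stage="mortality",
        converged=bool(abs(achieved - target) / target < tol_rel),
        achieved={"asr_mortality_2040": achieved, "n_histories": stubs.n},
        targets={"asr_mortality_target": target},
        params={"mortality_scale": scale},
        iterations=0,
        seed=seed,
    )
    return fitted, report


# ---------------------------------------------------------------------------
# Stage 3: cure slope


def calibrate_cure(
    survival: SurvivalParams,
    model: ModelSpec,
    reference_rr: float = 0.80,
    sim_budget: int = 200_000,
    seed: int = 1,
    tol: float = 0.02,
    confirm_seed: int | None = None,
):
    """Fit beta so the reference screening scenario yields ``reference_rr``.

    With common random numbers each detected savable man has an exact cure
    threshold beta_i = -log(1-u)/lead, so averted in-window deaths are a step
    function of beta; beta is placed between the order statistics bracketing
    the required number of averted deaths. A fresh-seed confirmation run is
    reported.
    """
    if not (0 < reference_rr <= 1):
        raise TargetError("reference_rr must lie in (0, 1]")

    stubs = _reference_cohort(model.pyramid.baseline_year, sim_budget)
    strategy = Strategy(
        test_ages=REFERENCE_TEST_AGES,
        start_year=model.pyramid.baseline_year + 2,
        threshold=REFERENCE_THRESHOLD,
        sensitivity=0.8,
        attendance=1.0,
    )
    ref_model = ModelSpec(
        variant=model.variant,
        nh_params=model.nh_params,
        survival=survival.with_cure_slope(0.0),
        lifetable=model.lifetable,
        pyramid=model.pyramid,
    )

    def rr_components(run_seed):
        lives = simulate_lives(ref_model, stubs, run_seed)
        arm = run_screening_arm(ref_model, lives, strategy, run_seed)
        horizon = stubs.baseline_age + REFERENCE_FOLLOWUP_YEARS
        d_cf = lives.cause_pc_cf & (lives.death_cf <= horizon)
        savable = (
            arm.screen.detected
            & ~arm.screen.overdiagnosed
            & d_cf
        )
        return lives, arm, d_cf, savable, horizon

    lives, arm, d_cf, savable, horizon = rr_components(seed)
    deaths_cf = int(d_cf.sum())
    if deaths_cf == 0:
        raise TargetError("no counterfactual cancer deaths in the reference window")
    need = int(round((1.0 - reference_rr) * deaths_cf))

    u_cure = _rng.child_rng(seed, _rng.STREAM_CURE).random(lives.n)
    lead = arm.screen.lead_time
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_thresholds = -np.log(1.0 - u_cure[savable]) / lead[savable]
    beta_thresholds = np.sort(beta_thresholds[np.isfinite(beta_thresholds)])

    if need <= 0:
        beta = 0.0
        exhausted = False
    elif need > beta_thresholds.size:
        beta = float(beta_thresholds[-1] * 2) if beta_thresholds.size else 1.0
        exhausted = True
    else:
        hi_b = beta_thresholds[need - 1]
        lo_next = beta_thresholds[need] if need < beta_thresholds.size else hi_b * 1.05
        beta = float(0.5 * (hi_b + lo_next))
        exhausted = False

    averted = int((beta_thresholds < beta).sum())
    rr_fit = (deaths_cf - averted) / deaths_cf

    # independent confirmation with a fresh seed
    c_seed = confirm_seed if confirm_seed is not None else seed + 7919
    fitted = survival.with_cure_slope(beta)
    conf_model = ModelSpec(
        variant=model.variant, nh_params=model.nh_params, survival=fitted,
        lifetable=model.lifetable, pyramid=model.pyramid,
    )
    lives_c = simulate_lives(conf_model, stubs, c_seed)
    arm_c = run_screening_arm(conf_model, lives_c, strategy, c_seed)
    horizon_c = stubs.baseline_age + REFERENCE_FOLLOWUP_YEARS
    d_cf_c = (lives_c.cause_pc_cf & (lives_c.death_cf <= horizon_c)).sum()
    d_scr_c = (arm_c.cause_pc & (arm_c.death_age <= horizon_c)).sum()
    rr_confirm = float(d_scr_c / d_cf_c) if d_cf_c else np.nan

    report = FitReport(
        stage="cure",
        converged=bool(not exhausted and abs(rr_fit - reference_rr) <= tol),
        achieved={"rr_fit": rr_fit, "rr_confirmation": rr_confirm, "deaths_noscreen_window": deaths_cf},
        targets={"reference_rr": reference_rr},
        params={"cure_slope": beta},
        iterations=1,
        seed=seed,
        notes="search bracket exhausted" if exhausted else "",
    )
    return fitted, report


def _reference_cohort(baseline_year: int, n: int) -> PersonStubs:
    """A trial-like cohort: ``n`` men all aged 55 at program start."""
    start = baseline_year + 2
    return PersonStubs(
        birth_year=np.full(n, start - REFERENCE_COHORT_AGE),
        baseline_age=np.full(n, float(REFERENCE_COHORT_AGE)),
        entry_year=np.full(n, start),
    )


# ---------------------------------------------------------------------------
# Orchestration


def calibrate_all(
    model: ModelSpec,
    targets: CalibrationTargets,
    sim_budget: int = 200_000,
    seed: int = 1,
):
    """Run the three stages in order; returns the calibrated model + reports."""
    nh_fit, rep_inc = calibrate_incidence(
        model.nh_params, targets, model.variant, model.lifetable, model.pyramid,
        model.survival, sim_budget=sim_budget, seed=seed,
    )
    model = ModelSpec(
        variant=model.variant, nh_params=nh_fit, survival=model.survival,
        lifetable=model.lifetable, pyramid=model.pyramid,
    )
    surv_fit, rep_mort = calibrate_mortality(
        model.survival, targets, model, sim_budget=max(sim_budget, 300_000), seed=seed,
    )
    model = ModelSpec(
        variant=model.variant, nh_params=nh_fit, survival=surv_fit,
        lifetable=model.lifetable, pyramid=model.pyramid,
    )
    surv_final, rep_cure = calibrate_cure(
        model.survival, model, reference_rr=targets.reference_rr,
        sim_budget=sim_budget, seed=seed,
    )
    model = ModelSpec(
        variant=model.variant, nh_params=nh_fit, survival=surv_final,
        lifetable=model.lifetable, pyramid=model.pyramid,
    )
    return model, {"incidence": rep_inc, "mortality": rep_mort, "cure": rep_cure}
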