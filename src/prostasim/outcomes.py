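"""Population outcome tables: rates, resource counts, harm-benefit ratios.

Rates are directly age-standardized to the simulated baseline-year (2020)
male population aged 40-84. Person-years are exact (birthdays fall on
January 1, so a man's integer age is constant within a calendar year).
Lives saved require a cause-of-death flip (a prostate-cancer death averted);
a merely delayed cancer death contributes to life-years gained only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demographics import PopulationPyramid
from .engine import Lives, ModelSpec, PairedArm

AGE_LO, AGE_HI = 40, 84
RATE_YEARS = (2020, 2040)
WINDOW = (2022, 2040)
UNDEFINED = "undefined"  # sentinel for ratios with zero lives saved


class RateError(ValueError):
    pass


@dataclass(frozen=True)
class StandardWeights:
    """Normalized age weights for direct standardization."""

    ages: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "weights", w)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")

    @classmethod
    def from_pyramid(cls, pyramid: PopulationPyramid) -> "StandardWeights":
        sel = (pyramid.ages >= AGE_LO) & (pyramid.ages <= AGE_HI)
        return cls(ages=pyramid.ages[sel], weights=pyramid.weights()[sel] / pyramid.weights()[sel].sum())


def age_standardized_rate(events_by_age, person_years_by_age, weights: StandardWeights) -> float:
    """Directly standardized rate per 100 000: sum_a w_a * events_a / py_a."""
    ev = np.asarray(events_by_age, dtype=float)
    py = np.asarray(person_years_by_age, dtype=float)
    if ev.shape != py.shape or ev.shape != weights.weights.shape:
        raise RateError("events, person-years and weights must align by age")
    bad = (py <= 0) & (ev > 0)
    if bad.any():
        raise RateError("events recorded in an age with zero person-years")
    with np.errstate(divide="ignore", invalid="ignore"):
        crude = np.where(py > 0, ev / py, 0.0)
    return float((weights.weights * crude).sum() * 1e5)


@dataclass
class OutcomeTable:
    """Per-year rates plus window totals for one strategy (or none)."""

    strategy_label: str
    years: pd.DataFrame  # year, events/PY/ASR columns, both arms
    totals: dict
    window: tuple = WINDOW

    def to_tidy_csv(self, path) -> None:
        tidy = self.years.melt(id_vars="year", var_name="measure", value_name="value")
        tidy.insert(0, "strategy", self.strategy_label)
        tidy.to_csv(path, index=False)

    def summary(self) -> dict:
        return {"strategy": self.strategy_label, "window": list(self.window), **self.totals}


def _events_by_year_age(event_year, event_age, years):
    """(n_years, n_ages) event counts for integer event ages 40-84."""
    out = np.zeros((years.size, AGE_HI - AGE_LO + 1))
    ok = np.isfinite(event_age)
    yr = np.asarray(event_year)[ok].astype(int)
    ag = np.floor(np.asarray(event_age)[ok]).astype(int)
    sel = (yr >= years[0]) & (yr <= years[-1]) & (ag >= AGE_LO) & (ag <= AGE_HI)
    np.add.at(out, (yr[sel] - years[0], ag[sel] - AGE_LO), 1.0)
    return out


def person_years_by_year_age(birth_year, entry_year, death_age, years):
    """Exact person-years at ages 40-84 for each calendar year."""
    n_ages = AGE_HI - AGE_LO + 1
    out = np.zeros((years.size, n_ages))
    birth_year = np.asarray(birth_year)
    death_age = np.asarray(death_age, dtype=float)
    for i, y in enumerate(years):
        a = y - birth_year
        alive = (a >= AGE_LO) & (a <= AGE_HI) & (y >= np.asarray(entry_year))
        py = np.clip(death_age[alive] - a[alive], 0.0, 1.0)
        np.add.at(out[i], a[alive] - AGE_LO, py)
    return out


def tally(
    lives: Lives,
    arm: PairedArm | None,
    weights: StandardWeights,
    rate_years: tuple = RATE_YEARS,
    window: tuple = WINDOW,
    count_scale: float = 1.0,
) -> OutcomeTable:
    """Tabulate paired outcomes; ``arm=None`` gives the no-screening table.

    ``count_scale`` divides absolute counts (use 1/multiplier when the
    population was simulated at a size multiplier).
    """
    years = np.arange(rate_years[0], rate_years[1] + 1)
    courses = lives.courses
    birth = lives.birth_year

    # --- no-screening arm events
    inc_cf = lives.diagnosed & ~lives.prevalent
    cdx = courses.cdx_age
    inc_cf_year = np.where(inc_cf, birth + np.floor(cdx), -1).astype(int)
    ev_inc_cf = _events_by_year_age(inc_cf_year, np.where(inc_cf, cdx, np.nan), years)
    mort_cf_year = birth + np.floor(lives.death_cf)
    ev_mort_cf = _events_by_year_age(
        np.where(lives.cause_pc_cf, mort_cf_year, -1).astype(int),
        np.where(lives.cause_pc_cf, lives.death_cf, np.nan),
        years,
    )
    py_cf = person_years_by_year_age(birth, lives.stubs.entry_year, lives.death_cf, years)

    rows = {
        "year": years,
        "incidence_noscreen": ev_inc_cf.sum(axis=1) * count_scale,
        "mortality_noscreen": ev_mort_cf.sum(axis=1) * count_scale,
        "py_noscreen": py_cf.sum(axis=1) * count_scale,
        "asr_incidence_noscreen": [
            age_standardized_rate(ev_inc_cf[i], py_cf[i], weights) for i in range(years.size)
        ],
        "asr_mortality_noscreen": [
            age_standardized_rate(ev_mort_cf[i], py_cf[i], weights) for i in range(years.size)
        ],
    }

    totals: dict = {}
    in_win = lambda yr: (yr >= window[0]) & (yr <= window[1])

    # no-screening-arm treatments among cases incident in the window
    cf_in_window = inc_cf & in_win(inc_cf_year) & (np.floor(cdx) >= AGE_LO) & (np.floor(cdx) <= AGE_HI)
    treats_cf = int((lives.treated_cf & cf_in_window).sum())

    if arm is not None:
        screen = arm.screen
        det = screen.detected
        # screening-arm incidence: detections plus clinical dx of the undetected
        inc_clin = inc_cf & ~det
        inc_clin_year = np.where(inc_clin, birth + np.floor(cdx), -1).astype(int)
        ev_inc_s = _events_by_year_age(inc_clin_year, np.where(inc_clin, cdx, np.nan), years)
        ev_inc_s += _events_by_year_age(
            np.where(det, screen.det_year, -1), np.where(det, screen.det_age, np.nan), years
        )
        mort_s_year = birth + np.floor(arm.death_age)
        ev_mort_s = _events_by_year_age(
            np.where(arm.cause_pc, mort_s_year, -1).astype(int),
            np.where(arm.cause_pc, arm.death_age, np.nan),
            years,
        )
        py_s = person_years_by_year_age(birth, lives.stubs.entry_year, arm.death_age, years)

        rows.update(
            {
                "incidence_screen": ev_inc_s.sum(axis=1) * count_scale,
                "mortality_screen": ev_mort_s.sum(axis=1) * count_scale,
                "py_screen": py_s.sum(axis=1) * count_scale,
                "asr_incidence_screen": [
                    age_standardized_rate(ev_inc_s[i], py_s[i], weights) for i in range(years.size)
                ],
                "asr_mortality_screen": [
                    age_standardized_rate(ev_mort_s[i], py_s[i], weights) for i in range(years.size)
                ],
            }
        )

        clin_in_window = inc_clin & in_win(inc_clin_year) & (np.floor(cdx) >= AGE_LO) & (np.floor(cdx) <= AGE_HI)
        treats_screen = int(
            (arm.treated_screen & det).sum() + (arm.treated_screen & clin_in_window).sum()
        )
        lives_saved = int((lives.cause_pc_cf & ~arm.cause_pc).sum())
        lyg = float((arm.death_age - lives.death_cf).sum())
        if lyg < -1e-6:
            raise RateError("screening arm lost life-years; pairing broken")

        totals.update(
            tests=screen.n_tests * count_scale,
            biopsies=screen.n_biopsies * count_scale,
            cancers_detected_total=(int(det.sum()) + int(clin_in_window.sum())) * count_scale,
            screen_detected=int(det.sum()) * count_scale,
            overdiagnoses=int(screen.overdiagnosed.sum()) * count_scale,
            treatments_screen_arm=treats_screen * count_scale,
            treatments_noscreen_arm=treats_cf * count_scale,
            additional_treatments=(treats_screen - treats_cf) * count_scale,
            lives_saved=lives_saved * count_scale,
            life_years_gained=lyg * count_scale,
        )
    else:
        totals.update(
            tests=0.0,
            biopsies=0.0,
            cancers_detected_total=int(cf_in_window.sum()) * count_scale,
            screen_detected=0.0,
            overdiagnoses=0.0,
            treatments_screen_arm=treats_cf * count_scale,
            treatments_noscreen_arm=treats_cf * count_scale,
            additional_treatments=0.0,
            lives_saved=0.0,
            life_years_gained=0.0,
        )

    label = arm.strategy.label if arm is not None else "none"
    return OutcomeTable(strategy_label=label, years=pd.DataFrame(rows), totals=totals, window=window)


def harm_benefit(outcomes: OutcomeTable) -> dict:
    """Resources per life saved; ``'undefined'`` when no lives are saved.

    The treatments ratio uses *additional* (screening-attributable) curative
    treatments; both treatment totals remain available in the table.
    """
    ls = outcomes.totals.get("lives_saved", 0.0)
    keys = {
        "tests_per_life_saved": "tests",
        "biopsies_per_life_saved": "biopsies",
        "overdiagnoses_per_life_saved": "overdiagnoses",
        "treatments_per_life_saved": "additional_treatments",
    }
    if ls is None or ls <= 0:
        return {k: UNDEFINED for k in keys}
    return {k: outcomes.totals[src] / ls for k, src in keys.items()}


def validate_screening_profile(
    model: ModelSpec,
    cohort: pd.DataFrame,
    seed: int,
    threshold: float = 10.0,
    sensitivity: float = 0.8,
    band_width: int = 5,
) -> pd.DataFrame:
    """Compare model first-test PSA and grade profiles with a screening cohort.

    For each ``band_width``-year age band: the proportion of first tests with
    PSA above ``threshold``, and the proportion of biopsy-diagnosed cancers
    with Gleason <= 7, simulated at the cohort's own test ages versus the
    cohort's empirical values, with 3-SE binomial bands.
    """
    from . import _rng, natural_history as nh

    ages = cohort["age"].to_numpy(dtype=float)
    n = ages.size
    rng = np.random.default_rng(seed)
    courses = nh.simulate_courses(model.nh_params, model.variant, n, rng)
    undiag = courses.cdx_age > ages
    has = courses.has_cancer_at(ages) & undiag
    if model.variant == "F":
        f = model.nh_params.require("F")
        psa = nh.psa_level_F(f, ages, courses.onset_age, courses.grade_onset, courses.psa_noise)
    else:
        p = model.nh_params.require("P")
        psa = nh.psa_at_state_P(
            p, ages, has, np.minimum(courses.stage_at(ages), 3), courses.grade_at(ages),
            rng.standard_normal(n),
        )
    exceed_sim = (psa > threshold) & undiag
    det_sim = exceed_sim & has & (rng.random(n) < sensitivity)
    grade_sim = courses.grade_at(ages)

    lo = int(np.floor(ages.min() / band_width) * band_width)
    hi = int(np.ceil((ages.max() + 1) / band_width) * band_width)
    records = []
    for b0 in range(lo, hi, band_width):
        in_band = (ages >= b0) & (ages < b0 + band_width)
        emp = cohort.loc[in_band]
        if emp.empty:
            warnings.warn(f"age band [{b0},{b0 + band_width}) empty in cohort; skipped")
            continue
        p_emp = float((emp["psa"] > threshold).mean())
        p_sim = float(exceed_sim[in_band].mean())
        n_band = int(in_band.sum())
        se = np.sqrt(max(p_emp * (1 - p_emp), p_sim * (1 - p_sim)) / n_band)
        rec = {
            "age_band": f"{b0}-{b0 + band_width - 1}",
            "n": n_band,
            "p_psa_gt_thresh_cohort": p_emp,
            "p_psa_gt_thresh_model": p_sim,
            "psa_within_3se": abs(p_emp - p_sim) <= 3 * max(se, 1e-12),
        }
        emp_gl = emp.loc[emp["gleason_group"] >= 0, "gleason_group"]
        sim_gl = grade_sim[in_band & det_sim]
        if len(emp_gl) and len(sim_gl):
            q_emp = float((emp_gl <= 1).mean())  # grade groups 0,1 are Gleason <= 7
            q_sim = float((sim_gl <= 1).mean())
            m = min(len(emp_gl), len(sim_gl))
            se_g = np.sqrt(max(q_emp * (1 - q_emp), q_sim * (1 - q_sim), 0.25 / m) / m)
            rec.update(
                p_gleason_le7_cohort=q_emp,
                p_gleason_le7_model=q_sim,
                gleason_within_3se=abs(q_emp - q_sim) <= 3 * se_g,
            )
        records.append(rec)
    return pd.DataFrame(records)
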