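"""Synthetic fixtures emulating the study population and screening data.

Nothing in this package downloads data: every input the pipeline consumes is
generated here — a Gompertz-Makeham lifetable tuned to a target life
expectancy, a population pyramid of 70 440 men aged 40-84 at 2020, age-group
clinical-incidence targets, default natural-history parameter sets for both
model variants, and a screening-cohort sample (n=4300, median first-test age
54) drawn from the packaged model itself so that validation comparisons are
internally consistent.

The numeric defaults are documented stand-ins: the incidence targets are
chosen to be plausible for a high-incidence Caribbean population of mostly
African ancestry, the mortality anchor (154.5 per 100 000 men 40-84) is the
midpoint of the no-screening level the projections are anchored to, and the
natural-history values are round numbers consistent with the published
prostate-cancer modeling literature rather than any proprietary fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .calibration import CalibrationTargets
from .demographics import LifeTable, PopulationPyramid, extrapolate_lifetable
from .engine import ModelSpec
from .natural_history import (
    NaturalHistoryParams,
    VariantFParams,
    VariantPParams,
    simulate_courses,
)
from .survival_benefit import SurvivalParams

BASELINE_YEAR = 2020
POPULATION_TOTAL = 70_440
COHORT_N = 4300
COHORT_MEDIAN_AGE = 54.0
ASR_MORTALITY_ANCHOR = 154.5  # per 100 000 men aged 40-84
REFERENCE_RR = 0.80
# per 100 000 person-years, age groups 40-54 / 55-69 / 70-84 (stand-ins)
INCIDENCE_TARGETS = (60.0, 600.0, 1400.0)


def make_lifetable(
    target_life_expectancy: float = 75.0,
    max_age: int = 84,
    makeham: float = 8e-4,
    gompertz_slope: float = 0.09,
) -> LifeTable:
    """Gompertz-Makeham lifetable solved for a target life expectancy.

    q(a) = 1 - exp(-(lambda + alpha * exp(gamma * a))); alpha is found by
    root bracketing so that implied life expectancy at birth matches the
    target within 0.5 years. Deterministic.
    """
    if not (50.0 <= target_life_expectancy <= 90.0):
        raise ValueError("target life expectancy must lie in [50, 90]")

    ages_full = np.arange(0, 121)

    def life_expectancy(log_alpha):
        h = makeham + np.exp(log_alpha) * np.exp(gompertz_slope * ages_full)
        q = -np.expm1(-h)
        surv = np.cumprod(1.0 - q)
        # deaths uniform within the year => half-year credit in the death year
        return surv.sum() + 0.5

    try:
        log_alpha = optimize.brentq(
            lambda la: life_expectancy(la) - target_life_expectancy, np.log(1e-8), np.log(1e-2)
        )
    except ValueError as err:
        raise ValueError(f"no Gompertz-Makeham solution for target {target_life_expectancy}") from err

    ages = np.arange(0, max_age + 1)
    h = makeham + np.exp(log_alpha) * np.exp(gompertz_slope * ages)
    return LifeTable(ages=ages, q=-np.expm1(-h))


def make_pyramid(
    total: int = POPULATION_TOTAL,
    baseline_year: int = BASELINE_YEAR,
    decline_rate: float = 0.03,
) -> PopulationPyramid:
    """Smoothly declining male pyramid, ages 40-84, summing exactly to total.

    Counts fall off exponentially with age (a mature, slowly growing
    population); annual age-40 entrants equal the baseline count at 40.
    """
    ages = np.arange(40, 85)
    shape = np.exp(-decline_rate * (ages - 40))
    raw = shape / shape.sum() * total
    counts = np.floor(raw).astype(int)
    # largest-remainder rounding to hit the total exactly
    short = total - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    counts[order[:short]] += 1
    return PopulationPyramid(
        ages=ages, counts=counts, baseline_year=baseline_year, annual_entrants=int(counts[0])
    )


def make_incidence_targets(scale: float = 1.0) -> CalibrationTargets:
    """Age-group clinical-incidence targets, steeply increasing with age."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return CalibrationTargets(
        incidence_per_100k=np.array(INCIDENCE_TARGETS) * scale,
        asr_mortality_target=ASR_MORTALITY_ANCHOR,
        reference_rr=REFERENCE_RR,
    )


# Shared latent-onset hazard: piecewise constant over 5-year bands from 35.
ONSET_EDGES = np.array([35.0, 40, 45, 50, 55, 60, 65, 70, 75, 120])
ONSET_HAZARD = np.array([0.002, 0.004, 0.008, 0.012, 0.016, 0.020, 0.024, 0.026, 0.028])


def default_nh_params(variant: str) -> NaturalHistoryParams:
    """Packaged natural-history parameter fixture for variant P or F."""
    if variant == "P":
        vp = VariantPParams(
            init_grade_probs=np.array([0.85, 0.12, 0.03]),
            stage_rates=np.array([0.08, 0.10, 0.12]),
            grade_rates=np.array([0.04, 0.05]),
            dx_rate=np.array(
                [
                    [0.008, 0.012, 0.020],
                    [0.030, 0.045, 0.060],
                    [0.080, 0.100, 0.130],
                    [0.500, 0.500, 0.500],
                ]
            ),
            psa_log_median=np.log(
                [[2.0, 2.5, 3.5], [4.0, 5.0, 7.0], [9.0, 11.0, 14.0], [25.0, 30.0, 40.0]]
            ),
            psa_sigma=0.7,
            benign_log_median_at_35=float(np.log(0.7)),
            benign_log_slope=0.015,
            benign_sigma=0.55,
        )
        return NaturalHistoryParams(onset_edges=ONSET_EDGES, onset_hazard=ONSET_HAZARD, variant_p=vp)
    if variant == "F":
        vf = VariantFParams(
            grade_mix_edges=np.array([35.0, 50.0, 65.0, 120.0]),
            grade_mix=np.array(
                [[0.70, 0.20, 0.10], [0.55, 0.27, 0.18], [0.40, 0.30, 0.30]]
            ),
            psa_log_intercept=float(np.log(0.7)),
            psa_pre_slope=0.02,
            psa_post_slope=np.array([0.10, 0.15, 0.22]),
            psa_sigma=0.45,
            dx_coef=0.02,
            met_coef=0.004,
        )
        return NaturalHistoryParams(onset_edges=ONSET_EDGES, onset_hazard=ONSET_HAZARD, variant_f=vf)
    raise ValueError(f"unknown variant {variant!r}")


def default_survival_params(mechanism: str = "cure_rate") -> SurvivalParams:
    """Exponential baseline survival stand-ins (pre-screening-era levels)."""
    return SurvivalParams(
        median_localized=np.array([14.0, 9.0, 5.0]),
        median_metastatic=np.array([3.5, 3.0, 2.0]),
        hr_treat=0.55,
        cure_slope=0.0,  # fitted by the cure calibration
        mechanism=mechanism,
    )


def default_model(variant: str = "F", mechanism: str = "cure_rate") -> ModelSpec:
    """Uncalibrated model over the packaged fixtures (lifetable closed at 95)."""
    lt = extrapolate_lifetable(make_lifetable(), 94)
    return ModelSpec(
        variant=variant,
        nh_params=default_nh_params(variant),
        survival=default_survival_params(mechanism),
        lifetable=lt,
        pyramid=make_pyramid(),
    )


def make_screening_cohort(
    n: int = COHORT_N,
    median_age: float = COHORT_MEDIAN_AGE,
    model: ModelSpec | None = None,
    seed: int = 2016,
    threshold: float = 10.0,
    sensitivity: float = 0.8,
) -> pd.DataFrame:
    """First-screening-test cohort sample drawn from the packaged model.

    Attendance ages follow a right-skewed distribution with the target
    median, clipped to 40-84; PSA and disease states come from the model so
    the sample is internally consistent. ``gleason_group`` is 0/1/2 for
    Gleason <=6 / 7 / >=8 when a biopsy found cancer, else -1.

    Men already clinically diagnosed by their test age are not screening
    attendees and are resampled.
    """
    if n < 100:
        raise ValueError("cohort size must be at least 100")
    if model is None:
        model = default_model("F")
    rng = np.random.default_rng(seed)

    rows = []
    need = n
    while need > 0:
        m = max(2 * need, 256)
        ages = np.clip(40.0 + rng.lognormal(np.log(median_age - 40.0), 0.5, m), 40.0, 84.0)
        courses = simulate_courses(model.nh_params, model.variant, m, rng)
        undiag = courses.cdx_age > ages
        if model.variant == "F":
            f = model.nh_params.require("F")
            from .natural_history import psa_level_F

            psa = psa_level_F(f, ages, courses.onset_age, courses.grade_onset, courses.psa_noise)
        else:
            p = model.nh_params.require("P")
            from .natural_history import psa_at_state_P

            psa = psa_at_state_P(
                p, ages, courses.has_cancer_at(ages),
                np.minimum(courses.stage_at(ages), 3), courses.grade_at(ages),
                rng.standard_normal(m),
            )
        biopsied = (psa > threshold) & undiag
        found = biopsied & courses.has_cancer_at(ages) & (rng.random(m) < sensitivity)
        grade = np.where(found, courses.grade_at(ages), -1)
        keep = np.where(undiag)[0][: min(need, int(undiag.sum()))]
        rows.append(
            pd.DataFrame(
                {
                    "age": np.round(ages[keep], 2),
                    "psa": np.round(psa[keep], 3),
                    "biopsied": biopsied[keep].astype(int),
                    "gleason_group": grade[keep].astype(int),
                }
            )
        )
        need -= keep.size
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "id", np.arange(1, n + 1))
    return out


@dataclass
class FixtureBundle:
    """Everything the pipeline needs, generated from one seed."""

    lifetable: LifeTable  # raw table, ages 0-84 (pre-extrapolation)
    pyramid: PopulationPyramid
    targets: CalibrationTargets
    nh_params_p: NaturalHistoryParams
    nh_params_f: NaturalHistoryParams
    survival: SurvivalParams
    cohort: pd.DataFrame


def fixture_bundle(seed: int = 2016, mechanism: str = "cure_rate") -> FixtureBundle:
    return FixtureBundle(
        lifetable=make_lifetable(),
        pyramid=make_pyramid(),
        targets=make_incidence_targets(),
        nh_params_p=default_nh_params("P"),
        nh_params_f=default_nh_params("F"),
        survival=default_survival_params(mechanism),
        cohort=make_screening_cohort(seed=seed),
    )


def write_fixtures(bundle: FixtureBundle, outdir) -> list:
    """Emit the CSV fixture files consumed by the pipeline; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    p = outdir / "lifetable.csv"
    bundle.lifetable.to_csv(p)
    paths.append(p)
    p = outdir / "pyramid.csv"
    bundle.pyramid.to_csv(p)
    paths.append(p)
    p = outdir / "incidence_targets.csv"
    bundle.targets.to_csv(p)
    paths.append(p)
    p = outdir / "screening_cohort.csv"
    bundle.cohort.to_csv(p, index=False)
    paths.append(p)
    from .config import params_to_yaml

    p = outdir / "model_params.yaml"
    params_to_yaml(bundle, p)
    paths.append(p)
    return paths
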