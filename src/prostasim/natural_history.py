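"""Latent prostate cancer onset and progression to clinical diagnosis.

Two structurally distinct variants are implemented:

* **Variant P** (progression-based): after onset, disease moves through
  clinical stages cT1 -> T2 -> T3 -> metastatic and Gleason grade groups
  <=6 -> 7 -> >=8 by competing exponential clocks, with a separate clock for
  clinical diagnosis whose rate depends on the current (stage, grade) state.
  Progression is not linked to PSA; PSA observed at a screening test is a
  state-conditional lognormal draw.

* **Variant F** (PSA-linked): Gleason grade is fixed at onset (older onset
  ages weight higher grades); each man carries a log-linear PSA growth
  trajectory with a changepoint at onset, and the hazards of clinical
  diagnosis and of metastasis at age ``a`` are proportional to the current
  PSA level.

Grades are indexed 0 (Gleason <=6), 1 (Gleason 7), 2 (Gleason >=8); variant-P
stages 0..3 are cT1, T2, T3, metastatic. The diagnosis hazard carries
age-band multipliers (``dx_mult``) — the only block the incidence
calibration is allowed to move.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import sample_expgrowth_piecewise, sample_piecewise_exponential

GRADE_LABELS = ("<=6", "7", ">=8")
STAGE_LABELS = ("cT1", "T2", "T3", "M")
PSA_AGE_ORIGIN = 35.0
AGE_CAP = 100.0

# Age bands over which the calibrated diagnosis-hazard multipliers apply.
DX_MULT_EDGES = np.array([0.0, 55.0, 70.0, 200.0])


class ConfigError(ValueError):
    """Raised for invalid or incomplete natural-history parameters."""


@dataclass(frozen=True)
class VariantPParams:
    init_grade_probs: np.ndarray  # (3,) grade mix at first appearance
    stage_rates: np.ndarray  # (3,) cT1->T2, T2->T3, T3->M per year
    grade_rates: np.ndarray  # (2,) <=6 -> 7, 7 -> >=8 per year
    dx_rate: np.ndarray  # (4, 3) clinical-diagnosis hazard by (stage, grade)
    psa_log_median: np.ndarray  # (4, 3) log PSA median by (stage, grade)
    psa_sigma: float  # lognormal sd of state-conditional PSA
    benign_log_median_at_35: float
    benign_log_slope: float  # per year of age
    benign_sigma: float

    def __post_init__(self):
        for name in ("init_grade_probs", "stage_rates", "grade_rates", "dx_rate", "psa_log_median"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.init_grade_probs.shape != (3,) or not np.isclose(self.init_grade_probs.sum(), 1.0):
            raise ConfigError("init_grade_probs must be 3 probabilities summing to 1")
        if self.stage_rates.shape != (3,) or self.grade_rates.shape != (2,):
            raise ConfigError("variant P needs 3 stage rates and 2 grade rates")
        if self.dx_rate.shape != (4, 3) or np.any(self.dx_rate < 0):
            raise ConfigError("dx_rate must be a nonnegative (4, 3) matrix")
        if np.any(self.stage_rates < 0) or np.any(self.grade_rates < 0):
            raise ConfigError("transition rates must be nonnegative")


@dataclass(frozen=True)
class VariantFParams:
    grade_mix_edges: np.ndarray  # onset-age band edges, len m+1
    grade_mix: np.ndarray  # (m, 3) grade probabilities by onset-age band
    psa_log_intercept: float  # log PSA at the age origin, cancer-free
    psa_pre_slope: float  # log-PSA per year of age before onset
    psa_post_slope: np.ndarray  # (3,) additional slope after onset, by grade
    psa_sigma: float  # per-person frozen lognormal noise
    dx_coef: float  # diagnosis hazard per (ng/mL * year)
    met_coef: float  # metastasis hazard per (ng/mL * year)

    def __post_init__(self):
        for name in ("grade_mix_edges", "grade_mix", "psa_post_slope"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.grade_mix.ndim != 2 or self.grade_mix.shape[1] != 3:
            raise ConfigError("grade_mix must be (bands, 3)")
        if self.grade_mix_edges.shape[0] != self.grade_mix.shape[0] + 1:
            raise ConfigError("grade_mix_edges must have one more entry than bands")
        if not np.allclose(self.grade_mix.sum(axis=1), 1.0):
            raise ConfigError("grade_mix rows must sum to 1")
        if self.psa_post_slope.shape != (3,):
            raise ConfigError("psa_post_slope needs one value per grade")
        if np.any(np.diff(self.psa_post_slope) < 0):
            raise ConfigError("post-onset PSA slopes must be nondecreasing in grade")
        if np.any(self.psa_post_slope < 0):
            raise ConfigError("post-onset PSA slopes must be >= pre-onset slope")
        if self.dx_coef < 0 or self.met_coef < 0:
            raise ConfigError("PSA link coefficients must be nonnegative")


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Shared onset model plus the variant-specific blocks."""

    onset_edges: np.ndarray  # age band edges from 35, len k+1
    onset_hazard: np.ndarray  # (k,) onset hazard per year within band
    variant_p: VariantPParams | None = None
    variant_f: VariantFParams | None = None
    dx_mult: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        object.__setattr__(self, "onset_edges", np.asarray(self.onset_edges, dtype=float))
        object.__setattr__(self, "onset_hazard", np.asarray(self.onset_hazard, dtype=float))
        object.__setattr__(self, "dx_mult", np.asarray(self.dx_mult, dtype=float))
        if self.onset_edges.shape[0] != self.onset_hazard.shape[0] + 1:
            raise ConfigError("onset_edges must have one more entry than onset_hazard")
        if np.any(self.onset_hazard < 0):
            raise ConfigError("onset hazards must be nonnegative")
        if self.dx_mult.shape != (DX_MULT_EDGES.shape[0] - 1,) or np.any(self.dx_mult < 0):
            raise ConfigError("dx_mult must be 3 nonnegative age-band multipliers")

    def require(self, variant: str):
        if variant == "P":
            if self.variant_p is None:
                raise ConfigError("variant P parameters missing")
            return self.variant_p
        if variant == "F":
            if self.variant_f is None:
                raise ConfigError("variant F parameters missing")
            return self.variant_f
        raise ConfigError(f"unknown variant {variant!r}")

    def with_dx_mult(self, mult) -> "NaturalHistoryParams":
        return replace(self, dx_mult=np.asarray(mult, dtype=float))


# ---------------------------------------------------------------------------
# Vectorized cohort sampling (structure-of-arrays).


@dataclass
class CourseArrays:
    """Disease courses for a cohort; ``inf`` encodes "never happens".

    Grade/stage transition ages describe the no-screening path up to clinical
    diagnosis; progression stops at diagnosis.
    """

    onset_age: np.ndarray
    grade_onset: np.ndarray  # grade index at onset (or first appearance)
    g7_age: np.ndarray  # age reaching grade 7 (variant P; else onset or inf)
    g8_age: np.ndarray
    t2_age: np.ndarray  # variant P stage transitions; inf for variant F
    t3_age: np.ndarray
    met_age: np.ndarray
    cdx_age: np.ndarray  # clinical (symptomatic) diagnosis age
    psa_noise: np.ndarray | None = None  # variant F frozen log-noise

    @property
    def n(self) -> int:
        return self.onset_age.shape[0]

    def grade_at(self, age) -> np.ndarray:
        """Grade index at ``age`` (valid for ages at or after onset)."""
        age = np.asarray(age, dtype=float)
        return (age >= self.g7_age).astype(int) + (age >= self.g8_age).astype(int)

    def stage_at(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return (
            (age >= self.t2_age).astype(int)
            + (age >= self.t3_age).astype(int)
            + (age >= self.met_age).astype(int)
        )

    def has_cancer_at(self, age) -> np.ndarray:
        return np.asarray(age, dtype=float) >= self.onset_age

    def metastatic_at(self, age) -> np.ndarray:
        return np.asarray(age, dtype=float) >= self.met_age


def sample_onset(params: NaturalHistoryParams, n: int, rng) -> np.ndarray:
    """Onset ages by inversion of the piecewise-constant onset hazard."""
    start = np.full(n, float(params.onset_edges[0]))
    return sample_piecewise_exponential(
        start, params.onset_edges, params.onset_hazard, rng.random(n), t_max=AGE_CAP
    )


def simulate_courses_P(params: NaturalHistoryParams, n: int, rng) -> CourseArrays:
    """Vectorized variant-P cohort: competing exponential clocks.

    The draw stream is shape-deterministic (fixed arrays per step), so two
    runs with the same seed and ``n`` consume identical randomness even when
    parameters differ — the basis for common-random-number calibration.
    """
    p = params.require("P")
    onset = sample_onset(params, n, rng)

    grade = _draw_categorical(np.broadcast_to(p.init_grade_probs, (n, 3)), rng.random(n))
    stage = np.zeros(n, dtype=int)
    age = onset.copy()
    cdx = np.full(n, np.inf)
    g7 = np.where(grade >= 1, onset, np.inf)
    g8 = np.where(grade >= 2, onset, np.inf)
    t2 = np.full(n, np.inf)
    t3 = np.full(n, np.inf)
    met = np.full(n, np.inf)

    max_steps = 6  # 3 stage moves + 2 grade moves + diagnosis
    for _ in range(max_steps):
        u_time = rng.random(n)
        u_type = rng.random(n)
        active = np.isfinite(age) & ~np.isfinite(cdx) & (age < AGE_CAP)
        if not active.any():
            continue  # keep consuming draws for stream determinism
        idx = np.where(active)[0]
        st, gr, a0 = stage[idx], grade[idx], age[idx]
        r_stage = np.where(st < 3, p.stage_rates[np.minimum(st, 2)], 0.0)
        r_grade = np.where(gr < 2, p.grade_rates[np.minimum(gr, 1)], 0.0)
        const = r_stage + r_grade
        d_base = p.dx_rate[st, gr]
        rates = const[:, None] + d_base[:, None] * params.dx_mult[None, :]
        t_ev = sample_piecewise_exponential(a0, DX_MULT_EDGES, rates, u_time[idx], t_max=AGE_CAP)
        ev_ok = np.isfinite(t_ev) & (t_ev < AGE_CAP)
        band = np.clip(np.searchsorted(DX_MULT_EDGES, t_ev, side="right") - 1, 0, 2)
        d_here = d_base * params.dx_mult[band]
        tot = const + d_here
        with np.errstate(invalid="ignore", divide="ignore"):
            p_stage = np.where(tot > 0, r_stage / tot, 0.0)
            p_grade = np.where(tot > 0, r_grade / tot, 0.0)
        u = u_type[idx]
        is_stage = ev_ok & (u < p_stage)
        is_grade = ev_ok & ~is_stage & (u < p_stage + p_grade)
        is_dx = ev_ok & ~is_stage & ~is_grade

        gidx = idx[is_stage]
        new_stage = stage[gidx] + 1
        stage[gidx] = new_stage
        t2[gidx[new_stage == 1]] = t_ev[is_stage][new_stage == 1]
        t3[gidx[new_stage == 2]] = t_ev[is_stage][new_stage == 2]
        met[gidx[new_stage == 3]] = t_ev[is_stage][new_stage == 3]

        gidx = idx[is_grade]
        new_grade = grade[gidx] + 1
        grade[gidx] = new_grade
        g7[gidx[new_grade == 1]] = t_ev[is_grade][new_grade == 1]
        g8[gidx[new_grade == 2]] = t_ev[is_grade][new_grade == 2]

        cdx[idx[is_dx]] = t_ev[is_dx]
        age[idx] = np.where(ev_ok, t_ev, np.inf)

    # reset grade/stage bookkeeping to grade at onset for path reconstruction
    grade_onset = np.where(np.isfinite(onset), _grade_at_onset(g7, g8, onset), 0)
    return CourseArrays(
        onset_age=onset,
        grade_onset=grade_onset,
        g7_age=g7,
        g8_age=g8,
        t2_age=t2,
        t3_age=t3,
        met_age=met,
        cdx_age=cdx,
    )


def _grade_at_onset(g7, g8, onset):
    return (g7 <= onset).astype(int) + (g8 <= onset).astype(int)


def _draw_categorical(probs: np.ndarray, u: np.ndarray) -> np.ndarray:
    cdf = np.cumsum(probs, axis=1)
    return (u[:, None] > cdf).sum(axis=1)


def simulate_courses_F(params: NaturalHistoryParams, n: int, rng) -> CourseArrays:
    """Vectorized variant-F cohort: PSA-linked diagnosis and metastasis."""
    f = params.require("F")
    onset = sample_onset(params, n, rng)
    has = np.isfinite(onset)

    band = np.clip(
        np.searchsorted(f.grade_mix_edges, np.where(has, onset, f.grade_mix_edges[0]), side="right") - 1,
        0,
        f.grade_mix.shape[0] - 1,
    )
    grade = _draw_categorical(f.grade_mix[band], rng.random(n))
    noise = rng.normal(0.0, f.psa_sigma, n)

    # PSA at onset (lognormal noise frozen per man)
    on_safe = np.where(has, onset, PSA_AGE_ORIGIN)
    log_p0 = f.psa_log_intercept + f.psa_pre_slope * (on_safe - PSA_AGE_ORIGIN) + noise
    growth = f.psa_pre_slope + f.psa_post_slope[grade]

    u_dx = rng.random(n)
    u_met = rng.random(n)
    cdx = np.full(n, np.inf)
    met = np.full(n, np.inf)
    if has.any():
        cdx_h = sample_expgrowth_piecewise(
            on_safe[has],
            np.exp(log_p0[has]),
            growth[has],
            f.dx_coef,
            DX_MULT_EDGES,
            params.dx_mult,
            u_dx[has],
            t_max=AGE_CAP,
        )
        met_h = sample_expgrowth_piecewise(
            on_safe[has],
            np.exp(log_p0[has]),
            growth[has],
            f.met_coef,
            DX_MULT_EDGES,
            np.ones_like(params.dx_mult),
            u_met[has],
            t_max=AGE_CAP,
        )
        cdx[has] = cdx_h
        met[has] = np.where(met_h <= cdx_h, met_h, np.inf)  # metastasis before dx only

    inf = np.full(n, np.inf)
    return CourseArrays(
        onset_age=onset,
        grade_onset=np.where(has, grade, 0),
        g7_age=np.where(has & (grade >= 1), onset, np.inf),
        g8_age=np.where(has & (grade >= 2), onset, np.inf),
        t2_age=inf.copy(),
        t3_age=inf.copy(),
        met_age=met,
        cdx_age=cdx,
        psa_noise=noise,
    )


def simulate_courses(params: NaturalHistoryParams, variant: str, n: int, rng) -> CourseArrays:
    if variant == "P":
        return simulate_courses_P(params, n, rng)
    if variant == "F":
        return simulate_courses_F(params, n, rng)
    raise ConfigError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# PSA observation models.


def psa_level_F(
    params: VariantFParams,
    age,
    onset_age,
    grade,
    noise,
) -> np.ndarray:
    """Deterministic variant-F PSA level given the frozen per-person draw.

    log PSA = intercept + pre_slope*(age-35) + post_slope[grade]*(age-onset)+
    + noise.
    """
    age = np.asarray(age, dtype=float)
    onset_age = np.asarray(onset_age, dtype=float)
    since = np.clip(age - onset_age, 0.0, None)
    since = np.where(np.isfinite(onset_age), since, 0.0)
    log_p = (
        params.psa_log_intercept
        + params.psa_pre_slope * (age - PSA_AGE_ORIGIN)
        + params.psa_post_slope[np.asarray(grade, dtype=int)] * since
        + np.asarray(noise, dtype=float)
    )
    return np.exp(log_p)


def psa_at_state_P(
    params: VariantPParams,
    age,
    has_cancer,
    stage,
    grade,
    z,
) -> np.ndarray:
    """Variant-P PSA observation: state-conditional lognormal draw.

    ``z`` are standard-normal draws (supplied so alternative strategies can
    share them). Cancer-free men use a benign distribution whose median
    grows log-linearly with age.
    """
    age = np.asarray(age, dtype=float)
    has_cancer = np.asarray(has_cancer, dtype=bool)
    benign = params.benign_log_median_at_35 + params.benign_log_slope * (age - PSA_AGE_ORIGIN)
    sick = params.psa_log_median[np.asarray(stage, dtype=int), np.asarray(grade, dtype=int)]
    mu = np.where(has_cancer, sick, benign)
    sigma = np.where(has_cancer, params.psa_sigma, params.benign_sigma)
    return np.exp(mu + sigma * np.asarray(z, dtype=float))


# ---------------------------------------------------------------------------
# Scalar (per-person) API mirroring the vectorized cohort samplers.


@dataclass
class DiseaseCourse:
    """One man's latent-to-clinical trajectory."""

    onset_age: float | None
    grade_path: list  # [(age, grade index)]
    stage_path: list  # [(age, stage index)] — variant P
    metastasis_age: float | None
    clinical_dx_age: float | None
    psa_params: dict | None = None  # variant F: grade, noise, onset

    def grade_at(self, age: float) -> int:
        g = 0
        for a, gi in self.grade_path:
            if age >= a:
                g = gi
        return g

    def stage_at(self, age: float) -> int:
        s = 0
        for a, si in self.stage_path:
            if age >= a:
                s = si
        return s


def _course_from_arrays(arr: CourseArrays, i: int, params: NaturalHistoryParams, variant: str):
    def opt(x):
        return float(x) if np.isfinite(x) else None

    onset = opt(arr.onset_age[i])
    grade_path, stage_path = [], []
    if onset is not None:
        grade_path.append((onset, int(arr.grade_onset[i])))
        if np.isfinite(arr.g7_age[i]) and arr.g7_age[i] > arr.onset_age[i]:
            grade_path.append((float(arr.g7_age[i]), 1))
        if np.isfinite(arr.g8_age[i]) and arr.g8_age[i] > arr.onset_age[i]:
            grade_path.append((float(arr.g8_age[i]), 2))
        stage_path.append((onset, 0))
        for t, s in ((arr.t2_age[i], 1), (arr.t3_age[i], 2), (arr.met_age[i], 3)):
            if np.isfinite(t):
                stage_path.append((float(t), s))
    psa_params = None
    if variant == "F" and arr.psa_noise is not None:
        psa_params = {
            "grade": int(arr.grade_onset[i]),
            "noise": float(arr.psa_noise[i]),
            "onset_age": onset,
        }
    return DiseaseCourse(
        onset_age=onset,
        grade_path=grade_path,
        stage_path=stage_path,
        metastasis_age=opt(arr.met_age[i]),
        clinical_dx_age=opt(arr.cdx_age[i]),
        psa_params=psa_params,
    )


def sample_disease_course_P(params: NaturalHistoryParams, rng) -> DiseaseCourse:
    """One variant-P disease course (see :func:`simulate_courses_P`)."""
    arr = simulate_courses_P(params, 1, rng)
    return _course_from_arrays(arr, 0, params, "P")


def sample_disease_course_F(params: NaturalHistoryParams, rng) -> DiseaseCourse:
    """One variant-F disease course (see :func:`simulate_courses_F`)."""
    arr = simulate_courses_F(params, 1, rng)
    return _course_from_arrays(arr, 0, params, "F")


def psa_level(params: NaturalHistoryParams, course: DiseaseCourse, age: float) -> float:
    """Variant-F PSA at ``age`` — deterministic given the frozen noise draw."""
    f = params.require("F")
    if age < PSA_AGE_ORIGIN:
        raise ValueError(f"age must be >= {PSA_AGE_ORIGIN}")
    pp = course.psa_params or {"grade": 0, "noise": 0.0, "onset_age": course.onset_age}
    onset = pp["onset_age"] if pp["onset_age"] is not None else np.inf
    return float(psa_level_F(f, age, onset, pp["grade"], pp["noise"]))
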