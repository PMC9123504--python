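"""Application of PSA screening strategies to simulated lives.

A strategy is one or a few protocol test ages with a common start year. A
man is tested at a protocol age if he reaches it alive, undiagnosed, and
inside the program window; a PSA above the biopsy threshold triggers a
12-core biopsy, which detects existing cancer with the biopsy sensitivity
and is a (counted) false positive in cancer-free men. Detection ends a
man's participation; a negative biopsy does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PROGRAM_END_YEAR = 2040  # protocol tests occur within the 2022-2040 window


class StrategyError(ValueError):
    pass


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class Strategy:
    """Screening protocol: test ages, start year, biopsy rule, attendance."""

    test_ages: tuple
    start_year: int = 2022
    threshold: float = 10.0  # ng/mL, biopsy iff PSA strictly above
    sensitivity: float = 0.8
    attendance: float = 1.0
    end_year: int = PROGRAM_END_YEAR

    def __post_init__(self):
        ages = tuple(int(a) for a in self.test_ages)
        object.__setattr__(self, "test_ages", ages)
        if len(ages) == 0:
            raise StrategyError("at least one test age required")
        if list(ages) != sorted(ages) or len(set(ages)) != len(ages):
            raise StrategyError("test ages must be strictly increasing")
        if ages[0] < 40 or ages[-1] > 84:
            raise StrategyError("test ages must lie within [40, 84]")
        if self.threshold <= 0:
            raise StrategyError("biopsy threshold must be positive")
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.attendance <= 1.0):
            raise StrategyError("sensitivity and attendance must lie in [0, 1]")

    @property
    def label(self) -> str:
        return "+".join(str(a) for a in self.test_ages)


@dataclass
class ScreenArm:
    """Vectorized screening outcomes for one cohort under one strategy.

    Per-person arrays (length n): detection flags and attributes; per-test
    event arrays (one entry per performed test) for resource counting.
    """

    n: int
    # per-test events
    test_person: np.ndarray
    test_age: np.ndarray
    test_year: np.ndarray
    test_psa: np.ndarray
    test_biopsied: np.ndarray
    test_detected: np.ndarray
    # per-person detection summary
    detected: np.ndarray
    det_age: np.ndarray
    det_year: np.ndarray
    det_stage: np.ndarray  # variant-P stage index at detection (0 for F localized)
    det_stage_class: np.ndarray  # 0 localized, 1 metastatic
    det_grade: np.ndarray
    overdiagnosed: np.ndarray
    lead_time: np.ndarray  # counterfactual dx age - detection age; nan if overdx

    @property
    def n_tests(self) -> int:
        return int(self.test_person.shape[0])

    @property
    def n_biopsies(self) -> int:
        return int(self.test_biopsied.sum())


def classify_detections(det_age, cdx_age, death_noscreen_age):
    """Overdiagnosis flag and lead time for screen detections.

    A detection is overdiagnosed iff, without screening, the man would never
    have been clinically diagnosed within his lifetime; otherwise the lead
    time is the counterfactual diagnosis age minus the detection age.
    """
    cdx = np.asarray(cdx_age, dtype=float)
    death = np.asarray(death_noscreen_age, dtype=float)
    overdx = ~(cdx < death)
    lead = np.where(overdx, np.nan, cdx - np.asarray(det_age, dtype=float))
    if np.any(lead[~overdx & np.isfinite(lead)] < -1e-9):
        raise ContractError("negative lead time: detection after counterfactual diagnosis")
    return overdx, lead


def run_screening(
    strategy: Strategy,
    birth_year: np.ndarray,
    entry_year: np.ndarray,
    death_noscreen: np.ndarray,
    cdx_age: np.ndarray,
    onset_age: np.ndarray,
    psa_of,
    state_of,
    u_attend: np.ndarray,
    u_sens: np.ndarray,
) -> ScreenArm:
    """Apply one strategy to a cohort (vectorized over men and test slots).

    Parameters
    ----------
    psa_of : callable(slot, idx, age) -> PSA values for the men ``idx`` at
        ``age``; strategy-independent draws keyed by slot give common random
        numbers across strategies.
    state_of : callable(idx, age) -> (stage_index, stage_class, grade) at a
        test age for men ``idx``.
    u_attend, u_sens : (n_slots, n) uniforms shared across strategies.
    """
    n = birth_year.shape[0]
    detected = np.zeros(n, dtype=bool)
    det_age = np.full(n, np.nan)
    det_year = np.full(n, -1, dtype=int)
    det_stage = np.zeros(n, dtype=int)
    det_stage_class = np.zeros(n, dtype=int)
    det_grade = np.zeros(n, dtype=int)

    ev_person, ev_age, ev_year, ev_psa, ev_biop, ev_det = [], [], [], [], [], []

    for slot, age in enumerate(strategy.test_ages):
        year = birth_year + age
        eligible = (
            (year >= strategy.start_year)
            & (year <= strategy.end_year)
            & (year >= entry_year)
            & (death_noscreen > age)
            & (cdx_age > age)
            & ~detected
        )
        attends = eligible & (u_attend[slot] < strategy.attendance)
        idx = np.where(attends)[0]
        if idx.size == 0:
            continue
        psa = psa_of(slot, idx, float(age))
        biopsy = psa > strategy.threshold
        cancer = onset_age[idx] <= age
        det = biopsy & cancer & (u_sens[slot][idx] < strategy.sensitivity)

        ev_person.append(idx)
        ev_age.append(np.full(idx.size, age))
        ev_year.append(year[idx])
        ev_psa.append(psa)
        ev_biop.append(biopsy)
        ev_det.append(det)

        hit = idx[det]
        detected[hit] = True
        det_age[hit] = age
        det_year[hit] = year[hit]
        stage, stage_class, grade = state_of(hit, float(age))
        det_stage[hit] = stage
        det_stage_class[hit] = stage_class
        det_grade[hit] = grade

    if ev_person:
        test_person = np.concatenate(ev_person)
        test_age = np.concatenate(ev_age)
        test_year = np.concatenate(ev_year)
        test_psa = np.concatenate(ev_psa)
        test_biopsied = np.concatenate(ev_biop)
        test_detected = np.concatenate(ev_det)
    else:
        test_person = np.empty(0, dtype=int)
        test_age = np.empty(0)
        test_year = np.empty(0, dtype=int)
        test_psa = np.empty(0)
        test_biopsied = np.empty(0, dtype=bool)
        test_detected = np.empty(0, dtype=bool)

    overdx = np.zeros(n, dtype=bool)
    lead = np.full(n, np.nan)
    if detected.any():
        o, l = classify_detections(
            det_age[detected], cdx_age[detected], death_noscreen[detected]
        )
        overdx[detected] = o
        lead[detected] = l

    return ScreenArm(
        n=n,
        test_person=test_person,
        test_age=test_age,
        test_year=test_year,
        test_psa=test_psa,
        test_biopsied=test_biopsied,
        test_detected=test_detected,
        detected=detected,
        det_age=det_age,
        det_year=det_year,
        det_stage=det_stage,
        det_stage_class=det_stage_class,
        det_grade=det_grade,
        overdiagnosed=overdx,
        lead_time=lead,
    )


# ---------------------------------------------------------------------------
# Scalar API over single disease courses.


@dataclass
class ScreenRecord:
    """One performed screening test."""

    test_age: float
    test_year: int
    psa_value: float
    biopsied: bool
    detected: bool
    detected_stage: int | None = None
    detected_grade: int | None = None
    lead_time: float | None = None
    overdiagnosed: bool | None = None


def apply_strategy(course, birth_year, death_noscreen_age, strategy, params, variant, rng):
    """Screen one man; returns the list of performed tests.

    ``course`` is a :class:`~prostasim.natural_history.DiseaseCourse`;
    ``death_noscreen_age`` is his no-screening death age (either cause).
    """
    from . import natural_history as nh

    records = []
    detected = False
    cdx = course.clinical_dx_age if course.clinical_dx_age is not None else np.inf
    onset = course.onset_age if course.onset_age is not None else np.inf
    for age in strategy.test_ages:
        year = birth_year + age
        if detected or year < strategy.start_year or year > strategy.end_year:
            continue
        if death_noscreen_age <= age or cdx <= age:
            continue
        if rng.random() >= strategy.attendance:
            continue
        if variant == "F":
            psa = nh.psa_level(params, course, float(age))
        else:
            p = params.require("P")
            has = onset <= age
            psa = float(
                nh.psa_at_state_P(
                    p, age, has, course.stage_at(age), course.grade_at(age), rng.normal()
                )
            )
        biopsied = psa > strategy.threshold
        has_cancer = onset <= age
        det = bool(biopsied and has_cancer and rng.random() < strategy.sensitivity)
        rec = ScreenRecord(
            test_age=float(age),
            test_year=int(year),
            psa_value=psa,
            biopsied=bool(biopsied),
            detected=det,
        )
        if det:
            detected = True
            rec.detected_stage = course.stage_at(age)
            rec.detected_grade = course.grade_at(age)
            o, l = classify_detections(
                np.array([age], dtype=float),
                np.array([cdx]),
                np.array([death_noscreen_age]),
            )
            rec.overdiagnosed = bool(o[0])
            rec.lead_time = None if rec.overdiagnosed else float(l[0])
        records.append(rec)
    return records


def classify_detection(record: ScreenRecord, cdx_age, death_noscreen_age):
    """Scalar overdiagnosis/lead-time classification for a detected record."""
    if not record.detected:
        raise ContractError("classify_detection requires a detected record")
    cdx = np.inf if cdx_age is None else cdx_age
    o, l = classify_detections(
        np.array([record.test_age]), np.array([cdx], dtype=float), np.array([death_noscreen_age], dtype=float)
    )
    return bool(o[0]), (None if o[0] else float(l[0]))
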