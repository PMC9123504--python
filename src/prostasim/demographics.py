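"""Lifetables, other-cause mortality, and population bookkeeping.

Other-cause (non prostate cancer) death is governed by an annual lifetable
``q(a)`` — the probability a man alive at exact age ``a`` dies before ``a+1``.
Published tables stop at 84; :func:`extrapolate_lifetable` extends them with
Holt-Winters double exponential smoothing on the log hazard and closes the
table so every simulated life is finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class LifeTableError(ValueError):
    """Raised for malformed lifetable inputs."""


@dataclass(frozen=True)
class LifeTable:
    """Annual other-cause death probabilities by single year of age.

    ``q[i]`` is the probability of death in the year of age ``ages[i]``.
    A *closed* table has ``q == 1`` at its final age, so no one survives it.
    """

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)
        if ages.ndim != 1 or q.shape != ages.shape or ages.size == 0:
            raise LifeTableError("ages and q must be matching 1-d arrays")
        if not np.all(np.diff(ages) == 1):
            raise LifeTableError("ages must increase in steps of one year")
        if np.any(q < 0) or np.any(q > 1) or not np.all(np.isfinite(q)):
            raise LifeTableError("q values must lie in [0, 1]")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def is_closed(self) -> bool:
        return bool(self.q[-1] >= 1.0)

    def hazard(self) -> np.ndarray:
        """Continuous-time hazard per year of age, -log(1 - q)."""
        q = np.clip(self.q, 0.0, 1.0 - 1e-12)
        return -np.log1p(-q)

    def survival_from(self, age: int) -> np.ndarray:
        """P(survive j further whole years | alive at ``age``), j = 0.."""
        i = int(age) - self.min_age
        if i < 0 or i >= self.ages.size:
            raise LifeTableError(f"age {age} outside table range")
        return np.concatenate([[1.0], np.cumprod(1.0 - self.q[i:])])

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        if not {"age", "qx"}.issubset(df.columns):
            raise LifeTableError("lifetable CSV needs columns age,qx")
        df = df.sort_values("age")
        return cls(ages=df["age"].to_numpy(), q=df["qx"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.q}).to_csv(path, index=False)


@dataclass(frozen=True)
class PopulationPyramid:
    """Men per single year of age at the baseline year, plus cohort entry."""

    ages: np.ndarray
    counts: np.ndarray
    baseline_year: int = 2020
    annual_entrants: int = 0

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "counts", counts)
        if ages.size == 0:
            raise ValueError("empty pyramid")
        if np.any(counts < 0):
            raise ValueError("pyramid counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def weights(self) -> np.ndarray:
        """Normalized age weights (the direct-standardization standard)."""
        return self.counts / self.counts.sum()

    @classmethod
    def from_csv(cls, path, baseline_year: int = 2020, annual_entrants: int = 0):
        df = pd.read_csv(path).sort_values("age")
        return cls(
            ages=df["age"].to_numpy(),
            counts=df["count"].to_numpy(),
            baseline_year=baseline_year,
            annual_entrants=annual_entrants,
        )

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "count": self.counts}).to_csv(path, index=False)


def extrapolate_lifetable(lt: LifeTable, target_max_age: int) -> LifeTable:
    """Extend a lifetable to ``target_max_age`` by Holt-Winters forecasting.

    The forecast is double exponential smoothing (additive trend, no
    seasonality) applied to the log mortality hazard over age, fitted on the
    observed tail (ages >= 60 where available). Forecast probabilities are
    clipped to (0, 1]; one closing row with q = 1 is appended at
    ``target_max_age + 1`` so the returned table is closed.

    Tables already reaching ``target_max_age`` are returned unchanged.
    """
    if lt.ages.size < 10:
        raise LifeTableError("need at least 10 ages to extrapolate")
    if int(target_max_age) <= lt.max_age:
        return lt

    from statsmodels.tsa.holtwinters import Holt

    fit_lo = max(lt.min_age, 60) if lt.max_age >= 70 else lt.min_age
    sel = lt.ages >= fit_lo
    log_h = np.log(lt.hazard()[sel])
    if not np.all(np.isfinite(log_h)):
        raise LifeTableError("zero or invalid hazards in the fitting tail")

    n_ahead = int(target_max_age) - lt.max_age
    model = Holt(log_h, initialization_method="estimated")
    fitted = model.fit(optimized=True)
    fc = np.asarray(fitted.forecast(n_ahead))
    q_new = np.clip(-np.expm1(-np.exp(fc)), 1e-12, 1.0)

    ages = np.concatenate([lt.ages, np.arange(lt.max_age + 1, target_max_age + 2)])
    q = np.concatenate([lt.q, q_new, [1.0]])
    return LifeTable(ages=ages, q=q)


def sample_other_cause_death_age(current_age: float, lt: LifeTable, rng) -> float:
    """Draw one age at other-cause death for a man alive at ``current_age``.

    Within the year of death the death time is uniform. A fractional current
    age is handled by thinning the first year's death probability.
    """
    if current_age > lt.max_age:
        raise LifeTableError("current_age beyond the lifetable")
    a0 = int(np.floor(current_age))
    frac = current_age - a0
    i = a0 - lt.min_age
    for j in range(i, lt.ages.size):
        qj = lt.q[j]
        lo = current_age if j == i else float(lt.ages[j])
        # uniform death time within the year => conditional death probability
        width = lt.ages[j] + 1.0 - lo
        p = qj * width / (1.0 - qj * (1.0 - width)) if width < 1.0 else qj
        if rng.random() < p:
            return float(lo + rng.random() * width)
    return float(lt.ages[-1] + rng.random())  # closed table: q=1 at final age


def sample_death_ages(current_ages: np.ndarray, lt: LifeTable, rng) -> np.ndarray:
    """Vectorized other-cause death ages for integer current ages.

    Consumes exactly two uniforms per subject regardless of outcome, so the
    draw stream is shape-deterministic (needed for common random numbers).
    """
    ages = np.asarray(current_ages)
    if not np.allclose(ages, np.round(ages)):
        raise LifeTableError("vectorized sampler requires integer current ages")
    ages = np.round(ages).astype(int)
    if ages.max(initial=lt.min_age) > lt.max_age or ages.min(initial=lt.max_age) < lt.min_age:
        raise LifeTableError("current ages outside the lifetable")
    if not lt.is_closed:
        raise LifeTableError("lifetable must be closed (q=1 at final age)")

    n = ages.shape[0]
    u_year = rng.random(n)
    u_frac = rng.random(n)
    out = np.empty(n, dtype=float)
    for a0 in np.unique(ages):
        mask = ages == a0
        surv = lt.survival_from(a0)  # P(survive j whole years)
        cdf = 1.0 - surv[1:]  # P(die within j+1 years)
        k = np.searchsorted(cdf, u_year[mask], side="right")
        k = np.minimum(k, cdf.size - 1)
        out[mask] = a0 + k + u_frac[mask]
    return out


@dataclass(frozen=True)
class PersonStubs:
    """Plain arrays describing who is simulated: one row per man."""

    birth_year: np.ndarray
    baseline_age: np.ndarray  # age at first simulated calendar year (entry)
    entry_year: np.ndarray

    @property
    def n(self) -> int:
        return self.birth_year.shape[0]


def build_population(
    pyramid: PopulationPyramid,
    start_year: int,
    end_year: int,
    multiplier: float = 1.0,
) -> PersonStubs:
    """Enumerate every simulated man: baseline residents plus age-40 entrants.

    Baseline men carry the pyramid's integer ages at ``pyramid.baseline_year``;
    entrants arrive at exact age 40 on January 1 of each year from
    ``baseline_year + 1`` through ``end_year``. Deterministic — counts are
    scaled by ``multiplier`` and rounded.
    """
    if start_year > end_year:
        raise ValueError("start_year must not exceed end_year")
    if pyramid.total == 0 and pyramid.annual_entrants == 0:
        raise ValueError("empty pyramid")

    counts = np.round(pyramid.counts * multiplier).astype(int)
    base_ages = np.repeat(pyramid.ages, counts)
    base_birth = pyramid.baseline_year - base_ages
    base_entry = np.full(base_ages.shape, pyramid.baseline_year)

    entry_years = np.arange(pyramid.baseline_year + 1, end_year + 1)
    n_ent = int(round(pyramid.annual_entrants * multiplier))
    ent_entry = np.repeat(entry_years, n_ent)
    ent_ages = np.full(ent_entry.shape, 40)
    ent_birth = ent_entry - 40

    return PersonStubs(
        birth_year=np.concatenate([base_birth, ent_birth]),
        baseline_age=np.concatenate([base_ages, ent_ages]).astype(float),
        entry_year=np.concatenate([base_entry, ent_entry]),
    )
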