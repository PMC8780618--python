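"""Cohort life tables and demographic parameters from rearing records.

A daily census of adult females yields survivorship ``l_x`` and age-specific
female fecundity ``m_x`` at pivotal ages ``x = d - 0.5``; from the schedule
come the net reproductive rate R0 = sum(l_x m_x), the cohort generation time
T = sum(x l_x m_x)/R0, the intrinsic rate of increase r (either Birch's
approximation ln(R0)/T or the exact root of sum(exp(-r x) l_x m_x) = 1),
the doubling time ln(2)/r and the finite rate of increase exp(r).
Confidence intervals use leave-one-female-out jackknife pseudo-values, with a
seeded bootstrap over females as an alternative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    EmptyCohortError,
    NumericError,
    SampleSizeError,
    SolverError,
    ValidationError,
)

__all__ = [
    "STAGES",
    "IndividualRecord",
    "LifeTableSchedule",
    "DemographicParameters",
    "SummaryStat",
    "ReproductionSummary",
    "build_life_table",
    "net_reproductive_rate",
    "generation_time",
    "intrinsic_rate_birch",
    "intrinsic_rate_lotka",
    "doubling_time",
    "finite_rate",
    "compute_parameters",
    "jackknife_parameters",
    "bootstrap_parameters",
    "reproduction_summary",
    "longevity_summary",
]

STAGES = ("egg", "L1", "L2", "L3", "pupa")

PARAMETER_NAMES = ("R0", "T", "r_m", "DT", "lambda")


@dataclass(eq=False)
class IndividualRecord:
    """One reared individual: immature stage durations, fate, and (for adult
    females) the daily egg-count trajectory from emergence to death."""

    individual_id: str
    sex: Literal["female", "male", "unknown"] = "unknown"
    stage_durations: dict[str, float] = field(default_factory=dict)
    died_in_stage: str | None = None
    adult_longevity: float = 0.0
    daily_eggs: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    eggs_hatched: int | None = None
    offspring_female_fraction: float | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male", "unknown"):
            raise ValidationError(f"invalid sex {self.sex!r}")
        unknown = set(self.stage_durations) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages {sorted(unknown)}")
        if any(v < 0 for v in self.stage_durations.values()):
            raise ValidationError("stage durations must be >= 0")
        if self.died_in_stage is not None:
            if self.died_in_stage not in STAGES:
                raise ValidationError(f"invalid stage {self.died_in_stage!r}")
            later = STAGES[STAGES.index(self.died_in_stage) + 1:]
            if any(s in self.stage_durations for s in later):
                raise ValidationError(
                    f"{self.individual_id}: durations recorded after death stage"
                )
        if self.adult_longevity < 0:
            raise ValidationError("adult_longevity must be >= 0")
        self.daily_eggs = np.asarray(self.daily_eggs, dtype=int)
        if np.any(self.daily_eggs < 0):
            raise ValidationError("daily egg counts must be >= 0")
        if self.daily_eggs.size > math.ceil(self.adult_longevity):
            raise ValidationError(
                f"{self.individual_id}: daily_eggs longer than adult lifespan"
            )

    @property
    def reached_adulthood(self) -> bool:
        return self.died_in_stage is None

    @property
    def total_eggs(self) -> int:
        return int(self.daily_eggs.sum())

    def egg_to_adult_days(self) -> float | None:
        if not self.reached_adulthood or set(STAGES) - set(self.stage_durations):
            return None
        return float(sum(self.stage_durations[s] for s in STAGES))


@dataclass
class LifeTableSchedule:
    """Rows of (pivotal age x, survivorship l_x, female fecundity m_x)."""

    x: np.ndarray
    lx: np.ndarray
    mx: np.ndarray
    age_origin: Literal["adult_emergence", "oviposition"] = "adult_emergence"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.lx = np.asarray(self.lx, dtype=float)
        self.mx = np.asarray(self.mx, dtype=float)
        if not (self.x.shape == self.lx.shape == self.mx.shape):
            raise ValidationError("x, lx, mx must have equal length")
        if self.x.size == 0:
            raise ValidationError("schedule must not be empty")
        if np.any(np.diff(self.x) <= 0):
            raise ValidationError("pivotal ages must be strictly increasing")
        if np.any(self.lx < 0) or np.any(self.lx > 1):
            raise ValidationError("l_x must lie in [0, 1]")
        if np.any(np.diff(self.lx) > 1e-12):
            raise ValidationError("l_x must be non-increasing")
        if np.any(self.mx < 0):
            raise ValidationError("m_x must be >= 0")

    @property
    def lxmx(self) -> np.ndarray:
        return self.lx * self.mx

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "lx": self.lx, "mx": self.mx,
                             "lxmx": self.lxmx})


@dataclass(frozen=True)
class DemographicParameters:
    """Point estimates; DT and lambda are derived from r_m, never stored."""

    r0: float
    t: float
    r_m: float
    r_method: Literal["birch", "lotka"]
    n_females: int
    ci_95: dict[str, tuple[float, float]] | None = None

    @property
    def dt(self) -> float:
        return doubling_time(self.r_m)

    @property
    def lam(self) -> float:
        return finite_rate(self.r_m)

    def as_dict(self) -> dict[str, float]:
        return {"R0": self.r0, "T": self.t, "r_m": self.r_m,
                "DT": self.dt, "lambda": self.lam}


def _female_cohort(records: Iterable[IndividualRecord]) -> list[IndividualRecord]:
    females = [r for r in records if r.sex == "female" and r.reached_adulthood]
    if not females:
        raise EmptyCohortError("no adult female records with oviposition data")
    return females


def build_life_table(records: Sequence[IndividualRecord],
                     age_origin: Literal["adult_emergence", "oviposition"] = "adult_emergence",
                     female_fraction: float = 0.5,
                     apply_egg_viability: bool = False,
                     egg_viability: float = 0.552,
                     apply_immature_survival: bool = False,
                     immature_duration: float | None = None) -> LifeTableSchedule:
    """Daily life table for the adult female cohort.

    For adult day d (interval (d-1, d]): l_x is the fraction of the starting
    female cohort alive during the interval and m_x the mean eggs laid per
    living female, scaled by ``female_fraction`` and optionally by egg
    viability.  With ``age_origin='oviposition'`` pivotal ages are shifted by
    the mean egg-to-adult duration (taken from the records, or
    ``immature_duration``), and ``apply_immature_survival`` additionally
    multiplies l_x by the observed egg-to-adult survival of the full cohort.
    """
    if not 0.0 <= female_fraction <= 1.0:
        raise ValidationError("female_fraction must lie in [0, 1]")
    if not 0.0 <= egg_viability <= 1.0:
        raise ValidationError("egg_viability must lie in [0, 1]")
    females = _female_cohort(records)
    n_f = len(females)
    last_day = max(max(math.ceil(f.adult_longevity), 1) for f in females)
    x = np.arange(1, last_day + 1) - 0.5
    alive = np.zeros(last_day)
    eggs = np.zeros(last_day)
    for f in females:
        days_alive = max(math.ceil(f.adult_longevity), 1)
        alive[:days_alive] += 1
        eggs[:f.daily_eggs.size] += f.daily_eggs
    lx = alive / n_f
    with np.errstate(invalid="ignore", divide="ignore"):
        mx = np.where(alive > 0, eggs / np.maximum(alive, 1), 0.0)
    mx = mx * female_fraction
    if apply_egg_viability:
        mx = mx * egg_viability
    if apply_immature_survival:
        n_all = len(records)
        survival = sum(r.reached_adulthood for r in records) / n_all
        lx = lx * survival
    if age_origin == "oviposition":
        if immature_duration is None:
            durations = [d for r in records if (d := r.egg_to_adult_days()) is not None]
            if not durations:
                raise ValidationError(
                    "oviposition origin needs complete stage durations or an "
                    "explicit immature_duration"
                )
            immature_duration = float(np.mean(durations))
        x = x + immature_duration
    elif age_origin != "adult_emergence":
        raise ValidationError(f"unknown age origin {age_origin!r}")
    return LifeTableSchedule(x=x, lx=lx, mx=mx, age_origin=age_origin)


# ---------------------------------------------------------------------------
# demographic parameters
# ---------------------------------------------------------------------------

def net_reproductive_rate(schedule: LifeTableSchedule) -> float:
    """R0 = sum l_x m_x."""
    return float(schedule.lxmx.sum())


def generation_time(schedule: LifeTableSchedule) -> float:
    """T = sum x l_x m_x / sum l_x m_x."""
    r0 = net_reproductive_rate(schedule)
    if r0 <= 0:
        raise NumericError("generation time undefined for R0 = 0")
    return float((schedule.x * schedule.lxmx).sum() / r0)


def intrinsic_rate_birch(r0: float, t: float) -> float:
    """Birch's approximation r = ln(R0)/T."""
    if r0 <= 0:
        raise ValidationError("R0 must be > 0")
    if t <= 0:
        raise ValidationError("T must be > 0")
    return math.log(r0) / t


def intrinsic_rate_lotka(schedule: LifeTableSchedule, tol: float = 1e-10) -> float:
    """Exact r solving sum(exp(-r x) l_x m_x) = 1 by Brent's method."""
    lxmx = schedule.lxmx
    x = schedule.x
    if lxmx.sum() <= 0:
        raise NumericError("no reproduction: Euler-Lotka root undefined")

    def residual(r: float) -> float:
        return float(np.exp(-r * x) @ lxmx - 1.0)

    lo, hi = -2.0, 5.0
    if residual(lo) < 0 or residual(hi) > 0:
        raise SolverError("no sign change for the Euler-Lotka root in [-2, 5]")
    r = optimize.brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16)
    if abs(residual(r)) > tol:
        raise SolverError(f"Euler-Lotka residual {residual(r):.3e} exceeds {tol:g}")
    return float(r)


def doubling_time(r_m: float) -> float:
    """DT = ln(2)/r_m; infinity (with a warning) for non-growing cohorts."""
    if r_m <= 0:
        warnings.warn("r_m <= 0: population not growing, doubling time infinite",
                      stacklevel=2)
        return math.inf
    return math.log(2.0) / r_m


def finite_rate(r_m: float) -> float:
    """lambda = exp(r_m)."""
    if not math.isfinite(r_m):
        raise ValidationError("r_m must be finite")
    return math.exp(r_m)


def compute_parameters(schedule: LifeTableSchedule,
                       r_method: Literal["birch", "lotka"] = "birch",
                       n_females: int = 0,
                       tol: float = 1e-10) -> DemographicParameters:
    r0 = net_reproductive_rate(schedule)
    t = generation_time(schedule)
    if r_method == "birch":
        r = intrinsic_rate_birch(r0, t)
    elif r_method == "lotka":
        r = intrinsic_rate_lotka(schedule, tol=tol)
    else:
        raise ValidationError(f"unknown r method {r_method!r}")
    return DemographicParameters(r0=r0, t=t, r_m=r, r_method=r_method,
                                 n_females=n_females)


def _point_estimates(records: Sequence[IndividualRecord], r_method: str,
                     build_kwargs: dict) -> np.ndarray:
    schedule = build_life_table(records, **build_kwargs)
    p = compute_parameters(schedule, r_method=r_method)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.array([p.r0, p.t, p.r_m, p.dt, p.lam])


def jackknife_parameters(records: Sequence[IndividualRecord],
                         r_method: Literal["birch", "lotka"] = "birch",
                         **build_kwargs) -> DemographicParameters:
    """Leave-one-female-out jackknife 95% CIs for R0, T, r_m, DT, lambda.

    Pseudo-values theta_j = n*theta_all - (n-1)*theta_(-j); the CI is
    mean(theta_j) +/- t_{0.975, n-1} * SE(theta_j).  The reported point
    estimate is the all-female estimate, not the pseudo-value mean.
    """
    females = _female_cohort(records)
    n = len(females)
    if n < 3:
        raise SampleSizeError("jackknife needs >= 3 female records")
    others = [r for r in records if r not in females]
    theta_all = _point_estimates(records, r_method, build_kwargs)
    pseudo = np.empty((n, theta_all.size))
    for j in range(n):
        subset = others + females[:j] + females[j + 1:]
        theta_minus = _point_estimates(subset, r_method, build_kwargs)
        pseudo[j] = n * theta_all - (n - 1) * theta_minus
    ci: dict[str, tuple[float, float]] = {}
    tcrit = stats.t.ppf(0.975, n - 1)
    for i, name in enumerate(PARAMETER_NAMES):
        col = pseudo[:, i]
        if not np.all(np.isfinite(col)):
            warnings.warn(f"non-finite jackknife pseudo-values for {name}",
                          stacklevel=2)
            ci[name] = (math.nan, math.nan)
            continue
        se = col.std(ddof=1) / math.sqrt(n)
        ci[name] = (float(col.mean() - tcrit * se), float(col.mean() + tcrit * se))
    schedule = build_life_table(records, **build_kwargs)
    point = compute_parameters(schedule, r_method=r_method, n_females=n)
    return DemographicParameters(r0=point.r0, t=point.t, r_m=point.r_m,
                                 r_method=point.r_method, n_females=n, ci_95=ci)


def bootstrap_parameters(records: Sequence[IndividualRecord],
                         r_method: Literal["birch", "lotka"] = "birch",
                         n_boot: int = 1000, seed: int = 0,
                         **build_kwargs) -> DemographicParameters:
    """Percentile bootstrap over females (seeded) as a jackknife alternative."""
    females = _female_cohort(records)
    n = len(females)
    if n < 3:
        raise SampleSizeError("bootstrap needs >= 3 female records")
    others = [r for r in records if r not in females]
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, len(PARAMETER_NAMES)))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        subset = others + [females[i] for i in idx]
        draws[b] = _point_estimates(subset, r_method, build_kwargs)
    ci = {}
    for i, name in enumerate(PARAMETER_NAMES):
        lo, hi = np.percentile(draws[:, i], [2.5, 97.5])
        ci[name] = (float(lo), float(hi))
    schedule = build_life_table(records, **build_kwargs)
    point = compute_parameters(schedule, r_method=r_method, n_females=n)
    return DemographicParameters(r0=point.r0, t=point.t, r_m=point.r_m,
                                 r_method=point.r_method, n_females=n, ci_95=ci)


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStat:
    mean: float
    se: float
    n: int


@dataclass(frozen=True)
class ReproductionSummary:
    fecundity: SummaryStat          # eggs per female per day
    fertility: SummaryStat          # % of eggs hatching
    pre_oviposition: SummaryStat    # days, emergence to first egg
    oviposition: SummaryStat        # days, first to last egg inclusive
    post_oviposition: SummaryStat   # days, last egg to death
    zero_layers: tuple[str, ...]    # females with no eggs (longevity only)
    fecundity_denominator: str


def _summ(values: list[float]) -> SummaryStat:
    if not values:
        return SummaryStat(mean=math.nan, se=math.nan, n=0)
    arr = np.asarray(values, dtype=float)
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else math.nan
    return SummaryStat(mean=float(arr.mean()), se=se, n=int(arr.size))


def reproduction_summary(records: Sequence[IndividualRecord],
                         fecundity_denominator: Literal["oviposition_days", "adult_days"]
                         = "oviposition_days") -> ReproductionSummary:
    """Table-style reproduction summary for adult females.  Females that never
    laid contribute to longevity only and are flagged in ``zero_layers``."""
    females = _female_cohort(records)
    fec, fert, pre, ovi, post = [], [], [], [], []
    zeros: list[str] = []
    for f in females:
        lay_days = np.flatnonzero(f.daily_eggs)
        if lay_days.size == 0:
            zeros.append(f.individual_id)
            continue
        first, last = int(lay_days[0]), int(lay_days[-1])
        span = last - first + 1
        pre.append(float(first))
        ovi.append(float(span))
        post.append(float(f.adult_longevity - (last + 1)))
        denom = span if fecundity_denominator == "oviposition_days" else max(
            f.adult_longevity, 1.0)
        fec.append(f.total_eggs / denom)
        if f.eggs_hatched is not None and f.total_eggs > 0:
            fert.append(100.0 * f.eggs_hatched / f.total_eggs)
    return ReproductionSummary(
        fecundity=_summ(fec), fertility=_summ(fert), pre_oviposition=_summ(pre),
        oviposition=_summ(ovi), post_oviposition=_summ(post),
        zero_layers=tuple(zeros), fecundity_denominator=fecundity_denominator,
    )


def longevity_summary(records: Sequence[IndividualRecord],
                      by: Sequence[str] = ("sex", "treatment")) -> pd.DataFrame:
    """Descriptive adult-longevity statistics per group (no inference)."""
    adults = [r for r in records if r.reached_adulthood]
    if not adults:
        raise EmptyCohortError("no adult records")
    df = pd.DataFrame({
        "sex": [r.sex for r in adults],
        "treatment": [r.treatment if r.treatment is not None else "" for r in adults],
        "longevity": [r.adult_longevity for r in adults],
    })
    grouped = df.groupby(list(by), dropna=False)["longevity"]
    out = grouped.agg(n="count", mean="mean",
                      se=lambda s: s.std(ddof=1) / math.sqrt(len(s)) if len(s) > 1 else math.nan,
                      min="min", max="max")
    return out.reset_index()
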