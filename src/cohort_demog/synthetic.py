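"""Synthetic head-capsule samples and individual-based cohorts.

Width samples are k-component lognormal mixtures whose component medians
follow a constant (or per-transition) growth ratio, so instar-calling can be
exercised against a known component count.  Cohorts are simulated individual
by individual: gamma stage durations, per-stage Bernoulli survival, a
pre-oviposition delay, an oviposition window with negative-binomial daily egg
counts, and a post-oviposition tail.  ``expected_parameters`` builds the exact
expected l_x/m_x schedule implied by a cohort configuration, giving a
deterministic oracle for parameter-recovery tests.

A single integer seed expands to per-individual substreams, so growing a
cohort does not reshuffle previously generated individuals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .demography import (
    STAGES,
    DemographicParameters,
    IndividualRecord,
    LifeTableSchedule,
    compute_parameters,
)
from .exceptions import ValidationError
from .morphometrics import HeadCapsuleSample

__all__ = [
    "MorphometryConfig",
    "CohortConfig",
    "generate_head_capsules",
    "generate_cohort",
    "expected_parameters",
    "paper_morphometry_defaults",
    "paper_cohort_defaults",
]


@dataclass(frozen=True)
class MorphometryConfig:
    """Lognormal mixture of head-capsule widths with geometric mean growth."""

    n_instars: int = 3
    base_width: float = 248.0          # um, median of the first component
    dyar_ratio: float | tuple[float, ...] = 1.5
    cv: float = 0.06                   # within-instar log-sd
    class_weights: tuple[float, ...] | None = None
    n: int = 98
    seed: int = 0
    with_lengths: bool = True
    length_ratio: float = 0.62         # median length/width allometry
    length_noise: float = 0.04

    def component_medians(self) -> np.ndarray:
        ratios = self.dyar_ratio
        if isinstance(ratios, (int, float)):
            ratios = (float(ratios),) * (self.n_instars - 1)
        if len(ratios) != self.n_instars - 1:
            raise ValidationError("need n_instars - 1 growth ratios")
        if any(r <= 1 for r in ratios):
            raise ValidationError("growth ratios must exceed 1")
        return self.base_width * np.cumprod(np.concatenate(([1.0], ratios)))

    def weights(self) -> np.ndarray:
        if self.class_weights is None:
            return np.full(self.n_instars, 1.0 / self.n_instars)
        w = np.asarray(self.class_weights, dtype=float)
        if w.size != self.n_instars or np.any(w < 0):
            raise ValidationError("class_weights must be a simplex vector of "
                                  "length n_instars")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValidationError("class_weights must sum to 1")
        return w

    def validate(self) -> None:
        if self.n_instars < 1:
            raise ValidationError("n_instars must be >= 1")
        if self.base_width <= 0:
            raise ValidationError("base_width must be positive")
        if not 0.0 < self.cv < 0.5:
            raise ValidationError("cv must lie in (0, 0.5)")
        if self.n < 1:
            raise ValidationError("n must be >= 1")
        self.component_medians()
        self.weights()


def paper_morphometry_defaults(n: int = 98, seed: int = 0) -> MorphometryConfig:
    """Three instars at the published scale: medians ~248/383/563 um with
    class weights 29/26/43 out of 98."""
    return MorphometryConfig(
        n_instars=3, base_width=248.14, dyar_ratio=(1.5447, 1.4694), cv=0.06,
        class_weights=(29 / 98, 26 / 98, 43 / 98), n=n, seed=seed,
    )


def generate_head_capsules(config: MorphometryConfig) -> HeadCapsuleSample:
    """Draw a width sample (and optional allometric lengths) from the mixture.

    Warns when adjacent components overlap by more than 50% (mode-test power
    collapses there): for log-normal components the overlap coefficient is
    2*Phi(-ln(ratio)/(2*cv)).
    """
    config.validate()
    medians = config.component_medians()
    if medians.size > 1:
        ratios = medians[1:] / medians[:-1]
        overlap = 2.0 * stats.norm.cdf(-np.log(ratios) / (2.0 * config.cv))
        if np.any(overlap > 0.5):
            warnings.warn(
                "adjacent width components overlap by more than 50%; "
                "mode-test power will collapse",
                stacklevel=2,
            )
    rng = np.random.default_rng(config.seed)
    counts = rng.multinomial(config.n, config.weights())
    widths = np.concatenate([
        med * np.exp(config.cv * rng.standard_normal(c))
        for med, c in zip(medians, counts)
    ])
    order = rng.permutation(config.n)
    widths = widths[order]
    lengths = None
    if config.with_lengths:
        lengths = (config.length_ratio * widths
                   * np.exp(config.length_noise * rng.standard_normal(config.n)))
    ids = [f"larva_{i + 1:03d}" for i in range(config.n)]
    return HeadCapsuleSample(widths=widths, lengths=lengths, larva_id=ids)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Stage-structured cohort with reproduction at the published magnitudes.

    Defaults follow the study's 27-degree rearing summaries: stage durations
    (egg/L1/L2/L3/pupa), pre-/oviposition/post-oviposition structure, daily
    fecundity, a roughly 1:1 offspring sex ratio and ~55% egg viability.
    """

    stage_means: tuple[float, ...] = (3.35, 2.6, 3.73, 2.05, 4.1)
    stage_sds: tuple[float, ...] = (1.39, 1.07, 2.09, 0.81, 1.15)
    stage_survival: tuple[float, ...] = (1.0, 0.95, 0.95, 1.0, 1.0)
    pre_ovi_mean: float = 4.05
    pre_ovi_sd: float = 1.79
    ovi_mean: float = 40.35
    ovi_sd: float = 15.8
    post_ovi_mean: float = 4.45
    post_ovi_sd: float = 4.47
    daily_fecundity_mean: float = 5.85
    fecundity_dispersion: float = 5.0   # negative-binomial shape
    egg_distribution: Literal["nbinom", "poisson"] = "nbinom"
    duration_distribution: Literal["gamma", "truncnorm"] = "gamma"
    trajectory: Literal["flat", "triangular"] = "flat"
    male_longevity_mean: float = 61.85
    male_longevity_sd: float = 26.4
    female_fraction: float = 0.5
    egg_viability: float = 0.552
    offspring_female_fraction: float = 0.5
    n_females: int = 20
    seed: int = 0

    def validate(self) -> None:
        if len(self.stage_means) != len(STAGES) or len(self.stage_sds) != len(STAGES):
            raise ValidationError(f"stage means/sds must have length {len(STAGES)}")
        if len(self.stage_survival) != len(STAGES):
            raise ValidationError(f"stage_survival must have length {len(STAGES)}")
        if any(m <= 0 for m in self.stage_means):
            raise ValidationError("stage means must be positive")
        if any(s < 0 for s in self.stage_sds):
            raise ValidationError("stage sds must be >= 0")
        if any(not 0.0 <= p <= 1.0 for p in self.stage_survival):
            raise ValidationError("stage survival must lie in [0, 1]")
        for name in ("pre_ovi_mean", "ovi_mean", "post_ovi_mean",
                     "daily_fecundity_mean", "male_longevity_mean"):
            if getattr(self, name) <= 0 and name != "post_ovi_mean":
                raise ValidationError(f"{name} must be positive")
        for name in ("female_fraction", "egg_viability",
                     "offspring_female_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.fecundity_dispersion <= 0:
            raise ValidationError("fecundity_dispersion must be positive")
        if self.n_females < 1:
            raise ValidationError("n_females must be >= 1")


def paper_cohort_defaults(n_females: int = 20, seed: int = 0) -> CohortConfig:
    return CohortConfig(n_females=n_females, seed=seed)


def _round_days(value: float) -> int:
    return int(math.floor(value + 0.5))  # half-up, mirrored in the oracle


def _draw_duration(rng: np.random.Generator, mean: float, sd: float,
                   dist: str) -> float:
    if sd == 0:
        return mean
    if dist == "gamma":
        shape = (mean / sd) ** 2
        return float(rng.gamma(shape, mean / shape))
    if dist == "truncnorm":
        a = -mean / sd
        return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                         random_state=rng))
    raise ValidationError(f"unknown duration distribution {dist!r}")


def _daily_means(config: CohortConfig, n_days: int) -> np.ndarray:
    f = config.daily_fecundity_mean
    if config.trajectory == "flat":
        return np.full(n_days, f)
    if config.trajectory == "triangular":
        # linear decline from 2f to ~0 across the window, mean preserved
        w = np.linspace(1.0, 0.0, n_days + 1)[:-1]
        return f * w * n_days / w.sum()
    raise ValidationError(f"unknown trajectory {config.trajectory!r}")


def _draw_eggs(rng: np.random.Generator, means: np.ndarray,
               config: CohortConfig) -> np.ndarray:
    if config.egg_distribution == "poisson":
        return rng.poisson(means)
    if config.egg_distribution == "nbinom":
        theta = config.fecundity_dispersion
        p = theta / (theta + means)
        return rng.negative_binomial(theta, p)
    raise ValidationError(f"unknown egg distribution {config.egg_distribution!r}")


def _simulate_individual(rng: np.random.Generator, sex: str, idx: int,
                         config: CohortConfig) -> IndividualRecord:
    durations: dict[str, float] = {}
    died_in: str | None = None
    for stage, mean, sd, surv in zip(STAGES, config.stage_means,
                                     config.stage_sds, config.stage_survival):
        durations[stage] = _draw_duration(rng, mean, sd,
                                          config.duration_distribution)
        if rng.random() > surv:
            died_in = stage
            break
    prefix = "f" if sex == "female" else "m"
    ident = f"{prefix}{idx + 1:04d}"
    if died_in is not None:
        return IndividualRecord(individual_id=ident, sex=sex,
                                stage_durations=durations, died_in_stage=died_in)
    if sex == "male":
        longevity = _draw_duration(rng, config.male_longevity_mean,
                                   config.male_longevity_sd,
                                   config.duration_distribution)
        return IndividualRecord(individual_id=ident, sex=sex,
                                stage_durations=durations,
                                adult_longevity=max(1.0, round(longevity)))
    pre = max(0, _round_days(_draw_duration(rng, config.pre_ovi_mean,
                                            config.pre_ovi_sd,
                                            config.duration_distribution)))
    ovi = max(1, _round_days(_draw_duration(rng, config.ovi_mean, config.ovi_sd,
                                            config.duration_distribution)))
    post = max(0, _round_days(_draw_duration(rng, config.post_ovi_mean,
                                             config.post_ovi_sd,
                                             config.duration_distribution)))
    longevity = pre + ovi + post
    eggs = np.zeros(longevity, dtype=int)
    means = _daily_means(config, ovi)
    eggs[pre:pre + ovi] = _draw_eggs(rng, means, config)
    # the window is defined by the first and last eggs, so its endpoint days
    # are zero-truncated: otherwise the realised pre/oviposition/post spans
    # would not mean what the configuration says
    for day, mean in ((pre, means[0]), (pre + ovi - 1, means[-1])):
        while eggs[day] == 0:
            eggs[day] = int(_draw_eggs(rng, np.array([mean]), config)[0])
    total = int(eggs.sum())
    hatched = int(rng.binomial(total, config.egg_viability)) if total else 0
    off_ff = None
    if hatched:
        off_ff = float(rng.binomial(hatched, config.offspring_female_fraction)
                       / hatched)
    return IndividualRecord(
        individual_id=ident, sex=sex, stage_durations=durations,
        adult_longevity=float(longevity), daily_eggs=eggs,
        eggs_hatched=hatched, offspring_female_fraction=off_ff,
    )


def _cohort_sizes(config: CohortConfig) -> tuple[int, int]:
    ff = config.female_fraction
    if ff == 0.0:
        return 0, config.n_females
    if ff == 1.0:
        return config.n_females, 0
    return config.n_females, int(round(config.n_females * (1.0 - ff) / ff))


def generate_cohort(config: CohortConfig) -> list[IndividualRecord]:
    """Simulate a cohort of ``n_females`` females (plus males per the sex
    ratio).  Per-individual substreams come from spawning the master seed."""
    config.validate()
    n_f, n_m = _cohort_sizes(config)
    streams = np.random.SeedSequence(config.seed).spawn(n_f + n_m)
    records: list[IndividualRecord] = []
    for i in range(n_f):
        records.append(_simulate_individual(np.random.default_rng(streams[i]),
                                            "female", i, config))
    for j in range(n_m):
        records.append(_simulate_individual(
            np.random.default_rng(streams[n_f + j]), "male", j, config))
    return records


# ---------------------------------------------------------------------------
# exact oracle
# ---------------------------------------------------------------------------

def _rounded_pmf(mean: float, sd: float, dist: str, lo: int,
                 tail: float = 1e-12) -> np.ndarray:
    """pmf of round-half-up(duration) clipped at ``lo``, on integers 0..hi."""
    if sd == 0:
        hi = max(lo, _round_days(mean))
        pmf = np.zeros(hi + 1)
        pmf[hi] = 1.0
        return pmf
    if dist == "gamma":
        shape = (mean / sd) ** 2
        dist_obj = stats.gamma(shape, scale=mean / shape)
    elif dist == "truncnorm":
        dist_obj = stats.truncnorm(-mean / sd, np.inf, loc=mean, scale=sd)
    else:
        raise ValidationError(f"unknown duration distribution {dist!r}")
    hi = int(math.ceil(dist_obj.ppf(1.0 - tail))) + 1
    hi = max(hi, lo + 1)
    edges = np.arange(0, hi + 1) + 0.5  # value v rounds from (v-0.5, v+0.5]
    cdf = dist_obj.cdf(edges)
    pmf = np.diff(np.concatenate(([0.0], cdf)))
    pmf[-1] += 1.0 - cdf[-1]
    if lo > 0:
        pmf[lo] += pmf[:lo].sum()
        pmf[:lo] = 0.0
    return pmf


def expected_parameters(config: CohortConfig,
                        age_origin: Literal["adult_emergence", "oviposition"]
                        = "adult_emergence",
                        r_method: Literal["birch", "lotka"] = "lotka",
                        ) -> tuple[DemographicParameters, LifeTableSchedule]:
    """Exact expected life-table schedule and parameters for a configuration.

    Works on the integer-day distributions the generator actually uses
    (rounded pre-/oviposition/post-oviposition durations): P(laying on adult
    day d) and P(alive through day d) are computed by convolution, then
    l_x = P(alive), m_x = female_fraction * f * P(lay)/P(alive) — the large-
    cohort limit of the empirical schedule.  Only the flat trajectory has this
    closed form.
    """
    config.validate()
    if config.trajectory != "flat":
        raise NotImplementedError("oracle is defined for the flat trajectory")
    if config.female_fraction == 0.0:
        raise ValidationError("no females in configuration: R0 = 0")
    dist = config.duration_distribution
    pre = _rounded_pmf(config.pre_ovi_mean, config.pre_ovi_sd, dist, lo=0)
    ovi = _rounded_pmf(config.ovi_mean, config.ovi_sd, dist, lo=1)
    post = _rounded_pmf(config.post_ovi_mean, config.post_ovi_sd, dist, lo=0)
    life = np.convolve(np.convolve(pre, ovi), post)
    d_max = life.size - 1
    days = np.arange(1, d_max + 1)
    # P(alive during day d) = P(pre + ovi + post >= d)
    p_alive = 1.0 - np.cumsum(life)[:-1]
    p_alive = np.clip(p_alive, 0.0, 1.0)
    # P(laying on day d) = sum_p P(pre = p) P(ovi >= d - p), p < d
    ovi_sf = 1.0 - np.cumsum(ovi)          # P(ovi > v) at integer v
    p_lay = np.zeros(d_max)
    for p, wp in enumerate(pre):
        if wp == 0.0:
            continue
        d_rel = days - p                   # ovi must be >= d_rel, i.e. > d_rel - 1
        valid = d_rel >= 1
        idx = np.clip(d_rel - 1, 0, ovi_sf.size - 1)
        sf = np.where(d_rel - 1 >= ovi_sf.size, 0.0, ovi_sf[idx])
        p_lay += wp * np.where(valid, sf, 0.0)
    # endpoint days of the window are zero-truncated in the generator, so
    # their expected egg count is f/(1 - P(0)) rather than f
    f = config.daily_fecundity_mean
    if config.egg_distribution == "nbinom":
        theta = config.fecundity_dispersion
        p_zero = (theta / (theta + f)) ** theta
    else:
        p_zero = math.exp(-f)
    f_plus = f / (1.0 - p_zero)
    # P(first laying day = d) = P(pre = d-1); P(last = d) = P(pre + ovi = d);
    # a one-day window is both endpoints at once, truncated only once
    pre_pad = np.zeros(d_max + 1)
    pre_pad[:pre.size] = pre
    p_first = pre_pad[days - 1]
    pre_ovi = np.convolve(pre, ovi)
    pre_ovi_pad = np.zeros(d_max + 1)
    pre_ovi_pad[:pre_ovi.size] = pre_ovi[:d_max + 1]
    p_last = pre_ovi_pad[days]
    p_both = p_first * ovi[1] if ovi.size > 1 else p_first
    p_endpoint = p_first + p_last - p_both
    expected_eggs = f * p_lay + (f_plus - f) * p_endpoint
    keep = p_alive > 1e-12
    p_alive, days = p_alive[keep], days[keep]
    expected_eggs = expected_eggs[keep]
    mx = config.female_fraction * expected_eggs / p_alive
    x = days - 0.5
    if age_origin == "oviposition":
        x = x + float(np.sum(config.stage_means))
    elif age_origin != "adult_emergence":
        raise ValidationError(f"unknown age origin {age_origin!r}")
    schedule = LifeTableSchedule(x=x, lx=p_alive, mx=mx, age_origin=age_origin)
    params = compute_parameters(schedule, r_method=r_method,
                                n_females=config.n_females)
    return params, schedule
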