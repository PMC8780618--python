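"""Larval instar determination from head-capsule width measurements.

The workflow mirrors classic instar analysis: estimate the width density,
test candidate mode counts with the excess-mass statistic calibrated by a
smoothed bootstrap at the critical bandwidth, cut the sample at the antimodes,
then summarise per-instar widths, successive growth ratios (Dyar's rule) and
the log-linear growth regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._excess_mass import excess_mass_statistic_sorted
from .exceptions import (
    ClassificationError,
    ConfigurationError,
    DegenerateSampleError,
    ResolutionError,
    SampleSizeError,
    ValidationError,
)

__all__ = [
    "HeadCapsuleSample",
    "DensityCurve",
    "ModeTestResult",
    "InstarCountResult",
    "InstarStats",
    "DyarResult",
    "GrowthRegression",
    "InstarClassification",
    "estimate_density",
    "count_modes",
    "excess_mass_statistic",
    "excess_mass_test",
    "find_instar_count",
    "split_at_antimodes",
    "instar_stats",
    "dyar_ratios",
    "growth_regression",
    "critical_bandwidth",
    "classify_instars",
]


@dataclass
class HeadCapsuleSample:
    """Vector of head-capsule widths (um) with optional per-larva metadata."""

    widths: np.ndarray
    lengths: np.ndarray | None = None
    larva_id: list[str] | None = None
    collection_day: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        if self.widths.ndim != 1:
            raise ValidationError("widths must be a 1-d vector")
        if self.widths.size == 0:
            raise ValidationError("widths must not be empty")
        if not np.all(np.isfinite(self.widths)):
            raise ValidationError("widths must be finite")
        if np.any(self.widths <= 0):
            raise ValidationError("widths must be strictly positive")
        if self.lengths is not None:
            self.lengths = np.asarray(self.lengths, dtype=float)
            if self.lengths.shape != self.widths.shape:
                raise ValidationError(
                    "lengths must have the same count as widths "
                    f"({self.lengths.size} != {self.widths.size})"
                )
        if self.collection_day is not None:
            self.collection_day = np.asarray(self.collection_day)

    @property
    def n(self) -> int:
        return int(self.widths.size)


@dataclass(frozen=True)
class DensityCurve:
    """Kernel density estimate evaluated on a regular grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass(frozen=True)
class ModeTestResult:
    k_null: int
    statistic: float
    p_value: float
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValidationError("excess-mass statistic must be >= 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value must lie in [0, 1]")


@dataclass(frozen=True)
class InstarCountResult:
    """Smallest non-rejected mode count, with the full per-k test table."""

    k: int
    saturated: bool  # True when every k <= k_max was rejected
    tests: tuple[ModeTestResult, ...]

    def __int__(self) -> int:
        return self.k


@dataclass(frozen=True)
class InstarStats:
    instar: int
    n: int
    mean: float
    se: float
    min: float
    max: float


@dataclass(frozen=True)
class DyarResult:
    ratios: tuple[float, ...]
    constant: float  # geometric mean of the successive ratios


@dataclass(frozen=True)
class GrowthRegression:
    slope: float
    intercept: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class InstarClassification:
    n_instars: int
    boundaries: tuple[float, ...]
    per_instar: tuple[InstarStats, ...]
    dyar: DyarResult | None
    regression: GrowthRegression | None
    mode_tests: tuple[ModeTestResult, ...] = field(default=())
    saturated: bool = False

    def __post_init__(self) -> None:
        if len(self.boundaries) != self.n_instars - 1:
            raise ValidationError("need n_instars - 1 boundaries")
        if list(self.boundaries) != sorted(self.boundaries):
            raise ValidationError("boundaries must be strictly increasing")
        means = [g.mean for g in self.per_instar]
        if any(b >= a for a, b in zip(means[1:], means[:-1])):
            raise ValidationError("per-instar means must be strictly increasing")


# ---------------------------------------------------------------------------
# density estimation and mode counting
# ---------------------------------------------------------------------------

def _bandwidth(widths: np.ndarray, rule: str | float) -> float:
    """Bandwidth in data units.  silverman: 0.9*min(sd, IQR/1.34)*n^(-1/5);
    scott: 1.06*sd*n^(-1/5); a float is taken verbatim."""
    if isinstance(rule, (int, float)) and not isinstance(rule, bool):
        h = float(rule)
        if h <= 0:
            raise ValidationError("fixed bandwidth must be positive")
        return h
    n = widths.size
    sd = float(np.std(widths, ddof=1))
    if sd == 0:
        raise DegenerateSampleError("sample has zero variance")
    if rule == "silverman":
        iqr = float(np.subtract(*np.percentile(widths, [75, 25])))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        return 0.9 * spread * n ** (-0.2)
    if rule == "scott":
        return 1.06 * sd * n ** (-0.2)
    raise ValidationError(f"unknown bandwidth rule {rule!r}")


def _kde_on_grid(widths: np.ndarray, h: float, grid_size: int,
                 pad: float = 4.0) -> DensityCurve:
    grid = np.linspace(widths.min() - pad * h, widths.max() + pad * h, grid_size)
    kde = stats.gaussian_kde(widths, bw_method=h / np.std(widths, ddof=1))
    return DensityCurve(grid=grid, density=kde(grid), bandwidth=h)


def estimate_density(sample: HeadCapsuleSample,
                     bandwidth_rule: str | float = "silverman",
                     grid_size: int = 512) -> DensityCurve:
    """Gaussian KDE of the widths on a grid extending 4 bandwidths past the
    data range (so the trapezoid integral is 1 to well within 1e-3)."""
    if sample.n < 5:
        raise SampleSizeError(f"need >= 5 observations, got {sample.n}")
    w = sample.widths
    if np.ptp(w) < 1e-8 * max(1.0, abs(float(w[0]))):
        raise DegenerateSampleError("sample has (numerically) zero variance")
    h = _bandwidth(w, bandwidth_rule)
    return _kde_on_grid(w, h, grid_size)


def count_modes(curve: DensityCurve) -> int:
    """Number of strict local maxima of the curve; plateaus (runs of equal
    values) collapse to a single mode and boundary maxima count."""
    d = np.asarray(curve.density, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValidationError("density curve must have >= 2 grid points")
    if np.any(d < 0) or not np.all(np.isfinite(d)):
        raise ValidationError("density values must be finite and >= 0")
    keep = np.concatenate(([True], np.diff(d) != 0.0))
    c = d[keep]
    padded = np.concatenate(([-np.inf], c, [-np.inf]))
    return int(np.sum((padded[1:-1] > padded[:-2]) & (padded[1:-1] > padded[2:])))


def _mode_count_at(widths: np.ndarray, h: float, grid_size: int = 512) -> int:
    return count_modes(_kde_on_grid(widths, h, grid_size))


def critical_bandwidth(widths: np.ndarray, k: int, grid_size: int = 512,
                       rtol: float = 1e-4) -> float:
    """Smallest bandwidth at which the Gaussian KDE shows at most k modes
    (binary search; mode count is monotone in h for the Gaussian kernel)."""
    widths = np.asarray(widths, dtype=float)
    hi = _bandwidth(widths, "silverman")
    for _ in range(60):
        if _mode_count_at(widths, hi, grid_size) <= k:
            break
        hi *= 1.5
    lo = hi
    for _ in range(60):
        lo /= 2.0
        if _mode_count_at(widths, lo, grid_size) > k:
            break
    else:
        return lo  # k modes at any bandwidth the grid can resolve
    while hi - lo > rtol * hi:
        mid = 0.5 * (lo + hi)
        if _mode_count_at(widths, mid, grid_size) <= k:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# excess-mass statistic and test
# ---------------------------------------------------------------------------

def excess_mass_statistic(sample: HeadCapsuleSample | np.ndarray, k: int) -> float:
    """D_{n,k}: extra probability mass a (k+1)-interval system captures over
    the best k-interval system, maximised over the mass level."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    w = sample.widths if isinstance(sample, HeadCapsuleSample) else np.asarray(sample, float)
    return excess_mass_statistic_sorted(np.sort(w), k)


def excess_mass_test(sample: HeadCapsuleSample, k_null: int,
                     n_boot: int = 500, seed: int = 0) -> ModeTestResult:
    """Test H0: exactly ``k_null`` modes against more modes.

    Calibration resamples from the data smoothed at the critical bandwidth
    for ``k_null`` modes (a k_null-modal density), with Silverman's variance
    correction; the p-value is the proportion of bootstrap statistics at least
    as large as the observed one.  Deterministic given (sample, k_null,
    n_boot, seed).
    """
    if sample.n < 10:
        raise SampleSizeError(f"need >= 10 observations, got {sample.n}")
    if n_boot < 100:
        raise ConfigurationError("n_boot < 100 gives an unreliable calibration")
    w = np.sort(sample.widths)
    observed = excess_mass_statistic_sorted(w, k_null)
    h_c = critical_bandwidth(w, k_null)
    xbar = w.mean()
    sd = w.std(ddof=1)
    shrink = 1.0 / np.sqrt(1.0 + (h_c / sd) ** 2)
    rng = np.random.default_rng(seed)
    n = w.size
    exceed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        y = xbar + shrink * (w[idx] - xbar + h_c * rng.standard_normal(n))
        if excess_mass_statistic_sorted(np.sort(y), k_null) >= observed:
            exceed += 1
    return ModeTestResult(k_null=k_null, statistic=float(observed),
                          p_value=exceed / n_boot, n_boot=n_boot, seed=seed)


def find_instar_count(sample: HeadCapsuleSample, k_max: int = 5,
                      alpha: float = 0.05, n_boot: int = 500,
                      seed: int = 0) -> InstarCountResult:
    """Smallest k in 1..k_max whose excess-mass test is not rejected at
    ``alpha``; if all are rejected, returns k_max flagged as saturated."""
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    tests: list[ModeTestResult] = []
    for k in range(1, k_max + 1):
        res = excess_mass_test(sample, k, n_boot=n_boot, seed=seed + k)
        tests.append(res)
        if res.p_value > alpha:
            return InstarCountResult(k=k, saturated=False, tests=tuple(tests))
    return InstarCountResult(k=k_max, saturated=True, tests=tuple(tests))


# ---------------------------------------------------------------------------
# classification and growth summaries
# ---------------------------------------------------------------------------

def split_at_antimodes(sample: HeadCapsuleSample, curve: DensityCurve,
                       k: int) -> np.ndarray:
    """Instar boundaries: for each pair of successive retained modes (the k
    tallest), the deepest antimode between them; ties go to the antimode
    closest to the geometric midpoint of the flanking modes."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k == 1:
        return np.empty(0)
    d = curve.density
    g = curve.grid
    interior = (d[1:-1] > d[:-2]) & (d[1:-1] > d[2:])
    max_idx = np.flatnonzero(interior) + 1
    if d[0] > d[1]:
        max_idx = np.concatenate(([0], max_idx))
    if d[-1] > d[-2]:
        max_idx = np.concatenate((max_idx, [d.size - 1]))
    if max_idx.size < k:
        raise ResolutionError(
            f"density shows {max_idx.size} modes but {k} requested; "
            "use a smaller bandwidth"
        )
    tallest = max_idx[np.argsort(d[max_idx])[::-1][:k]]
    tallest = np.sort(tallest)
    bounds = []
    for left, right in zip(tallest[:-1], tallest[1:]):
        seg = d[left:right + 1]
        depth = seg.min()
        cand = np.flatnonzero(seg == depth) + left
        if cand.size > 1:
            mid = np.sqrt(g[left] * g[right])
            cand = cand[[int(np.argmin(np.abs(g[cand] - mid)))]]
        bounds.append(float(g[cand[0]]))
    return np.asarray(bounds)


def instar_stats(sample: HeadCapsuleSample,
                 boundaries: Sequence[float]) -> list[InstarStats]:
    """Per-instar (n, mean, SE, min, max).  Intervals are closed on the left
    and open on the right, the last closed on both sides."""
    b = np.asarray(boundaries, dtype=float)
    if b.size and np.any(np.diff(b) <= 0):
        raise ClassificationError("boundaries must be strictly increasing")
    w = sample.widths
    labels = np.searchsorted(b, w, side="right")
    out: list[InstarStats] = []
    for i in range(b.size + 1):
        grp = w[labels == i]
        if grp.size == 0:
            raise ClassificationError(f"instar class {i + 1} is empty")
        se = float(grp.std(ddof=1) / np.sqrt(grp.size)) if grp.size > 1 else float("nan")
        out.append(InstarStats(instar=i + 1, n=int(grp.size), mean=float(grp.mean()),
                               se=se, min=float(grp.min()), max=float(grp.max())))
    means = [g.mean for g in out]
    if any(b2 <= a2 for a2, b2 in zip(means[:-1], means[1:])):
        raise ClassificationError("per-instar means are not strictly increasing")
    return out


def dyar_ratios(means: Sequence[float]) -> DyarResult:
    """Successive growth ratios mean_{i+1}/mean_i and their geometric mean."""
    m = np.asarray(means, dtype=float)
    if m.size < 2:
        raise ValidationError("need >= 2 instar means")
    if np.any(np.diff(m) <= 0):
        raise ValidationError("instar means must be strictly increasing")
    ratios = m[1:] / m[:-1]
    constant = float(np.exp(np.mean(np.log(ratios))))
    return DyarResult(ratios=tuple(float(r) for r in ratios), constant=constant)


def growth_regression(widths: Sequence[float],
                      instar_labels: Sequence[int]) -> GrowthRegression:
    """OLS of ln(width) on instar index.  e^slope is an alternative estimator
    of the growth constant."""
    w = np.asarray(widths, dtype=float)
    idx = np.asarray(instar_labels, dtype=float)
    if w.size < 3:
        raise SampleSizeError("need >= 3 points for the growth regression")
    if np.unique(idx).size < 2:
        raise ValidationError("need >= 2 instar classes for a regression")
    fit = stats.linregress(idx, np.log(w))
    return GrowthRegression(slope=float(fit.slope), intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue ** 2), n=int(w.size))


def classify_instars(sample: HeadCapsuleSample, k_max: int = 5,
                     alpha: float = 0.05, n_boot: int = 500, seed: int = 0,
                     bandwidth_rule: str | float = "silverman",
                     grid_size: int = 512) -> InstarClassification:
    """Full pipeline: choose the instar count, cut at antimodes, summarise."""
    count = find_instar_count(sample, k_max=k_max, alpha=alpha,
                              n_boot=n_boot, seed=seed)
    k = count.k
    curve = estimate_density(sample, bandwidth_rule, grid_size)
    if count_modes(curve) < k:
        # over-smoothed at the default rule: shrink to the critical bandwidth
        h = critical_bandwidth(sample.widths, k, grid_size)
        curve = _kde_on_grid(sample.widths, h, grid_size)
        for _ in range(20):
            if count_modes(curve) >= k:
                break
            h *= 0.98
            curve = _kde_on_grid(sample.widths, h, grid_size)
    boundaries = split_at_antimodes(sample, curve, k)
    stats_ = instar_stats(sample, boundaries)
    dyar = dyar_ratios([g.mean for g in stats_]) if k >= 2 else None
    regression = None
    if k >= 2:
        labels = np.searchsorted(boundaries, sample.widths, side="right") + 1
        regression = growth_regression(sample.widths, labels)
    if count.saturated:
        warnings.warn(
            f"all mode counts up to k_max={k_max} rejected; reporting k_max",
            stacklevel=2,
        )
    return InstarClassification(
        n_instars=k,
        boundaries=tuple(float(b) for b in boundaries),
        per_instar=tuple(stats_),
        dyar=dyar,
        regression=regression,
        mode_tests=count.tests,
        saturated=count.saturated,
    )
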