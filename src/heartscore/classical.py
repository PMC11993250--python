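"""Classical statistics implemented from their formulas: Welch's t-test,
one-way ANOVA and BCa bootstrap confidence intervals, plus lumen-width
region comparisons.

Only the distribution functions (Student t, F, normal) come from scipy;
the statistics themselves are computed explicitly so each formula is
visible and testable against independent implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import f as f_dist
from scipy.stats import norm
from scipy.stats import t as t_dist

from .blueprint import AORTA_POSITIONS, HEART_POSITIONS, LUMEN_POSITIONS
from .tables import LumenMeasurement


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_x: float
    mean_y: float
    var_x: float
    var_y: float
    n_x: int
    n_y: int


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class BcaInterval:
    statistic: float
    lower: float
    upper: float
    n_boot: int
    alpha: float
    bias_correction: float  # z0
    acceleration: float  # a
    seed: Optional[int]
    degenerate: bool = False


@dataclass(frozen=True)
class RegionWidths:
    """Per-embryo mean lumen widths (µm): posterior aorta = mean(A2,A3,A4),
    heart proper = mean(A6,A7)."""

    embryo_id: str
    posterior_aorta_width: float
    heart_proper_width: float


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-tailed two-sample unequal-variance t-test.

    t = (mx - my) / sqrt(sx^2/nx + sy^2/ny), with Welch-Satterthwaite
    (fractional) degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"each sample needs >= 2 observations (got {nx}, {ny})")
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples have zero variance; t is undefined")
    se2 = vx / nx + vy / ny
    t = (mx - my) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return TTestResult(float(t), float(df), p, float(mx), float(my), float(vx), float(vy), nx, ny)


def pooled_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Equal-variance (pooled) two-sample t-test; used for the F = t^2 identity."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"each sample needs >= 2 observations (got {nx}, {ny})")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance; t is undefined")
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    df = nx + ny - 2
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return TTestResult(float(t), float(df), p, float(x.mean()), float(y.mean()),
                       float(x.var(ddof=1)), float(y.var(ddof=1)), nx, ny)


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical equal-variance one-way decomposition.

    F = (SSB / (k-1)) / (SSW / (n-k)).  Raises on zero within-group sum of
    squares (all observations constant within groups), where F is undefined.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} needs >= 2 observations")
    all_values = np.concatenate(arrays)
    grand = all_values.mean()
    k = len(arrays)
    n = len(all_values)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if ssw == 0:
        raise ValueError("zero within-group sum of squares; F is undefined")
    f = (ssb / (k - 1)) / (ssw / (n - k))
    p = float(f_dist.sf(f, k - 1, n - k))
    return AnovaResult(float(f), k - 1, n - k, p)


def _bca_endpoints(z0: float, a: float, alpha: float) -> Tuple[float, float]:
    """Adjusted percentile levels of the BCa construction."""
    z_lo = norm.ppf(alpha / 2)
    z_hi = norm.ppf(1 - alpha / 2)
    a1 = float(norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo))))
    a2 = float(norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi))))
    return a1, a2


def _boot_statistics(
    sample: np.ndarray, statistic_fn: Callable, idx: np.ndarray
) -> np.ndarray:
    resamples = sample[idx]
    try:  # vectorised fast path for axis-aware statistics (np.mean, np.median, ...)
        stats = np.asarray(statistic_fn(resamples, axis=1), dtype=float)
        if stats.shape == (idx.shape[0],):
            return stats
    except TypeError:
        pass
    return np.array([float(statistic_fn(row)) for row in resamples])


def bca_bootstrap_ci(
    sample: Sequence[float],
    statistic_fn: Callable = np.mean,
    n_boot: int = 5000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> BcaInterval:
    """Bias-corrected and accelerated bootstrap interval (Efron).

    z0 comes from the position of the observed statistic in the bootstrap
    distribution (strictly-below fraction plus half the ties — the midpoint
    tie convention); the acceleration a from jackknife skewness.  A
    degenerate bootstrap distribution (all resample statistics equal)
    collapses the interval to the point value with ``degenerate=True``.
    """
    x = np.asarray(sample, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"sample size {n} < 3")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    theta = float(statistic_fn(x))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = _boot_statistics(x, statistic_fn, idx)
    if np.ptp(boot) == 0:
        return BcaInterval(theta, theta, theta, n_boot, alpha, 0.0, 0.0, seed, degenerate=True)
    below = np.count_nonzero(boot < theta)
    ties = np.count_nonzero(boot == theta)
    frac = (below + 0.5 * ties) / n_boot
    frac = min(max(frac, 1 / (n_boot + 1)), n_boot / (n_boot + 1))  # keep z0 finite
    z0 = float(norm.ppf(frac))
    # jackknife acceleration
    jack = np.array([float(statistic_fn(np.delete(x, i))) for i in range(n)])
    jmean = jack.mean()
    d = jmean - jack
    denom = (d**2).sum() ** 1.5
    a = float((d**3).sum() / (6 * denom)) if denom > 0 else 0.0
    a1, a2 = _bca_endpoints(z0, a, alpha)
    lower, upper = np.quantile(boot, [a1, a2])
    return BcaInterval(theta, float(lower), float(upper), n_boot, alpha, z0, a, seed)


def bca_mean_difference_ci(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 5000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> BcaInterval:
    """Two-sample BCa interval for mean(x) - mean(y).

    Each group is resampled independently; the jackknife for the
    acceleration leaves out one observation at a time across both groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 3 or ny < 3:
        raise ValueError("each group needs >= 3 observations")
    theta = float(x.mean() - y.mean())
    rng = np.random.default_rng(seed)
    bx = x[rng.integers(0, nx, size=(n_boot, nx))].mean(axis=1)
    by = y[rng.integers(0, ny, size=(n_boot, ny))].mean(axis=1)
    boot = bx - by
    if np.ptp(boot) == 0:
        return BcaInterval(theta, theta, theta, n_boot, alpha, 0.0, 0.0, seed, degenerate=True)
    below = np.count_nonzero(boot < theta)
    ties = np.count_nonzero(boot == theta)
    frac = (below + 0.5 * ties) / n_boot
    frac = min(max(frac, 1 / (n_boot + 1)), n_boot / (n_boot + 1))
    z0 = float(norm.ppf(frac))
    jack = np.concatenate(
        [
            [np.delete(x, i).mean() - y.mean() for i in range(nx)],
            [x.mean() - np.delete(y, j).mean() for j in range(ny)],
        ]
    )
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    a = float((d**3).sum() / (6 * denom)) if denom > 0 else 0.0
    a1, a2 = _bca_endpoints(z0, a, alpha)
    lower, upper = np.quantile(boot, [a1, a2])
    return BcaInterval(theta, float(lower), float(upper), n_boot, alpha, z0, a, seed)


def region_lumen_widths(measurements: Iterable[LumenMeasurement]) -> RegionWidths:
    """Collapse one embryo's five diameters into the two region widths.

    Replicate diameters at one position (e.g. from several Z planes) are
    averaged per position before the region means.
    """
    ms = list(measurements)
    if not ms:
        raise ValueError("no measurements")
    embryos = {m.embryo_id for m in ms}
    if len(embryos) > 1:
        raise ValueError(f"measurements span several embryos: {sorted(embryos)}")
    by_pos: Dict[str, List[float]] = {}
    for m in ms:
        by_pos.setdefault(m.position, []).append(m.diameter)
    missing = [p for p in LUMEN_POSITIONS if p not in by_pos]
    if missing:
        raise ValueError(f"embryo {ms[0].embryo_id!r}: missing lumen positions {missing}")
    pos_mean = {p: float(np.mean(v)) for p, v in by_pos.items()}
    aorta = float(np.mean([pos_mean[p] for p in AORTA_POSITIONS]))
    heart = float(np.mean([pos_mean[p] for p in HEART_POSITIONS]))
    return RegionWidths(ms[0].embryo_id, aorta, heart)


def cohort_region_widths(
    measurements: Iterable[LumenMeasurement], genotype: str
) -> List[RegionWidths]:
    """Per-embryo region widths for every complete embryo of a genotype."""
    by_embryo: Dict[str, List[LumenMeasurement]] = {}
    for m in measurements:
        if m.genotype == genotype:
            by_embryo.setdefault(m.embryo_id, []).append(m)
    if not by_embryo:
        raise ValueError(f"genotype {genotype!r} absent from lumen measurements")
    return [region_lumen_widths(ms) for ms in by_embryo.values()]


def compare_region_widths(
    measurements: Iterable[LumenMeasurement], genotype: str
) -> TTestResult:
    """Welch test of heart-proper vs posterior-aorta widths within a genotype.

    Positive statistic means the heart proper is wider (dilated) than the
    posterior aorta, the wild-type configuration.
    """
    widths = cohort_region_widths(measurements, genotype)
    if len(widths) < 2:
        raise ValueError(f"genotype {genotype!r}: need >= 2 complete embryos, got {len(widths)}")
    heart = [w.heart_proper_width for w in widths]
    aorta = [w.posterior_aorta_width for w in widths]
    return welch_t_test(heart, aorta)
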