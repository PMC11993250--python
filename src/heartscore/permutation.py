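"""Embryo-level permutation inference on defect proportions.

Hemisegments of one embryo are correlated in their chance of carrying a
defect, so hemisegment-level contingency tests (e.g. a pooled Fisher exact
test) are anti-conservative.  Inference is instead carried out on the
embryo-level defect proportions Y_j with the indicator general linear model

    Y_j = beta0 + beta1 * I_j + e_j

where I_j = 1 for embryos of the test genotype.  The least-squares
estimates are the group means: beta0 is the reference-group mean and beta1
the difference of group means.  Significance of H0: beta1 = 0 comes from a
randomization test: the genotype labels are shuffled among embryos, beta1
is re-estimated for each shuffle, and

    p = (n + 1) / (N + 1)

with N shuffles and n of them meeting the exceedance rule.  The default
rule is two-sided, |beta1_perm| >= |beta1_obs|, with ties counted as
exceedances, which keeps the test valid (conservative).  An exact variant
enumerates every distinct assignment of group labels and serves as the
oracle for the sampled test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.stats import fisher_exact

from .scoring import DefectClass, SegmentRange, cohort_responses, resolve_segment_range
from .tables import EmbryoTable

ALTERNATIVES = ("two_sided", "greater", "less")

#: relative tolerance when comparing permuted statistics to the observed
#: one: group means re-summed in a different order can differ by a few ulp,
#: and a true tie must still count as an exceedance.
_TIE_RTOL = 1e-9

_EXACT_GUARD = 1_000_000


@dataclass(frozen=True)
class IndicatorFit:
    """Least-squares fit of the single-indicator model (group means)."""

    beta0: float
    beta1: float
    group_sizes: tuple  # (n_indicator0, n_indicator1)


@dataclass(frozen=True)
class PermutationResult:
    observed_beta1: float
    n_permutations: int  # N
    n_exceed: int  # n
    p_value: float
    alternative: str
    seed: Optional[int]
    method: str  # "sampled" | "exact"
    metadata: Dict = field(default_factory=dict)

    @property
    def p_add_one(self) -> float:
        """(n+1)/(N+1), the sampled-test convention (reported alongside the
        raw n/N proportion for the exact test)."""
        return (self.n_exceed + 1) / (self.n_permutations + 1)


def _validate_inputs(responses, indicators):
    y = np.asarray(responses, dtype=float)
    ind = np.asarray(indicators, dtype=int)
    if y.shape != ind.shape or y.ndim != 1:
        raise ValueError(f"responses and indicators must be equal-length 1-d; got {y.shape} vs {ind.shape}")
    if not np.isin(ind, (0, 1)).all():
        raise ValueError("indicators must be 0/1")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses are proportions and must lie in [0, 1]")
    n1 = int(ind.sum())
    if n1 == 0 or n1 == len(ind):
        raise ValueError("both indicator groups must be non-empty")
    return y, ind, n1


def fit_indicator_glm(responses: Sequence[float], indicators: Sequence[int]) -> IndicatorFit:
    """Closed-form least squares on the indicator design.

    beta0 = mean of the indicator-0 group, beta1 = difference of means.
    """
    y, ind, n1 = _validate_inputs(responses, indicators)
    n0 = len(ind) - n1
    mean0 = float(y[ind == 0].mean())
    mean1 = float(y[ind == 1].mean())
    return IndicatorFit(beta0=mean0, beta1=mean1 - mean0, group_sizes=(n0, n1))


def _count_exceedances(perm_stats: np.ndarray, observed: float, alternative: str) -> int:
    scale = max(1.0, abs(observed))
    tol = _TIE_RTOL * scale
    if alternative == "two_sided":
        return int(np.count_nonzero(np.abs(perm_stats) >= abs(observed) - tol))
    if alternative == "greater":
        return int(np.count_nonzero(perm_stats >= observed - tol))
    if alternative == "less":
        return int(np.count_nonzero(perm_stats <= observed + tol))
    raise ValueError(f"invalid alternative {alternative!r}; expected one of {ALTERNATIVES}")


def sampled_permutation_pvalue(
    responses: Sequence[float],
    indicators: Sequence[int],
    n_permutations: int = 1_000_000,
    seed: Optional[int] = None,
    alternative: str = "two_sided",
    _chunk: int = 100_000,
) -> PermutationResult:
    """Monte-Carlo randomization test of beta1 = 0.

    Each permutation is an independent uniform shuffle of the label vector
    (the identity shuffle is not excluded); p = (n+1)/(N+1).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"invalid alternative {alternative!r}; expected one of {ALTERNATIVES}")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y, ind, n1 = _validate_inputs(responses, indicators)
    n = len(y)
    n0 = n - n1
    observed = float(y[ind == 1].mean() - y[ind == 0].mean())
    total = float(y.sum())
    rng = np.random.default_rng(seed)
    n_exceed = 0
    done = 0
    while done < n_permutations:
        m = min(_chunk, n_permutations - done)
        labels = np.broadcast_to(ind, (m, n))
        perm = rng.permuted(labels, axis=1)
        sum1 = perm @ y
        # beta1 = mean(group1) - mean(group0), from the group-1 sum alone
        stats = sum1 / n1 - (total - sum1) / n0
        n_exceed += _count_exceedances(stats, observed, alternative)
        done += m
    p = (n_exceed + 1) / (n_permutations + 1)
    return PermutationResult(
        observed_beta1=observed,
        n_permutations=n_permutations,
        n_exceed=n_exceed,
        p_value=p,
        alternative=alternative,
        seed=seed,
        method="sampled",
    )


def exact_permutation_pvalue(
    responses: Sequence[float],
    indicators: Sequence[int],
    alternative: str = "two_sided",
) -> PermutationResult:
    """Exact randomization test enumerating all C(n, n1) label assignments.

    The observed assignment is included; p = n/N over the enumeration (the
    add-one convention is available as ``p_add_one``).  Guarded at 10^6
    assignments.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"invalid alternative {alternative!r}; expected one of {ALTERNATIVES}")
    y, ind, n1 = _validate_inputs(responses, indicators)
    n = len(y)
    n0 = n - n1
    n_assign = math.comb(n, n1)
    if n_assign > _EXACT_GUARD:
        raise ValueError(f"C({n},{n1}) = {n_assign} assignments exceeds the enumeration guard {_EXACT_GUARD}")
    observed = float(y[ind == 1].mean() - y[ind == 0].mean())
    total = float(y.sum())
    idx = np.fromiter(
        (i for comb in combinations(range(n), n1) for i in comb), dtype=np.intp, count=n_assign * n1
    ).reshape(n_assign, n1)
    sum1 = y[idx].sum(axis=1)
    stats = sum1 / n1 - (total - sum1) / n0
    n_exceed = _count_exceedances(stats, observed, alternative)
    return PermutationResult(
        observed_beta1=observed,
        n_permutations=n_assign,
        n_exceed=n_exceed,
        p_value=n_exceed / n_assign,
        alternative=alternative,
        seed=None,
        method="exact",
    )


def compare_genotypes(
    table: EmbryoTable,
    genotype_a: str,
    genotype_b: str,
    defect_class: DefectClass,
    segment_range: SegmentRange = "A2_A8",
    n_permutations: int = 1_000_000,
    seed: Optional[int] = None,
    alternative: str = "two_sided",
) -> PermutationResult:
    """Permutation test of genotype_b vs genotype_a (reference, I_j = 0)
    on embryo defect proportions."""
    defect_class = DefectClass(defect_class)
    segs = resolve_segment_range(segment_range)
    resp_a = cohort_responses(table, genotype_a, defect_class, segs)
    resp_b = cohort_responses(table, genotype_b, defect_class, segs)
    y = [r.proportion for r in resp_a] + [r.proportion for r in resp_b]
    ind = [0] * len(resp_a) + [1] * len(resp_b)
    result = sampled_permutation_pvalue(y, ind, n_permutations, seed, alternative)
    result.metadata.update(
        genotype_a=genotype_a,
        genotype_b=genotype_b,
        defect_class=defect_class.value,
        segment_range=segs,
        n_embryos=(len(resp_a), len(resp_b)),
    )
    return result


def fisher_hemisegment_pvalue(
    table: EmbryoTable,
    genotype_a: str,
    genotype_b: str,
    defect_class: DefectClass,
    segment_range: SegmentRange = "A2_A8",
) -> float:
    """Naive pooled hemisegment-level Fisher exact test (two-sided).

    Provided as the invalid comparator: it treats correlated hemisegments
    of one embryo as independent trials and is anti-conservative under
    within-embryo correlation.
    """
    from .scoring import cohort_defect_fraction

    a = cohort_defect_fraction(table, genotype_a, defect_class, segment_range)
    b = cohort_defect_fraction(table, genotype_b, defect_class, segment_range)
    contingency = [[a.defective, a.scored - a.defective], [b.defective, b.scored - b.defective]]
    return float(fisher_exact(contingency, alternative="two-sided")[1])


def bonferroni(p_values: Sequence[float]) -> list:
    """Optional Bonferroni adjustment for families of pairwise comparisons."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
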