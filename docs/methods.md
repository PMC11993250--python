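# Methods

## The scoring model

The *Drosophila* embryonic dorsal vessel at stage 16 is a linear heart
tube of 104 contractile cardial cells (CCs). Its abdominal hemisegments
A2–A8 (two per segment, left and right) each carry two *seven-up* (Svp)
lineage CCs followed by four *tinman* (Tin) lineage CCs, except A8, which
is abbreviated to two Svp and two Tin CCs; anterior to the first Svp CCs
of A2 lie the 12 CCs of the anterior aorta per row. This blueprint is the
package's fixed reference (`ReferenceBlueprint`); it implies
2 × (12 + 7×2 + 6×4 + 2) = 104 CCs.

Because the Tin complement arises from two successive **symmetric**
progenitor divisions and the Svp pair from an earlier division followed by
**asymmetric** divisions, count deviations are read as lineage-specific
division defects: any Tin-count deviation (up or down) is a *symmetric*
defect; any Svp-count deviation an *asymmetric-or-earlier* defect. The
two classes are scored independently per hemisegment — a hemisegment may
carry both — and signed deltas are kept for diagnostics. Means in
summaries are rounded to one decimal only at the presentation layer.

Unscoreable hemisegments are simply absent rows; every denominator counts
present records only. Two segment-range presets exist: `A2_A8` (full
abdominal range) and `A3_A8`, which excludes A2 so that a fully penetrant
A2-specific Svp phenotype does not dominate the statistics of an
unrelated comparison.

## Inference on clustered binary outcomes

Hemisegments of one embryo are correlated in their chance of carrying a
defect, so the embryo — not the hemisegment — is the experimental unit.
For a two-genotype comparison the model is

    Y_j = β₀ + β₁ I_j + ε_j

with Y_j the proportion of defective hemisegments of embryo *j* and I_j
the genotype indicator. Least squares on this design reduces to group
means: β̂₀ is the reference-group mean and β̂₁ the difference of group
means (checked against a generic least-squares solve in the tests).
Because the proportions are non-normal and heteroscedastic, significance
of H₀: β₁ = 0 comes from a randomization test: genotype labels are
shuffled among embryos, β̂₁ recomputed, and

    p = (n + 1) / (N + 1),

with N the number of shuffles and n the number of permuted estimates
meeting the exceedance rule. Defaults: N = 10⁶ independent uniform
shuffles (the identity shuffle not excluded), two-sided exceedance
|β̂₁,perm| ≥ |β̂₁,obs| with ties counted as exceedances. The tie rule plus
the add-one formula make the test valid (if conservative) at any N.
One-sided alternatives use the signed comparisons. Permuted statistics
are compared to the observed one with a 10⁻⁹ relative tolerance so that
floating-point noise from re-summing the same responses in a different
order cannot drop a true tie.

An exact variant enumerates all C(n, n₁) distinct label assignments
(guarded at 10⁶) and reports p = n/N over the enumeration; it serves as
the oracle for the sampled test (agreement within 3 Monte-Carlo standard
errors at N = 10⁵ on ≤ 8-embryo data).

A pooled hemisegment-level 2×2 Fisher exact test is provided only as the
invalid comparator: under within-embryo correlation it treats correlated
trials as independent and its type-I error inflates several-fold (the
validity study below measures ≈ 0.37 at nominal 0.05), while the
embryo-level permutation test stays at its level.

No multiple-comparison correction is applied by default; an optional
Bonferroni helper exists for families of pairwise comparisons.

## Classical statistics

Implemented from their formulas (scipy supplies only the t/F/normal
distribution functions):

* **Welch t** — t = (m_x − m_y)/√(s²_x/n_x + s²_y/n_y) with
  Welch–Satterthwaite fractional df, two-tailed p. At equal variances and
  equal n it reduces to the pooled test with df = 2n − 2.
* **One-way ANOVA** — classical equal-variance between/within
  decomposition (for two groups F = t² of the pooled test). Zero
  within-group sum of squares is an error: F is undefined there.
* **BCa bootstrap** — Efron's bias-corrected and accelerated interval.
  z₀ is the normal quantile of the observed statistic's position in the
  bootstrap distribution, using the strictly-below fraction plus half the
  ties (midpoint tie convention), clipped to [1/(B+1), B/(B+1)] to stay
  finite; the acceleration a comes from jackknife skewness. Default
  B = 5000, α = 0.05. A degenerate bootstrap distribution (all resample
  statistics equal) collapses the interval to the point value with a
  `degenerate` flag. A two-sample version for mean differences resamples
  the groups independently and jackknifes over all observations; this
  mean-difference statistic is the default for between-group intervals
  (per-group means are also supported via the one-sample form).

## Lumen widths

Per embryo, five internal diameters are measured (µm): A2, A3, A4 in the
posterior aorta and A6, A7 in the heart proper (A5/A8 are not measured
positions; the reader rejects them). The posterior-aorta width is the
mean over A2–A4, the heart-proper width the mean over A6–A7; replicate
diameters at one position are averaged per position first. Each
genotype's two region-width samples are compared with the two-tailed
Welch test, positive t meaning a dilated heart proper.

## Synthetic cohort generator

The generator emulates the *structure* of a per-hemisegment scoring
spreadsheet, not the biology: phenotypes are encoded phenomenologically
as count distributions.

* **Clustering** — per embryo and defect class, a defect probability is
  drawn from a Beta distribution with mean m and intra-class correlation
  ρ (shapes a = m(1−ρ)/ρ, b = (1−m)(1−ρ)/ρ; ρ = 0 degenerates to the
  fixed rate m; ICC identity ρ = 1/(a+b+1)); hemisegment defect
  indicators are Bernoulli at the embryo's rate. The beta-binomial is the
  minimal model with the one property the inference depends on —
  within-embryo correlation.
* **Magnitudes** — given a defect, the signed deviation is drawn from a
  configurable distribution over nonzero integers (default ±1 with
  probability 0.4 each, ±2 with 0.1 each). Counts are clamped at 0; Svp
  counts are additionally capped at 4 unless supernumerary Svp deviations
  are explicitly allowed.
* **Deterministic phenotypes** — applied after the stochastic defects,
  overriding them, so penetrance-1 phenotypes are exact: the A2
  single-Svp reduction (svp_count := 1 with configurable penetrance) and
  an additive distribution of supernumerary Tin CCs in A8.
* **Ancillary models** — anterior-aorta counts per row (rounded normal,
  clamped ≥ 0); lumen diameters per region (normal truncated at 0, exact
  at sd = 0); per-hemisegment missingness.
* **Seeding** — every embryo uses an independent substream keyed by
  (master seed, domain, embryo index), so enlarging a cohort never
  perturbs existing embryos and regeneration from (config, seed) is
  bit-identical.

### Presets

All presets use 15 bilateral A2–A8 embryos and ρ = 0.3. No empirical
estimate of the within-embryo correlation exists, so ρ is a framework
parameter, not an estimate; 0.3 encodes substantial but not dominant
clustering and is fixed across presets.

| preset | symmetric m | asymmetric m | deterministic flags | lumen (aorta / heart, µm) |
|---|---|---|---|---|
| `wild_type` | 0 | 0 | — | 0.66 / 2.18 |
| `trx_like` | 0.25 | 0 | A2 single-Svp penetrance 1; A8 Tin surplus {0:.1, 1:.5, 2:.3, 3:.1} | 0.66 / 0.66 |
| `trr_like` | 0.15 | 4/30 | supernumerary Svp allowed | 0.66 / 2.0 |
| `set1_like` | 0.15 | 7/30 | supernumerary Svp allowed | 0.66 / 2.0 |

The wild-type lumen means are the reported region widths; sd = 0.1 µm in
both regions. The asymmetric rates 4/30 and 7/30 are the observed A2
deviation fractions for the corresponding genotypes; the symmetric rates
and the A8 surplus distribution (mean surplus 1.4 Tin CCs per
hemisegment, giving segment means near 6.8) are phenomenological choices
that reproduce the qualitative contrast — trx-like differs from wild type
only in the symmetric class over A3–A8, the other mutants in both
classes. The generator makes no claim about real penetrances beyond the
deterministic 30/30 A2 phenotype.

What passing tests on these cohorts show: the scoring bookkeeping, the
validity of the embryo-level test under clustering, and the qualitative
genotype contrasts. What they cannot show: anything about real scoring
noise (mis-segmentation, staining artefacts), non-beta-binomial
correlation structure, or the true effect sizes in real embryos.

## Numerical and design choices

* Embryo proportions are exact rationals of small integers in floating
  point; group means are compared with the tie tolerance above.
* The exact-enumeration guard (10⁶ assignments) keeps memory and time
  bounded; beyond it the sampled test is the tool.
* Degenerate inputs fail loudly (zero-variance Welch, zero within-group
  SS ANOVA, empty groups, < 3 observations for BCa) except where a
  defined fallback exists (degenerate BCa interval).
* Problem sizes in the test suite: the validity study uses 2000 replicate
  null pairs at N = 999 shuffles; the power grid 200 replicates per
  effect size at N = 499; BCa coverage 4000 replicate n = 30 normal
  samples at B = 999 (extra replicates tighten Monte-Carlo precision);
  the end-to-end contrast 40 replicate cohort pairs at N = 10⁴. The
  analysis drivers use the full N = 10⁶ and B = 5000 defaults.

## Known limitations

* The generator's defect indicators share one embryo-level rate per
  class; real embryos may show segment-specific rates (e.g. A8-restricted
  phenotypes), which the deterministic flags only partly capture.
* The permutation test assumes exchangeability of embryos across
  genotypes under the null; batch effects between cohorts would violate
  it.
* BCa intervals for a mean at n = 30 undercover slightly (≈ 93% empirical
  at nominal 95%) — a known property of the construction, matched by
  independent implementations.
* Ingesting a spreadsheet that tabulates signed count *changes* requires
  the documented delta→count converter (`counts_from_deltas`); whether a
  given source records deltas or absolute counts must be known to the
  caller.
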