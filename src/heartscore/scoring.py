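"""Defect classification against the blueprint and cohort aggregation.

A hemisegment carries a *symmetric* cell-division defect when its Tin CC
count deviates from the blueprint expectation (the Tin lineage arises from
two successive symmetric divisions), and an *asymmetric-or-earlier* defect
when its Svp CC count deviates (the two Svp CCs arise from an earlier
division followed by asymmetric divisions).  Increases and decreases both
count as defects; signed deltas are retained for diagnostics.  The two
classes are scored independently and a hemisegment may carry both.

Aggregation happens at two levels: per-embryo defect proportions (the
response variable of the permutation model) and pooled cohort fractions
(the per-genotype quantities plotted in defect-fraction panels).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Dict, NamedTuple, Optional, Sequence, Tuple, Union

from .blueprint import SEGMENTS, ReferenceBlueprint, reference_blueprint
from .tables import EmbryoTable, HemisegmentRecord


class DefectClass(str, Enum):
    SYMMETRIC = "symmetric"
    ASYMMETRIC_OR_EARLIER = "asymmetric_or_earlier"


#: Named segment-range presets.  A2_A8 is the full abdominal range;
#: A3_A8 excludes A2, where a fully penetrant Svp phenotype would dominate
#: the statistics of genotypes scored over the restricted range.
SEGMENT_RANGES: Dict[str, Tuple[str, ...]] = {
    "A2_A8": SEGMENTS,
    "A3_A8": SEGMENTS[1:],
}

SegmentRange = Union[str, Sequence[str]]


def resolve_segment_range(segment_range: SegmentRange) -> Tuple[str, ...]:
    if isinstance(segment_range, str):
        try:
            return SEGMENT_RANGES[segment_range]
        except KeyError:
            if segment_range in SEGMENTS:
                return (segment_range,)
            raise ValueError(
                f"unknown segment range {segment_range!r}; presets are {sorted(SEGMENT_RANGES)}"
            ) from None
    segs = tuple(s.upper() for s in segment_range)
    bad = [s for s in segs if s not in SEGMENTS]
    if bad:
        raise ValueError(f"unknown segments {bad}")
    return segs


@dataclass(frozen=True)
class DefectCall:
    """Per-hemisegment classification relative to the blueprint."""

    symmetric_defect: bool
    asymmetric_or_earlier_defect: bool
    tin_delta: int
    svp_delta: int

    def has(self, defect_class: DefectClass) -> bool:
        if defect_class == DefectClass.SYMMETRIC:
            return self.symmetric_defect
        return self.asymmetric_or_earlier_defect


@dataclass(frozen=True)
class EmbryoResponse:
    """Per-embryo defect proportion: the response Y_j of the indicator model."""

    embryo_id: str
    genotype: str
    defect_class: DefectClass
    segment_range: Tuple[str, ...]
    scored_hemisegments: int
    defective_hemisegments: int

    @property
    def proportion(self) -> float:
        return self.defective_hemisegments / self.scored_hemisegments


class CohortFraction(NamedTuple):
    defective: int
    scored: int
    fraction: float


class SummaryStats(NamedTuple):
    n: int
    mean: float
    sd: float


def classify_hemisegment(
    record: HemisegmentRecord, blueprint: Optional[ReferenceBlueprint] = None
) -> DefectCall:
    """Score one hemisegment against the blueprint.

    Deltas are observed minus expected; any nonzero deviation in either
    direction flags the corresponding defect class.
    """
    bp = blueprint or reference_blueprint()
    if record.segment not in bp.segments:
        raise KeyError(f"unknown segment {record.segment!r}")
    tin_delta = record.tin_count - bp.expected_tin[record.segment]
    svp_delta = record.svp_count - bp.expected_svp[record.segment]
    return DefectCall(
        symmetric_defect=tin_delta != 0,
        asymmetric_or_earlier_defect=svp_delta != 0,
        tin_delta=tin_delta,
        svp_delta=svp_delta,
    )


def embryo_defect_proportion(
    table: EmbryoTable,
    embryo_id: str,
    defect_class: DefectClass,
    segment_range: SegmentRange = "A2_A8",
    genotype: Optional[str] = None,
    blueprint: Optional[ReferenceBlueprint] = None,
) -> EmbryoResponse:
    """Proportion of defective hemisegments for one embryo over a range.

    Only present (scoreable) records enter the denominator.
    """
    segs = resolve_segment_range(segment_range)
    recs = table.select(genotype=genotype, embryo_id=embryo_id, segments=segs)
    if genotype is None:
        gts = {r.genotype for r in recs}
        if len(gts) > 1:
            raise ValueError(
                f"embryo_id {embryo_id!r} is ambiguous across genotypes {sorted(gts)}; pass genotype="
            )
    if not recs:
        raise ValueError(f"no scored hemisegments for embryo {embryo_id!r} in range {segs}")
    defect_class = DefectClass(defect_class)
    calls = [classify_hemisegment(r, blueprint) for r in recs]
    defective = sum(c.has(defect_class) for c in calls)
    return EmbryoResponse(
        embryo_id=embryo_id,
        genotype=genotype if genotype is not None else recs[0].genotype,
        defect_class=defect_class,
        segment_range=segs,
        scored_hemisegments=len(recs),
        defective_hemisegments=defective,
    )


def cohort_responses(
    table: EmbryoTable,
    genotype: str,
    defect_class: DefectClass,
    segment_range: SegmentRange = "A2_A8",
    blueprint: Optional[ReferenceBlueprint] = None,
) -> list:
    """Embryo responses for every embryo of a genotype (stable embryo order)."""
    ids = table.embryo_ids(genotype)
    if not ids:
        raise ValueError(f"genotype {genotype!r} absent from table")
    return [
        embryo_defect_proportion(table, e, defect_class, segment_range, genotype=genotype, blueprint=blueprint)
        for e in ids
    ]


def cohort_defect_fraction(
    table: EmbryoTable,
    genotype: str,
    defect_class: DefectClass,
    segment_range: SegmentRange = "A2_A8",
    blueprint: Optional[ReferenceBlueprint] = None,
) -> CohortFraction:
    """Pooled defective/scored hemisegment fraction for one genotype."""
    responses = cohort_responses(table, genotype, defect_class, segment_range, blueprint)
    defective = sum(r.defective_hemisegments for r in responses)
    scored = sum(r.scored_hemisegments for r in responses)
    return CohortFraction(defective, scored, defective / scored)


def _mean_sd(values: Sequence[float]) -> Tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, float("nan")
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def segment_cc_summary(
    table: EmbryoTable,
    genotype: str,
    segment: str,
    lineage: str,
    blueprint: Optional[ReferenceBlueprint] = None,
) -> SummaryStats:
    """Per-segment CC count summary: a segment pools its two contralateral
    hemisegments (left + right), one value per embryo.

    Embryos with only one row scored for the segment are excluded with a
    warning; the mean/sd are over the remaining segments.
    """
    if lineage not in ("svp", "tin"):
        raise ValueError(f"lineage must be 'svp' or 'tin', got {lineage!r}")
    segment = segment.upper()
    if segment not in SEGMENTS:
        raise ValueError(f"unknown segment {segment!r}")
    values = []
    for embryo in table.embryo_ids(genotype):
        recs = table.select(genotype=genotype, embryo_id=embryo, segments=(segment,))
        rows = {r.row: r for r in recs}
        if set(rows) != {"left", "right"}:
            if rows:
                warnings.warn(
                    f"embryo {embryo!r}: unpaired {segment} hemisegment (rows {sorted(rows)}); segment excluded",
                    stacklevel=2,
                )
            continue
        attr = "svp_count" if lineage == "svp" else "tin_count"
        values.append(getattr(rows["left"], attr) + getattr(rows["right"], attr))
    if not values:
        raise ValueError(f"no complete {segment} segments for genotype {genotype!r}")
    mean, sd = _mean_sd(values)
    return SummaryStats(len(values), mean, sd)


def segment_cc_values(table: EmbryoTable, genotype: str, segment: str, lineage: str) -> list:
    """Per-segment (left+right) counts, one per embryo with both rows scored."""
    segment = segment.upper()
    attr = "svp_count" if lineage == "svp" else "tin_count"
    values = []
    for embryo in table.embryo_ids(genotype):
        rows = {r.row: r for r in table.select(genotype=genotype, embryo_id=embryo, segments=(segment,))}
        if set(rows) == {"left", "right"}:
            values.append(getattr(rows["left"], attr) + getattr(rows["right"], attr))
    return values


def anterior_cc_summary(table: EmbryoTable, genotype: str, row: str) -> SummaryStats:
    """Mean/sd of anterior-aorta CC counts for one row across embryos.

    Anterior counts attach to A2 records (one per row per embryo).
    """
    row = row.lower()
    recs = [
        r
        for r in table.select(genotype=genotype, segments=("A2",), row=row)
        if r.anterior_cc_count is not None
    ]
    if not recs:
        raise ValueError(f"no anterior CC counts for genotype {genotype!r}, row {row!r}")
    values = [r.anterior_cc_count for r in recs]
    mean, sd = _mean_sd(values)
    return SummaryStats(len(values), mean, sd)


def anterior_cc_values(table: EmbryoTable, genotype: str, row: str) -> list:
    return [
        r.anterior_cc_count
        for r in table.select(genotype=genotype, segments=("A2",), row=row.lower())
        if r.anterior_cc_count is not None
    ]
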