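"""Wild-type anatomical blueprint of the Drosophila embryonic dorsal vessel.

The stage-16 dorsal vessel is a linear heart tube of 104 contractile
cardial cells (CCs).  The abdominal hemisegments A2..A8 each carry two
Svp-lineage CCs followed by four Tin-lineage CCs, except the posteriormost
A8 hemisegment which is abbreviated to two Svp and two Tin CCs.  Anterior
to the first Svp CCs of A2 lie the 12 CCs (per row) of the anterior aorta.
Defect scoring throughout the package compares observed per-hemisegment
counts against this blueprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Tuple

SEGMENTS: Tuple[str, ...] = ("A2", "A3", "A4", "A5", "A6", "A7", "A8")
ROWS: Tuple[str, str] = ("left", "right")

#: positions at which internal lumen diameter is measured (no A5 / A8)
LUMEN_POSITIONS: Tuple[str, ...] = ("A2", "A3", "A4", "A6", "A7")
AORTA_POSITIONS: Tuple[str, ...] = ("A2", "A3", "A4")
HEART_POSITIONS: Tuple[str, ...] = ("A6", "A7")


@dataclass(frozen=True)
class ReferenceBlueprint:
    """Expected per-row, per-hemisegment CC composition of the dorsal vessel.

    Attributes
    ----------
    anterior_aorta_ccs_per_row
        CCs per row anterior to the first Svp CC of the A2 hemisegment.
    expected_svp, expected_tin
        Expected Svp / Tin CC count per hemisegment, keyed by segment.
    segments, rows
        Ordered segment labels and the two contralateral rows.
    """

    anterior_aorta_ccs_per_row: int = 12
    expected_svp: Mapping[str, int] = field(
        default_factory=lambda: {s: 2 for s in SEGMENTS}
    )
    expected_tin: Mapping[str, int] = field(
        default_factory=lambda: {s: (2 if s == "A8" else 4) for s in SEGMENTS}
    )
    segments: Tuple[str, ...] = SEGMENTS
    rows: Tuple[str, str] = ROWS

    def expected(self, segment: str, lineage: str) -> int:
        """Expected count for one hemisegment of ``segment`` in ``lineage``
        (``"svp"`` or ``"tin"``)."""
        if segment not in self.segments:
            raise KeyError(f"unknown segment {segment!r}; expected one of {self.segments}")
        table = self.expected_svp if lineage == "svp" else self.expected_tin
        if lineage not in ("svp", "tin"):
            raise KeyError(f"unknown lineage {lineage!r}; expected 'svp' or 'tin'")
        return table[segment]

    def without_segment(self, segment: str) -> "ReferenceBlueprint":
        """A modified blueprint with one segment removed (diagnostics only)."""
        keep = tuple(s for s in self.segments if s != segment)
        return replace(
            self,
            segments=keep,
            expected_svp={s: self.expected_svp[s] for s in keep},
            expected_tin={s: self.expected_tin[s] for s in keep},
        )


def reference_blueprint() -> ReferenceBlueprint:
    """The canonical wild-type blueprint (2 Svp + 4 Tin per hemisegment,
    2 Svp + 2 Tin in A8, 12 anterior-aorta CCs per row)."""
    return ReferenceBlueprint()


def total_cc_count(blueprint: ReferenceBlueprint) -> int:
    """Total CC count of the vessel implied by a blueprint.

    Both rows contribute the anterior aorta plus every hemisegment's
    Svp and Tin complement; the canonical blueprint gives 104.
    """
    per_row = blueprint.anterior_aorta_ccs_per_row + sum(
        blueprint.expected_svp[s] + blueprint.expected_tin[s] for s in blueprint.segments
    )
    return 2 * per_row
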