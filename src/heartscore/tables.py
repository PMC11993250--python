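"""Tabular data model: per-hemisegment CC counts and lumen diameters.

The hemisegment table mirrors a per-hemisegment scoring spreadsheet: one
row per (genotype, embryo, left/right row, segment) with the observed Svp
and Tin CC counts, plus an optional anterior-aorta CC count attached to A2
rows.  Hemisegments that could not be scored are simply absent; downstream
denominators count present records only.

Files are UTF-8 delimited text (comma or tab, auto-detected from the
header line) with fixed column names.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, TextIO, Union

import pandas as pd

from .blueprint import LUMEN_POSITIONS, ROWS, SEGMENTS, ReferenceBlueprint, reference_blueprint

HEMISEGMENT_COLUMNS = (
    "genotype",
    "embryo_id",
    "row",
    "segment",
    "svp_count",
    "tin_count",
    "anterior_cc_count",
)
LUMEN_COLUMNS = ("genotype", "embryo_id", "position", "diameter")


class TableValidationError(ValueError):
    """A delimited table violated the schema (bad label, count or key)."""


@dataclass(frozen=True)
class HemisegmentRecord:
    """One scored hemisegment."""

    genotype: str
    embryo_id: str
    row: str  # "left" | "right"
    segment: str  # "A2".."A8"
    svp_count: int
    tin_count: int
    anterior_cc_count: Optional[int] = None

    def key(self):
        return (self.genotype, self.embryo_id, self.row, self.segment)


@dataclass
class EmbryoTable:
    """A validated collection of hemisegment records.

    The key (genotype, embryo_id, row, segment) is unique; missing
    hemisegments are absent rows rather than sentinel counts.
    """

    records: List[HemisegmentRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            k = rec.key()
            if k in seen:
                raise TableValidationError(f"duplicate hemisegment key {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def genotypes(self) -> List[str]:
        out = []
        for rec in self.records:
            if rec.genotype not in out:
                out.append(rec.genotype)
        return out

    def embryo_ids(self, genotype: str) -> List[str]:
        out = []
        for rec in self.records:
            if rec.genotype == genotype and rec.embryo_id not in out:
                out.append(rec.embryo_id)
        return out

    def select(
        self,
        genotype: Optional[str] = None,
        embryo_id: Optional[str] = None,
        segments: Optional[Sequence[str]] = None,
        row: Optional[str] = None,
    ) -> List[HemisegmentRecord]:
        segs = set(segments) if segments is not None else None
        return [
            r
            for r in self.records
            if (genotype is None or r.genotype == genotype)
            and (embryo_id is None or r.embryo_id == embryo_id)
            and (segs is None or r.segment in segs)
            and (row is None or r.row == row)
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [
                {
                    "genotype": r.genotype,
                    "embryo_id": r.embryo_id,
                    "row": r.row,
                    "segment": r.segment,
                    "svp_count": r.svp_count,
                    "tin_count": r.tin_count,
                    "anterior_cc_count": r.anterior_cc_count,
                }
                for r in self.records
            ],
            columns=list(HEMISEGMENT_COLUMNS),
        )
        return df

    def extend(self, other: "EmbryoTable") -> "EmbryoTable":
        return EmbryoTable(
            records=list(self.records) + list(other.records),
            provenance=f"{self.provenance}+{other.provenance}",
        )


@dataclass(frozen=True)
class LumenMeasurement:
    """Internal lumen diameter (µm) at one of the five measured positions."""

    genotype: str
    embryo_id: str
    position: str  # A2, A3, A4, A6, A7
    diameter: float


def _detect_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _open_stream(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        return open(source, "r", encoding="utf-8", newline="")
    return source


def _normalise_row_label(value: str, line_no: int) -> str:
    v = str(value).strip().lower()
    if v not in ROWS:
        raise TableValidationError(f"row {line_no}: unknown row label {value!r} (expected left/right)")
    return v


def _normalise_segment(value: str, line_no: int) -> str:
    v = str(value).strip().upper()
    if v not in SEGMENTS:
        raise TableValidationError(
            f"row {line_no}: unknown segment label {value!r} (expected {'/'.join(SEGMENTS)})"
        )
    return v


def _parse_count(value, column: str, line_no: int, optional: bool = False) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == "":
        if optional:
            return None
        raise TableValidationError(f"row {line_no}: missing {column}")
    s = str(value).strip()
    try:
        f = float(s)
    except ValueError:
        raise TableValidationError(f"row {line_no}: non-numeric {column} {value!r}") from None
    if f != int(f):
        raise TableValidationError(f"row {line_no}: non-integer {column} {value!r}")
    n = int(f)
    if n < 0:
        raise TableValidationError(f"row {line_no}: negative {column} {n}")
    return n


def read_hemisegment_table(source: Union[str, TextIO], sep: Optional[str] = None) -> EmbryoTable:
    """Read and validate a hemisegment-count table from delimited text.

    Raises :class:`TableValidationError` naming the first offending row for
    duplicate keys, unknown segment/row labels or bad counts.
    """
    stream = _open_stream(source)
    close = isinstance(source, str)
    try:
        text = stream.read()
    finally:
        if close:
            stream.close()
    if not text.strip():
        raise TableValidationError("empty table: no header line")
    if sep is None:
        sep = _detect_sep(text.splitlines()[0])
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in HEMISEGMENT_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing required columns: {missing}")
    has_anterior = "anterior_cc_count" in df.columns

    records: List[HemisegmentRecord] = []
    seen = {}
    for idx, raw in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        row = raw._asdict() if hasattr(raw, "_asdict") else dict(zip(df.columns, raw))
        rec = HemisegmentRecord(
            genotype=str(row["genotype"]).strip(),
            embryo_id=str(row["embryo_id"]).strip(),
            row=_normalise_row_label(row["row"], idx),
            segment=_normalise_segment(row["segment"], idx),
            svp_count=_parse_count(row["svp_count"], "svp_count", idx),
            tin_count=_parse_count(row["tin_count"], "tin_count", idx),
            anterior_cc_count=(
                _parse_count(row.get("anterior_cc_count"), "anterior_cc_count", idx, optional=True)
                if has_anterior
                else None
            ),
        )
        k = rec.key()
        if k in seen:
            raise TableValidationError(f"row {idx}: duplicate hemisegment key {k} (first seen at row {seen[k]})")
        seen[k] = idx
        records.append(rec)
    provenance = source if isinstance(source, str) else getattr(source, "name", "<stream>")
    return EmbryoTable(records=records, provenance=str(provenance))


def write_hemisegment_table(table: EmbryoTable, dest: Union[str, TextIO], sep: str = ",") -> None:
    """Write a table as delimited text; round-trips through the reader."""
    df = table.to_frame()
    df["anterior_cc_count"] = df["anterior_cc_count"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    if isinstance(dest, str):
        df.to_csv(dest, sep=sep, index=False)
    else:
        df.to_csv(dest, sep=sep, index=False)


def read_lumen_table(source: Union[str, TextIO], sep: Optional[str] = None) -> List[LumenMeasurement]:
    """Read lumen-diameter measurements; positions restricted to the five
    measured points (A2-A4 posterior aorta, A6-A7 heart proper)."""
    stream = _open_stream(source)
    close = isinstance(source, str)
    try:
        text = stream.read()
    finally:
        if close:
            stream.close()
    if not text.strip():
        raise TableValidationError("empty table: no header line")
    if sep is None:
        sep = _detect_sep(text.splitlines()[0])
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in LUMEN_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"missing required columns: {missing}")
    out: List[LumenMeasurement] = []
    seen = {}
    for idx, row in enumerate(df.to_dict("records"), start=2):
        pos = str(row["position"]).strip().upper()
        if pos not in LUMEN_POSITIONS:
            raise TableValidationError(
                f"row {idx}: unknown lumen position {row['position']!r} "
                f"(measured positions are {'/'.join(LUMEN_POSITIONS)})"
            )
        try:
            diam = float(str(row["diameter"]).strip())
        except ValueError:
            raise TableValidationError(f"row {idx}: non-numeric diameter {row['diameter']!r}") from None
        if not diam > 0:
            raise TableValidationError(f"row {idx}: non-positive diameter {diam}")
        m = LumenMeasurement(
            genotype=str(row["genotype"]).strip(),
            embryo_id=str(row["embryo_id"]).strip(),
            position=pos,
            diameter=diam,
        )
        k = (m.genotype, m.embryo_id, m.position)
        if k in seen:
            raise TableValidationError(f"row {idx}: duplicate lumen position {k} (first seen at row {seen[k]})")
        seen[k] = idx
        out.append(m)
    return out


def write_lumen_table(measurements: Iterable[LumenMeasurement], dest: Union[str, TextIO], sep: str = ",") -> None:
    df = pd.DataFrame(
        [
            {"genotype": m.genotype, "embryo_id": m.embryo_id, "position": m.position, "diameter": m.diameter}
            for m in measurements
        ],
        columns=list(LUMEN_COLUMNS),
    )
    df.to_csv(dest, sep=sep, index=False)


def counts_from_deltas(
    df: pd.DataFrame, blueprint: Optional[ReferenceBlueprint] = None
) -> pd.DataFrame:
    """Convert a table of signed count *changes* into absolute counts.

    Scoring spreadsheets often tabulate the change (if any) relative to the
    wild-type expectation rather than the absolute count.  Given columns
    ``svp_delta`` / ``tin_delta`` this returns a frame with ``svp_count`` /
    ``tin_count`` = blueprint expectation + signed delta.
    """
    bp = blueprint or reference_blueprint()
    out = df.copy()
    segs = out["segment"].astype(str).str.upper()
    bad = sorted(set(segs) - set(bp.segments))
    if bad:
        raise TableValidationError(f"unknown segment labels {bad}")
    svp_exp = segs.map(bp.expected_svp)
    tin_exp = segs.map(bp.expected_tin)
    out["svp_count"] = svp_exp + out["svp_delta"].fillna(0).astype(int)
    out["tin_count"] = tin_exp + out["tin_delta"].fillna(0).astype(int)
    if (out["svp_count"] < 0).any() or (out["tin_count"] < 0).any():
        raise TableValidationError("delta implies a negative count")
    return out.drop(columns=["svp_delta", "tin_delta"])
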