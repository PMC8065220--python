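"""Protein annotation records and the tab-separated interchange dialect.

The dialect is modeled on UniProt tab downloads: one protein per row,
feature strings in UniProt flat-file style (``DISULFID 27..39``,
``TOPO_DOM 1..50; /note=Extracellular``), semicolon-separated within a
cell. Coordinates are 1-based inclusive throughout, following UniProt
convention; no 0-based representation is exposed.

Columns (UTF-8, header row required)::

    accession  gene_id  length  sequence  cysteines  signal_peptide
    topo_domains  disulfides  locations

``sequence`` is optional; when present, cysteine positions are derived
from it, otherwise they are taken from the explicit ``cysteines`` column
(comma-separated 1-based indices).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FeatureKind",
    "FeatureSpan",
    "DisulfideBond",
    "ProteinRecord",
    "AnnotationError",
    "ParseError",
    "ValidationError",
    "parse_records",
    "write_records",
    "read_records",
    "save_records",
    "validate_record",
]

COLUMNS = (
    "accession",
    "gene_id",
    "length",
    "sequence",
    "cysteines",
    "signal_peptide",
    "topo_domains",
    "disulfides",
    "locations",
)


class AnnotationError(ValueError):
    """Base class for annotation-dialect errors."""


class ParseError(AnnotationError):
    """Malformed row or feature string; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


class ValidationError(AnnotationError):
    """Structurally parseable input that violates a record invariant."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


class FeatureKind(enum.Enum):
    SIGNAL = "SIGNAL"
    TOPO_DOM = "TOPO_DOM"
    DISULFID = "DISULFID"


@dataclass(frozen=True)
class FeatureSpan:
    """A positional annotation feature, 1-based inclusive coordinates.

    ``positions_known=False`` is permitted only for DISULFID features
    (UniProt writes unknown bond endpoints as ``?``).
    """

    kind: FeatureKind
    start: int
    end: int
    note: str = ""
    positions_known: bool = True

    def __post_init__(self):
        if self.positions_known:
            if self.start < 1:
                raise ValidationError(f"feature start {self.start} < 1")
            if self.end < self.start:
                raise ValidationError(
                    f"feature end {self.end} < start {self.start}"
                )
        elif self.kind is not FeatureKind.DISULFID:
            raise ValidationError(
                f"positions_known=False not permitted for {self.kind.value}"
            )


@dataclass(frozen=True)
class DisulfideBond:
    """One annotated disulfide. ``None`` marks an unknown endpoint.

    Intrachain bonds with both endpoints known satisfy ``cys_a < cys_b``.
    Interchain bonds engage a single cysteine of this chain (the partner
    lives on another chain); they may be written ``a..a`` or ``a..?``.
    """

    cys_a: int | None
    cys_b: int | None
    interchain: bool = False

    def __post_init__(self):
        for p in (self.cys_a, self.cys_b):
            if p is not None and p < 1:
                raise ValidationError(f"disulfide position {p} < 1")
        if (
            not self.interchain
            and self.positions_known
            and not self.cys_a < self.cys_b
        ):
            raise ValidationError(
                f"intrachain bond requires cys_a < cys_b, got "
                f"{self.cys_a}..{self.cys_b}"
            )

    @property
    def positions_known(self) -> bool:
        return self.cys_a is not None and self.cys_b is not None

    def chain_positions(self) -> tuple[int, ...]:
        """Known cysteine positions this bond engages on this chain."""
        if self.interchain:
            # one cysteine of this chain; a..a duplicates are collapsed
            known = {p for p in (self.cys_a, self.cys_b) if p is not None}
            return tuple(sorted(known))[:1]
        return tuple(p for p in (self.cys_a, self.cys_b) if p is not None)


@dataclass
class ProteinRecord:
    """One protein's length, cysteines, and annotation features."""

    accession: str
    gene_id: str
    length: int
    cysteine_positions: tuple[int, ...] = ()
    signal_peptide: FeatureSpan | None = None
    topo_domains: tuple[FeatureSpan, ...] = ()
    disulfides: tuple[DisulfideBond, ...] = ()
    locations: tuple[str, ...] = ()
    sequence: str | None = None

    def __post_init__(self):
        self.cysteine_positions = tuple(self.cysteine_positions)
        self.topo_domains = tuple(self.topo_domains)
        self.disulfides = tuple(self.disulfides)
        self.locations = tuple(self.locations)


def validate_record(record: ProteinRecord, line: int | None = None) -> None:
    """Raise :class:`ValidationError` on the first invariant violation."""
    r = record
    if r.length < 1:
        raise ValidationError(f"{r.accession}: length {r.length} < 1", line)
    if r.sequence is not None and len(r.sequence) != r.length:
        raise ValidationError(
            f"{r.accession}: sequence length {len(r.sequence)} != declared "
            f"length {r.length}",
            line,
        )
    cys = r.cysteine_positions
    if list(cys) != sorted(set(cys)):
        raise ValidationError(
            f"{r.accession}: cysteine positions not unique and sorted", line
        )
    for p in cys:
        if not 1 <= p <= r.length:
            raise ValidationError(
                f"{r.accession}: cysteine position {p} outside [1, {r.length}]",
                line,
            )
    if r.sequence is not None:
        seq_cys = tuple(
            i + 1 for i, aa in enumerate(r.sequence) if aa.upper() == "C"
        )
        if cys and cys != seq_cys:
            raise ValidationError(
                f"{r.accession}: cysteine column disagrees with sequence", line
            )
    spans = list(r.topo_domains)
    if r.signal_peptide is not None:
        spans.append(r.signal_peptide)
    for span in spans:
        if span.end > r.length:
            raise ValidationError(
                f"{r.accession}: feature {span.kind.value} "
                f"{span.start}..{span.end} exceeds length {r.length}",
                line,
            )
    cys_set = set(cys)
    for bond in r.disulfides:
        for p in bond.chain_positions():
            if p > r.length:
                raise ValidationError(
                    f"{r.accession}: disulfide position {p} exceeds length",
                    line,
                )
            if cys_set and p not in cys_set:
                raise ValidationError(
                    f"{r.accession}: disulfide position {p} is not an "
                    f"annotated cysteine",
                    line,
                )


# ---------------------------------------------------------------------------
# feature-string grammar

_SPAN_RE = re.compile(
    r"^(?P<kind>SIGNAL|TOPO_DOM|DISULFID)\s+(?P<a>\?|\d+)\.\.(?P<b>\?|\d+)$"
)
_NOTE_RE = re.compile(r'^/note=(?:"(?P<q>[^"]*)"|(?P<u>.*))$')


def _split_features(cell: str) -> list[tuple[str, str]]:
    """Split a cell into (feature, note) pairs.

    Segments are semicolon-separated; a segment starting with ``/`` is a
    qualifier attached to the preceding feature.
    """
    out: list[tuple[str, str]] = []
    for seg in cell.split(";"):
        seg = seg.strip()
        if not seg:
            continue
        if seg.startswith("/"):
            if not out:
                raise ParseError(f"dangling qualifier {seg!r}")
            m = _NOTE_RE.match(seg)
            if m is None:
                raise ParseError(f"malformed qualifier {seg!r}")
            note = m.group("q") if m.group("q") is not None else m.group("u")
            feat, _ = out[-1]
            out[-1] = (feat, note.strip())
        else:
            out.append((seg, ""))
    return out


def _parse_span(feat: str, note: str) -> tuple[FeatureKind, int | None, int | None]:
    m = _SPAN_RE.match(feat)
    if m is None:
        raise ParseError(f"malformed feature string {feat!r}")
    a = None if m.group("a") == "?" else int(m.group("a"))
    b = None if m.group("b") == "?" else int(m.group("b"))
    return FeatureKind(m.group("kind")), a, b


def _parse_feature_cell(cell: str, expect: FeatureKind) -> list:
    out = []
    for feat, note in _split_features(cell):
        kind, a, b = _parse_span(feat, note)
        if kind is not expect:
            raise ParseError(
                f"feature {feat!r}: expected {expect.value} in this column"
            )
        if expect is FeatureKind.DISULFID:
            out.append(
                DisulfideBond(a, b, interchain=note.lower() == "interchain")
            )
        else:
            if a is None or b is None:
                raise ParseError(
                    f"unknown positions not permitted for {expect.value}"
                )
            out.append(FeatureSpan(kind, a, b, note=note))
    return out


def _format_span(span: FeatureSpan) -> str:
    s = f"{span.kind.value} {span.start}..{span.end}"
    if span.note:
        s += f"; /note={span.note}"
    return s


def _format_bond(bond: DisulfideBond) -> str:
    a = "?" if bond.cys_a is None else str(bond.cys_a)
    b = "?" if bond.cys_b is None else str(bond.cys_b)
    s = f"DISULFID {a}..{b}"
    if bond.interchain:
        s += "; /note=Interchain"
    return s


# ---------------------------------------------------------------------------
# table-level parse / write

def parse_records(text: str | Iterable[str]) -> list[ProteinRecord]:
    """Parse the annotation dialect into :class:`ProteinRecord` objects.

    Every grammatical row parses or raises a located error; nothing is
    silently dropped. Duplicate accessions are a validation error.
    """
    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text]
    if not lines:
        raise ParseError("empty input: header row required")
    header = tuple(lines[0].rstrip("\r").split("\t"))
    if header != COLUMNS:
        raise ParseError(
            f"unexpected header {header!r}; expected {COLUMNS!r}", line=1
        )
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        cells = raw.rstrip("\r").split("\t")
        if len(cells) != len(COLUMNS):
            raise ParseError(
                f"expected {len(COLUMNS)} columns, got {len(cells)}", lineno
            )
        row = dict(zip(COLUMNS, cells))
        try:
            record = _parse_row(row)
            validate_record(record, line=lineno)
        except AnnotationError as exc:
            if exc.line is None:
                raise type(exc)(str(exc), line=lineno) from None
            raise
        if record.accession in seen:
            raise ValidationError(
                f"duplicate accession {record.accession}", lineno
            )
        seen.add(record.accession)
        records.append(record)
    return records


def _parse_row(row: dict[str, str]) -> ProteinRecord:
    try:
        length = int(row["length"])
    except ValueError:
        raise ParseError(f"non-integer length {row['length']!r}") from None
    sequence = row["sequence"] or None
    if sequence is not None:
        cys = tuple(i + 1 for i, aa in enumerate(sequence) if aa.upper() == "C")
    elif row["cysteines"]:
        try:
            cys = tuple(int(p) for p in row["cysteines"].split(","))
        except ValueError:
            raise ParseError(
                f"malformed cysteine list {row['cysteines']!r}"
            ) from None
    else:
        cys = ()
    signals = _parse_feature_cell(row["signal_peptide"], FeatureKind.SIGNAL)
    if len(signals) > 1:
        raise ValidationError("more than one signal peptide")
    topo = _parse_feature_cell(row["topo_domains"], FeatureKind.TOPO_DOM)
    bonds = _parse_feature_cell(row["disulfides"], FeatureKind.DISULFID)
    locations = tuple(
        loc.strip() for loc in row["locations"].split(";") if loc.strip()
    )
    return ProteinRecord(
        accession=row["accession"],
        gene_id=row["gene_id"],
        length=length,
        cysteine_positions=cys,
        signal_peptide=signals[0] if signals else None,
        topo_domains=tuple(topo),
        disulfides=tuple(bonds),
        locations=locations,
        sequence=sequence,
    )


def write_records(records: Sequence[ProteinRecord]) -> str:
    """Serialize records to the dialect; inverse of :func:`parse_records`."""
    lines = ["\t".join(COLUMNS)]
    for r in records:
        validate_record(r)
        lines.append(
            "\t".join(
                (
                    r.accession,
                    r.gene_id,
                    str(r.length),
                    r.sequence or "",
                    "" if r.sequence else ",".join(map(str, r.cysteine_positions)),
                    _format_span(r.signal_peptide) if r.signal_peptide else "",
                    "; ".join(_format_span(s) for s in r.topo_domains),
                    "; ".join(_format_bond(b) for b in r.disulfides),
                    "; ".join(r.locations),
                )
            )
        )
    return "\n".join(lines) + "\n"


def read_records(path: str | Path) -> list[ProteinRecord]:
    return parse_records(Path(path).read_text(encoding="utf-8"))


def save_records(records: Sequence[ProteinRecord], path: str | Path) -> None:
    Path(path).write_text(write_records(records), encoding="utf-8")
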