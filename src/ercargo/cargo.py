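"""ER-cargo filtering and hypoxia-induction grouping.

ER cargo is defined operationally: a signal-peptide-bearing protein whose
subcellular location includes "secreted" or "cell membrane" and excludes
"endoplasmic reticulum" and "golgi apparatus" (residents of those
compartments are not cargo in transit). Cargo is then split by transcript
response to 24 h anoxia in HCT116 and/or HepG2 cells: induced (fold
change above 2 in at least one cell line) versus noninduced (below 1.2 in
every measured cell line). Fold changes are linear ratios, not log2.

Genes whose fold changes fall between the two bands belong to neither
published group and are assigned ``EXCLUDED`` rather than silently
dropped; genes absent from the expression table are ``UNMEASURED``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import ProteinRecord

__all__ = [
    "CargoClass",
    "InductionGroup",
    "SelectionConfig",
    "CargoAssignment",
    "CELL_LINES",
    "read_expression_table",
    "validate_expression_table",
    "classify_cargo",
    "assign_induction",
    "build_groups",
    "assignment_table",
]

CELL_LINES = ("HCT116", "HepG2")

EXPRESSION_COLUMNS = ("gene_id", "cell_line", "fold_change")


class CargoClass(enum.Enum):
    SECRETED = "secreted"
    MEMBRANE = "membrane"
    NOT_CARGO = "not_cargo"


class InductionGroup(enum.Enum):
    INDUCED = "induced"
    NONINDUCED = "noninduced"
    EXCLUDED = "excluded"
    UNMEASURED = "unmeasured"


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds and location vocabulary for the cargo filter."""

    induced_threshold: float = 2.0
    noninduced_threshold: float = 1.2
    cargo_locations: frozenset[str] = frozenset({"secreted", "cell membrane"})
    excluded_locations: frozenset[str] = frozenset(
        {"endoplasmic reticulum", "golgi apparatus"}
    )
    membrane_location: str = "cell membrane"

    def __post_init__(self):
        if not self.noninduced_threshold < self.induced_threshold:
            raise ValueError(
                "noninduced_threshold must be below induced_threshold"
            )


@dataclass(frozen=True)
class CargoAssignment:
    accession: str
    cargo_class: CargoClass
    induction_group: InductionGroup | None

    def __post_init__(self):
        if self.cargo_class is CargoClass.NOT_CARGO and self.induction_group:
            raise ValueError("induction_group defined only for cargo")


def _matches(locations: Iterable[str], term: str) -> bool:
    # case-insensitive substring match, mirroring a keyword filter
    term = term.lower()
    return any(term in loc.lower() for loc in locations)


def classify_cargo(
    record: ProteinRecord, config: SelectionConfig = SelectionConfig()
) -> CargoClass:
    """Classify one record as SECRETED, MEMBRANE, or NOT_CARGO.

    Requires a signal peptide and a cargo location; any excluded
    (ER/Golgi-resident) location disqualifies regardless of other matches.
    """
    if record.signal_peptide is None:
        return CargoClass.NOT_CARGO
    if any(_matches(record.locations, t) for t in config.excluded_locations):
        return CargoClass.NOT_CARGO
    if not any(_matches(record.locations, t) for t in config.cargo_locations):
        return CargoClass.NOT_CARGO
    if _matches(record.locations, config.membrane_location):
        return CargoClass.MEMBRANE
    return CargoClass.SECRETED


def validate_expression_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(EXPRESSION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    bad_lines = set(table["cell_line"]) - set(CELL_LINES)
    if bad_lines:
        raise ValueError(f"unknown cell lines {sorted(bad_lines)}")
    if (table["fold_change"] <= 0).any():
        raise ValueError("fold changes must be positive linear ratios")
    if table.duplicated(["gene_id", "cell_line"]).any():
        raise ValueError("duplicate (gene_id, cell_line) rows")
    return table


def read_expression_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "cell_line": str})
    return validate_expression_table(table)


def assign_induction(
    record: ProteinRecord,
    table: pd.DataFrame,
    config: SelectionConfig = SelectionConfig(),
) -> InductionGroup:
    """Assign the hypoxia-induction group from measured fold changes.

    INDUCED wins if any cell line exceeds the high threshold (the "and/or"
    rule); NONINDUCED requires every measured cell line below the low
    threshold; intermediate patterns are EXCLUDED.
    """
    folds = table.loc[table["gene_id"] == record.gene_id, "fold_change"]
    if folds.empty:
        return InductionGroup.UNMEASURED
    if (folds > config.induced_threshold).any():
        return InductionGroup.INDUCED
    if (folds < config.noninduced_threshold).all():
        return InductionGroup.NONINDUCED
    return InductionGroup.EXCLUDED


def build_groups(
    records: Sequence[ProteinRecord],
    table: pd.DataFrame,
    config: SelectionConfig = SelectionConfig(),
) -> dict[tuple[CargoClass, InductionGroup], list[str]]:
    """Partition cargo records into (cargo_class, induction_group) groups.

    The partition is exhaustive and disjoint over cargo records and
    order-invariant (accessions are sorted). EXCLUDED and UNMEASURED
    groups are reported so the caller can log them; downstream two-group
    comparisons use only INDUCED and NONINDUCED.
    """
    validate_expression_table(table)
    groups: dict[tuple[CargoClass, InductionGroup], list[str]] = {
        (c, g): []
        for c in (CargoClass.SECRETED, CargoClass.MEMBRANE)
        for g in InductionGroup
    }
    # index once; per-record scans are quadratic on large proteomes
    by_gene = {
        gene: sub["fold_change"]
        for gene, sub in table.groupby("gene_id", sort=False)
    }
    for record in records:
        cls = classify_cargo(record, config)
        if cls is CargoClass.NOT_CARGO:
            continue
        folds = by_gene.get(record.gene_id)
        if folds is None or folds.empty:
            grp = InductionGroup.UNMEASURED
        elif (folds > config.induced_threshold).any():
            grp = InductionGroup.INDUCED
        elif (folds < config.noninduced_threshold).all():
            grp = InductionGroup.NONINDUCED
        else:
            grp = InductionGroup.EXCLUDED
        groups[(cls, grp)].append(record.accession)
    for members in groups.values():
        members.sort()
    return groups


def assignment_table(
    records: Sequence[ProteinRecord],
    groups: Mapping[tuple[CargoClass, InductionGroup], Sequence[str]],
) -> pd.DataFrame:
    """Flatten a grouping into a tidy (accession, cargo_class, group) table."""
    lookup: dict[str, tuple[CargoClass, InductionGroup]] = {}
    for (cls, grp), accs in groups.items():
        for acc in accs:
            lookup[acc] = (cls, grp)
    rows = []
    for record in records:
        cls, grp = lookup.get(record.accession, (CargoClass.NOT_CARGO, None))
        rows.append(
            {
                "accession": record.accession,
                "cargo_class": cls.value,
                "induction_group": grp.value if grp else "",
            }
        )
    return pd.DataFrame(rows, columns=["accession", "cargo_class", "induction_group"])
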