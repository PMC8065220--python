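"""Per-protein disulfide-architecture metrics.

For each ER cargo protein the module counts intrachain (D) and interchain
(I) disulfide bonds, bond density per 100 amino acids, the range of each
intrachain bond (number of residues strictly between the paired
cysteines), and the fraction of cysteines engaged in a bond,
(2D + I) / n_cysteines. Every cysteine not annotated in a disulfide is
treated as a free thiol.

For membrane proteins, the intracellular (cytosolic) portion never sees
the ER oxidative folding machinery, so residues inside topological
domains annotated "Cytoplasmic" are excluded before anything is counted:
cysteines, bond endpoints, and the length denominator all refer to the
remaining (effective) region. A bond is dropped iff either endpoint lies
outside the region. Bonds with unknown endpoint coordinates still count
toward D or I — the architecture exists even if the coordinates are
missing — but contribute no range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import DisulfideBond, ProteinRecord
from .cargo import CargoClass, InductionGroup

__all__ = [
    "DisulfideMetrics",
    "MetricsTable",
    "effective_region",
    "compute_metrics",
    "metrics_table",
    "RANGE_CONVENTIONS",
]

RANGE_CONVENTIONS = ("between", "delta")

CYTOPLASMIC_NOTE = "cytoplasmic"


@dataclass(frozen=True)
class DisulfideMetrics:
    """Architecture metrics for one protein within its effective region.

    ``fraction_cys_bonded`` is ``None`` (undefined) when the region
    contains no cysteines; such proteins are omitted from
    fraction-of-cysteines group comparisons.
    """

    accession: str
    D: int
    I: int
    effective_length: int
    bonds_per_100aa: float
    bond_ranges: tuple[int, ...]
    fraction_cys_bonded: float | None
    n_cysteines: int
    n_free_cys: int

    def __post_init__(self):
        if self.n_free_cys < 0:
            raise ValueError(
                f"{self.accession}: more bonded cysteines than cysteines "
                f"(2*{self.D}+{self.I} > {self.n_cysteines})"
            )


def effective_region(
    record: ProteinRecord, cargo_class: CargoClass
) -> set[int]:
    """Residue indices retained for counting (1-based, inclusive).

    Secreted proteins keep the full chain. Membrane proteins lose the
    union of their Cytoplasmic topological domains (overlaps are not
    double-counted). The signal peptide is retained; excluding it is a
    choice left to upstream annotation.
    """
    region = set(range(1, record.length + 1))
    if cargo_class is not CargoClass.MEMBRANE:
        return region
    for span in record.topo_domains:
        if CYTOPLASMIC_NOTE in span.note.lower():
            region.difference_update(range(span.start, span.end + 1))
    return region


def _bond_in_region(bond: DisulfideBond, region: set[int]) -> bool:
    # unknown endpoints cannot exclude a bond; known ones outside do
    return all(p in region for p in bond.chain_positions())


def compute_metrics(
    record: ProteinRecord,
    cargo_class: CargoClass,
    range_convention: str = "between",
) -> DisulfideMetrics:
    """Compute :class:`DisulfideMetrics` for one record.

    ``range_convention`` selects the bond-range definition: ``"between"``
    counts residues strictly between the paired cysteines (j - i - 1);
    ``"delta"`` is the plain index difference (j - i).
    """
    if range_convention not in RANGE_CONVENTIONS:
        raise ValueError(f"unknown range convention {range_convention!r}")
    region = effective_region(record, cargo_class)
    if not region:
        raise ValueError(f"{record.accession}: empty effective region")
    n_cys = sum(1 for p in record.cysteine_positions if p in region)
    D = 0
    I = 0
    ranges: list[int] = []
    offset = 1 if range_convention == "between" else 0
    for bond in record.disulfides:
        if not _bond_in_region(bond, region):
            continue
        if bond.interchain:
            I += 1
        else:
            D += 1
            if bond.positions_known:
                ranges.append(bond.cys_b - bond.cys_a - offset)
    eff_len = len(region)
    bonded = 2 * D + I
    return DisulfideMetrics(
        accession=record.accession,
        D=D,
        I=I,
        effective_length=eff_len,
        bonds_per_100aa=100.0 * (D + I) / eff_len,
        bond_ranges=tuple(ranges),
        fraction_cys_bonded=bonded / n_cys if n_cys > 0 else None,
        n_cysteines=n_cys,
        n_free_cys=n_cys - bonded,
    )


@dataclass
class MetricsTable:
    """Per-protein metrics plus the pooled per-bond range table.

    ``per_protein``: one row per cargo protein (accession, cargo_class,
    induction_group, D, I, effective_length, bonds_per_100aa,
    fraction_cys_bonded, n_cysteines, n_free_cys, mean_bond_range).
    ``bond_ranges``: long format, one row per intrachain bond with known
    endpoints (accession, cargo_class, induction_group, bond_range) —
    the pooled values behind per-bond range comparisons.
    """

    per_protein: pd.DataFrame
    bond_ranges: pd.DataFrame


PER_PROTEIN_COLUMNS = (
    "accession",
    "cargo_class",
    "induction_group",
    "D",
    "I",
    "effective_length",
    "bonds_per_100aa",
    "fraction_cys_bonded",
    "n_cysteines",
    "n_free_cys",
    "mean_bond_range",
)

RANGE_COLUMNS = ("accession", "cargo_class", "induction_group", "bond_range")


def metrics_table(
    records: Sequence[ProteinRecord],
    groups: Mapping[tuple[CargoClass, InductionGroup], Sequence[str]],
    range_convention: str = "between",
) -> MetricsTable:
    """Tabulate metrics for every cargo protein in ``groups``.

    Values are per protein, never aggregated across proteins, except for
    the pooled per-bond ranges emitted as the companion long table.
    """
    by_acc = {r.accession: r for r in records}
    if len(by_acc) != len(records):
        raise ValueError("duplicate accessions in record list")
    rows = []
    range_rows = []
    for (cls, grp), accessions in sorted(
        groups.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
    ):
        for acc in accessions:
            record = by_acc[acc]
            m = compute_metrics(record, cls, range_convention)
            rows.append(
                {
                    "accession": acc,
                    "cargo_class": cls.value,
                    "induction_group": grp.value,
                    "D": m.D,
                    "I": m.I,
                    "effective_length": m.effective_length,
                    "bonds_per_100aa": m.bonds_per_100aa,
                    "fraction_cys_bonded": (
                        math.nan
                        if m.fraction_cys_bonded is None
                        else m.fraction_cys_bonded
                    ),
                    "n_cysteines": m.n_cysteines,
                    "n_free_cys": m.n_free_cys,
                    "mean_bond_range": (
                        sum(m.bond_ranges) / len(m.bond_ranges)
                        if m.bond_ranges
                        else math.nan
                    ),
                }
            )
            for r in m.bond_ranges:
                range_rows.append(
                    {
                        "accession": acc,
                        "cargo_class": cls.value,
                        "induction_group": grp.value,
                        "bond_range": r,
                    }
                )
    per_protein = pd.DataFrame(rows, columns=list(PER_PROTEIN_COLUMNS))
    bond_ranges = pd.DataFrame(range_rows, columns=list(RANGE_COLUMNS))
    return MetricsTable(per_protein=per_protein, bond_ranges=bond_ranges)
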