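"""Disulfide metrics: worked examples, brute-force oracle, invariants."""

from __future__ import annotations

import math
import re

import pytest

from ercargo.annotation import (
    DisulfideBond,
    FeatureKind,
    FeatureSpan,
    ProteinRecord,
    write_records,
    COLUMNS,
)
from ercargo.cargo import CargoClass, build_groups
from ercargo.metrics import compute_metrics, effective_region, metrics_table
from ercargo.simulate import ProteomeSimConfig, simulate_proteome


def secreted(length, bonds=(), cys=(), topo=()):
    positions = sorted(
        set(cys)
        | {p for b in bonds for p in (b.cys_a, b.cys_b) if p is not None}
    )
    return ProteinRecord(
        accession="X1",
        gene_id="GX",
        length=length,
        cysteine_positions=tuple(positions),
        disulfides=tuple(bonds),
        topo_domains=tuple(topo),
    )


def topo(a, b, note="Cytoplasmic"):
    return FeatureSpan(FeatureKind.TOPO_DOM, a, b, note=note)


class TestEffectiveRegion:
    def test_secreted_keeps_full_chain(self):
        rec = secreted(200)
        assert len(effective_region(rec, CargoClass.SECRETED)) == 200

    def test_membrane_drops_cytoplasmic_tail(self):
        rec = secreted(250, topo=(topo(201, 250),))
        region = effective_region(rec, CargoClass.MEMBRANE)
        assert len(region) == 200
        assert 201 not in region and 200 in region

    def test_overlapping_cytoplasmic_spans_are_unioned(self):
        rec = secreted(250, topo=(topo(10, 30), topo(20, 40)))
        region = effective_region(rec, CargoClass.MEMBRANE)
        assert len(region) == 250 - 31

    def test_noncytoplasmic_domains_are_kept(self):
        rec = secreted(250, topo=(topo(10, 30, note="Extracellular"),))
        assert len(effective_region(rec, CargoClass.MEMBRANE)) == 250


class TestWorkedExamples:
    def test_ldlr_architecture(self, ldlr_like_record):
        m = compute_metrics(ldlr_like_record, CargoClass.MEMBRANE)
        assert (m.D, m.I) == (30, 0)
        assert m.n_cysteines == 63
        assert m.fraction_cys_bonded == pytest.approx(60 / 63)
        assert m.n_free_cys == 3

    def test_ca9_architecture(self, ca9_like_record):
        m = compute_metrics(ca9_like_record, CargoClass.MEMBRANE)
        assert (m.D, m.I) == (1, 1)
        assert m.n_cysteines == 5
        assert m.fraction_cys_bonded == pytest.approx(0.6)
        assert m.n_free_cys == 2

    def test_density_and_ranges(self):
        rec = secreted(200, bonds=(DisulfideBond(27, 39), DisulfideBond(50, 51)))
        m = compute_metrics(rec, CargoClass.SECRETED)
        assert m.bonds_per_100aa == pytest.approx(1.0)
        assert m.bond_ranges == (11, 0)

    def test_delta_range_convention(self):
        rec = secreted(200, bonds=(DisulfideBond(27, 39),))
        m = compute_metrics(rec, CargoClass.SECRETED, range_convention="delta")
        assert m.bond_ranges == (12,)

    def test_unknown_position_bond_counts_but_has_no_range(self):
        rec = secreted(
            100,
            bonds=(DisulfideBond(10, None), DisulfideBond(20, None, interchain=True)),
            cys=(30,),
        )
        m = compute_metrics(rec, CargoClass.SECRETED)
        assert (m.D, m.I) == (1, 1)
        assert m.bond_ranges == ()

    def test_bond_with_endpoint_in_cytoplasm_is_excluded(self):
        rec = secreted(
            300,
            bonds=(DisulfideBond(10, 250), DisulfideBond(20, 40)),
            topo=(topo(200, 300),),
        )
        m = compute_metrics(rec, CargoClass.MEMBRANE)
        assert m.D == 1  # the 10..250 bond straddles the excluded tail

    def test_no_cysteines_leaves_fraction_undefined(self):
        m = compute_metrics(secreted(100), CargoClass.SECRETED)
        assert m.fraction_cys_bonded is None
        assert m.n_cysteines == 0


class TestInvariants:
    def test_cysteine_conservation_on_generator_output(self, small_proteome):
        records, table, truth = small_proteome
        lookup = truth.proteome.set_index("accession")
        for rec in records:
            cls = lookup.loc[rec.accession, "cargo_class"]
            if cls == "not_cargo":
                continue
            m = compute_metrics(rec, CargoClass(cls))
            assert 2 * m.D + m.I + m.n_free_cys == m.n_cysteines

    def test_cysteine_free_cytoplasmic_domain_changes_only_length_terms(self):
        bonds = (DisulfideBond(20, 60),)
        base = secreted(300, bonds=bonds, cys=(80,))
        trimmed = secreted(300, bonds=bonds, cys=(80,), topo=(topo(200, 260),))
        m0 = compute_metrics(base, CargoClass.MEMBRANE)
        m1 = compute_metrics(trimmed, CargoClass.MEMBRANE)
        assert (m1.D, m1.I) == (m0.D, m0.I)
        assert m1.fraction_cys_bonded == m0.fraction_cys_bonded
        assert m1.effective_length == m0.effective_length - 61
        assert m1.bonds_per_100aa > m0.bonds_per_100aa


# ---------------------------------------------------------------------------
# independent brute-force oracle: recount everything from the serialized row

_FEAT = re.compile(r"(SIGNAL|TOPO_DOM|DISULFID) (\?|\d+)\.\.(\?|\d+)")


def oracle_metrics(tsv_row: str, cargo_class: str) -> dict:
    """Recount D, I, cysteines and ranges by rescanning one written row."""
    cells = dict(zip(COLUMNS, tsv_row.split("\t")))
    length = int(cells["length"])
    keep = [True] * (length + 1)  # index 0 unused
    if cargo_class == "membrane":
        for chunk in cells["topo_domains"].split(";"):
            chunk = chunk.strip()
            if chunk.startswith("/note=") and "cytoplasmic" in chunk.lower():
                a, b = last_span
                for i in range(a, b + 1):
                    keep[i] = False
            m = _FEAT.match(chunk)
            if m and m.group(1) == "TOPO_DOM":
                last_span = (int(m.group(2)), int(m.group(3)))
    if cells["sequence"]:
        cys = [i + 1 for i, aa in enumerate(cells["sequence"]) if aa == "C"]
    else:
        cys = [int(p) for p in cells["cysteines"].split(",") if p]
    n_cys = sum(1 for p in cys if keep[p])
    D = I = 0
    ranges = []
    segments = [s.strip() for s in cells["disulfides"].split(";") if s.strip()]
    i = 0
    while i < len(segments):
        m = _FEAT.match(segments[i])
        assert m and m.group(1) == "DISULFID"
        inter = (
            i + 1 < len(segments)
            and segments[i + 1].lower() == "/note=interchain"
        )
        if inter:
            i += 1
        a = None if m.group(2) == "?" else int(m.group(2))
        b = None if m.group(3) == "?" else int(m.group(3))
        endpoints = [p for p in (a, b) if p is not None]
        if inter:
            endpoints = sorted(set(endpoints))[:1]
        if all(keep[p] for p in endpoints):
            if inter:
                I += 1
            else:
                D += 1
                if a is not None and b is not None:
                    ranges.append(b - a - 1)
        i += 1
    eff_len = sum(keep[1:])
    return {
        "D": D,
        "I": I,
        "effective_length": eff_len,
        "bonds_per_100aa": 100.0 * (D + I) / eff_len,
        "bond_ranges": tuple(ranges),
        "n_cysteines": n_cys,
        "n_free_cys": n_cys - 2 * D - I,
        "fraction_cys_bonded": (2 * D + I) / n_cys if n_cys else None,
    }


def test_oracle_equivalence_on_synthetic_proteome(small_proteome):
    records, table, truth = small_proteome
    lookup = truth.proteome.set_index("accession")["cargo_class"]
    rows = write_records(records).splitlines()[1:]
    for rec, row in zip(records, rows):
        cls = lookup[rec.accession]
        if cls == "not_cargo":
            continue
        m = compute_metrics(rec, CargoClass(cls))
        o = oracle_metrics(row, cls)
        assert m.D == o["D"] and m.I == o["I"]
        assert m.effective_length == o["effective_length"]
        assert m.bonds_per_100aa == pytest.approx(o["bonds_per_100aa"])
        assert tuple(sorted(m.bond_ranges)) == tuple(sorted(o["bond_ranges"]))
        assert m.n_cysteines == o["n_cysteines"]
        assert m.n_free_cys == o["n_free_cys"]


class TestMetricsTable:
    def test_empty_input(self):
        t = metrics_table([], {})
        assert t.per_protein.empty and t.bond_ranges.empty

    def test_one_row_per_cargo_protein_unique_keys(self, small_proteome):
        records, table, truth = small_proteome
        groups = build_groups(records, table)
        t = metrics_table(records, groups)
        assert t.per_protein["accession"].is_unique
        n_cargo = (truth.proteome["cargo_class"] != "not_cargo").sum()
        assert len(t.per_protein) == n_cargo

    def test_pooled_ranges_match_per_protein_counts(self, small_proteome):
        records, table, _ = small_proteome
        groups = build_groups(records, table)
        t = metrics_table(records, groups)
        # every ranged bond appears exactly once in the long table
        by_acc = t.bond_ranges.groupby("accession").size()
        for _, r in t.per_protein.iterrows():
            expected = by_acc.get(r["accession"], 0)
            assert expected <= r["D"]
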