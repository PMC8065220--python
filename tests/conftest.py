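"""Shared fixtures: hand-built reference proteins and small simulations."""

from __future__ import annotations

import pytest

from ercargo.annotation import (
    DisulfideBond,
    FeatureKind,
    FeatureSpan,
    ProteinRecord,
)
from ercargo.simulate import ProteomeSimConfig, simulate_proteome


@pytest.fixture(scope="session")
def ldlr_like_record() -> ProteinRecord:
    """An LDLR-architecture protein: 30 intrachain bonds concentrated in
    the N-terminal region, 3 free cysteines, 63 cysteines total."""
    bonds = tuple(
        DisulfideBond(10 * k + 30, 10 * k + 37) for k in range(30)
    )
    cys = sorted(
        [b.cys_a for b in bonds] + [b.cys_b for b in bonds] + [400, 500, 600]
    )
    return ProteinRecord(
        accession="LDLR_LIKE",
        gene_id="LDLR",
        length=860,
        cysteine_positions=tuple(cys),
        signal_peptide=FeatureSpan(FeatureKind.SIGNAL, 1, 21),
        disulfides=bonds,
        locations=("Cell membrane",),
    )


@pytest.fixture(scope="session")
def ca9_like_record() -> ProteinRecord:
    """A CA9-architecture monomer: one intrachain bond, one interchain
    (homodimer) bond, two free cysteines, 5 cysteines total."""
    return ProteinRecord(
        accession="CA9_LIKE",
        gene_id="CA9",
        length=459,
        cysteine_positions=(41, 100, 130, 200, 300),
        signal_peptide=FeatureSpan(FeatureKind.SIGNAL, 1, 37),
        disulfides=(
            DisulfideBond(100, 130),
            DisulfideBond(41, None, interchain=True),
        ),
        locations=("Cell membrane",),
    )


SMALL_SIM = ProteomeSimConfig(
    n_induced=30,
    n_noninduced=60,
    n_excluded=6,
    n_unmeasured=6,
    n_noncargo=12,
    seed=11,
)


@pytest.fixture(scope="session")
def small_proteome():
    """A ~110-record simulated proteome shared across fast tests."""
    return simulate_proteome(SMALL_SIM)
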