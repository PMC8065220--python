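"""Pulse-chase densitometry fractions.

Radioactive pulse-chase experiments follow a cohort of newly synthesized,
:sup:`35`\\ S-labeled protein over chase time; gel band intensities
(background-subtracted, arbitrary units) quantify how much of the cohort
has been secreted, dimerized, or acquired Golgi-type glycosylation. Three
fraction conventions appear in the source experiments:

* **secreted** — secreted signal at time *t* relative to the total
  (secreted + lysate) signal at a reference chase time (15 min, the
  earliest point where folding intermediates have resolved);
* **dimer** — dimer signal at *t* relative to the total
  (dimer + monomer) at the 0-min reference;
* **golgi** — contemporaneous: Golgi-form / (Golgi-form + ER-form)
  within the same lane, no reference time.

"Relative to the X-min time point" is read as normalization by the total
signal at the reference chase time, so loss or gain versus the reference
stays visible; contemporaneous normalization can be selected per call.
All fractions are invariant under global rescaling of intensities.

Oxidative folding fitness is the summary percentage of a protein that
reaches its normoxic conformation at the last assayed chase time in
0% O2, relative to normoxia, capped at 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BANDS",
    "KineticsResult",
    "read_band_table",
    "validate_band_table",
    "fraction_secreted",
    "fraction_dimer",
    "fraction_golgi",
    "kinetics_curve",
    "folding_fitness",
]

BANDS = ("LYSATE", "SECRETED", "MONOMER", "DIMER", "ER_FORM", "GOLGI_FORM")

BAND_COLUMNS = ("condition", "replicate", "chase_min", "band", "intensity")

#: numerator and denominator bands per fraction mode
_MODES = {
    "secreted": ("SECRETED", ("SECRETED", "LYSATE"), 15),
    "dimer": ("DIMER", ("DIMER", "MONOMER"), 0),
    "golgi": ("GOLGI_FORM", ("GOLGI_FORM", "ER_FORM"), None),
}


@dataclass(frozen=True)
class KineticsResult:
    """Replicate-summarized fraction at one (condition, chase time)."""

    condition: str
    chase_min: int
    fractions: tuple[float, ...]  # one per replicate
    mean: float
    sd: float
    sem: float
    n: int


def validate_band_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(BAND_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"band table missing columns {sorted(missing)}")
    bad = set(table["band"]) - set(BANDS)
    if bad:
        raise ValueError(f"unknown bands {sorted(bad)}")
    if (table["intensity"] < 0).any():
        raise ValueError("band intensities must be non-negative")
    if (table["chase_min"] < 0).any():
        raise ValueError("chase times must be non-negative")
    if table.duplicated(["condition", "replicate", "chase_min", "band"]).any():
        raise ValueError("duplicate (condition, replicate, chase_min, band)")
    return table


def read_band_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return validate_band_table(table)


def _band(
    table: pd.DataFrame, condition: str, replicate, t: int, band: str
) -> float:
    sel = (
        (table["condition"] == condition)
        & (table["replicate"] == replicate)
        & (table["chase_min"] == t)
        & (table["band"] == band)
    )
    hit = table.loc[sel, "intensity"]
    if hit.empty:
        raise ValueError(
            f"missing band {band} at t={t} min for ({condition!r}, "
            f"replicate {replicate})"
        )
    return float(hit.iloc[0])


def _fraction(
    table: pd.DataFrame,
    condition: str,
    t: int,
    mode: str,
    t_ref: int | None,
) -> KineticsResult:
    numerator_band, denom_bands, default_ref = _MODES[mode]
    if t_ref is None:
        t_ref = default_ref
    replicates = sorted(
        table.loc[table["condition"] == condition, "replicate"].unique()
    )
    if not replicates:
        raise ValueError(f"no replicates for condition {condition!r}")
    fractions = []
    for rep in replicates:
        num = _band(table, condition, rep, t, numerator_band)
        ref_t = t if t_ref is None else t_ref
        total = sum(
            _band(table, condition, rep, ref_t, b) for b in denom_bands
        )
        if total <= 0:
            raise ValueError(
                f"zero reference total at t={ref_t} min for "
                f"({condition!r}, replicate {rep})"
            )
        fractions.append(num / total)
    arr = np.asarray(fractions)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else math.nan
    return KineticsResult(
        condition=condition,
        chase_min=int(t),
        fractions=tuple(float(f) for f in fractions),
        mean=float(arr.mean()),
        sd=sd,
        sem=sd / math.sqrt(arr.size) if arr.size > 1 else math.nan,
        n=int(arr.size),
    )


def fraction_secreted(
    table: pd.DataFrame, condition: str, t: int, t_ref: int = 15
) -> KineticsResult:
    """Secreted(t) / (Secreted + Lysate) at the reference chase time."""
    validate_band_table(table)
    return _fraction(table, condition, t, "secreted", t_ref)


def fraction_dimer(
    table: pd.DataFrame, condition: str, t: int, t_ref: int = 0
) -> KineticsResult:
    """Dimer(t) / (Dimer + Monomer) at the reference chase time.

    Dimer intensity is taken as-is; no stoichiometric doubling for the
    two labeled monomers per dimer (the published quantification does not
    state one).
    """
    validate_band_table(table)
    return _fraction(table, condition, t, "dimer", t_ref)


def fraction_golgi(table: pd.DataFrame, condition: str, t: int) -> KineticsResult:
    """Golgi-form / (Golgi-form + ER-form), same-lane normalization."""
    validate_band_table(table)
    return _fraction(table, condition, t, "golgi", t)


def kinetics_curve(
    table: pd.DataFrame,
    condition: str,
    mode: str,
    times: Sequence[int] | None = None,
    t_ref: int | None = None,
) -> pd.DataFrame:
    """Fractions across chase times; tidy table for plotting or export."""
    validate_band_table(table)
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {sorted(_MODES)}")
    if times is None:
        times = sorted(
            table.loc[table["condition"] == condition, "chase_min"].unique()
        )
    rows = []
    for t in times:
        ref = t if mode == "golgi" else t_ref
        res = _fraction(table, condition, int(t), mode, ref)
        rows.append(
            {
                "condition": condition,
                "chase_min": res.chase_min,
                "fraction": res.mean,
                "sd": res.sd,
                "sem": res.sem,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def folding_fitness(
    fraction_anoxia: float, fraction_normoxia: float
) -> float:
    """Percentage of the normoxic endpoint reached in anoxia, capped at 100.

    Defined relative to the longest chase time assessed: 100 x
    (anoxic fraction / normoxic fraction). A protein that fully matures
    in anoxia scores 100%; one that never reaches its normoxic
    conformation scores 0%.
    """
    if fraction_normoxia <= 0:
        raise ValueError(
            "folding fitness undefined: normoxic fraction must be positive"
        )
    if fraction_anoxia < 0:
        raise ValueError("fractions must be non-negative")
    return min(100.0 * fraction_anoxia / fraction_normoxia, 100.0)
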