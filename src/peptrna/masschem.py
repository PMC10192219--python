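"""Monoisotopic mass arithmetic for modified nascent peptides.

Nascent peptides recovered from peptidyl-tRNAs are analysed either as
N-acetylated peptidyl-adenosines (the nuclease-P1 / alkaline-phosphatase
digestion product, which retains the tRNA 3'-terminal adenosine as an ester)
or as free-acid peptides released by mild alkaline hydrolysis, optionally
carrying a single C-terminal 18O label when hydrolysis is performed in
[18O]water.  This module computes neutral monoisotopic masses and m/z for
those species.

Two residue-mass tables are provided:

``paper``
    The accurate residue masses published with the original reference
    databases, with cysteine fixed as carbamidomethyl-Cys (iodoacetamide
    alkylation).
    These deviate from exact atomic sums by up to ~3e-4 Da; they are kept
    verbatim because reference databases built from them reproduce the
    published matching behaviour bit-for-bit.

``standard``
    Exact monoisotopic residue masses from :mod:`pyteomics.mass`, with the
    same fixed carbamidomethyl-Cys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

from pyteomics import mass as _pmass

__all__ = [
    "ResidueMassTable",
    "PeptideSpecies",
    "NTermMod",
    "CTermState",
    "WATER",
    "PROTON",
    "ADENOSINE",
    "ACETYL",
    "FORMYL",
    "MET_OXIDATION",
    "O18_DELTA",
    "CARBAMIDOMETHYL",
    "paper_table",
    "standard_table",
    "load_table",
    "neutral_mass",
    "mz_from_neutral",
    "label_shift_18O",
    "ppm_error",
]

# Monoisotopic constants (Da). Not printed in the source methods; fixed here
# and cross-checked against pyteomics atomic compositions in the test suite.
WATER = 18.010565          # H2O
PROTON = 1.0072765         # H+
ADENOSINE = 267.096754     # C10H13N5O4
ACETYL = 42.010565         # +C2H2O on the alpha-amino group
FORMYL = 27.994915         # +CHO-H, i.e. +CO
MET_OXIDATION = 15.994915  # +O
O18_DELTA = 2.004246       # 18O - 16O
CARBAMIDOMETHYL = 57.021464  # +C2H3NO on Cys thiol

# Accurate residue masses as published with the original reference lists.
# Cys is carbamidomethylated (Cys*) throughout; free Cys is not representable.
_PAPER_RESIDUES: dict[str, float] = {
    "A": 71.03697,
    "R": 156.10078,
    "N": 114.04274,
    "D": 115.02677,
    "C": 160.03041,   # carbamidomethyl-Cys
    "Q": 128.05834,
    "E": 129.04237,
    "G": 57.02137,
    "H": 137.05871,
    "I": 113.08377,
    "L": 113.08377,
    "K": 128.09464,
    "M": 131.04024,
    "F": 147.06817,
    "P": 97.05257,
    "S": 87.03187,
    "T": 101.04747,
    "W": 186.07904,
    "Y": 163.06307,
    "V": 99.06817,
}

_STANDARD_RESIDUES: dict[str, float] = {
    aa: (_pmass.std_aa_mass["C"] + CARBAMIDOMETHYL if aa == "C"
         else _pmass.std_aa_mass[aa])
    for aa in _PAPER_RESIDUES
}


class NTermMod(str, Enum):
    """N-terminal modification state."""

    NONE = "none"
    ACETYL = "acetyl"
    FORMYL = "formyl"


class CTermState(str, Enum):
    """C-terminal chemistry of the species being massed."""

    FREE_ACID = "free_acid"
    ADENOSINE_ESTER = "adenosine_ester"
    FREE_ACID_18O = "free_acid_18o"


class AlphabetError(ValueError):
    """A sequence contains a residue absent from the mass table."""


@dataclass(frozen=True)
class ResidueMassTable:
    """Residue -> monoisotopic mass map plus the modification constants.

    Parameters
    ----------
    residues
        Mapping of one-letter residue codes to monoisotopic masses (Da).
        Cys entries are expected to already include the carbamidomethyl
        group (fixed modification).
    table_id
        Short label ("paper", "standard", or a file path for custom tables).
    """

    residues: Mapping[str, float]
    table_id: str = "custom"
    water: float = WATER
    proton: float = PROTON
    adenosine: float = ADENOSINE
    acetyl: float = ACETYL
    formyl: float = FORMYL
    met_oxidation: float = MET_OXIDATION
    o18_delta: float = O18_DELTA

    def __post_init__(self) -> None:
        for aa, m in self.residues.items():
            if m <= 0:
                raise ValueError(f"nonpositive residue mass for {aa!r}: {m}")

    def mass_of(self, residue: str) -> float:
        try:
            return self.residues[residue]
        except KeyError:
            raise AlphabetError(
                f"residue {residue!r} not in mass table {self.table_id!r}"
            ) from None

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(self.residues)


_PAPER_TABLE = ResidueMassTable(_PAPER_RESIDUES, table_id="paper")
_STANDARD_TABLE = ResidueMassTable(_STANDARD_RESIDUES, table_id="standard")


def paper_table() -> ResidueMassTable:
    """The verbatim printed residue-mass table (default everywhere)."""
    return _PAPER_TABLE


def standard_table() -> ResidueMassTable:
    """Exact atomic-composition residue masses (pyteomics)."""
    return _STANDARD_TABLE


def load_table(spec: str | Path) -> ResidueMassTable:
    """Resolve ``paper``, ``standard``, or a two-column TSV path."""
    if spec == "paper":
        return paper_table()
    if spec == "standard":
        return standard_table()
    path = Path(spec)
    residues: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        aa, m = line.split("\t")[:2]
        residues[aa] = float(m)
    return ResidueMassTable(residues, table_id=str(path))


@dataclass(frozen=True)
class PeptideSpecies:
    """A concrete chemical species of a nascent peptide.

    ``sequence`` runs N→C. ``met_oxidations`` counts oxidized methionines
    (variable modification seen during sample handling).
    """

    sequence: str
    n_term_mod: NTermMod = NTermMod.NONE
    c_term_state: CTermState = CTermState.FREE_ACID
    met_oxidations: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("empty peptide sequence")
        if self.met_oxidations < 0:
            raise ValueError("met_oxidations must be >= 0")
        if self.met_oxidations > self.sequence.count("M"):
            raise ValueError(
                "more Met oxidations than Met residues in sequence"
            )


def neutral_mass(
    species: PeptideSpecies, table: ResidueMassTable | None = None
) -> float:
    """Neutral monoisotopic mass (Da) of a peptide species.

    The free acid is the residue-mass sum plus one water.  Esterification to
    adenosine (the tRNA 3'-end digestion product) replaces the C-terminal
    hydroxyl's water with adenosine: net ``+adenosine − water`` relative to
    the free acid.  A single C-terminal 18O (hydrolysis in [18O]water) adds
    the 18O−16O isotope delta.
    """
    table = table or paper_table()
    m = sum(table.mass_of(aa) for aa in species.sequence) + table.water
    if species.n_term_mod is NTermMod.ACETYL:
        m += table.acetyl
    elif species.n_term_mod is NTermMod.FORMYL:
        m += table.formyl
    m += species.met_oxidations * table.met_oxidation
    if species.c_term_state is CTermState.ADENOSINE_ESTER:
        m += table.adenosine - table.water
    elif species.c_term_state is CTermState.FREE_ACID_18O:
        m += table.o18_delta
    return m


def mz_from_neutral(mass: float, charge: int, *, proton: float = PROTON) -> float:
    """m/z of the [M+zH]z+ ion from a neutral mass."""
    if mass <= 0:
        raise ValueError(f"nonpositive neutral mass: {mass}")
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * proton) / charge


def neutral_from_mz(mz: float, charge: int, *, proton: float = PROTON) -> float:
    """Inverse of :func:`mz_from_neutral`."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return mz * charge - charge * proton


def label_shift_18O(
    species: PeptideSpecies, table: ResidueMassTable | None = None
) -> float:
    """Mass delta added by single C-terminal 18O labelling on hydrolysis.

    Only a free-acid peptide can carry the label: the ester oxygen belongs
    to the adenosine while the peptide is still attached, and the already
    labelled form cannot be labelled twice (single-label model).
    """
    table = table or paper_table()
    if species.c_term_state is not CTermState.FREE_ACID:
        raise ValueError(
            "18O labelling applies only on hydrolysis of a free-acid "
            f"peptide (got c_term_state={species.c_term_state.value})"
        )
    return table.o18_delta


def ppm_error(observed: float, reference: float) -> float:
    """Signed relative mass error in parts per million."""
    if reference <= 0:
        raise ValueError(f"nonpositive reference mass: {reference}")
    return (observed - reference) / reference * 1e6
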