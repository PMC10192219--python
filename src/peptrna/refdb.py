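"""Reference peptide databases for pep-tRNA profiling.

Builds, from a CDS FASTA, the set of N-terminal peptide references a
dropped-off peptidyl-tRNA could carry:

* cognate peptides — ORF prefixes over a length range (default 3–14
  residues), each annotated with its drop-off codon position;
* Met-trimmed counterparts when the second residue satisfies the
  methionine-aminopeptidase (MAP) specificity rule (small residue:
  G, A, S, T, C, P, V, N, D, L or I);
* single-substitution variants — every cognate peptide with one residue
  replaced by any of the other nineteen, excluding replacements with zero
  mass change (I↔L), which mass-only profiling cannot evidence.

Drop-off positions are 1-based codon positions with the initiator Met as
codon 1, so a Met-trimmed k-mer ends at codon k+1. Substitution sites are
recorded as offsets from the C-terminus (0 = drop-off site) to mirror the
C0X…C-kX class naming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

from .masschem import (
    CTermState,
    NTermMod,
    PeptideSpecies,
    ResidueMassTable,
    neutral_mass,
    paper_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MAP_ELIGIBLE",
    "START_CODONS",
    "OrfRecord",
    "PeptideRef",
    "OrfValidationError",
    "translate_cds",
    "build_cognate_db",
    "build_substitution_db",
    "export_search_fasta",
    "dropoff_position",
    "db_to_frame",
    "write_db_tsv",
    "read_db_tsv",
]

#: Second residues for which MAP removes the initiator Met.
MAP_ELIGIBLE = frozenset("GASTCPVNDLI")

#: Start codons accepted in CDS validation; all translate as initiator Met.
START_CODONS = frozenset({"ATG", "GTG", "TTG"})

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class OrfValidationError(ValueError):
    """A CDS fails the frame / start / internal-stop checks."""


@dataclass(frozen=True)
class OrfRecord:
    """One coding sequence with its translation and optional expression."""

    gene_id: str
    cds: str
    protein: str
    tpm: float | None = None


@dataclass(frozen=True, slots=True)
class PeptideRef:
    """One reference peptide, cognate or single-substitution variant.

    ``sub_offset`` counts residues back from the C-terminus (0 = the
    drop-off site); None means cognate. ``dropoff_codon_pos`` is the codon
    position (initiator = 1) from which a pep-tRNA carrying this peptide
    dissociated.
    """

    gene_id: str
    sequence: str
    met_trimmed: bool
    dropoff_codon_pos: int
    neutral_mass: float
    sub_offset: int | None = None
    sub_from: str | None = None
    sub_to: str | None = None

    @property
    def is_substitution(self) -> bool:
        return self.sub_offset is not None


def translate_cds(cds: str) -> str:
    """Translate an in-frame CDS, forcing the initiator codon to Met.

    Raises :class:`OrfValidationError` on frame violations, unrecognized
    start codons, or internal stops. The trailing stop codon is optional
    (its absence is tolerated; presence is the normal case).
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise OrfValidationError(f"CDS length {len(cds)} not divisible by 3")
    if len(cds) < 6:
        raise OrfValidationError("CDS shorter than two codons")
    start = cds[:3]
    if start not in START_CODONS:
        raise OrfValidationError(f"unrecognized start codon {start}")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    has_stop = codons[-1] in _STOP_CODONS
    body = codons[1:-1] if has_stop else codons[1:]
    for i, codon in enumerate(body, start=2):
        if codon in _STOP_CODONS:
            raise OrfValidationError(f"internal stop codon at position {i}")
    tail = str(Seq("".join(body)).translate(table=11))
    if "*" in tail or "X" in tail:
        raise OrfValidationError("untranslatable codon in CDS")
    return "M" + tail


def orf_from_cds(gene_id: str, cds: str, tpm: float | None = None) -> OrfRecord:
    return OrfRecord(gene_id=gene_id, cds=cds.upper().replace("U", "T"),
                     protein=translate_cds(cds), tpm=tpm)


def dropoff_position(sequence_length: int, met_trimmed: bool) -> int:
    """Codon position of the drop-off site for a peptide of given length."""
    return sequence_length + 1 if met_trimmed else sequence_length


def _ref_mass(sequence: str, table: ResidueMassTable) -> float:
    # Profiling references are N-acetylated free acids (acetylation
    # stabilizes the acyl bond before digestion; hydrolysis releases the
    # free acid analysed by LC/MS).
    return neutral_mass(
        PeptideSpecies(sequence, NTermMod.ACETYL, CTermState.FREE_ACID),
        table,
    )


def build_cognate_db(
    orfs: Iterable[OrfRecord],
    min_len: int = 3,
    max_len: int = 14,
    table: ResidueMassTable | None = None,
) -> list[PeptideRef]:
    """Cognate N-terminal peptide references over a length range.

    For each ORF one reference per prefix length in ``[min_len, max_len]``
    (capped by the protein length), plus Met-trimmed counterparts of each
    length in the same range when the second residue is MAP-eligible.
    Malformed ORFs are skipped with a logged summary count.
    """
    if not (2 <= min_len <= max_len):
        raise ValueError(f"need 2 <= min_len <= max_len, got {min_len}..{max_len}")
    table = table or paper_table()
    refs: list[PeptideRef] = []
    skipped = 0
    for orf in orfs:
        protein = orf.protein
        if not protein or protein[0] != "M":
            skipped += 1
            continue
        try:
            for length in range(min_len, min(max_len, len(protein)) + 1):
                seq = protein[:length]
                refs.append(
                    PeptideRef(
                        gene_id=orf.gene_id,
                        sequence=seq,
                        met_trimmed=False,
                        dropoff_codon_pos=dropoff_position(length, False),
                        neutral_mass=_ref_mass(seq, table),
                    )
                )
            if len(protein) >= 2 and protein[1] in MAP_ELIGIBLE:
                # Trimmed k-mer covers protein residues 2..k+1.
                for length in range(
                    min_len, min(max_len, len(protein) - 1) + 1
                ):
                    seq = protein[1 : length + 1]
                    refs.append(
                        PeptideRef(
                            gene_id=orf.gene_id,
                            sequence=seq,
                            met_trimmed=True,
                            dropoff_codon_pos=dropoff_position(length, True),
                            neutral_mass=_ref_mass(seq, table),
                        )
                    )
        except Exception:
            skipped += 1
            continue
    if skipped:
        logger.warning("build_cognate_db: skipped %d malformed ORF(s)", skipped)
    return refs


def build_substitution_db(
    cognate: Sequence[PeptideRef],
    positions: str | Iterable[int] = "all",
    table: ResidueMassTable | None = None,
) -> list[PeptideRef]:
    """Single-substitution variants of every cognate reference.

    ``positions`` is either ``"all"`` or a set of C-terminal offsets
    (0 = drop-off site). For each cognate peptide and allowed position, one
    variant per substituted residue among the other nineteen, excluding
    substitutions with zero mass change (I↔L): mass-only profiling cannot
    distinguish them from the cognate parent.
    """
    if not cognate:
        raise ValueError("empty cognate database")
    table = table or paper_table()
    alphabet = sorted(table.alphabet)
    offsets = None if positions == "all" else sorted(set(positions))
    variants: list[PeptideRef] = []
    for ref in cognate:
        seq = ref.sequence
        n = len(seq)
        offs = range(n) if offsets is None else [k for k in offsets if k < n]
        for k in offs:
            i = n - 1 - k
            orig = seq[i]
            orig_mass = table.mass_of(orig)
            for sub in alphabet:
                if sub == orig or table.mass_of(sub) == orig_mass:
                    continue
                variant_seq = seq[:i] + sub + seq[i + 1 :]
                # recompute from scratch: bit-identical to a direct mass
                # calculation of the variant sequence
                variants.append(
                    PeptideRef(
                        gene_id=ref.gene_id,
                        sequence=variant_seq,
                        met_trimmed=ref.met_trimmed,
                        dropoff_codon_pos=ref.dropoff_codon_pos,
                        neutral_mass=_ref_mass(variant_seq, table),
                        sub_offset=k,
                        sub_from=orig,
                        sub_to=sub,
                    )
                )
    return variants


def export_search_fasta(
    db: Sequence[PeptideRef],
    wildcard_positions: Iterable[int] = (),
    length_split: Sequence[tuple[int, int]] | None = None,
) -> dict[str, str]:
    """Export peptide FASTA text for external search engines.

    ``wildcard_positions`` are C-terminal offsets replaced by ``X`` (any
    residue), the convention used when searching for substituted peptides.
    ``length_split`` is a list of inclusive (lo, hi) residue-length ranges;
    one FASTA text is returned per range (a peptide on a range boundary
    appears in every range containing it). With no split a single text is
    returned under the key ``"all"``.
    """
    wildcards = sorted(set(wildcard_positions))
    ranges = list(length_split) if length_split else None
    if ranges:
        for (a1, b1) in ranges:
            for (a2, b2) in ranges:
                if (a1, b1) < (a2, b2) and a2 <= b1 and a1 <= b2:
                    logger.warning(
                        "export_search_fasta: overlapping length ranges "
                        "%s and %s", (a1, b1), (a2, b2),
                    )
    out: dict[str, list[str]] = {}

    def key_for(length: int) -> list[str]:
        keys = []
        if ranges is None:
            keys.append("all")
        else:
            for lo, hi in ranges:
                if lo <= length <= hi:
                    keys.append(f"{lo}-{hi}")
        return keys

    for ref in db:
        seq = list(ref.sequence)
        for k in wildcards:
            if k < len(seq):
                seq[len(seq) - 1 - k] = "X"
        variant = "trimmed" if ref.met_trimmed else "full"
        if ref.is_substitution:
            variant += f"|C-{ref.sub_offset}X:{ref.sub_from}>{ref.sub_to}"
        header = f">{ref.gene_id}|pos{ref.dropoff_codon_pos}|{variant}"
        entry = f"{header}\n{''.join(seq)}\n"
        for key in key_for(len(ref.sequence)):
            out.setdefault(key, []).append(entry)
    return {k: "".join(v) for k, v in out.items()}


_DB_COLUMNS = [
    "gene_id", "sequence", "met_trimmed", "sub_offset", "sub_from",
    "sub_to", "dropoff_pos", "neutral_mass",
]


def db_to_frame(db: Sequence[PeptideRef]) -> pd.DataFrame:
    """Flatten a reference database into a tidy DataFrame."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in db],
            "sequence": [r.sequence for r in db],
            "met_trimmed": [r.met_trimmed for r in db],
            "sub_offset": [r.sub_offset for r in db],
            "sub_from": [r.sub_from for r in db],
            "sub_to": [r.sub_to for r in db],
            "dropoff_pos": [r.dropoff_codon_pos for r in db],
            "neutral_mass": [r.neutral_mass for r in db],
        },
        columns=_DB_COLUMNS,
    )


def write_db_tsv(db: Sequence[PeptideRef], path: str | Path) -> None:
    db_to_frame(db).to_csv(path, sep="\t", index=False)


def read_db_tsv(path: str | Path) -> list[PeptideRef]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    refs = []
    for row in df.itertuples(index=False):
        sub_offset = None if pd.isna(row.sub_offset) else int(row.sub_offset)
        refs.append(
            PeptideRef(
                gene_id=str(row.gene_id),
                sequence=str(row.sequence),
                met_trimmed=bool(row.met_trimmed),
                dropoff_codon_pos=int(row.dropoff_pos),
                neutral_mass=float(row.neutral_mass),
                sub_offset=sub_offset,
                sub_from=None if sub_offset is None else str(row.sub_from),
                sub_to=None if sub_offset is None else str(row.sub_to),
            )
        )
    return refs
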