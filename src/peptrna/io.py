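"""Format adapters: FASTA, TSV mass lists, TPM and anticodon tables."""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .codonstats import AnticodonEntry
from .masschem import neutral_from_mz
from .matchclass import MassPeak
from .refdb import OrfRecord, OrfValidationError, orf_from_cds

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "read_orf_fasta",
    "read_tpm_tsv",
    "read_peaks_tsv",
    "read_anticodon_tsv",
    "write_tsv",
    "read_tsv",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a FASTA file (multi-line, CRLF tolerated)."""
    with open(path, newline=None) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def read_orf_fasta(
    path: str | Path,
    tpm: Mapping[str, float] | None = None,
) -> list[OrfRecord]:
    """Parse and validate a CDS FASTA into ORF records.

    Records failing CDS validation (frame, start codon, internal stop)
    are skipped with a logged summary count.
    """
    orfs: list[OrfRecord] = []
    skipped = 0
    for gene_id, seq in read_fasta(path):
        try:
            orfs.append(
                orf_from_cds(gene_id, seq, tpm=tpm.get(gene_id) if tpm else None)
            )
        except OrfValidationError as exc:
            logger.warning("skipping %s: %s", gene_id, exc)
            skipped += 1
    if skipped:
        logger.warning("read_orf_fasta: skipped %d invalid CDS record(s)", skipped)
    return orfs


def read_tpm_tsv(path: str | Path) -> dict[str, float]:
    """Two-column ``gene_id<TAB>tpm`` table (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.iloc[0, 1] is not None:
        try:
            float(df.iloc[0, 1])
        except ValueError:  # header row
            df = df.iloc[1:]
    return {str(g): float(t) for g, t in zip(df.iloc[:, 0], df.iloc[:, 1])}


def read_peaks_tsv(path: str | Path) -> list[MassPeak]:
    """MS feature list from TSV.

    Accepts either a ``mass`` column (neutral monoisotopic Da) or ``mz``
    with an optional ``charge`` column (charge 1 assumed when absent);
    optional ``rt``, ``intensity``, ``sample``, ``timepoint``, ``peak_id``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "mass" in df.columns:
        masses = df["mass"].astype(float)
    elif "mz" in df.columns:
        charges = (
            df["charge"].astype(int) if "charge" in df.columns
            else pd.Series(1, index=df.index)
        )
        masses = pd.Series(
            [neutral_from_mz(mz, z) for mz, z in zip(df["mz"], charges)],
            index=df.index,
        )
    else:
        raise ValueError("peaks TSV needs a 'mass' or 'mz' column")
    peaks = []
    for i, row in df.iterrows():
        peaks.append(
            MassPeak(
                neutral_mass=float(masses[i]),
                intensity=float(row.get("intensity", 0.0) or 0.0),
                rt=float(row["rt"]) if "rt" in df.columns and pd.notna(row["rt"]) else None,
                sample=str(row.get("sample", "") or ""),
                timepoint=str(row.get("timepoint", "") or ""),
                peak_id=str(row["peak_id"]) if "peak_id" in df.columns else f"p{i}",
            )
        )
    return peaks


def read_anticodon_tsv(path: str | Path) -> list[AnticodonEntry]:
    """``trna_id<TAB>anticodon`` table (5'→3' anticodons)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str,
                     names=["trna_id", "anticodon"])
    if df.iloc[0, 0].lower() in {"trna_id", "trna"}:
        df = df.iloc[1:]
    return [AnticodonEntry(t, a) for t, a in zip(df["trna_id"], df["anticodon"])]


def write_tsv(
    df: pd.DataFrame, path: str | Path, header_comments: Sequence[str] = ()
) -> None:
    """TSV with optional ``#``-prefixed header comment lines."""
    buf = _io.StringIO()
    for line in header_comments:
        buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
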