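"""Codon-level statistics at pep-tRNA drop-off sites.

Given annotated drop-off events (matched peptides with their drop-off
codon positions) and the ORF set they came from, this module tallies the
codons at and next to drop-off sites, computes TPM-weighted positional
codon usage in the transcriptome, classifies codon–anticodon pairings by
mismatch count, quantifies how early-ORF codon usage deviates from overall
usage, groups ORFs by where their pep-tRNAs drop off, and compares
amino-acid frequencies between detected peptides and ORF N-termini.

Codons are keyed in RNA alphabet (AAA, UUU, ...), positions are 1-based
with the start codon as position 1, and stop codons never enter drop-off
tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matchclass import MatchRecord
from .refdb import OrfRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SENSE_CODONS",
    "CodonTally",
    "AnticodonEntry",
    "codon_at",
    "dropoff_codon_tally",
    "adjacent_codon_tally",
    "tpm_weighted_usage",
    "gc_group",
    "mismatch_count",
    "r_squared",
    "usage_deviation",
    "orf_grouping",
    "aa_frequency_comparison",
]

_STOPS = {"UAA", "UAG", "UGA"}
_BASES = "ACGU"

#: The 61 sense codons, RNA alphabet, lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}  # codon base · anticodon base


def _rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


@dataclass(frozen=True)
class CodonTally:
    """A codon → count/weight table with explicit normalization state."""

    values: pd.Series
    normalized: bool = False

    def normalize(self) -> "CodonTally":
        total = float(self.values.sum())
        if total <= 0:
            raise ValueError("cannot normalize an empty tally")
        out = self.values / total
        return CodonTally(out, normalized=True)

    def __getitem__(self, codon: str) -> float:
        return float(self.values.get(_rna(codon), 0.0))


@dataclass(frozen=True)
class AnticodonEntry:
    """A tRNA's anticodon, written 5'→3' in RNA alphabet."""

    trna_id: str
    anticodon: str
    wobble: bool = False

    def __post_init__(self) -> None:
        ac = _rna(self.anticodon)
        if len(ac) != 3 or any(b not in _BASES for b in ac):
            raise ValueError(f"invalid anticodon {self.anticodon!r}")
        object.__setattr__(self, "anticodon", ac)


def codon_at(orf: OrfRecord, position: int) -> str | None:
    """RNA codon at a 1-based codon position (start = 1); None if beyond
    the coding region (stop codon excluded)."""
    n_sense = len(orf.protein)
    if position < 1 or position > n_sense:
        return None
    return _rna(orf.cds[3 * (position - 1) : 3 * position])


def _empty_tally() -> pd.Series:
    return pd.Series(0.0, index=list(SENSE_CODONS))


def dropoff_codon_tally(
    records: Iterable[MatchRecord],
    orfs: Mapping[str, OrfRecord] | Sequence[OrfRecord],
    offset: int = 0,
    normalize: bool = False,
) -> dict[str, CodonTally]:
    """Tally the codon at (drop-off position + offset) per record class.

    Records whose target position falls beyond the ORF's coding region are
    skipped with a warning. Returns one :class:`CodonTally` per class
    label present among assigned records.
    """
    if not isinstance(orfs, Mapping):
        orfs = {o.gene_id: o for o in orfs}
    tallies: dict[str, pd.Series] = {}
    skipped = 0
    for rec in records:
        best = rec.best_candidate
        if best is None:
            continue
        orf = orfs.get(best.gene_id)
        if orf is None:
            skipped += 1
            continue
        codon = codon_at(orf, best.dropoff_codon_pos + offset)
        if codon is None or codon in _STOPS:
            skipped += 1
            continue
        tally = tallies.setdefault(rec.class_label, _empty_tally())
        tally[codon] += 1
    if skipped:
        logger.warning(
            "dropoff_codon_tally: skipped %d record(s) with unresolvable "
            "or out-of-range positions", skipped,
        )
    out = {label: CodonTally(s) for label, s in tallies.items()}
    if normalize:
        out = {label: t.normalize() for label, t in out.items()}
    return out


def adjacent_codon_tally(
    records: Iterable[MatchRecord],
    orfs: Mapping[str, OrfRecord] | Sequence[OrfRecord],
    offset: int = 1,
    normalize: bool = False,
) -> dict[str, CodonTally]:
    """Tally codons adjacent to the drop-off site (default: 3' neighbour)."""
    return dropoff_codon_tally(records, orfs, offset=offset, normalize=normalize)


def tpm_weighted_usage(
    orfs: Sequence[OrfRecord],
    position_range: tuple[int, int] = (5, 17),
) -> CodonTally:
    """Transcriptome codon usage at early positions, weighted by TPM share.

    For each ORF the sense codons at positions ``a..b`` (capped by ORF
    length) are counted and multiplied by that ORF's share of total TPM;
    the weighted counts are summed over ORFs and normalized to
    frequencies. Invariant to global TPM rescaling.
    """
    a, b = position_range
    if not (2 <= a <= b):
        raise ValueError(f"need 2 <= a <= b, got {position_range}")
    tpms = np.array(
        [o.tpm if o.tpm is not None else 0.0 for o in orfs], dtype=float
    )
    total_tpm = tpms.sum()
    if total_tpm <= 0:
        raise ValueError("all-zero TPM: weighted usage undefined")
    tally = _empty_tally()
    for orf, tpm in zip(orfs, tpms):
        if tpm == 0:
            continue
        weight = tpm / total_tpm
        for pos in range(a, b + 1):
            codon = codon_at(orf, pos)
            if codon is not None and codon not in _STOPS:
                tally[codon] += weight
    return CodonTally(tally).normalize()


def gc_group(codon: str) -> int:
    """Number of G or C bases in the codon (groups 0–3)."""
    c = _rna(codon)
    if len(c) != 3 or any(b not in _BASES for b in c):
        raise ValueError(f"invalid codon {codon!r}")
    return sum(b in "GC" for b in c)


def mismatch_count(
    codon: str,
    anticodon: AnticodonEntry | str,
    wobble: bool | None = None,
) -> tuple[int, str]:
    """Count mismatches of a codon–anticodon pairing and classify it.

    Codon position i (5'→3') pairs with anticodon position 4−i.
    Watson–Crick pairs (A·U, G·C) count as matches; with ``wobble``
    enabled, G·U / U·G at codon position 3 also counts. The class is
    ``cognate`` (0 mismatches), ``near_cognate`` (1) or ``multiple`` (≥2).
    """
    if isinstance(anticodon, str):
        anticodon = AnticodonEntry("", anticodon)
    if wobble is None:
        wobble = anticodon.wobble
    c = _rna(codon)
    if len(c) != 3 or any(b not in _BASES for b in c):
        raise ValueError(f"invalid codon {codon!r}")
    ac = anticodon.anticodon
    mismatches = 0
    for i in range(3):  # codon position i+1 pairs anticodon position 3-i
        pair = (c[i], ac[2 - i])
        if pair in _WC_PAIRS:
            continue
        if wobble and i == 2 and pair in _WOBBLE_PAIRS:
            continue
        mismatches += 1
    cls = ("cognate", "near_cognate")[mismatches] if mismatches < 2 else "multiple"
    return mismatches, cls


def r_squared(
    freqs_x: CodonTally | pd.Series,
    freqs_y: CodonTally | pd.Series,
    exclude: Iterable[str] = (),
) -> float:
    """Coefficient of determination between two codon frequency sets.

    Squared Pearson correlation over the shared codon set, optionally
    after removing named codons (e.g. a dominant AAA) from both.
    """
    x = freqs_x.values if isinstance(freqs_x, CodonTally) else freqs_x
    y = freqs_y.values if isinstance(freqs_y, CodonTally) else freqs_y
    shared = x.index.intersection(y.index).difference(
        [_rna(c) for c in exclude]
    )
    if len(shared) < 3:
        raise ValueError("too few shared codons for a correlation")
    r = np.corrcoef(x.loc[shared].to_numpy(), y.loc[shared].to_numpy())[0, 1]
    return float(r**2)


def _window_usage(
    orfs: Sequence[OrfRecord], a: int, b: int | None
) -> pd.Series:
    tally = _empty_tally()
    for orf in orfs:
        top = len(orf.protein) if b is None else min(b, len(orf.protein))
        for pos in range(a, top + 1):
            codon = codon_at(orf, pos)
            if codon is not None and codon not in _STOPS:
                tally[codon] += 1
    return tally


def usage_deviation(
    orfs: Sequence[OrfRecord],
    window: tuple[int, int | None],
) -> tuple[pd.Series, float]:
    """Per-codon (window usage / total usage) ratio and its spread σ.

    Both usages are normalized frequencies over positions ≥ 2 (the
    constant initiator codon is excluded); ``window=(2, None)`` therefore
    gives all ratios 1 and σ = 0. Codons unused in the whole ORF set are
    excluded with a warning. σ is the population standard deviation of
    the ratio vector.
    """
    a, b = window
    if a < 2 or (b is not None and b < a):
        raise ValueError(f"invalid window {window}")
    win = _window_usage(orfs, a, b)
    tot = _window_usage(orfs, 2, None)
    used = tot[tot > 0].index
    dropped = len(tot) - len(used)
    if dropped:
        logger.warning(
            "usage_deviation: %d codon(s) unused in the ORF set; excluded",
            dropped,
        )
    win_f = win.loc[used] / win.loc[used].sum()
    tot_f = tot.loc[used] / tot.loc[used].sum()
    ratio = win_f / tot_f
    return ratio, float(np.std(ratio.to_numpy(), ddof=0))


def orf_grouping(
    records: Iterable[MatchRecord],
    orfs: Sequence[OrfRecord],
    tpm_quantile: float = 0.8,
    early_positions: frozenset[int] | set[int] = frozenset({5, 6}),
) -> pd.DataFrame:
    """Group highly expressed ORFs by where their pep-tRNAs drop off.

    ORFs at or above the ``tpm_quantile`` TPM quantile are partitioned:
    group 1 — a drop-off detected at one of the early positions; group 2 —
    drop-offs detected only at later positions; group 3 — no drop-off
    detected. Returns a frame (gene_id, tpm, group), a disjoint and
    exhaustive partition of the restricted set.
    """
    tpms = np.array(
        [o.tpm if o.tpm is not None else 0.0 for o in orfs], dtype=float
    )
    threshold = float(np.quantile(tpms, tpm_quantile)) if len(tpms) else 0.0
    top = [o for o, t in zip(orfs, tpms) if t >= threshold]
    detected: dict[str, set[int]] = {}
    for rec in records:
        best = rec.best_candidate
        if best is not None:
            detected.setdefault(best.gene_id, set()).add(
                best.dropoff_codon_pos
            )
    early = set(early_positions)
    rows = []
    for orf in top:
        positions = detected.get(orf.gene_id, set())
        if not positions:
            group = 3
        elif positions & early:
            group = 1
        else:
            group = 2
        rows.append((orf.gene_id, orf.tpm, group))
    return pd.DataFrame(rows, columns=["gene_id", "tpm", "group"])


_AA20 = tuple("ACDEFGHIKLMNPQRSTVWY")


def aa_frequency_comparison(
    peptides: Iterable[str],
    orfs: Sequence[OrfRecord],
    window: tuple[int, int] = (2, 10),
) -> pd.DataFrame:
    """Residue frequencies in detected peptides vs ORF N-terminal windows.

    Returns a frame indexed by residue with columns ``peptide_freq``,
    ``orf_freq`` (each summing to 1) and their ratio (< 1 for residues
    depleted in detected peptides, e.g. bulky aromatics that anchor the
    nascent chain in the exit tunnel).
    """
    a, b = window
    pep_counts = pd.Series(0.0, index=list(_AA20))
    for pep in peptides:
        for aa in pep:
            if aa in pep_counts.index:
                pep_counts[aa] += 1
    orf_counts = pd.Series(0.0, index=list(_AA20))
    for orf in orfs:
        for aa in orf.protein[a - 1 : b]:
            if aa in orf_counts.index:
                orf_counts[aa] += 1
    if pep_counts.sum() == 0 or orf_counts.sum() == 0:
        raise ValueError("empty peptide or ORF residue counts")
    out = pd.DataFrame(
        {
            "peptide_freq": pep_counts / pep_counts.sum(),
            "orf_freq": orf_counts / orf_counts.sum(),
        }
    )
    out["ratio"] = out["peptide_freq"] / out["orf_freq"]
    return out
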