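"""Synthetic ORFeomes and ground-truthed mass lists.

The generator emulates the statistical structure the profiling pipeline
assumes: a toy ORFeome (valid CDSs, optionally AU-rich in early codon
positions), drop-off events concentrated at early codons, single-residue
miscoding concentrated at the C-terminal drop-off site, deterministic
initiator-Met trimming by the MAP rule, Gaussian ppm-scale mass error, and
unassignable decoy masses.  Every non-decoy peak carries a truth record,
so precision/recall of the whole pipeline can be measured exactly.

Defaults mirror the conditions reported for the real measurements: a
~20.8% miscoding share split 286:10:4:4 over substitution offsets 0..3,
C0X drop-offs concentrated at codon positions 5–9, 1 ppm mass error
against a 5 ppm matching tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .masschem import (
    CTermState,
    NTermMod,
    PeptideSpecies,
    ResidueMassTable,
    neutral_mass,
    paper_table,
)
from .matchclass import MassPeak, MatchRecord, substitution_label
from .refdb import (
    MAP_ELIGIBLE,
    OrfRecord,
    PeptideRef,
    orf_from_cds,
)

__all__ = [
    "SimConfig",
    "simulate_orfeome",
    "simulate_dropoff_peaks",
    "evaluate_recovery",
    "orfs_to_fasta",
]

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_DNA = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

# Substitution-offset mix of the miscoded events (286:10:4:4 over C0..C-3).
_DEFAULT_OFFSET_PROBS = {0: 286 / 304, 1: 10 / 304, 2: 4 / 304, 3: 4 / 304}

# Drop-off position weights. Cognate events spread over codons 3-14;
# miscoded events confined to the early window, codons 5-9.
_DEFAULT_COGNATE_POS = {
    3: 0.06, 4: 0.10, 5: 0.14, 6: 0.14, 7: 0.12, 8: 0.11, 9: 0.09,
    10: 0.07, 11: 0.06, 12: 0.05, 13: 0.03, 14: 0.03,
}
_DEFAULT_MISCODE_POS = {5: 0.21, 6: 0.23, 7: 0.23, 8: 0.18, 9: 0.15}


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study.

    ``seed`` is mandatory; all randomness flows from it through
    per-stage child generators, so reruns are byte-identical.
    """

    seed: int
    n_orfs: int = 200
    orf_len_range: tuple[int, int] = (25, 60)  # sense codons incl. start
    au_rich_early: bool = True
    au_rich_window: tuple[int, int] = (2, 8)
    au_bias_strength: float = 1.6  # weight multiplier per A/U base
    n_events: int = 5000
    p_miscoding: float = 0.208
    offset_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_OFFSET_PROBS)
    )
    cognate_pos_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_COGNATE_POS)
    )
    miscode_pos_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISCODE_POS)
    )
    ppm_sigma: float = 1.0
    tol_ppm: float = 5.0
    n_decoys_sample: int = 1000
    n_decoys_control: int = 500
    tpm_lognorm_sigma: float = 1.5

    def __post_init__(self) -> None:
        for p in (self.p_miscoding, *self.offset_probs.values()):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")


def _rngs(config: SimConfig) -> list[np.random.Generator]:
    root = np.random.default_rng(config.seed)
    return root.spawn(4)  # orfeome, tpm, events, decoys


def _codon_weights(au_bias: float | None) -> np.ndarray:
    w = np.ones(len(_SENSE_DNA))
    if au_bias is not None:
        for i, codon in enumerate(_SENSE_DNA):
            w[i] = au_bias ** sum(b in "AT" for b in codon)
    return w / w.sum()


def simulate_orfeome(config: SimConfig) -> list[OrfRecord]:
    """Generate a toy ORFeome with TPM values.

    CDSs start with ATG, contain no internal stop and end with TAA.
    With ``au_rich_early`` enabled, codons in the early window are drawn
    with weights favouring A/U-rich codons, emulating the reduced RNA
    structure around bacterial start codons; later positions are uniform
    over the 61 sense codons.
    """
    rng_orf, rng_tpm, _, _ = _rngs(config)
    uniform_w = _codon_weights(None)
    early_w = _codon_weights(
        config.au_bias_strength if config.au_rich_early else None
    )
    a, b = config.au_rich_window
    lo, hi = config.orf_len_range
    orfs: list[OrfRecord] = []
    tpms = np.exp(
        rng_tpm.normal(0.0, config.tpm_lognorm_sigma, size=config.n_orfs)
    )
    tpms = tpms / tpms.sum() * 1e6  # transcripts per million
    for i in range(config.n_orfs):
        n_codons = int(rng_orf.integers(lo, hi + 1))
        codons = ["ATG"]
        for pos in range(2, n_codons + 1):
            w = early_w if a <= pos <= b else uniform_w
            codons.append(_SENSE_DNA[rng_orf.choice(len(_SENSE_DNA), p=w)])
        cds = "".join(codons) + "TAA"
        orfs.append(orf_from_cds(f"orf{i:04d}", cds, tpm=float(tpms[i])))
    return orfs


def orfs_to_fasta(orfs: Sequence[OrfRecord]) -> str:
    return "".join(f">{o.gene_id}\n{o.cds}\n" for o in orfs)


def _apply_map(protein: str, dropoff_pos: int) -> tuple[str, bool]:
    """Deterministic MAP trimming: eligible second residue and a peptide
    longer than a trimer loses the initiator Met."""
    if len(protein) >= 2 and protein[1] in MAP_ELIGIBLE and dropoff_pos >= 4:
        return protein[1:dropoff_pos], True
    return protein[:dropoff_pos], False


def _draw(rng: np.random.Generator, probs: Mapping[int, float]) -> int:
    keys = sorted(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    return int(keys[rng.choice(len(keys), p=p / p.sum())])


def simulate_dropoff_peaks(
    orfs: Sequence[OrfRecord],
    config: SimConfig,
    table: ResidueMassTable | None = None,
    reference_masses: Sequence[float] | None = None,
) -> tuple[list[MassPeak], list[MassPeak], pd.DataFrame]:
    """Simulate the t30 sample and t0 control mass lists with truth.

    Returns ``(sample, control, truth)``. Sample peaks are N-acetylated
    free-acid masses of the planted peptides with Gaussian ppm error, plus
    decoys; the control holds decoys only (chemical background present
    before pep-tRNA accumulation). Decoy masses are drawn uniformly over
    the signal mass range but rejected within 2× tolerance of any
    reference mass so truth labels stay unambiguous.

    ``reference_masses`` is the database the decoys must avoid; by default
    it is rebuilt here from the ORFs (cognate 3–14 plus all single
    substitutions).
    """
    table = table or paper_table()
    _, _, rng_ev, rng_decoy = _rngs(config)
    tpms = np.array([o.tpm or 1.0 for o in orfs], dtype=float)
    p_orf = tpms / tpms.sum()
    alphabet = sorted(table.alphabet)

    truth_rows = []
    sample: list[MassPeak] = []
    total_p = sum(config.cognate_pos_probs.values()) + sum(
        config.miscode_pos_probs.values()
    )
    if config.p_miscoding == 0 and total_p == 0:
        import logging

        logging.getLogger(__name__).warning(
            "simulate_dropoff_peaks: degenerate config; empty sample"
        )
        return [], [], pd.DataFrame()

    for i in range(config.n_events):
        orf = orfs[int(rng_ev.choice(len(orfs), p=p_orf))]
        miscoded = bool(rng_ev.random() < config.p_miscoding)
        pos_probs = (
            config.miscode_pos_probs if miscoded else config.cognate_pos_probs
        )
        # cap the drop-off position by the ORF's sense-codon count
        usable = {
            p: w for p, w in pos_probs.items() if p <= len(orf.protein)
        }
        dropoff = _draw(rng_ev, usable)
        seq, trimmed = _apply_map(orf.protein, dropoff)
        sub_offset = sub_from = sub_to = None
        if miscoded:
            sub_offset = _draw(rng_ev, config.offset_probs)
            if sub_offset >= len(seq):
                sub_offset = 0
            idx = len(seq) - 1 - sub_offset
            orig = seq[idx]
            orig_mass = table.mass_of(orig)
            choices = [
                aa for aa in alphabet
                if aa != orig and table.mass_of(aa) != orig_mass
            ]
            sub = choices[int(rng_ev.integers(len(choices)))]
            sub_from, sub_to = orig, sub
            seq = seq[:idx] + sub + seq[idx + 1 :]
        true_mass = neutral_mass(
            PeptideSpecies(seq, NTermMod.ACETYL, CTermState.FREE_ACID), table
        )
        observed = true_mass * (
            1.0 + rng_ev.normal(0.0, config.ppm_sigma) * 1e-6
        )
        peak_id = f"pk{i:05d}"
        sample.append(
            MassPeak(observed, intensity=1.0, sample="sim", timepoint="t30",
                     peak_id=peak_id)
        )
        truth_rows.append(
            {
                "peak_id": peak_id,
                "kind": "signal",
                "gene_id": orf.gene_id,
                "sequence": seq,
                "met_trimmed": trimmed,
                "sub_offset": sub_offset,
                "sub_from": sub_from,
                "sub_to": sub_to,
                "dropoff_pos": dropoff,
                "true_mass": true_mass,
            }
        )

    if reference_masses is None:
        from .refdb import build_cognate_db, build_substitution_db

        cog = build_cognate_db(orfs, 3, 14, table=table)
        refs = np.array(
            [r.neutral_mass for r in cog]
            + [r.neutral_mass for r in build_substitution_db(cog, "all", table)]
        )
    else:
        refs = np.asarray(reference_masses, dtype=float)
    refs = np.sort(refs)
    signal_masses = [p.neutral_mass for p in sample]
    m_lo = min(signal_masses) if signal_masses else 300.0
    m_hi = max(signal_masses) if signal_masses else 1700.0

    def draw_decoys(n: int, timepoint: str, prefix: str) -> list[MassPeak]:
        decoys: list[MassPeak] = []
        guard = 0
        while len(decoys) < n and guard < 100 * n:
            guard += 1
            m = float(rng_decoy.uniform(m_lo, m_hi))
            delta = m * 2 * config.tol_ppm * 1e-6
            lo = np.searchsorted(refs, m - delta, side="left")
            hi = np.searchsorted(refs, m + delta, side="right")
            if hi > lo:  # within 2x tolerance of some reference
                continue
            pid = f"{prefix}{len(decoys):05d}"
            decoys.append(
                MassPeak(m, intensity=1.0, sample="sim",
                         timepoint=timepoint, peak_id=pid)
            )
        return decoys

    sample_decoys = draw_decoys(config.n_decoys_sample, "t30", "dk")
    control = draw_decoys(config.n_decoys_control, "t0", "ck")
    for d in sample_decoys:
        truth_rows.append(
            {
                "peak_id": d.peak_id, "kind": "decoy", "gene_id": None,
                "sequence": None, "met_trimmed": None, "sub_offset": None,
                "sub_from": None, "sub_to": None, "dropoff_pos": None,
                "true_mass": d.neutral_mass,
            }
        )
    truth = pd.DataFrame(truth_rows)
    return sample + sample_decoys, control, truth


def _truth_label(row) -> str:
    if row["kind"] == "decoy":
        return "unassigned"
    if row["sub_offset"] is None or (
        isinstance(row["sub_offset"], float) and np.isnan(row["sub_offset"])
    ):
        return "cognate"
    return substitution_label(int(row["sub_offset"]))


def flag_mass_degenerate(
    truth: pd.DataFrame,
    cognate_db: Sequence[PeptideRef],
    substitution_db: Sequence[PeptideRef],
    tol_ppm: float = 5.0,
) -> pd.Series:
    """Identify truths whose class is not recoverable from mass alone.

    A truth is mass-degenerate when matching its *exact* (noiseless) mass
    against the databases yields a winning class different from the truth
    class — e.g. a substituted peptide whose composition coincides with a
    cognate peptide elsewhere (Val+Thr = Leu+Ser and similar identities
    make such collisions common), or a C-1X mass indistinguishable from a
    C0X variant of the same parent. No matcher can recover these from a
    mass list; they generalize the I↔L case the substitution database
    already excludes. Returns a boolean Series aligned with ``truth``.
    """
    from .matchclass import match_peaks

    signal = truth[truth["kind"] == "signal"]
    ideal_peaks = [
        MassPeak(m, peak_id=pid)
        for pid, m in zip(signal["peak_id"], signal["true_mass"])
    ]
    ideal = match_peaks(ideal_peaks, cognate_db, substitution_db, tol_ppm)
    ideal_label = {r.peak.peak_id: r.class_label for r in ideal}
    labels = truth.apply(_truth_label, axis=1)
    return pd.Series(
        [
            kind == "signal" and ideal_label.get(pid) != lab
            for pid, kind, lab in zip(truth["peak_id"], truth["kind"], labels)
        ],
        index=truth.index,
    )


def evaluate_recovery(
    truth: pd.DataFrame,
    records: Sequence[MatchRecord],
    cognate_db: Sequence[PeptideRef] | None = None,
    substitution_db: Sequence[PeptideRef] | None = None,
    tol_ppm: float = 5.0,
) -> pd.DataFrame:
    """Per-class precision/recall of the pipeline against planted truth.

    Decoys are expected to end up ``noise`` or ``unassigned`` (both count
    as correct rejection and are reported under ``unassigned``).  When the
    reference databases are supplied, mass-degenerate truths — those whose
    class is unidentifiable from mass alone (see
    :func:`flag_mass_degenerate`) — are excluded from the confusion
    counts, exactly as I↔L substitutions are excluded from the database.
    """
    predicted = {
        r.peak.peak_id: (
            "unassigned" if r.class_label == "noise" else r.class_label
        )
        for r in records
    }
    t = truth.copy()
    if cognate_db is not None and substitution_db is not None:
        degenerate = flag_mass_degenerate(
            t, cognate_db, substitution_db, tol_ppm
        )
        t = t[~degenerate]
    t["truth_label"] = t.apply(_truth_label, axis=1)
    t["predicted"] = t["peak_id"].map(predicted)
    labels = sorted(set(t["truth_label"]) | set(t["predicted"].dropna()))
    rows = []
    for label in labels:
        tp = int(((t.truth_label == label) & (t.predicted == label)).sum())
        fn = int(((t.truth_label == label) & (t.predicted != label)).sum())
        fp = int(((t.truth_label != label) & (t.predicted == label)).sum())
        rows.append(
            {
                "class_label": label,
                "n_truth": tp + fn,
                "tp": tp,
                "precision": tp / (tp + fp) if tp + fp else np.nan,
                "recall": tp / (tp + fn) if tp + fn else np.nan,
            }
        )
    return pd.DataFrame(rows)
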