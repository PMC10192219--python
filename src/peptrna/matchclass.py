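"""Annotation of observed MS features against nascent-peptide references.

The triage mirrors how dropped-off pep-tRNA peptides are called from a
deconvoluted mass list: features present in the t=0 control are removed as
chemical noise; survivors are matched at a ppm tolerance first against the
cognate database, then against the single-substitution database; matched
substitutions are typed by the offset of the substituted residue from the
C-terminal drop-off site (C0X at the site itself, C-1X one residue
upstream, ...); everything else is unassigned.  Every input peak receives
exactly one class, so the class counts always partition the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .masschem import ppm_error
from .refdb import PeptideRef

__all__ = [
    "MassPeak",
    "MatchRecord",
    "CLASS_NOISE",
    "CLASS_COGNATE",
    "CLASS_UNASSIGNED",
    "substitution_label",
    "subtract_noise",
    "match_peaks",
    "classify_substitution",
    "summarize_classes",
    "positional_distribution",
    "records_to_frame",
]

CLASS_NOISE = "noise"
CLASS_COGNATE = "cognate"
CLASS_UNASSIGNED = "unassigned"


def substitution_label(offset: int, group_beyond: int = 3) -> str:
    """Class label for a substitution offset: C0X, C-1X, ..., C-kX(k>3)."""
    if offset < 0:
        raise ValueError(f"negative substitution offset: {offset}")
    if offset > group_beyond:
        return f"C-kX(k>{group_beyond})"
    return "C0X" if offset == 0 else f"C-{offset}X"


@dataclass(frozen=True)
class MassPeak:
    """One observed MS feature (neutral monoisotopic mass)."""

    neutral_mass: float
    intensity: float = 0.0
    rt: float | None = None
    sample: str = ""
    timepoint: str = ""
    peak_id: str | None = None

    def __post_init__(self) -> None:
        if self.neutral_mass <= 0:
            raise ValueError(f"nonpositive peak mass: {self.neutral_mass}")
        if self.intensity < 0:
            raise ValueError(f"negative intensity: {self.intensity}")


@dataclass(frozen=True)
class MatchRecord:
    """A peak with its class and ranked candidate references.

    ``candidates`` holds (reference, Δppm) pairs within tolerance for the
    winning class only, sorted by |Δppm| then gene_id (deterministic
    tie-break); ``best_candidate`` is the first of them. The peak is
    counted once regardless of how many references it matches.
    """

    peak: MassPeak
    class_label: str
    candidates: tuple[tuple[PeptideRef, float], ...] = ()

    @property
    def best_candidate(self) -> PeptideRef | None:
        return self.candidates[0][0] if self.candidates else None

    @property
    def best_ppm(self) -> float | None:
        return self.candidates[0][1] if self.candidates else None


def subtract_noise(
    peaks: Sequence[MassPeak],
    control: Sequence[MassPeak],
    tol_ppm: float = 5.0,
) -> tuple[list[MassPeak], list[MatchRecord]]:
    """Remove peaks within ``tol_ppm`` of any control-sample mass.

    Returns ``(kept, removed)`` where removed peaks are wrapped as
    :class:`MatchRecord` with the ``noise`` label; the two lists partition
    the input exhaustively. An empty control is a warned no-op.
    """
    if tol_ppm <= 0:
        raise ValueError(f"tolerance must be > 0 ppm, got {tol_ppm}")
    if not control:
        import logging

        logging.getLogger(__name__).warning(
            "subtract_noise: empty control list; nothing removed"
        )
        return list(peaks), []
    ctrl = np.sort(np.array([p.neutral_mass for p in control], dtype=float))
    kept: list[MassPeak] = []
    removed: list[MatchRecord] = []
    for peak in peaks:
        m = peak.neutral_mass
        # symmetric window in the peak's own ppm scale
        delta = m * tol_ppm * 1e-6
        lo = np.searchsorted(ctrl, m - delta, side="left")
        hi = np.searchsorted(ctrl, m + delta, side="right")
        hit = any(
            abs(ppm_error(m, ref)) <= tol_ppm for ref in ctrl[lo:hi]
        )
        if hit:
            removed.append(MatchRecord(peak, CLASS_NOISE))
        else:
            kept.append(peak)
    return kept, removed


class _MassIndex:
    """Sorted-mass index over a reference database (binary-search windows)."""

    def __init__(self, refs: Sequence[PeptideRef]):
        self.refs = list(refs)
        self.masses = np.array([r.neutral_mass for r in self.refs], dtype=float)
        self.order = np.argsort(self.masses, kind="stable")
        self.sorted_masses = self.masses[self.order]

    def query(self, mass: float, tol_ppm: float) -> list[tuple[PeptideRef, float]]:
        """All references within tol_ppm of ``mass`` (ppm relative to the
        reference mass), ranked by |Δppm|, then substitution offset, then
        gene_id and sequence.

        Exact composition identities (e.g. Val+Thr = Leu+Ser) make mass
        ties common, and a tied mass never determines the substitution
        offset; ties (|Δppm| equal to 1e-4 ppm) are broken toward the
        smallest offset because drop-off-site substitutions dominate
        miscoding overwhelmingly.
        """
        # Window in Da: |obs - ref| <= tol * ref / 1e6; bracket generously
        # using the observed mass, then filter exactly.
        delta = mass * tol_ppm * 1e-6 * (1 + 2 * tol_ppm * 1e-6)
        lo = np.searchsorted(self.sorted_masses, mass - delta, side="left")
        hi = np.searchsorted(self.sorted_masses, mass + delta, side="right")
        hits = []
        for idx in self.order[lo:hi]:
            ref = self.refs[idx]
            dppm = ppm_error(mass, ref.neutral_mass)
            if abs(dppm) <= tol_ppm:
                hits.append((ref, dppm))
        hits.sort(
            key=lambda h: (
                round(abs(h[1]), 4),
                h[0].sub_offset if h[0].sub_offset is not None else 0,
                h[0].gene_id,
                h[0].sequence,
            )
        )
        return hits


def match_peaks(
    peaks: Sequence[MassPeak],
    cognate_db: Sequence[PeptideRef],
    substitution_db: Sequence[PeptideRef],
    tol_ppm: float = 5.0,
    precedence: Sequence[str] = ("cognate", "substitution"),
    group_beyond: int = 3,
) -> list[MatchRecord]:
    """Assign each peak exactly one class at the given ppm tolerance.

    Databases are tried in ``precedence`` order; the first with any hit
    wins (default: cognate before substitution, matching the profiling
    triage). Within the substitution stage the class is the smallest
    substitution offset among in-tolerance candidates (C0X before C-1X
    before deeper offsets), since a mass tie never determines the offset
    and drop-off-site substitutions dominate miscoding. Unmatched peaks
    are ``unassigned``.
    """
    if tol_ppm <= 0:
        raise ValueError(f"tolerance must be > 0 ppm, got {tol_ppm}")
    indexes = {
        "cognate": _MassIndex(cognate_db),
        "substitution": _MassIndex(substitution_db),
    }
    records: list[MatchRecord] = []
    for peak in peaks:
        record = None
        for stage in precedence:
            hits = indexes[stage].query(peak.neutral_mass, tol_ppm)
            if hits:
                if stage == "cognate":
                    label = CLASS_COGNATE
                else:
                    # Precedence ladder within substitutions, mirroring the
                    # staged searches (drop-off-site substitutions before
                    # deeper offsets): the class is the smallest offset
                    # present among in-tolerance hits, and the candidate
                    # list is restricted to that class.
                    k = min(h[0].sub_offset for h in hits)
                    label = substitution_label(k, group_beyond)
                    if k > group_beyond:
                        hits = [
                            h for h in hits if h[0].sub_offset > group_beyond
                        ]
                    else:
                        hits = [h for h in hits if h[0].sub_offset == k]
                record = MatchRecord(peak, label, tuple(hits))
                break
        if record is None:
            record = MatchRecord(peak, CLASS_UNASSIGNED)
        records.append(record)
    return records


def classify_substitution(record: MatchRecord, group_beyond: int = 3) -> str:
    """Label C-kX from the best candidate's substitution offset."""
    best = record.best_candidate
    if best is None or not best.is_substitution:
        raise ValueError(
            "classify_substitution requires a substitution best candidate"
        )
    return substitution_label(best.sub_offset, group_beyond)


def summarize_classes(records: Iterable[MatchRecord]) -> pd.DataFrame:
    """Per-class counts, proportions, and mass medians.

    Proportions are over all records (they sum to 1); ``median_mass`` is
    the per-class median peak mass.
    """
    rows = [
        (r.class_label, r.peak.neutral_mass) for r in records
    ]
    if not rows:
        return pd.DataFrame(
            columns=["class_label", "count", "proportion", "median_mass"]
        )
    df = pd.DataFrame(rows, columns=["class_label", "mass"])
    out = (
        df.groupby("class_label")["mass"]
        .agg(count="size", median_mass="median")
        .reset_index()
    )
    out["proportion"] = out["count"] / out["count"].sum()
    return out[["class_label", "count", "proportion", "median_mass"]]


def positional_distribution(
    records: Iterable[MatchRecord],
) -> pd.DataFrame:
    """Counts and cumulative fractions by drop-off codon position per class.

    Records without a best candidate (noise/unassigned) are excluded; the
    cumulative fraction within each class is nondecreasing and reaches 1.
    """
    rows = [
        (r.class_label, r.best_candidate.dropoff_codon_pos)
        for r in records
        if r.best_candidate is not None
    ]
    if not rows:
        return pd.DataFrame(
            columns=["class_label", "dropoff_pos", "count", "fraction",
                     "cumulative_fraction"]
        )
    df = pd.DataFrame(rows, columns=["class_label", "dropoff_pos"])
    tallies = (
        df.groupby(["class_label", "dropoff_pos"])
        .size()
        .rename("count")
        .reset_index()
        .sort_values(["class_label", "dropoff_pos"], kind="stable")
    )
    tallies["fraction"] = tallies.groupby("class_label")["count"].transform(
        lambda c: c / c.sum()
    )
    tallies["cumulative_fraction"] = tallies.groupby("class_label")[
        "fraction"
    ].cumsum()
    return tallies.reset_index(drop=True)


def records_to_frame(records: Sequence[MatchRecord]) -> pd.DataFrame:
    """One row per peak with the best candidate flattened."""
    rows = []
    for r in records:
        best = r.best_candidate
        rows.append(
            {
                "peak_id": r.peak.peak_id,
                "neutral_mass": r.peak.neutral_mass,
                "intensity": r.peak.intensity,
                "rt": r.peak.rt,
                "sample": r.peak.sample,
                "timepoint": r.peak.timepoint,
                "class_label": r.class_label,
                "gene_id": best.gene_id if best else None,
                "sequence": best.sequence if best else None,
                "met_trimmed": best.met_trimmed if best else None,
                "sub_offset": best.sub_offset if best else None,
                "dropoff_pos": best.dropoff_codon_pos if best else None,
                "delta_ppm": r.best_ppm,
                "n_candidates": len(r.candidates),
            }
        )
    return pd.DataFrame(rows)
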