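"""Orchestration of the full profiling run and external-table import."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .masschem import load_table
from .matchclass import (
    match_peaks,
    positional_distribution,
    records_to_frame,
    subtract_noise,
    summarize_classes,
)
from .refdb import build_cognate_db, build_substitution_db, db_to_frame

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_profile", "import_identifications"]


@dataclass(frozen=True)
class RunConfig:
    """All inputs and knobs of one profiling run.

    Paths must exist at run start; the serialized config (and its hash)
    is stamped into every output header so a bundle is traceable to the
    exact configuration that produced it.
    """

    orfs: str
    peaks: str
    control: str | None = None
    tpm: str | None = None
    out_dir: str = "profile_out"
    tol_ppm: float = 5.0
    min_len: int = 3
    max_len: int = 14
    substitution_positions: str = "all"  # "all" or "c0..c-3"
    precedence: tuple[str, ...] = ("cognate", "substitution")
    mass_table: str = "paper"

    def hash(self) -> str:
        # out_dir is where results land, not part of the run's identity
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def validate_paths(self) -> None:
        for p in (self.orfs, self.peaks, self.control, self.tpm):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _positions(spec: str):
    if spec == "all":
        return "all"
    if spec.startswith("c0..c-"):
        return set(range(int(spec.split("c-")[-1]) + 1))
    raise ValueError(f"bad substitution position spec {spec!r}")


def run_profile(config: RunConfig) -> dict:
    """Run the whole triage: databases → noise subtraction → matching.

    Writes the database dump, per-peak match table, positional
    distribution and a JSON summary (class tallies plus per-stage counts)
    under ``config.out_dir``; returns the bundle in memory as well.
    Raises (exit nonzero from the CLI) on any validation error before
    writing anything.
    """
    config.validate_paths()
    table = load_table(config.mass_table)
    tpm = pio.read_tpm_tsv(config.tpm) if config.tpm else None
    orfs = pio.read_orf_fasta(config.orfs, tpm=tpm)
    if not orfs:
        raise ValueError("no valid ORFs parsed")
    peaks = pio.read_peaks_tsv(config.peaks)
    control = pio.read_peaks_tsv(config.control) if config.control else []

    cognate_db = build_cognate_db(orfs, config.min_len, config.max_len, table)
    substitution_db = build_substitution_db(
        cognate_db, _positions(config.substitution_positions), table
    )
    kept, noise_records = subtract_noise(peaks, control, config.tol_ppm)
    matched = match_peaks(
        kept, cognate_db, substitution_db, config.tol_ppm,
        precedence=config.precedence,
    )
    records = noise_records + matched
    summary = summarize_classes(records)
    positional = positional_distribution(records)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    identity = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    stamp = [f"config_hash: {config.hash()}",
             f"config: {json.dumps(identity, sort_keys=True, default=str)}"]
    pio.write_tsv(db_to_frame(cognate_db), out / "cognate_db.tsv", stamp)
    pio.write_tsv(records_to_frame(records), out / "matched.tsv", stamp)
    pio.write_tsv(positional, out / "positional.tsv", stamp)
    counts = {
        "peaks_in": len(peaks),
        "noise_removed": len(noise_records),
        "matched_cognate": int(
            (summary.set_index("class_label")["count"].get("cognate", 0))
        ),
        "matched_substitution": int(
            summary[~summary.class_label.isin(["cognate", "noise", "unassigned"])][
                "count"
            ].sum()
        ),
        "unassigned": int(
            summary.set_index("class_label")["count"].get("unassigned", 0)
        ),
    }
    (out / "summary.json").write_text(
        json.dumps(
            {
                "config_hash": config.hash(),
                "stage_counts": counts,
                "classes": summary.to_dict(orient="records"),
            },
            indent=2,
        )
    )
    logger.info("run_profile: %s", counts)
    return {
        "orfs": orfs,
        "cognate_db": cognate_db,
        "substitution_db": substitution_db,
        "records": records,
        "summary": summary,
        "positional": positional,
        "stage_counts": counts,
    }


def import_identifications(
    table: pd.DataFrame,
    max_ppm: float = 5.0,
    min_score: float = 30.0,
    max_pep_expect: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Filter and disambiguate an external search-engine result table.

    Expected columns: ``query_id`` (one MS/MS identification event),
    ``gene_id``, ``sequence``, ``score``, ``pep_expect``, ``delta_ppm``,
    ``is_cognate`` (bool), optional ``tpm``. Rows failing any filter
    (|Δppm| < ``max_ppm``, score > ``min_score``, pepExpect <
    ``max_pep_expect``) are dropped. When several candidate genes survive
    for one query, the candidate list is narrowed by higher score, then
    preference for cognate over non-cognate, then higher TPM; a query
    still ambiguous after that is excluded entirely.

    Returns (assigned rows, number of excluded ambiguous queries).
    """
    df = table.copy()
    if "tpm" not in df.columns:
        df["tpm"] = 0.0
    df["tpm"] = df["tpm"].fillna(0.0)
    df = df[
        (df["delta_ppm"].abs() < max_ppm)
        & (df["score"] > min_score)
        & (df["pep_expect"] < max_pep_expect)
    ]
    kept = []
    excluded = 0
    for _, group in df.groupby("query_id", sort=False):
        g = group
        for col, best in (
            ("score", "max"),
            ("is_cognate", "max"),
            ("tpm", "max"),
        ):
            if len(g) == 1:
                break
            top = g[col].max() if best == "max" else g[col].min()
            g = g[g[col] == top]
        if len(g) == 1:
            kept.append(g)
        else:
            excluded += 1
    out = (
        pd.concat(kept, ignore_index=True)
        if kept
        else df.iloc[0:0].reset_index(drop=True)
    )
    return out, excluded
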