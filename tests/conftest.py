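"""Shared fixtures: toy ORFs and a small seeded synthetic bundle."""

from __future__ import annotations

import pytest

from peptrna.refdb import OrfRecord, orf_from_cds
from peptrna.simdata import SimConfig, simulate_dropoff_peaks, simulate_orfeome

# One codon per residue for deterministic reverse translation of toy ORFs.
CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def make_orf(gene_id: str, protein: str, tpm: float | None = None) -> OrfRecord:
    """Toy ORF whose CDS reverse-translates the given protein (+TAA stop)."""
    assert protein.startswith("M")
    cds = "".join(CODON[aa] for aa in protein) + "TAA"
    return orf_from_cds(gene_id, cds, tpm=tpm)


@pytest.fixture(scope="session")
def rplj_like_orf() -> OrfRecord:
    # N-terminus M-ALNLQDK...: MAP-eligible (Ala), Lys at codon 8 (AAA).
    return make_orf("rplJ", "MALNLQDKKEYVTRS")


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded synthetic bundle for unit-level pipeline tests."""
    cfg = SimConfig(
        seed=11, n_orfs=30, n_events=400,
        n_decoys_sample=80, n_decoys_control=40,
    )
    orfs = simulate_orfeome(cfg)
    sample, control, truth = simulate_dropoff_peaks(orfs, cfg)
    return cfg, orfs, sample, control, truth
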