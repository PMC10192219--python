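# peptrna

Mass-spectrometric profiling of **peptidyl-tRNA drop-off** — the dissociation
of a tRNA still carrying its nascent peptide from the ribosome during early
translation elongation. In *E. coli*, dropped-off pep-tRNAs accumulate when
peptidyl-tRNA hydrolase is inactivated; their nascent peptides can then be
released, measured by LC/MS as accurate neutral masses, and annotated against
the N-terminal sequences of the ORFeome. Roughly a fifth of such peptides
carry a single amino-acid substitution, overwhelmingly at the C-terminal
drop-off site, which is the signature of miscoding followed by rejection of
the erroneous pep-tRNA.

This package implements the computational side of that experiment for
scientists analysing deconvoluted peak lists (or simulating them):

* **`masschem`** — monoisotopic mass arithmetic for modified nascent peptides
  and peptidyl-adenosines: N-acetyl / N-formyl termini, carbamidomethyl-Cys
  (fixed), Met oxidation, the tRNA-derived 3′-adenosine ester, and the +2 Da
  C-terminal ¹⁸O label from hydrolysis in [¹⁸O]water.
* **`refdb`** — reference databases from a CDS FASTA: cognate N-terminal
  peptides over a length range (default 3–14 residues), initiator-Met-trimmed
  variants per the methionine-aminopeptidase rule (second residue ∈
  G,A,S,T,C,P,V,N,D,L,I), and all single-substitution variants with non-zero
  mass change; FASTA export with `X` wildcards for external search engines.
* **`matchclass`** — the peak triage: chemical-noise subtraction against a
  t=0 control, matching at a ppm tolerance (default |Δppm| ≤ 5) over a sorted
  mass index, and classification as cognate or C₀X…C₋ₖX (substitution k
  residues upstream of the C-terminal drop-off site).
* **`quant`** — drop-off arithmetic: f-Met-Ado-referenced normalization and
  time courses, the ±tylosin **drop-off frequency** (relative abundance
  without drug ÷ with saturating drug), the n-mer **drop-off rate**
  n/(n + (n+1)), and log–log calibration-curve absolute quantification.
* **`codonstats`** — codon tallies at (and next to) drop-off sites,
  TPM-weighted positional codon usage, GC grouping, codon–anticodon mismatch
  classification (cognate / near-cognate / multiple), early-ORF codon-usage
  deviation, ORF grouping by drop-off position, and residue-frequency
  comparisons.
* **`simdata`** — a seeded synthetic generator (toy ORFeome, planted drop-off
  and miscoding events, Gaussian ppm error, unassignable decoys) with exact
  ground truth, so the whole pipeline is testable without any external data.
* **`io` / `pipeline` / `cli`** — TSV/FASTA adapters, one-shot orchestration
  with config-stamped outputs, import of filtered external search-engine
  identification tables, and the `peptrna` command-line tool.

## The arithmetic at the core

For a peptide with residues $r_1 \dots r_n$ the neutral monoisotopic mass is

$$M = \sum_i m(r_i) + m_{\mathrm{H_2O}} + \Delta_{\text{N-term}} + k\,\Delta_{\mathrm{ox}},$$

with $\Delta_{\text{N-term}}$ the acetyl (+42.010565 Da) or formyl
(+27.994915 Da) modification and $\Delta_{\mathrm{ox}}$ Met oxidation.
Esterification to the tRNA 3′-adenosine replaces the C-terminal water:
$M_{\text{Ado}} = M + m_{\mathrm{Ado}} - m_{\mathrm{H_2O}}$, and
$[M+zH]^{z+} = (M + z\,m_p)/z$. A peak of observed mass $x$ matches reference
$M$ when $|x - M|/M \times 10^6 \le 5$ ppm. Two residue tables ship: the
`paper` table (the published accurate residue masses, default) and a
`standard` table from exact atomic compositions; they differ by ≲3×10⁻⁴ Da
per residue, and both reproduce the reference peptidyl-adenosine ions
Ac-Ala-Ado *m/z* 381.15, Ac-Met-Ala-Ado 512.19 and f-Met-Ado 427.14.

## Worked example

Simulate a small ground-truthed experiment, then run the full triage:

```sh
peptrna simulate --seed 7 --n-orfs 40 --n-events 600 --out sim
peptrna match --peaks sim/peaks_t30.tsv --control sim/peaks_t0.tsv \
              --orfs sim/orfs.fna --tpm sim/tpm.tsv --out profile
```

which prints the stage counts:

```json
{
  "peaks_in": 1600,
  "noise_removed": 3,
  "matched_cognate": 492,
  "matched_substitution": 108,
  "unassigned": 997
}
```

The 600 planted drop-off events are all recovered (492 cognate + 108
substituted, i.e. 18% non-cognate, close to the planted 20.8% miscoding rate
minus mass-degenerate cases); the 1,600 input peaks also contain 1,000
unassignable decoys, of which 3 coincided with the t=0 control list and were
removed as chemical noise and 997 remained unassigned. `profile/matched.tsv`
holds one row per peak with its class, best reference (gene, sequence,
drop-off codon position) and Δppm; `profile/positional.tsv` the per-class
drop-off-position distribution.

The library surface mirrors the CLI, e.g.:

```python
from peptrna import (build_cognate_db, build_substitution_db, match_peaks,
                     neutral_mass, PeptideSpecies)
```

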