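# Methods

## The measurement being modelled

During early elongation, a peptidyl-tRNA can dissociate from the ribosome
("drop-off"). When peptidyl-tRNA hydrolase is inactive, these species
accumulate and their nascent peptides can be recovered chemically: the
α-amino group is acetylated to stabilize the acyl bond, nuclease digestion
leaves the peptide esterified to the tRNA's 3′-terminal adenosine
(peptidyl-adenosine), or mild alkaline hydrolysis releases the free-acid
peptide. LC/MS of these products yields a deconvoluted list of neutral
monoisotopic masses. The computational task is to decide, for each mass,
whether it is (a) chemical background, (b) a cognate N-terminal peptide of
some ORF, (c) a single-substitution variant of such a peptide — typed by how
far the substituted residue sits from the C-terminal drop-off site — or
(d) unassignable, and then to summarize drop-off positions, codon usage and
abundances.

## Mass model

Neutral mass = Σ residue masses + water + N-terminal delta (acetyl
+42.010565, formyl +27.994915) + k × Met-oxidation (+15.994915). The
adenosine ester replaces the C-terminal water (net +adenosine − water,
adenosine = C₁₀H₁₃N₅O₄ = 267.096754 Da); hydrolysis in [¹⁸O]water adds one
¹⁸O−¹⁶O delta (+2.004246 Da, nominal +2). Ions are singly protonated unless
a charge is given explicitly (proton 1.0072765 Da). Cysteine is always
carbamidomethylated (iodoacetamide alkylation precedes analysis); free Cys
is not representable by default.

Two residue tables are provided. The default `paper` table is the published
list of accurate residue masses used to build the original reference
databases; it deviates from exact atomic sums by up to ~3×10⁻⁴ Da
(e.g. carbamidomethyl-Cys 160.03041 printed vs 160.03065 computed). The
`standard` table uses exact monoisotopic masses from pyteomics. The source
of the small deviations is not documented anywhere we could find, so both
tables ship and the discrepancy is exposed rather than hidden; all
2-decimal reference ions agree under either table, and the unit tests pin
the disagreement to < 5×10⁻⁴ Da per residue.

## Reference databases

From each valid CDS (start codon ATG/GTG/TTG translated as initiator Met,
length a multiple of three, no internal stop) the cognate database holds
every N-terminal prefix of length 3–14 (configurable; the sequence-export
convention uses 4–10 and 10–16 with the boundary length present in both
files). When the second residue is small (G, A, S, T, C, P, V, N, D, L, I)
methionine aminopeptidase removes the initiator Met, so Met-trimmed
counterparts of each length are added. Positions are 1-based codon positions
with the initiator as codon 1; a peptide of length L dissociated from codon
L, or L+1 if Met-trimmed — hence a trimmed heptamer maps to the eighth
codon. Trimming eligibility is decided on the cognate second residue even
for substitution variants at that position, because trimming acts
co-translationally on the true N-terminus.

The substitution database contains, for every cognate peptide and position
(recorded as offset from the C-terminus: 0 = drop-off site), one variant per
replacement residue among the other nineteen, excluding replacements with
zero mass change (Ile↔Leu): mass-only profiling cannot evidence them, so
keeping them would only create false candidates. Sequence-level FASTA export
keeps all positions and writes `X` wildcards where a search engine should
accept any residue.

## Matching and classification

Peaks present in the t=0 control list (within tolerance) are removed as
chemical noise first. Survivors are matched at |Δppm| ≤ 5 (inclusive
boundary; relative to the reference mass) using a sorted mass index with
binary-search windows, contractually equivalent to an all-pairs scan (a
property test enforces this). Classes are assigned by precedence: cognate
before substitution, and within substitutions the smallest offset present
among in-tolerance candidates (C₀X before C₋₁X before deeper offsets),
mirroring the staged database searches of the original workflow. The
precedence ladder matters because exact composition identities —
Val+Thr = Leu+Ser, Gly+Gly = Asn, Ala+Gly = Gln, and anagrams — make mass
ties common, and a tied mass never determines the substitution offset; the
ladder resolves ties toward the biologically dominant interpretation.
Within the winning class candidates are ranked by |Δppm| (rounded at
10⁻⁴ ppm so float noise cannot reorder genuine ties), then gene id, then
sequence; a peak is counted once regardless of how many references it
matches. Every input peak receives exactly one label, so class counts
always partition the input — an invariant asserted on every run.

## Quantification

Abundances are referenced to formyl-Met-adenosine, whose level is
insensitive to hydrolase inactivation. Time courses divide by the t=0 value
(aminoacyl species) or by the per-timepoint reference (dipeptidyl species).
The drop-off frequency divides the relative abundance without tylosin by
that at saturating tylosin (which dissociates essentially all elongating
dipeptidyl-tRNAs and so approximates total flux); values above 100% are
possible with noisy inputs and are flagged, never clipped. The drop-off
rate at a codon is n-mer/(n-mer + (n+1)-mer) on absolute amounts, invariant
to common rescaling. Calibration curves are ordinary least squares in
log₁₀(area) vs log₁₀(amount) with the slope free (not constrained to 1);
inversion outside the fitted amount range is flagged as extrapolation.
Summed-abundance output is the raw reference-normalized sum with an
optional percent-of-baseline rescaling (baseline timepoint configurable,
default t=0), since the published percentile convention is ambiguous.

## Codon statistics

Drop-off-site codons are tallied per class from the matched records and the
ORF set; the 3′-adjacent codon uses offset +1. Transcriptome usage at
positions 5–17 weights each ORF's codon counts by its share of total TPM
and is invariant to global TPM rescaling. Codon–anticodon pairing aligns
codon position i with anticodon position 4−i; matches are strict
Watson–Crick by default, with an optional wobble policy (G·U/U·G at codon
position 3 only) because the original mismatch-counting rule is not stated;
0/1/≥2 mismatches classify pairs as cognate/near-cognate/multiple. R² is
the squared Pearson correlation over the shared codon set, with an option
to exclude named codons. Early-ORF usage deviation computes per-codon
(window frequency / total frequency) over positions ≥ 2 and reports the
population standard deviation of that 61-codon ratio vector; codons absent
from the whole ORF set are excluded with a warning. ORF grouping restricts
to ORFs at or above a TPM quantile (default 0.8) and partitions them into
drop-off detected at positions 5–6 (group 1), only later (group 2), or not
at all (group 3). Group comparisons elsewhere use the two-sided Wilcoxon
rank-sum test as reporting plumbing.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
ribosome kinetics. One seeded generator is split into per-stage child
streams, so every output is byte-identical under a fixed seed. Defaults are
the study conditions: 200 ORFs of 25–60 sense codons with AU-rich codon
bias in positions 2–8 (weight 1.6 per A/U base, emulating reduced mRNA
structure around start codons); TPM log-normal (σ=1.5), normalized to a
million. 5,000 drop-off events are drawn TPM-weighted across ORFs; 20.8%
are miscoded, with substitution offsets mixed 286:10:4:4 over C₀…C₋₃ and
drop-off positions confined to codons 5–9; cognate events spread over
codons 3–14 with an early-biased profile. Met trimming is applied
deterministically by the MAP rule to peptides longer than trimers.
True masses are exact mass-arithmetic values (asserted bit-for-bit);
observed masses add Gaussian relative error (σ = 1 ppm against the 5 ppm
tolerance). Decoys (1,000 in the sample, 500 in the control; the control
contains only decoys) are uniform over the signal mass range but rejected
within twice the tolerance of any reference mass, so their truth labels
stay unambiguous.

What the generator does **not** emulate: retention-time structure, isotope
envelopes and charge-state errors, intensity dynamics, correlated (bulk
calibration) mass error, multiple substitutions and truncations, and the
sequence-level biases of a real transcriptome. Passing recovery tests
therefore demonstrates the correctness of the annotation arithmetic and
its tie-handling under realistic mass-degeneracy, not the biological
fidelity of any real dataset.

## Evaluation against planted truth

Precision and recall are computed per class after matching the generated
lists end-to-end. A planted truth is **mass-degenerate** when matching its
exact, noiseless mass already yields a different class — for example a
substituted peptide whose composition coincides with a cognate peptide of
another gene. Such truths are unidentifiable from a mass list by
construction (the same reason Ile↔Leu substitutions are excluded from the
database) and are excluded from the confusion counts; in the default
conditions they are ~5% of planted events. On the remainder the seeded
study recovers cognate peptides with recall ≥ 0.99, reproduces the planted
C₀X fraction within its 95% binomial interval, and places ≥ 95% of C₀X
detections at codon positions 5–9. The cognate/substitution precedence also
means a genuinely miscoded mass that collides with a cognate reference is
*reported* cognate — the same conservative bias the real workflow has.

## Problem sizes and numerical choices

The default test and acceptance runs use 200 ORFs (≈3,900 cognate and
≈620,000 substitution references) and 6,500 peaks, chosen as the smallest
scale at which all planted effects are statistically resolvable; matching
uses numpy binary search and runs in seconds. Degenerate inputs (empty
control, empty classes, all-zero TPM, zero baselines) warn or raise as
documented per operation rather than silently producing output. TSVs are
written with full float precision and read back with round-trip parsing so
pipelines are byte-stable; every output carries the configuration hash
(excluding the output directory) for idempotence checks.

## Known limitations

* Mass-only classification is bounded by composition degeneracy; offsets
  and gene assignments for tied masses are conventions, not evidence.
  Sequence-level claims need MS/MS, which this package only supports by
  exporting search databases and importing filtered identification tables
  (|Δppm| < 5, score > 30, expectation < 0.05, with score → cognate → TPM
  disambiguation and exclusion of residual ties).
* The profiling substitution database includes Met-trimmed variants; the
  original convention is unstated, and the flag is carried in all outputs
  so either convention can be filtered downstream.
* Isolated-tRNA search databases defaulting to 4–10/10–16 residues follow
  the written methods; the alternative 4–17 convention mentioned elsewhere
  is available through configuration.
* Modified-nucleoside-aware decoding (e.g. ac⁴C, lysidine) is out of scope
  for mismatch counting; anticodons are treated as plain RNA triplets.
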