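"""Codon statistics: tallies, weighted usage, pairing, deviation, grouping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_orf
from peptrna.codonstats import (
    SENSE_CODONS,
    AnticodonEntry,
    aa_frequency_comparison,
    adjacent_codon_tally,
    codon_at,
    dropoff_codon_tally,
    gc_group,
    mismatch_count,
    orf_grouping,
    r_squared,
    tpm_weighted_usage,
    usage_deviation,
)
from peptrna.matchclass import MassPeak, MatchRecord
from peptrna.refdb import PeptideRef
from peptrna.simdata import SimConfig, simulate_orfeome


def _record(gene_id, pos, label="cognate", seq_len=None):
    ref = PeptideRef(
        gene_id=gene_id, sequence="A" * (seq_len or pos),
        met_trimmed=False, dropoff_codon_pos=pos, neutral_mass=500.0,
        sub_offset=None if label == "cognate" else 0,
        sub_from=None if label == "cognate" else "A",
        sub_to=None if label == "cognate" else "G",
    )
    return MatchRecord(MassPeak(500.0, peak_id="p"), label, ((ref, 0.0),))


class TestDropoffTally:
    def test_trimmed_heptamer_tallies_lysine_codon(self, rplj_like_orf):
        # ALNLQDK dissociates from codon 8 of the template (AAA)
        records = [_record("rplJ", 8)]
        tallies = dropoff_codon_tally(records, [rplj_like_orf])
        assert tallies["cognate"]["AAA"] == 1

    def test_empty_records_give_empty_tally(self):
        assert dropoff_codon_tally([], []) == {}

    def test_planted_codons_counted_exactly(self, rplj_like_orf):
        records = [_record("rplJ", p) for p in (3, 3, 8)] + [
            _record("rplJ", 8, label="C0X")
        ]
        tallies = dropoff_codon_tally(records, [rplj_like_orf])
        codon3 = codon_at(rplj_like_orf, 3)
        assert tallies["cognate"][codon3] == 2
        assert tallies["cognate"]["AAA"] == 1
        assert tallies["C0X"]["AAA"] == 1

    def test_out_of_range_positions_skipped(self, rplj_like_orf):
        tallies = dropoff_codon_tally([_record("rplJ", 99)], [rplj_like_orf])
        assert tallies == {}

    def test_adjacent_tally_offsets(self, rplj_like_orf):
        records = [_record("rplJ", 7)]
        site = dropoff_codon_tally(records, [rplj_like_orf])
        adjacent = adjacent_codon_tally(records, [rplj_like_orf])
        zero = adjacent_codon_tally(records, [rplj_like_orf], offset=0)
        assert site["cognate"][codon_at(rplj_like_orf, 7)] == 1
        assert adjacent["cognate"][codon_at(rplj_like_orf, 8)] == 1
        assert zero["cognate"].values.equals(site["cognate"].values)

    def test_normalized_tally_sums_to_one(self, rplj_like_orf):
        records = [_record("rplJ", p) for p in (3, 5, 8, 8)]
        tallies = dropoff_codon_tally(records, [rplj_like_orf], normalize=True)
        assert tallies["cognate"].values.sum() == pytest.approx(1.0)


class TestTpmWeightedUsage:
    def test_equal_tpm_single_codon_orfs_split_evenly(self):
        a = make_orf("a", "M" + "K" * 20, tpm=5.0)
        b = make_orf("b", "M" + "V" * 20, tpm=5.0)
        usage = tpm_weighted_usage([a, b], (5, 17))
        assert usage["AAA"] == pytest.approx(0.5)
        assert usage["GUU"] == pytest.approx(0.5)

    def test_global_tpm_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        cfg = SimConfig(seed=21, n_orfs=12)
        orfs = simulate_orfeome(cfg)
        scaled = [
            type(o)(o.gene_id, o.cds, o.protein, o.tpm * 10.0) for o in orfs
        ]
        u1 = tpm_weighted_usage(orfs, (5, 17)).values
        u2 = tpm_weighted_usage(scaled, (5, 17)).values
        assert np.allclose(u1.to_numpy(), u2.to_numpy())

    def test_matches_brute_force_weighted_count(self):
        cfg = SimConfig(seed=22, n_orfs=8)
        orfs = simulate_orfeome(cfg)
        usage = tpm_weighted_usage(orfs, (5, 9)).values
        total_tpm = sum(o.tpm for o in orfs)
        expected = {c: 0.0 for c in SENSE_CODONS}
        for o in orfs:
            for pos in range(5, 10):
                codon = codon_at(o, pos)
                if codon is not None:
                    expected[codon] += o.tpm / total_tpm
        norm = sum(expected.values())
        for codon in SENSE_CODONS:
            assert usage[codon] == pytest.approx(expected[codon] / norm)

    def test_all_zero_tpm_rejected(self):
        orf = make_orf("a", "MKKKKK", tpm=0.0)
        with pytest.raises(ValueError):
            tpm_weighted_usage([orf], (5, 17))


class TestGcGroup:
    @pytest.mark.parametrize(
        ("codon", "group"), [("AAA", 0), ("GCG", 3), ("AUG", 1), ("ACG", 2)]
    )
    def test_groups(self, codon, group):
        assert gc_group(codon) == group

    def test_invalid_codon_rejected(self):
        with pytest.raises(ValueError):
            gc_group("AXA")


class TestMismatchCount:
    def test_full_watson_crick_pairing(self):
        assert mismatch_count("AAA", "UUU") == (0, "cognate")

    def test_ile1_reading_lysine_codon_is_multiple_mismatch(self):
        # tRNA-Ile1 anticodon GAU against AAA: two mismatched positions
        count, cls = mismatch_count("AAA", AnticodonEntry("Ile1", "GAU"))
        assert (count, cls) == (2, "multiple")

    def test_single_mismatch_is_near_cognate(self):
        count, cls = mismatch_count("AAG", "UUU")
        assert (count, cls) == (1, "near_cognate")

    def test_wobble_policy_at_codon_position_three(self):
        strict = mismatch_count("GGU", "GCC", wobble=False)
        wobbly = mismatch_count("GGU", "GCC", wobble=True)
        assert strict == (1, "near_cognate")
        assert wobbly == (0, "cognate")
        # wobble never applies at codon positions 1-2
        assert mismatch_count("UGG", "CCG", wobble=True)[0] == 1

    def test_zero_iff_full_pairing(self):
        rng = np.random.default_rng(12)
        bases = "ACGU"
        complement = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(50):
            codon = "".join(rng.choice(list(bases), size=3))
            perfect = "".join(complement[b] for b in reversed(codon))
            assert mismatch_count(codon, perfect)[0] == 0

    def test_invalid_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            mismatch_count("ABC", "UUU")
        with pytest.raises(ValueError):
            AnticodonEntry("x", "UU")


class TestRSquared:
    def _tally(self, values):
        return pd.Series(values, index=list(SENSE_CODONS)[: len(values)])

    def test_identical_tallies_give_one(self):
        x = self._tally([0.2, 0.3, 0.1, 0.4])
        assert r_squared(x, x) == pytest.approx(1.0)

    def test_matches_independent_pearson(self):
        rng = np.random.default_rng(9)
        x = self._tally(rng.uniform(size=20))
        y = self._tally(rng.uniform(size=20))
        r, _ = stats.pearsonr(x.to_numpy(), y.to_numpy())
        assert r_squared(x, y) == pytest.approx(r**2)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(10)
        x = self._tally(rng.uniform(size=15))
        y = self._tally(rng.uniform(size=15))
        assert r_squared(x, y) == pytest.approx(r_squared(x * 3 + 1, y))

    def test_exclusion_removes_named_codon(self):
        x = self._tally([10.0, 0.1, 0.2, 0.3, 0.15])
        y = self._tally([9.0, 0.3, 0.1, 0.25, 0.2])
        with_aaa = r_squared(x, y)
        without = r_squared(x, y, exclude=["AAA"])
        r, _ = stats.pearsonr(x.iloc[1:].to_numpy(), y.iloc[1:].to_numpy())
        assert without == pytest.approx(r**2)
        assert with_aaa != pytest.approx(without)


class TestUsageDeviation:
    def test_window_covering_everything_gives_unit_ratios(self):
        cfg = SimConfig(seed=23, n_orfs=15, au_rich_early=False)
        orfs = simulate_orfeome(cfg)
        ratios, sigma = usage_deviation(orfs, (2, None))
        assert np.allclose(ratios.to_numpy(), 1.0)
        assert sigma == pytest.approx(0.0, abs=1e-12)

    def test_early_au_bias_inflates_early_window_deviation(self):
        cfg = SimConfig(seed=24, n_orfs=150, au_rich_early=True)
        orfs = simulate_orfeome(cfg)
        _, sigma_early = usage_deviation(orfs, (2, 8))
        _, sigma_late = usage_deviation(orfs, (9, 15))
        assert sigma_early > sigma_late

    def test_matches_brute_force_sigma(self):
        cfg = SimConfig(seed=25, n_orfs=20)
        orfs = simulate_orfeome(cfg)
        a, b = 2, 8
        win = {c: 0.0 for c in SENSE_CODONS}
        tot = {c: 0.0 for c in SENSE_CODONS}
        for o in orfs:
            for pos in range(2, len(o.protein) + 1):
                c = codon_at(o, pos)
                tot[c] += 1
                if a <= pos <= b:
                    win[c] += 1
        used = [c for c in SENSE_CODONS if tot[c] > 0]
        wsum, tsum = sum(win[c] for c in used), sum(tot[c] for c in used)
        ratios = [(win[c] / wsum) / (tot[c] / tsum) for c in used]
        expected = float(np.std(ratios))
        _, sigma = usage_deviation(orfs, (a, b))
        assert sigma == pytest.approx(expected)


class TestOrfGrouping:
    def _orfs(self):
        return [
            make_orf("hi1", "MKAVLWSTPQRS", tpm=100.0),
            make_orf("hi2", "MKAVLWSTPQRS", tpm=90.0),
            make_orf("hi3", "MKAVLWSTPQRS", tpm=80.0),
            make_orf("lo1", "MKAVLWSTPQRS", tpm=1.0),
        ]

    def test_planted_detections_grouped_exactly(self):
        orfs = self._orfs()
        records = [_record("hi1", 5), _record("hi1", 9), _record("hi2", 9)]
        groups = orf_grouping(records, orfs, tpm_quantile=0.25)
        lookup = dict(zip(groups.gene_id, groups.group))
        assert lookup == {"hi1": 1, "hi2": 2, "hi3": 3}

    def test_no_detections_all_group_three(self):
        groups = orf_grouping([], self._orfs(), tpm_quantile=0.5)
        assert set(groups.group) == {3}

    def test_quantile_zero_considers_all_orfs(self):
        groups = orf_grouping([], self._orfs(), tpm_quantile=0.0)
        assert len(groups) == 4

    def test_partition_disjoint_and_exhaustive(self):
        orfs = self._orfs()
        records = [_record("hi1", 6)]
        groups = orf_grouping(records, orfs, tpm_quantile=0.5)
        assert groups.gene_id.is_unique
        assert groups.group.isin([1, 2, 3]).all()


class TestAaFrequencyComparison:
    def test_identical_distributions_give_unit_ratios(self):
        orfs = [make_orf("g", "MKAVLWSTPQ")]
        window = (2, 10)
        peptides = [orfs[0].protein[1:10]]
        out = aa_frequency_comparison(peptides, orfs, window)
        present = out[out.orf_freq > 0]
        assert np.allclose(present.ratio.to_numpy(), 1.0)
        assert out.peptide_freq.sum() == pytest.approx(1.0)
        assert out.orf_freq.sum() == pytest.approx(1.0)

    def test_planted_aromatic_depletion_detected(self):
        rng = np.random.default_rng(30)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        orfs = [
            make_orf(f"g{i}", "M" + "".join(rng.choice(list(aas), size=12)))
            for i in range(40)
        ]
        # peptides sample the same windows but with aromatics removed
        peptides = [
            o.protein[1:10].replace("F", "A").replace("Y", "A").replace("W", "A")
            for o in orfs
        ]
        out = aa_frequency_comparison(peptides, orfs, (2, 10))
        for aa in "FYW":
            if out.loc[aa, "orf_freq"] > 0:
                assert out.loc[aa, "ratio"] < 1.0
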