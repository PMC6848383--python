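"""Telomeric read classification, MTL and TRV estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_random_reads
from telomaint import telomere_metrics as tm
from telomaint.readset import ReadSet
from telomaint.synth_data import (TelomereProfile, SequencingParams,
                                  simulate_telomere_readset)

COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(COMP)[::-1]


class TestTelomericReference:
    def test_tandem_concatenation(self):
        assert tm.build_telomeric_reference("TTAGGG", 18) == "TTAGGG" * 3

    def test_rotations_occur_as_substrings(self):
        ref = tm.build_telomeric_reference("TTAGGG", 60)
        for r in range(6):
            assert ("TTAGGG"[r:] + "TTAGGG"[:r]) in ref

    def test_rounds_up_to_whole_units(self):
        assert len(tm.build_telomeric_reference("TTAGGG", 100)) == 102

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            tm.build_telomeric_reference("TTAGNG", 100)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=8),
           st.integers(min_value=1, max_value=200))
    def test_length_and_periodicity(self, pattern, target):
        ref = tm.build_telomeric_reference(pattern, target)
        assert len(ref) >= target
        assert len(ref) % len(pattern) == 0
        assert ref == pattern * (len(ref) // len(pattern))


class TestClassification:
    def test_pure_repeat_read_is_telomeric(self):
        rs = ReadSet(["a"], ["TTAGGG" * 16])
        assert len(tm.classify_reads(rs)) == 1

    def test_offset_pure_repeat_is_telomeric_with_full_base_count(self):
        seq = ("TTAGGG" * 20)[3:3 + 96]
        out = tm.classify_reads(ReadSet(["a"], [seq]))
        assert len(out) == 1
        assert out.telo_bases[0] == 96

    def test_reverse_complement_is_telomeric(self):
        seq = ("TTAGGG" * 20)[2:2 + 90]
        out = tm.classify_reads(ReadSet(["a", "b"], [seq, rc(seq)]))
        assert len(out) == 2
        assert out.telo_bases[0] == out.telo_bases[1]

    def test_random_reads_rarely_classified(self):
        bg = make_random_reads(20_000, seed=3)
        assert len(tm.classify_reads(bg)) / len(bg) < 0.01

    def test_strict_mode_requires_repeat_fraction(self):
        # 40 telomeric + 60 random bases: junction read, below 0.8 fraction
        seq = "TTAGGG" * 7 + make_random_reads(1, 58, seed=1).sequences[0]
        rs = ReadSet(["a"], [seq])
        assert len(tm.classify_reads(rs, include_junctions=False)) == 0
        out = tm.classify_reads(rs)
        assert len(out) == 1            # junction rule admits it
        assert out.telo_bases[0] == 42  # counts only the tiled edge run

    def test_mismatch_budget_respected(self):
        # every unit carries 2 substitutions: not telomeric at budget 1
        unit = "TAACGG"
        rs = ReadSet(["a"], [unit * 16])
        assert len(tm.classify_reads(rs)) == 0
        assert len(tm.classify_reads(rs, max_mismatch_per_unit=2)) == 1


class TestMTL:
    def test_zero_signal_gives_zero_mtl(self):
        est = tm.estimate_mtl(ReadSet([], [], telo_bases=np.array([], dtype=int)),
                              10.0, 46)
        assert est.mtl == 0.0

    def test_normalisation_arithmetic(self):
        telo = ReadSet(["a"], ["TTAGGG" * 16],
                       telo_bases=np.array([46_000], dtype=np.int64))
        est = tm.estimate_mtl(telo, 10.0, 46)
        assert est.mtl == pytest.approx(100.0)

    def test_rejects_zero_coverage(self):
        with pytest.raises(ValueError):
            tm.estimate_mtl(ReadSet([], []), 0.0, 46)

    def test_recovery_on_simulated_sample(self, small_telomere_readset):
        rs = small_telomere_readset
        telo = tm.classify_reads(rs)
        est = tm.estimate_mtl(telo, 5.0, 46)
        true_mtl = rs.truth["tracts"]["true_length"].sum() / 46
        assert est.mtl == pytest.approx(true_mtl, rel=0.05)

    def test_monotonicity_in_reads(self, small_telomere_readset):
        """Adding telomeric reads never decreases the telomeric base count;
        adding random background reads never changes it."""
        telo = tm.classify_reads(small_telomere_readset)
        base = int(telo.telo_bases.sum())
        extra = ReadSet(["x"], ["TTAGGG" * 20])
        more = tm.classify_reads(
            ReadSet.concat([small_telomere_readset, extra]))
        assert int(more.telo_bases.sum()) == base + 120
        bg = make_random_reads(5_000, seed=42)
        with_bg = tm.classify_reads(ReadSet.concat([small_telomere_readset, bg]))
        assert int(with_bg.telo_bases.sum()) == base

    def test_strand_invariance(self, small_telomere_readset):
        rs = small_telomere_readset
        flipped = ReadSet(rs.names, [rc(s) for s in rs.sequences])
        a = tm.classify_reads(rs)
        b = tm.classify_reads(flipped)
        assert int(a.telo_bases.sum()) == int(b.telo_bases.sum())
        est_a = tm.estimate_mtl(a, 5.0, 46)
        est_b = tm.estimate_mtl(b, 5.0, 46)
        ta = tm.profile_trv(a, est_a)
        tb = tm.profile_trv(b, est_b)
        assert ta.fraction == tb.fraction


class TestTRV:
    def test_pure_canonical_has_zero_noncanonical(self, small_telomere_readset):
        telo = tm.classify_reads(small_telomere_readset)
        est = tm.estimate_mtl(telo, 5.0, 46)
        trv = tm.profile_trv(telo, est)
        assert trv.noncanonical_total == 0.0

    def test_conservation_canonical_plus_variants_equals_mtl(self, spiked_telomere_readset):
        telo = tm.classify_reads(spiked_telomere_readset)
        est = tm.estimate_mtl(telo, 10.0, 92)
        trv = tm.profile_trv(telo, est)
        assert sum(trv.per_end_mean.values()) == pytest.approx(est.mtl, abs=1e-9)
        assert sum(trv.fraction.values()) == pytest.approx(1.0, abs=1e-9)

    def test_spike_recovery(self, spiked_telomere_readset):
        rs = spiked_telomere_readset
        telo = tm.classify_reads(rs)
        est = tm.estimate_mtl(telo, 10.0, 92)
        trv = tm.profile_trv(telo, est)
        uc = rs.truth["unit_counts"]
        tot = sum(len(k) * v for k, v in uc.items())
        for variant in ("TGAGGG", "TTAGGGG"):
            truth_frac = len(variant) * uc[variant] / tot
            assert trv.fraction[variant] == pytest.approx(truth_frac, abs=0.01)

    def test_variant_keys_are_edit1_neighbours(self, spiked_telomere_readset):
        telo = tm.classify_reads(spiked_telomere_readset)
        est = tm.estimate_mtl(telo, 10.0, 92)
        trv = tm.profile_trv(telo, est)
        from telomaint._tiling import build_unit_tables

        vocab = set(build_unit_tables().vocab)
        assert set(trv.fraction) <= vocab


class TestPairedDeltas:
    def _tiny_pair(self, t_ref, t_tum, seed):
        out = []
        for T, s in ((t_ref, seed), (t_tum, seed + 1)):
            prof = TelomereProfile(n_ends=16, end_lengths=float(T))
            params = SequencingParams(genome_coverage=5.0,
                                      background_genome_length=20_000, seed=s)
            out.append(simulate_telomere_readset(prof, params))
        return out

    def test_identical_readsets_give_zero_delta(self):
        ref, _ = self._tiny_pair(800, 800, 5)
        deltas, mean = tm.paired_mtl_deltas([("p", ref, ref)], {"p": (5.0, 5.0)},
                                            n_ends=16)
        assert deltas[0].delta == 0.0 and mean == 0.0

    def test_shortening_is_negative_and_antisymmetric(self):
        ref, tum = self._tiny_pair(1200, 600, 7)
        d1, m1 = tm.paired_mtl_deltas([("p", ref, tum)], {"p": (5.0, 5.0)}, n_ends=16)
        d2, m2 = tm.paired_mtl_deltas([("p", tum, ref)], {"p": (5.0, 5.0)}, n_ends=16)
        assert m1 < 0
        assert m1 == pytest.approx(-m2)

    def test_unmatched_pair_id_rejected(self):
        ref, tum = self._tiny_pair(500, 400, 9)
        with pytest.raises(ValueError, match="coverage"):
            tm.paired_mtl_deltas([("p", ref, tum)], {"q": (5.0, 5.0)}, n_ends=16)
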