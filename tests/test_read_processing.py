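import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nuccas import library_design as ld
from nuccas import read_processing as rp

from oracles import (
    best_overlap_bruteforce,
    min_edits_infix,
    quality_trim_bruteforce,
    revcomp,
)


def read_of(seq: str, qual=40) -> rp.Read:
    if isinstance(qual, int):
        qual = (qual,) * len(seq)
    return rp.Read(seq, tuple(qual))


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        r = read_of("ACGTACGT", 40)
        assert rp.quality_trim_3prime(r) == r

    def test_low_quality_tail_removed(self):
        r = rp.Read("ACGTA", (40, 40, 40, 2, 2))
        out = rp.quality_trim_3prime(r, 30)
        assert out.seq == "ACG"

    def test_uniformly_bad_read_becomes_empty(self):
        out = rp.quality_trim_3prime(read_of("ACGT", 2), 30)
        assert len(out) == 0

    @given(st.lists(st.integers(min_value=0, max_value=41), min_size=0, max_size=40))
    def test_matches_suffix_sum_oracle(self, quals):
        r = rp.Read("A" * len(quals), tuple(quals))
        out = rp.quality_trim_3prime(r, 30)
        cut = quality_trim_bruteforce(tuple(quals), 30)
        assert out.seq == r.seq[:cut]
        assert len(out) <= len(r)


def make_pair(fragment: str, start1: int, len1: int, start2: int, len2: int):
    """Reads from a fragment: r1 senses [start1, start1+len1),
    r2 is the reverse complement of [start2, start2+len2)."""
    r1 = fragment[start1 : start1 + len1]
    r2 = revcomp(fragment[start2 : start2 + len2])
    return read_of(r1), read_of(r2)


class TestMergePair:
    def test_clean_30nt_overlap(self):
        rng = random.Random(0)
        frag = "".join(rng.choice("ACGT") for _ in range(90))
        r1, r2 = make_pair(frag, 0, 60, 30, 60)
        out = rp.merge_pair(r1, r2)
        assert isinstance(out, rp.MergedRead)
        assert (len(out.seq), out.overlap_len, out.n_diffs) == (90, 30, 0)
        assert out.seq == frag

    def test_nineteen_base_overlap_is_too_short(self):
        rng = random.Random(1)
        frag = "".join(rng.choice("ACGT") for _ in range(61))
        r1, r2 = make_pair(frag, 0, 40, 21, 40)
        out = rp.merge_pair(r1, r2, min_overlap=20)
        assert out == rp.MergeRejection("too_short_overlap")

    def test_three_mismatches_in_overlap_rejected(self):
        rng = random.Random(2)
        frag = "".join(rng.choice("ACGT") for _ in range(95))
        r1, r2 = make_pair(frag, 0, 60, 35, 60)
        swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
        s2 = list(r2.seq)
        for pos in (40, 45, 50):  # inside the 25-nt overlap after revcomp
            s2[pos] = swap[s2[pos]]
        out = rp.merge_pair(r1, rp.Read("".join(s2), r2.qual))
        assert out == rp.MergeRejection("too_many_diffs")

    def test_higher_quality_base_wins_at_mismatch(self):
        r1 = rp.Read("AAAAAAAAAAAAAAAAAAAAG", (30,) * 20 + (10,))
        r2_sense = "AAAAAAAAAAAAAAAAAAAAT"
        r2 = rp.Read(revcomp(r2_sense), (35,) * 21)
        out = rp.merge_pair(r1, r2, min_overlap=20)
        assert out.seq[-1] == "T" and out.n_diffs == 1

    def test_equal_quality_mismatch_becomes_n(self):
        r1 = read_of("A" * 20 + "G", 30)
        r2 = rp.Read(revcomp("A" * 20 + "T"), (30,) * 21)
        out = rp.merge_pair(r1, r2, min_overlap=20)
        assert out.seq[-1] == "N"
        assert out.qual[-1] == 2

    def test_empty_read_is_no_overlap(self):
        out = rp.merge_pair(read_of(""), read_of("ACGT" * 10))
        assert out == rp.MergeRejection("no_overlap")

    @given(st.data())
    def test_agrees_with_exhaustive_enumeration(self, data):
        frag = data.draw(st.text(alphabet="ACGT", min_size=30, max_size=120))
        len1 = data.draw(st.integers(10, min(80, len(frag))))
        len2 = data.draw(st.integers(10, min(80, len(frag))))
        start2 = len(frag) - len2
        r1, r2 = make_pair(frag, 0, len1, start2, len2)
        # sprinkle up to 2 substitutions into r1
        n_err = data.draw(st.integers(0, 2))
        s1 = list(r1.seq)
        for _ in range(n_err):
            i = data.draw(st.integers(0, len(s1) - 1))
            s1[i] = data.draw(st.sampled_from("ACGT"))
        r1 = read_of("".join(s1))
        out = rp.merge_pair(r1, r2, min_overlap=10, max_diffs=2)
        oracle = best_overlap_bruteforce(r1.seq, revcomp(r2.seq), 10, 2)
        if oracle is None:
            assert isinstance(out, rp.MergeRejection)
        else:
            assert isinstance(out, rp.MergedRead)
            assert (out.overlap_len, out.n_diffs) == (oracle[0], oracle[1])


class TestPrimerAndLength:
    P5 = "ACGTACGTACGTACGTACGT"
    P3 = "TTGCAGGCATTGCAGGCATT"

    def test_exact_primers_removed(self):
        core = "G" * 40
        assert rp.trim_primers(self.P5 + core + self.P3, self.P5, self.P3) == core

    def test_absent_primer_leaves_sequence(self):
        seq = "G" * 40
        assert rp.trim_primers(seq, self.P5, self.P3) == seq

    def test_one_mismatch_within_error_rate_removed(self):
        p5_mut = "T" + self.P5[1:]
        core = "G" * 40
        out = rp.trim_primers(p5_mut + core + self.P3, self.P5, self.P3, 0.1)
        assert out == core

    @pytest.mark.parametrize(
        "length,keep",
        [(173, False), (174, True), (200, True), (220, True), (221, False)],
    )
    def test_length_filter_bounds_inclusive(self, length, keep):
        assert rp.length_filter("A" * length) is keep


@pytest.fixture(scope="module")
def small_library():
    rng = np.random.default_rng(17)
    return {f"m{i}": "".join(rng.choice(list("ACGT"), 230)) for i in range(8)}


class TestMatchRead:
    def test_exact_internal_window_assigned(self, small_library):
        read = small_library["m3"][20:200]
        res = rp.match_read(read, small_library)
        assert res.status == "assigned"
        assert res.member_id == "m3"
        assert res.identity == 1.0
        assert res.aligned_cols == 180

    def test_three_mismatches_in_180_is_low_identity(self, small_library):
        read = list(small_library["m3"][20:200])
        for i in (30, 90, 150):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        res = rp.match_read("".join(read), small_library)
        assert res.status == "low_identity"
        assert res.identity == pytest.approx(177 / 180)

    def test_149_column_perfect_alignment_too_short(self, small_library):
        read = small_library["m5"][40:189]
        res = rp.match_read(read, small_library, min_cols=150)
        assert res.status == "too_short_alignment"
        assert res.aligned_cols == 149

    def test_threshold_values_are_inclusive(self, small_library):
        read = list(small_library["m2"][10:210])  # 200 columns
        for i in (5, 100, 190):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        res = rp.match_read("".join(read), small_library)
        assert res.status == "assigned"  # 197/200 = 0.985 exactly
        read150 = small_library["m2"][10:160]
        assert rp.match_read(read150, small_library).status == "assigned"

    def test_tie_between_members_is_ambiguous(self):
        lib = {"a": "ACGT" * 50, "b": "ACGT" * 50 + ""}
        lib["b"] = lib["a"][:100] + "TTTT" + lib["a"][104:]
        read = lib["a"][:160]
        lib2 = {"a": lib["a"], "dup": lib["a"][:230]}
        res = rp.match_read(read, lib2)
        assert res.status == "ambiguous"

    def test_best_hit_is_edit_distance_optimal(self, toy_library):
        """Matcher's chosen member minimizes infix edit distance, verified
        against a hand-rolled dynamic program over every member."""
        rng = np.random.default_rng(23)
        members = dict(list(toy_library.sequences().items())[:12])
        members = {k: v[:160] for k, v in members.items()}
        for _ in range(6):
            source = rng.choice(list(members))
            read = list(members[source][20:140])
            for _ in range(rng.integers(0, 3)):
                i = int(rng.integers(0, len(read)))
                read[i] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            res = rp.match_read(read, members, min_identity=0.9, min_cols=100)
            dists = {m: min_edits_infix(read, seq) for m, seq in members.items()}
            best = min(dists.values())
            argmin = {m for m, d in dists.items() if d == best}
            if res.status == "assigned":
                assert res.member_id in argmin
                assert dists[res.member_id] == best


class TestCountsAndPipeline:
    def test_counts_and_rejections_conserve_total(self):
        results = (
            [rp.MatchResult("A", 1.0, 200, "assigned")] * 100
            + [rp.MatchResult(None, 0.9, 200, "low_identity")] * 7
            + [rp.MatchResult(None, 1.0, 100, "too_short_alignment")] * 3
        )
        counts, rej = rp.count_reads(results)
        assert counts == {"A": 100}
        assert sum(counts.values()) + sum(rej.values()) == 110

    def test_count_table_order_invariant(self):
        results = [
            rp.MatchResult(m, 1.0, 200, "assigned") for m in ["A", "B", "A", "C"]
        ]
        fwd, _ = rp.count_reads(results)
        rev, _ = rp.count_reads(results[::-1])
        assert fwd == rev

    def test_pipeline_conserves_input_pairs(self, toy_library, toy_params):
        from nuccas import digestion_simulator as sim

        cfg = sim.SimConfig(seed=77, n_reads=300, error_rate=0.01, n_replicates=1)
        counts_in = {m: 20 for m in list(toy_library.member_ids)[:10]}
        pairs = sim.simulate_read_pairs(
            counts_in, toy_library, cfg, np.random.default_rng(5)
        )
        counts, rej = rp.process_read_pairs(pairs, toy_library, toy_params)
        assert sum(counts.values()) + sum(rej.values()) == len(pairs)
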