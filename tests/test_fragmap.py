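import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import brute_force_map
from ceact.seqio import Read, Transcript, revcomp
from ceact.fragmap import (
    Fragment, MappingPolicy,
    build_index, fragment_reads, map_fragment, run_four_rounds,
)
from conftest import random_seq


POLICY = MappingPolicy()


def _read(seq, qual=30):
    return Read("r0", seq, tuple([qual] * len(seq)))


def _frag(seq, qual=30, fid="f0"):
    return Fragment(fid, seq, tuple([qual] * len(seq)), "A")


class TestFragmentation:
    @pytest.mark.parametrize(
        "length,expected",
        [(120, [60, 60]), (100, [60, 40]), (70, [60]), (39, []), (40, [40]), (60, [60])],
    )
    def test_cutting_rule(self, length, expected):
        frags = fragment_reads([_read("A" * length)])
        assert [len(f.seq) for f in frags] == expected

    def test_qualities_cut_in_register(self):
        r = Read("r", "ACGT" * 25, tuple(range(100)))
        f1, f2 = fragment_reads([r])
        assert f1.qual == tuple(range(60))
        assert f2.qual == tuple(range(60, 100))
        assert f1.seq + f2.seq == r.seq

    @given(st.integers(0, 400))
    @settings(deadline=None, max_examples=100)
    def test_base_conservation(self, length):
        frags = fragment_reads([_read("C" * length)])
        total = sum(len(f.seq) for f in frags)
        assert total <= length
        assert length - total < 40 or (length < 40 and total == 0)
        assert all(40 <= len(f.seq) <= 60 for f in frags)


class TestIndex:
    def test_kmer_lookup(self):
        rng = np.random.default_rng(0)
        s = random_seq(rng, 500)
        idx = build_index([Transcript("t0", s)])
        probe = s[100 : 100 + idx.k].encode()
        hits = idx.candidates(probe)
        assert (0, 100) in hits
        assert idx.candidates(b"N" * idx.k) == []


class TestMapFragment:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.ref = random_seq(rng, 2000)
        self.index = build_index([Transcript("t0", self.ref)])

    def test_verbatim_fragment_maps_at_source(self):
        frag = _frag(self.ref[300:350])
        hit = map_fragment(frag, self.index)
        assert hit is not None
        assert (hit.transcript_id, hit.position, hit.strand) == ("t0", 305, "+")
        assert hit.n_mismatches == 0

    def test_reverse_strand_fragment(self):
        frag = _frag(revcomp(self.ref[300:350]))
        hit = map_fragment(frag, self.index)
        assert hit is not None
        assert (hit.position, hit.strand) == (305, "-")
        assert hit.n_mismatches == 0

    def test_one_seed_mismatch_tolerated(self):
        s = list(self.ref[300:350])
        s[15] = {"A": "C"}.get(s[15], "A")  # inside seed after 5-base trim
        hit = map_fragment(_frag("".join(s)), self.index)
        assert hit is not None and hit.n_mismatches == 1

    def test_two_seed_mismatches_rejected(self):
        s = list(self.ref[300:350])
        for pos in (10, 20):
            s[pos] = {"A": "C"}.get(s[pos], "A")
        assert map_fragment(_frag("".join(s)), self.index) is None

    def test_quality_budget_rejects_heavy_mismatches(self):
        s = list(self.ref[300:350])
        for pos in (34, 39, 44):  # outside the 28-base seed (post-trim)
            s[pos] = {"A": "C"}.get(s[pos], "A")
        assert map_fragment(_frag("".join(s), qual=30), self.index) is None  # 90 > 70
        hit = map_fragment(_frag("".join(s), qual=20), self.index)  # 60 <= 70
        assert hit is not None and hit.n_mismatches == 3

    def test_too_short_fragment_unmapped(self):
        assert map_fragment(_frag("ACGTACGTAC"), self.index) is None

    def test_duplicate_placement_tie_broken_by_position(self):
        block = self.ref[100:160]
        ref2 = self.ref[:1000] + block + self.ref[1000:]
        idx = build_index([Transcript("t0", ref2)])
        hit = map_fragment(_frag(block), idx)
        assert hit.position == 105
        assert hit.n_ties >= 1

    def test_agreement_with_exhaustive_scan(self):
        rng = np.random.default_rng(2)
        transcripts = [("t%02d" % i, random_seq(rng, 500)) for i in range(10)]
        index = build_index([Transcript(tid, s) for tid, s in transcripts])
        for trial in range(200):
            tid, src = transcripts[rng.integers(len(transcripts))]
            start = int(rng.integers(0, len(src) - 55))
            s = list(src[start : start + 55])
            for _ in range(rng.integers(0, 4)):  # 0-3 substitutions
                p = int(rng.integers(len(s)))
                s[p] = "ACGT"[rng.integers(4)]
            if rng.random() < 0.5:
                s = list(revcomp("".join(s)))
            if rng.random() < 0.1:
                s = list(random_seq(rng, 55))
            qual = tuple(int(q) for q in rng.integers(10, 41, size=len(s)))
            frag = Fragment("f", "".join(s), qual, "A")
            expected = brute_force_map(frag.seq, frag.qual, transcripts, POLICY)
            got = map_fragment(frag, index)
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert (got.transcript_id, got.position, got.strand,
                        got.n_mismatches, got.qual_mismatch_sum) == expected


class TestFourRounds:
    def _reads(self, rng, ref, n, pop):
        out = []
        for i in range(n):
            start = int(rng.integers(0, len(ref) - 120))
            out.append(Read(f"{pop}r{i}", ref[start : start + 120],
                            tuple([35] * 120), pop))
        return out

    def test_identical_inputs_give_identical_rounds(self):
        rng = np.random.default_rng(3)
        cons = [Transcript(f"pair{i:06d}", random_seq(rng, 400)) for i in range(3)]
        genome = "".join(t.seq for t in cons)
        reads = self._reads(rng, genome, 50, "A")
        rounds = run_four_rounds(reads, reads, cons, cons)
        assert all(r.counts == rounds[0].counts for r in rounds)
        assert all(r.total_mapped == rounds[0].total_mapped for r in rounds)

    def test_empty_population_b(self):
        rng = np.random.default_rng(4)
        cons = [Transcript("pair000000", random_seq(rng, 400))]
        reads = self._reads(rng, cons[0].seq, 20, "A")
        rounds = run_four_rounds(reads, [], cons, cons)
        assert rounds[2].total_mapped == 0 and rounds[3].total_mapped == 0
        assert rounds[0].total_mapped > 0

    def test_pair_id_mismatch_rejected(self):
        a = [Transcript("pair000000", "A" * 100)]
        b = [Transcript("pair000001", "A" * 100)]
        with pytest.raises(ValueError):
            run_four_rounds([], [], a, b)

    def test_perfect_remap_without_noise(self):
        rng = np.random.default_rng(5)
        cons = [Transcript(f"pair{i:06d}", random_seq(rng, 600)) for i in range(3)]
        reads = []
        for i, t in enumerate(cons):
            for j in range(10):
                start = int(rng.integers(0, len(t.seq) - 100))
                reads.append(Read(f"A{i}_{j}", t.seq[start : start + 100],
                                  tuple([35] * 100), "A"))
        rounds = run_four_rounds(reads, [], cons, cons)
        assert rounds[0].remap_fraction == 1.0


class TestSamOutput:
    def test_sam_readable_by_pysam(self, tmp_path):
        import pysam
        rng = np.random.default_rng(6)
        cons = [Transcript("pair000000", random_seq(rng, 400))]
        frags = [_frag(cons[0].seq[50:100], fid="fA"),
                 _frag(revcomp(cons[0].seq[200:250]), fid="fB")]
        idx = build_index(cons)
        hits = [map_fragment(f, idx) for f in frags]
        assert all(h is not None for h in hits)
        sam = tmp_path / "out.sam"
        from ceact.fragmap import write_sam
        write_sam(hits, frags, cons, sam)
        with pysam.AlignmentFile(str(sam)) as fh:
            recs = list(fh)
        assert [r.query_name for r in recs] == ["fA", "fB"]
        assert recs[0].reference_start == 55
        assert not recs[0].is_reverse and recs[1].is_reverse
        assert all(r.cigarstring == "40M" for r in recs)
        assert all(r.get_tag("NM") == 0 for r in recs)
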