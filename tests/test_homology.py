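import math

import numpy as np
import pytest

from _oracles import sw_affine_score
from ceact.seqio import Transcript, revcomp
from ceact.homology import (
    HomologyHit, ScoringScheme,
    bit_score, build_conversion_table, evalue, extract_consensus,
    highest_scoring_window, karlin_lambda, local_align,
)
from conftest import random_seq


SCORING = ScoringScheme()


class TestLocalAlign:
    def test_perfect_match(self):
        rng = np.random.default_rng(0)
        s = random_seq(rng, 100)
        hit = [h for h in local_align(s, s) if h.strand == "+"][0]
        assert hit.raw_score == 100
        assert hit.identity == 1.0
        assert hit.query_interval == (0, 100)
        assert hit.target_interval == (0, 100)

    def test_single_mismatch_score(self):
        hits = local_align("ACGTACGT", "ACGTTCGT")
        plus = [h for h in hits if h.strand == "+"][0]
        assert plus.raw_score == 5  # 7 matches - 1 mismatch * 2
        assert plus.identity == 7 / 8

    def test_reverse_complement_hit(self):
        rng = np.random.default_rng(1)
        s = random_seq(rng, 80)
        hits = local_align(s, revcomp(s))
        minus = [h for h in hits if h.strand == "-"][0]
        assert minus.identity == 1.0
        assert minus.raw_score == 80

    def test_scores_match_reference_dp_on_mutated_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            q = random_seq(rng, int(rng.integers(30, 150)))
            t = list(q)
            for i in range(len(t)):
                if rng.random() < 0.1:
                    t[i] = "ACGT"[rng.integers(4)]
            t = "".join(t)
            expected = sw_affine_score(q, t)
            plus = [h for h in local_align(q, t) if h.strand == "+"]
            got = plus[0].raw_score if plus else 0
            assert got == expected


class TestEvalue:
    def test_lambda_solves_karlin_altschul_identity(self):
        lam = karlin_lambda(SCORING)
        p_match, p_mis = 0.25, 0.75
        resid = p_match * math.exp(lam * 1) + p_mis * math.exp(lam * -2) - 1.0
        assert abs(resid) < 1e-10

    def test_zero_score_never_significant(self):
        assert evalue(0, 500, 100_000, SCORING) >= 1.0

    def test_linear_in_search_space(self):
        e1 = evalue(100, 500, 10_000, SCORING)
        e2 = evalue(100, 500, 20_000, SCORING)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_monotone_decreasing_and_bit_linear(self):
        es = [evalue(s, 500, 10_000, SCORING) for s in range(0, 200, 10)]
        assert all(a > b for a, b in zip(es, es[1:]))
        b1, b2, b3 = (bit_score(s, SCORING) for s in (10, 20, 30))
        assert b3 - b2 == pytest.approx(b2 - b1, rel=1e-9)


class TestConversionTable:
    def test_identical_transcriptomes_self_pair(self):
        rng = np.random.default_rng(3)
        ts_a = [Transcript(f"a{i}", random_seq(rng, 400), "A") for i in range(8)]
        ts_b = [Transcript(f"b{i}", t.seq, "B") for i, t in enumerate(ts_a)]
        table = build_conversion_table(ts_a, ts_b)
        assert len(table) == 8
        assert all(ida[1:] == idb[1:] for ida, idb, _ in table)

    def test_unrelated_transcript_excluded(self):
        rng = np.random.default_rng(4)
        ts_a = [Transcript("a0", random_seq(rng, 400), "A"),
                Transcript("orphan", random_seq(rng, 500), "A")]
        ts_b = [Transcript("b0", ts_a[0].seq, "B")]
        table = build_conversion_table(ts_a, ts_b)
        assert [(ida, idb) for ida, idb, _ in table] == [("a0", "b0")]

    def test_diverged_pair_recovered(self):
        rng = np.random.default_rng(5)
        a = random_seq(rng, 1000)
        b = "".join(
            c if rng.random() > 0.05 else "ACGT"[rng.integers(4)] for c in a
        )
        table = build_conversion_table(
            [Transcript("a0", a, "A")], [Transcript("b0", b, "B")]
        )
        assert len(table) == 1
        assert table[0][2].e_value <= 1e-20

    def test_symmetric_under_population_swap(self):
        rng = np.random.default_rng(6)
        ts_a, ts_b = [], []
        for i in range(6):
            s = random_seq(rng, 500)
            m = "".join(c if rng.random() > 0.03 else "ACGT"[rng.integers(4)] for c in s)
            ts_a.append(Transcript(f"a{i}", s, "A"))
            ts_b.append(Transcript(f"b{i}", m, "B"))
        fwd = {(x, y) for x, y, _ in build_conversion_table(ts_a, ts_b)}
        rev = {(y, x) for x, y, _ in build_conversion_table(ts_b, ts_a)}
        assert fwd == rev


class TestWindowAndConsensus:
    def _hit(self, score, qiv=(0, 50), tiv=(0, 50), strand="+"):
        return HomologyHit("q", "t", qiv, tiv, strand, score,
                           bit_score(score, SCORING), 1e-30, 1.0)

    def test_highest_scoring_window(self):
        h1, h2 = self._hit(120), self._hit(80)
        assert highest_scoring_window([h1, h2]) is h1
        assert highest_scoring_window([h2]) is h2
        long, short = self._hit(100, (0, 100)), self._hit(100, (20, 80))
        assert highest_scoring_window([short, long]) is long
        with pytest.raises(ValueError):
            highest_scoring_window([])

    def test_identical_transcriptomes_full_length_consensus(self):
        rng = np.random.default_rng(7)
        ts_a = [Transcript(f"a{i}", random_seq(rng, 300), "A") for i in range(4)]
        ts_b = [Transcript(f"b{i}", t.seq, "B") for i, t in enumerate(ts_a)]
        table = build_conversion_table(ts_a, ts_b)
        cons_a, cons_b, pairs = extract_consensus(table, ts_a, ts_b)
        assert [t.seq for t in cons_a] == [t.seq for t in ts_a]
        assert [t.seq for t in cons_b] == [t.seq for t in ts_a]
        assert all(p.identity == 1.0 for p in pairs)

    def test_minus_strand_consensus_forward_normalised(self):
        rng = np.random.default_rng(8)
        s = random_seq(rng, 400)
        ts_a = [Transcript("a0", s, "A")]
        ts_b = [Transcript("b0", revcomp(s), "B")]
        table = build_conversion_table(ts_a, ts_b)
        assert table[0][2].strand == "-"
        cons_a, cons_b, pairs = extract_consensus(table, ts_a, ts_b)
        assert cons_a[0].seq == cons_b[0].seq == s

    def test_consensus_lengths_match_intervals(self, demo_dataset):
        for p in demo_dataset["result"]["pairs"]:
            assert len(p.seq_A) == p.interval_A[1] - p.interval_A[0]
            assert len(p.seq_B) == p.interval_B[1] - p.interval_B[0]
            assert p.pair_id == p.pair_id.strip()
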