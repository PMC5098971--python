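"""Read fragmentation and mismatch-tolerant ungapped mapping.

Long pyrosequencing reads are cut into 40-60 nt fragments (greedy
left-to-right: consecutive 60-mers, a final remainder >= 40 nt kept,
shorter remainders dropped) and mapped end-to-end, without gaps, onto a
consensus transcriptome.

The mapping policy emulates a Bowtie1-style ``-n 1 -5 5 -3 5`` invocation:
5 bases are trimmed from each fragment end, at most one mismatch is
tolerated in the first 28 post-trim bases (the seed), and the Phred
qualities of all mismatched bases across the placement may sum to at most
70.  Among the placements satisfying the policy the fragment is assigned
to the single best one, under a total deterministic order: fewest
mismatches, then lowest quality-mismatch sum, then smallest transcript id,
then smallest offset, then plus strand.

Candidate placements are generated by exact lookup of two disjoint
half-seed blocks in a k-mer index: any placement with <= 1 seed mismatch
leaves at least one block exact (pigeonhole), so the index enumerates
every placement the policy could accept.  Reverse-strand placements
compare the fragment's reverse complement against the forward reference;
the seed stays anchored at the fragment's own 5' end.  ``N`` never matches
anything, including ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import Read, Transcript

__all__ = [
    "Fragment",
    "MappingPolicy",
    "FragmentHit",
    "RoundCounts",
    "fragment_reads",
    "ConsensusIndex",
    "build_index",
    "map_fragment",
    "map_fragments",
    "run_four_rounds",
    "write_sam",
    "write_count_table",
]

_N = ord("N")
_COMP = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP[_x] = _y

ROUND_DESCRIPTIONS = {
    1: "population-A reads on population-A consensus",
    2: "population-A reads on population-B consensus",
    3: "population-B reads on population-B consensus",
    4: "population-B reads on population-A consensus",
}


@dataclass(frozen=True)
class Fragment:
    """A 40-60 nt slice of a read, named parent id + ordinal."""

    id: str
    seq: str
    qual: tuple[int, ...]
    population: str


@dataclass(frozen=True)
class MappingPolicy:
    trim5: int = 5
    trim3: int = 5
    seed_len: int = 28
    max_seed_mismatches: int = 1
    max_qual_mismatch_sum: int = 70

    def __post_init__(self) -> None:
        if min(self.trim5, self.trim3, self.seed_len,
               self.max_seed_mismatches, self.max_qual_mismatch_sum) < 0:
            raise ValueError("mapping policy fields must be non-negative")


@dataclass(frozen=True)
class FragmentHit:
    fragment_id: str
    transcript_id: str
    position: int          # 0-based offset of the (trimmed) placement
    strand: str
    n_mismatches: int
    qual_mismatch_sum: int
    aligned_len: int = 0
    n_ties: int = 0        # co-optimal placements under the tie order


@dataclass
class RoundCounts:
    """Mapped-fragment tally for one of the four mapping rounds."""

    round_id: int
    reference: str                 # "A" or "B" consensus
    population: str                # population whose fragments were mapped
    counts: dict[str, int]         # pair_id -> mapped fragments
    total_mapped: int
    n_fragments: int
    n_tied: int = 0

    @property
    def remap_fraction(self) -> float:
        return self.total_mapped / self.n_fragments if self.n_fragments else float("nan")


def fragment_reads(
    reads: Iterable[Read], max_len: int = 60, min_len: int = 40
) -> list[Fragment]:
    """Cut quality-trimmed reads into consecutive max_len pieces.

    A final remainder of at least *min_len* is kept; anything shorter is
    dropped, so every fragment length lies in [min_len, max_len].
    """
    if not min_len <= max_len:
        raise ValueError("need min_len <= max_len")
    out: list[Fragment] = []
    for read in reads:
        n = len(read.seq)
        k = 0
        for start in range(0, n - min_len + 1, max_len):
            end = min(start + max_len, n)
            out.append(
                Fragment(
                    f"{read.id}/f{k}",
                    read.seq[start:end],
                    read.qual[start:end],
                    read.population,
                )
            )
            k += 1
    return out


class ConsensusIndex:
    """Exact k-mer lookup over a consensus transcriptome (forward strand).

    k is half the seed length; minus-strand placements are found by looking
    up blocks of the fragment's reverse complement, so only the forward
    reference needs indexing.  Rebuilding from the same transcriptome is
    deterministic.
    """

    def __init__(self, transcripts: Sequence[Transcript], policy: MappingPolicy = MappingPolicy()):
        if not transcripts:
            raise ValueError("cannot index an empty transcriptome")
        self.policy = policy
        self.k = max(1, policy.seed_len // 2)
        self.ids = [t.id for t in transcripts]
        self.arrays = [
            np.frombuffer(t.seq.encode("ascii"), dtype=np.uint8) for t in transcripts
        ]
        # transcript order for tie-breaking is lexicographic id order
        self._rank = np.argsort(np.array(self.ids, dtype=object), kind="stable")
        self._id_rank = {self.ids[i]: r for r, i in enumerate(self._rank)}
        self._lookup: dict[bytes, list[tuple[int, int]]] = {}
        k = self.k
        for ti, arr in enumerate(self.arrays):
            b = arr.tobytes()
            for pos in range(len(b) - k + 1):
                self._lookup.setdefault(b[pos : pos + k], []).append((ti, pos))

    def candidates(self, kmer: bytes) -> list[tuple[int, int]]:
        return self._lookup.get(kmer, [])


def build_index(
    consensus: Sequence[Transcript], policy: MappingPolicy = MappingPolicy()
) -> ConsensusIndex:
    return ConsensusIndex(consensus, policy)


def _evaluate_placement(
    ref: np.ndarray,
    pos: int,
    frag: np.ndarray,
    qual: np.ndarray,
    seed_mask: np.ndarray,
    policy: MappingPolicy,
) -> tuple[int, int] | None:
    """Apply the policy to one ungapped end-to-end placement.

    *frag*/*qual*/*seed_mask* are in reference orientation.  Returns
    (n_mismatches, qual_mismatch_sum) or None if rejected.
    """
    L = len(frag)
    if pos < 0 or pos + L > len(ref):
        return None
    window = ref[pos : pos + L]
    mism = (window != frag) | (window == _N) | (frag == _N)
    if int(np.count_nonzero(mism & seed_mask)) > policy.max_seed_mismatches:
        return None
    qsum = int(qual[mism].sum())
    if qsum > policy.max_qual_mismatch_sum:
        return None
    return int(np.count_nonzero(mism)), qsum


def _oriented(
    frag: np.ndarray, qual: np.ndarray, seed_mask: np.ndarray, strand: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if strand == "+":
        return frag, qual, seed_mask
    return _COMP[frag][::-1], qual[::-1], seed_mask[::-1]


def map_fragment(
    fragment: Fragment, index: ConsensusIndex, policy: MappingPolicy | None = None
) -> FragmentHit | None:
    """Best placement of one fragment, or None if unmapped.

    The seed (first ``seed_len`` post-trim bases, fragment orientation) may
    contain at most ``max_seed_mismatches`` mismatches and the placement's
    quality-weighted mismatch sum at most ``max_qual_mismatch_sum``; ties
    are broken by mismatches, quality sum, transcript id, offset, strand.
    """
    if policy is None:
        policy = index.policy
    t5, t3 = policy.trim5, policy.trim3
    if len(fragment.seq) < t5 + t3 + 1:
        return None
    seq = fragment.seq[t5 : len(fragment.seq) - t3 if t3 else None]
    frag = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    qual = np.asarray(fragment.qual[t5 : len(fragment.qual) - t3 if t3 else None], dtype=np.int64)
    L = len(frag)
    seed_span = min(policy.seed_len, L)
    seed_mask = np.zeros(L, dtype=bool)
    seed_mask[:seed_span] = True
    k = index.k

    oriented = {st: _oriented(frag, qual, seed_mask, st) for st in "+-"}

    # candidate generation: two disjoint k-blocks inside the seed, on each strand
    cand: set[tuple[int, int, str]] = set()
    if seed_span >= 2 * k and policy.max_seed_mismatches <= 1:
        for strand in "+-":
            b = oriented[strand][0].tobytes()
            # seed occupies the first seed_span fragment bases; in reference
            # orientation that is the leftmost (strand +) or rightmost
            # (strand -) seed_span bases of the placement
            offs = (0, k) if strand == "+" else (L - seed_span, L - seed_span + k)
            for off in offs:
                for ti, pos in index.candidates(b[off : off + k]):
                    cand.add((ti, pos - off, strand))
    else:
        # degenerate policy (short seed or >1 seed mismatch): exhaustive scan
        for strand in "+-":
            for ti, ref in enumerate(index.arrays):
                for pos in range(len(ref) - L + 1):
                    cand.add((ti, pos, strand))

    best: tuple | None = None
    best_hit: FragmentHit | None = None
    n_ties = 0
    for ti, pos, strand in sorted(cand):
        s, q, m = oriented[strand]
        res = _evaluate_placement(index.arrays[ti], pos, s, q, m, policy)
        if res is None:
            continue
        nm, qsum = res
        key = (nm, qsum, index._id_rank[index.ids[ti]], pos, 0 if strand == "+" else 1)
        if best is None or key < best:
            if best is not None and key[:2] == best[:2]:
                n_ties += 1
            else:
                n_ties = 0
            best = key
            best_hit = FragmentHit(
                fragment.id, index.ids[ti], pos, strand, nm, qsum, aligned_len=L
            )
        elif key[:2] == best[:2]:
            n_ties += 1
    if best_hit is not None and n_ties:
        best_hit = FragmentHit(
            best_hit.fragment_id, best_hit.transcript_id, best_hit.position,
            best_hit.strand, best_hit.n_mismatches, best_hit.qual_mismatch_sum,
            best_hit.aligned_len, n_ties,
        )
    return best_hit


def map_fragments(
    fragments: Iterable[Fragment],
    index: ConsensusIndex,
    policy: MappingPolicy | None = None,
) -> list[FragmentHit]:
    hits = []
    for frag in fragments:
        h = map_fragment(frag, index, policy)
        if h is not None:
            hits.append(h)
    return hits


def _count_round(
    round_id: int,
    fragments: Sequence[Fragment],
    index: ConsensusIndex,
    reference: str,
    population: str,
    policy: MappingPolicy,
) -> RoundCounts:
    counts = {tid: 0 for tid in index.ids}
    n_tied = 0
    total = 0
    for frag in fragments:
        h = map_fragment(frag, index, policy)
        if h is None:
            continue
        counts[h.transcript_id] += 1
        total += 1
        if h.n_ties:
            n_tied += 1
    return RoundCounts(round_id, reference, population, counts, total, len(fragments), n_tied)


def run_four_rounds(
    reads_a: Sequence[Read],
    reads_b: Sequence[Read],
    consensus_a: Sequence[Transcript],
    consensus_b: Sequence[Transcript],
    policy: MappingPolicy = MappingPolicy(),
    max_len: int = 60,
    min_len: int = 40,
) -> list[RoundCounts]:
    """The four mapping rounds of the consensus quantification step.

    Round 1: A reads on A consensus; round 2: A reads on B consensus;
    round 3: B reads on B consensus; round 4: B reads on A consensus.
    Counts are keyed by pair id (the consensus transcript ids), which both
    consensus sets share, so rounds over different references are
    commensurable.
    """
    ids_a = {t.id for t in consensus_a}
    ids_b = {t.id for t in consensus_b}
    if ids_a != ids_b:
        raise ValueError("consensus sets are not paired: pair_id mismatch")
    frags_a = fragment_reads(reads_a, max_len, min_len)
    frags_b = fragment_reads(reads_b, max_len, min_len)
    idx_a = ConsensusIndex(consensus_a, policy)
    idx_b = ConsensusIndex(consensus_b, policy)
    return [
        _count_round(1, frags_a, idx_a, "A", "A", policy),
        _count_round(2, frags_a, idx_b, "B", "A", policy),
        _count_round(3, frags_b, idx_b, "B", "B", policy),
        _count_round(4, frags_b, idx_a, "A", "B", policy),
    ]


def write_sam(
    hits: Sequence[FragmentHit],
    fragments: Sequence[Fragment],
    consensus: Sequence[Transcript],
    path: str | Path,
    policy: MappingPolicy = MappingPolicy(),
) -> None:
    """Emit mapped fragments as SAM (ungapped CIGAR, NM = mismatches)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": t.id, "LN": len(t.seq)} for t in consensus],
    }
    tid_of = {t.id: i for i, t in enumerate(consensus)}
    frag_of = {f.id: f for f in fragments}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for h in hits:
            f = frag_of[h.fragment_id]
            t5 = policy.trim5
            seq = f.seq[t5 : len(f.seq) - policy.trim3 if policy.trim3 else None]
            qual = f.qual[t5 : len(f.qual) - policy.trim3 if policy.trim3 else None]
            if h.strand == "-":
                seq = seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
                qual = qual[::-1]
            a = pysam.AlignedSegment()
            a.query_name = h.fragment_id
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in qual)
            )
            a.reference_id = tid_of[h.transcript_id]
            a.reference_start = h.position
            a.cigarstring = f"{len(seq)}M"
            a.flag = 16 if h.strand == "-" else 0
            a.mapping_quality = 255
            a.set_tag("NM", h.n_mismatches)
            out.write(a)


def write_count_table(rounds: Sequence[RoundCounts], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tround\tcount\n")
        for rc in rounds:
            for pid in sorted(rc.counts):
                fh.write(f"{pid}\t{rc.round_id}\t{rc.counts[pid]}\n")
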