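"""Homolog pairing and consensus-transcriptome construction.

The two populations' transcriptomes were assembled independently, so there
is no shared reference to quantify against.  This module builds one: every
transcript of population A is searched against population B with local
(Smith-Waterman) alignment on both strands, significant matches are turned
into a conversion table of reciprocal-best homolog pairs, and for each pair
the highest-scoring alignment window is cut out of both transcripts.  The
two resulting sets of matched windows — the *consensus transcriptomes* —
are coordinate-compatible per pair and serve as the mapping references for
the four quantification rounds.

Alignment significance uses the ungapped Karlin-Altschul statistic
``E = m * n * 2**(-bit score)`` with ``bit = (lambda*S - ln K) / ln 2``;
``lambda`` is solved numerically from the identity
``sum_ij p_i p_j exp(lambda * s_ij) = 1`` at the configured background base
composition, so any match/mismatch scheme stays self-consistent.  The K
constant is taken from the standard ungapped nucleotide table where known
(0.621 for +1/-2) with a conservative fallback otherwise; at the default
cutoff of 1e-20 the pairing decision is insensitive to K.

Alignment itself is delegated to Biopython's C Smith-Waterman
(``Bio.Align.PairwiseAligner``) with affine gap costs; a gap of length L
costs ``gap_open + gap_extend * L``.  ``N`` matches nothing, including
another ``N``.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .seqio import Transcript, revcomp

__all__ = [
    "ScoringScheme",
    "HomologyHit",
    "ConsensusPair",
    "local_align",
    "evalue",
    "bit_score",
    "karlin_lambda",
    "build_conversion_table",
    "highest_scoring_window",
    "extract_consensus",
    "write_conversion_table",
    "consensus_fasta_records",
]

# Tabulated ungapped K for standard nucleotide schemes (match, mismatch).
_K_TABLE = {(1, -2): 0.621, (1, -3): 0.711, (1, -4): 0.738, (2, -3): 0.41}
_K_FALLBACK = 0.3

_UNIFORM = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class ScoringScheme:
    """Nucleotide scoring: positive match, negative mismatch, affine gaps."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    background: tuple[float, float, float, float] = _UNIFORM  # p(A), p(C), p(G), p(T)

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap costs must be positive")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")


@dataclass(frozen=True)
class HomologyHit:
    """One scored local-alignment window between two transcripts.

    Intervals are 0-based half-open on the forward strand of each sequence;
    ``strand`` is the orientation of the target relative to the query.
    ``identity`` is the fraction of aligned columns (gap columns included)
    that match.
    """

    query_id: str
    target_id: str
    query_interval: tuple[int, int]
    target_interval: tuple[int, int]
    strand: str
    raw_score: int
    bit_score: float
    e_value: float
    identity: float


@dataclass(frozen=True)
class ConsensusPair:
    """The matched homologous windows of one reciprocal-best pair.

    ``seq_B`` is stored on the A-relative forward strand (reverse
    complemented when the underlying hit was on the minus strand).
    """

    pair_id: str
    id_A: str
    id_B: str
    seq_A: str
    seq_B: str
    interval_A: tuple[int, int]
    interval_B: tuple[int, int]
    strand: str
    identity: float
    raw_score: int


# --- Karlin-Altschul statistics -------------------------------------------

_lambda_cache: dict[tuple, float] = {}


def karlin_lambda(scoring: ScoringScheme) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0."""
    key = (scoring.match, scoring.mismatch, scoring.background)
    if key in _lambda_cache:
        return _lambda_cache[key]
    p = scoring.background
    p_match = sum(x * x for x in p)
    p_mis = 1.0 - p_match

    def f(lam: float) -> float:
        return p_match * math.exp(lam * scoring.match) + p_mis * math.exp(
            lam * scoring.mismatch
        ) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    lam = float(brentq(f, 1e-9, hi, xtol=1e-14, rtol=1e-15))
    _lambda_cache[key] = lam
    return lam


def karlin_k(scoring: ScoringScheme) -> float:
    return _K_TABLE.get((scoring.match, scoring.mismatch), _K_FALLBACK)


def bit_score(raw_score: float, scoring: ScoringScheme) -> float:
    lam = karlin_lambda(scoring)
    return (lam * raw_score - math.log(karlin_k(scoring))) / math.log(2.0)


def evalue(
    raw_score: float,
    query_len: int,
    db_total_len: int,
    scoring: ScoringScheme,
) -> float:
    """Expected number of chance local alignments scoring >= raw_score."""
    if raw_score < 0:
        raise ValueError("raw_score must be >= 0")
    return query_len * db_total_len * 2.0 ** (-bit_score(raw_score, scoring))


# --- pairwise alignment ---------------------------------------------------

_aligner_cache: dict[tuple, Align.PairwiseAligner] = {}


def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    key = (scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend)
    if key in _aligner_cache:
        return _aligner_cache[key]
    mat = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            mat[a, b] = scoring.match if a == b else scoring.mismatch
    for a in "ACGTN":  # N matches nothing, not even N
        mat[a, "N"] = scoring.mismatch
        mat["N", a] = scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    _aligner_cache[key] = aligner
    return aligner


def _align_one_strand(
    query: str, target: str, scoring: ScoringScheme
) -> tuple[int, tuple[int, int], tuple[int, int], float] | None:
    """Optimal local alignment on the given (forward) orientation.

    Returns (raw_score, query interval, target interval, identity) or None
    when the optimal local score is 0 (empty alignment).
    """
    aligner = _aligner(scoring)
    score = aligner.score(query, target)
    if score <= 0:
        return None
    aln = aligner.align(query, target)[0]
    qblocks, tblocks = aln.aligned
    qs, qe = int(qblocks[0][0]), int(qblocks[-1][1])
    ts, te = int(tblocks[0][0]), int(tblocks[-1][1])
    counts = aln.counts()
    ncols = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / ncols if ncols else 0.0
    return int(score), (qs, qe), (ts, te), identity


def local_align(
    query: Transcript | str,
    target: Transcript | str,
    scoring: ScoringScheme = ScoringScheme(),
    query_id: str = "query",
    target_id: str = "target",
) -> list[HomologyHit]:
    """Smith-Waterman local alignment of query vs target on both strands.

    Returns the optimal local alignment per strand (at most two hits, plus
    strand first), each with traceback coordinates, identity and raw score.
    The reported E-value treats the single target as the whole database;
    `build_conversion_table` rescales against the full transcriptome.
    """
    if isinstance(query, Transcript):
        query_id, query = query.id, query.seq
    if isinstance(target, Transcript):
        target_id, target = target.id, target.seq
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    hits: list[HomologyHit] = []
    for strand in "+-":
        t = target if strand == "+" else revcomp(target)
        res = _align_one_strand(query, t, scoring)
        if res is None:
            continue
        score, qiv, tiv, identity = res
        if strand == "-":
            tiv = (len(target) - tiv[1], len(target) - tiv[0])
        hits.append(
            HomologyHit(
                query_id=query_id,
                target_id=target_id,
                query_interval=qiv,
                target_interval=tiv,
                strand=strand,
                raw_score=score,
                bit_score=bit_score(score, scoring),
                e_value=evalue(score, len(query), len(target), scoring),
                identity=identity,
            )
        )
    return hits


def highest_scoring_window(hits: Sequence[HomologyHit]) -> HomologyHit:
    """The hit with maximal raw score.

    Ties go to the longer query interval, then the smaller query start.
    """
    if not hits:
        raise ValueError("no hits to choose from")
    return max(
        hits,
        key=lambda h: (
            h.raw_score,
            h.query_interval[1] - h.query_interval[0],
            -h.query_interval[0],
        ),
    )


# --- conversion table -----------------------------------------------------


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def build_conversion_table(
    transcripts_a: Sequence[Transcript],
    transcripts_b: Sequence[Transcript],
    scoring: ScoringScheme = ScoringScheme(),
    e_cutoff: float = 1e-20,
    word_size: int = 11,
    min_word_hits: int = 3,
) -> list[tuple[str, str, HomologyHit]]:
    """Reciprocal-best homolog pairs between the two transcriptomes.

    Candidate pairs sharing at least *min_word_hits* exact words of
    *word_size* nt (either strand) are scored by Smith-Waterman; a pair is
    eligible when its E-value passes *e_cutoff* in both search directions
    (query length x database total length).  Each transcript's best-scoring
    eligible partner is computed (ties: higher raw score, then smaller id)
    and only reciprocal-best pairs are retained, giving the one-to-one
    conversion table.  Transcripts without a significant reciprocal match
    are excluded.  Set ``min_word_hits=0`` to disable the word prescreen
    and score every pair.
    """
    if not transcripts_a or not transcripts_b:
        raise ValueError("both transcriptomes must be non-empty")
    total_a = sum(len(t) for t in transcripts_a)
    total_b = sum(len(t) for t in transcripts_b)

    if min_word_hits > 0:
        index: dict[str, list[int]] = {}
        for j, tb in enumerate(transcripts_b):
            for w in _kmer_set(tb.seq, word_size):
                index.setdefault(w, []).append(j)
        candidates: list[tuple[int, int]] = []
        for i, ta in enumerate(transcripts_a):
            counter: Counter[int] = Counter()
            words = _kmer_set(ta.seq, word_size) | _kmer_set(revcomp(ta.seq), word_size)
            for w in words:
                for j in index.get(w, ()):
                    counter[j] += 1
            candidates.extend((i, j) for j, c in counter.items() if c >= min_word_hits)
    else:
        candidates = [
            (i, j) for i in range(len(transcripts_a)) for j in range(len(transcripts_b))
        ]

    aligner = _aligner(scoring)
    eligible: dict[tuple[int, int], int] = {}
    for i, j in candidates:
        qa, qb = transcripts_a[i].seq, transcripts_b[j].seq
        score = max(aligner.score(qa, qb), aligner.score(qa, revcomp(qb)))
        if score <= 0:
            continue
        e_ab = evalue(score, len(qa), total_b, scoring)
        e_ba = evalue(score, len(qb), total_a, scoring)
        if max(e_ab, e_ba) <= e_cutoff:
            eligible[(i, j)] = int(score)

    def best(partners: dict[int, list[tuple[int, int]]], ids: Sequence[Transcript]):
        out = {}
        for k, cands in partners.items():
            out[k] = min(cands, key=lambda sj: (-sj[0], ids[sj[1]].id))[1]
        return out

    by_a: dict[int, list[tuple[int, int]]] = {}
    by_b: dict[int, list[tuple[int, int]]] = {}
    for (i, j), score in eligible.items():
        by_a.setdefault(i, []).append((score, j))
        by_b.setdefault(j, []).append((score, i))
    best_a = best(by_a, transcripts_b)
    best_b = best(by_b, transcripts_a)

    table: list[tuple[str, str, HomologyHit]] = []
    for i, j in sorted(best_a.items()):
        if best_b.get(j) != i:
            continue
        ta, tb = transcripts_a[i], transcripts_b[j]
        hits = local_align(ta, tb, scoring)
        hit = highest_scoring_window(hits)
        hit = dataclasses.replace(
            hit, e_value=evalue(hit.raw_score, len(ta), total_b, scoring)
        )
        table.append((ta.id, tb.id, hit))
    table.sort(key=lambda row: row[0])
    return table


def extract_consensus(
    conversion_table: Sequence[tuple[str, str, HomologyHit]],
    transcripts_a: Sequence[Transcript],
    transcripts_b: Sequence[Transcript],
) -> tuple[list[Transcript], list[Transcript], list[ConsensusPair]]:
    """Cut each pair's alignment window out of both source transcripts.

    The extracted region is the contiguous source substring spanned by the
    alignment (gap columns do not split the window).  Minus-strand windows
    are reverse complemented on the B side so both members of a pair are on
    the same (A-relative forward) strand.  Consensus transcripts are keyed
    by pair id, so the two sets are positionally paired.
    """
    seq_a = {t.id: t.seq for t in transcripts_a}
    seq_b = {t.id: t.seq for t in transcripts_b}
    cons_a: list[Transcript] = []
    cons_b: list[Transcript] = []
    pairs: list[ConsensusPair] = []
    for n, (id_a, id_b, hit) in enumerate(conversion_table):
        qs, qe = hit.query_interval
        ts, te = hit.target_interval
        wa = seq_a[id_a][qs:qe]
        wb = seq_b[id_b][ts:te]
        if hit.strand == "-":
            wb = revcomp(wb)
        if not wa or not wb:
            raise ValueError(f"empty consensus window for pair ({id_a}, {id_b})")
        pair_id = f"pair{n:06d}"
        cons_a.append(Transcript(pair_id, wa, "A"))
        cons_b.append(Transcript(pair_id, wb, "B"))
        pairs.append(
            ConsensusPair(
                pair_id=pair_id,
                id_A=id_a,
                id_B=id_b,
                seq_A=wa,
                seq_B=wb,
                interval_A=(qs, qe),
                interval_B=(ts, te),
                strand=hit.strand,
                identity=hit.identity,
                raw_score=hit.raw_score,
            )
        )
    return cons_a, cons_b, pairs


def write_conversion_table(
    table: Sequence[tuple[str, str, HomologyHit]], path: str | Path
) -> None:
    """Tabular-alignment-style TSV of the conversion table."""
    with open(path, "w") as fh:
        fh.write("qid\ttid\tqs\tqe\tts\tte\tstrand\tscore\tbitscore\tevalue\tidentity\n")
        for id_a, id_b, h in table:
            fh.write(
                f"{id_a}\t{id_b}\t{h.query_interval[0]}\t{h.query_interval[1]}\t"
                f"{h.target_interval[0]}\t{h.target_interval[1]}\t{h.strand}\t"
                f"{h.raw_score}\t{h.bit_score:.2f}\t{h.e_value:.3g}\t{h.identity:.4f}\n"
            )


def consensus_fasta_records(
    pairs: Sequence[ConsensusPair], side: str
) -> list[Transcript]:
    """Consensus windows as FASTA-ready records with provenance headers."""
    if side not in ("A", "B"):
        raise ValueError("side must be 'A' or 'B'")
    out = []
    for p in pairs:
        src = p.id_A if side == "A" else p.id_B
        iv = p.interval_A if side == "A" else p.interval_B
        seq = p.seq_A if side == "A" else p.seq_B
        out.append(Transcript(f"{p.pair_id}|{side}|src={src}|{iv[0]}-{iv[1]}", seq, side))
    return out
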