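"""Independent reference implementations used only as test oracles.

Deliberately naive: quadratic DP for local alignment, exhaustive scans for
mapping, full enumeration for ORFs, and a from-scratch codon table.  They
share no code with the package paths they check.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def sw_affine_score(
    q: str, t: str, match: int = 1, mismatch: int = -2,
    gap_open: int = 5, gap_extend: int = 2,
) -> int:
    """Smith-Waterman optimal local score, affine gaps, O(nm) DP.

    A gap of length L costs gap_open + gap_extend * L; N matches nothing.
    """
    n, m = len(q), len(t)
    neg = -(10 ** 9)
    first = gap_open + gap_extend
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), neg, dtype=np.int64)  # gap in query (left moves)
    F = np.full((n + 1, m + 1), neg, dtype=np.int64)  # gap in target (up moves)
    best = 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        for j in range(1, m + 1):
            tj = t[j - 1]
            s = match if (qi == tj and qi != "N") else mismatch
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            h = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            H[i][j] = h
            if h > best:
                best = h
    return int(best)


def brute_force_map(fragment_seq, fragment_qual, transcripts, policy):
    """Exhaustive ungapped mapping: every offset on every strand.

    *transcripts* is a list of (id, seq).  Returns the policy-optimal
    placement (tid, pos, strand, n_mismatches, qual_mismatch_sum) under the
    total order (mismatches, qual sum, transcript id, offset, + before -),
    or None.
    """
    t5, t3 = policy.trim5, policy.trim3
    if len(fragment_seq) < t5 + t3 + 1:
        return None
    seq = fragment_seq[t5: len(fragment_seq) - t3 if t3 else None]
    qual = np.asarray(fragment_qual[t5: len(fragment_qual) - t3 if t3 else None], dtype=np.int64)
    L = len(seq)
    span = min(policy.seed_len, L)
    candidates = []
    id_order = sorted(tid for tid, _ in transcripts)
    rank = {tid: i for i, tid in enumerate(id_order)}
    for tid, ref in transcripts:
        ref_a = np.frombuffer(ref.encode(), dtype=np.uint8)
        if len(ref_a) < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(ref_a, L)
        for strand in "+-":
            if strand == "+":
                f = np.frombuffer(seq.encode(), dtype=np.uint8)
                q = qual
                seed = np.zeros(L, dtype=bool)
                seed[:span] = True
            else:
                f = np.frombuffer(rc(seq).encode(), dtype=np.uint8)
                q = qual[::-1]
                seed = np.zeros(L, dtype=bool)
                seed[:span] = True
                seed = seed[::-1]
            mm = (win != f) | (win == ord("N")) | (f == ord("N"))
            seed_mm = mm[:, seed].sum(axis=1)
            qsum = (mm * q).sum(axis=1)
            nm = mm.sum(axis=1)
            ok = (seed_mm <= policy.max_seed_mismatches) & (qsum <= policy.max_qual_mismatch_sum)
            for pos in np.flatnonzero(ok):
                candidates.append(
                    (int(nm[pos]), int(qsum[pos]), rank[tid], int(pos),
                     0 if strand == "+" else 1, tid, strand)
                )
    if not candidates:
        return None
    nm, qsum, _, pos, _, tid, strand = min(candidates)
    return tid, pos, strand, nm, qsum


_CODONS = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRR"
       "IIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODONS[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]


def translate(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        out.append(_CODONS.get(seq[i:i + 3], "X"))
    return "".join(out)


def brute_longest_orf(seq: str, min_aa: int):
    """Enumerate every stop-free codon run in all six frames.

    Returns (frame, aa_start, aa_len) of the winner under the tie order
    (longest, frame order +1..+3,-1..-3, leftmost) or None if < min_aa.
    """
    frames = ["+1", "+2", "+3", "-1", "-2", "-3"]
    best = None
    for rank, frame in enumerate(frames):
        off = int(frame[1]) - 1
        s = seq if frame[0] == "+" else rc(seq)
        pep = translate(s[off:])
        start = 0
        for chunk in pep.split("*"):
            if chunk:
                key = (-len(chunk), rank, start)
                if best is None or key < best[0]:
                    best = (key, (frame, start, len(chunk)))
            start += len(chunk) + 1
    if best is None or -best[0][0] < min_aa:
        return None
    return best[1]
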