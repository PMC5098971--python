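"""Synthetic data: diverged transcriptome pairs and 454-like reads.

Generates the full ground-truth surface the pipeline needs for testing:

* a pair of transcriptomes descended from a common ancestral set, each
  lineage mutated independently at half the target divergence, so the
  expected pairwise identity of a homolog pair is ~(1 - divergence);
* per-transcript expression weights with known log2(B/A) ratios;
* single-end reads emulating 454 titanium data: lengths around 400 nt,
  uniform substitution errors, homopolymer-biased one-base indels, and
  Phred qualities decaying linearly toward the 3' end so that Q20 end
  trimming is actually exercised.

Reads are drawn from transcripts with probability proportional to
weight x length.  Under that sampling scheme RPKM is an unbiased estimator
of the weight, which is the premise of the downstream fold-change step.

All randomness flows from a single :class:`numpy.random.Generator` seeded
from ``SimConfig.seed``; the same seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqio import Read, Transcript

__all__ = [
    "SimConfig",
    "TruthRow",
    "generate_transcriptome_pair",
    "simulate_reads",
    "draw_log2fc",
    "write_truth_table",
    "read_truth_table",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Defaults emulate the kind of dataset the method was designed for: two
    recently separated populations whose homologous transcripts are ~96%
    identical, sequenced on a long-read pyrosequencing platform.
    """

    n_transcripts: int = 200
    len_range: tuple[int, int] = (500, 1500)
    gc_fraction: float = 0.45
    divergence: float = 0.04          # per-site substitution prob between the two copies
    indel_rate: float = 0.001         # per-site one-base indel prob, per lineage
    expr_log2fc: Sequence[float] | None = None  # true log2(B/A); default: drawn log-normal
    expr_sigma: float = 1.0           # sd of log2fc draw when expr_log2fc is None
    reads_per_population: int = 5000
    read_len_mean: float = 400.0
    read_len_sd: float = 100.0
    error_sub_rate: float = 0.005     # per-base sequencing substitution prob
    homopolymer_indel_rate: float = 0.02  # per run of >=3 identical bases
    qual_start: int = 38              # 5' Phred level
    qual_end: int = 15                # 3' Phred level (< 20 so trimming bites)
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        if self.len_range[0] > self.len_range[1]:
            raise ValueError(f"len_range min > max: {self.len_range}")
        for name in ("gc_fraction", "divergence", "indel_rate", "error_sub_rate",
                     "homopolymer_indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.expr_log2fc is not None and len(self.expr_log2fc) != self.n_transcripts:
            raise ValueError("expr_log2fc must have one value per transcript")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one simulated homolog pair."""

    pair_id: str
    id_A: str
    id_B: str
    true_log2fc: float     # log2(B expression / A expression)
    true_identity: float   # substitution-level identity of the two copies


def _decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Substitute each site with probability *rate*; returns (copy, hit mask)."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    idx = np.flatnonzero(hit)
    if idx.size:
        # replace with one of the three other bases
        cur = np.searchsorted(_BASES, out[idx])  # _BASES is sorted (A<C<G<T)
        shift = rng.integers(1, 4, size=idx.size)
        out[idx] = _BASES[(cur + shift) % 4]
    return out, hit


def _apply_indels(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0.0:
        return seq
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    if not hit.size:
        return seq
    pieces: list[np.ndarray] = []
    prev = 0
    for pos in hit:
        if rng.random() < 0.5:  # deletion of this base
            pieces.append(seq[prev:pos])
        else:                   # duplication of this base
            pieces.append(seq[prev : pos + 1])
            pieces.append(seq[pos : pos + 1])
        prev = pos + 1
    pieces.append(seq[prev:])
    return np.concatenate(pieces)


def draw_log2fc(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Log-normal expression ratios: log2fc ~ Normal(0, sigma)."""
    return rng.normal(0.0, sigma, size=n)


def generate_transcriptome_pair(
    config: SimConfig,
) -> tuple[list[Transcript], list[Transcript], list[TruthRow]]:
    """Simulate two diverged transcriptomes plus their truth table.

    Each ancestral sequence is drawn i.i.d. at the target GC content and
    copied into both populations; each copy is then mutated independently at
    ``divergence / 2`` so the expected pairwise identity is ~(1 - divergence).
    One-base indels (rate ``indel_rate`` per site per lineage) are applied
    after substitutions; the recorded ``true_identity`` is the
    substitution-level identity on the ancestral coordinate frame.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.expr_log2fc is not None:
        log2fc = np.asarray(config.expr_log2fc, dtype=float)
    else:
        log2fc = draw_log2fc(config.n_transcripts, config.expr_sigma, rng)

    gc = config.gc_fraction
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    ts_a: list[Transcript] = []
    ts_b: list[Transcript] = []
    truth: list[TruthRow] = []
    for i in range(config.n_transcripts):
        length = int(rng.integers(config.len_range[0], config.len_range[1] + 1))
        anc = rng.choice(_BASES, size=length, p=base_p)
        copy_a, hit_a = _mutate(anc, config.divergence / 2, rng)
        copy_b, hit_b = _mutate(anc, config.divergence / 2, rng)
        ident = float(np.mean(copy_a == copy_b))
        copy_a = _apply_indels(copy_a, config.indel_rate, rng)
        copy_b = _apply_indels(copy_b, config.indel_rate, rng)
        id_a, id_b = f"A_t{i:05d}", f"B_t{i:05d}"
        ts_a.append(Transcript(id_a, _decode(copy_a), "A"))
        ts_b.append(Transcript(id_b, _decode(copy_b), "B"))
        truth.append(TruthRow(f"anc{i:05d}", id_a, id_b, float(log2fc[i]), ident))
    return ts_a, ts_b, truth


def _homopolymer_runs(seq: np.ndarray, min_run: int = 3) -> list[tuple[int, int]]:
    """(start, end) of maximal runs of >= min_run identical bases."""
    if len(seq) == 0:
        return []
    change = np.flatnonzero(seq[1:] != seq[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(seq)]))
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_run]


def simulate_reads(
    transcripts: Sequence[Transcript],
    expression_weights: Sequence[float],
    config: SimConfig,
    population: str = "A",
    rng: np.random.Generator | None = None,
) -> tuple[list[Read], list[tuple[str, str]]]:
    """Simulate 454-like single-end reads from a weighted transcript set.

    Source transcripts are chosen with probability proportional to
    weight x length; start positions are uniform; lengths are
    Normal(read_len_mean, read_len_sd) truncated to [40, transcript length];
    strand is uniform.  Substitution errors, homopolymer one-base indels and
    a linear 5'->3' quality decay (with +-2 jitter) are applied.

    Returns the reads and the read->source-transcript truth pairs.
    """
    if not transcripts:
        raise ValueError("cannot simulate reads from an empty transcript set")
    weights = np.asarray(expression_weights, dtype=float)
    if len(weights) != len(transcripts) or np.any(weights <= 0):
        raise ValueError("need one strictly positive weight per transcript")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    arrs = [np.frombuffer(t.seq.encode("ascii"), dtype=np.uint8) for t in transcripts]
    lens = np.array([len(a) for a in arrs], dtype=float)
    p = weights * lens
    p /= p.sum()
    n = config.reads_per_population
    sources = rng.choice(len(transcripts), size=n, p=p)
    raw_lens = rng.normal(config.read_len_mean, config.read_len_sd, size=n)

    comp = np.zeros(256, dtype=np.uint8)
    for x, y in zip(b"ACGTN", b"TGCAN"):
        comp[x] = y

    reads: list[Read] = []
    truth: list[tuple[str, str]] = []
    for j in range(n):
        src = int(sources[j])
        tarr = arrs[src]
        rlen = int(np.clip(round(raw_lens[j]), 40, len(tarr)))
        start = int(rng.integers(0, len(tarr) - rlen + 1))
        frag = tarr[start : start + rlen]
        if rng.random() < 0.5:
            frag = comp[frag][::-1]
        # homopolymer indels, the dominant 454 error mode
        hp = _homopolymer_runs(frag)
        if hp and config.homopolymer_indel_rate > 0:
            keep: list[np.ndarray] = []
            prev = 0
            for s, e in hp:
                if rng.random() < config.homopolymer_indel_rate:
                    keep.append(frag[prev:s])
                    run = frag[s:e]
                    if rng.random() < 0.5:
                        keep.append(run[:-1])       # one-base deletion
                    else:
                        keep.append(np.concatenate((run, run[-1:])))  # insertion
                    prev = e
            keep.append(frag[prev:])
            frag = np.concatenate(keep)
        frag, _ = _mutate(frag, config.error_sub_rate, rng)
        m = len(frag)
        qual = np.linspace(config.qual_start, config.qual_end, num=m)
        qual = np.clip(np.rint(qual + rng.integers(-2, 3, size=m)), 2, 41).astype(int)
        rid = f"{population}_r{j:07d}"
        reads.append(Read(rid, _decode(frag), tuple(int(q) for q in qual), population))
        truth.append((rid, transcripts[src].id))
    return reads, truth


def write_truth_table(truth: Sequence[TruthRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tid_A\tid_B\ttrue_log2fc\ttrue_identity\n")
        for row in truth:
            fh.write(
                f"{row.pair_id}\t{row.id_A}\t{row.id_B}\t"
                f"{row.true_log2fc:.6f}\t{row.true_identity:.6f}\n"
            )


def read_truth_table(path) -> list[TruthRow]:
    rows: list[TruthRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["pair_id", "id_A", "id_B", "true_log2fc", "true_identity"]
        if header != expected:
            raise ValueError(f"{path}: unexpected truth-table header {header}")
        for line in fh:
            pid, ida, idb, fc, ident = line.rstrip("\n").split("\t")
            rows.append(TruthRow(pid, ida, idb, float(fc), float(ident)))
    return rows
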