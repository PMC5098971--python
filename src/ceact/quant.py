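"""RPKM quantification, fold-change and differential-expression classes.

Per consensus pair and per mapping round, expression is measured as RPKM
(reads per kilobase of transcript per million mapped reads):

    RPKM = 1e9 * count / (reference_length * total_mapped_in_round)

The reference length is that of the sequence the round actually mapped
against (rounds 1 and 4 map on the A consensus, rounds 2 and 3 on the B
consensus; pair members may differ in length by indels), and the
total-mapped denominator is per round.  Population-level RPKMs average
rounds 1-2 (population A reads) and rounds 3-4 (population B reads); the
fold-change is

    FC = log2(RPKM_B / RPKM_A)

with population A in the sGSL role, so FC >= 1 marks a pair *down*-regulated
in A and FC <= -1 *up*-regulated in A (both thresholds inclusive).  When
either averaged RPKM is zero the fold-change is undefined and the pair is
excluded from classification; an epsilon-pseudocount policy is available
instead.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .fragmap import RoundCounts
from .homology import ConsensusPair

__all__ = [
    "FcThresholds",
    "PseudocountPolicy",
    "ExpressionRecord",
    "ExpressionSummary",
    "rpkm",
    "average_population_rpkm",
    "fold_change",
    "classify",
    "expression_table",
    "write_expression_table",
    "write_summary",
]

UP_IN_A = "up_in_A"
DOWN_IN_A = "down_in_A"
UNCHANGED = "unchanged"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class FcThresholds:
    """Inclusive fold-change cutoffs, in the A-is-sGSL orientation."""

    down_cutoff: float = 1.0    # fc >= down_cutoff: down-regulated in A
    up_cutoff: float = -1.0     # fc <= up_cutoff: up-regulated in A

    def __post_init__(self) -> None:
        if not self.down_cutoff > 0 > self.up_cutoff:
            raise ValueError("need down_cutoff > 0 > up_cutoff")


@dataclass(frozen=True)
class PseudocountPolicy:
    """Zero-RPKM handling: mark undefined (default) or add epsilon to both sides."""

    mode: str = "undefined"     # "undefined" | "epsilon"
    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        if self.mode not in ("undefined", "epsilon"):
            raise ValueError(f"unknown pseudocount mode {self.mode!r}")
        if self.mode == "epsilon" and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class ExpressionRecord:
    pair_id: str
    len_A: int
    len_B: int
    counts: tuple[int, int, int, int]
    rpkms: tuple[float, float, float, float]
    rpkm_A: float
    rpkm_B: float
    fc: float | None
    klass: str


@dataclass
class ExpressionSummary:
    n_pairs: int
    n_up: int
    n_down: int
    n_unchanged: int
    n_undefined: int

    def as_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_up_in_A": self.n_up,
            "n_down_in_A": self.n_down,
            "n_unchanged": self.n_unchanged,
            "n_undefined": self.n_undefined,
        }


def rpkm(count: int, transcript_len_nt: int, total_mapped_in_round: int) -> float:
    """RPKM = 1e9 * count / (len * total); zero when nothing mapped."""
    if transcript_len_nt < 1:
        raise ValueError("transcript length must be >= 1")
    if total_mapped_in_round < 0 or count < 0:
        raise ValueError("counts must be non-negative")
    if total_mapped_in_round == 0:
        return 0.0
    return 1e9 * count / (transcript_len_nt * total_mapped_in_round)


def average_population_rpkm(
    rpkms: Sequence[float],
) -> tuple[float, float]:
    """Arithmetic means of rounds (1,2) and rounds (3,4)."""
    r1, r2, r3, r4 = rpkms
    return (r1 + r2) / 2.0, (r3 + r4) / 2.0


def fold_change(
    rpkm_b: float,
    rpkm_a: float,
    policy: PseudocountPolicy = PseudocountPolicy(),
) -> float | None:
    """log2(RPKM_B / RPKM_A); None when undefined under the zero policy."""
    if rpkm_a < 0 or rpkm_b < 0:
        raise ValueError("RPKM values must be non-negative")
    if policy.mode == "epsilon":
        rpkm_a += policy.epsilon
        rpkm_b += policy.epsilon
    if rpkm_a == 0.0 or rpkm_b == 0.0:
        return None
    # log difference rather than log of the ratio: negation under a
    # population-role swap is then exact in floating point
    return math.log2(rpkm_b) - math.log2(rpkm_a)


def classify(fc: float, thresholds: FcThresholds = FcThresholds()) -> str:
    """Inclusive threshold classification of a defined fold-change."""
    if fc >= thresholds.down_cutoff:
        return DOWN_IN_A
    if fc <= thresholds.up_cutoff:
        return UP_IN_A
    return UNCHANGED


def expression_table(
    rounds: Sequence[RoundCounts],
    pairs: Sequence[ConsensusPair],
    thresholds: FcThresholds = FcThresholds(),
    policy: PseudocountPolicy = PseudocountPolicy(),
) -> tuple[list[ExpressionRecord], ExpressionSummary]:
    """One expression record per consensus pair, plus summary counts.

    Expects the four mapping rounds in order; all rounds and the pair list
    must agree on the pair-id key set.
    """
    if len(rounds) != 4 or [r.round_id for r in rounds] != [1, 2, 3, 4]:
        raise ValueError("expected mapping rounds 1..4 in order")
    pair_ids = [p.pair_id for p in pairs]
    for r in rounds:
        if set(r.counts) != set(pair_ids):
            raise ValueError(f"round {r.round_id} pair_ids inconsistent with pairs")
    ref_len = {
        "A": {p.pair_id: len(p.seq_A) for p in pairs},
        "B": {p.pair_id: len(p.seq_B) for p in pairs},
    }
    records: list[ExpressionRecord] = []
    tallies = {UP_IN_A: 0, DOWN_IN_A: 0, UNCHANGED: 0, UNDEFINED: 0}
    for p in pairs:
        counts = tuple(r.counts[p.pair_id] for r in rounds)
        rpkms = tuple(
            rpkm(c, ref_len[r.reference][p.pair_id], r.total_mapped)
            for c, r in zip(counts, rounds)
        )
        rpkm_a, rpkm_b = average_population_rpkm(rpkms)
        fc = fold_change(rpkm_b, rpkm_a, policy)
        klass = UNDEFINED if fc is None else classify(fc, thresholds)
        tallies[klass] += 1
        records.append(
            ExpressionRecord(
                p.pair_id, len(p.seq_A), len(p.seq_B),
                counts, rpkms, rpkm_a, rpkm_b, fc, klass,
            )
        )
    summary = ExpressionSummary(
        len(records), tallies[UP_IN_A], tallies[DOWN_IN_A],
        tallies[UNCHANGED], tallies[UNDEFINED],
    )
    return records, summary


def write_expression_table(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    cols = (
        "pair_id\tlen_A\tlen_B\tc1\tc2\tc3\tc4\t"
        "rpkm1\trpkm2\trpkm3\trpkm4\trpkm_A\trpkm_B\tfc\tclass\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for r in records:
            fc = "NA" if r.fc is None else f"{r.fc:.6f}"
            fh.write(
                f"{r.pair_id}\t{r.len_A}\t{r.len_B}\t"
                + "\t".join(str(c) for c in r.counts) + "\t"
                + "\t".join(f"{x:.6f}" for x in r.rpkms)
                + f"\t{r.rpkm_A:.6f}\t{r.rpkm_B:.6f}\t{fc}\t{r.klass}\n"
            )


def write_summary(summary: ExpressionSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(summary.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
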