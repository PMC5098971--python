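"""Six-frame translation and longest-ORF extraction.

An ORF here is a maximal run of non-stop codons in one of the six reading
frames (+1, +2, +3 on the forward strand, -1, -2, -3 on the reverse
complement), stop-to-stop: no start codon is required, and the sequence
ends act as run boundaries.  The longest such run per transcript is kept
when it reaches the minimum length (default 80 amino acids, inclusive).
Translation uses the standard genetic code; codons containing N translate
to 'X' (which is not a stop, so it does not break a run).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq

from .seqio import Transcript, revcomp

__all__ = ["OrfResult", "FRAMES", "six_frame_translate", "longest_orf", "write_orf_table"]

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


@dataclass(frozen=True)
class OrfResult:
    """The accepted longest ORF of one transcript.

    ``nt_interval`` is 0-based half-open on the forward strand; its length
    is exactly ``3 * length_aa`` and it re-translates (in ``frame``) to
    ``peptide``, which contains no stop symbol.
    """

    transcript_id: str
    frame: str
    nt_interval: tuple[int, int]
    peptide: str

    @property
    def length_aa(self) -> int:
        return len(self.peptide)


def _translate(seq: str) -> str:
    n = len(seq) - len(seq) % 3  # ignore trailing 1-2 nt
    return str(Seq(seq[:n]).translate())


def six_frame_translate(seq: str) -> dict[str, str]:
    """Peptides (stop symbols included) for all six reading frames."""
    seq = seq.upper()
    if len(seq) < 3:
        return {}
    rc = revcomp(seq)
    out: dict[str, str] = {}
    for off in range(3):
        out[f"+{off + 1}"] = _translate(seq[off:])
        out[f"-{off + 1}"] = _translate(rc[off:])
    return out


def _forward_interval(frame: str, aa_start: int, aa_len: int, seq_len: int) -> tuple[int, int]:
    """Map a codon run in a given frame onto the forward strand."""
    off = int(frame[1]) - 1
    lo = off + 3 * aa_start
    hi = lo + 3 * aa_len
    if frame[0] == "+":
        return lo, hi
    return seq_len - hi, seq_len - lo  # coordinates were on the reverse complement


def longest_orf(
    transcript: Transcript | str, min_aa: int = 80, transcript_id: str = "seq"
) -> OrfResult | None:
    """Longest stop-free codon run over all six frames, or None if < min_aa.

    Ties are broken by frame order +1, +2, +3, -1, -2, -3, then by the
    leftmost run within the frame.
    """
    if isinstance(transcript, Transcript):
        transcript_id, seq = transcript.id, transcript.seq
    else:
        seq = transcript
    best: tuple[int, int, int] | None = None  # (-aa_len, frame_rank, aa_start)
    best_payload: tuple[str, int, int] | None = None
    for rank, frame in enumerate(FRAMES):
        off = int(frame[1]) - 1
        s = seq if frame[0] == "+" else revcomp(seq)
        pep = _translate(s[off:])
        start = 0
        for chunk in pep.split("*"):
            if chunk and (best is None or (-len(chunk), rank, start) < best):
                best = (-len(chunk), rank, start)
                best_payload = (frame, start, len(chunk))
            start += len(chunk) + 1
    if best_payload is None or -best[0] < min_aa:
        return None
    frame, aa_start, aa_len = best_payload
    off = int(frame[1]) - 1
    s = seq if frame[0] == "+" else revcomp(seq)
    peptide = _translate(s[off:])[aa_start : aa_start + aa_len]
    return OrfResult(
        transcript_id,
        frame,
        _forward_interval(frame, aa_start, aa_len, len(seq)),
        peptide,
    )


def write_orf_table(results: Sequence[OrfResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tframe\tstart\tend\tlength_aa\n")
        for r in results:
            fh.write(
                f"{r.transcript_id}\t{r.frame}\t{r.nt_interval[0]}\t"
                f"{r.nt_interval[1]}\t{r.length_aa}\n"
            )
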