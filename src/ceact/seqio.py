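"""Sequence I/O, quality trimming, contig filtering and assembly QC.

Reads and transcripts are the two atomic record types of the pipeline: a
:class:`Read` is a single-end pyrosequencing read with per-base Phred
qualities, a :class:`Transcript` is an assembled contig.  Both carry a
population label (``"A"`` or ``"B"``) so that downstream stages can keep the
two populations' data apart without relying on file naming.

FASTA/FASTQ parsing and writing are delegated to Biopython; qualities are
fixed to the Phred+33 encoding (no autodetection).  Sequences are normalised
to uppercase ``A/C/G/T/N`` on read; ``N`` never matches anything in alignment
or mapping.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Read",
    "Transcript",
    "QcReport",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "trim_read_ends",
    "filter_min_length",
    "n50",
    "remap_fraction",
    "gc_fraction",
    "assembly_qc",
    "write_qc_report",
]

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised for malformed FASTA/FASTQ input."""


@dataclass(frozen=True)
class Read:
    """A single-end read with per-base Phred qualities."""

    id: str
    seq: str
    qual: tuple[int, ...]
    population: str = "A"

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ParseError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Transcript:
    """An assembled contig with a population label."""

    id: str
    seq: str
    population: str = "A"

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class QcReport:
    """Assembly quality summary for one population's transcriptome.

    ``remap_fraction`` is computed over post-splitting fragments because
    mapping operates on fragments; the raw read-level count is carried
    alongside so both conventions are reported.
    """

    population: str
    n_contigs: int
    total_bases: int
    n50: int
    gc_fraction: float
    remap_fraction: float = float("nan")
    fragments_mapped: int = 0
    fragments_total: int = 0
    reads_total: int = 0

    def as_rows(self) -> list[tuple[str, str]]:
        return [
            ("population", self.population),
            ("n_contigs", str(self.n_contigs)),
            ("total_bases", str(self.total_bases)),
            ("n50", str(self.n50)),
            ("gc_fraction", f"{self.gc_fraction:.6f}"),
            ("remap_fraction", f"{self.remap_fraction:.6f}"),
            ("fragments_mapped", str(self.fragments_mapped)),
            ("fragments_total", str(self.fragments_total)),
            ("reads_total", str(self.reads_total)),
        ]


def _normalise(seq: str, record_id: str) -> str:
    s = str(seq).upper()
    bad = set(s) - _VALID
    if bad:
        raise ParseError(
            f"record {record_id!r}: invalid characters {sorted(bad)} "
            "(alphabet is A/C/G/T/N)"
        )
    return s


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, population: str = "A") -> list[Transcript]:
    """Parse a (wrapped or unwrapped) FASTA file into transcripts.

    Sequences are uppercased; duplicate ids and empty sequences are
    rejected with an error naming the offending record.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
        if first and not first.startswith(">"):
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
        handle.seek(0)
        out: list[Transcript] = []
        seen: set[str] = set()
        for i, rec in enumerate(SeqIO.parse(handle, "fasta"), start=1):
            if len(rec.seq) == 0:
                raise ParseError(f"{path}: record {i} ({rec.id!r}): empty sequence")
            if rec.id in seen:
                raise ParseError(f"{path}: record {i}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            out.append(Transcript(rec.id, _normalise(rec.seq, rec.id), population))
    return out


def write_fasta(transcripts: Iterable[Transcript], path: str | Path, width: int = 80) -> None:
    """Write transcripts as multi-line FASTA (lines wrapped at *width*)."""
    with open(path, "w") as handle:
        for t in transcripts:
            handle.write(f">{t.id}\n")
            for i in range(0, len(t.seq), width):
                handle.write(t.seq[i : i + width] + "\n")


def read_fastq(path: str | Path, population: str = "A") -> list[Read]:
    """Parse Phred+33 FASTQ into reads; qualities decoded to integers."""
    path = Path(path)
    out: list[Read] = []
    seen: set[str] = set()
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq"), start=1):
            if rec.id in seen:
                raise ParseError(f"{path}: record {i}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            qual = tuple(rec.letter_annotations["phred_quality"])
            out.append(Read(rec.id, _normalise(rec.seq, rec.id), qual, population))
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: {exc}") from exc
    return out


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    records = (
        SeqRecord(
            Seq(r.seq),
            id=r.id,
            description="",
            letter_annotations={"phred_quality": list(r.qual)},
        )
        for r in reads
    )
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fastq")


def trim_read_ends(read: Read, q_threshold: int = 20) -> Read:
    """Trim low-quality bases from both ends of a read.

    Scans inward from the 5' end removing bases with quality below
    *q_threshold* until the first base at or above it, and likewise from the
    3' end.  Interior low-quality bases are retained.  A read whose bases are
    all below threshold comes back empty (callers discard empty reads).
    """
    q = read.qual
    lo = 0
    while lo < len(q) and q[lo] < q_threshold:
        lo += 1
    hi = len(q)
    while hi > lo and q[hi - 1] < q_threshold:
        hi -= 1
    if lo == 0 and hi == len(q):
        return read
    return Read(read.id, read.seq[lo:hi], q[lo:hi], read.population)


def filter_min_length(transcripts: Sequence[Transcript], min_len: int = 200) -> list[Transcript]:
    """Drop contigs shorter than *min_len* nucleotides (boundary kept)."""
    return [t for t in transcripts if len(t.seq) >= min_len]


def n50(lengths: Sequence[int]) -> int:
    """N50 of a contig length set.

    The length at which the cumulative sum of descending-sorted lengths
    first reaches half the assembly total (a tie at exactly half counts as
    reached).
    """
    if not lengths:
        raise ValueError("n50 of an empty length set is undefined")
    if any(x <= 0 for x in lengths):
        raise ValueError("contig lengths must be positive")
    half = sum(lengths) / 2
    acc = 0
    for x in sorted(lengths, reverse=True):
        acc += x
        if acc >= half:
            return x
    raise AssertionError("unreachable")


def remap_fraction(fragments_mapped: int, fragments_total: int) -> float:
    """Fraction of fragments that mapped back to the assembly."""
    if fragments_total == 0:
        raise ValueError("remap fraction undefined for zero fragments")
    if not 0 <= fragments_mapped <= fragments_total:
        raise ValueError("need 0 <= fragments_mapped <= fragments_total")
    return fragments_mapped / fragments_total


def gc_fraction(transcripts: Sequence[Transcript]) -> float:
    gc = total = 0
    for t in transcripts:
        gc += t.seq.count("G") + t.seq.count("C")
        total += len(t.seq) - t.seq.count("N")
    return gc / total if total else 0.0


def assembly_qc(
    transcripts: Sequence[Transcript],
    population: str,
    fragments_mapped: int = 0,
    fragments_total: int = 0,
    reads_total: int = 0,
) -> QcReport:
    """Standard assembly statistics plus the remap fraction, if supplied."""
    lengths = [len(t) for t in transcripts]
    return QcReport(
        population=population,
        n_contigs=len(transcripts),
        total_bases=sum(lengths),
        n50=n50(lengths) if lengths else 0,
        gc_fraction=gc_fraction(transcripts),
        remap_fraction=(
            remap_fraction(fragments_mapped, fragments_total) if fragments_total else float("nan")
        ),
        fragments_mapped=fragments_mapped,
        fragments_total=fragments_total,
        reads_total=reads_total,
    )


def write_qc_report(report: QcReport, path: str | Path) -> None:
    """Serialise a QC report as a flat metric/value TSV."""
    with open(path, "w") as handle:
        handle.write("metric\tvalue\n")
        for k, v in report.as_rows():
            handle.write(f"{k}\t{v}\n")


def format_qc_report(report: QcReport) -> str:
    buf = io.StringIO()
    for k, v in report.as_rows():
        buf.write(f"  {k:18s} {v}\n")
    return buf.getvalue()
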