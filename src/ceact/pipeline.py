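"""End-to-end orchestration: simulate, run the full analysis, evaluate.

The full run executes the staged procedure — quality trim reads, drop short
contigs, build the homolog conversion table, extract the two consensus
transcriptomes, fragment the reads, run the four mapping rounds, and compute
the RPKM / fold-change expression table — writing every intermediate
artifact under a fixed directory schema:

    01_trim/        trimmed reads, filtered transcriptomes
    02_consensus/   conversion table, consensus FASTAs
    03_map/         per-round count tables
    04_expression/  expression table TSV + JSON summary
    qc/             per-population assembly QC reports
    manifest.json   parameters, input checksums, package version

Reruns with identical config and inputs are byte-identical (the manifest
carries no timestamps).  Population A plays the sGSL role in the
fold-change orientation by convention; set ``sgsl_role: B`` to swap the
two input datasets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import fragmap, homology, quant, seqio, synthetic
from .fragmap import MappingPolicy
from .homology import ScoringScheme
from .quant import FcThresholds, PseudocountPolicy

__all__ = ["RunConfig", "run_all", "simulate", "evaluate", "write_recovery_report"]

log = logging.getLogger("ceact")


@dataclass
class RunConfig:
    """Everything a full run needs; YAML round-trips losslessly.

    Defaults are the method's stated operating point: Q20 end trimming,
    200 nt contig floor, 1e-20 homology cutoff, 40-60 nt fragments, the
    Bowtie1-style ``-n 1 -5 5 -3 5`` mapping emulation and inclusive
    fold-change cutoffs at +-1.
    """

    transcripts_a: str = ""
    transcripts_b: str = ""
    reads_a: str = ""
    reads_b: str = ""
    out_dir: str = "ceact_out"
    q_threshold: int = 20
    min_contig_len: int = 200
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    e_cutoff: float = 1e-20
    word_size: int = 11
    min_word_hits: int = 3
    frag_min: int = 40
    frag_max: int = 60
    policy: MappingPolicy = field(default_factory=MappingPolicy)
    thresholds: FcThresholds = field(default_factory=FcThresholds)
    pseudocount: PseudocountPolicy = field(default_factory=PseudocountPolicy)
    sgsl_role: str = "A"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scoring"]["background"] = list(self.scoring.background)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "scoring" in d:
            s = dict(d["scoring"])
            if "background" in s:
                s["background"] = tuple(s["background"])
            d["scoring"] = ScoringScheme(**s)
        if "policy" in d:
            d["policy"] = MappingPolicy(**d["policy"])
        if "thresholds" in d:
            d["thresholds"] = FcThresholds(**d["thresholds"])
        if "pseudocount" in d:
            d["pseudocount"] = PseudocountPolicy(**d["pseudocount"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis; returns a result dict with key outputs.

    Stages abort with :class:`StageError` naming the failing stage.
    """
    out = Path(config.out_dir)
    for sub in ("01_trim", "02_consensus", "03_map", "04_expression", "qc"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    for p in (config.transcripts_a, config.transcripts_b, config.reads_a, config.reads_b):
        if not Path(p).exists():
            raise StageError("input", f"input file not found: {p}")

    inputs = {
        "transcripts_a": config.transcripts_a,
        "transcripts_b": config.transcripts_b,
        "reads_a": config.reads_a,
        "reads_b": config.reads_b,
    }
    if config.sgsl_role == "B":  # swap datasets so population A is the sGSL role
        inputs["transcripts_a"], inputs["transcripts_b"] = (
            inputs["transcripts_b"], inputs["transcripts_a"])
        inputs["reads_a"], inputs["reads_b"] = inputs["reads_b"], inputs["reads_a"]
    elif config.sgsl_role != "A":
        raise StageError("config", f"sgsl_role must be 'A' or 'B', got {config.sgsl_role!r}")

    with _stage("load"):
        ts_a = seqio.read_fasta(inputs["transcripts_a"], "A")
        ts_b = seqio.read_fasta(inputs["transcripts_b"], "B")
        reads_a = seqio.read_fastq(inputs["reads_a"], "A")
        reads_b = seqio.read_fastq(inputs["reads_b"], "B")

    with _stage("trim"):
        trimmed = {}
        for pop, reads in (("A", reads_a), ("B", reads_b)):
            tr = [seqio.trim_read_ends(r, config.q_threshold) for r in reads]
            kept = [r for r in tr if len(r) > 0]
            log.info("population %s: %d/%d reads retained after Q%d end trim",
                     pop, len(kept), len(reads), config.q_threshold)
            seqio.write_fastq(kept, out / "01_trim" / f"reads_{pop}.trimmed.fastq")
            trimmed[pop] = kept

    with _stage("contig_filter"):
        filtered = {}
        for pop, ts in (("A", ts_a), ("B", ts_b)):
            ok = seqio.filter_min_length(ts, config.min_contig_len)
            log.info("population %s: %d/%d contigs >= %d nt",
                     pop, len(ok), len(ts), config.min_contig_len)
            seqio.write_fasta(ok, out / "01_trim" / f"transcripts_{pop}.filtered.fasta")
            filtered[pop] = ok

    with _stage("conversion_table"):
        table = homology.build_conversion_table(
            filtered["A"], filtered["B"], config.scoring, config.e_cutoff,
            config.word_size, config.min_word_hits,
        )
        log.info("conversion table: %d reciprocal-best pairs "
                 "(%d A and %d B transcripts lacked significant matches)",
                 len(table), len(filtered["A"]) - len(table),
                 len(filtered["B"]) - len(table))
        homology.write_conversion_table(table, out / "02_consensus" / "conversion_table.tsv")
        if not table:
            raise StageError("conversion_table", "no homolog pairs passed the E-value cutoff")

    with _stage("consensus"):
        cons_a, cons_b, pairs = homology.extract_consensus(table, filtered["A"], filtered["B"])
        seqio.write_fasta(homology.consensus_fasta_records(pairs, "A"),
                          out / "02_consensus" / "consensus_A.fasta")
        seqio.write_fasta(homology.consensus_fasta_records(pairs, "B"),
                          out / "02_consensus" / "consensus_B.fasta")

    with _stage("map"):
        rounds = fragmap.run_four_rounds(
            trimmed["A"], trimmed["B"], cons_a, cons_b,
            config.policy, config.frag_max, config.frag_min,
        )
        for rc in rounds:
            log.info("round %d (%s): %d/%d fragments mapped (%.1f%%)",
                     rc.round_id, fragmap.ROUND_DESCRIPTIONS[rc.round_id],
                     rc.total_mapped, rc.n_fragments, 100 * rc.remap_fraction)
        fragmap.write_count_table(rounds, out / "03_map" / "counts.tsv")

    with _stage("qc"):
        for pop, rid in (("A", 1), ("B", 3)):
            rc = rounds[rid - 1]
            rep = seqio.assembly_qc(
                filtered[pop], pop,
                fragments_mapped=rc.total_mapped,
                fragments_total=rc.n_fragments,
                reads_total=len(trimmed[pop]),
            )
            seqio.write_qc_report(rep, out / "qc" / f"qc_{pop}.tsv")
            log.info("QC population %s:\n%s", pop, seqio.format_qc_report(rep))

    with _stage("expression"):
        records, summary = quant.expression_table(
            rounds, pairs, config.thresholds, config.pseudocount
        )
        quant.write_expression_table(records, out / "04_expression" / "expression.tsv")
        quant.write_summary(summary, out / "04_expression" / "summary.json")
        log.info("expression: %s", summary.as_dict())

    manifest = {
        "tool": "ceact",
        "version": _version(),
        "parameters": config.to_dict(),
        "input_sha256": {k: _sha256(Path(v)) for k, v in inputs.items()},
        "n_pairs": len(pairs),
        "summary": summary.as_dict(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "conversion_table": table,
        "pairs": pairs,
        "rounds": rounds,
        "records": records,
        "summary": summary,
        "manifest": manifest,
    }


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


class _stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        log.info("stage %s ...", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and not isinstance(exc, StageError):
            raise StageError(self.name, str(exc)) from exc
        return False


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("ceact")
    except PackageNotFoundError:
        return "unknown"


def simulate(sim: synthetic.SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic dataset (FASTA x2, FASTQ x2, truth TSVs).

    Validates the configuration before touching the filesystem; output is
    deterministic per seed.
    """
    sim.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ts_a, ts_b, truth = synthetic.generate_transcriptome_pair(sim)
    rng = np.random.default_rng(sim.seed + 1)
    fc = np.array([t.true_log2fc for t in truth])
    w_a = 2.0 ** (-fc / 2)
    w_b = 2.0 ** (fc / 2)
    reads_a, rt_a = synthetic.simulate_reads(ts_a, w_a, sim, "A", rng)
    reads_b, rt_b = synthetic.simulate_reads(ts_b, w_b, sim, "B", rng)

    paths = {
        "transcripts_a": out / "transcripts_A.fasta",
        "transcripts_b": out / "transcripts_B.fasta",
        "reads_a": out / "reads_A.fastq",
        "reads_b": out / "reads_B.fastq",
        "truth": out / "truth.tsv",
        "read_truth": out / "read_truth.tsv",
    }
    seqio.write_fasta(ts_a, paths["transcripts_a"])
    seqio.write_fasta(ts_b, paths["transcripts_b"])
    seqio.write_fastq(reads_a, paths["reads_a"])
    seqio.write_fastq(reads_b, paths["reads_b"])
    synthetic.write_truth_table(truth, paths["truth"])
    with open(paths["read_truth"], "w") as fh:
        fh.write("read_id\ttranscript_id\n")
        for rid, tid in rt_a + rt_b:
            fh.write(f"{rid}\t{tid}\n")
    return paths


def evaluate(
    records: Sequence[quant.ExpressionRecord],
    pairs: Sequence[homology.ConsensusPair],
    truth: Sequence[synthetic.TruthRow],
    thresholds: FcThresholds = FcThresholds(),
) -> dict:
    """Compare estimated fold-changes against simulation ground truth.

    Pairs are matched to truth rows through their population-A source
    transcript id.  Reports per-pair error, median absolute error, sign
    agreement at |true log2fc| >= 1, a class confusion matrix, and any
    unmatched ids (listed, not fatal).
    """
    truth_by_a = {t.id_A: t for t in truth}
    pair_by_id = {p.pair_id: p for p in pairs}
    per_pair = []
    unmatched = []
    for rec in records:
        p = pair_by_id.get(rec.pair_id)
        t = truth_by_a.get(p.id_A) if p is not None else None
        if t is None:
            unmatched.append(rec.pair_id)
            continue
        err = None if rec.fc is None else rec.fc - t.true_log2fc
        per_pair.append({
            "pair_id": rec.pair_id,
            "id_A": p.id_A,
            "true_log2fc": t.true_log2fc,
            "fc": rec.fc,
            "error": err,
            "class": rec.klass,
            "true_class": quant.classify(t.true_log2fc, thresholds),
        })
    errors = [abs(x["error"]) for x in per_pair if x["error"] is not None]
    strong = [x for x in per_pair
              if x["fc"] is not None and abs(x["true_log2fc"]) >= 1.0]
    agree = [x for x in strong if (x["fc"] > 0) == (x["true_log2fc"] > 0)]
    classes = (quant.UP_IN_A, quant.DOWN_IN_A, quant.UNCHANGED, quant.UNDEFINED)
    confusion = {tc: {c: 0 for c in classes} for tc in classes}
    for x in per_pair:
        confusion[x["true_class"]][x["class"]] += 1
    return {
        "n_pairs_evaluated": len(per_pair),
        "n_unmatched": len(unmatched),
        "unmatched": unmatched,
        "median_abs_error": float(np.median(errors)) if errors else float("nan"),
        "mean_abs_error": float(np.mean(errors)) if errors else float("nan"),
        "n_strong_truth": len(strong),
        "sign_agreement": len(agree) / len(strong) if strong else float("nan"),
        "confusion": confusion,
        "per_pair": per_pair,
    }


def write_recovery_report(report: dict, path: str | Path) -> None:
    slim = {k: v for k, v in report.items() if k != "per_pair"}
    with open(path, "w") as fh:
        json.dump(slim, fh, indent=2, sort_keys=True)
        fh.write("\n")
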