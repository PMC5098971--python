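# Methods

## The estimation problem

Two populations, A and B, each contribute a pool of long single-end reads
and an independently assembled transcriptome. Because the assemblies are
independent, neither is a valid common reference: contig boundaries,
lengths and even strand orientations differ between the two, so read
counts on the two assemblies are not directly comparable. The procedure
implemented here restores comparability by quantifying only on *matched
homologous windows* (the consensus transcriptomes) and by normalising
within each read-set × reference combination (mapping round) before
comparing across populations.

The population labelled A plays the "sGSL" role of the fold-change
orientation throughout: `FC = log2(RPKM_B / RPKM_A)`, so positive FC means
higher expression in B, i.e. *down*-regulation in A. `FC ≥ 1` and
`FC ≤ −1` (inclusive) are the classification cutoffs.

## Stage-by-stage model and conventions

**Trimming.** End trimming scans inward from each read end and removes
bases with Phred quality < 20 until the first base ≥ 20; interior
low-quality bases are kept. The rule is idempotent. Fully low-quality
reads become empty and are discarded by the pipeline.

**Contig filter.** Contigs shorter than 200 nt are excluded; exactly
200 nt is kept. N50 is the length at which descending-sorted contigs
first accumulate ≥ half the assembly total (a tie at exactly half counts
as reached).

**Homology search.** Local alignment is Smith–Waterman with affine gaps
(match +1, mismatch −2; a gap of length L costs 5 + 2L), run on both
strands; `N` matches nothing, including `N`. Significance uses the
ungapped Karlin–Altschul statistic: λ is solved numerically (bisection to
1e−14) from `Σᵢⱼ pᵢpⱼ exp(λ sᵢⱼ) = 1` at the configured background
composition (uniform by default), so any match/mismatch scheme remains
self-consistent. The K constant is tabulated for standard nucleotide
schemes (0.621 for +1/−2) with a conservative 0.3 fallback; computing K
exactly requires the full random-walk machinery and, at the `E ≤ 1e-20`
cutoff, moves no pairing decision — true homolog pairs sit at E ≈ 10⁻³⁰⁰
and chance pairs at E ≫ 1.

**Pairing.** The conversion table keeps reciprocal-best hits only: each
transcript's best-scoring partner with E below the cutoff in *both* search
directions, retained when mutual (ties: higher raw score, then smaller
id). One-to-one pairing is required for unambiguous per-pair RPKM
comparison. An exact-word prescreen (≥3 shared 11-mers, either strand)
limits full alignment to plausible pairs; it mirrors standard seeded
search and is symmetric under swapping A and B. `local_align` itself never
prescreens. Setting `min_word_hits=0` disables the prescreen.

**Consensus extraction.** Per pair, the highest-scoring alignment window
(ties: longer query interval, then leftmost) is cut from both transcripts
as the contiguous source substring spanned by the alignment — gap columns
do not split the window, so the two members may differ in length by the
alignment's indels. Minus-strand windows are reverse complemented on the
B side. Both consensus sets are keyed by pair id.

**Fragmentation and mapping.** Reads are cut greedily left-to-right into
60 nt pieces with a final remainder kept if ≥ 40 nt. Mapping emulates a
Bowtie1-style `-n 1 -5 5 -3 5` invocation: trim 5 nt from each fragment
end, then accept ungapped end-to-end placements with ≤1 mismatch in the
first 28 post-trim bases (the seed, anchored at the fragment's own 5′
end on either strand) and a summed Phred quality over all mismatched
bases ≤ 70. Among accepted placements the single best is chosen under a
total order (mismatches, quality sum, transcript id, offset, + strand),
making output byte-deterministic; ties are counted and reported.
Candidates come from exact lookup of two disjoint 14 nt half-seed blocks
(pigeonhole: ≤1 seed mismatch leaves one block exact), so the seeded
search provably enumerates every acceptable placement; degenerate
policies (seed shorter than two blocks, or >1 seed mismatch) fall back to
an exhaustive scan. Fragments overhanging consensus-window edges go
unmapped (end-to-end only). Multireads are assigned to their best
placement; reverse-strand hits count normally (cDNA is unstranded).

**Quantification.** `RPKM = 10⁹·c/(L·N)` per pair per round, with `N` the
round's total mapped fragments and `L` the length of the reference the
round actually mapped against (rounds 1 and 4 use the A window, rounds 2
and 3 the B window). Population RPKMs are the means of rounds 1–2 and
3–4. Each population's mean thus contains one same-population and one
cross-population round, so divergence-driven mapping losses (which are
approximately uniform across pairs) cancel to first order in the
fold-change. FC is computed as `log2(RPKM_B) − log2(RPKM_A)` rather than
the log of the ratio so that swapping population roles negates FC exactly
in floating point. When either averaged RPKM is zero FC is undefined and
the pair is excluded from classification; an ε-pseudocount mode
(`mode: epsilon`) is available instead. Remap fractions are reported over
post-splitting fragments (mapping operates on fragments); raw read counts
are carried in the QC report so the read-level convention is also
recoverable.

**ORF extraction.** An ORF is a maximal stop-free codon run in one of six
frames, stop-to-stop with no start-codon requirement (sequence ends bound
runs); the longest run is kept if ≥ 80 aa (inclusive). Standard genetic
code; codons containing N give `X`, which does not terminate a run. Ties:
frame order +1, +2, +3, −1, −2, −3, then leftmost.

## The synthetic-data generator

The generator stands in for a real two-population 454 study. Ancestral
transcripts are drawn i.i.d. at 45% GC, lengths uniform in a configurable
range (default 500–1500 nt); each population copy is substituted
independently at `divergence/2` per site so expected pairwise identity is
~(1 − divergence), with the default 4% divergence placing essentially all
pairs above 95% identity. One-base indels (default 0.001/site/lineage)
are applied after substitutions; recorded `true_identity` is the
substitution-level identity on the ancestral frame. Expression weights
are log-normal by default (`log2fc ~ N(0, 1)`) or a user grid; reads are
sampled ∝ weight × length (making RPKM an unbiased weight-ratio
estimator), start uniform, strand uniform, length ~N(400, 100) truncated
to [40, transcript length] — a 454-titanium-like profile. Errors:
uniform substitutions (0.5%/base) and, at each homopolymer run ≥3, a
one-base insertion or deletion with probability 0.02 — the dominant 454
error mode. Qualities decay linearly 5′→3′ from Q38 to Q15 with ±2
jitter, so Q20 end trimming is genuinely exercised. Base-call quality is
independent of whether the base is an error — a simplification; real
error bases have lower quality, so the quality-weighted mismatch budget
is slightly more permissive here than on real data.

Not emulated: flowgram-level noise, chimeric/misassembled contigs,
paralog families, expression-dependent library biases. Passing tests
therefore demonstrate correctness of the procedure under a clean
divergence-plus-noise model, not robustness to assembly artefacts.

## Experiment sizes

The recovery experiment uses 200 pairs (500–1000 nt, 2% divergence, fold
grid {−3…3}) with 52 000 reads per population, sized so every pair
averages ≥100 mapped fragments per side even at the grid extremes; at
that coverage the median |FC error| lands near 0.1 and sign agreement at
|true FC| ≥ 1 is complete. The null control uses 100 pairs at equal
weights and 10 000 reads per population; the recall experiment 200 pairs
at 5% divergence, 300–800 nt, no reads. These sizes run the whole
acceptance script in roughly two minutes on one CPU.

## Known limitations

- E-values are calibration-grade, not publication-grade: K is tabulated
  or approximated, and gapped statistics reuse the ungapped λ.
- The mapper is single-best ungapped; fragments spanning true indels go
  unmapped, which is absorbed by round normalisation but wastes coverage
  at high divergence.
- No replicate-level variance model: classification is threshold-only, by
  design; with two pooled libraries there is no within-population
  replication to estimate dispersion from.
- Reciprocal-best pairing drops genuine many-to-many homology (recent
  paralogs); such transcripts are excluded rather than mis-assigned.
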