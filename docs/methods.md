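# Methods

## The read model

Smart-seq3-family libraries contain two read populations. 5′ reads begin
with the invariant TSO tag (`ATTGCGCAATG`), an 8-nt random UMI, optionally a
2-nt spacer (the improved-TSO design inserts `WW`, W = A/T, between the UMI
and the overhang), and a `GGG` overhang templated by the non-templated
cytosines the reverse transcriptase appends; the cDNA follows. Internal
reads derive from Tn5 tagmentation of the transcript body and carry no tag.
Both populations are needed for full-transcript coverage; their balance is a
library-quality metric reported per cell both as the bounded fraction
UMI/(UMI+internal) and as the raw ratio UMI:internal, since both conventions
are in circulation.

### Tag detection and quality filtering

Tag detection is an anchored (position-0) Hamming comparison with a mismatch
budget (default 2). Indels are not modelled: the library structure fixes the
tag position, so sliding or gapped matching would only add false positives.
Quality filtering discards a read when the index barcode has ≥4 bases under
phred 20 or the UMI has ≥3 bases under phred 20. The boundary semantics
("N bases under Q" read as *fails at ≥ N*) is one of two defensible readings
of the convention; it is the stricter one and is exposed as a config switch
(`strict_greater`). The UMI filter runs after tag detection (a UMI exists
only for tagged reads); the barcode filter applies to every read whenever
index reads are present, and is skipped with a log line otherwise.

## TSO strand invasion

During reverse transcription the TSO can anneal directly to template
sequence resembling its 3′ end (UMI+GGG) and prime from there ("strand
invasion"). The resulting read carries a pseudo-UMI copied from the
template, which breaks UMI-based molecule counting. Because the mis-priming
site flanks the read's 5′ mapping position, the artifact is detectable in
the reference: the detector reads a 20-bp window of genome sequence
upstream of the read start for plus-strand mappings, or downstream of
(read start + read length) for minus-strand mappings, and slides the
read's UMI — both with and without the GGG overhang — across it, counting
substitutions only. A read is called artifactual when the minimum distance
is ≤ the budget (0, 1 or 2; default 2, the most stringent screen).
Removal drops the read *and its mate* so no orphans remain; a flag mode
annotates instead (`ZF`/`ZA` tags).

Decisions worth recording:

- **Minus-strand anchor.** The 5′ end of a minus-strand read is estimated
  as read start + *query* length by default, faithful to the procedure as
  described; `anchor="reference_span"` uses the CIGAR span instead, which
  differs for spliced or indel-containing reads.
- **Window orientation.** Minus-strand windows are reverse-complemented
  before matching, so the search always runs in read orientation. This is
  the only orientation under which the priming mechanism is detectable
  symmetrically on both strands; the strand-symmetry property test pins it.
- **Tie-breaking.** When both query variants reach the same distance the
  overhang variant is reported (more specific).
- Candidates are primary, mapped, first-in-pair (for paired data),
  UMI-tagged records with mapping quality > 0; everything else is counted
  but never verdict-ed.

The background rate matters for interpretation: a random 8-mer (+GGG)
matches a random 20-bp window within 2 mismatches ~5.5% of the time (the
acceptance script estimates this by Monte Carlo). The simulator therefore
*guarantees* clean windows (minimum distance ≥3) for non-artifact UMI
reads by re-drawing molecule UMIs, so detector sensitivity and specificity
are exactly measurable; a `guarantee_clean_windows=False` mode leaves
windows unconstrained to test the false-positive rate against the null.

## Feature assignment and UMI collapse

Aligned blocks come from the CIGAR (N splits blocks). A read is **exon**
when all blocks lie inside exons of exactly one gene, **intron** when it
overlaps an intron (and possibly exons) of exactly one gene, **ambiguous**
when compatible with more than one gene (dropped from counting, not
fractionally assigned), and **intergenic** otherwise — including the rare
single-gene overlap that spills outside the gene body without touching an
intron. Assignment ignores strand by default (the chemistry is unstranded
after tagmentation); a strand-aware mode exists.

Molecule counts are connected components of the graph joining UMIs at
Hamming distance ≤1, computed per (gene, cell). This simple-cluster variant
is the default; a directional variant (edge a→b requires
count(a) ≥ 2·count(b)−1) is provided because the two differ on balanced
count configurations and the field uses both. UMI layers use UMI reads
only; read layers count every assigned read; the exon+intron layers merge
the exon and intron classes.

## Spliced / nascent classification

Fully spliced (exon–exon) reads have ≥1 N CIGAR operation *and* exclusive
exon assignment to one gene; nascent (exon–intron) reads overlap both exon
and intron of the same gene. The per-cell percentage uses as denominator
every read assigned to any gene (single-gene exon/intron plus multi-gene
ambiguous reads, which count as "other"); intergenic reads are excluded.
The policy is recorded in the output metadata and both pct_spliced and
pct_nascent are reported. Cells with zero assigned reads get a missing
(NaN) percentage rather than zero.

## Per-cell QC and downsampling

The cell filters are strict inequalities taken literally from their
"more than"/"less than" phrasing: pass requires pct feature-mapped > 50,
read pairs > 20,000, genes (exon+intron quantification) > 500 and
pct mito < 15; a cell at a boundary fails with a machine-readable reason.
Gene filtering keeps genes expressed (nonzero) in ≥10 passing cells and is
idempotent. For single-end data "read pairs" means reads; mitochondrial
reads are identified by contig (`chrM`/`MT`), with a gene-list override.

Downsampling is uniform sampling of raw read names without replacement; a
cell with fewer reads than the target is excluded (an outcome, not an
error). The saturation expectation used to validate it is closed-form: with
N reads of which n_g hit gene g, sampling d reads detects g with
probability 1 − C(N−n_g, d)/C(N, d).

## The simulator

The simulator is the package's test-bed: a random genome (one main contig
plus `chrM` when mitochondrial simulation is on), non-overlapping gene
models on both strands (exons ≥ read_length+30 bp, introns ≥ 40 bp, so
every read geometry fits), and per-cell reads drawn per the configured
fractions. Per read: UMI vs internal ~ Bernoulli(frac_umi_reads); UMI reads
become artifacts with frac_artifact (or exactly n_artifacts_per_level per
level); non-artifact reads draw a velocity class
(spliced/nascent/other ~ (0.3, 0.2, rest) by default) and, within "other",
a mitochondrial gene with the cell's mito fraction (drawn once per cell
from mito_fraction_range, default 2–10%). Defaults — 8-nt UMI, tag
`ATTGCGCAATG`, `GGG` overhang, 100-bp reads, 50% UMI reads — mirror the
protocol's library structure; 20 nuclear genes and 2,000 reads/cell keep
unit runs fast while the end-to-end checks use 20 cells × 10,000 reads.

Reads of one molecule share a gene and a UMI, but velocity class and
fragment geometry are drawn per read. Biologically the splicing state is a
property of the molecule, not the read; the per-read draw was chosen so
that per-cell class counts are exactly binomial, making the 3σ recovery
checks well-specified. Consequences: the simulator does not reproduce
within-molecule class correlation, and passing fraction-recovery tests says
nothing about duplicate-heavy libraries.

Artifacts are planted in a dedicated intergenic zone with non-overlapping
loci: the window is randomized, the UMI(+GGG) written in read orientation
at a random offset with exactly k substitutions confined to the UMI part,
and the locus re-drawn until a brute-force scan confirms the minimum
distance over all offsets and both variants equals k exactly. Minus-strand
plantings are reverse-complemented into reference coordinates.

Other simplifications, deliberate and visible in the outputs: no sequencing
error model (base qualities are constant Q40 except in the corrupt-quality
mode, which plants exactly 2/3 bad UMI bases and 3/4 bad barcode bases to
bracket the filter boundaries), no PCR chimeras, uniform transcript
abundance, exact pre-computed alignments (no aligner in the loop), and
paired mates that mirror the first read's span. Determinism is a contract:
one SimConfig, byte-identical FASTQ/SAM/GTF/FASTA/truth outputs.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; GTF (1-based closed) is the
  single conversion boundary.
- Windows are clipped at contig edges; a window shorter than a query makes
  that variant unmatchable, and an empty window never matches.
- Mixed-length UMI multisets are an error in collapse; an empty multiset
  collapses to 0.
- Downsampling preserves input read order; sampling at full depth returns
  the input unchanged.
- All randomness flows from numpy Generators seeded from the config/CLI
  seed; independent streams are derived per stage.

## Known limitations

- The detector treats fuzzy matching as Hamming distance (no indels), so a
  strand-invasion event with an indel in the invaded tract would escape.
- Exact runtime scales linearly in reads with pure-Python inner loops;
  the intended scale is simulation-backed validation and moderate desk
  analyses, not production alignment streams of 10⁸ reads.
- QC defaults target real-data scale (20,000 read pairs, 500 genes); on
  toy simulations every cell fails depth/genes by construction, which the
  QC tests exercise through designed profiles instead.
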