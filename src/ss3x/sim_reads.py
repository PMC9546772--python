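"""Synthetic Smart-seq3-structured reads with complete ground truth.

The simulator emits a toy genome (FASTA), gene models (GTF), per-cell reads
(FASTQ: R1 = cDNA read, I1 = index/barcode read, optional R2 mate), a
pre-aligned coordinate-sorted SAM carrying cell-barcode (BC) and UMI (UB)
tags, and a truth table labelling every read.

Read structure follows the Smart-seq3 TSO design: 5'-tagged reads start with
the invariant tag (default ATTGCGCAATG), an 8-nt UMI, an optional spacer
(the improved-TSO "WW" variant) and a GGG overhang, followed by cDNA;
internal (tagmentation-derived) reads are plain transcript fragments.
Strand-invasion artifacts are planted by embedding the read's UMI(+GGG) in
the genomic window flanking the read's 5' mapping position at a controlled
Hamming distance, which is exactly what the TSO filter later looks for.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from ._dna import BASES, hamming, mutate_positions, random_dna, revcomp
from .annotation import GeneModel, write_gtf

DEFAULT_TAG = "ATTGCGCAATG"
DEFAULT_OVERHANG = "GGG"
PHRED_HIGH = "I"  # Q40
PHRED_LOW = "4"   # Q19, just under the phred-20 filter threshold
WINDOW_WIDTH = 20
# planted-clean UMI reads are guaranteed >= this distance from their window
CLEAN_MIN_DISTANCE = 3
# (n_bad_barcode, n_bad_umi) combinations exercised by the corrupt-quality mode;
# they bracket the filter boundaries (barcode fails at >=4, UMI at >=3 bad bases)
CORRUPT_SPECS = ((3, 2), (4, 2), (3, 3), (4, 3))


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment.

    Fractions are per-read probabilities; with a fixed seed all outputs are
    byte-identical across runs.
    """

    n_cells: int = 8
    reads_per_cell: int = 2000
    frac_umi_reads: float = 0.5
    frac_artifact: float = 0.0
    artifact_mismatch_levels: tuple[int, ...] = (0, 1, 2)
    n_artifacts_per_level: int | None = None
    umi_length: int = 8
    tag_sequence: str = DEFAULT_TAG
    overhang: str = DEFAULT_OVERHANG
    spacer: str = ""
    frac_spliced: float = 0.3
    frac_nascent: float = 0.2
    mito_fraction_range: tuple[float, float] = (0.02, 0.10)
    read_length: int = 100
    paired: bool = False
    seed: int = 0
    # genome / annotation shape
    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (1, 4)
    n_mito_genes: int = 3
    molecules_per_gene: int = 20
    barcode_length: int = 8
    contig: str = "chr1"
    mito_contig: str = "chrM"
    # perturbation modes for testing the parser and the detector null
    corrupt_fraction: float = 0.0
    frac_tag_mutated: float = 0.0
    tag_mutation_levels: tuple[int, ...] = (1, 2, 3)
    guarantee_clean_windows: bool = True

    @property
    def structure_length(self) -> int:
        return (
            len(self.tag_sequence)
            + self.umi_length
            + len(self.spacer)
            + len(self.overhang)
        )

    @property
    def cdna_length(self) -> int:
        return self.read_length - self.structure_length

    def validate(self) -> None:
        for name in ("frac_umi_reads", "frac_artifact", "frac_spliced",
                     "frac_nascent", "corrupt_fraction", "frac_tag_mutated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_spliced + self.frac_nascent > 1.0:
            raise ValueError("frac_spliced + frac_nascent must be <= 1")
        lo, hi = self.mito_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("mito_fraction_range must satisfy 0 <= lo <= hi <= 1")
        p_other = 1.0 - self.frac_spliced - self.frac_nascent
        if self.n_mito_genes > 0 and hi > 0 and hi >= p_other:
            raise ValueError(
                "mito_fraction_range upper bound must be below the "
                "non-spliced/non-nascent fraction"
            )
        if self.cdna_length < 20:
            raise ValueError(
                "read_length too short to hold tag+UMI+spacer+overhang plus cDNA"
            )
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")
        if set(self.tag_sequence + self.overhang + self.spacer) - set(BASES):
            raise ValueError("tag/overhang/spacer must be A/C/G/T")
        for k in self.artifact_mismatch_levels:
            if k not in (0, 1, 2):
                raise ValueError("artifact_mismatch_levels must be within {0,1,2}")
            if k > self.umi_length:
                raise ValueError("mismatch level exceeds UMI length")


class SimSizingError(ValueError):
    """Genome too small to host the requested gene models or artifact loci."""


@dataclass
class SyntheticGenome:
    """In-memory toy genome; contigs are mutable during artifact planting."""

    contigs: dict[str, bytearray]
    gene_region: tuple[str, int, int]
    artifact_region: tuple[str, int, int]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def sequence(self, contig: str) -> str:
        return self.contigs[contig].decode()

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Clipped substring [start, end) of a contig."""
        seq = self.contigs[contig]
        return seq[max(0, start):max(0, min(end, len(seq)))].decode()

    def write_fasta(self, path, width: int = 70) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                s = seq.decode()
                for i in range(0, len(s), width):
                    fh.write(s[i:i + width] + "\n")
        return path


def _expected_artifacts(config: SimConfig) -> int:
    if config.n_artifacts_per_level is not None:
        return config.n_artifacts_per_level * len(config.artifact_mismatch_levels)
    n = config.n_cells * config.reads_per_cell
    return int(np.ceil(n * config.frac_umi_reads * config.frac_artifact * 1.5)) + 20


def make_genome(config: SimConfig) -> SyntheticGenome:
    """Random genome sized to host the configured genes and artifact loci."""
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    lo_ex, hi_ex = config.exons_per_gene
    max_gene_span = (
        hi_ex * (config.read_length + 130) + hi_ex * 160 + 120
    )
    gene_zone = config.n_genes * max_gene_span + 400
    stride = config.cdna_length + WINDOW_WIDTH + 28
    artifact_zone = _expected_artifacts(config) * stride + 400
    total = 200 + gene_zone + 200 + artifact_zone + 200
    total = max(total, 2000)

    def _random_contig(n):
        return bytearray(random_dna(rng, n), "ascii")

    contigs = {config.contig: _random_contig(total)}
    want_mito = config.n_mito_genes > 0 and config.mito_fraction_range[1] > 0
    if want_mito:
        mito_len = max(400, config.n_mito_genes * (config.read_length + 220) + 200)
        contigs[config.mito_contig] = _random_contig(mito_len)
    gene_region = (config.contig, 200, 200 + gene_zone)
    art_start = 200 + gene_zone + 200
    return SyntheticGenome(
        contigs=contigs,
        gene_region=gene_region,
        artifact_region=(config.contig, art_start, art_start + artifact_zone),
    )


def make_gene_models(
    genome: SyntheticGenome,
    n_genes: int,
    exons_per_gene: tuple[int, int] = (1, 4),
    seed: int = 0,
    n_mito_genes: int = 0,
    read_length: int = 100,
    mito_contig: str = "chrM",
) -> list[GeneModel]:
    """Place non-overlapping genes on both strands inside the gene region.

    Every exon is at least read_length+30 bp so contiguous reads fit inside
    one exon, and every intron is >= 40 bp so nascent reads can span an
    exon-intron boundary.
    """
    rng = np.random.default_rng([seed, 1])
    contig, region_start, region_end = genome.gene_region
    lo, hi = exons_per_gene
    genes: list[GeneModel] = []
    cursor = region_start
    for i in range(n_genes):
        n_ex = int(rng.integers(lo, hi + 1))
        exons = []
        pos = cursor
        for j in range(n_ex):
            elen = int(rng.integers(read_length + 30, read_length + 131))
            exons.append((pos, pos + elen))
            pos += elen
            if j < n_ex - 1:
                pos += int(rng.integers(40, 161))
        if pos > region_end:
            raise SimSizingError(
                f"cannot place {n_genes} genes inside region of "
                f"{region_end - region_start} bp"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"G{i + 1:04d}", contig, strand, tuple(exons)))
        cursor = pos + int(rng.integers(60, 121))
    if n_mito_genes > 0:
        if mito_contig not in genome.contigs:
            raise SimSizingError("mito genes requested but genome has no mito contig")
        mlen = len(genome.contigs[mito_contig])
        pos = 50
        for i in range(n_mito_genes):
            elen = int(rng.integers(read_length + 30, read_length + 131))
            if pos + elen > mlen - 50:
                raise SimSizingError("mito contig too small for requested genes")
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel(f"mt-G{i + 1:02d}", mito_contig, strand,
                          ((pos, pos + elen),))
            )
            pos += elen + 60
    return genes


# ---------------------------------------------------------------------------
# read geometry samplers (reference coordinates, 0-based half-open blocks)

def _sample_other(gene: GeneModel, L: int, rng) -> list[tuple[int, int]]:
    fitting = [e for e in gene.exons if e[1] - e[0] >= L]
    es, ee = fitting[int(rng.integers(0, len(fitting)))]
    s = int(rng.integers(es, ee - L + 1))
    return [(s, s + L)]


def _sample_spliced(gene: GeneModel, L: int, rng) -> list[tuple[int, int]]:
    j = int(rng.integers(0, len(gene.exons) - 1))
    e1, e2 = gene.exons[j], gene.exons[j + 1]
    a = int(rng.integers(10, L - 9))  # bases on the upstream exon
    a = min(a, e1[1] - e1[0])
    a = max(a, L - (e2[1] - e2[0]))
    return [(e1[1] - a, e1[1]), (e2[0], e2[0] + L - a)]


def _sample_nascent(gene: GeneModel, L: int, rng) -> list[tuple[int, int]]:
    j = int(rng.integers(0, len(gene.exons) - 1))
    exon_end = gene.exons[j][1]
    intron_len = gene.exons[j + 1][0] - exon_end
    o = int(rng.integers(5, min(L - 5, intron_len) + 1))  # bases inside intron
    s = exon_end - (L - o)
    return [(s, s + L)]


def _min_query_distance(umi: str, overhang: str, window: str) -> int:
    """Brute-force min Hamming distance of UMI / UMI+overhang over a window."""
    best = 10 ** 9
    for q in (umi + overhang, umi):
        L = len(q)
        for off in range(len(window) - L + 1):
            d = hamming(q, window[off:off + L])
            if d < best:
                best = d
    return best


def _oriented_window(genome: SyntheticGenome, contig: str, start: int,
                     aligned_len: int, strand: str) -> str:
    """The flanking genomic window in read orientation (see tso_filter)."""
    if strand == "+":
        return genome.fetch(contig, start - WINDOW_WIDTH, start)
    five_prime = start + aligned_len
    return revcomp(genome.fetch(contig, five_prime, five_prime + WINDOW_WIDTH))


@dataclass
class SimOutput:
    """Paths plus in-memory truth for one simulated experiment."""

    outdir: Path
    fasta: Path
    gtf: Path
    fastq_r1: Path
    fastq_i1: Path
    fastq_r2: Path | None
    sam: Path
    truth_tsv: Path
    cells_tsv: Path
    truth: pd.DataFrame
    cells: pd.DataFrame
    genes: list[GeneModel]
    genome: SyntheticGenome
    config: SimConfig


def simulate_reads(
    genome: SyntheticGenome,
    genes: list[GeneModel],
    config: SimConfig,
    outdir,
) -> SimOutput:
    """Simulate reads, write FASTQ/SAM/GTF/FASTA/truth, return everything.

    Deterministic: a fixed SimConfig yields byte-identical output files.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, 2])
    L_umi = config.cdna_length
    L_int = config.read_length

    nuclear = [g for g in genes if g.contig != config.mito_contig]
    multi = [g for g in nuclear if len(g.exons) >= 2]
    mito_genes = [g for g in genes if g.contig == config.mito_contig]
    if (config.frac_spliced > 0 or config.frac_nascent > 0) and not multi:
        raise ValueError("spliced/nascent reads requested but no multi-exon gene")
    if not nuclear:
        raise ValueError("no nuclear genes to simulate from")

    # distinct cell barcodes; the barcode string is the cell identifier
    barcodes: list[str] = []
    seen = set()
    while len(barcodes) < config.n_cells:
        bc = random_dna(rng, config.barcode_length)
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)
    lo_m, hi_m = config.mito_fraction_range
    use_mito = bool(mito_genes) and hi_m > 0
    mito_targets = (
        rng.uniform(lo_m, hi_m, size=config.n_cells) if use_mito
        else np.zeros(config.n_cells)
    )

    # ---- phase 1: skeleton (cell, umi/internal) -------------------------
    reads: list[dict] = []
    for ci, cell in enumerate(barcodes):
        for _ in range(config.reads_per_cell):
            reads.append({
                "name": f"r{len(reads):08d}",
                "cell": cell,
                "cell_index": ci,
                "is_umi": bool(rng.random() < config.frac_umi_reads),
                "artifact_level": None,
            })

    # ---- phase 2: artifact assignment ----------------------------------
    umi_indices = [i for i, r in enumerate(reads) if r["is_umi"]]
    levels = tuple(config.artifact_mismatch_levels)
    if config.n_artifacts_per_level is not None:
        need = config.n_artifacts_per_level * len(levels)
        if need > len(umi_indices):
            raise ValueError(
                f"requested {need} artifacts but only {len(umi_indices)} UMI reads"
            )
        chosen = rng.choice(len(umi_indices), size=need, replace=False)
        assigned = np.repeat(np.array(levels), config.n_artifacts_per_level)
        for pos, lvl in zip(chosen, assigned):
            reads[umi_indices[int(pos)]]["artifact_level"] = int(lvl)
    elif config.frac_artifact > 0:
        for i in umi_indices:
            if rng.random() < config.frac_artifact:
                reads[i]["artifact_level"] = int(levels[int(rng.integers(0, len(levels)))])

    # ---- phase 3: gene / class / geometry for non-artifact reads -------
    p_other = 1.0 - config.frac_spliced - config.frac_nascent
    molecules: dict[tuple[str, str], dict[int, tuple[str, str]]] = {}
    for r in reads:
        if r["artifact_level"] is not None:
            r.update(velocity_class="other", gene=None, molecule=None,
                     umi=None, mito=False)
            continue
        u = rng.random()
        if u < config.frac_spliced:
            vclass = "spliced"
            gene = multi[int(rng.integers(0, len(multi)))]
        elif u < config.frac_spliced + config.frac_nascent:
            vclass = "nascent"
            gene = multi[int(rng.integers(0, len(multi)))]
        else:
            vclass = "other"
            m = mito_targets[r["cell_index"]]
            if use_mito and rng.random() < m / p_other:
                gene = mito_genes[int(rng.integers(0, len(mito_genes)))]
            else:
                gene = nuclear[int(rng.integers(0, len(nuclear)))]
        L = L_umi if r["is_umi"] else L_int
        sampler = {"spliced": _sample_spliced, "nascent": _sample_nascent,
                   "other": _sample_other}[vclass]
        blocks = sampler(gene, L, rng)
        r.update(
            velocity_class=vclass,
            gene=gene.gene_id,
            contig=gene.contig,
            strand=gene.strand,
            blocks=blocks,
            mito=gene.contig == config.mito_contig,
            molecule=None,
            umi=None,
        )
        if r["is_umi"]:
            key = (r["cell"], gene.gene_id)
            pool = molecules.setdefault(key, {})
            idx = int(rng.integers(0, config.molecules_per_gene))
            if idx not in pool:
                pool[idx] = (f"{r['cell']}:{gene.gene_id}:m{idx}",
                             random_dna(rng, config.umi_length))
            r["molecule"], r["umi"] = pool[idx]

    # ---- phase 4: plant artifacts (mutates the genome) -----------------
    art_contig, art_start, art_end = genome.artifact_region
    cursor = art_start
    qlen = config.umi_length + len(config.overhang)
    stride = L_umi + WINDOW_WIDTH + 28
    seq_arr = genome.contigs[art_contig]
    for r in reads:
        lvl = r["artifact_level"]
        if lvl is None:
            continue
        if cursor + stride > art_end:
            raise SimSizingError("artifact region exhausted; enlarge genome")
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            w0 = cursor
            start = cursor + WINDOW_WIDTH
        else:
            start = cursor
            w0 = cursor + L_umi
        for _attempt in range(200):
            umi = random_dna(rng, config.umi_length)
            seq_arr[w0:w0 + WINDOW_WIDTH] = random_dna(rng, WINDOW_WIDTH).encode()
            off = int(rng.integers(0, WINDOW_WIDTH - qlen + 1))
            mm_pos = rng.choice(config.umi_length, size=lvl, replace=False)
            planted = mutate_positions(umi + config.overhang, mm_pos, rng)
            if strand == "+":
                seq_arr[w0 + off:w0 + off + qlen] = planted.encode()
            else:
                a = w0 + WINDOW_WIDTH - off - qlen
                seq_arr[a:a + qlen] = revcomp(planted).encode()
            window = _oriented_window(genome, art_contig, start, L_umi, strand)
            if _min_query_distance(umi, config.overhang, window) == lvl:
                break
        else:
            raise RuntimeError("failed to plant artifact at requested level")
        r.update(
            umi=umi, strand=strand, contig=art_contig,
            blocks=[(start, start + L_umi)],
        )
        cursor += stride

    # ---- phase 5: guarantee clean windows for non-artifact UMI reads ---
    if config.guarantee_clean_windows:
        by_molecule: dict[str, list[dict]] = {}
        for r in reads:
            if r["is_umi"] and r["artifact_level"] is None:
                by_molecule.setdefault(r["molecule"], []).append(r)
        for mol, group in by_molecule.items():
            windows = [
                _oriented_window(genome, r["contig"], r["blocks"][0][0],
                                 sum(e - s for s, e in r["blocks"]), r["strand"])
                for r in group
            ]
            umi = group[0]["umi"]
            for _attempt in range(500):
                if all(
                    _min_query_distance(umi, config.overhang, w) >= CLEAN_MIN_DISTANCE
                    for w in windows
                ):
                    break
                umi = random_dna(rng, config.umi_length)
            else:
                raise RuntimeError(f"could not find a clean UMI for molecule {mol}")
            for r in group:
                r["umi"] = umi

    # ---- phase 6: tag mutations and corrupt qualities ------------------
    for r in reads:
        r["tag_mismatches"] = 0
        r["n_bad_barcode"] = 0
        r["n_bad_umi"] = 0
        if r["is_umi"] and config.frac_tag_mutated > 0 and \
                rng.random() < config.frac_tag_mutated:
            k = int(config.tag_mutation_levels[
                int(rng.integers(0, len(config.tag_mutation_levels)))])
            r["tag_mismatches"] = k
        if config.corrupt_fraction > 0 and rng.random() < config.corrupt_fraction:
            spec = CORRUPT_SPECS[int(rng.integers(0, len(CORRUPT_SPECS)))]
            r["n_bad_barcode"] = spec[0]
            r["n_bad_umi"] = spec[1] if r["is_umi"] else 0

    # ---- phase 7: emit FASTQ / SAM / truth -----------------------------
    fasta = genome.write_fasta(outdir / "genome.fa")
    gtf = write_gtf(genes, outdir / "genes.gtf")

    contig_order = list(genome.contigs)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(genome.contigs[c])} for c in contig_order],
    })
    tid = {c: i for i, c in enumerate(contig_order)}

    r1_path = outdir / "reads_R1.fastq"
    i1_path = outdir / "reads_I1.fastq"
    r2_path = outdir / "reads_R2.fastq" if config.paired else None
    sam_path = outdir / "alignments.sam"

    sam_records: list[tuple[int, int, int, pysam.AlignedSegment]] = []
    truth_rows = []

    with open(r1_path, "w") as f_r1, open(i1_path, "w") as f_i1:
        f_r2 = open(r2_path, "w") if config.paired else None
        try:
            for r in reads:
                blocks = r["blocks"]
                ref_seq = "".join(
                    genome.fetch(r["contig"], s, e) for s, e in blocks
                )
                as_seq = revcomp(ref_seq) if r["strand"] == "-" else ref_seq
                if r["is_umi"]:
                    tag_used = config.tag_sequence
                    if r["tag_mismatches"]:
                        pos = rng.choice(len(tag_used), size=r["tag_mismatches"],
                                         replace=False)
                        tag_used = mutate_positions(tag_used, pos, rng)
                    fq_seq = (tag_used + r["umi"] + config.spacer
                              + config.overhang + as_seq)
                else:
                    fq_seq = as_seq
                qual = [PHRED_HIGH] * len(fq_seq)
                if r["n_bad_umi"]:
                    u0 = len(config.tag_sequence)
                    pos = rng.choice(config.umi_length, size=r["n_bad_umi"],
                                     replace=False)
                    for p in pos:
                        qual[u0 + int(p)] = PHRED_LOW
                f_r1.write(f"@{r['name']}\n{fq_seq}\n+\n{''.join(qual)}\n")

                bc_qual = [PHRED_HIGH] * config.barcode_length
                if r["n_bad_barcode"]:
                    pos = rng.choice(config.barcode_length,
                                     size=r["n_bad_barcode"], replace=False)
                    for p in pos:
                        bc_qual[int(p)] = PHRED_LOW
                f_i1.write(f"@{r['name']}\n{r['cell']}\n+\n{''.join(bc_qual)}\n")

                # SAM record(s); SEQ stored in reference orientation
                is_rev = r["strand"] == "-"
                cig = []
                for bi, (s, e) in enumerate(blocks):
                    if bi:
                        cig.append((3, s - blocks[bi - 1][1]))  # N
                    cig.append((0, e - s))  # M
                a = pysam.AlignedSegment(header)
                a.query_name = r["name"]
                a.query_sequence = ref_seq
                a.reference_id = tid[r["contig"]]
                a.reference_start = blocks[0][0]
                a.mapping_quality = 255
                a.cigartuples = cig
                a.query_qualities = pysam.qualitystring_to_array(
                    PHRED_HIGH * len(ref_seq))
                flag = 16 if is_rev else 0
                tags = [("BC", r["cell"])]
                if r["is_umi"]:
                    tags.append(("UB", r["umi"]))
                if config.paired:
                    flag |= 0x1 | 0x2 | 0x40 | (0x20 if not is_rev else 0)
                    a.next_reference_id = tid[r["contig"]]
                    a.next_reference_start = blocks[0][0]
                    b = pysam.AlignedSegment(header)
                    b.query_name = r["name"]
                    b.query_sequence = ref_seq
                    b.reference_id = tid[r["contig"]]
                    b.reference_start = blocks[0][0]
                    b.mapping_quality = 255
                    b.cigartuples = cig
                    b.query_qualities = pysam.qualitystring_to_array(
                        PHRED_HIGH * len(ref_seq))
                    b.flag = (0x1 | 0x2 | 0x80
                              | (0 if is_rev else 0x10)
                              | (0x20 if is_rev else 0))
                    b.next_reference_id = tid[r["contig"]]
                    b.next_reference_start = blocks[0][0]
                    b.set_tags(tags)
                    mate_seq = revcomp(ref_seq) if not is_rev else ref_seq
                    f_r2.write(f"@{r['name']}\n{mate_seq}\n+\n"
                               f"{PHRED_HIGH * len(mate_seq)}\n")
                    sam_records.append(
                        (tid[r["contig"]], blocks[0][0], 1, b))
                a.flag = flag
                a.set_tags(tags)
                sam_records.append((tid[r["contig"]], blocks[0][0], 0, a))

                truth_rows.append({
                    "read_name": r["name"],
                    "cell": r["cell"],
                    "class": "umi_read" if r["is_umi"] else "internal_read",
                    "artifact_level": (
                        "none" if r["artifact_level"] is None
                        else str(r["artifact_level"])
                    ),
                    "velocity_class": r["velocity_class"],
                    "gene_id": r["gene"] or "",
                    "molecule_id": r["molecule"] or "",
                    "umi": r["umi"] or "",
                    "mito": int(bool(r.get("mito"))),
                    "tag_mismatches": r["tag_mismatches"],
                    "n_bad_barcode": r["n_bad_barcode"],
                    "n_bad_umi": r["n_bad_umi"],
                    "contig": r["contig"],
                    "start": blocks[0][0],
                    "strand": r["strand"],
                })
        finally:
            if f_r2 is not None:
                f_r2.close()

    sam_records.sort(key=lambda t: (t[0], t[1], t[3].query_name, t[2]))
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for _, _, _, rec in sam_records:
            out.write(rec)

    truth = pd.DataFrame(truth_rows)
    truth_tsv = outdir / "truth.tsv"
    truth.to_csv(truth_tsv, sep="\t", index=False)
    cells = pd.DataFrame({"cell": barcodes, "mito_target": mito_targets})
    cells_tsv = outdir / "cells.tsv"
    cells.to_csv(cells_tsv, sep="\t", index=False)

    return SimOutput(
        outdir=outdir, fasta=fasta, gtf=gtf, fastq_r1=r1_path,
        fastq_i1=i1_path, fastq_r2=r2_path, sam=sam_path,
        truth_tsv=truth_tsv, cells_tsv=cells_tsv, truth=truth, cells=cells,
        genes=genes, genome=genome, config=config,
    )


def simulate(config: SimConfig, outdir) -> SimOutput:
    """Convenience wrapper: genome -> gene models -> reads in one call."""
    genome = make_genome(config)
    genes = make_gene_models(
        genome,
        n_genes=config.n_genes,
        exons_per_gene=config.exons_per_gene,
        seed=config.seed,
        n_mito_genes=(config.n_mito_genes
                      if config.mito_fraction_range[1] > 0 else 0),
        read_length=config.read_length,
        mito_contig=config.mito_contig,
    )
    return simulate_reads(genome, genes, config, outdir)


def read_truth(path) -> pd.DataFrame:
    """Load a simulator truth table, preserving string columns."""
    return pd.read_csv(
        path, sep="\t",
        dtype={"artifact_level": str, "gene_id": str, "molecule_id": str,
               "umi": str, "cell": str},
        keep_default_na=False,
    )
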