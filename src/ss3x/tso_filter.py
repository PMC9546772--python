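"""Detection and removal of TSO strand-invasion artifact reads.

The TSO can mis-prime directly on genomic (or cDNA) sequence that resembles
its UMI+GGG 3' end; the resulting read carries a "UMI" that is actually a
copy of template sequence. Such reads are detectable because the genomic
sequence flanking the read's 5' mapping position contains the read's UMI
(with or without the GGG overhang).

For each candidate alignment (primary, mapped, first-in-pair for paired
data, carrying a UMI tag) a 20-bp window of genome sequence is read:
upstream of the read start for plus-strand mappings, or downstream of
read start + read length for minus-strand mappings. Minus-strand windows
are reverse-complemented so the search always runs in read orientation.
The UMI and UMI+overhang are slid over the window and a read is called
artifactual when the minimum Hamming distance is at or below the mismatch
budget (0, 1 or 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

from ._dna import hamming, revcomp

WINDOW_WIDTH = 20


@dataclass(frozen=True)
class WindowSpec:
    """Genomic window to search, 0-based half-open, clipped to the contig."""

    contig: str
    start: int
    end: int
    orientation: str  # "as_reference" | "reverse_complement"

    def __post_init__(self):
        if self.end - self.start > WINDOW_WIDTH:
            raise ValueError("window wider than the configured width")


@dataclass
class ArtifactCall:
    """Per-read verdict of the strand-invasion detector."""

    read_name: str
    umi: str
    window: str
    best_mismatches: int | None
    matched_offset: int | None
    overhang_used: bool

    def verdict(self, max_mm: int) -> bool:
        return self.best_mismatches is not None and self.best_mismatches <= max_mm


class MissingContigError(KeyError):
    pass


class _GenomeAdapter:
    """Uniform clipped-fetch access over pyfaidx.Fasta, mappings, or the
    simulator's SyntheticGenome."""

    def __init__(self, genome):
        if isinstance(genome, (str, Path)):
            import pyfaidx
            genome = pyfaidx.Fasta(str(genome))
        self._genome = genome

    def length(self, contig: str) -> int:
        g = self._genome
        if hasattr(g, "contigs"):  # SyntheticGenome
            if contig not in g.contigs:
                raise MissingContigError(contig)
            return len(g.contigs[contig])
        if contig not in g:
            raise MissingContigError(contig)
        return len(g[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        n = self.length(contig)
        start = max(0, start)
        end = max(start, min(end, n))
        g = self._genome
        if hasattr(g, "contigs"):  # SyntheticGenome
            return g.fetch(contig, start, end)
        return str(g[contig][start:end]).upper()


def select_reads(alignments, umi_tag: str = "UB", counters: dict | None = None):
    """Yield detector candidates from an alignment stream.

    Paired data: primary, mapped, first-in-pair records; single-end: all
    primary mapped records. Secondary/supplementary/unmapped records, reads
    with mapping quality 0 and reads lacking the UMI tag are skipped (and
    counted when a counters dict is supplied).
    """
    c = counters if counters is not None else {}
    for key in ("records", "candidates", "skipped_flags", "skipped_mapq0",
                "skipped_no_umi"):
        c.setdefault(key, 0)
    for read in alignments:
        c["records"] += 1
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            c["skipped_flags"] += 1
            continue
        if read.is_paired and not read.is_read1:
            c["skipped_flags"] += 1
            continue
        if read.mapping_quality == 0:
            c["skipped_mapq0"] += 1
            continue
        if not read.has_tag(umi_tag):
            c["skipped_no_umi"] += 1
            continue
        c["candidates"] += 1
        yield read


def compute_window(
    contig: str,
    start: int,
    is_reverse: bool,
    read_length: int,
    contig_length: int,
    width: int = WINDOW_WIDTH,
) -> WindowSpec:
    """Window spec for a mapped read.

    Plus strand: [start - width, start) in reference orientation.
    Minus strand: [start + read_length, start + read_length + width),
    returned flagged for reverse complement so matching runs in read
    orientation. Windows are clipped at contig edges; a window fully
    outside the contig comes back empty.
    """
    if not is_reverse:
        w_start = max(0, start - width)
        w_end = max(0, min(start, contig_length))
        return WindowSpec(contig, w_start, max(w_start, w_end), "as_reference")
    five_prime = start + read_length
    w_start = min(max(0, five_prime), contig_length)
    w_end = min(five_prime + width, contig_length)
    return WindowSpec(contig, w_start, max(w_start, w_end), "reverse_complement")


def window_sequence(genome: _GenomeAdapter, spec: WindowSpec) -> str:
    seq = genome.fetch(spec.contig, spec.start, spec.end)
    return revcomp(seq) if spec.orientation == "reverse_complement" else seq


def fuzzy_match(
    umi: str, overhang: str, window_sequence: str, max_mm: int
) -> tuple[bool, int | None, int | None, bool]:
    """Slide UMI+overhang and bare UMI over a window, Hamming distance only.

    Returns (matched, best_mismatches, offset, overhang_used), minimizing
    over offsets and both query variants; ties prefer the overhang variant
    (the more specific query). Variants longer than the window are
    unmatchable; an empty window never matches.
    """
    best: tuple[int, int, bool] | None = None
    for used, query in ((True, umi + overhang), (False, umi)):
        qlen = len(query)
        for off in range(len(window_sequence) - qlen + 1):
            mm = hamming(query, window_sequence[off:off + qlen])
            if best is None or mm < best[0]:
                best = (mm, off, used)
    if best is None:
        return False, None, None, False
    return best[0] <= max_mm, best[0], best[1], best[2]


def classify_alignment(
    read: pysam.AlignedSegment,
    genome: _GenomeAdapter,
    overhang: str = "GGG",
    umi_tag: str = "UB",
    max_mm: int = 2,
    anchor: str = "query_length",
    width: int = WINDOW_WIDTH,
) -> ArtifactCall:
    """Run the detector on one candidate alignment.

    anchor controls the minus-strand 5'-end estimate: "query_length" (read
    start + query length, faithful to the described procedure) or
    "reference_span" (CIGAR span on the reference, which differs for
    spliced/indel reads).
    """
    contig = read.reference_name
    if anchor == "query_length":
        rlen = read.query_length or read.infer_query_length() or 0
    elif anchor == "reference_span":
        rlen = read.reference_end - read.reference_start
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    spec = compute_window(
        contig, read.reference_start, read.is_reverse, rlen,
        genome.length(contig), width,
    )
    window = window_sequence(genome, spec)
    umi = str(read.get_tag(umi_tag))
    matched, best_mm, offset, used = fuzzy_match(umi, overhang, window, max_mm)
    return ArtifactCall(read.query_name, umi, window, best_mm, offset, used)


@dataclass
class FilterReport:
    max_mm: int
    mode: str
    counters: dict
    flagged_at: dict[int, int]
    artifact_read_names: set[str]
    n_removed_records: int = 0
    per_cell: pd.DataFrame | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "max_mm": self.max_mm,
            "mode": self.mode,
            "counters": self.counters,
            "flagged_at": {str(k): v for k, v in self.flagged_at.items()},
            "n_artifact_reads": len(self.artifact_read_names),
            "n_removed_records": self.n_removed_records,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path:
            Path(path).write_text(text)
        return text


def filter_alignment_file(
    in_path,
    genome,
    out_path=None,
    max_mm: int = 2,
    mode: str = "remove",
    umi_tag: str = "UB",
    cell_tag: str = "BC",
    overhang: str = "GGG",
    anchor: str = "query_length",
    width: int = WINDOW_WIDTH,
) -> FilterReport:
    """Detect artifact reads in a SAM/BAM file and remove or flag them.

    mode="remove" drops the artifact read and its mate (no orphan mates);
    mode="flag" keeps all records, annotating flagged ones with ZA
    (best mismatch count) and ZF (1 = artifact at the given budget).
    A contig present in the alignments but absent from the genome raises
    MissingContigError naming the contig.
    """
    if mode not in ("remove", "flag"):
        raise ValueError(f"mode must be 'remove' or 'flag', got {mode!r}")
    adapter = genome if isinstance(genome, _GenomeAdapter) else _GenomeAdapter(genome)
    counters: dict = {}
    flagged_at = {0: 0, 1: 0, 2: 0}
    artifact_names: set[str] = set()
    best_by_name: dict[str, int | None] = {}
    per_cell: dict[str, dict[str, int]] = {}

    with pysam.AlignmentFile(str(in_path), check_sq=False) as af:
        for read in select_reads(af, umi_tag=umi_tag, counters=counters):
            call = classify_alignment(
                read, adapter, overhang=overhang, umi_tag=umi_tag,
                max_mm=max_mm, anchor=anchor, width=width,
            )
            cell = str(read.get_tag(cell_tag)) if read.has_tag(cell_tag) else ""
            stats = per_cell.setdefault(
                cell, {"scanned": 0, "flagged": 0, "removed": 0})
            stats["scanned"] += 1
            best_by_name[read.query_name] = call.best_mismatches
            if call.best_mismatches is not None:
                for k in flagged_at:
                    if call.best_mismatches <= k:
                        flagged_at[k] += 1
            if call.verdict(max_mm):
                artifact_names.add(read.query_name)
                stats["flagged"] += 1
                if mode == "remove":
                    stats["removed"] += 1

    report = FilterReport(
        max_mm=max_mm, mode=mode, counters=counters, flagged_at=flagged_at,
        artifact_read_names=artifact_names,
    )
    if out_path is not None:
        n_removed = 0
        with pysam.AlignmentFile(str(in_path), check_sq=False) as af:
            out_mode = "wb" if str(out_path).endswith(".bam") else "w"
            with pysam.AlignmentFile(str(out_path), out_mode,
                                     header=af.header) as out:
                for read in af:
                    if read.query_name in artifact_names:
                        if mode == "remove":
                            n_removed += 1
                            continue
                        read.set_tag("ZF", 1)
                        best = best_by_name.get(read.query_name)
                        if best is not None:
                            read.set_tag("ZA", best)
                    out.write(read)
        report.n_removed_records = n_removed
    report.per_cell = (
        pd.DataFrame.from_dict(per_cell, orient="index")
        .rename_axis("cell").reset_index()
    )
    return report
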