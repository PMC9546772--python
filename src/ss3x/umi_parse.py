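"""Classify raw reads into UMI-containing vs internal and extract UMIs.

A UMI-containing read starts (position 0, no sliding) with the TSO tag
sequence, matched by Hamming distance with a mismatch budget (default 2),
followed by the UMI, an optional spacer and the GGG overhang. Reads failing
the per-base phred filters on the index barcode or the UMI are discarded:
by default a barcode with >= 4 bases under phred 20, or a UMI with >= 3
bases under phred 20, fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pysam

from ._dna import hamming, phred_from_string
from .sim_reads import DEFAULT_OVERHANG, DEFAULT_TAG

UMI_READ = "umi_read"
INTERNAL_READ = "internal_read"
DISCARDED = "discarded"


@dataclass
class ParseConfig:
    tag_sequence: str = DEFAULT_TAG
    max_tag_mismatches: int = 2
    umi_length: int = 8
    overhang: str = DEFAULT_OVERHANG
    spacer: str = ""
    barcode_min_phred: int = 20
    barcode_max_bad_bases: int = 4
    umi_min_phred: int = 20
    umi_max_bad_bases: int = 3
    # ">= N bad bases fails" (default) vs "> N bad bases fails"
    strict_greater: bool = False

    def __post_init__(self):
        if self.max_tag_mismatches >= len(self.tag_sequence):
            raise ValueError("max_tag_mismatches must be < tag length")
        if self.umi_length < 1:
            raise ValueError("umi_length must be >= 1")

    @property
    def structure_length(self) -> int:
        return (len(self.tag_sequence) + self.umi_length
                + len(self.spacer) + len(self.overhang))


@dataclass
class ParsedRead:
    read_name: str
    cell: str | None
    klass: str  # umi_read | internal_read | discarded
    umi: str | None
    tag_mismatches: int | None
    trimmed_sequence: str
    discard_reason: str | None = None


def detect_tag(read_sequence: str, config: ParseConfig) -> tuple[bool, int | None]:
    """Anchored Hamming comparison of the read prefix against the tag.

    Returns (is_umi_read, mismatches); a read too short to contain the full
    tag+UMI+spacer+overhang structure is never a UMI read.
    """
    tag = config.tag_sequence
    if len(read_sequence) < len(tag):
        return False, None
    mm = hamming(read_sequence[:len(tag)], tag)
    return mm <= config.max_tag_mismatches, mm


def quality_filter(
    barcode_quals, umi_quals, config: ParseConfig
) -> tuple[bool, str | None]:
    """Apply the per-base phred filters; either argument may be None to skip.

    Fails when the number of bases under the phred threshold reaches the
    configured count (>= by default).
    """
    def _fails(quals, min_phred, max_bad):
        n_bad = sum(1 for q in quals if q < min_phred)
        return n_bad > max_bad if config.strict_greater else n_bad >= max_bad

    if barcode_quals is not None and _fails(
            barcode_quals, config.barcode_min_phred, config.barcode_max_bad_bases):
        return False, "barcode_quality"
    if umi_quals is not None and _fails(
            umi_quals, config.umi_min_phred, config.umi_max_bad_bases):
        return False, "umi_quality"
    return True, None


def extract_umi(read_name: str, sequence: str, config: ParseConfig) -> ParsedRead:
    """Extract the UMI and trim tag+UMI+spacer+overhang off a tagged read."""
    tag_len = len(config.tag_sequence)
    if len(sequence) < config.structure_length:
        return ParsedRead(read_name, None, DISCARDED, None, None, "",
                          discard_reason="truncated")
    umi = sequence[tag_len:tag_len + config.umi_length]
    trimmed = sequence[config.structure_length:]
    return ParsedRead(read_name, None, UMI_READ, umi, None, trimmed)


def parse_read(
    read_name: str,
    sequence: str,
    qualities: str,
    config: ParseConfig,
    barcode_quals: list[int] | None = None,
    cell: str | None = None,
) -> ParsedRead:
    """Classify one read and apply quality filters.

    The barcode filter (when index-read qualities are given) applies to every
    read; the UMI filter applies after tag detection, to UMI reads only.
    """
    is_umi, mm = detect_tag(sequence, config)
    if is_umi and len(sequence) < config.structure_length:
        return ParsedRead(read_name, cell, DISCARDED, None, mm, "",
                          discard_reason="truncated")
    umi_quals = None
    if is_umi:
        tag_len = len(config.tag_sequence)
        umi_quals = phred_from_string(
            qualities[tag_len:tag_len + config.umi_length])
    ok, reason = quality_filter(barcode_quals, umi_quals, config)
    if not ok:
        return ParsedRead(read_name, cell, DISCARDED, None, mm, "",
                          discard_reason=reason)
    if is_umi:
        parsed = extract_umi(read_name, sequence, config)
        parsed.cell = cell
        parsed.tag_mismatches = mm
        return parsed
    return ParsedRead(read_name, cell, INTERNAL_READ, None, mm, sequence)


def parse_fastq(
    r1_path,
    config: ParseConfig | None = None,
    i1_path=None,
    out_fastq=None,
    out_tsv=None,
) -> pd.DataFrame:
    """Parse a FASTQ file (optionally with a matched index read file).

    Returns one row per read with its class, UMI and discard reason; when
    out_fastq is given, trimmed sequences of retained reads are written.
    """
    config = config or ParseConfig()
    rows = []
    out_fh = open(out_fastq, "w") if out_fastq else None
    try:
        with pysam.FastxFile(str(r1_path)) as r1:
            i1 = pysam.FastxFile(str(i1_path)) if i1_path else None
            for entry in r1:
                cell = None
                bc_quals = None
                if i1 is not None:
                    idx = next(i1)
                    if idx.name != entry.name:
                        raise ValueError(
                            f"index read {idx.name} does not match {entry.name}")
                    cell = idx.sequence
                    bc_quals = phred_from_string(idx.quality)
                parsed = parse_read(entry.name, entry.sequence, entry.quality,
                                    config, barcode_quals=bc_quals, cell=cell)
                rows.append({
                    "read_name": parsed.read_name,
                    "cell": parsed.cell or "",
                    "class": parsed.klass,
                    "umi": parsed.umi or "",
                    "tag_mismatches": (
                        -1 if parsed.tag_mismatches is None
                        else parsed.tag_mismatches),
                    "discard_reason": parsed.discard_reason or "",
                })
                if out_fh is not None and parsed.klass != DISCARDED:
                    trimmed_qual = (
                        entry.quality[-len(parsed.trimmed_sequence):]
                        if parsed.trimmed_sequence else "")
                    out_fh.write(f"@{parsed.read_name}\n"
                                 f"{parsed.trimmed_sequence}\n+\n{trimmed_qual}\n")
            if i1 is not None:
                i1.close()
    finally:
        if out_fh is not None:
            out_fh.close()
    df = pd.DataFrame(rows)
    if out_tsv:
        df.to_csv(out_tsv, sep="\t", index=False)
    return df
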