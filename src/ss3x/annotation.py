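"""Gene models and GTF input/output.

Coordinates are 0-based half-open everywhere in memory; the single conversion
point to the GTF convention (1-based, closed) is the writer/reader pair below.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class GeneModel:
    """A gene as a strand plus sorted, non-overlapping exon intervals.

    Introns are derived as the gaps between consecutive exons; a single-exon
    gene has none.
    """

    gene_id: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) < 1:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = None
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(f"gene {self.gene_id}: bad exon ({start}, {end})")
            if prev_end is not None and start <= prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted and non-overlapping"
                )
            prev_end = end

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    def contains_in_exon(self, start: int, end: int) -> bool:
        """True if [start, end) lies entirely inside one exon."""
        return any(es <= start and end <= ee for es, ee in self.exons)


def write_gtf(genes: list[GeneModel], path) -> Path:
    """Write gene models as GTF (gene + exon features, 1-based closed)."""
    path = Path(path)
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.contig}\tss3x\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for es, ee in g.exons:
                fh.write(
                    f"{g.contig}\tss3x\texon\t{es + 1}\t{ee}\t.\t{g.strand}\t.\t{attrs}\n"
                )
    return path


def _parse_attrs(attr_field: str) -> dict[str, str]:
    out = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf(path) -> list[GeneModel]:
    """Read gene models back from GTF (exon features define the gene)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            contig, _, _, start, end, _, strand, _, attrs = fields[:9]
            gene_id = _parse_attrs(attrs).get("gene_id")
            if gene_id is None:
                raise ValueError(f"exon line without gene_id in {path}")
            if gene_id not in exons:
                exons[gene_id] = []
                meta[gene_id] = (contig, strand)
                order.append(gene_id)
            exons[gene_id].append((int(start) - 1, int(end)))
    genes = []
    for gid in order:
        contig, strand = meta[gid]
        genes.append(
            GeneModel(gid, contig, strand, tuple(sorted(exons[gid])))
        )
    return genes
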