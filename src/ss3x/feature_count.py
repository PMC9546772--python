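"""Exon/intron feature assignment and error-corrected UMI counting.

Reads are assigned from their CIGAR-derived aligned blocks: a read is
"exon" when every block lies inside exons of exactly one gene, "intron"
when it overlaps an intron (and possibly exons) of exactly one gene,
"ambiguous" when compatible with more than one gene (dropped from
counting rather than fractionally assigned), and "intergenic" otherwise.
Assignment ignores read strand by default — the chemistry is unstranded
after tagmentation — with a strand-aware mode available.

UMI counts are error-corrected by merging UMIs within Hamming distance 1:
the molecule count is the number of connected components of that graph
(a directional, count-aware variant is available).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam
from intervaltree import IntervalTree
from scipy import io as spio
from scipy import sparse

from ._dna import hamming
from .annotation import GeneModel, read_gtf

MITO_CONTIGS = {"chrM", "MT", "M", "chrMT"}

EXON = "exon"
INTRON = "intron"
AMBIGUOUS = "ambiguous"
INTERGENIC = "intergenic"


class FeatureIndex:
    """Interval lookup of (gene, exon/intron) features per contig."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise ValueError("duplicate gene_id in annotation")
        self.trees: dict[str, IntervalTree] = {}
        for g in genes:
            tree = self.trees.setdefault(g.contig, IntervalTree())
            for es, ee in g.exons:
                tree.addi(es, ee, (g.gene_id, EXON))
            for is_, ie in g.introns:
                tree.addi(is_, ie, (g.gene_id, INTRON))
        self.mito_genes = {
            g.gene_id for g in genes if g.contig in MITO_CONTIGS
        }

    @classmethod
    def from_gtf(cls, path) -> "FeatureIndex":
        return cls(read_gtf(path))

    def query(self, contig: str, blocks) -> dict[str, set[str]]:
        """gene_id -> set of feature classes overlapped by any block."""
        tree = self.trees.get(contig)
        hits: dict[str, set[str]] = {}
        if tree is None:
            return hits
        for start, end in blocks:
            for iv in tree.overlap(start, end):
                gid, feat = iv.data
                hits.setdefault(gid, set()).add(feat)
        return hits


def assign_read(
    blocks,
    contig: str,
    index: FeatureIndex,
    strand: str | None = None,
) -> tuple[str | None, str]:
    """Assign CIGAR blocks to (gene_id, class).

    strand, when given, restricts candidate genes to that strand
    (strand-aware mode); default ignores strand.
    """
    hits = index.query(contig, blocks)
    if strand is not None:
        hits = {g: f for g, f in hits.items()
                if index.genes[g].strand == strand}
    if not hits:
        return None, INTERGENIC
    if len(hits) > 1:
        return None, AMBIGUOUS
    (gene_id, feats), = hits.items()
    gene = index.genes[gene_id]
    if all(gene.contains_in_exon(s, e) for s, e in blocks):
        return gene_id, EXON
    if INTRON in feats:
        return gene_id, INTRON
    # gene overlap that spills outside the gene body without touching an
    # intron (e.g. hanging off the terminal exon): not assignable
    return None, INTERGENIC


def collapse_umis(umis, method: str = "cluster") -> int:
    """Error-corrected molecule count for one (gene, cell) UMI multiset.

    method="cluster": connected components of the Hamming<=1 graph over
    distinct UMIs. method="directional": count-aware variant where an edge
    a->b requires count(a) >= 2*count(b) - 1, seeded from the most abundant
    UMI. method="unique": no correction.
    """
    counts = Counter(umis)
    if not counts:
        return 0
    lengths = {len(u) for u in counts}
    if len(lengths) != 1:
        raise ValueError(f"mixed UMI lengths: {sorted(lengths)}")
    unique = list(counts)
    n = len(unique)
    if method == "unique":
        return n
    if method == "cluster":
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if hamming(unique[i], unique[j]) <= 1:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
        return len({find(i) for i in range(n)})
    if method == "directional":
        order = sorted(range(n), key=lambda i: (-counts[unique[i]], unique[i]))
        assigned = [False] * n
        clusters = 0
        for i in order:
            if assigned[i]:
                continue
            clusters += 1
            stack = [i]
            assigned[i] = True
            while stack:
                a = stack.pop()
                for b in range(n):
                    if assigned[b]:
                        continue
                    if hamming(unique[a], unique[b]) <= 1 and \
                            counts[unique[a]] >= 2 * counts[unique[b]] - 1:
                        assigned[b] = True
                        stack.append(b)
        return clusters
    raise ValueError(f"unknown collapse method {method!r}")


@dataclass
class CountResult:
    """Gene x cell layers plus the per-cell tallies the QC module consumes."""

    layers: dict[str, pd.DataFrame]
    cell_stats: pd.DataFrame
    collapse_method: str

    def layer(self, name: str) -> pd.DataFrame:
        return self.layers[name]


def build_matrices(
    alignments_path,
    index: FeatureIndex,
    cells: list[str] | None = None,
    umi_tag: str = "UB",
    cell_tag: str = "BC",
    collapse: str = "cluster",
    strand_aware: bool = False,
) -> CountResult:
    """Count assigned reads and error-corrected molecules per gene and cell.

    UMI layers (umi_exon, umi_exon_intron) are built from UMI-carrying reads
    only; read layers (reads_exon, reads_exon_intron) count every assigned
    read. For paired data only first-in-pair records are counted. Records
    without a cell tag go to an "unassigned" column.
    """
    genes = sorted(index.genes)
    seen_cells: list[str] = list(cells) if cells else []
    seen_set = set(seen_cells)

    read_counts = {"exon": Counter(), "exon_intron": Counter()}
    umi_sets: dict[str, dict[tuple[str, str], list[str]]] = {
        "exon": {}, "exon_intron": {},
    }
    cell_stats: dict[str, Counter] = {}

    with pysam.AlignmentFile(str(alignments_path), check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_paired and not read.is_read1:
                continue
            cell = (str(read.get_tag(cell_tag))
                    if read.has_tag(cell_tag) else "unassigned")
            if cell not in seen_set:
                seen_set.add(cell)
                seen_cells.append(cell)
            stats = cell_stats.setdefault(cell, Counter())
            stats["n_reads"] += 1
            umi = str(read.get_tag(umi_tag)) if read.has_tag(umi_tag) else None
            stats["n_umi_reads" if umi else "n_internal_reads"] += 1
            if read.reference_name in MITO_CONTIGS:
                stats["n_mito_reads"] += 1
            blocks = read.get_blocks()
            gene, klass = assign_read(
                blocks, read.reference_name, index,
                strand="-" if (strand_aware and read.is_reverse)
                else ("+" if strand_aware else None),
            )
            stats[f"n_{klass}"] += 1
            if gene is None:
                continue
            key = (gene, cell)
            if klass == EXON:
                read_counts["exon"][key] += 1
            read_counts["exon_intron"][key] += 1
            if umi is not None:
                if klass == EXON:
                    umi_sets["exon"].setdefault(key, []).append(umi)
                umi_sets["exon_intron"].setdefault(key, []).append(umi)

    cols = seen_cells or []
    layers: dict[str, pd.DataFrame] = {}
    for feat in ("exon", "exon_intron"):
        reads_df = pd.DataFrame(0, index=genes, columns=cols, dtype=int)
        for (g, c), v in read_counts[feat].items():
            reads_df.at[g, c] = v
        layers[f"reads_{feat}"] = reads_df
        umi_df = pd.DataFrame(0, index=genes, columns=cols, dtype=int)
        for (g, c), umis in umi_sets[feat].items():
            umi_df.at[g, c] = collapse_umis(umis, method=collapse)
        layers[f"umi_{feat}"] = umi_df

    stat_cols = ["n_reads", "n_umi_reads", "n_internal_reads", "n_mito_reads",
                 "n_exon", "n_intron", "n_ambiguous", "n_intergenic"]
    stats_df = pd.DataFrame(
        [{**{k: cell_stats.get(c, Counter()).get(k, 0) for k in stat_cols},
          "cell": c} for c in cols]
    )
    if not stats_df.empty:
        stats_df = stats_df[["cell"] + stat_cols]
    else:
        stats_df = pd.DataFrame(columns=["cell"] + stat_cols)
    return CountResult(layers=layers, cell_stats=stats_df,
                       collapse_method=collapse)


def write_mtx(matrix: pd.DataFrame, outdir, prefix: str = "") -> Path:
    """Write a gene x cell layer as MatrixMarket plus row/column TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / f"{prefix}matrix.mtx"),
                 sparse.csr_matrix(matrix.to_numpy()))
    pd.Series(matrix.index).to_csv(
        outdir / f"{prefix}genes.tsv", sep="\t", index=False, header=False)
    pd.Series(matrix.columns).to_csv(
        outdir / f"{prefix}cells.tsv", sep="\t", index=False, header=False)
    return outdir / f"{prefix}matrix.mtx"
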