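"""Per-cell QC metrics, cell/gene filtering and equal-depth downsampling.

Cell filters follow the standard stringent plate-based screen, with the
stated boundaries taken literally as strict inequalities: a cell passes
when it has *more than* 50% of read pairs mapped to exons+introns, *more
than* 20,000 read pairs, *more than* 500 genes detected (exon+intron
quantification) and *less than* 15% of read pairs mapped to mitochondrial
genes. A gene must then be expressed in at least ten passing cells.

The UMI:internal balance is reported both as the bounded fraction
UMI/(UMI+internal) and as the raw ratio UMI/internal, since either
convention is in use.

Downsampling is uniform sampling of raw reads without replacement to a
common target depth; a cell with fewer reads than the target is excluded
(a reported outcome, not an error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class QCThresholds:
    min_pct_exon_intron: float = 50.0   # exclusive
    min_read_pairs: int = 20000         # exclusive
    min_genes: int = 500                # exclusive
    max_pct_mito: float = 15.0          # exclusive
    min_cells_per_gene: int = 10

    def __post_init__(self):
        for name in ("min_pct_exon_intron", "min_read_pairs", "min_genes",
                     "max_pct_mito", "min_cells_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def profile_cells(
    cell_stats: pd.DataFrame,
    umi_exon_intron: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Per-cell QC profile from counting output.

    cell_stats is the per-cell tally table from build_matrices;
    umi_exon_intron is the gene x cell exon+intron molecule layer used for
    the genes-detected metric. Adds pass_qc and a machine-readable
    fail_reasons column (';'-joined).
    """
    thresholds = thresholds or QCThresholds()
    rows = []
    for _, s in cell_stats.iterrows():
        cell = s["cell"]
        n = int(s["n_reads"])
        n_feat = int(s["n_exon"]) + int(s["n_intron"])
        pct_ei = 100.0 * n_feat / n if n else 0.0
        pct_mito = 100.0 * int(s["n_mito_reads"]) / n if n else 0.0
        n_genes = (
            int((umi_exon_intron[cell] > 0).sum())
            if cell in umi_exon_intron.columns else 0
        )
        n_umi = int(s["n_umi_reads"])
        n_int = int(s["n_internal_reads"])
        denom = n_umi + n_int
        rows.append({
            "cell": cell,
            "n_read_pairs": n,
            "pct_exon_intron_mapped": pct_ei,
            "n_genes_exon_intron": n_genes,
            "pct_mito": pct_mito,
            "n_umi_reads": n_umi,
            "n_internal_reads": n_int,
            "frac_umi": n_umi / denom if denom else np.nan,
            "ratio_umi_internal": n_umi / n_int if n_int else np.inf,
        })
    profiles = pd.DataFrame(rows)
    return apply_thresholds(profiles, thresholds)


def apply_thresholds(
    profiles: pd.DataFrame, thresholds: QCThresholds | None = None
) -> pd.DataFrame:
    """Evaluate the strict pass/fail rules on a per-cell profile table."""
    thresholds = thresholds or QCThresholds()
    out = profiles.copy()
    reasons = []
    for _, s in out.iterrows():
        fails = []
        if not s["pct_exon_intron_mapped"] > thresholds.min_pct_exon_intron:
            fails.append("low_feature_mapping")
        if not s["n_read_pairs"] > thresholds.min_read_pairs:
            fails.append("low_depth")
        if not s["n_genes_exon_intron"] > thresholds.min_genes:
            fails.append("low_genes")
        if not s["pct_mito"] < thresholds.max_pct_mito:
            fails.append("high_mito")
        reasons.append(";".join(fails))
    out["fail_reasons"] = reasons
    out["pass_qc"] = [r == "" for r in reasons]
    return out


def filter_genes(
    matrix: pd.DataFrame, min_cells: int = 10
) -> pd.DataFrame:
    """Keep genes with a nonzero count in at least min_cells cells.

    Idempotent; intended to run on QC-passing cells only.
    """
    keep = (matrix > 0).sum(axis=1) >= min_cells
    return matrix.loc[keep]


def downsample_cell(
    reads: Sequence, target_depth: int, seed=None
) -> list | None:
    """Uniform sample of raw reads without replacement, order-preserving.

    Returns None when the cell has fewer reads than the target (the cell
    is excluded from equal-depth comparisons). target == available returns
    the input unchanged.
    """
    n = len(reads)
    if target_depth > n:
        return None
    if target_depth == n:
        return list(reads)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    idx = rng.choice(n, size=target_depth, replace=False)
    idx.sort()
    return [reads[int(i)] for i in idx]


def downsample_cells(
    reads_by_cell: dict[str, Sequence], target_depth: int, seed: int = 0
) -> dict[str, list | None]:
    """Downsample every cell to a common raw depth (None = excluded)."""
    rng = np.random.default_rng(seed)
    return {
        cell: downsample_cell(reads, target_depth, rng)
        for cell, reads in sorted(reads_by_cell.items())
    }


def expected_genes_detected(gene_read_counts: Iterable[int],
                            depth: int) -> float:
    """Closed-form expected number of distinct genes at a given raw depth.

    For a cell with N reads of which n_g hit gene g, sampling d reads
    without replacement detects g with probability 1 - C(N-n_g, d)/C(N, d).
    """
    counts = [int(c) for c in gene_read_counts]
    total = sum(counts)
    if depth > total:
        raise ValueError("depth exceeds available reads")
    denom = math.comb(total, depth)
    return float(sum(
        1.0 - math.comb(total - c, depth) / denom if total - c >= depth else 1.0
        for c in counts if c > 0
    ))
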