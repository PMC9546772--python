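"""Feature assignment and error-corrected UMI counting."""

import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ss3x.annotation import GeneModel
from ss3x.feature_count import (
    FeatureIndex,
    assign_read,
    build_matrices,
    collapse_umis,
)
from ss3x.tso_filter import filter_alignment_file

# two genes on one contig, the second pair overlapping each other
TOY_GENES = [
    GeneModel("gA", "chr1", "+", ((100, 200), (300, 400))),
    GeneModel("gB", "chr1", "-", ((380, 450),)),
    GeneModel("gC", "chr2", "+", ((50, 150), (250, 350))),
]
TOY_INDEX = FeatureIndex(TOY_GENES)


def _brute_assign(blocks, contig, genes):
    """Independent interval-arithmetic oracle for read assignment."""
    def overlaps(a, b):
        return max(a[0], b[0]) < min(a[1], b[1])

    candidates = {}
    for g in genes:
        if g.contig != contig:
            continue
        feats = set()
        for b in blocks:
            if any(overlaps(b, e) for e in g.exons):
                feats.add("exon")
            if any(overlaps(b, i) for i in g.introns):
                feats.add("intron")
        if feats:
            candidates[g.gene_id] = feats
    if not candidates:
        return None, "intergenic"
    if len(candidates) > 1:
        return None, "ambiguous"
    gid, feats = next(iter(candidates.items()))
    g = next(x for x in genes if x.gene_id == gid)
    if all(any(e[0] <= b[0] and b[1] <= e[1] for e in g.exons) for b in blocks):
        return gid, "exon"
    if "intron" in feats:
        return gid, "intron"
    return None, "intergenic"


@pytest.mark.parametrize(
    "blocks,contig,expected",
    [
        ([(110, 160)], "chr1", ("gA", "exon")),          # inside one exon
        ([(150, 180), (310, 330)], "chr1", ("gA", "exon")),  # spliced, exonic
        ([(180, 240)], "chr1", ("gA", "intron")),        # exon->intron boundary
        ([(220, 260)], "chr1", ("gA", "intron")),        # fully intronic
        ([(390, 420)], "chr1", (None, "ambiguous")),     # gA exon + gB exon
        ([(500, 560)], "chr1", (None, "intergenic")),
        ([(40, 120)], "chr2", (None, "intergenic")),     # hangs off gene start
        ([(110, 160)], "chr3", (None, "intergenic")),    # unknown contig
    ],
)
def test_assignment_semantics(blocks, contig, expected):
    assert assign_read(blocks, contig, TOY_INDEX) == expected
    assert _brute_assign(blocks, contig, TOY_GENES) == expected


def test_strand_aware_mode_restricts_candidates():
    # (390, 420) overlaps gA (+) and gB (-): strand resolves the ambiguity
    assert assign_read([(390, 395)], "chr1", TOY_INDEX, strand="-") == \
        ("gB", "exon")


@pytest.mark.parametrize(
    "umis,expected",
    [
        (["AAAAAAAA"] * 5, 1),
        (["AAAAAAAA", "AAAAAAAT"], 1),
        (["AAAAAAAA", "AAAAAATT"], 2),
        ([], 0),
        (["AAAAAAAA", "AAAAAAAT", "AAAAAATT"], 1),  # chained components
    ],
)
def test_umi_collapse_examples(umis, expected):
    assert collapse_umis(umis) == expected


def test_mixed_umi_lengths_error():
    with pytest.raises(ValueError, match="mixed"):
        collapse_umis(["AAAA", "AAAAA"])


def _brute_components(umis):
    """BFS over the Hamming<=1 graph of distinct UMIs."""
    nodes = sorted(set(umis))
    seen = set()
    comps = 0
    for start in nodes:
        if start in seen:
            continue
        comps += 1
        stack = [start]
        while stack:
            u = stack.pop()
            if u in seen:
                continue
            seen.add(u)
            for v in nodes:
                if v not in seen and sum(a != b for a, b in zip(u, v)) <= 1:
                    stack.append(v)
    return comps


@settings(derandomize=True, max_examples=200)
@given(st.lists(st.text(alphabet="AC", min_size=4, max_size=4),
                min_size=0, max_size=15))
def test_collapse_equals_bruteforce_components(umis):
    # two-letter alphabet makes Hamming-1 neighbours common
    assert collapse_umis(umis) == _brute_components(umis)


def test_directional_collapse_splits_balanced_pairs():
    # equal counts: no directional edge (5 >= 2*5-1 is false), two molecules
    assert collapse_umis(["AAAAAAAA"] * 5 + ["AAAAAAAT"] * 5,
                         method="directional") == 2
    # skewed counts: error reads absorbed into the abundant molecule
    assert collapse_umis(["AAAAAAAA"] * 10 + ["AAAAAAAT"] * 1,
                         method="directional") == 1


def test_empty_alignment_file_gives_zero_matrices(tmp_path):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 1000}]})
    path = tmp_path / "empty.sam"
    with pysam.AlignmentFile(str(path), "w", header=header):
        pass
    res = build_matrices(path, TOY_INDEX, cells=["c1", "c2"])
    for layer in res.layers.values():
        assert layer.shape == (3, 2)
        assert (layer.to_numpy() == 0).all()


def test_counting_conservation_and_umi_bounds(sim_small):
    """Per-cell class tallies partition the reads; molecules <= distinct
    UMIs <= reads for every (gene, cell)."""
    index = FeatureIndex.from_gtf(sim_small.gtf)
    res = build_matrices(sim_small.sam, index,
                         cells=list(sim_small.cells["cell"]))
    s = res.cell_stats
    assert (s["n_exon"] + s["n_intron"] + s["n_ambiguous"] + s["n_intergenic"]
            == s["n_reads"]).all()
    assert (s["n_umi_reads"] + s["n_internal_reads"] == s["n_reads"]).all()
    umi = res.layers["umi_exon_intron"]
    reads = res.layers["reads_exon_intron"]
    assert (umi.to_numpy() <= reads.to_numpy()).all()
    assert (umi.to_numpy() >= 0).all()
    # umi layers restricted to umi reads: column sums bounded by umi reads
    per_cell_umi = umi.sum(axis=0)
    for _, row in s.iterrows():
        assert per_cell_umi[row["cell"]] <= row["n_umi_reads"]


def test_tso_filtering_never_increases_counts(sim_small, tmp_path):
    out = tmp_path / "filtered.sam"
    filter_alignment_file(sim_small.sam, sim_small.fasta, out_path=out,
                          max_mm=2)
    index = FeatureIndex.from_gtf(sim_small.gtf)
    cells = list(sim_small.cells["cell"])
    before = build_matrices(sim_small.sam, index, cells=cells)
    after = build_matrices(out, index, cells=cells)
    for name in before.layers:
        assert (after.layers[name].to_numpy()
                <= before.layers[name].to_numpy()).all()


def test_umi_matrix_recovers_truth_molecules(sim_clean):
    """With one molecule per (gene, cell), the exon+intron UMI matrix equals
    the number of distinct truth molecules observed per (gene, cell)."""
    index = FeatureIndex.from_gtf(sim_clean.gtf)
    res = build_matrices(sim_clean.sam, index,
                         cells=list(sim_clean.cells["cell"]))
    truth = sim_clean.truth
    umi_reads = truth[truth["class"] == "umi_read"]
    expected = (
        umi_reads.groupby(["gene_id", "cell"])["molecule_id"]
        .nunique()
    )
    layer = res.layers["umi_exon_intron"]
    for (gene, cell), n_mol in expected.items():
        assert layer.at[gene, cell] == n_mol
    assert int(layer.to_numpy().sum()) == int(expected.sum())
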