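"""TSO strand-invasion detector: windows, fuzzy matching, filtering."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ss3x._dna import revcomp
from ss3x.sim_reads import SimConfig, simulate
from ss3x.tso_filter import (
    MissingContigError,
    _GenomeAdapter,
    classify_alignment,
    compute_window,
    filter_alignment_file,
    fuzzy_match,
    select_reads,
    window_sequence,
)


def _brute_fuzzy(umi, overhang, window):
    best = None
    for used, q in ((True, umi + overhang), (False, umi)):
        for off in range(len(window) - len(q) + 1):
            d = sum(a != b for a, b in zip(q, window[off:off + len(q)]))
            if best is None or d < best[0]:
                best = (d, off, used)
    return best


def _header(contigs):
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": c, "LN": n} for c, n in contigs.items()],
    })


def _read(header, name, contig, start, length, reverse=False, umi=None,
          paired=False, read1=True, unmapped=False, secondary=False):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = "A" * length
    a.reference_id = list(header.references).index(contig)
    a.reference_start = start
    a.cigartuples = [(0, length)]
    a.mapping_quality = 60
    flag = 0
    if reverse:
        flag |= 0x10
    if paired:
        flag |= 0x1 | (0x40 if read1 else 0x80)
    if unmapped:
        flag |= 0x4
    if secondary:
        flag |= 0x100
    a.flag = flag
    if umi:
        a.set_tag("UB", umi)
    return a


# ---------------------------------------------------------------------------
# fuzzy matching

def test_exact_umi_with_overhang_matches_at_zero():
    window = "TTTTT" + "ACGTACGTGGG" + "TTTT"
    matched, mm, off, used = fuzzy_match("ACGTACGT", "GGG", window, 0)
    assert matched and mm == 0 and off == 5 and used is True


def test_distant_umi_never_matches_within_budget():
    matched, mm, off, used = fuzzy_match("CCCCCCCC", "GGG", "A" * 20, 2)
    assert not matched and mm == 8


def test_empty_or_short_window_is_unmatchable():
    assert fuzzy_match("ACGTACGT", "GGG", "", 2) == (False, None, None, False)
    # window shorter than UMI+GGG but long enough for the bare UMI
    matched, mm, off, used = fuzzy_match("ACGTACGT", "GGG", "ACGTACGT", 2)
    assert matched and mm == 0 and used is False


@settings(derandomize=True, max_examples=500)
@given(st.text(alphabet="ACGT", min_size=8, max_size=8),
       st.text(alphabet="ACGT", min_size=0, max_size=20))
def test_fuzzy_match_equals_bruteforce_scan(umi, window):
    matched, mm, off, used = fuzzy_match(umi, "GGG", window, 2)
    brute = _brute_fuzzy(umi, "GGG", window)
    if brute is None:
        assert (matched, mm) == (False, None)
    else:
        assert mm == brute[0]
        assert matched == (brute[0] <= 2)


# ---------------------------------------------------------------------------
# window geometry

def test_plus_strand_window_is_upstream_of_read_start():
    spec = compute_window("chr1", 100, False, 30, 10000)
    assert (spec.start, spec.end, spec.orientation) == (80, 100, "as_reference")


def test_plus_strand_window_clips_at_contig_edge():
    spec = compute_window("chr1", 5, False, 30, 10000)
    assert (spec.start, spec.end) == (0, 5)


def test_minus_strand_window_is_downstream_and_reversed():
    spec = compute_window("chr1", 100, True, 30, 10000)
    assert (spec.start, spec.end) == (130, 150)
    assert spec.orientation == "reverse_complement"
    genome = _GenomeAdapter({"chr1": "A" * 130 + "ACGTACGTGGGTTTTTTTTT" + "A" * 9850})
    assert window_sequence(genome, spec) == revcomp("ACGTACGTGGGTTTTTTTTT")


def test_window_fully_outside_contig_is_empty():
    spec = compute_window("chr1", 995, True, 30, 1000)
    assert spec.start == spec.end == 1000


def test_strand_symmetry_of_verdicts():
    """Reverse-complementing the genome and flipping the strand flag gives
    identical artifact calls."""
    rng = np.random.default_rng(5)
    n, L = 400, 30
    for _ in range(50):
        contig = "".join("ACGT"[i] for i in rng.integers(0, 4, n))
        umi = "".join("ACGT"[i] for i in rng.integers(0, 4, 8))
        start = int(rng.integers(40, n - L - 40))
        fwd = _GenomeAdapter({"c": contig})
        rev = _GenomeAdapter({"c": revcomp(contig)})
        h = _header({"c": n})
        plus = _read(h, "r", "c", start, L, reverse=False, umi=umi)
        minus = _read(h, "r", "c", n - start - L, L, reverse=True, umi=umi)
        call_plus = classify_alignment(plus, fwd)
        call_minus = classify_alignment(minus, rev)
        assert call_plus.best_mismatches == call_minus.best_mismatches
        assert call_plus.window == call_minus.window


# ---------------------------------------------------------------------------
# read selection

def test_mate2_only_paired_input_yields_no_candidates():
    h = _header({"c": 1000})
    reads = [_read(h, f"r{i}", "c", 100, 30, paired=True, read1=False,
                   umi="ACGTACGT") for i in range(5)]
    counters = {}
    assert list(select_reads(reads, counters=counters)) == []
    assert counters["skipped_flags"] == 5


def test_single_end_primary_mapped_reads_all_pass():
    h = _header({"c": 1000})
    reads = [_read(h, f"r{i}", "c", 100, 30, umi="ACGTACGT") for i in range(7)]
    reads.append(_read(h, "bad1", "c", 100, 30, umi="ACGTACGT", unmapped=True))
    reads.append(_read(h, "bad2", "c", 100, 30, umi="ACGTACGT", secondary=True))
    reads.append(_read(h, "noumi", "c", 100, 30))
    counters = {}
    out = list(select_reads(reads, counters=counters))
    assert len(out) == 7
    assert counters["skipped_no_umi"] == 1
    assert counters["skipped_flags"] == 2


def test_candidates_equal_truth_umi_first_in_pair_count(sim_paired):
    with pysam.AlignmentFile(str(sim_paired.sam)) as af:
        counters = {}
        n = sum(1 for _ in select_reads(af, counters=counters))
    truth = sim_paired.truth
    assert n == (truth["class"] == "umi_read").sum()


# ---------------------------------------------------------------------------
# file-level filtering

def test_removal_sets_nest_across_mismatch_budgets(sim_small):
    flagged = {
        k: filter_alignment_file(sim_small.sam, sim_small.fasta,
                                 max_mm=k).artifact_read_names
        for k in (0, 1, 2)
    }
    assert flagged[0] <= flagged[1] <= flagged[2]


def test_paired_removal_leaves_no_orphan_mates(sim_paired, tmp_path):
    out = tmp_path / "filtered.sam"
    report = filter_alignment_file(sim_paired.sam, sim_paired.fasta,
                                   out_path=out, max_mm=2, mode="remove")
    assert report.artifact_read_names
    mates = {}
    with pysam.AlignmentFile(str(out)) as af:
        for read in af:
            mates.setdefault(read.query_name, []).append(read.is_read1)
            assert read.query_name not in report.artifact_read_names
    assert all(len(v) == 2 for v in mates.values())


def test_flag_mode_keeps_all_records_and_annotates(sim_small, tmp_path):
    out = tmp_path / "flagged.sam"
    report = filter_alignment_file(sim_small.sam, sim_small.fasta,
                                   out_path=out, max_mm=2, mode="flag")
    with pysam.AlignmentFile(str(out)) as af:
        records = list(af)
    with pysam.AlignmentFile(str(sim_small.sam)) as af:
        assert len(records) == sum(1 for _ in af)
    flagged = {r.query_name for r in records if r.has_tag("ZF")}
    assert flagged == report.artifact_read_names


def test_missing_contig_is_a_hard_error(sim_small):
    with pytest.raises(MissingContigError):
        filter_alignment_file(sim_small.sam, {"not_chr1": "ACGT" * 100})


def test_false_positive_rate_bounded_by_null_match_probability(tmp_path):
    """With windows left unconstrained, the chance a random 8-mer UMI
    (+GGG) matches a random 20-bp window within 2 mismatches is estimated
    by Monte Carlo; the detector's false-positive rate on artifact-free
    data must sit within sampling error of that null probability."""
    cfg = SimConfig(n_cells=2, reads_per_cell=1500, frac_umi_reads=1.0,
                    frac_artifact=0.0, seed=31,
                    guarantee_clean_windows=False)
    sim = simulate(cfg, tmp_path / "null")
    report = filter_alignment_file(sim.sam, sim.fasta, max_mm=2)
    n_umi = (sim.truth["class"] == "umi_read").sum()
    fp_rate = len(report.artifact_read_names) / n_umi

    rng = np.random.default_rng(17)
    trials = 5000
    hits = 0
    for _ in range(trials):
        umi = "".join("ACGT"[i] for i in rng.integers(0, 4, 8))
        window = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
        if _brute_fuzzy(umi, "GGG", window)[0] <= 2:
            hits += 1
    p_null = hits / trials
    se = np.sqrt(p_null * (1 - p_null) * (1 / trials + 1 / n_umi))
    assert fp_rate <= p_null + 4 * se
    assert fp_rate > 0  # unconstrained windows do produce chance matches
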