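"""Filtration rules, consensus merging, benchmarking metrics and the
SNV utilities — each checked against independent oracles where one
exists (brute-force matching, closed-form statistics)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sclongread.io_model import (
    AlignmentSegment,
    GenomeInterval,
    ReadAlignment,
    SNVCall,
    SVCall,
)
from sclongread.svconsensus import (
    benchmark_svs,
    compute_metrics,
    duplication_telomere_test,
    extract_cell_svs,
    filter_bulk_calls,
    filter_cell_calls,
    filter_indel_size,
    match_ngs_style,
    merge_across_cells,
    mutation_spectrum,
    snv_fpr,
    snv_multicell_support,
    substitution_class,
)

# ---------------------------------------------------------------------------
# helpers / oracles
# ---------------------------------------------------------------------------


def _del(chrom, start, end, cell=None, support=2, filters=("PASS",)):
    return SVCall("DEL", GenomeInterval(chrom, start, end), svlen=-(end - start),
                  cell_id=cell, read_support=support, total_depth=max(support, 1),
                  filters=frozenset(filters))


def _linked_oracle(a, b, dist, tra_dist):
    """Plain-arithmetic link test, written independently of the library."""
    if a.svtype != b.svtype:
        return False
    if a.svtype == "TRA":
        pa = sorted([(a.locus.chrom, a.locus.start), (a.mate.chrom, a.mate.start)])
        pb = sorted([(b.locus.chrom, b.locus.start), (b.mate.chrom, b.mate.start)])
        return (
            pa[0][0] == pb[0][0]
            and pa[1][0] == pb[1][0]
            and abs(pa[0][1] - pb[0][1]) <= tra_dist
            and abs(pa[1][1] - pb[1][1]) <= tra_dist
        )
    return (
        a.locus.chrom == b.locus.chrom
        and abs(a.locus.start - b.locus.start) <= dist
        and abs(a.locus.end - b.locus.end) <= dist
    )


def _brute_force_benchmark(test, truth, dist=1000, tra_dist=50_000):
    """Exhaustive all-pairs multimatch: TP/FP/FN by definition."""
    tp = sum(
        1 for c in test if any(_linked_oracle(c, t, dist, tra_dist) for t in truth)
    )
    fn = sum(
        1 for t in truth if not any(_linked_oracle(c, t, dist, tra_dist) for c in test)
    )
    return tp, len(test) - tp, fn


def _brute_force_clusters(calls, dist=1000, tra_dist=50_000):
    """Single-linkage connected components by repeated expansion."""
    unassigned = list(range(len(calls)))
    clusters = []
    while unassigned:
        comp = {unassigned.pop(0)}
        grew = True
        while grew:
            grew = False
            for i in list(unassigned):
                if any(_linked_oracle(calls[i], calls[j], dist, tra_dist) for j in comp):
                    comp.add(i)
                    unassigned.remove(i)
                    grew = True
        clusters.append(frozenset(comp))
    return set(clusters)


def _random_calls(rng, n, span=100_000, types=("DEL", "INS", "DUP", "INV", "TRA")):
    calls = []
    for _ in range(n):
        svtype = types[int(rng.integers(0, len(types)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(100, 3_000))
        cell = f"c{int(rng.integers(0, 5))}"
        if svtype == "TRA":
            p2 = int(rng.integers(0, span))
            calls.append(SVCall("TRA", GenomeInterval("chr1", start, start + 1),
                                mate=GenomeInterval("chr2", p2, p2 + 1), cell_id=cell))
        elif svtype == "INS":
            calls.append(SVCall("INS", GenomeInterval("chr1", start, start + 1),
                                svlen=length, cell_id=cell))
        else:
            svlen = {"DEL": -length, "DUP": length, "INV": 0}[svtype]
            calls.append(SVCall(svtype, GenomeInterval("chr1", start, start + length),
                                svlen=svlen, cell_id=cell))
    return calls


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


class TestComputeMetrics:
    def test_perfect_counts(self):
        rep = compute_metrics(5, 0, 0)
        assert (rep.precision, rep.recall, rep.fpr, rep.fnr, rep.hm, rep.f1) == (
            1.0, 1.0, 0.0, 0.0, 0.0, 1.0
        )

    def test_printed_formula_example(self):
        rep = compute_metrics(3, 1, 2)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.6)
        assert rep.fpr == pytest.approx(0.25)
        assert rep.fnr == pytest.approx(0.4)
        assert rep.hm == pytest.approx(0.30769, abs=1e-5)
        assert rep.f1 == pytest.approx(0.66667, abs=1e-5)

    def test_undefined_ratios_are_nan(self):
        rep = compute_metrics(0, 0, 0)
        assert math.isnan(rep.precision) and math.isnan(rep.recall)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 10_000), st.integers(0, 10_000))
    def test_identities(self, tp, fp, fn):
        rep = compute_metrics(tp, fp, fn)
        if tp + fp > 0:
            assert rep.fpr + rep.precision == pytest.approx(1.0)
        if not math.isnan(rep.hm):
            assert rep.hm <= max(rep.fpr, rep.fnr) + 1e-12
        if not math.isnan(rep.f1):
            assert rep.f1 <= 1.0 + 1e-12


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def _aln(segs, read_len, rid="r1", cell="c0"):
    return ReadAlignment(rid, cell, segs, read_len)


class TestExtraction:
    def test_cigar_deletion_becomes_del_call(self):
        seg = AlignmentSegment("r1", 0, 2000, GenomeInterval("chr1", 10_000, 14_000),
                               "+", cigar="1000M2000D1000M")
        calls = extract_cell_svs([_aln([seg], 2000)])
        assert len(calls) == 1
        c = calls[0]
        assert (c.svtype, c.locus.start, c.locus.end, c.svlen) == ("DEL", 11_000, 13_000, -2000)

    def test_small_indel_below_threshold_ignored(self):
        seg = AlignmentSegment("r1", 0, 2000, GenomeInterval("chr1", 10_000, 12_030),
                               "+", cigar="1000M30D1000M")
        assert extract_cell_svs([_aln([seg], 2000)]) == []

    def test_cross_chromosome_split_pair_is_tra(self):
        s1 = AlignmentSegment("r1", 0, 1000, GenomeInterval("chr1", 5_000, 6_000), "+")
        s2 = AlignmentSegment("r1", 1000, 2000, GenomeInterval("chr5", 9_000, 10_000), "+")
        calls = extract_cell_svs([_aln([s1, s2], 2000)])
        assert len(calls) == 1
        c = calls[0]
        assert c.svtype == "TRA"
        assert c.locus.chrom == "chr1" and abs(c.locus.start - 6_000) <= 1
        assert c.mate.chrom == "chr5" and abs(c.mate.start - 9_000) <= 1

    def test_colinear_split_pair_with_gap_is_del(self):
        s1 = AlignmentSegment("r1", 0, 1000, GenomeInterval("chr1", 5_000, 6_000), "+")
        s2 = AlignmentSegment("r1", 1000, 2000, GenomeInterval("chr1", 8_000, 9_000), "+")
        calls = extract_cell_svs([_aln([s1, s2], 2000)])
        assert [c.svtype for c in calls] == ["DEL"]
        assert (calls[0].locus.start, calls[0].locus.end) == (6_000, 8_000)

    def test_confined_chiastic_read_not_emitted_as_dup(self):
        # a read confined to the inferred unit is circle-compatible
        s1 = AlignmentSegment("r1", 0, 800, GenomeInterval("chr1", 5_200, 6_000), "+")
        s2 = AlignmentSegment("r1", 800, 2000, GenomeInterval("chr1", 4_000, 5_200), "+")
        assert extract_cell_svs([_aln([s1, s2], 2000)]) == []

    def test_overhanging_chiastic_read_is_dup(self):
        # read extends 1 kb upstream of the duplicated unit
        s1 = AlignmentSegment("r1", 0, 3000, GenomeInterval("chr1", 3_000, 6_000), "+")
        s2 = AlignmentSegment("r1", 3000, 4000, GenomeInterval("chr1", 4_000, 5_000), "+")
        calls = extract_cell_svs([_aln([s1, s2], 4000)])
        assert [c.svtype for c in calls] == ["DUP"]
        assert (calls[0].locus.start, calls[0].locus.end) == (4_000, 6_000)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


class TestFilters:
    @pytest.mark.parametrize(
        "filters,support,kept",
        [
            (("PASS",), 2, True),
            (("IMPRECISE",), 10, False),
            (("SHADOWED",), 5, False),
            (("PASS",), 1, False),
        ],
    )
    def test_cell_filtration(self, filters, support, kept):
        call = _del("chr1", 100, 300, support=support, filters=filters)
        assert (filter_cell_calls([call]) == [call]) is kept

    @pytest.mark.parametrize(
        "support,depth,kept",
        [(4, 20, True), (4, 40, False), (3, 10, False), (6, 40, False)],
    )
    def test_bulk_filtration(self, support, depth, kept):
        call = SVCall("DEL", GenomeInterval("chr1", 100, 300), svlen=-200,
                      read_support=support, total_depth=depth)
        assert (filter_bulk_calls([call]) == [call]) is kept

    def test_indel_size_floor(self):
        small = _del("chr1", 100, 180)
        big = _del("chr1", 100, 300)
        inv = SVCall("INV", GenomeInterval("chr1", 0, 60), svlen=0)
        assert filter_indel_size([small, big, inv]) == [big, inv]


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


class TestMerge:
    def test_two_cells_merge_within_distance(self):
        a = _del("chr1", 1000, 2000, cell="A")
        b = _del("chr1", 1500, 2500, cell="B")
        (m,) = merge_across_cells([[a], [b]])
        assert m.supporting_cells == {"A", "B"}
        assert m.locus.start == 1250 and m.locus.end == 2250

    def test_different_types_never_merge(self):
        d = _del("chr1", 1000, 2000, cell="A")
        i = SVCall("INS", GenomeInterval("chr1", 1000, 1001), svlen=1000, cell_id="B")
        merged = merge_across_cells([[d], [i]], min_cells=1)
        assert len(merged) == 2

    def test_single_cell_identity(self):
        a = _del("chr1", 1000, 2000, cell="A")
        (m,) = merge_across_cells([[a]], min_cells=1)
        assert (m.svtype, m.locus) == (a.svtype, a.locus)

    def test_min_cells_threshold_drops_private_calls(self):
        a = _del("chr1", 1000, 2000, cell="A")
        b = _del("chr1", 90_000, 91_000, cell="B")
        assert merge_across_cells([[a], [b]], min_cells=2) == []

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        callsets = [_random_calls(rng, 10) for _ in range(4)]
        merged = merge_across_cells(callsets, min_cells=1)
        shuffled = merge_across_cells(callsets[::-1], min_cells=1)
        assert merged == shuffled

    def test_idempotence_on_separated_clusters(self):
        # consensus calls further apart than the linking distance are a
        # fixed point of the merge (interleaved clusters are the one case
        # where median consensus can create new links; see methods note)
        rng = np.random.default_rng(7)
        callsets = [_random_calls(rng, 10, span=2_000_000) for _ in range(4)]
        merged = merge_across_cells(callsets, min_cells=1)
        again = merge_across_cells([merged], min_cells=1)
        assert [(c.svtype, c.locus, c.mate) for c in again] == [
            (c.svtype, c.locus, c.mate) for c in merged
        ]

    def test_clusters_match_brute_force_single_linkage(self):
        """Cluster membership equals the exhaustive connected-component
        oracle on random instances of <= 50 calls."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            calls = _random_calls(rng, int(rng.integers(2, 50)), span=20_000)
            pairs = merge_across_cells([calls], min_cells=0)
            got = set()
            index = {id(c): i for i, c in enumerate(calls)}
            for _, members in pairs:
                got.add(frozenset(index[id(m)] for m in members))
            assert got == _brute_force_clusters(calls)


# ---------------------------------------------------------------------------
# benchmarking
# ---------------------------------------------------------------------------


class TestBenchmark:
    def test_truth_against_itself_is_perfect(self):
        rng = np.random.default_rng(13)
        truth = _random_calls(rng, 20)
        rep, _ = benchmark_svs(truth, truth)
        assert rep.precision == 1.0 and rep.recall == 1.0 and rep.hm == 0.0

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            test = _random_calls(rng, int(rng.integers(1, 50)), span=30_000)
            truth = _random_calls(rng, int(rng.integers(1, 50)), span=30_000)
            rep, _ = benchmark_svs(test, truth)
            assert (rep.tp, rep.fp, rep.fn) == _brute_force_benchmark(test, truth)


class TestNgsMatching:
    def test_reciprocal_overlap_is_strict(self):
        a = [_del("chr1", 1000, 2000)]
        b = [_del("chr1", 1900, 3000)]  # overlap 100 = exactly 10% of a
        assert match_ngs_style(a, b) == []

    def test_identical_deletions_match(self):
        a = [_del("chr1", 1000, 2000)]
        assert match_ngs_style(a, a) == [(0, 0)]

    @pytest.mark.parametrize("pos,expected", [(5999, [(0, 0)]), (6100, [])])
    def test_insertion_breakpoint_window(self, pos, expected):
        a = [SVCall("INS", GenomeInterval("chr1", 5000, 5001), svlen=300)]
        b = [SVCall("INS", GenomeInterval("chr1", pos, pos + 1), svlen=300)]
        assert match_ngs_style(a, b) == expected

    def test_other_types_rejected(self):
        with pytest.raises(ValueError):
            match_ngs_style([SVCall("INV", GenomeInterval("chr1", 0, 10), svlen=0)], [])


# ---------------------------------------------------------------------------
# duplication placement
# ---------------------------------------------------------------------------


def _arms(n_chrom=2, length=10_000_000):
    arms = []
    for i in range(n_chrom):
        cen = int(0.45 * length)
        arms.append((GenomeInterval(f"chr{i+1}", 0, cen), f"chr{i+1}p"))
        arms.append((GenomeInterval(f"chr{i+1}", cen, length), f"chr{i+1}q"))
    return arms


def _dups_at_positions(rel_positions, arms):
    calls = []
    for k, r in enumerate(rel_positions):
        iv, name = arms[k % len(arms)]
        if name.endswith("q"):
            mid = iv.start + int(r * len(iv))
        else:
            mid = iv.end - 1 - int(r * len(iv))
        calls.append(SVCall("DUP", GenomeInterval(iv.chrom, max(mid - 50, 0), mid + 50),
                            svlen=100))
    return calls


class TestDuplicationTelomereTest:
    def test_equal_counts_give_p_one(self):
        arms = _arms()
        rel = np.linspace(0.005, 0.995, 100)  # one per window
        counts, p = duplication_telomere_test(_dups_at_positions(rel, arms), arms)
        assert counts.sum() == 100
        assert p == pytest.approx(1.0)

    def test_uniform_placement_not_rejected(self):
        # calibration: under uniform placement the test should rarely fire
        arms = _arms()
        rng = np.random.default_rng(31)
        ps = []
        for _ in range(20):
            rel = rng.random(500)
            _, p = duplication_telomere_test(_dups_at_positions(rel, arms), arms)
            ps.append(p)
        assert np.median(ps) > 0.05
        assert sum(p > 0.01 for p in ps) >= 16

    def test_telomere_enrichment_detected(self):
        """60% of events in the last decile: uniformity rejected far below
        the 1e-3 level."""
        arms = _arms()
        rng = np.random.default_rng(37)
        rel = np.concatenate([rng.uniform(0.9, 1.0, 300), rng.random(200)])
        _, p = duplication_telomere_test(_dups_at_positions(rel, arms), arms)
        assert p < 1e-3

    def test_outside_arm_skipped(self):
        arms = [(GenomeInterval("chr1", 0, 1000), "chr1p")]
        call = SVCall("DUP", GenomeInterval("chr2", 10, 110), svlen=100)
        counts, p = duplication_telomere_test([call], arms)
        assert counts.sum() == 0


# ---------------------------------------------------------------------------
# SNV utilities
# ---------------------------------------------------------------------------


class TestSnvSupport:
    def test_cells_equal_bulk_is_perfect(self):
        bulk = [SNVCall("chr1", p, "A", "T") for p in (10, 20, 30)]
        cells = {c: bulk for c in ("c1", "c2")}
        rep = snv_multicell_support(cells, bulk, k=1)
        assert rep.precision == 1.0 and rep.recall == 1.0

    def test_same_position_different_alt_is_fp(self):
        bulk = [SNVCall("chr1", 10, "A", "T")]
        cells = {"c1": [SNVCall("chr1", 10, "A", "G")]}
        rep = snv_multicell_support(cells, bulk, k=1)
        assert rep.tp == 0 and rep.fp == 1

    def test_precision_monotone_in_k(self, snv_sim):
        """Private per-cell noise cannot recur across cells, so precision
        never drops as the support threshold rises."""
        precisions = []
        for k in range(1, 5):
            rep = snv_multicell_support(snv_sim.snv_callsets, snv_sim.bulk_snvs, k)
            precisions.append(rep.precision)
        assert all(b >= a - 1e-12 for a, b in zip(precisions, precisions[1:]))
        assert precisions[-1] > precisions[0]


class TestSnvFpr:
    def test_no_false_positives(self):
        bulk = [SNVCall("chr1", 10, "A", "T")]
        assert snv_fpr(bulk, bulk, 1000) == 0.0

    def test_rate_arithmetic(self):
        bulk = []
        cell = [SNVCall("chr1", 10, "A", "T"), SNVCall("chr1", 20, "C", "G")]
        assert snv_fpr(cell, bulk, 100_000) == pytest.approx(2e-5)

    def test_rate_scale_invariance(self):
        cell = [SNVCall("chr1", p, "A", "T") for p in range(1, 5)]
        assert snv_fpr(cell, [], 1000) == snv_fpr(cell * 2, [], 2000) * 2 / 2

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            snv_fpr([], [], 0)


class TestSpectrum:
    def test_strand_complement_collapse(self):
        assert substitution_class("C", "T") == "CG>TA"
        assert substitution_class("G", "A") == "CG>TA"

    def test_all_twelve_substitutions_classified(self):
        seen = {}
        for ref in "ACGT":
            for alt in "ACGT":
                if ref == alt:
                    continue
                seen.setdefault(substitution_class(ref, alt), []).append((ref, alt))
        assert len(seen) == 6
        assert all(len(v) == 2 for v in seen.values())

    def test_reference_mismatch_raises(self, small_sim):
        ref = small_sim.reference
        pos = 100
        actual = ref.base("chr1", pos - 1)
        wrong = "A" if actual != "A" else "C"
        other = "G" if wrong != "G" else "T"
        snv = SNVCall("chr1", pos, wrong, other)
        with pytest.raises(ValueError):
            mutation_spectrum([snv], ref)

    def test_uniform_snvs_near_uniform_classes(self, snv_sim):
        """Random substitutions on balanced sequence spread evenly over
        the six classes (±3 sd multinomial)."""
        counts = mutation_spectrum(snv_sim.bulk_snvs, snv_sim.reference)
        n = sum(counts.values())
        exp = n / 6
        sd = math.sqrt(n * (1 / 6) * (5 / 6))
        for v in counts.values():
            assert abs(v - exp) <= 3 * sd
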