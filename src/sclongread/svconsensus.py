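"""Structural-variant filtration, multi-cell consensus and benchmarking.

The multi-cell consensus is the core noise-suppression device of sparse
single-cell long-read SV calling: amplification chimeras and other
per-cell artifacts are private to one cell, so requiring a call to recur
(same type, breakpoints within 1 kb; translocation breakpoints within
±50 kb) in at least two cells removes them while true clonal variants
survive.  Benchmarking follows distance/type matching with multimatch
semantics and reports precision, recall, F1, FPR, FNR and the harmonic
mean HM = 2·FPR·FNR/(FPR+FNR).

Also here: a minimal split-read/CIGAR SV extractor (plumbing standing in
for a production long-read caller), the duplication-vs-telomere placement
test, and SNV benchmarking utilities (multi-cell support, per-base false
positive rate, six-class mutation spectrum).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
from bisect import bisect_left, bisect_right
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from sclongread.io_model import (
    GenomeInterval,
    MetricsReport,
    ReadAlignment,
    SNVCall,
    SVCall,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(tp: int, fp: int, fn: int) -> MetricsReport:
    """Derive the six benchmarking metrics from confusion counts.

    precision = TP/(TP+FP); recall = TP/(TP+FN); FPR = FP/(TP+FP);
    FNR = FN/(TP+FN); HM = 2·FPR·FNR/(FPR+FNR); F1 = 2·P·R/(P+R).
    0/0 ratios are NaN; HM is 0 when FPR = FNR = 0 and F1 is 0 when
    precision = recall = 0 (well-defined limits).
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    fpr = _ratio(fp, tp + fp)
    fnr = _ratio(fn, tp + fn)
    if math.isnan(fpr) or math.isnan(fnr):
        hm = float("nan")
    elif fpr == fnr == 0:
        hm = 0.0
    else:
        hm = 2 * fpr * fnr / (fpr + fnr)
    if math.isnan(precision) or math.isnan(recall):
        f1 = float("nan")
    elif precision == recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(tp, fp, fn, precision, recall, f1, fpr, fnr, hm)


# ---------------------------------------------------------------------------
# extraction from alignments (plumbing caller)
# ---------------------------------------------------------------------------


def _cigar_indels(seg, min_len: int) -> list[tuple[str, int, int]]:
    """(svtype, ref_pos, length) for D/I runs >= min_len in one segment."""
    import re

    out = []
    pos = seg.target.start
    for m in re.finditer(r"(\d+)([MIDNSHP=X])", seg.cigar or f"{seg.query_span}M"):
        n, op = int(m.group(1)), m.group(2)
        if op == "D" and n >= min_len:
            out.append(("DEL", pos, n))
        if op == "I" and n >= min_len:
            out.append(("INS", pos, n))
        if op in "MDN=X":
            pos += n
    return out


def extract_cell_svs(
    alignments: Iterable[ReadAlignment],
    min_len: int = 50,
    cluster_dist: int = 1000,
    max_query_gap: int = 100,
    chiastic_overhang_tol: int = 50,
) -> list[SVCall]:
    """Extract per-cell SV candidates from CIGARs and split alignments.

    DEL/INS come from CIGAR D/I runs >= ``min_len`` (DEL also from
    colinear same-strand split pairs with a reference gap >= min_len and
    query gap < ``max_query_gap``); TRA from cross-chromosome split pairs;
    INV from same-chromosome opposite-strand pairs; DUP from same-strand
    chiastic pairs (read-later segment genomically upstream).  A chiastic
    pair is emitted as DUP only when the read shows genomic context beyond
    the inferred repeat unit (overhang > ``chiastic_overhang_tol``) or
    wraps the unit more than once — a read confined to the unit is
    indistinguishable from a circle junction and is left to the ecDNA
    stage.  Events are clustered per type within ``cluster_dist``;
    read_support = number of distinct reads in the cluster.
    """
    events: list[SVCall] = []
    cell = None
    for ra in alignments:
        cell = cell or ra.cell_id
        for seg in ra.segments:
            for svtype, pos, length in _cigar_indels(seg, min_len):
                if svtype == "DEL":
                    locus = GenomeInterval(seg.target.chrom, pos, pos + length)
                    events.append(SVCall("DEL", locus, svlen=-length, cell_id=ra.cell_id, read_support=1))
                else:
                    locus = GenomeInterval(seg.target.chrom, pos, pos + 1)
                    events.append(SVCall("INS", locus, svlen=length, cell_id=ra.cell_id, read_support=1))
        for s1, s2 in zip(ra.segments, ra.segments[1:]):
            if abs(s2.query_start - s1.query_end) > max_query_gap:
                continue
            t1, t2 = s1.target, s2.target
            if t1.chrom != t2.chrom:
                bp1 = t1.end if s1.strand == "+" else t1.start
                bp2 = t2.start if s2.strand == "+" else t2.end
                events.append(
                    SVCall(
                        "TRA",
                        GenomeInterval(t1.chrom, max(bp1 - 1, 0), max(bp1, 1)),
                        mate=GenomeInterval(t2.chrom, max(bp2 - 1, 0), max(bp2, 1)),
                        cell_id=ra.cell_id,
                        read_support=1,
                    )
                )
            elif s1.strand != s2.strand:
                # the inverted interval is bounded by the two
                # junction-adjacent coordinates: for +/- pairs the segment
                # ends, for -/+ pairs the segment starts
                if s1.strand == "+":
                    lo, hi = sorted((t1.end, t2.end))
                else:
                    lo, hi = sorted((t1.start, t2.start))
                events.append(
                    SVCall(
                        "INV",
                        GenomeInterval(t1.chrom, lo, max(hi, lo + 1)),
                        cell_id=ra.cell_id,
                        read_support=1,
                    )
                )
            elif s1.strand == "+" and t2.start >= t1.end:
                gap = t2.start - t1.end
                if gap >= min_len:
                    events.append(
                        SVCall(
                            "DEL",
                            GenomeInterval(t1.chrom, t1.end, t2.start),
                            svlen=-gap,
                            cell_id=ra.cell_id,
                            read_support=1,
                        )
                    )
            else:
                # chiastic: read-later segment genomically upstream
                if s1.strand == "+":
                    first, second = s1, s2
                else:
                    first, second = s2, s1
                unit_lo = second.target.start
                unit_hi = first.target.end
                if unit_hi <= unit_lo:
                    continue
                overhang = max(unit_lo - first.target.start, 0) + max(
                    second.target.end - unit_hi, 0
                )
                wraps = ra.read_length >= (unit_hi - unit_lo) + chiastic_overhang_tol
                if overhang > chiastic_overhang_tol or wraps:
                    events.append(
                        SVCall(
                            "DUP",
                            GenomeInterval(t1.chrom, unit_lo, unit_hi),
                            svlen=unit_hi - unit_lo,
                            cell_id=ra.cell_id,
                            read_support=1,
                        )
                    )
    return _cluster_within_cell(events, cluster_dist)


def _cluster_within_cell(events: list[SVCall], dist: int) -> list[SVCall]:
    merged = merge_across_cells(
        [events], dist=dist, tra_dist=dist, min_cells=0
    )
    out = []
    for call, members in merged:
        out.append(
            dataclasses.replace(
                call,
                read_support=len(members),
                total_depth=len(members),
                cell_id=members[0].cell_id,
                supporting_cells=frozenset(),
            )
        )
    return out


# ---------------------------------------------------------------------------
# filtration
# ---------------------------------------------------------------------------


def filter_cell_calls(calls: Iterable[SVCall], min_reads: int = 2) -> list[SVCall]:
    """Keep only PASS calls supported by at least ``min_reads`` reads."""
    return [
        c
        for c in calls
        if c.filters == frozenset({"PASS"}) and c.read_support >= min_reads
    ]


def filter_bulk_calls(
    calls: Iterable[SVCall], min_reads: int = 4, min_ratio: float = 0.15
) -> list[SVCall]:
    """Bulk filtration: PASS, >= ``min_reads`` supporting reads, and
    support ratio strictly larger than ``min_ratio`` of local depth."""
    out = []
    for c in calls:
        if c.filters != frozenset({"PASS"}) or c.read_support < min_reads:
            continue
        if c.total_depth <= 0:
            logger.warning("bulk call at %s has zero depth; removed", c.locus)
            continue
        if c.read_support / c.total_depth > min_ratio:
            out.append(c)
    return out


def filter_indel_size(calls: Iterable[SVCall], min_indel: int = 100) -> list[SVCall]:
    """Drop DEL/INS shorter than ``min_indel`` bp (long-read platforms
    show frequent small-indel errors); other types pass through."""
    return [
        c
        for c in calls
        if c.svtype not in ("DEL", "INS") or abs(c.svlen) >= min_indel
    ]


# ---------------------------------------------------------------------------
# cross-cell consensus merging
# ---------------------------------------------------------------------------


def _tra_key(call: SVCall) -> tuple:
    """Canonical (chrom pair, breakpoints) with sorted chromosome order."""
    a = (call.locus.chrom, call.locus.start)
    b = (call.mate.chrom, call.mate.start)
    return tuple(sorted([a, b]))


def _linked(a: SVCall, b: SVCall, dist: int, tra_dist: int) -> bool:
    if a.svtype != b.svtype:
        return False
    if a.svtype == "TRA":
        ka, kb = _tra_key(a), _tra_key(b)
        if ka[0][0] != kb[0][0] or ka[1][0] != kb[1][0]:
            return False
        return (
            abs(ka[0][1] - kb[0][1]) <= tra_dist
            and abs(ka[1][1] - kb[1][1]) <= tra_dist
        )
    return (
        a.locus.chrom == b.locus.chrom
        and abs(a.locus.start - b.locus.start) <= dist
        and abs(a.locus.end - b.locus.end) <= dist
    )


class _UnionFind:
    def __init__(self, n: int):
        self.p = list(range(n))

    def find(self, i: int) -> int:
        while self.p[i] != i:
            self.p[i] = self.p[self.p[i]]
            i = self.p[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.p[self.find(i)] = self.find(j)


def merge_across_cells(
    callsets: Sequence[Sequence[SVCall]],
    dist: int = 1000,
    tra_dist: int = 50_000,
    min_cells: int = 2,
) -> list[SVCall] | list[tuple[SVCall, list[SVCall]]]:
    """Single-linkage consensus merge of per-cell call sets.

    Calls of the same type are linked when both breakpoints are within
    ``dist`` bp (both translocation breakpoints within ``tra_dist``, with
    matching chromosome pair).  Each connected cluster becomes one
    consensus call at the member-median breakpoints with
    ``supporting_cells`` = union of member cells; clusters supported by
    fewer than ``min_cells`` cells are discarded.  The result is invariant
    under permutation of the input cells.

    With ``min_cells=0`` the (consensus, members) pairs are returned
    instead — used internally for within-cell read clustering.
    """
    flat = [c for cs in callsets for c in cs]
    flat.sort(key=SVCall.sort_key)
    n = len(flat)
    uf = _UnionFind(n)
    # sort-window neighbor scan per svtype keeps this near O(n log n)
    by_type: dict[str, list[int]] = {}
    for i, c in enumerate(flat):
        by_type.setdefault(c.svtype, []).append(i)
    for svtype, idxs in by_type.items():
        reach = tra_dist if svtype == "TRA" else dist
        key = (
            (lambda i: _tra_key(flat[i])[0][1])
            if svtype == "TRA"
            else (lambda i: flat[i].locus.start)
        )
        idxs = sorted(idxs, key=key)
        starts = [key(i) for i in idxs]
        for a_pos, i in enumerate(idxs):
            hi = bisect_right(starts, starts[a_pos] + reach)
            for b_pos in range(a_pos + 1, hi):
                j = idxs[b_pos]
                if _linked(flat[i], flat[j], dist, tra_dist):
                    uf.union(i, j)
    clusters: dict[int, list[SVCall]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(flat[i])
    results: list[tuple[SVCall, list[SVCall]]] = []
    for members in clusters.values():
        members.sort(key=SVCall.sort_key)
        cells = frozenset(
            m.cell_id for m in members if m.cell_id is not None
        ) | frozenset(c for m in members for c in m.supporting_cells)
        consensus = _consensus_call(members, cells)
        results.append((consensus, members))
    results.sort(key=lambda t: t[0].sort_key())
    if min_cells == 0:
        return results
    return [
        cons
        for cons, _ in results
        if len(cons.supporting_cells) >= min_cells
    ]


def _consensus_call(members: list[SVCall], cells: frozenset[str]) -> SVCall:
    svtype = members[0].svtype
    med = lambda xs: int(np.median(sorted(xs)))
    if svtype == "TRA":
        keys = [_tra_key(m) for m in members]
        c1 = keys[0][0][0]
        c2 = keys[0][1][0]
        p1 = med([k[0][1] for k in keys])
        p2 = med([k[1][1] for k in keys])
        return SVCall(
            "TRA",
            GenomeInterval(c1, p1, p1 + 1),
            mate=GenomeInterval(c2, p2, p2 + 1),
            read_support=sum(m.read_support for m in members),
            supporting_cells=cells,
        )
    start = med([m.locus.start for m in members])
    end = max(med([m.locus.end for m in members]), start + 1)
    svlen = med([m.svlen for m in members])
    if svtype == "DEL":
        svlen = min(svlen, -1)
    elif svtype in ("INS", "DUP"):
        svlen = max(svlen, 1)
    return SVCall(
        svtype,
        GenomeInterval(members[0].locus.chrom, start, end),
        svlen=svlen,
        read_support=sum(m.read_support for m in members),
        supporting_cells=cells,
    )


# ---------------------------------------------------------------------------
# benchmarking
# ---------------------------------------------------------------------------


def benchmark_svs(
    test_calls: Sequence[SVCall],
    truth_calls: Sequence[SVCall],
    dist: int = 1000,
    tra_dist: int = 50_000,
    multimatch: bool = True,
) -> tuple[MetricsReport, list[tuple[int, int]]]:
    """Match test calls against a truth set by type and breakpoint distance.

    A test call is a TP when at least one truth call of the same type has
    both breakpoints within ``dist`` (``tra_dist`` for TRA); with
    multimatch several test calls may claim the same truth call.  FN are
    truth calls matched by no test call.  Indels shorter than the
    platform error floor should be excluded beforehand
    (:func:`filter_indel_size`).  Returns the metrics and the matched
    (test index, truth index) pairs.
    """
    pairs: list[tuple[int, int]] = []
    truth_by_type: dict[str, list[int]] = {}
    for j, t in enumerate(truth_calls):
        truth_by_type.setdefault(t.svtype, []).append(j)
    order: dict[str, tuple[list[int], list[int]]] = {}
    for svtype, js in truth_by_type.items():
        key = (
            (lambda j: _tra_key(truth_calls[j])[0][1])
            if svtype == "TRA"
            else (lambda j: truth_calls[j].locus.start)
        )
        js_sorted = sorted(js, key=key)
        order[svtype] = (js_sorted, [key(j) for j in js_sorted])
    matched_test: set[int] = set()
    matched_truth: set[int] = set()
    for i, c in enumerate(test_calls):
        if c.svtype not in order:
            continue
        reach = tra_dist if c.svtype == "TRA" else dist
        pos = _tra_key(c)[0][1] if c.svtype == "TRA" else c.locus.start
        js_sorted, starts = order[c.svtype]
        lo = bisect_left(starts, pos - reach)
        hi = bisect_right(starts, pos + reach)
        hits = [
            j
            for j in js_sorted[lo:hi]
            if _linked(c, truth_calls[j], dist, tra_dist)
        ]
        if not hits:
            continue
        if not multimatch:
            # one-to-one: claim the nearest still-unmatched truth call
            free = [j for j in hits if j not in matched_truth]
            if not free:
                continue
            hits = [min(free, key=lambda j: _match_distance(c, truth_calls[j]))]
        matched_test.add(i)
        for j in hits:
            matched_truth.add(j)
            pairs.append((i, j))
    tp = len(matched_test)
    fp = len(test_calls) - tp
    fn = len(truth_calls) - len(matched_truth)
    return compute_metrics(tp, fp, fn), pairs


def _match_distance(a: SVCall, b: SVCall) -> int:
    if a.svtype == "TRA":
        ka, kb = _tra_key(a), _tra_key(b)
        return abs(ka[0][1] - kb[0][1]) + abs(ka[1][1] - kb[1][1])
    return abs(a.locus.start - b.locus.start) + abs(a.locus.end - b.locus.end)


def match_ngs_style(
    a_calls: Sequence[SVCall], b_calls: Sequence[SVCall]
) -> list[tuple[int, int]]:
    """Cross-platform matching for comparing against short-read call sets.

    Deletions match on reciprocal overlap strictly larger than 10% of each
    interval; insertions on breakpoints within ±1 kb.  Other types are
    rejected.
    """
    for c in itertools.chain(a_calls, b_calls):
        if c.svtype not in ("DEL", "INS"):
            raise ValueError(f"match_ngs_style accepts DEL/INS only, got {c.svtype}")
    pairs = []
    for i, a in enumerate(a_calls):
        for j, b in enumerate(b_calls):
            if a.svtype != b.svtype:
                continue
            if a.svtype == "DEL":
                ov = a.locus.overlap_len(b.locus)
                if ov / len(a.locus) > 0.10 and ov / len(b.locus) > 0.10:
                    pairs.append((i, j))
            else:
                if (
                    a.locus.chrom == b.locus.chrom
                    and abs(a.locus.start - b.locus.start) <= 1000
                ):
                    pairs.append((i, j))
    return pairs


# ---------------------------------------------------------------------------
# duplication placement along chromosome arms
# ---------------------------------------------------------------------------


def duplication_telomere_test(
    dup_calls: Sequence[SVCall],
    arm_annotation: Sequence[tuple[GenomeInterval, str]],
    n_windows: int = 100,
) -> tuple[np.ndarray, float]:
    """Bin duplications by relative centromere→telomere arm position.

    Each duplication midpoint is assigned a relative position r in [0, 1)
    along its arm (0 = centromere, 1 = telomere; p-arm orientation
    reversed accordingly), pooled across arms into ``n_windows`` equal
    bins, and tested against the uniform multinomial with a chi-square
    goodness-of-fit test (df = n_windows - 1).  Returns (counts, p).
    """
    counts = np.zeros(n_windows, dtype=int)
    for call in dup_calls:
        mid = (call.locus.start + call.locus.end) // 2
        r = None
        for iv, name in arm_annotation:
            if iv.chrom == call.locus.chrom and iv.start <= mid < iv.end:
                frac = (mid - iv.start) / len(iv)
                # q arms run centromere->telomere left to right; p arms the
                # opposite way
                r = 1.0 - frac if name.endswith("p") else frac
                break
        if r is None:
            logger.warning("duplication at %s outside any arm; skipped", call.locus)
            continue
        counts[min(int(r * n_windows), n_windows - 1)] += 1
    if counts.sum() == 0:
        return counts, 1.0
    if np.all(counts == counts[0]):
        return counts, 1.0
    _, p = stats.chisquare(counts)
    return counts, float(p)


# ---------------------------------------------------------------------------
# SNV benchmarking
# ---------------------------------------------------------------------------


def snv_multicell_support(
    snv_callsets: Mapping[str, Sequence[SNVCall]],
    bulk_snvs: Sequence[SNVCall],
    k: int = 1,
) -> MetricsReport:
    """Benchmark SNVs supported by at least ``k`` cells against bulk.

    Candidates are SNVs called with an identical alternative allele in
    >= k cells; a candidate is TP when the bulk set carries the same
    (chrom, pos, alt), FP otherwise (a bulk call at the same position
    with a different alt does not rescue it).  recall here is detection
    efficiency, TP / |bulk|.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    support: dict[tuple, set[str]] = {}
    for cell, calls in snv_callsets.items():
        for s in calls:
            support.setdefault(s.key, set()).add(cell)
    candidates = {key for key, cells in support.items() if len(cells) >= k}
    bulk_keys = {s.key for s in bulk_snvs}
    tp = len(candidates & bulk_keys)
    fp = len(candidates - bulk_keys)
    fn = len(bulk_keys) - tp
    return compute_metrics(tp, fp, fn)


def snv_fpr(
    cell_snvs: Sequence[SNVCall],
    bulk_snvs: Sequence[SNVCall],
    covered_bases: int,
) -> float:
    """Per-base false-positive rate: cell calls absent from bulk
    (position + alt) divided by the cell's covered bases."""
    if covered_bases <= 0:
        raise ValueError("covered_bases must be > 0")
    bulk_keys = {s.key for s in bulk_snvs}
    fp = sum(1 for s in cell_snvs if s.key not in bulk_keys)
    return fp / covered_bases


#: Six base-substitution classes with strand-complementary pairs collapsed
#: (e.g. C→T and G→A are both "CG>TA").
SPECTRUM_CLASSES = ("CG>TA", "CG>AT", "CG>GC", "TA>AT", "TA>CG", "TA>GC")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def substitution_class(ref: str, alt: str) -> str:
    """Map one substitution to its strand-collapsed class."""
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"bad substitution {ref}>{alt}")
    if ref in "GA":  # collapse to the C/T (pyrimidine) strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    pair = {"C": "CG", "T": "TA"}[ref]
    alt_pair = alt + _COMPLEMENT[alt]
    return f"{pair}>{alt_pair}"


def mutation_spectrum(
    snvs: Sequence[SNVCall], reference=None
) -> dict[str, int]:
    """Count SNVs per substitution class.

    When a reference is given (any object with ``base(chrom, pos0)``),
    each SNV's ref base is verified against it and a mismatch raises.
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for s in snvs:
        if reference is not None:
            actual = reference.base(s.chrom, s.pos - 1)
            if actual != s.ref_base:
                raise ValueError(
                    f"{s.chrom}:{s.pos} ref {s.ref_base} != reference {actual}"
                )
        counts[substitution_class(s.ref_base, s.alt_base)] += 1
    return counts
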