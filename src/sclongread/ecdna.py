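"""Extrachromosomal circular DNA (ecDNA) detection from chiastic reads.

A read that traverses the junction of a circular template aligns back to
the linear reference as exactly two segments on the same chromosome and
strand, in *chiastic* order: the segment that comes first on the read maps
genomically downstream of the one that comes second.  The inferred circle
is [start of the read-later segment, end of the read-earlier segment).
A circle linearized by a single transposition event yields a full-length
read of exactly the circle length, so independent copies give distinct
reads of identical length — evidence a tandem repeat cannot produce.

The pipeline is a fixed composition that only removes or merges, never
invents candidates:

1. detect chiastic two-segment reads;
2. remove candidates whose junction falls in a long (>1 kb) tandem
   repeat (junctions inside repeats are unmappable evidence);
3. remove candidates matching a multi-cell (>=4) consensus duplication
   within ±100 bp (head-to-tail duplication junctions are the one
   confounder with the same read signature);
4. merge candidates across cells (±50 bp) and keep those supported by
   at least two cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from sclongread.io_model import (
    DEFAULT_MITO_CHROM,
    EcDNACandidate,
    GenomeInterval,
    ReadAlignment,
    SVCall,
)

logger = logging.getLogger(__name__)


def detect_chiastic_reads(
    alignments: Iterable[ReadAlignment],
    max_query_gap: int = 50,
    junction_tol: int = 50,
    full_length_frac: float = 0.95,
) -> list[EcDNACandidate]:
    """Find reads whose alignment is exactly two chiastic segments.

    A read qualifies iff it has exactly two aligned segments on the same
    chromosome and strand, with the read-earlier segment genomically
    downstream of the read-later one (minus-strand reads are normalized
    to genome orientation first), the query gap/overlap between segments
    is <= ``max_query_gap``, and the segments overlap genomically by at
    most ``junction_tol``.  Non-qualifying reads are counted and skipped.
    """
    candidates = []
    n_skipped = 0
    for ra in alignments:
        cand = _read_candidate(ra, max_query_gap, junction_tol, full_length_frac)
        if cand is None:
            n_skipped += 1
        else:
            candidates.append(cand)
    logger.info(
        "chiastic detection: %d candidates, %d reads skipped",
        len(candidates),
        n_skipped,
    )
    return candidates


def _read_candidate(
    ra: ReadAlignment,
    max_query_gap: int,
    junction_tol: int,
    full_length_frac: float,
) -> EcDNACandidate | None:
    if len(ra.segments) != 2:
        return None
    s1, s2 = ra.segments  # query order
    t1, t2 = s1.target, s2.target
    if t1.chrom != t2.chrom or s1.strand != s2.strand:
        return None
    if abs(s2.query_start - s1.query_end) > max_query_gap:
        return None
    # normalize minus-strand reads to genome orientation: reading the
    # reverse complement swaps which segment crossed the junction first
    first, second = (s1, s2) if s1.strand == "+" else (s2, s1)
    lo = second.target.start
    hi = first.target.end
    if lo >= hi:
        return None  # colinear (deletion-like), not chiastic
    # the segments may abut but not overlap genomically by more than the
    # junction tolerance (a read covering more than one circle length
    # would; so would repeat expansions)
    overlap = min(first.target.end, second.target.end) - max(
        first.target.start, second.target.start
    )
    if overlap > junction_tol:
        return None
    covered = s1.query_span + s2.query_span
    full = covered >= full_length_frac * ra.read_length
    return EcDNACandidate(
        circle=GenomeInterval(t1.chrom, lo, hi),
        supporting_reads=[ra.read_id],
        supporting_cells=frozenset({ra.cell_id}),
        full_length_read=full,
        full_length_sizes=[ra.read_length] if full else [],
    )


def filter_tandem_repeats(
    candidates: Sequence[EcDNACandidate],
    trf_intervals: Sequence[GenomeInterval],
    junction_tol: int = 50,
    min_repeat_len: int = 1000,
) -> list[EcDNACandidate]:
    """Remove candidates whose junction lies in a long tandem repeat.

    Only annotation entries strictly longer than ``min_repeat_len`` count;
    a candidate is removed when either junction breakpoint falls inside,
    or within ``junction_tol`` of, a qualifying repeat.  The circle body
    may legitimately contain repeats — only the junction is tested.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in trf_intervals:
        if len(iv) > min_repeat_len:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    out = []
    for cand in candidates:
        tree = trees.get(cand.circle.chrom)
        if tree is not None and (
            tree.overlaps(cand.junction_left - junction_tol, cand.junction_left + junction_tol + 1)
            or tree.overlaps(cand.junction_right - junction_tol, cand.junction_right + junction_tol + 1)
        ):
            continue
        out.append(cand)
    return out


def filter_duplications(
    candidates: Sequence[EcDNACandidate],
    dup_calls: Sequence[SVCall],
    min_dup_cells: int = 4,
    tol: int = 100,
) -> list[EcDNACandidate]:
    """Remove candidates explained by multi-cell consensus duplications.

    A candidate is removed when a DUP consensus call supported by at
    least ``min_dup_cells`` cells has both coordinates within ±``tol``
    of the candidate's junction coordinates.
    """
    strong = [
        d
        for d in dup_calls
        if d.svtype == "DUP" and len(d.supporting_cells) >= min_dup_cells
    ]
    out = []
    for cand in candidates:
        hit = any(
            d.locus.chrom == cand.circle.chrom
            and abs(d.locus.start - cand.junction_left) <= tol
            and abs(d.locus.end - cand.junction_right) <= tol
            for d in strong
        )
        if not hit:
            out.append(cand)
    return out


def merge_ecdna(
    candidates: Sequence[EcDNACandidate],
    tol: int = 50,
    min_cells: int = 2,
) -> list[EcDNACandidate]:
    """Merge per-read candidates across cells by single linkage.

    Candidates are linked when both junction coordinates are within
    ±``tol``; each cluster becomes one consensus candidate at the
    member-median coordinates with the union of supporting reads and
    cells.  Clusters seen in fewer than ``min_cells`` distinct cells are
    dropped ("supported by at least two cells" = >=1 read in each of >=2
    cells).  Permutation-invariant.
    """
    cands = sorted(
        candidates,
        key=lambda c: (c.circle.chrom, c.circle.start, c.circle.end, c.supporting_reads),
    )
    n = len(cands)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    by_chrom: dict[str, list[int]] = {}
    for i, c in enumerate(cands):
        by_chrom.setdefault(c.circle.chrom, []).append(i)
    for idxs in by_chrom.values():
        idxs.sort(key=lambda i: cands[i].circle.start)
        for a_pos, i in enumerate(idxs):
            for b_pos in range(a_pos + 1, len(idxs)):
                j = idxs[b_pos]
                if cands[j].circle.start - cands[i].circle.start > tol:
                    break
                if abs(cands[i].circle.end - cands[j].circle.end) <= tol:
                    ri, rj = find(i), find(j)
                    parent[ri] = rj
    clusters: dict[int, list[EcDNACandidate]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(cands[i])
    merged = []
    for members in clusters.values():
        cells = frozenset(c for m in members for c in m.supporting_cells)
        if len(cells) < min_cells:
            continue
        start = int(np.median([m.circle.start for m in members]))
        end = int(np.median([m.circle.end for m in members]))
        merged.append(
            EcDNACandidate(
                circle=GenomeInterval(members[0].circle.chrom, start, max(end, start + 1)),
                supporting_reads=sorted(
                    r for m in members for r in m.supporting_reads
                ),
                supporting_cells=cells,
                full_length_read=any(m.full_length_read for m in members),
                full_length_sizes=sorted(
                    s for m in members for s in m.full_length_sizes
                ),
            )
        )
    merged.sort(key=lambda c: (c.circle.chrom, c.circle.start, c.circle.end))
    return merged


@dataclass(frozen=True)
class LengthEvidence:
    """Same-length evidence for one merged candidate."""

    modal_length: int
    modal_reads: int
    modal_cells: int
    n_groups: int
    heterogeneous: bool


def same_length_evidence(
    candidate: EcDNACandidate,
    read_info: Mapping[str, tuple[str, int]] | None = None,
    tol: int = 20,
) -> LengthEvidence | None:
    """Group a candidate's full-length reads by read length (±``tol``,
    single linkage on sorted lengths).

    Distinct circle copies linearized by single cuts produce reads of
    exactly the circle length, so a dominant length group spanning
    multiple cells strengthens the circle (vs tandem repeat)
    interpretation.  Reads at clearly different lengths (dimers, repeat
    expansions) flag the candidate heterogeneous.  ``read_info`` maps
    read_id -> (cell_id, read_length) and enables an exact per-cell count
    for the modal group; without it the candidate's cell set is used.
    Returns None when no full-length reads exist — the candidate keeps
    junction-only status.
    """
    if read_info is not None:
        pairs = sorted(
            (length, cell)
            for r in candidate.supporting_reads
            if r in read_info
            for cell, length in [read_info[r]]
        )
        sizes = [p[0] for p in pairs]
    else:
        pairs = None
        sizes = sorted(candidate.full_length_sizes)
    if not sizes:
        return None
    groups: list[list[int]] = [[0]]
    for i in range(1, len(sizes)):
        if sizes[i] - sizes[groups[-1][-1]] <= tol:
            groups[-1].append(i)
        else:
            groups.append([i])
    modal = max(groups, key=len)
    if pairs is not None:
        modal_cells = len({pairs[i][1] for i in modal})
    else:
        modal_cells = len(candidate.supporting_cells)
    return LengthEvidence(
        modal_length=int(np.median([sizes[i] for i in modal])),
        modal_reads=len(modal),
        modal_cells=modal_cells,
        n_groups=len(groups),
        heterogeneous=len(groups) > 1,
    )


def run_pipeline(
    cell_alignments: Mapping[str, Iterable[ReadAlignment]],
    trf_intervals: Sequence[GenomeInterval] = (),
    dup_calls: Sequence[SVCall] = (),
    max_query_gap: int = 50,
    junction_tol: int = 50,
    dup_tol: int = 100,
    min_dup_cells: int = 4,
    merge_tol: int = 50,
    min_cells: int = 2,
    mito_chrom: str = DEFAULT_MITO_CHROM,
) -> tuple[list[EcDNACandidate], list[EcDNACandidate]]:
    """Run the full detection pipeline over all cells.

    Returns (nuclear candidates, mitochondrial candidates); the
    mitochondrial contig is reported separately since it is a known
    circle serving as a positive control.
    """
    per_read: list[EcDNACandidate] = []
    for cell, alns in cell_alignments.items():
        per_read.extend(
            detect_chiastic_reads(
                alns, max_query_gap=max_query_gap, junction_tol=junction_tol
            )
        )
    per_read = filter_tandem_repeats(per_read, trf_intervals, junction_tol=junction_tol)
    per_read = filter_duplications(
        per_read, dup_calls, min_dup_cells=min_dup_cells, tol=dup_tol
    )
    nuclear = [c for c in per_read if c.circle.chrom != mito_chrom]
    mito = [c for c in per_read if c.circle.chrom == mito_chrom]
    return (
        merge_ecdna(nuclear, tol=merge_tol, min_cells=min_cells),
        merge_ecdna(mito, tol=merge_tol, min_cells=1),
    )


def run_pipeline_with_dup_evidence(
    cell_alignments: Mapping[str, Sequence[ReadAlignment]],
    trf_intervals: Sequence[GenomeInterval] = (),
    **kwargs,
) -> tuple[list[EcDNACandidate], list[EcDNACandidate]]:
    """Full pipeline deriving the duplication evidence from the reads.

    Per-cell DUP calls are extracted from the alignments (any PASS call
    counts as duplication evidence — the ±100 bp / >=4-cell requirement
    of the filter is its own specificity control) and merged across cells
    before the candidate filter runs.
    """
    from sclongread.svconsensus import extract_cell_svs, merge_across_cells

    dup_sets = []
    for cell, alns in cell_alignments.items():
        calls = extract_cell_svs(alns)
        dup_sets.append([c for c in calls if c.svtype == "DUP"])
    dup_consensus = merge_across_cells(dup_sets, min_cells=1)
    return run_pipeline(
        cell_alignments, trf_intervals, dup_consensus, **kwargs
    )


def candidates_to_tsv(
    candidates: Sequence[EcDNACandidate], path: str
) -> None:
    """Write merged candidates as a BED-like TSV."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstart\tend\tn_cells\tn_reads\tfull_length_reads\tmodal_length\n"
        )
        for c in candidates:
            ev = same_length_evidence(c)
            fh.write(
                "\t".join(
                    [
                        c.circle.chrom,
                        str(c.circle.start),
                        str(c.circle.end),
                        str(len(c.supporting_cells)),
                        str(len(c.supporting_reads)),
                        str(len(c.full_length_sizes)),
                        str(ev.modal_length) if ev else "NA",
                    ]
                )
                + "\n"
            )
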