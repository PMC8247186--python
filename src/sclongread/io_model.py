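"""Domain types and file I/O shared by all pipeline stages.

Coordinate discipline: every in-memory coordinate is 0-based half-open.
The only place 1-based coordinates appear is at the VCF boundary, where
``write_sv_vcf``/``read_sv_vcf`` convert on the way out/in.

Structural variants are typed DEL/INS/DUP/INV/TRA.  A translocation is one
logical call with two breakpoints; on disk it becomes a pair of BND records
reunited through MATEID on read.  Read support is carried in INFO keys
``SUPPORT`` and ``DEPTH``; post-merge cell support in ``SUPP_CELLS``.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

logger = logging.getLogger(__name__)

SV_TYPES = ("DEL", "INS", "DUP", "INV", "TRA")
FILTER_FLAGS = ("PASS", "IMPRECISE", "SHADOWED")

#: Default name of the mitochondrial contig.  Mitochondrial reads are
#: flagged and reported separately, never dropped: the mitochondrial genome
#: is a bona fide circular DNA and serves as a positive control for
#: circle detection.
DEFAULT_MITO_CHROM = "chrM"

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_OPS = frozenset("MIS=X")
_REF_OPS = frozenset("MDN=X")


class RecordError(ValueError):
    """A single malformed record (carries enough context to identify it)."""


def cigar_lengths(cigar: str) -> tuple[int, int]:
    """Return (query_consumed, reference_consumed) lengths of a CIGAR.

    Query-consuming ops: M I S = X.  Reference-consuming: M D N = X.
    Hard clips consume neither.  Raises :class:`RecordError` on a malformed
    string.
    """
    pos = 0
    q = r = 0
    for m in _CIGAR_RE.finditer(cigar):
        if m.start() != pos:
            raise RecordError(f"malformed CIGAR {cigar!r}")
        pos = m.end()
        n, op = int(m.group(1)), m.group(2)
        if op in _QUERY_OPS:
            q += n
        if op in _REF_OPS:
            r += n
    if pos != len(cigar) or not cigar:
        raise RecordError(f"malformed CIGAR {cigar!r}")
    return q, r


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class AlignmentSegment:
    """One aligned segment of a read (primary or supplementary).

    ``query_start``/``query_end`` are 0-based half-open offsets on the
    original read orientation; ``strand`` gives the genome strand the
    segment aligns to.  The clipped-out CIGAR (no S/H ops) must be
    consistent with both the query span and the target span.
    """

    read_id: str
    query_start: int
    query_end: int
    target: GenomeInterval
    strand: str
    mapq: int = 60
    cigar: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (0 <= self.query_start < self.query_end):
            raise ValueError("require 0 <= query_start < query_end")
        if self.cigar:
            q, r = cigar_lengths(self.cigar)
            qspan = self.query_end - self.query_start
            if q != qspan:
                raise RecordError(
                    f"{self.read_id}: CIGAR query length {q} != span {qspan}"
                )
            if r != len(self.target):
                raise RecordError(
                    f"{self.read_id}: CIGAR ref length {r} != "
                    f"target span {len(self.target)}"
                )

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@dataclass
class ReadAlignment:
    """All aligned segments of one long read, sorted by query offset."""

    read_id: str
    cell_id: str
    segments: list[AlignmentSegment]
    read_length: int

    def __post_init__(self) -> None:
        if any(s.read_id != self.read_id for s in self.segments):
            raise ValueError("segment read_id mismatch")
        self.segments.sort(key=lambda s: (s.query_start, s.query_end))
        if self.segments and self.read_length < max(
            s.query_end for s in self.segments
        ):
            raise ValueError("read_length shorter than aligned span")

    @property
    def primary(self) -> AlignmentSegment:
        """The segment with the longest query span (ties: first in read)."""
        return max(self.segments, key=lambda s: (s.query_span, -s.query_start))

    def is_mito(self, mito_chrom: str = DEFAULT_MITO_CHROM) -> bool:
        return any(s.target.chrom == mito_chrom for s in self.segments)


@dataclass
class SVCall:
    """A typed structural-variant call.

    For TRA the two breakpoints live in ``locus`` (breakpoint 1) and
    ``mate`` (breakpoint 2), each a width-1 interval; ``svlen`` is 0.
    """

    svtype: str
    locus: GenomeInterval
    svlen: int = 0
    mate: GenomeInterval | None = None
    read_support: int = 0
    total_depth: int = 0
    filters: frozenset[str] = frozenset({"PASS"})
    cell_id: str | None = None
    supporting_cells: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if (self.svtype == "TRA") != (self.mate is not None):
            raise ValueError("mate present iff svtype is TRA")
        if self.svtype == "DEL" and self.svlen >= 0:
            raise ValueError("DEL requires svlen < 0")
        if self.svtype in ("INS", "DUP") and self.svlen <= 0:
            raise ValueError(f"{self.svtype} requires svlen > 0")
        if self.read_support < 0:
            raise ValueError("read_support must be >= 0")
        if 0 < self.total_depth < self.read_support:
            raise ValueError("read_support exceeds total_depth")
        self.filters = frozenset(self.filters)
        self.supporting_cells = frozenset(self.supporting_cells)

    def sort_key(self) -> tuple:
        mate = self.mate
        return (
            self.svtype,
            self.locus.chrom,
            self.locus.start,
            self.locus.end,
            "" if mate is None else mate.chrom,
            -1 if mate is None else mate.start,
            self.cell_id or "",
        )


@dataclass(frozen=True)
class SNVCall:
    """A single-nucleotide variant keyed by (chrom, 1-based pos, alt)."""

    chrom: str
    pos: int  # 1-based, VCF-style
    ref_base: str
    alt_base: str
    cell_id: str = "bulk"
    supporting_cells: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for b in (self.ref_base, self.alt_base):
            if b not in "ACGT" or len(b) != 1:
                raise ValueError(f"bad base {b!r}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt_base)


@dataclass
class EcDNACandidate:
    """An inferred circular-DNA interval with its junction evidence.

    The circle junction joins ``circle.end`` back to ``circle.start``; a
    chiastic read crosses it once (or, for a full-length read from a
    single-cut circle, covers the whole circle).
    """

    circle: GenomeInterval
    supporting_reads: list[str]
    supporting_cells: frozenset[str]
    full_length_read: bool = False
    full_length_sizes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.supporting_reads:
            raise ValueError("supporting_reads must be non-empty")
        self.supporting_cells = frozenset(self.supporting_cells)

    @property
    def junction_left(self) -> int:
        return self.circle.start

    @property
    def junction_right(self) -> int:
        return self.circle.end


@dataclass
class CNVProfile:
    """Per-window read-count copy-number profile for one sample.

    All vectors are aligned with ``windows``; ``gap_mask`` is True for
    windows overlapping assembly gaps (excluded from normalization, CV and
    correlation).  ``segments`` is a list of (start_idx, end_idx, mean)
    over window indices, half-open.
    """

    windows: list[GenomeInterval]
    raw_counts: "np.ndarray"
    ratios: "np.ndarray"
    copy_number: "np.ndarray | None" = None
    segments: list[tuple[int, int, float]] | None = None
    gap_mask: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        import numpy as np

        n = len(self.windows)
        self.raw_counts = np.asarray(self.raw_counts, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(n, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.copy_number is not None:
            self.copy_number = np.asarray(self.copy_number, dtype=float)
        for v in (self.raw_counts, self.ratios, self.gap_mask):
            if len(v) != n:
                raise ValueError("vector length != number of windows")

    @property
    def unmasked(self) -> "np.ndarray":
        return ~self.gap_mask

    def segment_values(self) -> "np.ndarray":
        """Per-window segmented copy number (segment mean broadcast)."""
        import numpy as np

        if self.segments is None:
            raise ValueError("profile has no segmentation")
        out = np.full(len(self.windows), np.nan)
        for lo, hi, mean in self.segments:
            out[lo:hi] = mean
        return out


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the derived benchmarking metrics.

    Conventions: a 0/0 ratio is reported as NaN (explicitly undefined)
    except hm = 0 when fpr = fnr = 0 and f1 = 0 when precision = recall = 0,
    which are well-defined limits.
    Identities: fpr = 1 - precision; hm <= max(fpr, fnr).
    """

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    fpr: float
    fnr: float
    hm: float

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "hm": self.hm,
        }


# ---------------------------------------------------------------------------
# SAM / BAM
# ---------------------------------------------------------------------------


def _segment_from_record(rec: pysam.AlignedSegment) -> AlignmentSegment:
    """Build an AlignmentSegment from one mapped SAM record.

    Query offsets are reported on the original read orientation: for a
    reverse-strand record the leading clip in SAM coordinates is the
    trailing clip on the read.
    """
    cig = rec.cigartuples or []
    if not cig:
        raise RecordError(f"{rec.query_name}: missing CIGAR")
    lead = cig[0][1] if cig[0][0] in (4, 5) else 0
    tail = cig[-1][1] if cig[-1][0] in (4, 5) else 0
    qlen = sum(n for op, n in cig if op in (0, 1, 4, 7, 8))  # M I S = X
    aligned = qlen - (cig[0][1] if cig[0][0] == 4 else 0) - (
        cig[-1][1] if cig[-1][0] == 4 else 0
    )
    strand = "-" if rec.is_reverse else "+"
    if strand == "+":
        qs = lead
    else:
        qs = tail
    qe = qs + aligned
    core = "".join(
        f"{n}{'MIDNSHP=X'[op]}" for op, n in cig if op not in (4, 5)
    )
    return AlignmentSegment(
        read_id=rec.query_name,
        query_start=qs,
        query_end=qe,
        target=GenomeInterval(
            rec.reference_name, rec.reference_start, rec.reference_end
        ),
        strand=strand,
        mapq=rec.mapping_quality,
        cigar=core,
    )


def read_alignments(path: str | Path, cell_id: str = "") -> list[ReadAlignment]:
    """Read SAM/BAM into ReadAlignments, assembling split reads.

    Primary and supplementary records of one read become the segments of a
    single :class:`ReadAlignment`; unmapped and secondary records are
    dropped.  Malformed CIGARs raise :class:`RecordError` naming the read.
    """
    by_read: dict[str, list[AlignmentSegment]] = {}
    lengths: dict[str, int] = {}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            seg = _segment_from_record(rec)
            by_read.setdefault(rec.query_name, []).append(seg)
            cig = rec.cigartuples or []
            total = sum(n for op, n in cig if op in (0, 1, 4, 5, 7, 8))
            lengths[rec.query_name] = max(
                lengths.get(rec.query_name, 0), total
            )
    out = []
    for rid in sorted(by_read):
        out.append(
            ReadAlignment(
                read_id=rid,
                cell_id=cell_id,
                segments=by_read[rid],
                read_length=lengths[rid],
            )
        )
    return out


def write_sam(
    alignments: Iterable[ReadAlignment],
    path: str | Path,
    reference_lengths: dict[str, int],
) -> None:
    """Write ReadAlignments as SAM with SA tags on split reads.

    The longest segment of each read is emitted as the primary record,
    the others as supplementary (flag 2048).  SEQ is omitted ('*'); the
    pipeline consumes coordinates and CIGARs only.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": c, "LN": int(l)} for c, l in reference_lengths.items()
        ],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for ra in alignments:
            if not ra.segments:
                continue
            prim = ra.primary
            sa_parts = {}
            for seg in ra.segments:
                nm = 0
                sa_parts[id(seg)] = (
                    f"{seg.target.chrom},{seg.target.start + 1},{seg.strand},"
                    f"{_sam_cigar(seg, ra.read_length)},{seg.mapq},{nm};"
                )
            for seg in ra.segments:
                a = pysam.AlignedSegment(fh.header)
                a.query_name = ra.read_id
                a.reference_name = seg.target.chrom
                a.reference_start = seg.target.start
                a.mapping_quality = seg.mapq
                a.cigarstring = _sam_cigar(seg, ra.read_length)
                a.flag = (16 if seg.strand == "-" else 0) | (
                    0 if seg is prim else 2048
                )
                others = "".join(
                    sa_parts[id(s)] for s in ra.segments if s is not seg
                )
                tags = [("RG", ra.cell_id)] if ra.cell_id else []
                if others:
                    tags.append(("SA", others))
                if tags:
                    a.set_tags(tags)
                fh.write(a)


def _sam_cigar(seg: AlignmentSegment, read_length: int) -> str:
    """CIGAR with soft clips, in SAM (genome) orientation."""
    lead = seg.query_start
    tail = read_length - seg.query_end
    core = seg.cigar or f"{seg.query_span}M"
    if seg.strand == "-":
        lead, tail = tail, lead
        ops = _CIGAR_RE.findall(core)
        core = "".join(f"{n}{op}" for n, op in reversed(ops))
    return (f"{lead}S" if lead else "") + core + (f"{tail}S" if tail else "")


# ---------------------------------------------------------------------------
# SV VCF
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed SV length">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">',
    '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting read count">',
    '##INFO=<ID=DEPTH,Number=1,Type=Integer,Description="Total read depth at the locus">',
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
    '##INFO=<ID=CELL,Number=1,Type=String,Description="Cell of origin">',
    '##INFO=<ID=SUPP_CELLS,Number=.,Type=String,Description="Cells supporting the merged call">',
    '##FILTER=<ID=IMPRECISE,Description="Imprecise structural variation">',
    '##FILTER=<ID=SHADOWED,Description="CNV overlaps with or is encapsulated by deletion">',
]


def write_sv_vcf(
    calls: Sequence[SVCall],
    path: str | Path,
    reference_lengths: dict[str, int] | None = None,
) -> None:
    """Write SV calls as a VCF 4.2 subset (TRA as paired BND records)."""
    contigs: dict[str, int] = dict(reference_lengths or {})
    for c in sorted(calls, key=SVCall.sort_key):
        contigs.setdefault(c.locus.chrom, 0)
        if c.mate is not None:
            contigs.setdefault(c.mate.chrom, 0)
    header = pysam.VariantHeader()
    for line in _VCF_HEADER_LINES:
        header.add_line(line)
    for chrom, length in contigs.items():
        header.add_line(
            f"##contig=<ID={chrom}" + (f",length={length}" if length else "") + ">"
        )
    ordered = sorted(calls, key=SVCall.sort_key)
    with pysam.VariantFile(str(path), "w", header=header) as fh:
        for i, call in enumerate(ordered):
            if call.svtype == "TRA":
                _write_bnd_pair(fh, call, i)
            else:
                rec = fh.new_record(
                    contig=call.locus.chrom,
                    start=call.locus.start,  # pysam start is 0-based
                    stop=call.locus.end,
                    alleles=("N", f"<{call.svtype}>"),
                    id=f"sv{i}",
                )
                rec.info["SVTYPE"] = call.svtype
                rec.info["SVLEN"] = call.svlen
                _set_common_info(rec, call)
                # reassign last: INFO writes re-sync END from rlen, which is
                # one past the 1-based inclusive end we want
                rec.stop = call.locus.end
                fh.write(rec)


def _set_common_info(rec, call: SVCall) -> None:
    if call.read_support:
        rec.info["SUPPORT"] = call.read_support
    if call.total_depth:
        rec.info["DEPTH"] = call.total_depth
    if call.cell_id:
        rec.info["CELL"] = call.cell_id
    if call.supporting_cells:
        rec.info["SUPP_CELLS"] = tuple(sorted(call.supporting_cells))
    for f in sorted(call.filters):
        rec.filter.add(f)


def _write_bnd_pair(fh, call: SVCall, i: int) -> None:
    assert call.mate is not None
    ids = (f"sv{i}_bnd1", f"sv{i}_bnd2")
    ends = (call.locus, call.mate)
    for k, (bid, bp) in enumerate(zip(ids, ends)):
        other = ends[1 - k]
        alt = f"N[{other.chrom}:{other.start + 1}["
        rec = fh.new_record(
            contig=bp.chrom,
            start=bp.start,
            alleles=("N", alt),
            id=bid,
        )
        rec.info["SVTYPE"] = "BND"
        rec.info["MATEID"] = ids[1 - k]
        _set_common_info(rec, call)
        rec.stop = bp.start + 1
        fh.write(rec)


_BND_ALT_RE = re.compile(r"[\[\]]([^\[\]:]+):(\d+)[\[\]]")


def read_sv_vcf(path: str | Path) -> list[SVCall]:
    """Read the SV VCF subset back into SVCalls, reuniting BND pairs.

    A BND record without its mate is dropped with a warning; a record
    missing SVTYPE raises :class:`RecordError`.
    """
    calls: list[SVCall] = []
    bnds: dict[str, pysam.VariantRecord] = {}
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                raise RecordError(f"{rec.chrom}:{rec.pos}: missing SVTYPE")
            if svtype == "BND":
                bnds[rec.id] = rec
            else:
                calls.append(_call_from_record(rec, svtype))
    seen: set[str] = set()
    for rid, rec in bnds.items():
        if rid in seen:
            continue
        mate_id = rec.info.get("MATEID")
        mate = bnds.get(mate_id)
        if mate is None:
            logger.warning("BND %s has no mate; dropped", rid)
            continue
        seen.update((rid, mate_id))
        calls.append(_tra_from_pair(rec, mate))
    calls.sort(key=SVCall.sort_key)
    return calls


def _filters_of(rec) -> frozenset[str]:
    keys = set(rec.filter.keys())
    return frozenset(keys) if keys else frozenset({"PASS"})


def _support_of(rec) -> tuple[int, int]:
    sup = rec.info.get("SUPPORT")
    dep = rec.info.get("DEPTH", 0)
    if sup is None:
        # fall back to FORMAT AD of the first sample when present
        for sample in rec.samples.values():
            ad = sample.get("AD")
            if ad:
                sup = ad[-1]
                dep = sum(a for a in ad if a is not None)
                break
    return int(sup or 0), int(dep or 0)


def _cells_of(rec) -> frozenset[str]:
    cells = rec.info.get("SUPP_CELLS", ())
    if isinstance(cells, str):
        cells = (cells,)
    return frozenset(cells)


def _call_from_record(rec, svtype: str) -> SVCall:
    start = rec.start  # 0-based
    end = rec.stop
    svlen = rec.info.get("SVLEN")
    if svlen is None:
        svlen = -(end - start) if svtype == "DEL" else (end - start)
    elif svtype in ("DEL", "DUP") and svlen != 0:
        # htslib re-derives END from SVLEN with a pad base; the span
        # itself is |SVLEN|, so recompute the half-open end from it
        end = start + abs(int(svlen))
    if svtype == "INS":
        end = start + 1
    sup, dep = _support_of(rec)
    return SVCall(
        svtype=svtype,
        locus=GenomeInterval(rec.chrom, start, max(end, start + 1)),
        svlen=int(svlen),
        read_support=sup,
        total_depth=dep,
        filters=_filters_of(rec),
        cell_id=rec.info.get("CELL"),
        supporting_cells=_cells_of(rec),
    )


def _tra_from_pair(rec, mate) -> SVCall:
    pair = sorted(
        (rec, mate), key=lambda r: (r.chrom, r.start, r.id)
    )
    a, b = pair
    sup, dep = _support_of(a)
    return SVCall(
        svtype="TRA",
        locus=GenomeInterval(a.chrom, a.start, a.start + 1),
        mate=GenomeInterval(b.chrom, b.start, b.start + 1),
        svlen=0,
        read_support=sup,
        total_depth=dep,
        filters=_filters_of(a),
        cell_id=a.info.get("CELL"),
        supporting_cells=_cells_of(a),
    )


# ---------------------------------------------------------------------------
# BED / TSV
# ---------------------------------------------------------------------------


def read_bed(
    path: str | Path, with_annotation: bool = False
) -> list[GenomeInterval] | list[tuple[GenomeInterval, tuple[str, ...]]]:
    """Read a >=3-column BED (0-based half-open) in file order.

    With ``with_annotation=True`` each interval is paired with the tuple of
    extra columns (opaque strings).  ``start >= end`` raises RecordError.
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise RecordError(f"{path}:{ln}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise RecordError(f"{path}:{ln}: start >= end")
            iv = GenomeInterval(chrom, start, end)
            out.append((iv, tuple(fields[3:])) if with_annotation else iv)
    return out


def write_bed(
    intervals: Iterable[GenomeInterval | tuple],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        for item in intervals:
            if isinstance(item, GenomeInterval):
                iv, extra = item, ()
            else:
                iv, extra = item[0], tuple(str(x) for x in item[1:])
            fh.write("\t".join([iv.chrom, str(iv.start), str(iv.end), *extra]))
            fh.write("\n")


def write_metrics_tsv(
    rows: Sequence[tuple[str, MetricsReport]], path: str | Path
) -> None:
    """Write one MetricsReport per labelled row as TSV with a header."""
    cols = ["label", "TP", "FP", "FN", "precision", "recall", "f1", "fpr", "fnr", "hm"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for label, rep in rows:
            d = rep.as_dict()
            fh.write(
                "\t".join([label] + [_fmt(d[c]) for c in cols[1:]]) + "\n"
            )


def _fmt(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return "NA"
    if float(x).is_integer():
        return str(int(x))
    return f"{x:.6g}"
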