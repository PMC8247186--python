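"""Synthetic single-cell long-read genome data generator.

Emulates the data-generating process of one-adaptor Tn5 tagmentation
sequencing of single cells: each cell's (diploid) genome is cut by a
low-density homogeneous Poisson process (rate 1/mean fragment length,
~6 kb fragments), *every* fragment is recoverable (one-adaptor chemistry,
no 50% loss), and fragments are subsampled to a target per-cell depth well
below 1x.  Planted deletions, insertions, duplications, inversions and
translocations reshape the per-cell donor genome, so reads spanning them
carry the corresponding CIGAR gaps or split alignments.  Planted
extrachromosomal circles are tagmented independently per copy: a circle
receiving exactly one transposition event yields a single full-length read
whose alignment is two same-strand segments in chiastic order and whose
length equals the circle length — distinct copies therefore give different
reads of exactly the same length, the signature that separates circles
from tandem repeats.

Alignments are produced analytically from the donor-genome geometry (read
mapping is upstream of this toolkit), and read base sequences are only
materialized on request: every downstream stage consumes coordinates and
CIGARs.

All randomness flows from ``SimConfig.seed`` through spawned numpy
generators; identical configs give identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from sclongread.io_model import (
    AlignmentSegment,
    GenomeInterval,
    ReadAlignment,
    SNVCall,
    SVCall,
    write_bed,
    write_sam,
    write_sv_vcf,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedSV:
    """A structural variant planted into a subset of cells.

    ``start``/``end`` are reference coordinates (0-based half-open).  For
    INS, ``end == start`` marks the insertion point and ``length`` the
    inserted bases; for TRA, (chrom,start) and (chrom2,start2) are the two
    fusion breakpoints of a reciprocal translocation.  ``cell_fraction``
    is the probability a given cell carries the variant (subclonality);
    carried variants sit on both haplotypes unless ``homozygous=False``.
    """

    svtype: str
    chrom: str
    start: int
    end: int
    length: int = 0
    cell_fraction: float = 1.0
    homozygous: bool = True
    chrom2: str | None = None
    start2: int | None = None

    def as_call(self) -> SVCall:
        if self.svtype == "TRA":
            return SVCall(
                "TRA",
                GenomeInterval(self.chrom, self.start, self.start + 1),
                mate=GenomeInterval(self.chrom2, self.start2, self.start2 + 1),
            )
        svlen = {
            "DEL": -(self.end - self.start),
            "INS": self.length,
            "DUP": self.end - self.start,
            "INV": 0,
        }[self.svtype]
        locus = GenomeInterval(self.chrom, self.start, max(self.end, self.start + 1))
        if self.svtype == "INV":
            return SVCall("INV", locus, svlen=0)
        return SVCall(self.svtype, locus, svlen=svlen)


@dataclass(frozen=True)
class PlantedCircle:
    """An extrachromosomal circle excised from the reference.

    ``copies_per_cell`` independent copies are tagmented in each carrying
    cell.  ``label`` distinguishes genuine circles from confounders
    planted deliberately (e.g. junctions placed inside repeat tracts).
    """

    interval: GenomeInterval
    copies_per_cell: int = 2
    cell_fraction: float = 1.0
    label: str = "circle"


@dataclass(frozen=True)
class CNVStep:
    """Absolute copy number over an interval (elsewhere = ploidy)."""

    interval: GenomeInterval
    copy_number: float


@dataclass
class SimConfig:
    """Study-design knobs for the generator.

    Defaults mirror the real assay: ~6 kb modal fragments from low-density
    Tn5, ~0.4x mean per-cell depth, >=1 kb reads, ~Q30 (0.1% substitution)
    consensus accuracy.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 5_000_000
    n_cells: int = 10
    ploidy: int = 2
    mean_fragment_bp: int = 6_000
    per_cell_coverage: float = 0.4
    min_read_bp: int = 1_000
    ccs_error_rate: float = 0.001
    svs: list[PlantedSV] = field(default_factory=list)
    circles: list[PlantedCircle] = field(default_factory=list)
    cnv_steps: list[CNVStep] = field(default_factory=list)
    per_cell_fp_calls: float = 0.0
    imprecise_fraction: float = 0.0
    repeat_density_per_mb: float = 0.0
    repeat_tracts: list[GenomeInterval] = field(default_factory=list)
    n_true_snvs: int = 0
    snv_fp_per_base: float = 0.0
    include_mito: bool = False
    mito_length: int = 16_569
    mito_chrom: str = "chrM"
    mito_copies_per_cell: int = 20

    def __post_init__(self) -> None:
        if self.mean_fragment_bp <= 0:
            raise ConfigError("mean_fragment_bp must be > 0")
        if self.per_cell_coverage < 0 or self.ccs_error_rate < 0:
            raise ConfigError("rates must be >= 0")
        if self.chrom_length_bp < 10 * self.mean_fragment_bp:
            raise ConfigError(
                "chromosome length must be >= 10x mean fragment length"
            )
        for sv in self.svs:
            if not (0 < sv.cell_fraction <= 1):
                raise ConfigError("cell_fraction must be in (0, 1]")
        for c in self.circles:
            if not (0 < c.cell_fraction <= 1):
                raise ConfigError("cell_fraction must be in (0, 1]")

    def chrom_names(self) -> list[str]:
        names = [f"chr{i + 1}" for i in range(self.n_chroms)]
        if self.include_mito:
            names.append(self.mito_chrom)
        return names

    def chrom_lengths(self) -> dict[str, int]:
        out = {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chroms)}
        if self.include_mito:
            out[self.mito_chrom] = self.mito_length
        return out


@dataclass
class Reference:
    """Synthetic reference: i.i.d. uniform ACGT with inserted repeat tracts."""

    sequences: dict[str, np.ndarray]  # uint8 arrays of ACGT bytes
    arms: list[tuple[GenomeInterval, str]]  # (interval, arm name ending p/q)
    repeats: list[GenomeInterval]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def base(self, chrom: str, pos0: int) -> str:
        return chr(self.sequences[chrom][pos0])

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                s = seq.tobytes().decode()
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")


@dataclass
class ReadOrigin:
    """Provenance of one emitted read."""

    read_id: str
    cell_id: str
    molecule: str  # "genome" or the label of a planted circle ("circle:<i>")
    spans: list[tuple[str, int, int, str]]  # (chrom, start, end, strand)
    chiastic: bool = False


@dataclass
class TruthSet:
    """Machine-readable ground truth for scoring recovery."""

    true_svs: list[SVCall]
    true_circles: list[PlantedCircle]
    circle_chiastic_cells: list[set[str]]  # per circle: cells with a wrap read
    circle_chiastic_reads: list[int]
    sv_cells: list[set[str]]  # per planted SV: carrier cells
    sv_support: dict[tuple[str, int], int]  # (cell, sv index) -> junction reads
    origins: dict[str, ReadOrigin]
    covered_bases: dict[str, int]  # per cell: breadth of coverage
    true_snvs: list[SNVCall]
    cnv_steps: list[CNVStep]

    def copy_number_at(self, config: SimConfig, chrom: str, pos: int) -> float:
        for step in self.cnv_steps:
            iv = step.interval
            if iv.chrom == chrom and iv.start <= pos < iv.end:
                return step.copy_number
        return float(config.ploidy)


@dataclass
class SimResult:
    config: SimConfig
    reference: Reference
    cells: dict[str, list[ReadAlignment]]
    truth: TruthSet
    sv_callsets: dict[str, list[SVCall]]
    snv_callsets: dict[str, list[SNVCall]]
    bulk_snvs: list[SNVCall]


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------


def build_reference(config: SimConfig, rng: np.random.Generator | None = None) -> Reference:
    """Generate the synthetic reference, chromosome arms and repeat track.

    Chromosome arms put the centromere at 45% of each chromosome; the
    repeat track plants tandem tracts (unit 10-100 bp tiled to 1.2-3 kb,
    all > 1 kb) at ``repeat_density_per_mb``, overwriting the background
    sequence so the annotation matches the bases.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    seqs: dict[str, np.ndarray] = {}
    arms: list[tuple[GenomeInterval, str]] = []
    repeats: list[GenomeInterval] = []
    for chrom, length in config.chrom_lengths().items():
        seq = BASES[rng.integers(0, 4, size=length)]
        if chrom != config.mito_chrom:
            cen = int(0.45 * length)
            arms.append((GenomeInterval(chrom, 0, cen), f"{chrom}p"))
            arms.append((GenomeInterval(chrom, cen, length), f"{chrom}q"))
            n_rep = rng.poisson(config.repeat_density_per_mb * length / 1e6)
            planted = [
                (int(rng.integers(0, length - 3_001)), int(rng.integers(1_200, 3_001)))
                for _ in range(n_rep)
            ] + [
                (iv.start, len(iv))
                for iv in config.repeat_tracts
                if iv.chrom == chrom
            ]
            for start, total in planted:
                unit = int(rng.integers(10, 101))
                tile = np.tile(seq[start : start + unit], total // unit + 1)[:total]
                seq[start : start + total] = tile
                repeats.append(GenomeInterval(chrom, start, start + total))
        seqs[chrom] = seq
    repeats.sort()
    return Reference(sequences=seqs, arms=arms, repeats=repeats)


# ---------------------------------------------------------------------------
# Tn5 fragmentation
# ---------------------------------------------------------------------------


def fragment_tn5(
    molecule_length: int, rate: float, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Cut a linear molecule by a homogeneous Poisson process.

    Returns the fragments between consecutive cuts, tiling [0, length)
    exactly — one-adaptor chemistry keeps *all* fragments.  ``rate`` is
    cuts per bp (0 is legal and returns the whole molecule).
    """
    if rate < 0:
        raise ConfigError("rate must be >= 0")
    n_cuts = rng.poisson(rate * molecule_length)
    if n_cuts == 0:
        return [(0, molecule_length)]
    cuts = np.sort(rng.integers(1, molecule_length, size=n_cuts))
    cuts = np.unique(cuts)
    bounds = np.concatenate(([0], cuts, [molecule_length]))
    return [
        (int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:]) if b > a
    ]


# ---------------------------------------------------------------------------
# donor genome construction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Piece:
    """One building block of a donor chromosome.

    Reference pieces map to [start, end) of ``chrom`` (strand - means the
    donor carries the reverse complement).  Novel pieces (chrom None)
    carry inserted sequence of the given length.
    """

    chrom: str | None
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


def _build_donor(
    config: SimConfig, svs: list[tuple[int, PlantedSV]]
) -> tuple[dict[str, list[_Piece]], dict[tuple[str, int], int]]:
    """Apply planted SVs to the reference, returning donor piece lists.

    Returns (donor chromosomes, junction map).  The junction map gives,
    for each (donor chrom, piece boundary index), the planted-SV index
    whose junction that boundary is — used to count junction-spanning
    reads as SV support.
    """
    chroms = {
        c: [_Piece(c, 0, l)] for c, l in config.chrom_lengths().items()
    }
    junctions: dict[tuple[str, int], int] = {}
    # TRA first: reciprocal exchange of chromosome tails.
    for idx, sv in svs:
        if sv.svtype != "TRA":
            continue
        a, b = sv.chrom, sv.chrom2
        pa, pb = sv.start, sv.start2
        la = config.chrom_lengths()[a]
        lb = config.chrom_lengths()[b]
        chroms[a] = [_Piece(a, 0, pa), _Piece(b, pb, lb)]
        chroms[b] = [_Piece(b, 0, pb), _Piece(a, pa, la)]
        junctions[(a, 1)] = idx
        junctions[(b, 1)] = idx

    def _locate(pieces: list[_Piece], chrom: str, pos: int) -> tuple[int, int]:
        for i, p in enumerate(pieces):
            if p.chrom == chrom and p.strand == "+" and p.start <= pos < p.end:
                return i, pos - p.start
        raise ConfigError(f"planted SV position {chrom}:{pos} not in donor")

    for idx, sv in svs:
        if sv.svtype == "TRA":
            continue
        # intra-chromosomal variants are applied inside one + piece
        target = None
        for dchrom, pieces in chroms.items():
            try:
                i, off = _locate(pieces, sv.chrom, sv.start)
                target = (dchrom, i, off)
                break
            except ConfigError:
                continue
        if target is None:
            raise ConfigError(f"cannot place {sv.svtype} at {sv.chrom}:{sv.start}")
        dchrom, i, off = target
        pieces = chroms[dchrom]
        p = pieces[i]
        if sv.svtype != "INS" and sv.end > p.end:
            raise ConfigError("planted SV crosses a donor piece boundary")
        left = _Piece(p.chrom, p.start, sv.start) if sv.start > p.start else None
        if sv.svtype == "DEL":
            mid: list[_Piece] = []
            right = _Piece(p.chrom, sv.end, p.end)
        elif sv.svtype == "INS":
            mid = [_Piece(None, 0, sv.length)]
            right = _Piece(p.chrom, sv.start, p.end)
        elif sv.svtype == "DUP":
            mid = [_Piece(p.chrom, sv.start, sv.end), _Piece(p.chrom, sv.start, sv.end)]
            right = _Piece(p.chrom, sv.end, p.end)
        elif sv.svtype == "INV":
            mid = [_Piece(p.chrom, sv.start, sv.end, "-")]
            right = _Piece(p.chrom, sv.end, p.end)
        else:  # pragma: no cover
            raise ConfigError(sv.svtype)
        new = ([left] if left else []) + mid + ([right] if right.length > 0 else [])
        # re-index junction map entries after the splice point
        shift = len(new) - 1
        junctions = {
            (c, (j + shift if c == dchrom and j > i else j)): v
            for (c, j), v in junctions.items()
        }
        # only non-seamless adjacencies are real junctions a read can show
        for b in range(1, len(new)):
            prev, nxt = new[b - 1], new[b]
            seamless = (
                prev.chrom is not None
                and prev.chrom == nxt.chrom
                and prev.strand == nxt.strand == "+"
                and prev.end == nxt.start
            )
            if not seamless:
                junctions[(dchrom, i + b)] = idx
        chroms[dchrom] = pieces[:i] + new + pieces[i + 1 :]
    return chroms, junctions


def _map_fragment(
    pieces: list[_Piece],
    cum: np.ndarray,
    a: int,
    b: int,
) -> list[tuple[str | None, int, int, str]]:
    """Map donor interval [a, b) to reference spans in read order."""
    spans = []
    i = int(np.searchsorted(cum, a, side="right") - 1)
    pos = a
    while pos < b:
        p = pieces[i]
        p_lo = int(cum[i])
        take_lo = pos - p_lo
        take_hi = min(b - p_lo, p.length)
        if p.chrom is None:
            spans.append((None, 0, take_hi - take_lo, "+"))
        elif p.strand == "+":
            spans.append((p.chrom, p.start + take_lo, p.start + take_hi, "+"))
        else:  # reverse piece: donor offset runs from end to start
            spans.append((p.chrom, p.end - take_hi, p.end - take_lo, "-"))
        pos = p_lo + take_hi
        i += 1
    return spans


def _spans_to_segments(
    read_id: str,
    spans: list[tuple[str | None, int, int, str]],
    max_cigar_gap: int = 100_000,
) -> tuple[list[AlignmentSegment], bool]:
    """Convert reference spans into alignment segments.

    Adjacent same-chrom same-strand spans separated by a small forward
    reference gap become one segment with a D op; a novel span flanked by
    mergeable refs becomes an I op; everything else starts a new split
    segment (DUP/circle junctions, inversions, translocations).  Returns
    the segments and whether the read is chiastic-split (same chrom/strand
    pair in reversed genomic order).
    """
    segments: list[AlignmentSegment] = []
    qpos = 0
    # group spans into segments
    groups: list[list[tuple]] = []
    for span in spans:
        merged = False
        if groups:
            g = groups[-1]
            last = g[-1]
            if span[0] is None and last[0] is not None:
                g.append(span)
                merged = True
            elif span[0] is not None and last[0] is None and len(g) >= 2:
                anchor = g[-2]
                if (
                    anchor[0] == span[0]
                    and anchor[3] == span[3] == "+"
                    and span[1] == anchor[2]
                ):
                    g.append(span)
                    merged = True
            elif (
                span[0] is not None
                and last[0] == span[0]
                and last[3] == span[3] == "+"
                and 0 <= span[1] - last[2] <= max_cigar_gap
            ):
                g.append(span)
                merged = True
        if not merged:
            # an unmerged trailing novel span stays soft-clipped
            groups.append([span])
    for g in groups:
        # trim unanchored novel spans at group edges (soft-clip territory)
        while g and g[0][0] is None:
            qpos += g[0][2] - g[0][1]
            g = g[1:]
        tail_clip = 0
        while g and g[-1][0] is None:
            tail_clip += g[-1][2] - g[-1][1]
            g = g[:-1]
        if not g:
            qpos += tail_clip
            continue
        strand = g[0][3]
        if strand == "-" and len(g) > 1:  # pragma: no cover - single spans only
            raise AssertionError("reverse groups are single spans")
        cig = []
        ref_lo = g[0][1]
        ref_hi = g[0][2]
        prev_end = g[0][2]
        qlen = g[0][2] - g[0][1]
        for span in g[1:]:
            if span[0] is None:
                cig.append(("I", span[2] - span[1]))
                qlen += span[2] - span[1]
            else:
                gap = span[1] - prev_end
                if gap > 0:
                    cig.append(("D", gap))
                cig.append(("M", span[2] - span[1]))
                qlen += span[2] - span[1]
                prev_end = span[2]
                ref_hi = span[2]
        # build CIGAR string: leading M then recorded ops, merging M runs
        ops: list[tuple[str, int]] = [("M", g[0][2] - g[0][1])]
        for op, n in cig:
            if op == "M" and ops[-1][0] == "M":
                ops[-1] = ("M", ops[-1][1] + n)
            else:
                ops.append((op, n))
        cigar = "".join(f"{n}{op}" for op, n in ops)
        segments.append(
            AlignmentSegment(
                read_id=read_id,
                query_start=qpos,
                query_end=qpos + qlen,
                target=GenomeInterval(g[0][0], ref_lo, ref_hi),
                strand=strand,
                cigar=cigar,
            )
        )
        qpos += qlen + tail_clip
    chiastic = False
    for s1, s2 in zip(segments, segments[1:]):
        if s1.target.chrom != s2.target.chrom or s1.strand != s2.strand:
            continue
        first, second = (s1, s2) if s1.strand == "+" else (s2, s1)
        # read-later segment maps genomically upstream of read-earlier end
        if second.target.start < first.target.end:
            chiastic = True
    return segments, chiastic


# ---------------------------------------------------------------------------
# per-cell simulation
# ---------------------------------------------------------------------------


def simulate_cell(
    reference: Reference,
    config: SimConfig,
    cell_id: str,
    rng: np.random.Generator,
    carried_svs: list[tuple[int, PlantedSV]],
    carried_circles: list[tuple[int, PlantedCircle]],
    truth: TruthSet,
) -> list[ReadAlignment]:
    """Emit one cell's reads (genomic + circle) and update the truth set.

    Each haplotype is tagmented independently at rate 1/mean_fragment_bp;
    a fragment starting where the planted copy number is c is kept with
    probability coverage*c/(2*ploidy), so realized depth tracks the
    planted profile.  Each circle copy is cut independently; every arc
    >= min_read_bp becomes a read, and the arc crossing the circle origin
    maps as a chiastic two-segment read.
    """
    rate = 1.0 / config.mean_fragment_bp
    reads: list[ReadAlignment] = []
    n = 0
    covered: dict[str, list[tuple[int, int]]] = {}

    def _emit(
        spans: list[tuple], molecule: str, forced_chiastic: bool | None = None
    ) -> ReadAlignment:
        nonlocal n
        rid = f"{cell_id}_r{n:06d}"
        n += 1
        read_len = sum(e - s for _, s, e, _ in spans)
        segments, chi = _spans_to_segments(rid, [(c, s, e, st) for c, s, e, st in spans])
        if forced_chiastic is not None:
            chi = forced_chiastic
        ra = ReadAlignment(rid, cell_id, segments, read_len)
        truth.origins[rid] = ReadOrigin(rid, cell_id, molecule, list(spans), chi)
        for c, s, e, _ in spans:
            if c is not None:
                covered.setdefault(c, []).append((s, e))
        reads.append(ra)
        return ra

    for hap in range(2):
        hap_svs = [
            (i, sv) for i, sv in carried_svs if sv.homozygous or hap == 0
        ]
        donor, junctions = _build_donor(config, hap_svs)
        for dchrom, pieces in donor.items():
            if dchrom == config.mito_chrom:
                continue  # handled as a circle below
            cum = np.concatenate(([0], np.cumsum([p.length for p in pieces])))
            total = int(cum[-1])
            frags = fragment_tn5(total, rate, rng)
            if not frags:
                continue
            keep_u = rng.random(len(frags))
            for (a, b), u in zip(frags, keep_u):
                if b - a < config.min_read_bp:
                    continue
                # copy-number factor at the fragment's (reference) start
                i0 = int(np.searchsorted(cum, a, side="right") - 1)
                p0 = pieces[i0]
                if p0.chrom is None:
                    ref_c, ref_p = pieces[max(i0 - 1, 0)].chrom, pieces[max(i0 - 1, 0)].start
                elif p0.strand == "+":
                    ref_c, ref_p = p0.chrom, p0.start + (a - int(cum[i0]))
                else:
                    ref_c, ref_p = p0.chrom, p0.end - (a - int(cum[i0])) - 1
                cn = truth.copy_number_at(config, ref_c, ref_p)
                p_keep = config.per_cell_coverage * cn / (2 * config.ploidy)
                if u >= p_keep:
                    continue
                spans = _map_fragment(pieces, cum, a, b)
                _emit(spans, "genome")
                # junction support: fragment spans piece boundary k when
                # cum[k] in (a, b)
                for (c2, k), sv_idx in junctions.items():
                    if c2 != dchrom:
                        continue
                    if 0 < k < len(pieces) and a < int(cum[k]) < b:
                        key = (cell_id, sv_idx)
                        truth.sv_support[key] = truth.sv_support.get(key, 0) + 1

    # circles (planted + optionally the mitochondrial genome)
    circle_list = list(carried_circles)
    if config.include_mito:
        mito = PlantedCircle(
            GenomeInterval(config.mito_chrom, 0, config.mito_length),
            copies_per_cell=config.mito_copies_per_cell,
            label="mito",
        )
        circle_list = circle_list + [(-1, mito)]
    for ci, circ in circle_list:
        iv = circ.interval
        L = len(iv)
        for _copy in range(circ.copies_per_cell):
            n_cuts = rng.poisson(rate * L)
            if n_cuts == 0:
                continue  # never linearized, never amplified
            offs = np.unique(rng.integers(0, L, size=n_cuts))
            for j, o in enumerate(offs):
                o = int(o)
                if j + 1 < len(offs):
                    arc = (o, int(offs[j + 1]))
                    if arc[1] - arc[0] < config.min_read_bp:
                        continue
                    _emit(
                        [(iv.chrom, iv.start + arc[0], iv.start + arc[1], "+")],
                        f"circle:{ci}",
                    )
                else:
                    # wrapping arc: from last cut through the origin to first
                    wrap_len = (L - o) + int(offs[0])
                    if wrap_len < config.min_read_bp:
                        continue
                    spans = [(iv.chrom, iv.start + o, iv.end, "+")]
                    if offs[0] > 0:
                        spans.append((iv.chrom, iv.start, iv.start + int(offs[0]), "+"))
                    chi = len(spans) == 2
                    _emit(spans, f"circle:{ci}", forced_chiastic=chi)
                    if chi and ci >= 0:
                        truth.circle_chiastic_cells[ci].add(cell_id)
                        truth.circle_chiastic_reads[ci] += 1

    # realized breadth of coverage
    total_cov = 0
    for c, ivs in covered.items():
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total_cov += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total_cov += cur_e - cur_s
    truth.covered_bases[cell_id] = total_cov
    return reads


# ---------------------------------------------------------------------------
# call-set emission
# ---------------------------------------------------------------------------


def emit_cell_callsets(
    truth: TruthSet,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, list[SVCall]], dict[str, list[SNVCall]], list[SNVCall]]:
    """Produce per-cell SV and SNV call sets with controlled noise.

    Each cell's SV calls are the planted variants it carries that are
    covered by >=1 junction-spanning read (support = that count), plus
    Poisson(per_cell_fp_calls) spurious calls at uniform loci, private to
    the cell with support drawn from {1, 2}.  A configurable fraction of
    calls is flagged IMPRECISE.  Bulk SNVs are the planted truth; per-cell
    SNV calls add private false positives at ``snv_fp_per_base`` over the
    cell's covered bases.
    """
    cells = sorted(truth.covered_bases)
    lengths = config.chrom_lengths()
    chroms = [c for c in lengths if c != config.mito_chrom]
    sv_sets: dict[str, list[SVCall]] = {c: [] for c in cells}
    for cell in cells:
        for idx, call in enumerate(truth.true_svs):
            if cell not in truth.sv_cells[idx]:
                continue
            support = truth.sv_support.get((cell, idx), 0)
            if support < 1:
                continue
            flt = frozenset({"PASS"})
            if config.imprecise_fraction and rng.random() < config.imprecise_fraction:
                flt = frozenset({"IMPRECISE"})
            sv_sets[cell].append(
                dataclasses.replace(
                    call,
                    read_support=support,
                    total_depth=max(support, 1),
                    filters=flt,
                    cell_id=cell,
                    supporting_cells=frozenset(),
                )
            )
        n_fp = rng.poisson(config.per_cell_fp_calls)
        for _ in range(n_fp):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            L = lengths[chrom]
            svtype = ("DEL", "INS", "DUP", "INV")[int(rng.integers(0, 4))]
            length = int(rng.integers(100, 5_000))
            start = int(rng.integers(0, L - length - 1))
            support = int(rng.integers(1, 3))
            flt = frozenset({"PASS"})
            if config.imprecise_fraction and rng.random() < config.imprecise_fraction:
                flt = frozenset({"IMPRECISE"})
            if svtype == "INS":
                locus = GenomeInterval(chrom, start, start + 1)
                svlen = length
            else:
                locus = GenomeInterval(chrom, start, start + length)
                svlen = -length if svtype == "DEL" else (length if svtype == "DUP" else 0)
            sv_sets[cell].append(
                SVCall(
                    svtype,
                    locus,
                    svlen=svlen,
                    read_support=support,
                    total_depth=max(support, 1),
                    filters=flt,
                    cell_id=cell,
                )
            )

    bulk_snvs = list(truth.true_snvs)
    snv_sets: dict[str, list[SNVCall]] = {c: [] for c in cells}
    if truth.true_snvs or config.snv_fp_per_base > 0:
        genome_bp = sum(lengths[c] for c in chroms)
        for cell in cells:
            breadth = truth.covered_bases.get(cell, 0) / max(genome_bp, 1)
            calls = [
                dataclasses.replace(s, cell_id=cell)
                for s in truth.true_snvs
                if rng.random() < breadth
            ]
            n_fp = rng.poisson(config.snv_fp_per_base * truth.covered_bases.get(cell, 0))
            taken = {s.key for s in calls}
            for _ in range(n_fp):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                pos = int(rng.integers(1, lengths[chrom]))
                ref = "ACGT"[int(rng.integers(0, 4))]
                alt = rng.choice([b for b in "ACGT" if b != ref])
                snv = SNVCall(chrom, pos, ref, str(alt), cell_id=cell)
                if snv.key in taken:
                    continue
                taken.add(snv.key)
                calls.append(snv)
            snv_sets[cell] = sorted(calls, key=lambda s: (s.chrom, s.pos, s.alt_base))
    return sv_sets, snv_sets, bulk_snvs


# ---------------------------------------------------------------------------
# whole-dataset driver
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full generator: reference, per-cell reads, truth, call sets."""
    ss = np.random.SeedSequence(config.seed)
    keys = ss.spawn(4 + config.n_cells)
    ref_rng = np.random.default_rng(keys[0])
    assign_rng = np.random.default_rng(keys[1])
    snv_rng = np.random.default_rng(keys[2])
    call_rng = np.random.default_rng(keys[3])
    reference = build_reference(config, ref_rng)

    sv_cells: list[set[str]] = [set() for _ in config.svs]
    circ_cells: list[set[str]] = [set() for _ in config.circles]
    cell_ids = [f"cell{i:03d}" for i in range(config.n_cells)]
    for cell in cell_ids:
        for i, sv in enumerate(config.svs):
            if assign_rng.random() < sv.cell_fraction:
                sv_cells[i].add(cell)
        for i, circ in enumerate(config.circles):
            if assign_rng.random() < circ.cell_fraction:
                circ_cells[i].add(cell)

    true_snvs = []
    lengths = config.chrom_lengths()
    chroms = [c for c in lengths if c != config.mito_chrom]
    seen = set()
    while len(true_snvs) < config.n_true_snvs:
        chrom = chroms[int(snv_rng.integers(0, len(chroms)))]
        pos = int(snv_rng.integers(1, lengths[chrom]))
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        ref = reference.base(chrom, pos - 1)
        alt = str(snv_rng.choice([b for b in "ACGT" if b != ref]))
        true_snvs.append(SNVCall(chrom, pos, ref, alt))
    true_snvs.sort(key=lambda s: (s.chrom, s.pos))

    truth = TruthSet(
        true_svs=[sv.as_call() for sv in config.svs],
        true_circles=list(config.circles),
        circle_chiastic_cells=[set() for _ in config.circles],
        circle_chiastic_reads=[0] * len(config.circles),
        sv_cells=sv_cells,
        sv_support={},
        origins={},
        covered_bases={},
        true_snvs=true_snvs,
        cnv_steps=list(config.cnv_steps),
    )
    truth.true_svs = [
        dataclasses.replace(c, supporting_cells=frozenset(sv_cells[i]))
        for i, c in enumerate(truth.true_svs)
    ]

    cells: dict[str, list[ReadAlignment]] = {}
    for ci, cell in enumerate(cell_ids):
        rng = np.random.default_rng(keys[4 + ci])
        carried = [
            (i, sv) for i, sv in enumerate(config.svs) if cell in sv_cells[i]
        ]
        circ = [
            (i, c) for i, c in enumerate(config.circles) if cell in circ_cells[i]
        ]
        cells[cell] = simulate_cell(
            reference, config, cell, rng, carried, circ, truth
        )

    sv_sets, snv_sets, bulk = emit_cell_callsets(truth, config, call_rng)
    return SimResult(
        config=config,
        reference=reference,
        cells=cells,
        truth=truth,
        sv_callsets=sv_sets,
        snv_callsets=snv_sets,
        bulk_snvs=bulk,
    )


def write_dataset(result: SimResult, outdir: str | Path, fasta: bool = True) -> None:
    """Write the generated dataset as plain-text files.

    Emits reference.fa, arms.bed, trf.bed, per-cell SAM / SV VCF / SNV
    VCF, truth.tsv (read origins) and simconfig.yaml.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = result.reference
    if fasta:
        ref.write_fasta(outdir / "reference.fa")
    write_bed(
        [(iv, name) for iv, name in ref.arms], outdir / "arms.bed"
    )
    write_bed(ref.repeats, outdir / "trf.bed")
    for cell, reads in result.cells.items():
        write_sam(reads, outdir / f"{cell}.sam", ref.lengths)
        write_sv_vcf(result.sv_callsets.get(cell, []), outdir / f"{cell}.sv.vcf", ref.lengths)
        _write_snv_vcf(result.snv_callsets.get(cell, []), outdir / f"{cell}.snv.vcf", ref.lengths)
    _write_snv_vcf(result.bulk_snvs, outdir / "bulk.snv.vcf", ref.lengths)
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("read_id\tcell_id\tmolecule\tchiastic\tspans\n")
        for rid in sorted(result.truth.origins):
            o = result.truth.origins[rid]
            spans = ";".join(
                f"{c}:{s}-{e}:{st}" for c, s, e, st in o.spans if c is not None
            )
            fh.write(f"{rid}\t{o.cell_id}\t{o.molecule}\t{int(o.chiastic)}\t{spans}\n")
    with open(outdir / "simconfig.yaml", "w") as fh:
        yaml.safe_dump(_config_dict(result.config), fh, sort_keys=True)


def _config_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _write_snv_vcf(
    snvs: Sequence[SNVCall], path: str | Path, lengths: dict[str, int]
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, l in lengths.items():
            fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snvs, key=lambda x: (x.chrom, x.pos, x.alt_base)):
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref_base}\t{s.alt_base}\t.\tPASS\t.\n"
            )


def read_snv_vcf(path: str | Path, cell_id: str = "bulk") -> list[SNVCall]:
    """Read a simple SNV VCF (SNV records only; indels skipped)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f[3]) != 1 or len(f[4]) != 1 or f[4] == ".":
                continue
            out.append(SNVCall(f[0], int(f[1]), f[3], f[4], cell_id=cell_id))
    return out
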