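"""Windowed copy-number profiling for sparse single-cell genomes.

At <1x depth per cell, read counts in fixed windows (default 1 Mb) are the
only usable copy-number signal.  The pipeline: count reads per window,
convert to ratios of total reads, scale so the genome-wide mean equals the
sample's known ploidy, smooth with circular binary segmentation (CBS), and
compare cells via the coefficient of variation (CV) against a baseline
profile and via Pearson correlation of segmented values (gap windows
removed).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from sclongread.io_model import CNVProfile, GenomeInterval, ReadAlignment

logger = logging.getLogger(__name__)


def make_windows(
    reference_lengths: dict[str, int], window_size: int = 1_000_000
) -> list[GenomeInterval]:
    """Tile each chromosome with fixed windows; last window truncated."""
    if window_size <= 0:
        raise ValueError("window_size must be > 0")
    windows = []
    for chrom, length in reference_lengths.items():
        for s in range(0, length, window_size):
            windows.append(GenomeInterval(chrom, s, min(s + window_size, length)))
    return windows


def window_counts(
    alignments: Iterable[ReadAlignment],
    reference_lengths: dict[str, int],
    window_size: int = 1_000_000,
    gap_intervals: Sequence[GenomeInterval] = (),
) -> CNVProfile:
    """Count each read once, in the window holding its primary segment's
    leftmost position, and convert to ratios of total counted reads.

    Reads on chromosomes absent from ``reference_lengths`` are skipped
    with a warning.  Windows overlapping any gap interval are masked.
    """
    windows = make_windows(reference_lengths, window_size)
    index: dict[str, int] = {}
    offset = 0
    n_win: dict[str, int] = {}
    for chrom, length in reference_lengths.items():
        index[chrom] = offset
        n_win[chrom] = -(-length // window_size)
        offset += n_win[chrom]
    counts = np.zeros(len(windows))
    empty = True
    for ra in alignments:
        if not ra.segments:
            continue
        seg = ra.primary
        chrom = seg.target.chrom
        if chrom not in index:
            logger.warning("read %s on unknown chromosome %s; skipped", ra.read_id, chrom)
            continue
        w = min(seg.target.start // window_size, n_win[chrom] - 1)
        counts[index[chrom] + w] += 1
        empty = False
    total = counts.sum()
    ratios = counts / total if total > 0 else np.zeros_like(counts)
    if empty:
        logger.warning("empty profile: no reads counted")
    mask = np.zeros(len(windows), dtype=bool)
    for gap in gap_intervals:
        for i, w in enumerate(windows):
            if w.overlaps(gap):
                mask[i] = True
    return CNVProfile(windows=windows, raw_counts=counts, ratios=ratios, gap_mask=mask)


def normalize_to_ploidy(profile: CNVProfile, ploidy: float) -> CNVProfile:
    """Scale ratios by the unique constant making the unmasked mean equal
    the sample ploidy (e.g. 3 for K562, 2 for diploid tumours)."""
    if ploidy < 1:
        raise ValueError("ploidy must be >= 1")
    base = (
        profile.copy_number if profile.copy_number is not None else profile.ratios
    )
    m = base[profile.unmasked].mean() if profile.unmasked.any() else 0.0
    if m <= 0:
        raise ValueError("cannot normalize an all-zero profile")
    return CNVProfile(
        windows=profile.windows,
        raw_counts=profile.raw_counts,
        ratios=profile.ratios,
        copy_number=base * (ploidy / m),
        segments=profile.segments,
        gap_mask=profile.gap_mask,
    )


def compute_cv(profile: CNVProfile, baseline: CNVProfile) -> float:
    """Coefficient of variation of the per-window cell/baseline quotient.

    CV = sd/mean of copy_number(cell)/copy_number(baseline) over windows
    unmasked in both profiles, with the sample standard deviation (n-1).
    The baseline may be a bulk profile or the mean single-cell profile.
    """
    if profile.windows != baseline.windows:
        raise ValueError("profile and baseline must share windows")
    a = profile.copy_number if profile.copy_number is not None else profile.ratios
    b = baseline.copy_number if baseline.copy_number is not None else baseline.ratios
    ok = profile.unmasked & baseline.unmasked & (b > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 unmasked windows with positive baseline")
    q = a[ok] / b[ok]
    return float(np.std(q, ddof=1) / np.mean(q))


# ---------------------------------------------------------------------------
# circular binary segmentation
# ---------------------------------------------------------------------------


def _max_arc_stat(x: np.ndarray) -> tuple[float, int, int]:
    """Max absolute circularized two-sample t statistic over arcs (i, j).

    The arc x[i:j] is compared against the rest of the segment; the sd is
    the segment-wide sd (the permutation test absorbs the approximation).
    """
    n = len(x)
    s = np.concatenate(([0.0], np.cumsum(x)))
    sd = x.std(ddof=1)
    if sd == 0 or n < 2:
        return 0.0, 0, n
    best = (0.0, 0, n)
    total = s[n]
    for k in range(1, n):  # arc length
        i = np.arange(0, n - k + 1)
        sums = s[i + k] - s[i]
        m_in = sums / k
        m_out = (total - sums) / (n - k)
        t = np.abs(m_in - m_out) / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
        j = int(np.argmax(t))
        if t[j] > best[0]:
            best = (float(t[j]), int(i[j]), int(i[j]) + k)
    return best


def _cbs_recurse(
    x: np.ndarray,
    lo: int,
    hi: int,
    seed: int,
    alpha: float,
    n_perm: int,
    out: list[tuple[int, int]],
) -> None:
    n = hi - lo
    if n < 3:
        out.append((lo, hi))
        return
    seg = x[lo:hi]
    stat, i, j = _max_arc_stat(seg)
    if stat == 0.0:
        out.append((lo, hi))
        return
    # the permutation stream depends only on (seed, segment bounds): the
    # same segment gets the same p-value at any alpha, so tightening alpha
    # can only prune splits, never create them
    rng = np.random.default_rng([seed, lo, hi])
    exceed = 0
    for _ in range(n_perm):
        perm_stat, _, _ = _max_arc_stat(rng.permutation(seg))
        if perm_stat >= stat:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    if p >= alpha:
        out.append((lo, hi))
        return
    cuts = sorted({lo, lo + i, lo + j, hi})
    for a, b in zip(cuts[:-1], cuts[1:]):
        if b > a:
            _cbs_recurse(x, a, b, seed, alpha, n_perm, out)


def cbs_segment(
    profile: CNVProfile,
    seed: int = 0,
    alpha: float = 0.01,
    n_perm: int = 1000,
) -> CNVProfile:
    """Segment the normalized profile by circular binary segmentation.

    Recursive binary splitting on the maximal circularized t statistic,
    accepting a split when its permutation p-value is below ``alpha``.
    Chromosomes are segmented independently; masked windows are excluded
    from the statistic and inherit no segment.  Deterministic given seed.
    """
    values = (
        profile.copy_number if profile.copy_number is not None else profile.ratios
    )
    segments: list[tuple[int, int, float]] = []
    # chromosome blocks over window indices
    chrom_bounds: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(profile.windows) + 1):
        if (
            i == len(profile.windows)
            or profile.windows[i].chrom != profile.windows[start].chrom
        ):
            chrom_bounds.append((start, i))
            start = i
    for ci, (lo, hi) in enumerate(chrom_bounds):
        idx = np.arange(lo, hi)[profile.unmasked[lo:hi]]
        if len(idx) == 0:
            continue
        x = values[idx]
        if len(idx) < 3:
            pieces = [(0, len(idx))]
        else:
            pieces = []
            _cbs_recurse(x, 0, len(x), seed + 7919 * ci, alpha, n_perm, pieces)
            pieces.sort()
        for a, b in pieces:
            w_lo, w_hi = int(idx[a]), int(idx[b - 1]) + 1
            segments.append((w_lo, w_hi, float(x[a:b].mean())))
    return CNVProfile(
        windows=profile.windows,
        raw_counts=profile.raw_counts,
        ratios=profile.ratios,
        copy_number=profile.copy_number,
        segments=segments,
        gap_mask=profile.gap_mask,
    )


def profile_correlation(a: CNVProfile, b: CNVProfile) -> float:
    """Pearson r of per-window segmented copy numbers, with gap-masked
    windows removed pairwise.  Raises on zero variance."""
    if a.windows != b.windows:
        raise ValueError("profiles must share windows")
    va = a.segment_values()
    vb = b.segment_values()
    ok = a.unmasked & b.unmasked & ~np.isnan(va) & ~np.isnan(vb)
    if ok.sum() < 2:
        raise ValueError("need >= 2 shared unmasked windows")
    xa, xb = va[ok], vb[ok]
    if np.std(xa) == 0 or np.std(xb) == 0:
        raise ValueError("zero variance in segmented values")
    r, _ = stats.pearsonr(xa, xb)
    return float(r)


def profile_to_tsv(profile: CNVProfile, path: str) -> None:
    """Write the per-window profile (TSV with header)."""
    seg = None
    if profile.segments is not None:
        seg = profile.segment_values()
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcount\tratio\tcopy_number\tsegment_mean\tgap\n")
        for i, w in enumerate(profile.windows):
            cn = "NA" if profile.copy_number is None else f"{profile.copy_number[i]:.6g}"
            sm = "NA" if seg is None or np.isnan(seg[i]) else f"{seg[i]:.6g}"
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{int(profile.raw_counts[i])}\t"
                f"{profile.ratios[i]:.6g}\t{cn}\t{sm}\t{int(profile.gap_mask[i])}\n"
            )
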