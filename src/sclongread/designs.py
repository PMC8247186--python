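"""Reference synthetic study designs.

Each builder returns a :class:`~sclongread.simulate.SimConfig` for one of
the benchmark scenarios the package is validated on.  The conditions are
the assay's: ~6 kb fragments, 0.4x per-cell depth, 30 cells, circles of
5 kb-1 Mb (capped at 200 kb here so multiple circles fit one
chromosome), duplication units of a few kb, and ~2e-5 per-base SNV false
positives.  Genome sizes are scaled to tens of megabases so a design
simulates in seconds while leaving every per-locus rate (junction read
counts, window counts, collision probabilities) at its full-genome
value.
"""

from __future__ import annotations

import numpy as np

from sclongread.io_model import GenomeInterval
from sclongread.simulate import CNVStep, PlantedCircle, PlantedSV, SimConfig

GENOME_60M = 60_000_000

#: window index of the planted copy-number step in :func:`cnv_design`
#: (chr4 q arm, 4 x 30 Mb genome at 1 Mb windows)
CNV_STEP_WINDOW = 3 * 30 + 14


def planted_circles(
    seed: int,
    n: int = 20,
    lo: int = 5_000,
    hi: int = 200_000,
    region: tuple[int, int] = (1_000_000, 25_000_000),
) -> list[PlantedCircle]:
    """n circles of 5-200 kb laid out without overlap on chr1."""
    rng = np.random.default_rng(seed)
    span = (region[1] - region[0]) // n
    out = []
    for i in range(n):
        size = min(int(rng.integers(lo, hi + 1)), span - 1000)
        start = region[0] + i * span + int(rng.integers(0, span - size))
        out.append(
            PlantedCircle(
                GenomeInterval("chr1", start, start + size),
                copies_per_cell=2,
                cell_fraction=0.5,
            )
        )
    return out


def circle_design(seed: int) -> SimConfig:
    """30 cells, 60 Mb, 0.4x, 20 planted circles, no errors, no dups."""
    return SimConfig(
        seed=seed,
        n_chroms=1,
        chrom_length_bp=GENOME_60M,
        n_cells=30,
        per_cell_coverage=0.4,
        ccs_error_rate=0.0,
        circles=planted_circles(seed),
    )


def confounder_design(seed: int) -> SimConfig:
    """The circle design plus the two chiastic confounders: 10
    head-to-tail duplications (2-5 kb units, clonal) and 20 circles whose
    junctions sit inside planted >1 kb tandem-repeat tracts."""
    rng = np.random.default_rng(seed + 1)
    dups = []
    for i in range(10):
        unit = int(rng.integers(2_000, 5_001))
        start = 30_000_000 + i * 1_000_000 + int(rng.integers(0, 500_000))
        dups.append(PlantedSV("DUP", "chr1", start, start + unit))
    tracts, artifacts = [], []
    for i in range(20):
        t0 = 45_000_000 + i * 600_000 + int(rng.integers(0, 100_000))
        tracts.append(GenomeInterval("chr1", t0, t0 + 2_000))
        size = int(rng.integers(8_000, 30_000))
        artifacts.append(
            PlantedCircle(
                GenomeInterval("chr1", t0 + 1_000, t0 + 1_000 + size),
                copies_per_cell=2,
                cell_fraction=0.5,
                label="repeat_artifact",
            )
        )
    return SimConfig(
        seed=seed,
        n_chroms=1,
        chrom_length_bp=GENOME_60M,
        n_cells=30,
        per_cell_coverage=0.4,
        ccs_error_rate=0.0,
        circles=planted_circles(seed) + artifacts,
        svs=dups,
        repeat_tracts=tracts,
    )


def planted_svs_for_consensus(seed: int, n_per_type: int = 10) -> list[PlantedSV]:
    """Clonal DEL/INS/DUP/INV truth spaced along chr1."""
    rng = np.random.default_rng(seed)
    out = []
    pos = 1_000_000
    for svtype in ("DEL", "INS", "DUP", "INV"):
        for _ in range(n_per_type):
            if svtype == "INS":
                out.append(PlantedSV("INS", "chr1", pos, pos,
                                     length=int(rng.integers(300, 1_000))))
            else:
                length = int(rng.integers(500, 5_000))
                out.append(PlantedSV(svtype, "chr1", pos, pos + length))
            pos += 600_000
    return out


def consensus_noise_design(seed: int) -> SimConfig:
    """Clonal SV truth plus 50 private false-positive calls per cell."""
    return SimConfig(
        seed=seed,
        n_chroms=1,
        chrom_length_bp=GENOME_60M,
        n_cells=30,
        per_cell_coverage=0.4,
        ccs_error_rate=0.0,
        svs=planted_svs_for_consensus(seed + 3),
        per_cell_fp_calls=50.0,
    )


def cnv_design(seed: int) -> SimConfig:
    """Ploidy-3 cells with chr4's q arm planted at copy 2.

    The planted arm (16/120 windows) is small against the genome, as a
    real arm is, so normalizing the genome-wide mean to the ploidy leaves
    the arm near its true copy number.
    """
    return SimConfig(
        seed=seed,
        n_chroms=4,
        chrom_length_bp=30_000_000,
        n_cells=4,
        ploidy=3,
        per_cell_coverage=0.4,
        cnv_steps=[CNVStep(GenomeInterval("chr4", 14_000_000, 30_000_000), 2.0)],
    )


def snv_design(seed: int) -> SimConfig:
    """Planted bulk SNV truth with private per-cell false positives at
    2e-5 per covered base."""
    return SimConfig(
        seed=seed,
        n_chroms=1,
        chrom_length_bp=20_000_000,
        n_cells=12,
        per_cell_coverage=0.4,
        n_true_snvs=3_000,
        snv_fp_per_base=2.0e-5,
    )
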