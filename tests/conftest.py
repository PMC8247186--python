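"""Shared synthetic study designs.

The heavier simulations (used both by unit tests and the acceptance
tests) are session-scoped so each design is generated once.  The designs
themselves live in :mod:`sclongread.designs`.
"""

from __future__ import annotations

import pytest

from sclongread.designs import (
    CNV_STEP_WINDOW,
    circle_design,
    cnv_design,
    confounder_design,
    consensus_noise_design,
    planted_circles,
    snv_design,
)
from sclongread.io_model import GenomeInterval
from sclongread.simulate import PlantedCircle, PlantedSV, SimConfig, simulate_dataset

__all__ = ["CNV_STEP_WINDOW", "planted_circles"]


@pytest.fixture(scope="session")
def circle_sim():
    return simulate_dataset(circle_design(seed=11))


@pytest.fixture(scope="session")
def confounder_sim():
    return simulate_dataset(confounder_design(seed=11))


@pytest.fixture(scope="session")
def noise_sim():
    return simulate_dataset(consensus_noise_design(seed=17))


@pytest.fixture(scope="session")
def cnv_sim():
    return simulate_dataset(cnv_design(seed=19))


@pytest.fixture(scope="session")
def snv_sim():
    return simulate_dataset(snv_design(seed=23))


@pytest.fixture(scope="session")
def small_sim():
    """A small mixed dataset exercising every variant class; fast."""
    cfg = SimConfig(
        seed=29,
        n_chroms=2,
        chrom_length_bp=3_000_000,
        n_cells=4,
        per_cell_coverage=0.5,
        svs=[
            PlantedSV("DEL", "chr1", 100_000, 102_000),
            PlantedSV("INS", "chr1", 200_000, 200_000, length=500),
            PlantedSV("DUP", "chr1", 300_000, 303_000),
            PlantedSV("INV", "chr1", 400_000, 410_000),
            PlantedSV("TRA", "chr1", 500_000, 500_001, chrom2="chr2", start2=1_500_000),
        ],
        circles=[PlantedCircle(GenomeInterval("chr1", 1_000_000, 1_008_000), copies_per_cell=3)],
    )
    return simulate_dataset(cfg)
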