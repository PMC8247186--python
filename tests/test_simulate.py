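"""Generator behavior: determinism, fragmentation statistics, planted
variant signatures, and call-set noise properties."""

import numpy as np
import pytest
from scipy import stats

from sclongread.io_model import GenomeInterval
from sclongread.simulate import (
    ConfigError,
    PlantedCircle,
    PlantedSV,
    SimConfig,
    build_reference,
    fragment_tn5,
    simulate_dataset,
    write_dataset,
)


class TestReference:
    def test_deterministic_fasta(self, tmp_path):
        cfg = SimConfig(seed=1, n_chroms=2, chrom_length_bp=200_000)
        for d in ("a", "b"):
            write_dataset(simulate_dataset(cfg), tmp_path / d)
        assert (tmp_path / "a/reference.fa").read_bytes() == (
            tmp_path / "b/reference.fa"
        ).read_bytes()

    def test_shape(self):
        cfg = SimConfig(seed=1, n_chroms=2, chrom_length_bp=5_000_000)
        ref = build_reference(cfg)
        assert set(ref.lengths) == {"chr1", "chr2"}
        assert all(l == 5_000_000 for l in ref.lengths.values())

    def test_repeat_count_in_poisson_band(self):
        """Repeat density 1/Mb over 10 Mb: count inside the Poisson 99%
        band around 10."""
        cfg = SimConfig(seed=4, n_chroms=1, chrom_length_bp=10_000_000,
                        repeat_density_per_mb=1.0)
        ref = build_reference(cfg)
        lo, hi = stats.poisson.ppf([0.005, 0.995], 10)
        assert lo <= len(ref.repeats) <= hi
        assert all(len(iv) > 1000 for iv in ref.repeats)

    def test_chrom_too_short_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(chrom_length_bp=10_000, mean_fragment_bp=6_000)


class TestFragmentTn5:
    def test_rate_zero_returns_whole_molecule(self):
        rng = np.random.default_rng(0)
        assert fragment_tn5(5_000, 0.0, rng) == [(0, 5_000)]

    def test_fragments_tile_molecule_exactly(self):
        rng = np.random.default_rng(1)
        frags = fragment_tn5(1_000_000, 1 / 6_000, rng)
        assert frags[0][0] == 0 and frags[-1][1] == 1_000_000
        assert all(a[1] == b[0] for a, b in zip(frags, frags[1:]))
        assert sum(b - a for a, b in frags) == 1_000_000

    def test_mean_fragment_length_matches_rate(self):
        """60 Mb at 1/6000 cuts per bp: mean length within 10% of 6 kb."""
        rng = np.random.default_rng(2)
        frags = fragment_tn5(60_000_000, 1 / 6_000, rng)
        mean = np.mean([b - a for a, b in frags])
        assert abs(mean - 6_000) / 6_000 < 0.10


class TestCoverageAccounting:
    def test_reads_per_cell_tracks_coverage(self, circle_sim):
        """0.4x of 60 Mb at ~6 kb reads: read count per cell within 20% of
        coverage * genome / fragment length."""
        expected = 0.4 * 60e6 / 6_000
        for cell, reads in circle_sim.cells.items():
            genomic = [
                r for r in reads
                if circle_sim.truth.origins[r.read_id].molecule == "genome"
            ]
            assert abs(len(genomic) - expected) / expected < 0.20

    def test_realized_depth_near_target(self, small_sim):
        genome = sum(small_sim.reference.lengths.values())
        for cell, reads in small_sim.cells.items():
            genomic_bp = sum(
                r.read_length for r in reads
                if small_sim.truth.origins[r.read_id].molecule == "genome"
            )
            assert abs(genomic_bp / genome - 0.5) < 0.15


class TestPlantedSignatures:
    def test_circle_single_cut_geometry(self, small_sim):
        """A circle cut once yields a full-length read whose two segments
        map tail-first then head: chr1:[s+o,e) then chr1:[s,s+o)."""
        circle = small_sim.config.circles[0].interval
        full = [
            r
            for rs in small_sim.cells.values()
            for r in rs
            if small_sim.truth.origins[r.read_id].molecule == "circle:0"
            and r.read_length == len(circle)
        ]
        assert full, "no single-cut full-length circle reads in this design"
        for r in full:
            if len(r.segments) != 2:
                continue
            s1, s2 = r.segments
            assert s1.target.end == circle.end
            assert s2.target.start == circle.start
            assert s1.target.start == s2.target.end  # contiguous around origin

    def test_distinct_copies_same_length(self, small_sim):
        """Different copies of the same circle give reads of exactly the
        circle's length."""
        circle = small_sim.config.circles[0].interval
        lengths = {
            r.read_length
            for rs in small_sim.cells.values()
            for r in rs
            if small_sim.truth.origins[r.read_id].molecule == "circle:0"
            and len(r.segments) == 2
            and r.segments[0].query_span + r.segments[1].query_span == r.read_length
            and r.read_length == len(circle)
        }
        assert lengths == {len(circle)} or lengths == set()

    def test_homozygous_deletion_appears_as_cigar_gap(self, small_sim):
        """Reads spanning the planted 2 kb deletion carry a 2000D op."""
        found = 0
        for rs in small_sim.cells.values():
            for r in rs:
                for seg in r.segments:
                    if "2000D" in seg.cigar:
                        t = seg.target
                        assert t.chrom == "chr1"
                        assert t.start < 100_000 < 102_000 < t.end
                        found += 1
        assert found >= 1

    def test_chiastic_reads_trace_to_circles_or_duplications(self, confounder_sim):
        """At error rate 0 every chiastic read in the emitted data comes
        from a planted circle or a head-to-tail duplication junction."""
        truth = confounder_sim.truth
        dup_idx = {
            i for i, sv in enumerate(confounder_sim.config.svs) if sv.svtype == "DUP"
        }
        for rs in confounder_sim.cells.values():
            for r in rs:
                o = truth.origins[r.read_id]
                if not o.chiastic:
                    continue
                from_circle = o.molecule.startswith("circle:")
                from_dup = o.molecule == "genome"  # only DUPs make genome reads chiastic
                assert from_circle or from_dup

    def test_every_read_has_one_origin_row(self, small_sim):
        ids = [r.read_id for rs in small_sim.cells.values() for r in rs]
        assert len(ids) == len(set(ids))
        assert set(ids) == set(small_sim.truth.origins)


class TestEmittedCallsets:
    def test_no_noise_means_only_truth(self, small_sim):
        """With per_cell_fp_calls=0 every emitted call matches a planted
        variant's type and locus."""
        truth_keys = {
            (c.svtype, c.locus.chrom, c.locus.start) for c in small_sim.truth.true_svs
        }
        for calls in small_sim.sv_callsets.values():
            for c in calls:
                assert (c.svtype, c.locus.chrom, c.locus.start) in truth_keys

    def test_spurious_calls_are_private_and_poisson(self, noise_sim):
        """50 expected FP calls/cell over 30 cells: total spurious count
        within the Poisson 99.9% band of 1500, each private to one cell."""
        truth_keys = {
            (c.svtype, c.locus.start) for c in noise_sim.truth.true_svs
        }
        n_fp = sum(
            1
            for calls in noise_sim.sv_callsets.values()
            for c in calls
            if (c.svtype, c.locus.start) not in truth_keys
        )
        lo, hi = stats.poisson.ppf([0.0005, 0.9995], 50 * 30)
        assert lo <= n_fp <= hi

    def test_clonal_deletion_called_in_most_cells(self, noise_sim):
        """A homozygous deletion at depth lambda is seen in a cell with
        probability ~1-exp(-lambda); across cells the rate agrees."""
        cfg = noise_sim.config
        del_idx = [i for i, sv in enumerate(cfg.svs) if sv.svtype == "DEL"]
        lam = cfg.per_cell_coverage  # expected junction-spanning reads/cell
        p_called = 1 - np.exp(-lam)
        rates = []
        for i in del_idx:
            n = sum(
                1 for cell in noise_sim.cells
                if noise_sim.truth.sv_support.get((cell, i), 0) >= 1
            )
            rates.append(n / cfg.n_cells)
        # binomial error around p_called over 10 SVs x 30 cells
        assert abs(np.mean(rates) - p_called) < 0.12


class TestDeterminism:
    def test_identical_configs_identical_outputs(self, tmp_path):
        cfg = SimConfig(
            seed=7, n_chroms=1, chrom_length_bp=1_000_000, n_cells=2,
            per_cell_coverage=0.3,
            svs=[PlantedSV("DEL", "chr1", 200_000, 202_000)],
            circles=[PlantedCircle(GenomeInterval("chr1", 600_000, 605_000))],
            per_cell_fp_calls=3.0,
        )
        for d in ("x", "y"):
            write_dataset(simulate_dataset(cfg), tmp_path / d)
        for name in ("cell000.sam", "cell000.sv.vcf", "truth.tsv", "trf.bed"):
            a = (tmp_path / "x" / name).read_bytes()
            b = (tmp_path / "y" / name).read_bytes()
            assert a == b, name
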