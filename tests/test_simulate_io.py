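"""Synthetic-data generators: calibration, determinism and format round-trips."""

import math

import numpy as np
import pytest

from ilsweep import (
    DEFAULT_X_MIXTURE,
    SimConfig,
    classify_triplet_site_patterns,
    expected_ils,
    overlap_bp,
    simulate_haplotype_panel,
    simulate_ils_windows,
    simulate_ils_windows_genealogical,
    simulate_interval_fixture,
    simulate_triplet_alignment,
)
from ilsweep.io import (
    read_bed,
    read_chrom_sizes,
    read_fasta,
    read_haplotype_panel_vcf,
    read_ils_track,
    write_bed,
    write_chrom_sizes,
    write_fasta,
    write_gff3,
    write_haplotype_panel_vcf,
    write_ils_track,
)
from ilsweep.regions import call_low_ils_regions


class TestIlsTrackGenerator:
    def test_all_neutral_mean_matches_gaussian_mode(self):
        cfg = SimConfig(seed=1, chrom_length=30_000_000)
        track, labels = simulate_ils_windows(cfg)
        vals = track.windows.ils.to_numpy()
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - DEFAULT_X_MIXTURE.mu) < 3 * se
        assert set(labels.regime) == {"neutral"}

    def test_genealogical_mode_matches_closed_form(self, scaled_demog):
        track, labels = simulate_ils_windows_genealogical(
            scaled_demog, n_windows=400, blocks_per_window=100, seed=2
        )
        p = expected_ils(scaled_demog.delta_tau, scaled_demog.theta_hc)
        vals = track.windows.ils.to_numpy()
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - p) < 3 * se
        # realized labels are the ground truth for the window values
        assert np.allclose(vals, labels.n_discordant / labels.n_blocks)

    def test_low_variance_limit(self):
        # gamma with huge shape at fixed mean: within-regime variance shrinks
        from ilsweep import MixtureFit

        tight = MixtureFit(p=0.632, mu=0.209, sigma=0.066, shape=4.139e4, rate=83.369e4)
        cfg = SimConfig(seed=3, chrom_length=20_000_000, mixture=tight,
                        planted_regions=[(0, 20_000_000, "low_ils")])
        track, _ = simulate_ils_windows(cfg)
        assert track.windows.ils.std() < 0.005

    def test_deterministic_under_seed(self):
        cfg = dict(seed=4, chrom_length=5_000_000, step_bp=20_000,
                   planted_regions=[(1_000_000, 3_000_000, "low_ils")])
        a, _ = simulate_ils_windows(SimConfig(**cfg))
        b, _ = simulate_ils_windows(SimConfig(**cfg))
        assert np.array_equal(a.windows.ils, b.windows.ils)

    def test_invalid_planted_regions(self):
        with pytest.raises(ValueError):
            SimConfig(chrom_length=1000, planted_regions=[(500, 1500, "sweep")])
        with pytest.raises(ValueError):
            SimConfig(chrom_length=10_000, planted_regions=[(0, 500, "odd")])


class TestTripletGenerator:
    def test_zero_mutation_rate_gives_invariant_alignment(self, scaled_demog):
        seqs, _ = simulate_triplet_alignment(scaled_demog, n_blocks=20, block_bp=100,
                                             u_scale=0.0, seed=5)
        arr = np.array([list(s) for s in seqs.values()])
        assert all(len(set(col)) == 1 for col in arr.T)

    def test_discordant_block_fraction_matches_closed_form(self, scaled_demog):
        _, labels = simulate_triplet_alignment(scaled_demog, n_blocks=4000, block_bp=10,
                                               u_scale=0.0, seed=6)
        p = expected_ils(scaled_demog.delta_tau, scaled_demog.theta_hc)
        frac = np.mean([t != "HC" for t in labels])
        se = math.sqrt(p * (1 - p) / len(labels))
        assert abs(frac - p) < 3 * se

    def test_site_level_discordance_consistent_with_labels(self, scaled_demog):
        seqs, labels = simulate_triplet_alignment(scaled_demog, n_blocks=800, block_bp=300,
                                                  u_scale=1.0, seed=7)
        c = classify_triplet_site_patterns(
            seqs["human"], seqs["chimp"], seqs["gorilla"], seqs["orang"]
        )
        # discordant informative sites only arise in discordant blocks, whose
        # internal branches are exponential(theta) while concordant blocks add
        # the unused part of the speciation interval; the realized block labels
        # bound the site-level discordance from above
        block_disc = np.mean([t != "HC" for t in labels])
        assert 0 < c.discordant_fraction < block_disc

    def test_outgroup_is_most_diverged(self, scaled_demog):
        seqs, _ = simulate_triplet_alignment(scaled_demog, n_blocks=300, block_bp=100,
                                             u_scale=1.0, seed=8)
        h = np.frombuffer(seqs["human"].encode(), dtype=np.uint8)
        c = np.frombuffer(seqs["chimp"].encode(), dtype=np.uint8)
        o = np.frombuffer(seqs["orang"].encode(), dtype=np.uint8)
        assert (h != o).mean() > (h != c).mean()


class TestPanelGenerator:
    def test_flat_diversity_without_sweeps(self):
        cfg = SimConfig(seed=9, chrom_length=10_000_000)
        panel, truth = simulate_haplotype_panel(cfg)
        from ilsweep import window_nucleotide_diversity

        track = window_nucleotide_diversity(panel, chrom_length=cfg.chrom_length)
        se = track.pi.std(ddof=1) / math.sqrt(len(track))
        assert abs(track.pi.mean() - cfg.pi_neutral) < 3 * se
        assert (truth.pi_target == cfg.pi_neutral).all()

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=10, chrom_length=2_000_000)
        a, _ = simulate_haplotype_panel(cfg)
        b, _ = simulate_haplotype_panel(cfg)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.haplotypes, b.haplotypes)


class TestIntervalFixture:
    def test_zero_overlap(self):
        q, r = simulate_interval_fixture(10_000_000, planted_overlap_fraction=0.0, seed=11)
        assert overlap_bp(q, r) == 0

    def test_full_overlap(self):
        q, r = simulate_interval_fixture(10_000_000, planted_overlap_fraction=1.0, seed=12)
        assert overlap_bp(q, r) == q.total_length

    def test_half_overlap(self):
        q, r = simulate_interval_fixture(10_000_000, planted_overlap_fraction=0.5, seed=13)
        assert overlap_bp(q, r) == q.total_length // 2

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            simulate_interval_fixture(1_000_000, n_query=8, lengths=200_000,
                                      planted_overlap_fraction=0.5, seed=14)


class TestRoundTrips:
    def test_ils_track(self, tmp_path):
        cfg = SimConfig(seed=15, chrom_length=3_000_000, step_bp=20_000)
        track, _ = simulate_ils_windows(cfg)
        path = tmp_path / "track.tsv"
        write_ils_track(track, path)
        back = read_ils_track(path)
        assert back.chrom == track.chrom
        assert np.allclose(back.windows.ils, track.windows.ils, atol=1e-6)
        regions_a = call_low_ils_regions(track)
        regions_b = call_low_ils_regions(back)
        assert len(regions_a) == len(regions_b)

    def test_bed_and_gff(self, tmp_path):
        q, _ = simulate_interval_fixture(10_000_000, planted_overlap_fraction=0.5, seed=16)
        path = tmp_path / "q.bed"
        write_bed(q, path)
        back = read_bed(path)
        assert np.array_equal(back.starts, q.starts)
        assert np.array_equal(back.ends, q.ends)
        # GFF3 writes 1-based inclusive coordinates
        from ilsweep import RegionSet
        import pandas as pd

        regions = RegionSet("chrX", pd.DataFrame(
            {"start": [100], "end": [500], "label": ["R1"], "mean_ils": [0.05]}
        ))
        gff = tmp_path / "r.gff3"
        write_gff3(regions, gff)
        line = [l for l in gff.read_text().splitlines() if not l.startswith("#")][0]
        fields = line.split("\t")
        assert (fields[3], fields[4]) == ("101", "500")

    def test_chrom_sizes(self, tmp_path):
        path = tmp_path / "chrom.sizes"
        write_chrom_sizes({"chrX": 155_270_560}, path)
        assert read_chrom_sizes(path) == {"chrX": 155_270_560}

    def test_fasta(self, tmp_path, scaled_demog):
        seqs, _ = simulate_triplet_alignment(scaled_demog, n_blocks=10, block_bp=50, seed=17)
        path = tmp_path / "aln.fa"
        write_fasta(seqs, path)
        assert read_fasta(path) == seqs

    def test_vcf(self, tmp_path):
        cfg = SimConfig(seed=18, chrom_length=500_000)
        panel, _ = simulate_haplotype_panel(cfg, n_haplotypes=7)  # odd: one haploid
        path = tmp_path / "panel.vcf"
        write_haplotype_panel_vcf(panel, path)
        back = read_haplotype_panel_vcf(path)
        assert np.array_equal(back.positions, panel.positions)
        assert np.array_equal(back.haplotypes, panel.haplotypes)
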