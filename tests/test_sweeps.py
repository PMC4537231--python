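"""Sweep trajectories, structured coalescent TMRCA and ILS footprints."""

import math

import numpy as np
import pytest

from ilsweep import (
    AncestralDemographyX,
    footprint_from_tmrca,
    neutral_tmrca,
    sample_fixation_trajectory,
    simulate_sweep_tmrca,
    sweep_footprint,
)


class TestDemographyType:
    def test_published_defaults(self):
        d = AncestralDemographyX()
        assert d.n_chrom == 109_800
        assert d.delta_tau_generations == pytest.approx(112_500.0)
        assert d.n_bins == 1000

    def test_invariants(self):
        with pytest.raises(ValueError):
            AncestralDemographyX(t_hc_years=6e6, t_hcg_years=5e6)


class TestTrajectories:
    def test_fixation_contract(self, small_sweep_demog, rng):
        for _ in range(20):
            traj = sample_fixation_trajectory(small_sweep_demog, 0.1, seed=rng)
            assert traj.counts[0] == 1
            assert traj.counts[-1] == small_sweep_demog.n_chrom
            assert np.all(traj.counts > 0)

    def test_soft_sweep_joins_at_standing_frequency(self, small_sweep_demog, rng):
        traj = sample_fixation_trajectory(
            small_sweep_demog, 0.2, mode="soft", f0=0.1, seed=rng
        )
        F = round(0.1 * small_sweep_demog.n_chrom)
        assert traj.counts[0] == 1
        assert traj.counts[traj.onset_index] == F
        assert traj.counts[-1] == small_sweep_demog.n_chrom

    def test_soft_from_single_copy_equals_hard_contract(self, small_sweep_demog, rng):
        traj = sample_fixation_trajectory(
            small_sweep_demog, 0.2, mode="soft", f0=1.0 / small_sweep_demog.n_chrom, seed=rng
        )
        assert traj.onset_index == 0
        assert traj.counts[0] == 1

    def test_conditional_fixation_time_band(self, small_sweep_demog, rng):
        # diffusion sanity band (2/s) ln(n_chrom) at moderately strong s
        s = 0.2
        durations = [
            sample_fixation_trajectory(small_sweep_demog, s, seed=rng).duration
            for _ in range(200)
        ]
        predicted = (2.0 / s) * math.log(small_sweep_demog.n_chrom)
        assert np.mean(durations) == pytest.approx(predicted, rel=0.25)

    def test_invalid_requests(self, small_sweep_demog):
        with pytest.raises(ValueError):
            sample_fixation_trajectory(small_sweep_demog, 0.0)
        with pytest.raises(ValueError):
            sample_fixation_trajectory(small_sweep_demog, 0.1, mode="soft")
        with pytest.raises(ValueError):
            sample_fixation_trajectory(small_sweep_demog, 0.1, mode="soft", f0=1.5)


class TestSweepTmrca:
    def test_neutral_control_matches_two_lineage_expectation(self, rng):
        # E[TMRCA] for two lineages equals the population size in chromosomes
        d = AncestralDemographyX(Ne=73_200.0, segment_genetic_length_cm=1.0)
        profiles = np.array([neutral_tmrca(d, rng) for _ in range(500)])
        assert profiles.mean() == pytest.approx(d.n_chrom, rel=0.05)

    def test_selected_site_coalesces_during_strong_sweep(self, small_sweep_demog, rng):
        profiles = []
        for _ in range(150):
            traj = sample_fixation_trajectory(small_sweep_demog, 0.2, seed=rng)
            profiles.append(simulate_sweep_tmrca(traj, small_sweep_demog, seed=rng))
        profiles = np.array(profiles)
        # near the selected site the mean TMRCA is far below neutral
        assert profiles[:, 0].mean() < 0.2 * small_sweep_demog.n_chrom

    def test_distant_bins_unaffected(self, rng):
        # bins >= 5 cM away at s = 0.05 sit within 10% of the neutral mean
        demog = AncestralDemographyX(
            Ne=2000.0, t_hc_years=1_000_000.0, t_hcg_years=1_000_000.0 + 3000 * 20.0,
            segment_genetic_length_cm=6.0,
        )
        profiles = []
        for _ in range(250):
            traj = sample_fixation_trajectory(demog, 0.05, seed=rng)
            profiles.append(simulate_sweep_tmrca(traj, demog, seed=rng))
        far = np.array(profiles)[:, 500:]
        assert far.mean() == pytest.approx(demog.n_chrom, rel=0.10)


class TestFootprint:
    def test_all_below_boundary_means_no_ils(self, small_sweep_demog):
        tm = np.full((10, small_sweep_demog.n_bins), 5.0)
        fp = footprint_from_tmrca(tm, small_sweep_demog)
        assert np.all(fp.ils_fraction == 0.0)
        assert fp.width_below_cm == small_sweep_demog.segment_genetic_length_cm

    def test_degenerate_threshold_spans_flank(self, small_sweep_demog, rng):
        tm = np.array([neutral_tmrca(small_sweep_demog, rng) for _ in range(20)])
        fp = footprint_from_tmrca(tm, small_sweep_demog, threshold=1.0)
        assert fp.width_below_cm == small_sweep_demog.segment_genetic_length_cm

    def test_ils_fraction_never_exceeds_two_thirds(self, small_sweep_demog, rng):
        tm = np.array([neutral_tmrca(small_sweep_demog, rng) for _ in range(50)])
        fp = footprint_from_tmrca(tm, small_sweep_demog)
        assert np.all(fp.ils_fraction <= 2.0 / 3.0)

    def test_neutral_ils_matches_closed_form(self, small_sweep_demog, rng):
        # 2/3 * P(Geom(1/n) > dtau) vs Monte Carlo, within 3 standard errors
        reps = 400
        tm = np.array([neutral_tmrca(small_sweep_demog, rng) for _ in range(reps)])
        fp = footprint_from_tmrca(tm, small_sweep_demog)
        n = small_sweep_demog.n_chrom
        boundary = small_sweep_demog.delta_tau_generations
        expected = (2.0 / 3.0) * (1.0 - 1.0 / n) ** boundary
        per_rep = (2.0 / 3.0) * (tm > boundary).mean(axis=1)
        se = per_rep.std(ddof=1) / math.sqrt(reps)
        assert abs(fp.ils_fraction.mean() - expected) < 3 * se

    def test_width_monotone_in_s_and_f0(self, small_sweep_demog, rng):
        weak = sweep_footprint(small_sweep_demog, 0.05, replicates=250, seed=rng)
        strong = sweep_footprint(small_sweep_demog, 0.5, replicates=250, seed=rng)
        assert strong.width_below_cm >= weak.width_below_cm
        soft = sweep_footprint(
            small_sweep_demog, 0.5, replicates=250, mode="soft", f0=0.2, seed=rng
        )
        assert soft.width_below_cm <= strong.width_below_cm

    def test_empty_replicates_rejected(self, small_sweep_demog):
        with pytest.raises(ValueError):
            footprint_from_tmrca(np.empty((0, 0)), small_sweep_demog)


def _marginal_chain_tmrca(traj, n, d, rng):
    """Independent oracle: two-lineage backward chain at one genetic distance.

    Each generation a lineage follows, with probability ``d``, a secondary
    parent drawn uniformly from the whole population (background re-drawn),
    otherwise its primary parent within its current background.  This is the
    exact marginal law of one position at distance ``d`` from the selected
    site, with none of the material-interval bookkeeping of the full
    simulator.
    """
    counts = traj.counts
    T = len(counts) - 1
    bg = [0, 0]
    for j in range(1, T + 1):
        k_parent = int(counts[T - j])
        parents = [0, 0]
        newbg = list(bg)
        for i in range(2):
            if rng.random() < d:
                p = int(rng.integers(n))
                newbg[i] = 0 if p < k_parent else 1
                parents[i] = p
            elif bg[i] == 0:
                parents[i] = int(rng.integers(max(k_parent, 1)))
            else:
                parents[i] = k_parent + int(rng.integers(max(n - k_parent, 1)))
        if parents[0] == parents[1] and newbg[0] == newbg[1]:
            return j
        bg = newbg
    return T + int(rng.geometric(1.0 / n))


class TestAgainstMarginalOracle:
    def test_structured_simulator_matches_marginal_chain(self, small_sweep_demog):
        """Per-bin TMRCA marginals from the full structured simulator agree
        with the independent single-position chain."""
        d = small_sweep_demog
        s = 0.2
        reps = 600
        rng = np.random.default_rng(17)
        boundary = d.delta_tau_generations
        dist, bin_idx = 0.005, 49  # 0.5 cM from the selected site
        oracle = np.array(
            [
                _marginal_chain_tmrca(
                    sample_fixation_trajectory(d, s, seed=rng), d.n_chrom, dist, rng
                )
                for _ in range(reps)
            ],
            dtype=float,
        )
        sim = np.array(
            [
                simulate_sweep_tmrca(sample_fixation_trajectory(d, s, seed=rng), d, seed=rng)[bin_idx]
                for _ in range(reps)
            ]
        )
        se_mean = math.hypot(oracle.std(ddof=1), sim.std(ddof=1)) / math.sqrt(reps)
        assert abs(oracle.mean() - sim.mean()) < 4 * se_mean
        p_o = (oracle > boundary).mean()
        p_s = (sim > boundary).mean()
        se_p = math.sqrt((p_o * (1 - p_o) + p_s * (1 - p_s)) / reps)
        assert abs(p_o - p_s) < 4 * max(se_p, 1e-3)


class TestAgainstMsprime:
    def test_neutral_recombining_tmrca_through_ils_calling(self, small_sweep_demog):
        """Feed msprime neutral coalescent-with-recombination TMRCAs through
        the footprint machinery and compare with the closed form."""
        msprime = pytest.importorskip("msprime")
        d = small_sweep_demog
        L = int(d.segment_genetic_length_cm / d.r_cm_per_mb * 1e6)
        bin_bp = int(d.bin_cm / d.r_cm_per_mb * 1e6)
        reps = 300
        profiles = np.empty((reps, d.n_bins))
        for i in range(reps):
            ts = msprime.sim_ancestry(
                samples=1,
                ploidy=2,
                population_size=d.n_chrom / 2.0,
                sequence_length=L,
                recombination_rate=1e-8 * d.r_cm_per_mb,
                random_seed=i + 1,
            )
            prof = np.empty(d.n_bins)
            for k in range(d.n_bins):
                tree = ts.at((k + 0.5) * bin_bp)
                prof[k] = tree.time(tree.root)
            profiles[i] = prof
        fp = footprint_from_tmrca(profiles, d)
        expected = (2.0 / 3.0) * math.exp(
            -d.delta_tau_generations / d.n_chrom
        )
        per_rep = (2.0 / 3.0) * (profiles > d.delta_tau_generations).mean(axis=1)
        se = per_rep.std(ddof=1) / math.sqrt(reps)
        assert abs(fp.ils_fraction.mean() - expected) < 4 * se
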