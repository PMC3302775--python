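"""Properties of the synthetic structured-population generator."""

import numpy as np
import pytest

from dartpop import (
    SyntheticConfig,
    filter_markers,
    pairwise_ld,
    simulate_population,
    simulate_q_replicates,
    spike_outliers,
    wc_fst,
)
from dartpop.concordance import ancestry_dissimilarity
from dartpop.ld import fit_ld_decay


def small_cfg(**kw):
    base = dict(
        n_groups=2,
        group_sizes=(30, 30),
        n_chromosomes=4,
        chromosome_length_bp=5_000_000,
        n_markers=200,
        seed=0,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestSimulatePopulation:
    def test_bit_identical_under_same_seed(self):
        a = simulate_population(small_cfg(seed=42))
        b = simulate_population(small_cfg(seed=42))
        np.testing.assert_array_equal(a[0].calls, b[0].calls)
        np.testing.assert_array_equal(a[1].positions_bp, b[1].positions_bp)
        assert a[2].group_labels == b[2].group_labels

    def test_positions_sorted_unique_per_chromosome(self):
        _, mmap, _ = simulate_population(small_cfg(seed=1))
        df = mmap.to_frame()
        for _, grp in df.groupby("chromosome"):
            pos = grp["position_bp"].to_numpy()
            assert (np.diff(pos) > 0).all()

    def test_missingness_close_to_requested(self):
        gm, _, _ = simulate_population(small_cfg(seed=2, missing_rate=0.2, n_markers=400))
        assert np.isnan(gm.calls).mean() == pytest.approx(0.2, abs=0.02)

    def test_no_differentiation_limit(self):
        """F -> 0 with a weak founder bottleneck gives theta near zero."""
        cfg = SyntheticConfig(
            n_groups=2,
            group_sizes=(100, 100),
            n_chromosomes=10,
            chromosome_length_bp=50_000_000,
            n_markers=1000,
            target_fst=0.001,
            founder_haplotypes_per_group=100,
            missing_rate=0.0,
            seed=3,
        )
        gm, _, truth = simulate_population(cfg)
        res = wc_fst(gm, truth.group_assignment())
        assert abs(np.nanmean(res.per_locus_theta)) < 0.02

    def test_configured_fst_recovered_at_default_conditions(self):
        """Default study conditions (K=6, unequal sizes, F=0.4)."""
        gm, _, truth = simulate_population(SyntheticConfig(seed=4))
        res = wc_fst(filter_markers(gm), truth.group_assignment())
        assert np.nanmean(res.per_locus_theta) == pytest.approx(0.4, abs=0.05)

    def test_no_recombination_two_founders_gives_distance_free_max_ld(self):
        """c=0, H=2: a chromosome is a single founder segment, so every
        polymorphic within-group pair is in complete LD regardless of
        distance."""
        cfg = SyntheticConfig(
            n_groups=1,
            group_sizes=(80,),
            n_chromosomes=1,
            chromosome_length_bp=10_000_000,
            n_markers=50,
            founder_haplotypes_per_group=2,
            per_bp_switch_rate=0.0,
            missing_rate=0.0,
            seed=5,
        )
        gm, mmap, _ = simulate_population(cfg)
        kept = filter_markers(gm, 1.0, 0.05)
        ld = pairwise_ld(kept, mmap, require_filtered=False)
        assert (ld.r2 > 0.99).all()
        # and no distance dependence
        assert abs(np.corrcoef(ld.dist_bp, ld.r2)[0, 1]) < 0.05 or ld.r2.std() < 1e-9

    def test_ld_decays_with_distance_over_seeds(self):
        """Mean r² in the shortest class exceeds the 1-10 Mb class at the
        default study conditions, averaged over 5 seeds."""
        short, far = [], []
        for seed in range(1, 6):
            gm, mmap, _ = simulate_population(SyntheticConfig(seed=seed))
            ld = pairwise_ld(filter_markers(gm), mmap)
            linked = ld[ld.same_chromosome]
            short.append(linked[linked.dist_bp <= 1e4].r2.mean())
            far.append(
                linked[(linked.dist_bp > 1e6) & (linked.dist_bp <= 1e7)].r2.mean()
            )
        assert np.nanmean(short) > np.mean(far)

    def test_decay_fit_positive_and_bins_monotone(self):
        """On a dense 200-accession, 1000-marker panel with a tight
        founder pool the decay is strong enough for the hyperbolic fit:
        a is positive/finite and bin means decrease with distance."""
        cfg = SyntheticConfig(
            n_groups=2,
            group_sizes=(100, 100),
            target_fst=0.05,
            n_chromosomes=10,
            chromosome_length_bp=5_000_000,
            n_markers=1000,
            founder_haplotypes_per_group=4,
            seed=3,
        )
        gm, mmap, _ = simulate_population(cfg)
        ld = pairwise_ld(filter_markers(gm), mmap)
        fit = fit_ld_decay(ld)
        assert 0 < fit.a < np.inf
        linked = ld[ld.same_chromosome]
        means = [
            linked[(linked.dist_bp > lo) & (linked.dist_bp <= hi)].r2.mean()
            for lo, hi in [(0, 1e4), (1e4, 5e4), (5e4, 1e5), (1e5, 1e6), (1e6, 1e7)]
        ]
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="group_sizes"):
            SyntheticConfig(n_groups=3, group_sizes=(5, 5))
        with pytest.raises(ValueError, match="chromosome too short"):
            SyntheticConfig(
                n_chromosomes=1, chromosome_length_bp=100, n_markers=1000
            )


class TestQReplicates:
    def test_noiseless_limit(self):
        rng = np.random.default_rng(0)
        truth = simulate_population(small_cfg(seed=6))[2].q
        reps = simulate_q_replicates(truth, concentration=1e7, n_runs=1, seed=1)
        assert np.abs(reps[0].q - truth.q).max() < 1e-3

    def test_label_permutation_removed_by_alignment(self):
        truth = simulate_population(small_cfg(seed=7))[2].q
        plain = simulate_q_replicates(truth, 200.0, permute_labels=False, n_runs=1, seed=2)[0]
        permuted = simulate_q_replicates(truth, 200.0, permute_labels=True, n_runs=1, seed=2)[0]
        d_plain = ancestry_dissimilarity(truth, plain).average
        d_perm = ancestry_dissimilarity(truth, permuted).average
        assert d_perm == pytest.approx(d_plain, abs=0.02)

    def test_run_count_and_shapes(self):
        truth = simulate_population(small_cfg(seed=8))[2].q
        reps = simulate_q_replicates(truth, 10.0, n_runs=10, seed=3)
        assert len(reps) == 10
        assert all(r.q.shape == truth.q.shape for r in reps)

    def test_invalid_concentration(self):
        truth = simulate_population(small_cfg(seed=9))[2].q
        with pytest.raises(ValueError):
            simulate_q_replicates(truth, 0.0)


class TestSpikeOutliers:
    def test_diversifying_spike_raises_locus_theta(self):
        cfg = small_cfg(seed=10, group_sizes=(60, 60), missing_rate=0.0)
        gm, _, truth = simulate_population(cfg)
        target = gm.marker_ids[5]
        gm2, truth2 = spike_outliers(gm, truth, [target], "diversifying", seed=0)
        res = wc_fst(gm2, truth2.group_assignment())
        j = gm2.marker_ids.index(target)
        assert res.per_locus_theta[j] > 0.9
        assert truth2.outlier_loci[target]["mode"] == "diversifying"

    def test_balancing_spike_flattens_locus_theta(self):
        cfg = small_cfg(seed=11, group_sizes=(60, 60), missing_rate=0.0)
        gm, _, truth = simulate_population(cfg)
        target = gm.marker_ids[7]
        gm2, truth2 = spike_outliers(gm, truth, [target], "balancing", seed=1)
        res = wc_fst(gm2, truth2.group_assignment())
        j = gm2.marker_ids.index(target)
        assert res.per_locus_theta[j] < 0.05

    def test_empty_list_is_identity(self):
        gm, _, truth = simulate_population(small_cfg(seed=12))
        gm2, truth2 = spike_outliers(gm, truth, [], "diversifying")
        assert gm2 is gm and truth2 is truth

    def test_unknown_locus_rejected(self):
        gm, _, truth = simulate_population(small_cfg(seed=13))
        with pytest.raises(KeyError):
            spike_outliers(gm, truth, ["nope"], "diversifying")
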