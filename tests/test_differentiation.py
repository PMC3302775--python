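"""Weir-Cockerham theta, permutation tests, the calibrated neutral
envelope and outlier classification."""

import numpy as np
import pytest

from dartpop import (
    BiallelicGenotypeMatrix,
    GroupAssignment,
    MultiAllelicGenotypeMatrix,
    SyntheticConfig,
    classify_outliers,
    fst_permutation_test,
    simulate_neutral_envelope,
    simulate_population,
    spike_outliers,
    wc_fst,
)


def direct_theta(sizes, freqs):
    """Independent spreadsheet-style evaluation of the variance components."""
    sizes = np.asarray(sizes, float)
    freqs = np.asarray(freqs, float)
    r = len(sizes)
    n_tot = sizes.sum()
    p_bar = (sizes * freqs).sum() / n_tot
    msp = (sizes * (freqs - p_bar) ** 2).sum() / (r - 1)
    msg = (sizes * freqs * (1 - freqs)).sum() / (sizes - 1).sum()
    n_c = (n_tot - (sizes**2).sum() / n_tot) / (r - 1)
    return (msp - msg) / (msp + (n_c - 1) * msg)


def panel_from_freqs(sizes, freqs, seed=None):
    """Deterministic single-locus panel realizing exact group frequencies."""
    calls, ids, labels = [], [], []
    for k, (n, p) in enumerate(zip(sizes, freqs)):
        ones = round(n * p)
        col = [1.0] * ones + [0.0] * (n - ones)
        calls.extend(col)
        ids.extend(f"g{k}_{i}" for i in range(n))
        labels.extend([k + 1] * n)
    gm = BiallelicGenotypeMatrix(ids, ["locus"], np.array(calls)[:, None])
    return gm, GroupAssignment.from_labels(ids, labels)


class TestWCFst:
    def test_fixed_alternate_alleles(self):
        gm, groups = panel_from_freqs([10, 10], [1.0, 0.0])
        res = wc_fst(gm, groups)
        assert res.global_theta == pytest.approx(1.0)

    def test_identical_frequencies_nonpositive(self):
        gm, groups = panel_from_freqs([10, 10], [0.5, 0.5])
        res = wc_fst(gm, groups)
        assert res.global_theta <= 0.0

    @pytest.mark.parametrize(
        "sizes, freqs",
        [
            ([10, 10], [0.9, 0.1]),
            ([10, 20, 5], [0.8, 0.3, 0.5]),
            ([12, 7, 9, 30], [0.25, 0.5, 0.75, 0.1]),
        ],
    )
    def test_matches_direct_variance_component_oracle(self, sizes, freqs):
        gm, groups = panel_from_freqs(sizes, freqs)
        res = wc_fst(gm, groups)
        # realized frequencies after rounding to whole accessions
        realized = [round(n * p) / n for n, p in zip(sizes, freqs)]
        assert res.global_theta == pytest.approx(direct_theta(sizes, realized))
        assert res.per_locus_theta[0] == pytest.approx(direct_theta(sizes, realized))

    def test_single_locus_global_equals_per_locus(self):
        gm, groups = panel_from_freqs([15, 25], [0.7, 0.2])
        res = wc_fst(gm, groups)
        assert res.global_theta == pytest.approx(res.per_locus_theta[0])

    def test_pairwise_matrix_symmetric(self):
        gm, _, truth = simulate_population(
            SyntheticConfig(
                n_groups=3,
                group_sizes=(20, 25, 30),
                n_chromosomes=2,
                chromosome_length_bp=10_000_000,
                n_markers=100,
                seed=20,
            )
        )
        res = wc_fst(gm, truth.group_assignment())
        pw = res.pairwise.to_numpy()
        assert np.allclose(pw, pw.T, equal_nan=True)
        assert np.isnan(np.diag(pw)).all()

    def test_unassigned_excluded(self):
        gm, groups = panel_from_freqs([10, 10], [1.0, 0.0])
        from dartpop import UNASSIGNED

        asg = dict(groups.assignments)
        # move two accessions of group 1 out of the analysis
        asg["g0_0"] = UNASSIGNED
        asg["g0_1"] = UNASSIGNED
        res = wc_fst(gm, GroupAssignment(asg))
        assert res.group_sizes[1] == 8

    def test_monomorphic_locus_excluded_from_multilocus(self):
        calls = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 1.0], [1.0, 0.0]])
        gm = BiallelicGenotypeMatrix(["a", "b", "c", "d"], ["mono", "poly"], calls)
        groups = GroupAssignment.from_labels(["a", "b", "c", "d"], [1, 1, 2, 2])
        res = wc_fst(gm, groups)
        assert np.isnan(res.per_locus_theta[0])
        assert res.n_loci_used == 1

    def test_multiallelic_two_allele_locus_matches_biallelic(self):
        gm_b, groups = panel_from_freqs([10, 10], [0.9, 0.1])
        labels = np.where(gm_b.calls[:, 0] == 1, "A", "B").astype(object)[:, None]
        gm_m = MultiAllelicGenotypeMatrix(gm_b.accession_ids, ["locus"], labels)
        assert wc_fst(gm_m, groups).global_theta == pytest.approx(
            wc_fst(gm_b, groups).global_theta
        )


class TestPermutationTest:
    def test_differentiated_panel_significant(self):
        gm, _, truth = simulate_population(
            SyntheticConfig(
                n_groups=3,
                group_sizes=(25, 25, 25),
                n_chromosomes=2,
                chromosome_length_bp=10_000_000,
                n_markers=150,
                missing_rate=0.0,
                seed=21,
            )
        )
        res = fst_permutation_test(gm, truth.group_assignment(), n_perm=199, seed=0)
        assert res["global"] == pytest.approx(1 / 200)

    def test_null_p_values_not_small(self):
        """With randomized labels the test should not reject."""
        rng = np.random.default_rng(5)
        calls = (rng.random((60, 80)) < 0.4).astype(float)
        gm = BiallelicGenotypeMatrix(
            [f"a{i}" for i in range(60)], [f"m{j}" for j in range(80)], calls
        )
        pvals = []
        for rep in range(10):
            labels = rng.permutation([1] * 30 + [2] * 30)
            groups = GroupAssignment.from_labels(gm.accession_ids, [int(x) for x in labels])
            pvals.append(fst_permutation_test(gm, groups, n_perm=100, seed=rep)["global"])
        # roughly uniform: mean near 0.5, not concentrated at 0
        assert 0.2 < np.mean(pvals) < 0.8

    def test_too_few_permutations_rejected(self):
        gm, groups = panel_from_freqs([10, 10], [0.9, 0.1])
        with pytest.raises(ValueError):
            fst_permutation_test(gm, groups, n_perm=0)


class TestNeutralEnvelope:
    def make_observed(self, seed=30):
        gm, _, truth = simulate_population(
            SyntheticConfig(
                n_groups=6,
                group_sizes=(50,) * 6,
                founder_haplotypes_per_group=50,
                n_markers=500,
                missing_rate=0.0,
                seed=seed,
            )
        )
        return wc_fst(gm, truth.group_assignment())

    def test_calibration_hits_explicit_target(self):
        obs = self.make_observed()
        env = simulate_neutral_envelope(
            obs, n_loci=20_000, deme_n=50, seed=1, target_mean_fst=0.42
        )
        assert env.achieved_mean_theta == pytest.approx(0.42, abs=0.005)

    def test_envelope_deterministic(self):
        obs = self.make_observed()
        e1 = simulate_neutral_envelope(obs, n_loci=5_000, seed=2)
        e2 = simulate_neutral_envelope(obs, n_loci=5_000, seed=2)
        assert e1.f_cal == e2.f_cal
        np.testing.assert_array_equal(e1.upper, e2.upper)

    def test_low_divergence_envelope_is_tight(self):
        obs = self.make_observed()
        env = simulate_neutral_envelope(
            obs, n_loci=10_000, seed=3, target_mean_fst=0.01
        )
        assert (env.upper < 0.2).all()

    def test_quantile_ordering(self):
        obs = self.make_observed()
        env = simulate_neutral_envelope(obs, n_loci=10_000, seed=4)
        assert (env.lower <= env.upper).all()


class TestClassifyOutliers:
    def test_spiked_loci_called_and_median_is_neutral(self):
        gm, _, truth = simulate_population(
            SyntheticConfig(
                n_groups=6,
                group_sizes=(50,) * 6,
                founder_haplotypes_per_group=50,
                n_markers=500,
                missing_rate=0.0,
                seed=31,
            )
        )
        div = gm.marker_ids[10:15]
        bal = gm.marker_ids[100:105]
        gm, truth = spike_outliers(gm, truth, div, "diversifying", seed=0)
        gm, truth = spike_outliers(gm, truth, bal, "balancing", seed=1)
        obs = wc_fst(gm, truth.group_assignment())
        env = simulate_neutral_envelope(obs, n_loci=20_000, deme_n=50, seed=5)
        calls = {c.marker_id: c for c in classify_outliers(obs, env)}
        assert all(calls[m].classification == "diversifying" for m in div)
        assert all(calls[m].classification == "balancing" for m in bal)
        # quantile positions are coherent with the calls
        assert all(calls[m].quantile_position > 0.95 for m in div)
        assert all(calls[m].quantile_position < 0.05 for m in bal)
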