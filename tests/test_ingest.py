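"""Mutation weighting, cluster detection/adjustment, tensor construction."""

import math

import numpy as np
import pandas as pd
import pytest

from mutopo.ingest import (ClusterCall, CohortWindowRates, SampleMeta,
                           adjust_cluster_weights, build_count_tensor,
                           critical_distance, detect_clusters,
                           full_multiplicity_weight, linked_gap_fraction,
                           local_rate, mutation_weight)


class TestMutationWeight:
    def test_identity_at_full_purity(self):
        assert mutation_weight(0.5, 1.0) == 0.5

    def test_purity_rescaling(self):
        assert mutation_weight(0.25, 0.5) == 0.5

    def test_full_multiplicity_reduces_at_diploid(self):
        for vaf in (0.1, 0.33, 0.5):
            for purity in (0.4, 0.75, 1.0):
                assert np.isclose(full_multiplicity_weight(vaf, purity, 2.0),
                                  vaf / purity)

    def test_cap_and_errors(self):
        assert mutation_weight(1.0, 0.25) == 2.0
        assert mutation_weight(1.0, 0.25, cap=None) == 4.0
        with pytest.raises(ValueError):
            mutation_weight(0.5, 0.0)
        with pytest.raises(ValueError):
            mutation_weight(-0.1, 1.0)
        with pytest.raises(ValueError):
            SampleMeta("s", purity=0.0)


class TestLocalRate:
    def test_uniform_cohort(self):
        L = 1_000_000
        df = pd.DataFrame({"chrom": "chr1",
                           "pos": np.linspace(0, L - 1, 2_000, dtype=int)})
        rates = CohortWindowRates.from_mutations(df, {"chr1": L})
        mu = rates.rate_at("chr1", np.array([500_000]))
        mu_hat = local_rate(mu, burden=300.0)
        assert np.isclose(mu_hat[0], 300.0 / L + 1.0 / 50_000, rtol=0.05)

    def test_burden_linearity(self):
        mu = np.array([2e-6])
        a = local_rate(mu, 100.0, pseudocount=0.0)
        b = local_rate(mu, 200.0, pseudocount=0.0)
        assert np.isclose(b[0], 2 * a[0])

    def test_hot_window_hand_computation(self):
        # 10% of 1,000 cohort mutations inside one 50-kb window on 1 Mb
        pos = np.concatenate([
            np.linspace(500_000 - 24_999, 500_000 + 24_999, 100, dtype=int),
            np.linspace(0, 400_000, 900, dtype=int)])
        df = pd.DataFrame({"chrom": "chr1", "pos": pos})
        rates = CohortWindowRates.from_mutations(df, {"chr1": 1_000_000})
        mu = rates.rate_at("chr1", np.array([500_000]))[0]
        assert np.isclose(mu, 0.1 / 50_000, rtol=1e-6)
        mu_hat = local_rate(np.array([mu]), burden=500.0)[0]
        assert np.isclose(mu_hat, 500 * 0.1 / 50_000 + 1 / 50_000)

    def test_empty_window_falls_back_to_genome_mean(self):
        df = pd.DataFrame({"chrom": ["chr1"], "pos": [10]})
        rates = CohortWindowRates.from_mutations(df, {"chr1": 500_000,
                                                      "chr2": 500_000})
        mu = rates.rate_at("chr2", np.array([250_000]))
        assert np.isclose(mu[0], 1.0 / 1_000_000)


class TestCriticalDistance:
    def test_printed_arithmetic(self):
        d = critical_distance(np.array([0.001]), alpha_clust=0.005)
        assert np.isclose(d[0], -2 * math.log(0.995) / 0.001)

    def test_vanishes_as_alpha_to_zero(self):
        d = critical_distance(np.array([0.001]), alpha_clust=1e-12)
        assert d[0] < 1e-5

    def test_halving_rate_doubles_distance(self):
        d1 = critical_distance(np.array([0.002]))
        d2 = critical_distance(np.array([0.001]))
        assert np.isclose(d2[0], 2 * d1[0])

    def test_alpha_domain(self):
        with pytest.raises(ValueError):
            critical_distance(np.array([0.1]), alpha_clust=0.0)
        with pytest.raises(ValueError):
            critical_distance(np.array([0.1]), alpha_clust=1.0)


def sparse_rates(L=10_000_000):
    """Cohort rates so low that d* exceeds the 10-kb cap."""
    df = pd.DataFrame({"chrom": ["chr9"], "pos": [1]})
    return CohortWindowRates.from_mutations(df, {"chr1": L})


class TestDetectClusters:
    def test_ten_kb_cap_binds(self):
        rates = sparse_rates()
        df = pd.DataFrame({"chrom": "chr1", "pos": [100_000, 110_001]})
        d_star = critical_distance(local_rate(
            rates.rate_at("chr1", np.array([100_000])), 2, 0.01))
        assert d_star[0] > 10_000  # cap is the binding constraint
        clusters = detect_clusters(df, rates, burden=2, pseudocount=0.01)
        assert [c.size for c in clusters] == [1, 1]
        df2 = pd.DataFrame({"chrom": "chr1", "pos": [100_000, 109_999]})
        clusters2 = detect_clusters(df2, rates, burden=2, pseudocount=0.01)
        assert [c.size for c in clusters2] == [2]

    def test_adjacent_run_forms_one_cluster(self):
        rates = sparse_rates()
        df = pd.DataFrame({"chrom": "chr1", "pos": [5_000, 5_001, 5_002]})
        clusters = detect_clusters(df, rates, burden=3)
        assert [c.size for c in clusters] == [3]

    def test_every_mutation_in_exactly_one_cluster(self, rng):
        rates = sparse_rates()
        df = pd.DataFrame({
            "chrom": rng.choice(["chr1", "chr2"], size=200),
            "pos": rng.integers(0, 1_000_000, size=200)})
        clusters = detect_clusters(df, rates)
        members = sorted(i for c in clusters for i in c.member_indices)
        assert len(members) == 200 and len(set(members)) == 200

    def test_null_calibration_of_gap_tests(self):
        # gaps drawn from the model's own null Exp(mu_hat/2) must be
        # flagged at rate alpha
        alpha = 0.005
        L = 50_000_000
        n = 60_000
        cohort = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.sort(np.random.default_rng(7).integers(0, L, 400_000))})
        rates = CohortWindowRates.from_mutations(cohort, {"chr1": L})
        burden = 5_000.0
        mu_hat = local_rate(np.array([400_000 * 50_000 / (L * 400_000)
                                      / 50_000]), burden)[0]
        rng = np.random.default_rng(42)
        gaps = rng.exponential(2.0 / mu_hat, size=n)
        pos = np.cumsum(gaps).astype(int)
        df = pd.DataFrame({"chrom": "chr1", "pos": pos[pos < L]})
        frac = linked_gap_fraction(df, rates, burden=burden,
                                   alpha_clust=alpha)
        se = math.sqrt(alpha * (1 - alpha) / len(df))
        assert abs(frac - alpha) < 4 * se


class TestAdjustWeights:
    def test_singleton_identity_and_division(self):
        clusters = [ClusterCall([0], np.ones(1), np.ones(1)),
                    ClusterCall([1, 2, 3], np.ones(3), np.ones(3))]
        w = np.array([0.7, 0.6, 0.6, 0.6])
        out = adjust_cluster_weights(w, clusters)
        assert out[0] == 0.7
        assert np.allclose(out[1:], 0.2)

    def test_cluster_mass_equals_mean_original_weight(self, rng):
        w = rng.random(5) + 0.1
        clusters = [ClusterCall(list(range(5)), np.ones(5), np.ones(5))]
        out = adjust_cluster_weights(w, clusters)
        assert np.isclose(out.sum(), w.mean())
        assert np.all(out <= w)

    def test_disabled_reproduces_raw(self, rng):
        w = rng.random(4)
        clusters = [ClusterCall(list(range(4)), np.ones(4), np.ones(4))]
        assert np.array_equal(adjust_cluster_weights(w, clusters,
                                                     enabled=False), w)


class TestBuildCountTensor:
    def test_mass_conservation_and_accumulation(self, small_world):
        binning, genome = small_world
        seq = genome["chr1"]
        pos = next(i for i in range(1_000, 2_000) if seq[i] == "C")
        muts = pd.DataFrame({
            "sample": ["s1", "s1", "s2"],
            "chrom": ["chr1"] * 3,
            "pos": [pos, pos, pos],
            "ref": ["C"] * 3, "alt": ["T"] * 3,
            "vaf": [0.4, 0.4, 0.3]})
        samples = [SampleMeta("s1", 0.8), SampleMeta("s2", 0.6)]
        Y = build_count_tensor(muts, binning, genome, samples,
                               cluster_adjust=False)
        assert np.isclose(Y.total_weight(), 0.4 / 0.8 * 2 + 0.3 / 0.6)
        # the two identical s1 mutations accumulate into one cell
        assert Y.n_cells == 2

    def test_cluster_adjustment_never_increases_total(self, small_world,
                                                      small_cohort):
        binning, genome = small_world
        mutations, _, meta = small_cohort
        samples = [SampleMeta(r.sample_id, r.purity)
                   for r in meta.itertuples()]
        Y_adj = build_count_tensor(mutations, binning, genome, samples)
        Y_raw = build_count_tensor(mutations, binning, genome, samples,
                                   cluster_adjust=False)
        assert Y_adj.total_weight() <= Y_raw.total_weight() + 1e-9

    def test_deterministic(self, small_world, small_cohort):
        binning, genome = small_world
        mutations, _, meta = small_cohort
        samples = [SampleMeta(r.sample_id, r.purity)
                   for r in meta.itertuples()]
        Y1 = build_count_tensor(mutations, binning, genome, samples)
        Y2 = build_count_tensor(mutations, binning, genome, samples)
        assert np.array_equal(Y1.weight, Y2.weight)
        assert np.array_equal(Y1.bin_idx, Y2.bin_idx)

    def test_mutation_outside_binned_genome_errors(self, small_world):
        binning, genome = small_world
        muts = pd.DataFrame({"sample": ["s1"], "chrom": ["chrXX"],
                             "pos": [500], "ref": ["C"], "alt": ["T"],
                             "vaf": [0.5]})
        with pytest.raises(KeyError):
            build_count_tensor(muts, binning, genome)

    def test_reference_mismatch_errors(self, small_world):
        binning, genome = small_world
        seq = genome["chr1"]
        pos = next(i for i in range(1_000, 2_000) if seq[i] == "C")
        muts = pd.DataFrame({"sample": ["s1"], "chrom": ["chr1"],
                             "pos": [pos], "ref": ["A"], "alt": ["T"],
                             "vaf": [0.5]})
        with pytest.raises(ValueError, match="mismatch"):
            build_count_tensor(muts, binning, genome)
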