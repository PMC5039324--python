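"""Determinism, moment checks and planted structure of the simulators."""

import numpy as np
import pandas as pd
import pytest

from transplantx.coexpr_filter import PATTERN_RULES
from transplantx.enrichment import hypergeom_upper
from transplantx.errors import ParameterError
from transplantx.syndata import (
    ExpressionSimParams,
    SnpSimParams,
    nb_log2_residual_sd,
    sample_pool_reads,
    simulate_counts,
    simulate_go_annotations,
    simulate_pool_snps,
)


class TestDeterminism:
    def test_same_seed_bit_identical_counts(self, design14):
        p = ExpressionSimParams(n_genes=200, seed=99)
        a = simulate_counts(design14, p)
        b = simulate_counts(design14, p)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seed_differs(self, design14):
        a = simulate_counts(design14, ExpressionSimParams(n_genes=200, seed=1))
        b = simulate_counts(design14, ExpressionSimParams(n_genes=200, seed=2))
        assert not a.counts.equals(b.counts)

    def test_snp_sim_deterministic(self, design14):
        p = SnpSimParams(n_sites=300, seed=5)
        a = simulate_pool_snps(design14, p)
        b = simulate_pool_snps(design14, p)
        np.testing.assert_array_equal(a.sync.counts, b.sync.counts)


class TestExpressionSim:
    def test_class_allocation_within_one_gene(self, design14):
        p = ExpressionSimParams(
            n_genes=1001, frac_h1=0.101, frac_h2=0.25, frac_h3=0.033,
            frac_pattern=0.0101, seed=0,
        )
        sim = simulate_counts(design14, p)
        counts = sim.truth["label"].value_counts()
        for label, frac in (
            ("H1", p.frac_h1),
            ("H2", p.frac_h2),
            ("H3", p.frac_h3),
            ("pattern", p.frac_pattern),
        ):
            assert abs(counts.get(label, 0) - frac * p.n_genes) <= 1

    def test_all_null_when_fractions_zero(self, design14):
        p = ExpressionSimParams(
            n_genes=50, frac_h1=0, frac_h2=0, frac_h3=0, frac_pattern=0, seed=1
        )
        sim = simulate_counts(design14, p)
        assert (sim.truth["label"] == "null").all()
        # noise-free means identical across treatments
        assert sim.log2_means.nunique(axis=1).max() == 1

    def test_fraction_sum_above_one_rejected(self, design14):
        with pytest.raises(ParameterError):
            simulate_counts(
                design14,
                ExpressionSimParams(n_genes=10, frac_h1=0.6, frac_h2=0.6),
            )

    def test_h2_expected_mean_ratio_is_2_to_the_effect(self, design14):
        p = ExpressionSimParams(
            n_genes=400, frac_h2=0.5, effect_h2_log2fc=-0.42,
            effect_sd_log2=0.0, seed=7,
        )
        sim = simulate_counts(design14, p)
        h2 = sim.truth["label"] == "H2"
        m = sim.log2_means.loc[h2]
        ratio_native = 2.0 ** (m["1550->1550"] - m["400->400"])
        ratio_back = 2.0 ** (m["1550->400"] - m["400->400"])
        np.testing.assert_allclose(ratio_native, 2.0**-0.42, rtol=1e-12)
        np.testing.assert_allclose(ratio_back, 2.0**-0.42, rtol=1e-12)

    def test_h1_pivots_around_midpoint(self, design14):
        p = ExpressionSimParams(
            n_genes=100, frac_h1=0.5, effect_sd_log2=0.0, seed=7
        )
        sim = simulate_counts(design14, p)
        h1 = sim.truth["label"] == "H1"
        m = sim.log2_means.loc[h1]
        # elevation (mean of the two endpoints) unchanged versus 400-origin line
        np.testing.assert_allclose(
            (m["1550->1550"] + m["1550->400"]) / 2,
            (m["400->400"] + m["400->1550"]) / 2,
            rtol=1e-12,
        )
        # but the slope differs by the planted swing
        np.testing.assert_allclose(
            m["1550->1550"] - m["1550->400"], p.effect_h1_log2fc, rtol=1e-12
        )

    def test_planted_pattern_genes_satisfy_all_rules_in_expectation(self, design14):
        sim = simulate_counts(
            design14,
            ExpressionSimParams(n_genes=300, frac_pattern=0.3, seed=9),
        )
        m = sim.log2_means.loc[sim.truth["label"] == "pattern"]
        for hi, lo in PATTERN_RULES:
            assert (m[hi] > m[lo]).all()

    def test_nb_variance_matches_moment_formula(self):
        """Sample variance of NB draws ~ mu + mu^2/k (Monte Carlo, 10^4 draws)."""
        rng = np.random.default_rng(123)
        mu, k = 80.0, 12.0
        draws = rng.negative_binomial(n=k, p=k / (k + mu), size=10_000)
        expected = mu + mu**2 / k
        assert draws.var() == pytest.approx(expected, rel=0.1)
        assert draws.mean() == pytest.approx(mu, rel=0.05)

    def test_simulated_null_gene_variance(self, design14):
        # one high-count null gene re-drawn many times via many genes
        p = ExpressionSimParams(
            n_genes=10_000, baseline_log2_mean=8, baseline_log2_sd=0.0,
            nb_dispersion=10.0, frac_h1=0, frac_h2=0, frac_h3=0, frac_pattern=0,
            depth_factor_range=(1.0, 1.0), seed=3,
        )
        sim = simulate_counts(design14, p)
        col = sim.counts.iloc[:, 0].to_numpy()
        mu = 2.0**8
        assert col.var() == pytest.approx(mu + mu**2 / 10.0, rel=0.05)

    def test_depth_factors_within_range(self, design14):
        sim = simulate_counts(design14, ExpressionSimParams(n_genes=10, seed=2))
        assert ((sim.depth_factors >= 0.5) & (sim.depth_factors <= 2.0)).all()


class TestSnpSim:
    def test_delta_zero_all_null(self, design14):
        snps = simulate_pool_snps(
            design14, SnpSimParams(n_sites=100, delta_f=0.0, frac_selected=0.5, seed=1)
        )
        assert (snps.truth["label"] == "null").all()

    def test_zero_frequency_means_all_reference_reads(self, design14):
        snps = simulate_pool_snps(
            design14,
            SnpSimParams(
                n_sites=50, delta_f=0.0, base_freq_range=(0.0, 0.0), seed=2
            ),
        )
        counts = snps.sync.counts
        assert (counts[:, :, 1:] == 0).all()  # no alternate/other reads at all
        assert (counts[:, :, 0] == 50).all()  # full coverage on the reference

    def test_biallelic_by_construction(self, design14):
        snps = simulate_pool_snps(design14, SnpSimParams(n_sites=80, seed=3))
        assert (snps.sync.counts[:, :, 2:] == 0).all()
        assert (
            snps.sync.counts[:, :, :2].sum(axis=2) == 50
        ).all()  # fixed coverage per pool

    def test_selected_sites_shift_only_1550_lineage(self, design14):
        params = SnpSimParams(
            n_sites=4000, coverage=4000, delta_f=0.4, frac_selected=0.5, seed=8
        )
        snps = simulate_pool_snps(design14, params)
        sel = (snps.truth["label"] == "selected").to_numpy()
        freqs = snps.sync.counts[:, :, 1] / params.coverage
        ids = design14.sample_ids
        f400 = freqs[:, ids.index("400A")]
        f1550 = freqs[:, ids.index("1550A")]
        f1550_back = freqs[:, ids.index("1550-400A")]
        f900 = freqs[:, ids.index("900A")]
        assert np.mean(f1550[sel] - f400[sel]) == pytest.approx(0.4, abs=0.01)
        # transplants inherit their origin lineage's frequency
        assert np.mean(f1550_back[sel] - f1550[sel]) == pytest.approx(0.0, abs=0.01)
        assert np.mean(f900[sel] - f400[sel]) == pytest.approx(0.0, abs=0.01)
        assert np.mean(np.abs(f1550[~sel] - f400[~sel])) < 0.02

    def test_pool_read_frequency_variance_law(self):
        """Var of read freq = p(1-p)(1/2N + (1 - 1/2N)/C) under two-stage sampling."""
        rng = np.random.default_rng(77)
        p, N, C, n = 0.3, 50, 50, 10_000
        reads = sample_pool_reads(
            rng, np.full(n, p), np.full(n, N), C, model="individuals_then_reads"
        )
        expected = p * (1 - p) * (1 / (2 * N) + (1 - 1 / (2 * N)) / C)
        assert (reads / C).var() == pytest.approx(expected, rel=0.08)
        # read-binomial model has strictly smaller variance p(1-p)/C
        reads_fixed = sample_pool_reads(
            rng, np.full(n, p), np.full(n, N), C, model="fixed_lineage_freq"
        )
        assert (reads_fixed / C).var() == pytest.approx(p * (1 - p) / C, rel=0.08)

    def test_invalid_params_rejected(self, design14):
        with pytest.raises(ParameterError):
            simulate_pool_snps(design14, SnpSimParams(delta_f=1.5))
        with pytest.raises(ParameterError):
            simulate_pool_snps(
                design14, SnpSimParams(delta_f=0.5, base_freq_range=(0.8, 0.9))
            )
        with pytest.raises(ParameterError):
            simulate_pool_snps(design14, SnpSimParams(pool_freq_model="teleport"))


class TestGoSim:
    def test_planted_factor_one_is_background(self):
        genes = [f"g{i}" for i in range(4000)]
        gm = simulate_go_annotations(
            genes, n_terms=5, planted=("GO:X", genes[:2000], 1.0),
            background_prob=0.2, seed=4,
        )
        in_subset = np.mean([("GO:X" in gm[g]) for g in genes[:2000]])
        outside = np.mean([("GO:X" in gm[g]) for g in genes[2000:]])
        assert in_subset == pytest.approx(outside, abs=0.04)
        assert in_subset == pytest.approx(0.2, abs=0.04)

    def test_saturating_factor_fully_annotates_subset(self):
        genes = [f"g{i}" for i in range(200)]
        gm = simulate_go_annotations(
            genes, n_terms=5, planted=("GO:X", genes[:20], 20.0),
            background_prob=0.05, seed=4,
        )
        assert all("GO:X" in gm[g] for g in genes[:20])

    def test_planted_p_value_decreases_with_factor(self):
        genes = [f"g{i}" for i in range(600)]
        subset = genes[:50]
        pvals = []
        for factor in (1.0, 4.0, 12.0):
            gm = simulate_go_annotations(
                genes, n_terms=10, planted=("GO:X", subset, factor),
                background_prob=0.05, seed=11,
            )
            k = sum("GO:X" in gm[g] for g in subset)
            K = sum("GO:X" in gm[g] for g in genes)
            pvals.append(hypergeom_upper(len(genes), K, len(subset), k))
        assert pvals[0] > pvals[1] > pvals[2]

    def test_empty_universe_rejected(self):
        with pytest.raises(ParameterError):
            simulate_go_annotations([], n_terms=3)

    def test_subset_outside_universe_rejected(self):
        with pytest.raises(ParameterError):
            simulate_go_annotations(
                ["g1"], n_terms=3, planted=("GO:X", ["alien"], 2.0)
            )


def test_nb_log2_residual_sd_matches_simulation():
    rng = np.random.default_rng(55)
    mu, k = 256.0, 20.0
    draws = rng.negative_binomial(n=k, p=k / (k + mu), size=20_000)
    empirical = np.log2(draws + 1.0).std()
    assert nb_log2_residual_sd(mu, k) == pytest.approx(empirical, rel=0.05)
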