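"""Slope/elevation pair tests and hypothesis classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from transplantx.errors import (
    DesignError,
    InsufficientReplicationError,
    ParameterError,
)
from transplantx.expression_prep import normalize, size_factors
from transplantx.syndata import (
    ExpressionSimParams,
    nb_log2_residual_sd,
    simulate_counts,
)
from transplantx.transplant_ancova import (
    TransplantLine,
    ancova_pair_test,
    classify_gene,
    scan_expression,
)


def line(origin, pts):
    return TransplantLine(origin_pco2=origin, points=tuple(pts))


# the 8-point worked fixture: two replicates per destination per line
FIXTURE_A = line(400, [(400, 1.30), (400, 1.10), (1550, 2.05), (1550, 1.85)])
FIXTURE_B = line(1550, [(400, 0.95), (400, 1.25), (1550, 1.40), (1550, 1.65)])


def oracle_fit(lineA, lineB):
    """Independent normal-equations fit of the centered interaction model."""
    xa, ya = zip(*lineA.points)
    xb, yb = zip(*lineB.points)
    x = np.array(xa + xb, dtype=float)
    y = np.array(ya + yb, dtype=float)
    g = np.array([-0.5] * len(xa) + [0.5] * len(xb))
    mid = (min(x) + max(x)) / 2
    X = np.stack([np.ones_like(x), x - mid, g, g * (x - mid)], axis=1)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    df = len(y) - 4
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    t = beta / np.sqrt(np.diag(cov))
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, p


class TestPairTest:
    def test_identical_lines_give_null_contrasts(self):
        a = line(400, [(400, 1.0), (400, 1.2), (900, 2.0), (900, 2.3)])
        b = line(900, [(400, 1.0), (400, 1.2), (900, 2.0), (900, 2.3)])
        r = ancova_pair_test(a, b)
        assert r.slope_diff == pytest.approx(0.0, abs=1e-12)
        assert r.elevation_diff == pytest.approx(0.0, abs=1e-12)
        assert r.slope_p == pytest.approx(1.0)
        assert r.elevation_p == pytest.approx(1.0)
        assert not r.degenerate

    def test_swapping_lines_negates_contrasts_keeps_p(self):
        r1 = ancova_pair_test(FIXTURE_A, FIXTURE_B)
        r2 = ancova_pair_test(FIXTURE_B, FIXTURE_A)
        assert r2.slope_diff == pytest.approx(-r1.slope_diff, rel=1e-12)
        assert r2.elevation_diff == pytest.approx(-r1.elevation_diff, rel=1e-12)
        assert r2.slope_p == pytest.approx(r1.slope_p, rel=1e-12)
        assert r2.elevation_p == pytest.approx(r1.elevation_p, rel=1e-12)

    def test_worked_fixture_matches_normal_equations_oracle(self):
        beta, p = oracle_fit(FIXTURE_A, FIXTURE_B)
        r = ancova_pair_test(FIXTURE_A, FIXTURE_B)
        assert r.elevation_diff == pytest.approx(beta[2], abs=1e-10)
        assert r.slope_diff == pytest.approx(beta[3], abs=1e-10)
        assert r.elevation_p == pytest.approx(p[2], abs=1e-10)
        assert r.slope_p == pytest.approx(p[3], abs=1e-10)
        assert r.residual_df == 4

    def test_degenerate_zero_residual_variance(self):
        # noise-free, truly different elevations, equal slopes
        a = line(400, [(400, 1.0), (400, 1.0), (900, 2.0), (900, 2.0)])
        b = line(900, [(400, 3.0), (400, 3.0), (900, 4.0), (900, 4.0)])
        r = ancova_pair_test(a, b)
        assert r.degenerate
        assert r.elevation_p == 0.0  # nonzero contrast
        assert r.slope_p == 1.0  # zero contrast

    def test_insufficient_replication(self):
        a = line(400, [(400, 1.0), (900, 2.0)])
        b = line(900, [(400, 1.1), (900, 2.2)])
        with pytest.raises(InsufficientReplicationError):
            ancova_pair_test(a, b)

    def test_mismatched_covariate_levels_rejected(self):
        a = line(400, [(400, 1.0), (400, 1.1), (900, 2.0), (900, 2.1)])
        b = line(1550, [(400, 1.0), (400, 1.1), (1550, 2.0), (1550, 2.1)])
        with pytest.raises(ParameterError):
            ancova_pair_test(a, b)

    def test_covariate_affine_invariance(self):
        r1 = ancova_pair_test(FIXTURE_A, FIXTURE_B)
        scale, shift = 0.001, -5.0

        def rescale(ln):
            return line(ln.origin_pco2, [(x * scale + shift, y) for x, y in ln.points])

        r2 = ancova_pair_test(rescale(FIXTURE_A), rescale(FIXTURE_B))
        assert r2.slope_p == pytest.approx(r1.slope_p, rel=1e-9)
        assert r2.elevation_p == pytest.approx(r1.elevation_p, rel=1e-9)
        assert r2.slope_diff == pytest.approx(r1.slope_diff / scale, rel=1e-9)
        assert r2.elevation_diff == pytest.approx(r1.elevation_diff, rel=1e-9)

    def test_response_scaling_invariance_of_p(self):
        def scale_y(ln, c):
            return line(ln.origin_pco2, [(x, y * c) for x, y in ln.points])

        r1 = ancova_pair_test(FIXTURE_A, FIXTURE_B)
        r2 = ancova_pair_test(scale_y(FIXTURE_A, 7.5), scale_y(FIXTURE_B, 7.5))
        assert r2.slope_p == pytest.approx(r1.slope_p, rel=1e-9)
        assert r2.elevation_p == pytest.approx(r1.elevation_p, rel=1e-9)


def expr_series(design, values_by_treatment, noise_sd, rng):
    vals = {}
    for s in design:
        base = values_by_treatment[s.treatment]
        vals[s.sample_id] = base + rng.normal(0, noise_sd)
    return pd.Series(vals)


class TestClassifyGene:
    @pytest.mark.parametrize(
        "delta_native, delta_back, expected",
        [
            (0.0, 0.0, "none"),  # flat gene
            (3.0, -3.0, "H1"),  # slope pivots at midpoint, elevation kept
            (3.0, 3.0, "H2"),  # whole line shifted
            (6.0, 1.0, "H3"),  # both
        ],
    )
    def test_strong_effect_recovery(self, design14, delta_native, delta_back, expected):
        """Planted deviations many residual SDs strong classify deterministically."""
        rng = np.random.default_rng(0)
        base = {t: 10.0 for t in design14.treatments()}
        base[(1550, 1550)] += delta_native
        base[(1550, 400)] += delta_back
        expr = expr_series(design14, base, noise_sd=0.3, rng=rng)
        cls, diag = classify_gene(expr, design14, alpha=0.05)
        assert cls == expected
        assert diag["plasticity"].residual_df == 4

    def test_missing_treatment_raises(self, design14):
        partial = type(design14)(
            samples=[s for s in design14 if s.treatment != (1550, 400)]
        )
        expr = pd.Series({s.sample_id: 1.0 for s in partial})
        with pytest.raises(DesignError):
            classify_gene(expr, partial)


class TestScanExpression:
    def test_empty_matrix_gives_empty_table(self, design14):
        m = pd.DataFrame(columns=design14.sample_ids)
        out = scan_expression(m, design14)
        assert out.empty
        assert out.attrs["class_counts"] == {"none": 0, "H1": 0, "H2": 0, "H3": 0}

    def test_single_gene_single_row(self, design14):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(
            rng.integers(50, 150, size=(1, 14)),
            index=["g"],
            columns=design14.sample_ids,
        )
        out = scan_expression(m, design14)
        assert list(out.index) == ["g"]
        assert out.loc["g", "hypothesis"] in {"none", "H1", "H2", "H3"}

    def test_scan_agrees_with_classify_gene(self, design14):
        sim = simulate_counts(
            design14, ExpressionSimParams(n_genes=30, seed=13, frac_h2=0.5)
        )
        m = np.log2(sim.counts.astype(float) + 1)
        out = scan_expression(sim.counts.astype(float), design14, scale="log2p1")
        for g in sim.counts.index[:10]:
            cls, _ = classify_gene(m.loc[g], design14)
            assert out.loc[g, "hypothesis"] == cls

    def test_positive_scaling_keeps_p_on_raw_scale(self, design14):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            rng.uniform(10, 100, size=(20, 14)), columns=design14.sample_ids
        )
        r1 = scan_expression(m, design14, scale="raw", compute_normality=False)
        r2 = scan_expression(m * 11.0, design14, scale="raw", compute_normality=False)
        np.testing.assert_allclose(r1["high_slope_p"], r2["high_slope_p"], rtol=1e-9)
        np.testing.assert_allclose(
            r1["high_elevation_p"], r2["high_elevation_p"], rtol=1e-9
        )

    def test_recovery_on_simulated_truth(self, design14):
        """Well-separated planted genes are mostly recovered class by class."""
        sep = 3 * nb_log2_residual_sd(256, 20)
        sim = simulate_counts(
            design14,
            ExpressionSimParams(
                n_genes=900,
                baseline_log2_mean=8.0,
                baseline_log2_sd=0.0,
                nb_dispersion=20.0,
                frac_h1=0.15,
                frac_h2=0.15,
                frac_h3=0.05,
                frac_pattern=0.0,
                effect_h1_log2fc=2 * sep,
                effect_h2_log2fc=sep,
                effect_sd_log2=0.0,
                effect_sign_alternate=True,
                seed=21,
            ),
        )
        norm = normalize(sim.counts, size_factors(sim.counts))
        out = scan_expression(norm, design14, compute_normality=False)
        truth = sim.truth["label"]
        for cls in ("H1", "H2"):
            mask = truth == cls
            sens = (out.loc[mask, "hypothesis"] == cls).mean()
            assert sens > 0.6, f"{cls} sensitivity {sens}"
        # the two single-contrast classes barely cross over
        h1_as_h2 = (out.loc[truth == "H1", "hypothesis"] == "H2").mean()
        h2_as_h1 = (out.loc[truth == "H2", "hypothesis"] == "H1").mean()
        assert max(h1_as_h2, h2_as_h1) < 0.1
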