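"""Bivariate model tests: Cholesky, independent pathway, correlations."""

import numpy as np
import pytest

from conftest import make_exact_moment_pairs2
from twinsleep import bivariate as bv
from twinsleep import simulate as sim
from twinsleep import univariate as uv


def duration_midpoint_paths(rg=0.54):
    """IP-structured generator: A totals .63/.44, target genetic correlation."""
    a_tot = (0.63, 0.44)
    lam1_sq = 0.35
    lam2_sq = (rg * np.sqrt(a_tot[0] * a_tot[1])) ** 2 / lam1_sq
    common = {"a": (lam1_sq, lam2_sq)}
    specific = {
        "a": (a_tot[0] - lam1_sq, a_tot[1] - lam2_sq),
        "c": (0.07, 0.30),
        "e": (0.30, 1.0 - a_tot[1] - 0.30),
    }
    return sim.BivariatePaths.from_ip_shares(common, specific)


class TestCholesky:
    def test_order_invariance_of_likelihood(self):
        paths = duration_midpoint_paths()
        cfg = sim.SimConfig(n_mz_pairs=1000, n_dz_pairs=1000, n_singletons=0,
                            seed=51, bivariate_paths=paths)
        pairs2 = sim.simulate_bivariate_cholesky(cfg)
        f12 = bv.fit_cholesky(pairs2, (1, 2))
        f21 = bv.fit_cholesky(pairs2, (2, 1))
        assert f12.fit.minus2LL == pytest.approx(f21.fit.minus2LL, abs=1e-6)

    def test_zero_cross_path_data_gives_null_correlations(self):
        paths = sim.BivariatePaths.from_ip_shares(
            common={}, specific={"a": (0.6, 0.5), "c": (0.1, 0.2),
                                 "e": (0.3, 0.3)})
        cfg = sim.SimConfig(n_mz_pairs=4000, n_dz_pairs=4000, n_singletons=0,
                            seed=52, bivariate_paths=paths)
        pairs2 = sim.simulate_bivariate_cholesky(cfg)
        fit = bv.fit_cholesky(pairs2)
        assert abs(fit.decomposition.rP) < 0.05
        assert abs(fit.decomposition.rG) < 0.15

    def test_genetic_correlation_recovery(self):
        """rG = .54 between duration- and midpoint-like traits is recovered."""
        paths = duration_midpoint_paths(rg=0.54)
        cfg = sim.SimConfig(n_mz_pairs=5000, n_dz_pairs=5000, n_singletons=0,
                            seed=53, bivariate_paths=paths)
        pairs2 = sim.simulate_bivariate_cholesky(cfg)
        fit = bv.fit_cholesky(pairs2)
        assert fit.decomposition.rG == pytest.approx(0.54, abs=0.05)
        # h2 checked at ~3 SD of the sampling error of 2(rMZ - rDZ)
        assert fit.decomposition.h2[0] == pytest.approx(0.63, abs=0.09)
        assert fit.decomposition.h2[1] == pytest.approx(0.44, abs=0.09)

    def test_population_moment_fit_reproduces_analytic_structure(self):
        """Just-identified Cholesky hits exact moments: rG to 1e-6."""
        paths = sim.BivariatePaths.from_ip_shares(
            common={"a": (0.35, 0.18)},
            specific={"a": (0.28, 0.26), "c": (0.07, 0.30), "e": (0.30, 0.26)},
        )
        pairs2 = make_exact_moment_pairs2(paths, n_mz=400, n_dz=400, seed=54)
        fit = bv.fit_cholesky(pairs2, n_restarts=1)
        analytic = bv.correlation_decomposition(
            {s: paths.source_cov(s) for s in ("a", "c", "e")})
        got = bv.correlation_decomposition(fit)
        assert got.rG == pytest.approx(analytic.rG, abs=1e-6)
        assert got.rP == pytest.approx(analytic.rP, abs=1e-6)
        # shared-genetic proportions: common-A shares over each trait's h2
        assert bv.shared_proportion(0.35, fit.decomposition.h2[0]) == 56
        assert bv.shared_proportion(0.18, fit.decomposition.h2[1]) == 41

    def test_dropping_zero_source_leaves_likelihood_unchanged(self):
        """No shared environment in truth: dropping C moves -2lnL < 1e-6."""
        paths = sim.BivariatePaths.from_ip_shares(
            common={"a": (0.3, 0.25)},
            specific={"a": (0.3, 0.25), "e": (0.4, 0.5)})
        pairs2 = make_exact_moment_pairs2(paths, n_mz=300, n_dz=300, seed=55)
        full = bv.fit_cholesky(pairs2, n_restarts=1)
        reduced = bv.fit_cholesky(pairs2, n_restarts=1, drop=("c",))
        assert reduced.fit.minus2LL == pytest.approx(full.fit.minus2LL,
                                                     abs=1e-6)
        assert reduced.fit.n_params == full.fit.n_params - 3

    def test_invalid_order_and_drop_rejected(self):
        paths = duration_midpoint_paths()
        pairs2 = make_exact_moment_pairs2(paths, n_mz=50, n_dz=50)
        with pytest.raises(ValueError):
            bv.fit_cholesky(pairs2, order=(1, 3))
        with pytest.raises(ValueError):
            bv.fit_cholesky(pairs2, drop=("e",))


class TestIndependentPathway:
    def test_self_consistency_recovery(self):
        """Equal-loadings IP generator is recovered by the constrained fit."""
        lam2 = 0.25
        paths = sim.BivariatePaths.from_ip_shares(
            common={"a": (lam2, lam2), "e": (0.05, 0.05)},
            specific={"a": (0.30, 0.20), "c": (0.10, 0.15),
                      "e": (0.30, 0.35)})
        cfg = sim.SimConfig(n_mz_pairs=5000, n_dz_pairs=5000, n_singletons=0,
                            seed=56, bivariate_paths=paths)
        pairs2 = sim.simulate_bivariate_cholesky(cfg)
        fit = bv.fit_independent_pathway(pairs2)
        assert fit.decomposition.common["a"][0] == pytest.approx(lam2, abs=0.04)
        assert fit.decomposition.specific["a"][0] == pytest.approx(0.30, abs=0.05)
        assert fit.decomposition.specific["c"][1] == pytest.approx(0.15, abs=0.05)

    def test_common_a_only_generator_recovers_null_components(self):
        paths = sim.BivariatePaths.from_ip_shares(
            common={"a": (0.5, 0.5)},
            specific={"e": (0.5, 0.5)})
        cfg = sim.SimConfig(n_mz_pairs=3000, n_dz_pairs=3000, n_singletons=0,
                            seed=57, bivariate_paths=paths)
        pairs2 = sim.simulate_bivariate_cholesky(cfg)
        fit = bv.fit_independent_pathway(pairs2)
        assert fit.decomposition.specific["a"][0] == pytest.approx(0.0, abs=0.05)
        assert fit.decomposition.common["c"][0] == pytest.approx(0.0, abs=0.05)

    def test_underidentified_constraints_rejected_before_fitting(self):
        paths = duration_midpoint_paths()
        pairs2 = make_exact_moment_pairs2(paths, n_mz=50, n_dz=50)
        with pytest.raises(ValueError, match="9"):
            bv.fit_independent_pathway(pairs2, constraints=("a", "c"))
        with pytest.raises(ValueError):
            bv.fit_independent_pathway(pairs2, constraints=("x",))

    def test_likelihood_ordering_saturated_cholesky_ip(self):
        """Saturated <= Cholesky <= constrained IP in -2lnL."""
        paths = duration_midpoint_paths()
        cfg = sim.SimConfig(n_mz_pairs=300, n_dz_pairs=300, n_singletons=40,
                            seed=58, bivariate_paths=paths)
        pairs2 = sim.simulate_bivariate_cholesky(cfg)
        sat = bv.fit_saturated_bivariate(pairs2)
        chol = bv.fit_cholesky(pairs2)
        ip = bv.fit_independent_pathway(pairs2)
        assert sat.minus2LL <= chol.fit.minus2LL + 1e-6
        assert chol.fit.minus2LL <= ip.fit.minus2LL + 1e-6

    def test_flip_trait_reverses_correlation_signs(self):
        paths = duration_midpoint_paths()
        pairs2 = make_exact_moment_pairs2(paths, n_mz=400, n_dz=400, seed=59)
        base = bv.fit_cholesky(pairs2, n_restarts=1)
        flipped = bv.fit_cholesky(bv.flip_trait(pairs2), n_restarts=1)
        assert flipped.decomposition.rG == pytest.approx(
            -base.decomposition.rG, abs=1e-5)
        assert flipped.decomposition.rP == pytest.approx(
            -base.decomposition.rP, abs=1e-5)


class TestCorrelationDecomposition:
    def test_contributions_sum_to_phenotypic_correlation(self):
        paths = duration_midpoint_paths()
        covs = {s: paths.source_cov(s) for s in ("a", "c", "e")}
        d = bv.correlation_decomposition(covs)
        assert sum(d.contributions.values()) == pytest.approx(d.rP, abs=1e-8)

    def test_single_source_overlap_identity(self):
        """Only A overlaps: rP = rG * sqrt(h2_1 h2_2)."""
        paths = duration_midpoint_paths()
        covs = {s: paths.source_cov(s) for s in ("a", "c", "e")}
        d = bv.correlation_decomposition(covs)
        h2 = (covs["a"][0, 0], covs["a"][1, 1])
        assert d.rP == pytest.approx(d.rG * np.sqrt(h2[0] * h2[1]), abs=1e-10)
        assert d.rC == 0.0 or np.isnan(d.rC) or abs(d.rC) < 1e-10

    def test_zero_variance_source_reports_nan(self):
        covs = {"a": np.diag([0.5, 0.5]), "c": np.zeros((2, 2)),
                "e": np.diag([0.5, 0.5])}
        d = bv.correlation_decomposition(covs)
        assert np.isnan(d.rC)
        assert d.rP == 0.0

    def test_all_zero_cross_paths(self):
        covs = {"a": np.diag([0.6, 0.5]), "c": np.diag([0.1, 0.2]),
                "e": np.diag([0.3, 0.3])}
        d = bv.correlation_decomposition(covs)
        assert (d.rP, d.rG, d.rC, d.rE) == (0.0, 0.0, 0.0, 0.0)


class TestSharedProportion:
    @pytest.mark.parametrize("common, total, expected", [
        (0.35, 0.63, 56), (0.18, 0.44, 41), (0.27, 0.27, 100),
    ])
    def test_printed_arithmetic(self, common, total, expected):
        assert bv.shared_proportion(common, total) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bv.shared_proportion(0.5, 0.0)
        with pytest.raises(ValueError):
            bv.shared_proportion(0.7, 0.6)


class TestConsistencyWithUnivariate:
    def test_per_trait_shares_match_univariate_ace(self):
        """Bivariate per-trait h2 agrees with the univariate fit on trait x."""
        paths = duration_midpoint_paths()
        cfg = sim.SimConfig(n_mz_pairs=2000, n_dz_pairs=2000, n_singletons=0,
                            seed=60, bivariate_paths=paths)
        pairs2 = sim.simulate_bivariate_cholesky(cfg)
        chol = bv.fit_cholesky(pairs2)
        pairs_x = pairs2[["family_id", "zygosity", "x_1", "x_2"]].rename(
            columns={"x_1": "y_1", "x_2": "y_2"})
        uni = uv.fit_ace_family(pairs_x, "ACE")
        assert chol.decomposition.h2[0] == pytest.approx(
            uni.components.a2, abs=0.03)
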