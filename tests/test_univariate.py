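"""ACE-family ML tests: oracle equivalence, model comparison, profile CIs."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_exact_moment_pairs
from twinsleep import simulate as sim
from twinsleep import univariate as uv


class TestFalconer:
    @pytest.mark.parametrize("rmz, rdz, expected", [
        (0.70, 0.39, (0.62, 0.08, 0.30)),   # sleep duration correlations
        (0.87, 0.65, (0.44, 0.43, 0.13)),   # sleep midpoint correlations
        (0.5, 0.25, (0.5, 0.0, 0.5)),
    ])
    def test_closed_form(self, rmz, rdz, expected):
        got = uv.falconer(rmz, rdz)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_negative_components_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            a2, c2, e2 = uv.falconer(0.49, 0.03)  # restorative-like: c2 < 0
        assert c2 == 0.0
        assert a2 == pytest.approx(0.92)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            uv.falconer(1.2, 0.5)


class TestSaturated:
    def test_ml_correlations_recover_generating_values(self):
        """Midpoint-like structure rMZ=.87, rDZ=.65 at 5k pairs per group."""
        cfg = sim.SimConfig(n_mz_pairs=5000, n_dz_pairs=5000, n_singletons=0,
                            seed=31, a2=0.44, c2=0.43, e2=0.13)
        pairs = sim.simulate_ace_pairs(cfg)
        fit = uv.fit_saturated(pairs)
        assert fit.correlations["MZ"] == pytest.approx(0.87, abs=0.02)
        assert fit.correlations["DZ"] == pytest.approx(0.65, abs=0.02)

    def test_identical_mz_twins_give_unit_correlation(self):
        rng = np.random.default_rng(32)
        y = rng.normal(size=60)
        pairs = pd.DataFrame({
            "family_id": [f"F{i}" for i in range(120)],
            "zygosity": ["MZ"] * 60 + ["DZ"] * 60,
            "y_1": np.r_[y, rng.normal(size=60)],
            "y_2": np.r_[y, rng.normal(size=60)],
        })
        fit = uv.fit_saturated(pairs)
        assert fit.correlations["MZ"] >= 0.99

    def test_ml_matches_product_moment_on_complete_pairs(self):
        """With equated means/variances, ML tracks the Pearson correlation."""
        cfg = sim.SimConfig(n_mz_pairs=500, n_dz_pairs=500, n_singletons=0,
                            seed=33)
        pairs = sim.simulate_ace_pairs(cfg)
        fit = uv.fit_saturated(
            pairs, uv.EquateFlags(order_means=True, order_vars=True))
        for zyg in ("MZ", "DZ"):
            sub = pairs[pairs.zygosity == zyg]
            pearson = np.corrcoef(sub.y_1, sub.y_2)[0, 1]
            assert fit.correlations[zyg] == pytest.approx(pearson, abs=0.01)

    def test_constraint_tests_report_nonsignificance_on_symmetric_data(self):
        cfg = sim.SimConfig(n_mz_pairs=300, n_dz_pairs=300, n_singletons=0,
                            seed=34)
        pairs = sim.simulate_ace_pairs(cfg)
        fit = uv.fit_saturated(pairs, test_constraints=True)
        assert set(fit.constraint_tests) == {
            "order_means", "order_vars", "zyg_means", "zyg_vars"}
        for t in fit.constraint_tests.values():
            assert t["p"] > 0.001  # data generated symmetric


class TestAceFamily:
    def test_population_moment_fit_matches_falconer_oracle(self):
        """On exact-moment data the ML fit equals the closed form to 1e-6."""
        pairs = make_exact_moment_pairs(0.70, 0.39, seed=35)
        fit = uv.fit_ace_family(pairs, "ACE")
        assert fit.components.a2 == pytest.approx(0.62, abs=1e-6)
        assert fit.components.c2 == pytest.approx(0.08, abs=1e-6)
        assert fit.components.e2 == pytest.approx(0.30, abs=1e-6)

    def test_equal_twin_correlations_zero_out_genetics(self):
        pairs = make_exact_moment_pairs(0.40, 0.40, seed=36)
        fit = uv.fit_ace_family(pairs, "ACE")
        assert fit.components.a2 == pytest.approx(0.0, abs=1e-5)

    def test_ae_recovery_at_paper_sample_size(self):
        """Restorative-sleep AE(0.43) recovered on average at 93+117 pairs."""
        vals = []
        for k in range(60):
            cfg = sim.SimConfig(n_mz_pairs=93, n_dz_pairs=117, n_singletons=0,
                                seed=3000 + k, a2=0.43, c2=0.0, e2=0.57)
            pairs = sim.simulate_ace_pairs(cfg)
            vals.append(uv.fit_ace_family(pairs, "AE",
                                          n_restarts=2).components.a2)
        assert np.mean(vals) == pytest.approx(0.43, abs=0.05)

    def test_likelihood_monotonicity_across_nested_models(self):
        cfg = sim.SimConfig(n_mz_pairs=200, n_dz_pairs=200, n_singletons=30,
                            seed=37)
        pairs = sim.simulate_ace_pairs(cfg)
        lls = {m: uv.fit_ace_family(pairs, m).fit.minus2LL
               for m in ("ACE", "AE", "CE", "E")}
        assert lls["ACE"] <= lls["AE"] + 1e-6
        assert lls["ACE"] <= lls["CE"] + 1e-6
        assert lls["AE"] <= lls["E"] + 1e-6
        assert lls["CE"] <= lls["E"] + 1e-6

    def test_estimates_invariant_to_pair_order_and_shuffling(self):
        cfg = sim.SimConfig(n_mz_pairs=150, n_dz_pairs=150, n_singletons=0,
                            seed=38)
        pairs = sim.simulate_ace_pairs(cfg)
        base = uv.fit_ace_family(pairs, "ACE")
        swapped = pairs.rename(columns={"y_1": "y_2", "y_2": "y_1"})
        shuffled = pairs.sample(frac=1.0, random_state=1)
        for variant in (swapped, shuffled):
            fit = uv.fit_ace_family(variant, "ACE")
            assert fit.components.a2 == pytest.approx(base.components.a2,
                                                      abs=1e-5)
            assert fit.fit.minus2LL == pytest.approx(base.fit.minus2LL,
                                                     abs=1e-6)

    def test_parameter_recovery_bias_small_at_scale(self):
        """|bias of a2-hat| < 0.03 at 1000+1000 pairs for a2 in {.2,.5,.8}."""
        for a2 in (0.2, 0.5, 0.8):
            c2 = min(0.15, (1 - a2) / 2)
            vals = []
            for k in range(200):
                cfg = sim.SimConfig(
                    n_mz_pairs=1000, n_dz_pairs=1000, n_singletons=0,
                    seed=10_000 + k, a2=a2, c2=c2, e2=1 - a2 - c2)
                pairs = sim.simulate_ace_pairs(cfg)
                vals.append(uv.fit_ace_family(pairs, "ACE",
                                              n_restarts=1).components.a2)
            assert abs(np.mean(vals) - a2) < 0.03

    def test_unknown_model_rejected(self):
        pairs = make_exact_moment_pairs(0.7, 0.4, n_mz=10, n_dz=10)
        with pytest.raises(ValueError):
            uv.fit_ace_family(pairs, "ADE")


class TestCompareModels:
    def test_ae_preferred_when_c_is_zero(self):
        """With no shared environment, AIC picks AE over ACE most of the time."""
        wins = 0
        for k in range(20):
            cfg = sim.SimConfig(n_mz_pairs=500, n_dz_pairs=500, n_singletons=0,
                                seed=4000 + k, a2=0.5, c2=0.0, e2=0.5)
            pairs = sim.simulate_ace_pairs(cfg)
            fits = [uv.fit_ace_family(pairs, m, n_restarts=2)
                    for m in ("ACE", "AE")]
            _, best = uv.compare_models(fits)
            wins += best == "AE"
        assert wins > 10

    def test_e_only_ranked_last_on_familial_data(self):
        pairs = make_exact_moment_pairs(0.7, 0.4, seed=39)
        fits = [uv.fit_ace_family(pairs, m) for m in ("ACE", "AE", "CE", "E")]
        table, _ = uv.compare_models(fits)
        assert table.model.iloc[-1] == "E"

    def test_mixed_datasets_rejected(self):
        f1 = uv.fit_ace_family(make_exact_moment_pairs(0.7, 0.4, seed=1), "AE")
        f2 = uv.fit_ace_family(make_exact_moment_pairs(0.7, 0.4, seed=2), "CE")
        with pytest.raises(ValueError, match="different"):
            uv.compare_models([f1, f2])

    def test_tie_breaks_by_fewer_parameters(self):
        pairs = make_exact_moment_pairs(0.5, 0.25, seed=40)  # c2 exactly 0
        ace = uv.fit_ace_family(pairs, "ACE")
        ae = uv.fit_ace_family(pairs, "AE")
        table, best = uv.compare_models([ace, ae])
        assert best == "AE"  # same likelihood, one fewer parameter


class TestProfileCI:
    def test_bounds_respect_parameter_limits(self):
        pairs = make_exact_moment_pairs(0.7, 0.4, n_mz=150, n_dz=150, seed=41)
        fit = uv.fit_ace_family(pairs, "ACE")
        for comp in ("a2", "c2", "e2"):
            lo, hi = uv.profile_ci(fit, comp)
            assert 0.0 <= lo <= getattr(fit.components, comp) <= hi <= 1.0

    def test_interval_narrows_with_sample_size(self):
        widths = []
        for n in (100, 1000):
            pairs = make_exact_moment_pairs(0.7, 0.4, n_mz=n, n_dz=n, seed=42)
            fit = uv.fit_ace_family(pairs, "ACE")
            lo, hi = uv.profile_ci(fit, "a2")
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_deviance_zero_at_estimate(self):
        pairs = make_exact_moment_pairs(0.7, 0.4, n_mz=200, n_dz=200, seed=43)
        fit = uv.fit_ace_family(pairs, "ACE")
        assert uv.profile_deviance(fit, "a2", fit.components.a2) < 1e-6

    def test_component_absent_from_model_rejected(self):
        pairs = make_exact_moment_pairs(0.7, 0.4, n_mz=100, n_dz=100, seed=44)
        fit = uv.fit_ace_family(pairs, "AE")
        with pytest.raises(ValueError):
            uv.profile_ci(fit, "c2")


class TestContainers:
    def test_variance_components_validated(self):
        with pytest.raises(ValueError):
            uv.VarianceComponents(0.7, 0.4, 0.2)
        vc = uv.VarianceComponents(0.62, 0.08, 0.30)
        assert vc.h2 == 0.62

    def test_aic_identity(self):
        mf = uv.ModelFit("ACE", 100.0, 4, True)
        assert mf.aic == 108.0
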