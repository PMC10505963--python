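"""One-way sensitivity, threshold search, and the probabilistic analysis."""

import logging

import numpy as np
import pandas as pd
import pytest

from psmcea import (PartitionedSurvivalCEA, ParamSpec, default_param_specs,
                    set_parameter, one_way, threshold_search, run_psa,
                    run_cea, NoThresholdError, SERP, CHEMO)


class TestParamSpec:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            ParamSpec("x", "x", 1.0, 2.0, 3.0, "gamma")

    def test_beta_support_enforced(self):
        with pytest.raises(ValueError):
            ParamSpec("u", "u", 0.5, 0.1, 1.5, "beta")

    def test_default_set_covers_published_rows(self, base_config):
        specs = default_param_specs(base_config)
        names = {s.name for s in specs}
        assert "costs.serplulimab_per_mg" in names
        assert "hr.os" in names and "hr.pfs" in names
        assert all(s.low <= s.base <= s.high for s in specs)


class TestSetParameter:
    def test_deep_copy_leaves_original_untouched(self, base_config):
        out = set_parameter(base_config, "costs.serplulimab_per_mg", 1.0)
        assert out.costs.serplulimab_per_mg == 1.0
        assert base_config.costs.serplulimab_per_mg == 8.32

    def test_hazard_ratio_rebuilds_comparator(self, base_config):
        cfg = set_parameter(base_config, "hr.os", 1.0)
        t = np.linspace(0, 300, 20)
        np.testing.assert_allclose(cfg.os_model[CHEMO].survival(t),
                                   cfg.os_model[SERP].survival(t))

    def test_unknown_parameter_named_in_error(self, base_config):
        with pytest.raises(KeyError, match="discout"):
            set_parameter(base_config, "costs.discout", 1.0)


class TestOneWay:
    def test_degenerate_range_gives_zero_width_bar(self, base_config):
        spec = ParamSpec("costs.terminal_care_per_patient", "terminal",
                         2596.0, 2596.0, 2596.0, "gamma")
        df = one_way(base_config, [spec])
        assert df.loc[0, "range"] == pytest.approx(0.0, abs=1e-9)

    def test_icer_increasing_in_serplulimab_price(self, base_config):
        icers = [run_cea(set_parameter(base_config,
                                       "costs.serplulimab_per_mg", v)
                         ).icer_per_qaly for v in (6.65, 8.32, 9.98)]
        assert icers[0] < icers[1] < icers[2]

    def test_top_drivers_include_weight_and_price(self, base_config):
        """Serplulimab price and body weight dominate the tornado."""
        df = PartitionedSurvivalCEA(base_config).one_way()
        top = set(df["parameter"].head(3))
        assert "body.weight_kg" in top
        assert "costs.serplulimab_per_mg" in top


class TestThresholdSearch:
    def test_solution_substitutes_back(self, base_config):
        wtp = 86_569.0
        price = threshold_search(base_config, "costs.serplulimab_per_mg", wtp)
        icer = run_cea(set_parameter(base_config, "costs.serplulimab_per_mg",
                                     price)).icer_per_qaly
        assert abs(icer - wtp) / wtp < 1e-4

    def test_no_sign_change_signalled(self, base_config):
        # ICER over a bracket of very low prices stays below a huge WTP
        with pytest.raises(NoThresholdError):
            threshold_search(base_config, "costs.serplulimab_per_mg",
                             1e9, bracket=(0.01, 8.32))


class TestPSA:
    def test_degenerate_distributions_reproduce_base(self, base_config):
        base = run_cea(base_config)
        specs = [ParamSpec("costs.serplulimab_per_mg", "p", 8.32, 8.32, 8.32,
                           "gamma"),
                 ParamSpec("utilities.pfs", "u", 0.673, 0.673, 0.673, "beta")]
        psa = run_psa(base_config, specs, n_iter=5, seed=0)
        np.testing.assert_allclose(psa.draws["delta_cost"], base.delta_cost)
        np.testing.assert_allclose(psa.draws["delta_qalys"], base.delta_qalys)

    def test_seed_reproducibility_bit_exact(self, base_config):
        specs = default_param_specs(base_config)
        a = run_psa(base_config, specs, n_iter=40, seed=123)
        b = run_psa(base_config, specs, n_iter=40, seed=123)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_draw_means_converge_to_base(self, base_config):
        """Sampled parameter means land within 3 SE-of-mean of base values."""
        specs = [s for s in default_param_specs(base_config) if s.in_psa]
        psa = run_psa(base_config, specs, n_iter=2000, seed=7)
        for s in specs:
            if s.dist == "lognormal":     # mean exceeds median; check median
                centre = float(np.median(psa.draws[s.name]))
                assert abs(centre - s.base) / s.base < 0.05
            else:
                tol = 3.0 * s.se / np.sqrt(2000) + 1e-12
                assert abs(psa.draws[s.name].mean() - s.base) < tol + \
                    0.02 * s.se   # small allowance for gamma/beta skew

    def test_ceac_monotone_and_anchored(self, base_config):
        specs = default_param_specs(base_config)
        psa = run_psa(base_config, specs, n_iter=300, seed=5,
                      lambda_grid=np.arange(0.0, 150_001.0, 5000.0))
        curve = psa.ceac()
        assert np.all(np.diff(curve["probability"]) >= 0)
        frac_saving = float((psa.draws["delta_cost"] < 0).mean())
        assert curve["probability"].iloc[0] == pytest.approx(frac_saving)

    def test_body_metrics_fixed_in_psa(self, base_config):
        psa = run_psa(base_config, default_param_specs(base_config),
                      n_iter=10, seed=3)
        assert "body.weight_kg" not in psa.draws.columns

    def test_beta_fallback_to_logit_normal(self, base_config, caplog):
        # moment-matching infeasible: variance >= m(1-m)
        spec = ParamSpec("utilities.pd", "u", 0.05, 0.0, 1.0, "beta")
        with caplog.at_level(logging.WARNING, logger="psmcea.sensitivity"):
            psa = run_psa(base_config, [spec], n_iter=50, seed=2)
        draws = psa.draws["utilities.pd"]
        assert ((draws > 0) & (draws < 1)).all()
        assert any("logit-normal" in r.message for r in caplog.records)
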