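"""Guyot-style pseudo-IPD reconstruction and the product-limit estimator."""

import numpy as np
import pytest

from psmcea import (DigitizedKM, PseudoIPD, reconstruct_ipd, km_estimator,
                    ReconstructionError, ParametricSurvival, SimulationSpec,
                    simulate_ipd, emit_digitized_km)
from psmcea.reconstruct import km_survival_at


class TestKMEstimator:
    def test_three_events_by_hand(self):
        ipd = PseudoIPD([1.0, 2.0, 3.0], [1, 1, 1])
        t, s = km_estimator(ipd)
        assert s[t == 1.0][0] == pytest.approx(2 / 3)
        assert s[t == 2.0][0] == pytest.approx(1 / 3)
        assert s[t == 3.0][0] == pytest.approx(0.0)

    def test_censoring_by_hand(self):
        ipd = PseudoIPD([1.0, 2.0], [1, 0])
        assert km_survival_at(ipd, [1.0, 1.5, 2.0]) == pytest.approx(
            [0.5, 0.5, 0.5])

    def test_km_median_near_half_for_large_exponential_sample(self):
        model = ParametricSurvival("exponential", (0.02,))
        ipd = simulate_ipd(SimulationSpec(model, n=500,
                                          admin_cutoff_weeks=1e6, seed=11))
        s_med = km_survival_at(ipd, [model.median()])[0]
        assert abs(s_med - 0.5) < 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            PseudoIPD([], [])


class TestReconstruction:
    def test_pure_event_curve(self):
        """Steps of 0.1 with no implied censoring give 10 event records."""
        km = DigitizedKM(times=np.arange(1.0, 11.0),
                         survival=np.round(1.0 - np.arange(1, 11) * 0.1, 10),
                         risk_times=[0.0], n_at_risk=[10])
        ipd = reconstruct_ipd(km)
        assert len(ipd) == 10
        assert ipd.n_events == 10
        np.testing.assert_allclose(np.sort(ipd.time), np.arange(1.0, 11.0))

    def test_flat_curve_is_all_censoring(self):
        km = DigitizedKM(times=np.arange(0.0, 50.0, 5.0),
                         survival=np.ones(10),
                         risk_times=[0.0, 20.0, 40.0],
                         n_at_risk=[30, 20, 10])
        ipd = reconstruct_ipd(km)
        assert len(ipd) == 30
        assert ipd.n_events == 0

    def test_record_count_matches_initial_risk_set(self):
        model = ParametricSurvival("weibull", (1.3, 0.02))
        ipd0 = simulate_ipd(SimulationSpec(model, n=150,
                                           admin_cutoff_weeks=120.0,
                                           random_censor_rate=0.004, seed=2))
        km = emit_digitized_km(ipd0, np.arange(0.0, 121.0, 13.0), seed=2)
        assert len(reconstruct_ipd(km)) == km.n_at_risk[0]

    @pytest.mark.parametrize("seed", [3, 4])
    def test_roundtrip_sup_norm(self, seed):
        """simulate -> digitize -> reconstruct tracks the original KM."""
        model = ParametricSurvival("weibull", (1.3, 0.02))
        ipd0 = simulate_ipd(SimulationSpec(model, n=200,
                                           admin_cutoff_weeks=120.0,
                                           random_censor_rate=0.004,
                                           seed=seed))
        km = emit_digitized_km(ipd0, np.arange(0.0, 121.0, 13.0), seed=seed)
        rec = reconstruct_ipd(km)
        grid = np.arange(0.0, 120.0, 1.0)
        err = np.max(np.abs(km_survival_at(rec, grid)
                            - km_survival_at(ipd0, grid)))
        assert err < 0.02

    def test_deterministic(self):
        model = ParametricSurvival("loglogistic", (2.0, 0.03))
        ipd0 = simulate_ipd(SimulationSpec(model, n=100,
                                           admin_cutoff_weeks=100.0, seed=9))
        km = emit_digitized_km(ipd0, [0.0, 50.0, 100.0], seed=9)
        a, b = reconstruct_ipd(km), reconstruct_ipd(km)
        np.testing.assert_array_equal(a.time, b.time)
        np.testing.assert_array_equal(a.event, b.event)

    def test_rising_risk_table_rejected(self):
        with pytest.raises(ReconstructionError):
            DigitizedKM(times=[0.0, 10.0], survival=[1.0, 0.9],
                        risk_times=[0.0, 10.0], n_at_risk=[10, 12])

    def test_infeasible_event_count_rejected(self):
        # curve implies ~9 events among 10 but 8 still at risk afterwards
        km = DigitizedKM(times=[0.0, 2.0, 4.0, 6.0],
                         survival=[1.0, 0.5, 0.2, 0.1],
                         risk_times=[0.0, 6.0], n_at_risk=[10, 8])
        with pytest.raises(ReconstructionError, match="interval"):
            reconstruct_ipd(km)

    def test_monotone_repair_of_jittered_input(self):
        km = DigitizedKM(times=[0.0, 1.0, 2.0, 3.0],
                         survival=[1.0, 0.8, 0.82, 0.6],
                         risk_times=[0.0], n_at_risk=[50])
        repaired = km.monotone()
        assert np.all(np.diff(repaired.survival) <= 0)


def test_csv_roundtrip(tmp_path):
    km = DigitizedKM(times=[0.0, 5.0, 10.0], survival=[1.0, 0.7, 0.4],
                     risk_times=[0.0, 10.0], n_at_risk=[20, 8])
    km.to_csv(tmp_path / "curve.csv", tmp_path / "risk.csv")
    back = DigitizedKM.from_csv(tmp_path / "curve.csv", tmp_path / "risk.csv")
    np.testing.assert_allclose(back.times, km.times)
    np.testing.assert_allclose(back.survival, km.survival)
    np.testing.assert_array_equal(back.n_at_risk, km.n_at_risk)
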