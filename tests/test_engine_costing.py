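"""Partitioned-survival engine and cost accumulation."""

import dataclasses

import numpy as np
import pytest

from psmcea import (ParametricSurvival, SERP, CHEMO, ARMS, run_trace,
                    arm_effectiveness, arm_costs, dose_serplulimab,
                    dose_carboplatin, dose_etoposide)
from psmcea.config import CostInputs
from psmcea.costing import COST_COMPONENTS


def _flat_config(base_config, horizon=52, discount=0.0):
    """Static cohort: nobody progresses or dies."""
    flat = ParametricSurvival("exponential", (0.0,))
    return base_config.replace(
        os_model={a: flat for a in ARMS}, pfs_model={a: flat for a in ARMS},
        horizon_weeks=horizon, annual_discount=discount)


class TestTrace:
    @pytest.mark.parametrize("arm", ARMS)
    def test_occupancy_conservation_and_monotone_death(self, base_config, arm):
        tr = run_trace(arm, base_config)
        total = tr.occ_pfs + tr.occ_pd + tr.occ_dead
        assert np.max(np.abs(total - 1.0)) < 1e-12
        assert np.all(tr.occ_pd >= 0.0)
        assert np.all(np.diff(tr.occ_dead) >= -1e-15)
        assert np.all(tr.deaths >= -1e-15)

    def test_identical_curves_leave_no_progressed_state(self, base_config):
        cfg = base_config.replace(pfs_model=dict(base_config.os_model))
        tr = run_trace(SERP, cfg)
        assert np.max(np.abs(tr.occ_pd)) == 0.0

    def test_static_cohort_one_year(self, base_config):
        cfg = _flat_config(base_config)
        tr = run_trace(SERP, cfg)
        eff = arm_effectiveness(tr, cfg)
        assert eff["life_years"] == pytest.approx(1.0, rel=1e-12)
        assert eff["qalys"] == pytest.approx(0.673, rel=1e-12)

    def test_pfs_crossing_os_is_clamped(self, base_config):
        # swap curves so nominal PFS lies above OS everywhere
        cfg = base_config.replace(os_model=dict(base_config.pfs_model),
                                  pfs_model=dict(base_config.os_model))
        tr = run_trace(SERP, cfg)
        assert tr.n_clamped > 0
        assert np.all(tr.occ_pd == 0.0)
        assert np.max(np.abs(tr.occ_pfs + tr.occ_dead - 1.0)) < 1e-12

    def test_trace_frame_export(self, base_config):
        df = run_trace(CHEMO, base_config).to_frame()
        assert list(df.columns[:5]) == ["cycle", "time_weeks", "occ_pfs",
                                        "occ_pd", "occ_dead"]
        assert len(df) == base_config.horizon_weeks + 1

    def test_ten_year_horizon_captures_mortality(self, base_config):
        """The comparator exceeds 98% cumulative mortality; the treatment
        arm's published log-logistic tail leaves ~3.5% alive at 10 years."""
        assert run_trace(CHEMO, base_config).occ_dead[-1] > 0.98
        assert run_trace(SERP, base_config).occ_dead[-1] > 0.95


class TestEffectiveness:
    def test_unit_utilities_make_qalys_equal_life_years(self, base_config):
        u = base_config.utilities
        u.pfs = u.pd = 1.0
        u.apply_ae_disutility = False
        for arm in ARMS:
            tr = run_trace(arm, base_config)
            eff = arm_effectiveness(tr, base_config)
            assert eff["qalys"] == pytest.approx(eff["disc_life_years"],
                                                 abs=1e-12)

    def test_ae_disutility_switch(self, base_config):
        tr = run_trace(SERP, base_config)
        off = arm_effectiveness(tr, base_config)["qalys"]
        base_config.utilities.apply_ae_disutility = True
        on = arm_effectiveness(tr, base_config)["qalys"]
        assert off - on == pytest.approx(0.050, abs=1e-12)

    def test_half_cycle_grid_refinement_stable(self, base_config):
        def qalys(cycle):
            cfg = base_config.replace(cycle_weeks=cycle)
            return arm_effectiveness(run_trace(SERP, cfg), cfg)["qalys"]
        q1, q05 = qalys(1.0), qalys(0.5)
        assert abs(q05 - q1) / q1 < 0.005


class TestDosing:
    def test_serplulimab_weight_based(self):
        assert dose_serplulimab(65.0) == pytest.approx(292.5)
        assert dose_serplulimab(40.96) == pytest.approx(184.32)
        with pytest.raises(ValueError):
            dose_serplulimab(0.0)

    def test_carboplatin_calvert_with_cap(self):
        assert dose_carboplatin(90.0, 5.0, 750.0) == pytest.approx(575.0)
        assert dose_carboplatin(130.0, 5.0, 750.0) == pytest.approx(750.0)
        assert dose_carboplatin(90.0, 0.0, 750.0) == 0.0
        with pytest.raises(ValueError):
            dose_carboplatin(-5.0)

    def test_etoposide_bsa_based(self):
        assert dose_etoposide(1.80) == pytest.approx(540.0)
        assert dose_etoposide(2.16) == pytest.approx(648.0)
        assert dose_etoposide(1.0) == pytest.approx(300.0)
        with pytest.raises(ValueError):
            dose_etoposide(-1.0)


class TestCosting:
    def test_total_equals_component_sum(self, base_config):
        for arm in ARMS:
            c = arm_costs(run_trace(arm, base_config), base_config)
            assert c["total"] == pytest.approx(
                sum(c[k] for k in COST_COMPONENTS), rel=1e-6)
            assert c["total"] == pytest.approx(c["drug"] + c["nondrug"],
                                               rel=1e-12)

    def test_zero_unit_costs_zero_total(self, base_config):
        zero = CostInputs(
            serplulimab_per_mg=0, etoposide_per_mg=0, carboplatin_per_mg=0,
            second_line_per_cycle={SERP: 0.0, CHEMO: 0.0},
            terminal_care_per_patient=0,
            supportive_per_cycle={"pfs": 0.0, "pd": 0.0},
            ae_management={SERP: 0.0, CHEMO: 0.0}, administration_per_unit=0)
        cfg = base_config.replace(costs=zero)
        assert arm_costs(run_trace(SERP, cfg), cfg)["total"] == 0.0

    @pytest.mark.parametrize("field,values", [
        ("serplulimab_price", [6.65, 8.32, 9.98]),
        ("weight", [50.0, 65.0, 90.0]),
    ])
    def test_costs_monotone_in_price_and_weight(self, base_config, field,
                                                values):
        totals = []
        for v in values:
            cfg = base_config.deepcopy()
            if field == "serplulimab_price":
                cfg.costs.serplulimab_per_mg = v
            else:
                cfg.body.weight_kg = v
            totals.append(arm_costs(run_trace(SERP, cfg), cfg)["total"])
        assert totals[0] < totals[1] < totals[2]

    def test_chemotherapy_confined_to_four_cycles(self, base_config):
        cfg = base_config.deepcopy()
        cfg.dosing = dataclasses.replace(cfg.dosing, chemo_cycles=0)
        c = arm_costs(run_trace(CHEMO, cfg), cfg)
        assert c["chemo_drug"] == 0.0
        base = arm_costs(run_trace(CHEMO, base_config), base_config)
        assert base["chemo_drug"] > 0.0

    def test_serplulimab_only_in_treatment_arm(self, base_config):
        serp = arm_costs(run_trace(SERP, base_config), base_config)
        chemo = arm_costs(run_trace(CHEMO, base_config), base_config)
        assert chemo["serplulimab_drug"] == 0.0
        assert serp["serplulimab_drug"] > 30_000.0

    def test_terminal_care_follows_death_mass(self, base_config):
        tr = run_trace(CHEMO, base_config)
        c = arm_costs(tr, base_config)
        expected = base_config.costs.terminal_care_per_patient * float(
            np.sum(tr.deaths * tr.discount))
        assert c["terminal_care"] == pytest.approx(expected, rel=1e-12)
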