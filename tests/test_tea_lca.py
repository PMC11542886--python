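"""Levelized cost, life-cycle inventory and characterization."""
import numpy as np
import pytest
from dataclasses import replace

from anaerobead.design import design_system, load_prices
from anaerobead.pipeline import evaluate_scenario
from anaerobead.tea_lca import (CashFlowSchedule,
                                biogas_energy_credit, build_inventory,
                                capital_recovery_factor, characterize,
                                levelized_cost)


def _brute_force_lc(schedule: CashFlowSchedule, tonnes: float) -> float:
    """Independent year-by-year NPV summation oracle."""
    r = schedule.discount_rate
    npv = 0.0
    for t in range(schedule.horizon + 1):
        cf = (schedule.revenue[t] - schedule.capital[t]
              - schedule.replacement[t] - schedule.om[t])
        npv += cf / (1.0 + r) ** t
    n = schedule.horizon
    crf = r * (1 + r) ** n / ((1 + r) ** n - 1) if r > 0 else 1.0 / n
    return -npv * crf / tonnes


class TestLevelizedCost:
    def test_zero_cash_flows(self):
        s = CashFlowSchedule.empty()
        assert levelized_cost(s, 100.0) == 0.0

    def test_single_capital_crf(self):
        s = CashFlowSchedule.empty(discount_rate=0.05, horizon=30)
        s.capital[0] = 1e6
        assert capital_recovery_factor(0.05, 30) == pytest.approx(0.06505, abs=5e-6)
        assert levelized_cost(s, 100.0) == pytest.approx(1e6 * 0.06505 / 100.0,
                                                         rel=1e-4)

    def test_undiscounted_limit(self):
        s = CashFlowSchedule.empty(discount_rate=0.0, horizon=30)
        s.capital[0] = 300.0
        s.om[1:] = 10.0
        assert levelized_cost(s, 1.0) == pytest.approx((300.0 + 300.0) / 30.0)

    def test_zero_removal_rejected(self):
        with pytest.raises(ValueError):
            levelized_cost(CashFlowSchedule.empty(), 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_npv_oracle(self, seed):
        rng = np.random.default_rng(seed)
        s = CashFlowSchedule.empty(discount_rate=rng.uniform(0.0, 0.12),
                                   horizon=int(rng.integers(5, 40)))
        s.capital[0] = rng.uniform(0, 1e6)
        s.replacement[:] = rng.uniform(0, 1e4, s.horizon + 1)
        s.om[1:] = rng.uniform(0, 5e4, s.horizon)
        s.revenue[1:] = rng.uniform(0, 3e4, s.horizon)
        tonnes = rng.uniform(10.0, 500.0)
        assert levelized_cost(s, tonnes) == pytest.approx(
            _brute_force_lc(s, tonnes), rel=1e-10)


class TestCharacterization:
    def test_empty_ledger(self, tables):
        out = characterize({}, tables.factors)
        assert out["net"] == 0.0

    def test_grid_electricity_reproduces_benchmark(self, tables):
        # 790 kWh per tonne at the derived grid factor -> 348 kg CO2eq
        out = characterize({"electricity": 790.0}, tables.factors)
        assert out["net"] == pytest.approx(348.0, abs=0.05)

    def test_credit_can_go_negative(self, tables):
        out = characterize({"electricity": 10.0,
                            "natural_gas_offset": -1e4}, tables.factors)
        assert out["net"] < 0.0

    def test_unresolvable_flow_named(self, tables):
        with pytest.raises(KeyError, match="mystery"):
            characterize({"mystery": 1.0}, tables.factors)

    def test_linear_superposition(self, tables, rng):
        flows = ["electricity", "natural_gas", "fugitive_ch4",
                 "peg_encapsulant", "concrete"]
        a = {f: float(rng.uniform(0, 10)) for f in flows}
        b = {f: float(rng.uniform(0, 10)) for f in flows}
        ab = {f: a[f] + b[f] for f in flows}
        net = lambda led: characterize(led, tables.factors)["net"]
        assert net(ab) == pytest.approx(net(a) + net(b), rel=1e-12)


class TestBiogasCredit:
    def test_zero_and_linearity(self):
        prices = load_prices()
        z = biogas_energy_credit(0.0, 0.0, prices)
        assert z["mj_per_d"] == 0.0
        one = biogas_energy_credit(10.0, 0.0, prices)
        two = biogas_energy_credit(20.0, 0.0, prices)
        assert two["mj_per_d"] == pytest.approx(2.0 * one["mj_per_d"])

    def test_pure_ch4_lhv(self):
        prices = load_prices()
        # 1 Nm^3 CH4 = 0.716 kg; energy should match the configured
        # volumetric LHV constant within 1%
        out = biogas_energy_credit(0.716, 0.0, prices)
        assert out["mj_per_d"] == pytest.approx(
            prices["ch4_lhv_mj_per_nm3"], rel=0.01)

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            biogas_energy_credit(-1.0, 0.0, load_prices())


class TestInventory:
    def test_fugitive_and_rejections(self, small_toy_run, tables):
        system, result = small_toy_run
        design = design_system(system.config, result, tables.curves,
                               tables.prices)
        led = build_inventory(design, tables.curves, design.energy,
                              fugitive_ch4_kg_yr=100.0, offset_mj_yr=0.0,
                              annual_cod_removed=10.0)
        assert led["fugitive_ch4"] == pytest.approx(10.0)
        with pytest.raises(ValueError):
            build_inventory(design, tables.curves, design.energy,
                            -1.0, 0.0, 10.0)
        with pytest.raises(ValueError):
            build_inventory(design, tables.curves, design.energy,
                            0.0, 0.0, 0.0)

    def test_peg_ledger_bookkeeping(self, small_toy_run, tables):
        # PEG flow per FU must equal initial mass x batches / project /
        # annual tonnage (cross-module bookkeeping oracle)
        system, result = small_toy_run
        design = design_system(system.config, result, tables.curves,
                               tables.prices)
        tonnes = 25.0
        led = build_inventory(design, tables.curves, design.energy,
                              0.0, 0.0, tonnes)
        expected = design.encapsulant["initial_mass_kg"] \
            * design.encapsulant["batches"] / 30.0 / tonnes
        assert led["peg_encapsulant"] == pytest.approx(expected, rel=1e-12)


class TestIndicatorPipeline:
    def test_breakdowns_sum_to_net(self, small_toy, tables, small_toy_run):
        _, result = small_toy_run
        ib = evaluate_scenario(small_toy["config"], small_toy["influent"],
                               small_toy["params"], small_toy["settings"],
                               tables, result=result)
        assert sum(ib.lc_contributions.values()) == pytest.approx(ib.lc, rel=1e-9)
        assert sum(ib.ci_contributions.values()) == pytest.approx(ib.ci, rel=1e-9)
        assert ib.metadata["factor_table_checksum"]

    def test_longer_bead_life_never_costs_more(self, small_toy, tables,
                                               small_toy_run):
        # lifetime acts only through the replacement schedule, so one
        # simulation prices all three lifetimes
        _, result = small_toy_run
        lcs, cis = [], []
        for life in (1.0, 10.0, 30.0):
            cfg = replace(small_toy["config"],
                          bead=replace(small_toy["config"].bead, lifetime=life))
            ib = evaluate_scenario(cfg, small_toy["influent"],
                                   small_toy["params"], small_toy["settings"],
                                   tables, result=result)
            lcs.append(ib.lc)
            cis.append(ib.ci)
        assert lcs[0] >= lcs[1] >= lcs[2]
        assert cis[0] >= cis[1] >= cis[2]
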