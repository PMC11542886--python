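"""Equipment sizing, material takeoffs, energy demands and cost lines.

Translates a converged scenario into vessel dimensions, material
quantities, electricity/heat demands and itemized capital and O&M costs
via parameterized power-law cost curves.  All coefficients live in the
bundled editable ``data/cost_curves.csv`` / ``data/prices.yaml`` tables
(documented placeholders, reported in output metadata) — no cost number is
hard-coded in this module.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from math import ceil, pi

import numpy as np
import pandas as pd
import yaml

from .reactors import SteadyStateResult, SystemConfig

G = 9.81           # m s^-2
RHO_WATER = 998.0  # kg m^-3
MU_WATER = 1.0e-3  # Pa s
CP_WATER = 4184.0  # J kg^-1 K^-1


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("anaerobead.data").joinpath(name)


def load_cost_curves(path=None) -> dict[str, "CostCurve"]:
    """Read the cost-curve table; returns a mapping item -> CostCurve."""
    src = path or _data_path("cost_curves.csv")
    df = pd.read_csv(src)
    curves = {}
    for _, row in df.iterrows():
        curves[row["item"]] = CostCurve(
            item=row["item"], base_cost=float(row["base_cost_usd2021"]),
            base_size=float(row["base_size"]), unit=row["unit"],
            exponent=float(row["exponent"]),
            install_factor=float(row["install_factor"]),
            lifetime=float(row["lifetime_yr"]))
    return curves


def load_prices(path=None) -> dict:
    src = path or _data_path("prices.yaml")
    with open(src) as fh:
        return yaml.safe_load(fh)


def table_checksum(path=None) -> str:
    """Short checksum of a bundled table, carried in output metadata."""
    src = path or _data_path("impact_factors.csv")
    with open(src, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()[:12]


@dataclass
class CostCurve:
    """Power-law installed-cost curve for one item."""

    item: str
    base_cost: float      # USD(2021) at base_size
    base_size: float
    unit: str
    exponent: float
    install_factor: float = 1.0
    lifetime: float = 30.0  # years

    def __post_init__(self) -> None:
        if self.base_cost < 0:
            raise ValueError(f"{self.item}: base cost must be >= 0")
        if not 0.0 < self.exponent <= 1.2:
            raise ValueError(f"{self.item}: exponent must be in (0, 1.2]")
        if self.lifetime <= 0:
            raise ValueError(f"{self.item}: lifetime must be positive")

    def installed_cost(self, size: float) -> float:
        if size < 0:
            raise ValueError("negative size")
        if size == 0:
            return 0.0
        return self.base_cost * (size / self.base_size) ** self.exponent \
            * self.install_factor


@dataclass
class MaterialTakeoff:
    """Item -> quantity map; units follow the cost-curve table."""

    items: dict[str, float] = field(default_factory=dict)

    def add(self, item: str, qty: float) -> None:
        if qty < 0:
            raise ValueError(f"negative quantity for {item}")
        self.items[item] = self.items.get(item, 0.0) + qty

    def __getitem__(self, item: str) -> float:
        return self.items.get(item, 0.0)


# ---------------------------------------------------------------------------
# sizing
# ---------------------------------------------------------------------------

def size_reactor(config: SystemConfig, flow: float,
                 headspace_fraction: float = 0.15,
                 aspect_ratio: float = 1.5,
                 wall_concrete: float = 0.20,
                 wall_rockwool: float = 0.05,
                 wall_steel: float = 0.003) -> tuple[list[dict], MaterialTakeoff]:
    """Cylindrical vessel dimensions and material takeoff, per stage.

    Working volume is flow x HRT (beads counted inside the working volume);
    total volume adds a headspace fraction.  Walls are concrete with
    rockwool insulation and a thin carbon-steel facing; the UASB adds a
    stainless three-phase separator sized on the cross-section.
    """
    config.validate()
    if flow <= 0 or config.total_hrt <= 0:
        raise ValueError("flow and HRT must be positive")
    takeoff = MaterialTakeoff()
    dims = []
    for s in range(config.stages):
        frac = (config.hrt_split if (config.stages == 2 and s == 0)
                else (1.0 - config.hrt_split) if config.stages == 2 else 1.0)
        v_work = flow * config.total_hrt * frac
        v_total = v_work * (1.0 + headspace_fraction)
        d = (4.0 * v_total / (aspect_ratio * pi)) ** (1.0 / 3.0)
        h = aspect_ratio * d
        shell_area = pi * d * h
        slab_area = pi * d ** 2 / 4.0
        area = shell_area + 2.0 * slab_area
        takeoff.add("concrete", area * wall_concrete)
        takeoff.add("rockwool", area * wall_rockwool)
        takeoff.add("carbon_steel", area * wall_steel * 7850.0)
        if config.reactor_type == "UASB":
            takeoff.add("stainless_steel", 40.0 * slab_area)  # separator
        dims.append({"working_volume": v_work, "total_volume": v_total,
                     "diameter": d, "height": h})
    # liquid piping (HDPE) and gas piping (stainless): flat + flow-scaled runs
    takeoff.add("hdpe", 50.0 + 2.0 * flow)
    takeoff.add("stainless_steel", 30.0 * config.stages)
    return dims, takeoff


def encapsulant_inventory(config: SystemConfig, working_volume: float,
                          project_years: float = 30.0) -> dict:
    """Initial encapsulant mass and the whole-batch replacement schedule.

    The bead inventory is replaced in whole batches at the end of each
    lifetime interval: ``batches = ceil(project_years / lifetime)`` over the
    project (initial fill included).
    """
    if config.bead is None:
        raise ValueError("encapsulant inventory requires a bead spec")
    if working_volume <= 0:
        raise ValueError("working volume must be positive")
    phi = config.bead_fraction
    bead_volume = working_volume * phi
    mass = bead_volume * config.bead.density
    batches = ceil(project_years / config.bead.lifetime)
    return {"bead_volume_m3": bead_volume, "initial_mass_kg": mass,
            "batches": batches, "lifetime_yr": config.bead.lifetime}


def minimum_fluidization_velocity(diameter_mm: float, bead_density: float,
                                  fluid_density: float = RHO_WATER,
                                  viscosity: float = MU_WATER) -> float:
    """Wen-Yu minimum fluidization velocity, m s^-1."""
    if bead_density <= fluid_density:
        raise ValueError("bead density must exceed fluid density to fluidize")
    d = diameter_mm / 1000.0
    ar = fluid_density * (bead_density - fluid_density) * G * d ** 3 / viscosity ** 2
    re_mf = np.sqrt(33.7 ** 2 + 0.0408 * ar) - 33.7
    return float(re_mf * viscosity / (fluid_density * d))


def fluidization_power(bead, bed_area: float, bed_height: float,
                       volume_fraction: float,
                       pump_efficiency: float = 0.7,
                       velocity_margin: float = 1.3) -> float:
    """Upflow pumping power to keep the bed fluidized, kW.

    The recirculation flow runs at ``velocity_margin`` times the Wen-Yu
    minimum fluidization velocity; the head is the buoyant weight of the
    bead inventory.  Monotone increasing in bead diameter and density
    difference.
    """
    if bed_area <= 0 or bed_height <= 0:
        raise ValueError("bed geometry must be positive")
    u_mf = minimum_fluidization_velocity(bead.diameter, bead.density)
    q_up = velocity_margin * u_mf * bed_area           # m^3 s^-1
    dp = volume_fraction * (bead.density - RHO_WATER) * G * bed_height  # Pa
    return q_up * dp / pump_efficiency / 1000.0        # kW


def packed_bed_pressure_drop(voidage: float, diameter_mm: float,
                             superficial_velocity: float,
                             fluid_density: float = RHO_WATER,
                             viscosity: float = MU_WATER) -> float:
    """Ergun pressure gradient through a packed bed, Pa m^-1."""
    if not 0.0 < voidage < 1.0:
        raise ValueError("voidage must be in (0, 1)")
    d = diameter_mm / 1000.0
    u = superficial_velocity
    lam = 150.0 * viscosity * (1.0 - voidage) ** 2 * u / (voidage ** 3 * d ** 2)
    turb = 1.75 * (1.0 - voidage) * fluid_density * u * abs(u) / (voidage ** 3 * d)
    return float(lam + turb)


def heating_duty(flow: float, t_in: float, t_op: float,
                 hx_effectiveness: float = 0.5,
                 boiler_efficiency: float = 0.8) -> dict:
    """Influent heating duty and natural-gas-equivalent demand.

    ``duty = rho cp Q dT (1 - effectiveness)``; zero when the operating
    temperature does not exceed the influent temperature.
    """
    if not 0.0 <= hx_effectiveness < 1.0:
        raise ValueError("HX effectiveness must be in [0, 1)")
    dt = max(t_op - t_in, 0.0)
    duty_kw = RHO_WATER * CP_WATER * (flow / 86400.0) * dt \
        * (1.0 - hx_effectiveness) / 1000.0
    ng_mj_d = duty_kw * 86400.0 / 1000.0 / boiler_efficiency
    return {"duty_kw": duty_kw, "ng_mj_per_d": ng_mj_d}


# ---------------------------------------------------------------------------
# costing
# ---------------------------------------------------------------------------

def cost_lines(takeoff: MaterialTakeoff, curves: dict[str, CostCurve],
               energy: dict[str, float], prices: dict,
               encapsulant: dict | None = None) -> dict:
    """Itemized installed capital and annual O&M, USD(2021).

    ``energy`` carries ``electricity_kw`` and ``heat_ng_mj_d``.  The
    encapsulant replacement purchases are amortized (undiscounted) over the
    project for the O&M view; the discounted schedule is built separately
    for the levelized cost.
    """
    capital: dict[str, float] = {}
    for item, qty in takeoff.items.items():
        if item not in curves:
            raise KeyError(f"no cost curve for takeoff item {item!r}")
        capital[item] = curves[item].installed_cost(qty)
    total_capital = sum(capital.values())

    om: dict[str, float] = {}
    kwh_yr = energy.get("electricity_kw", 0.0) * 24.0 * 365.0
    om["electricity"] = kwh_yr * prices["electricity_usd_per_kwh"]
    om["heat"] = energy.get("heat_ng_mj_d", 0.0) * 365.0 \
        * prices["natural_gas_usd_per_mj"]
    om["maintenance"] = prices["maintenance_fraction"] * total_capital
    if encapsulant is not None and encapsulant["batches"] > 1:
        batch_cost = curves["peg_encapsulant"].installed_cost(
            encapsulant["initial_mass_kg"])
        om["encapsulant_replacement"] = batch_cost \
            * (encapsulant["batches"] - 1) / prices["project_years"]
    return {"capital": capital, "total_capital": total_capital,
            "om": om, "total_om": sum(om.values())}


# ---------------------------------------------------------------------------
# scenario-level design
# ---------------------------------------------------------------------------

@dataclass
class ScenarioDesign:
    """Design outputs of one converged scenario."""

    dims: list[dict]
    takeoff: MaterialTakeoff
    encapsulant: dict | None
    energy: dict[str, float]          # electricity_kw, heat_ng_mj_d
    costs: dict
    equipment_capital: dict[str, float]


def design_system(config: SystemConfig, result: SteadyStateResult,
                  curves: dict[str, CostCurve] | None = None,
                  prices: dict | None = None) -> ScenarioDesign:
    """Full sizing + costing pass for one converged scenario."""
    curves = curves or load_cost_curves()
    prices = prices or load_prices()
    flow = result.flow
    dims, takeoff = size_reactor(config, flow)

    encap = None
    if config.bead is not None:
        v_work_total = sum(d["working_volume"] for d in dims)
        encap = encapsulant_inventory(config, v_work_total,
                                      prices["project_years"])
        takeoff.add("peg_encapsulant", encap["initial_mass_kg"])

    # --- energy demands -----------------------------------------------------
    eff_pump = prices["pump_efficiency"]
    elec_kw = RHO_WATER * G * (flow / 86400.0) * 8.0 / eff_pump / 1000.0  # influent lift
    if config.reactor_type == "fluidized_bed":
        for d in dims:
            bed_area = pi * d["diameter"] ** 2 / 4.0
            elec_kw += fluidization_power(config.bead, bed_area, d["height"],
                                          config.bead_volume_fraction,
                                          eff_pump)
    elif config.reactor_type == "packed_bed":
        for d in dims:
            bed_area = pi * d["diameter"] ** 2 / 4.0
            u = flow / 86400.0 / bed_area
            dp = packed_bed_pressure_drop(config.bed_voidage,
                                          config.bead.diameter, u)
            elec_kw += dp * d["height"] * (flow / 86400.0) / eff_pump / 1000.0
    if config.h2_extraction == "vacuum":
        # isothermal-ish compression work per Nm^3 of stage-1 gas
        q1 = result.biogas_flow[0]
        elec_kw += 0.1 * q1 / 24.0 * np.log(1.013 / config.vacuum_pressure)
    elif config.h2_extraction == "membrane":
        q_re = config.membrane_recirculation * flow
        elec_kw += RHO_WATER * G * (q_re / 86400.0) * 5.0 / eff_pump / 1000.0
    if config.effluent_degassing:
        elec_kw += 0.05 * flow / 24.0     # kWh/m^3 on the effluent stream

    heat = heating_duty(flow, 22.0, config.temperature,
                        boiler_efficiency=prices["boiler_efficiency"])

    # --- auxiliary equipment ------------------------------------------------
    gas_total = max(result.total_biogas_flow, 1e-6)
    equip = {
        "water_pump": curves["water_pump"].installed_cost(flow),
        "gas_holder": curves["gas_holder"].installed_cost(gas_total),
        "iron_sponge_scrubber": curves["iron_sponge_scrubber"].installed_cost(gas_total),
        "control_system": curves["control_system"].installed_cost(1.0),
    }
    if config.temperature > 22.0:
        equip["heat_exchanger"] = curves["heat_exchanger"].installed_cost(
            max(heat["duty_kw"] / (1.0 - 0.5), 1.0))
    if config.h2_extraction == "vacuum":
        equip["vacuum_pump"] = curves["vacuum_pump"].installed_cost(
            max(0.1 * result.biogas_flow[0] / 24.0, 0.5))
    elif config.h2_extraction == "membrane":
        area = 0.5 * config.membrane_recirculation * flow  # m^2, loading rule
        equip["h2_membrane"] = curves["membrane_contactor"].installed_cost(area)
    if config.effluent_degassing:
        equip["degassing_membrane"] = curves["membrane_contactor"].installed_cost(
            2.0 * flow)

    energy = {"electricity_kw": float(elec_kw),
              "heat_ng_mj_d": heat["ng_mj_per_d"]}
    costs = cost_lines(takeoff, curves, energy, prices, encap)
    costs["capital"].update(equip)
    costs["total_capital"] = sum(costs["capital"].values())
    costs["om"]["maintenance"] = prices["maintenance_fraction"] * costs["total_capital"]
    costs["total_om"] = sum(costs["om"].values())
    return ScenarioDesign(dims=dims, takeoff=takeoff, encapsulant=encap,
                          energy=energy, costs=costs,
                          equipment_capital=equip)
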