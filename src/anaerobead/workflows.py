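"""Orchestration of the three analysis stages over the scenario pipeline.

Thin glue between the enumeration/sampling machinery, the steady-state
simulator and the TEA/LCA pipeline: every function here maps tabular
inputs (decision rows, parameter samples, grids) to tabular indicator
outputs ready for CSV export.
"""
from __future__ import annotations

import copy
from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd

from .adm1 import InfluentSpec, KineticParameterSet
from .analytics import (DecisionSpace, GridMapResult, enumerate_scenarios,
                        lhs_sample, pairwise_delta, stage3_map)
from .beads import BeadSpec
from .pipeline import (AnalysisTables, evaluate_degassing_variants,
                       evaluate_scenario)
from .reactors import SimulationSettings, SystemConfig
from .synth import make_parameter_space

#: per-variable baseline options for the pairwise impact analysis
PAIRWISE_BASELINES = {
    "reactor_type": "UASB",
    "stages": 1,
    "h2_extraction": "passive",
    "effluent_degassing": False,
    "temperature": 22.0,
    "total_hrt": 1.0,
    "bead_diameter": 2.0,
    "bead_lifetime": 30.0,
    "bead_volume_fraction": 0.10,
}

_KINETIC_NAMES = ("k_dis", "k_hyd_ch", "k_m_ac", "K_S_ac", "k_m_pro",
                  "k_m_h2", "k_dec", "kLa")


# ---------------------------------------------------------------------------
# Stage I
# ---------------------------------------------------------------------------

def run_stage1(space: DecisionSpace, influent: InfluentSpec,
               params: KineticParameterSet,
               settings: SimulationSettings | None = None,
               tables: AnalysisTables | None = None,
               limit: int | None = None,
               progress: bool = False) -> pd.DataFrame:
    """Evaluate the (optionally truncated) enumeration.

    Returns the decision table with appended ``rcod``, ``lc``, ``ci`` and
    ``converged`` columns.  Degassing enters as its own decision, so each
    scenario is simulated once and priced per its own degassing choice.
    """
    tables = tables or AnalysisTables.default()
    settings = settings or SimulationSettings.fast()
    df = enumerate_scenarios(space)
    if limit is not None:
        df = df.iloc[:limit].copy()
    rcod, lc, ci, conv = [], [], [], []
    for i, (_, row) in enumerate(df.iterrows()):
        ib = evaluate_scenario(row["config"], influent, params, settings,
                               tables)
        rcod.append(ib.rcod)
        lc.append(ib.lc)
        ci.append(ib.ci)
        conv.append(ib.metadata["converged"])
        if progress and (i + 1) % 10 == 0:
            print(f"  stage 1: {i + 1}/{len(df)} scenarios", flush=True)
    out = df.drop(columns=["config"]).copy()
    out["rcod"], out["lc"], out["ci"], out["converged"] = rcod, lc, ci, conv
    return out


def stage1_impacts(results: pd.DataFrame, indicator: str,
                   baselines: dict | None = None) -> pd.DataFrame:
    """Pairwise relative impacts of every decision variable on one
    indicator, concatenated across variables."""
    baselines = baselines or PAIRWISE_BASELINES
    frames = []
    for var, base in baselines.items():
        if var not in results or results[var].nunique(dropna=True) < 2:
            continue
        frames.append(pairwise_delta(results, results[indicator], var, base))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Stage II
# ---------------------------------------------------------------------------

def apply_sample(row: pd.Series, reactor_type: str,
                 influent: InfluentSpec, params: KineticParameterSet,
                 tables: AnalysisTables,
                 settings: SimulationSettings):
    """Instantiate a scenario from one uncertainty-sample row.

    Stage-II systems are single-stage, ambient-temperature, passive
    collection (the Stage-I screening result); both degassing variants are
    priced downstream from the same steady state.
    """
    kin = {k: float(row[k]) for k in _KINETIC_NAMES if k in row}
    p = dc_replace(params, **kin)

    inf = influent
    upd = {}
    if "influent_s_cat" in row:
        upd["s_cat"] = float(row["influent_s_cat"])
    if "influent_s_IN" in row:
        upd["s_IN"] = float(row["influent_s_IN"])
    if upd:
        inf = dc_replace(influent, **upd)

    bead = None
    vf = void = None
    if reactor_type != "UASB":
        bead = BeadSpec(
            diameter=float(row["bead_diameter"]),
            diffusivity_ratio=float(row["diffusivity_ratio"]),
            max_encapsulation_density=float(row["max_encapsulation_density"]),
            lifetime=float(row["bead_lifetime"]),
            density=float(row["bead_density"]))
        if reactor_type == "fluidized_bed":
            vf = float(row["bead_volume_fraction"])
        else:
            void = float(row["bed_voidage"])
    cfg = SystemConfig(
        reactor_type=reactor_type, stages=1, temperature=22.0,
        total_hrt=float(row["total_hrt"]), h2_extraction="passive",
        effluent_degassing=False, bead=bead, bead_volume_fraction=vf,
        bed_voidage=void,
        uasb_retention_factor=float(row.get("uasb_retention_factor", 50.0)))

    tb = AnalysisTables(copy.deepcopy(tables.curves),
                        dict(tables.prices),
                        copy.deepcopy(tables.factors))
    if "encapsulant_unit_cost" in row:
        tb.curves["peg_encapsulant"].base_cost = float(row["encapsulant_unit_cost"])
    if "encapsulant_gwp" in row:
        tb.factors.factors["peg_encapsulant"]["GWP100"] = float(row["encapsulant_gwp"])
    if "electricity_price" in row:
        tb.prices["electricity_usd_per_kwh"] = float(row["electricity_price"])
    if "natural_gas_price" in row:
        tb.prices["natural_gas_usd_per_mj"] = float(row["natural_gas_price"])
    if "degassing_efficiency" in row:
        tb.prices["degassing_efficiency"] = float(row["degassing_efficiency"])
    if "maintenance_fraction" in row:
        tb.prices["maintenance_fraction"] = float(row["maintenance_fraction"])
    if "biogas_leak_fraction" in row:
        tb.prices["biogas_leak_fraction"] = float(row["biogas_leak_fraction"])

    st = settings
    if "inoculum_density" in row:
        st = dc_replace(settings, inoculum_density=float(row["inoculum_density"]))
    return cfg, inf, p, tb, st


INDICATOR_DIRECTIONS = {
    "rcod": "higher_better",
    "lc_degassed": "lower_better", "lc_plain": "lower_better",
    "ci_degassed": "lower_better", "ci_plain": "lower_better",
}


def run_stage2(reactor_type: str, n: int, seed: int,
               influent: InfluentSpec, params: KineticParameterSet,
               settings: SimulationSettings | None = None,
               tables: AnalysisTables | None = None,
               samples: pd.DataFrame | None = None,
               progress: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monte Carlo uncertainty run for one reactor type.

    Returns ``(samples, indicators)`` where indicators carries the five
    monitored outputs: rCOD and LC/CI each with and without effluent
    degassing.  Passing a precomputed ``samples`` frame (drawn from a
    shared distribution set) enables paired cross-reactor comparisons.
    """
    tables = tables or AnalysisTables.default()
    settings = settings or SimulationSettings.fast()
    if samples is None:
        dist = make_parameter_space(reactor_type)
        samples = lhs_sample(dist, n, seed)
    rows = []
    for i, (_, row) in enumerate(samples.iterrows()):
        cfg, inf, p, tb, st = apply_sample(row, reactor_type, influent,
                                           params, tables, settings)
        both = evaluate_degassing_variants(cfg, inf, p, st, tb)
        rows.append({
            "rcod": both[False].rcod,
            "lc_plain": both[False].lc, "ci_plain": both[False].ci,
            "lc_degassed": both[True].lc, "ci_degassed": both[True].ci,
            "converged": both[False].metadata["converged"],
        })
        if progress and (i + 1) % 10 == 0:
            print(f"  stage 2 [{reactor_type}]: {i + 1}/{len(samples)}",
                  flush=True)
    return samples, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage III
# ---------------------------------------------------------------------------

STAGE3_SETUPS = {
    "fluidized_bed": {
        "param_grid_ranges": {"bead_lifetime": (1.0, 30.0),
                              "k_m_ac": (2.0, 12.0)},
        "dv_bounds": {"total_hrt": (1.0 / 24.0, 5.0),
                      "bead_volume_fraction": (0.03, 0.25)},
    },
    "packed_bed": {
        "param_grid_ranges": {"bead_lifetime": (1.0, 30.0),
                              "diffusivity_ratio": (0.1, 1.0)},
        "dv_bounds": {"total_hrt": (1.0 / 24.0, 5.0)},
    },
}


def make_stage3_objective(reactor_type: str, influent: InfluentSpec,
                          params: KineticParameterSet,
                          settings: SimulationSettings,
                          tables: AnalysisTables,
                          degassing: bool = True):
    """Objective closure minimizing CI over the decision variables.

    Systems use 1 mm beads (maximizing interfacial area) and, for packed
    beds, loose packing (voidage 0.45); all non-mapped parameters stay at
    their baseline values.
    """
    if reactor_type not in STAGE3_SETUPS:
        raise ValueError("stage III maps encapsulated reactors only")

    def objective(pvals: dict, dvs: dict) -> dict:
        p = params
        if "k_m_ac" in pvals:
            p = dc_replace(p, k_m_ac=pvals["k_m_ac"])
        bead = BeadSpec(diameter=1.0,
                        diffusivity_ratio=pvals.get("diffusivity_ratio", 0.5),
                        max_encapsulation_density=60.0,
                        lifetime=pvals.get("bead_lifetime", 10.0))
        if reactor_type == "fluidized_bed":
            cfg = SystemConfig(reactor_type=reactor_type, stages=1,
                               temperature=22.0,
                               total_hrt=dvs["total_hrt"],
                               effluent_degassing=degassing, bead=bead,
                               bead_volume_fraction=dvs["bead_volume_fraction"])
        else:
            cfg = SystemConfig(reactor_type=reactor_type, stages=1,
                               temperature=22.0,
                               total_hrt=dvs["total_hrt"],
                               effluent_degassing=degassing, bead=bead,
                               bed_voidage=0.45)
        ib = evaluate_scenario(cfg, influent, p, settings, tables)
        return {"objective": ib.ci, "ci": ib.ci, "lc": ib.lc,
                "rcod": ib.rcod,
                "converged_sim": ib.metadata["converged"]}

    return objective


def run_stage3(reactor_type: str, influent: InfluentSpec,
               params: KineticParameterSet,
               settings: SimulationSettings | None = None,
               tables: AnalysisTables | None = None,
               grid_shape: tuple[int, int] = (12, 15),
               n_starts: int = 8, seed: int = 1,
               maxfev: int = 60, degassing: bool = True) -> GridMapResult:
    """Map the R&D target space for one reactor type.

    The default 12 x 15 grid yields 180 evaluated parameter pairs; reduced
    shapes (e.g. 3 x 3) are used in the fast presets.
    """
    tables = tables or AnalysisTables.default()
    settings = settings or SimulationSettings.tiny()
    setup = STAGE3_SETUPS[reactor_type]
    grid = {name: np.linspace(lo, hi, m)
            for (name, (lo, hi)), m in zip(setup["param_grid_ranges"].items(),
                                           grid_shape)}
    obj = make_stage3_objective(reactor_type, influent, params, settings,
                                tables, degassing)
    return stage3_map(obj, grid, setup["dv_bounds"], n_starts=n_starts,
                      seed=seed, maxfev=maxfev)
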