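"""Synthetic inputs: influent streams, parameter spaces, toy systems.

Everything the analysis stages need is generated programmatically from the
study inputs (50 m^3 d^-1 brewery wastewater, 6760 mg L^-1 total /
5640 mg L^-1 soluble COD) plus documented default assumptions, so the whole
pipeline bootstraps offline.
"""
from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path

from .adm1 import InfluentSpec, KineticParameterSet
from .analytics import (DecisionSpace, ParameterDistributionSet,
                        ParameterSpec)
from .beads import BeadSpec
from .design import _data_path
from .pipeline import AnalysisTables
from .reactors import SimulationSettings, SystemConfig


def make_influent(flow: float = 50.0, tcod: float = 6760.0,
                  scod: float = 5640.0, **overrides) -> InfluentSpec:
    """Brewery influent spec with default fractionation weights."""
    if scod > tcod:
        raise ValueError("soluble COD cannot exceed total COD")
    spec = InfluentSpec(flow=flow, total_cod=tcod, soluble_cod=scod,
                        **overrides)
    spec.validate()
    return spec


def default_kinetics() -> KineticParameterSet:
    return KineticParameterSet()


def make_decision_space(reduced: bool = False) -> DecisionSpace:
    """Full Stage-I decision space; ``reduced`` shrinks the option sets for
    fast end-to-end runs while keeping every decision variable active."""
    if not reduced:
        return DecisionSpace()
    return DecisionSpace(
        stages=(1,), temperatures=(22.0,), hrts=(1.0, 2.0),
        degassing=(False, True), bead_diameters=(2.0, 10.0),
        bead_lifetimes=(1.0, 30.0), volume_fractions=(0.10, 0.40))


_KINETIC_SPECS = [
    ParameterSpec("k_dis", "uniform", 0.25, 1.0, unit="1/d", kind="kinetic"),
    ParameterSpec("k_hyd_ch", "uniform", 5.0, 15.0, unit="1/d", kind="kinetic"),
    ParameterSpec("k_m_ac", "uniform", 4.0, 12.0, unit="COD/COD/d", kind="kinetic"),
    ParameterSpec("K_S_ac", "uniform", 0.05, 0.30, unit="kgCOD/m3", kind="kinetic"),
    ParameterSpec("k_m_pro", "uniform", 6.0, 20.0, unit="COD/COD/d", kind="kinetic"),
    ParameterSpec("k_m_h2", "uniform", 17.0, 50.0, unit="COD/COD/d", kind="kinetic"),
]

_SHARED_TECH = [
    ParameterSpec("encapsulant_unit_cost", "triangular", 6.0, 18.0, mode=12.0,
                  unit="USD/kg"),
    ParameterSpec("encapsulant_gwp", "triangular", 2.0, 5.0, mode=3.4,
                  unit="kgCO2e/kg"),
    ParameterSpec("electricity_price", "uniform", 0.06, 0.12, unit="USD/kWh",
                  kind="decision"),
    ParameterSpec("degassing_efficiency", "uniform", 0.70, 0.95, unit="-"),
    ParameterSpec("biogas_leak_fraction", "loguniform", 0.005, 0.05, unit="-"),
]

_BEAD_TECH = [
    ParameterSpec("bead_lifetime", "uniform", 1.0, 10.0, unit="yr"),
    ParameterSpec("diffusivity_ratio", "uniform", 0.2, 1.0, unit="-"),
    ParameterSpec("max_encapsulation_density", "uniform", 30.0, 120.0,
                  unit="kgCOD/m3"),
    ParameterSpec("bead_density", "uniform", 1050.0, 1200.0, unit="kg/m3"),
]


def make_parameter_space(reactor_type: str) -> ParameterDistributionSet:
    """The 18-parameter uncertainty space for one reactor type.

    Decision variables are uniform; technological parameters carry
    literature-style triangular/log-uniform families.  The HRT range keeps
    the organic loading between the study's 1.36 and 40.6
    kg-COD m^-3 d^-1 bounds (4 h to 5 d at 6.76 kg m^-3).
    """
    hrt = ParameterSpec("total_hrt", "uniform", 4.0 / 24.0, 5.0, unit="d",
                        kind="decision")
    if reactor_type == "fluidized_bed":
        specs = _KINETIC_SPECS + [
            hrt,
            ParameterSpec("bead_diameter", "uniform", 1.0, 5.0, unit="mm",
                          kind="decision"),
            ParameterSpec("bead_volume_fraction", "uniform", 0.03, 0.25,
                          unit="-", kind="decision"),
        ] + _BEAD_TECH + _SHARED_TECH
    elif reactor_type == "packed_bed":
        specs = _KINETIC_SPECS + [
            hrt,
            ParameterSpec("bead_diameter", "uniform", 1.0, 5.0, unit="mm",
                          kind="decision"),
            ParameterSpec("bed_voidage", "uniform", 0.35, 0.45, unit="-"),
        ] + _BEAD_TECH + _SHARED_TECH
    elif reactor_type == "UASB":
        specs = _KINETIC_SPECS + [
            hrt,
            ParameterSpec("k_dec", "uniform", 0.01, 0.04, unit="1/d",
                          kind="kinetic"),
            ParameterSpec("uasb_retention_factor", "uniform", 20.0, 100.0,
                          unit="-"),
            ParameterSpec("kLa", "uniform", 100.0, 300.0, unit="1/d"),
            ParameterSpec("inoculum_density", "uniform", 5.0, 40.0,
                          unit="kgCOD/m3"),
            ParameterSpec("influent_s_cat", "uniform", 0.02, 0.08,
                          unit="kmol/m3"),
            ParameterSpec("influent_s_IN", "uniform", 0.005, 0.03,
                          unit="kmol/m3"),
            ParameterSpec("natural_gas_price", "uniform", 0.003, 0.008,
                          unit="USD/MJ", kind="decision"),
            ParameterSpec("maintenance_fraction", "uniform", 0.015, 0.04,
                          unit="1/yr"),
        ] + _SHARED_TECH[2:]  # no encapsulant entries for suspended growth
    else:
        raise ValueError(f"unknown reactor type {reactor_type!r}")
    out = ParameterDistributionSet(specs)
    if len(out) != 18:  # pragma: no cover - construction invariant
        raise AssertionError(f"expected 18 parameters, got {len(out)}")
    return out


def make_toy_system(scale: str = "tiny") -> dict:
    """Fast, fully configured scenarios for testing.

    ``tiny``: a single-guild acetate chemostat (UASB with retention factor
    1 and inhibition switched off) whose washout boundary has the
    closed-form chemostat solution.  ``small``: a compact encapsulated
    fluidized-bed scenario that converges in seconds.
    """
    if scale == "tiny":
        influent = InfluentSpec(
            flow=10.0, total_cod=3000.0, soluble_cod=3000.0,
            soluble_weights={"S_ac": 1.0}, particulate_weights={"X_c": 1.0},
            s_cat=0.08, s_an=0.005, s_IC=0.03, s_IN=0.02,
            temperature=308.15)
        params = KineticParameterSet(
            K_S_IN=1e-8, K_I_nh3=1e3, pH_UL_ac=3.0, pH_LL_ac=2.0,
            pH_UL_aa=3.0, pH_LL_aa=2.0, pH_UL_h2=3.0, pH_LL_h2=2.0)
        config = SystemConfig(reactor_type="UASB", stages=1,
                              temperature=35.0, total_hrt=4.0,
                              uasb_retention_factor=1.0)
        settings = SimulationSettings(t_end=600.0, tol=1e-4, rtol=1e-6,
                                      atol=1e-10, max_extensions=2,
                                      inoculum_density=1.0)
    elif scale == "small":
        influent = InfluentSpec(
            flow=10.0, total_cod=4000.0, soluble_cod=3600.0,
            s_cat=0.06, s_an=0.01, temperature=308.15)
        config = SystemConfig(
            reactor_type="fluidized_bed", stages=1, temperature=35.0,
            total_hrt=1.0,
            bead=BeadSpec(diameter=2.0, diffusivity_ratio=0.8,
                          max_encapsulation_density=60.0, lifetime=10.0),
            bead_volume_fraction=0.2)
        params = KineticParameterSet()
        settings = SimulationSettings(shell_count=3, t_end=800.0, tol=5e-3,
                                      rtol=1e-5, atol=1e-8,
                                      max_extensions=1)
    else:
        raise ValueError("scale must be 'tiny' or 'small'")
    return {"config": config, "influent": influent, "params": params,
            "settings": settings}


@dataclass
class FixtureSet:
    """Everything a full offline analysis run needs."""

    influent: InfluentSpec = field(default_factory=make_influent)
    kinetics: KineticParameterSet = field(default_factory=default_kinetics)
    decision_space: DecisionSpace = field(default_factory=DecisionSpace)
    parameter_spaces: dict = field(default_factory=lambda: {
        rt: make_parameter_space(rt)
        for rt in ("UASB", "packed_bed", "fluidized_bed")})
    tables: AnalysisTables = field(default_factory=AnalysisTables.default)
    seed: int = 1

    @classmethod
    def default(cls, seed: int = 1) -> "FixtureSet":
        return cls(seed=seed)


def write_fixtures(directory: str | Path, seed: int = 1) -> Path:
    """Materialize the editable default tables into a fixtures directory."""
    import yaml

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("cost_curves.csv", "impact_factors.csv", "prices.yaml"):
        shutil.copy(_data_path(name), out / name)
    fx = FixtureSet.default(seed)
    meta = {
        "seed": seed,
        "influent": {"flow_m3_d": fx.influent.flow,
                     "total_cod_mg_l": fx.influent.total_cod,
                     "soluble_cod_mg_l": fx.influent.soluble_cod},
        "kinetics": fx.kinetics.to_dict(),
        "parameter_spaces": {
            rt: [s.__dict__ for s in ps.specs]
            for rt, ps in fx.parameter_spaces.items()},
    }
    with open(out / "fixtures.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return out
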