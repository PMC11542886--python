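"""ADM1 biokinetics evaluated at a point.

Implements the standard Anaerobic Digestion Model No. 1 component set and
the 19 biochemical processes (disintegration, hydrolysis, eight substrate
uptakes, seven biomass decays) with Monod uptake kinetics, non-competitive
H2 and free-ammonia inhibition, lower-pH inhibition, algebraic charge-balance
pH closure and Henry's-law gas-liquid transfer.

Units: concentrations kg-COD m^-3 (organics) or kmol m^-3 (S_IC, S_IN,
ions); rates per day; temperature K; pressures bar.

The stoichiometric matrix is built programmatically with automatic carbon
and nitrogen balancing into S_IC / S_IN, so elemental and COD closure hold
to machine precision for every process column.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from . import components as cmp

R_BAR = 0.083145  # bar m^3 kmol^-1 K^-1
T_STD = 298.15


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ADM1State:
    """Concentrations at one spatial location plus temperature.

    ``conc`` is ordered by :data:`anaerobead.components.NAMES`.
    """

    conc: np.ndarray
    temperature: float = 295.15  # K (22 degC default, ambient operation)

    def __post_init__(self) -> None:
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.shape != (cmp.N_COMP,):
            raise ValueError(
                f"state vector must have length {cmp.N_COMP}, got {self.conc.shape}"
            )
        if not np.all(np.isfinite(self.conc)):
            raise ValueError("non-finite concentration in state")

    @classmethod
    def zeros(cls, temperature: float = 295.15) -> "ADM1State":
        return cls(np.zeros(cmp.N_COMP), temperature)

    @classmethod
    def from_dict(cls, values: dict[str, float], temperature: float = 295.15) -> "ADM1State":
        c = np.zeros(cmp.N_COMP)
        for name, v in values.items():
            if name not in cmp.IDX:
                raise KeyError(f"unknown component {name!r}")
            c[cmp.IDX[name]] = v
        return cls(c, temperature)

    def __getitem__(self, name: str) -> float:
        return float(self.conc[cmp.IDX[name]])

    def copy(self) -> "ADM1State":
        return ADM1State(self.conc.copy(), self.temperature)


@dataclass
class GasPhaseState:
    """Headspace partial pressures and flow for one reactor stage."""

    p_ch4: float = 0.0   # bar
    p_co2: float = 0.0   # bar
    p_h2: float = 0.0    # bar
    headspace_volume: float = 1.0  # m^3
    outflow: float = 0.0  # Nm^3 d^-1
    temperature: float = 295.15

    @property
    def p_h2o(self) -> float:
        """Saturation water vapor pressure, bar (Antoine-like van't Hoff)."""
        return 0.0313 * np.exp(5290.0 * (1.0 / T_STD - 1.0 / self.temperature))

    def validate(self) -> None:
        if min(self.p_ch4, self.p_co2, self.p_h2) < 0:
            raise ValueError("negative partial pressure")
        if self.outflow < 0:
            raise ValueError("negative gas outflow")


@dataclass
class KineticParameterSet:
    """ADM1 kinetic, stoichiometric and physicochemical parameters.

    Defaults are the widely used mesophilic (35 degC) benchmark values;
    rate constants are Arrhenius-corrected to the operating temperature via
    :meth:`at_temperature`.
    """

    # first-order steps, d^-1
    k_dis: float = 0.5
    k_hyd_ch: float = 10.0
    k_hyd_pr: float = 10.0
    k_hyd_li: float = 10.0
    # Monod maxima, kg-COD kg-COD^-1 d^-1
    k_m_su: float = 30.0
    k_m_aa: float = 50.0
    k_m_fa: float = 6.0
    k_m_c4: float = 20.0
    k_m_pro: float = 13.0
    k_m_ac: float = 8.0
    k_m_h2: float = 35.0
    # half saturations, kg-COD m^-3
    K_S_su: float = 0.5
    K_S_aa: float = 0.3
    K_S_fa: float = 0.4
    K_S_c4: float = 0.2
    K_S_pro: float = 0.1
    K_S_ac: float = 0.15
    K_S_h2: float = 7e-6
    # yields, kg-COD biomass per kg-COD substrate
    Y_su: float = 0.10
    Y_aa: float = 0.08
    Y_fa: float = 0.06
    Y_c4: float = 0.06
    Y_pro: float = 0.04
    Y_ac: float = 0.05
    Y_h2: float = 0.06
    # decay, d^-1
    k_dec: float = 0.02
    # product fractions
    f_sI_xc: float = 0.1
    f_xI_xc: float = 0.2
    f_ch_xc: float = 0.2
    f_pr_xc: float = 0.2
    f_li_xc: float = 0.3
    f_fa_li: float = 0.95
    f_bu_su: float = 0.13
    f_pro_su: float = 0.27
    f_ac_su: float = 0.41
    f_h2_su: float = 0.19
    f_va_aa: float = 0.23
    f_bu_aa: float = 0.26
    f_pro_aa: float = 0.05
    f_ac_aa: float = 0.40
    f_h2_aa: float = 0.06
    # inhibition
    K_S_IN: float = 1e-4      # kmol m^-3, nitrogen limitation
    K_I_h2_fa: float = 5e-6   # kg-COD m^-3
    K_I_h2_c4: float = 1e-5
    K_I_h2_pro: float = 3.5e-6
    K_I_nh3: float = 1.8e-3   # kmol m^-3
    # lower-pH inhibition limits (upper, lower)
    pH_UL_aa: float = 5.5
    pH_LL_aa: float = 4.0
    pH_UL_ac: float = 7.0
    pH_LL_ac: float = 6.0
    pH_UL_h2: float = 6.0
    pH_LL_h2: float = 5.0
    # acid-base dissociation constants (25 degC)
    Ka_va: float = 10 ** -4.86
    Ka_bu: float = 10 ** -4.82
    Ka_pro: float = 10 ** -4.88
    Ka_ac: float = 10 ** -4.76
    Ka_co2: float = 10 ** -6.35
    Ka_nh4: float = 10 ** -9.25
    Kw: float = 1e-14
    # gas transfer
    kLa: float = 200.0  # d^-1
    # temperature handling
    T_ref: float = 308.15      # K, reference for rate constants (35 degC)
    theta_arrhenius: float = 0.07  # K^-1, rate ~ exp(theta (T - T_ref))

    def validate(self) -> None:
        for name in ("k_dis", "k_hyd_ch", "k_hyd_pr", "k_hyd_li",
                     "k_m_su", "k_m_aa", "k_m_fa", "k_m_c4", "k_m_pro",
                     "k_m_ac", "k_m_h2", "K_S_su", "K_S_aa", "K_S_fa",
                     "K_S_c4", "K_S_pro", "K_S_ac", "K_S_h2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("Y_su", "Y_aa", "Y_fa", "Y_c4", "Y_pro", "Y_ac", "Y_h2"):
            y = getattr(self, name)
            if not 0.0 < y < 1.0:
                raise ValueError(f"{name} must be in (0,1)")

    def at_temperature(self, temperature: float) -> "KineticParameterSet":
        """Return a copy with rate constants Arrhenius-scaled to ``temperature``."""
        f = float(np.exp(self.theta_arrhenius * (temperature - self.T_ref)))
        scaled = {k: getattr(self, k) * f for k in
                  ("k_dis", "k_hyd_ch", "k_hyd_pr", "k_hyd_li", "k_m_su",
                   "k_m_aa", "k_m_fa", "k_m_c4", "k_m_pro", "k_m_ac",
                   "k_m_h2", "k_dec")}
        return replace(self, **scaled)

    def to_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.__dict__.items()}


@dataclass
class InfluentSpec:
    """Measured influent composition plus COD fractionation weights.

    Default weights split the soluble pool across fermentable sugars, amino
    acids, LCFA, VFAs and a small soluble-inert residue (the split is a
    configuration input; only the COD totals are measured), and send all
    particulate COD to the composite pool.
    """

    flow: float = 50.0            # m^3 d^-1
    total_cod: float = 6760.0     # mg L^-1
    soluble_cod: float = 5640.0   # mg L^-1
    soluble_weights: dict[str, float] = field(default_factory=lambda: {
        "S_su": 0.50, "S_aa": 0.20, "S_fa": 0.05, "S_va": 0.01,
        "S_bu": 0.04, "S_pro": 0.06, "S_ac": 0.12, "S_I": 0.02,
    })
    particulate_weights: dict[str, float] = field(default_factory=lambda: {"X_c": 1.0})
    # non-COD makeup, kmol m^-3
    s_IN: float = 0.013
    s_IC: float = 0.008
    s_cat: float = 0.045
    s_an: float = 0.010
    temperature: float = 295.15   # K

    def validate(self) -> None:
        if self.flow <= 0:
            raise ValueError("flow must be positive")
        if self.soluble_cod > self.total_cod:
            raise ValueError("soluble COD exceeds total COD")
        for pool, w in (("soluble", self.soluble_weights),
                        ("particulate", self.particulate_weights)):
            vals = np.array(list(w.values()), float)
            if np.any(vals < 0):
                raise ValueError(f"negative {pool} fractionation weight")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"{pool} fractionation weights must sum to 1")
        for name in self.soluble_weights:
            if cmp.SOLUBLE_COD[cmp.IDX[name]] != 1.0:
                raise ValueError(f"{name} is not a soluble COD component")
        for name in self.particulate_weights:
            if cmp.IDX[name] not in set(cmp.PARTICULATE.tolist()):
                raise ValueError(f"{name} is not a particulate component")

    @property
    def cod_mass_flow(self) -> float:
        """Influent COD mass flow, kg d^-1."""
        return self.flow * self.total_cod / 1000.0


# ---------------------------------------------------------------------------
# stoichiometry
# ---------------------------------------------------------------------------

N_PROCESS = 19


def build_stoichiometry(p: KineticParameterSet) -> np.ndarray:
    """Petersen matrix, shape (N_COMP, 19).

    Carbon and nitrogen are closed into S_IC / S_IN per process column, so
    column sums weighted by COD, C or N content vanish identically.
    """
    i = cmp.IDX
    S = np.zeros((cmp.N_COMP, N_PROCESS))

    def setcol(j: int, **coefs: float) -> None:
        for name, v in coefs.items():
            S[i[name], j] += v

    setcol(0, X_c=-1.0, S_I=p.f_sI_xc, X_I=p.f_xI_xc,
           X_ch=p.f_ch_xc, X_pr=p.f_pr_xc, X_li=p.f_li_xc)
    setcol(1, X_ch=-1.0, S_su=1.0)
    setcol(2, X_pr=-1.0, S_aa=1.0)
    setcol(3, X_li=-1.0, S_fa=p.f_fa_li, S_su=1.0 - p.f_fa_li)
    setcol(4, S_su=-1.0, S_bu=(1 - p.Y_su) * p.f_bu_su,
           S_pro=(1 - p.Y_su) * p.f_pro_su, S_ac=(1 - p.Y_su) * p.f_ac_su,
           S_h2=(1 - p.Y_su) * p.f_h2_su, X_su=p.Y_su)
    setcol(5, S_aa=-1.0, S_va=(1 - p.Y_aa) * p.f_va_aa,
           S_bu=(1 - p.Y_aa) * p.f_bu_aa, S_pro=(1 - p.Y_aa) * p.f_pro_aa,
           S_ac=(1 - p.Y_aa) * p.f_ac_aa, S_h2=(1 - p.Y_aa) * p.f_h2_aa,
           X_aa=p.Y_aa)
    setcol(6, S_fa=-1.0, S_ac=(1 - p.Y_fa) * 0.7,
           S_h2=(1 - p.Y_fa) * 0.3, X_fa=p.Y_fa)
    setcol(7, S_va=-1.0, S_pro=(1 - p.Y_c4) * 0.54,
           S_ac=(1 - p.Y_c4) * 0.31, S_h2=(1 - p.Y_c4) * 0.15, X_c4=p.Y_c4)
    setcol(8, S_bu=-1.0, S_ac=(1 - p.Y_c4) * 0.8,
           S_h2=(1 - p.Y_c4) * 0.2, X_c4=p.Y_c4)
    setcol(9, S_pro=-1.0, S_ac=(1 - p.Y_pro) * 0.57,
           S_h2=(1 - p.Y_pro) * 0.43, X_pro=p.Y_pro)
    setcol(10, S_ac=-1.0, S_ch4=1 - p.Y_ac, X_ac=p.Y_ac)
    setcol(11, S_h2=-1.0, S_ch4=1 - p.Y_h2, X_h2=p.Y_h2)
    for j, guild in enumerate(("X_su", "X_aa", "X_fa", "X_c4", "X_pro",
                               "X_ac", "X_h2")):
        setcol(12 + j, **{guild: -1.0, "X_c": 1.0})

    # close C and N balances into the inorganic pools
    ic, iN = i["S_IC"], i["S_IN"]
    for j in range(N_PROCESS):
        S[ic, j] = 0.0
        S[iN, j] = 0.0
        S[ic, j] = -float(cmp.CARBON @ S[:, j])
        S[iN, j] = -float(cmp.NITROGEN @ S[:, j])
    return S


# ---------------------------------------------------------------------------
# process rates
# ---------------------------------------------------------------------------

def _ph_inhibition(pH: np.ndarray, UL: float, LL: float) -> np.ndarray:
    """Lower-pH-only inhibition switch (exponential form)."""
    low = np.exp(-3.0 * ((pH - UL) / (UL - LL)) ** 2)
    return np.where(pH < UL, low, 1.0)


def process_rates(conc: np.ndarray, p: KineticParameterSet,
                  pH: np.ndarray) -> np.ndarray:
    """Rates of the 19 biochemical processes, kg-COD m^-3 d^-1.

    ``conc`` may be (N_COMP,) or (n_loc, N_COMP); ``pH`` scalar or (n_loc,).
    Concentrations are floored at zero inside the kinetic expressions so
    that tiny negative excursions during stiff integration stay harmless.
    """
    c = np.atleast_2d(np.maximum(conc, 0.0))
    pH = np.broadcast_to(np.asarray(pH, float), (c.shape[0],))
    i = cmp.IDX
    g = lambda n: c[:, i[n]]

    # free ammonia from pH
    h = 10.0 ** (-pH)
    s_nh3 = g("S_IN") * p.Ka_nh4 / (p.Ka_nh4 + h)

    I_IN = g("S_IN") / (g("S_IN") + p.K_S_IN)
    I_pH_aa = _ph_inhibition(pH, p.pH_UL_aa, p.pH_LL_aa)
    I_pH_ac = _ph_inhibition(pH, p.pH_UL_ac, p.pH_LL_ac)
    I_pH_h2 = _ph_inhibition(pH, p.pH_UL_h2, p.pH_LL_h2)
    I_h2_fa = 1.0 / (1.0 + g("S_h2") / p.K_I_h2_fa)
    I_h2_c4 = 1.0 / (1.0 + g("S_h2") / p.K_I_h2_c4)
    I_h2_pro = 1.0 / (1.0 + g("S_h2") / p.K_I_h2_pro)
    I_nh3 = 1.0 / (1.0 + s_nh3 / p.K_I_nh3)

    monod = lambda s, K: s / (K + s)
    eps = 1e-12
    rho = np.empty((c.shape[0], N_PROCESS))
    rho[:, 0] = p.k_dis * g("X_c")
    rho[:, 1] = p.k_hyd_ch * g("X_ch")
    rho[:, 2] = p.k_hyd_pr * g("X_pr")
    rho[:, 3] = p.k_hyd_li * g("X_li")
    rho[:, 4] = p.k_m_su * monod(g("S_su"), p.K_S_su) * g("X_su") * I_pH_aa * I_IN
    rho[:, 5] = p.k_m_aa * monod(g("S_aa"), p.K_S_aa) * g("X_aa") * I_pH_aa * I_IN
    rho[:, 6] = (p.k_m_fa * monod(g("S_fa"), p.K_S_fa) * g("X_fa")
                 * I_pH_aa * I_IN * I_h2_fa)
    rho[:, 7] = (p.k_m_c4 * monod(g("S_va"), p.K_S_c4) * g("X_c4")
                 * g("S_va") / (g("S_va") + g("S_bu") + eps)
                 * I_pH_aa * I_IN * I_h2_c4)
    rho[:, 8] = (p.k_m_c4 * monod(g("S_bu"), p.K_S_c4) * g("X_c4")
                 * g("S_bu") / (g("S_va") + g("S_bu") + eps)
                 * I_pH_aa * I_IN * I_h2_c4)
    rho[:, 9] = (p.k_m_pro * monod(g("S_pro"), p.K_S_pro) * g("X_pro")
                 * I_pH_aa * I_IN * I_h2_pro)
    rho[:, 10] = (p.k_m_ac * monod(g("S_ac"), p.K_S_ac) * g("X_ac")
                  * I_pH_ac * I_IN * I_nh3)
    rho[:, 11] = p.k_m_h2 * monod(g("S_h2"), p.K_S_h2) * g("X_h2") * I_pH_h2 * I_IN
    for j, guild in enumerate(("X_su", "X_aa", "X_fa", "X_c4", "X_pro",
                               "X_ac", "X_h2")):
        rho[:, 12 + j] = p.k_dec * g(guild)
    return rho if np.asarray(conc).ndim == 2 else rho[0]


def reaction_rates(state: ADM1State, params: KineticParameterSet,
                   pH: float) -> np.ndarray:
    """Net production rate per component from the 19 ADM1 processes.

    Returns a vector aligned with the component registry, kg-COD m^-3 d^-1
    (kmol m^-3 d^-1 for S_IC and S_IN).
    """
    if np.any(state.conc < 0):
        raise ValueError("negative concentration in state")
    if not 0.0 < pH < 14.0:
        raise ValueError("pH out of (0, 14)")
    params.validate()
    S = build_stoichiometry(params)
    rho = process_rates(state.conc, params, pH)
    return S @ rho


# ---------------------------------------------------------------------------
# pH / charge balance
# ---------------------------------------------------------------------------

def _charge_balance_terms(conc: np.ndarray, p: KineticParameterSet):
    """Totals entering the charge balance, all kmol m^-3, from a (n, N) array."""
    i = cmp.IDX
    vfa_tot = {k: np.maximum(conc[..., i[k]], 0.0) / m
               for k, m in cmp.COD_PER_MOL_VFA.items()}
    return {
        "cat": np.maximum(conc[..., i["S_cat"]], 0.0),
        "an": np.maximum(conc[..., i["S_an"]], 0.0),
        "ic": np.maximum(conc[..., i["S_IC"]], 0.0),
        "inn": np.maximum(conc[..., i["S_IN"]], 0.0),
        "vfa": vfa_tot,
    }


def _charge_balance(h, t, p: KineticParameterSet):
    ka = {"S_va": p.Ka_va, "S_bu": p.Ka_bu, "S_pro": p.Ka_pro, "S_ac": p.Ka_ac}
    f = t["cat"] + t["inn"] * h / (h + p.Ka_nh4) + h \
        - t["ic"] * p.Ka_co2 / (p.Ka_co2 + h) - p.Kw / h - t["an"]
    for k, tot in t["vfa"].items():
        f = f - tot * ka[k] / (ka[k] + h)
    return f


def solve_ph(state: ADM1State, params: KineticParameterSet | None = None) -> float:
    """Solve the algebraic charge balance for pH.

    The balance is strictly monotone in the proton concentration, so the
    root is unique; it is bracketed in pH (0, 14) and solved with Brent's
    method to a residual far below 1e-10 kmol m^-3.
    """
    p = params or KineticParameterSet()
    if not np.all(np.isfinite(state.conc)):
        raise ValueError("non-finite ionic state")
    t = _charge_balance_terms(state.conc, p)
    f = lambda h: float(_charge_balance(h, t, p))
    lo, hi = 1e-14, 1.0
    flo, fhi = f(lo), f(hi)
    if flo > 0 and fhi > 0 or flo < 0 and fhi < 0:
        raise ValueError("charge balance has no root in pH (0, 14)")
    h = brentq(f, lo, hi, xtol=1e-16, rtol=8.9e-16, maxiter=200)
    return float(-np.log10(h))


def solve_ph_vec(conc: np.ndarray, p: KineticParameterSet,
                 h0: np.ndarray | None = None) -> np.ndarray:
    """Vectorized charge-balance pH for a (n_loc, N_COMP) array.

    Damped Newton on the proton concentration with positivity clamping;
    the balance is monotone so the iteration is globally convergent.
    """
    n = conc.shape[0]
    t = _charge_balance_terms(conc, p)
    h = np.full(n, 1e-7) if h0 is None else np.clip(h0, 1e-14, 1.0)
    ka = {"S_va": p.Ka_va, "S_bu": p.Ka_bu, "S_pro": p.Ka_pro, "S_ac": p.Ka_ac}
    for _ in range(60):
        fval = _charge_balance(h, t, p)
        dfdh = 1.0 + p.Kw / h ** 2 \
            + t["inn"] * p.Ka_nh4 / (h + p.Ka_nh4) ** 2 \
            + t["ic"] * p.Ka_co2 / (p.Ka_co2 + h) ** 2
        for k, tot in t["vfa"].items():
            dfdh = dfdh + tot * ka[k] / (ka[k] + h) ** 2
        step = fval / dfdh
        h_new = np.clip(h - step, h * 0.1, h * 10.0)
        h_new = np.clip(h_new, 1e-14, 1.0)
        if np.all(np.abs(h_new - h) <= 1e-12 * h + 1e-18):
            h = h_new
            break
        h = h_new
    return -np.log10(h)


# ---------------------------------------------------------------------------
# gas transfer
# ---------------------------------------------------------------------------

def henry_constants(temperature: float) -> dict[str, float]:
    """Henry solubilities, kmol m^-3 bar^-1, van't Hoff corrected."""
    invd = 1.0 / T_STD - 1.0 / temperature
    R = 8.314
    return {
        "h2": 7.8e-4 * np.exp(-4180.0 / R * invd),
        "ch4": 1.4e-3 * np.exp(-14240.0 / R * invd),
        "co2": 3.5e-2 * np.exp(-19410.0 / R * invd),
    }


def gas_transfer(state: ADM1State, gas: GasPhaseState, kLa: float,
                 params: KineticParameterSet | None = None) -> dict[str, float]:
    """Liquid-to-gas transfer rates at one point.

    Returns ``{"h2": ..., "ch4": ..., "co2": ...}`` with H2/CH4 in
    kg-COD m^-3 d^-1 and CO2 in kmol m^-3 d^-1; positive means transfer out
    of the liquid.
    """
    if kLa < 0:
        raise ValueError("kLa must be nonnegative")
    p = params or KineticParameterSet()
    gas.validate()
    KH = henry_constants(state.temperature)
    ph = solve_ph(state, p)
    h = 10.0 ** (-ph)
    s_co2 = state["S_IC"] * h / (h + p.Ka_co2)
    return {
        "h2": kLa * (state["S_h2"] - cmp.COD_PER_MOL_H2 * KH["h2"] * gas.p_h2),
        "ch4": kLa * (state["S_ch4"] - cmp.COD_PER_MOL_CH4 * KH["ch4"] * gas.p_ch4),
        "co2": kLa * (s_co2 - KH["co2"] * gas.p_co2),
    }


# ---------------------------------------------------------------------------
# influent fractionation and COD accounting
# ---------------------------------------------------------------------------

def fractionate_influent(spec: InfluentSpec) -> ADM1State:
    """Map the measured COD totals onto the ADM1 component vector.

    The returned state reproduces the specified soluble and total COD
    exactly (to rounding) by construction.
    """
    spec.validate()
    c = np.zeros(cmp.N_COMP)
    s_cod = spec.soluble_cod / 1000.0        # kg m^-3
    x_cod = (spec.total_cod - spec.soluble_cod) / 1000.0
    for name, w in spec.soluble_weights.items():
        c[cmp.IDX[name]] = w * s_cod
    for name, w in spec.particulate_weights.items():
        c[cmp.IDX[name]] = w * x_cod
    c[cmp.IDX["S_IN"]] = spec.s_IN
    c[cmp.IDX["S_IC"]] = spec.s_IC
    c[cmp.IDX["S_cat"]] = spec.s_cat
    c[cmp.IDX["S_an"]] = spec.s_an
    return ADM1State(c, spec.temperature)


def cod_of(state: ADM1State, basis: Literal["total", "soluble"] = "total") -> float:
    """Sum of COD-carrying components, kg-COD m^-3."""
    if basis == "total":
        w = cmp.COD_WEIGHT
    elif basis == "soluble":
        w = cmp.SOLUBLE_COD
    else:
        raise ValueError("basis must be 'total' or 'soluble'")
    return float(w @ state.conc)
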