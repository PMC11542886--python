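"""Component registry for the anaerobic digestion state vector.

The state vector follows the standard ADM1 component set (12 soluble, 12
particulate species) plus a strong-cation / strong-anion pair used only for
charge-balance closure.  All organic components are carried on a COD basis
(kg-COD m^-3); inorganic carbon and nitrogen are molar (kmol m^-3).

Registry metadata (COD weight, carbon and nitrogen content, aqueous
diffusivity) is stored as aligned numpy vectors so that rate and transport
kernels can stay fully vectorized.
"""
from __future__ import annotations

import numpy as np

#: ordered component names
NAMES: tuple[str, ...] = (
    # --- soluble, COD basis unless noted ---
    "S_su",   # monosaccharides
    "S_aa",   # amino acids
    "S_fa",   # long-chain fatty acids
    "S_va",   # total valerate
    "S_bu",   # total butyrate
    "S_pro",  # total propionate
    "S_ac",   # total acetate
    "S_h2",   # dissolved hydrogen
    "S_ch4",  # dissolved methane
    "S_IC",   # inorganic carbon, kmol C m^-3
    "S_IN",   # inorganic nitrogen, kmol N m^-3
    "S_I",    # soluble inerts
    # --- particulate ---
    "X_c",    # composite particulate
    "X_ch",   # carbohydrates
    "X_pr",   # proteins
    "X_li",   # lipids
    "X_su",   # sugar degraders
    "X_aa",   # amino-acid degraders
    "X_fa",   # LCFA degraders
    "X_c4",   # valerate/butyrate degraders
    "X_pro",  # propionate degraders
    "X_ac",   # acetoclastic methanogens
    "X_h2",   # hydrogenotrophic methanogens
    "X_I",    # particulate inerts
    # --- ions, kmol m^-3 ---
    "S_cat",  # strong cations
    "S_an",   # strong anions
)

N_COMP = len(NAMES)
IDX: dict[str, int] = {n: i for i, n in enumerate(NAMES)}

_i = IDX  # shorthand

#: indices of the seven biomass guilds
BIOMASS = np.array([_i[n] for n in ("X_su", "X_aa", "X_fa", "X_c4", "X_pro", "X_ac", "X_h2")])

#: soluble components (diffusible in hydrogel); ions included
SOLUBLE = np.array([_i[n] for n in NAMES[:12]] + [_i["S_cat"], _i["S_an"]])
PARTICULATE = np.array([_i[n] for n in NAMES[12:24]])

#: COD weight of each component (1 for COD-basis organics, 0 for molar species)
COD_WEIGHT = np.ones(N_COMP)
for _n in ("S_IC", "S_IN", "S_cat", "S_an"):
    COD_WEIGHT[_i[_n]] = 0.0

#: soluble COD mask (COD-carrying soluble components)
SOLUBLE_COD = np.zeros(N_COMP)
for _n in ("S_su", "S_aa", "S_fa", "S_va", "S_bu", "S_pro", "S_ac", "S_h2", "S_ch4", "S_I"):
    SOLUBLE_COD[_i[_n]] = 1.0

# Carbon content, kmol C per kg COD (per kmol for S_IC); standard ADM1 values.
CARBON = np.zeros(N_COMP)
_c = {
    "S_su": 0.0313, "S_aa": 0.03, "S_fa": 0.0217, "S_va": 0.024, "S_bu": 0.025,
    "S_pro": 0.0268, "S_ac": 0.0313, "S_ch4": 0.0156, "S_I": 0.03,
    "X_c": 0.02786, "X_ch": 0.0313, "X_pr": 0.03, "X_li": 0.022, "X_I": 0.03,
    "S_IC": 1.0,
}
for _n in ("X_su", "X_aa", "X_fa", "X_c4", "X_pro", "X_ac", "X_h2"):
    _c[_n] = 0.0313  # biomass
for _n, _v in _c.items():
    CARBON[_i[_n]] = _v

# Nitrogen content, kmol N per kg COD (per kmol for S_IN).
NITROGEN = np.zeros(N_COMP)
_nv = {"S_aa": 0.007, "X_pr": 0.007, "S_IN": 1.0,
       "X_c": 0.0376 / 14.0, "S_I": 0.06 / 14.0, "X_I": 0.06 / 14.0}
for _n in ("X_su", "X_aa", "X_fa", "X_c4", "X_pro", "X_ac", "X_h2"):
    _nv[_n] = 0.08 / 14.0
for _n, _v in _nv.items():
    NITROGEN[_i[_n]] = _v

# Aqueous diffusivities at ~25 degC, m^2 d^-1 (literature order-of-magnitude
# values; particulates do not diffuse).
_D_m2_s = {
    "S_su": 6.0e-10, "S_aa": 9.0e-10, "S_fa": 5.0e-10,
    "S_va": 8.0e-10, "S_bu": 9.0e-10, "S_pro": 1.0e-9, "S_ac": 1.2e-9,
    "S_h2": 4.5e-9, "S_ch4": 1.5e-9, "S_IC": 1.9e-9, "S_IN": 2.0e-9,
    "S_I": 6.0e-10, "S_cat": 1.3e-9, "S_an": 1.5e-9,
}
AQUEOUS_DIFFUSIVITY = np.zeros(N_COMP)
for _n, _v in _D_m2_s.items():
    AQUEOUS_DIFFUSIVITY[_i[_n]] = _v * 86400.0

#: grams of COD per mole of gas
COD_PER_MOL_CH4 = 64.0   # g COD mol^-1
COD_PER_MOL_H2 = 16.0    # g COD mol^-1

#: molar-mass-on-COD conversion for VFAs, g COD per mol acid
COD_PER_MOL_VFA = {"S_va": 208.0, "S_bu": 160.0, "S_pro": 112.0, "S_ac": 64.0}


def names() -> list[str]:
    """Return the ordered component names as a list."""
    return list(NAMES)


def index_of(name: str) -> int:
    """Index of a component, raising ``KeyError`` for unknown names."""
    return IDX[name]
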