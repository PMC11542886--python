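"""Three-stage design analysis.

Stage I: deterministic enumeration of the discrete decision space and
pairwise relative impacts (indicator difference between baseline and
alternative scenarios differing in one decision, normalized by the
indicator range over the whole enumeration).

Stage II: Latin hypercube Monte Carlo over the uncertain parameter space
with Monte Carlo filtering — two-sample Kolmogorov-Smirnov tests between
the "desirable" (top 25%) and "undesirable" (bottom 75%) sample groups per
indicator.

Stage III: two-dimensional grids over pairs of key technological
parameters with a seeded multi-start bounded optimization of the decision
variables minimizing carbon intensity at every grid point.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .beads import BeadSpec
from .reactors import SystemConfig

DECISION_COLUMNS = (
    "reactor_type", "stages", "h2_extraction", "vacuum_pressure",
    "membrane_recirculation", "effluent_degassing", "temperature",
    "total_hrt", "bead_diameter", "bead_lifetime", "bead_volume_fraction",
)


# ---------------------------------------------------------------------------
# Stage I: discrete decision space
# ---------------------------------------------------------------------------

@dataclass
class DecisionSpace:
    """Option sets for the discrete decision variables.

    Applicability rules: bead decisions apply to encapsulated reactors
    only; the volume fraction to fluidized beds only; active H2 extraction
    attaches to the first stage of two-stage systems, so single-stage
    systems admit passive collection only.
    """

    reactor_types: tuple = ("UASB", "packed_bed", "fluidized_bed")
    stages: tuple = (1, 2)
    temperatures: tuple = (22.0, 35.0)
    hrts: tuple = (1.0, 2.0, 4.0, 12.0)
    degassing: tuple = (False, True)
    vacuum_pressures: tuple = (0.1, 0.4)
    membrane_recirculations: tuple = (1.0, 50.0)
    bead_diameters: tuple = (2.0, 5.0, 10.0)
    bead_lifetimes: tuple = (1.0, 10.0, 30.0)
    volume_fractions: tuple = (0.10, 0.25, 0.40)
    default_voidage: float = 0.40
    bead_defaults: dict = field(default_factory=lambda: {
        "diffusivity_ratio": 0.5, "max_encapsulation_density": 60.0,
        "density": 1100.0})

    def h2_modes(self, stages: int) -> list[tuple]:
        """(mode, parameter) options; active extraction needs two stages."""
        if stages == 1:
            return [("passive", None)]
        modes: list[tuple] = [("passive", None)]
        modes += [("vacuum", p) for p in self.vacuum_pressures]
        modes += [("membrane", r) for r in self.membrane_recirculations]
        return modes

    def restricted(self, **overrides) -> "DecisionSpace":
        return dc_replace(self, **overrides)


def enumerate_scenarios(space: DecisionSpace) -> pd.DataFrame:
    """Deterministic, duplicate-free cross product of applicable options.

    Returns one row per scenario with the decision values (inapplicable
    decisions are NaN/None) and a ``config`` column holding the validated
    :class:`SystemConfig`.
    """
    for name in ("reactor_types", "stages", "temperatures", "hrts",
                 "degassing"):
        if not getattr(space, name):
            raise ValueError(f"empty option set: {name}")
    rows = []
    for rt in space.reactor_types:
        encapsulated = rt != "UASB"
        if encapsulated and (not space.bead_diameters or not space.bead_lifetimes):
            raise ValueError("empty bead option set for encapsulated reactor")
        if rt == "fluidized_bed" and not space.volume_fractions:
            raise ValueError("empty volume-fraction option set")
        diameters = space.bead_diameters if encapsulated else (None,)
        lifetimes = space.bead_lifetimes if encapsulated else (None,)
        vfs = space.volume_fractions if rt == "fluidized_bed" else (None,)
        for st in space.stages:
            for mode, mpar in space.h2_modes(st):
                for deg in space.degassing:
                    for T in space.temperatures:
                        for hrt in space.hrts:
                            for d in diameters:
                                for life in lifetimes:
                                    for vf in vfs:
                                        rows.append(dict(
                                            reactor_type=rt, stages=st,
                                            h2_extraction=mode,
                                            vacuum_pressure=mpar if mode == "vacuum" else None,
                                            membrane_recirculation=mpar if mode == "membrane" else None,
                                            effluent_degassing=deg,
                                            temperature=T, total_hrt=hrt,
                                            bead_diameter=d,
                                            bead_lifetime=life,
                                            bead_volume_fraction=vf))
    df = pd.DataFrame(rows)
    dup = df.duplicated()
    if dup.any():  # pragma: no cover - construction guarantees uniqueness
        raise AssertionError("duplicate scenarios generated")
    df["config"] = [config_from_decisions(r, space) for r in rows]
    df.index.name = "scenario"
    return df


def config_from_decisions(row: dict, space: DecisionSpace) -> SystemConfig:
    """Build and validate a SystemConfig from one decision row."""
    rt = row["reactor_type"]
    bead = None
    vf = None
    voidage = None
    if rt != "UASB":
        bead = BeadSpec(diameter=row["bead_diameter"],
                        lifetime=row["bead_lifetime"],
                        **space.bead_defaults)
        if rt == "fluidized_bed":
            vf = row["bead_volume_fraction"]
        else:
            voidage = space.default_voidage
    cfg = SystemConfig(
        reactor_type=rt, stages=row["stages"],
        temperature=row["temperature"], total_hrt=row["total_hrt"],
        h2_extraction=row["h2_extraction"],
        vacuum_pressure=row["vacuum_pressure"] or 0.1,
        membrane_recirculation=row["membrane_recirculation"] or 1.0,
        effluent_degassing=row["effluent_degassing"],
        bead=bead, bead_volume_fraction=vf, bed_voidage=voidage)
    cfg.validate()
    return cfg


def pairwise_delta(decisions: pd.DataFrame, indicator: pd.Series,
                   variable: str, baseline) -> pd.DataFrame:
    """Relative impact samples of one decision variable.

    For every baseline-alternative pair differing only in ``variable``
    (matching on every other decision that applies to both scenarios),
    ``delta = (Y_alt - Y_base) / (Y_max - Y_min)`` with the range taken
    over the whole enumeration.
    """
    y = np.asarray(indicator, float)
    y_rng = np.nanmax(y) - np.nanmin(y)
    if y_rng == 0:
        raise ValueError("degenerate normalization: indicator has zero range")
    cols = [c for c in DECISION_COLUMNS if c != variable and c in decisions]
    applicable = decisions[variable].notna()
    base_mask = applicable & (decisions[variable] == baseline)
    alt_mask = applicable & (decisions[variable] != baseline)
    base_idx = np.flatnonzero(base_mask.to_numpy())
    alt_idx = np.flatnonzero(alt_mask.to_numpy())
    if base_idx.size == 0 or alt_idx.size == 0:
        raise ValueError("no baseline or no alternative scenarios")
    other = decisions[cols].to_numpy(dtype=object)
    base_vals = other[base_idx]
    out = []
    for ai in alt_idx:
        av = other[ai]
        # match where both sides have applicable (non-null) values
        both = ~(pd.isna(base_vals) | pd.isna(av)[None, :])
        eq = (base_vals == av[None, :]) | ~both
        hits = base_idx[eq.all(axis=1)]
        for bi in hits:
            out.append((variable, baseline, decisions[variable].iloc[ai],
                        int(bi), int(ai), (y[ai] - y[bi]) / y_rng))
    return pd.DataFrame(out, columns=["variable", "baseline", "alternative",
                                      "baseline_scenario",
                                      "alternative_scenario", "delta"])


# ---------------------------------------------------------------------------
# Stage II: uncertainty + Monte Carlo filtering
# ---------------------------------------------------------------------------

@dataclass
class ParameterSpec:
    """One uncertain parameter: family, bounds and role."""

    name: str
    family: Literal["uniform", "triangular", "loguniform"]
    low: float
    high: float
    mode: float | None = None
    unit: str = ""
    kind: Literal["decision", "technological", "kinetic"] = "technological"

    def validate(self) -> None:
        if not np.isfinite(self.low) or not np.isfinite(self.high):
            raise ValueError(f"{self.name}: bounds must be finite")
        if self.high <= self.low:
            raise ValueError(f"{self.name}: high must exceed low")
        if self.kind == "decision" and self.family != "uniform":
            raise ValueError(f"{self.name}: decision variables are uniform")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.family == "uniform":
            return self.low + (self.high - self.low) * u
        if self.family == "loguniform":
            return np.exp(np.log(self.low)
                          + (np.log(self.high) - np.log(self.low)) * u)
        c = (self.mode - self.low) / (self.high - self.low)
        return stats.triang.ppf(u, c, loc=self.low,
                                scale=self.high - self.low)


@dataclass
class ParameterDistributionSet:
    """Named uncertain parameters defining the Monte Carlo space."""

    specs: list[ParameterSpec]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        for s in self.specs:
            s.validate()

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def __len__(self) -> int:
        return len(self.specs)


def lhs_sample(dist_set: ParameterDistributionSet, n: int,
               seed: int) -> pd.DataFrame:
    """Latin hypercube sample: one draw per equal-probability stratum per
    parameter; deterministic under a fixed seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = stats.qmc.LatinHypercube(d=len(dist_set), seed=seed)
    u = sampler.random(n)
    data = {s.name: s.ppf(u[:, j]) for j, s in enumerate(dist_set.specs)}
    return pd.DataFrame(data)


@dataclass
class KSResult:
    """Two-sample Kolmogorov-Smirnov outcome."""

    statistic: float
    p_value: float
    n_a: int
    n_b: int


def ks_two_sample(a, b) -> KSResult:
    """Two-sample KS test: exact ECDF maximum, asymptotic p-value.

    ``D`` is the maximum absolute difference between the two empirical
    CDFs; the p-value uses the asymptotic Kolmogorov distribution at the
    effective sample size ``n_a n_b / (n_a + n_b)``.
    """
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = np.sqrt(a.size * b.size / (a.size + b.size))
    p = float(special.kolmogorov(en * d))
    return KSResult(d, min(max(p, 0.0), 1.0), a.size, b.size)


def monte_carlo_filter(samples: pd.DataFrame, indicator: pd.Series,
                       direction: Literal["higher_better", "lower_better"],
                       quantile: float = 0.25) -> pd.DataFrame:
    """Monte Carlo filtering: KS distance per parameter between the
    desirable (top ``quantile``) and undesirable groups."""
    y = np.asarray(indicator, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("indicator must be finite for all samples")
    if direction == "higher_better":
        cut = np.quantile(y, 1.0 - quantile)
        desirable = y >= cut
    elif direction == "lower_better":
        cut = np.quantile(y, quantile)
        desirable = y <= cut
    else:
        raise ValueError("direction must be higher_better or lower_better")
    if desirable.sum() < 2 or (~desirable).sum() < 2:
        raise ValueError("group with fewer than 2 samples")
    rows = []
    for name in samples.columns:
        x = samples[name].to_numpy(float)
        res = ks_two_sample(x[desirable], x[~desirable])
        rows.append((name, res.statistic, res.p_value, res.n_a, res.n_b))
    return pd.DataFrame(rows, columns=["parameter", "D", "p",
                                       "n_desirable", "n_undesirable"])


def reactor_preference_filter(samples: pd.DataFrame,
                              indicator_a: pd.Series,
                              indicator_b: pd.Series,
                              lower_better: bool = True) -> pd.DataFrame:
    """KS filtering on the sign of a paired indicator difference.

    Groups are the samples where system A outperforms system B versus the
    opposite (evaluations must share the identical sample matrix).
    """
    ya = np.asarray(indicator_a, float)
    yb = np.asarray(indicator_b, float)
    if ya.shape != yb.shape or ya.size != len(samples):
        raise ValueError("indicators must be paired on the sample matrix")
    a_better = (ya < yb) if lower_better else (ya > yb)
    if a_better.sum() < 2 or (~a_better).sum() < 2:
        raise ValueError(
            f"degenerate split: {int(a_better.sum())} vs "
            f"{int((~a_better).sum())} samples")
    rows = []
    for name in samples.columns:
        x = samples[name].to_numpy(float)
        res = ks_two_sample(x[a_better], x[~a_better])
        rows.append((name, res.statistic, res.p_value, res.n_a, res.n_b))
    return pd.DataFrame(rows, columns=["parameter", "D", "p",
                                       "n_a_better", "n_b_better"])


def rank_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (coefficient, p-value)."""
    r, p = stats.spearmanr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Stage III: grid mapping with nested bounded optimization
# ---------------------------------------------------------------------------

@dataclass
class GridMapResult:
    """Per-grid-point optimized decision variables and indicators."""

    table: pd.DataFrame
    param_names: tuple[str, str]
    dv_names: tuple[str, ...]


def stage3_map(objective: Callable[[dict, dict], dict],
               param_grid: dict[str, np.ndarray],
               dv_bounds: dict[str, tuple[float, float]],
               n_starts: int = 8, seed: int = 0,
               maxfev: int = 60) -> GridMapResult:
    """Minimize an objective over decision variables at every grid point.

    ``objective(params, dvs)`` returns a dict with key ``objective`` plus
    any extra indicator fields to record.  The search stands in for a
    bounded global optimization: a seeded Latin-hypercube pre-screen of the
    box is evaluated first and bounded local searches (Powell) are polished
    from the best pre-screen points.  Nonconverged points are flagged,
    never dropped.
    """
    if len(param_grid) != 2:
        raise ValueError("param_grid must name exactly two parameters")
    (pa, va), (pb, vb) = param_grid.items()
    dv_names = tuple(dv_bounds)
    lo = np.array([dv_bounds[k][0] for k in dv_names])
    hi = np.array([dv_bounds[k][1] for k in dv_names])
    rng = np.random.default_rng(seed)
    n_screen = max(8 * n_starts, 16)
    screen = lo + (hi - lo) * stats.qmc.LatinHypercube(
        d=len(dv_names), seed=rng.integers(2 ** 31)).random(n_screen)
    rows = []
    for x1 in np.asarray(va, float):
        for x2 in np.asarray(vb, float):
            pvals = {pa: float(x1), pb: float(x2)}
            best, ok = None, False
            cache: dict = {}

            def f(x):
                key = tuple(np.round(x, 12))
                if key not in cache:
                    out = objective(pvals, dict(zip(dv_names, np.clip(x, lo, hi))))
                    cache[key] = out
                return cache[key]["objective"]

            screened = sorted(screen, key=f)
            for x0 in screened[:max(n_starts, 1)]:
                res = optimize.minimize(
                    f, x0, method="Powell",
                    bounds=list(zip(lo, hi)),
                    options={"maxfev": maxfev, "xtol": 1e-3, "ftol": 1e-4})
                cand_x = np.clip(res.x, lo, hi)
                cand_f = f(cand_x)  # evaluate at the clipped point
                if best is None or cand_f < best["fun"]:
                    best = {"x": cand_x, "fun": float(cand_f)}
                    ok = bool(res.success) or res.status == 1
            # a budget-limited line search may end away from the best point
            # it visited; the cache holds every evaluation, so report the
            # best point actually seen
            x_seen, out_seen = min(cache.items(),
                                   key=lambda kv: kv[1]["objective"])
            if out_seen["objective"] < best["fun"]:
                best = {"x": np.clip(np.asarray(x_seen, float), lo, hi),
                        "fun": float(out_seen["objective"])}
            extra = objective(pvals, dict(zip(dv_names, best["x"])))
            row = {pa: x1, pb: x2, "objective": best["fun"],
                   "converged": ok}
            row.update({f"dv_{k}": v for k, v in zip(dv_names, best["x"])})
            row.update({k: v for k, v in extra.items() if k != "objective"})
            rows.append(row)
    return GridMapResult(pd.DataFrame(rows), (pa, pb), dv_names)


def grid_1d(low: float, high: float, n: int) -> np.ndarray:
    return np.linspace(low, high, n)
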