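"""Decision-space enumeration, pairwise impacts, LHS, KS machinery and the
grid-mapping optimizer."""
import numpy as np
import pandas as pd
import pytest

from anaerobead.analytics import (DecisionSpace, ParameterDistributionSet,
                                  ParameterSpec, enumerate_scenarios,
                                  ks_two_sample, lhs_sample,
                                  monte_carlo_filter, pairwise_delta,
                                  rank_correlation,
                                  reactor_preference_filter, stage3_map)


def independent_count(space: DecisionSpace) -> int:
    """Sum-product oracle for the enumeration size, written without the
    enumeration loop."""
    total = 0
    for rt in space.reactor_types:
        n_bead = (len(space.bead_diameters) * len(space.bead_lifetimes)
                  if rt != "UASB" else 1)
        n_vf = len(space.volume_fractions) if rt == "fluidized_bed" else 1
        for st in space.stages:
            n_h2 = 1 if st == 1 else (1 + len(space.vacuum_pressures)
                                      + len(space.membrane_recirculations))
            total += (n_h2 * len(space.degassing) * len(space.temperatures)
                      * len(space.hrts) * n_bead * n_vf)
    return total


class TestEnumeration:
    def test_default_space_has_3552_scenarios(self):
        space = DecisionSpace()
        df = enumerate_scenarios(space)
        assert len(df) == independent_count(space) == 3552

    def test_uasb_restriction_has_96(self):
        space = DecisionSpace(reactor_types=("UASB",))
        df = enumerate_scenarios(space)
        assert len(df) == independent_count(space) == 96

    def test_every_config_validates(self):
        space = DecisionSpace(hrts=(1.0,), temperatures=(22.0,),
                              degassing=(False,))
        df = enumerate_scenarios(space)
        for cfg in df["config"]:
            cfg.validate()  # raises on violation

    def test_emptied_option_set_rejected(self):
        with pytest.raises(ValueError):
            enumerate_scenarios(DecisionSpace(hrts=()))
        with pytest.raises(ValueError):
            enumerate_scenarios(DecisionSpace(volume_fractions=()))

    def test_deterministic_ordering(self):
        a = enumerate_scenarios(DecisionSpace()).drop(columns="config")
        b = enumerate_scenarios(DecisionSpace()).drop(columns="config")
        pd.testing.assert_frame_equal(a, b)


class TestPairwiseDelta:
    def _toy(self):
        decisions = pd.DataFrame({
            "reactor_type": ["UASB", "UASB", "UASB"],
            "total_hrt": [1.0, 2.0, 4.0],
        })
        indicator = pd.Series([1.0, 2.0, 4.0])
        return decisions, indicator

    def test_toy_delta_arithmetic(self):
        decisions, y = self._toy()
        out = pairwise_delta(decisions, y, "total_hrt", baseline=1.0)
        d12 = out[out["alternative"] == 2.0]["delta"].iloc[0]
        assert d12 == pytest.approx(1.0 / 3.0)
        assert np.all(np.abs(out["delta"]) <= 1.0)

    def test_pair_spanning_range_has_unit_delta(self):
        decisions, y = self._toy()
        out = pairwise_delta(decisions, y, "total_hrt", baseline=1.0)
        assert out["delta"].abs().max() == pytest.approx(1.0)

    def test_equal_indicator_gives_zero(self):
        decisions, _ = self._toy()
        y = pd.Series([5.0, 5.0, 6.0])
        out = pairwise_delta(decisions, y, "total_hrt", baseline=1.0)
        assert out[out["alternative"] == 2.0]["delta"].iloc[0] == 0.0

    def test_antisymmetric_under_swap(self):
        decisions, y = self._toy()
        fwd = pairwise_delta(decisions, y, "total_hrt", baseline=1.0)
        rev = pairwise_delta(decisions, y, "total_hrt", baseline=2.0)
        d_fwd = fwd[fwd["alternative"] == 2.0]["delta"].iloc[0]
        d_rev = rev[rev["alternative"] == 1.0]["delta"].iloc[0]
        assert d_fwd == pytest.approx(-d_rev)

    def test_degenerate_range_rejected(self):
        decisions, _ = self._toy()
        with pytest.raises(ValueError, match="degenerate"):
            pairwise_delta(decisions, pd.Series([2.0, 2.0, 2.0]),
                           "total_hrt", 1.0)


def _uniform_set(k: int = 4) -> ParameterDistributionSet:
    return ParameterDistributionSet([
        ParameterSpec(f"p{i}", "uniform", float(i), float(i + 1),
                      kind="decision") for i in range(k)])


class TestLHS:
    def test_single_sample_inside_support(self):
        df = lhs_sample(_uniform_set(), 1, seed=3)
        for i, c in enumerate(df.columns):
            assert i <= df[c].iloc[0] <= i + 1

    def test_stratification_exact(self):
        n = 64
        df = lhs_sample(_uniform_set(), n, seed=5)
        for i, c in enumerate(df.columns):
            strata = np.floor((df[c].to_numpy() - i) * n).astype(int)
            assert sorted(strata) == list(range(n))

    def test_seed_determinism(self):
        a = lhs_sample(_uniform_set(), 50, seed=11)
        b = lhs_sample(_uniform_set(), 50, seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = lhs_sample(_uniform_set(), 50, seed=12)
        assert not a.equals(c)


def _brute_force_d(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


class TestKS:
    def test_identical_and_disjoint(self):
        assert ks_two_sample([1, 2, 3], [1, 2, 3]).statistic == 0.0
        assert ks_two_sample([1, 2, 3], [4, 5, 6]).statistic == 1.0

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [1.0, 2.0])

    def test_brute_force_oracle_small(self, rng):
        for _ in range(200):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(size=rng.integers(2, 12))
            assert ks_two_sample(a, b).statistic == pytest.approx(
                _brute_force_d(a, b), abs=1e-12)

    def test_matches_scipy(self, rng):
        from scipy import stats
        a = rng.normal(size=80)
        b = rng.normal(0.4, size=120)
        mine = ks_two_sample(a, b)
        ref = stats.ks_2samp(a, b, method="asymp")
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)


class TestMonteCarloFilter:
    def test_group_sizes_at_n1000(self, rng):
        X = pd.DataFrame(rng.random((1000, 3)), columns=list("abc"))
        y = pd.Series(rng.random(1000))
        out = monte_carlo_filter(X, y, "higher_better")
        assert out["n_desirable"].iloc[0] == 250
        assert out["n_undesirable"].iloc[0] == 750

    def test_monotone_driver_attains_max_distance(self, rng):
        n = 500
        X = pd.DataFrame(rng.random((n, 5)),
                         columns=[f"p{i}" for i in range(5)])
        y = pd.Series(X["p2"] ** 2)  # indicator driven by p2 only
        out = monte_carlo_filter(X, y, "higher_better")
        assert out.loc[out["D"].idxmax(), "parameter"] == "p2"
        assert out[out["parameter"] == "p2"]["p"].iloc[0] < 1e-6

    def test_lower_better_direction(self, rng):
        n = 400
        X = pd.DataFrame(rng.random((n, 2)), columns=["a", "b"])
        y = pd.Series(X["a"])
        out = monte_carlo_filter(X, y, "lower_better")
        assert out.loc[out["D"].idxmax(), "parameter"] == "a"

    def test_nonfinite_indicator_rejected(self, rng):
        X = pd.DataFrame(rng.random((10, 2)))
        y = pd.Series(np.r_[np.nan, np.ones(9)])
        with pytest.raises(ValueError):
            monte_carlo_filter(X, y, "higher_better")


class TestReactorPreferenceFilter:
    def test_identical_indicators_rejected(self, rng):
        X = pd.DataFrame(rng.random((50, 2)), columns=["a", "b"])
        y = pd.Series(rng.random(50))
        with pytest.raises(ValueError, match="degenerate"):
            reactor_preference_filter(X, y, y.copy())

    def test_threshold_driver_found(self, rng):
        n = 300
        X = pd.DataFrame({"hrt": rng.uniform(0, 5, n),
                          "noise": rng.random(n)})
        ya = pd.Series(np.where(X["hrt"] > 2.5, 1.0, 3.0))
        yb = pd.Series(np.full(n, 2.0))
        out = reactor_preference_filter(X, ya, yb, lower_better=True)
        assert out.loc[out["D"].idxmax(), "parameter"] == "hrt"

    def test_brute_force_grouping(self, rng):
        n = 100
        X = pd.DataFrame({"x": rng.random(n)})
        ya = pd.Series(rng.random(n))
        yb = pd.Series(rng.random(n))
        out = reactor_preference_filter(X, ya, yb)
        mask = ya.to_numpy() < yb.to_numpy()
        expected = _brute_force_d(X["x"][mask], X["x"][~mask])
        assert out["D"].iloc[0] == pytest.approx(expected, abs=1e-12)


class TestRankCorrelation:
    def test_monotone_pair(self):
        x = np.arange(20.0)
        r, p = rank_correlation(x, np.exp(x / 5.0))
        assert r == pytest.approx(1.0)


class TestStage3Map:
    @staticmethod
    def _quadratic(pvals, dvs):
        # analytic minimizer at (0.3, 0.7) regardless of grid point
        val = (dvs["u"] - 0.3) ** 2 + 2.0 * (dvs["v"] - 0.7) ** 2 + pvals["a"]
        return {"objective": val}

    def test_recovers_analytic_minimizer(self):
        gm = stage3_map(self._quadratic,
                        {"a": np.array([0.0, 1.0]), "b": np.array([0.0])},
                        {"u": (0.0, 1.0), "v": (0.0, 1.0)},
                        n_starts=3, seed=7, maxfev=200)
        assert np.allclose(gm.table["dv_u"], 0.3, atol=0.01)
        assert np.allclose(gm.table["dv_v"], 0.7, atol=0.01)

    def test_grid_shape_180(self):
        va = np.linspace(0, 1, 12)
        vb = np.linspace(0, 1, 15)
        gm = stage3_map(lambda p, d: {"objective": d["u"] ** 2},
                        {"a": va, "b": vb}, {"u": (-1.0, 1.0)},
                        n_starts=1, seed=0, maxfev=30)
        assert len(gm.table) == 180

    def test_monotone_objective_pins_dvs_to_bounds(self):
        gm = stage3_map(lambda p, d: {"objective": d["u"] + 2 * d["v"]},
                        {"a": np.array([0.0]), "b": np.array([0.0])},
                        {"u": (1.0, 2.0), "v": (3.0, 4.0)},
                        n_starts=2, seed=1, maxfev=100)
        assert gm.table["dv_u"].iloc[0] == pytest.approx(1.0, abs=1e-3)
        assert gm.table["dv_v"].iloc[0] == pytest.approx(3.0, abs=1e-3)

    def test_seed_determinism(self):
        args = ({"a": np.array([0.0, 1.0]), "b": np.array([0.5])},
                {"u": (0.0, 1.0), "v": (0.0, 1.0)})
        a = stage3_map(self._quadratic, *args, n_starts=2, seed=9, maxfev=50)
        b = stage3_map(self._quadratic, *args, n_starts=2, seed=9, maxfev=50)
        pd.testing.assert_frame_equal(a.table, b.table)
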