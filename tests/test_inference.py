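"""ABC core: reference tables, rejection, model choice, posteriors, errors."""

import numpy as np
import pandas as pd
import pytest

from coalabc.inference import (
    ReferenceTable,
    build_reference_table,
    confusion_analysis,
    estimate_model_probabilities,
    estimate_posteriors,
    nearest_fraction,
    rmae,
)
from coalabc.scenarios import PriorSpec, parse_config


def synthetic_table(rng, n=500, n_stats=3, n_scen=2, signal=0.0):
    """A reference table built directly from random numbers (independent of
    the genetic simulator) for testing the ABC machinery itself."""
    scen = np.repeat(np.arange(1, n_scen + 1), n)
    theta = rng.uniform(0, 10, size=len(scen))
    stats = rng.normal(size=(len(scen), n_stats))
    stats[:, 0] += signal * scen
    df = pd.DataFrame(stats, columns=[f"S{i}" for i in range(n_stats)])
    df.insert(0, "theta", theta)
    df.insert(0, "scenario", scen)
    return ReferenceTable(
        df=df,
        param_names=["theta"],
        stat_names=[f"S{i}" for i in range(n_stats)],
        meta={},
    )


class TestReferenceTable:
    def test_row_count_and_header(self, two_pop_config):
        table = build_reference_table(
            two_pop_config, 30, ["NAL", "HET", "FST"], seed=5
        )
        assert len(table) == 30
        assert table.df.columns[0] == "scenario"
        assert table.param_names == list(two_pop_config.priors)
        assert table.stat_names[0].startswith("NAL")

    def test_same_seed_reproduces_identical_tables(self, two_pop_config, tmp_path):
        t1 = build_reference_table(two_pop_config, 20, ["NAL", "FST"], seed=9)
        t2 = build_reference_table(two_pop_config, 20, ["NAL", "FST"], seed=9)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        t1.to_tsv(p1)
        t2.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_tsv_round_trip(self, two_pop_config, tmp_path):
        t = build_reference_table(two_pop_config, 10, ["NAL"], seed=1)
        path = tmp_path / "t.tsv"
        t.to_tsv(path)
        back = ReferenceTable.from_tsv(path)
        assert back.stat_names == t.stat_names
        assert back.param_names == t.param_names
        assert np.allclose(back.df.to_numpy(), t.df.to_numpy())


class TestNearestFraction:
    def test_observed_row_has_zero_distance(self, rng):
        table = synthetic_table(rng)
        obs = table.df[table.stat_names].iloc[37]
        ret = nearest_fraction(table, obs, 0.05)
        assert 37 in ret.indices
        assert ret.distances[0] == 0.0

    def test_fraction_one_retains_everything(self, rng):
        table = synthetic_table(rng, n=50)
        obs = pd.Series(0.0, index=table.stat_names)
        ret = nearest_fraction(table, obs, 1.0)
        assert len(ret.indices) == len(table)

    def test_matches_brute_force_sort(self, rng):
        table = synthetic_table(rng, n=500)
        obs = pd.Series(rng.normal(size=3), index=table.stat_names)
        ret = nearest_fraction(table, obs, 0.01)
        X = table.stats()
        med = np.median(X, axis=0)
        mad = np.median(np.abs(X - med), axis=0)
        d = np.sqrt((((X - obs.to_numpy()) / mad) ** 2).sum(axis=1))
        brute = np.argsort(d, kind="stable")[:10]
        assert set(ret.indices) == set(brute)

    def test_zero_spread_statistic_excluded_with_warning(self, rng):
        table = synthetic_table(rng, n=200)
        table.df["S2"] = 1.0
        obs = pd.Series([0.0, 0.0, 5.0], index=table.stat_names)
        with pytest.warns(UserWarning, match="zero spread"):
            ret = nearest_fraction(table, obs, 0.05)
        assert np.all(np.isfinite(ret.distances))


class TestModelChoice:
    def test_single_scenario_subset_is_degenerate(self, rng):
        table = synthetic_table(rng, n_scen=1)
        ret = nearest_fraction(table, pd.Series(0.0, index=table.stat_names), 0.05)
        res = estimate_model_probabilities(ret)
        assert res.method == "degenerate"
        assert res.probabilities.iloc[0] == 1.0

    def test_uninformative_statistics_give_even_odds(self, rng):
        table = synthetic_table(rng, n=2000, signal=0.0)
        ret = nearest_fraction(table, pd.Series(0.0, index=table.stat_names), 0.05)
        res = estimate_model_probabilities(ret)
        p = res.probabilities
        assert abs(p.loc[1] - 0.5) < 0.15
        lo = res.table.set_index("scenario")["lo"]
        hi = res.table.set_index("scenario")["hi"]
        assert lo.loc[1] <= 0.5 + 0.1 and hi.loc[1] >= 0.5 - 0.1

    def test_probabilities_sum_to_one(self, rng):
        for signal in (0.0, 1.0, 5.0):
            table = synthetic_table(rng, n=800, n_scen=3, signal=signal)
            obs = pd.Series([signal * 2, 0, 0], index=table.stat_names)
            ret = nearest_fraction(table, obs, 0.02)
            res = estimate_model_probabilities(ret)
            assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_informative_statistic_drives_choice(self, rng):
        table = synthetic_table(rng, n=2000, signal=2.0)
        obs = pd.Series([2.0 * 2, 0, 0], index=table.stat_names)
        ret = nearest_fraction(table, obs, 0.05)
        res = estimate_model_probabilities(ret)
        assert res.best() == 2


class TestPosteriors:
    def test_conjugate_normal_recovery(self, rng):
        """ABC with local-linear adjustment recovers the analytic posterior
        of a normal mean with a wide uniform prior: N(obs, sigma^2/n)."""
        sigma_over_sqrt_n = 0.5
        prior = PriorSpec("theta", "uniform", -20.0, 20.0)
        theta = prior.draw(rng, 40_000)
        xbar = theta + rng.normal(0, sigma_over_sqrt_n, size=len(theta))
        df = pd.DataFrame({"scenario": 1, "theta": theta, "XBAR": xbar})
        table = ReferenceTable(df=df, param_names=["theta"], stat_names=["XBAR"], meta={})
        obs = pd.Series({"XBAR": 1.3})
        ret = nearest_fraction(table, obs, 0.01)
        post = estimate_posteriors(ret, {"theta": prior})
        vals = post.params["theta"].to_numpy()
        w = post.weights / post.weights.sum()
        mean = float((vals * w).sum())
        var = float(((vals - mean) ** 2 * w).sum())
        assert abs(mean - 1.3) < 0.05 * max(1.0, abs(1.3))
        assert abs(np.sqrt(var) - sigma_over_sqrt_n) / sigma_over_sqrt_n < 0.15

    def test_adjusted_values_respect_prior_support(self, rng):
        prior = PriorSpec("theta", "uniform", 0.0, 10.0)
        theta = prior.draw(rng, 5000)
        stat = theta + rng.normal(0, 3.0, size=len(theta))
        df = pd.DataFrame({"scenario": 1, "theta": theta, "S": stat})
        table = ReferenceTable(df=df, param_names=["theta"], stat_names=["S"], meta={})
        # an observed value far outside pushes the regression adjustment hard
        ret = nearest_fraction(table, pd.Series({"S": 30.0}), 0.02)
        post = estimate_posteriors(ret, {"theta": prior})
        vals = post.params["theta"].to_numpy()
        assert np.all(vals > 0.0) and np.all(vals < 10.0)

    def test_mixed_scenario_subset_rejected(self, rng):
        table = synthetic_table(rng, n=200, n_scen=2)
        ret = nearest_fraction(table, pd.Series(0.0, index=table.stat_names), 0.5)
        with pytest.raises(ValueError, match="single-scenario"):
            estimate_posteriors(ret, {"theta": PriorSpec("theta", "uniform", 0, 10)})


class TestConfusion:
    def test_identical_scenarios_confuse_maximally(self):
        """Two scenarios with the same history carry no signal: type I error
        approaches 1/2."""
        text = """
[priors]
N ~ U[500,2000]
MU ~ U[1e-4,1e-3]
P ~ U[0.1,0.3]
[loci]
microsat 3 <A> motif=2 mu=MU P=P
[samples]
A 6
[scenario 1]
pop A N
sample 0 A
[scenario 2]
pop A N
sample 0 A
"""
        cfg = parse_config(text)
        table = build_reference_table(cfg, 400, ["NAL", "HET", "VAR"], seed=3)
        res = confusion_analysis(cfg, table, ["NAL", "HET", "VAR"], n_test=40, seed=4)
        for _, row in res.iterrows():
            # 3 SE binomial band around 1/2
            assert abs(row["type1"] - 0.5) < 3 * np.sqrt(0.25 / 40) + 1e-9

    def test_distinct_scenarios_beat_chance(self):
        text = """
[priors]
MU ~ U[1e-4,1e-3]
P ~ U[0.1,0.3]
[loci]
microsat 6 <A> motif=2 mu=MU P=P
[samples]
A 8
[scenario 1]
pop A 100
sample 0 A
[scenario 2]
pop A 8000
sample 0 A
"""
        cfg = parse_config(text)
        table = build_reference_table(cfg, 400, ["NAL", "HET", "VAR"], seed=6)
        res = confusion_analysis(cfg, table, ["NAL", "HET", "VAR"], n_test=30, seed=7)
        assert (res["type1"] < 0.3).all()


class TestRmae:
    def test_exact_estimates_give_zero(self):
        assert rmae([1, 2, 3], [1, 2, 3])["rmae"] == 0.0

    def test_hand_computed_median(self):
        r = rmae([10, 20, 30], [11, 18, 36])
        assert r["rmae"] == pytest.approx(0.1)

    def test_invariant_to_rescaling(self, rng):
        t = rng.uniform(1, 10, 50)
        e = t * rng.uniform(0.5, 1.5, 50)
        assert rmae(t, e)["rmae"] == pytest.approx(rmae(10 * t, 10 * e)["rmae"])

    def test_zero_truth_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero truth"):
            r = rmae([0.0, 10.0], [1.0, 11.0])
        assert r["rmae"] == pytest.approx(0.1)

    def test_prior_baseline(self):
        prior = PriorSpec("N", "uniform", 0, 100)
        r = rmae([25.0, 50.0], [25.0, 50.0], prior=prior)
        assert r["baseline"] == pytest.approx(np.median([25 / 25, 0 / 50]))
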