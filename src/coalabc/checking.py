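"""Goodness-of-fit checks for scenario-prior and scenario-posterior fits.

Two tools:

* a prior-predictive check ("evaluate scenario-prior combination"): simulate
  up to 10,000 datasets from the prior, rank each observed summary statistic
  in the simulated distribution, and project everything on principal
  components to see whether the observed point sits inside the simulated
  cloud;
* a posterior-predictive check ("model checking"): resimulate datasets with
  parameter sets resampled from an ABC posterior sample and locate the
  observed test quantities in the posterior-predictive distribution.

For a test quantity t, q = Prob(t_sim < t_obs) is estimated with the
add-one/half-tie rule (k + ties/2 + 1)/(n + 2) so q never reaches 0 or 1
exactly; the two-sided tail probability is p = q for q <= 0.5 and 1 - q
otherwise.  Benjamini-Hochberg step-up controls the false discovery rate
across test quantities.  Checking statistics should ideally be disjoint
from the statistics used for inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorSample, simulate_dataset, _row_rng
from .scenarios import Config, Scenario, draw_parameters
from .sumstats import summarize_dataset

__all__ = [
    "CheckReport",
    "tail_probabilities",
    "bh_adjust",
    "prior_predictive_sample",
    "prior_predictive_check",
    "posterior_predictive_sample",
    "posterior_predictive_check",
    "pca_check",
    "PcaProjection",
]


def tail_probabilities(
    sim_stats: pd.DataFrame, observed: pd.Series
) -> pd.DataFrame:
    """Per-statistic cumulative probability q = Prob(t_sim < t_obs) and
    two-sided tail probability p."""
    rows = []
    n = len(sim_stats)
    if n < 1:
        raise ValueError("need at least one simulated dataset")
    for name in sim_stats.columns:
        t = sim_stats[name].to_numpy()
        t_obs = float(observed[name])
        k = float(np.sum(t < t_obs))
        ties = float(np.sum(t == t_obs))
        q = (k + 0.5 * ties + 1.0) / (n + 2.0)
        p = q if q <= 0.5 else 1.0 - q
        rows.append({"stat": name, "observed": t_obs, "q": q, "p": p})
    return pd.DataFrame(rows)


def bh_adjust(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (significant flags, adjusted p)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def _stars(p_adj: float) -> str:
    if p_adj <= 0.001:
        return "***"
    if p_adj <= 0.01:
        return "**"
    if p_adj <= 0.05:
        return "*"
    return ""


@dataclass
class PcaProjection:
    """Coordinates of prior cloud, posterior cloud and observed point on the
    principal planes of the prior-predictive statistic cloud."""

    prior_coords: np.ndarray
    observed_coords: np.ndarray
    explained_variance_ratio: np.ndarray
    components: np.ndarray
    stat_names: list[str]
    posterior_coords: np.ndarray | None = None


@dataclass
class CheckReport:
    """Tail probabilities and PCA diagnostics of one model check."""

    table: pd.DataFrame       # stat, observed, q, p, p_adj, significant, stars
    alpha: float
    pca: PcaProjection | None = None
    sim_stats: pd.DataFrame | None = None

    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def _finish_report(sim_stats, observed, alpha, pca=None) -> CheckReport:
    tab = tail_probabilities(sim_stats, observed)
    reject, p_adj = bh_adjust(tab["p"].to_numpy(), alpha)
    tab["p_adj"] = p_adj
    tab["significant"] = reject
    tab["stars"] = [_stars(x) if r else "" for x, r in zip(p_adj, reject)]
    return CheckReport(table=tab, alpha=alpha, pca=pca, sim_stats=sim_stats)


def prior_predictive_sample(
    config: Config,
    scenario: Scenario,
    selection: list[str],
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Summary statistics of ``n`` datasets simulated from the prior."""
    if n < 1:
        raise ValueError("need n >= 1 simulated datasets")
    rows = []
    for i in range(n):
        rng = _row_rng(seed, 20_000 + scenario.id, i)
        params = draw_parameters(config.priors, config.conditions, rng)
        ds = simulate_dataset(config, scenario, params, rng)
        rows.append(summarize_dataset(ds, selection))
    return pd.DataFrame(rows).reset_index(drop=True)


def prior_predictive_check(
    config: Config,
    scenario: Scenario,
    observed: pd.Series,
    selection: list[str],
    n: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> CheckReport:
    """Evaluate a scenario-prior combination against an observed dataset."""
    if n < 2:
        raise ValueError("need n >= 2 simulated datasets")
    sims = prior_predictive_sample(config, scenario, selection, n, seed)
    pca = pca_check(sims, observed)
    return _finish_report(sims, observed, alpha, pca)


def posterior_predictive_sample(
    posterior: PosteriorSample,
    config: Config,
    selection: list[str],
    n: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Statistics of ``n`` datasets simulated with parameter sets resampled
    (with replacement, proportionally to weights) from an ABC posterior."""
    if len(posterior.params) == 0:
        raise ValueError("empty posterior sample")
    if n < 1:
        raise ValueError("need n >= 1 simulated datasets")
    scen = config.scenario(posterior.scenario_id)
    w = np.asarray(posterior.weights, float)
    w = w / w.sum() if w.sum() > 0 else np.full(len(w), 1.0 / len(w))
    pick_rng = _row_rng(seed, 30_000 + scen.id, 0)
    picks = pick_rng.choice(len(posterior.params), size=n, replace=True, p=w)
    rows = []
    for i, pick in enumerate(picks):
        rng = _row_rng(seed, 30_000 + scen.id, i + 1)
        params = dict(config_defaults(config))
        params.update(posterior.params.iloc[pick].to_dict())
        ds = simulate_dataset(config, scen, params, rng)
        rows.append(summarize_dataset(ds, selection))
    return pd.DataFrame(rows).reset_index(drop=True)


def config_defaults(config: Config) -> dict[str, float]:
    """Prior medians for parameters not carried by a posterior sample
    (e.g. nuisance rate means when the posterior only covers a subset)."""
    return {name: p.median() for name, p in config.priors.items()}


def posterior_predictive_check(
    posterior: PosteriorSample,
    config: Config,
    observed: pd.Series,
    selection: list[str],
    n: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    prior_stats: pd.DataFrame | None = None,
) -> CheckReport:
    """Model checking of one scenario-posterior combination.

    ``selection`` is the checking statistic set, which may (and ideally
    should) differ from the statistics used for inference.  If
    ``prior_stats`` is provided, a PCA fitted on the prior cloud is included
    with the posterior cloud and observed point projected on it."""
    sims = posterior_predictive_sample(posterior, config, selection, n, seed)
    pca = None
    if prior_stats is not None:
        pca = pca_check(prior_stats, observed, posterior_stats=sims)
    return _finish_report(sims, observed, alpha, pca)


def pca_check(
    prior_stats: pd.DataFrame,
    observed: pd.Series,
    posterior_stats: pd.DataFrame | None = None,
) -> PcaProjection:
    """PCA fitted on the prior-predictive cloud (centered, unit-scaled);
    the posterior cloud and the observed point are projected onto the same
    axes.  Constant statistics are excluded with a warning."""
    from sklearn.decomposition import PCA

    X = prior_stats.to_numpy(float)
    names = list(prior_stats.columns)
    sd = X.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"constant statistics excluded from PCA: {dropped}")
    names = [n for n, k in zip(names, keep) if k]
    if len(names) < 2:
        raise ValueError("need at least 2 non-constant statistics for PCA")
    X = X[:, keep]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    Z = (X - mu) / sd
    n_comp = min(Z.shape[0], Z.shape[1])
    pca = PCA(n_components=n_comp)
    prior_coords = pca.fit_transform(Z)
    obs = observed[names].to_numpy(float)
    observed_coords = pca.transform(((obs - mu) / sd)[None, :])[0]
    post_coords = None
    if posterior_stats is not None:
        P = posterior_stats[names].to_numpy(float)
        post_coords = pca.transform((P - mu) / sd)
    return PcaProjection(
        prior_coords=prior_coords,
        observed_coords=observed_coords,
        explained_variance_ratio=pca.explained_variance_ratio_,
        components=pca.components_,
        stat_names=names,
        posterior_coords=post_coords,
    )
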