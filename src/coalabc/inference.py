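"""ABC core: reference tables, rejection, model choice and posteriors.

A reference table holds, per simulated dataset, the scenario id, the drawn
parameter values and the summary-statistic vector.  Inference then proceeds
by rejection: statistics are standardized by their median absolute deviation
over the whole table, the Euclidean-closest fraction (default 1%) of rows to
the observed vector is retained, and

* scenario choice fits a polychotomous (multinomial) logistic regression of
  the scenario indicator on the statistic differences, evaluated at the
  observed point (delta-method 95% CI on the fitted probabilities);
* parameter estimation applies local-linear regression with an Epanechnikov
  kernel to logit-transformed parameters, adjusting the retained draws to
  the observed point and back-transforming into the prior support.

Performance of a scenario-prior design is measured by type I / type II error
rates of the scenario choice over pseudo-observed datasets and by the
relative median absolute error (RMAE) of posterior point estimates.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import simulate_genealogy
from .mutation import (
    MicrosatModel,
    SequenceModel,
    allele_lengths,
    draw_locus_rates,
    mutate_microsat,
    mutate_sequence,
)
from .scenarios import Config, Scenario, draw_parameters
from .sumstats import GenotypeDataset, Locus, SampleInfo, summarize_dataset

__all__ = [
    "ReferenceTable",
    "ModelChoiceResult",
    "PosteriorSample",
    "simulate_dataset",
    "build_reference_table",
    "nearest_fraction",
    "estimate_model_probabilities",
    "estimate_posteriors",
    "confusion_analysis",
    "rmae",
]

_LOCUS_RATE_SHAPE = 2.0  # gamma shape of the per-locus rate hierarchy
_P_LOC_MAX = 0.99        # per-locus geometric parameter is truncated below 1


def _row_rng(seed: int, scenario_id: int, row: int) -> np.random.Generator:
    """Per-row generator so parallel table builds are order-independent."""
    return np.random.default_rng(np.random.SeedSequence((seed, scenario_id, row)))


def _resolve_rate(value, params: dict[str, float]) -> float:
    return params[value] if isinstance(value, str) else float(value)


def simulate_dataset(
    config: Config,
    scenario: Scenario,
    params: dict[str, float],
    rng: np.random.Generator,
) -> GenotypeDataset:
    """Simulate one multimarker dataset under ``scenario`` with parameter
    values ``params``.

    Microsatellite loci receive per-locus rates mu_loc, P_loc (and SNI rate)
    from Gamma(mean = dataset-level mean, shape 2); sequence loci draw their
    per-locus mean rate directly from the configured prior.
    """
    sample_times = {e.pop: e.time for e in scenario.events if e.kind == "sample"}
    sample_order = [e.pop for e in scenario.events if e.kind == "sample"]
    samples = []
    for pop in sample_order:
        spec = config.samples[pop]
        t = _resolve_rate(sample_times[pop], params)
        samples.append(
            SampleInfo(pop, t, spec.n_individuals, spec.female_fraction)
        )
    dataset = GenotypeDataset(samples=samples)

    mic_loci = [l for l in config.loci if l.kind == "microsat"]
    mic_mu = {}
    mic_p = {}
    mic_sni = {}
    if mic_loci:
        # the hierarchy is drawn jointly per rate-parameter name so loci
        # sharing a dataset-level mean share one gamma family
        by_mu: dict = {}
        for l in mic_loci:
            by_mu.setdefault((l.mu_param if isinstance(l.mu_param, str) else l.mu_param), []).append(l.name)
        for key, names in by_mu.items():
            mean = _resolve_rate(key, params)
            rates = draw_locus_rates(mean, _LOCUS_RATE_SHAPE, len(names), rng)
            mic_mu.update(zip(names, rates))
        by_p: dict = {}
        for l in mic_loci:
            by_p.setdefault(l.p_param, []).append(l.name)
        for key, names in by_p.items():
            mean = _resolve_rate(key, params)
            ps = np.minimum(
                draw_locus_rates(mean, _LOCUS_RATE_SHAPE, len(names), rng), _P_LOC_MAX
            )
            mic_p.update(zip(names, ps))
        by_sni: dict = {}
        for l in mic_loci:
            if l.sni_param is not None:
                by_sni.setdefault(l.sni_param, []).append(l.name)
        for key, names in by_sni.items():
            mean = _resolve_rate(key, params)
            rates = draw_locus_rates(mean, _LOCUS_RATE_SHAPE, len(names), rng)
            mic_sni.update(zip(names, rates))

    for spec in config.loci:
        tree = simulate_genealogy(
            scenario, params, spec, config.samples, rng,
            population_female_fraction=config.population_female_fraction,
        )
        if spec.kind == "microsat":
            model = MicrosatModel(
                mu=mic_mu[spec.name],
                p=mic_p[spec.name],
                sni_rate=mic_sni.get(spec.name, 0.0),
                range_width=spec.range_width,
                motif=spec.motif,
            )
            rep, off = mutate_microsat(tree, model, rng)
            data = allele_lengths(rep, off, spec.motif)
        else:
            if isinstance(spec.rate_param, str):
                rate = float(config.priors[spec.rate_param].draw(rng))
            else:
                rate = float(spec.rate_param)
            model = SequenceModel(
                kind=spec.model,
                rate=rate,
                kappa=spec.kappa,
                kappa1=spec.kappa1,
                kappa2=spec.kappa2,
                freqs=spec.freqs,
                invariant=spec.invariant,
                gamma_shape=spec.gamma_shape,
            )
            data = mutate_sequence(tree, model, spec.length, rng)
        dataset.loci.append(
            Locus(
                name=spec.name,
                category=spec.category,
                kind=spec.kind,
                data=data,
                sample_index=tree.leaf_sample,
                motif=spec.motif,
            )
        )
    return dataset


# ---------------------------------------------------------------------------
# Reference tables

@dataclass
class ReferenceTable:
    """Rows = simulated datasets: scenario id, parameters, statistics."""

    df: pd.DataFrame
    param_names: list[str]
    stat_names: list[str]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def stats(self) -> np.ndarray:
        return self.df[self.stat_names].to_numpy()

    def to_tsv(self, path) -> None:
        header = json.dumps(
            {
                "params": self.param_names,
                "stats": self.stat_names,
                **{k: v for k, v in self.meta.items()},
            }
        )
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            self.df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTable":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# "):
                raise ValueError("missing reference-table header line")
            meta = json.loads(first[2:])
            df = pd.read_csv(fh, sep="\t")
        params = meta.pop("params")
        stats = meta.pop("stats")
        return cls(df=df, param_names=params, stat_names=stats, meta=meta)


def _one_row(config, scenario, selection, seed, row):
    rng = _row_rng(seed, scenario.id, row)
    params = draw_parameters(config.priors, config.conditions, rng)
    dataset = simulate_dataset(config, scenario, params, rng)
    stats = summarize_dataset(dataset, selection)
    return params, stats


def build_reference_table(
    config: Config,
    n_per_scenario: int,
    selection: list[str],
    seed: int,
    scenario_ids: list[int] | None = None,
    workers: int = 1,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` datasets per scenario and summarize them.

    Bitwise-reproducible for a given seed with ``workers=1``; with more
    workers the multiset of rows is seed-reproducible (each row has its own
    generator keyed by (seed, scenario, row))."""
    scen = (
        config.scenarios
        if scenario_ids is None
        else [config.scenario(i) for i in scenario_ids]
    )
    jobs = [(s, i) for s in scen for i in range(n_per_scenario)]
    if workers > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=workers, batch_size=256)(
            delayed(_one_row)(config, s, selection, seed, i) for s, i in jobs
        )
    else:
        results = [_one_row(config, s, selection, seed, i) for s, i in jobs]

    param_names = list(config.priors)
    stat_names = list(results[0][1].index)
    rows = np.empty((len(jobs), 1 + len(param_names) + len(stat_names)))
    for r, ((s, _i), (params, stats)) in enumerate(zip(jobs, results)):
        rows[r, 0] = s.id
        rows[r, 1:1 + len(param_names)] = [params[p] for p in param_names]
        rows[r, 1 + len(param_names):] = stats.to_numpy()
    df = pd.DataFrame(rows, columns=["scenario", *param_names, *stat_names])
    df["scenario"] = df["scenario"].astype(int)
    return ReferenceTable(
        df=df,
        param_names=param_names,
        stat_names=stat_names,
        meta={"seed": seed, "n_per_scenario": n_per_scenario,
              "scenario_ids": [s.id for s in scen]},
    )


# ---------------------------------------------------------------------------
# Rejection

def _mad_scale(X: np.ndarray, stat_names: list[str]) -> np.ndarray:
    """Median absolute deviation per statistic; zero-spread statistics are
    excluded from distances (scale set to inf) with a warning."""
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    dead = mad <= 0
    if np.any(dead):
        names = [stat_names[i] for i in np.flatnonzero(dead)]
        warnings.warn(f"statistics with zero spread excluded from distance: {names}")
        mad = mad.copy()
        mad[dead] = np.inf
    return mad


@dataclass
class RetainedSet:
    """The closest fraction of a reference table to one observed vector."""

    table: ReferenceTable
    indices: np.ndarray       # row indices into table.df, by increasing distance
    distances: np.ndarray
    scale: np.ndarray         # per-statistic MAD used for standardization
    observed: np.ndarray

    @property
    def df(self) -> pd.DataFrame:
        return self.table.df.iloc[self.indices]

    def standardized_diffs(self) -> np.ndarray:
        X = self.table.stats()[self.indices]
        return (X - self.observed) / self.scale


def nearest_fraction(
    table: ReferenceTable,
    observed: pd.Series | np.ndarray,
    fraction: float = 0.01,
    scale: np.ndarray | None = None,
) -> RetainedSet:
    """Retain the ceil(fraction * n) rows closest to ``observed`` in
    MAD-standardized Euclidean distance (ties broken by row index)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    obs = _align_observed(table, observed)
    X = table.stats()
    if scale is None:
        scale = _mad_scale(X, table.stat_names)
    Z = (X - obs) / scale
    d = np.sqrt(np.sum(Z * Z, axis=1))
    n_keep = math.ceil(fraction * len(X))
    order = np.lexsort((np.arange(len(d)), d))[:n_keep]
    return RetainedSet(
        table=table, indices=order, distances=d[order], scale=scale, observed=obs
    )


def _align_observed(table: ReferenceTable, observed) -> np.ndarray:
    if isinstance(observed, pd.Series):
        missing = [s for s in table.stat_names if s not in observed.index]
        if missing:
            raise ValueError(f"observed vector lacks statistics {missing}")
        return observed[table.stat_names].to_numpy(float)
    obs = np.asarray(observed, float)
    if obs.shape != (len(table.stat_names),):
        raise ValueError("observed vector has wrong length")
    return obs


# ---------------------------------------------------------------------------
# Model choice

@dataclass
class ModelChoiceResult:
    """Posterior probability (and 95% CI) per competing scenario."""

    table: pd.DataFrame  # columns: scenario, prob, lo, hi
    method: str          # "mnlogit" | "proportion" | "degenerate"

    @property
    def probabilities(self) -> pd.Series:
        return self.table.set_index("scenario")["prob"]

    def best(self) -> int:
        return int(self.table.loc[self.table["prob"].idxmax(), "scenario"])


def estimate_model_probabilities(retained: RetainedSet) -> ModelChoiceResult:
    """Multinomial logistic regression of the scenario indicator on the
    standardized statistic differences, evaluated at the observed point."""
    import statsmodels.api as sm

    y = retained.df["scenario"].to_numpy(int)
    classes = np.unique(y)
    if len(classes) == 1:
        tab = pd.DataFrame(
            {"scenario": classes, "prob": [1.0], "lo": [1.0], "hi": [1.0]}
        )
        return ModelChoiceResult(table=tab, method="degenerate")

    Z = retained.standardized_diffs()
    keep = np.isfinite(Z).all(axis=0) & (Z.std(axis=0) > 1e-10)
    Z = Z[:, keep]
    X = np.column_stack([np.ones(len(Z)), Z])
    codes = np.searchsorted(classes, y)
    try:
        res = None
        with warnings.catch_warnings():
            # separation makes the MLE drift to infinity; the capped-iteration
            # iterate still carries the right (saturating) probabilities
            warnings.simplefilter("ignore")
            model = sm.MNLogit(codes, X)
            for method, maxiter in (("newton", 100), ("lbfgs", 500)):
                try:
                    res = model.fit(method=method, maxiter=maxiter, disp=0)
                    if np.all(np.isfinite(np.asarray(res.params))):
                        break
                except (np.linalg.LinAlgError, ValueError):
                    res = None
        if res is None or not np.all(np.isfinite(np.asarray(res.params))):
            raise np.linalg.LinAlgError("multinomial fit failed")
        beta = np.asarray(res.params)        # (k_feat, K-1)
        eta = beta[0]                        # intercepts = value at observed point
        expo = np.exp(np.concatenate([[0.0], eta]) - max(0.0, eta.max()))
        p = expo / expo.sum()
        # delta method through the intercept covariance
        k_feat = X.shape[1]
        K = len(classes)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cov = np.asarray(res.cov_params())
            idx = [j * k_feat for j in range(K - 1)]  # intercepts, per equation
            V_eta = cov[np.ix_(idx, idx)]
            J = np.zeros((K, K - 1))
            for i in range(K):
                for j in range(1, K):
                    J[i, j - 1] = p[i] * ((1.0 if i == j else 0.0) - p[j])
            V_p = J @ V_eta @ J.T
            se = np.sqrt(np.clip(np.diag(V_p), 0.0, None))
            if not np.all(np.isfinite(se)):
                se = np.zeros(K)
        except (np.linalg.LinAlgError, ValueError):
            se = np.zeros(K)
        lo = np.clip(p - 1.96 * se, 0.0, 1.0)
        hi = np.clip(p + 1.96 * se, 0.0, 1.0)
        tab = pd.DataFrame({"scenario": classes, "prob": p, "lo": lo, "hi": hi})
        return ModelChoiceResult(table=tab, method="mnlogit")
    except (np.linalg.LinAlgError, ValueError, RuntimeError):
        # perfect separation or singular design: categorical proportions
        counts = np.array([(y == c).sum() for c in classes], float)
        p = counts / counts.sum()
        se = np.sqrt(p * (1 - p) / counts.sum())
        tab = pd.DataFrame(
            {
                "scenario": classes,
                "prob": p,
                "lo": np.clip(p - 1.96 * se, 0, 1),
                "hi": np.clip(p + 1.96 * se, 0, 1),
            }
        )
        return ModelChoiceResult(table=tab, method="proportion")


# ---------------------------------------------------------------------------
# Parameter estimation

def _transform(x: np.ndarray, prior) -> np.ndarray:
    a, b = prior.support
    if math.isfinite(b):
        return np.log((x - a) / (b - x))
    return np.log(x)


def _back_transform(z: np.ndarray, prior) -> np.ndarray:
    a, b = prior.support
    if math.isfinite(b):
        return a + (b - a) / (1.0 + np.exp(-z))
    return np.exp(z)


def _clip_to_support(x: np.ndarray, prior) -> np.ndarray:
    a, b = prior.support
    if math.isfinite(b):
        eps = 1e-9 * (b - a)
        return np.clip(x, a + eps, b - eps)
    return np.clip(x, 1e-300, None)


def weighted_quantile(values: np.ndarray, q, weights: np.ndarray) -> np.ndarray:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    if cw[-1] <= 0:
        return np.quantile(v, q)
    cw = (cw - 0.5 * w) / cw[-1]
    return np.interp(q, cw, v)


@dataclass
class PosteriorSample:
    """Weighted, regression-adjusted parameter vectors for one scenario."""

    scenario_id: int
    params: pd.DataFrame      # adjusted draws, columns = parameter names
    weights: np.ndarray
    ridged: bool = False

    def median(self) -> pd.Series:
        return pd.Series(
            {
                c: float(weighted_quantile(self.params[c].to_numpy(), 0.5, self.weights))
                for c in self.params.columns
            }
        )

    def quantiles(self, qs=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
        return pd.DataFrame(
            {
                c: weighted_quantile(self.params[c].to_numpy(), qs, self.weights)
                for c in self.params.columns
            },
            index=list(qs),
        )


def estimate_posteriors(
    retained: RetainedSet,
    priors: dict,
    param_names: list[str] | None = None,
) -> PosteriorSample:
    """Local-linear regression adjustment of the retained parameter draws.

    Parameters are mapped to an unbounded scale (logit over the prior
    bounds, log for unbounded priors), regressed on the standardized
    statistic differences with Epanechnikov weights (bandwidth = largest
    retained distance), residual-adjusted to the observed point, and
    back-transformed.  The retained subset must come from one scenario.
    """
    scen_ids = retained.df["scenario"].unique()
    if len(scen_ids) != 1:
        raise ValueError("posterior estimation needs a single-scenario subset")
    param_names = param_names or retained.table.param_names
    theta = retained.df[param_names].to_numpy(float)
    Z = retained.standardized_diffs()
    Z = Z[:, np.isfinite(Z).all(axis=0)]
    d = retained.distances
    dmax = d.max()
    w = 1.0 - (d / dmax) ** 2 if dmax > 0 else np.ones_like(d)
    w = np.clip(w, 0.0, None)
    if w.sum() <= 0:
        w = np.ones_like(d)

    T = np.column_stack(
        [_transform(_clip_to_support(theta[:, j], priors[p]), priors[p])
         for j, p in enumerate(param_names)]
    )
    X = np.column_stack([np.ones(len(Z)), Z])
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    Tw = T * sw[:, None]
    ridged = False
    beta, _, rank, _ = np.linalg.lstsq(Xw, Tw, rcond=None)
    if rank < X.shape[1]:
        ridged = True
        lam = 1e-8
        A = Xw.T @ Xw + lam * np.eye(X.shape[1])
        beta = np.linalg.solve(A, Xw.T @ Tw)
    # adjusted transformed draws = value at the observed point + residual
    T_adj = T - Z @ beta[1:, :]
    out = {}
    for j, p in enumerate(param_names):
        a, b = priors[p].support
        col = T_adj[:, j]
        if math.isfinite(b):
            # clip on the transformed scale via the bounded back-transform
            vals = _back_transform(col, priors[p])
            eps = 1e-9 * (b - a)
            vals = np.clip(vals, a + eps, b - eps)
        else:
            vals = _back_transform(col, priors[p])
        out[p] = vals
    return PosteriorSample(
        scenario_id=int(scen_ids[0]),
        params=pd.DataFrame(out),
        weights=w,
        ridged=ridged,
    )


# ---------------------------------------------------------------------------
# Performance evaluation

def classify_batch(
    table: ReferenceTable, observed_df: pd.DataFrame, fraction: float = 0.01
) -> tuple[np.ndarray, list[ModelChoiceResult]]:
    """Model choice for many observed vectors against one reference table;
    returns the chosen scenario ids and the full results."""
    scale = _mad_scale(table.stats(), table.stat_names)
    choices = []
    results = []
    for _, row in observed_df[table.stat_names].iterrows():
        retained = nearest_fraction(table, row, fraction, scale=scale)
        res = estimate_model_probabilities(retained)
        results.append(res)
        choices.append(res.best())
    return np.asarray(choices), results


def confusion_analysis(
    config: Config,
    table: ReferenceTable,
    selection: list[str],
    n_test: int,
    fraction: float = 0.01,
    seed: int = 0,
    scenario_ids: list[int] | None = None,
) -> pd.DataFrame:
    """Type I / type II error rates of scenario choice.

    Simulates ``n_test`` pseudo-observed datasets per scenario from the
    priors, classifies each by highest posterior probability, and reports
    per scenario the type I error (true scenario not chosen) and type II
    error (scenario chosen when another was true), with binomial standard
    errors."""
    ids = scenario_ids or [s.id for s in config.scenarios]
    truth = []
    stats_rows = []
    for sid in ids:
        scen = config.scenario(sid)
        for i in range(n_test):
            rng = _row_rng(seed, 10_000 + sid, i)
            params = draw_parameters(config.priors, config.conditions, rng)
            ds = simulate_dataset(config, scen, params, rng)
            stats_rows.append(summarize_dataset(ds, selection))
            truth.append(sid)
    truth = np.asarray(truth)
    observed_df = pd.DataFrame(stats_rows).reset_index(drop=True)
    chosen, _ = classify_batch(table, observed_df, fraction)

    rows = []
    for sid in ids:
        own = truth == sid
        t1 = float(np.mean(chosen[own] != sid))
        n1 = int(own.sum())
        t2 = float(np.mean(chosen[~own] == sid))
        n2 = int((~own).sum())
        rows.append(
            {
                "scenario": sid,
                "type1": t1,
                "type1_se": math.sqrt(max(t1 * (1 - t1), 1e-12) / n1),
                "type2": t2,
                "type2_se": math.sqrt(max(t2 * (1 - t2), 1e-12) / n2),
            }
        )
    return pd.DataFrame(rows)


def rmae(
    truths: np.ndarray,
    estimates: np.ndarray,
    prior=None,
) -> dict[str, float]:
    """Relative median absolute error of point estimates.

    RMAE = median over test datasets of |estimate - truth| / truth; test
    sets with zero truth are excluded with a warning.  If ``prior`` is
    given, also reports the prior-only baseline in which every estimate is
    the prior median."""
    truths = np.asarray(truths, float)
    estimates = np.asarray(estimates, float)
    if truths.shape != estimates.shape:
        raise ValueError("truths and estimates must have matching shapes")
    ok = truths != 0
    if not np.all(ok):
        warnings.warn(f"excluding {int((~ok).sum())} test sets with zero truth")
    truths, estimates = truths[ok], estimates[ok]
    out = {"rmae": float(np.median(np.abs(estimates - truths) / truths))}
    if prior is not None:
        m = prior.median()
        out["baseline"] = float(np.median(np.abs(m - truths) / truths))
    return out
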