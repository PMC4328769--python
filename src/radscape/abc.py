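"""ABC model choice among divergence scenarios.

The rejection ("direct") estimate is the share of each scenario among the
reference-table rows closest to the observed summary statistics in
standardized Euclidean distance; the logistic estimate fits a multinomial
regression of scenario identity on the (centred) statistics over the
retained rows and evaluates the class probabilities at the observed point.

Priors follow the log-uniform convention: effective sizes 1-400,000
(nuclear) or 0.25-100,000 (mitochondrial, fourfold-smaller scale),
divergence times 1,000-10,000,000 generations, mutation rates 1e-8-1e-6
(nuclear, mean 1e-7) or 1e-7-1e-5 (mitochondrial, mean 1e-6) per site per
generation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .scenarios import Scenario
from .simulate import SampleDesign, simulate_marker
from .stats import SummaryStatVector, summary_stats


@dataclass(frozen=True)
class PriorConfig:
    """Log-uniform prior bounds for one marker."""

    ne_bounds: tuple[float, float]
    time_bounds: tuple[float, float] = (1_000.0, 10_000_000.0)
    mutation_rate_bounds: tuple[float, float] = (1e-8, 1e-6)

    def __post_init__(self) -> None:
        for lo, hi in (self.ne_bounds, self.time_bounds, self.mutation_rate_bounds):
            if not 0 < lo < hi:
                raise ConfigurationError("prior bounds must satisfy 0 < lower < upper")


def rad_prior() -> PriorConfig:
    return PriorConfig(ne_bounds=(1.0, 400_000.0), mutation_rate_bounds=(1e-8, 1e-6))


def mito_prior() -> PriorConfig:
    return PriorConfig(ne_bounds=(0.25, 100_000.0), mutation_rate_bounds=(1e-7, 1e-5))


def log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=size))


@dataclass
class ParameterDraw:
    sizes: dict[str, float]
    times: list[float]
    mutation_rate: float

    def flat(self) -> dict[str, float]:
        out = {f"ne_{r}": v for r, v in self.sizes.items()}
        out.update({f"t{i + 1}": t for i, t in enumerate(self.times)})
        out["mu"] = self.mutation_rate
        return out


def sample_prior(config: PriorConfig, scenario: Scenario, rng) -> ParameterDraw:
    """One joint draw: per-region sizes, sorted event times, mutation rate.

    Event times are drawn independently log-uniformly and sorted; assigning
    them in the scenario's template order preserves the topology's
    root-path ordering constraints.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sizes = {r: float(log_uniform(rng, *config.ne_bounds)) for r in scenario.leaves}
    times = sorted(
        float(log_uniform(rng, *config.time_bounds)) for _ in scenario.events
    )
    mu = float(log_uniform(rng, *config.mutation_rate_bounds))
    return ParameterDraw(sizes, times, mu)


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, summary statistics) rows."""

    scenario_names: list[str]
    scenario_idx: np.ndarray  # (N,)
    params: pd.DataFrame
    stats: np.ndarray  # (N, n_stats)
    stat_names: list[str]
    stat_mean: np.ndarray = field(init=False)
    stat_sd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.stat_mean = np.nanmean(self.stats, axis=0)
            self.stat_sd = np.nanstd(self.stats, axis=0)
        self.stat_mean = np.nan_to_num(self.stat_mean)

    @property
    def n_rows(self) -> int:
        return len(self.scenario_idx)

    def usable_stats(self) -> np.ndarray:
        """Columns with positive, finite spread (zero-SD stats are dropped
        from the distance with a warning)."""
        ok = np.isfinite(self.stat_sd) & (self.stat_sd > 0)
        if not ok.all():
            dropped = [self.stat_names[i] for i in np.where(~ok)[0]]
            warnings.warn(f"dropping degenerate summary statistics: {dropped}")
        return ok

    def standardized(self, values: np.ndarray) -> np.ndarray:
        """Standardize; NaN sentinels are imputed to 0 (the table mean)
        after standardization, with companion indicator columns for any
        statistic that is ever undefined in the table."""
        values = np.atleast_2d(np.asarray(values, dtype=float))
        ok = self.usable_stats()
        z = (values[:, ok] - self.stat_mean[ok]) / self.stat_sd[ok]
        nan_mask = np.isnan(z)
        z[nan_mask] = 0.0
        ever_nan = np.isnan(self.stats[:, ok]).any(axis=0)
        if ever_nan.any():
            z = np.hstack([z, np.isnan(values[:, ok][:, ever_nan]).astype(float)])
        return z


def build_reference_table(
    scenarios: dict[str, Scenario],
    config: PriorConfig,
    design: SampleDesign,
    n_per_scenario: int,
    rng_seed: int,
) -> ReferenceTable:
    """Simulate `n_per_scenario` datasets per scenario and summarize each.

    Each row redraws all parameters from the prior, simulates the design
    under the scenario via the coalescent engine and computes the
    summary-statistic vector.
    """
    if len(scenarios) < 2:
        raise ConfigurationError("model choice needs at least two scenarios")
    names = list(scenarios)
    rng = np.random.default_rng(rng_seed)
    sim_seeds = np.random.SeedSequence(rng_seed).generate_state(
        len(names) * n_per_scenario, dtype=np.uint32
    )

    rows_idx: list[int] = []
    rows_params: list[dict] = []
    rows_stats: list[np.ndarray] = []
    stat_names: list[str] | None = None
    r = 0
    for si, name in enumerate(names):
        scenario = scenarios[name]
        for _ in range(n_per_scenario):
            draw = sample_prior(config, scenario, rng)
            sim_scenario = scenario.with_parameters(sizes=draw.sizes, times=draw.times)
            sim_design = replace(design, mutation_rate=draw.mutation_rate)
            dataset = simulate_marker(sim_scenario, sim_design, int(sim_seeds[r]))
            vec = summary_stats(dataset)
            if stat_names is None:
                stat_names = vec.names
            rows_idx.append(si)
            rows_params.append({"scenario": name, **draw.flat()})
            rows_stats.append(vec.values)
            r += 1

    return ReferenceTable(
        scenario_names=names,
        scenario_idx=np.asarray(rows_idx, dtype=np.int64),
        params=pd.DataFrame(rows_params),
        stats=np.vstack(rows_stats),
        stat_names=list(stat_names),
    )


@dataclass
class ModelChoiceResult:
    scenario_names: list[str]
    probabilities: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    method: str
    n_used: int
    regularized: bool = False

    def best(self) -> str:
        return self.scenario_names[int(np.argmax(self.probabilities))]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario_names,
                "probability": self.probabilities,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _distances(observed, table: ReferenceTable) -> np.ndarray:
    if isinstance(observed, SummaryStatVector):
        observed = observed.values
    z_obs = table.standardized(observed)
    z_tab = table.standardized(table.stats)
    return np.sqrt(((z_tab - z_obs) ** 2).sum(axis=1))


def abc_direct(observed, table: ReferenceTable, n_closest: int = 500) -> ModelChoiceResult:
    """Rejection estimate: scenario shares among the closest rows, with
    Wilson binomial confidence intervals."""
    if not 1 <= n_closest <= table.n_rows:
        raise ConfigurationError("n_closest must lie in [1, table rows]")
    from statsmodels.stats.proportion import proportion_confint

    d = _distances(observed, table)
    nearest = np.argsort(d, kind="stable")[:n_closest]
    counts = np.bincount(table.scenario_idx[nearest], minlength=len(table.scenario_names))
    probs = counts / n_closest
    lo, hi = proportion_confint(counts, n_closest, alpha=0.05, method="wilson")
    return ModelChoiceResult(
        table.scenario_names, probs, np.atleast_1d(lo), np.atleast_1d(hi),
        method="direct", n_used=n_closest,
    )


def _softmax_probs_and_ci(intercepts: np.ndarray, cov: np.ndarray | None, K: int):
    """Class probabilities at the observed point (features = 0) and delta-
    method CIs from the intercept covariance block (reference class first)."""
    eta = np.concatenate([[0.0], intercepts])
    e = np.exp(eta - eta.max())
    p = e / e.sum()
    if cov is None:
        return p, np.full(K, np.nan), np.full(K, np.nan)
    # dp_k / d eta_j for j = 1..K-1 (intercepts of non-reference classes)
    J = np.zeros((K, K - 1))
    for k_ in range(K):
        for j in range(1, K):
            J[k_, j - 1] = p[k_] * ((1.0 if j == k_ else 0.0) - p[j])
    var = np.clip(np.diag(J @ cov @ J.T), 0.0, None)
    half = 1.959963984540054 * np.sqrt(var)
    return p, np.clip(p - half, 0, 1), np.clip(p + half, 0, 1)


def abc_logistic(
    observed, table: ReferenceTable, n_retained: int = 500, ci: bool = True
) -> ModelChoiceResult:
    """Logistic-regression estimate on the retained closest rows.

    Falls back to a ridge-regularized multinomial fit (flagged, no CI)
    when the maximum-likelihood fit separates or fails to converge.
    """
    if not 1 <= n_retained <= table.n_rows:
        raise ConfigurationError("n_retained must lie in [1, table rows]")
    d = _distances(observed, table)
    nearest = np.argsort(d, kind="stable")[:n_retained]
    y_raw = table.scenario_idx[nearest]
    present = np.unique(y_raw)
    K_all = len(table.scenario_names)

    if len(present) == 1:
        probs = np.zeros(K_all)
        probs[present[0]] = 1.0
        return ModelChoiceResult(
            table.scenario_names, probs, probs.copy(), probs.copy(),
            method="logistic", n_used=n_retained,
        )

    z_obs = table.standardized(
        observed.values if isinstance(observed, SummaryStatVector) else observed
    )
    X = table.standardized(table.stats)[nearest] - z_obs
    remap = {c: i for i, c in enumerate(present)}
    y = np.array([remap[c] for c in y_raw])
    K = len(present)

    probs_sub = lo_sub = hi_sub = None
    if ci:
        probs_sub, lo_sub, hi_sub = _mnlogit_ml(X, y, K)
    if probs_sub is None:
        probs_sub = _ridge_fallback(X, y, K)
        lo_sub = hi_sub = np.full(K, np.nan)
        regularized = True
    else:
        regularized = False

    probs = np.zeros(K_all)
    lo = np.zeros(K_all)
    hi = np.zeros(K_all)
    probs[present] = probs_sub
    lo[present] = lo_sub
    hi[present] = hi_sub
    return ModelChoiceResult(
        table.scenario_names, probs, lo, hi,
        method="logistic", n_used=n_retained, regularized=regularized,
    )


def _mnlogit_ml(X: np.ndarray, y: np.ndarray, K: int):
    """Maximum-likelihood multinomial fit; None on separation/failure."""
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MNLogit(y, Xc).fit(disp=0, maxiter=200, method="newton")
        if not fit.mle_retvals.get("converged", False):
            return None, None, None
        params = np.asarray(fit.params)  # (n_features+1, K-1)
        cov = np.asarray(fit.cov_params())
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(cov)):
            return None, None, None
        intercepts = params[0, :]
        n_feat = Xc.shape[1]
        # intercept entries sit at positions j*n_feat for class j
        pos = [j * n_feat for j in range(K - 1)]
        cov_int = cov[np.ix_(pos, pos)]
        return _softmax_probs_and_ci(intercepts, cov_int, K)
    except Exception:
        return None, None, None


def _ridge_fallback(X: np.ndarray, y: np.ndarray, K: int) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0, max_iter=2000)
    clf.fit(X, y)
    p = clf.predict_proba(np.zeros((1, X.shape[1])))[0]
    out = np.zeros(K)
    out[clf.classes_] = p
    return out


def pseudo_observed_recovery(
    scenarios: dict[str, Scenario],
    true_scenario: str,
    table: ReferenceTable,
    design: SampleDesign,
    n_replicates: int = 50,
    n_closest: int = 500,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Model-choice recovery experiment.

    Simulates `n_replicates` pseudo-observed datasets under the true
    scenario's own parameters (not prior draws) and records which scenario
    each ABC estimator ranks first.
    """
    seeds = np.random.SeedSequence(rng_seed).generate_state(n_replicates, dtype=np.uint32)
    rows = []
    for rep in range(n_replicates):
        dataset = simulate_marker(scenarios[true_scenario], design, int(seeds[rep]))
        vec = summary_stats(dataset)
        direct = abc_direct(vec, table, n_closest)
        logistic = abc_logistic(vec, table, n_closest, ci=False)
        rows.append(
            {
                "replicate": rep,
                "direct_best": direct.best(),
                "logistic_best": logistic.best(),
                "direct_p_true": direct.probabilities[table.scenario_names.index(true_scenario)],
                "logistic_p_true": logistic.probabilities[table.scenario_names.index(true_scenario)],
                "direct_sum": float(direct.probabilities.sum()),
                "logistic_sum": float(logistic.probabilities.sum()),
            }
        )
    return pd.DataFrame(rows)
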