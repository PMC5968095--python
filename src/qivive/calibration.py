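"""Bayesian refinement of the sensitive PBPK parameters.

Observed MAA concentration-time data are fitted by random-walk
Metropolis-Hastings over the route-specific sensitive parameter set (oral:
BW, PS2, KEX; inhalation: BW, QPC, PS2, KEX) plus the residual error scale
sigma.  The default measurement model is multiplicative log-normal — the
observation equals the model prediction times exp(eps), eps ~ N(0, sigma^2)
— which treats scatter about the prediction as a combination of measurement
error and structural model error.  An additive Gaussian variant is
available.  Posterior summaries mirror a median + central 95% interval
layout with a Gelman-Rubin convergence diagnostic, and posterior-predictive
percentile bands are read off per time point across the retained draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from qivive.pbpk import (
    ExposureScenario,
    PBPKParameters,
    simulate,
)
from qivive.sensitivity import default_screening_ranges

__all__ = [
    "Uniform",
    "TruncatedNormal",
    "PriorSpec",
    "ObservedDataset",
    "PosteriorSampleSet",
    "PredictiveBand",
    "default_priors",
    "log_likelihood",
    "run_mcmc",
    "posterior_summary",
    "predictive_band",
    "SENSITIVE_PARAMETERS",
]

#: Route-specific sensitive parameter sets carried into calibration and ABC.
SENSITIVE_PARAMETERS = {
    "oral": ("BW", "PS2", "KEX"),
    "inhalation": ("BW", "QPC", "PS2", "KEX"),
}


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Uniform:
    lo: float
    hi: float

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"uniform prior requires lo < hi, got ({self.lo}, {self.hi})")

    @property
    def mean(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def support(self) -> tuple[float, float]:
        return (self.lo, self.hi)

    def logpdf(self, x: float) -> float:
        return -math.log(self.hi - self.lo) if self.lo <= x <= self.hi else -math.inf

    def sample(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.lo, self.hi, size=size)


@dataclass(frozen=True)
class TruncatedNormal:
    mu: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self):
        if self.sd <= 0 or not self.lo < self.hi:
            raise ValueError("truncated normal requires sd > 0 and lo < hi")

    @property
    def _dist(self):
        a, b = (self.lo - self.mu) / self.sd, (self.hi - self.mu) / self.sd
        return stats.truncnorm(a, b, loc=self.mu, scale=self.sd)

    @property
    def mean(self) -> float:
        return float(self._dist.mean())

    def support(self) -> tuple[float, float]:
        return (self.lo, self.hi)

    def logpdf(self, x: float) -> float:
        return float(self._dist.logpdf(x))

    def sample(self, rng: np.random.Generator, size=None):
        return self._dist.rvs(size=size if size is not None else 1,
                              random_state=rng) if size is not None else float(
            self._dist.rvs(random_state=rng))


@dataclass(frozen=True)
class PriorSpec:
    """Ordered priors for the calibrated parameters plus the error scale."""

    parameters: dict[str, Uniform | TruncatedNormal]
    sigma: Uniform | TruncatedNormal = field(default_factory=lambda: Uniform(0.01, 1.0))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.parameters)

    def all_items(self) -> list[tuple[str, Uniform | TruncatedNormal]]:
        return list(self.parameters.items()) + [("sigma", self.sigma)]

    def log_prior(self, theta: np.ndarray) -> float:
        return sum(pr.logpdf(v) for (_, pr), v in zip(self.all_items(), theta))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return np.array([pr.sample(rng) for _, pr in self.all_items()], float)

    def in_support(self, theta: np.ndarray) -> bool:
        return all(pr.support()[0] <= v <= pr.support()[1]
                   for (_, pr), v in zip(self.all_items(), theta))


def default_priors(route: str, widen: float = 1.0) -> PriorSpec:
    """Uniform priors on the +/-15% screening ranges for the route's
    sensitive parameters; ``widen`` symmetrically expands each interval."""
    ranges = default_screening_ranges()
    priors: dict[str, Uniform | TruncatedNormal] = {}
    for name in SENSITIVE_PARAMETERS[route]:
        i = ranges.names.index(name)
        lo, hi = ranges.mins[i], ranges.maxs[i]
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo) * widen
        priors[name] = Uniform(max(mid - half, 1e-12), mid + half)
    return PriorSpec(parameters=priors)


# ---------------------------------------------------------------------------
# data
# ---------------------------------------------------------------------------

@dataclass
class ObservedDataset:
    """Replicate concentration observations tied to an exposure scenario."""

    times: np.ndarray          # h
    concentrations: np.ndarray  # mM
    replicates: np.ndarray     # replicate id per record
    scenario: ExposureScenario

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.concentrations = np.asarray(self.concentrations, float)
        self.replicates = np.asarray(self.replicates)
        if not (len(self.times) == len(self.concentrations) == len(self.replicates)):
            raise ValueError("ragged observation records")
        if self.times.max() > self.scenario.t_end + 1e-9:
            raise ValueError("observation times exceed the scenario horizon")

    def __len__(self) -> int:
        return len(self.times)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scenario: ExposureScenario) -> "ObservedDataset":
        return cls(df["time_h"].to_numpy(), df["conc_mM"].to_numpy(),
                   df["replicate"].to_numpy(), scenario)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.times, "conc_mM": self.concentrations,
                             "replicate": self.replicates})

    def unique_times(self) -> np.ndarray:
        return np.unique(self.times)


def _predict_at(params: PBPKParameters, data: ObservedDataset) -> np.ndarray:
    """Venous-blood MAA prediction at every observation record's time."""
    import dataclasses
    ut = data.unique_times()
    scenario = dataclasses.replace(data.scenario, output_grid=ut)
    ts = simulate(params, scenario)
    lookup = dict(zip(np.round(ts.times, 9), ts.cv_maa))
    return np.array([lookup[round(t, 9)] for t in data.times])


def log_likelihood(params: PBPKParameters, sigma: float, data: ObservedDataset,
                   error_model: str = "lognormal",
                   predictions: np.ndarray | None = None) -> float:
    """Log-likelihood of the observations given a parameter set.

    ``lognormal``: each observation is prediction * exp(eps); the density is
    the full log-normal density of the observation (predictions floored at
    1e-12 before the log).  ``gaussian``: additive normal errors.
    Replicates at one time are i.i.d. given the prediction.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    obs = data.concentrations
    pred = _predict_at(params, data) if predictions is None else predictions
    if error_model == "lognormal":
        if np.any(obs <= 0):
            raise ValueError("log-normal error model requires strictly positive observations")
        mu = np.log(np.maximum(pred, 1e-12))
        z = (np.log(obs) - mu) / sigma
        return float(np.sum(-np.log(obs * sigma * math.sqrt(2 * math.pi)) - 0.5 * z**2))
    elif error_model == "gaussian":
        z = (obs - pred) / sigma
        return float(np.sum(-math.log(sigma * math.sqrt(2 * math.pi)) - 0.5 * z**2))
    raise ValueError(f"unknown error model {error_model!r}")


# ---------------------------------------------------------------------------
# Metropolis-Hastings
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSampleSet:
    """Retained draws (columns: parameters + sigma, chain, iteration)."""

    draws: pd.DataFrame
    parameter_names: tuple[str, ...]
    acceptance_rates: tuple[float, ...]
    seed: int | None

    @property
    def n_chains(self) -> int:
        return int(self.draws["chain"].nunique())

    def matrix(self, names=None) -> np.ndarray:
        return self.draws[list(names or self.parameter_names)].to_numpy()


def run_mcmc(priors: PriorSpec, data: ObservedDataset, baseline: PBPKParameters,
             n_iter: int = 30_000, n_chains: int = 2, seed: int | None = None,
             burn_in: int = 5_000, error_model: str = "lognormal",
             adapt_interval: int = 50, loglik_fn=None) -> PosteriorSampleSet:
    """Random-walk Metropolis over (calibrated parameters, sigma).

    Per-parameter Gaussian steps; step scales adapt during burn-in toward a
    25-40% acceptance rate and are then frozen.  Burn-in draws are
    discarded.  With ``data=None`` the sampler explores the prior alone
    (useful for validation).
    """
    if n_chains < 2:
        raise ValueError("at least 2 chains are required for diagnostics")
    rng_master = np.random.default_rng(seed)
    chain_seeds = rng_master.integers(0, 2**31 - 1, size=n_chains)
    items = priors.all_items()
    names = [n for n, _ in items]
    d = len(items)

    def logpost(theta: np.ndarray) -> float:
        lp = priors.log_prior(theta)
        if not np.isfinite(lp):
            return -math.inf
        if loglik_fn is not None:
            return lp + loglik_fn(theta)
        if data is None:
            return lp
        p = baseline.replace(**dict(zip(priors.names, theta[:-1])))
        return lp + log_likelihood(p, theta[-1], data, error_model)

    frames = []
    acc_rates = []
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta = priors.sample(rng)
        lp = logpost(theta)
        while not np.isfinite(lp):
            theta = priors.sample(rng)
            lp = logpost(theta)
        scales = np.array([0.1 * (pr.support()[1] - pr.support()[0]) for _, pr in items])
        kept = np.empty((n_iter - burn_in, d))
        n_acc_window = 0
        n_acc_post = 0
        for it in range(n_iter):
            prop = theta + scales * rng.standard_normal(d)
            lp_prop = logpost(prop)
            if math.log(rng.random()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                n_acc_window += 1
                if it >= burn_in:
                    n_acc_post += 1
            if it < burn_in and (it + 1) % adapt_interval == 0:
                rate = n_acc_window / adapt_interval
                if rate < 0.25:
                    scales *= 0.8
                elif rate > 0.40:
                    scales *= 1.25
                n_acc_window = 0
            if it >= burn_in:
                kept[it - burn_in] = theta
        rate = n_acc_post / max(n_iter - burn_in, 1)
        if rate < 0.01:
            raise RuntimeError(
                f"chain {c}: acceptance rate {rate:.3%} below 1% after adaptation; "
                f"final step scales {dict(zip(names, scales))}")
        acc_rates.append(rate)
        df = pd.DataFrame(kept, columns=names)
        df["chain"] = c
        df["iteration"] = np.arange(len(kept))
        frames.append(df)

    draws = pd.concat(frames, ignore_index=True)
    return PosteriorSampleSet(draws=draws, parameter_names=tuple(names),
                              acceptance_rates=tuple(acc_rates), seed=seed)


def _gelman_rubin(chains: list[np.ndarray]) -> float:
    """Potential scale reduction factor over same-length chains."""
    m = len(chains)
    n = min(len(c) for c in chains)
    arr = np.stack([c[:n] for c in chains])
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(math.sqrt(var_hat / W))


def posterior_summary(s: PosteriorSampleSet) -> pd.DataFrame:
    """Median, central 95% interval and R-hat per parameter."""
    if len(s.draws) < 100:
        raise ValueError("at least 100 retained draws are required")
    rows = []
    for name in s.parameter_names:
        x = s.draws[name].to_numpy()
        med, lo, hi = np.quantile(x, [0.5, 0.025, 0.975])
        chains = [g[name].to_numpy() for _, g in s.draws.groupby("chain")]
        rhat = _gelman_rubin(chains) if len(chains) >= 2 else float("nan")
        if np.isfinite(rhat) and rhat > 1.1:
            warnings.warn(f"parameter {name}: R-hat {rhat:.3f} > 1.1 "
                          "(chains may not have converged)", stacklevel=2)
        rows.append({"parameter": name, "median": med, "lo2.5": lo,
                     "hi97.5": hi, "rhat": rhat})
    return pd.DataFrame(rows)


@dataclass
class PredictiveBand:
    """Per-time percentiles of predicted venous-blood MAA across draws."""

    times: np.ndarray
    percentiles: tuple[float, ...]
    values: np.ndarray  # (n_percentiles, n_times)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times})
        for q, row in zip(self.percentiles, self.values):
            df[f"p{q:g}"] = row
        return df


def predictive_band(s: PosteriorSampleSet, scenario: ExposureScenario,
                    baseline: PBPKParameters,
                    percentiles: tuple[float, ...] = (2.5, 50.0, 97.5),
                    max_draws: int | None = None,
                    seed: int | None = None) -> PredictiveBand:
    """Parameter-uncertainty band: one simulation per retained draw, then
    empirical percentiles of venous-blood MAA at each output time.
    Observation noise is not added."""
    if len(s.draws) < 100 and max_draws is None:
        raise ValueError("at least 100 retained draws are required")
    draws = s.draws
    if max_draws is not None and len(draws) > max_draws:
        idx = np.random.default_rng(seed).choice(len(draws), max_draws, replace=False)
        draws = draws.iloc[np.sort(idx)]
    param_names = [n for n in s.parameter_names if n != "sigma"]
    times = scenario.grid()
    curves = []
    n_failed = 0
    for _, row in draws.iterrows():
        p = baseline.replace(**{n: row[n] for n in param_names})
        try:
            curves.append(simulate(p, scenario).cv_maa)
        except Exception:
            n_failed += 1
    if n_failed > 0.01 * len(draws):
        raise RuntimeError(f"{n_failed}/{len(draws)} predictive simulations failed")
    values = np.percentile(np.vstack(curves), percentiles, axis=0)
    return PredictiveBand(times=times, percentiles=tuple(percentiles), values=values)
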