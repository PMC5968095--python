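"""Two-phase ABC reverse dosimetry: from in vitro MAA concentration to a
posterior distribution of in vivo EGME dose.

For each target venous-blood MAA peak concentration (the in vitro assay
concentration treated as the internal dose metric), the joint posterior of
external dose and the sensitive PBPK parameters is characterised
likelihood-free: a draw is "accepted" when the simulated Cmax falls within a
relative-error tolerance of the target.  Phase one is plain rejection
sampling from the priors at a deliberately relaxed 7.5% tolerance; the
retained draws seed a multivariate-Gaussian proposal (their sample mean and
covariance, intentionally more diffuse than the 5% posterior) for phase two,
a Marjoram-type ABC-MCMC at 5% tolerance: a proposed move is accepted iff
it stays in prior support, passes the prior Metropolis ratio, and its
simulated Cmax satisfies the tolerance.  Two thinned chains are pooled.
Posterior dose summaries, optional filtering to externally calibrated
parameter ranges, and rank-paired dose-response percentile curves complete
the reverse-dosimetry step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from qivive.calibration import PriorSpec, TruncatedNormal, Uniform, SENSITIVE_PARAMETERS
from qivive.pbpk import (
    ExposureScenario,
    PBPKParameters,
    dose_for_target_cmax,
    simulate,
    dose_metrics,
)

__all__ = [
    "TargetSpec",
    "ABCConfig",
    "relative_error",
    "abc_priors",
    "abc_scenario",
    "rejection_phase",
    "build_proposal",
    "abc_mcmc",
    "run_two_phase_abc",
    "filter_by_ranges",
    "summarize_dose",
    "qivive_table",
    "dose_response_curves",
]

#: Default in vitro target concentrations, mM.
DEFAULT_TARGETS_MM = (0.28, 0.55, 1.11, 2.77, 5.55, 11.1)


def relative_error(cmax: float, target: float) -> float:
    """|cmax - target| / target."""
    if target <= 0:
        raise ValueError("target concentration must be positive")
    return abs(cmax - target) / target


@dataclass(frozen=True)
class TargetSpec:
    """One reverse-dosimetry target: the venous-blood MAA peak to match."""

    target_cmax: float
    route: str
    scenario: ExposureScenario

    def __post_init__(self):
        if self.target_cmax <= 0:
            raise ValueError("target_cmax must be positive")
        if self.route not in ("oral", "inhalation"):
            raise ValueError(f"unknown route {self.route!r}")


@dataclass(frozen=True)
class ABCConfig:
    """Tuning constants of the two-phase ABC sampler."""

    n_reject: int = 200
    tol_reject: float = 0.075
    tol_mcmc: float = 0.05
    n_chains: int = 2
    retained_per_chain: int = 2500
    thin: int = 2
    proposal_scale: float = 1.0
    seed: int = 0
    max_iter_factor: int = 50   # chain-length cap = factor * retained * thin

    def __post_init__(self):
        if self.tol_mcmc > self.tol_reject:
            raise ValueError("tol_mcmc must not exceed tol_reject")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


def abc_scenario(route: str) -> ExposureScenario:
    """Exposure scenario template used for ABC simulation.

    The acceptance statistic is the day-5 peak for inhalation; the horizon
    stops shortly after the final exposure window with a fine (0.1 h) output
    grid around the peak region and a coarser grid earlier, which the peak
    search never visits.
    """
    if route == "oral":
        return ExposureScenario.oral(1.0, t_end=50.0)
    grid = np.concatenate([np.arange(0.0, 96.0, 0.5),
                           np.arange(96.0, 120.0 + 1e-9, 0.1)])
    return ExposureScenario.inhalation(1.0, t_end=120.0, output_grid=grid)


def abc_priors(route: str, target: float,
               baseline: PBPKParameters,
               scenario: ExposureScenario | None = None) -> tuple[PriorSpec, float]:
    """Joint priors over (dose, sensitive parameters) for one target.

    The dose prior is uniform on (0.5 d0, 1.6 d0) around the baseline
    forward-dosimetry dose d0 for the target; parameter priors are wide
    uniforms enveloping the plausible physiological spread, except body
    weight, which is tightly constrained around 0.250 kg.  Returns the
    priors and d0.
    """
    scenario = scenario or abc_scenario(route)
    d0 = dose_for_target_cmax(baseline, route, target, scenario=scenario)
    params: dict[str, Uniform | TruncatedNormal] = {
        "dose": Uniform(0.5 * d0, 1.6 * d0),
        "BW": TruncatedNormal(0.250, 0.0025, 0.245, 0.255),
    }
    if route == "inhalation":
        params["QPC"] = Uniform(7.0, 23.0)
    params["PS2"] = Uniform(0.30, 1.35)
    params["KEX"] = Uniform(0.0015, 0.0075)
    return PriorSpec(parameters=params), d0


_SAMPLE_COLUMNS = ("target_mM", "phase", "chain", "dose", "BW", "QPC", "PS2",
                   "KEX", "cmax_mM", "rel_error")


def _simulate_cmax(baseline: PBPKParameters, scenario: ExposureScenario,
                   theta: np.ndarray, names: tuple[str, ...]) -> float:
    values = dict(zip(names, theta))
    dose = values.pop("dose")
    p = baseline.replace(**values)
    ts = simulate(p, scenario.with_dose(dose))
    return dose_metrics(ts).cmax


def _as_frame(rows: list[dict], target: float) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["target_mM"] = target
    for col in _SAMPLE_COLUMNS:
        if col not in df:
            df[col] = np.nan
    extras = [c for c in df.columns if c not in _SAMPLE_COLUMNS]
    return df[list(_SAMPLE_COLUMNS) + extras]


def rejection_phase(t: TargetSpec, priors: PriorSpec, cfg: ABCConfig,
                    baseline: PBPKParameters,
                    rng: np.random.Generator | None = None,
                    cmax_fn=None) -> tuple[pd.DataFrame, float]:
    """Phase one: independent prior draws, retained when the simulated Cmax
    is within ``tol_reject`` relative error of the target.

    ``cmax_fn(theta, names) -> float`` substitutes the PBPK simulator (e.g.
    an analytic surrogate in validation)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    names = priors.names  # (dose, BW, [QPC], PS2, KEX)
    rows = []
    n_acc = 0
    for _ in range(cfg.n_reject):
        theta = np.array([pr.sample(rng) for _, pr in priors.parameters.items()])
        cmax = (cmax_fn(theta, names) if cmax_fn is not None
                else _simulate_cmax(baseline, t.scenario, theta, names))
        err = relative_error(cmax, t.target_cmax)
        if err <= cfg.tol_reject:
            n_acc += 1
            rows.append({**dict(zip(names, theta)), "cmax_mM": cmax,
                         "rel_error": err, "phase": "rejection", "chain": -1})
    if n_acc == 0:
        raise RuntimeError(
            f"rejection phase retained 0 of {cfg.n_reject} draws for target "
            f"{t.target_cmax} mM; widen the dose prior or tol_reject")
    return _as_frame(rows, t.target_cmax), n_acc / cfg.n_reject


def build_proposal(retained: pd.DataFrame,
                   names: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean and (jittered) covariance of the retained draws, used as
    the ABC-MCMC random-walk proposal covariance."""
    X = retained[list(names)].to_numpy(float)
    if len(X) < len(names) + 2:
        raise RuntimeError(
            f"need at least {len(names) + 2} retained samples to estimate a "
            f"covariance, got {len(X)}")
    mean = X.mean(axis=0)
    cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
    try:
        np.linalg.cholesky(cov)
        return mean, cov
    except np.linalg.LinAlgError:
        warnings.warn("retained-sample covariance is singular; adding "
                      "diagonal jitter to the proposal", stacklevel=2)
    jitter = 1e-12
    eye = np.eye(len(names))
    while True:
        try:
            np.linalg.cholesky(cov + jitter * eye)
            return mean, cov + jitter * eye
        except np.linalg.LinAlgError:
            jitter *= 10
            if jitter > 1e6:
                raise RuntimeError("could not regularise the proposal covariance")


def abc_mcmc(t: TargetSpec, priors: PriorSpec, proposal: tuple[np.ndarray, np.ndarray],
             cfg: ABCConfig, baseline: PBPKParameters,
             init: pd.DataFrame,
             rng: np.random.Generator | None = None,
             cmax_fn=None) -> tuple[pd.DataFrame, tuple[float, ...]]:
    """Phase two: ABC-MCMC chains at the strict tolerance.

    Each chain starts from a randomly chosen rejection-phase retained draw
    (already inside the posterior, so no burn-in); proposals are
    multivariate Gaussian with the rejection-phase covariance; acceptance
    requires prior support, the prior Metropolis ratio, and a simulated
    Cmax within ``tol_mcmc``.  Every ``thin``-th state is retained until
    ``retained_per_chain``; chains are pooled.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    names = priors.names
    _, cov = proposal
    if cfg.proposal_scale == 0.0:
        L = np.zeros_like(np.atleast_2d(cov))  # degenerate: chain never moves
    else:
        L = cfg.proposal_scale * np.linalg.cholesky(cov)
    if len(init) < cfg.n_chains:
        raise RuntimeError(
            f"need at least {cfg.n_chains} rejection-phase samples to "
            f"initialise the chains, got {len(init)}")
    # start inside the strict-tolerance posterior where possible so no
    # retained state violates tol_mcmc
    strict = init[init["rel_error"] <= cfg.tol_mcmc]
    if len(strict) >= cfg.n_chains:
        init = strict.reset_index(drop=True)
    else:
        init = init.nsmallest(max(cfg.n_chains, len(init)), "rel_error"
                              ).reset_index(drop=True)
    start_idx = rng.choice(len(init), size=cfg.n_chains, replace=False)

    frames = []
    acc_rates = []
    max_iter = cfg.max_iter_factor * cfg.retained_per_chain * cfg.thin
    for c in range(cfg.n_chains):
        row = init.iloc[start_idx[c]]
        theta = row[list(names)].to_numpy(float)
        cmax = float(row["cmax_mM"])
        err = relative_error(cmax, t.target_cmax)
        lp = sum(pr.logpdf(v) for (_, pr), v in
                 zip(priors.parameters.items(), theta))
        rows = []
        n_prop = 0
        n_acc = 0
        it = 0
        while len(rows) < cfg.retained_per_chain:
            it += 1
            if it > max_iter:
                raise RuntimeError(
                    f"chain {c}: exceeded iteration cap {max_iter} with only "
                    f"{len(rows)} retained samples (partial result)")
            prop = theta + L @ rng.standard_normal(len(names))
            n_prop += 1
            lp_prop = sum(pr.logpdf(v) for (_, pr), v in
                          zip(priors.parameters.items(), prop))
            if np.isfinite(lp_prop) and math.log(rng.random()) < lp_prop - lp:
                cmax_prop = (cmax_fn(prop, names) if cmax_fn is not None
                             else _simulate_cmax(baseline, t.scenario, prop, names))
                err_prop = relative_error(cmax_prop, t.target_cmax)
                if err_prop <= cfg.tol_mcmc:
                    theta, cmax, err, lp = prop, cmax_prop, err_prop, lp_prop
                    n_acc += 1
            if it % cfg.thin == 0:
                rows.append({**dict(zip(names, theta)), "cmax_mM": cmax,
                             "rel_error": err, "phase": "mcmc", "chain": c})
        rate = n_acc / n_prop
        acc_rates.append(rate)
        if rate < 0.05:
            warnings.warn(f"chain {c}: ABC-MCMC acceptance rate {rate:.1%} "
                          "below 5%", stacklevel=2)
        frames.append(_as_frame(rows, t.target_cmax))
    return pd.concat(frames, ignore_index=True), tuple(acc_rates)


def run_two_phase_abc(target: float, route: str, cfg: ABCConfig,
                      baseline: PBPKParameters,
                      scenario: ExposureScenario | None = None) -> dict:
    """Full pipeline for one target: priors, rejection phase, proposal,
    ABC-MCMC; returns a dict with the pooled samples and diagnostics."""
    scenario = scenario or abc_scenario(route)
    priors, d0 = abc_priors(route, target, baseline, scenario)
    t = TargetSpec(target_cmax=target, route=route, scenario=scenario)
    rng = np.random.default_rng(cfg.seed)
    retained, acc_frac = rejection_phase(t, priors, cfg, baseline, rng)
    proposal = build_proposal(retained, priors.names)
    pooled, acc_rates = abc_mcmc(t, priors, proposal, cfg, baseline, retained, rng)
    return {
        "target_mM": target, "route": route, "d0": d0,
        "rejection_samples": retained, "rejection_acceptance": acc_frac,
        "pooled": pooled, "mcmc_acceptance": acc_rates,
        "priors": priors,
    }


def filter_by_ranges(samples: pd.DataFrame,
                     ranges: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Retain samples whose named parameters all lie inside the given
    closed intervals (e.g. externally calibrated 95% ranges)."""
    mask = np.ones(len(samples), dtype=bool)
    for name, (lo, hi) in ranges.items():
        if name not in samples.columns:
            raise KeyError(f"samples carry no column {name!r}")
        x = samples[name].to_numpy(float)
        mask &= (x >= lo) & (x <= hi)
    out = samples[mask].reset_index(drop=True)
    if len(out) == 0:
        warnings.warn("calibrated-range filtering removed every sample",
                      stacklevel=2)
    return out


def summarize_dose(samples: pd.DataFrame, stat: str = "median",
                   interval: float = 0.95) -> dict[str, float]:
    """Central statistic and empirical central interval of dose, plus
    per-parameter medians/intervals."""
    if len(samples) == 0:
        raise ValueError("empty sample set")
    alpha = 0.5 * (1.0 - interval)
    out: dict[str, float] = {"n": float(len(samples))}
    for col in ("dose", "BW", "QPC", "PS2", "KEX"):
        if col not in samples.columns or samples[col].isna().all():
            continue
        x = samples[col].to_numpy(float)
        out[f"{col}_median"] = float(np.quantile(x, 0.5))
        out[f"{col}_mean"] = float(x.mean())
        out[f"{col}_lo"] = float(np.quantile(x, alpha))
        out[f"{col}_hi"] = float(np.quantile(x, 1.0 - alpha))
    out["dose_central"] = out[f"dose_{'mean' if stat == 'mean' else 'median'}"]
    return out


def qivive_table(targets, route: str, cfg: ABCConfig,
                 baseline: PBPKParameters,
                 calibrated_ranges: dict[str, tuple[float, float]] | None = None,
                 response: pd.DataFrame | None = None,
                 include_zero: bool = True) -> tuple[pd.DataFrame, dict[float, pd.DataFrame]]:
    """Run the two-phase ABC for every target and summarise the in vivo
    dose per in vitro concentration.

    Returns the summary table (mean dose and central 95% interval per
    target, before/after calibrated-range filtering) plus the per-target
    pooled sample sets.  A zero-concentration control row passes through as
    dose zero.  ``response`` (columns ``conc_mM`` + response summaries) is
    joined when given.
    """
    rows = []
    pooled_sets: dict[float, pd.DataFrame] = {}
    seed_seq = np.random.SeedSequence(cfg.seed)
    seeds = seed_seq.generate_state(len(list(targets)))
    for target, sub_seed in zip(targets, seeds):
        run = run_two_phase_abc(target, route, replace(cfg, seed=int(sub_seed) % 2**31),
                                baseline)
        pooled = run["pooled"]
        pooled_sets[target] = pooled
        n_before = len(pooled)
        filtered = pooled
        if calibrated_ranges:
            usable = {k: v for k, v in calibrated_ranges.items()
                      if k in pooled.columns and not pooled[k].isna().all()}
            filtered = filter_by_ranges(pooled, usable)
        s = summarize_dose(filtered if len(filtered) else pooled, stat="mean")
        rows.append({
            "target_mM": target,
            "dose_mean": s["dose_mean"], "dose_median": s["dose_median"],
            "dose_lo2.5": s["dose_lo"], "dose_hi97.5": s["dose_hi"],
            "n_pooled": n_before, "n_filtered": len(filtered),
            "rejection_acceptance": run["rejection_acceptance"],
            "mcmc_acceptance_mean": float(np.mean(run["mcmc_acceptance"])),
        })
    table = pd.DataFrame(rows).sort_values("target_mM").reset_index(drop=True)
    if include_zero:
        zero = {c: 0.0 for c in table.columns}
        zero.update({"target_mM": 0.0, "n_pooled": 0, "n_filtered": 0})
        table = pd.concat([pd.DataFrame([zero]), table], ignore_index=True)
    if not table["dose_mean"].is_monotonic_increasing:
        warnings.warn("mean dose is not monotone in the target concentration",
                      stacklevel=2)
    if response is not None:
        table = table.merge(response, how="left",
                            left_on="target_mM", right_on="conc_mM")
    return table, pooled_sets


def dose_response_curves(pooled_sets: dict[float, pd.DataFrame],
                         percentiles: tuple[float, ...] = (2.5, 50.0, 97.5),
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Rank-paired dose profiles across targets.

    Within each target the retained doses are sorted; pairing by rank builds
    sample-level monotone dose-response profiles whose per-target marginal
    quantiles equal the original ones.  Unequal retained counts are matched
    by random subsampling (with a warning).  Returns per-target percentiles
    of the paired profiles.
    """
    counts = {t: len(df) for t, df in pooled_sets.items()}
    n = min(counts.values())
    if len(set(counts.values())) > 1:
        warnings.warn(f"unequal retained counts {counts}; subsampling to {n}",
                      stacklevel=2)
    rng = rng if rng is not None else np.random.default_rng(0)
    sorted_doses = {}
    for t, df in pooled_sets.items():
        doses = df["dose"].to_numpy(float)
        if len(doses) > n:
            doses = rng.choice(doses, size=n, replace=False)
        sorted_doses[t] = np.sort(doses)
    rows = []
    for t in sorted(sorted_doses):
        doses = sorted_doses[t]
        row = {"target_mM": t}
        for q in percentiles:
            row[f"p{q:g}"] = float(np.quantile(doses, q / 100.0))
        rows.append(row)
    return pd.DataFrame(rows)
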