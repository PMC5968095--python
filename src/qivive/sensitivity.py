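"""Time-resolved global sensitivity analysis of venous-blood MAA.

Two-phase design: Morris elementary-effects screening over all 25 model
parameters to discard the negligible ones, then the extended Fourier
Amplitude Sensitivity Test (eFAST) on the retained subset for quantitative
main effects S_i and total effects S_Ti, evaluated at every output time
point.  Lowry-plot data (ranked stacked effects with cumulative variance
bounds) summarise one time point.

Both estimators operate on a generic vectorised model ``f(X) -> Y`` with
``X`` of shape (n, d) in physical units and ``Y`` of shape (n, t); a factory
binds the PBPK simulator to an exposure scenario.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from qivive.pbpk import (
    ExposureScenario,
    PBPKParameters,
    PARAMETER_ORDER,
    simulate,
)

__all__ = [
    "ParameterRanges",
    "MorrisResult",
    "EfastResult",
    "LowryData",
    "InvalidDesignError",
    "default_screening_ranges",
    "bind_pbpk_model",
    "morris_screen",
    "select_parameters",
    "efast",
    "lowry_data",
]


class InvalidDesignError(ValueError):
    """A sensitivity design violates its sampling conditions."""


@dataclass(frozen=True)
class ParameterRanges:
    """Ordered per-parameter [min, max] intervals for sensitivity sampling."""

    names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self):
        if len(self.names) != len(self.mins) or len(self.names) != len(self.maxs):
            raise ValueError("names/mins/maxs length mismatch")
        if np.any(self.maxs <= self.mins):
            bad = [n for n, lo, hi in zip(self.names, self.mins, self.maxs) if hi <= lo]
            raise ValueError(f"min must be < max for parameters {bad}")

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def from_dict(cls, d: dict[str, tuple[float, float]]) -> "ParameterRanges":
        names = tuple(d)
        mins = np.array([d[n][0] for n in names], float)
        maxs = np.array([d[n][1] for n in names], float)
        return cls(names, mins, maxs)

    @classmethod
    def from_csv(cls, path) -> "ParameterRanges":
        df = pd.read_csv(path)
        return cls(tuple(df["parameter"]),
                   df["min"].to_numpy(float), df["max"].to_numpy(float))

    def subset(self, names: Sequence[str]) -> "ParameterRanges":
        idx = [self.names.index(n) for n in names]
        return ParameterRanges(tuple(names), self.mins[idx], self.maxs[idx])

    def scale(self, u: np.ndarray) -> np.ndarray:
        """Map unit-hypercube samples (n, d) to physical units."""
        return self.mins + np.asarray(u) * (self.maxs - self.mins)


def default_screening_ranges() -> ParameterRanges:
    """The bundled +/-15% screening ranges for the 25 rat EGME parameters."""
    ref = resources.files("qivive.data").joinpath("egme_parameter_ranges.csv")
    with resources.as_file(ref) as path:
        return ParameterRanges.from_csv(path)


def bind_pbpk_model(baseline: PBPKParameters, scenario: ExposureScenario,
                    names: Sequence[str],
                    output_times: np.ndarray | None = None,
                    rtol: float = 1e-8) -> Callable[[np.ndarray], np.ndarray]:
    """Wrap the PBPK simulator as a vectorised map from named parameter
    values to venous-blood MAA concentrations at the output times."""
    import dataclasses
    names = list(names)
    if output_times is not None:
        scenario = dataclasses.replace(scenario, output_grid=np.asarray(output_times, float))

    def model(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        out = []
        for i, row in enumerate(X):
            p = baseline.replace(**dict(zip(names, row)))
            try:
                ts = simulate(p, scenario, rtol=rtol)
            except Exception as exc:
                raise RuntimeError(f"simulation failed at design point {i}: {exc}") from exc
            out.append(ts.cv_maa)
        return np.vstack(out)

    model.times = scenario.grid()
    return model


# ---------------------------------------------------------------------------
# Morris elementary-effects screening
# ---------------------------------------------------------------------------

@dataclass
class MorrisResult:
    """mu* (mean absolute elementary effect) and sigma per parameter and
    output time; arrays of shape (n_parameters, n_times)."""

    names: tuple[str, ...]
    times: np.ndarray
    mu_star: np.ndarray
    sigma: np.ndarray

    def max_mu_star(self) -> np.ndarray:
        """Max-over-time mu* per parameter."""
        return self.mu_star.max(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.names):
            rows.append(pd.DataFrame({
                "time_h": self.times, "parameter": name,
                "mu_star": self.mu_star[i], "sigma": self.sigma[i],
            }))
        return pd.concat(rows, ignore_index=True)


def _morris_trajectory(d: int, levels: int, delta: float,
                       rng: np.random.Generator) -> np.ndarray:
    """One (d+1, d) trajectory on the unit hypercube grid."""
    # grid values from which the base point may start so that +delta stays in [0,1]
    n_base = levels // 2
    base = rng.integers(0, n_base, size=d) / (levels - 1)
    order = rng.permutation(d)
    signs = np.where(rng.random(d) < 0.5, -1.0, 1.0)
    # flip any step that would leave the cube
    for j in range(d):
        if base[j] + signs[j] * delta < -1e-12 or base[j] + signs[j] * delta > 1 + 1e-12:
            signs[j] = -signs[j]
    traj = np.empty((d + 1, d))
    traj[0] = base
    x = base.copy()
    for k, j in enumerate(order):
        x = x.copy()
        x[j] = x[j] + signs[j] * delta
        traj[k + 1] = x
    return np.clip(traj, 0.0, 1.0)


def morris_screen(model: Callable[[np.ndarray], np.ndarray],
                  ranges: ParameterRanges,
                  r: int = 20, levels: int = 6,
                  seed: int | None = None) -> MorrisResult:
    """Morris one-at-a-time screening with ``r`` random trajectories.

    Elementary effects are computed on the unit hypercube (so mu* is
    comparable across parameters with different units); ``delta`` follows
    the standard choice levels / (2 (levels - 1)).
    """
    if r < 4:
        raise InvalidDesignError("at least r = 4 trajectories are required")
    if levels % 2 != 0:
        raise InvalidDesignError("levels must be even")
    rng = np.random.default_rng(seed)
    d = len(ranges)
    delta = levels / (2.0 * (levels - 1))

    ee = None  # (r, d, t)
    for k in range(r):
        traj = _morris_trajectory(d, levels, delta, rng)
        Y = model(ranges.scale(traj))  # (d+1, t)
        if ee is None:
            ee = np.empty((r, d, Y.shape[1]))
        # recover which parameter moved at each step
        for step in range(d):
            diff = traj[step + 1] - traj[step]
            j = int(np.argmax(np.abs(diff)))
            ee[k, j] = (Y[step + 1] - Y[step]) / diff[j]

    mu_star = np.abs(ee).mean(axis=0)
    sigma = ee.std(axis=0, ddof=1)
    times = getattr(model, "times", None)
    if times is None:
        times = np.arange(ee.shape[2], dtype=float)
    return MorrisResult(tuple(ranges.names), np.asarray(times, float), mu_star, sigma)


def select_parameters(m: MorrisResult, threshold_fraction: float = 0.05) -> list[str]:
    """Retain parameters whose max-over-time mu* reaches the given fraction
    of the overall largest mu*; returned in canonical model-parameter order."""
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    maxima = m.max_mu_star()
    cutoff = threshold_fraction * maxima.max()
    kept = [n for n, v in zip(m.names, maxima) if v >= cutoff]
    if not kept:
        raise RuntimeError(
            "no parameter reaches the screening threshold; lower threshold_fraction")
    order = {n: i for i, n in enumerate(PARAMETER_ORDER)}
    return sorted(kept, key=lambda n: order.get(n, len(order)))


# ---------------------------------------------------------------------------
# extended FAST
# ---------------------------------------------------------------------------

@dataclass
class EfastResult:
    """Main effects S_i and total effects S_Ti per parameter and output
    time; arrays of shape (n_parameters, n_times)."""

    names: tuple[str, ...]
    times: np.ndarray
    Si: np.ndarray
    STi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.names):
            rows.append(pd.DataFrame({
                "time_h": self.times, "parameter": name,
                "Si": self.Si[i], "STi": self.STi[i],
            }))
        return pd.concat(rows, ignore_index=True)

    def at_time(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        j = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[j] - t) > 1e-9:
            raise ValueError(f"time {t} not on the output grid")
        return self.Si[:, j], self.STi[:, j]


def efast(model: Callable[[np.ndarray], np.ndarray],
          ranges: ParameterRanges,
          n_per_curve: int = 2000, M: int = 4,
          seed: int | None = None) -> EfastResult:
    """Extended-FAST variance decomposition.

    One search curve per parameter: the parameter of interest is driven at
    the highest admissible frequency, the complement at low frequencies, and
    the Fourier spectrum of the model output along the curve partitions the
    variance.  ``n_per_curve`` model runs are spent per parameter; the
    sampling condition ``n_per_curve >= 65 M^2`` keeps the interference-free
    bandwidth wide enough for ``M`` harmonics.
    """
    d = len(ranges)
    n_min = 65 * M * M
    if n_per_curve < n_min:
        raise InvalidDesignError(
            f"eFAST requires n_per_curve >= 65*M^2 = {n_min} (got {n_per_curve})")
    N = int(n_per_curve)
    if N % 2 == 0:
        N += 1  # odd sample count gives a symmetric spectrum
    rng = np.random.default_rng(seed)

    omega_max = (N - 1) // (2 * M)
    omega_compl_max = max(1, omega_max // (2 * M))
    s = (2.0 * np.pi / N) * np.arange(N)

    Si = STi = None
    for i in range(d):
        freqs = np.empty(d)
        freqs[i] = omega_max
        others = [j for j in range(d) if j != i]
        if d > 1:
            # spread complementary frequencies over [1, omega_compl_max] to
            # avoid low-order resonances between complement parameters
            if omega_compl_max >= d - 1:
                compl = np.floor(np.linspace(1, omega_compl_max, d - 1))
            else:
                compl = 1 + (np.arange(d - 1) % omega_compl_max)
            for k, j in enumerate(others):
                freqs[j] = compl[k]
        phi = rng.uniform(0, 2 * np.pi, size=d)
        # search curve through the unit hypercube
        U = 0.5 + np.arcsin(np.sin(freqs[None, :] * s[:, None] + phi[None, :])) / np.pi
        Y = model(ranges.scale(U))  # (N, t)
        if Si is None:
            Si = np.zeros((d, Y.shape[1]))
            STi = np.zeros((d, Y.shape[1]))
        c = np.fft.rfft(Y, axis=0) / N
        power = 2.0 * np.abs(c[1:(N - 1) // 2 + 1]) ** 2  # (N//2, t)
        V = power.sum(axis=0)
        # a (near-)constant output has no variance to decompose; guard against
        # FFT round-off noise masquerading as signal
        degenerate = V <= 1e-20 * (np.abs(Y).max(axis=0) ** 2 + 1e-300)
        V = np.where(degenerate, np.inf, V)
        harmonics = omega_max * np.arange(1, M + 1) - 1  # index into power
        D_main = power[harmonics].sum(axis=0)
        D_compl = power[: omega_max // 2].sum(axis=0)
        Si[i] = D_main / V
        STi[i] = np.where(degenerate, 0.0, 1.0 - D_compl / V)

    times = getattr(model, "times", None)
    if times is None:
        times = np.arange(Si.shape[1], dtype=float)
    return EfastResult(tuple(ranges.names), np.asarray(times, float), Si, STi)


# ---------------------------------------------------------------------------
# Lowry plot data
# ---------------------------------------------------------------------------

@dataclass
class LowryData:
    """Ranked variance decomposition at one time point: per-parameter main
    effect and interaction share, with cumulative lower/upper bounds on the
    explained variance."""

    parameters: tuple[str, ...]
    main_effect: np.ndarray          # S_i, in ranked order
    interaction: np.ndarray          # S_Ti - S_i
    cumulative_main: np.ndarray      # lower bound curve
    cumulative_upper: np.ndarray     # min(1, cumulative S_Ti)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameters,
            "Si": self.main_effect,
            "interaction": self.interaction,
            "cumulative_main": self.cumulative_main,
            "cumulative_upper": self.cumulative_upper,
        })


def lowry_data(e: EfastResult, t: float) -> LowryData:
    """Rank parameters by total effect at time ``t`` and build the Lowry
    ribbon: the explained variance lies between the cumulative sum of main
    effects and the (capped) cumulative sum of total effects."""
    Si, STi = e.at_time(t)
    order = np.argsort(-STi, kind="stable")
    names = tuple(e.names[i] for i in order)
    s, st = Si[order], STi[order]
    lower = np.cumsum(s)
    upper = np.minimum(1.0, np.cumsum(st))
    upper = np.maximum(upper, lower)
    return LowryData(names, s, st - s, lower, upper)
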