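"""Seeded generators of synthetic experimental data.

The concentration-time datasets the calibration step targets (replicate
plasma MAA measurements after a single oral EGME gavage or repeated vapour
exposure) are not redistributable, so this module generates stand-ins from
the PBPK model itself: a forward run of the generating parameter set with
multiplicative log-normal noise, mirroring the calibration error model.
Every generated dataset is accompanied by a truth record so recovery tests
never hard-code generator internals.  The module also exposes the bundled,
checksummed fixture tables (baseline parameters, screening ranges,
calibrated intervals, in vitro embryotoxicity responses).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable

import numpy as np
import pandas as pd

from qivive.bmd import QuantalDataset, QUANTAL_FAMILIES
from qivive.calibration import ObservedDataset
from qivive.pbpk import (
    ExposureScenario,
    PBPKParameters,
    baseline_parameters,
    simulate,
)
from qivive.sensitivity import ParameterRanges, default_screening_ranges

__all__ = [
    "SyntheticTimecourseSpec",
    "SyntheticQuantalSpec",
    "gen_timecourse",
    "gen_quantal",
    "fixtures",
    "Fixtures",
    "default_oral_timecourse_spec",
    "default_inhalation_timecourse_spec",
    "embryotoxicity_quantal",
    "DEFAULT_TARGETS_MM",
]

#: Default log-scale noise SD for synthetic concentration data.
DEFAULT_SIGMA = 0.15

#: Default in vitro MAA target concentrations (mM).
DEFAULT_TARGETS_MM = (0.28, 0.55, 1.11, 2.77, 5.55, 11.1)


@dataclass(frozen=True)
class SyntheticTimecourseSpec:
    """Recipe for a synthetic replicate concentration-time dataset."""

    parameters: PBPKParameters
    scenario: ExposureScenario
    sample_times: tuple[float, ...]
    n_replicates: int = 4
    sigma: float = DEFAULT_SIGMA
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if max(self.sample_times) > self.scenario.t_end + 1e-9:
            raise ValueError("sampling times exceed the scenario horizon")
        if min(self.sample_times) <= 0:
            raise ValueError("sampling times must be positive")


def default_oral_timecourse_spec(parameters: PBPKParameters | None = None,
                                 sigma: float = DEFAULT_SIGMA,
                                 seed: int = 0) -> SyntheticTimecourseSpec:
    """Single oral gavage of 3.3 mmol/kg, ~9 sampling times over 48 h."""
    return SyntheticTimecourseSpec(
        parameters=parameters or baseline_parameters(),
        scenario=ExposureScenario.oral(3.3, t_end=50.0),
        sample_times=(1.0, 2.0, 4.0, 6.0, 9.0, 12.0, 24.0, 36.0, 48.0),
        sigma=sigma, seed=seed)


def default_inhalation_timecourse_spec(parameters: PBPKParameters | None = None,
                                       ppm: float = 50.0,
                                       sigma: float = DEFAULT_SIGMA,
                                       seed: int = 0) -> SyntheticTimecourseSpec:
    """5-day, 6 h/day vapour exposure with daily samples plus an
    elimination phase out to 168 h."""
    return SyntheticTimecourseSpec(
        parameters=parameters or baseline_parameters(),
        scenario=ExposureScenario.inhalation(ppm, t_end=170.0),
        sample_times=(6.0, 24.0, 30.0, 54.0, 78.0, 102.0, 110.0,
                      120.0, 132.0, 144.0, 168.0),
        sigma=sigma, seed=seed)


def gen_timecourse(spec: SyntheticTimecourseSpec) -> tuple[ObservedDataset, dict]:
    """Forward-simulate the generating parameters and apply multiplicative
    log-normal noise: obs = pred * exp(eps), eps ~ N(0, sigma^2) i.i.d."""
    import dataclasses
    scenario = dataclasses.replace(spec.scenario,
                                   output_grid=np.asarray(spec.sample_times, float))
    ts = simulate(spec.parameters, scenario)
    pred = ts.cv_maa
    if np.any(pred <= 0):
        bad = [t for t, c in zip(ts.times, pred) if c <= 0]
        raise ValueError(f"model predicts zero concentration at times {bad}; "
                         "log-normal noise undefined there")
    rng = np.random.default_rng(spec.seed)
    times, conc, reps = [], [], []
    for r in range(spec.n_replicates):
        eps = rng.normal(0.0, spec.sigma, size=len(pred))
        times.append(np.asarray(spec.sample_times))
        conc.append(pred * np.exp(eps))
        reps.append(np.full(len(pred), r))
    data = ObservedDataset(np.concatenate(times), np.concatenate(conc),
                           np.concatenate(reps), spec.scenario)
    truth = {"parameters": spec.parameters.as_dict(), "sigma": spec.sigma,
             "seed": spec.seed, "predictions": dict(zip(spec.sample_times, pred))}
    return data, truth


@dataclass(frozen=True)
class SyntheticQuantalSpec:
    """Recipe for a synthetic quantal dose-response dataset."""

    family: str
    params: tuple[float, float, float]  # (a, b, c)
    doses: tuple[float, ...]
    n_total: int = 24
    groups: tuple[str, ...] = ("lab1",)
    seed: int = 0

    def __post_init__(self):
        if self.family not in QUANTAL_FAMILIES:
            raise ValueError(f"unknown quantal family {self.family!r}")


def gen_quantal(spec: SyntheticQuantalSpec) -> tuple[QuantalDataset, dict]:
    """Binomial responders at each dose/group under the generating curve."""
    f = QUANTAL_FAMILIES[spec.family]
    a, b, c = spec.params
    probs = np.array([f(d, a, b, c) for d in spec.doses])
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("generating parameters give probabilities outside [0, 1]")
    rng = np.random.default_rng(spec.seed)
    doses, n_tot, n_resp, groups = [], [], [], []
    for g in spec.groups:
        k = rng.binomial(spec.n_total, probs)
        doses.extend(spec.doses)
        n_tot.extend([spec.n_total] * len(spec.doses))
        n_resp.extend(k.tolist())
        groups.extend([g] * len(spec.doses))
    data = QuantalDataset(np.array(doses), np.array(n_tot), np.array(n_resp),
                          np.array(groups))
    truth = {"family": spec.family, "params": spec.params,
             "probabilities": dict(zip(spec.doses, probs)), "seed": spec.seed}
    return data, truth


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------

_FIXTURE_SHA256 = {
    "egme_rat_parameters.yaml": "4fd3897af1119bb00783fccc4d3d10b000cc5f0d6d0070061325f3fb2db8a190",
    "egme_parameter_ranges.csv": "fbfebbdac68bec87e1bd0990f09e0521034887cf2a719c484c1a04d976be91b4",
    "egme_calibrated_ranges.csv": "98a1130a86fca89342967d04add65a13a8264d4d95174f1430315dcb47edb785",
    "maa_embryotoxicity.csv": "9b7b9b7bf6326724421b7d00a8a62c38e247284a99897b050ba09f395d454ef7",
}


class CorruptedFixtureError(RuntimeError):
    pass


def _read_fixture(name: str) -> str:
    text = resources.files("qivive.data").joinpath(name).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise CorruptedFixtureError(
            f"fixture {name} checksum mismatch: {digest} != {_FIXTURE_SHA256[name]}")
    return text


@dataclass(frozen=True)
class Fixtures:
    """Immutable bundled inputs for the EGME/MAA workflow."""

    parameters: PBPKParameters
    screening_ranges: ParameterRanges
    calibrated_ranges: dict[str, dict[str, tuple[float, float]]]
    embryotoxicity: pd.DataFrame
    targets_mM: tuple[float, ...] = DEFAULT_TARGETS_MM


def fixtures() -> Fixtures:
    """Load and checksum-verify the bundled datasets."""
    import io
    import yaml
    _read_fixture("egme_rat_parameters.yaml")
    params = baseline_parameters()
    _read_fixture("egme_parameter_ranges.csv")
    ranges = default_screening_ranges()
    cal = pd.read_csv(io.StringIO(_read_fixture("egme_calibrated_ranges.csv")))
    cal_ranges: dict[str, dict[str, tuple[float, float]]] = {}
    for route, g in cal.groupby("route"):
        cal_ranges[route] = {r.parameter: (r.lo, r.hi) for r in g.itertuples()}
    embryo = pd.read_csv(io.StringIO(_read_fixture("maa_embryotoxicity.csv")))
    return Fixtures(parameters=params, screening_ranges=ranges,
                    calibrated_ranges=cal_ranges, embryotoxicity=embryo)


def embryotoxicity_quantal(doses: np.ndarray | None = None) -> QuantalDataset:
    """Pooled quantal reconstruction of the in vitro embryotoxicity assay.

    Per-test counts are not available, only the mean number of
    non-differentiated embryoid bodies (out of 24) over six tests; the
    pooled responders are approximated as round(6 * mean) out of 6 * 24.
    ``doses`` defaults to the in vitro concentrations themselves (mM).
    """
    f = fixtures()
    df = f.embryotoxicity
    if doses is None:
        doses = df["conc_mM"].to_numpy(float)
    doses = np.asarray(doses, float)
    n_total = (df["n_tests"] * df["n_embryoid_bodies"]).to_numpy(int)
    n_resp = np.round(df["n_tests"] * df["mean_nondifferentiated"]).to_numpy(int)
    return QuantalDataset(doses, n_total, n_resp, None)
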