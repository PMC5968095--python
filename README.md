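# qivive

Probabilistic quantitative in vitro to in vivo extrapolation (QIVIVE) for
the rat EGME/MAA system: a PBPK model, global sensitivity analysis,
Bayesian calibration, two-phase ABC reverse dosimetry, and quantal
benchmark-dose derivation.

## The problem

Embryotoxicity assays measure the response of embryoid bodies to
methoxyacetic acid (MAA) — the toxic metabolite of the industrial solvent
ethylene glycol monomethyl ether (EGME) — at known medium concentrations
(mM). Regulatory use needs the *in vivo* dose-response instead: what oral
dose (mmol/kg bw) or vapour exposure (ppm) of EGME gives a rat the same
internal MAA exposure? Deterministic "iterative forward dosimetry" answers
with a single number per concentration, silently assuming the
pharmacokinetic model and its parameters are exact. This package instead
treats the question statistically: it returns the *posterior distribution*
of external dose consistent with each target concentration, propagating
both parameter uncertainty and model error, and carries that distribution
through to a benchmark dose with a proper lower confidence bound.

## The method

1. **PBPK model** — a flow-limited compartment model (liver, fat, slowly
   and rapidly perfused tissue, venous blood) for EGME and MAA, with
   saturable hepatic metabolism (Michaelis-Menten, 1:1 molar conversion)
   and first-order urinary MAA clearance. Output: the venous-blood MAA
   concentration C(t) and its peak C_max.
2. **Global sensitivity analysis** — Morris screening of all 25 parameters,
   then eFAST main/total effects (S_i, S_Ti) on the retained set, resolved
   over time. The sensitive sets are {BW, PS2, K_ex} (oral) and
   {BW, QPC, PS2, K_ex} (inhalation).
3. **Calibration** — Metropolis-Hastings over the sensitive parameters with
   a multiplicative log-normal error model against replicate
   concentration-time data, giving refined 95% parameter intervals.
4. **ABC reverse dosimetry** — for each target C_max: 200 prior draws of
   (dose, parameters) retained within 7.5% relative error of the target,
   then ABC-MCMC (2 chains, multivariate Gaussian proposal from the
   retained-sample covariance, 5% tolerance, thin 2, 2500 kept per chain,
   pooled). Summaries are reported before and after filtering samples to
   the calibrated parameter intervals.
5. **Benchmark dose** — the resulting dose-response table is fitted with
   four quantal families (log-logistic, log-probit, Weibull, two-stage) by
   binomial maximum likelihood; the reported BMDL₁₀ is the
   profile-likelihood lower bound of the most conservative adequately
   fitting model at a benchmark response of 0.1 (extra risk).

All baseline parameters, screening ranges, calibrated intervals and the
in vitro response table ship as checksummed fixtures; synthetic replicate
datasets for calibration are generated from the model itself with seeded
log-normal noise. See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

```python
from qivive import baseline_parameters, simulate, dose_metrics, summarize_dose
from qivive.pbpk import ExposureScenario
from qivive.reverse_dosimetry import ABCConfig, run_two_phase_abc

p = baseline_parameters()

# forward simulation: single oral gavage of 3.3 mmol/kg EGME
m = dose_metrics(simulate(p, ExposureScenario.oral(3.3)))
print(f"Cmax = {m.cmax:.3f} mM at t = {m.t_cmax:.1f} h; AUC = {m.auc:.1f} mM*h")

# reverse dosimetry: which oral dose gives a 0.28 mM MAA peak?
run = run_two_phase_abc(0.28, "oral",
                        ABCConfig(n_reject=100, retained_per_chain=250, seed=1), p)
s = summarize_dose(run["pooled"])
print(f"oral dose for 0.28 mM: median {s['dose_median']:.3f} "
      f"(95% interval {s['dose_lo']:.3f}-{s['dose_hi']:.3f}) mmol/kg, "
      f"n = {int(s['n'])} pooled samples")
```

prints

```
Cmax = 4.397 mM at t = 3.7 h; AUC = 130.2 mM*h
oral dose for 0.28 mM: median 0.213 (95% interval 0.118-0.315) mmol/kg, n = 500 pooled samples
```

The first line is the deterministic kinetic profile of a 3.3 mmol/kg
gavage: MAA peaks at 4.4 mM about 4 h after dosing. The second line is the
reverse question at a low in vitro concentration: a median oral dose of
about 0.21 mmol/kg produces a 0.28 mM MAA peak, and the 95% interval spans
roughly ±45% around it — that spread *is* the methodological point,
reflecting parameter uncertainty plus the 5% model-error tolerance rather
than a single optimised number. (The example uses a reduced sampler size;
defaults retain 5 000 samples per target.)

The same pipeline is scriptable from the shell:

```sh
qivive all --seed 42 --out results/     # gsa -> calibrate -> qivive -> bmd
qivive qivive --seed 42 --out results/  # reverse dosimetry only (unfiltered)
```

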