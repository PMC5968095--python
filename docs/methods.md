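# Methods

`qivive` implements a probabilistic workflow for quantitative in vitro to
in vivo extrapolation (QIVIVE), demonstrated on ethylene glycol monomethyl
ether (EGME) and its embryotoxic metabolite methoxyacetic acid (MAA) in the
rat. The workflow converts a set of in vitro MAA assay concentrations into
posterior distributions of the external EGME dose (oral gavage, mmol/kg bw)
or vapour exposure (ppm) that would produce the same peak MAA concentration
in venous blood, and then derives a quantal benchmark dose from the
resulting in vivo dose-response table. Four stages run in sequence: global
sensitivity analysis, Bayesian calibration, two-phase ABC reverse
dosimetry, and benchmark-dose analysis.

## PBPK model

The kinetic core is a flow-limited PBPK model with four perfused tissue
groups (liver, fat, slowly perfused, rapidly perfused) and a mixed
venous-blood pool, duplicated for the two chemicals. EGME enters from a
first-order gut depot (oral, uptake rate `KUP` = 4 h⁻¹) or through the
lungs, where the arterial concentration follows the algebraic steady-state
balance CA = (QC·CV + QP·Cinh)/(QC + QP/PB). With the blood:air partition
coefficient PB = 32 800, inhaled EGME is essentially completely absorbed and
post-exposure exhalation is negligible. Hepatic metabolism is
Michaelis-Menten in the venous liver concentration, with the whole-liver
capacity scaled from `VMAX` (nmol h⁻¹ per 10⁶ hepatocytes) by a
hepatocellularity of 110×10⁶ cells per g liver and liver density 1 g/mL;
the scaled baseline capacity is 1.576 mmol/h against KM = 6.3 mM. MAA is
produced 1:1 on a molar basis, is non-volatile (arterial = venous blood
concentration), distributes with its own partition coefficients, and is
cleared by a urinary clearance `KEX` (L/h) acting on the venous blood pool.

Body composition is constrained by the Gelman-style re-parameterisation:
whenever fractional volumes or flows are perturbed independently they are
rescaled by a common factor so volumes sum to 0.911 of body weight and
flows to the full cardiac output. Cardiac output and alveolar ventilation
scale linearly with body weight (the parameter table gives per-kg units).
Vapour concentrations convert to mmol/L air through the molar volume
24.45 L/mol (25 °C). All bookkeeping is in mmol and mM so molecular weights
never enter except through that single ppm bridge.

The system (16 states: 11 concentrations/amounts plus 5 cumulative ledgers)
is integrated with LSODA at relative tolerance 1e-8 and absolute tolerance
1e-12. Inhalation exposure is a square wave, 6 h/day on consecutive days;
integration restarts at every window edge so the solver never steps across
a discontinuity. Mass balance is checked on two ledgers — net absorbed EGME
against stored + metabolised, and formed MAA against stored + excreted —
and holds to ~1e-13 of the administered amount in practice (the test gate
is 1e-6). The peak statistic Cmax is the grid maximum refined by a local
parabola, which removes the output-grid sampling error (~3e-5 relative at a
0.1 h grid) from the ABC acceptance statistic.

Structural choices worth flagging: the venous-blood MAA concentration is
reported as the plasma-equivalent with no blood:plasma ratio; exhalation is
handled implicitly by the arterial balance rather than by a separate lung
compartment; and the metabolite chain stops at MAA. At the published
posterior-median parameters the model reproduces the oral kinetics closely
(0.30 mM peak at 0.267 mmol/kg against a 0.28 mM target) but needs roughly
a third more vapour than the original source model for the same day-5 peak,
i.e. its effective MAA elimination during a multi-day exposure is somewhat
faster. This is an irreducible reconstruction uncertainty — the source
model's equations are not published — and it propagates into the inhalation
dose tables (see Limitations).

## Global sensitivity analysis

Stage one screens all 25 model parameters over ±15% ranges with the Morris
elementary-effects method (default r = 20 trajectories, 6 levels,
Δ = levels/(2(levels−1)), effects computed on the unit hypercube so μ* is
comparable across units), time-resolved over the output grid. Parameters
whose max-over-time μ* reaches 5% of the overall largest are retained; the
threshold is configurable because the appropriate cut depends on how much
residual variance one is willing to discard downstream. Stage two runs
eFAST on the retained set: one search curve per parameter, the parameter of
interest driven at ω_max = (N−1)/(2M) with M = 4 interference harmonics and
N = 2000 points per curve by default; complementary parameters take
frequencies spread over [1, ω_max/(2M)] — spreading rather than stacking
them avoids low-order resonances between complement parameters, which
otherwise make the curve's sampled variance strongly phase-dependent. Main
effects come from the spectrum at harmonics of ω_max, total effects from
one minus the low-frequency (complement) share. The estimator reproduces
the analytic Ishigami indices within 0.03 and exact variance fractions for
additive models within 0.02. Lowry tables rank parameters by total effect
and bound the cumulatively explained variance between ΣSᵢ and min(1, ΣS_Ti).

Both routes retain the parameters used downstream (oral: BW, PS2, KEX;
inhalation: additionally QPC). PS2 — the MAA slowly-perfused-tissue:blood
partition coefficient — controls the MAA distribution volume and dominates
variance around the concentration peak; BW and KEX take over during
elimination, and QPC governs intake under inhalation.

## Bayesian calibration

Sensitive parameters are refined against replicate MAA concentration-time
data by random-walk Metropolis-Hastings over (parameters, σ). The default
error model is multiplicative log-normal — observation = prediction·exp(ε),
ε ~ N(0, σ²) — which absorbs both assay error and structural model error;
an additive Gaussian variant is available and agrees to second order in the
small-residual, small-σ limit. Priors are uniform on the ±15% screening
ranges (σ ~ U(0.01, 1)); defaults are 2 chains × 30 000 iterations with a
5 000-iteration burn-in during which per-parameter step scales adapt toward
25-40% acceptance and are then frozen. Summaries are type-7 empirical
quantiles with a Gelman-Rubin R̂ per parameter (warning above 1.1), and
posterior-predictive bands are per-time 2.5/50/97.5 percentiles over one
simulation per retained draw (parameter uncertainty only; observation noise
is not added).

Because the original digitised rat datasets are not redistributable, the
package's synthetic-data module generates stand-ins by forward-simulating a
generating parameter set and applying the same log-normal noise (default
σ = 0.15 on the log scale, chosen as a realistic assay-plus-model scatter
for this kind of plasma time-course data; the oral design samples ~9 times
over 48 h, the inhalation design daily samples plus an elimination phase to
168 h). Truth records accompany every dataset. What passing recovery tests
show is therefore internal consistency — the sampler recovers parameters
from data the model itself generated under the assumed error law — not
agreement with any particular laboratory's animals; real data would add
structural misfit that only widens σ.

## Two-phase ABC reverse dosimetry

For each target in vitro concentration (0.28, 0.55, 1.11, 2.77, 5.55,
11.1 mM; a 0 mM control passes through as dose 0) the joint posterior of
(dose, sensitive parameters) is characterised likelihood-free, with a draw
accepted when the simulated venous MAA Cmax lies within a relative-error
tolerance of the target. Phase one draws 200 independent prior samples and
retains those within 7.5%; their sample mean and covariance define a
multivariate-Gaussian random-walk proposal that is deliberately more
diffuse than the 5% posterior. Phase two is a Marjoram-type ABC-MCMC: a
proposed move is accepted iff it stays inside prior support, passes the
prior Metropolis ratio (automatic for uniforms), and its simulated Cmax is
within 5%. Two chains start from rejection-phase draws that already satisfy
the strict tolerance (so no burn-in), every second state is retained until
2 500 per chain, and the chains are pooled. Every retained sample stores
its achieved Cmax and relative error, so the pool can be re-filtered at
stricter tolerances without re-simulation.

Priors: dose ~ U(0.5·d₀, 1.6·d₀) where d₀ is the deterministic
forward-dosimetry dose at baseline parameters (found by bracketing plus
Brent's method on the strictly monotone dose→Cmax map); BW ~ truncated
normal (0.250, 0.0025) on (0.245, 0.255) kg; PS2 ~ U(0.30, 1.35);
KEX ~ U(0.0015, 0.0075) L/h; QPC ~ U(7, 23) L h⁻¹ kg⁻¹ (inhalation only).
These envelope the plausible physiological spread; the original study's
exact priors are not published, and the procedural rates (rejection-phase
retention, MCMC acceptance, filter fraction) are sensitive to that choice —
see Limitations.

Dose summaries per target are the pooled median/mean with a central 95%
interval, reported before and after restricting samples to externally
calibrated 95% parameter intervals (filtering shrinks the dose interval
substantially because it pins down PS2 and KEX). Dose-response curves pair
samples across targets by dose rank, which builds monotone sample-level
profiles while preserving each target's marginal quantiles exactly.

For speed the inhalation ABC simulations stop at 120 h (the day-5 peak
always falls at the end of the last exposure window, near 102-103 h) with a
0.1 h output grid over the peak region and a 0.5 h grid earlier; the oral
runs use a 0.1 h grid over 50 h. A full two-phase run is ~10 200 ODE
solutions per target (roughly one to three minutes on one CPU depending on
route).

## Benchmark-dose analysis

The in vitro embryotoxicity responses (mean non-differentiated embryoid
bodies out of 24, over six tests) are mapped to quantal counts as
round(6·mean) responders out of 144 — an explicit approximation, since the
per-test counts behind the pooled means are not available — and paired with
the ABC mean doses per concentration. Four quantal families are fitted by
binomial maximum likelihood (log-logistic, log-probit, Weibull, two-stage),
each of the form P(d) = a + (1−a)·F(d; b, c), with multi-start Nelder-Mead
in an unconstrained transform (logit a, log b, log c). Adequacy is the
deviance against the saturated model on χ² with (dose groups − parameters)
degrees of freedom, threshold p > 0.05. The benchmark dose uses the
extra-risk definition F(BMD) = BMR with BMR = 0.1, so the BMD is invariant
to background; BMDL is the profile-likelihood lower bound at critical value
2.706 (χ²₁ 90% two-sided ≡ 95% one-sided), computed by eliminating b
through the closed-form inversion of the extra-risk condition, profiling
over (a, c), and bisecting the deficit function to 1e-4 relative precision.
The reported result is the most conservative adequate model (smallest
BMDL; ties to fewer parameters, then family-name order). The profile bound
agrees with a 2 000-resample parametric bootstrap within ~1% on seeded
data. A per-group background is available as a grouping covariate when a
dataset carries laboratory labels.

## Reproducibility

Every stochastic component takes an explicit seed; no wall-clock entropy is
used anywhere. The workflow runner derives one child stream per stage from
the master seed via `numpy.random.SeedSequence.spawn` in a fixed stage
order, so a stage re-run under the same configuration is byte-identical
regardless of which other stages ran. Numeric CSV outputs are written with
17 significant digits to permit bit-exact regression comparisons.

## Limitations

- The PBPK right-hand side is a reconstruction: the source model's
  equations (and the original study's ABC priors and Morris design) are not
  published. The oral route reproduces the published dose tables within
  ~15%; the inhalation route needs ~30-50% more ppm for the same internal
  peak, so inhalation dose tables should be read as order-of-magnitude
  anchored, not calibrated.
- Procedural rates (rejection retention ~12-16% here vs ~20-25% published;
  ABC-MCMC acceptance ~25% vs ~60%; calibrated-range filter retaining ~2%
  vs ~10%) scale directly with prior width and are therefore not
  comparable across prior choices.
- The oral Morris screen retains more parameters (~17 at the default 5%
  threshold) than the published 11, and the PS2→BW ranking switch after an
  oral dose occurs earlier than reported, both consistent with the
  reconstructed model's earlier concentration peak.
- Calibration and recovery tests run against synthetic data generated by
  the model itself; they validate the inference machinery, not the model's
  fidelity to any real animal study.
- The quantal reconstruction from pooled response means discards
  between-test variability, so goodness-of-fit p-values for the
  embryotoxicity analysis are optimistic; per-laboratory covariate analysis
  is supported in the code but untestable without the per-test counts.
- Scope ends at the rat: no dermal route, no pregnancy/fetal compartments,
  no human extrapolation, no metabolites beyond MAA.
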