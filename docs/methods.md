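# Methods

## The four-state linkage model

A protein with two conformations (closed, open) and one titratable residue
occupies four species: CH, C⁻, OpH, Op⁻. Vertical equilibria are acid
dissociations with conformation-specific (microscopic) constants
pK_CH and pK_OpH; horizontal equilibria are conformational, with
K_H = [OpH]/[CH] and K_D = [Op⁻]/[C⁻]. Free energies around the loop sum
to zero, so K_H = K_D·10^(pK_OpH − pK_CH): the model has three free
parameters. Activities are identified with concentrations, pH with
−log₁₀ of the hydrogen-ion activity, and all constants are dimensionless
on the 1 M reference state; the analysis lives entirely in
equilibrium-constant space.

With u = 10^(pH − pK_CH), mass balance gives unnormalized weights
(1, u, K_H, K_D·u) for (CH, C⁻, OpH, Op⁻). Populations are computed in
log space (weights shifted by their maximum exponent before
exponentiation), so mole fractions are finite and normalized for any
finite pH — the extreme-pH limits are part of the tested contract.

The total open fraction is a logistic in pH with midpoint at
u* = (1 + K_H)/(1 + K_D). Any observable affine in the open fraction —
the signal model S(pH) = α·x_closed + β·x_open with limiting values α, β —
therefore has its inflection at

    pK_app = pK_CH + log₁₀((1 + K_H)/(1 + K_D)),

the apparent pKa. The closed form was adopted only after an independent
numeric oracle (sign-change bracketing and bisection of the second
pH-derivative of S, bracketed around the maximum of |dS/dpH|) confirmed it
to 1×10⁻³ on 200 randomized cycles; the oracle remains in the public API
(`apparent_pka_numeric`) and in the test suite. The finite-difference step
is 0.01 pH units: large enough that the centred second difference stays
above double-precision roundoff even for transitions whose open-fraction
plateaus differ by as little as 1×10⁻⁶, while the O(h²) truncation shift
of the located root (~1×10⁻⁴ pH) stays inside the agreement band.

Degenerate cycles: when pK_CH = pK_OpH exactly (hence K_H = K_D), the
conformational populations carry no pH dependence and no inflection
exists; the closed form is extended by continuity (pK_app = pK_CH, the
single-site limit) while the numeric route raises a "transition undefined"
error, as it does for any cycle whose open-fraction plateaus differ by
≤ 1×10⁻⁹.

Design quantities: `optimal_kd` maximizes min(x_CH at pH_low, x_Op⁻ at
pH_high); since the first fraction is strictly decreasing and the second
strictly increasing in K_D, the maximin is their crossing, found by
bisection on log₁₀ K_D over [−2, 6] to 1×10⁻⁴. `valid_kd_range` bounds
K_D by the requirement that the off-pathway species stay below a threshold
(default 10%): in the default asymptotic mode the limiting fractions have
closed forms (x_C⁻ → 1/(1+K_D) as pH → ∞, x_OpH → K_H/(1+K_H) as
pH → −∞) giving bounds of 9 and ≈1761 at threshold 0.10 for the reference
pK values; a fixed-pH mode evaluates the same fractions at two supplied pH
values instead. The asymptotic mode is the default because "extreme pH"
is otherwise a free choice.

Reference parameterization: pK_CH = 8.5, pK_OpH = 4.3, K_D = 100,
signal limits α = 0.03, β = 0.55 (the plateaus of an NO-dissociation
titration). These defaults give K_H = 6.31×10⁻³, an apparent pKa of 6.50,
~10% minority conformations at pH 5.5 and 7.5, and a residual closed
population of 24.6% at pH 7.0.

## Estimation from constant-pH-style time series

Under ergodic sampling the protonated fraction f at solvent pH obeys
Henderson–Hasselbalch, so pKa = pH + log₁₀(f/(1−f)). `pka_from_counts`
propagates the binomial standard error of f through the log-odds,
se = 1/(ln10·√(n·f·(1−f))), explicitly labeled an i.i.d.-frames
approximation; f = 0 or 1 yields a one-sided censored estimate
("pKa < pH" / "pKa > pH") rather than an infinity — no estimator in the
package emits non-finite numbers.

`fit_titration` maximizes the binomial likelihood of per-pH counts under
f(pH) = 1/(1 + 10^(n_H·(pH − pKa))) (Nelder–Mead on the negative
log-likelihood, log-odds evaluated via `log_expit` for stability), with
the Hill coefficient n_H fixed at 1 by default — the single-ideal-site
assumption — and freed only as a diagnostic. Standard errors come from the
central-difference Hessian of the negative log-likelihood; they match the
analytic Fisher information on noiseless grids to five decimals. The
nominal ±2 se coverage of such Wald intervals is 95.45%, and simulation at
2000 replicates measures ≈95.6% on binomial data; the calibration test
asserts a 3σ band around that rate.

`conditional_pka` partitions post-burn-in frames by conformation label and
inverts each partition's counts: this is what isolates the two microscopic
pKa values that the pooled titration cannot see. Burn-in defaults to the
first 10% of frames.

Trajectory analytics use trailing windows: `running_average` (expanding
mean fill-in for the first window−1 entries, flagged), `running_pka`
(window counts through the Henderson–Hasselbalch inversion; entries
censored when the window is uniform), and `detect_transition` (first
crossing of the midpoint between two reference basins that persists for a
set number of frames, default 50; trailing smoothing delays the reported
onset by up to window−1 frames, which is documented and tested).
Uncertainty for autocorrelated series comes from a moving-block bootstrap
(overlapping blocks, default length 100 frames, percentile 2.5/97.5);
the i.i.d. binomial stderr is reported alongside where applicable.

Windowed pKa readings saturate: a window of w frames cannot report a value
further than log₁₀(w−1) from the solvent pH, so sparse protonation in the
open state at pH 7.5 reads as ~4.5–5.5 spikes or "<" censoring rather than
a clean 4.3. Tests condition on windows wholly inside one conformation for
this reason.

## The synthetic-trajectory generator

A discrete-time Markov chain over the four species stands in for
constant-pH MD. Two Metropolis move types act on the state:

* protonation flips, attempted every `mc_interval` steps (default 10,
  echoing the every-10-MD-steps protonation sampling of constant-pH
  schemes), with deprotonation ΔG/kT = ln10·(pK_conf − pH), where pK_conf
  is the microscopic pKa of the current conformation — free energies are
  expressed in kT units so temperature never appears;
* conformational flips at fixed protonation, attempted with probability
  `p_conf_attempt` per step (default 0.01), with closed→open
  ΔG/kT = −ln K, K = K_H (protonated) or K_D (deprotonated).

Both acceptance ratios reproduce the corresponding equilibrium ratios
exactly (unit-tested to 1×10⁻¹²), so the joint chain satisfies detailed
balance with the four-state distribution and its stationary species
frequencies match the analytic populations — the module's principal oracle
test. Rates are fictitious: only the equilibrium constants are physical.
The 100:1 protonation-to-conformation attempt ratio makes opening follow
deprotonation visibly, giving trajectories the qualitative shape of real
constant-pH runs. Setting `p_conf_attempt = 0` freezes the conformation,
reducing the chain to a single-site titration whose stationary protonated
fraction is the Henderson–Hasselbalch value (also tested).

Each step is recorded as a frame. Observables are drawn per frame from
conformation-conditional Gaussians with defaults taken from closed/open
summary statistics of the nitrophorin system: the Asp30–Leu130 gating
distance 3.5±0.3 Å closed / 8±1 Å open, the Asp35–Asp129 escape-route
distance 5±1 / 14±3 Å, and the Asp30 SASA 9±4 / 40±2 Å². Draws are
truncated at zero by resampling (physical observables are non-negative);
for the closed-state SASA (mean 9, sd 4) this shifts the emitted mean to
9.128 and tests use truncated-normal moments as the oracle. Frames carry a
fictitious timescale of 1×10⁻⁴ ns per frame so a 10⁶-step run spans
~100 ns, comparable to the constant-pH MD runs the generator emulates; no
quantitative kinetic claim rests on it.

Reproducibility: uniforms are pre-drawn in fixed order per step from a
seeded generator, so trajectories are bit-identical given (parameters,
seed); multi-pH campaigns derive per-point seeds as base_seed + index so
any single pH can be rerun in isolation.

What the generator does *not* emulate: atomic coordinates and forces,
conformational intermediates, pH-dependent observable drift within a
conformation, heterogeneous or multi-site titration, and realistic
transition kinetics. Passing recovery tests therefore demonstrate the
correctness of the estimators under the four-state model's own
assumptions — exchangeable two-basin dynamics with Henderson–Hasselbalch
protonation — not their robustness to the full complexity of MD data.

## Statistical checks and problem sizes

Stationarity is asserted at five pH values (4, 5.5, 6.5, 7.5, 9) with
10⁶-step chains: empirical species frequencies must sit within 3 Monte
Carlo standard errors of the analytic populations, the error estimated by
batch means (100 batches) because conformational dwell times of order 10³
steps leave frames strongly autocorrelated — a naive binomial standard
error at n = 10⁶ would be ~30-fold too small and would reject a correct
sampler. The naive binomial value is kept only as a floor for very rare
species. Parameter recovery uses an 8-point pH grid (3…10) at 2×10⁵
frames per point: conformation-conditioned fits must land within 0.1 pK
units of 8.5/4.3 and the cycle rebuilt from them must reproduce the
apparent pKa within 0.1. These sizes keep the full suite under a minute
on one core while leaving comfortable statistical margins.

## Known limitations

* Exactly one titratable site and two conformations; no tautomers, no
  site–site coupling, no multi-proton cooperativity (the Hill option is a
  diagnostic, not a mechanistic model).
* The signal model is affine in the open fraction; observables that react
  to protonation as well as conformation are out of scope.
* Censored pKa estimates carry no likelihood information into downstream
  fits; titration fits simply require two informative (0 < f < 1) points.
* Block-bootstrap block length is fixed by the user (default 100 frames);
  no automatic autocorrelation-time estimation is attempted.
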