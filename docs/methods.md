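# Methods

## Reaction scheme and rate law

The package models hydrolysis of butyrylthiocholine (BTCh) by human
butyrylcholinesterase (hBChE) monitored by Ellman chemistry: released
thiocholine couples to DTNB and the yellow TCh–TNB⁻ chromophore is read at
412 nm.  The inhibition scheme allows the inhibitor to bind free enzyme
(dissociation constant Ki, nM) and the enzyme–substrate complex (Kii, nM),
and lets the accumulating reaction product compete with substrate on free
enzyme (Kp, µM).  Under the rapid-equilibrium assumption — binding steps
equilibrate much faster than turnover, appropriate for fast-binding
inhibitors — the rate is

    v = kcat·E0·S / [ Km·(1 + I/Ki + P/Kp) + S·(1 + I/Kii) ]

in µM s⁻¹, with S, P, Km, Kp in µM and I, Ki, Kii, E0 in nM.  Branches
switched off in the `SchemeSpec` drop their denominator term.  Progress
curves integrate dP/dt = v with the exact conservation S = S0 − P (LSODA,
rtol 1e-8, atol 1e-10 µM), so mass balance holds by construction and the
uninhibited 50 µM curve reaches its plateau (complete hydrolysis) within
the 10-minute read.

Assumptions worth stating: enzyme is trace-level (E0 ≪ S0; a warning fires
at E0 ≥ 1 % of S0), inhibitor depletion by enzyme binding is neglected
(E0 ≪ Ki; a warning fires at E0 > Ki/5), and no tight-binding (Morrison)
correction, pre-steady-state burst, or temperature/pH dependence is
modeled.  Free inhibitor is treated as constant.

A mass-action formulation integrates the explicit species system
(E, ES, EI, ESI, EP, S, P).  Inhibitor binding uses an association rate
k_on (nM⁻¹ s⁻¹) with dissociation k_on·Ki from E and k_on·Kii from ES
(ESI is formed through ES + I); substrate and product binding are given
fast rates whose dissociation is forced ≥ 100 × kcat so those steps stay
quasi-equilibrated.  In the k_on → ∞ limit this converges pointwise to the
rapid-equilibrium law (tested at three increasing k_on values); at small
k_on it produces the early-phase curvature characteristic of slow binding,
which `linearity_diagnostic` detects as a quadratic-over-linear
contribution above 2 % on the initial window (default 5 % of total signal
change, at least 8 points, capped at 10 % substrate depletion).

## Identifiability at a single substrate concentration

All progress curves of the reference design share one S0.  Substituting
P = S0 − S into the rate law shows the five constants enter through only
four identifiable combinations: with c = Km/Kp,

    kcat/(1−c),  (Km + c·S0)/(1−c),  (Km/Ki)/(1−c),  1/(Kii·(1−c))

parameterize the model exactly, so a one-dimensional family of constant
sets produces *identical* curve families.  Numerically, sets with Ki
differing by ±40 % reproduce each other's curves to ~1e-9 µM.  Two
consequences are built into the package:

1. `GlobalKineticsRegressor` measures the curvature of the objective and
   attaches an "unidentifiable" warning when a flat direction is present
   (it also fires when no inhibited curves are provided, which leaves
   Ki/Kii undetermined).
2. The recovery workflow (`bchekit.workflows.simulate_and_refit`, also the
   acceptance script) treats Km as known — the Michaelis constant is a
   property of the enzyme–substrate pair, routinely characterized from
   substrate-only experiments at several S0 before any inhibitor work —
   and fits kcat, Kp, Ki, Kii freely.  Fixing any single constant breaks
   the degeneracy; with Km fixed, noiseless refits recover the remaining
   constants to ~1e-9 relative and the scheme without product inhibition
   is fully identifiable with *all* parameters free.

## Global fitting

Residuals are computed on the recorded signal (absorbance when present,
else product concentration), all inhibitor concentrations and replicates
simultaneously, never averaged.  Optimization runs in log-parameter space
(positivity for free) with `scipy.optimize.least_squares` (TRF), bounds
three decades around heuristic initials, and multistart (default 5; the
first start uses the heuristics — Km, kcat from the uninhibited curve's
early rate, Ki from the concentration halving it — and the rest jitter by
up to ×/÷3).  The finite-difference step is 1e-4 in log-space so parameter
derivatives are not drowned by ODE-integrator noise.  Standard errors come
from the Gauss–Newton covariance (delta method back from log space); model
ranking uses AICc = n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1), ascending, with
ties (ΔAICc < 2) broken toward fewer parameters.  Non-convergence is
reported as a flagged result, never an exception, and non-converged
candidates are excluded from ranking.  Confidence intervals are
percentile residual-bootstrap (resampled residuals re-added to fitted
curves, single-start refits from the point estimate; an error is raised
if more than 20 % of replicate refits fail).

## Endpoint dose–response

The screening assay is simulated at 500 µM substrate with 2-minute reads
(distinct from the 50 µM progress-curve conditions).  Initial velocities
are ordinary-least-squares slopes over the early window (< 10 % substrate
depletion, ≥ 5 samples); residual activity is RA = vi/v0 × 100.  The
four-parameter logistic is fitted by least squares with IC50 in log space;
top ∈ [80, 120] and bottom ∈ [−10, 20] are bounded to stabilize sparse
designs (the defaults of an 8-point half-log triplicate dilution).
Censored potencies ("> 100 µM") are carried as explicit bounds and
propagate through the selectivity ratio; reports round IC50 to two
significant figures and SR to the nearest integer.

The closed-form mechanistic IC50 at zero product,
IC50 = (Km + S)/(Km/Ki + S/Kii), is cross-checked against a bisection on
simulated early-phase velocity ratios; a 1:1 enantiomer mixture extends the
rate-law denominator additively with each enantiomer at half the total
concentration, and its IC50 is solved by bracketing + Brent.  For purely
competitive enantiomers this reduces to the harmonic mean of the
single-agent IC50s.

## ADME calculators

Caco-2: cumulative transported amount at sample k is
Q_k = V·C_k + Σ_{j<k} v_w·C_j (withdrawn volume v_w replaced with blank
buffer — standard mass balance); Papp = (dQ/dt)/(A·C0) with dQ/dt the OLS
slope over all seven 20-minute samples (subset configurable), reported in
nm/s.  A sink-condition warning fires when any acceptor concentration
exceeds 10 % of C0; the data are flagged, not truncated.  ER =
Papp(B→A)/Papp(A→B).  Brain-to-plasma ratios use the 1 g ≈ 1 mL tissue
convention and aggregate as mean ± SEM; solubility converts as
mM = 1000·(mg/mL)/MW; LC-MS/MS QC metrics are ME = B/A − 1, RE = C/B,
PE = C/A (so PE = RE·(1+ME) identically); the novel-object discrimination
index is DI = (EC − EA)/(EA + EC) × 100, with animals under 5 s total
exploration excluded upstream.

## Synthetic data

Each generator is the exact inverse partner of one analyzer: noiseless
generate → analyze round-trips are identities.  Noise is additive Gaussian
on the recorded signal; defaults are 0.5 % of the plateau signal for
kinetics (0.25 µM at S0 = 50 µM), 3 RA points for dose–response, and 2 %
of each acceptor sample for Caco-2.  These magnitudes emulate a modern
UV/vis plate/cuvette reader; real data additionally contain baseline
drift, heteroscedasticity and plate-position effects that the generators
deliberately omit, so passing recovery tests demonstrate correctness of
the estimators under the stated noise model, not robustness to every
instrumental artifact.  Identical seeds reproduce datasets bit-for-bit.

The named ground-truth sets in `TRUTH_SETS` carry the measured inhibition
constants of the characterized compounds (purified enzyme: 10.2 / 14.9 /
6.6 nM; full plasma: 22.7 / 52.0 / 12.1 nM) together with representative
hBChE/BTCh values for the constants a single-S0 design cannot pin down
independently (Km = 22 µM, kcat = 800 s⁻¹, Kp = 100 µM, Kii chosen ~3 × Ki),
constrained so the uninhibited 50 µM curve plateaus inside the 10-minute
read.  The default sampling interval for simulated reads is 2 s (301
points per curve), a realistic spectrophotometer cadence that keeps global
fits fast.

## Numerical choices and limitations

- Integrator LSODA, rtol 1e-8 / atol 1e-10 µM (plateau detection needs the
  tight late-phase control); the mass-action system verifies enzyme
  conservation to 1e-6 relative at every reported time.
- Optimizer tolerances 1e-12 (ftol/xtol/gtol), max 2000 evaluations per
  start; bootstrap refits are single-start from the point estimate.
- Degenerate inputs raise typed errors: negative concentrations and short
  windows (`InputError`), enabled branches without constants
  (`ConfigurationError`), malformed CSVs with the offending column or row
  named (`ParseError`), integrator failures (`NumericError`).
- The bootstrap-coverage check in the test suite runs on a reduced
  two-curve design with two free parameters (100 datasets × 100 bootstrap
  replicates) — the same code path as the full design at a tractable cost;
  the recovery bias check uses 8 seeds at a 5 s sampling interval.
- ε(TNB⁻) defaults to 14,150 M⁻¹ cm⁻¹ at 412 nm and is configuration,
  never fitted; fitting operates on product concentration or on absorbance
  with ε treated as exactly known.
- Not modeled: tight-binding corrections, plasma protein binding, PBPK,
  Hill-slope mechanistic interpretation, plate-reader vendor formats.
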