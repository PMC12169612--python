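# bchekit

Quantitative analysis tools for characterizing butyrylcholinesterase (BChE)
inhibitors in a lead-optimization campaign: mechanistic progress-curve
kinetics, endpoint Ellman-assay dose–response analysis, and the small
closed-form ADME/bioanalytical calculators that accompany such a study
(Caco-2 permeability, brain-to-plasma partitioning, solubility conversion,
LC-MS/MS validation metrics, novel-object discrimination index).

It is written for medicinal chemists and enzymologists who need to go from
raw time–absorbance traces or residual-activity tables to inhibition
constants, IC50s and selectivity ratios — and for methodologists who want
every step testable against synthetic data with known ground truth.

## The model

The core is mixed inhibition of Michaelis–Menten hydrolysis with product
inhibition and explicit substrate depletion.  Under rapid equilibrium
(fast-binding inhibitor) the instantaneous hydrolysis rate is

    v = kcat · E0 · S / [ Km (1 + I/Ki + P/Kp) + S (1 + I/Kii) ]

with substrate S and product P in µM, inhibitor I in nM, enzyme E0 in nM;
Ki and Kii are the inhibitor's dissociation constants from free enzyme and
from the enzyme–substrate complex, and Kp is the product-inhibition
constant.  Progress curves are obtained by integrating dP/dt = v with
S(t) = S0 − P(t).  A full mass-action formulation of the same binding
topology is available for validating the fast-binding limit and for
constructing slow-binding controls.

A family of progress curves across inhibitor concentrations is fitted
globally (shared constants, all curves and replicates simultaneously) by
least squares in log-parameter space with multistart; candidate binding
topologies (competitive / uncompetitive / mixed) are ranked by AICc, and
parameter uncertainty comes from a residual bootstrap.

Endpoint screening data are summarized by residual activity
RA = vi/v0 × 100 % and the four-parameter logistic
RA(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill); selectivity is
SR = IC50(hAChE)/IC50(hBChE).  Caco-2 permeability is
Papp = (dQ/dt)/(A·C0) with the cumulative transported amount corrected for
withdrawn-and-replaced samples, and the efflux ratio is
ER = Papp(B→A)/Papp(A→B).

An important identifiability fact, handled explicitly (see
`docs/methods.md`): with all curves at a single substrate concentration the
five constants (Km, kcat, Kp, Ki, Kii) are not jointly identifiable — the
package's recovery workflow therefore treats Km as independently known and
fits the remaining four, and the fitter flags flat objective directions.

## Worked example

```python
import bchekit as bk
from bchekit import synthetic, fitting

# simulate duplicate noisy progress curves at the reference design:
# 50 uM butyrylthiocholine, 0.5 nM hBChE, I = 0/10/20/50/100/200 nM, 10 min
truth = bk.TRUTH_SETS["r-minus-3-purified"]          # Ki = 6.6 nM ground truth
cond = bk.AssayConditions()
data = synthetic.generate_progress_set(
    truth, bk.MIXED_SCHEME, cond, replicates=2,
    noise=synthetic.NoiseSpec(sigma=0.25, seed=2024))

# global refit: Km known, kcat/Kp/Ki/Kii free
fit = fitting.fit_progress_set(
    data, bk.MIXED_SCHEME,
    fitting.FitConfig(free_parameters=("kcat", "Kp", "Ki", "Kii"),
                      multistart=3, seed=2024),
    fixed_params={"Km": truth.Km})
print(f"Ki = {fit.estimates.Ki:.2f} nM, Kii = {fit.estimates.Kii:.1f} nM, "
      f"converged = {fit.converged}")
```

prints

```
Ki = 6.59 nM, Kii = 20.1 nM, converged = True
```

i.e. the generating Ki of 6.6 nM is recovered to about 0.2 % under the
stated noise; `fit.standard_errors`, `fit.aicc` and
`fitting.confidence_intervals(...)` quantify the uncertainty.  The same
workflow is exposed on the command line:

```
bchekit simulate --truth r-minus-3-purified --seed 2024 --out set.csv
bchekit fit set.csv --conditions set.conditions.json --out fit.json
bchekit ic50 dose_response.csv
bchekit papp caco2.csv --geometry geom.json
```

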