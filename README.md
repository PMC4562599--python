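# ghkfit

Ion-selectivity inference for ligand-gated channels from whole-cell
voltage-clamp data. `ghkfit` simulates agonist-evoked macrocurrents under
defined ionic solutions, extracts reversal potentials (E_rev) from
current–voltage relationships, and estimates the relative chloride/sodium
permeability P_Cl/P_Na by fitting the Goldman–Hodgkin–Katz (GHK) voltage
equation to dilution-potential data.

It is aimed at channel electrophysiologists and modellers who want a tested,
reproducible version of the classic dilution-potential analysis used to
decide whether a Cys-loop receptor pore (GlyR, GABA_A R, tyramine-gated
chloride channels and their engineered cation-selective variants) passes
anions or cations.

## The model

For a pore permeant to Na⁺ and Cl⁻ the GHK voltage equation gives the zero
current potential

```
E_rev = (RT/F) ln [ (P_Na (a_Na)_o + P_Cl (a_Cl)_i) / (P_Na (a_Na)_i + P_Cl (a_Cl)_o) ]
```

where `(a_ion)_o/(a_ion)_i` are extracellular/intracellular activities. In a
dilution-potential experiment the bath NaCl is reduced (1×, 0.5×, 0.25×
against a symmetric internal solution) and the shift ΔE_rev is plotted
against the bath Cl⁻ activity; the curve interpolates between the Na⁺ Nernst
limit (P_Cl/P_Na → 0) and the Cl⁻ Nernst limit (P_Cl/P_Na → ∞), so a
single-parameter least-squares fit in log(P_Cl/P_Na) pins down the
selectivity. Multi-ion cases (K⁺ pooling, Ca²⁺) are handled through the GHK
flux equation with the reversal potential found numerically.

The package ships the standard solution recipes for these experiments
(ES1–ES5 bath series, I1/I2 pipette solutions, the symmetric-NaCl dilution
series) with exact per-ion accounting, plus a seeded macrocurrent simulator
(GHK-scaled peaks, mono-exponential desensitization, replicate-to-replicate
lognormal amplitude variability, Gaussian trace noise) so every stage of the
analysis can be validated end to end.

## Worked example

Run the full pipeline — simulate a dilution-potential study for a strongly
anion-selective channel (P_Cl/P_Na = 18.8), extract reversal potentials, and
refit the GHK equation:

```sh
ghkfit run-all --seed 7 --out out/
cat out/report.txt
```

```
P_Cl/P_Na dilution-potential fit
  config hash     : 018f6bce31c40620
  master seed     : 7
  activity model  : unity
  internal        : I2
  externals       : 1NaCl, 0.5NaCl, 0.25NaCl
  P_Cl/P_Na       : 21.94  (95% CI 18.02 – 28.04)
  residual rmse   : 0.0543 mV over 2 points
  classification  : anion_selective
```

The fitted ratio (21.9, CI 18.0–28.0) recovers the generating value 18.8
within the uncertainty of a single simulated study: reversal potentials are
read off a 7-point I-V protocol (−60…+60 mV in 20 mV steps) by
interpolation, and with four noisy replicates per condition the ratio is
only determined to a few tens of percent — which is exactly what the
confidence interval reports. `classification` applies the default
thresholds (>5 anion-selective, <0.5 cation-selective). A YAML config
(`--config`) controls the channel, solutions, protocol, kinetics, noise,
activity model and analysis options; `out/` also contains the raw traces,
I-V tables, E_rev records and the dilution curve as CSV/JSON.

The same computation is available as a library:

```python
from ghkfit import (registry, ActivityModel, PhysicalContext,
                    analytic_dilution_experiment, build_dilution_curve, fit_pcl_pna)

reg, unity, ctx = registry(), ActivityModel(), PhysicalContext()
externals = [(1.0, reg["1NaCl"]), (0.5, reg["0.5NaCl"]), (0.25, reg["0.25NaCl"])]
exp = analytic_dilution_experiment(18.8, reg["I2"], externals, unity, ctx)
fit = fit_pcl_pna(build_dilution_curve(exp, unity), reg["I2"], externals,
                  unity, ctx, n_bootstrap=0)
print(fit.p_cl_over_p_na)   # 18.799999...  (noise-free round trip)
```

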