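# Methods

## Scope and model

`ghkfit` implements the constant-field (Goldman–Hodgkin–Katz) treatment of
ion selectivity for a ligand-gated channel studied under whole-cell voltage
clamp. The channel is reduced to a map of relative permeabilities
P_ion/P_Na (P_Na ≡ 1); gating, desensitization state models, single-channel
conductance and voltage-dependent block are out of scope. Two GHK layers are
used:

* the **voltage equation** for the Na⁺/Cl⁻ pair,
  `E_rev = (RT/F) ln[(P_Na a_Na,o + P_Cl a_Cl,i)/(P_Na a_Na,i + P_Cl a_Cl,o)]`,
  with the anion's inside activity in the numerator and outside activity in
  the denominator (the sign flip relative to cations);
* the **flux equation** per ion, `I_S ∝ P_S z f(u)(a_i − a_o e^{−u})`, with
  `u = zV/(RT/F)` and `f(u) = u/(1 − e^{−u})`, summed over permeant ions.
  Its zero defines E_rev for arbitrary permeability maps and is found by
  Brent's method on [−150, +150] mV. `f` is continuous through `u = 0`
  (`f(0) = 1`, evaluated via `expm1` elsewhere), so no special-casing leaks
  into results. Divalents (Ca²⁺) enter only through the flux equation —
  no closed voltage form with divalents exists — which suffices here
  because the biological conclusion being reproduced is that Ca²⁺
  permeation is negligible (P_Ca ≈ 0 gives bath-Ca²⁺ swaps < 2 mV of
  E_rev shift).

Conventions: membrane potential is inside − outside; outward cation flux is
positive current; temperatures are kelvin internally (default 295.15 K =
22 °C, the stated room temperature; no recording temperature is published
for these experiments, so it is configurable); RT/F is computed from CODATA
constants each time, never hard-coded (≈25.43 mV at 22 °C).

## Solutions and activities

Solutions are salt recipes (mM) with derived per-ion totals; every salt's
formula unit must be exactly electroneutral. The built-ins transcribe the
published recipes: ES1 (standard bath, 165 mM Cl⁻), ES2 (low Na⁺ by NMDG⁺
substitution), ES3 (low Cl⁻ by gluconate substitution), ES4 (high K⁺), ES5
(high Ca²⁺), pipette solutions I1 (K⁺-rich) and I2 (symmetric NaCl), and
the 1/0.5/0.25 NaCl dilution series (145/72.5/36.25 mM) whose lost
osmolarity is recorded as added sucrose.

Two published descriptions of ES3 disagree (the recipe sums to 45 mM Cl⁻;
the figure legend states 30 mM), so both are shipped as `ES3_recipe` and
`ES3_legend` with no bare `ES3` alias; callers must choose.

Choices a user should know about:

* **Neutral units.** HEPES, glucose, sucrose, EGTA, BAPTA and the
  nucleotide salts (Mg-ATP, Na-GTP, cGMP, cAMP) are modelled as single
  neutral formula units: their charge states are pH-dependent and
  unpublished, so they contribute neither ion totals nor ionic strength.
  Consequently I1 carries no Na⁺ (the 0.5 mM from Na-GTP is folded into the
  neutral unit) — irrelevant at the precision of these fits. pH titrants
  are likewise excluded (amounts unknown) but can be added explicitly.
* **Activity model.** The default is `unity` (activity = concentration):
  the published fits define activities but state no coefficient model, and
  in the shift-based fit the coefficient largely cancels. A Davies-equation
  mode (A = 0.509 √M⁻¹ at 25 °C, linear term 0.3) is provided for
  sensitivity analysis; it moves the dilution curve's x-coordinates
  (activities) but not the measured shifts.

## Synthetic recordings

The generator produces the statistical structure the analysis assumes, per
(condition, holding potential, replicate):

* **Peak amplitude** = `conductance_scale × GHK flux(V) × amplitude factor`.
  The default `conductance_scale = 0.1` puts peaks in the tens-to-hundreds
  of pA, typical of whole-cell macrocurrents in cultured muscle cells.
* **Waveform**: zero baseline (default 50 ms), instantaneous rise at
  agonist onset (a linear `rise_time` is optional — only the decay law of
  the real currents is published, so the template is the simplest shape
  consistent with the recordings), then mono-exponential desensitization
  `I(t) = I_o e^{−t/τ_d} + I_∞` over the 250 ms agonist window, with
  `I_∞ = plateau_fraction × peak`. Defaults τ_d = 100 ms and plateau
  fraction 0.3 are arbitrary round numbers (no kinetic constants are
  published) of the right order for a desensitizing Cys-loop receptor.
* **Replicate variability**: one lognormal amplitude factor (unit mean,
  CV default 0.2) per (condition, replicate) — a replicate models one cell
  whose channel density is shared across the voltage protocol. Lognormal
  keeps peak signs consistent.
* **Trace noise**: additive Gaussian, default sd 2 pA.
* **Seeding**: a single seed drives a `SeedSequence` tree (condition →
  replicate), making output bit-identical across runs; the CLI derives
  per-stage seeds from one master seed the same way.

What the generator does **not** emulate: series-resistance and capacitance
artifacts, liquid-junction potentials, leak currents, rundown, and any
current component not described by GHK flux through a fixed permeability
map. Passing tests therefore demonstrate that the analysis chain is
self-consistent and recovers known ground truth under the assumed noise
structure — not that these artifacts would be handled correctly in real
recordings (junction potentials in particular cancel only because the fit
uses shifts).

## I-V analysis

* **Peak**: signed extremum of the baseline-subtracted current over the
  agonist window (baseline = mean of all pre-agonist samples). The global
  extremum is used rather than the onset value; for a monotonically
  decaying template they coincide.
* **Decay fit**: `scipy.optimize.curve_fit` on the post-peak segment with
  time re-zeroed at the peak; ≥10 samples required; a constant segment
  raises an "unidentifiable" error rather than returning a junk τ_d.
* **Replicate QC (80% rule)**: an experiment is discarded when the maximum
  pairwise relative difference `|p_i − p_j| / max(|p_i|, |p_j|)` of
  replicate peaks exceeds 0.80. The published rule does not define the
  denominator; the larger magnitude is used (configurable). The rule is
  applied to the replicate peaks at the holding potential with the largest
  mean response, where it has the most power; failing QC discards the whole
  condition. All-zero peaks are discarded as "no response"; a single
  replicate passes vacuously with a flag.
* **Averaging/normalization**: per potential, the mean of the first three
  QC-passing replicates (replicate order is exchangeable by construction);
  means are then divided by I_max = max |mean peak|. Averaging before
  normalizing is immaterial for E_rev, which is invariant under positive
  rescaling.
* **E_rev**: linear interpolation between the sign-change bracketing pair
  (the extraction method is not published; interpolation is the simplest
  reproducible choice). With multiple sign changes the bracket nearest
  0 mV is used and flagged. An optional local quadratic refinement
  (`erev_method: quad`) reduces the ≤1.5 mV interpolation error of the
  20 mV grid by about an order of magnitude on noise-free curves; it is off
  by default to keep the default chain simple. A standard error is attached
  when ≥2 replicates yield individual zero crossings (SEM of per-replicate
  E_rev values).

## Permeability fit

The fit target is the **shift** ΔE_rev = E_rev(dilution) − E_rev(reference)
against bath Cl⁻ activity, matching how dilution-potential data are
plotted and cancelling condition-independent offsets (junction potentials);
fitting absolute potentials is available through the same predictor. The
single parameter is log(P_Cl/P_Na) — positivity enforced, anion- and
cation-favoring channels treated symmetrically. The objective (sum of
squared shift residuals) is scanned on a 49-point grid over log-ratio
[−12, 12] and refined by bounded scalar minimization around the grid
optimum; the grid subsumes multi-start and guards the flat ratio → 0/∞
limits, where the objective plateaus. On noise-free data the objective is
unimodal (verified by grid scan in the tests) and round trips recover
generating ratios across [10⁻², 10²] to better than 10⁻⁴ relative.

Uncertainty is a parametric bootstrap (default 1000 resamples, seeded):
each observed shift is resampled from N(obs, se) — se from the E_rev
records, falling back to the residual rmse — and refit; 95% percentile
bounds are reported. At the realistic design (shift sd 1.5 mV, five
experiments) empirical coverage is ≥85% in the seeded suite; mild
undercoverage is expected at such small n.

Classification: P_Cl/P_Na > 5 → anion-selective, < 0.5 → cation-selective,
else nonselective. The defaults separate the two reported channel classes
(≈18.8 vs ≈0.19) by more than an order of magnitude on either side.

For fits involving the K⁺-rich pipette solution I1, monovalent cations are
pooled at equal permeability (P_K = P_Na), the standard treatment for a
channel that does not distinguish them; the I2-based dilution fits contain
no K⁺, so pooling is inert there. Bath-swap shift analysis (high K⁺, high
Ca²⁺) reports a difference of means with a seeded percentile-bootstrap CI
and a direction label only when the CI excludes zero; no p-values are
produced.

## Problem sizes and numerical choices

The test suite and the acceptance script run simulated studies at the
published design scale: 7 holding potentials, 3 averaged traces per
condition, 4–5 independent experiments, 1 ms sampling over 300 ms sweeps.
Monte-Carlo checks use 30–50 seeds and 250–500 bootstrap resamples; the
whole suite completes in well under a minute on one core. Root finding uses
Brent's method at xtol 10⁻¹⁰ mV; the GHK flux factor is evaluated with
`expm1`; dilution factors outside (0, 1] and non-electroneutral salts are
rejected at construction.

## Known limitations

* The GHK framework assumes independent ion movement in a constant field;
  anomalous mole-fraction effects, saturation and block are not modelled.
* Divalent permeability is only treated through the flux equation; a
  channel with substantial P_Ca would need a bi-ionic formalism this
  package does not provide.
* The simulator's noise model (Gaussian trace noise + lognormal amplitude)
  is a deliberate idealization; real recording artifacts listed above are
  absent, so QC behaviour on real data may differ.
* Absolute simulated E_rev values for the K⁺-rich internal depend on the
  neutral-unit bookkeeping of I1 (e.g. its trace Na⁺); only shifts are
  robust to this and the inference is therefore shift-based.
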