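# Methods

## Model structure and assumptions

The consortium is modelled as a well-mixed batch culture with six
states: producer biomass `X_V`, consumer biomass `X_E` (both in OD600
units), alginate `S` (g/L), acetate `A` (g/L), 3-HP `P` (mg/L) and
ampicillin `C` (µg/mL).  The structural commitments are:

* **Monod growth.**  Each strain grows on its primary substrate with
  saturating kinetics.  The producer may additionally re-assimilate
  acetate once alginate runs low; this diauxie is smooth, gated by
  `g(S) = K_rep/(K_rep + S)`, to avoid ODE discontinuities a hard switch
  would introduce.
* **Growth-coupled fluxes.**  Substrate uptake, acetate overflow
  (`φ_A` g acetate per g alginate) and product formation (`Y_PA` mg 3-HP
  per g acetate) are all proportional to the corresponding gross growth
  rate.  A consequence worth knowing: a cell whose *net* growth is
  cancelled by antibiotic kill still converts substrate, so suppression
  of net producer growth does not by itself stop the carbon supply —
  only producer decline does.
* **Growth-linked antibiotic kill.**  The death rate is
  `α·μ·C/(K_kill + C)`: β-lactams act on growing cells, so non-growing
  cells are not killed.  A growth-independent variant
  (`growth_linked_kill=False`) replaces the instantaneous rate with
  `μ_max` for sensitivity analyses.
* **Public-good detoxification only.**  Ampicillin is removed from the
  shared medium in proportion to β-lactamase activity and consumer
  biomass (`dC/dt = −k_cat·β(P)·X_E·C`).  The consumer enjoys no
  cell-autonomous (periplasmic) protection before bulk detoxification;
  protection is entirely a public good.  This is the simplest mechanism
  consistent with the observed growth rescue, and it is a known
  simplification.
* **Circuit law.**  `β(P)` is zero (no *bla*), constant
  (constitutive expression at strength `beta_0`), or Hill-activated,
  `beta_0 + (beta_1 − beta_0)·P^n/(K_P^n + P^n)`, for the
  product-inducible guider.  Constitutive promoter strength is exposed
  as a continuous `beta_0` rather than a fixed promoter list.
* **Post-depletion product loss.**  3-HP decays at
  `k_deg·g(S)·(X_V+X_E)·P` — second-order in biomass and product, gated
  open only as alginate depletes, reflecting product consumption by
  either strain once the preferred carbon source is gone.  `k_deg = 0`
  disables it; likewise `mu_max_ac = 0` disables producer acetate
  re-use.  Both terms ship enabled because the calibration endpoints
  (declining late-time titres, low commensal titre) favour them.
* **Units.**  Biomass is carried in OD600-equivalent units throughout;
  yields are OD per g/L consumed.  No OD→gDCW conversion is applied
  anywhere.

Not modelled: spatial structure, plasmid loss, circuit expression
burden, pH/oxygen effects, single-cell stochasticity, fed-batch or
chemostat operation.

## Parameters and defaults

Flat keys (`producer.*`, `consumer.*`, `production.*`, `circuit.*`)
serialize to YAML via `save_params`/`load_params`.  The shipped defaults
divide into three provenance classes:

1. **Measured anchors (held fixed).**  `producer.mu_max_primary = 0.83
   h⁻¹`, `consumer.mu_max_primary = 0.16 h⁻¹` (monoculture growth-rate
   measurements) and `production.y_pa = 27.282` mg/g, which reproduces
   the consumer monoculture batch (272.82 mg/L of 3-HP from 10 g/L
   acetate) exactly under the model's flux bookkeeping.
2. **Regime-setting choices.**  The susceptibility constants
   (`alpha_kill` 4.5/2.0, `k_kill` 25/6 µg/mL for producer/consumer)
   place the producer in the observed dose-response window: marginal
   inhibition at 5 µg/mL (kill fraction ≈ 0.75), collapse without
   detoxification at 10 (≈ 1.29), rapid collapse at 20 (≈ 2.0).  A
   saturating kill law cannot make the 5→10 µg/mL contrast arbitrarily
   steep (the factor is bounded by 2), which forces the large `k_kill`
   for the producer.  The circuit constants (`beta_0 = 0.02`,
   `beta_1 = 0.3`, `K_P = 50` mg/L, `n = 2`, `k_cat = 0.08`) give a
   basal leak too weak to rescue growth alone and an induced clearance
   on the multi-hour timescale that sustains a long
   "suppressed-production" window before producer recovery.
3. **Calibrated constants.**  `phi_a = 0.4769`, `producer.y_x = 0.5444`,
   `consumer.y_x = 0.271`, `producer.mu_max_ac = 0.2787`,
   `k_pdeg = 0.0013` were refined by bounded least squares
   (`scripts/calibrate_defaults.py`) against the 48-h co-culture
   endpoints of the ampicillin dose series: titres 68.35, 125.40 and
   293.55 mg/L and consumer fractions 18.5%, 29.15% and 40.4% at 0, 5
   and 10 µg/mL.

The 20 µg/mL titre endpoint (199.40 mg/L) is excluded from the
calibration objective and unattainable by design: at that dose only
~2.5 g/L of alginate is consumed, which under any fixed stoichiometry
anchored to `y_pa = 27.282` mg/g caps the titre near 40 mg/L.  The
experimental titre therefore implies a strongly condition-dependent
yield that a fixed-yield model cannot represent; the model keeps the
qualitative shape (titre maximal at 10, depressed at 20) and the ledger
of what it reproduces quantitatively stops there.

A second known compression: with the monoculture `μ_max` values driving
simple Monod kinetics, the simulated commensal batch exhausts 20 g/L of
alginate within ~6 h, much faster than real fermentations, where uptake
slows for reasons outside the model (mass transfer, product inhibition,
physiological state).  Endpoint comparisons at 48 h are unaffected, but
simulated and experimental *time courses* should not be compared
point-by-point mid-run.

## Experiment designs

* `scan_amp` — one batch per initial ampicillin dose from the standard
  inoculum (producer OD 0.5, consumer OD 2, 20 g/L alginate); summary
  rows report the 48-h titre, peak acetate (taken on the dense solver
  grid, not the 6-h output grid), final OD, final consumer fraction and
  alginate consumed.
* `scan_inoculum` — titre versus (producer, consumer) inoculum pairs.
* `growth_matrix` — ΔOD600 between 0 and 24 h for exogenous 3-HP ×
  ampicillin combinations.  The consumer's product yield is zeroed here:
  the assay emulates a *non-producing* consumer strain so the only 3-HP
  present is the exogenous dose driving the circuit.  The horizon (24 h)
  is configurable.
* `compare_strategies` — final titres of the commensal baseline, a
  ladder of constitutive strengths (default grid 0.003–3, spanning three
  orders of magnitude like a weak-to-strong promoter series), and the
  guider, at one dose.

## Synthetic measurement layer

`make_study` simulates a design and samples it every 6 h over 0–48 h
(nine points, the cadence of flask sampling), applying mean-one
lognormal multiplicative noise per channel (default CV 5%, matching
typical triplicate scatter; the replicate noise of real fermentation data is rarely tabulated, so the default is an assumption)
plus optional additive detection floors; concentrations are truncated at
zero and ratios clipped to [0, 1].  Lognormal noise was chosen over
Gaussian specifically to keep concentrations positive.

The assay-level generators mirror the two calibrated instruments of
a typical alginate-fermentation workflow.  The carbazole readout is a linear absorbance curve
(default slope 0.45 AU per g/L, calibrated over 0–2 g/L) with Gaussian
residuals; inversion clamps at zero and flags estimates beyond the
calibrated range for dilution.  Cytometry counts are a single binomial
draw over `n_cells` (default floor 10⁵; below 10⁴ a warning is raised)
with the success probability given by a linear instrument calibration
perturbed by symmetric gate misclassification (default ε = 0.5%; a
standard-curve correction exists in practice, implying imperfect
gating).  `estimate_ratio` inverts both distortions, making the
estimator unbiased in expectation with bias below one binomial standard
error across true ratios 0.1–0.9.

All generators are pure functions of (inputs, seed); per-condition
streams are split from the study seed via `numpy.random.SeedSequence`.

## Calibration machinery

The objective is a sum over conditions, channels and times of squared
residuals scaled per channel by its noise scale (or, absent one, the
channel's maximum observed value) — without this weighting the g/L-scale
alginate channel dominates the mg/L and OD channels.  Missing values are
skipped; an integration failure inside the optimizer contributes a large
finite penalty per data point rather than raising, keeping the search
inside the feasible region.

`fit` runs bounded `scipy.optimize.least_squares` from multiple starts:
the base parameter point first, then the leading points of one seeded
Latin-hypercube pool (so start sets are nested in `n_starts`, making
best-of-n losses monotone for nested seeded sets).  Default 20 starts,
bounds ±10× around the base values; both overridable.  Results carry
per-start losses, the fixed mask and the seed; fixing every parameter
turns `fit` into a scorer for hand-parameterized models.

`bootstrap` resamples residuals on the **relative** scale: measurement
noise is multiplicative, so relative residuals (observed/fitted − 1) are
the exchangeable quantity, pooled within channel and re-applied
multiplicatively to fitted trajectories.  Two refinements matter in
practice.  Fitted values near zero (below 10⁻³ of the channel scale) are
left unperturbed — multiplicative noise cannot move them, and additive
resampling there badly misstates the information they carry.  A channel
with fewer than five informative points cannot characterize its own
residual distribution and draws from the all-channel pool instead;
without this, a channel whose information is concentrated in a single
point (e.g. acetate at the depletion front) receives the *same* residual
in every replicate and its variance contribution collapses, producing
severely overconfident intervals.  Each replicate is refit from the
point estimate, and the point estimate is included among the replicate
draws so percentile intervals always contain it.

Identifiability caveat: only parameters demonstrated sensitive by a
finite-difference loss check (the maximal growth rates, overflow
stoichiometry and yields under the standard four-dose design) should be
read from fits; others are reported but not asserted on.  Both fitted and hand-parameterized workflows are supported via
`fixed_mask`.

## Numerical choices

* Integration: `scipy.integrate.solve_ivp` with LSODA (adaptive,
  stiff-capable), `rtol = 1e-8`, `atol = 1e-10` for presentation runs
  and `1e-6`/`1e-8` inside fitting loops; deterministic for fixed
  inputs.  Output states are clipped at zero; the right-hand side treats
  solver-induced negative excursions as zero, so no component's outflow
  can drive it below zero.
* Oracle check: a fixed-step classical RK4 integrator at h = 0.001 h,
  written independently in the tests, agrees with the adaptive solution
  to 1e-4 relative on 12-h runs.
* Degenerate inputs: an empty culture reports its population ratio as
  missing (NaN), never 0; an all-missing observation set scores 0 with a
  warning; event-terminated runs append the event time to the output
  grid.
* Fold-changes round half-up to one decimal for presentation.
* C-mole yield uses 3-HP as free acid (90.08 g/mol, 3 C) and alginate
  per anhydrouronate residue (176.12 g/mol, 6 C).  The residue basis
  (polymerized monomer) was chosen over the monomeric sodium salt
  (~198 g/mol); the constants are isolated in one block in
  `metrics.py` and swappable.

## Problem sizes

Default study sizes keep every computation interactive: 48-h batches
with 9 output samples, dose series of 4, growth matrices of 3 × 6,
recovery fits of 2 free parameters × 8 starts on 4 × 9-sample studies,
and bootstraps of 15–20 replicates.  All scale linearly if enlarged.

## Known limitations

* Fixed stoichiometric yields cannot reproduce condition-dependent
  yield shifts (the 20 µg/mL endpoint above).
* The Monod timescale compresses substrate consumption relative to real
  fermentations (see above); the model is an endpoint/ordering model,
  not a trajectory-matching one, unless re-calibrated on time-course
  data.
* No cell-autonomous ampicillin resistance for the consumer; at very
  high doses the model may under-predict consumer survival.
* Passing tests on synthetic data demonstrate internal consistency and
  recoverability under the stated noise model — not that real
  fermentation data obey that noise model.
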