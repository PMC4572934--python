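# Methods

## Assay model and normalization

A dual-luciferase screen reports two counts per well: firefly luminescence
driven by the pathway reporter (here an NF-κB response element induced by
TNFα) and renilla luminescence from a constitutive co-transfected control.
The ratio RLU = firefly/renilla removes shared multiplicative nuisance —
cell number, transfection efficiency, dispensing volume — because both
reporters scale with it.

Within each (plate, replicate), activities are normalized to the mean RLU
of that plate-replicate's TNFα control wells. This makes the induced
control mean exactly 1 by construction (asserted to 1e-12 in the tests)
and removes per-plate-replicate batch effects. Normalization is strictly
per plate-replicate; no cross-plate information is used.

Wells with renilla = 0 have undefined RLU. They are never silently
dropped: the replicate is excluded from scoring, the compound is scored on
its remaining replicates against a null of matching dimensionality, and a
compound with no usable replicate is routed to the viability-excluded set.

## Hit statistic and p-values

Each compound's statistic is the Manhattan (L1) distance between its
replicate activity vector and the all-ones control-mean vector,
D = Σ_r |a_r − 1|. Summing per-replicate deviations (rather than using the
replicate mean) rewards consistent deviation across replicates.

Two null models are provided, both built exclusively from the TNFα control
wells of the same library plate, each control well scored exactly as a
compound would be:

- **empirical** (default): upper-tail add-one estimator
  p = (#{D_null ≥ D} + 1)/(n + 1). It makes no distributional assumption
  and never returns p = 0; its granularity is 1/(n + 1), so the control
  pool must be large enough to resolve the significance level (see layout
  below). Ties count toward the tail (≥), the conservative convention.
- **half_normal**: σ = RMS of the null distances, p = 2(1 − Φ(D/σ)).
  A smooth alternative for small control pools; note the sum of several
  folded normals is lighter-tailed than a half-normal with matched RMS, so
  this option is markedly conservative at conventional α and suits
  screens that prioritize specificity.

p-values are two-sided in spirit (distance is unsigned); the inhibitory
direction is imposed as a separate filter (mean activity < 1), and the
final viability filter retains a compound only if its median renilla
across replicates is ≥ 0.5 × the plate renilla median (boundary
inclusive). The threshold is exposed (`--viability-threshold`) since no
community-standard cutoff exists. Filters are applied in the order
significance → direction → viability, and the flowchart report counts the
removals of each stage. No multiple-testing correction is applied by
default, matching common primary-screen practice of a raw p ≤ 0.05 call;
a Benjamini–Hochberg option (`bh=True`) is available. Null models default
to per-plate scope; `pool_plates=True` pools control distances across
plates.

## Synthetic screen generator

The generator emulates the screen the pipeline targets: 4 × 384-well
plates, 300 library compounds per plate at 10 µM in the presence of TNFα,
assayed in triplicate. Per-well counts follow

    renilla = renilla_mean × plate_effect × cyto × LN(cv)
    firefly = rlu_mean × renilla × LN(cv)

where LN(cv) is a mean-one lognormal factor (σ² = ln(1 + cv²)),
plate_effect = exp(N(0, plate_effect_sd²)) is one scalar per
(plate, replicate), and cyto = cytotoxic_renilla_frac for cytotoxic
compounds (else 1). Consequences the tests rely on:

- RLU = rlu_mean × LN(cv): the ratio is unbiased with CV =
  measurement_cv, free of plate effects (the normalization's job is to
  absorb what remains in raw counts).
- Cytotoxicity depresses both reporters proportionally — ratio unbiased,
  renilla low — exactly the failure mode the viability filter targets.
- The noise-free limit (cv = 0, plate_effect_sd = 0) is an exact
  evaluation of the mean model.

Mean RLUs: DMSO and agonist-alone wells sit at `dmso_baseline_rlu` (0.2),
TNFα wells at `tnfa_baseline_rlu` (2.0) — a 10-fold induction typical of
NF-κB reporters; agonist+TNFα wells retain half the induced component
(`gw_inhibition_frac = 0.5`). True inhibitors (5% of the library) reduce
the induced component by a fraction drawn uniformly from [0.7, 0.9];
cytotoxic compounds (2%) retain 30% of renilla. Measurement CV defaults to
0.1 and the plate-effect SD to 0.15 — plausible values for automated
luminescence assays; no published variance estimates exist for this assay
class to fit against, so they are declared, not fitted.

**Default layout.** Controls occupy edge columns: 40 TNFα wells
(columns 1, 24, and rows I–P of column 23), 8 DMSO, 8 agonist, 8
agonist+TNFα; 300 compounds fill columns 3–22. Forty TNFα wells were
chosen because the empirical null's smallest attainable p is 1/(n+1):
n = 40 resolves p = 0.024 < 0.05, so the default α is actually reachable;
fewer than ~20 anchor wells would make every compound non-significant by
construction.

**What the generator does not emulate:** spatial plate artifacts (edge
evaporation, row/column gradients — hence no B-score/median-polish step),
compound fluorescence interference, signal drift across the read order,
and correlated noise between the two reporters. Passing tests therefore
demonstrate the statistical machinery is correct under the declared noise
model, not that real screens are free of artifacts the model omits.

## Dose–response fitting

The 4PL model y = bottom + (top − bottom)/(1 + (EC50/c)^h) is fit on
log10 concentration by bounded least squares (trust-region reflective,
ftol = xtol = 1e-14) with multi-start initialization: h ∈ {±0.5, ±1, ±2} ×
log-EC50 at the dose quartiles — 18 starts — keeping the best optimum.
4PL least squares is multimodal in (h, EC50); the grid covers both
orientations so inhibition curves are handled by the sign of h, never by
reflecting the data. Fits are canonicalized via the exact identity
(b, t, h, e) ≡ (t, b, −h, e) so that top ≥ bottom always holds. The bottom
asymptote is constrained ≥ 0 by default (luminescence), removable with
`bottom_min=None`. An EC50 more than one log-unit outside the dosed range
is flagged `extrapolated` rather than rejected. At least 4 distinct
concentrations are required. Relative efficacy is the fitted span as a
percentage of a reference fit's span. EC50 confidence intervals use
case-resampling bootstrap percentiles (resamples with < 4 distinct doses
are redrawn); no analytic SE is reported because the profile is
asymmetric in log-dose.

## Numerical and design choices

- Empirical p-values use `searchsorted` on the sorted null pool;
  equality with brute-force counting is asserted exactly in tests.
- Degenerate nulls (all control distances 0) raise rather than emit p = 1
  for everything: a screen with zero control variance is unanalyzable.
- Screen tables round-trip exactly: floats are written at full precision
  and parsed with `float_precision="round_trip"`.
- Outputs carry a provenance header (version, seed, config hash) and no
  timestamps, so identical (config, seed) runs are byte-identical.
- The flowchart regression fixture (default config, seed 42:
  1200 tested → 103 significant → 35 removed by direction → 0 removed by
  viability → 68 hits) was recorded at first build and frozen.
- Z′-factor is computed between TNFα and DMSO controls as a QC readout
  only; it never gates hits.
- Manual rescue of structural analogs of hits (a practice in published
  screens) is intentionally out of algorithmic scope; score tables are
  plain DataFrames/TSVs to which an annotated manual-add list can be
  appended downstream.

## Known limitations

- **Calibration vs. false-discovery proportion.** The default empirical
  null is calibrated: on null screens ~5% of compounds reach p ≤ 0.05
  (measured 0.056 pooled over 10 screens). At 5% true-inhibitor
  prevalence this necessarily yields ≈ 1140 × 0.05 × P(inhibiting |
  significant, null) ≈ 20–30 false hits against ~60 true ones, an FDP
  near 0.3. A raw p ≤ 0.05 rule cannot bound FDP at 0.10 under these
  conditions; enabling `bh=True` (Benjamini–Hochberg) or the conservative
  half-normal null trades sensitivity-threshold calibration for FDP
  control. The default remains the raw rule because that is the
  convention for primary-screen triage, where false positives are
  tolerated and removed in confirmation screens.
- Sensitivity claims hold for strong spiked effects (70–90% inhibition at
  CV 0.1); weak inhibitors near the noise floor are not recoverable at
  n = 3 replicates and no claim is made for them.
- The generator's scale parameters (problem sizes: 10 null screens and
  5 spike-in screens in the acceptance checks, 100 curves for 4PL
  recovery) are the package's own validation sizes, chosen to estimate
  each rate with adequate precision.
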