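# lucihits

Hit selection and dose–response analysis for plate-based dual-luciferase
reporter screens.

## The problem

High-throughput reporter screens measure a pathway-specific firefly
luciferase signal against a constitutive renilla luciferase control in
every well of a 384-well plate. A typical campaign — the kind this package
targets — screens an FDA-approved drug library (e.g. Prestwick, 1,200
compounds on four plates, each plate assayed in triplicate) for compounds
that suppress TNFα-induced NF-κB transcriptional activity, with on-plate
DMSO, reference-agonist (GW4064), TNFα, and agonist+TNFα control wells.
Analysts must then answer three questions per compound: is its effect
statistically distinguishable from the induced controls, is the effect in
the inhibitory direction, and is it a genuine pathway effect rather than
cytotoxicity or poor transfection?

`lucihits` implements that analysis as a tested, reusable pipeline, plus a
seeded synthetic-screen generator so the whole chain can be validated
against known ground truth.

## The method

For each well, the readout is the ratio **RLU = firefly / renilla**,
which cancels well-to-well differences in cell number and transfection.
Within each (plate, replicate), activities are normalized to the plate's
TNFα anchor:

    a_i = RLU_i / mean(RLU over TNFα wells of the same plate-replicate)

so the induced control mean is exactly 1. Each compound's hit statistic is
the **Manhattan (L1) distance** of its replicate activity vector from the
control mean:

    D = Σ_r |a_r − 1|

Distances are converted to p-values with the **empirical upper-tail CDF**
of the distances of the same plate's TNFα control wells, using the add-one
(permutation-style) estimator

    p = (#{D_null ≥ D} + 1) / (n_null + 1)

which never returns 0 (a parametric half-normal tail, `p = 2(1 − Φ(D/σ))`
with σ the RMS null distance, is available as an option). A compound is a
**hit** if p ≤ α (default 0.05), its mean activity is < 1 (inhibition),
and it passes the **viability filter**: median renilla across replicates
of at least half the plate renilla median. Stage counts are reported as a
hit-selection flowchart.

Dose–response curves are fit by multi-start least squares to the
four-parameter logistic

    y = bottom + (top − bottom) / (1 + (EC50 / c)^h)

on log concentration; the midpoint of an inhibition fit (h < 0) is the
IC50, and relative efficacy of a partial agonist is
`100 × span / span_reference`. Case-resampling bootstrap intervals on the
EC50 are available.

The estimators follow scikit-learn conventions: `HitCaller(...).fit(screen)`
exposes `scores_`, `flowchart_`, `null_models_`; `FourPLRegressor().fit(conc,
response)` exposes `bottom_`, `top_`, `hill_`, `ec50_` and composes with
sklearn tooling (`get_params`, `clone`).

## Worked example

Run the full pipeline — simulate a Prestwick-scale screen, call hits, fit
an inhibition dose–response curve — from the packaged demo configuration:

```
lucihits run --config examples/demo_config.yaml --out-dir demo_run
```

which prints (abridged):

```
lucihits v0.1.0 seed=42 config_sha=f624186a2ab3
simulate: 4368 wells
call-hits: {'n_tested': 1200, 'n_significant': 103, 'n_removed_by_direction': 35,
            'n_removed_by_viability': 0, 'n_hits': 68, 'alpha': 0.05,
            'viability_threshold': 0.5}
fit-dr: ec50 = 1.3609e-06 M
```

Of 1,200 simulated compounds, 103 have distance p ≤ 0.05 against their
plate's control-derived null; 35 of those deviate upward (activation, not
inhibition) and are removed; none of the remaining significant inhibitors
fail the renilla filter in this run, leaving 68 hits — the 59 spiked-in
true inhibitors plus false positives consistent with a raw p ≤ 0.05 rule.
The fitted IC50 of the simulated inhibition curve (true value 1.4 µM, 5%
noise) is 1.36 µM. Per-compound results land in `demo_run/scores.tsv`:

```
compound_id plate_id n_replicates mean_activity distance  p_value inhibits renilla_ok significant hit
CMPD-0021   P1       3            0.948964      0.589893  0.02439 True     True       True        True
CMPD-0028   P1       3            0.264248      2.207256  0.02439 True     True       True        True
```

The same steps are available separately as `lucihits simulate`,
`lucihits call-hits --screen screen.csv --layout layout.csv`, and
`lucihits fit-dr --curves curves.csv --orientation inhibition`, or as
library calls (`generate_screen`, `select_hits`, `fit_4pl`).

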