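# Methods

`nmdarprof` quantifies the functional consequences of NMDA receptor (NMDAR)
missense variants from four kinds of raw measurement — concentration–response
amplitude tables, whole-cell current traces, plate-reader absorbance time
courses, and before/after amplitude pairs — and combines the per-assay results
into a composite charge-transfer index that summarizes net gain or loss of
receptor function relative to wild type (WT).

## Models fitted

**Agonist activation.** Response amplitudes across an agonist ladder follow
the Hill equation

    Response(%) = 100 / (1 + (EC50/[agonist])^N)

fitted per cell by nonlinear least squares (lmfit, trust-region
`least_squares` backend).  EC50 is optimized in log10 space (the likelihood
is far closer to quadratic there), the Hill slope N is bounded to [0.3, 5],
and the maximal response ("top") is a free parameter.  Five log-spaced EC50
initializations spanning the data range guard against local minima on sparse
ladders; the lowest-RSS solution wins.  Responses are normalized to the
*fitted* top rather than the largest observed point, because for
potency-shifted variants the highest tested concentration can be
sub-saturating.  A fit that terminates at a parameter bound, or a series with
no resolvable concentration dependence, is flagged `converged=False` and
excluded from aggregation — never silently defaulted.

**Inhibition with a residual plateau.** Negative allosteric modulators
(Mg²⁺, Zn²⁺) are fitted with

    Response(%) = (100 − minimum) / (1 + ([modulator]/IC50)^N) + minimum

where `minimum` is the residual response at saturating modulator, constrained
to [0, 100).  Responses are percent of the unmodulated control.  If no tested
concentration exceeds the fitted IC50 the plateau is unconstrained and a
wide-CI warning is attached to the result.

**Aggregation.** Composite curves and summary tables use the mean of
per-cell parameter estimates with a Student-t 95% CI (df = n − 1), not a
pooled global fit: each cell is the independent experimental unit.
Ratio-valued quantities (percent-of-WT, fold potentiation) are summarized on
the log scale and exponentiated, because ratios are multiplicative and
right-skewed.  Group comparisons use the classic pooled-variance unpaired
Student's t-test (Welch available behind a flag); no multiple-testing
correction is applied, and the number of tests performed is recorded in the
profile.

**Current kinetics.** Baseline is the mean of the 50 ms preceding agonist
application; the peak is the extremum within the application window (flagged
non-responsive below 3× the baseline SD); steady state is the mean of the
final 10% of the window; densities are normalized by cell capacitance.
Rise time is the 10–90% interval on the rising phase by linear interpolation
between samples, floored at one sample interval.  Decays are fitted as
A_f·exp(−t/τ_f) + A_s·exp(−t/τ_s) (plus a plateau for desensitization
windows); a single-exponential fallback is selected when the second component
does not improve the fit by an F-test at α = 0.01.  The weighted time
constant τ_w = (A_f τ_f + A_s τ_s)/(A_f + A_s) approximates the decay of the
synaptic current.  The deactivation window starts one sample after agonist
removal to skip the solution-exchange artifact; component amplitudes (hence
%fast) therefore refer to the window start, which shifts %fast by ~0.1%
relative while leaving the time constants exact.  %fast is an amplitude
fraction, not a relative-charge fraction, and is labeled as such.  Charge
transfer is the trapezoidal integral of baseline-subtracted current density
from application start to the end of the trace, with a warning when the tail
has not decayed below 5% of peak.  Inward currents are negative on disk; all
reported densities are magnitudes.

**Open probability from MTSEA.** MTSEA covalently locks open channels
carrying an engineered gate cysteine, so the fold potentiation of the steady
agonist-evoked current is inversely related to the pre-modification open
probability: P_open = (γ_MTSEA/γ_CONTROL)·(1/potentiation).  "Potentiation"
is the plain after/before current ratio (a ratio of 3.26 is reported as
326%); this reading reproduces the published WT/variant P_open pair
self-consistently with a single conductance ratio, whereas an
"increase-above-baseline" reading does not.  The chord-conductance ratio is
not measurable here; it ships as a configuration constant (default 0.8476,
calibrated by inverting the relation on WT GluN1/GluN2A with P_open 0.26 at
3.26-fold potentiation) with the calibration helper exposed and the source
recorded in every output.

**Surface expression.** Each well's nitrocefin absorbance slope is an OLS
regression over the well's linear range, chosen as the longest prefix with
R² ≥ 0.98 (minimum 10 reads, configurable) — enzymatic turnover plateaus
once substrate or enzyme saturates, and the fit window must precede that.
The surface/total ratio is background-subtracted on both numerator and
denominator, making it invariant to overall scaling and to any common
background ramp.  The no-GluN2 control is a QC gate (surface signal < 10% of
the cotransfected signal) and never enters the ratio.  Percent-of-WT pairs
variant and WT experiments one-to-one and aggregates geometrically.

**Composite charge-transfer index.** The synaptic index is the product of
the mutant/WT ratios of τ_w, P_open, surface expression, occupancy at 3 µM
glycine and 1 mM glutamate, and the Mg²⁺ term; the nonsynaptic index drops
the τ_w term and evaluates glutamate occupancy at an ambient 0.1 µM.  Two
deliberate choices:

* The Mg²⁺ term defaults to the ratio of *unblocked fractional responses* at
  1 mM (from the inhibition model at −60 mV), since charge scales with the
  current that actually flows; the percentage-inhibition reading is exposed
  as an option.  At IC50s of 19 vs 22 µM the two readings differ by ~15%
  (1.154 vs 0.997), so the choice is material and is always recorded in the
  result's composition.
* The synaptic index is computed both with and without the open-probability
  term.  Published composite values assembled from component tables are
  sometimes reproducible only with one of the two; both are first-class
  outputs with the composition recorded verbatim, and no silent
  reconciliation is attempted.

Occupancy terms need a Hill slope; when a fitted slope is unavailable the
default is N = 1.5 for both agonists (typical of NMDAR composite fits,
configurable), and `sensitivity_scan` tabulates both indices across a grid
of assumed slopes to expose the dependence — for a potency-reduced variant
the nonsynaptic index scales roughly as (EC50_wt/EC50_mut)^N, so the slope
assumption dominates that index's absolute value.

## Synthetic data generator

The generator emulates the data model each analysis fits, with known ground
truth: Hill/inhibition amplitudes with multiplicative Gaussian noise
(CV-parameterized, truncated at zero so amplitudes stay non-negative);
bi-exponential decays sampled at 20 kHz with additive Gaussian noise
(injected post-filter; hardware anti-alias filtering is not modeled); linear
absorbance ramps with per-well rate scatter and per-read noise; and
potentiation pairs with mean-unbiased lognormal ratio scatter.  Randomness
derives from one master seed with a separate child stream per generator and
per cell, so identical configurations are bit-reproducible and adding cells
never perturbs earlier cells.  Decay traces anchor the post-removal
bi-exponential at the level actually reached at the end of the application,
which coincides with the nominal peak to machine precision for prolonged
(1.5 s) applications.

What the generator does *not* emulate — and what passing tests therefore do
not establish about real recordings: solution-exchange kinetics and open-tip
artifacts, series-resistance error, channel gating stochasticity (decays are
drawn from the fitted bi-exponential form itself, not a kinetic scheme),
rundown/desensitization history effects, and enzyme-kinetic (Michaelis–
Menten) curvature in the reporter assay.  Parameter-recovery results show
the estimators are correct under the assumed noise model, not that the model
captures every failure mode of the bench data.

## Numerical choices and degenerate inputs

Optimizer tolerances are set to 1e−15 (ftol/xtol/gtol) so that zero-noise
data reproduce generating parameters to ≤1e−6 relative, which the tests
assert.  Tie-breaks and edge cases: bi-exponential components are sorted so
τ_fast ≤ τ_slow; rise times use a first-crossing convention and flag
non-monotone rises; instantaneous steps report the one-sample resolution
floor; a background-only plate raises a degenerate-assay error; n = 1 groups
yield flagged degenerate CIs rather than errors; potentiation below the
conductance ratio (which would imply P_open > 1) raises a domain error naming
the violated precondition.

## Problem sizes in the test and acceptance runs

Simulation-based checks run at the sample sizes of the study they emulate
(10–16 cells per curve, 12–14 cells for inhibition, 5 paired plate
experiments, 4 wells per condition, 30 one-minute reads) with 5%
multiplicative noise.  Repeated-replicate property checks use 20 replicate
experiments (EC50 recovery), 25 traces (τ_w at 1% additive noise), and 500
replicates (CI coverage) — sizes chosen so the estimator properties they
assert (median errors below 5%/3%, coverage 90–99%) are sampled stably.

## Known limitations

Fitted Hill slopes from sparse 8-point ladders are weakly identified and are
always reported alongside EC50s rather than trusted downstream; Mg²⁺ block
is treated per holding potential (no voltage-dependent block model); the
composite index is a scalar product of ratios, not a synaptic conductance
simulation; and EC50 point estimates from right-skewed per-cell
distributions carry a small (~2–4%) upward bias under arithmetic-mean
aggregation, which is retained deliberately because it mirrors how per-cell
estimates are conventionally tabulated.
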