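# Methods

## The measurement problem

A short maximal effort (~2 min) is monitored breath-by-breath with a
portable gas analyser through a seated baseline, the effort itself and
a seated recovery, with capillary lactate sampled at minutes 1, 3, 5
and 7 of recovery.  The quantities of interest are (i) the parameters
of the VO₂ on-transient, (ii) the accumulated above-baseline O₂ cost
of the effort and the excess post-exercise O₂ consumption (EPOC), and
(iii) a partition of the total energy expenditure into oxidative,
glycolytic and phosphagen pathways.

## Data model

`BreathSeries` stores one row per breath (time, VO₂, VCO₂, VE,
respiratory frequency, tidal volume, heart rate, artifact flag) with
phase marks and body mass.  VO₂ is kept in absolute mL·min⁻¹
internally; the kinetics models are expressed per kilogram, so mass
normalization happens at fitting/presentation time while the energy
integrals use absolute volumes.  Phase intervals are half-open
[start, end), which keeps the three phases an exact partition of the
record set.  Artifact flags are annotations (manual review or
simulator injection), not automatic detections.

## Breath editing

The chain runs in a fixed order: artifact exclusion → ±3 SD retention
→ 3-breath centered moving average (shrinking at phase edges, applied
within phases so the onset is not smeared into baseline) → 10-s
temporal average anchored at each phase start (each non-empty bin
emits the member mean at the bin midpoint).

The retention rule needs care on this protocol.  Exercise VO₂ spans
roughly an order of magnitude within the phase, so a literal
phase-wide mean ± 3 SD band on raw VO₂ deterministically deletes the
first seconds of the transient — precisely the data the delay estimate
needs — while being far too wide to catch ordinary spikes elsewhere.
The default mode is therefore trend-aware: each breath's deviation is
measured from a 5-breath running median (exact on monotone segments,
so a rising transient is never flagged), and compared against 3× a
breath-scatter scale estimated once, as the SD of
linear-interpolation residuals pooled over the session (~500 breaths,
so the scale estimate is tight and a single pass suffices).  The
literal band is available as `mode="band"` for stationary data and is
what the brute-force mean/SD oracle in the tests checks.  A removed
breath is removed whole, across all channels.

Smoothing interacts with fitting: the 10-s temporal average is
appropriate for display and for the oxygen integrals, but with a time
constant near 14 s it leaves only ~12 points per effort and biases the
onset, so kinetics fits in the analysis scripts use the cleaned,
moving-averaged, *unbinned* breath series.  The editing chain (without
the temporal average) changes fitted primary parameters by under 5% on
low-noise data — it denoises rather than distorts — and this is
enforced by a test.

## Kinetics model and fitting

On-transient: VO₂(t) = A₀ + H(t−TDp)·Ap·(1 − e^−(t−TDp)/τp), with an
optional second (slow) component gated at TDsc ≥ TDp; the
off-transient subtracts the same components from the end-exercise
level A₀.  H is the Heaviside step (H(0)=1); each component vanishes
at its own delay, so the model is continuous there.

Fitting is trust-region-reflective least squares on mass-normalized
VO₂ against phase-relative time, with bounds τ ∈ [0.1, 120] s,
TD ∈ [0, 30] s, amplitudes ≥ 0, and heuristic initialization (A₀ from
the earliest points, amplitude from the final 30 s, TD at 10% of
amplitude, τ at 63% minus TD).  Up to five jittered restarts draw
from a fixed-seed generator, so a fit is deterministic for identical
input.  For the bi-exponential model the second delay is parameterized
as TDp + δ with δ ≥ 0, which enforces the ordering constraint by
construction.

**Cardiodynamic exclusion.** The first seconds of the VO₂ response
reflect pulmonary blood flow rather than muscle O₂ extraction and are
conventionally excluded.  `fit_transient` defaults to a 20 s window,
but for efforts with TD ≈ 4 s and τ ≈ 14 s the primary rise is
essentially complete within 20 s, so excluding it removes the
information that identifies TD and τ.  The analysis scripts and the
acceptance computation therefore pass `exclude_s=0`; the option
remains for protocols with slower kinetics, and the interaction with
TD estimates is the reason the default is not silently zero.

**Bootstrap.** Uncertainty comes from residual resampling: B synthetic
datasets are built as fitted curve + residuals resampled with
replacement, each refit warm-started at the point estimate, and
percentile 2.5/97.5 bounds reported.  Residual resampling (rather than
case resampling) preserves the single transient's time grid.
Resampled residuals are inflated by √(n/(n−p)) because least-squares
residuals underestimate the error scale by the degrees of freedom the
model absorbed; without this the 95% intervals are measurably narrow
(coverage ≈ 0.89 rather than ≈ 0.92 in simulation).  Fixed seed ⇒
bit-identical output.

## Oxygen integrals

Net VO₂ is instantaneous VO₂ minus the baseline-phase mean rate,
clipped at zero so breath noise below baseline cannot contribute
negative energy.  Integration is trapezoidal over the sampled breaths
with the first/last values held constant out to the phase edges, so a
constant net rate integrates to rate × full phase duration.
Accumulated VO₂ is reported both as the net volume (L) and as that
volume over the effort duration (L·min⁻¹), covering both readings of
"accumulated VO₂" in use.  EPOC uses the same integral over the first
5 min of recovery (configurable; blood sampling extends to minute 7,
statistics conventionally quote minute 5).

## Energy partition

* Oxidative: net O₂ volume × 20.9 kJ·L⁻¹.
* Glycolytic: net lactate (peak post-exercise sample − baseline,
  floored at 0) × 3 mL O₂·kg⁻¹·mM⁻¹ × body mass, then × 20.9 kJ·L⁻¹.
  The peak is taken over the 1/3/5/7-min samples since the peak minute
  varies between subjects.
* Phosphagen: split PCr = 18.5 mmol·kg⁻¹ × (1 − e^−t/23.4 s) × mass.
  The literature supplies both an energy equivalent (0.468 kJ·mmol⁻¹)
  and a P/O ratio (6.25) without composing them, and the two imply
  very different absolute energies (≈ 756 kJ vs ≈ 121 kJ for a 117 s
  effort at 87.9 kg).  Both conventions are implemented; the default
  report uses the O₂-equivalent route and every `EnergyBreakdown`
  carries a `convention_tag`.  Neither convention applied to total
  body mass reproduces a ~15% phosphagen share, which suggests an
  effective contracting-muscle mass basis that cannot be recovered
  from published constants alone; a `muscle_fraction` multiplier
  (default 1.0) is exposed for sensitivity analyses.  This is the
  package's largest known systematic uncertainty and the reason the
  default cohort totals exceed published totals.

Metabolic power is total energy over effort duration (kJ/s = kW);
caloric expenditure converts an O₂ volume at 5.05 kcal·L⁻¹ ×
4.184 kJ·kcal⁻¹, reported separately for the effort and the recovery
window.  All constants live in `EnergyConstants`, every field
overridable and echoed into the output for provenance.

## Cohort statistics

Paired two-sided t-tests (degenerate zero-variance differences raise
rather than returning a meaningless statistic); Cohen's d from summary
statistics with three variants.  The pooled-SD d uses the small-sample
correction J = 1 − 3/(4·df − 1) with df = n − 1, the paired-design
degrees of freedom — this is the variant consistent with the published
lactate effect size (9.8 from 1.5 ± 0.3 → 20.7 ± 2.6 at n = 14); the
glucose and RPE rows do not match any single variant exactly and the
variant is therefore always tagged in output.  One-way
repeated-measures ANOVA (pingouin) with pairwise paired t-tests
Bonferroni-adjusted (p × m, capped at 1); no sphericity correction is
applied and the metadata says so.  The interpretation bands for |d|
(trivial < 0.2, medium 0.2–0.5, large ≥ 0.5) follow the convention
used for this cohort, nonstandard as they are.

## Synthetic-data generator

The generator defines the study conditions for every test: subject
parameters are truncated-normal draws at the published cohort means
and SDs (see `CohortSpec` defaults), deterministic per
(master_seed, index).  Baseline VO₂ defaults to 0.6 L·min⁻¹, from
which the mass-normalized A₀ is derived.  Baseline lasts 180 s (a
standard steady baseline for kinetics work; the protocol length is not
published), recovery 420 s to cover the minute-7 blood sample.

Breath timing: gamma-distributed intervals, shape 8 (CV ≈ 35%), mean
2.4 s at baseline and 1.2 s during exercise/recovery — plausible for
25–50 breaths·min⁻¹; no breath-timing data are published.

Breath-to-breath VO₂ scatter is additive with SD 2 mL·kg⁻¹·min⁻¹ and
**uniform** on ±√3·SD rather than Gaussian.  Real breath scatter is
effectively bounded; a bounded noise model makes the artifact concept
well-defined (a deviation of ≥ 5 SD cannot arise from a clean breath)
and gives the editing chain an exact ground truth: the breaths the
chain should remove are exactly the injected, flagged spikes.  With
unbounded Gaussian noise ~0.3% of clean breaths would fall outside any
±3 SD rule and "correct cleaning" would be ill-posed.  Gaussian noise
remains available (`NoiseSpec(dist="gaussian")`).  Artifacts are
injected per breath with probability 0.02 as upward spikes of 5–10
noise-SDs, flagged, mimicking cough/dropout transients.

Recovery kinetics are not published for this cohort; the off-transient
defaults (amplitude fraction 0.75 ± 0.05 of the primary, τ 45 ± 8 s,
TD 5 ± 2 s, starting from the end-exercise model value so VO₂ is
continuous across the boundary) keep recovery VO₂ elevated above
baseline through minute 5, matching the reported persistent EPOC.
Ancillary channels (HR, VE, VCO₂ via an RER profile, fr from the
actual breath intervals, VT = VE/fr) are smooth invented phase
profiles at plausible ranges — no numeric traces are published — and
carry no analysis weight.

What passing tests show, and what they do not: the synthetic sessions
reproduce the delayed-exponential structure, breath-interval
stochasticity, bounded scatter, injected artifacts and the lactate
time-course shape, so they exercise estimation, integration,
partitioning and statistics end-to-end with known truth.  They do not
emulate slow-component emergence, breath-volume-coupled (heteroscedastic
or autocorrelated) noise, movement artifacts with realistic temporal
clustering, or lactate kinetics beyond a rise-and-mild-decline —
results on real recordings depend on those features and on the manual
artifact review being conscientious.

## Problem sizes and numerics

Optimizer tolerances are 1e-12 (ftol/xtol/gtol), tight enough that
noiseless transients are recovered to ≤ 1e-4 relative error.
Bootstrap defaults to B = 1000 in the analysis scripts; simulation
suites use B = 200 with 100–200 replicate subjects, which keeps the
full test suite and the acceptance script to a few minutes while
leaving Monte-Carlo error well inside the asserted bands.  Degenerate
inputs (zero-variance scopes, empty phases, fewer points than
parameters, zero totals) raise informative errors or, where the
convention is harmless (SD = 0 retention scope), pass data through
unchanged.
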