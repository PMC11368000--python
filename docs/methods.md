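# Methods

`cardiopop` implements a population-based in vitro cardiotoxicity
assessment: a multi-donor iPSC-derived-cardiomyocyte calcium-flux screen is
analyzed from raw per-well traces through hierarchical Bayesian
concentration-response modeling to hazard calls, inter-individual
variability factors, multi-endpoint ranking, and probabilistic margins of
exposure. Because no machine-readable per-well screening data are public,
the package ships a first-class synthetic study generator with the same
statistical structure the analysis assumes; every stage is validated
against that generative model.

## Phenotypes

Five phenotypes are scored per well from a paired baseline/post-treatment
recording (8 frames/s for 100 s, 800 frames per phase) plus a nuclei count:

| phenotype | channel | direction | POD benchmark |
|---|---|---|---|
| positive chronotrope | beat-rate ratio (treated/baseline, vehicle-normalized) | increase | EC05 |
| negative chronotrope | beat-rate ratio | decrease | EC05 |
| QT-prolongation proxy | decay-to-rise ratio | increase | EC05 |
| asystole | beat-rate ratio | decrease | EC95 |
| cytotoxicity | nuclei count | decrease | EC10 |

The decay-to-rise ratio is the per-beat time from peak back to baseline
divided by the time from baseline to peak; asystole is zero treated peaks
without concurrent cell loss.

### Beat detection and timing

Peaks are local maxima with prominence at least 20% of the trace range,
separated by at least 0.25 s (a 240 beats/min ceiling); both parameters are
configurable. The published processing used an unreleased custom script, so
these defaults are declared, not inferred. The baseline level for beat
timing sits 10% of the beat's prominence above the local inter-beat minimum
on each side; rise time runs from the upward crossing (linearly
interpolated between frames) to the peak and decay time from the peak to
the downward crossing; beats truncated by the recording window are dropped
from the average. When scoring a well, both phases share one amplitude
reference (the larger of the two phases' ranges): a quiescent
post-treatment trace containing only measurement noise is then judged
against the well's true beating amplitude and correctly yields zero peaks.
All thresholds are relative, so every feature is invariant to positive
rescaling of the fluorescence values.

At 8 Hz, beat timings carry an irreducible quantization error; on
noise-free synthetic beats the measured rise and decay are within
2/rate_hz ≈ 0.25 s of truth, and the beat count (hence beat rate) is
exact. The cytotoxicity flag that feeds the asystole call marks wells whose
nuclei count falls below 0.9 of the plate vehicle mean, mirroring the EC10
benchmark direction.

## Plate QC

Each well's channels are divided by the mean of the 15 vehicle wells
(0.5% DMSO) on its own plate; a plate without vehicle wells is a hard
error. Normalization is idempotent. Plates are gated on directional
positive-control behaviour — isoproterenol must raise the beat-rate ratio
above 1, propranolol lower it below 1, sotalol raise the decay-to-rise
ratio above 1 — and spontaneously beating vehicle wells; only directions
are checked because control effect sizes are donor-specific. Replicate
agreement is summarized by Pearson correlation on raw values.

Control-well variability is decomposed into donor, plate-within-donor,
vehicle-vs-media and residual components. Donor and plate enter a nested
random-effects model fitted by REML (statsmodels MixedLM); the
vehicle-vs-media contrast is a fixed effect whose contribution is measured
as explained variance; a method-of-moments estimator with negative
components truncated at zero is the fallback when REML fails. CVs are
computed on raw units.

## Population concentration-response model

For one chemical × phenotype, the vehicle-normalized response of donor *d*
at concentration *c* is

    y ~ Normal( r_d(c), σ_resid ),
    r_d(c) = 1 ± Emax_d · c^n / (EC50_d^n + c^n),

baseline anchored at 1, sign fixed by the phenotype's adverse direction.
Donor-level random effects are lognormal on EC50 and Emax; the Hill
coefficient is shared across donors because four test concentrations
cannot identify donor-specific slopes. All parameters are fitted on the
natural-log scale; Emax is truncated at 1 so decreasing responses stay
non-negative.

Priors (declared defaults, overridable): log EC50 ~ N(log √(c_min·c_max),
2); log Emax ~ N(log 0.2, 1) truncated at 0; log n ~ N(0, 0.5);
half-normal(1) on both population SDs; half-normal(0.2) on the residual SD.

### Sampling

The posterior is explored with emcee's affine-invariant ensemble sampler,
vectorized over walkers, run as independent ensembles playing the role of
chains (4 by default). The model uses the **centered** parameterization
(donor log-parameters as free coordinates; Z-scores derived afterwards):
with informative per-donor data the centered geometry mixes far better for
an ensemble sampler than the non-centered funnel. Walkers are initialized
overdispersed but coherently — each walker's donor-level spread matches its
own population-SD coordinate, and the ensemble spans SDs from 0.2 to 1.5 —
because an ensemble whose members all start with tightly clustered donor
parameters cannot generate proposals that spread them.

The first half of every chain is discarded as warmup. Convergence requires
rank-normalized split-R̂ ≤ 1.2 for every parameter (arviz); on failure the
iteration count doubles up to a ceiling. Full mode runs 8,000–32,000
iterations per chain; desk mode (the default, used throughout the tests)
runs 2,000 with an 8,000 ceiling. A converged fit is subsampled to 1,000
retained draws, 250 per chain, seeded. Draws are reported even when
convergence fails, flagged `converged = False`.

### PODs

The POD for benchmark change *b* has the closed form
EC50·(b/(Emax−b))^(1/n), censored at +∞ when Emax ≤ b (verified against a
bracketing bisection root-finder to 1e-6 relative error). Per retained
draw: the median-individual POD uses the population-median parameters; the
sensitive-individual POD is the 5th percentile of PODs over 1,000 virtual
individuals sampled from the random-effect distribution (seeded); donor
PODs use donor-level parameters. Summaries are posterior medians with 90%
CIs computed as order statistics (interpolating between infinite censored
draws would produce NaN). A summary is censored when more than half the
draws are.

## Activity calls and TDVF05

A combination is **active** when (i) R̂ ≤ 1.2, (ii) the model-fit CV is
below 20%, (iii) the population-median POD is below 3× the top tested
concentration (300 µM), and (iv) the posterior 5th percentile of Emax
exceeds a 10% change. It qualifies for **population-variability** analysis
when additionally (5) the 90% CI of the median POD spans < 100-fold,
(6) the 90% CI of the sensitive POD spans < 100-fold, and (7) at least half
the donors have non-missing data at ≥ 3 concentrations. The published
"coefficient of variability for model fit" is ambiguous; it is implemented
as the posterior-median residual SD expressed as % of the control level
(1.0), with the POD-posterior CV available behind `fit_cv_basis="pod"`.

TDVF05 — the ratio of the median individual's POD to the sensitive
(5th-percentile) individual's POD — is computed draw-wise and summarized by
the posterior median of the ratio (not the ratio of summaries), preserving
the draw-wise ordering; draws with a censored sensitive POD are excluded
with their fraction recorded. Values are banded against the conventional
default toxicodynamic factor 10^(1/2) ≈ 3.16 and the total default of 10.
With a lognormal random effect only on EC50 and unit Hill slope,
TDVF05 = exp(1.645·σ) in closed form; recovery at σ = 0.7 (≈ 3.16) is part
of the validation suite, and zero population variance gives exactly 1.

## ToxPi ranking

Per phenotype slice, scores are linear in −log10(POD) between the slice's
observed extremes; censored/inactive entries and constant slices score 0;
the overall score is the (equal-)weighted slice mean, ranked descending
with lexicographic tie-breaks. The slice input is the minimum
donor-specific POD per chemical (most sensitive donor), configurable to the
population median. The cited ToxPi convention fixes inputs and weights but
not the transform; the −log10 min–max scaling is the standard choice.

## IVIVE and margins of exposure

Oral exposure (median + 95th-percentile of the predicted population-median
exposure, mg/kg BW/day) is fitted to a lognormal matching both quantiles
exactly (z95 = 1.6449) and sampled by Monte Carlo. Doses convert to
steady-state plasma concentration via a per-unit-dose factor from a
well-stirred three-compartment steady-state clearance model,
CL = 24·(fup·GFR + Q_l·fup·Clint/(Q_l + fup·Clint)) L/day/kg with defaults
GFR = 1.53 mL/min/kg and liver blood flow 1.24 L/h/kg; the conservative
alternative assumes no hepatic clearance (Clint = 0). fup = 0 is rejected
(infinite Css) with the chemical excluded. Biomonitoring blood ranges, when
given, are used directly as internal concentrations without TK conversion.

MOE(population median) = q05(median-individual POD draws) / q95(internal
concentration); MOE(random individual) uses draws built by sampling a
posterior draw plus fresh Z-scores per parameter. The summary MOE is the
minimum across active phenotypes and exposure routes, banded at exactly 1
and 100. The internal-concentration distribution reflects exposure
uncertainty only; a hook exists for compounding TK uncertainty. Degenerate
inputs (point-mass POD and exposure) reduce the full Monte-Carlo pipeline
to the deterministic ratio exactly.

## Structure-activity analysis

Bioactivity enters as log10(POD µM) for each phenotype × donor plus the
across-donor minimum per phenotype (5 × (n_donors + 1) variables; 85 at
16 donors). Censored or inactive entries are imputed at 300 µM — 3× the
top tested concentration, consistent with activity criterion (iii) —
configurable to exclusion. Descriptors pass a variation filter keeping
only columns where at least two chemicals differ from the modal value
(the filter is idempotent).

Spearman correlations (average-rank ties, two-sided t-approximation
p-values, matching scipy) are screened at BH-FDR q < 0.1 across all
descriptor × variable pairs. Predictions use ridge regression with a
common penalty: outer leave-one-out (or seeded k-fold) cross-validation,
inner leave-one-out on each training fold to pick the penalty from a grid
(10^−2 to 10^5, 30 points — wide enough that a pure-noise phenotype can be
shrunk to a near-constant predictor), columns standardized per training
fold. The implementation is a closed-form SVD path (hat-matrix
leave-one-out identities) verified in tests against scikit-learn's Ridge at
fixed penalty; the SVD per fold depends only on the descriptors, so the
permutation test re-runs the full nested procedure cheaply. Empirical
significance uses label permutations (one shared chemical permutation per
round): p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1), Holm-adjusted and
BH-FDR-corrected across variables. Desk mode uses 999 permutations; full
mode 10,000. Under the null the empirical p-values are uniform (checked by
KS test in the validation suite).

## Synthetic study generator

The generator emulates the reference screen design: 16 donors (one
384-well plate each by default; multi-plate layouts when the library
exceeds capacity), 56 chemicals across the 8 structural subclasses of the
registry, four concentrations (0.1/1/10/100 µM), 15 vehicle + 5 media
wells, three positive controls in concentration-response, six intra-plate
replicate chemicals, and donors assigned to 6 batches. A 16×24 plate has a
308-well interior; the 76 edge wells are non-experimental.

Generative structure mirrors the fitted model: population Hill parameters
per active chemical × phenotype; donor-level lognormal effects on EC50
(log-SD 0.7 by default — centred on the conventional 10^(1/2) variability
factor) and Emax (log-SD 0.2); a single multiplicative lognormal plate
factor per measurement channel (SD 0.05); multiplicative well noise
(CV 5%); donor-specific baselines (30 beats/min, decay-to-rise 3, 2,000
nuclei, 10% lognormal spread). Traces are built beat-by-beat as
fast-exponential-rise / slower-exponential-decay transients whose time
constants place the 10%-amplitude crossings at the target rise/decay
durations; the published work does not specify waveform morphology, and any
shape reproducing peak timing and rise/decay durations is equivalent for
the features scored here. Exposure, TK and descriptor values not supplied
per chemical are sampled from documented ranges (oral medians 10^−8 to
10^−4 mg/kg/day; MW 200–600; fup 0.01–0.5 log-uniform; Clint 0–5 L/h/kg).
Descriptor matrices optionally carry planted structure-activity signal
(a few substructure counts and the chain-length/MW block co-vary with true
potency).

All randomness derives from one root seed through named child streams
(`SeedSequence((seed, stream_index))`), so identical configurations yield
byte-identical bundles and any component can be regenerated independently.

### What the generator does not emulate

Pixel-level microscopy, arrhythmic waveform morphologies (early
afterdepolarization-like shapes), plate-position (edge-gradient) effects,
compound stability artifacts, and non-lognormal donor populations. Passing
tests therefore demonstrate the statistical machinery is correct under the
assumed generative structure, not that the assumptions hold for any
particular real screen.

## Problem sizes and validation scale

Routine tests and the acceptance script run desk-scale problems chosen as
the package's own validation scale: 3–16 donors, 4–6 chemicals through the
full pipeline, desk-mode MCMC (4 × 2,000 iterations), 99–999 permutations,
and 200 reduced fits (8 donors, 2 × 600 iterations) for simulation-based
calibration, where the 90% CI for the population EC50 covers the
prior-drawn truth at 90% ± a few points. Production analyses should use
`mode="full"` (8,000–32,000 iterations, 10,000 permutations).

## Known limitations

* The ensemble sampler can fail R̂ on hard posteriors (strong variance,
  few donors); such fits are flagged and fail activity criterion (i) rather
  than being silently accepted — a small fraction of desk-mode fits on
  high-variance chemicals do this by design.
* Population SDs shrink toward the half-normal prior with few donors;
  TDVF05 estimates at 16 donors are mildly conservative.
* The decay-to-rise ratio at 8 Hz carries sampling-phase quantization noise
  of order 10% per well; it averages out across beats and wells but makes
  small Emax values (< ~0.15) hard to resolve on the QT channel.
* Exposure uncertainty only (no TK uncertainty) enters the MOE Monte
  Carlo, matching the declared reading of the published procedure.
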