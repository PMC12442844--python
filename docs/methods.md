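# Methods

## The measurement model

All concentrations are mass fractions of ethanol in fruit pulp, expressed
as percent weight/weight (% w/w). Three instruments measure a transformed,
diluted proxy of that quantity; each is calibrated against standard series
made by serially diluting 70 % ethanol with water, and the calibration
line is applied directly to sample responses (classical calibration with
the regression run as concentration-on-response, so the fitted slope and
intercept invert a raw reading in one step).

**MOS headspace sensor.** The sensing chip's conductivity rises with
ethanol vapor roughly as a power law, so the sensor is calibrated by
regressing the *natural log* of the known standard concentrations on the
output voltage; predictions are exponentially back-transformed and
multiplied by the slurry dilution factor. The back-transform makes
negative predictions impossible. Temperature affects the response but was
controlled physically in the field protocol; it is recorded on readings
and not modelled.

**Portable GC.** The chromatograph emits a voltage trace; ethanol elutes
as a peak whose onset is expected 50–54 s after injection. The integrator
estimates the baseline as the median signal over [0, onset window − 5 s]
(the median resists injection spikes), takes the peak start at the first
in-window sample exceeding baseline + 1.2 mV (falling back to the window
start when the peak is too small to cross), ends the peak at the first
post-maximum sample at or below baseline + 1.2 mV (trace end if never
reached — the threshold exists to stop slowly-tailing returns), and
integrates (signal − baseline) trapezoidally on the native sampling grid,
clamping the area at zero and reporting mV·min. Peak areas then pass
through an identity-transform calibration. GC samples are typically run
undiluted; a dilution factor ≥ 1 is honored when supplied.

The peak *start* rule deserves a flag: the field protocol defines only the
onset expectation window and the 1.2 mV end rule, so the start is defined
symmetrically with the same threshold. This is an implementation choice, a
known deviation-risk point when comparing against traces integrated
interactively.

**Dichromate (Cr₂) colorimetry.** Absorbance at 580 nm of the reacted
slurry supernatant is linear in supernatant ethanol. The whole-fruit
concentration is max(0, slope·A + intercept) × dilution factor × (1 − dry
mass fraction), where the dry-mass fraction is the centrifuged pellet's
dry mass over total centrifuged mass, scaled up by the dilution factor
(and required to stay below 1). Negative predictions are rounded up to
zero after dilution scaling — equivalent to clamping before scaling for
any dilution ≥ 1, stated for determinism.

**Calibration diagnostics.** Each fit reports the adjusted R² of the
regression on its fitted (possibly log) scale and the MAE of
back-transformed predictions against the known standard concentrations,
in % w/w. Fits require ≥ 3 standards; constant responses are a degenerate
design and an error, as is an adjusted R² with non-positive residual
degrees of freedom (no silent NaN). Pre/post bracketing series (run
immediately before and after a sample batch to absorb drift) are *pooled*
into one fit; averaging two separate fits is the rejected alternative —
pooling splits linear drift evenly without assuming which series is right.

## Exposure and dosage

Species summaries use the arithmetic mean and sample SD (n − 1) over each
species' fruits, keeping only species with ≥ 3 ripe samples. Congeners may
be pooled (samples concatenated, feeding percentages summed) before
summarizing. The site-level exposure statistic weights species means by
annual feeding-time percentages renormalized over the sampled species:
w_i = f_i / Σ f_j, C̄ = Σ w_i c̄_i. Contribution fractions are
w_i c̄_i / C̄; coverage is Σ f_j on the raw percentage scale.

The **weighted SD** is defined as the feeding-weighted SD of the species
means, √(Σ w_i (c̄_i − C̄)²). The population behind the published "± SD"
is not stated anywhere authoritative; this definition is the package's
choice, and it is deliberately the only uncertainty source propagated
downstream (pooled per-sample SD is the plausible alternative; swapping it
in means passing a different `weighted_sd_pct` to the dosage stage, which
is agnostic).

Dosage is a linear chain: fruit g/day = bulk intake × fruit fraction of
diet; ethanol g/day = fruit g × C̄/100; dose = g / body mass; drinks =
dose / (10 g / 70 kg) = dose / 0.14. Because every step is linear in
concentration, the SD scales through identically. Body masses and intakes
are literature constants, treated as exact. All intermediates carry full
float precision; rounding (grams and SDs to 1 dp, dose to 2 dp, drinks to
1 dp) happens only in `display_row`. This matters: a weighted
concentration of 0.3181 % prints 13.6 g/day where its pre-rounded 0.32 %
would print 13.7 g.

The ground-vs-canopy contrast treats the *species* as the unit (one mean
per species) and uses Welch's unequal-variance t test; two identical
constant groups return the exact null (t = 0, p = 1) rather than 0/0.

## Validation statistics

* Repeatability MAE: per replicate set, mean |x − set mean|; overall, the
  mean of per-set values.
* Error budget: per standard level, the maximum |known − predicted|
  calibration errors of the compared methods are summed; the per-level
  sums are averaged, and the repeat-sampling error is added. Additivity
  (total = mean + repeat) holds by construction.
* Agreement screen: with both methods assumed unbiased, each deviates from
  the pair mean by |a − b|/2; pairs are counted under a threshold
  (typically the budget total).
* IQR outliers: outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] with
  linear-interpolation quartiles (the 1.5 coefficient and the quartile
  convention are configurable in principle; alternatives shift fences by
  fractions of one IQR on small n).
* Paired test: the Wilcoxon signed-rank test (the paired counterpart of
  the Mann-Whitney U, conventional statistic V = sum of positive-
  difference ranks). Zero differences are dropped, tied |differences| take
  midranks — so two opposite unit differences give V = 1.5, not 1 or 2.
  The two-sided p is exact for ≤ 25 informative pairs, computed by dynamic
  programming over doubled ranks (identical, verified, to full 2ⁿ
  enumeration); beyond that, a normal approximation with tie correction
  Σ(t³ − t)/48 and continuity correction.

## The synthetic generator

The generator's defaults are the study conditions the pipeline is tested
under; they emulate the field measurement processes, not any particular
dataset.

* Species ethanol laws are **zero-truncated normals** (means and SDs at
  the field scale: species means drawn uniform on [0.05, 0.55] % w/w,
  SDs on [0.15, 0.30] %, feeding percentages on [0.5, 18] %). Truncation
  is by resampling, keeping the density proper; near-zero fruits occur
  naturally, as in the field.
* MOS forward model: v = 2.5 + 0.5·ln(c) volts plus N(0, 0.025 V) noise.
  These values reproduce a repeat-assay MAE of ≈ 0.004 % w/w at
  concentrations near 0.10 %, the field method's repeatability scale. A
  detection floor of 10⁻⁴ % keeps the log defined at zero concentration;
  round-trip exactness is claimed above the floor.
* GC forward model: Gaussian peak (FWHM 10 s) on a 2 mV baseline, area
  = 700 mV·s per % w/w of headspace concentration, sampled at 10 Hz over
  120 s, trace noise N(0, 0.5 mV). The onset sits at 52 s; a *noisy*
  model jitters it uniformly over [50, 54] s per injection, while a
  noiseless model keeps it fixed so repeated simulations are
  bit-identical.
* Cr₂ forward model: A = 1.25·c + 0.05 absorbance units plus N(0, 0.018)
  noise — a whole-fruit repeat MAE of ≈ 0.02 % at typical dilution 2 and
  dry mass ≈ 0.15.
* All randomness descends from one integer seed through named
  SeedSequence substreams; identical seeds give bit-identical output.

What the generator does **not** emulate: instrument drift within a series
(pre/post series are drawn from the same model), temperature and humidity
sensitivity, non-ethanol volatiles cross-reacting with the MOS chip or
co-eluting on the GC, and between-fruit heterogeneity in dilution
behavior. Passing tests therefore demonstrate the correctness of the
inference chain under its own stated model, not robustness to these field
effects.

## Numerical conventions

* **Noiseless GC round trips use a zero return threshold.** The 1.2 mV
  end rule is a noise-floor convention for field traces; applied to
  noiseless simulations it truncates an amplitude-*dependent* tail
  fraction, breaking the exact proportionality of area to concentration
  at the ~10⁻³ relative level across a standard series. With the
  threshold at zero the integration window is fixed, area is exactly
  linear in amplitude, and simulate → calibrate → convert recovers ground
  truth to machine precision (the recovery checks assert 10⁻⁶). With the
  field threshold applied consistently to standards and samples, recovery
  at mid-series concentrations is still within ~0.3 % relative.
* Trapezoidal integration on a 0.1 s grid agrees with a 10× finer grid to
  well under 1 % for all tested peak shapes (Gaussian peaks are smooth,
  so the composite trapezoid converges fast).
* Clamping to zero is applied to final areas and concentrations, never to
  intermediate signals.
* Species names are grouped after whitespace normalization; duplicate
  sample ids within one file are an integrity error.

## Problem sizes

The recovery experiment uses 15 species × 30 fruits × 200 replicates with
the default Cr₂ noise, comparing the mean recovered feeding-weighted
concentration against the truth implied by the truncated-normal species
means at 2 Monte-Carlo SE; the whole experiment runs in seconds. Oracle
cross-checks use 100 random instances per statistic, with exact 2ⁿ
enumeration for the signed-rank test at n ≤ 10.

## Known limitations

* The % v/v display conversion (≈ 1.3× higher than % w/w) is a reporting
  helper only and never enters computation.
* Headspace partitioning at high dilution is assumed exactly linear (the
  dilution factor multiplies straight through).
* The agreement screen's published pair counts depend on per-sample field
  tables that are not distributed; the screen itself is fully tested on
  synthetic pairs with budget-calibrated noise.
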