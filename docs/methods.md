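# Methods

## Scope and data model

`mpnflux` quantifies how a picocyanobacterium growing on methylphosphonate
(MPn) as its sole phosphorus source balances its carbon and phosphorus
books. Because no replicate-level raw data are deposited for this study
system, the package pairs every estimator with a seeded synthetic generator
whose defaults are the published summary values; the analysis modules never
know whether their input came from the generator or from a real instrument
export.

Five input streams are modelled: cell-density time series (CSV), ¹⁴C
incubation records (CSV), macromolecular-fractionation dpm tables (CSV),
colorimetric formate-assay plates (CSV), and tabular protein alignments
(12-column TSV) with genome metadata (CSV).

## Growth kinetics

Batch growth is logistic, N(t) = K·N₀·e^{μt}/(K + N₀(e^{μt} − 1)), with
μ the maximum specific growth rate (d⁻¹), K the carrying capacity
(cells ml⁻¹) and N₀ the inoculum. Two estimators:

- **Linear-interval rate.** OLS slope of ln N vs t over a contiguous
  window. The interval is chosen deterministically: scan all windows of at
  least 4 points (or the whole series when shorter) whose maximum density
  stays below half the highest observed density, take the best r², break
  ties toward longer windows then earlier starts, and drop the density cap
  only if no window satisfies it. The cap excludes stationary phase, where
  the ln-slope flattens; on noiseless logistic data with N₀ ≪ K the
  estimate agrees with the true μ within a fraction of a percent.
- **Logistic fit.** Bounded least squares on ln-density (multiplicative
  error structure), initialised at K₀ = 1.05 × max density, N₀ = first
  density, μ₀ = the window slope. Failures are reported via a
  `converged=False` flag, never as silent numbers. The fit is invariant to
  density-unit rescaling (K and N₀ scale, μ does not).

The window estimator is unbiased but noisy on short noisy series (±~0.05 on
triplicate means at 5% CV); the logistic fit, which uses the whole curve,
recovers the configured μ to within ~0.005 under the same conditions and is
what the acceptance pipeline reports.

## Radiotracer calculus

Scintillation counts (dpm, already background- and quench-corrected) are
converted to moles through the effective specific activity of the substrate
pool after isotope dilution:

    SA_eff = A / ([tracer] + [carrier]),   [tracer] = A / SA_stock

with A the added activity (µCi ml⁻¹) and SA in Ci mol⁻¹, so rates count
moles of *total* (labelled + unlabelled) substrate. 1 Ci = 2.22 × 10¹² dpm
(definitional). Per-cell rates divide by cells × volume × duration and are
reported in zmol C cell⁻¹ h⁻¹ (10⁻²¹ mol); daily rates in
amol C cell⁻¹ d⁻¹ (10⁻¹⁸ mol) compose light and dark hourly rates over a
12 h:12 h photoperiod, or may be measured directly over 24 h. CO₂-trap
samples enter the same arithmetic with the trapped dpm as numerator.

Note: composing the default hourly rates (250 light / 89 dark) over 12/12 h
yields 4.07 amol d⁻¹, whereas the budget's default daily assimilation input
is the independently measured 4.3 amol d⁻¹; both paths are exposed and the
budget treats the 24-h value as an input.

## Budget closure

With v_assim the daily MPn-carbon assimilation flux and Q_P the phosphorus
quota, the 1:1 C:P stoichiometry of MPn makes v_assim a direct proxy for
the P supply, giving the quota-limited growth rate μ_P = v_assim/Q_P
(Droop-style quota argument). The deficit μ_obs − μ_P is the growth not
explained by assimilated MPn. The per-cell formate excess (MPn-grown minus
reference-grown inventory) closes it: dividing v_assim by the excess asks
how many quota-equivalents of one-carbon units transit the formate pool per
day.

The excretion *flux* is reconstructed from the excess inventory as
v_excr = excess × μ_P (inventory accrued once per quota-limited doubling).
An alternative construction v_excr = v_assim × excess/Q_P is kept behind
the `excretion_model="assim_scaled"` flag; the two are algebraically
identical whenever μ_P = v_assim/Q_P exactly and differ only when a rounded
μ_P is supplied, so the flag mainly documents the convention. Fate
fractions are each flux over v_assim + v_excr + v_co2 and always sum to 1.

Reporting conventions: rates half-up to 2 decimals, percentages half-up to
integers (Python's built-in banker's rounding would turn 0.215 into 0.21).
Both the raw and the rounded-input variants of the deficit and the
"deficit explained" fraction are carried, since summary arithmetic on
rounded inputs is common in the literature this serves. The CO₂
contribution to the deficit is constructed as (v_co2/Q_P)/deficit — the
growth rate the CO₂-lost carbon could have supported — and the construction
is printed next to the number in the reconciliation report rather than
chosen silently.

## Fractionation, TLC, calibration

Fraction percentages are relative to the dpm of *intact* cell pellets, so
their sum (the recovery) is a measured quantity, not forced to 100% —
carrier additions and counting artefacts can push it above 1 and extraction
losses below. The brucite split is simply ppt/(ppt + supernatant).

TLC spots are assigned to the nearest nucleotide/nucleoside standard in
Euclidean (Rf₁, Rf₂) space, with exact ties resolved to the
lexicographically smaller compound name and flagged, and spots farther than
a cutoff (default 0.1 Rf units ≈ 1 cm spots on a 10 cm sheet) left
unassigned. A brute-force nearest-neighbour scan is the property-test
oracle. Purine localisation is the purine share of assigned dpm.

Calibrations (formate assay, molybdenum-blue phosphorus) are OLS lines of
signal on amount; inversion floors negative amounts at zero and returns a
clipped mask. The formate-assay forward model uses a 50 µl well, so a
48 amol cell⁻¹ inventory at a 6 × 10⁸ cells ml⁻¹ yield is 1.44 nmol per
well, inside the 0–10 nmol standard range.

## Survey statistics

Presence screening takes the best hit per (genome, reference protein) —
max bitscore, ties to max identity — and calls the pathway present when
both PhnY and PhnZ identities are strictly greater than the threshold
(default 97%). The query (reference) strains are flagged and excluded from
detection counts, but included in the numerators of regional presence
proportions, whose denominators likewise count every surveyed genome.

The enrichment test is a 2×2 chi-square with Yates continuity correction
(deviations shrunk by 0.5, never past zero), df = 1; the one-sided p is
half the chi-square tail when the observed direction matches the
alternative. The default for the North-Atlantic-vs-North-Pacific contrast
is one-sided with correction on: on counts 14/219 vs 1/187 this yields
χ² = 8.15 and p = 0.002151. The North Pacific numerator of 1 is itself a
reconstruction from the printed proportion (0.5% of 187), corroborated by
the χ² reproduction. ANOVA and Tukey HSD are computed from sums of squares
and the studentized-range distribution (Tukey–Kramer standard error for
unequal n); scipy's `f_oneway`, `chi2_contingency` and statsmodels'
`pairwise_tukeyhsd` serve as independent oracles in the tests only.

The embedded 18-genome survey table is printed metadata; per-genome
alignment identities are published only as bounds (">97%") apart from the
reference self-hits (100/100) and the one low-light match (99.6/100), so
the fixture's remaining identities are synthetic stand-ins above the
threshold, which is the only property the screen consumes.

## Synthetic generator

Ground-truth defaults are the study conditions: growth rates 0.42 (Pi),
0.39 (HMPn), 0.35 (MPn), 0.18 (phosphite) d⁻¹; K = 6 × 10⁸ cells ml⁻¹
(3 × 10⁸ for phosphite, roughly half), N₀ = 10⁶; hourly MPn-C rates
250 (light) / 89 (dark) zmol cell⁻¹ h⁻¹ and 0.09 amol cell⁻¹ d⁻¹ to CO₂;
Q_P = 20 amol cell⁻¹; formate 48 (MPn/HMPn) vs 27 (Pi/phosphite)
amol cell⁻¹; fractionation split 42/1.5/41/19/0.5% renormalised to a
simplex (the measured percentages sum to 104% because they are expressed
against separately counted intact pellets); calibration slope
0.05 absorbance nmol⁻¹, intercept 0.01.

Noise conventions, chosen because only means ± SD are published:
multiplicative lognormal on densities (mean-1 factor, CV default 5%,
reverse-engineered from the ±0.03 spread on μ = 0.42), Poisson on dpm
(counting statistics; quench correction assumed upstream), multinomial on
fraction dpm, Gaussian on absorbances (default SD 0, i.e. noise-free unless
asked). One global seed feeds fixed per-stream `SeedSequence` substreams,
so streams are decoupled and outputs byte-reproducible.

What the generator does *not* emulate: lag and death phases, diel
physiology beyond a constant light/dark rate split, intracellular formate
pool dynamics, uptake saturation kinetics, alignment score geometry beyond
the identity column, and any correlation between streams. Passing recovery
tests therefore demonstrate estimator correctness under the declared noise
models, not robustness to real-instrument artefacts.

## Problem sizes and numerics

Tests and the acceptance pipeline run at desk scale: triplicate curves of
22 daily points, 500-replicate Poisson ensembles, 1000-replicate lognormal
means, 2000 simulated 2×2 tables — a few seconds end to end on one CPU.
Logistic fits use `scipy.optimize.least_squares` with tolerances 10⁻¹²;
zero-noise recovery tests assert at 10⁻⁹–10⁻¹² relative, Monte-Carlo means
at 1–2%, and seeded triplicate growth-rate recovery within the published
±0.03. Degenerate inputs (constant series, zero deficits, empty pools,
zero slopes) raise or flag explicitly rather than propagate NaNs.

## Known limitations

- The published "1.7% of the deficit" for the CO₂ contribution is not
  reproducible from the printed rounded inputs under any construction we
  found ((v_co2/Q_P)/deficit gives 2.09%); likewise the printed
  formate-supported rate of 0.21 d⁻¹ (4.3/21 = 0.2048 rounds to 0.20).
  Both presumably reflect unrounded primary data; the package reports its
  own computed values and states the construction used.
- The excreted/assimilated split computed here (50.7/48.3%) reproduces the
  published "roughly half each" but with the two labels' magnitudes
  interchanged relative to the printed ~49/~51; the exact published
  arithmetic is not stated, so no attempt is made to match the labels.
- The presence screen applies only the identity rule; coverage and e-value
  cutoffs are not part of the published criterion and are not imposed.
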