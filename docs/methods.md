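# Methods

This note documents the models, defaults and numerical choices behind
`cevalid`, and what the simulation-based tests do and do not demonstrate
about real data.

## Signal model

A simulated run is

```
signal(t) = b0 + b1·t + h·exp(−(t − t_m)²/(2σ_p²)) + ε(t),   ε ~ N(0, σ_b²)
```

on a uniform grid of `sampling_rate` points per minute over `run_length`
minutes. The analyte peak is a single Gaussian: the assay it emulates shows
one symmetric analyte peak and no interfering peaks, and the half-height
plate-number formula assumes Gaussian shape. The response law is imposed on
the **corrected** area: a run at concentration `C` draws a target corrected
area `S·C + b + N(0, noise_sd)` and an apex time
`t_m = migration_time + N(0, jitter_sd)`, and the Gaussian is scaled so its
raw area is `target × t_m`. Corrected area is therefore exactly the
configured line plus noise, independent of migration-time jitter — the same
velocity-normalisation property the corrected area has on a real CE
instrument.

Degraded samples scale the analyte peak by `(1 − degraded_fraction)` and
synthesise no degradation-product peaks; degradation chemistry and kinetics
are out of scope.

### Defaults and where they come from

| parameter | default | rationale |
|---|---|---|
| calibration_levels | 70…120 µg/mL, step 10 | the assay's linear range, six levels |
| replicates | 3 | triplicate calibration |
| response_slope / intercept | 2281.7 / −24495 | the assay's calibration line (corrected-area units per µg/mL) |
| noise_sd | 1657 area units | √(pure-error mean square 2 744 346.59) of the reference calibration ANOVA |
| migration_time | 3.2 min | the analyte's migration time |
| migration_jitter_sd | 0.02 min | the reference SST migration-time SD |
| peak_sigma | 0.0306 min | inverts N = 5.54(t/w½)² at the reference plate-number scale (~10 900) |
| sampling_rate | 600 min⁻¹ (10 Hz) | typical CE detector rate; ≈ 18 samples per σ |
| baseline level / drift / noise | 2 mAU, 0.1 mAU/min, 0.05 mAU | "small baseline oscillation" regime; drift exercises the baseline estimator |

With `noise_sd = 1657` the expected R² of a six-level triplicate calibration
is ≈ 0.998. The reference study's printed R² (0.9994) and its printed ANOVA
are not mutually consistent — the ANOVA's pooled residual implies the larger
scatter — and the ANOVA, being the fully itemised record, is taken as the
study condition.

Speciation uses the sequential macroscopic-dissociation model: with `m`
ascending pKa values there are `m+1` states and the state that has lost `k`
protons has weight `10^(Σ_{i≤k}(pH − pKa_i))`, normalised per pH (computed
via log-sum-exp). Microspecies-resolved constants beyond the two published
macroscopic pKas (3.22, 9.03) are not recoverable, so a micro-state model is
deliberately not attempted.

## Peak metrology

- **Baseline**: two-pass robust linear fit. Pass 1 fits the lowest-quartile
  signal points (peak-free but biased low by construction); pass 2 refits on
  all points within 5·MAD of that line, which restores an unbiased baseline
  whose residual noise has median ≈ 0.
- **Detection**: local maxima of the net signal above `min_height`, with an
  equal prominence requirement so noise wiggles riding on a peak flank are
  not counted. A run with no qualifying maximum returns an empty list plus a
  warning — that is how blank runs present.
- **Boundaries**: from the apex, walk outward until the net signal reaches
  the baseline crossing (default), or a configurable fraction of peak height
  (`bound_frac=0.001` gives the 0.1 %-of-height rule). The crossing rule is
  the default because a fixed 0.1 % cut discards ≈ 2×10⁻⁴ of a Gaussian's
  area, which is visible in the noiseless round-trip (the fit then recovers
  the slope to only ~4 significant figures instead of ≥ 6).
- **Measurement**: trapezoidal integration of the net signal between the
  boundaries; half-height and 10 %-height widths by linear interpolation of
  the crossing points; `N = 5.54·(t/w½)²`; asymmetry = leading/trailing
  half-width at 10 % height (< 1 ⇒ fronting). A peak with fewer than five
  samples above half height is rejected with a sampling-rate hint rather
  than measured badly.

Overlapping-peak deconvolution and non-Gaussian (e.g. exponentially
modified) fitting are out of scope.

## Validation statistics

The lack-of-fit ANOVA partitions a balanced `k`-level, `r`-replicate
calibration (`N = k·r`):

- `SS_between = r·Σ(ȳ_i − ȳ)²` (df `k−1`), split into
- `SS_regression = S²·Sxx` over all N points (df 1) and
- `SS_deviation = SS_between − SS_regression` (df `k−2`);
- `SS_residue = Σ_i Σ_j (y_ij − ȳ_i)²` (df `N−k`), pure error;
- `SS_total = SS_between + SS_residue` (df `N−1`).

Each effect is tested against the pure-error mean square, with critical
values from the F distribution at α = 0.05 by default. Additivity of SS and
df is asserted at construction (1e−6 relative). Unbalanced data are refused
by the ANOVA (the plain fit and R² remain available) rather than silently
approximated. Note that the classical identity "regression F = slope-t²"
holds against the *pooled* residual (df `N−2`), not against pure error; the
test suite checks the pooled form.

σ for LOD/LOQ defaults to the calibration residual SD (the most common
reading of "standard deviation of the response"), with intercept-SD and
blank-SD selectable. All SDs use the sample (n−1) denominator. Intermediate
precision is the RSD of per-day mean contents. Statistics are carried at
full precision; the 2-decimal rendering is presentation only.

## Robustness

The screening design is the fixed 15×7 matrix with seven nominal entries,
four +1 and four −1 per factor, and run 8 entirely nominal (it is not an
orthogonal two-level Plackett–Burman matrix, so it is stored as a literal and
any user-supplied design must satisfy the same 4/4/7 balance). The nominal
reference mean for a factor uses **all seven** of its nominal-level runs,
not run 8 alone — an interpretive choice that uses all the data and is
consistent with the two-mean differences the reference study reports.

For each side `s ∈ {+1, −1}`: `D_i = |mean(runs at s) − mean(nominal runs)|`,
`S = √((2/7)·ΣD²)`, criterion `√2·S`. A factor-side passes when `D` is
strictly below the criterion (the all-zero degenerate case passes by
definition); the method is robust overall iff all 14 comparisons pass.

Because `S` is built from the same seven deviations it judges, the verdict
is scale-invariant: multiplying all D by `k` leaves every flag unchanged.
A consequence worth knowing: under a pure null (no true effects, i.i.d. run
noise), each D is roughly half-normal with the criterion sitting near 2
standard deviations, so each comparison has a ≈ 5 % false-alarm rate and at
least one of the 14 flags fires in roughly half of null studies. The screen
is a coarse ruggedness check, not a calibrated hypothesis test; the test
suite asserts only that the per-comparison null flag rate stays below 20 %.

## Pipeline and reproducibility

`run_full_validation` derives one sub-seed per stage from the master seed
via `numpy.random.SeedSequence`, so identical config+seed produces a
byte-identical JSON report (timestamp aside) while stages stay statistically
independent. Study sizes follow the emulated validation: 18 calibration
runs, 10 SST runs, triplicate content, 7 repeatability determinations, 3
days × 3 for intermediate precision, triplicate recovery at 80/100/120 % of
the working concentration, 15 robustness runs. A full default report is a
few seconds of compute. Every stage CSV carries the config hash and seed in
a comment header.

Where the raw observations behind a published summary were never printed,
the package reconstructs an exactly consistent synthetic stand-in instead:
`reference_calibration_dataset()` builds an 18-point dataset whose ANOVA
reproduces the reference sums of squares to floating precision (level means
on the implied line plus a quadratic contrast scaled to the lack-of-fit SS;
(1, 0, −1) within-level residuals scaled to the pure-error SS). It is
synthetic and labelled as such; only its sums of squares are meaningful.

## What passing tests do and do not show

The simulator draws i.i.d. Gaussian noise, a single ideal Gaussian peak and
a linear baseline. Passing tests therefore demonstrate the *statistics* are
computed correctly and the pipeline recovers known truth under those
assumptions. They do not demonstrate robustness to real-instrument
artefacts: baseline steps, peak tailing/fronting, co-migrating impurities,
drifting electroosmotic flow, or heteroscedastic response — none of which
the generator emulates. The reference study's own headline numbers that
depend on unpublished raw areas (content 99.94 %, recovery 100.59 %,
repeatability RSD 1.62 %, LOD 0.77, LOQ 2.32 µg/mL) are consequently not
reproduction targets; they are covered by exactness/identity properties
(noiseless content = 100.00 %, LOQ/LOD = 10/3, slope recovery within
Monte-Carlo error) instead.

Two further reference-data inconsistencies are handled explicitly: the
(−1)-side Youden criterion recomputed from its own printed |D| values is
0.8057 (printed: 0.80; the printed deviations were evidently rounded after
the criterion was computed), and the reference SST table's printed SDs do
not reproduce from its own printed replicates. The package reproduces the
formulas; those specific printed summaries are asserted only to one unit in
their last printed digit, or not at all.
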