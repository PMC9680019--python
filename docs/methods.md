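# Methods

`thermocal` implements a chemometric pipeline for in-situ solute
concentration monitoring by ATR-UV or mid-IR spectrometry across a wide
temperature range, as used for cooling-crystallization development:
temperature correction of spectra by **loading space standardization
(LSS)**, **PLS calibration** with random-subset cross-validation, and
**solubility-curve determination** from stepped-heating slurry
experiments.  Because no experimental spectra accompany the study system
(L-ascorbic acid in MeCN/H2O 80:20 w/w), a synthetic generator produces
data with the statistical structure the analysis assumes; all empirical
claims below are about what the code computes on that generator.

## The LSS model

At temperature *t*, the spectra of a family of samples are assumed to
factor as

    X(t) = S P(t)^T + E,

with composition scores `S` (n_samples x K) independent of temperature
and loadings `P(t)` (p x K) whose entries vary smoothly with *t*; the
nonlinear effect of temperature on absorbance is modelled entrywise by a
second-order polynomial in standardized temperature
`t~ = (t - mean)/sd` (standardisation over the design temperatures, for
conditioning; the coefficients are stored with the model).

Fitting (`lss.fit_lss`):

1. For each design temperature `t_m`, assemble the block `X_m` with one
   fixed row ordering: composition-major, replicate-minor, truncated to
   the dataset-wide minimum replicate count so all blocks are congruent.
2. SVD of the reference block `X_ref = U S V^T` (reference temperature =
   the transform target by default).  Reference scores `G = U_K S_K`.
   Factor signs are fixed by making the largest-magnitude element of each
   right-singular vector positive; factors are ordered by singular value.
3. Regression loadings per temperature: `P_m = X_m^T G (G^T G)^{-1}`.
   Anchoring every temperature to the *same* scores is what makes the
   loadings comparable across temperatures without factor alignment.
4. Ordinary least squares of each loading entry on `(1, t~, t~^2)`.

The number of factors K is chosen from the reference-block singular
values: the smallest K whose cumulative squared-singular-value fraction
reaches 0.995 (`select_n_components`).  On the default generator this
rule selects K = 2 — one solute component and one background/solvent
component — matching the two-component choice appropriate for a
solvent-referenced single-solute system.

Applying (`lss.apply_lss`): a spectrum measured at `t_m` is projected
onto `P(t_m)` for scores `s`, the out-of-plane residual
`e = x - s P(t_m)^T` is carried over unchanged, and the spectrum is
rebuilt at the target: `x* = s P(t*)^T + e`.  Consequences, all tested:
the transform is the exact identity when `t_m = t*`; it is idempotent at
the target; the residual norm is conserved; and on noise-free data that
are exactly rank-K with exactly quadratic loadings the corrected spectrum
equals the true target-temperature spectrum to numerical precision
(observed ~1e-15 relative).  Score projection refuses loading matrices
with condition number above 1e12.

Design choices made where the formulation was genuinely open: the
per-temperature loadings are obtained by score-anchored regression (not
per-temperature SVDs with factor alignment, which would need an extra
alignment step and is noted as a possible extension); replicates are
paired across temperatures by replicate index, which is harmless because
scores depend on composition only; the residual is retained rather than
discarded, preserving variation outside the K-factor space.

## PLS calibration and cross-validation

Univariate NIPALS with mean centering (`pls.fit_pls`); for a single
response each component is closed-form.  The regression vector is
`b = W (P^T W)^{-1} q`, and with as many components as the centred rank
PLS reproduces the minimum-norm least-squares solution — both identities
are enforced by tests against a pseudoinverse oracle and against
scikit-learn's `PLSRegression` as an independent implementation.

Cross-validation (`pls.random_subset_cv`) uses random subsets: per
iteration (default 20) the grouping units are randomly partitioned into
3 folds and each fold is held out once, with re-centering on every
training remainder; squared errors are pooled over folds and iterations
into one RMSECV per latent-variable count.  The grouping unit defaults
to the *sample* — a (concentration, temperature) experiment with all its
replicates — because letting replicates of a held-out sample remain in
training would understate RMSECV.  The reading of "3 splits" as a full
partition (each unit held out once per iteration) follows the
random-subsets CV convention; a single random 1/3 holdout per iteration
is the other possible reading.  Latent variables are selected by a
parsimony rule: the smallest count whose RMSECV is within 10% of the
curve minimum (the qualitative "minimal number with suitable accuracy"
made operational; the fraction is exposed in the API).  `max_lv`
defaults to min(15, columns, smallest-training-fold rows - 1); inside CV
a fold whose response is fitted exactly before `max_lv` components keeps
its last fit for the remaining counts, since further components cannot
change predictions.

## Preprocessing

Savitzky–Golay first derivative: local least-squares quadratic over an
odd window (7 points for IR, 15 for UV by convention here), derivative
reported per axis unit (divided by the grid spacing, so results are
invariant to resampling).  Edges are trimmed rather than extrapolated —
(window-1)/2 points per side — and the axis is cropped to match; the
derivative is taken on the full spectrum first and the working range
(1831–709 cm^-1 for IR, 218–285 nm for UV) is selected afterwards, so
the stated range is retained in full.  Mean centering is fitted on
calibration data and reused on new data (inside PLS).  A dataset-level
preprocessing tag (`absorbance`, `absorbance:sg15d1`,
`absorbance:lss50`, ...) travels with every dataset and model, and
chained models refuse mismatched tags.

## The synthetic generator

Spectra are sums of Gaussian bands plus a linear-in-axis baseline and
i.i.d. Gaussian noise per channel.  Solute band heights scale linearly
with concentration (Beer–Lambert); band centre, width, fractional height
and the baseline follow quadratic polynomials in temperature.  Two modes:

* **realistic** (default): band centres and widths move with
  temperature, so per-temperature loadings are only approximately
  polynomial in T and the correction is exercised under model error;
* **linearized**: centres and widths frozen, only quadratic
  height/baseline scaling active.  The data are then exactly rank-2
  (solute + background) with loadings exactly quadratic in T, the regime
  in which the correction is provably exact; this mode backs the
  exactness tests.

Default UV instrument (chosen once as the study conditions): axis
200–320 nm at 1 nm; solute band at 244 nm (sigma 12 nm, 0.048 AU per
g/100 g) with a mostly linear ~5 nm red-shift, slight broadening and
~10% height loss over −10..75 °C; a weaker background band at 272 nm
(0.10 AU, residual solvent absorption against the solvent-referenced
background) and a slow baseline drift, sized so the reference-temperature
slice genuinely carries two significant SVD factors; noise sd 1.5e-3 AU.
A mid-IR configuration (650–1900 cm^-1 at 4 cm^-1, temperature-sensitive
solute bands at 1765/1695/1200/1115 cm^-1, comparatively insensitive
solvent bands at 1620/1375/920 cm^-1) is provided with the same
machinery.  Replicates default to 5 per sample: the acquisition protocol
yielded 14 (IR) and 22 (UV) usable replicates and both counts are
supported, but 5 keeps the default problem size small (200 calibration
spectra) without changing any structural property.

Experiment builders reproduce the study designs exactly: the 40-sample
calibration table (4/8/12 g/100 g at ten temperatures −10..75 °C, 16 at
30..75 °C, 20 at 50..75 °C — the design is taken literally and not
censored by solubility, since metastable clear solutions are part of the
calibration space), the two validation points (5 g/100 g at 20 °C and
15 g/100 g at 65 °C), and a stepped-heating slurry (holds 0..70 °C in
10 °C steps, 5 °C/min ramps, 30 min holds).  Ground-truth solubility is
a van 't Hoff curve `S(T) = exp(A − B/T_K)` with defaults A = 8.1,
B = 1600 K and metastable factor 1.6, chosen so every design point
satisfies `c <= 1.6 * S(T)` (e.g. 12 g/100 g at −10 °C sits just inside
the metastable zone) — a two-parameter monotone stand-in for the
empirical curve, sufficient for recovery tests.  During each hold the
supernatant relaxes exponentially toward `S(T_hold)` with time constant
`kinetics_tau` (default 300 s, so a 30 min hold spans six time
constants and the endpoint is within 0.25% of equilibrium); dissolution
during the short ramps is neglected and one mid-ramp spectrum is emitted
so that hold-window extraction has something to exclude.

What the generator does **not** emulate: ATR penetration-depth optics,
heteroscedastic or spectrally correlated noise, nucleation events, or
drift between replicate experiments.  Passing tests therefore show that
the algorithms are correct under the stated model — rank structure,
smooth temperature effects, additive noise — not that the specific
numeric performance transfers to any real instrument.

## Workflows

`run_calibration_comparison` benchmarks four variants on one
calibration/validation pair: `global_raw`, `global_deriv`,
`global_lss` (correction fitted only on the three lower concentrations,
which cover all ten temperatures, then applied to the whole set with
50 °C as the target — the lowest temperature present for every
concentration) and `local_isothermal` (the 50 °C slice, a benchmark
with temperature effects absent).  Each variant is cross-validated with
one shared seed, its LV count selected, refitted, and both validation
samples summarised (RMSE, mean, min, max, RSD).  On the default
realistic scenario at seed 0 the comparison reproduces the qualitative
pattern that motivates the correction: the uncorrected global model
needs 4 LVs while corrected and local models need 1; RMSECV orders
local (0.0075) <= corrected (0.0084) <= uncorrected (0.0219) g/100 g;
and validation RSD improves roughly threefold with correction.  (These
numbers are recomputed by the test suite and `scripts/acceptance.py`;
no agreement with the study's instrument-specific values is claimed.)

Solubility determination: `extract_hold_endpoints` takes the explicit
hold windows from the generator or a profile file (no automatic plateau
detection — stabilized regions are declared, which is deterministic and
testable) and picks the latest spectrum of each hold, the point at which
the slurry is closest to equilibrium; the prediction chain (preprocess →
optional LSS → PLS) turns the endpoints into a solubility curve.
`bias_metrics` compares curves only on exactly matching temperature
grids (no interpolation between methods' grids), reporting per-hold
bias, mean bias and bias range; the reference curve is the generator's
ground truth evaluated at the hold temperatures, standing in for
gravimetric/transmittance reference measurements.  `fit_vant_hoff`
recovers (A, B) by linear least squares of ln S on 1/T_K, exactly on
exact points.  With the best uncorrected global chain (raw absorbance
for UV, first derivative for IR — each technique's better-performing
uncorrected variant) versus the corrected chain, the corrected
predictions have smaller mean bias and bias range on the default
scenario.

## Numerical conventions and limitations

* Axes are stored strictly increasing regardless of instrument
  convention; one internal direction removes a class of sign errors.
* Unknown concentration (slurry supernatant) is an explicit missing
  value, never 0.
* CSV serialisation uses shortest round-trip float strings, so
  write → read is bit-exact (property-tested).
* All randomness flows through `numpy.random.default_rng(seed)`;
  generators, CV and the full comparison are bit-reproducible under a
  fixed seed.
* Singular/ill-conditioned projections raise rather than warn
  (condition-number threshold 1e12); quadratic identifiability requires
  at least three distinct temperatures.
* Default problem sizes (5 replicates, 200 calibration spectra,
  20 x 3-fold CV, up to 15 LVs) were chosen so the entire suite runs in
  seconds; replicate counts up to the acquisition protocol's 14/22 are
  supported unchanged.
* Not implemented (out of scope): SNV/MSC preprocessing, piecewise
  direct standardization, multi-response PLS, nucleation simulation,
  vendor file formats.
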