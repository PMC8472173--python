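# Methods

This note records the models implemented in `caulirheo`, the defaults and
numerical choices behind them, and what the synthetic-data generator does
and does not emulate.

## Creep model

The loading (hold) segment of a creep/recovery test is modelled as

    J(t) = J0 + sum_i Ji (1 - exp(-t/RTi)) + JN t,       t in [0, T]

a Maxwell spring (J0) and dashpot (JN) in series with up to four
Kelvin-Voigt elements (Ji, RTi). Units: compliances in kPa^-1, relaxation
times in s. JN is stored in kPa^-1 s^-1 so the flow term JN*t is
dimensionally a compliance; reports that quote JN in kPa^-1 implicitly
multiply by 1 s.

**Fitting domain.** Only the loading segment is fitted: the model above
describes creep under constant stress, not recovery. The recovery segment
is used exclusively by the descriptor stage (Jeq, ERA).

**Unloading model.** For generated curves the recovery branch follows
standard Burgers recovery: the elastic compliance J0 recoils instantly at
unload, each Kelvin-Voigt branch relaxes as
Ji (1 - e^(-T/RTi)) e^(-tau/RTi), and the plastic offset JN*T persists.
This makes ERA well defined on synthetic data.

**Loss functions.** Ordinary least squares by default; a robust soft-L1
(Huber-like) loss is available with scale 1.345 x 1.4826 x MAD of the
residuals at the initial guess, for curves with occasional displacement
spikes.

**Initialization and bounds.** The objective is multimodal in the RTi, so
the start matters more than polish: J0 from the first loading sample, JN
from the slope of the last 25% of the hold, the remaining amplitude split
evenly over the retarded elements, RTi log-spaced over [1, T/2]. All
compliances are bounded nonnegative; RTi is bounded within (0, T] because a
retarded element slower than the observation window is not identifiable
from the window (see Limitations). Convergence tolerances are 1e-15 so
noiseless round trips recover generating parameters to better than 1e-6
relative error.

**Canonical ordering.** Fitted elements are sorted by increasing RTi, which
removes label switching and makes parameter vectors comparable across fits
and bootstrap draws.

**Order selection.** Candidate orders m = 1..max_m are fitted; fits whose
residual mean fails a zero-mean t-test (alpha 0.05) are excluded; among the
rest the fit with Durbin-Watson statistic closest to 2 wins. Because an
extra element with vanishing amplitude reproduces the smaller model's
residuals almost exactly, exact ties never occur in floating point; the
smallest order within 0.05 of the best |DW - 2| is returned, which is how
the "smaller m wins" parsimony rule is made operational.

**Lack of fit.** E% = 100 sqrt( sum((Jfit - Jobs)/Jfit)^2 / (N - p) ), the
root of the dof-corrected mean squared relative residual, with p the number
of fitted parameters. The relative residual is taken against the fitted
value, which is strictly positive for valid parameters. With 0.5%
multiplicative instrument noise this statistic sits near 0.5 and stays
below 2 across the standard suite.

**Confidence intervals.** Parametric bootstrap: synthetic curves are drawn
as fitted values plus Gaussian noise at the residual standard deviation,
refitted at the same order (warm-started at the point estimate), and
2.5/97.5 percentiles taken per parameter; 500 draws by default. More than
20% refit failures aborts with diagnostics. Pooled over the parameters of a
one-element model at study noise levels, empirical coverage of the 95%
intervals measures ~0.97 (the acceptance suite checks [0.90, 0.99] over
200 truth/refit cycles of a 121-point curve, 150 draws per cycle — sizes
chosen so the whole property suite stays desk-scale).

## Descriptors

- Ur: trapezoidal integral of J over [0, T]. The closed form
  J0 T + sum Ji (T - RTi(1 - e^(-T/RTi))) + JN T^2/2 is kept in the library
  as an independent cross-check (0.1% agreement at 1-s sampling).
- JR = J0 + sum Ji; fractions J0/Ur, sum Ji/Ur, JN/Ur are reported as
  literal ratios with their mixed units.
- Jmax is the maximum compliance over the loading segment; Jeq is the mean
  over the final 5% of the recovery segment — "end of recovery" needs a
  window, and averaging suppresses sampling noise. ERA = 100(Jmax-Jeq)/Jmax,
  EPR = (J0 + sum Ji)/JN (raises for JN = 0, where the ratio is infinite).
- E0 = 1/J0 (kPa) and EtaN = 1/JN (kPa s) are reciprocal-parameter moduli
  used as supplementary variables in the PCA. They are this package's
  definitions for the otherwise loosely specified "modulus-like"
  supplementary quantities.
- EPR carries seconds when JN is in kPa^-1 s^-1; it is treated as a
  unitless score with that convention fixed.

## Softening kinetics

ERA(t) = ERAinf + (ERA0 - ERAinf) exp(-k t^n), with ERA0 fixed to the mean
of the t = 0 observations and (k, n, ERAinf) fitted by bounded nonlinear
least squares (k in [1e-8, 50] min^-n, n in [0.05, 5], ERAinf in
[0, ERA0]). This is the unique fixed-order decay consistent with the two
limits ERA(0) = ERA0 and ERA(inf) = ERAinf. With fewer than four distinct
time points n is fixed (to 1 in the pipeline, the apparent first-order
regime); ERAinf landing on a bound is flagged. Replicates are pooled rather
than averaged, so the fit weights time points by their replicate counts.
t50 = [ln((ERA0-ERAinf)/(0.5 ERA0-ERAinf))/k]^(1/n) whenever
ERAinf < ERA0/2, otherwise ERA never falls to half its fresh level and t50
is undefined.

## Extractability stage

- Fold changes are cooked/fresh ratios on a common basis, reported at 2
  decimals. Dry-to-wet conversion multiplies by the dry-matter fraction
  (1 - W%/100). Wet-basis fold changes therefore equal dry-basis fold
  changes times the dry-matter-fraction ratio, a composition identity the
  tests enforce.
- MRA: 70/30 calibration/validation split, stratified by variety x method
  when those labels exist so both splits span the cooking design;
  deterministic under the split seed. Predictor selection is forward
  stepwise with entry p < 0.05 and removal p > 0.10 (the conventional
  reading of "stepwise"). Standard errors come from the OLS covariance
  (X'X)^-1 sigma^2. Accuracy is the mean absolute relative error (%) and
  the R^2 of predicted vs observed on the held-out rows only; validation
  rows never touch the coefficients.
- PCA: correlation-matrix PCA (z-scored active columns, ddof 1), so
  eigenvalues sum to the number of active variables. A variable's loading
  is its Pearson correlation with the component scores; supplementary
  variables — which take no part in defining the components — get the same
  score-correlation coordinates, the standard inactive-variable convention.
  Component signs are fixed by making the largest-magnitude coefficient
  positive. Components with numerically zero eigenvalue carry no direction;
  coordinates on them are reported as 0.

## Synthetic-data generator

The generator emulates the study design: two varieties (Depurple, Cheddar),
three cooking methods (boiling B, steaming S, sous-vide SV), heating times
0/10/25/40 min, 6 rheology and 3 chemistry replicates per condition. Noise
is multiplicative Gaussian throughout — instrument displacement error
scales with signal — with default CVs of 0.005 (creep curves), 0.02
(descriptor replicates, the level at which kinetic-order recovery is
assessed) and 0.05 (chemistry).

- **Creep curves**: exact Burgers loading, standard Burgers recovery,
  600 s + 600 s at 1-s sampling. Condition-level parameters scale a fresh
  parameter set (relaxation times 8/45/90 s) by the softening fraction
  1 - ERA(t)/ERA0 and solve JN in closed form so the curve's analytic ERA
  matches the decay trajectory: JN = A(100 - ERA)/(ERA T) with
  A = J0 + sum Ji (1 - e^(-T/RTi)).
- **Kinetics**: first-order (n = 1) ERA decay per variety x method, rates
  ordered B > S > SV and Cheddar faster than Depurple, plateaus 18-30%.
- **EPR companion**: V-shaped in heating time with the minimum at 10 min —
  cell separation dominates early, wall loosening later — then a linear
  rebound that is steeper in Cheddar. The exact shape is a generator
  choice; only its monotonicity pattern is used by tests.
- **Water**: bounded first-order approach W0 + dW(1 - e^(-t/12 min)), with
  fresh levels 92.3/92.8% and uptake 4.2/2.2/1.5 percentage points for
  B/S/SV.
- **Chemistry**: totals are linear in (ERA, EPR) with negative ERA and
  positive EPR coefficients; individual compounds are fixed fractions of
  the totals (beta-sitosterol > campesterol > stigmasterol; gamma > alpha >
  delta tocopherol), so totals equal the sum of their components exactly.
- **Heating profiles**: first-order approach to plateaus of 98/96/85 degC,
  sampled every 10 s, with rise rates solved so the 40->80 degC traverse is
  1.83/2.67/5.5 min for B/S/SV.
- **Compression curves**: power-law load c d^p (p >= 1 gives the observed
  upward concavity), prefactor solved from the target stiffness, specimen
  height set to twice the maximum displacement so the test ends at 0.5
  deformation.

What the generator does **not** emulate: heat-transfer physics inside the
tissue, chromatographic measurement error structure, replicate-level
correlation between rheology and chemistry (tables are joined on condition
means), biological between-head variability, or any nonlinearity in the
descriptor-to-concentration link. Passing tests therefore demonstrate that
the estimators recover the generating structure at realistic noise levels —
not that real tissue obeys these trajectories.

## Numerical choices and degenerate inputs

- Trapezoidal integration for Ur and strain energy release (0.1% accuracy
  at the default sampling).
- Linear interpolation at temperature-threshold crossings (10-s sampling
  would otherwise quantize crossing times to +-10 s); a profile starting at
  or above a threshold is taken to cross at its first sample.
- Compression-curve integration starts at the first sample at or above the
  5 N preload; the sub-preload region is instrument seating.
- Exact fits (all-zero residuals) report DW = 2 rather than the undefined
  0/0; the standalone `durbin_watson` raises on all-zero input.
- Replicate pooling, tie margins, and bound flags are described above.

## Known limitations

- On the loading segment alone, a retarded element with RTi comparable to
  the hold duration is nearly collinear with the flow term JN t: fits of
  noisy curves can trade amplitude between the slowest element and JN while
  changing the residuals imperceptibly. E% and the reversible/irreversible
  split at the curve level are robust to this; individual slow-element
  parameters and EPR computed from low-JN fits are not. Joint
  loading+recovery fitting would resolve the degeneracy but is outside the
  fitted model's domain here.
- The parametric bootstrap assumes homoscedastic Gaussian residuals; under
  the multiplicative noise model the residual variance grows with J, so
  per-parameter coverage is uneven (conservative for J0, slightly
  anticonservative for JN) even though pooled coverage is near nominal.
- The stepwise entry/removal thresholds are conventions; with only two
  candidate predictors the procedure reduces to at most two entry tests and
  one removal check.
- `fold_change` rounds to 2 decimals by contract; chains of fold changes
  should be computed from raw concentrations, not from rounded ratios.
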