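# Methods

## Model and transform

The reaction yield is observed as a fluorescence signal y > 0 (RFU) at
settings of k factors. On the natural-log scale the yield is modelled as the
full second-order polynomial in *coded* factors x ∈ ℝᵏ (factorial levels at
±1, centre at 0):

ln y = β₀ + Σᵢ βᵢxᵢ + Σᵢ<ⱼ βᵢⱼxᵢxⱼ + Σᵢ βᵢᵢxᵢ² + ε,  ε ~ N(0, σ²).

The log link encodes the assumption of *multiplicative* measurement error,
which is typical for fluorescence intensities: replicate scatter grows with
the mean, and taking logs stabilizes it. The natural log (not log₁₀) is
used throughout; the bundled study's centre-point responses average
ln ≈ 10.2, consistent with that choice. No term selection is performed: the
full quadratic (1 + k + k(k−1)/2 + k terms) is always fitted, by ordinary
least squares via statsmodels. Back-transformed predictions are exp(x'β̂),
the conditional median under the log-normal error model; no smearing/bias
correction is applied, matching standard response-surface practice.

## Design construction

`build_ccd` emits the 2^k factorial points in lexicographic sign order,
then axial pairs (−α before +α) by factor index, then the centre
replicates; run order carries no randomization scheme. The default axial
distance is the rotatable α = 2^(k/4) (1.682 for k = 3, displayed rounded
as 1.68). Coding is defined from the factorial ±1 levels, so axial actual
values lie beyond the factorial range; coding/decoding is an exact affine
pair and actual values are rounded (2 decimals) only at CSV serialization.

## ANOVA, lack of fit, PRESS

Residual variation is split into pure error — the within-group sum of
squares over replicate groups, i.e. runs with identical coded coordinates
after rounding to 6 decimals — and lack of fit. F ratios use the upper tail
of the F distribution. The overall regression p-value is displayed as
"<= 0.0001" below 10⁻⁴. PRESS uses the exact linear-least-squares
leave-one-out identity e₍ᵢ₎ = eᵢ/(1 − hᵢᵢ); predicted R² = 1 − PRESS/SS_total.
This identity is verified against brute-force leave-one-out refits in the
tests. Leverages of 1 (saturated designs) make PRESS undefined and raise.
Coefficient t tests raise when the residual variance is numerically zero
(below 1e−20 of the mean squared response), since standard errors are then
meaningless.

## Desirability optimization

A single maximize goal uses the Derringer ramp
d = clip(((y − L)/(T − L)), 0, 1)^w and composites combine as the
importance-weighted geometric mean D = (Π dᵢ^{rᵢ})^{1/Σrᵢ}. D is invariant
to rescaling all importances. The optimizer searches a dense coded grid
(default 101 points per axis) over the *factorial* box [−1, 1]^k — not the
axial sphere — then polishes with bounded Nelder–Mead from the best grid
point; for a monotone single-response maximize goal the polish maximizes
the predicted response itself so the argmax stays sharp on the d = 1
plateau. Grid ties break toward smaller coded values in factor order, and
the polish is accepted only if it does not lower the desirability, so the
result is deterministic and never worse than the grid optimum. Because a
monotone ramp cannot move the argmax, the optimum *location* is invariant
to the ramp limits, weights and importances; the absolute D value is
configuration-dependent and is therefore reported but not treated as a
reproducible quantity. `solution_set` returns the grid points with
D ≥ threshold and their per-factor actual-value ranges, a practical "design
space" summary; each returned point is re-verifiable by direct evaluation.

On the bundled study the fitted surface's continuous argmax over the
factorial box is (72 °C, 69.2 min, 110 µL). The study selected 68.8 min
from its near-optimal solution family (65.7–70.3 min at D ≥ 0.998); the
surface is so flat there that predictions at 68.8 and 69.2 min differ by
under 0.01%, so any point of that window is operationally equivalent.

## Validation statistics

All SDs use the n−1 denominator — this choice reproduces the bundled
accuracy table's SD cells and day RSDs exactly. Calibration is unweighted
OLS (scipy `linregress`); LOD and LOQ back-calculate mean-blank + 3·SD and
+ 10·SD through the fitted line and require a positive slope. Accuracy
passes when every level's mean recovery lies in [98, 102]% and %RSD ≤ 1;
precision when every day's repeatability %RSD_r ≤ 2 and the intermediate
%RSD_R ≤ 2. Limits are inclusive ("≤" semantics): a value exactly at a
limit passes. The intermediate-precision default is the arithmetic mean of
per-day RSDs — the convention that matches the bundled study's printed
value — with pooled and one-way-ANOVA (within + between variance
components, between clipped at zero) methods available; the method used is
recorded in the report. Robustness pools all replicate recoveries per
varied parameter into one %RSD. The bundled robustness table prints only
condition means (n = 3 each), not the 9 underlying replicates, so its
printed RSDs cannot be recomputed exactly; ingestion and the pooled
statistic are exercised instead. Stability reports the maximum percent
deviation from the first timepoint, the %RSD over the window and a
least-squares drift slope.

## Synthetic generators

`TrueSurface` defaults to the bundled study's fitted coefficients, so
synthetic experiments are anchored to realistic effect sizes. Noise is
multiplicative by default (Gaussian on the ln scale, SD 0.13 — calibrated
once to the spread of the four centre-point replicates of the bundled
design, which is the only replicate-level noise information available); an
additive option exists for sensitivity checks. Calibration, recovery and
time-series generators add Gaussian noise on their natural scales. Every
generator takes an explicit integer seed through `numpy.random.default_rng`
and is bit-reproducible; what the generators do *not* emulate includes
plate-position effects, inner-filter/quenching nonlinearity at high
concentration, reagent-batch drift and heteroscedastic calibration error —
so passing synthetic tests demonstrates correctness of the statistics, not
robustness to those real-world artifacts.

## Problem sizes in the test suite

Monte-Carlo checks use 2,000 replicates for coefficient-CI coverage
(tolerance ±5 percentage points around the nominal 95%), 500 replicates for
calibration slope/SE consistency, and 200 replicates (grid density 21) for
the end-to-end yield-efficiency property (recovered optimum achieving ≥95%
of the true optimal yield in ≥80% of replicates); these sizes give
Monte-Carlo standard errors comfortably below the asserted tolerances.

## Known limitations

- Single-response optimization is the validated path; the multi-response
  composite is implemented and unit-tested but has no bundled reference.
- The ln transform is fixed by construction, not selected (no Box–Cox
  machinery), and no robust or weighted regression is offered.
- Designs are rotatable CCDs only: no face-centred, Box–Behnken, blocking
  or run-order randomization support.
- `read_design_csv` reconstructs factor levels from the coded/actual
  columns by an affine fit of the two extreme levels; files with inconsistent
  coding will round-trip the coded values but may shift the recovered
  actual levels.
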