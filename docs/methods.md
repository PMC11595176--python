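# Methods

This note records the models implemented in `bindspec`, their assumptions,
the defaults that matter, and the numerical choices made where the design
was genuinely open.

## Equilibrium binding

### Single-class model

Assumptions: all `n` sites per protein molecule are identical and
independent; ligand and protein exchange freely (`LP ⇌ L + P`,
`K_d = [L][P]/[LP]`); absorbance at the analysis wavelength is the linear
superposition of a free and a bound species (Beer–Lambert, two absorbing
states).  Cooperative (Hill-type) binding is deliberately out of scope: a
Scatchard curve cannot distinguish anti-cooperativity from site
heterogeneity, so the package only offers the heterogeneous-site model.

The bound-species signal is the minus root of the mass-balance quadratic.
We evaluate it in product form, `xA_LP = l·ε_b·2P/(S + √(S² − 4P))` with
`S = C_T + nC_H + K_d` and `P = nC_H·C_T`, which is algebraically identical
to the textbook `½(S − √(S² − 4P))` but avoids catastrophic cancellation
when `4P ≪ S²` (small `K_d` or strongly unbalanced concentrations).  The
back-substitution property test (reproduce `K_d` to 1e-9 relative from the
root) only holds in this form.  Tiny negative discriminants from rounding
are clamped to zero and logged.

Fitting: `scipy.optimize.least_squares` (trust-region reflective) with
bounds `n ∈ (0, 10]`, `K_d ∈ [0, 100] µM`, `ε_b ∈ (0, 10] µM⁻¹cm⁻¹`;
deterministic initialisation `ε_b ← A_LP/(l·C_T)` at the last
excess-protein point, `n ← 1`, `K_d ← 1 µM`.  Standard errors come from the
SVD-based covariance of the Jacobian scaled by the residual variance;
`R² = 1 − SS_res/SS_tot`.  Bound fractions outside `[0, 1]` (noise) are
propagated unclamped — clamping would bias the fit — and reported via a
warning; downstream operations drop non-physical points with logged counts.

Identifiability: with the default design (ligand ≤ 6.04 µM, protein 2 µM,
site capacity `nC_H ≈ 5.4 µM`), saturation is only approached, so `K_d` is
weakly constrained (its standard error is routinely of the order of the
estimate — consistent with the large uncertainty quoted for this kind of
fit), while `n` and `ε_b` are recovered to a few percent at 0.005
absorbance noise.

### Two-class Scatchard analysis

Assumptions: two independent site classes, `K_d1 < K_d2`; bound ligand
measured through a difference absorbance with a single extinction constant.
`[LP] = ΔA/(l·ε)`, `[L] = C_T − [LP]`; `ν = [LP]/C_H`; `ratio = ν/[L]`.

The estimator fits ordinary least-squares lines to the low- and
high-occupancy subsets of the occupancy-sorted points.  The subset split is
not part of the published procedure, so the default (`split="auto"`) scans
every split leaving ≥ 3 points per side and maximises the summed squared
correlation coefficients (ties: minimal total SSE); an explicit split index
overrides.  `K_d1 = −1/slope_low`, `K_d2 = −1/slope_high`; site counts by
the limit approximation (`n₁ = intercept_low·K_d1`, `n₂ =` x-intercept of
the high line) or by solving the exact intercept system
(`n₁/K_d1 + n₂/K_d2`, `n₁ + n₂`).

**Known limitation (quantified).**  The limit estimates are intrinsically
biased at any finite design.  The true limiting slope of the two-class
Scatchard curve at `[L] → 0` is `−(n₁/K_d1² + n₂/K_d2²)/(n₁/K_d1 +
n₂/K_d2)`, which equals `−1/K_d1` only when the weak-class term is
negligible; for the default parameter set (0.79/0.15/2.2/1.8) the weak
class contributes ~19% to the denominator, making the apparent `K_d1`
≈ 0.18 µM even in the exact limit.  At the default fixed-ligand design
(5 µM ligand, 1–12 µM protein) the lowest free-ligand concentrations
reached are ≈ 0.09–0.14 µM ≈ `K_d1`, so finite-secant bias pushes the
noiseless estimate to `K_d1 ≈ 0.23–0.30 µM` and `n₁ ≈ 1.4–1.7` depending
on the split; under noise the low-occupancy end (where the free-ligand
concentration is a small difference of two comparable numbers) is the
noisiest part of the plot and the estimates scatter widely.  Consequently
a round trip "generate from two-class parameters → re-estimate by the
limit procedure" does **not** close on the generating strong-class
parameters; the package reports what the procedure yields and exposes the
less-biased `exact_intercepts` variant.  The forward model, transform and
equilibrium solver themselves are exact (property-tested to 1e-8/1e-9).

The forward equilibrium `L + [LP](L) = C_T` is solved by bracketed
bisection on `[0, C_T]` (the left side is strictly increasing, so the root
is unique); tests cross-check it against an independent Brent solver.

## Triplet-decay kinetics

Model: `ΔA(t) = ΔA₀ + Σ Aᵢ exp(−t/tᵢ)`, one or two components.  The
mono-vs-bi decision, made by inspection in practice, is encoded
reproducibly: fit both, keep the bi-exponential only if it improves SSE by
more than a configurable 10%.  Initialisation is deterministic: baseline
from the tail mean (last 5% of points), fast lifetime from the log-linear
slope over the first decade of the baseline-subtracted decay, slow lifetime
5× the fast one.  Lifetimes are reported ascending; a bi-exponential whose
lifetimes collapse within 1e-3 relative raises a degeneracy error (auto
mode falls back to one component).  Traces are expected to sample the
slower lifetime (≥ ~6 points per decade; warned otherwise).  Time is µs at
the data model; `io.ms_to_us` converts.

## Transition detection

### Segmented regression

Exhaustive search over contiguous partitions (2 or 3 blocks, ≥ 3 points
each — the smallest block for which a correlation coefficient is defined)
maximising Σ R² with SSE tie-break; per-segment OLS; breakpoints from
intersections of adjacent lines.  Segments are unconstrained lines (not
forced to meet), so the intersection abscissa is the transition estimate.
Near-parallel adjacent segments (slope difference ≤ 1e-3 relative) or an
intersection falling outside the data range make the breakpoint unstable:
it falls back to the midpoint of the partition boundary and the fit is
flagged `low_confidence` rather than erroring, so noisy single-line data
degrade gracefully.  Breakpoints are equivariant under x-shifts and
invariant under y-scaling (property-tested), hence also invariant to the
sign convention of the ellipticity axis.  Breakpoints found on a
concentration axis can be converted to ligand:protein molar ratios by
dividing by the protein concentration.

### Melt curves and T_m

DSF channels F330 and F350 and their ratio track tryptophan emission
through unfolding.  `find_tm` fits a centred moving-window polynomial
(default quadratic, window 21 points — i.e. a Savitzky–Golay derivative)
and locates local maxima of dF/dT inside a temperature window (default
50–90 °C) with minimum separation 5 °C and prominence ≥ 5% of the
in-window maximum; peak positions are refined by a three-point parabola,
giving sub-grid accuracy.  A quadratic window is used because the
derivative of a symmetric sigmoid is locally even around its maximum;
degree and window are configurable.  For a logistic transition the
derivative maximum sits exactly at the midpoint and a linear baseline only
offsets the derivative, so F350-channel peaks are unbiased; the
F350/F330 *ratio* channel is a quotient of sigmoids with drifting
baselines and its derivative peaks sit near, not exactly at, the midpoints
(≈ 0.5 °C shift for the default synthetic curve) — the F350 channel is
therefore the default.

## Synthetic data

Generators emulate measured quantities, not instruments: no shot noise
physics, lamp drift or inner-filter effects.  Noise defaults (the study
reports none): 0.005 absorbance additive for titrations, 1% multiplicative
for decay traces, 2% of signal range for CD/DSF channels.  `NoiseSpec`
carries the distribution, σ, seed and an `sigma_is_range_fraction` flag so
the range-relative convention is expressible within the additive kind;
identical specs give byte-identical output, and a master seed fans out to
child seeds through numpy `SeedSequence` (`spawn_seeds`).

Choices where the source data are silent: the free-ligand extinction at
the 423 nm analysis wavelength is set to 0.08 µM⁻¹cm⁻¹ (off-peak for the
free species, below the bound-state 0.20); the encapsulated-ligand
lifetime defaults to 2000 µs (a representative value of the reported
1.9–2.3 ms range); melt baselines are linear and decreasing with
temperature with logistic steps of −3000 (F330) / +4000 (F350) counts per
transition so the ratio rises through unfolding; the ellipticity series
use kinks at 1.5 and 6.0 µM for 0.5 µM protein (molar ratios 3 and 12) and
a 57 °C kink for the thermal series.

What passing round-trip tests show — and what they do not: noiseless
closure proves the fitters invert the generators' functional forms
exactly, and noisy recovery quantifies estimator spread under idealised
Gaussian noise; neither certifies behaviour on real spectra with
correlated baselines, aggregation, inner-filter effects or instrument
drift.

## Problem sizes

Default runs use 12-point titrations, 12-point protein grids, 201–401
point decay traces, 281-point melt curves, 23–25 point ellipticity series,
and 30–200 replicate Monte-Carlo checks — sizes chosen to match the
emulated experiments while keeping the full suite and the acceptance
script comfortably fast on a single CPU.
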