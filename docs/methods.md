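# Methods

## The design problem

A two-channel orthogonal wavelet filter bank is determined by its
analysis low-pass FIR filter a₀ of even length N; the high-pass and
synthesis filters follow by quadrature conjugation (a₁(n) = (−1)ⁿ
a₀(N−1−n), b₀ = reverse(a₀), b₁(n) = (−1)^{n+1} a₀(n)), giving perfect
reconstruction with delay N−1 and zero distortion. The design criterion
is the mean squared spectral localization

σ_f² = (1 / 2πE) ∫_{−π}^{π} f² |A₀(e^{jf})|² df,

minimized subject to double-shift orthonormality
Σₙ a₀(n)a₀(n−2m) = δ(m) and M vanishing moments
Σₘ (−1)ᵐ mᵏ a₀(m) = 0, k = 0..M−1.

In the product-filter variable p = autocorr(a₀) the problem is convex:
σ_f² = s·p with s(0) = π²/3, s(m) = −4/m² for odd m, 0 otherwise
(from (1/π)∫₀^π f² cos(mf) df = 2(−1)ᵐ/m²); orthonormality is the
half-band constraint p(0)=1, p(2m)=0; regularity is linear; and the
remaining condition is spectral nonnegativity P(e^{jf}) ≥ 0, a
semi-infinite constraint equivalent (KYP lemma) to the existence of a
PSD matrix Z with p(m) = Σₙ Z[n,n+m].

## Solver

The implementation solves the convex program in three stages, all
deterministic:

1. **Cutting-plane LP.** Free variables are p(m) at odd lags (N/2 of
   them). Nonnegativity is enforced on an adaptive frequency set: start
   from a uniform grid (2049 points), solve with HiGHS, locate negative
   minima of the spectrum on a dense grid (2¹⁵ points), refine each to
   machine precision, add them as cuts, repeat (at most 15 rounds or
   until the worst violation exceeds −1e−10). The LP value is kept as a
   lower-bound sanity check.

2. **Touch-point polish.** At the semi-infinite optimum the spectrum
   touches zero at finitely many interior frequencies (double zeros).
   Candidate touch points are the refined minima that remain small after
   dividing out the (2+2cos f)^M regularity factor — this filter
   separates genuine interior zeros from numerical noise in the high-order
   tail at π — capped by the degree bound (N−1−M)/2 and the free
   dimension N/2 − M. The square system {linear constraints, P(f_t)=0,
   P′(f_t)=0} is then solved by Newton/least squares.

3. **Tap-space refinement.** At degenerate optima (the touch zero
   merging into the 2M-fold zero at π) the convex-stage solution can be
   infeasible at the ~1e−11 level, which is fatal for exact spectral
   factorization. The final stage therefore optimizes directly over the
   reduced filter q in a₀ = (z+1)^M ⊛ q — regularity is exact by
   construction — minimizing s·autocorr(a₀) subject to double-shift
   orthonormality (SLSQP, then a Gauss–Newton projection onto the
   constraint manifold). Two starts are used: the factor of the
   convex-stage solution, and the always-feasible maximal-regularity
   (Daubechies) filter with its surplus zeros at z = −1 released. The
   better feasible result wins. This guarantees the design never does
   worse than the same-length Daubechies filter and reaches constraint
   residuals ~1e−15.

The delivered product filter is the autocorrelation of the refined taps
with the half-band structure snapped exactly; the PSD certificate is the
rank-one matrix a₀a₀ᵀ, which satisfies the trace parameterization
identically. `solver_status` reflects the refined solution's constraint
residuals (threshold 10 × `solver_tolerance`), not the LP bound gap,
which can be loose by ~1e−5 near the degenerate tail.

An empirical note: for (N,M) = (6,2) and (8,3) the MSSL optimum
coincides with the maximal-regularity Daubechies solution; for (12,3),
(16,4), (20,5), (24,6) it is strictly better (e.g. 0.8468 vs 0.8849 at
N=16).

## Spectral factorization

a₀ is recovered from p as the minimum-phase factor: the 2M zeros at
z = −1 and any optimizer-reported touch zeros are deflated by
least-squares deconvolution (stable for unit-circle divisors, unlike
synthetic division); the strictly positive remainder is rooted; roots
are deduplicated by reciprocal pairing with inward reflection; and a
Gauss–Newton refinement over q removes the rooting error. The residual
must be below 1e−7 or a `FactorizationError` is raised. Conventions:
Σa₀ = √2 (so P(e^{j0}) = 2) and a positive tap sum.

## Decomposition

Five-level dyadic analysis uses periodic (circular) extension — the only
critically-sampled convention with exact energy conservation for
orthogonal banks — implemented by FFT circular correlation with
even-phase downsampling; synthesis is the exact adjoint, so the round
trip is the identity with no delay to compensate. Epoch lengths must be
divisible by 2⁵ (5-minute epochs at 128 Hz are: 38 400 = 1200·32).
Band naming: SB1 = level-1 detail (32–64 Hz at 128 Hz sampling) down to
SB5 = level-5 detail (2–4 Hz), SB6 = level-5 approximation (0–2 Hz).

## Features

**LOGE** is log Σ|r(n)|² per band; natural log by default, base 10 by
configuration (the choice only rescales the downstream linear index).
For an orthonormal bank Σ_bands exp(LOGE) equals the epoch energy — the
additivity test exploits this.

**SFD** estimates the box-counting dimension of the band's graph. The
graph is normalized affinely to the unit square (this makes the
estimate exactly amplitude-scale-invariant); boxes of side 2^{−k} are
counted for dyadic scales k = 3..9 (restricted so a box column contains
at least two samples); the least-squares slope of log(count) against
log(2ᵏ) is the estimate, clamped to [1, 2] with a warning. Counting
uses the continuous (variation) form — each column contributes
max(span/side, 1) boxes — because integer counting at the trace lengths
used here (≈10³–10⁴ samples) biases rough traces toward dimension 1:
for midpoint-displacement traces with Hurst H = 0.5 at 4096 points,
integer counting gives ≈1.39 against the theoretical 2−H = 1.5, the
variation form ≈1.46. Smooth and constant curves still measure exactly
1. Katz and Higuchi estimators are provided as alternates since
published feature magnitudes do not disambiguate the estimator.

Midpoint displacement is itself a slightly smoothed approximation of
fractional Brownian motion, so the ±0.1 tolerance on 2−H in the tests
absorbs both estimator and generator bias.

## Ranking and the index

Feature ranking uses the two-sided pooled-variance Student's t between
the two classes with df = n₁+n₂−2, ranked by |t|. The pooled test is
the stated convention; with strongly unequal class sizes Welch's
variant is statistically safer and is available by flag. No
multiple-testing correction is applied — the output is a ranking, not an
inference. A null simulation (both classes standard normal, 200 + 200,
1000 replicates) checks the implementation's type-I rate at α = 0.05.

The Hypertension Diagnosis Index is the affine combination

HDI = 6 − (3·LOGE_SB2 + 4·LOGE_SB3 + SFD_SB6) − 15·(SFD_SB2 + SFD_SB3 + SFD_SB4),

implemented exactly as published. **Known inconsistency:** evaluating
this formula at the published per-class feature means yields ≈ −163.8,
far outside the published decision ranges (LRHT 1.501–2.355, HRHT
2.774–6.084); the printed equation is likely a typeset corruption of a
rescaled form. It is deliberately not repaired; `HDIFormula` lets a
user substitute coefficients and intercept without code changes.
Classification uses the published ranges (values in neither range are
`indeterminate`) or, when configured, a scalar two-way threshold whose
default 2.5645 is the midpoint of the gap between the ranges. The
published headline table is labeled for channel CH3 (lead V5), hence
the CLI's channel default.

## Synthetic records

`synthesize_record` emits three channels (CH1–CH3, relative gains
0.6/1.0/0.8) at 128 Hz: a strictly periodic train of Gaussian-derivative
QRS-like complexes (σ = 12 ms) with a T-wave bump, plus AR(1) noise
(coefficient 0.9) scaled to a configurable stationary standard
deviation, drawn independently per channel from a seeded generator.
Defaults: 60 bpm, noise σ = 0.1, duration 2 h 10 min 12 s (999 936
samples — the Holter length whose 5-minute segmentation yields 26
epochs per channel, hence 3172/442 epochs for 122/17 records).

What the generator does *not* emulate: hypertensive vs normotensive
morphology, heart-rate variability, artifacts, baseline wander, or
inter-subject variation. Passing tests on synthetic data therefore
validate the pipeline's arithmetic, determinism and invariances — not
any clinical discrimination claim. Reproducing the published per-class
feature statistics and index ranges requires the original Holter
recordings, which the WFDB reader can ingest but which are not bundled.

## Numerical choices and limitations

- Population (1/n) standard deviation in the Z-score; it changes values
  in the third decimal for short epochs, so it is fixed and stated.
- Trailing partial epochs are discarded (matches the 26-per-record
  arithmetic exactly).
- Epochs failing feature extraction are skipped with a logged summary
  rather than aborting a whole run.
- The WFDB reader supports single-segment records with one interleaved
  .dat file in formats 16 and 80 — enough for 8-bit Holter archives —
  and maps channels from the description field in header order.
- Problem sizes in the test suite (epoch lengths 256–38 400, 1000-rep
  null calibration, 4096-point fractal traces) were chosen as the
  smallest sizes at which the checked identities and tolerances are
  meaningful.
- Acceptance-scale runs use noiseless synthetic records for the
  epoch-count arithmetic; counts are independent of waveform content.
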