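# Methods

## Model of the visual front end

A photoreceptor's linear response to a moving panorama is

    V_i(t) = ∫ dt' T(t') ∫ dx M(x − x_i) c(x − v(t − t')),

with M a Gaussian acceptance profile (FWHM 5.7°), T a causal exponential
(time constant 10 ms), receptors at x_i = offset + (i−1)·5.1°, and c(x) a
360°, 1°-sampled contrast row treated as periodic in azimuth. Clips last
800 ms on a 5 ms grid; every model reads out only the final time point, so
the zero-state filter transient is buried inside the clip.

Discretization choices (validated in the tests against a dense 10×-finer
quadrature of the double integral, < 2 % relative RMS after the startup
transient):

* The spatial integral runs on the panorama's 1° grid with the Gaussian
  sampled at pixel centers and renormalized to unit sum; kernels are
  truncated at ±3σ (< 1 % mass loss). Sub-pixel translation uses periodic
  linear interpolation of the blurred panorama.
* The temporal integral is a causal discrete convolution with the
  exponential kernel discretized by first-order hold (the exact convolution
  of the continuous exponential with the linear interpolant of the sampled
  signal). A plainly sampled geometric kernel at dt = τ/2 would bias the
  filter's effective lag from 10 ms down to ≈ 7.7 ms; the first-order-hold
  weights keep the lag exactly τ. The kernel is normalized to unit sum, so
  filter gain is a pure bookkeeping convention (fitted weights absorb it).

The correlator's filters f(t) = t·e^(−t/τ) and g = df/dt (τ = 20 ms) are
sampled on the same grid; f is normalized to unit sum, g scaled by the same
factor and mean-adjusted so its discrete sum is exactly zero (g must
annihilate constants — a static scene produces no motion signal).

## The naturalistic motion ensemble

Each motion draws a panorama uniformly from the image set, an offset
uniform on [0°, 360°), and a velocity from N(0, (90 °/s)²), using three
independent child streams of one master seed. Left-right symmetry is
enforced exactly, not statistically: each clip's mirror partner is stored
as the receptor-reversed array {V3, V2, V1} with negated velocity, which is
identical to re-simulating the reflected panorama at the mirrored offset
but free of floating-point asymmetry. Mirror partners are adjacent rows
and are atomic units of every cross-validation split.

Desk-scale defaults are 1000 synthetic panoramas and 10⁴ mirror pairs
(2×10⁴ clips), which resolve the accuracy ordering of the hierarchy with
across-split SDs below 0.02; `paper_scale=True` raises the ensemble to
5×10⁵ pairs for publication-quality error bars.

## Synthetic panoramas

The generator emulates the three statistics of natural scenes that drive
every qualitative result: a heavy-tailed contrast marginal, light–dark
asymmetry, and spatial correlations decaying with distance. A Gaussian
random field with amplitude spectrum ∝ k^(−slope) (slope 1 by default, the
natural-scene value) is normalized to an exactly standard-normal pixel
marginal, then passed pointwise through the monotone map

    t(z) = s(z) + λ·(s(z)² − E[s²]),   s(z) = sign(z)|z|^b,

where λ ≥ 0 is the asymmetry (skew) parameter and the exponent b is solved
by Brent's method so that the kurtosis of t(Z), computed by Gauss–Hermite
quadrature, equals the configured target. The default study conditions are
target kurtosis 8 and λ = 0.35, giving a pooled kurtosis ≈ 8 and skewness
≈ +1.9 — comparable to the heavy-tailed, positively skewed statistics of
photoreceptor-filtered natural scenes. At λ = 0, b = 1 the generator
reduces to the Gaussian field (kurtosis 3).

What the generator does *not* emulate: occlusions, vertical structure,
luminance gradients, and the particular spectra of any published image
database. Passing tests therefore demonstrate the *mechanisms* — that
light–dark asymmetry makes ON/OFF-separated and odd-order correlators
useful, and how glider responses follow — not the numerical accuracy values
obtained on any specific natural-image database, which depend on that
database's exact statistics.

Natural images are supported through the preprocessing path: intensity →
contrast (I − I₀)/I₀ with I₀ the per-image mean (images with I₀ = 0 are
rejected), vertical Gaussian blur (FWHM 5.7°), central-row extraction,
reflective tiling to 360°, and block-averaging to 1° pixels. Tiling uses a
symmetric reflection *centered on the row*, so mirroring the input image
mirrors the output panorama exactly when the row and the panorama have the
same pixel-count parity (off by at most one input pixel otherwise).

## Estimator models

All models map the six filtered channels (f∗V1), (g∗V1), …, (g∗V3) at the
readout time to a scalar estimate and are linear in their fitted weights:

* **HRC** — one predictor, R = f₁g₂ − g₁f₂.
* **Converging 3-point correlator** — two conventions are implemented,
  f₁²g₂ − f₂²g₁ (same-site low-pass squared, the default) and
  f₁f₂g₂ − f₂f₁g₁ (two-site low-pass product), because the channel
  assignment of the two low-pass inputs admits both readings; neither is
  privileged, and both are mirror-antisymmetric and odd in contrast.
* **Weighted 4-quadrant** — Q_ab = [f₁]_a[g₂]_b − [g₁]_b[f₂]_a with
  half-wave rectifications [x]±; Σ_ab Q_ab = R is an exact identity, so
  equal weights reproduce the HRC. The quadrant basis can be reparameterized
  into four orthogonal correlation classes by ±1 sign patterns (scaled by
  1/4): the uniform pattern is the HRC ("even = 2"); patterns symmetric
  under the contrast-inversion swap (++↔−−, +−↔−+) capture even-order
  structure, antisymmetric patterns capture odd-order structure. Which of
  the two odd patterns is labeled "odd" versus "odd*" is a convention and
  is configurable.
* **Polynomial nonlinearities** — all monomials of total degree 1–4 over
  2, 4, or 6 channels (constant excluded, since a constant term cannot help
  estimate a zero-mean velocity): 14 predictors for the antisymmetrized
  bivariate model (x^i y^j of one pair minus the mirror pair), 69 for the
  4-channel model, 209 for the 6-channel two-detector model. Exponent
  tuples are ordered lexicographically; the ordering is frozen and
  serialized with model files. Fourth order is the minimum that captures
  2-point responses (order 2), parity-inverting 3-point responses (order
  3), and parity-asymmetric magnitudes (order 4).

Mirror antisymmetry of the 4- and 6-channel polynomial fits is obtained by
fitting on the mirror-symmetrized ensemble rather than by constraining the
features; the residual asymmetry of a fitted model is measurable (evaluate
on receptor-reversed banks) and reported by the tests, not assumed.

**Front-end nonlinearities** act between the photoreceptor signals and the
correlator's temporal filters. All three are rank transforms of the pooled
signal values (all receptors, time points, and motions ranked together;
ties share the mean rank): gaussianize maps ranks through the inverse
Gaussian CDF (output kurtosis 3), equalize scales ranks to [−1, 1] (uniform
output, kurtosis 1.8), binarize thresholds at configured percentiles into
alternating ±1 bands (median split: symmetric Bernoulli output, kurtosis 1,
the minimum attainable). The pooled transform deliberately mixes training
and test data — it is the estimator's published definition; a leakage-free
`fit`/`apply` mode (lookup frozen on a training pool, applied by
interpolation) is also provided.

## Fitting and evaluation

Weights minimize the training-fold MSE (ordinary least squares, no
intercept). Accuracy is the correlation r between estimate and velocity on
the held-out fold of a twofold split; 20 random splits give the accuracy
SD. After scaling an estimator by the optimal gain r·σ_v/σ_R (applied
about the sample means; the velocity mean is exactly zero on any
mirror-paired fold), MSE = σ_v²(1 − r²) holds as a finite-sample identity,
which the tests verify to 1e−6 relative. Rank-deficient designs fall back
to the minimum-norm solution with a warning rather than failing.

Training accuracy is exactly monotone along HRC ⊂ quadrant and HRC ⊂
14 ⊂ 69 ⊂ 209-predictor polynomials, since each earlier model is a weight
subspace of the later one. The rectified quadrant model is *not* a subspace
of the fourth-order polynomials (its polynomial expansion is infinite
order); the observed quadrant ≤ 69-predictor training ordering is an
empirical regularity of the study ensembles, asserted as such.

Lasso predictor selection z-scores the predictors (so one L1 penalty is
comparable across monomials of wildly different magnitudes), sweeps a
logarithmic penalty grid spanning empty to full supports, and refits each
selected support by plain OLS on the original columns — the penalty picks
predictors, never final weights. Planted-model recovery (5 true predictors
of 50, noise SD equal to signal SD, n = 10⁴) is part of the test suite.

## Glider benchmark

Gliders are ±1 movies (3 s, 40 Hz, 5° pixels, 72 pixels = 360° with
periodic wrap) in which a pixel product is pinned to a parity: rightward
2-point, s(x,t) = p·s(x−1,t−1); rightward 3-point converging,
s(x,t) = p·s(x−1,t−1)·s(x,t−1); diverging, the converging stimulus
reversed in both time and space; leftward, the spatial reflection. The
first frame is fair ±1, every later pixel deterministic, so the enforced
products hold exhaustively and `audit_glider` re-verifies them on any
stimulus — the implemented corner conventions are machine-checkable rather
than pictorial. The periodic 72-pixel width lets 60 estimators at 5.1°
spacing sit without edge effects; movies are held piecewise constant in
space and time (display-like rendering, no sub-frame interpolation).

Responses: per condition, 25 instantiations; each presented rightward and
leftward (matched seeds); each response is the model output averaged over
60 estimators and the last 2 s; leftward responses are negated and pooled
with rightward; the table reports mean ± SEM over instantiations,
normalized by the mean positive-2-point response (a model with zero
positive-2-point response returns raw values with a warning).

## Numerical and degenerate-input conventions

Moments use population normalization (no small-sample correction), and
kurtosis is μ₄/σ⁴ without the −3 shift. Zero-variance samples, empty
pools, all-zero intensity images, empty image lists, non-finite velocities,
undersampled kernels (dt ≥ τ), and spatial-covariance lags ≥ 180° (aliased
under periodicity) are rejected with errors; a zero-variance estimator
scales to the null estimate with a warning.

## Known limitations

* No photoreceptor adaptation, noise, or saturation; velocity is constant
  within a clip; horizontal motion only.
* Temporal filter shapes are fixed (f, g above); alternative kernel
  families are out of scope, as is any biophysical circuit model of the
  ON/OFF pathways.
* Glider predictions are open-loop model outputs; no turning dynamics or
  motor gain, so comparisons with behavior are about signs and relative
  magnitudes, not absolute turning amplitudes.
* The lasso support-size-versus-accuracy curve is qualitative: grid,
  standardization, and the choice of a single representative sparse model
  are implementation conventions.
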