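# Methods

## The estimation problem

A transmission-microscopy image of a striated cardiomyocyte shows a
quasi-periodic intensity pattern along the cell axis; the fundamental
spatial period of that pattern is the mean sarcomere length (SL).  Typical
recordings resolve one sarcomere (~1.8 um) with only 4–5 pixels
(~0.4 um/px), and the usable window — bounded by cell morphology, attached
carbon fibres and uneven background — contains a modest number of repeats.
The task is therefore subpixel period estimation from short, finite,
possibly trended signals, per video frame.

## Signal model and similarity measures

Each image line is modelled as the piecewise-linear interpolant `f(x)` of
its pixel samples `f_i`, `i = 0..N-1`, with pixel centres at integer
coordinates and support `0 <= x <= L`, `L = N-1`.  Three measures of
similarity between the line and its copy shifted by `s` are implemented:

- **finite** (the primary estimator):
  `F(s) = ∫₀^{L-s} [f(x+s) - f(x)]² dx`, the squared difference over the
  *overlap only*.  For a signal exactly periodic with period `P` it
  vanishes at `s = P` regardless of where the window cuts the waveform, so
  its first positive minimum is unbiased by the finite window.
- **acf**: `F(s) = ∫₀^{L-s} f(x+s) f(x) dx`, the overlap (zero-padded)
  autocorrelation; its first positive maximum marks the period but rides
  on a window that shrinks with `s`.
- **acf_periodic**: the autocorrelation of the N-periodic extension of the
  sample sequence (FFT convention; the wrap segment interpolates node
  `N-1` back to node `0`), integrated over one full period.

Because `f` is piecewise linear with breakpoints at the integers, each
measure restricted to a unit shift cell `s = k + t`, `t ∈ [0,1]`, is a
cubic polynomial in `t` whose coefficients are finite sums of products of
samples.  The implementation derives these coefficients in closed form
(per cell, the overlap splits into a leading part of length `1-t` pairing
segments `j`/`j+k` and a trailing part of length `t` pairing
`j`/`j+k+1`), vectorised over all cells.  The curves are exact up to
rounding; unit tests verify them against adaptive quadrature of the
interpolant to 1e-8 relative (they agree to ~1e-15).

The period is located analytically: the derivative of each cubic is solved
in closed form, critical points are classified by one-sided derivative
signs (which also handles extrema sitting exactly on cell boundaries), and
the estimate is the first local minimum (maximum for the ACF variants)
inside the search bounds that follows an opposite extremum at smaller
shift — this skips the trivial well at `F(0) = 0`.  A **contrast** value,
the relative depth of the extremum against that preceding opposite
extremum, gates validity.  For maxima the depth is normalised by the peak
value rather than by the preceding minimum, which can be near zero for
zero-mean signals.

For a region of interest (ROI) the per-line curves are summed
coefficient-wise before locating the minimum (default), which keeps
signal-free lines from breaking the estimate; alternatively the per-line
minima are averaged, excluding invalid lines.  On heterogeneous fixtures
the two aggregations differ in the third decimal of the period.

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `s_min` | 2.0 px | lower search bound; skips the `F(0)` well |
| `s_max` | `(N-1)/2` px | upper search bound (half the line support) |
| `contrast_threshold` | 0.1 | minimum relative extremum depth for validity |
| `period_hint` | 4.5 px | expected period; sets the detrend blur scale (1.8 um at 0.4 um/px) |
| `pixel_size_um` | 0.411 | reference microscope calibration |
| `frame_interval_s` | 0.005 | reference 200 Hz acquisition |

## Error structure

Two error sources are kept apart deliberately:

1. **Boundary bias.**  Evaluated on *exact continuous* sinusoids (no
   sampling), the finite measure recovers the period to < 1e-6 relative
   for every tested `(N, P)`, while both ACF variants carry a modulated
   boundary bias: the periodic variant over- and under-estimates
   (alternating sign as `P` varies, up to ~5% at N = 50), and the overlap
   variant underestimates with an amplitude that oscillates with the
   boundary mismatch, vanishing when the window holds a whole number of
   periods.  The continuous reference evaluates the integrals by composite
   Gauss–Legendre quadrature (panel count scaled to the number of
   oscillations, machine-precision for these integrands, validated against
   adaptive quadrature to 1e-10 in the tests), scans shifts at step 0.01
   and refines the extremum by bounded scalar minimisation to 1e-9.
2. **Interpolation (pixelation) bias.**  On *sampled* sinusoids the
   piecewise-linear model flattens the waveform slightly and the estimate
   oscillates around the truth.  At N = 50 the finite method errs by at
   most ~0.6% for `P ∈ [4.0, 4.6]` (inside the 1% envelope), the periodic
   ACF by up to ~1.8% (inside 2%); the error decays as `P` grows at fixed
   `N/P`.  Around `P ≈ 4.3` px the phase-averaged finite-method bias is a
   smooth ≈ −0.45% that rises through zero near `P ≈ 4.5`; this matters
   for orientation fitting (below).

## Detrending

Backgrounds (out-of-focus nuclei, illumination, fibre shadows) are removed
per line before estimation.  The line is blurred with a Gaussian whose
half-width-at-half-maximum is one tenth of the period hint (truncated at
4 sigma, reflect padding, unit-sum kernel — `scipy.ndimage`), the strict
local maxima and minima of the blurred signal (plateaus counted once, at
their centre) are joined by linear envelopes extended flat to the
boundaries, and the trend is the envelope midline.  The oscillatory part
is the residual; the stored trend is re-derived as `input − oscillatory`
so the decomposition reconstructs the input to the last bit on
realistically scaled data (for pathological dynamic ranges one rounding
ulp of the overall scale is unavoidable).  Lines with fewer than two
maxima or two minima fall back to a flat trend at the blurred mean, so
signal-free lines come out as (near-)zero oscillation.  The amplitude of
the oscillatory part is intentionally not normalised — amplitude
variation is real signal uncertainty and should remain visible.

The envelope-midline rule is one concrete realisation of
"trend extraction from local extrema"; it is isolated behind
`detrend_line` so an alternative can be swapped in.

## ROI geometry and orientation

Pixels sit at integer (row, col) coordinates, 0-based.  A ROI is a
rectangle of `height` lines × `width` samples, centred anywhere, rotated
about its centre; rotated ROIs are resampled by bilinear interpolation
(`angle = 0` with integral coordinates is an exact copy; bilinear
resampling reproduces planes exactly).

Cutting a `P`-periodic lattice of stripes at angle `a` relative to the
lattice orientation `a0` yields an apparent period `P / cos(a − a0)`.
`orientation_scan` estimates the period over a sweep of ROI angles and
fits the reciprocal model `1/SL = A cos a + B sin a` by linear least
squares — an exact linearisation of the cosine model — giving
`a0 = atan2(B, A)` and the corrected period `1/√(A² + B²)` (the corrected
period via `SL(0)·cos(a0)` is also reported).  Because the interpolation
bias varies smoothly with the apparent period, an angle window that is
asymmetric about `a0` leaks the odd component of that bias into the fit
(~0.5° at `P = 4.32`); the optional `recenter` iteration repeats the scan
with the window symmetric about the fitted `a0`, cancelling the odd
component (residual ~0.1°).  The corrected period still inherits the
intrinsic ≈ −0.45% interpolation bias at `P ≈ 4.3` — no orientation
correction can remove a bias that is already present at perfect
alignment.

`sensitivity_map` repeats the estimate over a grid of ROI centres and
masks invalid results, exposing spatial heterogeneity (small ROIs) or its
averaging (large ROIs) and the dead zones around occlusions.

## Time series

`trace_timeseries` applies the estimator per frame on a fixed ROI,
converts to um, and reports the shortening rate as the 3-point central
finite difference (one-sided at the ends; a frame that fails validity
stays NaN — it invalidates its own rate and any rate that uses it, and is
never interpolated).  On synthetic twitches the finite-extent trace
follows the true period within 1% at every frame, while the
spectrum-peak baseline stair-steps: its three-point parabolic refinement
of the discrete power spectrum sticks near bin frequencies, producing
plateaus (≥ 3 consecutive values equal to within 0.001 px) precisely
while the true period is moving, and spurious spikes in the rate.

## Baselines

The conventional estimators are implemented as commonly deployed:
per-line Fourier power spectra (optional Hann window) averaged over the
ROI, peak bin restricted to the period band, three-point parabolic
refinement on raw power values (degenerate curvature → offset 0); and the
averaged discrete circular autocorrelation (power-spectrum inversion)
with the first integer-lag local maximum refined the same way.  Both
require near-zero-mean input and are therefore run after detrending.

## Synthetic data

The generator renders an oriented striation lattice
`I(r,c) = A(r,c)·[sin(2πu/P + φ) + w₂ sin(4πu/P + 2φ)] + T(r,c) + ε`,
`u = c·cos a0 + r·sin a0`, with: scalar or per-pixel amplitude; an
optional second harmonic `w₂` for the dark/light band asymmetry of real
Z-disk / A–I-band patterns (default 0 so analytic expectations hold);
polynomial background trends per row/column (degree ≤ 2); additive
Gaussian noise from a seeded generator (bit-reproducible); and dark
occlusion bands — carbon-fibre stand-ins — that scale the amplitude by
`1 − depth` under a Gaussian cross-profile.  Contraction stacks modulate
the period with a smooth twitch `P(t) = P_dia − (P_dia − P_sys)·h(t)`
(`h` a normalised rise-and-decay; defaults 4.35 → 4.0 px over 200 frames
at 5 ms, onset 0.1 s, rise 40 ms, decay 120 ms), with the lattice phase
anchored at the image centre so the pattern compresses about a fixed
material point.  Every generator records its ground truth.

What the generator does **not** emulate: the optical point-spread
function, photon shot noise, sarcomere disorder/dislocations, amplitude
flicker, or genuine cell heterogeneity.  Passing the recovery tests
therefore demonstrates correctness of the estimators under the stated
signal model, not performance on arbitrary microscopy data; the
published live-cell numbers are represented only by qualitative fixture
analogues.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at the scales the method
targets in practice: lines of N ≈ 50–64 samples, ROIs around 54 × 31,
error grids of 61–181 period values, 200-frame twitches — the full suite
completes in about a minute on one core.  Floating tolerances (node
continuity 1e-9 relative, extremum refinement 1e-9, quadrature
cross-checks 1e-8/1e-10) are exposed as defaults, not baked in.  Ties
between an interior derivative root and a cell boundary resolve toward
the smaller shift; degenerate parabola curvature in the baselines yields
a zero offset; all estimators are invariant to intensity sign and (after
detrending) offset, so no dark-vs-light band convention is needed.

## Known limitations

- The interpolation bias (up to ~0.6% at 4–5 px/period) is intrinsic to
  the piecewise-linear signal model and bounds the absolute accuracy at
  the typical 4–5 px/sarcomere sampling; it shrinks rapidly for longer
  periods.
- Detrending is strictly per line; 2-D structure is not used.
- The orientation fit assumes a single coherent lattice in the ROI.
- No real-time guarantees; the sensitivity map is O(centres × estimate).
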