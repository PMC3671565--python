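# sarcfit

Subpixel estimation of the mean sarcomere length — the fundamental spatial
period of the striation pattern — from transmission-microscopy images of
cardiomyocytes, and more generally of any quasi-periodic 1-D/2-D intensity
signal on a short, finite window.

## Why another period estimator

FFT- and autocorrelation-based sarcomere-length readouts implicitly extend
the image window periodically (or pad it with zeros).  On a window holding
only ~10 sarcomeres the resulting boundary mismatch modulates the estimate
systematically, and since the mismatch changes as the cell contracts, it
cannot be calibrated away; it shows up as stair-step plateaus in the
SL-vs-time trace and spurious spikes in the shortening rate.

`sarcfit` instead minimises a **finite-extent least-squares similarity
measure**: with the line profile modelled as the piecewise-linear
interpolant f(x) of its samples,

    F(s) = ∫₀^{L−s} [f(x+s) − f(x)]² dx,        L = N − 1,

integrated over the overlap only.  For a periodic signal F vanishes exactly
at the period, wherever the window cuts the waveform — the estimator is
unbiased by the finite extent.  Because f is piecewise linear, F is an
*exact piecewise cubic* in s whose coefficients are finite sums of sample
products, so the first positive minimum (the period, in px) is located in
closed form at subpixel resolution.  SL in um is then `period_px ×
pixel_size_um`, and the apparent period of a ROI tilted by α against the
striation lattice follows `P / cos(α − α₀)`, which an angle sweep inverts
to find the lattice orientation α₀ and the corrected SL.

The conventional estimators (overlap and periodic autocorrelation, Fourier
spectrum peak with three-point parabolic refinement) are included as
baselines, together with a per-line detrend preprocessor (envelope-midline
background removal), ROI sensitivity maps, twitch tracing with shortening
rates, and a synthetic generator with known ground truth (oriented
lattices, background trends, sensor noise, carbon-fibre-like occlusions,
contraction stacks).

## Worked example

Estimate the period of a synthetic striation image (true period 4.32 px,
uneven background, 2% noise) with the statsmodels-style model interface:

```python
import sarcfit as sf

spec = sf.StriationSpec(width=64, height=31, period_px=4.32,
                        noise_sigma=0.02, trend_col=(0.5, 0.01), seed=6)
img = sf.make_striation_image(spec)

res = sf.StriationPeriodModel(img, method="finite", detrend=True,
                              period_hint=4.32, pixel_size_um=0.411).fit()
print(res.summary())
```

```
Striation period fit
============================================
method:            finite (sum)
lines (valid):     31 (31)
samples per line:  64
search bounds px:  [2, 31.5]
detrend:           True (hint 4.32 px)
--------------------------------------------
valid:             True
period [px]:       4.2990
period s.e. [px]:  0.0002
contrast:          0.992
sarcomere length:  1.7669 um (0.411 um/px)
```

The fit reads: all 31 ROI lines contributed; the similarity minimum at
4.299 px is deep (contrast 0.99 ≈ a clean periodic signal) and the
per-line spread is ~0.0002 px.  The ~0.5% gap to the true 4.32 px is the
known piecewise-linear interpolation bias at ~4.3 px/period (see
`docs/methods.md`); at 0.411 um/px the mean sarcomere length is 1.767 um.

The same machinery is scriptable from the shell:

```sh
sarcfit simulate stack.tif --frames 200 --period-px 4.35   # synthetic twitch
sarcfit trace stack.tif trace.csv --roi-center 15 31.5 \
        --roi-height 31 --roi-width 54                     # SL(t) + rate CSV
sarcfit orientation image.tif                              # α₀, corrected SL
sarcfit sensitivity image.tif map --stride 2               # SL map TIFF/CSV
sarcfit error-table bias.csv --mode continuous --method finite
```

Library-level entry points mirror the subcommands: `estimate_period`,
`orientation_scan`, `sensitivity_map`, `trace_timeseries`,
`period_error_table`.

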