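"""Unit and property tests for the piecewise-cubic similarity core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sarcfit as sf
from sarcfit.similarity import default_s_max

from oracles import acf_peak_period, dft_peak_period, similarity_quad

METHODS = ("finite", "acf", "acf_periodic")

line_strategy = st.lists(
    st.floats(-50, 50, allow_nan=False, allow_infinity=False),
    min_size=5, max_size=24,
).map(np.asarray)


# ---------------------------------------------------------------------------
# curve construction
# ---------------------------------------------------------------------------

def test_constant_line_finite_curve_vanishes():
    curve = sf.build_similarity(np.full(10, 5.0), "finite")
    assert np.abs(curve.coeffs).max() == 0.0


def test_integer_period_two_gives_exact_zero():
    curve = sf.build_similarity([0, 1, 0, 1, 0, 1, 0, 1], "finite")
    assert curve(2.0) == pytest.approx(0.0, abs=1e-14)


@pytest.mark.parametrize("method", METHODS)
def test_curve_matches_quadrature_oracle(method, rng):
    f = rng.normal(size=30)
    curve = sf.build_similarity(f, method)
    shifts = rng.uniform(0.0, curve.support - 1e-9, 60)
    vals = curve(shifts)
    ref = np.array([similarity_quad(f, method, s) for s in shifts])
    scale = max(1.0, np.abs(ref).max())
    assert np.abs(vals - ref).max() <= 1e-8 * scale


@pytest.mark.parametrize("method", METHODS)
def test_curve_continuity_at_nodes(method, rng):
    f = rng.normal(size=25)
    curve = sf.build_similarity(f, method)
    p = curve.to_ppoly()
    nodes = np.arange(1, curve.n_segments, dtype=float)
    jump = np.abs(p(nodes - 1e-11) - p(nodes + 1e-11)).max()
    fmax = np.abs(curve(np.linspace(0, curve.support, 500))).max()
    assert jump <= 1e-9 * (1.0 + fmax)


def test_finite_curve_nonnegative_and_zero_at_origin(rng):
    f = rng.normal(size=40)
    curve = sf.build_similarity(f, "finite")
    s = np.linspace(0.0, curve.support, 2000)
    vals = curve(s)
    assert curve(0.0) == pytest.approx(0.0, abs=1e-12)
    assert vals.min() >= -1e-12 * np.abs(vals).max()


def test_periodic_curve_wraps_modulo_n(rng):
    f = rng.normal(size=16)
    curve = sf.build_similarity(f, "acf_periodic")
    assert curve.n_segments == 16
    for s in (0.0, 3.7, 9.2):
        assert curve(s) == pytest.approx(curve(s + 16.0), rel=1e-12)


def test_too_short_line_raises():
    with pytest.raises(sf.InputTooShortError):
        sf.build_similarity([1.0, 2.0, 3.0], "finite")


def test_unknown_method_raises():
    with pytest.raises(ValueError):
        sf.build_similarity(np.zeros(8), "wavelet")


# ---------------------------------------------------------------------------
# invariance properties
# ---------------------------------------------------------------------------

@settings(max_examples=30, deadline=None, derandomize=True)
@given(line=line_strategy, c=st.floats(-100, 100, allow_nan=False))
def test_finite_measure_is_offset_invariant(line, c):
    """Adding a constant leaves the squared-difference measure unchanged."""
    a = sf.build_similarity(line, "finite")
    b = sf.build_similarity(line + c, "finite")
    scale = 1.0 + np.abs(a.coeffs).max()
    assert np.abs(a.coeffs - b.coeffs).max() <= 1e-9 * scale


def test_acf_measures_are_not_offset_invariant(sine43):
    for method in ("acf", "acf_periodic"):
        a = sf.build_similarity(sine43, method)
        b = sf.build_similarity(sine43 + 3.0, method)
        assert np.abs(a.coeffs - b.coeffs).max() > 1.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(line=line_strategy)
def test_finite_measure_is_reversal_invariant(line):
    a = sf.build_similarity(line, "finite")
    b = sf.build_similarity(line[::-1], "finite")
    scale = 1.0 + np.abs(a.coeffs).max()
    assert np.abs(a.coeffs - b.coeffs).max() <= 1e-9 * scale


def test_accumulation_is_linear(rng):
    f1, f2 = rng.normal(size=30), rng.normal(size=30)
    c1 = sf.build_similarity(f1, "finite")
    c2 = sf.build_similarity(f2, "finite")
    total = sf.accumulate_curves([c1, c2])
    shifts = rng.uniform(0, c1.support, 100)
    assert np.allclose(total(shifts), c1(shifts) + c2(shifts), rtol=1e-12)
    # m identical copies scale every coefficient by m
    triple = sf.accumulate_curves([c1, c1, c1])
    assert np.allclose(triple.coeffs, 3.0 * c1.coeffs, rtol=1e-12)
    # the all-zero curve is the identity
    zero = sf.build_similarity(np.zeros(30), "finite")
    assert np.allclose(sf.accumulate_curves([c1, zero]).coeffs, c1.coeffs)


def test_accumulating_mixed_curves_raises(rng):
    c1 = sf.build_similarity(rng.normal(size=20), "finite")
    c2 = sf.build_similarity(rng.normal(size=20), "acf")
    c3 = sf.build_similarity(rng.normal(size=12), "finite")
    with pytest.raises(sf.IncompatibleCurvesError):
        sf.accumulate_curves([c1, c2])
    with pytest.raises(sf.IncompatibleCurvesError):
        sf.accumulate_curves([c1, c3])
    with pytest.raises(sf.IncompatibleCurvesError):
        sf.accumulate_curves([])


# ---------------------------------------------------------------------------
# period location
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("period", [3, 4, 6])
def test_exactly_periodic_line_recovers_integer_period(period, rng):
    pattern = rng.normal(size=period)
    line = np.tile(pattern, 48 // period + 2)
    curve = sf.build_similarity(line, "finite")
    assert curve(float(period)) <= 1e-12 * np.abs(curve.coeffs).max()
    est = sf.locate_fundamental(curve, s_min=period - 1.0, s_max=3 * period)
    assert est.valid
    assert est.period_px == pytest.approx(period, abs=1e-9)


def test_quarter_wave_tile_gives_exact_four():
    line = np.tile([0.0, 1.0, 0.0, -1.0], 12)
    est = sf.locate_fundamental(sf.build_similarity(line, "finite"), 2.0, 10.0)
    assert est.valid and est.period_px == pytest.approx(4.0, abs=1e-12)
    assert est.contrast == pytest.approx(1.0, abs=1e-9)


def test_monotone_ramp_has_no_fundamental():
    est = sf.locate_fundamental(
        sf.build_similarity(np.arange(30.0), "finite"), 2.0, 14.0)
    assert not est.valid
    assert math.isnan(est.period_px)
    assert est.contrast == 0.0


def test_sampled_sinusoid_within_one_percent(sine43):
    est = sf.locate_fundamental(sf.build_similarity(sine43, "finite"),
                                2.0, 10.0)
    assert est.valid
    assert abs(est.period_px / 4.3 - 1.0) <= 0.01


def test_bad_bounds_raise(sine43):
    curve = sf.build_similarity(sine43, "finite")
    with pytest.raises(ValueError):
        sf.locate_fundamental(curve, 0.0, 10.0)
    with pytest.raises(ValueError):
        sf.locate_fundamental(curve, 5.0, 3.0)
    with pytest.raises(ValueError):
        sf.locate_fundamental(curve, 2.0, 100.0)


def test_pixelation_error_decays_with_longer_waveforms():
    """At fixed N/P the interpolation error shrinks as P grows."""
    def band_max_error(P0):
        errs = []
        for P in np.linspace(0.97 * P0, 1.03 * P0, 25):
            n = int(round(10 * P)) + 1
            est = sf.locate_fundamental(
                sf.build_similarity(sf.make_sine_line(n, P), "finite"),
                s_min=P * 0.6, s_max=min(P * 1.8, (n - 1) / 2.0))
            errs.append(abs(est.period_px / P - 1.0))
        return max(errs)

    e4, e8 = band_max_error(4.3), band_max_error(8.6)
    assert e8 < e4


# ---------------------------------------------------------------------------
# FFT / ACF baselines
# ---------------------------------------------------------------------------

def test_fft_on_bin_sinusoid_is_exact():
    line = sf.make_sine_line(64, 8.0)
    est = sf.estimate_period_fft([line], 2.0, 16.0)
    assert est.valid
    assert est.period_px == pytest.approx(8.0, abs=1e-9)


def test_fft_constant_line_is_invalid():
    assert not sf.estimate_period_fft([np.zeros(50)], 2.0, 10.0).valid


def test_fft_matches_independent_dft_oracle(sine43):
    est = sf.estimate_period_fft([sine43], 2.0, 10.0)
    ref = dft_peak_period([sine43], 2.0, 10.0)
    assert est.period_px == pytest.approx(ref, abs=1e-9)
    # off-bin frequency: boundary mismatch biases the estimate
    assert abs(est.period_px - 4.3) > 1e-4


def test_fft_hann_window_changes_but_stays_close(sine43):
    plain = sf.estimate_period_fft([sine43], 2.0, 10.0)
    hann = sf.estimate_period_fft([sine43], 2.0, 10.0, window="hann")
    assert hann.valid
    assert hann.period_px != plain.period_px
    assert hann.period_px == pytest.approx(
        dft_peak_period([sine43], 2.0, 10.0, window="hann"), abs=1e-9)


def test_fft_narrow_band_raises(sine43):
    with pytest.raises(ValueError):
        sf.estimate_period_fft([sine43], 24.0, 24.5)


def test_acf_quadratic_integer_period_exact():
    line = np.tile([0.0, 1.0, 0.0, -1.0], 12)
    est = sf.estimate_period_acf_quadratic([line], 2.0, 10.0)
    assert est.valid and est.period_px == pytest.approx(4.0, abs=1e-12)


def test_acf_quadratic_zero_line_invalid():
    assert not sf.estimate_period_acf_quadratic([np.zeros(48)], 2.0, 10.0).valid


def test_acf_quadratic_matches_direct_acf_oracle(sine43):
    est = sf.estimate_period_acf_quadratic([sine43], 2.0, 10.0)
    ref = acf_peak_period([sine43], 2.0, 10.0)
    assert est.period_px == pytest.approx(ref, abs=1e-9)


# ---------------------------------------------------------------------------
# estimate_period dispatcher
# ---------------------------------------------------------------------------

def test_identical_lines_sum_equals_per_line_mean():
    lines = np.tile(sf.make_sine_line(50, 4.3), (31, 1))
    a = sf.estimate_period(lines, "finite", mode="sum")
    b = sf.estimate_period(lines, "finite", mode="per_line_mean")
    assert a.period_px == pytest.approx(b.period_px, abs=1e-12)


def test_sum_and_per_line_mean_differ_slightly(heterogeneous_lines):
    """On a heterogeneous ROI the two aggregation rules disagree in the
    third decimal while both stay close to the underlying period."""
    a = sf.estimate_period(heterogeneous_lines, "finite", mode="sum")
    b = sf.estimate_period(heterogeneous_lines, "finite", mode="per_line_mean")
    diff = abs(a.period_px - b.period_px)
    assert 1e-4 < diff < 2e-2
    assert abs(a.period_px / 4.32 - 1.0) < 0.01
    assert abs(b.period_px / 4.32 - 1.0) < 0.01


def test_dead_lines_excluded_from_per_line_mean(heterogeneous_lines):
    lines = heterogeneous_lines.copy()
    dead = [3, 10, 17, 24, 30]
    lines[dead] = 0.0
    a = sf.estimate_period(lines, "finite", mode="sum")
    b = sf.estimate_period(lines, "finite", mode="per_line_mean")
    assert a.valid
    assert b.valid and b.n_lines == 31 - len(dead)


def test_all_invalid_lines_gives_invalid_estimate():
    est = sf.estimate_period(np.zeros((5, 40)), "finite", mode="per_line_mean")
    assert not est.valid


def test_per_frame_default_s_max_is_half_support():
    assert default_s_max(50, "finite") == pytest.approx(24.5)
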