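"""Similarity-measure construction and subpixel fundamental-period location.

A line profile is modelled as the piecewise-linear interpolant ``f(x)`` of its
pixel samples ``f_i`` (pixel centres at integer coordinates, continuous support
``0 <= x <= L`` with ``L = N - 1``).  Three similarity measures of the profile
with its own shifted copy are supported:

``finite``
    ``F(s) = int_0^{L-s} [f(x+s) - f(x)]^2 dx`` -- the squared-difference
    overlap integral.  For an exactly periodic signal it vanishes at the
    period, so its first positive minimum is an *unbiased* period estimate
    on a finite window.
``acf``
    ``F(s) = int_0^{L-s} f(x+s) f(x) dx`` -- the overlap (zero-padded)
    autocorrelation; its first positive maximum marks the period but is
    biased by the shrinking overlap window.
``acf_periodic``
    ``F(s) = int_0^{N} g(x+s) g(x) dx`` where ``g`` is the N-periodic
    extension of the sample sequence (linear interpolation across the wrap
    segment from node ``N-1`` back to node ``0``; the discrete-FFT
    convention).  Biased by the wrap-around boundary mismatch.

Because ``f`` is piecewise linear with breakpoints at the integers, each
measure restricted to an integer shift cell ``s = k + t``, ``t in [0, 1]``,
is a cubic polynomial in ``t`` whose coefficients are finite sums of products
of the samples.  The curves are therefore represented *exactly* (up to
rounding) as piecewise cubics, and the period is located in closed form from
the cubic coefficients.

Conventional baselines -- discrete Fourier power-spectrum peak and discrete
periodic ACF peak, each refined by a three-point parabola -- are provided for
comparison; they exhibit the boundary bias the similarity approach avoids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.interpolate import PPoly

__all__ = [
    "SIMILARITY_METHODS",
    "SimilarityCurve",
    "PeriodEstimate",
    "InputTooShortError",
    "IncompatibleCurvesError",
    "build_similarity",
    "accumulate_curves",
    "locate_fundamental",
    "continuous_reference_estimate",
    "estimate_period_fft",
    "estimate_period_acf_quadratic",
    "estimate_period",
]

SIMILARITY_METHODS = ("finite", "acf", "acf_periodic")
ALL_METHODS = SIMILARITY_METHODS + ("fft_spectrum", "acf_quadratic")

#: default lower search bound (px); skips the trivial F(0) extremum
DEFAULT_S_MIN = 2.0
#: default relative extremum depth below which an estimate is marked invalid
DEFAULT_CONTRAST_THRESHOLD = 0.1


class InputTooShortError(ValueError):
    """Line profile has fewer samples than the method requires."""


class IncompatibleCurvesError(ValueError):
    """Similarity curves with mixed methods/lengths cannot be accumulated."""


def as_line(values) -> np.ndarray:
    """Validate and return a line profile as a float array (N >= 4, finite)."""
    f = np.asarray(values, dtype=float)
    if f.ndim != 1:
        raise ValueError(f"line profile must be 1-D, got shape {f.shape}")
    if f.size < 4:
        raise InputTooShortError(
            f"line profile needs at least 4 samples, got {f.size}"
        )
    if not np.all(np.isfinite(f)):
        raise ValueError("line profile contains non-finite values")
    return f


@dataclass
class SimilarityCurve:
    """A similarity measure as a piecewise cubic polynomial over the shift axis.

    ``coeffs[k] = (a, b, c, d)`` so that ``F(k + t) = a + b t + c t^2 + d t^3``
    for fractional shift ``t in [0, 1]``, ``k = 0..K-1``.
    """

    method: str
    coeffs: np.ndarray            # (K, 4), ascending powers of t
    n_samples: int                # N of the originating profile(s)
    extremum_kind: Literal["minimum", "maximum"]
    n_lines: int = 1              # number of accumulated line profiles

    @property
    def n_segments(self) -> int:
        return self.coeffs.shape[0]

    @property
    def support(self) -> float:
        """Largest admissible shift (K, equal to L or N for periodic)."""
        return float(self.n_segments)

    def __call__(self, s) -> np.ndarray | float:
        """Evaluate F at shift(s) ``s``; periodic curves wrap modulo N."""
        s_arr = np.asarray(s, dtype=float)
        scalar = s_arr.ndim == 0
        x = np.atleast_1d(s_arr).copy()
        if self.method == "acf_periodic":
            x %= self.n_segments
        out = self.to_ppoly()(x)
        return float(out[0]) if scalar else out

    def to_ppoly(self) -> PPoly:
        """scipy PPoly view (highest-power-first coefficient layout)."""
        c = self.coeffs.T[::-1]   # (4, K), t^3 first
        x = np.arange(self.n_segments + 1, dtype=float)
        return PPoly(c, x, extrapolate=False)

    def to_frame(self, step: float = 0.01):
        """Sampled (shift, value) table, e.g. for CSV export."""
        import pandas as pd

        s = np.arange(0.0, self.support + 0.5 * step, step)
        s[-1] = min(s[-1], self.support)
        return pd.DataFrame({"shift": s, "value": self(s)})


@dataclass
class PeriodEstimate:
    """A subpixel fundamental-period estimate in pixels.

    ``contrast`` is the relative depth of the located extremum against the
    preceding opposite extremum; ``valid`` requires it to clear the
    configured threshold (and the estimate to lie in the search bounds).
    """

    period_px: float
    valid: bool
    contrast: float
    method: str
    extremum_value: float = math.nan
    n_lines: int = 1

    @classmethod
    def invalid(cls, method: str, n_lines: int = 1) -> "PeriodEstimate":
        return cls(math.nan, False, 0.0, method, math.nan, n_lines)


# ---------------------------------------------------------------------------
# exact piecewise-cubic coefficients
# ---------------------------------------------------------------------------

def _finite_coeffs(f: np.ndarray) -> np.ndarray:
    """Cubic cell coefficients of the squared-difference overlap integral.

    For ``s = k + t`` the overlap splits per unit cell ``j`` into a leading
    part of length ``1-t`` (segments ``j`` vs ``j+k``) and a trailing part of
    length ``t`` (segments ``j`` vs ``j+k+1``); each contributes a cubic in
    ``t`` with coefficients built from sample differences.
    """
    N = f.size
    df = np.diff(f)                       # slopes, length N-1
    K = N - 1
    k = np.arange(K)[:, None]             # (K, 1)
    j = np.arange(K)[None, :]             # (1, K) ; j ranges over unit cells
    M = (N - 1) - k                       # number of leading parts per k

    idx = np.minimum(j + k, N - 2)        # clipped; masked entries unused
    lead = j < M
    a0 = np.where(lead, f[np.minimum(j + k, N - 1)] - f[np.minimum(j, N - 1)], 0.0)
    a1 = np.where(lead, df[idx], 0.0)
    B = np.where(lead, df[idx] - df[np.minimum(j, N - 2)], 0.0)

    trail = j < M - 1
    idx2 = np.minimum(j + k + 1, N - 2)
    c0 = np.where(trail, f[np.minimum(j + k + 1, N - 1)] - f[np.minimum(j + 1, N - 1)], 0.0)
    c1 = np.where(trail, df[np.minimum(j, N - 2)], 0.0)
    D = np.where(trail, df[idx2] - df[np.minimum(j, N - 2)], 0.0)

    coeffs = np.empty((K, 4))
    coeffs[:, 0] = np.sum(a0 * a0 + B * a0 + B * B / 3.0, axis=1)
    coeffs[:, 1] = np.sum(2 * a0 * a1 - a0 * a0 + B * (a1 - 2 * a0) - B * B, axis=1) \
        + np.sum(c0 * c0, axis=1)
    coeffs[:, 2] = np.sum(a1 * a1 - 2 * a0 * a1 + B * (a0 - 2 * a1) + B * B, axis=1) \
        + np.sum(2 * c0 * c1 + D * c0, axis=1)
    coeffs[:, 3] = np.sum(-a1 * a1 + B * a1 - B * B / 3.0, axis=1) \
        + np.sum(c1 * c1 + D * c1 + D * D / 3.0, axis=1)
    return coeffs


def _acf_overlap_terms(alpha, beta, q0, q1, gamma=None, delta=None,
                       alpha2=None, beta2=None):
    """Leading/trailing cubic contributions of a product overlap integral.

    Leading part (length ``1-t``): left factor ``q0 + q1 u``, right factor
    ``(alpha + beta t) + beta u``.  Trailing part (length ``t``): left factor
    ``(gamma - delta t) + delta v``, right factor ``alpha2 + beta2 v``.
    Returns per-cell arrays of the four ascending-power coefficients.
    """
    E = alpha * q1 + beta * q0
    G = beta * q1
    t0 = q0 * alpha + E / 2.0 + G / 3.0
    t1 = q0 * (beta - alpha) - E - G / 2.0
    t2 = -q0 * beta + E / 2.0
    t3 = G / 6.0
    if gamma is not None:
        t1 = t1 + alpha2 * gamma
        t2 = t2 + (beta2 * gamma - alpha2 * delta) / 2.0
        t3 = t3 - beta2 * delta / 6.0
    return t0, t1, t2, t3


def _acf_coeffs(f: np.ndarray) -> np.ndarray:
    """Cubic cell coefficients of the overlap (zero-padded) autocorrelation."""
    N = f.size
    df = np.diff(f)
    K = N - 1
    k = np.arange(K)[:, None]
    j = np.arange(K)[None, :]
    M = (N - 1) - k

    lead = j < M
    jk = np.minimum(j + k, N - 2)
    jj = np.minimum(j, N - 2)
    alpha = np.where(lead, f[np.minimum(j + k, N - 1)], 0.0)
    beta = np.where(lead, df[jk], 0.0)
    q0 = np.where(lead, f[np.minimum(j, N - 1)], 0.0)
    q1 = np.where(lead, df[jj], 0.0)

    trail = j < M - 1
    jk1 = np.minimum(j + k + 1, N - 2)
    alpha2 = np.where(trail, f[np.minimum(j + k + 1, N - 1)], 0.0)
    beta2 = np.where(trail, df[jk1], 0.0)
    gamma = np.where(trail, f[np.minimum(j + 1, N - 1)], 0.0)
    delta = np.where(trail, df[jj], 0.0)

    t0, t1, t2, t3 = _acf_overlap_terms(alpha, beta, q0, q1,
                                        gamma, delta, alpha2, beta2)
    # the trailing part of the last populated cell (j = M-1) must not
    # contribute -- _acf_overlap_terms already zeroed it through the masks
    coeffs = np.empty((K, 4))
    coeffs[:, 0] = t0.sum(axis=1)
    coeffs[:, 1] = t1.sum(axis=1)
    coeffs[:, 2] = t2.sum(axis=1)
    coeffs[:, 3] = t3.sum(axis=1)
    return coeffs


def _acf_periodic_coeffs(f: np.ndarray) -> np.ndarray:
    """Cubic cell coefficients of the N-periodic autocorrelation."""
    N = f.size
    fp = np.concatenate([f, f[:1]])
    dfp = np.diff(fp)                      # length N, includes wrap slope
    k = np.arange(N)[:, None]
    j = np.arange(N)[None, :]
    jk = (j + k) % N
    jk1 = (j + k + 1) % N
    j1 = (j + 1) % N

    t0, t1, t2, t3 = _acf_overlap_terms(
        f[jk], dfp[jk], f[j], dfp[j],
        f[j1], dfp[j % N], f[jk1], dfp[jk1],
    )
    coeffs = np.empty((N, 4))
    coeffs[:, 0] = t0.sum(axis=1)
    coeffs[:, 1] = t1.sum(axis=1)
    coeffs[:, 2] = t2.sum(axis=1)
    coeffs[:, 3] = t3.sum(axis=1)
    return coeffs


def build_similarity(line, method: str = "finite") -> SimilarityCurve:
    """Build the piecewise-cubic similarity curve of one line profile.

    Parameters
    ----------
    line : array-like
        Intensity samples ``f_i`` on the unit pixel grid (N >= 4).
    method : {'finite', 'acf', 'acf_periodic'}
        Which similarity integral to evaluate (see module docstring).
    """
    f = as_line(line)
    if method == "finite":
        coeffs = _finite_coeffs(f)
        kind = "minimum"
    elif method == "acf":
        coeffs = _acf_coeffs(f)
        kind = "maximum"
    elif method == "acf_periodic":
        coeffs = _acf_periodic_coeffs(f)
        kind = "maximum"
    else:
        raise ValueError(f"unknown similarity method {method!r}; "
                         f"expected one of {SIMILARITY_METHODS}")
    return SimilarityCurve(method=method, coeffs=coeffs, n_samples=f.size,
                           extremum_kind=kind)


def accumulate_curves(curves: Sequence[SimilarityCurve]) -> SimilarityCurve:
    """Coefficient-wise sum of similarity curves (the ROI superposition).

    All curves must share method, segment count and extremum kind.
    """
    if not curves:
        raise IncompatibleCurvesError("cannot accumulate an empty curve list")
    first = curves[0]
    for c in curves[1:]:
        if (c.method != first.method or c.n_segments != first.n_segments
                or c.extremum_kind != first.extremum_kind):
            raise IncompatibleCurvesError(
                f"curve ({c.method}, K={c.n_segments}) incompatible with "
                f"({first.method}, K={first.n_segments})"
            )
    total = np.sum([c.coeffs for c in curves], axis=0)
    return SimilarityCurve(method=first.method, coeffs=total,
                           n_samples=first.n_samples,
                           extremum_kind=first.extremum_kind,
                           n_lines=sum(c.n_lines for c in curves))


# ---------------------------------------------------------------------------
# extremum location
# ---------------------------------------------------------------------------

def _critical_points(curve: SimilarityCurve, s_hi: float) -> np.ndarray:
    """Stationary/sign-change points of F' in (0, s_hi], sorted, deduped.

    Interior roots of the per-segment quadratic derivative are found in
    closed form; segment nodes where the one-sided derivative changes sign
    without an interior root (a kink extremum) are included as well.
    """
    pts: list[float] = []
    K = curve.n_segments
    kmax = min(K, int(math.ceil(s_hi)))
    for k in range(kmax):
        _, b, c, d = curve.coeffs[k]
        # F'(t) = b + 2c t + 3d t^2
        if abs(d) > 0.0:
            disc = 4 * c * c - 12 * d * b
            if disc >= 0:
                sq = math.sqrt(disc)
                for t in ((-2 * c - sq) / (6 * d), (-2 * c + sq) / (6 * d)):
                    if -1e-12 <= t <= 1 + 1e-12:
                        pts.append(k + min(max(t, 0.0), 1.0))
        elif c != 0.0:
            t = -b / (2 * c)
            if -1e-12 <= t <= 1 + 1e-12:
                pts.append(k + min(max(t, 0.0), 1.0))
    # kink extrema at the nodes
    dcoef = curve.coeffs
    for k in range(1, kmax):
        a_, b_, c_, d_ = dcoef[k - 1]
        left = b_ + 2 * c_ + 3 * d_          # F'(k^-)
        right = dcoef[k][1]                  # F'(k^+)
        if left == 0.0 or right == 0.0 or (left < 0) != (right < 0):
            pts.append(float(k))
    pts = np.array(sorted(p for p in pts if 1e-12 < p <= s_hi + 1e-12))
    if pts.size == 0:
        return pts
    keep = np.concatenate([[True], np.diff(pts) > 1e-9])
    return pts[keep]


def _classify(curve: SimilarityCurve, s: float, eps: float = 1e-7) -> str:
    """'minimum' / 'maximum' / 'none' from one-sided derivative signs."""
    dp = curve.to_ppoly().derivative()
    lo = max(s - eps, 0.0)
    hi = min(s + eps, curve.support)
    dl = float(dp(lo)) if lo < s else 0.0
    dr = float(dp(hi)) if hi > s else 0.0
    if dl < 0 and dr > 0:
        return "minimum"
    if dl > 0 and dr < 0:
        return "maximum"
    return "none"


def locate_fundamental(curve: SimilarityCurve,
                       s_min: float = DEFAULT_S_MIN,
                       s_max: float | None = None,
                       contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
                       ) -> PeriodEstimate:
    """Locate the fundamental period on a similarity curve in closed form.

    For a minimum-kind curve (``finite``) the estimate is the first local
    minimum in ``[s_min, s_max]`` that follows a local maximum at a smaller
    shift (this skips the trivial well at ``F(0) = 0``); for maximum-kind
    curves (``acf``/``acf_periodic``) it is the first local maximum that
    follows a local minimum.  ``contrast`` measures the relative depth of the
    extremum against the preceding opposite extremum; an estimate is only
    ``valid`` if the contrast clears ``contrast_threshold``.
    """
    if s_max is None:
        s_max = default_s_max(curve.n_samples, curve.method)
    if not (0 < s_min < s_max <= curve.support + 1e-9):
        raise ValueError(
            f"need 0 < s_min < s_max <= support, got "
            f"({s_min}, {s_max}) with support {curve.support}"
        )
    cands = _critical_points(curve, s_max)
    prev_opp: tuple[float, float] | None = None   # (shift, value)
    want = curve.extremum_kind
    opp = "maximum" if want == "minimum" else "minimum"
    for s in cands:
        kind = _classify(curve, float(s))
        if kind == opp:
            prev_opp = (float(s), float(curve(float(s))))
        elif kind == want and s_min - 1e-12 <= s <= s_max + 1e-12:
            if prev_opp is None:
                continue
            val = float(curve(float(s)))
            ref = prev_opp[1]
            if want == "minimum":
                denom = abs(ref)
                contrast = (ref - val) / denom if denom > 0 else 0.0
            else:
                denom = abs(val)
                contrast = (val - ref) / denom if denom > 0 else 0.0
            valid = contrast >= contrast_threshold
            if not valid:
                # too shallow: keep scanning for a deeper qualifying extremum
                continue
            return PeriodEstimate(float(s), True, float(contrast),
                                  curve.method, val, curve.n_lines)
    return PeriodEstimate.invalid(curve.method, curve.n_lines)


def default_s_max(n_samples: int, method: str) -> float:
    """Default upper search bound: half the profile support."""
    return (n_samples - 1) / 2.0


# ---------------------------------------------------------------------------
# continuous-signal reference (no pixelation)
# ---------------------------------------------------------------------------

def _gl_nodes(n_panels: int, order: int = 10):
    x, w = np.polynomial.legendre.leggauss(order)
    edges = np.linspace(0.0, 1.0, n_panels + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    half = 0.5 * np.diff(edges)
    nodes = (mid[:, None] + half[:, None] * x[None, :]).ravel()
    weights = (half[:, None] * w[None, :]).ravel()
    return nodes, weights


def _continuous_F(s, P: float, L: float, method: str,
                  nodes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Quadrature evaluation of a similarity integral of sin(2 pi x / P).

    ``s`` may be an array.  Integrals over the (shift-dependent) overlap are
    mapped to [0, 1]; the periodic variant (extension period L) splits into
    the overlap part plus the wrap-around part, both smooth.
    """
    s = np.atleast_1d(np.asarray(s, dtype=float))
    w0 = 2 * math.pi / P

    def overlap(sv, fun):
        span = (L - sv)[:, None]
        x = span * nodes[None, :]
        vals = fun(x, sv[:, None])
        return (span * weights[None, :] * vals).sum(axis=1)

    if method == "finite":
        out = overlap(s, lambda x, sv: (np.sin(w0 * (x + sv)) - np.sin(w0 * x)) ** 2)
    elif method == "acf":
        out = overlap(s, lambda x, sv: np.sin(w0 * (x + sv)) * np.sin(w0 * x))
    elif method == "acf_periodic":
        sw = np.mod(s, L)
        out = overlap(sw, lambda x, sv: np.sin(w0 * (x + sv)) * np.sin(w0 * x))
        # wrap part: x in [L-s, L], shifted argument re-enters at x + s - L
        span = sw[:, None]
        x = (L - sw)[:, None] + span * nodes[None, :]
        vals = np.sin(w0 * (x + sw[:, None] - L)) * np.sin(w0 * x)
        out = out + (span * weights[None, :] * vals).sum(axis=1)
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    return out


def continuous_reference_estimate(P: float, N: int, method: str = "finite",
                                  s_min: float = DEFAULT_S_MIN,
                                  s_max: float | None = None,
                                  grid_step: float = 0.01,
                                  refine_tol: float = 1e-9,
                                  contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
                                  ) -> PeriodEstimate:
    """Period estimate for the *continuous* sinusoid ``sin(2 pi x / P)``.

    Evaluates the same three similarity integrals for the exact sinusoid on
    ``0 <= x <= N-1`` (no piecewise-linear sampling) by composite
    Gauss-Legendre quadrature on a shift grid of step ``grid_step``, then
    refines the first qualifying extremum by bracketed scalar minimisation to
    ``refine_tol``.  This isolates the boundary bias of the ACF variants from
    pixelation effects: the finite measure recovers ``P`` exactly.
    """
    from scipy.optimize import minimize_scalar

    if P <= 0:
        raise ValueError("P must be positive")
    L = float(N - 1)
    if s_max is None:
        s_max = L / 2.0
    if not (0 < s_min < s_max <= L):
        raise ValueError("need 0 < s_min < s_max <= N-1")

    n_panels = max(16, 4 * int(math.ceil(L / P)) + 4)
    nodes, weights = _gl_nodes(n_panels)

    def F(s):
        return _continuous_F(s, P, L, method, nodes, weights)

    grid = np.arange(0.0, s_max + grid_step, grid_step)
    grid = grid[grid <= s_max + 1e-12]
    vals = F(grid)

    want_min = method == "finite"
    sign = 1.0 if want_min else -1.0
    v = sign * vals
    interior = np.arange(1, len(grid) - 1)
    is_min = (v[interior] <= v[interior - 1]) & (v[interior] <= v[interior + 1])
    is_max = (v[interior] >= v[interior - 1]) & (v[interior] >= v[interior + 1])

    def refine(i, as_minimum):
        lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
        obj = (lambda s: float(F(s)[0])) if as_minimum else \
              (lambda s: -float(F(s)[0]))
        res = minimize_scalar(obj, bounds=(lo, hi), method="bounded",
                              options={"xatol": refine_tol})
        return float(res.x), float(F(res.x)[0])

    prev_opp_val = None
    for idx in interior:
        ii = idx - 1
        if is_max[ii] and not is_min[ii]:
            _, prev_opp_val = refine(idx, as_minimum=not want_min)
        elif is_min[ii] and not is_max[ii]:
            s_star, val = refine(idx, as_minimum=want_min)
            if not (s_min - grid_step <= s_star <= s_max):
                continue
            if prev_opp_val is None:
                continue
            if want_min:
                denom = abs(prev_opp_val)
                contrast = (prev_opp_val - val) / denom if denom > 0 else 0.0
            else:
                denom = abs(val)
                contrast = (val - prev_opp_val) / denom if denom > 0 else 0.0
            if contrast < contrast_threshold:
                continue
            return PeriodEstimate(s_star, True, float(contrast), method,
                                  float(val), 1)
    return PeriodEstimate.invalid(method)


# ---------------------------------------------------------------------------
# discrete FFT / ACF baselines
# ---------------------------------------------------------------------------

def _as_line_matrix(lines) -> np.ndarray:
    if isinstance(lines, np.ndarray) and lines.ndim == 2:
        mat = np.asarray(lines, dtype=float)
    else:
        rows = [as_line(l) for l in lines]
        if not rows:
            raise ValueError("need at least one line profile")
        n = rows[0].size
        if any(r.size != n for r in rows):
            raise IncompatibleCurvesError("line profiles differ in length")
        mat = np.vstack(rows)
    if mat.shape[0] == 0:
        raise ValueError("need at least one line profile")
    as_line(mat[0])
    return mat


def _parabolic_offset(ym1: float, y0: float, yp1: float) -> float:
    """Vertex offset of the parabola through three equispaced samples."""
    denom = 2.0 * (ym1 - 2.0 * y0 + yp1)
    if abs(denom) <= 1e-15 * max(abs(y0), 1e-300):
        return 0.0
    d = (ym1 - yp1) / denom
    return min(max(d, -0.5), 0.5)


def estimate_period_fft(lines, s_min: float = DEFAULT_S_MIN,
                        s_max: float | None = None,
                        window: str | None = None,
                        contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
                        ) -> PeriodEstimate:
    """Fourier power-spectrum baseline with three-point parabolic refinement.

    Per-line power spectra (optionally Hann-windowed) are averaged, the peak
    bin in the period band ``[s_min, s_max]`` is refined by a parabola on the
    raw power values, and the period is ``N / (m* + delta)``.
    """
    mat = _as_line_matrix(lines)
    n = mat.shape[1]
    if s_max is None:
        s_max = default_s_max(n, "fft_spectrum")
    if window == "hann":
        mat = mat * np.hanning(n)[None, :]
    elif window not in (None, "none"):
        raise ValueError(f"unknown window {window!r}")
    power = np.abs(np.fft.rfft(mat, axis=1)) ** 2
    spec = power.mean(axis=0)
    m_lo = max(1, int(math.ceil(n / s_max)))
    m_hi = min(spec.size - 2, int(math.floor(n / s_min)))
    if m_hi - m_lo + 1 < 3:
        raise ValueError("search bounds map to fewer than 3 frequency bins")
    band = spec[m_lo:m_hi + 1]
    peak = float(band.max())
    if peak <= 0.0:
        return PeriodEstimate.invalid("fft_spectrum", mat.shape[0])
    m_star = m_lo + int(np.argmax(band))
    delta = _parabolic_offset(spec[m_star - 1], spec[m_star], spec[m_star + 1])
    period = n / (m_star + delta)
    others = np.delete(band, m_star - m_lo)
    contrast = max(0.0, (peak - float(others.mean())) / peak) if others.size else 1.0
    valid = contrast >= contrast_threshold and s_min <= period <= s_max
    if not valid:
        return PeriodEstimate.invalid("fft_spectrum", mat.shape[0])
    return PeriodEstimate(float(period), True, float(contrast),
                          "fft_spectrum", peak, mat.shape[0])


def estimate_period_acf_quadratic(lines, s_min: float = DEFAULT_S_MIN,
                                  s_max: float | None = None,
                                  contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
                                  ) -> PeriodEstimate:
    """Discrete periodic-ACF baseline with parabolic peak refinement.

    The per-line circular autocorrelation (power-spectrum inversion) is
    averaged over lines; the first integer-lag local maximum in the band is
    refined by a three-point parabola on the ACF values.
    """
    mat = _as_line_matrix(lines)
    n = mat.shape[1]
    if s_max is None:
        s_max = default_s_max(n, "acf_quadratic")
    acf = np.fft.irfft(np.abs(np.fft.rfft(mat, axis=1)) ** 2, n=n, axis=1)
    acf = acf.mean(axis=0)
    if acf[0] <= 0.0:
        return PeriodEstimate.invalid("acf_quadratic", mat.shape[0])
    r_lo = max(1, int(math.ceil(s_min)))
    r_hi = min(n - 2, int(math.floor(s_max)))
    for r in range(r_lo, r_hi + 1):
        if acf[r] >= acf[r - 1] and acf[r] >= acf[r + 1] and \
                (acf[r] > acf[r - 1] or acf[r] > acf[r + 1]):
            delta = _parabolic_offset(acf[r - 1], acf[r], acf[r + 1])
            period = r + delta
            prev_min = float(np.min(acf[1:r + 1]))
            contrast = (float(acf[r]) - prev_min) / float(acf[0])
            valid = contrast >= contrast_threshold and s_min <= period <= s_max
            if not valid:
                continue
            return PeriodEstimate(float(period), True, float(contrast),
                                  "acf_quadratic", float(acf[r]), mat.shape[0])
    return PeriodEstimate.invalid("acf_quadratic", mat.shape[0])


# ---------------------------------------------------------------------------
# top-level dispatcher
# ---------------------------------------------------------------------------

def estimate_period(lines, method: str = "finite", mode: str = "sum",
                    s_min: float = DEFAULT_S_MIN, s_max: float | None = None,
                    contrast_threshold: float = DEFAULT_CONTRAST_THRESHOLD,
                    detrend: bool = False, period_hint: float = 4.5,
                    window: str | None = None) -> PeriodEstimate:
    """Estimate the fundamental period of a set of line profiles.

    Parameters
    ----------
    lines : 2-D array or sequence of 1-D arrays
        Image lines (e.g. the rows of a ROI), all the same length.
    method : {'finite', 'acf', 'acf_periodic', 'fft_spectrum', 'acf_quadratic'}
    mode : {'sum', 'per_line_mean'}
        For similarity methods: either accumulate the per-line curves and
        locate the extremum of the superposition (robust to signal-free
        lines; the default) or locate per line and average the valid
        estimates.  Ignored by the FFT/ACF baselines.
    detrend : bool
        Remove the slowly varying background of each line first (see
        :mod:`sarcfit.detrend`), using ``period_hint``.
    """
    mat = _as_line_matrix(lines)
    if detrend:
        from .detrend import detrend_line

        mat = np.vstack([detrend_line(row, period_hint).oscillatory
                         for row in mat])
    n = mat.shape[1]
    if s_max is None:
        s_max = default_s_max(n, method)

    if method == "fft_spectrum":
        return estimate_period_fft(mat, s_min, s_max, window=window,
                                   contrast_threshold=contrast_threshold)
    if method == "acf_quadratic":
        return estimate_period_acf_quadratic(
            mat, s_min, s_max, contrast_threshold=contrast_threshold)
    if method not in SIMILARITY_METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {ALL_METHODS}")

    curves = [build_similarity(row, method) for row in mat]
    if mode == "sum":
        return locate_fundamental(accumulate_curves(curves), s_min, s_max,
                                  contrast_threshold)
    if mode == "per_line_mean":
        ests = [locate_fundamental(c, s_min, s_max, contrast_threshold)
                for c in curves]
        good = [e for e in ests if e.valid]
        if not good:
            return PeriodEstimate.invalid(method, mat.shape[0])
        period = float(np.mean([e.period_px for e in good]))
        contrast = float(np.mean([e.contrast for e in good]))
        return PeriodEstimate(period, True, contrast, method,
                              float(np.mean([e.extremum_value for e in good])),
                              len(good))
    raise ValueError(f"unknown mode {mode!r}; expected 'sum' or 'per_line_mean'")
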