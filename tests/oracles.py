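"""Independent oracles used by the test suite.

These deliberately avoid the package's semianalytic code paths: similarity
integrals are computed by adaptive quadrature of the piecewise-linear
interpolant, the spectrum peak by an explicitly coded DFT, and the circular
ACF by the direct O(N^2) sum.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad


def _pl_eval(f, x):
    """Scalar piecewise-linear interpolant of samples f at integer nodes."""
    n = len(f)
    if x <= 0.0:
        return f[0]
    if x >= n - 1:
        return f[n - 1]
    k = int(math.floor(x))
    t = x - k
    return f[k] * (1.0 - t) + f[k + 1] * t


def similarity_quad(f, method: str, s: float) -> float:
    """Adaptive-quadrature value of a similarity integral at shift s."""
    f = [float(v) for v in f]
    n = len(f)
    L = n - 1
    if method == "acf_periodic":
        fp = f + [f[0]]

        def g(x):
            return _pl_eval(fp, x % n)

        def integrand(x):
            return g(x + s) * g(x)

        pts = sorted({p for k in range(n + 1)
                      for p in (float(k), (k - s) % n) if 0.0 < p < n})
        val, _ = quad(integrand, 0.0, n, points=pts, limit=50 + 4 * len(pts))
        return val
    hi = L - s
    if hi <= 0.0:
        return 0.0
    if method == "finite":
        def integrand(x):
            return (_pl_eval(f, x + s) - _pl_eval(f, x)) ** 2
    elif method == "acf":
        def integrand(x):
            return _pl_eval(f, x + s) * _pl_eval(f, x)
    else:
        raise ValueError(method)
    pts = sorted({p for k in range(n)
                  for p in (float(k), k - s) if 0.0 < p < hi})
    val, _ = quad(integrand, 0.0, hi, points=pts, limit=50 + 4 * len(pts))
    return val


def dft_peak_period(lines, s_min: float, s_max: float,
                    window: str | None = None) -> float:
    """Spectrum-peak period via an explicitly coded DFT and parabola."""
    mat = np.atleast_2d(np.asarray(lines, dtype=float))
    n = mat.shape[1]
    if window == "hann":
        mat = mat * np.hanning(n)[None, :]
    m = np.arange(n // 2 + 1)
    i = np.arange(n)
    basis = np.exp(-2j * math.pi * np.outer(m, i) / n)
    spec = (np.abs(mat @ basis.T) ** 2).mean(axis=0)
    m_lo = max(1, int(math.ceil(n / s_max)))
    m_hi = min(spec.size - 2, int(math.floor(n / s_min)))
    band = spec[m_lo:m_hi + 1]
    m_star = m_lo + int(np.argmax(band))
    ym1, y0, yp1 = spec[m_star - 1], spec[m_star], spec[m_star + 1]
    denom = 2.0 * (ym1 - 2.0 * y0 + yp1)
    delta = 0.0 if abs(denom) <= 1e-15 * max(abs(y0), 1e-300) else (ym1 - yp1) / denom
    return n / (m_star + delta)


def circular_acf_direct(f) -> np.ndarray:
    """O(N^2) circular autocorrelation of one line."""
    f = np.asarray(f, dtype=float)
    n = f.size
    return np.array([np.sum(f * np.roll(f, -r)) for r in range(n)])


def acf_peak_period(lines, s_min: float, s_max: float) -> float:
    """First-local-max circular-ACF period via the direct sum and parabola."""
    mat = np.atleast_2d(np.asarray(lines, dtype=float))
    acf = np.mean([circular_acf_direct(row) for row in mat], axis=0)
    n = acf.size
    for r in range(max(1, int(math.ceil(s_min))),
                   min(n - 2, int(math.floor(s_max))) + 1):
        if acf[r] >= acf[r - 1] and acf[r] >= acf[r + 1] and \
                (acf[r] > acf[r - 1] or acf[r] > acf[r + 1]):
            ym1, y0, yp1 = acf[r - 1], acf[r], acf[r + 1]
            denom = 2.0 * (ym1 - 2.0 * y0 + yp1)
            delta = 0.0 if abs(denom) <= 1e-15 * abs(y0) else (ym1 - yp1) / denom
            return r + delta
    return math.nan


def count_plateaus(x, moving=None, tol: float = 0.001, run: int = 3) -> int:
    """Number of disjoint runs of `run` consecutive values equal within tol.

    With `moving` (boolean mask), only windows that lie entirely in the
    moving region count -- this excludes stretches where the underlying
    quantity is genuinely constant.
    """
    x = np.asarray(x, dtype=float)
    count = 0
    i = 0
    while i <= len(x) - run:
        if moving is not None and not np.all(moving[i:i + run]):
            i += 1
            continue
        w = x[i:i + run]
        if np.all(np.isfinite(w)) and w.max() - w.min() <= tol:
            count += 1
            i += run
        else:
            i += 1
    return count
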