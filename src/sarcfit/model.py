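"""Model/Results interface for striation-period estimation.

:class:`StriationPeriodModel` bundles the data (image lines or an image +
ROI), the estimator choice and its settings; :meth:`~StriationPeriodModel.fit`
returns a :class:`StriationPeriodResults` carrying the subpixel period, its
physical conversion, a dispersion-based uncertainty from the per-line
estimates, diagnostics and a ``summary()`` table.

Example
-------
>>> import numpy as np
>>> from sarcfit import StriationPeriodModel
>>> lines = np.sin(2 * np.pi * np.arange(50) / 4.3)[None, :].repeat(5, 0)
>>> res = StriationPeriodModel(lines, detrend=False).fit()
>>> round(res.period_px, 2)
4.33
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import similarity as _sim
from .detrend import detrend_line
from .roi import Roi, extract_roi, px_to_um
from .similarity import (SIMILARITY_METHODS, PeriodEstimate, SimilarityCurve,
                         accumulate_curves, build_similarity,
                         locate_fundamental)

__all__ = ["StriationPeriodModel", "StriationPeriodResults"]


class StriationPeriodModel:
    """Fundamental-period model of a set of striation line profiles.

    Parameters
    ----------
    lines : 2-D array or sequence of 1-D arrays
        Image lines (ROI rows).  Use :meth:`from_image` to extract them
        from a full image with a (possibly rotated) ROI.
    method : {'finite', 'acf', 'acf_periodic', 'fft_spectrum', 'acf_quadratic'}
        'finite' is the unbiased finite-extent squared-difference measure;
        the others are the conventional biased baselines.
    mode : {'sum', 'per_line_mean'}
        How per-line similarity measures are combined (see
        :func:`sarcfit.similarity.estimate_period`).
    detrend : bool
        Remove the slowly varying background per line before estimation.
    pixel_size_um : float, optional
        When given, results also report the period in micrometres.
    """

    def __init__(self, lines, method: str = "finite", mode: str = "sum",
                 detrend: bool = True,
                 period_hint: float = 4.5,
                 s_min: float = _sim.DEFAULT_S_MIN,
                 s_max: float | None = None,
                 contrast_threshold: float = _sim.DEFAULT_CONTRAST_THRESHOLD,
                 window: str | None = None,
                 pixel_size_um: float | None = None):
        self.lines = _sim._as_line_matrix(lines)
        self.method = method
        self.mode = mode
        self.detrend = detrend
        self.period_hint = period_hint
        self.s_min = s_min
        self.s_max = (s_max if s_max is not None
                      else _sim.default_s_max(self.lines.shape[1], method))
        self.contrast_threshold = contrast_threshold
        self.window = window
        self.pixel_size_um = pixel_size_um

    @classmethod
    def from_image(cls, image, roi: Roi | None = None, **kwargs
                   ) -> "StriationPeriodModel":
        """Build the model from an image, optionally restricted to a ROI."""
        img = np.asarray(image, dtype=float)
        lines = extract_roi(img, roi) if roi is not None else img
        return cls(lines, **kwargs)

    def fit(self) -> "StriationPeriodResults":
        """Estimate the period and collect per-line diagnostics."""
        work = self.lines
        if self.detrend:
            work = np.vstack([detrend_line(row, self.period_hint).oscillatory
                              for row in work])
        opts = dict(s_min=self.s_min, s_max=self.s_max,
                    contrast_threshold=self.contrast_threshold)
        curve = None
        per_line = np.full(work.shape[0], np.nan)
        if self.method in SIMILARITY_METHODS:
            curves = [build_similarity(row, self.method) for row in work]
            for i, c in enumerate(curves):
                e = locate_fundamental(c, **opts)
                if e.valid:
                    per_line[i] = e.period_px
            curve = accumulate_curves(curves)
            if self.mode == "sum":
                est = locate_fundamental(curve, **opts)
            else:
                est = _sim.estimate_period(work, self.method,
                                           mode="per_line_mean", **opts)
        else:
            est = _sim.estimate_period(work, self.method, window=self.window,
                                       **opts)
        return StriationPeriodResults(model=self, estimate=est, curve=curve,
                                      per_line_period_px=per_line,
                                      detrended_lines=work)


@dataclass
class StriationPeriodResults:
    """Fit results: the subpixel period estimate and its diagnostics."""

    model: StriationPeriodModel
    estimate: PeriodEstimate
    curve: SimilarityCurve | None
    per_line_period_px: np.ndarray
    detrended_lines: np.ndarray = field(repr=False)

    @property
    def valid(self) -> bool:
        return self.estimate.valid

    @property
    def period_px(self) -> float:
        return self.estimate.period_px

    @property
    def contrast(self) -> float:
        return self.estimate.contrast

    @property
    def sl_um(self) -> float:
        """Mean sarcomere length in um (requires ``pixel_size_um``)."""
        if self.model.pixel_size_um is None:
            raise ValueError("model has no pixel_size_um configured")
        return px_to_um(self.period_px, self.model.pixel_size_um)

    @property
    def n_lines_valid(self) -> int:
        return int(np.isfinite(self.per_line_period_px).sum())

    @property
    def period_se_px(self) -> float:
        """Standard error of the per-line estimates (dispersion-based).

        NaN when fewer than two lines produced a valid per-line estimate
        (e.g. for the FFT/ACF baselines, which pool lines in the spectrum).
        """
        good = self.per_line_period_px[np.isfinite(self.per_line_period_px)]
        if good.size < 2:
            return math.nan
        return float(good.std(ddof=1) / math.sqrt(good.size))

    def summary(self) -> str:
        m = self.model
        lines = [
            "Striation period fit",
            "=" * 44,
            f"method:            {m.method} ({m.mode})",
            f"lines (valid):     {m.lines.shape[0]} ({self.n_lines_valid})",
            f"samples per line:  {m.lines.shape[1]}",
            f"search bounds px:  [{m.s_min:g}, {m.s_max:g}]",
            f"detrend:           {m.detrend} (hint {m.period_hint:g} px)",
            "-" * 44,
            f"valid:             {self.valid}",
            f"period [px]:       {self.period_px:.4f}",
            f"period s.e. [px]:  {self.period_se_px:.4f}",
            f"contrast:          {self.contrast:.3f}",
        ]
        if m.pixel_size_um is not None and self.valid:
            lines.append(f"sarcomere length:  {self.sl_um:.4f} um "
                         f"({m.pixel_size_um:g} um/px)")
        return "\n".join(lines)

    def plot_curve(self, ax=None, n_points: int = 500):
        """Plot the (accumulated) similarity curve with the extremum marked."""
        if self.curve is None:
            raise ValueError("no similarity curve (FFT/ACF baseline fit)")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = np.linspace(0.0, self.curve.support, n_points)
        ax.plot(s, self.curve(s), label=f"F ({self.curve.method})")
        if self.valid:
            ax.axvline(self.period_px, color="C3", ls="--",
                       label=f"period = {self.period_px:.3f} px")
        ax.set_xlabel("shift s [px]")
        ax.set_ylabel("similarity measure")
        ax.legend()
        return ax
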