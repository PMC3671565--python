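"""Image-stack and trace I/O plus run configuration.

TIFF (single/multi-page, integer or float) is the native stack format;
PNG files, sequences or directories are also accepted.  Integer pixel data
are promoted to float64 without rescaling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .roi import DEFAULT_FRAME_INTERVAL_S, DEFAULT_PIXEL_SIZE_UM, SarcomereTrace

__all__ = [
    "StackFormatError",
    "RunConfig",
    "read_image_stack",
    "write_image_stack",
    "write_trace_csv",
    "read_trace_csv",
]


class StackFormatError(ValueError):
    """Unreadable stack or mixed frame shapes."""


def read_image_stack(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack, a PNG, or a directory/sequence of PNGs.

    Returns ``(frames, metadata)`` with ``frames`` of shape (F, H, W) in
    float64 (integer pixels promoted without rescaling).  Mixed frame shapes
    raise :class:`StackFormatError` naming the offending frame.
    """
    if isinstance(path, (list, tuple)):
        frames = [_read_single(Path(p)) for p in path]
        return _stack_frames(frames, [str(p) for p in path])
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if p.is_dir():
        pngs = sorted(p.glob("*.png"))
        if not pngs:
            raise StackFormatError(f"no PNG files found in directory {p}")
        return _stack_frames([_read_single(q) for q in pngs],
                             [str(q) for q in pngs])
    if p.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(p) as tf:
            pages = [pg.asarray() for pg in tf.pages]
        if not pages:
            raise StackFormatError(f"{p} contains no pages")
        return _stack_frames(pages, [f"{p}#page{i}" for i in range(len(pages))])
    if p.suffix.lower() == ".png":
        return _stack_frames([_read_single(p)], [str(p)])
    raise StackFormatError(f"unsupported stack format: {p.suffix!r} ({p})")


def _read_single(p: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(p)
    if arr.ndim == 3:          # collapse RGB(A) to luminance-free first channel
        arr = arr[..., 0]
    return arr


def _stack_frames(frames, names) -> tuple[np.ndarray, dict]:
    shape0 = np.asarray(frames[0]).shape
    for i, f in enumerate(frames):
        if np.asarray(f).shape != shape0:
            raise StackFormatError(
                f"frame {names[i]} has shape {np.asarray(f).shape}, "
                f"expected {shape0}"
            )
        if np.asarray(f).ndim != 2:
            raise StackFormatError(f"frame {names[i]} is not 2-D")
    arr = np.stack([np.asarray(f, dtype=np.float64) for f in frames])
    return arr, {"n_frames": arr.shape[0], "shape": shape0,
                 "source_dtype": str(np.asarray(frames[0]).dtype)}


def write_image_stack(frames, path) -> None:
    """Write a float stack as multi-page TIFF (value-exact round trip)."""
    import tifffile

    arr = np.asarray(frames, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    tifffile.imwrite(path, arr, photometric="minisblack")


def write_trace_csv(trace: SarcomereTrace, path) -> None:
    """Write a trace as CSV (one row per frame, full float precision).

    Invalid frames keep their row with ``valid=False`` and empty sl/rate
    cells.
    """
    df = trace.to_frame()
    df.to_csv(path, index=False, na_rep="")


def read_trace_csv(path) -> pd.DataFrame:
    """Read back a trace CSV (empty cells as NaN)."""
    return pd.read_csv(path, float_precision="round_trip")


_CONFIG_DEFAULTS = dict(
    input=None,
    output=None,
    method="finite",
    mode="sum",
    pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
    frame_interval_s=DEFAULT_FRAME_INTERVAL_S,
    s_min=2.0,
    s_max=None,
    contrast_threshold=0.1,
    detrend=True,
    period_hint=4.5,
    roi_center=None,
    roi_height=31,
    roi_width=54,
    roi_angle_deg=0.0,
    window=None,
    seed=0,
    log_level="INFO",
)

_VALID_METHODS = ("finite", "acf", "acf_periodic", "fft_spectrum",
                  "acf_quadratic")


@dataclass
class RunConfig:
    """Validated run configuration (CLI flags / YAML file)."""

    input: str | None = None
    output: str | None = None
    method: str = "finite"
    mode: str = "sum"
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    s_min: float = 2.0
    s_max: float | None = None
    contrast_threshold: float = 0.1
    detrend: bool = True
    period_hint: float = 4.5
    roi_center: tuple[float, float] | None = None
    roi_height: int = 31
    roi_width: int = 54
    roi_angle_deg: float = 0.0
    window: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.method not in _VALID_METHODS:
            raise ValueError(f"method must be one of {_VALID_METHODS}")
        if self.mode not in ("sum", "per_line_mean"):
            raise ValueError("mode must be 'sum' or 'per_line_mean'")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be > 0")
        if self.s_min <= 0 or (self.s_max is not None and self.s_max <= self.s_min):
            raise ValueError("need 0 < s_min < s_max")
        if not 0 <= self.contrast_threshold <= 1:
            raise ValueError("contrast_threshold must be in [0, 1]")
        if self.period_hint < 3:
            raise ValueError("period_hint must be >= 3 px")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if data.get("roi_center") is not None:
            data = dict(data)
            data["roi_center"] = tuple(float(x) for x in data["roi_center"])
        return cls(**data)

    def estimator_options(self) -> dict:
        return dict(method=self.method, mode=self.mode, s_min=self.s_min,
                    s_max=self.s_max,
                    contrast_threshold=self.contrast_threshold,
                    detrend=self.detrend, period_hint=self.period_hint,
                    window=self.window)
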