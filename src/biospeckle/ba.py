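"""Biospeckle activity: frame-pair correlation and BA time-courses.

The temporal correlation between a reference frame A and a later frame B
is the centered, normalized cross-correlation over pixels (m, n),

    r = sum_mn (A_mn - Abar)(B_mn - Bbar)
        / sqrt( sum_mn (A_mn - Abar)^2 * sum_mn (B_mn - Bbar)^2 ),

and the biospeckle activity is BA = 1 - r: zero for a static scene,
approaching one when the speckle has fully decorrelated, with 2 as the
algebraic upper bound (r = -1).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .errors import DegenerateFrameError, EstimationFailureError, WindowError

__all__ = [
    "BACurve",
    "CurveSummary",
    "correlation",
    "ba",
    "ba_curve",
    "estimate_speckle_size",
    "summarize_curve",
    "curve_to_csv",
    "curve_from_csv",
]


def _as_float_frame(frame: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(frame, dtype=np.float64)
    if arr.size < 2:
        raise DegenerateFrameError(f"{name} needs at least 2 pixels")
    if not np.all(np.isfinite(arr)):
        raise DegenerateFrameError(f"{name} contains non-finite values")
    return arr


def correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Centered normalized cross-correlation between two equal-shape frames.

    Frames are promoted to float64 first, so integer gray levels cannot
    overflow. Raises :class:`DegenerateFrameError` on zero-variance
    input rather than returning NaN.
    """
    a = _as_float_frame(a, "frame A")
    b = _as_float_frame(b, "frame B")
    if a.shape != b.shape:
        raise DegenerateFrameError(f"frame shapes differ: {a.shape} vs {b.shape}")
    ac = a - a.mean()
    bc = b - b.mean()
    ssa = float((ac * ac).sum())
    ssb = float((bc * bc).sum())
    if ssa == 0.0:
        raise DegenerateFrameError("reference frame has zero variance")
    if ssb == 0.0:
        raise DegenerateFrameError("comparison frame has zero variance")
    return float((ac * bc).sum() / np.sqrt(ssa * ssb))


def ba(a: np.ndarray, b: np.ndarray) -> float:
    """Biospeckle activity of a frame pair: 1 - correlation, in [0, 2]."""
    return 1.0 - correlation(a, b)


@dataclass
class BACurve:
    """Per-lag BA against the reference frame, with replicate provenance."""

    lags: np.ndarray
    times: np.ndarray
    ba: np.ndarray
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.ba = np.asarray(self.ba, dtype=float)
        if not (len(self.lags) == len(self.times) == len(self.ba)):
            raise ValueError("lags, times and ba must have equal length")

    @property
    def span_s(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0


def _resolve_roi(shape: tuple[int, int], roi) -> tuple:
    if roi is None:
        return (slice(None), slice(None))
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != shape:
            raise ValueError(f"boolean ROI shape {roi.shape} does not match frame {shape}")
        return (roi,)
    ry, rx = roi
    if ry.stop is not None and ry.stop > shape[0] or rx.stop is not None and rx.stop > shape[1]:
        raise ValueError("ROI exceeds frame bounds")
    return (ry, rx)


def ba_curve(sequence, roi=None, fps: float | None = None) -> BACurve:
    """BA of frame k against frame 0, for k = 1 .. n_frames - 1.

    ``sequence`` is a :class:`~biospeckle.synthetic.SpeckleSequence` or a
    bare (n_frames, h, w) array (then ``fps`` is required). ``roi``
    restricts the correlation to a sub-region: a (slice, slice) pair or
    a boolean mask.
    """
    if hasattr(sequence, "frames"):
        frames = np.asarray(sequence.frames)
        fps = sequence.fps
        meta = dict(sequence.meta)
    else:
        frames = np.asarray(sequence)
        if fps is None:
            raise ValueError("fps is required when passing a bare frame array")
        meta = {"fps": fps}
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (n_frames >= 2, h, w) stack")

    sel = _resolve_roi(frames.shape[1:], roi)
    data = frames[(slice(None),) + sel].reshape(frames.shape[0], -1).astype(np.float64)
    centered = data - data.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", centered, centered)
    zero = np.flatnonzero(ss == 0.0)
    if zero.size:
        raise DegenerateFrameError(f"frame {zero[0]} has zero variance within the ROI")
    num = centered[1:] @ centered[0]
    r = num / np.sqrt(ss[1:] * ss[0])
    lags = np.arange(1, frames.shape[0])
    return BACurve(lags=lags, times=lags / fps, ba=1.0 - r, meta=meta)


# ---------------------------------------------------------------------------
# Speckle-size estimation


def _radial_profile(c: np.ndarray) -> np.ndarray:
    h, w = c.shape
    cy, cx = h // 2, w // 2
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    nbins = min(h, w) // 2
    idx = np.clip(np.rint(r).astype(int), 0, nbins)
    prof = np.bincount(idx.ravel(), weights=c.ravel(), minlength=nbins + 1)
    counts = np.bincount(idx.ravel(), minlength=nbins + 1)
    return prof[:nbins] / counts[:nbins]


def estimate_speckle_size(frame: np.ndarray) -> float:
    """Speckle size in pixels: FWHM of the radially averaged normalized
    intensity autocovariance, after subtracting the large-lag background.
    """
    arr = _as_float_frame(frame, "frame")
    arr = arr - arr.mean()
    var = float((arr**2).mean())
    if var == 0.0:
        raise DegenerateFrameError("frame has zero variance")
    spec = np.abs(np.fft.fft2(arr)) ** 2
    cov = np.fft.fftshift(np.fft.ifft2(spec).real) / arr.size / var
    prof = _radial_profile(cov)
    background = float(np.median(prof[len(prof) // 2 :]))
    prof = (prof - background) / (prof[0] - background)
    below = np.flatnonzero(prof <= 0.5)
    if below.size == 0 or below[0] == 0:
        raise EstimationFailureError("autocovariance half-width not bracketed")
    i = below[0]
    # linear interpolation between radius bins i-1 and i
    r_half = (i - 1) + (prof[i - 1] - 0.5) / (prof[i - 1] - prof[i])
    return float(2.0 * r_half)


# ---------------------------------------------------------------------------
# Curve summaries


@dataclass(frozen=True)
class CurveSummary:
    """Early-window mean BA, late plateau mean BA, and the initial
    least-squares slope (BA per second) of one curve."""

    early_mean: float
    plateau_mean: float
    initial_slope: float


def summarize_curve(
    curve: BACurve,
    early_window_s: float = 5.0,
    plateau_window_s: float = 5.0,
) -> CurveSummary:
    """Summarize a BA curve: mean over 0 < t <= early_window_s, mean over
    the final plateau_window_s, and the least-squares slope over the
    early window."""
    span = curve.span_s
    if span < early_window_s or span < plateau_window_s:
        raise WindowError(
            f"curve spans {span:.3f} s, shorter than the requested window"
        )
    t, y = curve.times, curve.ba
    early = (t > 0) & (t <= early_window_s)
    plateau = t > span - plateau_window_s
    slope = float(np.polyfit(t[early], y[early], 1)[0]) if early.sum() >= 2 else 0.0
    return CurveSummary(
        early_mean=float(y[early].mean()),
        plateau_mean=float(y[plateau].mean()),
        initial_slope=slope,
    )


# ---------------------------------------------------------------------------
# Serialization


def curve_to_csv(curve: BACurve, path: str | Path) -> None:
    """Write a BA curve as CSV with metadata in '#' header lines."""
    with open(path, "w") as fh:
        for key in sorted(curve.meta):
            fh.write(f"# {key}={curve.meta[key]}\n")
        fh.write("lag,time_s,ba\n")
        for lag, t, v in zip(curve.lags, curve.times, curve.ba):
            fh.write(f"{lag},{t:.9g},{v:.12g}\n")


def curve_from_csv(path: str | Path) -> BACurve:
    meta: dict = {}
    body = _io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
            else:
                body.write(line)
    body.seek(0)
    data = np.genfromtxt(body, delimiter=",", names=True)
    data = np.atleast_1d(data)
    return BACurve(lags=data["lag"], times=data["time_s"], ba=data["ba"], meta=meta)
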