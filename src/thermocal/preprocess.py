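"""Spectral preprocessing: range selection, Savitzky-Golay first
derivative and mean centering.

The derivative is the slope of a local least-squares quadratic fit over a
moving odd-length window, reported per axis unit (per nm or per cm^-1).
Edges are trimmed -- (window-1)/2 points per side -- rather than padded,
so derivative values never rest on extrapolated data; the axis is cropped
to match.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .exceptions import AxisSpacingError, ParameterError, RangeError
from .spectra_core import SpectralAxis, SpectralDataset


@dataclass(frozen=True)
class PreprocessSpec:
    """Range + optional first-derivative filtering applied before modelling.

    ``sg_window`` is the odd filter width in points (``None`` disables the
    derivative); ``sg_polyorder`` is fixed at 2 (local quadratic).
    ``center`` records that models built downstream mean-centre the data
    (centering itself is fitted inside PLS so validation data use the
    calibration means).
    """

    range_lo: float
    range_hi: float
    sg_window: int | None = None
    sg_polyorder: int = 2
    center: bool = True

    def __post_init__(self) -> None:
        if not self.range_lo < self.range_hi:
            raise ParameterError("range_lo must be < range_hi")
        if self.sg_window is not None:
            _check_window(self.sg_window, self.sg_polyorder)

    def apply(self, dataset: SpectralDataset) -> SpectralDataset:
        """Derivative (on the full axis) first, then range selection, so
        the requested range is retained in full."""
        out = dataset
        if self.sg_window is not None:
            out = sg_first_derivative(out, self.sg_window)
        return crop_range(out, self.range_lo, self.range_hi)

    def to_dict(self) -> dict:
        return {
            "range_lo": self.range_lo,
            "range_hi": self.range_hi,
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "center": self.center,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessSpec":
        return cls(
            range_lo=float(d["range_lo"]),
            range_hi=float(d["range_hi"]),
            sg_window=None if d.get("sg_window") in (None, "") else int(d["sg_window"]),
            sg_polyorder=int(d.get("sg_polyorder", 2)),
            center=bool(d.get("center", True)),
        )


def _check_window(window: int, polyorder: int = 2) -> None:
    if window % 2 == 0:
        raise ParameterError(f"filter window must be odd, got {window}")
    if window < 5:
        raise ParameterError(f"filter window must be >= 5 points, got {window}")
    if window <= polyorder:
        raise ParameterError("filter window must exceed the polynomial order")


def crop_range(dataset: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Retain axis points v with lo <= v <= hi (closed interval)."""
    mask = (dataset.axis.values >= lo) & (dataset.axis.values <= hi)
    if not mask.any():
        raise RangeError(
            f"range [{lo}, {hi}] retains no axis points "
            f"(axis spans [{dataset.axis.values[0]:g}, {dataset.axis.values[-1]:g}])"
        )
    axis = SpectralAxis(kind=dataset.axis.kind, values=dataset.axis.values[mask])
    return SpectralDataset(
        axis=axis,
        intensities=dataset.intensities[:, mask].copy(),
        meta=list(dataset.meta),
        preprocessing=dataset.preprocessing,
    )


def sg_first_derivative(dataset: SpectralDataset, window: int) -> SpectralDataset:
    """Savitzky-Golay first derivative (local quadratic), edges trimmed.

    Requires a uniformly spaced axis (relative tolerance 1e-6).  Output
    units are input units per axis unit; the preprocessing tag is extended
    with ``:sg{window}d1``.
    """
    _check_window(window)
    axis = dataset.axis
    if len(axis) < window:
        raise ParameterError(
            f"window ({window}) exceeds axis length ({len(axis)})"
        )
    if not axis.is_uniform(rtol=1e-6):
        raise AxisSpacingError("derivative filtering requires a uniformly spaced axis")
    h = axis.spacing
    half = (window - 1) // 2

    deriv = savgol_filter(
        dataset.intensities, window_length=window, polyorder=2, deriv=1,
        delta=h, axis=1, mode="interp",
    )
    deriv = deriv[:, half:-half]
    new_axis = SpectralAxis(kind=axis.kind, values=axis.values[half:-half])
    return SpectralDataset(
        axis=new_axis,
        intensities=deriv,
        meta=list(dataset.meta),
        preprocessing=f"{dataset.preprocessing}:sg{window}d1",
    )


def fit_center(X: np.ndarray) -> np.ndarray:
    """Column means of a calibration matrix, for reuse on new data."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ParameterError("fit_center needs a 2-D matrix with >= 1 row")
    return X.mean(axis=0)


def apply_center(X: np.ndarray, mean: np.ndarray) -> np.ndarray:
    """Subtract a stored mean vector (calibration means, not the data's own)."""
    X = np.asarray(X, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != mean.shape[0]:
        raise ParameterError(
            f"matrix has {X.shape[1]} columns but mean vector has {mean.shape[0]}"
        )
    return X - mean[None, :]
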