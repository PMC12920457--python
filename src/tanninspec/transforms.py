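"""The 12 spectral forms: reflectance R and 11 mathematical transformations.

Point transforms (1/R, lgR, lg(1/R); lg = log10) are element-wise after an
epsilon clamp.  Derivatives are divided differences along the wavenumber
axis (robust to non-uniform grids), applied iteratively for second order;
each derivative shortens the axis by one band and moves it to the midpoints
of consecutive wavenumbers.  No smoothing is applied before differentiation
by default (flag available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .datasets import SampleSpectrumSet

logger = logging.getLogger(__name__)

__all__ = ["TRANSFORM_TAGS", "TransformedSpectra", "SpectralTransformer", "apply_transform", "transform_bank"]

#: Canonical ordering of the 12 spectral forms.
TRANSFORM_TAGS = (
    "R", "1/R", "lgR", "lg(1/R)",
    "R'", "(1/R)'", "lg'R", "lg'(1/R)",
    "R''", "(1/R)''", "lg''R", "lg''(1/R)",
)

# tag -> (base form, derivative order)
_TAG_SPEC = {
    "R": ("R", 0), "1/R": ("1/R", 0), "lgR": ("lgR", 0), "lg(1/R)": ("lg(1/R)", 0),
    "R'": ("R", 1), "(1/R)'": ("1/R", 1), "lg'R": ("lgR", 1), "lg'(1/R)": ("lg(1/R)", 1),
    "R''": ("R", 2), "(1/R)''": ("1/R", 2), "lg''R": ("lgR", 2), "lg''(1/R)": ("lg(1/R)", 2),
}

EPSILON = 1e-9


@dataclass
class TransformedSpectra:
    """A (sample x band') matrix under one spectral form, with its axis."""

    tag: str
    values: np.ndarray
    wavenumbers: np.ndarray
    sample_ids: np.ndarray
    n_clamped: int = 0


def _point_transform(values: np.ndarray, base: str, epsilon: float) -> tuple:
    n_clamped = 0
    if base != "R":
        n_clamped = int((values < epsilon).sum())
        if n_clamped:
            logger.warning("clamped %d reflectance cells below epsilon=%g", n_clamped, epsilon)
        values = np.maximum(values, epsilon)
    if base == "R":
        out = values
    elif base == "1/R":
        out = 1.0 / values
    elif base == "lgR":
        out = np.log10(values)
    elif base == "lg(1/R)":
        out = -np.log10(values)
    else:  # pragma: no cover - guarded by _TAG_SPEC lookup
        raise ValueError(base)
    return out, n_clamped


def divided_difference(values: np.ndarray, wavenumbers: np.ndarray) -> tuple:
    """First divided difference along the band axis, midpoint output grid."""
    dv = np.diff(values, axis=-1)
    dw = np.diff(wavenumbers)
    return dv / dw, 0.5 * (wavenumbers[1:] + wavenumbers[:-1])


class SpectralTransformer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer applying one of the 12 spectral forms.

    Parameters
    ----------
    tag : str
        One of :data:`TRANSFORM_TAGS`.
    wavenumbers : array or None
        Band axis used for divided differences; unit spacing if None.
    epsilon : float
        Clamp for log/reciprocal guards.
    smooth_window, smooth_polyorder : Savitzky-Golay smoothing applied before
        differentiation when ``smooth_window`` is set (default off).
    """

    def __init__(self, tag="R", wavenumbers=None, epsilon=EPSILON, smooth_window=None, smooth_polyorder=2):
        self.tag = tag
        self.wavenumbers = wavenumbers
        self.epsilon = epsilon
        self.smooth_window = smooth_window
        self.smooth_polyorder = smooth_polyorder

    def fit(self, X, y=None):
        if self.tag not in _TAG_SPEC:
            raise ValueError(f"unknown transform tag {self.tag!r}; expected one of {TRANSFORM_TAGS}")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x bands)")
        self.n_features_in_ = X.shape[1]
        w = self.wavenumbers
        self.input_wavenumbers_ = np.arange(X.shape[1], dtype=float) if w is None else np.asarray(w, dtype=float)
        if self.input_wavenumbers_.size != X.shape[1]:
            raise ValueError("wavenumbers length must match number of bands")
        _, order = _TAG_SPEC[self.tag]
        axis = self.input_wavenumbers_
        for _ in range(order):
            axis = 0.5 * (axis[1:] + axis[:-1])
        self.output_wavenumbers_ = axis
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        base, order = _TAG_SPEC[self.tag]
        values, n_clamped = _point_transform(X, base, self.epsilon)
        if order and self.smooth_window:
            values = savgol_filter(values, self.smooth_window, self.smooth_polyorder, axis=-1)
        axis = self.input_wavenumbers_
        for _ in range(order):
            values, axis = divided_difference(values, axis)
        self.n_clamped_ = n_clamped
        if not np.all(np.isfinite(values)):
            raise FloatingPointError(f"non-finite values after transform {self.tag!r}")
        return values


def apply_transform(spectra: SampleSpectrumSet, tag: str, epsilon: float = EPSILON) -> TransformedSpectra:
    """Apply one spectral form to a per-sample spectrum set."""
    tr = SpectralTransformer(tag=tag, wavenumbers=spectra.wavenumbers, epsilon=epsilon)
    values = tr.fit(spectra.reflectance).transform(spectra.reflectance)
    return TransformedSpectra(
        tag=tag,
        values=values,
        wavenumbers=tr.output_wavenumbers_,
        sample_ids=spectra.sample_ids.copy(),
        n_clamped=tr.n_clamped_,
    )


def transform_bank(spectra: SampleSpectrumSet, epsilon: float = EPSILON) -> list:
    """All 12 spectral forms in canonical order."""
    return [apply_transform(spectra, tag, epsilon=epsilon) for tag in TRANSFORM_TAGS]
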