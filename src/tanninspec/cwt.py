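"""Continuous wavelet transform of spectra at dyadic scales.

The transform of spectrum v is the discrete approximation of

    w(a, b) = integral v(j) * (1/sqrt(a)) * psi((j - b) / a) dj

where j is the band index (unit spacing), a the scale and b the translation,
evaluated at every band index b so the output has the same length as the
input.  The default mother wavelet is gaus4, the fourth derivative of the
Gaussian exp(-t^2/2), sign-normalised so psi(0) > 0 and scaled to unit L2
norm:

    psi(t) = (105 sqrt(pi) / 16)^(-1/2) * (t^4 - 6 t^2 + 3) * exp(-t^2/2)

Boundaries use symmetric reflection; the boundary-affected half-width per
scale is reported in the feature metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator, TransformerMixin

from .transforms import TransformedSpectra

__all__ = [
    "DEFAULT_SCALES",
    "mother_wavelet",
    "cwt_spectrum",
    "cwt_features",
    "WaveletFeatures",
    "CWTFeaturizer",
]

#: Dyadic scales 2^1 .. 2^10.
DEFAULT_SCALES = tuple(2**k for k in range(1, 11))

#: Effective support half-width of the supported wavelets (|psi| < ~1e-13 outside).
_SUPPORT = 8.0

_GAUS4_NORM = (105.0 * np.sqrt(np.pi) / 16.0) ** -0.5


def mother_wavelet(t, wavelet_id: str = "gaus4") -> np.ndarray:
    """Evaluate the mother wavelet at (dimensionless) ``t``.

    gaus4 is required; mexh and morl are optional extras.  All are even and
    scaled to unit L2 norm; gaus4 and mexh are exactly zero-mean.
    """
    t = np.asarray(t, dtype=float)
    if wavelet_id == "gaus4":
        return _GAUS4_NORM * (t**4 - 6.0 * t**2 + 3.0) * np.exp(-0.5 * t**2)
    if wavelet_id == "mexh":
        norm = 2.0 / (np.sqrt(3.0) * np.pi**0.25)
        return norm * (1.0 - t**2) * np.exp(-0.5 * t**2)
    if wavelet_id == "morl":
        return np.pi**-0.25 * np.cos(5.0 * t) * np.exp(-0.5 * t**2)
    raise ValueError(f"unsupported wavelet_id {wavelet_id!r} (supported: gaus4, mexh, morl)")


def _kernel(scale: float, wavelet_id: str) -> np.ndarray:
    half = int(np.ceil(_SUPPORT * scale))
    m = np.arange(-half, half + 1, dtype=float)
    return mother_wavelet(m / scale, wavelet_id) / np.sqrt(scale)


def cwt_spectrum(signal, scales, wavelet_id: str = "gaus4") -> np.ndarray:
    """CWT coefficient rows, one per scale, same length as ``signal``.

    Accepts a 1-D signal or a 2-D (samples x bands) matrix; for a matrix the
    result has shape (n_scales, n_samples, n_bands).
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    n = x.shape[1]
    if n < 2:
        raise ValueError("signal must have at least 2 bands")
    scales = [float(a) for a in np.atleast_1d(scales)]
    for a in scales:
        if a <= 0:
            raise ValueError("scales must be positive")
        if a > n:
            raise ValueError(f"scale {a} exceeds signal length {n}")
    out = np.empty((len(scales), x.shape[0], n))
    for k, a in enumerate(scales):
        ker = _kernel(a, wavelet_id)
        half = (ker.size - 1) // 2
        padded = np.pad(x, ((0, 0), (half, half)), mode="symmetric")
        # correlation with an even kernel == convolution
        conv = fftconvolve(padded, ker[None, :], mode="same", axes=1)
        out[k] = conv[:, half : half + n]
    if np.ndim(signal) == 1:
        return out[:, 0, :]
    return out


@dataclass
class WaveletFeatures:
    """Per-scale coefficient matrices of one spectral form."""

    source_tag: str
    wavelet_id: str
    scales: tuple
    coefficients: dict  # scale -> (n_samples, n_bands) matrix
    wavenumbers: np.ndarray
    sample_ids: np.ndarray
    boundary_halfwidth: dict = field(default_factory=dict)  # scale -> bands affected

    def matrix(self, scale) -> np.ndarray:
        return self.coefficients[scale]


def cwt_features(
    spectra: TransformedSpectra,
    scales=DEFAULT_SCALES,
    wavelet_id: str = "gaus4",
) -> WaveletFeatures:
    """Row-wise CWT of a transformed spectrum set at the given scales."""
    coeffs = cwt_spectrum(spectra.values, scales, wavelet_id)
    scales = tuple(float(a) for a in np.atleast_1d(scales))
    return WaveletFeatures(
        source_tag=spectra.tag,
        wavelet_id=wavelet_id,
        scales=scales,
        coefficients={a: coeffs[k] for k, a in enumerate(scales)},
        wavenumbers=np.asarray(spectra.wavenumbers).copy(),
        sample_ids=np.asarray(spectra.sample_ids).copy(),
        boundary_halfwidth={a: int(np.ceil(_SUPPORT * a / 2)) for a in scales},
    )


class CWTFeaturizer(BaseEstimator, TransformerMixin):
    """sklearn transformer producing CWT coefficients at a single scale."""

    def __init__(self, scale=2.0, wavelet_id="gaus4"):
        self.scale = scale
        self.wavelet_id = wavelet_id

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x bands)")
        if self.scale > X.shape[1]:
            raise ValueError(f"scale {self.scale} exceeds signal length {X.shape[1]}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return cwt_spectrum(X, [self.scale], self.wavelet_id)[0]
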