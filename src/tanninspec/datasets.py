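"""In-memory containers for spectral scans and tannin references.

A :class:`SpectrumSet` holds raw replicate scans (one row per scan); a
:class:`SampleSpectrumSet` holds one averaged spectrum per sample.  Both keep
the wavenumber axis (cm^-1, strictly ascending) alongside the reflectance
matrix.  Reference tannin contents (mg/g, one value per sample) live in a
:class:`TanninTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SpectrumSet", "SampleSpectrumSet", "TanninTable"]


def _check_axis(wavenumbers: np.ndarray) -> np.ndarray:
    w = np.asarray(wavenumbers, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise ValueError("wavenumber axis must be 1-D with at least 2 bands")
    if not np.all(np.diff(w) > 0):
        raise ValueError("wavenumbers must be strictly increasing")
    return w


@dataclass
class SpectrumSet:
    """Replicate reflectance scans on a shared wavenumber grid.

    Parameters
    ----------
    wavenumbers : (n_bands,) array, strictly increasing, cm^-1.
    reflectance : (n_scans, n_bands) array, dimensionless in (0, 1].
    sample_ids : (n_scans,) int array, one id per scan.
    replicate_index : (n_scans,) int array, 0-based replicate number.
    management_mode : (n_scans,) str array, orchard-management label.
    """

    wavenumbers: np.ndarray
    reflectance: np.ndarray
    sample_ids: np.ndarray
    replicate_index: np.ndarray
    management_mode: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = _check_axis(self.wavenumbers)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        self.replicate_index = np.asarray(self.replicate_index)
        self.management_mode = np.asarray(self.management_mode, dtype=object)
        n, b = self.reflectance.shape
        if b != self.wavenumbers.size:
            raise ValueError("reflectance width does not match wavenumber axis")
        for name in ("sample_ids", "replicate_index", "management_mode"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must have one entry per scan")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if np.any(self.reflectance <= 0):
            raise ValueError("reflectance must be strictly positive")
        counts = pd.Series(self.sample_ids).value_counts()
        if counts.nunique() > 1:
            raise ValueError("every sample must have the same replicate count")

    @property
    def n_scans(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def unique_sample_ids(self) -> np.ndarray:
        return pd.unique(self.sample_ids)

    def copy(self) -> "SpectrumSet":
        return SpectrumSet(
            self.wavenumbers.copy(),
            self.reflectance.copy(),
            self.sample_ids.copy(),
            self.replicate_index.copy(),
            self.management_mode.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table: sample_id, replicate, mode, then one column per band."""
        meta = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "replicate": self.replicate_index,
                "mode": self.management_mode,
            }
        )
        spec = pd.DataFrame(self.reflectance, columns=[f"{w:.4f}".rstrip("0").rstrip(".") for w in self.wavenumbers])
        return pd.concat([meta, spec], axis=1)


@dataclass
class SampleSpectrumSet:
    """One spectrum per sample, typically the mean of its replicate scans."""

    wavenumbers: np.ndarray
    reflectance: np.ndarray
    sample_ids: np.ndarray
    management_mode: np.ndarray
    n_replicates_averaged: int = 1

    def __post_init__(self) -> None:
        self.wavenumbers = _check_axis(self.wavenumbers)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        self.management_mode = np.asarray(self.management_mode, dtype=object)
        n, b = self.reflectance.shape
        if b != self.wavenumbers.size:
            raise ValueError("reflectance width does not match wavenumber axis")
        if self.sample_ids.shape != (n,) or self.management_mode.shape != (n,):
            raise ValueError("per-sample metadata must have one entry per row")
        if pd.Series(self.sample_ids).duplicated().any():
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def subset(self, sample_ids) -> "SampleSpectrumSet":
        keep = np.isin(self.sample_ids, np.asarray(list(sample_ids)))
        return SampleSpectrumSet(
            self.wavenumbers.copy(),
            self.reflectance[keep].copy(),
            self.sample_ids[keep].copy(),
            self.management_mode[keep].copy(),
            self.n_replicates_averaged,
        )


@dataclass
class TanninTable:
    """Per-sample reference tannin content in mg/g."""

    table: pd.Series  # index: sample_id, values: tannin mg/g

    def __post_init__(self) -> None:
        self.table = pd.Series(self.table, dtype=float)
        self.table.index.name = "sample_id"
        self.table.name = "tannin_mg_g"
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample_id in tannin table")
        if not np.all(np.isfinite(self.table.to_numpy())):
            raise ValueError("tannin values must be finite")
        if np.any(self.table.to_numpy() <= 0):
            raise ValueError("tannin values must be positive")

    def values_for(self, sample_ids) -> np.ndarray:
        ids = np.asarray(sample_ids)
        missing = set(ids) - set(self.table.index)
        if missing:
            raise KeyError(f"sample ids missing from tannin table: {sorted(missing)}")
        return self.table.loc[ids].to_numpy()

    @property
    def sample_ids(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def copy(self) -> "TanninTable":
        return TanninTable(self.table.copy())

    def subset(self, sample_ids) -> "TanninTable":
        keep = [s for s in self.table.index if s in set(sample_ids)]
        return TanninTable(self.table.loc[keep].copy())
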