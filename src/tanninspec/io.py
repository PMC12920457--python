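"""Reading/writing wide spectral CSV tables and replicate averaging.

Format: comma-separated, UTF-8, '.' decimal.  Header is
``sample_id,replicate,mode,<wavenumber_1>,...,<wavenumber_n>`` with
wavenumber column names printed to at most 4 decimal places.  Reflectance
values round-trip bit-exactly (written with repr precision).  Files with a
descending wavenumber axis are accepted and flipped with a logged notice.
JCAMP-DX and vendor binary formats (SPA/OPUS) are out of scope.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datasets import SampleSpectrumSet, SpectrumSet, TanninTable

logger = logging.getLogger(__name__)

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_tannin_csv",
    "read_tannin_csv",
    "average_replicates",
]

_META_COLS = ("sample_id", "replicate", "mode")


def _fmt_wavenumber(w: float) -> str:
    s = f"{w:.4f}".rstrip("0").rstrip(".")
    return s


def write_spectra_csv(spectra: SpectrumSet, path) -> None:
    """Write scans as a wide CSV (one row per scan)."""
    cols = [_fmt_wavenumber(w) for w in spectra.wavenumbers]
    df = pd.DataFrame(spectra.reflectance, columns=cols)
    df.insert(0, "mode", spectra.management_mode)
    df.insert(0, "replicate", spectra.replicate_index)
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path) -> SpectrumSet:
    """Read and validate a wide spectral CSV.

    Raises ``ValueError`` naming the offending row/column on missing values,
    non-positive reflectance or a non-monotonic wavenumber axis.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing_meta = [c for c in _META_COLS if c not in df.columns]
    if missing_meta:
        raise ValueError(f"{path}: missing metadata columns {missing_meta}")
    band_cols = [c for c in df.columns if c not in _META_COLS]
    try:
        wavenumbers = np.array([float(c) for c in band_cols])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavenumber column header: {exc}") from exc
    values = df[band_cols].to_numpy(dtype=float)

    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"{path}: missing value at row {r}, column {band_cols[c]}")
    if (values <= 0).any():
        r, c = np.argwhere(values <= 0)[0]
        raise ValueError(f"{path}: non-positive reflectance at row {r}, column {band_cols[c]}")

    diffs = np.diff(wavenumbers)
    if np.all(diffs < 0):
        logger.info("%s: descending wavenumber axis, flipping to ascending", path)
        wavenumbers = wavenumbers[::-1]
        values = values[:, ::-1]
    elif not np.all(diffs > 0):
        bad = int(np.flatnonzero(~(diffs > 0))[0])
        raise ValueError(
            f"{path}: wavenumber axis not strictly monotonic near column {band_cols[bad]}"
        )

    sset = SpectrumSet(
        wavenumbers=wavenumbers,
        reflectance=values,
        sample_ids=df["sample_id"].to_numpy(),
        replicate_index=df["replicate"].to_numpy(),
        management_mode=df["mode"].to_numpy(dtype=object),
    )
    logger.info("%s: read %d scans x %d bands", path, sset.n_scans, sset.n_bands)
    return sset


def write_tannin_csv(tannins: TanninTable, path) -> None:
    tannins.table.rename("tannin_mg_g").to_csv(path, header=True)


def read_tannin_csv(path) -> TanninTable:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (sample_id, tannin)")
    return TanninTable(pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy()))


def average_replicates(spectra: SpectrumSet) -> SampleSpectrumSet:
    """Collapse replicate scans to one representative spectrum per sample.

    Band-wise arithmetic mean over each sample's scans; row order follows the
    first appearance of each sample id.
    """
    ids = spectra.unique_sample_ids()
    n_rep_seen = set()
    rows = np.empty((ids.size, spectra.n_bands))
    modes = np.empty(ids.size, dtype=object)
    for k, sid in enumerate(ids):
        mask = spectra.sample_ids == sid
        n_rep_seen.add(int(mask.sum()))
        rows[k] = spectra.reflectance[mask].mean(axis=0)
        modes[k] = spectra.management_mode[mask][0]
    n_rep = max(n_rep_seen)
    logger.info("averaged %d scans -> %d samples (%d replicates each)", spectra.n_scans, ids.size, n_rep)
    return SampleSpectrumSet(
        wavenumbers=spectra.wavenumbers.copy(),
        reflectance=rows,
        sample_ids=ids,
        management_mode=modes,
        n_replicates_averaged=n_rep,
    )
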