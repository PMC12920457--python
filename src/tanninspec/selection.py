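"""Pearson correlation profiling and characteristic-band selection.

Per feature, the Pearson coefficient r against the reference tannin values
and its two-sided p-value from t = r * sqrt((n-2) / (1-r^2)) with n-2
degrees of freedom.  A band is characteristic when p < alpha AND
|r| > critical_r; by default critical_r is derived from alpha and n (so the
two gates coincide), but it can be overridden.  No multiple-testing
correction is applied by default (flag available for Benjamini-Hochberg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationProfile",
    "ProfileSummary",
    "pearson_profile",
    "critical_r_threshold",
    "summarize_profile",
    "select_optimal_scale",
    "CorrelationBandSelector",
]


@dataclass
class CorrelationProfile:
    axis: np.ndarray  # wavenumber (or any feature coordinate)
    r: np.ndarray
    p: np.ndarray
    selected: np.ndarray
    critical_r: float
    alpha: float
    n: int


@dataclass
class ProfileSummary:
    nfb: int
    pos_extremum: float | None  # max positive r (None if no such feature)
    neg_extremum: float | None  # min negative r
    mean_abs_r: float | None


def critical_r_threshold(n: int, alpha: float = 0.01) -> float:
    """Smallest |r| whose two-sided p equals ``alpha`` at df = n - 2."""
    if n < 3:
        raise ValueError("need n >= 3")
    tc = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
    return float(tc / np.sqrt(n - 2 + tc**2))


def _pearson_columns(F: np.ndarray, y: np.ndarray) -> tuple:
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    Fc = F - F.mean(axis=0)
    sf = np.sqrt((Fc**2).sum(axis=0))
    constant = sf == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Fc.T @ yc) / (sf * sy)
    r = np.where(constant, 0.0, np.clip(r, -1.0, 1.0))
    return r, constant


def pearson_profile(features, y, alpha: float = 0.01, critical_r: float = None, axis=None) -> CorrelationProfile:
    """Per-feature Pearson r / two-sided p profile against ``y``."""
    F = np.asarray(features, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = F.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    if y.shape[0] != n:
        raise ValueError("features and y have inconsistent lengths")
    if np.ptp(y) == 0:
        raise ValueError("response y is constant")

    r, constant = _pearson_columns(F, y)
    if constant.any():
        logger.info("%d constant feature columns set to r=0, p=1", int(constant.sum()))
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p = np.where(constant, 1.0, p)

    crit = critical_r_threshold(n, alpha) if critical_r is None else float(critical_r)
    selected = (p < alpha) & (np.abs(r) > crit)
    axis = np.arange(F.shape[1], dtype=float) if axis is None else np.asarray(axis, dtype=float)
    return CorrelationProfile(axis=axis, r=r, p=p, selected=selected, critical_r=crit, alpha=alpha, n=n)


def summarize_profile(profile: CorrelationProfile, over: str = "selected") -> ProfileSummary:
    """Band-count and correlation summary in the style of a transform table.

    ``over="selected"`` (default) restricts extrema and mean |r| to the
    characteristic bands; ``over="all"`` uses every feature.
    """
    if over not in ("selected", "all"):
        raise ValueError("over must be 'selected' or 'all'")
    mask = profile.selected if over == "selected" else np.ones_like(profile.selected, dtype=bool)
    r = profile.r[mask]
    nfb = int(profile.selected.sum())
    pos = r[r > 0]
    neg = r[r < 0]
    return ProfileSummary(
        nfb=nfb,
        pos_extremum=float(pos.max()) if pos.size else None,
        neg_extremum=float(neg.min()) if neg.size else None,
        mean_abs_r=float(np.abs(r).mean()) if r.size else None,
    )


def select_optimal_scale(profiles: dict) -> tuple:
    """Pick the CWT scale maximising mean |r| over characteristic bands.

    ``profiles`` maps scale -> CorrelationProfile.  Ties break toward the
    smaller scale.  Returns (best_scale, per-scale summary DataFrame).
    """
    if not profiles:
        raise ValueError("no scale profiles given")
    rows = []
    for scale in sorted(profiles):
        s = summarize_profile(profiles[scale])
        rows.append(
            {
                "scale": scale,
                "nfb": s.nfb,
                "pos_extremum": s.pos_extremum,
                "neg_extremum": s.neg_extremum,
                "mean_abs_r": s.mean_abs_r,
            }
        )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["mean_abs_r"])
    valid = valid[valid["nfb"] > 0]
    if valid.empty:
        raise ValueError("no scale selected any characteristic band")
    best = valid.loc[valid["mean_abs_r"].idxmax(), "scale"]  # idxmax: first max -> smaller scale
    return best, table


class CorrelationBandSelector(SelectorMixin, BaseEstimator):
    """sklearn feature selector keeping bands significantly correlated with y.

    Parameters: ``alpha`` (two-sided significance level), ``critical_r``
    (override for the |r| gate; derived from alpha and n when None),
    ``fdr`` (apply Benjamini-Hochberg to the p-gate when True).
    """

    def __init__(self, alpha=0.01, critical_r=None, fdr=False):
        self.alpha = alpha
        self.critical_r = critical_r
        self.fdr = fdr

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        profile = pearson_profile(X, y, alpha=self.alpha, critical_r=self.critical_r)
        if self.fdr:
            m = profile.p.size
            order = np.argsort(profile.p)
            ranked = profile.p[order] * m / np.arange(1, m + 1)
            passed = np.zeros(m, dtype=bool)
            below = np.flatnonzero(ranked <= self.alpha)
            if below.size:
                passed[order[: below.max() + 1]] = True
            profile.selected = passed & (np.abs(profile.r) > profile.critical_r)
        self.profile_ = profile
        self.support_ = profile.selected.copy()
        return self

    def _get_support_mask(self):
        return self.support_
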