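"""Monte-Carlo cross-validation outlier screening.

Repeated random train/validation splits (default 60/40, 2000 iterations)
each fit a mean-centered PLS model (default 20 latent variables) on the
training part and predict the validation part.  Per-sample absolute
prediction errors are accumulated across iterations; samples whose error
mean or error standard deviation exceed the configured thresholds
(defaults: mean > 10, SD > 2, in response units mg/g) are flagged.

The printed default thresholds come from the walnut study's own error scale;
on other data (including the synthetic generator at low noise) they are
deliberately conservative and may flag nothing — re-tune via ``MCConfig``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datasets import SampleSpectrumSet, TanninTable
from .pls import NipalsPLS

logger = logging.getLogger(__name__)

__all__ = ["MCConfig", "OutlierReport", "MonteCarloOutlierDetector", "mc_outlier_scan", "apply_outlier_removal"]


@dataclass
class MCConfig:
    n_iterations: int = 2000
    train_fraction: float = 0.6
    n_components: int = 20
    mean_threshold: float = 10.0  # mg/g
    sd_threshold: float = 2.0  # mg/g
    rule: str = "or"  # "or" | "and" combination of the two exceedances
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.mean_threshold <= 0 or self.sd_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.rule not in ("or", "and"):
            raise ValueError("rule must be 'or' or 'and'")


@dataclass
class OutlierReport:
    """Per-sample Monte-Carlo error statistics and flags, plus config echo."""

    table: pd.DataFrame  # columns: sample_id, n_val, mean_err, sd_err, flagged
    config: MCConfig

    @property
    def flagged_ids(self) -> list:
        return self.table.loc[self.table["flagged"], "sample_id"].tolist()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


class MonteCarloOutlierDetector(BaseEstimator):
    """sklearn-style detector; ``fit`` computes per-sample error statistics.

    Fitted attributes: ``means_``, ``sds_``, ``counts_``, ``flags_``,
    ``report_`` (DataFrame as in :class:`OutlierReport`).
    """

    def __init__(self, n_iterations=2000, train_fraction=0.6, n_components=20,
                 mean_threshold=10.0, sd_threshold=2.0, rule="or", seed=0):
        self.n_iterations = n_iterations
        self.train_fraction = train_fraction
        self.n_components = n_components
        self.mean_threshold = mean_threshold
        self.sd_threshold = sd_threshold
        self.rule = rule
        self.seed = seed

    def _config(self) -> MCConfig:
        cfg = MCConfig(
            n_iterations=self.n_iterations,
            train_fraction=self.train_fraction,
            n_components=self.n_components,
            mean_threshold=self.mean_threshold,
            sd_threshold=self.sd_threshold,
            rule=self.rule,
            seed=self.seed,
        )
        cfg.validate()
        return cfg

    def fit(self, X, y):
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        if n < 5:
            raise ValueError("need at least 5 samples for the Monte-Carlo scan")
        n_train = int(np.floor(cfg.train_fraction * n))
        n_train = max(3, n_train)

        rng = np.random.default_rng(cfg.seed)
        err_sum = np.zeros(n)
        err_sumsq = np.zeros(n)
        counts = np.zeros(n, dtype=int)
        for _ in range(cfg.n_iterations):
            perm = rng.permutation(n)
            tr, va = perm[:n_train], perm[n_train:]
            model = NipalsPLS(n_components=cfg.n_components).fit(X[tr], y[tr])
            err = np.abs(model.predict(X[va]) - y[va])
            err_sum[va] += err
            err_sumsq[va] += err**2
            counts[va] += 1

        if np.any(counts == 0):
            missing = int((counts == 0).sum())
            raise RuntimeError(
                f"{missing} samples never appeared in validation; increase n_iterations"
            )
        means = err_sum / counts
        with np.errstate(invalid="ignore"):
            var = np.where(counts > 1, (err_sumsq - counts * means**2) / np.maximum(counts - 1, 1), 0.0)
        sds = np.sqrt(np.maximum(var, 0.0))

        exceed_mean = means > cfg.mean_threshold
        exceed_sd = sds > cfg.sd_threshold
        flags = (exceed_mean | exceed_sd) if cfg.rule == "or" else (exceed_mean & exceed_sd)

        self.means_, self.sds_, self.counts_, self.flags_ = means, sds, counts, flags
        self.config_ = cfg
        logger.info("MC scan: %d iterations, %d/%d samples flagged", cfg.n_iterations, int(flags.sum()), n)
        return self


def mc_outlier_scan(spectra: SampleSpectrumSet, tannins: TanninTable, cfg: MCConfig = None) -> OutlierReport:
    """Run the Monte-Carlo outlier screen on averaged spectra."""
    cfg = cfg or MCConfig()
    cfg.validate()
    y = tannins.values_for(spectra.sample_ids)
    det = MonteCarloOutlierDetector(**asdict(cfg)).fit(spectra.reflectance, y)
    table = pd.DataFrame(
        {
            "sample_id": spectra.sample_ids,
            "n_val": det.counts_,
            "mean_err": det.means_,
            "sd_err": det.sds_,
            "flagged": det.flags_,
        }
    )
    return OutlierReport(table=table, config=det.config_)


def apply_outlier_removal(spectra: SampleSpectrumSet, tannins: TanninTable, ids_or_report) -> tuple:
    """Drop flagged/listed samples consistently from both tables.

    Idempotent; an empty list is the identity.  Ids must exist in both the
    spectra and the tannin table.
    """
    if isinstance(ids_or_report, OutlierReport):
        ids = ids_or_report.flagged_ids
    else:
        ids = list(ids_or_report)
    have_spec = set(spectra.sample_ids.tolist())
    have_tan = set(tannins.sample_ids.tolist())
    if have_spec != have_tan:
        raise ValueError("spectra and tannin table cover different sample ids")
    unknown = [i for i in ids if i not in have_spec]
    if unknown:
        raise KeyError(f"cannot remove unknown sample ids: {unknown}")
    keep = [s for s in spectra.sample_ids if s not in set(ids)]
    return spectra.subset(keep), tannins.subset(keep)
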