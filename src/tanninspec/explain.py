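"""Shapley-value attribution for fitted calibration models.

Uses the interventional (marginal) value function: for a coalition S of
features, v(S) is the mean model output over a background set with the
features in S taken from the explained sample and the rest from each
background row.  The exact method enumerates all 2^d coalitions (d <= 12);
the sampled method averages marginal contributions over seeded random
feature permutations.  Both depend only on the model's predict contract, so
they apply to any regressor and admit a brute-force cross-check; values may
differ numerically from path-dependent tree-specific algorithms.

Axioms honoured (tested): efficiency (base + sum(phi) = prediction),
null player (a feature the model never uses gets phi = 0), symmetry
(duplicated columns share credit equally under the exact method).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["AttributionResult", "shapley_attribute", "rank_and_export"]

_EXACT_MAX_FEATURES = 12


@dataclass
class AttributionResult:
    base_value: float  # mean model output over the background set (mg/g)
    phi: np.ndarray  # (n_explained, n_features), mg/g
    feature_names: np.ndarray
    explained: np.ndarray  # the explained feature matrix
    method: str  # "exact" | "permutation"
    n_background: int
    n_permutations: int | None
    seed: int | None
    mc_tolerance: np.ndarray | None = None  # per-instance SE of sum(phi), sampled method

    def ranking(self) -> pd.DataFrame:
        mean_abs = np.abs(self.phi).mean(axis=0)
        order = np.argsort(mean_abs)[::-1]
        return pd.DataFrame(
            {
                "feature": self.feature_names[order],
                "mean_abs_phi": mean_abs[order],
                "rank": np.arange(1, order.size + 1),
            }
        )


def _predict_mean_blocks(model, blocks: np.ndarray, n_bg: int) -> np.ndarray:
    """Predict a stack of (n_blocks * n_bg, d) rows, return per-block means."""
    preds = np.asarray(model.predict(blocks), dtype=float)
    return preds.reshape(-1, n_bg).mean(axis=1)


def _exact_phi(model, background: np.ndarray, x: np.ndarray) -> np.ndarray:
    d = x.size
    n_bg = background.shape[0]
    n_subsets = 1 << d
    masks = (np.arange(n_subsets)[:, None] >> np.arange(d)) & 1  # (2^d, d)
    # Build all coalition-modified background blocks and predict in chunks.
    v = np.empty(n_subsets)
    chunk = max(1, (1 << 18) // max(n_bg, 1))
    for start in range(0, n_subsets, chunk):
        m = masks[start : start + chunk]
        block = np.where(m[:, None, :].astype(bool), x[None, None, :], background[None, :, :])
        v[start : start + m.shape[0]] = _predict_mean_blocks(model, block.reshape(-1, d), n_bg)
    sizes = masks.sum(axis=1)
    phi = np.zeros(d)
    fact_weight = np.array([1.0 / (comb(d - 1, s) * d) for s in range(d)])
    for j in range(d):
        without = np.flatnonzero(masks[:, j] == 0)
        with_j = without | (1 << j)
        phi[j] = np.sum(fact_weight[sizes[without]] * (v[with_j] - v[without]))
    return phi


def _permutation_phi(model, background: np.ndarray, x: np.ndarray, n_permutations: int, rng) -> tuple:
    d = x.size
    n_bg = background.shape[0]
    phi = np.zeros(d)
    totals = np.empty(n_permutations)
    # batch whole permutation walks into few predict calls (memory-capped)
    budget_floats = 1 << 24
    per_perm = (d + 1) * n_bg * d
    batch = int(np.clip(budget_floats // max(per_perm, 1), 1, n_permutations))
    done = 0
    while done < n_permutations:
        b_sz = min(batch, n_permutations - done)
        orders = np.stack([rng.permutation(d) for _ in range(b_sz)])
        blocks = np.broadcast_to(background, (b_sz, d + 1, n_bg, d)).copy()
        for b in range(b_sz):
            for i, j in enumerate(orders[b]):
                blocks[b, i + 1 :, :, j] = x[j]
        v = _predict_mean_blocks(model, blocks.reshape(-1, d), n_bg).reshape(b_sz, d + 1)
        contrib = np.diff(v, axis=1)
        for b in range(b_sz):
            phi[orders[b]] += contrib[b]
        totals[done : done + b_sz] = v[:, -1] - v[:, 0]
        done += b_sz
    phi /= n_permutations
    se = float(totals.std(ddof=1) / np.sqrt(n_permutations)) if n_permutations > 1 else np.nan
    return phi, se


def shapley_attribute(
    model,
    background,
    explain,
    method: str = "auto",
    n_permutations: int = 2000,
    seed: int = 0,
    feature_names=None,
    max_background: int = 100,
) -> AttributionResult:
    """Shapley attributions of ``model`` for each row of ``explain``.

    ``method``: "exact" (enumeration, requires <= 12 features),
    "permutation" (seeded sampling), or "auto" (exact when feasible).
    The background is subsampled to ``max_background`` rows (seeded).
    """
    background = np.asarray(background, dtype=float)
    explain = np.atleast_2d(np.asarray(explain, dtype=float))
    if background.size == 0:
        raise ValueError("background set must be nonempty")
    d = explain.shape[1]
    rng = np.random.default_rng(seed)
    if background.shape[0] > max_background:
        idx = rng.choice(background.shape[0], max_background, replace=False)
        background = background[idx]

    if method == "auto":
        method = "exact" if d <= _EXACT_MAX_FEATURES else "permutation"
    if method == "exact" and d > _EXACT_MAX_FEATURES:
        raise ValueError(
            f"exact enumeration supports at most {_EXACT_MAX_FEATURES} features "
            f"(got {d}); use method='permutation'"
        )
    if method not in ("exact", "permutation"):
        raise ValueError("method must be 'exact', 'permutation' or 'auto'")

    base = float(np.mean(model.predict(background)))
    phi = np.empty((explain.shape[0], d))
    tol = np.empty(explain.shape[0]) if method == "permutation" else None
    for i, x in enumerate(explain):
        if method == "exact":
            phi[i] = _exact_phi(model, background, x)
        else:
            phi[i], tol[i] = _permutation_phi(model, background, x, n_permutations, rng)

    names = (
        np.asarray(feature_names)
        if feature_names is not None
        else np.array([f"f{j}" for j in range(d)])
    )
    return AttributionResult(
        base_value=base,
        phi=phi,
        feature_names=names,
        explained=explain,
        method=method,
        n_background=background.shape[0],
        n_permutations=n_permutations if method == "permutation" else None,
        seed=seed,
        mc_tolerance=tol,
    )


def rank_and_export(result: AttributionResult, top_k: int = 10, n_waterfall: int = 2, seed: int = 0) -> dict:
    """Ranked importance table plus beeswarm / bar / waterfall export frames.

    Beeswarm: (feature, phi, feature_value) triples for the top-k features.
    Waterfall: per chosen sample (seeded draw of ``n_waterfall``), each
    feature's signed contribution from the base value to the prediction.
    """
    d = result.feature_names.size
    if top_k > d:
        logger.warning("top_k=%d clipped to %d features", top_k, d)
        top_k = d
    ranking = result.ranking().head(top_k).reset_index(drop=True)

    name_to_idx = {n: j for j, n in enumerate(result.feature_names)}
    top_idx = [name_to_idx[n] for n in ranking["feature"]]
    bees = []
    for i in range(result.phi.shape[0]):
        for j in top_idx:
            bees.append(
                {
                    "sample": i,
                    "feature": result.feature_names[j],
                    "phi": result.phi[i, j],
                    "feature_value": result.explained[i, j],
                }
            )
    beeswarm = pd.DataFrame(bees)

    bar = pd.DataFrame(
        {
            "feature": result.feature_names,
            "mean_abs_phi": np.abs(result.phi).mean(axis=0),
        }
    ).sort_values("mean_abs_phi", ascending=False, ignore_index=True)

    rng = np.random.default_rng(seed)
    n_wf = min(n_waterfall, result.phi.shape[0])
    chosen = rng.choice(result.phi.shape[0], n_wf, replace=False)
    wf_rows = []
    for i in chosen:
        order = np.argsort(np.abs(result.phi[i]))[::-1]
        cum = result.base_value
        for j in order:
            cum += result.phi[i, j]
            wf_rows.append(
                {
                    "sample": int(i),
                    "feature": result.feature_names[j],
                    "phi": result.phi[i, j],
                    "cumulative": cum,
                }
            )
    waterfall = pd.DataFrame(wf_rows)
    return {"ranking": ranking, "beeswarm": beeswarm, "bar": bar, "waterfall": waterfall}
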