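"""Random 6:4 train/validation partitioning and per-set tannin statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import TanninTable

__all__ = ["SplitResult", "split", "describe_sets"]


@dataclass
class SplitResult:
    train_ids: np.ndarray
    val_ids: np.ndarray
    ratio: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": np.concatenate([self.train_ids, self.val_ids]),
                "set": ["train"] * len(self.train_ids) + ["val"] * len(self.val_ids),
            }
        )


def split(ids, ratio: float = 0.6, seed: int = 0, stratify_by=None) -> SplitResult:
    """Uniform random partition: floor(ratio * n) ids to train, rest to val.

    ``stratify_by`` (optional mapping id -> stratum label) applies the ratio
    within each stratum instead of globally.
    """
    ids = np.asarray(list(ids))
    n = ids.size
    if n < 2:
        raise ValueError("need at least 2 ids to split")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if stratify_by is None:
        perm = rng.permutation(n)
        k = int(np.floor(ratio * n))
        train, val = ids[perm[:k]], ids[perm[k:]]
    else:
        labels = np.asarray([stratify_by[i] for i in ids])
        train_parts, val_parts = [], []
        for lab in pd.unique(labels):
            sub = ids[labels == lab]
            perm = rng.permutation(sub.size)
            k = int(np.floor(ratio * sub.size))
            train_parts.append(sub[perm[:k]])
            val_parts.append(sub[perm[k:]])
        train, val = np.concatenate(train_parts), np.concatenate(val_parts)
    return SplitResult(train_ids=train, val_ids=val, ratio=ratio, seed=seed)


def describe_sets(tannins: TanninTable, split_result: SplitResult) -> pd.DataFrame:
    """n / mean / median / SD / CV% of tannin for the full, train and val sets."""
    sets = {
        "full": np.concatenate([split_result.train_ids, split_result.val_ids]),
        "train": split_result.train_ids,
        "val": split_result.val_ids,
    }
    rows = []
    for name, ids in sets.items():
        if len(ids) == 0:
            raise ValueError(f"{name} set is empty")
        v = tannins.values_for(ids)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
        mean = float(np.mean(v))
        rows.append(
            {
                "set": name,
                "n": int(v.size),
                "mean": mean,
                "median": float(np.median(v)),
                "sd": sd,
                "cv_percent": 100.0 * sd / mean,
            }
        )
    return pd.DataFrame(rows)
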