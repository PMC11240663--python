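"""Training/test-set construction: bird-level split, purity cleaning and
per-strain per-behaviour upsampling.

The split is at the level of birds, not windows — no bird contributes
windows to both sides, which is the guard against the pseudo-replication
that inflates accuracy when windows from one animal appear in both
training and test data.  Each strain is split 80:20 (test count =
``max(1, round((1 - ratio) * n))``), so strains of 8/10/15 birds give
2/2/3 test birds.

Training windows must be 100 % pure; test windows >= 60 % pure.  Training
data are then balanced by sampling each (strain x behaviour) cell with
replacement up to the globally largest cell count; original rows are
always retained and test data are never resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import errors
from .names import BEHAVIOURS


@dataclass
class SplitPlan:
    """Bird-level train/test assignment, disjoint and exhaustive."""

    train_birds: dict[str, str] = field(default_factory=dict)  # bird_id -> strain
    test_birds: dict[str, str] = field(default_factory=dict)
    ratio: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.train_birds) & set(self.test_birds)
        if overlap:
            raise ValueError(f"birds in both splits: {sorted(overlap)[:3]}")


def split_birds(
    birds: list[tuple[str, str]], ratio: float = 0.8, seed: int = 0
) -> SplitPlan:
    """Randomly assign birds to train/test within each strain.

    ``birds`` is a list of (bird_id, strain).  Per strain the test count
    is ``max(1, round((1 - ratio) * n))`` (round half up); assignment is
    deterministic given ``seed``.
    """
    by_strain: dict[str, list[str]] = {}
    for bird_id, strain in birds:
        by_strain.setdefault(strain, []).append(bird_id)
    rng = np.random.default_rng(seed)
    plan = SplitPlan(ratio=ratio, seed=seed)
    for strain in sorted(by_strain):
        ids = sorted(by_strain[strain])
        if len(ids) < 2:
            raise errors.StrainTooSmall(f"strain {strain} has {len(ids)} bird(s)")
        n_test = max(1, int(math.floor((1.0 - ratio) * len(ids) + 0.5)))
        order = rng.permutation(len(ids))
        test_ids = {ids[i] for i in order[:n_test]}
        for bird_id in ids:
            target = plan.test_birds if bird_id in test_ids else plan.train_birds
            target[bird_id] = strain
    return plan


def upsample_balance(train_table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Balance (strain x behaviour) cells by sampling with replacement.

    Every cell is topped up to the size of the globally largest cell;
    original rows are always retained, so no feature value absent from the
    input can appear.  Applied to training data only.
    """
    strains = sorted(train_table["strain"].unique())
    for strain in strains:
        for behaviour in BEHAVIOURS:
            n = ((train_table["strain"] == strain) & (train_table["behaviour"] == behaviour)).sum()
            if n == 0:
                raise errors.EmptyCell(f"no ({strain}, {behaviour}) training rows")
    counts = train_table.groupby(["strain", "behaviour"], observed=True).size()
    target = int(counts.max())
    rng = np.random.default_rng(seed)
    pieces: list[pd.DataFrame] = []
    for (strain, behaviour), n in counts.sort_index().items():
        cell = train_table[
            (train_table["strain"] == strain) & (train_table["behaviour"] == behaviour)
        ]
        pieces.append(cell)
        extra = target - int(n)
        if extra > 0:
            pieces.append(cell.iloc[rng.integers(0, len(cell), size=extra)])
    return pd.concat(pieces, ignore_index=True)


def build_datasets(
    features_by_bird: dict[str, pd.DataFrame],
    plan: SplitPlan,
    train_purity: float = 1.0,
    test_purity: float = 0.6,
    seed: int = 0,
    balance: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the cleaned, balanced training table and the test table.

    ``features_by_bird`` maps bird_id to that bird's full feature table
    (windows at any purity).  Training keeps only 100 %-pure windows of
    training birds, then upsamples; testing keeps >= 60 %-pure windows of
    test birds, untouched.
    """
    missing = [
        b for b in list(plan.train_birds) + list(plan.test_birds)
        if b not in features_by_bird
    ]
    if missing:
        raise KeyError(f"no feature table for birds {missing[:3]}")

    def gather(bird_ids, purity):
        parts = []
        for bird_id in sorted(bird_ids):
            t = features_by_bird[bird_id]
            parts.append(t[t["purity"] >= purity - 1e-12])
        return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()

    train = gather(plan.train_birds, train_purity)
    test = gather(plan.test_birds, test_purity)
    if balance:
        train = upsample_balance(train, seed=seed)
    return train, test
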