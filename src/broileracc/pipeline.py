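"""End-to-end convenience drivers: simulate -> decompose -> features ->
split -> balance -> train -> evaluate.

These functions wire the individual modules together the way the study
design prescribes: bird-level 80:20 split within each training strain,
100 %-pure training windows balanced per (strain x behaviour), >= 60 %-pure
test windows left untouched, a 100-tree forest, and two test conditions —
*test 1* on held-out birds of the training strains and *test 2* on birds
of a strain never seen in training.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import ForestModel, train_forest
from .dataset import build_datasets, split_birds
from .evaluate import ConfusionMatrix3, Metrics, confusion, metrics_report
from .features import WindowSpec, extract_features
from .io import AccelTrace, LabelTrack
from .signal import decompose
from .simulate import DEFAULT_PROFILES, SimConfig, simulate_flock


def extract_flock_features(
    birds: list[tuple[AccelTrace, LabelTrack]],
    spec: WindowSpec = WindowSpec(),
    purity_threshold: float = 0.6,
) -> dict[str, pd.DataFrame]:
    """Decompose and window every bird; returns bird_id -> feature table.

    The threshold is the *loosest* purity kept (the test criterion);
    training-grade 100 %-pure windows are selected downstream from the
    ``purity`` column.
    """
    out: dict[str, pd.DataFrame] = {}
    for trace, track in birds:
        filtered = decompose(trace)
        out[trace.bird_id] = extract_features(
            filtered, track, spec=spec, purity_threshold=purity_threshold
        )
    return out


@dataclass
class PipelineResult:
    """Trained model plus both test evaluations."""

    model: ForestModel
    train_table: pd.DataFrame
    test1_cm: ConfusionMatrix3
    test1_metrics: dict[str, Metrics]
    test2_cm: ConfusionMatrix3 | None
    test2_metrics: dict[str, Metrics] | None


def _evaluate(model: ForestModel, test: pd.DataFrame) -> tuple[ConfusionMatrix3, dict]:
    cm = confusion(test["behaviour"].to_numpy(), model.predict(test))
    return cm, metrics_report(cm)


def run_synthetic_pipeline(
    seed: int,
    train_strains: dict[str, int] | None = None,
    test_strain: tuple[str, int] | None = ("FGC", 8),
    session_s: float = 300.0,
    fs: float = 50.0,
    n_trees: int = 100,
    ratio: float = 0.8,
    attributes: list[str] | None = None,
    features_by_bird: dict[str, pd.DataFrame] | None = None,
    test2_features: pd.DataFrame | None = None,
) -> PipelineResult:
    """Run the whole pipeline on a simulated flock.

    Pre-extracted feature tables can be passed in (``features_by_bird``,
    ``test2_features``) to re-train on the same data with a different
    attribute set; otherwise the flock is simulated from ``seed``.
    """
    train_strains = train_strains or {"CNV": 8, "SGH": 10, "SGN": 15}
    if features_by_bird is None:
        config = SimConfig(strains=train_strains, session_s=session_s, fs=fs, seed=seed)
        features_by_bird = extract_flock_features(simulate_flock(config))
    bird_strains = [
        (bird_id, t["strain"].iloc[0]) for bird_id, t in features_by_bird.items()
    ]
    plan = split_birds(bird_strains, ratio=ratio, seed=seed)
    train, test1 = build_datasets(features_by_bird, plan, seed=seed)
    model = train_forest(train, n_trees=n_trees, seed=seed, attributes=attributes)
    cm1, rep1 = _evaluate(model, test1)

    cm2 = rep2 = None
    if test2_features is None and test_strain is not None:
        strain, n_birds = test_strain
        config2 = SimConfig(
            strains={strain: n_birds}, session_s=session_s, fs=fs, seed=seed + 7919
        )
        tables = extract_flock_features(
            simulate_flock(config2, profiles=DEFAULT_PROFILES)
        )
        test2_features = pd.concat(tables.values(), ignore_index=True)
    if test2_features is not None and len(test2_features):
        cm2, rep2 = _evaluate(model, test2_features)
    return PipelineResult(
        model=model,
        train_table=train,
        test1_cm=cm1,
        test1_metrics=rep1,
        test2_cm=cm2,
        test2_metrics=rep2,
    )
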