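"""Shared fixtures: small simulated birds and the multi-seed pipeline runs.

The ten-seed end-to-end results are expensive (a full simulate ->
decompose -> features -> split -> balance -> train -> evaluate pass per
seed, plus a posture-ablated retrain), so they are computed once per
session and shared between the learnability, ablation and acceptance
tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from broileracc.names import STATIC_FEATURES, TILT_FEATURES
from broileracc.pipeline import extract_flock_features, run_synthetic_pipeline
from broileracc.simulate import DEFAULT_PROFILES, SimConfig, simulate_bird, simulate_flock

N_SEEDS = 10


@pytest.fixture(scope="session")
def one_bird():
    """One simulated CNV bird: (trace, track), 5 min at 50 Hz."""
    return simulate_bird(
        DEFAULT_PROFILES["CNV"], SimConfig(seed=123), bird_id="CNV_fix", seed=123
    )


@pytest.fixture(scope="session")
def small_flock():
    """A small mixed flock (2 birds per training strain, 1-min sessions)."""
    config = SimConfig(
        strains={"CNV": 2, "SGH": 2, "SGN": 2}, session_s=60.0, seed=42
    )
    return simulate_flock(config)


@pytest.fixture(scope="session")
def pipeline_runs():
    """Per-seed end-to-end results: full attribute set and with the
    posture families (static + tilt) zeroed out.

    Returns a list of dicts with keys 'full' and 'ablated', each a
    PipelineResult over the default study-sized flock (33 training-strain
    birds, 8 unseen-strain test birds, 5-min sessions at 50 Hz).
    """
    posture_cols = STATIC_FEATURES + TILT_FEATURES
    runs = []
    for seed in range(N_SEEDS):
        feats = extract_flock_features(simulate_flock(SimConfig(seed=seed)))
        test2 = pd.concat(
            extract_flock_features(
                simulate_flock(SimConfig(strains={"FGC": 8}, seed=seed + 7919))
            ).values(),
            ignore_index=True,
        )
        full = run_synthetic_pipeline(
            seed=seed, features_by_bird=feats, test2_features=test2
        )
        ablated = run_synthetic_pipeline(
            seed=seed,
            features_by_bird={
                b: t.assign(**{c: 0.0 for c in posture_cols}) for b, t in feats.items()
            },
            test2_features=test2.assign(**{c: 0.0 for c in posture_cols}),
        )
        runs.append({"full": full, "ablated": ablated})
    return runs


def median_metric(runs, which: str, cls: str, metric: str) -> float:
    """Across-seed median of one metric (percent)."""
    return float(
        np.median(
            [
                getattr(
                    (r[which].test2_metrics if cls == "test2_overall" else r[which].test1_metrics)[
                        "overall" if cls == "test2_overall" else cls
                    ],
                    metric,
                )
                for r in runs
            ]
        )
    )
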