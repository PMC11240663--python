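"""Canonical attribute and column names for the 99-attribute feature table.

The five attribute families and their sizes:

* dynamic per-axis summary stats     27  (``dyn_{x,y,z}_{9 stats}``)
* static  per-axis summary stats     27  (``stat_{x,y,z}_{9 stats}``)
* VeDBA summary stats                 9  (``vedba_{9 stats}``)
* tilt-angle stats                   12  (``{roll,pitch,yaw}_{4 stats}``)
* spectral peak frequency/amplitude  24  (``{freq,amp}_{x,y,z}_{4 stats}``)

Order here is the on-disk column order and is part of the file contract.
"""

from __future__ import annotations

STATS9 = ("min", "max", "absmean", "iqr", "skew", "kurt", "entropy", "npeaks", "ntroughs")
STATS4 = ("min", "max", "absmean", "iqr")
AXES = ("x", "y", "z")
BEHAVIOURS = ("sit", "stand", "walk")
OTHER = "other"

METADATA_COLUMNS = ("bird_id", "strain", "window_start_s", "behaviour", "purity")


def _family(prefixes: tuple[str, ...], stats: tuple[str, ...]) -> list[str]:
    return [f"{p}_{s}" for p in prefixes for s in stats]


DYNAMIC_FEATURES = _family(tuple(f"dyn_{a}" for a in AXES), STATS9)
STATIC_FEATURES = _family(tuple(f"stat_{a}" for a in AXES), STATS9)
VEDBA_FEATURES = _family(("vedba",), STATS9)
TILT_FEATURES = _family(("roll", "pitch", "yaw"), STATS4)
SPECTRAL_FEATURES = _family(
    tuple(f"{q}_{a}" for q in ("freq", "amp") for a in AXES), STATS4
)

FEATURE_FAMILIES = {
    "dynamic": DYNAMIC_FEATURES,
    "static": STATIC_FEATURES,
    "vedba": VEDBA_FEATURES,
    "tilt": TILT_FEATURES,
    "spectral": SPECTRAL_FEATURES,
}

FEATURE_NAMES: list[str] = (
    DYNAMIC_FEATURES + STATIC_FEATURES + VEDBA_FEATURES + TILT_FEATURES + SPECTRAL_FEATURES
)

assert len(FEATURE_NAMES) == 99
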