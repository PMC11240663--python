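"""Reading and writing of on-disk artefacts.

Three plain-text dialects are supported:

* acceleration traces — CSV ``time_s,x_g,y_g,z_g`` (time in seconds from
  recording start, acceleration in g);
* behaviour labels — CSV ``bird_id,strain,behaviour,start_s,end_s`` with
  half-open ``[start, end)`` intervals, or an ELAN-exported ``.eaf`` XML
  annotation document (one tier, selectable by name);
* feature tables — CSV with five metadata columns followed by the 99
  canonical attribute columns (see :mod:`broileracc.names`).

Every reader validates its target type's invariants and raises a typed
error from :mod:`broileracc.errors` instead of returning a broken object.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import errors
from .names import BEHAVIOURS, FEATURE_NAMES, METADATA_COLUMNS, OTHER

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ("time_s", "x_g", "y_g", "z_g")
LABEL_COLUMNS = ("bird_id", "strain", "behaviour", "start_s", "end_s")

#: acceptable relative jitter of time steps around the nominal 1/fs period
_JITTER_TOL = 0.01


@dataclass
class AccelTrace:
    """Raw tri-axial acceleration recording for one bird.

    Axes follow the surge/sway/heave convention: x forward-back, y
    side-to-side, z up-down.  Units are g; ``t`` is seconds from recording
    start on a uniform grid with period ``1/fs``.
    """

    bird_id: str
    strain: str
    fs: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.t)
        if n < 1:
            raise errors.EmptyInput("trace has no samples")
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise errors.LengthMismatch("t/x/y/z lengths differ")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if n > 1:
            steps = np.diff(self.t)
            if np.any(steps <= 0):
                raise errors.NonMonotonicTime("time not strictly increasing")
            if np.max(np.abs(steps - 1.0 / self.fs)) > max(1e-6, _JITTER_TOL / self.fs):
                raise errors.IrregularSampling("time steps deviate from 1/fs")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs


@dataclass
class LabelTrack:
    """Ordered non-overlapping behaviour intervals for one bird.

    Intervals are half-open ``[start_s, end_s)`` and sorted; gaps
    (unannotated time) are allowed.  Behaviour is one of sit/stand/walk or
    ``other``.
    """

    bird_id: str
    strain: str
    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv[0])
        prev_end = -np.inf
        for start, end, behaviour in self.intervals:
            if not start < end:
                raise ValueError(f"empty interval [{start}, {end})")
            if start < prev_end:
                raise errors.OverlappingIntervals(
                    f"interval starting at {start} overlaps previous ending {prev_end}"
                )
            if behaviour not in BEHAVIOURS and behaviour != OTHER:
                raise errors.UnknownBehaviour(behaviour)
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)


def _infer_fs(t: np.ndarray) -> float:
    if len(t) < 2:
        raise errors.EmptyInput("cannot infer sampling rate from a single sample")
    return 1.0 / float(np.median(np.diff(t)))


def read_accel(
    path: str | Path,
    fs_override: float | None = None,
    bird_id: str = "",
    strain: str = "",
) -> AccelTrace:
    """Read an acceleration trace CSV.

    The sampling rate is inferred from the median time step unless
    ``fs_override`` is given, in which case the two must agree within 1 %.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise errors.MissingColumn(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise errors.EmptyInput(f"{path}: no data rows")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        raise errors.NonMonotonicTime(f"{path}: time not strictly increasing")
    fs = _infer_fs(t) if len(t) > 1 else (fs_override or 0.0)
    if fs_override is not None and len(t) > 1:
        if abs(fs - fs_override) / fs_override > 0.01:
            raise errors.IrregularSampling(
                f"{path}: inferred fs {fs:.3f} Hz disagrees with override "
                f"{fs_override:.3f} Hz by more than 1 %"
            )
        fs = fs_override
    if fs <= 0:
        raise errors.EmptyInput(f"{path}: single-row file needs fs_override")
    return AccelTrace(
        bird_id=bird_id or Path(path).stem,
        strain=strain,
        fs=fs,
        t=t,
        x=df["x_g"].to_numpy(dtype=float),
        y=df["y_g"].to_numpy(dtype=float),
        z=df["z_g"].to_numpy(dtype=float),
    )


def write_accel(trace: AccelTrace, path: str | Path) -> Path:
    """Write an acceleration trace in the canonical CSV dialect."""
    path = Path(path)
    pd.DataFrame(
        {"time_s": trace.t, "x_g": trace.x, "y_g": trace.y, "z_g": trace.z}
    ).to_csv(path, index=False, float_format="%.9g")
    return path


def _map_behaviour(raw: str, strict: bool) -> str:
    b = raw.strip().lower()
    if b in BEHAVIOURS or b == OTHER:
        return b
    if strict:
        raise errors.UnknownBehaviour(raw)
    logger.info("mapping behaviour %r -> 'other'", raw)
    return OTHER


def read_labels(
    path: str | Path,
    dialect: str = "tabular",
    tier: str | None = None,
    strict: bool = False,
    bird_id: str = "",
    strain: str = "",
) -> LabelTrack:
    """Read a behaviour label track.

    ``dialect`` is ``"tabular"`` (CSV) or ``"elan-xml"`` (ELAN ``.eaf``
    export; ``tier`` selects the annotation tier, default the first).
    Behaviours outside sit/stand/walk map to ``other`` unless ``strict``.
    """
    if dialect == "tabular":
        return _read_labels_csv(path, strict)
    if dialect == "elan-xml":
        return _read_labels_eaf(path, tier, strict, bird_id, strain)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_labels_csv(path: str | Path, strict: bool) -> LabelTrack:
    df = pd.read_csv(path)
    missing = [c for c in LABEL_COLUMNS if c not in df.columns]
    if missing:
        raise errors.MissingColumn(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise errors.EmptyInput(f"{path}: no data rows")
    intervals = [
        (float(r.start_s), float(r.end_s), _map_behaviour(str(r.behaviour), strict))
        for r in df.itertuples()
    ]
    return LabelTrack(
        bird_id=str(df["bird_id"].iloc[0]),
        strain=str(df["strain"].iloc[0]),
        intervals=intervals,
    )


def _read_labels_eaf(
    path: str | Path, tier: str | None, strict: bool, bird_id: str, strain: str
) -> LabelTrack:
    """Parse an ELAN .eaf document: time-slot table plus one annotation tier."""
    root = ET.parse(path).getroot()
    slots: dict[str, float] = {}
    for ts in root.findall("./TIME_ORDER/TIME_SLOT"):
        value = ts.get("TIME_VALUE")
        if value is not None:
            slots[ts.get("TIME_SLOT_ID", "")] = float(value) / 1000.0
    tiers = root.findall("./TIER")
    if not tiers:
        raise errors.EmptyInput(f"{path}: no TIER elements")
    if tier is not None:
        chosen = [t for t in tiers if t.get("TIER_ID") == tier]
        if not chosen:
            raise errors.MissingColumn(f"{path}: no tier named {tier!r}")
        node = chosen[0]
    else:
        node = tiers[0]
    intervals: list[tuple[float, float, str]] = []
    for ann in node.iter("ALIGNABLE_ANNOTATION"):
        t1 = slots.get(ann.get("TIME_SLOT_REF1", ""))
        t2 = slots.get(ann.get("TIME_SLOT_REF2", ""))
        value_el = ann.find("ANNOTATION_VALUE")
        if t1 is None or t2 is None or value_el is None:
            continue
        intervals.append((t1, t2, _map_behaviour(value_el.text or "", strict)))
    if not intervals:
        raise errors.EmptyInput(f"{path}: tier has no alignable annotations")
    return LabelTrack(
        bird_id=bird_id or Path(path).stem, strain=strain, intervals=intervals
    )


def write_labels(track: LabelTrack, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [
            {
                "bird_id": track.bird_id,
                "strain": track.strain,
                "behaviour": b,
                "start_s": s,
                "end_s": e,
            }
            for s, e, b in track.intervals
        ]
    ).to_csv(path, index=False, float_format="%.9g")
    return path


# --- feature tables ----------------------------------------------------

ALL_COLUMNS = list(METADATA_COLUMNS) + FEATURE_NAMES


def validate_feature_table(table: pd.DataFrame) -> None:
    """Raise :class:`SchemaMismatch` unless all canonical columns exist."""
    missing = [c for c in ALL_COLUMNS if c not in table.columns]
    if missing:
        raise errors.SchemaMismatch(f"feature table missing columns: {missing[:5]}...")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    validate_feature_table(table)
    path = Path(path)
    table[ALL_COLUMNS].to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_feature_table(table)
    table = table[ALL_COLUMNS]
    # numeric columns are floats by contract even when every value is whole
    numeric = ["window_start_s", "purity"] + FEATURE_NAMES
    table[numeric] = table[numeric].astype(float)
    return table
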