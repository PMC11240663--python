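"""Windowing, purity labelling and the 99-attribute feature computation.

Filtered traces are split into 3 s windows with 50 % overlap (defaults).
Each window receives the behaviour occupying the largest share of its
duration, provided that share (the *purity*) reaches a threshold —
training uses 1.0 (pure windows only), testing 0.6.  Unannotated time and
``other`` behaviours count against purity.

Per retained window, 99 attributes are computed in five families:

* 9 summary statistics (min, max, absolute mean, IQR, skewness, kurtosis,
  Shannon entropy, peak count, trough count) of each dynamic axis (27),
  each static axis (27) and VeDBA (9);
* min/max/absmean/IQR of roll, pitch and yaw (12);
* min/max/absmean/IQR of spectral-peak frequencies and amplitudes of each
  dynamic axis (24).

Skewness and kurtosis use the (N-1)-denominator moment form with the
sample standard deviation:

    skew = sum((k - mean)^3) / (N - 1) / sd^3
    kurt = sum((k - mean)^4) / (N - 1) / sd^4

with the convention skew = kurt = 0 for a constant window (sd = 0).
All computations are vectorised across windows; extraction is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import errors
from .io import LabelTrack
from .names import (
    BEHAVIOURS,
    FEATURE_NAMES,
    METADATA_COLUMNS,
    STATS4,
    STATS9,
)
from .signal import FilteredTrace

DEFAULT_ENTROPY_BINS = 10
DEFAULT_SPECTRAL_FLOOR = 0.05


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 3 s windows, 50 % overlap by default."""

    length_s: float = 3.0
    overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("length_s must be positive")
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap_frac must be in [0, 1)")

    @property
    def step_s(self) -> float:
        return self.length_s * (1.0 - self.overlap_frac)


def segment(n_samples: int, fs: float, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open sample-index ranges of the sliding windows.

    Windows hold exactly ``round(length_s * fs)`` samples, spaced
    ``round(step_s * fs)`` apart; a trailing partial window is discarded.
    Returns an empty list when the trace is shorter than one window.
    """
    w = int(round(spec.length_s * fs))
    hop = max(1, int(round(spec.step_s * fs)))
    if n_samples < w:
        return []
    starts = range(0, n_samples - w + 1, hop)
    return [(s, s + w) for s in starts]


def window_label(
    start_s: float,
    end_s: float,
    track: LabelTrack,
    purity_threshold: float,
) -> tuple[str, float] | None:
    """Label one window by behaviour purity, or discard it.

    Purity is the fraction of the window occupied by its most-represented
    behaviour among sit/stand/walk.  Returns ``(behaviour, purity)`` when
    purity >= threshold, else ``None``.  Ties break by the fixed order
    sit < stand < walk (deterministic; ties below any threshold > 0.5
    are discarded anyway).
    """
    if not 0 < purity_threshold <= 1:
        raise ValueError("purity_threshold must be in (0, 1]")
    occupancy = dict.fromkeys(BEHAVIOURS, 0.0)
    for iv_start, iv_end, behaviour in track.intervals:
        if behaviour not in occupancy:
            continue
        lo = max(start_s, iv_start)
        hi = min(end_s, iv_end)
        if hi > lo:
            occupancy[behaviour] += hi - lo
    best = max(BEHAVIOURS, key=lambda b: occupancy[b])
    purity = occupancy[best] / (end_s - start_s)
    if purity >= purity_threshold - 1e-12:
        return best, min(purity, 1.0)
    return None


# --- per-window statistics (vectorised over a windows-by-samples matrix) ---


def _moments(W: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n = W.shape[1]
    mean = W.mean(axis=1)
    dev = W - mean[:, None]
    sd = np.sqrt((dev**2).sum(axis=1) / (n - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = (dev**3).sum(axis=1) / (n - 1) / sd**3
        kurt = (dev**4).sum(axis=1) / (n - 1) / sd**4
    zero = sd == 0
    skew[zero] = 0.0
    kurt[zero] = 0.0
    return mean, sd, skew, kurt


def _entropy_rows(W: np.ndarray, n_bins: int) -> np.ndarray:
    """Shannon entropy (nats) of each row, histogrammed into equal-width
    bins over the row's own range; constant rows give 0."""
    n_rows, n = W.shape
    lo = W.min(axis=1)
    rng = W.max(axis=1) - lo
    ok = rng > 0
    idx = np.zeros_like(W, dtype=np.int64)
    if ok.any():
        scaled = (W[ok] - lo[ok, None]) / rng[ok, None] * n_bins
        idx[ok] = np.clip(scaled.astype(np.int64), 0, n_bins - 1)
    flat = idx + (np.arange(n_rows) * n_bins)[:, None]
    counts = np.bincount(flat.ravel(), minlength=n_rows * n_bins).reshape(
        n_rows, n_bins
    )
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    H = -terms.sum(axis=1)
    H[~ok] = 0.0
    return H


def _peak_trough_rows(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counts of local maxima/minima per row; plateaus count once.

    Works on the forward-filled sign of successive differences: a peak is
    a +1 -> -1 transition, a trough a -1 -> +1 transition, so a flat-topped
    extremum registers exactly once.
    """
    d = np.diff(W, axis=1)
    s = np.sign(d).astype(np.int8)
    nz = s != 0
    idx = np.where(nz, np.arange(s.shape[1])[None, :], 0)
    filled = np.take_along_axis(s, np.maximum.accumulate(idx, axis=1), axis=1)
    # leading flat run must stay signless, not inherit column 0's sign
    filled = np.where(np.maximum.accumulate(nz, axis=1), filled, 0)
    peaks = ((filled[:, :-1] == 1) & (filled[:, 1:] == -1)).sum(axis=1)
    troughs = ((filled[:, :-1] == -1) & (filled[:, 1:] == 1)).sum(axis=1)
    return peaks.astype(float), troughs.astype(float)


def _stats9_matrix(W: np.ndarray, n_bins: int = DEFAULT_ENTROPY_BINS) -> np.ndarray:
    """The 9 summary statistics per row, columns ordered as STATS9."""
    if W.shape[1] < 2:
        raise errors.SeriesTooShort("stats need >= 2 samples")
    _, _, skew, kurt = _moments(W)
    q25, q75 = np.percentile(W, [25, 75], axis=1)
    peaks, troughs = _peak_trough_rows(W) if W.shape[1] >= 3 else (
        np.zeros(W.shape[0]),
        np.zeros(W.shape[0]),
    )
    return np.column_stack(
        [
            W.min(axis=1),
            W.max(axis=1),
            np.abs(W).mean(axis=1),
            q75 - q25,
            skew,
            kurt,
            _entropy_rows(W, n_bins),
            peaks,
            troughs,
        ]
    )


def _stats4_matrix(W: np.ndarray) -> np.ndarray:
    q25, q75 = np.percentile(W, [25, 75], axis=1)
    return np.column_stack(
        [W.min(axis=1), W.max(axis=1), np.abs(W).mean(axis=1), q75 - q25]
    )


def stats9(series: np.ndarray, n_bins: int = DEFAULT_ENTROPY_BINS) -> tuple[float, ...]:
    """(min, max, absmean, IQR, skew, kurt, entropy, n_peaks, n_troughs)."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) < 2:
        raise errors.SeriesTooShort("stats9 needs a 1-D series of length >= 2")
    return tuple(_stats9_matrix(series[None, :], n_bins)[0])


def shannon_entropy(series: np.ndarray, n_bins: int = DEFAULT_ENTROPY_BINS) -> float:
    """Histogram Shannon entropy in nats over the series' own range."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    series = np.asarray(series, dtype=float)
    return float(_entropy_rows(series[None, :], n_bins)[0])


def count_peaks_troughs(series: np.ndarray) -> tuple[int, int]:
    """Counts of strict local maxima and minima (plateaus count once)."""
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        raise errors.SeriesTooShort("need >= 3 samples")
    p, t = _peak_trough_rows(series[None, :])
    return int(p[0]), int(t[0])


def _spectra(W: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    n = W.shape[1]
    F = np.abs(np.fft.rfft(W - W.mean(axis=1, keepdims=True), axis=1)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return F, freqs


def _spectral_stats_matrix(
    W: np.ndarray, fs: float, floor: float = DEFAULT_SPECTRAL_FLOOR
) -> np.ndarray:
    """Per row: min/max/absmean/IQR of spectral-peak frequencies, then the
    same four of peak amplitudes; all zeros when no peak clears the floor."""
    F, freqs = _spectra(W, fs)
    interior = F[:, 1:-1]
    is_peak = (interior > F[:, :-2]) & (interior > F[:, 2:])
    ceiling = F.max(axis=1, keepdims=True)
    is_peak &= interior >= floor * ceiling
    out = np.zeros((W.shape[0], 8))
    for i in range(W.shape[0]):
        cols = np.flatnonzero(is_peak[i]) + 1
        if len(cols) == 0:
            continue
        pf, pa = freqs[cols], F[i, cols]
        for j, v in enumerate((pf, pa)):
            q25, q75 = np.percentile(v, [25, 75])
            out[i, 4 * j : 4 * j + 4] = (v.min(), v.max(), np.abs(v).mean(), q75 - q25)
    return out


def spectral_peak_stats(
    series: np.ndarray, fs: float, floor: float = DEFAULT_SPECTRAL_FLOOR
) -> tuple[float, ...]:
    """Spectral-peak frequency and amplitude statistics of one window.

    The magnitude spectrum of the mean-removed series is scanned for local
    maxima at least ``floor`` times the spectrum maximum; returns
    min/max/absmean/IQR of the peak frequencies then of the peak
    amplitudes (8 zeros when no peak qualifies).
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 8:
        raise errors.SeriesTooShort("need >= 8 samples for a spectrum")
    return tuple(_spectral_stats_matrix(series[None, :], fs, floor)[0])


def extract_features(
    filtered: FilteredTrace,
    track: LabelTrack,
    spec: WindowSpec = WindowSpec(),
    purity_threshold: float = 1.0,
    entropy_bins: int = DEFAULT_ENTROPY_BINS,
    spectral_floor: float = DEFAULT_SPECTRAL_FLOOR,
    drop_edge_windows: bool = False,
) -> pd.DataFrame:
    """Feature table of one bird: metadata plus the 99 attributes per
    retained window.

    Windows failing the purity threshold are discarded; when
    ``drop_edge_windows`` is set, windows overlapping the filter's flagged
    edge samples are discarded too (by default they are retained).
    """
    trace = filtered.parent
    fs = trace.fs
    t0 = float(trace.t[0])
    spans = segment(len(trace), fs, spec)
    rows_meta: list[dict] = []
    keep: list[int] = []
    for k, (i0, i1) in enumerate(spans):
        if drop_edge_windows and filtered.edge_flag[i0:i1].any():
            continue
        start_s = t0 + i0 / fs
        end_s = t0 + i1 / fs
        labelled = window_label(start_s, end_s, track, purity_threshold)
        if labelled is None:
            continue
        behaviour, purity = labelled
        rows_meta.append(
            {
                "bird_id": trace.bird_id,
                "strain": trace.strain,
                "window_start_s": start_s,
                "behaviour": behaviour,
                "purity": purity,
            }
        )
        keep.append(k)
    if not keep:
        return pd.DataFrame(columns=list(METADATA_COLUMNS) + FEATURE_NAMES)

    starts = np.array([spans[k][0] for k in keep])
    w = spans[0][1] - spans[0][0]
    gather = starts[:, None] + np.arange(w)[None, :]

    def windows(series: np.ndarray) -> np.ndarray:
        return series[gather]

    blocks: list[np.ndarray] = []
    for series in (filtered.dyn_x, filtered.dyn_y, filtered.dyn_z):
        blocks.append(_stats9_matrix(windows(series), entropy_bins))
    for series in (filtered.stat_x, filtered.stat_y, filtered.stat_z):
        blocks.append(_stats9_matrix(windows(series), entropy_bins))
    blocks.append(_stats9_matrix(windows(filtered.vedba), entropy_bins))
    for series in (filtered.roll, filtered.pitch, filtered.yaw):
        blocks.append(_stats4_matrix(windows(series)))
    spectral = [
        _spectral_stats_matrix(windows(series), fs, spectral_floor)
        for series in (filtered.dyn_x, filtered.dyn_y, filtered.dyn_z)
    ]
    # spectral blocks interleave as freq_{x,y,z} then amp_{x,y,z}
    blocks.extend(m[:, :4] for m in spectral)
    blocks.extend(m[:, 4:] for m in spectral)

    values = np.hstack(blocks)
    assert values.shape[1] == 99
    return pd.concat(
        [pd.DataFrame(rows_meta), pd.DataFrame(values, columns=FEATURE_NAMES)],
        axis=1,
    )


# sanity: STATS9/STATS4 orderings drive the matrix column order above
assert STATS9[:4] == STATS4
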