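"""Static/dynamic decomposition, VeDBA and tilt angles.

The movement-generated (dynamic) component of each axis is isolated with a
1.75-22.05 Hz band-pass; the gravitational (static) component with a
1.78 Hz low-pass.  Both are 4th-order Butterworth filters applied forward
and backward (zero phase) so samples stay aligned with behaviour labels.
The two cut-off bands overlap slightly by design, so dynamic + static only
approximately reconstructs the raw signal and no such identity is assumed.

VeDBA (vectorial dynamic body acceleration) is the per-sample Euclidean
norm of the three dynamic components — the standard scalar activity proxy.

Tilt angles are computed from the STATIC components (the rotated
gravitational field vector):

* roll  = atan(Y / sqrt(X^2 + Z^2))
* yaw   = atan(Z / sqrt(Y^2 + X^2))
* pitch = atan(X / sqrt(Y^2 + Z^2))

The roll and yaw forms are taken as printed in the source toolchain; pitch
is the axis-symmetric completion (an assumption, documented in the methods
note).  When a denominator is zero the angle is +-pi/2 by the sign of the
numerator, and 0 when the numerator is also zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from . import errors
from .io import AccelTrace

logger = logging.getLogger(__name__)

BANDPASS_LOW_HZ = 1.75
BANDPASS_HIGH_HZ = 22.05
LOWPASS_HZ = 1.78
FILTER_ORDER = 4


@dataclass
class FilteredTrace:
    """Per-axis static and dynamic components plus VeDBA and tilt series.

    ``edge_flag`` marks the first and last ceil(fs) samples where the
    zero-phase filter's reflected padding can distort the output; windows
    overlapping flagged samples may optionally be dropped downstream.
    """

    parent: AccelTrace
    dyn_x: np.ndarray
    dyn_y: np.ndarray
    dyn_z: np.ndarray
    stat_x: np.ndarray
    stat_y: np.ndarray
    stat_z: np.ndarray
    vedba: np.ndarray
    roll: np.ndarray
    pitch: np.ndarray
    yaw: np.ndarray
    edge_flag: np.ndarray

    def __len__(self) -> int:
        return len(self.parent)

    @property
    def fs(self) -> float:
        return self.parent.fs


def _sos(kind: str, cutoffs, fs: float):
    return sps.butter(FILTER_ORDER, cutoffs, btype=kind, fs=fs, output="sos")


def _min_samples(sos: np.ndarray) -> int:
    # sosfiltfilt default padlen is 3 * (2 * n_sections + 1); need > padlen
    return 3 * (2 * sos.shape[0] + 1) + 1


def decompose(trace: AccelTrace) -> FilteredTrace:
    """Split a raw trace into static and dynamic components per axis.

    Also fills in VeDBA and tilt angles so the result is ready for feature
    extraction.  Raises :class:`TraceTooShort` when the trace cannot
    support the zero-phase filter's edge padding.
    """
    fs = trace.fs
    high = BANDPASS_HIGH_HZ
    nyq = fs / 2.0
    if high >= nyq:
        high = 0.99 * nyq
        logger.warning(
            "band-pass upper edge %.2f Hz not realisable at fs=%.2f Hz; "
            "clipped to %.2f Hz",
            BANDPASS_HIGH_HZ,
            fs,
            high,
        )
    sos_band = _sos("bandpass", (BANDPASS_LOW_HZ, high), fs)
    sos_low = _sos("lowpass", LOWPASS_HZ, fs)
    need = max(_min_samples(sos_band), _min_samples(sos_low))
    if len(trace) < need:
        raise errors.TraceTooShort(
            f"{len(trace)} samples < {need} required for zero-phase filtering"
        )

    def run(sos, x):
        return sps.sosfiltfilt(sos, x)

    dyn = [run(sos_band, a) for a in (trace.x, trace.y, trace.z)]
    stat = [run(sos_low, a) for a in (trace.x, trace.y, trace.z)]
    v = vedba(*dyn)
    roll, pitch, yaw = tilt_angles(*stat)
    edge = np.zeros(len(trace), dtype=bool)
    k = min(int(np.ceil(fs)), len(trace))
    edge[:k] = True
    edge[len(trace) - k :] = True
    return FilteredTrace(
        parent=trace,
        dyn_x=dyn[0],
        dyn_y=dyn[1],
        dyn_z=dyn[2],
        stat_x=stat[0],
        stat_y=stat[1],
        stat_z=stat[2],
        vedba=v,
        roll=roll,
        pitch=pitch,
        yaw=yaw,
        edge_flag=edge,
    )


def vedba(dyn_x: np.ndarray, dyn_y: np.ndarray, dyn_z: np.ndarray) -> np.ndarray:
    """Vectorial dynamic body acceleration: sqrt(x^2 + y^2 + z^2) per sample."""
    dyn_x, dyn_y, dyn_z = (np.asarray(a, dtype=float) for a in (dyn_x, dyn_y, dyn_z))
    if not (len(dyn_x) == len(dyn_y) == len(dyn_z)):
        raise errors.LengthMismatch("dynamic component lengths differ")
    return np.sqrt(dyn_x**2 + dyn_y**2 + dyn_z**2)


def _tilt(num: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # atan2 gives the +-pi/2 degenerate-denominator convention for free
    # (atan2(0, 0) == 0), and the denominator sqrt is always >= 0.
    return np.arctan2(num, np.sqrt(a**2 + b**2))


def tilt_angles(
    stat_x: np.ndarray, stat_y: np.ndarray, stat_z: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Roll, pitch, yaw (radians) of the gravitational field vector."""
    stat_x, stat_y, stat_z = (
        np.asarray(a, dtype=float) for a in (stat_x, stat_y, stat_z)
    )
    if not (len(stat_x) == len(stat_y) == len(stat_z)):
        raise errors.LengthMismatch("static component lengths differ")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 0/0 handled by arctan2
        roll = _tilt(stat_y, stat_x, stat_z)
        pitch = _tilt(stat_x, stat_y, stat_z)
        yaw = _tilt(stat_z, stat_y, stat_x)
    return roll, pitch, yaw
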