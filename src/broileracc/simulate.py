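"""Synthetic broiler-flock accelerometry with annotated behaviours.

The generator emulates the statistical structure the classification
pipeline relies on, so every stage can be exercised without the original
recordings:

* **Bout structure.**  Each 5-min session is an alternating sequence of
  sit/stand/walk bouts.  Transitions are restricted to sit <-> stand and
  stand <-> walk — a bird does not go from sitting straight to walking.
  Bout durations are log-normal (the standard right-skewed choice when
  the sd is of the order of the mean), moment-matched per strain and
  behaviour to the study-population averages bundled in
  :data:`DEFAULT_PROFILES`, truncated below at 0.5 s.
* **Posture.**  The static (gravitational) signal is a unit gravity
  vector pitched by a posture-dependent angle — sitting tilts the device
  relative to standing — interpolated smoothly over 0.3 s at transitions.
* **Gait.**  Walking superimposes a stride sinusoid at 1/stride_period Hz
  (default 1 Hz, about one stride per second) plus a half-amplitude
  second harmonic on the surge and heave axes.
* **Idle motion and noise.**  Sitting and standing add band-limited
  (2.5-8 Hz) idle motion on all axes — standing with a larger amplitude
  than sitting — and every bout carries a log-normal vigour multiplier,
  so bout-to-bout amplitude varies the way animal movement does and the
  two stationary postures overlap dynamically while differing statically.
  All behaviours add white sensor noise.  Expected dynamic amplitudes are
  ordered sit < stand < walk by construction, so VeDBA separates the
  classes in expectation.

Everything is deterministic given the seed; per-bird streams are derived
with :class:`numpy.random.SeedSequence` so flocks are reproducible
bird-by-bird.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AccelTrace, LabelTrack, write_accel, write_labels
from .names import BEHAVIOURS

MIN_BOUT_S = 0.5
TRANSITION_SMOOTH_S = 0.3
#: sd of the per-bout log-normal vigour multiplier (idle motion / gait)
IDLE_VIGOUR_SIGMA = 0.35
GAIT_VIGOUR_SIGMA = 0.3
#: idle-motion band (Hz); kept above the static low-pass cut-off so
#: posture (gravity) recovery is not contaminated by tremor/sway
IDLE_BAND_HZ = (2.5, 8.0)

#: allowed behaviour transitions (no direct sit <-> walk)
TRANSITIONS: dict[str, tuple[str, ...]] = {
    "sit": ("stand",),
    "stand": ("sit", "walk"),
    "walk": ("stand",),
}


@dataclass(frozen=True)
class BoutLaw:
    """Mean and sd (seconds) of a behaviour's average bout duration."""

    mean_s: float
    sd_s: float

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the moment-matched log-normal."""
        cv2 = (self.sd_s / self.mean_s) ** 2
        sigma2 = np.log1p(cv2)
        mu = np.log(self.mean_s) - sigma2 / 2.0
        return mu, float(np.sqrt(sigma2))


@dataclass(frozen=True)
class StrainProfile:
    """Generative parameters for one strain.

    Bout-duration laws come from per-strain behaviour statistics; the
    movement amplitudes (g) must be ordered sit < stand < walk, and the
    posture pitch offsets (rad) make sitting and standing differ in
    static orientation.
    """

    name: str
    bouts: dict[str, BoutLaw]
    stride_period_s: float = 1.0
    walk_amp_g: float = 0.35
    stand_sway_amp_g: float = 0.05
    sit_residual_amp_g: float = 0.03
    sit_pitch_rad: float = -0.35
    stand_pitch_rad: float = 0.0
    noise_sd_g: float = 0.01

    def __post_init__(self) -> None:
        missing = [b for b in BEHAVIOURS if b not in self.bouts]
        if missing:
            raise ValueError(f"profile {self.name} missing bout laws for {missing}")
        if not self.sit_residual_amp_g < self.stand_sway_amp_g < self.walk_amp_g:
            raise ValueError("amplitudes must be ordered sit < stand < walk")
        if any(law.sd_s < 0 for law in self.bouts.values()):
            raise ValueError("bout sds must be >= 0")


def _profile(name, sit, stand, walk) -> StrainProfile:
    return StrainProfile(
        name=name,
        bouts={"sit": BoutLaw(*sit), "stand": BoutLaw(*stand), "walk": BoutLaw(*walk)},
    )


#: average bout duration mean/sd (s) per strain: one fast-growing
#: conventional strain (CNV), two slower-growing strains (SGH, SGN) and the
#: independent-study fast-growing strain (FGC, a.k.a. CFG).
DEFAULT_PROFILES: dict[str, StrainProfile] = {
    "CNV": _profile("CNV", (42.45, 42.97), (3.43, 1.87), (3.02, 1.58)),
    "SGH": _profile("SGH", (38.17, 50.48), (4.40, 3.50), (4.29, 2.33)),
    "SGN": _profile("SGN", (36.84, 43.06), (4.51, 2.61), (3.31, 1.58)),
    "FGC": _profile("FGC", (48.43, 25.65), (3.67, 2.55), (3.30, 2.22)),
}
DEFAULT_PROFILES["CFG"] = DEFAULT_PROFILES["FGC"]


@dataclass
class SimConfig:
    """Flock-level simulation settings.

    Defaults mirror the study conditions: strains CNV/SGH/SGN with
    8/10/15 birds, 5-min focal sessions, 50 Hz sampling.
    """

    strains: dict[str, int] = field(
        default_factory=lambda: {"CNV": 8, "SGH": 10, "SGN": 15}
    )
    session_s: float = 300.0
    fs: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_s <= 0 or self.fs <= 0:
            raise ValueError("session_s and fs must be positive")


def sample_bout_durations(
    law: BoutLaw, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Log-normal bout durations, rejection-truncated below at 0.5 s."""
    mu, sigma = law.lognormal_params()
    out = rng.lognormal(mu, sigma, size=size)
    bad = out < MIN_BOUT_S
    while bad.any():
        out[bad] = rng.lognormal(mu, sigma, size=int(bad.sum()))
        bad = out < MIN_BOUT_S
    return out


def sample_bouts(
    profile: StrainProfile,
    session_s: float,
    seed: int,
    bird_id: str = "bird",
) -> LabelTrack:
    """One session's behaviour sequence as a gap-free label track.

    Bouts alternate under the transition constraint; the final bout is
    truncated so interval lengths sum exactly to ``session_s``.
    """
    if session_s <= 0:
        raise ValueError("session_s must be positive")
    rng = np.random.default_rng(seed)
    behaviour = str(rng.choice(BEHAVIOURS))
    t = 0.0
    intervals: list[tuple[float, float, str]] = []
    while t < session_s:
        dur = float(sample_bout_durations(profile.bouts[behaviour], 1, rng)[0])
        end = min(t + dur, session_s)
        intervals.append((t, end, behaviour))
        t = end
        behaviour = str(rng.choice(TRANSITIONS[behaviour]))
    return LabelTrack(bird_id=bird_id, strain=profile.name, intervals=intervals)


def _behaviour_codes(track: LabelTrack, t: np.ndarray) -> np.ndarray:
    codes = np.zeros(len(t), dtype=np.int8)  # default sit
    lookup = {b: i for i, b in enumerate(BEHAVIOURS)}
    for start, end, behaviour in track.intervals:
        mask = (t >= start) & (t < end)
        codes[mask] = lookup[behaviour]
    return codes


def _bandlimited_noise(
    n: int, fs: float, low: float, high: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-sd noise confined to [low, high] Hz via FFT masking."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum[(freqs < low) | (freqs > high)] = 0.0
    shaped = np.fft.irfft(spectrum, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def synth_trace(
    track: LabelTrack,
    profile: StrainProfile,
    fs: float = 50.0,
    seed: int = 0,
) -> AccelTrace:
    """Synthesise the tri-axial acceleration for one behaviour sequence."""
    if not track.intervals:
        raise ValueError("track has no intervals")
    rng = np.random.default_rng(seed)
    session_s = track.intervals[-1][1]
    n = int(round(session_s * fs))
    t = np.arange(n) / fs
    codes = _behaviour_codes(track, t)
    sit, walk = codes == 0, codes == 2

    # posture: gravity pitched about the sway axis, smoothed at transitions
    pitch_target = np.where(sit, profile.sit_pitch_rad, profile.stand_pitch_rad)
    k = max(1, int(round(TRANSITION_SMOOTH_S * fs)))
    kernel = np.ones(k) / k
    pitch = np.convolve(
        np.pad(pitch_target, (k, k), mode="edge"), kernel, mode="same"
    )[k:-k]
    x = np.sin(pitch)
    y = np.zeros(n)
    z = np.cos(pitch)

    # per-bout vigour: idle-motion and gait amplitude envelopes (g per
    # sample); standing idles with a larger isotropic amplitude than
    # sitting, and each bout draws a log-normal multiplier so amplitude
    # varies bout to bout (the two postures overlap dynamically)
    idle = np.zeros(n)
    gait = np.zeros(n)
    for start, end, behaviour in track.intervals:
        seg = slice(int(round(start * fs)), int(round(end * fs)))
        base = (
            profile.stand_sway_amp_g
            if behaviour == "stand"
            else profile.sit_residual_amp_g
        )
        idle[seg] = base * rng.lognormal(0.0, IDLE_VIGOUR_SIGMA)
        if behaviour == "walk":
            gait[seg] = profile.walk_amp_g * rng.lognormal(0.0, GAIT_VIGOUR_SIGMA)

    # gait: stride fundamental plus half-amplitude second harmonic on
    # heave and surge while walking
    f0 = 1.0 / profile.stride_period_s
    stride = np.sin(2 * np.pi * f0 * t) + 0.5 * np.sin(4 * np.pi * f0 * t)
    phase = rng.uniform(0, 2 * np.pi)
    stride_x = np.sin(2 * np.pi * f0 * t + phase) + 0.5 * np.sin(
        4 * np.pi * f0 * t + 2 * phase
    )
    z = z + gait * stride * walk
    x = x + 0.6 * gait * stride_x * walk

    # band-limited idle motion on all axes while stationary
    stationary = ~walk
    lo, hi = IDLE_BAND_HZ
    x = x + idle * _bandlimited_noise(n, fs, lo, hi, rng) * stationary
    y = y + idle * _bandlimited_noise(n, fs, lo, hi, rng) * stationary
    z = z + idle * _bandlimited_noise(n, fs, lo, hi, rng) * stationary

    # white sensor noise on every axis
    x = x + rng.normal(0.0, profile.noise_sd_g, n)
    y = y + rng.normal(0.0, profile.noise_sd_g, n)
    z = z + rng.normal(0.0, profile.noise_sd_g, n)

    return AccelTrace(
        bird_id=track.bird_id, strain=track.strain, fs=fs, t=t, x=x, y=y, z=z
    )


def simulate_bird(
    profile: StrainProfile,
    config: SimConfig,
    bird_id: str,
    seed: int,
) -> tuple[AccelTrace, LabelTrack]:
    """Label track plus matching trace for one bird."""
    track = sample_bouts(profile, config.session_s, seed=seed, bird_id=bird_id)
    trace = synth_trace(track, profile, fs=config.fs, seed=seed + 1)
    return trace, track


def simulate_flock(
    config: SimConfig,
    profiles: dict[str, StrainProfile] | None = None,
) -> list[tuple[AccelTrace, LabelTrack]]:
    """Simulate every bird in the configured flock, deterministically.

    Bird ids are ``{strain}_{index:02d}``; per-bird seeds are spawned from
    the config seed so the flock is reproducible as a whole.
    """
    profiles = profiles or DEFAULT_PROFILES
    ss = np.random.SeedSequence(config.seed)
    n_total = sum(config.strains.values())
    child_seeds = ss.generate_state(2 * n_total) % (2**31 - 1)
    birds: list[tuple[AccelTrace, LabelTrack]] = []
    i = 0
    for strain in sorted(config.strains):
        profile = profiles[strain]
        for j in range(config.strains[strain]):
            birds.append(
                simulate_bird(
                    profile, config, bird_id=f"{strain}_{j:02d}", seed=int(child_seeds[2 * i])
                )
            )
            i += 1
    return birds


def write_flock(
    config: SimConfig,
    out_dir: str | Path,
    profiles: dict[str, StrainProfile] | None = None,
) -> pd.DataFrame:
    """Write per-bird trace and label CSVs plus a manifest; returns the
    manifest (bird_id, strain, trace/label paths, seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trace, track in simulate_flock(config, profiles):
        trace_path = out_dir / f"{trace.bird_id}_trace.csv"
        label_path = out_dir / f"{trace.bird_id}_labels.csv"
        write_accel(trace, trace_path)
        write_labels(track, label_path)
        rows.append(
            {
                "bird_id": trace.bird_id,
                "strain": trace.strain,
                "trace_file": trace_path.name,
                "label_file": label_path.name,
                "seed": config.seed,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
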