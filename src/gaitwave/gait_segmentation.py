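"""Gait-event detection from the right-thigh IMU angle.

Initial contact is the per-stride maximum of the thigh flexion angle; a
gait cycle runs between two successive initial contacts and is split
into stance and swing at the minimum thigh angle inside the cycle.
Angles are assumed flexion-positive (a sign flag flips the convention)
and already smooth; an optional moving-average pre-smoother handles
noisy traces.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "GaitEvents",
    "detect_initial_contacts",
    "split_stance_swing",
    "validate_cycles",
    "events_to_eeg_indices",
    "segment_recording",
]


@dataclass
class GaitEvents:
    """Initial contacts, stance/swing boundaries and per-cycle validity."""

    contacts: np.ndarray       # s, strictly increasing
    stance_ends: np.ndarray    # s, one per cycle, inside (c_i, c_{i+1})
    cycle_valid: np.ndarray    # bool, one per cycle

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=float)
        self.stance_ends = np.asarray(self.stance_ends, dtype=float)
        self.cycle_valid = np.asarray(self.cycle_valid, dtype=bool)
        if np.any(np.diff(self.contacts) <= 0):
            raise ValueError("contact times must be strictly increasing")
        n_cycles = max(len(self.contacts) - 1, 0)
        if len(self.stance_ends) != n_cycles or len(self.cycle_valid) != n_cycles:
            raise ValueError("stance_ends/cycle_valid must have one entry per cycle")
        lo, hi = self.contacts[:-1], self.contacts[1:]
        if np.any((self.stance_ends <= lo) | (self.stance_ends >= hi)):
            raise ValueError("each stance end must lie strictly inside its cycle")

    @property
    def n_cycles(self) -> int:
        return len(self.contacts) - 1 if len(self.contacts) else 0

    @property
    def stride_count(self) -> int:
        """Number of valid cycles."""
        return int(self.cycle_valid.sum())

    @property
    def cycle_durations(self) -> np.ndarray:
        return np.diff(self.contacts)

    @property
    def stance_fractions(self) -> np.ndarray:
        """Stance duration as a fraction of each cycle (swing = 1 - this)."""
        return (self.stance_ends - self.contacts[:-1]) / self.cycle_durations


def smooth_angle(angle: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average for noisy traces (odd window)."""
    angle = np.asarray(angle, dtype=float)
    if window < 2:
        return angle
    if window % 2 == 0:
        window += 1
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(angle, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def detect_initial_contacts(angle: np.ndarray, imu_rate: float,
                            min_period: float = 0.5,
                            prominence: float = 5.0,
                            flexion_positive: bool = True,
                            presmooth_window: int = 0) -> np.ndarray:
    """Initial-contact times: prominent thigh-angle maxima.

    Peaks need at least ``prominence`` degrees of rise over the
    surrounding troughs and ``min_period`` seconds of separation
    (defaults sized for slow walking, stride period >= ~1 s).  Flat
    peaks resolve to the first sample of the plateau.
    """
    angle = np.asarray(angle, dtype=float)
    if angle.size == 0:
        raise ValueError("empty angle series")
    if not np.all(np.isfinite(angle)):
        raise ValueError("angle series contains non-finite values")
    if imu_rate <= 0:
        raise ValueError("imu_rate must be positive")
    if not flexion_positive:
        angle = -angle
    if presmooth_window:
        angle = smooth_angle(angle, presmooth_window)
    distance = max(int(round(min_period * imu_rate)), 1)
    peaks, props = sps.find_peaks(angle, prominence=prominence,
                                  distance=distance, plateau_size=1)
    # tie-break flat peaks to the first sample of the plateau
    idx = props.get("left_edges", peaks)
    return np.asarray(idx, dtype=float) / imu_rate


def split_stance_swing(angle: np.ndarray, contacts: np.ndarray,
                       imu_rate: float,
                       flexion_positive: bool = True) -> np.ndarray:
    """Stance->swing boundary per cycle: the angle minimum inside it.

    The minimum is searched strictly between consecutive contacts; flat
    minima resolve to the first sample.
    """
    angle = np.asarray(angle, dtype=float)
    contacts = np.asarray(contacts, dtype=float)
    if len(contacts) < 2:
        raise ValueError("need at least two contacts to form a cycle")
    if not flexion_positive:
        angle = -angle
    out = np.empty(len(contacts) - 1)
    for i, (t0, t1) in enumerate(zip(contacts[:-1], contacts[1:])):
        i0 = int(round(t0 * imu_rate))
        i1 = int(round(t1 * imu_rate))
        if i1 - i0 < 3:
            raise ValueError(
                f"cycle {i} spans only {i1 - i0} IMU samples; cannot split")
        seg = angle[i0 + 1:i1]  # strictly inside the cycle
        out[i] = (i0 + 1 + int(np.argmin(seg))) / imu_rate
    return out


def validate_cycles(events: GaitEvents, policy: str = "median") -> GaitEvents:
    """Flag outlier cycles.

    ``"median"`` (default) invalidates cycles whose duration falls
    outside [0.5, 1.5] x the median duration; ``"none"`` keeps all.
    """
    if events.n_cycles < 1:
        raise ValueError("no cycles to validate")
    if policy == "none":
        valid = np.ones(events.n_cycles, dtype=bool)
    elif policy == "median":
        durations = events.cycle_durations
        med = float(np.median(durations))
        valid = (durations >= 0.5 * med) & (durations <= 1.5 * med)
    else:
        raise ValueError(f"unknown validation policy {policy!r}")
    return replace(events, cycle_valid=valid)


def events_to_eeg_indices(events: GaitEvents, eeg_rate: float,
                          n_eeg_samples: int | None = None,
                          valid_only: bool = True) -> list[tuple[int, int]]:
    """Half-open EEG sample ranges [start, end) per (valid) cycle.

    Events and EEG share t = 0 (sync markers); ``index = round(t * rate)``
    and adjacent cycles share their boundary sample exactly once.
    """
    idx = np.rint(events.contacts * eeg_rate).astype(int)
    ranges = []
    for i in range(events.n_cycles):
        if valid_only and not events.cycle_valid[i]:
            continue
        start, end = int(idx[i]), int(idx[i + 1])
        if start < 0 or (n_eeg_samples is not None and end > n_eeg_samples):
            raise ValueError(
                f"cycle [{start}, {end}) falls outside the EEG record "
                f"of {n_eeg_samples} samples")
        ranges.append((start, end))
    return ranges


def segment_recording(angle: np.ndarray, imu_rate: float,
                      min_period: float = 0.5, prominence: float = 5.0,
                      flexion_positive: bool = True,
                      presmooth_window: int = 0,
                      policy: str = "median") -> GaitEvents:
    """Full segmentation: contacts, stance splits, validity flags."""
    contacts = detect_initial_contacts(
        angle, imu_rate, min_period=min_period, prominence=prominence,
        flexion_positive=flexion_positive, presmooth_window=presmooth_window)
    if len(contacts) < 2:
        raise ValueError("fewer than two initial contacts detected")
    stance_ends = split_stance_swing(angle, contacts, imu_rate,
                                     flexion_positive=flexion_positive)
    events = GaitEvents(contacts=contacts, stance_ends=stance_ends,
                        cycle_valid=np.ones(len(contacts) - 1, dtype=bool))
    return validate_cycles(events, policy=policy)
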