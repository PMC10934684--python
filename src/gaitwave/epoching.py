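"""Per-cycle normalization and ensemble averaging into cycle matrices.

Every valid gait cycle of cleaned EEG is amplitude-normalized to its
local peak (per electrode, per cycle) and time-normalized to 100 points
spanning [0%, 100%) of the cycle; cycles are ensemble-averaged into one
30-electrode x 100-phase-point matrix per subject, and subjects into
mean/SD maps per group x condition cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import DEFAULT_MONTAGE, MontageInfo

__all__ = [
    "N_PHASE_POINTS",
    "CycleMatrix",
    "GroupMap",
    "extract_cycles",
    "normalize_cycle",
    "ensemble_average_subject",
    "ensemble_average_group",
]

#: Number of gait-phase samples per normalized cycle (percent resolution).
N_PHASE_POINTS = 100


@dataclass
class CycleMatrix:
    """One subject's ensemble-averaged 30 x 100 normalized amplitude map.

    Rows follow the montage's active-label order; columns are percent of
    the gait cycle.  Each constituent cycle trace had per-electrode peak
    magnitude 1 before averaging, so entries live in [-1, 1].
    """

    values: np.ndarray
    subject_id: str
    group: str
    condition: str
    n_cycles_averaged: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (30, N_PHASE_POINTS):
            raise ValueError(
                f"cycle matrix must be 30 x {N_PHASE_POINTS}, "
                f"got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cycle matrix contains non-finite values")

    @property
    def cell(self) -> str:
        return self.group + self.condition


@dataclass
class GroupMap:
    """Across-subject mean and sample SD for one design cell."""

    mean: np.ndarray
    sd: np.ndarray
    cell: str
    n_subjects: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != self.sd.shape:
            raise ValueError("mean/sd shape mismatch")
        if self.n_subjects < 2:
            raise ValueError("a group map needs at least 2 subjects")
        if np.any(self.sd < 0):
            raise ValueError("sd must be non-negative")


def extract_cycles(eeg_cleaned: np.ndarray,
                   index_ranges) -> list[np.ndarray]:
    """Slice the cleaned EEG into per-cycle segments.

    Ranges are half-open [start, end) sample intervals and must be
    ordered and non-overlapping (adjacent ranges may share a boundary).
    """
    eeg_cleaned = np.asarray(eeg_cleaned, dtype=float)
    n_samp = eeg_cleaned.shape[1]
    segments = []
    prev_end = None
    for start, end in index_ranges:
        if start < 0 or end > n_samp:
            raise ValueError(
                f"range [{start}, {end}) outside record of {n_samp} samples")
        if end <= start:
            raise ValueError(f"empty or inverted range [{start}, {end})")
        if prev_end is not None and start < prev_end:
            raise ValueError(
                f"range [{start}, {end}) overlaps previous range ending at "
                f"{prev_end}")
        prev_end = end
        segments.append(eeg_cleaned[:, start:end])
    return segments


def normalize_cycle(segment: np.ndarray,
                    montage: MontageInfo = DEFAULT_MONTAGE,
                    per_electrode: bool = True) -> np.ndarray:
    """Amplitude-normalize to the local peak, then resample to 100 points.

    Per electrode the cycle trace is divided by its maximum absolute
    value within the cycle (the local peak); with
    ``per_electrode=False`` a single peak across all electrodes is used
    instead.  The normalized trace is then linearly interpolated onto
    100 evenly spaced points covering [0%, 100%) of the cycle (the next
    cycle's shared boundary sample is excluded).
    """
    segment = np.asarray(segment, dtype=float)
    n_ch, length = segment.shape
    if length < 4:
        raise ValueError(f"cycle of {length} samples is too short to resample")
    peaks = np.max(np.abs(segment), axis=1)
    if per_electrode:
        flat = np.nonzero(peaks == 0)[0]
        if flat.size:
            labels = montage.active_labels if n_ch == montage.n_active else None
            name = labels[flat[0]] if labels else f"row {flat[0]}"
            raise ValueError(f"flat (all-zero) electrode trace: {name}")
        normalized = segment / peaks[:, None]
    else:
        peak = peaks.max()
        if peak == 0:
            raise ValueError("flat (all-zero) cycle segment")
        normalized = segment / peak
    # sample i sits at phase i/L; targets at k/100 of the cycle
    positions = np.arange(N_PHASE_POINTS) * length / N_PHASE_POINTS
    xp = np.arange(length, dtype=float)
    out = np.empty((n_ch, N_PHASE_POINTS))
    for c in range(n_ch):
        out[c] = np.interp(positions, xp, normalized[c])
    return out


def ensemble_average_subject(traces, subject_id: str = "S00",
                             group: str = "O",
                             condition: str = "sSC") -> CycleMatrix:
    """Elementwise mean across a subject's normalized cycle traces."""
    traces = [np.asarray(t, dtype=float) for t in traces]
    if not traces:
        raise ValueError("no cycle traces to average")
    shape = traces[0].shape
    for t in traces[1:]:
        if t.shape != shape:
            raise ValueError(f"trace shape mismatch: {t.shape} vs {shape}")
    stacked = np.stack(traces)
    return CycleMatrix(values=stacked.mean(axis=0), subject_id=subject_id,
                       group=group, condition=condition,
                       n_cycles_averaged=len(traces))


def ensemble_average_group(matrices, cell: str) -> GroupMap:
    """Across-subject mean and sample SD (n-1) for one design cell."""
    matrices = list(matrices)
    if len(matrices) < 2:
        raise ValueError("group averaging needs at least 2 subjects")
    for m in matrices:
        if m.cell != cell:
            raise ValueError(
                f"matrix from cell {m.cell!r} mixed into {cell!r} average")
    stacked = np.stack([m.values for m in matrices])
    return GroupMap(mean=stacked.mean(axis=0), sd=stacked.std(axis=0, ddof=1),
                    cell=cell, n_subjects=len(matrices))
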