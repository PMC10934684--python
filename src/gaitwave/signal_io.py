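"""Recording I/O, montage constants, and the stride-count table.

The analysis montage is a 32-electrode 10-20 cap: 30 active scalp
electrodes plus two mastoids (M1/M2), referenced at CPz with ground at
AFz.  Reference and ground never appear in analysis matrices; mastoids
are recorded but excluded from the 30-row cycle matrices.

EEG travels as EDF (16-bit, 1-second data records); the thigh-angle IMU
stream and the stride-count table travel as plain CSV.  EDF files are
read through :func:`mne.io.read_raw_edf`; writing uses a minimal EDF
writer implemented here.
"""

from __future__ import annotations

import io
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EEG_RATE",
    "IMU_RATE",
    "MontageInfo",
    "DEFAULT_MONTAGE",
    "RawRecording",
    "StepTable",
    "write_recording",
    "read_recording",
    "read_step_table",
    "load_reference_step_table",
    "summarize_steps",
]

#: Acquisition rates of the emulated hardware (Hz).
EEG_RATE = 512.0
IMU_RATE = 200.0

_ACTIVE_LABELS = (
    "Fp1", "Fp2", "Fpz", "F3", "F4", "F7", "F8", "Fz",
    "FC1", "FC2", "FC5", "FC6", "C3", "C4", "Cz", "T7", "T8",
    "CP1", "CP2", "CP5", "CP6", "P3", "P4", "P7", "P8", "Pz",
    "POz", "O1", "O2", "Oz",
)

# Approximate 2-D scalp coordinates (top view, nose up, unit head radius)
# used for spatially smooth synthetic mixing and topography-based
# component classification.  (x: left-negative, y: anterior-positive.)
_POSITIONS_2D = {
    "Fp1": (-0.31, 0.95), "Fpz": (0.0, 1.0), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.40, 0.55), "Fz": (0.0, 0.52),
    "F4": (0.40, 0.55), "F8": (0.81, 0.59),
    "FC5": (-0.68, 0.30), "FC1": (-0.22, 0.27), "FC2": (0.22, 0.27),
    "FC6": (0.68, 0.30),
    "T7": (-1.0, 0.0), "C3": (-0.50, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.50, 0.0), "T8": (1.0, 0.0),
    "CP5": (-0.68, -0.30), "CP1": (-0.22, -0.27), "CP2": (0.22, -0.27),
    "CP6": (0.68, -0.30),
    "P7": (-0.81, -0.59), "P3": (-0.40, -0.55), "Pz": (0.0, -0.52),
    "P4": (0.40, -0.55), "P8": (0.81, -0.59),
    "POz": (0.0, -0.76), "O1": (-0.31, -0.95), "Oz": (0.0, -1.0),
    "O2": (0.31, -0.95),
    "M1": (-1.05, -0.35), "M2": (1.05, -0.35),
}


@dataclass(frozen=True)
class MontageInfo:
    """Electrode layout of the recording cap.

    ``active_labels`` are the 30 scalp electrodes that form the rows of
    every analysis matrix, in canonical order.  Mastoids are carried in
    recordings but dropped from analysis; reference and ground are not
    recorded at all.
    """

    active_labels: tuple[str, ...] = _ACTIVE_LABELS
    mastoids: tuple[str, ...] = ("M1", "M2")
    reference: str = "CPz"
    ground: str = "AFz"

    def __post_init__(self) -> None:
        if len(self.active_labels) != 30:
            raise ValueError("montage must define exactly 30 active labels")
        if len(set(self.active_labels)) != 30:
            raise ValueError("active labels must be unique")
        overlap = {self.reference, self.ground} & set(self.active_labels)
        if overlap:
            raise ValueError(f"reference/ground cannot be active: {overlap}")

    @property
    def recorded_labels(self) -> tuple[str, ...]:
        """All channels present in a raw file (active + mastoids)."""
        return self.active_labels + self.mastoids

    @property
    def n_active(self) -> int:
        return len(self.active_labels)

    def index(self, label: str) -> int:
        """Row index of an active electrode (case/underscore tolerant)."""
        key = _norm_label(label)
        for i, lab in enumerate(self.active_labels):
            if _norm_label(lab) == key:
                return i
        raise KeyError(f"electrode {label!r} is not an active montage label")

    def positions(self, labels=None) -> np.ndarray:
        """(n, 2) approximate scalp coordinates for ``labels``."""
        labels = self.active_labels if labels is None else labels
        return np.array([_POSITIONS_2D[lab] for lab in labels])


DEFAULT_MONTAGE = MontageInfo()


def _norm_label(label: str) -> str:
    return label.replace("_", "").replace(" ", "").upper()


@dataclass
class GroundTruth:
    """Generator-side truth attached to synthetic recordings."""

    contact_times: np.ndarray          # s, one per initial contact
    stance_end_times: np.ndarray       # s, one per cycle
    cycle_template: np.ndarray         # gait-locked waveform on [0, 1) phase
    template_electrode_gain: np.ndarray  # per recorded channel, unitless
    sources: dict = field(default_factory=dict)  # name -> source time series


@dataclass
class RawRecording:
    """One subject x condition recording: EEG + thigh-angle IMU.

    EEG is channels x samples in microvolts; the IMU stream is the right
    thigh flexion angle in degrees.  Both streams share t = 0 through the
    sync markers (emulated as a common start marker).
    """

    eeg: np.ndarray
    imu_angle: np.ndarray
    eeg_rate: float = EEG_RATE
    imu_rate: float = IMU_RATE
    markers: list = field(default_factory=lambda: [(0.0, "sync_start")])
    subject_id: str = "S00"
    group: str = "O"
    condition: str = "sSC"
    channel_labels: tuple[str, ...] = DEFAULT_MONTAGE.recorded_labels
    truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=float)
        self.imu_angle = np.asarray(self.imu_angle, dtype=float)
        if self.eeg.ndim != 2:
            raise ValueError("eeg must be channels x samples")
        if len(self.channel_labels) != self.eeg.shape[0]:
            raise ValueError(
                f"eeg has {self.eeg.shape[0]} channels but "
                f"{len(self.channel_labels)} labels"
            )
        if self.group not in ("O", "T"):
            raise ValueError(f"group must be 'O' or 'T', got {self.group!r}")
        if self.condition not in ("sSC", "SC"):
            raise ValueError(f"condition must be 'sSC' or 'SC', got {self.condition!r}")

    @property
    def cell(self) -> str:
        """Design cell name, e.g. ``'TsSC'``."""
        return self.group + self.condition

    @property
    def duration(self) -> float:
        return self.eeg.shape[1] / self.eeg_rate

    def active_eeg(self, montage: MontageInfo = DEFAULT_MONTAGE) -> np.ndarray:
        """EEG restricted to the 30 active electrodes in montage order."""
        norm = {_norm_label(l): i for i, l in enumerate(self.channel_labels)}
        rows = []
        for lab in montage.active_labels:
            key = _norm_label(lab)
            if key not in norm:
                raise KeyError(f"recording is missing active electrode {lab!r}")
            rows.append(norm[key])
        return self.eeg[rows]


# --------------------------------------------------------------------------
# EDF writing (minimal EDF, 16-bit, 1-second records) and reading via mne
# --------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, eeg_uv: np.ndarray, rate: float, labels,
              patient_id: str = "X") -> None:
    """Write microvolt EEG to an EDF file (one 1-s data record per second).

    The last partial second, if any, is padded by repeating the final
    sample; readers should trim to the sample count stored in the
    side-car manifest.
    """
    eeg_uv = np.asarray(eeg_uv, dtype=float)
    n_ch, n_samp = eeg_uv.shape
    spr = int(round(rate))  # samples per 1-s record
    n_rec = math.ceil(n_samp / spr)
    pad = n_rec * spr - n_samp
    if pad:
        eeg_uv = np.concatenate([eeg_uv, np.repeat(eeg_uv[:, -1:], pad, axis=1)], axis=1)

    phys_min = np.floor(eeg_uv.min(axis=1))
    phys_max = np.ceil(eeg_uv.max(axis=1))
    flat = phys_max <= phys_min
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    header = io.BytesIO()
    header.write(_edf_field("0", 8))
    header.write(_edf_field(patient_id, 80))
    header.write(_edf_field("gaitwave recording", 80))
    header.write(_edf_field("01.01.20", 8))
    header.write(_edf_field("00.00.00", 8))
    header.write(_edf_field(str(256 * (1 + n_ch)), 8))
    header.write(_edf_field("", 44))
    header.write(_edf_field(str(n_rec), 8))
    header.write(_edf_field("1", 8))
    header.write(_edf_field(str(n_ch), 4))
    for lab in labels:
        header.write(_edf_field(lab, 16))
    for _ in range(n_ch):
        header.write(_edf_field("AgAgCl electrode", 80))
    for _ in range(n_ch):
        header.write(_edf_field("uV", 8))
    for v in phys_min:
        header.write(_edf_field(f"{v:.0f}", 8))
    for v in phys_max:
        header.write(_edf_field(f"{v:.0f}", 8))
    for _ in range(n_ch):
        header.write(_edf_field(str(dig_min), 8))
    for _ in range(n_ch):
        header.write(_edf_field(str(dig_max), 8))
    for _ in range(n_ch):
        header.write(_edf_field("", 80))
    for _ in range(n_ch):
        header.write(_edf_field(str(spr), 8))
    for _ in range(n_ch):
        header.write(_edf_field("", 32))

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((eeg_uv - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header.getvalue())
        for r in range(n_rec):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())  # channel-sequential within record


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF file; returns (microvolt data, rate, labels)."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    data_uv = raw.get_data() * 1e6  # mne holds volts
    return data_uv, float(raw.info["sfreq"]), list(raw.ch_names)


def write_recording(rec: RawRecording, out_dir, stem: str | None = None) -> dict:
    """Persist a recording as EDF (EEG) + CSV (IMU) + JSON manifest.

    Returns the manifest dictionary (also written to ``<stem>.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{rec.subject_id}_{rec.condition}"
    edf_path = out_dir / f"{stem}.edf"
    imu_path = out_dir / f"{stem}_imu.csv"
    man_path = out_dir / f"{stem}.json"

    write_edf(edf_path, rec.eeg, rec.eeg_rate, rec.channel_labels,
              patient_id=rec.subject_id)
    t = np.arange(rec.imu_angle.size) / rec.imu_rate
    pd.DataFrame({"time_s": t, "thigh_angle_deg": rec.imu_angle}).to_csv(
        imu_path, index=False)

    manifest = {
        "subject_id": rec.subject_id,
        "group": rec.group,
        "condition": rec.condition,
        "eeg_rate": rec.eeg_rate,
        "imu_rate": rec.imu_rate,
        "n_eeg_samples": int(rec.eeg.shape[1]),
        "markers": [[float(t0), lab] for t0, lab in rec.markers],
        "edf": edf_path.name,
        "imu_csv": imu_path.name,
    }
    man_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def read_recording(edf_path, imu_csv_path, manifest_entry: dict,
                   montage: MontageInfo = DEFAULT_MONTAGE) -> RawRecording:
    """Load a recording from EDF + IMU CSV, validating against the montage.

    All 30 active electrodes must be present (matched case- and
    underscore-insensitively); missing mastoids are tolerated.  The IMU
    time column must be strictly increasing and consistent with the
    manifest's sampling rate.
    """
    data_uv, rate, labels = read_edf(edf_path)
    man_rate = float(manifest_entry.get("eeg_rate", rate))
    if abs(rate - man_rate) > 1e-6 * max(rate, man_rate):
        raise ValueError(
            f"EDF sampling rate {rate} Hz does not match manifest {man_rate} Hz")

    norm = {_norm_label(l): i for i, l in enumerate(labels)}
    rows, kept = [], []
    for lab in montage.active_labels:
        key = _norm_label(lab)
        if key not in norm:
            raise ValueError(f"EDF is missing active electrode {lab!r}")
        rows.append(norm[key])
        kept.append(lab)
    for lab in montage.mastoids:
        key = _norm_label(lab)
        if key in norm:
            rows.append(norm[key])
            kept.append(lab)
    eeg = data_uv[rows]
    n_keep = manifest_entry.get("n_eeg_samples")
    if n_keep is not None:
        eeg = eeg[:, : int(n_keep)]

    imu = pd.read_csv(imu_csv_path)
    if "time_s" not in imu.columns or "thigh_angle_deg" not in imu.columns:
        raise ValueError("IMU CSV must have columns time_s, thigh_angle_deg")
    t = imu["time_s"].to_numpy(float)
    if t.size == 0:
        raise ValueError("IMU CSV is empty")
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone time in IMU CSV")
    imu_rate = float(manifest_entry.get("imu_rate", IMU_RATE))
    if t.size > 1:
        dt = float(np.median(np.diff(t)))
        if abs(dt - 1.0 / imu_rate) > 0.01 / imu_rate:
            raise ValueError(
                f"IMU sample spacing {dt:.6f}s inconsistent with "
                f"manifest rate {imu_rate} Hz")

    markers = [(float(m[0]), str(m[1])) for m in manifest_entry.get(
        "markers", [[0.0, "sync_start"]])]
    return RawRecording(
        eeg=eeg,
        imu_angle=imu["thigh_angle_deg"].to_numpy(float),
        eeg_rate=man_rate,
        imu_rate=imu_rate,
        markers=markers,
        subject_id=str(manifest_entry.get("subject_id", "S00")),
        group=str(manifest_entry.get("group", "O")),
        condition=str(manifest_entry.get("condition", "sSC")),
        channel_labels=tuple(kept),
    )


# --------------------------------------------------------------------------
# Stride-count table
# --------------------------------------------------------------------------

@dataclass
class StepTable:
    """Per-subject stride counts over the 3-min walks, both conditions."""

    frame: pd.DataFrame  # columns: subject_id, group, steps_sSC, steps_SC

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "steps_sSC", "steps_SC"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"step table missing columns: {sorted(missing)}")
        for col in ("steps_sSC", "steps_SC"):
            vals = self.frame[col]
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise ValueError(f"non-integer stride counts in {col}")
            if (vals < 0).any():
                raise ValueError(f"negative stride counts in {col}")
        bad = set(self.frame["group"]) - {"O", "T"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.frame)


def read_step_table(csv_path) -> StepTable:
    """Read a stride-count CSV (subject_id, group, steps_sSC, steps_SC)."""
    frame = pd.read_csv(csv_path)
    if frame.empty:
        raise ValueError("step table is empty")
    return StepTable(frame)


def load_reference_step_table() -> StepTable:
    """The packaged reference stride-count table (24 walkers, O/T groups)."""
    with resources.files("gaitwave.data").joinpath("step_counts.csv").open() as fh:
        frame = pd.read_csv(fh)
    return StepTable(frame)


def _round_half_away(x: float, decimals: int = 1) -> float:
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def summarize_steps(table: StepTable) -> dict[tuple[str, str], tuple[float, float]]:
    """Mean and sample SD of stride counts per (group, condition) cell.

    SD uses the n-1 denominator; both numbers are rounded
    half-away-from-zero to one decimal, the convention of the printed
    summary row they mirror.
    """
    out: dict[tuple[str, str], tuple[float, float]] = {}
    for group, sub in table.frame.groupby("group"):
        if len(sub) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 subjects")
        for cond, col in (("sSC", "steps_sSC"), ("SC", "steps_SC")):
            vals = sub[col].to_numpy(float)
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1))
            out[(group, cond)] = (_round_half_away(mean), _round_half_away(sd))
    return out
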