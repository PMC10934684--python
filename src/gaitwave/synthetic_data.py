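"""Synthetic walking cohorts: synchronized EEG + thigh-IMU recordings.

The generator emulates the acquisition geometry of a mobile walking
study — 32-channel EEG at 512 Hz and a right-thigh orientation angle at
200 Hz sharing t = 0 — with known ground truth, so every downstream
stage (filtering, ICA, gait segmentation, epoching, SnPM) is testable
without real data.

A subject is built from:

* a gait clock: initial-contact times with configurable stride rate and
  stride-duration variability; the thigh angle has one flexion maximum
  per stride (initial contact) and one minimum (stance -> swing) at a
  fixed fraction of the cycle;
* a gait-locked cortical source: a stereotyped delta-band waveform
  repeated each cycle and warped to the cycle's duration, projected to
  the scalp with a smooth centro-frontal gain profile;
* artifact sources with the walking-EEG inventory (blink + eye-drift
  ocular pair, one glossokinetic, two burst-modulated EMG) and their
  characteristic topographies;
* 1/f-shaped background noise per channel;
* an optional injected group x condition effect: an amplitude bump
  confined to a gait-phase window at named electrodes, added only in
  the affected design cells.

Two cohort paths exist.  ``generate_cohort`` produces full signal-level
recordings.  ``generate_cohort_matrices`` emulates the *post-epoching*
statistics directly — per-subject 30 x 100 normalized cycle matrices
whose noise shrinks with the subject's stride count as 1/sqrt(n_cycles),
exactly what ensemble averaging across strides does — and is the
workhorse for statistical calibration studies where thousands of
subjects are needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epoching import CycleMatrix, N_PHASE_POINTS
from .signal_io import (DEFAULT_MONTAGE, EEG_RATE, IMU_RATE, GroundTruth,
                        MontageInfo, RawRecording)

__all__ = [
    "GaitModel",
    "ArtifactModel",
    "EffectSpec",
    "CohortDataset",
    "CELLS",
    "cycle_template",
    "generate_subject",
    "generate_cohort",
    "generate_cohort_matrices",
    "STRIDE_COUNT_DISTRIBUTIONS",
]

CELLS = ("OsSC", "OSC", "TsSC", "TSC")

#: Stride-count (strides per 3 min) mean/SD per design cell, matching the
#: study conditions this generator emulates: self-selected overground and
#: treadmill walking are dispersed, metronome-cued walking is tight.
STRIDE_COUNT_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "TsSC": (116.7, 17.0),
    "OsSC": (88.4, 16.0),
    "TSC": (68.0, 0.7),
    "OSC": (68.0, 0.8),
}

_REFERENCE_DURATION = 180.0  # s, the 3-min walk the counts refer to


@dataclass(frozen=True)
class GaitModel:
    """Kinematic parameters of one walking bout.

    ``stride_rate`` in strides/s, ``stride_cv`` the coefficient of
    variation of stride duration, ``stance_fraction`` the fraction of
    each cycle spent in stance (minimum thigh angle at that phase), and
    ``duration`` the bout length in seconds.
    """

    stride_rate: float
    stride_cv: float = 0.0
    stance_fraction: float = 0.6
    duration: float = 180.0

    def __post_init__(self) -> None:
        if self.stride_rate <= 0:
            raise ValueError("stride_rate must be positive")
        if self.stride_cv < 0:
            raise ValueError("stride_cv must be non-negative")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class ArtifactModel:
    """Amplitudes (microvolts) and rates of the artifact sources."""

    ocular_rate: float = 0.25     # blinks per second
    ocular_amp: float = 100.0
    glossokinetic_amp: float = 30.0
    emg_amp: float = 10.0
    emg_band: tuple[float, float] = (20.0, 60.0)

    def __post_init__(self) -> None:
        if min(self.ocular_rate, self.ocular_amp, self.glossokinetic_amp,
               self.emg_amp) < 0:
            raise ValueError("artifact rates/amplitudes must be >= 0")
        lo, hi = self.emg_band
        if not (13.0 < lo < hi < 100.0):
            raise ValueError("emg_band must sit within (13, 100) Hz")

    @classmethod
    def silent(cls) -> "ArtifactModel":
        return cls(ocular_rate=0.0, ocular_amp=0.0, glossokinetic_amp=0.0,
                   emg_amp=0.0)


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth injected amplitude effect.

    ``amplitude_delta`` is expressed in the units of the stream it is
    injected into: microvolts at the signal level, normalized amplitude
    (a.u.) at the matrix level.  ``affected_cells`` names the design
    cells that receive the bump; ``factor`` records which ANOVA effect
    the injection is meant to drive.
    """

    electrodes: tuple[str, ...] = ("Fz",)
    phase_window: tuple[float, float] = (3.0, 8.0)
    amplitude_delta: float = 0.0
    factor: str = "interaction"
    affected_cells: frozenset[str] = frozenset({"TsSC"})

    def __post_init__(self) -> None:
        lo, hi = self.phase_window
        if not 0 <= lo < hi <= 100:
            raise ValueError("phase_window must satisfy 0 <= start < end <= 100")
        if self.factor not in ("group", "condition", "interaction"):
            raise ValueError(f"unknown factor {self.factor!r}")
        bad = set(self.affected_cells) - set(CELLS)
        if bad:
            raise ValueError(f"unknown design cells: {sorted(bad)}")
        for e in self.electrodes:
            DEFAULT_MONTAGE.index(e)  # raises on unknown labels

    @classmethod
    def null(cls) -> "EffectSpec":
        return cls(amplitude_delta=0.0)

    def applies_to(self, cell: str) -> bool:
        return self.amplitude_delta != 0 and cell in self.affected_cells


@dataclass
class CohortDataset:
    """A generated 2-group x 2-condition cohort with its manifest."""

    recordings: list[RawRecording]
    manifest: list[dict]
    effect: EffectSpec
    seed: int

    @property
    def n_subjects(self) -> int:
        return len({m["subject_id"] for m in self.manifest})


# --------------------------------------------------------------------------
# Waveforms
# --------------------------------------------------------------------------

# Harmonic mix of the gait-locked waveform: stride harmonics 2-4 with
# amplitudes/phases chosen so the magnitude peak falls in mid stance
# (25% of the cycle) and the early-stance decile stays below 0.3 of the
# peak.  Two constraints drive this: (i) at slow walking cadences the
# stride fundamental sits under the 0.5 Hz delta high-pass corner, so
# the waveform must live in harmonics >= 2 to survive filtering intact;
# (ii) under per-cycle peak normalization an amplitude change that
# coincides with the trace maximum is unobservable by construction, so
# the peak must sit away from the early-stance region where
# phase-confined effects are typically injected.
_TEMPLATE_HARMONICS = ((2, 1.0, 5.3539), (3, 0.4962, 2.2695),
                       (4, 0.3955, 1.5512))


def _template_raw(phase: np.ndarray) -> np.ndarray:
    phase = np.asarray(phase)
    return sum(a * np.sin(2 * np.pi * h * phase + p)
               for h, a, p in _TEMPLATE_HARMONICS)


_probe = np.linspace(0.0, 1.0, 10001, endpoint=False)
_TEMPLATE_PEAK = float(np.max(np.abs(_template_raw(_probe))))
del _probe


def cycle_template(phase: np.ndarray) -> np.ndarray:
    """Stereotyped gait-locked delta waveform on phase in [0, 1).

    Built from stride harmonics 2-4 so that, at slow walking cadences
    (stride rates well below 1 Hz), its spectral content sits inside
    the delta passband rather than under the 0.5 Hz high-pass corner.
    Peak magnitude 1, reached in mid stance (25% of the cycle).
    """
    return _template_raw(phase) / _TEMPLATE_PEAK

THIGH_ANGLE_MAX = 30.0  # deg, at initial contact
THIGH_ANGLE_MIN = -10.0  # deg, at the stance -> swing transition


def _thigh_angle_from_phase(phase: np.ndarray, stance_fraction: float
                            ) -> np.ndarray:
    """Thigh angle over the cycle: max at phase 0, min at stance end.

    Quarter-sinusoid segments with a sub-linear exponent give a smooth
    (zero-slope) minimum at the stance -> swing transition but a sharp
    reversal at initial contact — the thigh swings forward into contact
    and reverses abruptly, which is what makes the per-stride maximum
    localizable to within a sample even on noisy traces.
    """
    phase = np.mod(phase, 1.0)
    amp = THIGH_ANGLE_MAX - THIGH_ANGLE_MIN
    sharp = 0.6  # < 1: cusp-like reversal at the contact peak
    stance = phase < stance_fraction
    out = np.empty_like(phase)
    st = phase[stance] / stance_fraction
    out[stance] = THIGH_ANGLE_MIN + amp * (
        1.0 - np.sin(0.5 * np.pi * st) ** sharp)
    sw = (phase[~stance] - stance_fraction) / (1.0 - stance_fraction)
    out[~stance] = THIGH_ANGLE_MIN + amp * (
        1.0 - np.cos(0.5 * np.pi * sw) ** sharp)
    return out


def _contact_times(gait: GaitModel, rng: np.random.Generator,
                   start_offset: float = 0.6,
                   end_margin: float = 0.25) -> np.ndarray:
    """Initial-contact times: first at ``start_offset``, last at least
    ``end_margin`` before the record end."""
    mean_t = 1.0 / gait.stride_rate
    sd_t = gait.stride_cv * mean_t
    contacts = [min(start_offset, gait.duration / 2)]
    limit = gait.duration - end_margin
    while True:
        step = mean_t if sd_t == 0 else max(rng.normal(mean_t, sd_t),
                                            0.3 * mean_t)
        nxt = contacts[-1] + step
        if nxt > limit:
            break
        contacts.append(nxt)
    return np.asarray(contacts)


def _phase_track(t: np.ndarray, contacts: np.ndarray,
                 nominal_period: float,
                 stance_fraction: float = 0.6) -> np.ndarray:
    """Continuous cycle phase: k + fraction inside cycle k.

    Extended with one virtual cycle of nominal duration before the
    first contact; after the last contact the phase is frozen once the
    stance minimum is reached (the walker stops), so no further thigh
    maximum occurs.
    """
    ext = np.concatenate([[contacts[0] - nominal_period], contacts,
                          [contacts[-1] + nominal_period]])
    phase = np.interp(t, ext, np.arange(len(ext)) - 1.0)
    tail_limit = len(contacts) - 1  # phase of the last real contact
    return np.minimum(phase, tail_limit + stance_fraction)


def _gaussian_profile(montage: MontageInfo, labels, center: tuple[float, float],
                      sigma: float) -> np.ndarray:
    pos = montage.positions(labels)
    d2 = np.sum((pos - np.asarray(center)) ** 2, axis=1)
    return np.exp(-d2 / (2 * sigma ** 2))


def _label_profile(labels, weights: dict[str, float],
                   background: float = 0.05) -> np.ndarray:
    return np.array([weights.get(lab, background) for lab in labels])


def _one_over_f_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                      rate: float, sd: float) -> np.ndarray:
    """Per-channel Gaussian noise with ~1/f amplitude spectrum, given SD."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / rate)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, freqs[1] if len(freqs) > 1 else 1.0))
    shaping[0] = 0.0
    colored = np.fft.irfft(spec * shaping, n=n_samp, axis=1)
    current = colored.std(axis=1, keepdims=True)
    current[current == 0] = 1.0
    return colored / current * sd


def _bandlimited_noise(rng: np.random.Generator, n_samp: int, rate: float,
                       band: tuple[float, float]) -> np.ndarray:
    """Unit-SD noise confined to ``band`` Hz (spectral masking)."""
    white = rng.standard_normal(n_samp)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / rate)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    out = np.fft.irfft(spec, n=n_samp)
    sd = out.std()
    return out / sd if sd > 0 else out


def _pulse_train(rng: np.random.Generator, n_samp: int, rate: float,
                 events_per_s: float, width_s: float) -> np.ndarray:
    """Raised-cosine pulses at Poisson times; unit peak amplitude."""
    out = np.zeros(n_samp)
    if events_per_s <= 0:
        return out
    n_events = rng.poisson(events_per_s * n_samp / rate)
    half = int(width_s * rate / 2)
    window = 0.5 * (1 + np.cos(np.linspace(-np.pi, np.pi, 2 * half + 1)))
    for center in np.sort(rng.integers(half, max(n_samp - half, half + 1),
                                       size=n_events)):
        out[center - half:center + half + 1] += window
    return out


def _phase_bump(phase_mod: np.ndarray, window_pct: tuple[float, float]
                ) -> np.ndarray:
    """Raised-cosine bump over a gait-phase window, peak 1, repeated
    every cycle."""
    lo, hi = window_pct[0] / 100.0, window_pct[1] / 100.0
    inside = (phase_mod >= lo) & (phase_mod < hi)
    out = np.zeros_like(phase_mod)
    rel = (phase_mod[inside] - lo) / (hi - lo)
    out[inside] = 0.5 * (1 - np.cos(2 * np.pi * rel))
    return out


# --------------------------------------------------------------------------
# Subject-level generation
# --------------------------------------------------------------------------

#: Scalp gain profiles of the generator's sources (computed lazily against
#: the recorded-channel list of the default montage).
def _source_profiles(montage: MontageInfo) -> dict[str, np.ndarray]:
    labels = montage.recorded_labels
    prof = {
        # centro-frontal cortical gain for the gait-locked component
        "gait": _gaussian_profile(montage, labels, (0.0, 0.25), 0.5),
        # blink: prefrontal, steep fall-off
        "blink": _gaussian_profile(montage, labels, (0.0, 1.1), 0.35),
        # lateral eye drift: F7/F8 dipole
        "eye_drift": (_gaussian_profile(montage, labels, (-0.85, 0.65), 0.3)
                      - _gaussian_profile(montage, labels, (0.85, 0.65), 0.3)),
        # glossokinetic: inferior-frontal / temporal ring
        "glossokinetic": _label_profile(labels, {
            "F7": 1.0, "F8": 1.0, "T7": 0.9, "T8": 0.9,
            "FC5": 0.5, "FC6": 0.5, "M1": 0.4, "M2": 0.4,
            "Fp1": 0.25, "Fp2": 0.25, "Fpz": 0.2}),
        "emg_left": _label_profile(labels, {
            "T7": 1.0, "FC5": 0.45, "CP5": 0.45, "M1": 0.6, "F7": 0.3}),
        "emg_right": _label_profile(labels, {
            "T8": 1.0, "FC6": 0.45, "CP6": 0.45, "M2": 0.6, "F8": 0.3}),
    }
    return prof


GAIT_COMPONENT_AMP = 5.0   # microvolts, gait-locked delta source peak
BACKGROUND_NOISE_SD = 3.0  # microvolts, 1/f background per channel


def generate_subject(gait: GaitModel, artifacts: ArtifactModel,
                     effect: EffectSpec, cell: str, seed: int,
                     subject_id: str | None = None,
                     montage: MontageInfo = DEFAULT_MONTAGE,
                     background_noise_sd: float = BACKGROUND_NOISE_SD,
                     gait_component_amp: float = GAIT_COMPONENT_AMP,
                     angle_noise_sd: float = 0.0) -> RawRecording:
    """One synthetic subject x condition recording with ground truth.

    Deterministic given ``seed``.  The returned recording carries a
    :class:`~gaitwave.signal_io.GroundTruth` with the true contact
    times, the embedded per-cycle template and every source time
    series.
    """
    if cell not in CELLS:
        raise ValueError(f"unknown design cell {cell!r}")
    rng = np.random.default_rng(seed)
    group, condition = cell[0], cell[1:]
    labels = montage.recorded_labels
    n_ch = len(labels)
    n_eeg = int(round(gait.duration * EEG_RATE))
    n_imu = int(round(gait.duration * IMU_RATE))
    t_eeg = np.arange(n_eeg) / EEG_RATE
    t_imu = np.arange(n_imu) / IMU_RATE

    contacts = _contact_times(gait, rng)
    nominal = 1.0 / gait.stride_rate
    phase_imu = _phase_track(t_imu, contacts, nominal, gait.stance_fraction)
    angle = _thigh_angle_from_phase(phase_imu, gait.stance_fraction)
    if angle_noise_sd > 0:
        # residual noise on a Kalman-smoothed orientation stream is
        # band-limited, not white: low-pass it to 15 Hz
        angle = angle + angle_noise_sd * _bandlimited_noise(
            rng, n_imu, IMU_RATE, (0.0, 15.0))
    stance_ends = contacts[:-1] + gait.stance_fraction * np.diff(contacts)

    phase_eeg = _phase_track(t_eeg, contacts, nominal, gait.stance_fraction)
    phase_mod = np.mod(phase_eeg, 1.0)
    profiles = _source_profiles(montage)

    gait_source = gait_component_amp * cycle_template(phase_mod)
    blink = artifacts.ocular_amp * _pulse_train(
        rng, n_eeg, EEG_RATE, artifacts.ocular_rate, width_s=0.3)
    eye_drift = 0.3 * artifacts.ocular_amp * _bandlimited_noise(
        rng, n_eeg, EEG_RATE, (0.05, 1.5)) if artifacts.ocular_amp else \
        np.zeros(n_eeg)
    gloss = artifacts.glossokinetic_amp * _pulse_train(
        rng, n_eeg, EEG_RATE, 0.1, width_s=0.8)
    # burst-modulated EMG, bursts locked to opposite gait phases
    emg_l = emg_r = np.zeros(n_eeg)
    if artifacts.emg_amp > 0:
        burst_l = 0.25 + _phase_bump(phase_mod, (55.0, 100.0))
        burst_r = 0.25 + _phase_bump(phase_mod, (5.0, 50.0))
        emg_l = artifacts.emg_amp * burst_l * _bandlimited_noise(
            rng, n_eeg, EEG_RATE, artifacts.emg_band)
        emg_r = artifacts.emg_amp * burst_r * _bandlimited_noise(
            rng, n_eeg, EEG_RATE, artifacts.emg_band)

    eeg = _one_over_f_noise(rng, n_ch, n_eeg, EEG_RATE, background_noise_sd)
    sources = {"gait": gait_source, "blink": blink, "eye_drift": eye_drift,
               "glossokinetic": gloss, "emg_left": emg_l, "emg_right": emg_r}
    for name, src in sources.items():
        eeg += np.outer(profiles[name], src)

    if effect.applies_to(cell):
        bump = effect.amplitude_delta * _phase_bump(phase_mod,
                                                    effect.phase_window)
        for lab in effect.electrodes:
            row = labels.index(lab) if lab in labels else montage.index(lab)
            eeg[row] += bump

    truth = GroundTruth(
        contact_times=contacts,
        stance_end_times=stance_ends,
        cycle_template=cycle_template(
            np.arange(N_PHASE_POINTS) / N_PHASE_POINTS),
        template_electrode_gain=profiles["gait"],
        sources=sources,
    )
    return RawRecording(
        eeg=eeg, imu_angle=angle, eeg_rate=EEG_RATE, imu_rate=IMU_RATE,
        markers=[(0.0, "sync_start")],
        subject_id=subject_id or f"{cell}_{seed}",
        group=group, condition=condition,
        channel_labels=labels, truth=truth)


# --------------------------------------------------------------------------
# Cohort-level generation
# --------------------------------------------------------------------------

def _draw_stride_rate(cell: str, rng: np.random.Generator) -> float:
    mean, sd = STRIDE_COUNT_DISTRIBUTIONS[cell]
    count = max(rng.normal(mean, sd), 30.0)
    return count / _REFERENCE_DURATION


def generate_cohort(n_per_group: int, effect: EffectSpec, seed: int,
                    duration: float = 180.0,
                    artifacts: ArtifactModel | None = None,
                    stride_cv: dict[str, float] | None = None,
                    **subject_kwargs) -> CohortDataset:
    """A full 2 x ``n_per_group`` x 2-condition signal-level cohort.

    Per-subject stride rates are drawn from the per-cell stride-count
    distributions (self-selected conditions dispersed, cued conditions
    tight around the metronome rate); every subject is recorded under
    both conditions with an independent child seed.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (ANOVA undefined below)")
    artifacts = artifacts if artifacts is not None else ArtifactModel()
    stride_cv = stride_cv or {"sSC": 0.03, "SC": 0.015}
    root = np.random.SeedSequence(seed)
    rate_rng = np.random.default_rng(root.spawn(1)[0])
    recordings: list[RawRecording] = []
    manifest: list[dict] = []
    child_seeds = iter(root.spawn(4 * n_per_group))
    for group in ("O", "T"):
        for i in range(n_per_group):
            sid = f"{group}{i + 1:02d}"
            for condition in ("sSC", "SC"):
                cell = group + condition
                child = next(child_seeds)
                sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
                gait = GaitModel(
                    stride_rate=_draw_stride_rate(cell, rate_rng),
                    stride_cv=stride_cv[condition],
                    duration=duration)
                rec = generate_subject(gait, artifacts, effect, cell,
                                       seed=sub_seed, subject_id=sid,
                                       **subject_kwargs)
                recordings.append(rec)
                manifest.append({
                    "subject_id": sid, "group": group, "condition": condition,
                    "seed": sub_seed,
                    "stride_rate": gait.stride_rate,
                    "true_contact_count": len(rec.truth.contact_times),
                    "effect_applied": effect.applies_to(cell),
                })
    return CohortDataset(recordings=recordings, manifest=manifest,
                         effect=effect, seed=seed)


#: Per-cycle noise scale of the matrix-level generator, in normalized
#: amplitude units: the background-to-component ratio of the signal-level
#: defaults (3 microvolt noise against a 5 microvolt gait component).
DEFAULT_CYCLE_NOISE_SD = 0.6


def generate_cohort_matrices(n_per_group: int, effect: EffectSpec, seed: int,
                             cycle_noise_sd: float = DEFAULT_CYCLE_NOISE_SD,
                             subject_gain_sd: float = 0.1,
                             montage: MontageInfo = DEFAULT_MONTAGE,
                             ) -> list[CycleMatrix]:
    """Subject-level cycle matrices emulating the epoching stage's output.

    Each subject x condition matrix is
    ``gain_s * template + effect_bump + noise`` where the per-point
    noise SD is ``cycle_noise_sd / sqrt(n_cycles)`` — ensemble
    averaging across the subject's strides is what shrinks the
    per-cycle noise — and ``n_cycles`` is drawn from the same per-cell
    stride-count distributions the signal-level cohort uses.  The
    subject gain is shared between conditions (a between-subject random
    effect).  ``effect.amplitude_delta`` is in normalized units here.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2 (ANOVA undefined below)")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    phases = np.arange(N_PHASE_POINTS) / N_PHASE_POINTS
    template_t = cycle_template(phases)
    gain = _source_profiles(montage)["gait"][:montage.n_active]
    template = np.outer(gain / gain.max(), template_t)
    bump_t = _phase_bump(phases, effect.phase_window)
    matrices: list[CycleMatrix] = []
    for group in ("O", "T"):
        for i in range(n_per_group):
            sid = f"{group}{i + 1:02d}"
            subject_gain = rng.normal(1.0, subject_gain_sd)
            for condition in ("sSC", "SC"):
                cell = group + condition
                mean, sd = STRIDE_COUNT_DISTRIBUTIONS[cell]
                n_cycles = max(int(round(rng.normal(mean, sd))), 10)
                values = subject_gain * template + rng.normal(
                    0.0, cycle_noise_sd / np.sqrt(n_cycles),
                    size=template.shape)
                if effect.applies_to(cell):
                    for lab in effect.electrodes:
                        values[montage.index(lab)] += \
                            effect.amplitude_delta * bump_t
                matrices.append(CycleMatrix(
                    values=values, subject_id=sid, group=group,
                    condition=condition, n_cycles_averaged=n_cycles))
    return matrices
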