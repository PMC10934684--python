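"""Band-specific Butterworth filtering around the ICA stage.

Each frequency band runs the same chain: a wide 4th-order Butterworth
band-pass plus a 50 Hz notch before ICA, then a band-defining 4th-order
low-pass after artifact removal.  Filters are applied forward-backward
(zero phase) by default so gait-phase alignment is untouched; the
causal single-pass variant is selectable.

Default band chains (pre-band-pass, post-low-pass, all order 4):

====== ============ =============
band   pre-band Hz  post low-pass
====== ============ =============
delta  0.5 - 100    4 Hz
theta  4.5 - 100    7.5 Hz
alpha  8   - 100    12 Hz
beta   13  - 100    30 Hz
====== ============ =============
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "BandDefinition",
    "NotchSpec",
    "BANDS",
    "prefilter",
    "postfilter",
    "band_chain_response",
    "lowpass_response",
]


@dataclass(frozen=True)
class BandDefinition:
    """One analysis band: pre-ICA passband and post-ICA low-pass cutoff."""

    name: str
    pre_band: tuple[float, float]
    post_lowpass: float
    order: int = 4

    def __post_init__(self) -> None:
        low, high = self.pre_band
        if not 0 < low < high:
            raise ValueError(f"invalid passband {self.pre_band}")
        if not 0 < self.post_lowpass < high:
            raise ValueError("post_lowpass must sit inside the passband")
        if self.order < 1:
            raise ValueError("order must be >= 1")


@dataclass(frozen=True)
class NotchSpec:
    """Power-line band-stop: Butterworth stopband centered at 50 Hz."""

    center: float = 50.0
    half_width: float = 1.0
    order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.half_width < self.center:
            raise ValueError("invalid notch geometry")


#: The four standard band chains.
BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", (0.5, 100.0), 4.0),
    "theta": BandDefinition("theta", (4.5, 100.0), 7.5),
    "alpha": BandDefinition("alpha", (8.0, 100.0), 12.0),
    "beta": BandDefinition("beta", (13.0, 100.0), 30.0),
}

DEFAULT_NOTCH = NotchSpec()


def _check_nyquist(freqs, rate: float) -> None:
    nyq = rate / 2.0
    for f in np.atleast_1d(freqs):
        if not 0 < f < nyq:
            raise ValueError(f"corner frequency {f} Hz outside (0, {nyq}) Hz")


def _bandpass_sos(band: BandDefinition, rate: float) -> np.ndarray:
    _check_nyquist(band.pre_band, rate)
    return sps.butter(band.order, band.pre_band, btype="bandpass",
                      fs=rate, output="sos")


def _notch_sos(notch: NotchSpec, rate: float) -> np.ndarray:
    edges = (notch.center - notch.half_width, notch.center + notch.half_width)
    _check_nyquist(edges, rate)
    return sps.butter(notch.order, edges, btype="bandstop", fs=rate,
                      output="sos")


def _lowpass_sos(band: BandDefinition, rate: float) -> np.ndarray:
    _check_nyquist(band.post_lowpass, rate)
    return sps.butter(band.order, band.post_lowpass, btype="lowpass",
                      fs=rate, output="sos")


def _apply(sos: np.ndarray, x: np.ndarray, zero_phase: bool,
           rate: float | None = None, low_corner: float | None = None
           ) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    order = sos.shape[0] * 2
    min_len = 3 * order
    if x.shape[-1] <= min_len:
        raise ValueError(
            f"signal too short ({x.shape[-1]} samples) for order-{order} "
            f"filtering (needs > {min_len})")
    if zero_phase:
        # pad by several time constants of the slowest pole: low corner
        # frequencies (0.5 Hz delta high-pass) settle over seconds, so
        # the filtfilt default of a few filter orders is far too short
        padlen = min_len
        if rate is not None and low_corner is not None and low_corner > 0:
            padlen = max(padlen, int(round(3.0 * rate / low_corner)))
        padlen = min(padlen, x.shape[-1] - 1)
        return sps.sosfiltfilt(sos, x, axis=-1, padtype="odd", padlen=padlen)
    return sps.sosfilt(sos, x, axis=-1)


def prefilter(eeg: np.ndarray, band: BandDefinition,
              notch: NotchSpec = DEFAULT_NOTCH, rate: float = 512.0,
              zero_phase: bool = True) -> np.ndarray:
    """Band-pass + 50 Hz notch ahead of ICA; shape-preserving.

    Zero-phase (forward-backward) by default, giving an effective order
    of 8 and no group delay; edge transients are suppressed with
    odd-symmetric extension padding.
    """
    if rate <= 2 * band.pre_band[1]:
        raise ValueError(
            f"rate {rate} Hz cannot represent passband up to "
            f"{band.pre_band[1]} Hz")
    out = _apply(_bandpass_sos(band, rate), eeg, zero_phase,
                 rate=rate, low_corner=band.pre_band[0])
    return _apply(_notch_sos(notch, rate), out, zero_phase,
                  rate=rate, low_corner=2 * notch.half_width)


def postfilter(eeg: np.ndarray, band: BandDefinition,
               rate: float = 512.0, zero_phase: bool = True) -> np.ndarray:
    """Band-defining low-pass applied after artifact removal."""
    return _apply(_lowpass_sos(band, rate), eeg, zero_phase,
                  rate=rate, low_corner=band.post_lowpass)


def band_chain_response(freqs, band: BandDefinition,
                        notch: NotchSpec = DEFAULT_NOTCH, rate: float = 512.0,
                        zero_phase: bool = True,
                        include_postlowpass: bool = False) -> np.ndarray:
    """|H(f)| of the designed pre-ICA chain, from the filter coefficients.

    With ``zero_phase`` the magnitude response of each stage is squared
    (the filter runs forward and backward).  This is the analytic
    reference the filtering operations are verified against.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    stages = [_bandpass_sos(band, rate), _notch_sos(notch, rate)]
    if include_postlowpass:
        stages.append(_lowpass_sos(band, rate))
    gain = np.ones_like(freqs)
    for sos in stages:
        _, h = sps.sosfreqz(sos, worN=2 * np.pi * freqs / rate)
        mag = np.abs(h)
        gain *= mag ** 2 if zero_phase else mag
    return gain


def lowpass_response(freqs, band: BandDefinition, rate: float = 512.0,
                     zero_phase: bool = True) -> np.ndarray:
    """|H(f)| of the post-ICA low-pass alone, from its coefficients."""
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    _, h = sps.sosfreqz(_lowpass_sos(band, rate), worN=2 * np.pi * freqs / rate)
    mag = np.abs(h)
    return mag ** 2 if zero_phase else mag
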