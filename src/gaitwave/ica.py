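"""FastICA decomposition and rule-based artifact-component handling.

The decomposition follows the classic staged fixed-point procedure:
per-channel mean removal, covariance eigendecomposition, retention of
the leading principal components, whitening, then symmetric fixed-point
iteration with the tanh contrast.  Five components are estimated by
default, mirroring the walking-EEG artifact inventory this pipeline
targets (two ocular, one glossokinetic, two muscular sources).

Component labels come from simple topography + spectrum rules: ocular
components load on the prefrontal row and live below 4 Hz; muscular
components carry most of their power above 20 Hz; glossokinetic
components are low-frequency with inferior-frontal/temporal weighting.
Anything else is kept as brain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal_io import DEFAULT_MONTAGE, MontageInfo

__all__ = [
    "IcaDecomposition",
    "IcLabel",
    "ClassifierThresholds",
    "fit_fastica",
    "classify_components",
    "remove_components",
]


@dataclass
class IcaDecomposition:
    """Result of a staged fastICA fit.

    ``sources = unmixing @ (eeg - channel_means)`` and
    ``eeg ~= channel_means + mixing @ sources + residual`` where the
    residual lives in the discarded principal subspace.
    """

    n_components: int
    unmixing: np.ndarray        # components x channels
    mixing: np.ndarray          # channels x components
    sources: np.ndarray         # components x samples
    whitener: np.ndarray        # components x channels
    channel_means: np.ndarray   # channels (microvolts)
    converged: bool = True
    n_iter: int = 0
    retained_variance: float = 1.0


@dataclass
class IcLabel:
    """Classification of one independent component."""

    component: int
    label: str  # ocular | glossokinetic | muscle | brain
    scores: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ClassifierThresholds:
    """Rule thresholds for component labelling (unitless shares).

    ``frontal_share``: fraction of squared mixing weight on Fp1/Fp2/Fpz
    required for an ocular call; ``inferior_share``: fraction on
    F7/F8/T7/T8 for a glossokinetic call; ``low_freq_ratio``: fraction
    of source power below 4 Hz; ``high_freq_ratio``: fraction above
    20 Hz for a muscle call.
    """

    frontal_share: float = 0.35
    inferior_share: float = 0.35
    low_freq_ratio: float = 0.55
    high_freq_ratio: float = 0.45


def fit_fastica(eeg: np.ndarray, n_components: int = 5, seed: int = 0,
                max_iter: int = 1000, tol: float = 1e-4) -> IcaDecomposition:
    """Staged fastICA: center, eigendecompose, retain PCs, whiten, iterate.

    Deterministic given ``seed`` (the only randomness is the initial
    rotation).  Uses the symmetric (parallel) orthogonalization and the
    tanh contrast.  Non-convergence is reported on the result, which is
    still returned.
    """
    eeg = np.asarray(eeg, dtype=float)
    if not np.all(np.isfinite(eeg)):
        raise ValueError("EEG contains non-finite values")
    n_ch, n_samp = eeg.shape
    if n_samp < 20 * n_ch:
        import warnings

        warnings.warn(
            f"only {n_samp} samples for {n_ch} channels; ICA may be unstable",
            stacklevel=2)

    # centering (remean)
    means = eeg.mean(axis=1)
    x = eeg - means[:, None]

    # decorrelation: covariance eigendecomposition (PCA)
    cov = (x @ x.T) / n_samp
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    positive = int(np.sum(evals > 1e-12 * max(evals.max(), 1e-30)))
    if positive < n_components:
        raise ValueError(
            f"data rank {positive} is below n_components={n_components}")
    lam = evals[:n_components]
    E = evecs[:, :n_components]
    retained = float(lam.sum() / evals.sum())

    # normalization (whitening): z has identity covariance
    whitener = (E / np.sqrt(lam)).T          # components x channels
    dewhitener = E * np.sqrt(lam)            # channels x components
    z = whitener @ x

    # symmetric fixed-point iteration, tanh contrast
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n_components, n_components))
    W = _sym_decorrelate(W)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        wz = W @ z                            # components x samples
        g = np.tanh(wz)
        g_prime = 1.0 - g ** 2
        W_new = (g @ z.T) / n_samp - g_prime.mean(axis=1)[:, None] * W
        W_new = _sym_decorrelate(W_new)
        # convergence: max deviation of |diag(W_new W^T)| from 1
        delta = float(np.max(np.abs(np.abs(np.einsum("ij,ij->i", W_new, W)) - 1)))
        W = W_new
        if delta < tol:
            converged = True
            break

    # fix signs for determinism: largest-|weight| channel loading positive
    unmixing = W @ whitener                   # components x channels
    mixing = dewhitener @ W.T                 # channels x components
    for k in range(n_components):
        j = int(np.argmax(np.abs(mixing[:, k])))
        if mixing[j, k] < 0:
            mixing[:, k] *= -1
            unmixing[k, :] *= -1
            W[k, :] *= -1
    sources = unmixing @ x

    return IcaDecomposition(
        n_components=n_components,
        unmixing=unmixing,
        mixing=mixing,
        sources=sources,
        whitener=whitener,
        channel_means=means,
        converged=converged,
        n_iter=it,
        retained_variance=retained,
    )


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^(-1/2) W (symmetric orthogonalization)."""
    s, u = np.linalg.eigh(W @ W.T)
    s = np.clip(s, 1e-12, None)
    return (u / np.sqrt(s)) @ u.T @ W


def _power_ratio(source: np.ndarray, rate: float,
                 low: float | None, high: float | None) -> float:
    """Fraction of Welch power in [low, high] Hz (None = open end)."""
    nper = min(source.size, 2048)
    f, p = sps.welch(source, fs=rate, nperseg=nper)
    total = np.trapezoid(p, f)
    if total <= 0:
        return 0.0
    mask = np.ones_like(f, dtype=bool)
    if low is not None:
        mask &= f >= low
    if high is not None:
        mask &= f <= high
    return float(np.trapezoid(p[mask], f[mask]) / total)


def _topo_share(column: np.ndarray, channel_labels, members) -> float:
    """Share of squared mixing weight carried by ``members`` channels."""
    norm = {lab.upper(): i for i, lab in enumerate(channel_labels)}
    total = float(np.sum(column ** 2))
    if total <= 0:
        return 0.0
    part = sum(column[norm[m.upper()]] ** 2 for m in members if m.upper() in norm)
    return float(part / total)


def classify_components(decomp: IcaDecomposition,
                        montage: MontageInfo = DEFAULT_MONTAGE,
                        rate: float = 512.0,
                        channel_labels=None,
                        thresholds: ClassifierThresholds = ClassifierThresholds(),
                        ) -> list[IcLabel]:
    """Label each component as ocular / glossokinetic / muscle / brain.

    Rules are evaluated in priority order ocular -> muscle ->
    glossokinetic; a component matching none is brain.  Always returns a
    label per component.
    """
    labels = list(channel_labels) if channel_labels is not None \
        else list(montage.active_labels)
    if decomp.mixing.shape[0] != len(labels):
        raise ValueError(
            f"decomposition has {decomp.mixing.shape[0]} channels but "
            f"{len(labels)} labels were given")

    out: list[IcLabel] = []
    for k in range(decomp.n_components):
        col = decomp.mixing[:, k]
        src = decomp.sources[k]
        frontal = _topo_share(col, labels, ("Fp1", "Fp2", "Fpz"))
        inferior = _topo_share(col, labels, ("F7", "F8", "T7", "T8"))
        low = _power_ratio(src, rate, None, 4.0)
        high = _power_ratio(src, rate, 20.0, None)
        scores = {
            "frontal_share": frontal,
            "inferior_share": inferior,
            "low_freq_ratio": low,
            "high_freq_ratio": high,
        }
        if frontal > thresholds.frontal_share and low > thresholds.low_freq_ratio:
            label = "ocular"
        elif high > thresholds.high_freq_ratio:
            label = "muscle"
        elif inferior > thresholds.inferior_share and low > thresholds.low_freq_ratio:
            label = "glossokinetic"
        else:
            label = "brain"
        out.append(IcLabel(component=k, label=label, scores=scores))
    return out


def remove_components(eeg: np.ndarray, decomp: IcaDecomposition,
                      reject) -> np.ndarray:
    """Subtract the scalp projection of the rejected components.

    ``cleaned = eeg - mixing[:, reject] @ sources[reject]``; channel
    means are untouched.  An empty rejection list returns the input
    unchanged.
    """
    eeg = np.asarray(eeg, dtype=float)
    reject = sorted(set(int(r) for r in reject))
    if not reject:
        return eeg
    if reject[0] < 0 or reject[-1] >= decomp.n_components:
        raise IndexError(
            f"reject indices {reject} out of range for "
            f"{decomp.n_components} components")
    return eeg - decomp.mixing[:, reject] @ decomp.sources[reject, :]
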