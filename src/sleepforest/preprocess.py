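"""Preprocessing: 0.5-30 Hz band-pass filtering and ICA-based ocular
artifact removal.

The sleep-relevant EEG band is 0.5-30 Hz, so every epoch is high-passed at
0.5 Hz (drift) and low-passed at 30 Hz (high-frequency noise), both as
4th-order Butterworth sections applied forward-backward for zero phase.

Ocular artifacts live below 16 Hz and therefore overlap the scoring bands;
they cannot be filtered out, so the two channels are unmixed with FastICA
(symmetric orthogonalization, tanh contrast) and components that are both
low-frequency-dominated and heavy-tailed are zeroed before back-projection.
With only two channels at most one component is removed by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .epoch_io import Epoch
from .errors import DegenerateInputError, InsufficientDataError


@dataclass(frozen=True)
class FilterSpec:
    highpass_hz: float = 0.5
    lowpass_hz: float = 30.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self):
        if not 0 < self.highpass_hz < self.lowpass_hz:
            raise ValueError("need 0 < highpass < lowpass")


@dataclass
class ICAResult:
    components: np.ndarray    # (n_comp, n_samples) source estimates
    mixing: np.ndarray        # (2, 2), x_centered = mixing @ components
    unmixing: np.ndarray      # (2, 2)
    mean: np.ndarray          # per-channel mean removed before unmixing
    artifact_flags: np.ndarray  # per-component boolean


def bandpass_filter(
    signal: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()
) -> np.ndarray:
    """Zero-phase 0.5-30 Hz band-pass (HP and LP Butterworth cascade)."""
    signal = np.asarray(signal, dtype=float)
    n = signal.shape[-1]
    if n <= 3 * spec.order * 4:  # sosfiltfilt padlen guard
        raise InsufficientDataError(
            f"signal too short ({n} samples) for order-{spec.order} filtering"
        )
    if fs <= 2 * spec.lowpass_hz:
        raise ValueError("sampling rate must exceed twice the low-pass cutoff")
    sos_hp = sps.butter(spec.order, spec.highpass_hz, btype="highpass", fs=fs, output="sos")
    sos_lp = sps.butter(spec.order, spec.lowpass_hz, btype="lowpass", fs=fs, output="sos")
    sos = np.vstack([sos_hp, sos_lp])
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, signal, axis=-1)
    return sps.sosfilt(sos, signal, axis=-1)


def filter_epoch(epoch: Epoch, spec: FilterSpec = FilterSpec()) -> Epoch:
    return replace(epoch, samples=bandpass_filter(epoch.samples, epoch.fs, spec))


# ---------------------------------------------------------------------------
# FastICA (symmetric orthogonalization, tanh contrast)
# ---------------------------------------------------------------------------

def _whiten(x: np.ndarray):
    """Eigendecomposition whitening of centered data (channels x samples)."""
    cov = x @ x.T / x.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval.min() < 1e-12 * max(eigval.max(), 1.0):
        raise DegenerateInputError(
            "rank-deficient input (channels are linearly dependent)"
        )
    whitener = eigvec @ np.diag(eigval ** -0.5) @ eigvec.T
    return whitener @ x, whitener


def _sym_decorrelate(w: np.ndarray) -> np.ndarray:
    s, u = np.linalg.eigh(w @ w.T)
    return u @ np.diag(s ** -0.5) @ u.T @ w


def fastica_decompose(
    epoch: Epoch | np.ndarray,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
    low_freq_frac: float = 0.6,
    kurt_thresh: float = 5.0,
    fs: float | None = None,
) -> ICAResult:
    """Unmix a 2-channel epoch into independent components.

    Deterministic for a fixed ``seed``.  Component sign/order is arbitrary
    (ICA identifiability).  ``artifact_flags`` marks components that look
    ocular: more than ``low_freq_frac`` of their power below 4 Hz *and*
    kurtosis above ``kurt_thresh``; at most the single highest-kurtosis
    qualifying component is flagged so a 2-channel recording is never
    entirely zeroed.
    """
    if isinstance(epoch, Epoch):
        x = epoch.samples
        fs = epoch.fs
    else:
        x = np.asarray(epoch, dtype=float)
        if fs is None:
            fs = 100.0
    if not np.isfinite(x).all():
        raise DegenerateInputError("non-finite samples")
    if x.std(axis=1).min() == 0:
        raise DegenerateInputError("zero-variance channel")
    mean = x.mean(axis=1, keepdims=True)
    xc = x - mean
    z, whitener = _whiten(xc)

    rng = np.random.default_rng(seed)
    n_comp = x.shape[0]
    w = _sym_decorrelate(rng.standard_normal((n_comp, n_comp)))
    for _ in range(max_iter):
        wx = w @ z
        g = np.tanh(wx)
        g_prime = (1.0 - g ** 2).mean(axis=1)
        w_new = (g @ z.T) / z.shape[1] - g_prime[:, None] * w
        w_new = _sym_decorrelate(w_new)
        delta = max(abs(abs(np.einsum("ij,ij->i", w_new, w)) - 1.0))
        w = w_new
        if delta < tol:
            break

    unmixing = w @ whitener          # sources = unmixing @ (x - mean)
    mixing = np.linalg.inv(unmixing)  # x - mean = mixing @ sources
    components = unmixing @ xc

    flags = np.zeros(n_comp, dtype=bool)
    qualify = []
    for i in range(n_comp):
        c = components[i]
        freqs, psd = sps.welch(c, fs=fs, nperseg=min(len(c), 2 * int(fs)))
        total = psd.sum()
        low = psd[freqs < 4.0].sum()
        m2 = ((c - c.mean()) ** 2).mean()
        kurt = ((c - c.mean()) ** 4).mean() / m2 ** 2 if m2 > 0 else 0.0
        if total > 0 and low / total > low_freq_frac and kurt > kurt_thresh:
            qualify.append((kurt, i))
    if qualify:
        flags[max(qualify)[1]] = True
    return ICAResult(
        components=components, mixing=mixing, unmixing=unmixing,
        mean=mean, artifact_flags=flags,
    )


def remove_ocular_components(epoch: Epoch, ica: ICAResult) -> Epoch:
    """Back-project with flagged components zeroed; identity (within
    numerical tolerance) when nothing is flagged."""
    comps = ica.components.copy()
    comps[ica.artifact_flags] = 0.0
    cleaned = ica.mixing @ comps
    if not ica.artifact_flags.all():
        cleaned = cleaned + ica.mean
    return replace(epoch, samples=cleaned)


def preprocess_epoch(
    epoch: Epoch,
    spec: FilterSpec = FilterSpec(),
    ica_enabled: bool = True,
    ica_seed: int = 0,
    low_freq_frac: float = 0.6,
    kurt_thresh: float = 5.0,
) -> Epoch:
    """Filter, then (optionally) remove flagged ocular components."""
    ep = filter_epoch(epoch, spec)
    if ica_enabled:
        ica = fastica_decompose(
            ep, seed=ica_seed, low_freq_frac=low_freq_frac, kurt_thresh=kurt_thresh
        )
        if ica.artifact_flags.any():
            ep = remove_ocular_components(ep, ica)
    return ep
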