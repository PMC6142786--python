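"""Per-epoch EEG feature extraction: 50 linear and 10 nonlinear features.

Linear features, per channel: absolute power, relative power, center
frequency and max power in each of the five scoring bands — delta
(0.5-2 Hz), sawtooth (2-4 Hz), theta (4-8 Hz), alpha (8-13 Hz), beta
(13-30 Hz) — plus the Hjorth parameters (Activity, Mobility, Complexity),
Skewness and Kurtosis on the broadband 0.5-30 Hz signal (25 x 2 = 50).

Nonlinear features, per channel: Shannon entropy of the amplitude
histogram, spectral entropy of the normalized 0.5-30 Hz power spectrum,
Kolmogorov entropy (Grassberger-Procaccia K2 correlation-entropy
estimate), the largest Lyapunov exponent (Wolf-style nearest-neighbor
divergence tracking) and C0-complexity, the fraction of signal energy not
explained by its dominant spectral components (5 x 2 = 10).

Feature names follow ``<channel>.<feature>[.<band>]`` and are listed in
:data:`FEATURE_NAMES` (also shipped as ``feature_manifest.json``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .epoch_io import CHANNELS, META_COLUMNS, Epoch
from .errors import DegenerateInputError, FeatureComputationError, InsufficientDataError
from .synthetic import BANDS, BAND_NAMES

FULL_RANGE = (0.5, 30.0)

_BAND_FEATURES = ("absolute_power", "relative_power", "center_frequency", "max_power")
_BROADBAND_FEATURES = ("activity", "mobility", "complexity", "skewness", "kurtosis")
_NONLINEAR_FEATURES = (
    "shannon_entropy",
    "spectral_entropy",
    "kolmogorov_entropy",
    "max_lyapunov",
    "c0_complexity",
)


def _build_feature_names() -> list:
    names = []
    for ch in CHANNELS:
        for feat in _BAND_FEATURES:
            for band in BAND_NAMES:
                names.append(f"{ch}.{feat}.{band}")
        for feat in _BROADBAND_FEATURES:
            names.append(f"{ch}.{feat}")
        for feat in _NONLINEAR_FEATURES:
            names.append(f"{ch}.{feat}")
    return names


#: the 60 canonical feature names, extraction order
FEATURE_NAMES = _build_feature_names()
assert len(FEATURE_NAMES) == 60


# ---------------------------------------------------------------------------
# time-domain moments
# ---------------------------------------------------------------------------

def hjorth_parameters(x: np.ndarray):
    """Activity, Mobility, Complexity.

    Activity is the sample variance (1/(n-1) denominator); Mobility is
    sqrt(var(dx)/var(x)) with the first-difference variance using a 1/(n-2)
    denominator; Complexity is the mobility of the differenced series
    divided by the mobility of the original (second differences, 1/(n-3)).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4:
        raise InsufficientDataError("need at least 4 samples for Hjorth parameters")
    v0 = x.var(ddof=1)
    xd = np.diff(x)
    xdd = np.diff(xd)
    v1 = xd.var(ddof=1)  # n-1 points, denominator (n-1)-1 = n-2
    v2 = xdd.var(ddof=1)  # n-2 points, denominator n-3
    activity = v0
    if v0 == 0 or v1 == 0:
        raise DegenerateInputError(
            "constant (or linearly drifting) signal: mobility/complexity undefined"
        )
    mobility = np.sqrt(v1 / v0)
    complexity = np.sqrt(v2 / v1) / mobility
    return activity, mobility, complexity


def _central_moments(x: np.ndarray):
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise InsufficientDataError("need at least 2 samples")
    d = x - x.mean()
    m2 = (d ** 2).mean()
    if m2 == 0:
        raise DegenerateInputError("zero variance")
    return d, m2


def skewness(x: np.ndarray) -> float:
    """Fisher-Pearson skewness m3 / m2^(3/2) with population (1/n) moments."""
    d, m2 = _central_moments(x)
    return float((d ** 3).mean() / m2 ** 1.5)


def kurtosis(x: np.ndarray) -> float:
    """Non-excess kurtosis m4 / m2^2 (Gaussian -> 3), population moments."""
    d, m2 = _central_moments(x)
    return float((d ** 4).mean() / m2 ** 2)


# ---------------------------------------------------------------------------
# spectral features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsdParams:
    """Welch estimator settings: 2-s Hamming windows, 50% overlap
    (frequency resolution 0.5 Hz at fs = 100)."""

    window_seconds: float = 2.0
    overlap: float = 0.5
    taper: str = "hamming"


@dataclass
class SpectralDensity:
    freqs: np.ndarray
    psd: np.ndarray
    fs: float


def power_spectral_density(
    x: np.ndarray, fs: float, params: PsdParams = PsdParams()
) -> SpectralDensity:
    """Welch averaged periodogram."""
    x = np.asarray(x, dtype=float)
    nperseg = int(params.window_seconds * fs)
    if len(x) < nperseg:
        raise InsufficientDataError(
            f"signal ({len(x)} samples) shorter than one PSD window ({nperseg})"
        )
    freqs, psd = sps.welch(
        x, fs=fs, window=params.taper, nperseg=nperseg,
        noverlap=int(nperseg * params.overlap),
    )
    return SpectralDensity(freqs=freqs, psd=psd, fs=fs)


def _band_weights(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Per-bin weights for one band.

    The five bands share endpoints, so a PSD bin sitting exactly on an
    interior band edge is split half-and-half between the two bands it
    borders; bins on the outer 0.5/30 Hz edges belong fully to their band.
    Summed over the five bands every 0.5-30 Hz bin is counted exactly once.
    """
    w = np.zeros_like(freqs)
    w[(freqs > lo) & (freqs < hi)] = 1.0
    for edge in (lo, hi):
        on_edge = np.isclose(freqs, edge)
        w[on_edge] = 1.0 if edge in FULL_RANGE else 0.5
    return w


def band_features(sd: SpectralDensity, band) -> tuple:
    """(absolute power, relative power, center frequency, max power) of one
    band.  Relative power is normalized by the total 0.5-30 Hz power;
    center frequency is the power-weighted mean frequency (spectral
    centroid) within the band."""
    name, lo, hi = band if len(band) == 3 else ("band", *band)
    df = sd.freqs[1] - sd.freqs[0]
    total_mask = (sd.freqs >= FULL_RANGE[0]) & (sd.freqs <= FULL_RANGE[1])
    total = sd.psd[total_mask].sum() * df
    if total <= 0:
        raise DegenerateInputError("zero total power in 0.5-30 Hz")
    w = _band_weights(sd.freqs, lo, hi)
    p = sd.psd * w
    absolute = p.sum() * df
    relative = absolute / total
    center = float((sd.freqs * p).sum() / p.sum()) if p.sum() > 0 else (lo + hi) / 2
    peak = float(sd.psd[w > 0].max()) if (w > 0).any() else 0.0
    return float(absolute), float(relative), center, peak


def shannon_entropy(x: np.ndarray, n_bins: int = 16, base: float = 2.0) -> float:
    """Entropy of the amplitude histogram over [min(x), max(x)]."""
    x = np.asarray(x, dtype=float)
    if x.min() == x.max():
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


def spectral_entropy(sd: SpectralDensity, base: float = 2.0) -> float:
    """Entropy of the normalized PSD restricted to 0.5-30 Hz."""
    mask = (sd.freqs >= FULL_RANGE[0]) & (sd.freqs <= FULL_RANGE[1])
    p = sd.psd[mask]
    total = p.sum()
    if total <= 0:
        raise DegenerateInputError("zero power in 0.5-30 Hz")
    p = p / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(base))


# ---------------------------------------------------------------------------
# nonlinear dynamics estimators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay-embedding settings shared by the K2 and Lyapunov estimators.

    ``dimension`` and ``delay`` (in samples) define the embedding;
    ``eps_factors`` scale the signal's standard deviation to the radii used
    for correlation sums; ``theiler`` excludes temporal neighbors;
    ``max_points`` caps the number of embedded vectors entering pairwise
    sums (evenly strided subsample); ``evolve_steps``/``max_steps`` bound
    the Wolf divergence tracking.
    """

    dimension: int = 3
    delay: int = 5
    eps_factors: tuple = (0.5, 0.7, 1.0)
    theiler: int = 50
    max_points: int = 400
    evolve_steps: int = 5
    max_steps: int = 150

    def __post_init__(self):
        if self.dimension < 1 or self.delay < 1:
            raise ValueError("dimension and delay must be >= 1")


def _embed(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    n = len(x) - (m - 1) * tau
    if n <= 0:
        raise InsufficientDataError("series too short for the requested embedding")
    idx = np.arange(n)[:, None] + tau * np.arange(m)[None, :]
    return x[idx]


def _pair_distances(emb: np.ndarray, theiler: int) -> np.ndarray:
    """Chebyshev distances of all Theiler-separated vector pairs."""
    n = len(emb)
    d = cdist(emb, emb, metric="chebyshev")
    ii, jj = np.triu_indices(n, k=1)
    keep = (jj - ii) > theiler
    return d[ii[keep], jj[keep]]


def _correlation_sum(emb: np.ndarray, eps: float, theiler: int) -> float:
    """Fraction of Theiler-separated vector pairs closer than eps
    (Chebyshev norm)."""
    dists = _pair_distances(emb, theiler)
    if len(dists) == 0:
        return 0.0
    return float((dists < eps).mean())


def kolmogorov_entropy(
    x: np.ndarray, cfg: EmbeddingConfig = EmbeddingConfig(), fs: float = 100.0
) -> float:
    """K2 (correlation) entropy estimate, in nats per second.

    K2(eps) = (1 / tau_s) * ln(C_m(eps) / C_{m+1}(eps)) with C_m the
    correlation sum at embedding dimension m; the reported value is the
    geometric mean over the configured radii, clamped at 0.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 500:
        raise InsufficientDataError("need at least 500 samples for K2 estimation")
    sd = x.std()
    if sd == 0:
        raise DegenerateInputError("constant signal")
    m, tau = cfg.dimension, cfg.delay
    emb_hi = _embed(x, m + 1, tau)
    if len(emb_hi) > cfg.max_points:
        stride = int(np.ceil(len(emb_hi) / cfg.max_points))
        emb_hi = emb_hi[::stride]
        theiler = max(1, cfg.theiler // stride)
    else:
        theiler = cfg.theiler
    emb_lo = emb_hi[:, :m]
    tau_s = tau / fs
    d_lo = _pair_distances(emb_lo, theiler)
    d_hi = _pair_distances(emb_hi, theiler)
    estimates = []
    for f in cfg.eps_factors:
        eps = f * sd
        c_lo = float((d_lo < eps).mean()) if len(d_lo) else 0.0
        c_hi = float((d_hi < eps).mean()) if len(d_hi) else 0.0
        if c_lo <= 0 or c_hi <= 0:
            raise DegenerateInputError(
                f"empty correlation sum at eps={eps:.3g}; increase the radius"
            )
        estimates.append(max(np.log(c_lo / c_hi) / tau_s, 0.0))
    # geometric mean over radii (estimates floored to keep the log finite;
    # any radius reporting ~0 entropy pulls the mean toward 0)
    floored = np.maximum(estimates, 1e-12)
    value = float(np.exp(np.log(floored).mean()))
    return 0.0 if value < 1e-8 else value


def max_lyapunov(
    x: np.ndarray, cfg: EmbeddingConfig = EmbeddingConfig(dimension=5), fs: float = 100.0
) -> float:
    """Largest Lyapunov exponent by Wolf-style divergence tracking, per
    second.

    The series is delay-embedded; the nearest Theiler-separated neighbor
    of the current trajectory point is evolved alongside it for
    ``evolve_steps`` samples, the log separation growth is accumulated, and
    the neighbor is replaced by a fresh nearest neighbor (orientation-free
    replacement).  Deterministic for fixed input and config.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 500:
        raise InsufficientDataError("need at least 500 samples for Lyapunov estimation")
    if x.std() == 0:
        raise DegenerateInputError("constant signal")
    emb = _embed(x, cfg.dimension, cfg.delay)
    n = len(emb)
    evolve = cfg.evolve_steps
    if n <= cfg.theiler + evolve + 1:
        raise InsufficientDataError("embedding too short for the Theiler window")
    tree = cKDTree(emb)
    k_query = min(n, 2 * cfg.theiler + 4)
    # below this separation two trajectory points are numerically coincident
    # (exactly periodic orbits): their divergence is counted as zero growth
    noise_floor = 1e-8 * float(np.linalg.norm(emb.std(axis=0)))

    # the tracker only ever sits at multiples of evolve_steps: batch the
    # neighbor queries for all of them up front
    visit = np.arange(0, n - evolve, evolve)[: cfg.max_steps + 1]
    _, nbr_idx = tree.query(emb[visit], k=k_query)
    nbr_idx = np.atleast_2d(nbr_idx)
    nbr_of = dict(zip(visit.tolist(), nbr_idx))

    def nearest(i: int) -> int:
        for j in nbr_of.get(i, ()):
            if abs(j - i) > cfg.theiler and j < n - evolve and j != i:
                return int(j)
        return -1

    i = 0
    j = nearest(i)
    if j < 0:
        raise DegenerateInputError("no admissible nearest neighbor found")
    total_log = 0.0
    total_steps = 0
    steps_done = 0
    while i + evolve < n and steps_done < cfg.max_steps:
        d0 = np.linalg.norm(emb[i] - emb[j])
        i2, j2 = i + evolve, j + evolve
        d1 = np.linalg.norm(emb[i2] - emb[j2])
        if d0 <= noise_floor and d1 <= noise_floor:
            total_steps += evolve  # coincident orbit points: zero divergence
        elif d0 > noise_floor and d1 > 0:
            total_log += np.log(d1 / d0)
            total_steps += evolve
        i = i2
        steps_done += 1
        j = nearest(i)  # replacement: fresh nearest neighbor
        if j < 0:
            break
    if total_steps == 0:
        raise DegenerateInputError("no admissible neighbors during tracking")
    return float(total_log / (total_steps / fs))


def c0_complexity(x: np.ndarray, r: float = 5.0) -> float:
    """C0-complexity: fraction of signal energy outside the dominant
    spectral components.

    The "regular" part y is the inverse FFT of the coefficients whose
    squared magnitude exceeds ``r`` times the mean squared magnitude (all
    others zeroed); the statistic is sum((x - y)^2) / sum(x^2) on the
    mean-removed signal.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 64:
        raise InsufficientDataError("need at least 64 samples for C0-complexity")
    x = x - x.mean()
    a0 = (x ** 2).sum()
    if a0 == 0:
        raise DegenerateInputError("all-zero signal after mean removal")
    spec = np.fft.fft(x)
    power = np.abs(spec) ** 2
    keep = power > r * power.mean()
    y = np.fft.ifft(np.where(keep, spec, 0.0)).real
    a1 = ((x - y) ** 2).sum()
    return float(a1 / a0)


# ---------------------------------------------------------------------------
# full 60-feature extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureConfig:
    psd: PsdParams = field(default_factory=PsdParams)
    shannon_bins: int = 16
    entropy_base: float = 2.0
    k2: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    lyapunov: EmbeddingConfig = field(
        default_factory=lambda: EmbeddingConfig(dimension=5)
    )
    c0_retention: float = 5.0


def extract_features(epoch: Epoch, config: FeatureConfig = FeatureConfig()) -> dict:
    """The 60 named features of one epoch; pure function of (epoch, config).

    Per-feature failures are re-raised as :class:`FeatureComputationError`
    with the feature name attached.
    """
    values = {}
    for c, ch in enumerate(epoch.channels):
        x = epoch.samples[c]
        current = [None]

        def run(name, fn):
            current[0] = f"{ch}.{name}"
            try:
                return fn()
            except Exception as exc:  # annotate and re-raise
                raise FeatureComputationError(current[0], str(exc)) from exc

        sd = run("psd", lambda: power_spectral_density(x, epoch.fs, config.psd))
        for band in BANDS:
            absolute, relative, center, peak = run(
                f"band.{band[0]}", lambda: band_features(sd, band)
            )
            values[f"{ch}.absolute_power.{band[0]}"] = absolute
            values[f"{ch}.relative_power.{band[0]}"] = relative
            values[f"{ch}.center_frequency.{band[0]}"] = center
            values[f"{ch}.max_power.{band[0]}"] = peak
        act, mob, cpx = run("hjorth", lambda: hjorth_parameters(x))
        values[f"{ch}.activity"] = act
        values[f"{ch}.mobility"] = mob
        values[f"{ch}.complexity"] = cpx
        values[f"{ch}.skewness"] = run("skewness", lambda: skewness(x))
        values[f"{ch}.kurtosis"] = run("kurtosis", lambda: kurtosis(x))
        values[f"{ch}.shannon_entropy"] = run(
            "shannon_entropy",
            lambda: shannon_entropy(x, config.shannon_bins, config.entropy_base),
        )
        values[f"{ch}.spectral_entropy"] = run(
            "spectral_entropy", lambda: spectral_entropy(sd, config.entropy_base)
        )
        values[f"{ch}.kolmogorov_entropy"] = run(
            "kolmogorov_entropy", lambda: kolmogorov_entropy(x, config.k2, epoch.fs)
        )
        values[f"{ch}.max_lyapunov"] = run(
            "max_lyapunov", lambda: max_lyapunov(x, config.lyapunov, epoch.fs)
        )
        values[f"{ch}.c0_complexity"] = run(
            "c0_complexity", lambda: c0_complexity(x, config.c0_retention)
        )
    return {name: values[name] for name in FEATURE_NAMES}


def extract_feature_matrix(
    epochs: list,
    meta: list | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> pd.DataFrame:
    """Feature table for a list of epochs: 60 feature columns plus the
    reserved metadata columns."""
    gender_by_subject = {m.subject_id: m.gender for m in (meta or [])}
    rows = []
    for ep in epochs:
        row = extract_features(ep, config)
        row["stage"] = ep.stage
        row["subject_id"] = ep.subject_id
        row["gender"] = gender_by_subject.get(ep.subject_id, "")
        row["epoch_id"] = ep.epoch_id
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_NAMES + list(META_COLUMNS))


# ---------------------------------------------------------------------------
# min-max normalization
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    minima: pd.Series
    maxima: pd.Series


def minmax_fit(matrix: pd.DataFrame, columns: list | None = None) -> NormalizationParams:
    """Learn per-feature min and max on a reference (training) set."""
    if len(matrix) < 1:
        raise InsufficientDataError("cannot fit normalization on an empty matrix")
    if columns is None:
        columns = [c for c in matrix.columns if c not in META_COLUMNS]
    sub = matrix[columns]
    return NormalizationParams(minima=sub.min(), maxima=sub.max())


def minmax_apply(
    matrix: pd.DataFrame, params: NormalizationParams, clip: bool = True
) -> pd.DataFrame:
    """(X - min) / (max - min) per fitted column; constant columns map to 0
    with a warning; unseen data outside the fitted range is clipped to
    [0, 1] by default."""
    out = matrix.copy()
    for col in params.minima.index:
        lo, hi = params.minima[col], params.maxima[col]
        if hi == lo:
            warnings.warn(f"constant feature {col!r}: normalized to 0")
            out[col] = 0.0
            continue
        scaled = (matrix[col] - lo) / (hi - lo)
        out[col] = scaled.clip(0.0, 1.0) if clip else scaled
    return out
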