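"""Synthetic dual-channel EEG with stage-specific spectral structure.

Each sleep stage is synthesized as a sum of band-limited noise components
whose relative powers follow the rhythms scorers look for: dominant alpha
(8-13 Hz) in relaxed wakefulness, prominent theta (4-8 Hz) in NREM1,
spindles (11-15 Hz bursts) and K-complexes (single biphasic ~1 s
deflections) in NREM2, delta (0.5-2 Hz) dominance in slow-wave sleep and a
broad beta-rich (>13 Hz) spectrum in REM.  A weak 1/f background and
channel-specific noise keep the two channels correlated but not identical,
and band components are filtered noise rather than pure tones so entropy
and complexity estimators stay non-degenerate.

Band order everywhere: delta (0.5-2), sawtooth (2-4), theta (4-8),
alpha (8-13), beta (13-30) Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from .epoch_io import CHANNELS, SIX_STATE, Epoch, SubjectMeta
from .errors import UnknownLabelError

#: (name, lo, hi) of the five scoring bands, Hz
BANDS = (
    ("delta", 0.5, 2.0),
    ("sawtooth", 2.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 30.0),
)

BAND_NAMES = tuple(b[0] for b in BANDS)


@dataclass(frozen=True)
class TransientSpec:
    """Spindle / K-complex occurrence parameters for one stage."""

    spindles_per_epoch: float = 0.0  # Poisson mean
    spindle_freq_hz: float = 13.0    # carrier within the 11-15 Hz sigma range
    spindle_duration_s: float = 0.8
    spindle_amplitude: float = 0.0   # multiple of background std
    k_complexes_per_epoch: float = 0.0
    k_amplitude: float = 0.0         # multiple of background std


@dataclass(frozen=True)
class StageProfile:
    """Spectral recipe for one stage: relative band-power targets summing
    to 1, an overall amplitude scale (microvolts RMS) and optional
    transients."""

    stage: str
    band_weights: tuple  # five values, order = BAND_NAMES, sum to 1
    amplitude_scale: float = 40.0
    transients: TransientSpec = field(default_factory=TransientSpec)

    def __post_init__(self):
        w = np.asarray(self.band_weights, dtype=float)
        if w.shape != (5,) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("band_weights must be 5 nonnegative values summing to 1")


def default_profiles() -> dict:
    """Stage profiles encoding the canonical stage/rhythm associations."""
    return {
        "WA": StageProfile("WA", (0.10, 0.10, 0.15, 0.45, 0.20), amplitude_scale=30.0),
        "NREM1": StageProfile("NREM1", (0.15, 0.15, 0.40, 0.20, 0.10), amplitude_scale=40.0),
        "NREM2": StageProfile(
            "NREM2", (0.25, 0.20, 0.30, 0.15, 0.10), amplitude_scale=50.0,
            transients=TransientSpec(
                spindles_per_epoch=2.0, spindle_amplitude=1.5,
                k_complexes_per_epoch=1.0, k_amplitude=1.8,
            ),
        ),
        "NREM3": StageProfile("NREM3", (0.55, 0.18, 0.12, 0.09, 0.06), amplitude_scale=75.0),
        "NREM4": StageProfile("NREM4", (0.65, 0.14, 0.10, 0.06, 0.05), amplitude_scale=85.0),
        "REM": StageProfile("REM", (0.15, 0.12, 0.18, 0.15, 0.40), amplitude_scale=30.0),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic cohort.

    ``stage_distribution`` covers the six stages in canonical order and
    roughly follows overnight stage prevalence (NREM2 dominant).
    ``gender_effect`` multiplies the delta band weight of every female
    profile before renormalization, giving correlation-based selection a
    real gender difference to find; 0 disables it.
    """

    n_subjects_per_gender: int = 2
    epochs_per_subject: int = 50
    stage_distribution: tuple = (0.081, 0.080, 0.465, 0.150, 0.076, 0.148)
    noise_exponent: float = 1.0      # 1/f^a background slope
    background_fraction: float = 0.10  # power fraction of the 1/f background
    channel_mix: float = 0.7         # shared-component fraction of channel 2
    artifact_rate: float = 0.0       # per-epoch ocular-artifact probability
    artifact_amplitude: float = 3.0  # multiple of epoch std
    gender_effect: float = 0.15
    seed: int = 0
    profiles: dict | None = None     # stage -> StageProfile; None = defaults
    # (the separability dial: pass flattened profiles for a harder task)

    def __post_init__(self):
        p = np.asarray(self.stage_distribution, dtype=float)
        if p.shape != (6,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("stage_distribution must be 6 probabilities summing to 1")


def _band_noise(n: int, fs: float, lo: float, hi: float, rng) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [lo, hi) Hz by spectral
    shaping (random Fourier coefficients outside the band zeroed), so band
    powers land on their targets without filter-skirt leakage into the
    narrow neighboring bands."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    coeff = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    mask = (freqs >= lo) & (freqs < hi)
    x = np.fft.irfft(np.where(mask, coeff, 0.0), n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(n: int, exponent: float, rng, fs: float = 100.0,
                lo: float = 0.5, hi: float = 30.0) -> np.ndarray:
    """Unit-variance 1/f^exponent background restricted to [lo, hi] Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    coeff = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    amp = np.zeros_like(freqs)
    mask = (freqs >= lo) & (freqs <= hi)
    amp[mask] = freqs[mask] ** (-exponent / 2.0)
    x = np.fft.irfft(amp * coeff, n)
    return x / x.std()


def _spindle(fs: float, freq: float, duration: float, rng) -> np.ndarray:
    """Amplitude-modulated sigma-band burst (Hann envelope)."""
    n = int(duration * fs)
    t = np.arange(n) / fs
    envelope = np.hanning(n)
    return envelope * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))


def _k_complex(fs: float) -> np.ndarray:
    """Single Gaussian-windowed biphasic deflection, ~1 s long."""
    n = int(1.0 * fs)
    t = np.linspace(-1.0, 1.0, n)
    return np.exp(-(t ** 2) / 0.18) * (-np.sin(np.pi * t * 1.5))


def _add_transients(x: np.ndarray, fs: float, spec: TransientSpec, rng) -> np.ndarray:
    n = len(x)
    sd = x.std()
    out = x.copy()
    for _ in range(rng.poisson(spec.spindles_per_epoch)):
        burst = _spindle(fs, spec.spindle_freq_hz, spec.spindle_duration_s, rng)
        start = rng.integers(0, max(1, n - len(burst)))
        out[start : start + len(burst)] += spec.spindle_amplitude * sd * burst
    for _ in range(rng.poisson(spec.k_complexes_per_epoch)):
        pulse = _k_complex(fs)
        start = rng.integers(0, max(1, n - len(pulse)))
        out[start : start + len(pulse)] += spec.k_amplitude * sd * pulse
    return out


def generate_epoch(
    stage: str,
    profile: StageProfile | None = None,
    fs: float = 100.0,
    duration: float = 30.0,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
    epoch_id: str = "sim:0",
    noise_exponent: float = 1.0,
    background_fraction: float = 0.10,
    channel_mix: float = 0.7,
) -> Epoch:
    """Synthesize one stage-labelled dual-channel epoch.

    The signal is a band-weight-scaled sum of band-limited noise plus a 1/f
    background; channel 2 shares ``channel_mix`` of its variance with
    channel 1.  Deterministic for a fixed ``rng`` state.
    """
    if stage not in SIX_STATE:
        raise UnknownLabelError(f"unknown stage {stage!r}")
    if profile is None:
        profile = default_profiles()[stage]
    if rng is None:
        rng = np.random.default_rng(0)
    n = int(fs * duration)
    w = np.asarray(profile.band_weights, dtype=float)

    # the 1/f background contributes its own band shares; compensate the
    # band-component variances so the *composite* spectrum matches w
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    bg_power = np.zeros_like(freqs)
    bg_mask = (freqs >= 0.5) & (freqs <= 30.0)
    bg_power[bg_mask] = freqs[bg_mask] ** (-noise_exponent)
    shares = np.array([
        bg_power[(freqs >= lo) & (freqs < hi)].sum() for _, lo, hi in BANDS
    ])
    shares /= shares.sum()
    w_adj = np.clip(w - background_fraction * shares, 0.0, None)
    if w_adj.sum() > 0:
        w_adj /= w_adj.sum()

    def one_channel() -> np.ndarray:
        parts = [
            np.sqrt(wb) * _band_noise(n, fs, lo, hi, rng)
            for wb, (_, lo, hi) in zip(w_adj, BANDS)
        ]
        x = np.sum(parts, axis=0) * np.sqrt(1.0 - background_fraction)
        x += np.sqrt(background_fraction) * _pink_noise(n, noise_exponent, rng, fs)
        return x

    shared = one_channel()
    own = one_channel()
    ch1 = shared
    ch2 = np.sqrt(channel_mix) * shared + np.sqrt(1.0 - channel_mix) * own
    samples = np.vstack([ch1, ch2])
    samples = samples * profile.amplitude_scale
    for c in range(2):
        samples[c] = _add_transients(samples[c], fs, profile.transients, rng)
    return Epoch(
        samples=samples, stage=stage, subject_id=subject_id,
        epoch_id=epoch_id, fs=fs, channels=CHANNELS,
    )


def inject_ocular_artifact(
    epoch: Epoch, amplitude: float, rng: np.random.Generator
) -> Epoch:
    """Return a copy of ``epoch`` with a low-frequency (<16 Hz) high-amplitude
    ocular transient added to both channels (channel-specific gain).

    ``amplitude`` is in multiples of the per-channel standard deviation;
    0 returns an identical copy.  Pure function: the input is not modified.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    samples = epoch.samples.copy()
    if amplitude > 0:
        n = epoch.n_samples
        # eye-movement-like slow deflection: ~1 s Gaussian-windowed ramp,
        # energy concentrated well below 16 Hz
        width = int(1.0 * epoch.fs)
        start = rng.integers(0, n - width)
        t = np.linspace(-2.5, 2.5, width)
        pulse = np.exp(-(t ** 2) / 2.0)
        gains = (1.0, rng.uniform(0.4, 0.8))  # frontal channel dominates
        for c, g in enumerate(gains):
            sd = samples[c].std()
            samples[c, start : start + width] += amplitude * sd * g * pulse
    return replace(epoch, samples=samples)


def generate_dataset(config: SimulationConfig):
    """Generate a full cohort: ``(epochs, metadata)``.

    Subjects alternate genders; female profiles get the delta-weight tweak
    ``(1 + gender_effect)`` before renormalization.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    base = config.profiles if config.profiles is not None else default_profiles()

    def gender_profiles(gender: str) -> dict:
        if gender != "female" or config.gender_effect == 0:
            return base
        out = {}
        for stage, prof in base.items():
            w = np.asarray(prof.band_weights, dtype=float).copy()
            w[0] *= 1.0 + config.gender_effect
            w /= w.sum()
            out[stage] = replace(prof, band_weights=tuple(w))
        return out

    epochs, meta = [], []
    for gender in ("female", "male"):
        profiles = gender_profiles(gender)
        for s in range(config.n_subjects_per_gender):
            sid = f"{gender[0].upper()}{s:03d}"
            meta.append(
                SubjectMeta(
                    subject_id=sid, gender=gender,
                    age=int(rng.integers(25, 60)), health_status="healthy",
                    cohort="SC",
                )
            )
            stages = rng.choice(
                6, size=config.epochs_per_subject, p=config.stage_distribution
            )
            for k, si in enumerate(stages):
                stage = SIX_STATE[si]
                ep = generate_epoch(
                    stage, profiles[stage], rng=rng, subject_id=sid,
                    epoch_id=f"{sid}:{k}",
                    noise_exponent=config.noise_exponent,
                    background_fraction=config.background_fraction,
                    channel_mix=config.channel_mix,
                )
                if config.artifact_rate > 0 and rng.random() < config.artifact_rate:
                    ep = inject_ocular_artifact(ep, config.artifact_amplitude, rng)
                epochs.append(ep)
    return epochs, meta
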