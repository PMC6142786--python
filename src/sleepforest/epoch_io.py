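"""Epoch containers, stage vocabularies, segmentation, sampling and table I/O.

The unit of analysis is the 30-second *epoch* (sleep segment): a fixed window
of dual-channel EEG (Fpz-Cz, Pz-Oz) sampled at 100 Hz and carrying one
six-state hypnogram label.  Six-state labels follow the R&K convention
(WA, NREM1, NREM2, NREM3, NREM4, REM) and can be merged into five-, four-,
three- and two-state schemes (NREM3+NREM4 -> SWS, NREM1+NREM2 -> light sleep,
all NREM -> NREM, everything but WA -> sleep).

Internally the six stages are encoded as integers 0..5 in the order above;
merged schemes use 0..k-1 in the order of :data:`SCHEME_LABELS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ChannelMismatchError,
    InsufficientDataError,
    TableFormatError,
    UnknownLabelError,
)

#: canonical channel names, in storage order
CHANNELS = ("Fpz-Cz", "Pz-Oz")

#: six-state stage vocabulary; index in this tuple == integer encoding
SIX_STATE = ("WA", "NREM1", "NREM2", "NREM3", "NREM4", "REM")

#: hypnogram annotations excluded from all downstream computation
EXCLUDED_LABELS = ("MOVEMENT", "?", "UNKNOWN")

#: merged label sets per scheme, in integer-encoding order
SCHEME_LABELS = {
    "six": SIX_STATE,
    "five": ("WA", "NREM1", "NREM2", "SWS", "REM"),
    "four": ("WA", "light sleep", "SWS", "REM"),
    "three": ("WA", "NREM", "REM"),
    "two": ("WA", "sleep"),
}

# six-state label -> merged label, one dict per scheme
_SCHEME_MAPS = {
    "six": {s: s for s in SIX_STATE},
    "five": {
        "WA": "WA", "NREM1": "NREM1", "NREM2": "NREM2",
        "NREM3": "SWS", "NREM4": "SWS", "REM": "REM",
    },
    "four": {
        "WA": "WA", "NREM1": "light sleep", "NREM2": "light sleep",
        "NREM3": "SWS", "NREM4": "SWS", "REM": "REM",
    },
    "three": {
        "WA": "WA", "NREM1": "NREM", "NREM2": "NREM",
        "NREM3": "NREM", "NREM4": "NREM", "REM": "REM",
    },
    "two": {
        "WA": "WA", "NREM1": "sleep", "NREM2": "sleep",
        "NREM3": "sleep", "NREM4": "sleep", "REM": "sleep",
    },
}

#: metadata columns reserved in feature tables (everything else is a feature)
META_COLUMNS = ("stage", "subject_id", "gender", "epoch_id")


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject demographics attached to every epoch of a recording."""

    subject_id: str
    gender: str  # "female" | "male"
    age: int
    health_status: str = ""
    cohort: str = "SC"  # "SC" (healthy) or "ST" (temazepam study)

    def __post_init__(self):
        if self.gender not in ("female", "male"):
            raise UnknownLabelError(f"gender must be female/male, got {self.gender!r}")
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")


@dataclass
class Epoch:
    """One 30-s, 2-channel, 100-Hz EEG window with its stage label.

    ``samples`` is a float array of shape (2, 3000) in microvolts, channel
    order matching ``channels``.
    """

    samples: np.ndarray
    stage: str
    subject_id: str
    epoch_id: str
    fs: float = 100.0
    channels: tuple = CHANNELS

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channels):
            raise ChannelMismatchError(
                f"expected {len(self.channels)} channels, got shape {self.samples.shape}"
            )
        if self.stage not in SIX_STATE:
            raise UnknownLabelError(f"unknown stage {self.stage!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def stage_index(self) -> int:
        return SIX_STATE.index(self.stage)


@dataclass(frozen=True)
class StageScheme:
    """A total mapping from the six R&K stages onto a merged label set."""

    name: str
    mapping: dict = field(compare=False)

    @classmethod
    def by_name(cls, name: str) -> "StageScheme":
        if name not in _SCHEME_MAPS:
            raise UnknownLabelError(
                f"unknown scheme {name!r}; choose from {sorted(_SCHEME_MAPS)}"
            )
        return cls(name=name, mapping=dict(_SCHEME_MAPS[name]))

    @property
    def labels(self) -> tuple:
        return SCHEME_LABELS[self.name]

    def encode(self, merged_label: str) -> int:
        return self.labels.index(merged_label)


def map_stage(stage: str, scheme: StageScheme | str) -> str:
    """Map a six-state label onto the merged label of ``scheme``."""
    if isinstance(scheme, str):
        scheme = StageScheme.by_name(scheme)
    try:
        return scheme.mapping[stage]
    except KeyError:
        raise UnknownLabelError(f"unknown stage {stage!r} for scheme {scheme.name!r}")


def segment_epochs(
    signals: np.ndarray,
    fs: float,
    epoch_seconds: float = 30.0,
    stages: list | None = None,
    subject_id: str = "",
    channels: tuple = CHANNELS,
) -> list:
    """Cut a continuous multi-channel recording into non-overlapping epochs.

    Epoch ``k`` covers the half-open sample range ``[k*N, (k+1)*N)`` with
    ``N = fs * epoch_seconds``; a trailing partial window is discarded.
    ``stages``, when given, supplies one six-state label per epoch (defaults
    to "WA").
    """
    if isinstance(signals, (list, tuple)):
        lengths = {len(np.asarray(ch)) for ch in signals}
        if len(lengths) > 1:
            raise ChannelMismatchError(f"channel lengths differ: {sorted(lengths)}")
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.ndim != 2:
        raise ChannelMismatchError("signals must be a 2-D channel x sample array")
    n_per = fs * epoch_seconds
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("fs * epoch_seconds must be an integer sample count")
    n_per = int(round(n_per))
    n_epochs = signals.shape[1] // n_per
    if stages is not None and len(stages) < n_epochs:
        raise InsufficientDataError(
            f"{n_epochs} epochs but only {len(stages)} stage labels"
        )
    out = []
    for k in range(n_epochs):
        stage = stages[k] if stages is not None else "WA"
        out.append(
            Epoch(
                samples=signals[:, k * n_per : (k + 1) * n_per].copy(),
                stage=stage,
                subject_id=subject_id,
                epoch_id=f"{subject_id}:{k}",
                fs=fs,
                channels=channels,
            )
        )
    return out


def sample_epochs(epochs: list, n: int, seed: int, record: str = "") -> list:
    """Uniform sample of ``n`` epochs without replacement, order preserved
    as drawn.  Reproducible for a fixed ``seed``."""
    if n > len(epochs):
        name = record or (epochs[0].subject_id if epochs else "<empty>")
        raise InsufficientDataError(
            f"record {name!r}: requested {n} epochs but only {len(epochs)} available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(epochs), size=n, replace=False)
    return [epochs[i] for i in idx]


def dataset_accounting(record_sizes: dict, per_record: int) -> int:
    """Total segment count when ``per_record`` epochs are drawn from every
    record; errors if any record is too short (no resampling fallback)."""
    for name, size in record_sizes.items():
        if size < per_record:
            raise InsufficientDataError(
                f"record {name!r}: requested {per_record} epochs but only {size} available"
            )
    return per_record * len(record_sizes)


# ---------------------------------------------------------------------------
# feature tables (canonical CSV interchange)
# ---------------------------------------------------------------------------

def write_feature_table(matrix: pd.DataFrame, path) -> None:
    """Write a feature matrix to CSV with full float precision.

    Columns: the 60 feature names plus the reserved metadata columns
    (``stage``, ``subject_id``, ``gender``, ``epoch_id``).
    """
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].tolist()
        raise TableFormatError(f"duplicate columns: {dupes}")
    matrix.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path)
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].tolist()
        raise TableFormatError(f"duplicate columns: {dupes}")
    feature_cols = [c for c in df.columns if c not in META_COLUMNS]
    for col in feature_cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise TableFormatError(
                f"non-numeric value {df[col][row]!r} at row {row}, column {col!r}"
            )
        df[col] = coerced
    return df


def feature_columns(matrix: pd.DataFrame) -> list:
    """Names of the feature columns (everything not reserved metadata)."""
    return [c for c in matrix.columns if c not in META_COLUMNS]


# ---------------------------------------------------------------------------
# plain-text hypnogram: one "epoch_index,stage_label" pair per line
# ---------------------------------------------------------------------------

def write_hypnogram(labels: list, path) -> None:
    with open(path, "w") as fh:
        for i, lab in enumerate(labels):
            fh.write(f"{i},{lab}\n")


def read_hypnogram(path) -> list:
    """Read labels; entries outside the six-state vocabulary (MOVEMENT, ?)
    are kept verbatim so the caller can flag them for exclusion."""
    labels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise TableFormatError(f"line {lineno}: expected 'index,label', got {line!r}")
            labels.append(parts[1])
    return labels


def usable_mask(labels: list) -> np.ndarray:
    """Boolean mask of hypnogram entries that are valid six-state labels."""
    return np.array([lab in SIX_STATE for lab in labels], dtype=bool)
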