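"""Optional EDF/EDF+ support: an mne-backed reader and a minimal writer
for test fixtures.

Real recordings come as EDF files with the two EEG channels (Fpz-Cz,
Pz-Oz) at 100 Hz plus a hypnogram.  Reading goes through ``mne``; the
writer emits just enough of the format (one data record per second,
16-bit samples, physical range equal to digital range so values are
stored losslessly on the integer grid) to build self-contained fixtures.
Hypnograms travel as the plain-text ``epoch_index,stage_label`` sidecar
format from :mod:`sleepforest.epoch_io`.
"""

from __future__ import annotations

import numpy as np

from .epoch_io import CHANNELS, SubjectMeta, read_hypnogram, usable_mask
from .errors import ChannelMismatchError, TableFormatError


def write_edf(
    path,
    signals: np.ndarray,
    fs: float = 100.0,
    channels=CHANNELS,
    patient_id: str = "X X X X",
) -> None:
    """Write a minimal EDF file; samples are rounded to integers and must
    fit in [-32768, 32767] (fixture-quality, microvolt units)."""
    signals = np.atleast_2d(np.asarray(signals))
    n_ch, n_samp = signals.shape
    if n_ch != len(channels):
        raise ChannelMismatchError(f"{n_ch} signals for {len(channels)} channel names")
    if n_samp % int(fs) != 0:
        raise TableFormatError("signal length must be a whole number of seconds")
    digital = np.round(signals).astype(np.int16)
    n_records = n_samp // int(fs)
    spr = int(fs)  # samples per record (1-s records)

    def pad(text, width):
        return str(text)[:width].ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8), pad(patient_id, 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(256 + 256 * n_ch, 8), pad("", 44), pad(n_records, 8),
        pad(1, 8), pad(n_ch, 4),
    ])
    sig_header = b"".join([
        b"".join(pad(ch, 16) for ch in channels),
        b"".join(pad("AgAgCl electrode", 80) for _ in channels),
        b"".join(pad("uV", 8) for _ in channels),
        b"".join(pad(-32768, 8) for _ in channels),   # physical min
        b"".join(pad(32767, 8) for _ in channels),    # physical max
        b"".join(pad(-32768, 8) for _ in channels),   # digital min
        b"".join(pad(32767, 8) for _ in channels),    # digital max
        b"".join(pad("", 80) for _ in channels),      # prefiltering
        b"".join(pad(spr, 8) for _ in channels),
        b"".join(pad("", 32) for _ in channels),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.astype("<i2").tobytes())


def read_edf_recording(
    path,
    hypnogram_path=None,
    channels=CHANNELS,
    meta: SubjectMeta | None = None,
):
    """Read an EDF recording: ``(signals_uV, meta, labels, usable)``.

    ``signals_uV`` contains only the requested channels (microvolts);
    ``labels`` is the per-epoch hypnogram (empty when no sidecar is given)
    and ``usable`` flags entries carrying a valid six-state label —
    MOVEMENT/unknown epochs are flagged for exclusion.
    """
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise TableFormatError(f"unreadable EDF header/file {path}: {exc}") from exc
    missing = [ch for ch in channels if ch not in raw.ch_names]
    if missing:
        raise ChannelMismatchError(
            f"channels {missing} absent from {path} (has {raw.ch_names})"
        )
    picks = [raw.ch_names.index(ch) for ch in channels]
    signals = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
    labels = read_hypnogram(hypnogram_path) if hypnogram_path else []
    usable = usable_mask(labels) if labels else np.zeros(0, dtype=bool)
    return signals, meta, labels, usable
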