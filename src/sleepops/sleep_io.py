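"""Polysomnography I/O: EDF recordings, hypnogram annotations, labeled epochs.

Reading goes through MNE (``mne.io.read_raw_edf`` for signals,
``mne.read_annotations`` for EDF+ hypnograms).  A minimal EDF/EDF+ writer is
included so synthetic recordings can exercise the same reader path; it covers
exactly the dialect the reader needs (single signal, 16-bit samples, one
annotation channel) and is not a general-purpose EDF exporter.

Conventions: sample indices are 0-based; epoch windows are half-open
``[start, start + n)``; signal amplitudes are microvolts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChannelNotFoundError, FormatError

logger = logging.getLogger(__name__)

#: Canonical stage order used everywhere (labels, confusion-matrix rows).
STAGES = ("W", "N1", "N2", "N3", "R")

#: Sleep-EDF (Rechtschaffen & Kales) annotation strings -> five-class labels.
#: Stages 3 and 4 merge into N3; movement/unscored epochs are dropped.
RAW_STAGE_MAP = {
    "Sleep stage W": "W",
    "Sleep stage 1": "N1",
    "Sleep stage 2": "N2",
    "Sleep stage 3": "N3",
    "Sleep stage 4": "N3",
    "Sleep stage R": "R",
}

DEFAULT_SAMPLING_RATE = 100.0
DEFAULT_EPOCH_SECONDS = 30


@dataclass
class LabeledEpoch:
    """One 30-s window of signal with its sleep-stage label and provenance."""

    samples: np.ndarray
    stage: str
    subject_id: str
    start_sample: int
    origin: str = "original"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.start_sample < 0:
            raise ValueError("start_sample must be >= 0")
        if self.origin not in ("original", "augmented"):
            raise ValueError(f"origin must be 'original' or 'augmented', got {self.origin!r}")


@dataclass
class Recording:
    """A continuous single-channel recording plus its hypnogram annotations.

    ``annotations`` is a list of ``(onset_seconds, duration_seconds, label)``
    with non-decreasing onsets; labels are the raw annotation strings.
    """

    signal: np.ndarray
    sampling_rate: float
    channel: str
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        onsets = [a[0] for a in self.annotations]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("annotation onsets must be non-decreasing")


def read_recording(
    signal_path: str | Path,
    annotation_path: str | Path | None = None,
    channel_name: str = "EEG Fpz-Cz",
    subject_id: str | None = None,
) -> Recording:
    """Load one channel of an EDF file and, optionally, its EDF+ hypnogram."""
    import mne

    signal_path = Path(signal_path)
    try:
        raw = mne.io.read_raw_edf(signal_path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - surface a single format error type
        raise FormatError(f"could not parse EDF file {signal_path}: {exc}") from exc
    if channel_name not in raw.ch_names:
        raise ChannelNotFoundError(
            f"channel {channel_name!r} not in {signal_path.name} "
            f"(available: {raw.ch_names})"
        )
    data = raw.get_data(picks=[channel_name], units="uV")[0]

    annotations: list[tuple[float, float, str]] = []
    if annotation_path is not None:
        try:
            ann = mne.read_annotations(annotation_path)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(
                f"could not parse annotation file {annotation_path}: {exc}"
            ) from exc
        annotations = [
            (float(o), float(d), str(desc))
            for o, d, desc in zip(ann.onset, ann.duration, ann.description)
        ]

    return Recording(
        signal=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel=channel_name,
        annotations=annotations,
        subject_id=subject_id or signal_path.stem,
    )


def epochs_from_recording(
    rec: Recording, epoch_seconds: int = DEFAULT_EPOCH_SECONDS
) -> list[LabeledEpoch]:
    """Tile each annotated stage run into consecutive non-overlapping epochs.

    Raw labels are mapped through ``RAW_STAGE_MAP`` (already-mapped five-class
    labels pass through); unmapped labels and trailing partial epochs are
    dropped, with counts logged.
    """
    n_per = rec.sampling_rate * epoch_seconds
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            f"epoch of {epoch_seconds} s is not an integer number of samples "
            f"at {rec.sampling_rate} Hz"
        )
    n_per = int(round(n_per))

    epochs: list[LabeledEpoch] = []
    n_dropped = 0
    for onset, duration, label in rec.annotations:
        stage = RAW_STAGE_MAP.get(label, label if label in STAGES else None)
        n_full = int(duration // epoch_seconds)
        if stage is None:
            n_dropped += n_full
            continue
        run_start = int(round(onset * rec.sampling_rate))
        for k in range(n_full):
            start = run_start + k * n_per
            if start + n_per > rec.signal.size:
                break  # trailing partial epoch
            epochs.append(
                LabeledEpoch(
                    samples=rec.signal[start : start + n_per],
                    stage=stage,
                    subject_id=rec.subject_id,
                    start_sample=start,
                )
            )
    if n_dropped:
        logger.info("dropped %d epochs with unmapped stage labels", n_dropped)
    return epochs


# ---------------------------------------------------------------------------
# Minimal EDF / EDF+ writing (fixture support for the reader path)
# ---------------------------------------------------------------------------

_DIG_MAX = 32767
_DIG_MIN = -32768


def _fixed(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf_signal(
    path: str | Path,
    signal: np.ndarray,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    channel: str = "EEG Fpz-Cz",
    subject_id: str = "X",
) -> None:
    """Write a single-channel EDF file (16-bit, 1-s data records, microvolts).

    The signal length must be a whole number of 1-s records.  Amplitudes are
    quantized to the 16-bit digital range spanning the signal's extremes, so a
    read-back differs from the input by at most one quantization step.
    """
    signal = np.asarray(signal, dtype=float)
    spr = int(round(sampling_rate))
    if abs(sampling_rate - spr) > 1e-9:
        raise ValueError("writer supports integer sampling rates only")
    if signal.size % spr != 0:
        raise ValueError("signal length must be a whole number of 1-s records")
    n_records = signal.size // spr

    vmax = float(np.max(np.abs(signal))) if signal.size else 0.0
    vmax = vmax if vmax > 0 else 1.0
    # Round the physical range to what the 8-char header field holds exactly,
    # then digitize against the stored value.
    pmax_str = f"{vmax * 1.001:.6g}"[:8]
    pmax = float(pmax_str)
    pmin_str = f"{-pmax:.6g}"[:8]
    pmin = float(pmin_str)
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.round((signal - pmin) * scale + _DIG_MIN).astype("<i2")

    header = b"".join(
        [
            _fixed("0", 8),
            _fixed(f"{subject_id} X X X", 80),
            _fixed("Startdate 01-JAN-2000 X X X", 80),
            _fixed("01.01.00", 8),
            _fixed("00.00.00", 8),
            _fixed(str(256 * 2), 8),
            _fixed("", 44),
            _fixed(str(n_records), 8),
            _fixed("1", 8),
            _fixed("1", 4),
            # per-signal header block
            _fixed(channel, 16),
            _fixed("", 80),
            _fixed("uV", 8),
            _fixed(pmin_str, 8),
            _fixed(pmax_str, 8),
            _fixed(str(_DIG_MIN), 8),
            _fixed(str(_DIG_MAX), 8),
            _fixed("", 80),
            _fixed(str(spr), 8),
            _fixed("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())


def write_edf_annotations(
    path: str | Path,
    annotations: list[tuple[float, float, str]],
    total_seconds: float,
) -> None:
    """Write an EDF+ annotation-only file (hypnogram) readable by MNE.

    All annotations go into a single data record as standard time-stamped
    annotation lists (TALs).
    """
    tals = bytearray(b"+0\x14\x14\x00")
    for onset, duration, label in annotations:
        tals += f"+{onset:g}\x15{duration:g}\x14{label}\x14\x00".encode("ascii")
    if len(tals) % 2:
        tals += b"\x00"
    spr = len(tals) // 2

    header = b"".join(
        [
            _fixed("0", 8),
            _fixed("X X X X", 80),
            _fixed("Startdate 01-JAN-2000 X X X", 80),
            _fixed("01.01.00", 8),
            _fixed("00.00.00", 8),
            _fixed(str(256 * 2), 8),
            _fixed("EDF+C", 44),
            _fixed("1", 8),
            _fixed(f"{total_seconds:g}", 8),
            _fixed("1", 4),
            _fixed("EDF Annotations", 16),
            _fixed("", 80),
            _fixed("", 8),
            _fixed("-1", 8),
            _fixed("1", 8),
            _fixed(str(_DIG_MIN), 8),
            _fixed(str(_DIG_MAX), 8),
            _fixed("", 80),
            _fixed(str(spr), 8),
            _fixed("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(bytes(tals))


def write_recording(
    rec: Recording, signal_path: str | Path, annotation_path: str | Path | None = None
) -> None:
    """Persist a Recording as an EDF signal file plus EDF+ hypnogram."""
    write_edf_signal(
        signal_path,
        rec.signal,
        sampling_rate=rec.sampling_rate,
        channel=rec.channel,
        subject_id=rec.subject_id or "X",
    )
    if annotation_path is not None:
        write_edf_annotations(
            annotation_path,
            rec.annotations,
            total_seconds=rec.signal.size / rec.sampling_rate,
        )


# ---------------------------------------------------------------------------
# Feature-table CSV schema
# ---------------------------------------------------------------------------

META_COLUMNS = ["subject_id", "start_sample", "origin", "stage"]


def write_feature_frame(frame: pd.DataFrame, path: str | Path) -> None:
    """Write an epochs-by-features table as CSV (meta columns first)."""
    cols = META_COLUMNS + [c for c in frame.columns if c not in META_COLUMNS]
    frame.loc[:, cols].to_csv(path, index=False)


def read_feature_frame(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"feature table {path} lacks columns {missing}")
    return frame
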