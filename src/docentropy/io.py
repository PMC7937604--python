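"""EEG recording container, file I/O, acquisition-matching filters, epoch
selection, and the affected/unaffected montage remapping.

Recordings are 16-channel 10-20 subsets sampled at a uniform rate (500 Hz in
the study design), band-limited at acquisition to 0.3-100 Hz; only the 50-Hz
mains notch is (re)applied in software. The left/right channel labels are
remapped to affected/unaffected (_A/_U) once the more severely injured
hemisphere is known — from imaging when available, otherwise by the lower
mean eyes-closed ApEn over the hemisphere's 8 channels (lower complexity =
more severe impairment).

File dialects: CSV with one column per channel, a header row of labels, and
a JSON sidecar carrying the sampling rate (``<stem>.json``); EDF is read via
:mod:`mne` when installed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from . import channels as ch
from .entropy import ApEnParams, apen

logger = logging.getLogger(__name__)


@dataclass
class EEGRecording:
    """One subject x condition multichannel epoch, in microvolts."""

    subject_id: str
    condition: str
    fs: float
    channel_labels: list[str]
    data: np.ndarray  # channels x samples

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel row required")
        if len(self.channel_labels) != 16:
            raise ValueError(
                f"expected 16 channels, got {len(self.channel_labels)}")
        if len(set(self.channel_labels)) != 16:
            raise ValueError("channel labels must be unique")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Epoch duration in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


@dataclass(frozen=True)
class MontageMap:
    """Affected-side assignment plus the induced label permutation."""

    affected_side: str              # 'left' or 'right'
    source: str                     # 'imaging' or 'apen_tiebreak'
    relabeled: tuple[str, ...] = tuple(ch.RELABELED)

    def __post_init__(self) -> None:
        if self.affected_side not in ("left", "right"):
            raise ValueError("affected_side must be 'left' or 'right'")
        if self.source not in ("imaging", "apen_tiebreak"):
            raise ValueError("source must be 'imaging' or 'apen_tiebreak'")

    @property
    def label_map(self) -> dict[str, str]:
        """Canonical 10-20 label -> relabeled _A/_U name."""
        return ch.relabel_map(self.affected_side)


def _validate_labels(labels: list[str]) -> list[str]:
    norm = [ch.normalize_label(lab) for lab in labels]
    missing = sorted(set(ch.RAW_LABELS) - set(norm))
    extra = sorted(set(norm) - set(ch.RAW_LABELS))
    if missing or extra:
        raise ValueError(
            f"channel mismatch: missing {missing or 'none'}, "
            f"unexpected {extra or 'none'}")
    return norm


def read_recording(path: str | Path, dialect: str | None = None,
                   subject_id: str | None = None,
                   condition: str | None = None) -> EEGRecording:
    """Read a 16-channel recording from CSV (+ JSON sidecar) or EDF.

    The dialect is inferred from the suffix when not given. Channel labels
    are validated against the 16-channel 10-20 montage (case-insensitive,
    T7/T8/P7/P8 accepted for T3/T4/T5/T6).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "EDF" if path.suffix.lower() == ".edf" else "CSV"
    if dialect.upper() == "EDF":
        return _read_edf(path, subject_id, condition)
    return _read_csv(path, subject_id, condition)


def _read_csv(path: Path, subject_id: str | None,
              condition: str | None) -> EEGRecording:
    frame = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"sidecar {sidecar} with the sampling rate is required for CSV")
    meta = json.loads(sidecar.read_text())
    labels = _validate_labels(list(frame.columns))
    data = frame.to_numpy(dtype=float).T
    return EEGRecording(
        subject_id=subject_id or meta.get("subject_id", path.stem),
        condition=condition or meta.get("condition", "eyes_closed"),
        fs=float(meta["fs"]),
        channel_labels=labels,
        data=data,
    )


def _read_edf(path: Path, subject_id: str | None,
              condition: str | None) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = _validate_labels(list(raw.ch_names))
    return EEGRecording(
        subject_id=subject_id or path.stem,
        condition=condition or "eyes_closed",
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        data=raw.get_data() * 1e6,  # mne returns volts
    )


def write_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as CSV plus a JSON sidecar; returns the CSV path."""
    path = Path(path)
    if path.suffix.lower() != ".csv":
        raise ValueError("only the CSV dialect is written; use a .csv path")
    frame = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    frame.to_csv(path, index=False, float_format="%.6f")
    sidecar = {"fs": rec.fs, "subject_id": rec.subject_id,
               "condition": rec.condition}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def notch_filter(rec: EEGRecording, freq: float = 50.0,
                 q: float = 30.0) -> EEGRecording:
    """Zero-phase second-order IIR notch at ``freq`` Hz per channel."""
    if freq >= rec.fs / 2:
        raise ValueError(f"notch frequency {freq} Hz is at or above Nyquist "
                         f"({rec.fs / 2} Hz)")
    b, a = signal.iirnotch(freq, q, fs=rec.fs)
    out = signal.filtfilt(b, a, rec.data, axis=1)
    return replace(rec, data=out)


def select_epoch(rec: EEGRecording, n_points: int = 32768,
                 amplitude_limit: float = 100.0) -> EEGRecording:
    """Earliest artifact-free window of ``n_points`` consecutive samples.

    The automated artifact criterion is an absolute amplitude threshold
    (default 100 uV) on every channel. Raises if no qualifying window
    exists, reporting the longest clean run found. The chosen start index is
    recorded on the result as ``epoch_start``.
    """
    if rec.n_samples < n_points:
        raise ValueError(f"recording has {rec.n_samples} samples, "
                         f"need at least {n_points}")
    clean = np.all(np.abs(rec.data) <= amplitude_limit, axis=0)
    # run-length of clean samples ending at each index
    run = np.zeros(rec.n_samples, dtype=int)
    acc = 0
    for i, ok in enumerate(clean):
        acc = acc + 1 if ok else 0
        run[i] = acc
    qualifying = np.nonzero(run >= n_points)[0]
    if len(qualifying) == 0:
        raise ValueError(
            f"no artifact-free window of {n_points} samples at "
            f"|amplitude| <= {amplitude_limit} uV; longest clean run is "
            f"{int(run.max())} samples")
    start = int(qualifying[0]) - n_points + 1
    out = replace(rec, data=rec.data[:, start:start + n_points].copy())
    out.epoch_start = start
    return out


def determine_affected_side(imaging_side: str,
                            eyes_closed_rec: EEGRecording | None = None,
                            p: ApEnParams | None = None) -> MontageMap:
    """Affected hemisphere from imaging, or by the ApEn tie-break.

    When imaging is inconclusive ('unknown'), the hemisphere with the lower
    mean eyes-closed ApEn over its 8 channels is labeled affected. An exact
    tie resolves to 'left' with a logged warning.
    """
    if imaging_side in ("left", "right"):
        return MontageMap(affected_side=imaging_side, source="imaging")
    if imaging_side != "unknown":
        raise ValueError("imaging_side must be 'left', 'right' or 'unknown'")
    if eyes_closed_rec is None:
        raise ValueError("eyes-closed recording required for the ApEn tie-break")

    rec = eyes_closed_rec
    pp = p if p is not None else ApEnParams(n_points=rec.n_samples)
    means = {}
    for side, labels in (("left", ch.LEFT_LABELS), ("right", ch.RIGHT_LABELS)):
        vals = [apen(rec.channel(lab), pp) for lab in labels]
        means[side] = float(np.mean(vals))
    if means["left"] == means["right"]:
        logger.warning("hemispheric mean ApEn exactly tied (%.6f); "
                       "labeling left as affected", means["left"])
        side = "left"
    else:
        side = "left" if means["left"] < means["right"] else "right"
    return MontageMap(affected_side=side, source="apen_tiebreak")


def remap_montage(rec: EEGRecording, montage: MontageMap) -> EEGRecording:
    """Reorder channels into the canonical relabeled order (FP_A, FP_U, ...).

    Pure permutation: data are not modified.
    """
    norm = _validate_labels(rec.channel_labels)
    label_map = montage.label_map
    new_of_old = {label_map[lab]: i for i, lab in enumerate(norm)}
    order = [new_of_old[lab] for lab in montage.relabeled]
    return replace(rec, channel_labels=list(montage.relabeled),
                   data=rec.data[order])


def invert_montage(rec: EEGRecording, montage: MontageMap) -> EEGRecording:
    """Undo :func:`remap_montage`, restoring canonical 10-20 labels."""
    inverse = {v: k for k, v in montage.label_map.items()}
    old_labels = [inverse[lab] for lab in rec.channel_labels]
    order = [old_labels.index(lab) for lab in ch.RAW_LABELS]
    return replace(rec, channel_labels=list(ch.RAW_LABELS), data=rec.data[order])
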