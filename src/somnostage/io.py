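"""PSG recordings and hypnograms: domain types, EDF/CSV readers and writers.

A :class:`Recording` holds the multi-channel signal of one night in
microvolts; a :class:`Hypnogram` holds the expert stage labels on the fixed
30-s epoch grid. Signals travel as EDF/EDF+; hypnograms as either a CSV
dialect (header ``epoch,stage``, 0-based epoch index, tokens W/N1/N2/N3/REM)
or EDF+ annotations whose durations are multiples of 30 s.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np

from . import _edf
from .stages import STAGES, indices_to_stages, stage_to_index

__all__ = [
    "Channel",
    "Recording",
    "Hypnogram",
    "EPOCH_SECONDS",
    "DEFAULT_MODALITY_PATTERNS",
    "infer_modality",
    "read_edf",
    "write_edf",
    "read_hypnogram",
    "write_hypnogram_csv",
    "write_hypnogram_edf",
    "align_labels",
]

EPOCH_SECONDS = 30

MODALITIES = ("EEG", "EOG", "EMG", "ECG")

# EDF channel labels vary across recorders; modality is inferred from a
# configurable regex map, first match wins, default EEG.
DEFAULT_MODALITY_PATTERNS: tuple[tuple[str, str], ...] = (
    (r"EOG|E[12]\b", "EOG"),
    (r"EMG|CHIN", "EMG"),
    (r"ECG|EKG", "ECG"),
)


def infer_modality(label: str, patterns=DEFAULT_MODALITY_PATTERNS) -> str:
    for pattern, modality in patterns:
        if re.search(pattern, label, flags=re.IGNORECASE):
            return modality
    return "EEG"


@dataclass
class Channel:
    label: str
    samples: np.ndarray  # microvolts
    rate: float  # Hz
    modality: str = "EEG"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError(f"channel {self.label!r}: rate must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(
                f"channel {self.label!r}: modality {self.modality!r} not in {MODALITIES}"
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class Recording:
    """One night of multi-channel PSG signal."""

    channels: list[Channel]
    start_time: datetime = field(default_factory=lambda: datetime(2000, 1, 1, 23, 0))
    subject_id: str = "S00"
    night_id: str = "N00"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("recording needs at least one channel")
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate channel labels: {labels}")
        durations = {round(c.duration, 9) for c in self.channels}
        if len(durations) != 1:
            raise ValueError(f"channels disagree on duration: {sorted(durations)} s")

    @property
    def duration(self) -> float:
        return self.channels[0].duration

    @property
    def channel_labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel(self, label: str) -> Channel:
        for c in self.channels:
            if c.label == label:
                return c
        raise KeyError(
            f"channel {label!r} not found; available: {self.channel_labels}"
        )


@dataclass
class Hypnogram:
    """Per-epoch stage indices (0-4 = W, N1, N2, N3, REM) on the 30-s grid."""

    stages: np.ndarray
    start_time: datetime = field(default_factory=lambda: datetime(2000, 1, 1, 23, 0))
    epoch_seconds: int = EPOCH_SECONDS

    def __post_init__(self) -> None:
        self.stages = np.asarray(self.stages, dtype=np.int64).ravel()
        if self.epoch_seconds != EPOCH_SECONDS:
            raise ValueError("epoch length is fixed at 30 s")
        if self.stages.size and (self.stages.min() < 0 or self.stages.max() > 4):
            raise ValueError("stage indices must lie in 0-4")

    def __len__(self) -> int:
        return self.stages.size

    @property
    def labels(self) -> list[str]:
        return indices_to_stages(self.stages)


def read_edf(path, channel_whitelist=None, modality_patterns=DEFAULT_MODALITY_PATTERNS,
             subject_id: str | None = None, night_id: str | None = None) -> Recording:
    """Read a Recording from an EDF/EDF+ file.

    ``channel_whitelist`` keeps only the named channels (error listing the
    available labels when one is missing). Microvolt scaling comes from the
    EDF header; modality from the label regex map.
    """
    path = Path(path)
    signals, _, start_time = _edf.read_edf(path)
    by_label = {s.label: s for s in signals}
    if channel_whitelist is not None:
        missing = [c for c in channel_whitelist if c not in by_label]
        if missing:
            raise KeyError(
                f"channel(s) {missing} not found in {path.name}; "
                f"available: {sorted(by_label)}"
            )
        keep = list(channel_whitelist)
    else:
        keep = [s.label for s in signals]
    channels = [
        Channel(
            label=lbl,
            samples=by_label[lbl].samples,
            rate=by_label[lbl].rate,
            modality=infer_modality(lbl, modality_patterns),
        )
        for lbl in keep
    ]
    return Recording(
        channels=channels,
        start_time=start_time,
        subject_id=subject_id or path.stem,
        night_id=night_id or path.stem,
    )


def write_edf(rec: Recording, path) -> None:
    """Write a Recording to EDF (16-bit; round trip exact to one quantization step)."""
    signals = [
        _edf.EdfSignal(label=c.label, samples=c.samples, rate=c.rate)
        for c in rec.channels
    ]
    _edf.write_edf(
        path,
        signals,
        start_time=rec.start_time,
        patient_id=rec.subject_id,
        recording_id=rec.night_id,
    )


def _expand_annotation(onset: float, duration: float, token: str, rk_merge: bool):
    if duration <= 0 or duration % EPOCH_SECONDS != 0:
        raise ValueError(
            f"annotation {token!r} at {onset} s: duration {duration} s is not a "
            f"positive multiple of {EPOCH_SECONDS} s"
        )
    idx = stage_to_index(token, rk_merge=rk_merge)
    return [idx] * int(duration // EPOCH_SECONDS)


def read_hypnogram(path, dialect: str = "csv", rk_merge: bool = True,
                   drop_unscored: bool = False) -> Hypnogram:
    """Read a hypnogram in the CSV dialect or from EDF+ annotations.

    The same staging in either form yields identical stage vectors. R&K
    tokens S3/S4 merge into N3 when ``rk_merge`` is set. ``drop_unscored``
    silently drops movement/unknown epochs ('?', 'M', 'Movement time');
    callers must then drop the matching signal epochs too.
    """
    path = Path(path)
    skip_tokens = {"?", "M", "MOVEMENT TIME", "SLEEP STAGE ?"}
    if dialect == "csv":
        stages = []
        start_time = datetime(2000, 1, 1, 23, 0)
        with open(path, newline="") as f:
            reader = csv.DictReader(f)
            if reader.fieldnames is None or "stage" not in reader.fieldnames:
                raise ValueError(f"{path}: expected CSV header 'epoch,stage'")
            for row in reader:
                token = row["stage"].strip()
                if drop_unscored and token.upper() in skip_tokens:
                    stages.append(-1)
                    continue
                stages.append(stage_to_index(token, rk_merge=rk_merge))
        stages = np.array(stages, dtype=np.int64)
        stages = stages[stages >= 0]
        return Hypnogram(stages=stages, start_time=start_time)
    if dialect == "edf+annotations":
        _, annotations, start_time = _edf.read_edf(path)
        stages: list[int] = []
        for onset, duration, text in sorted(annotations):
            if drop_unscored and text.strip().upper() in skip_tokens:
                continue
            stages.extend(_expand_annotation(onset, duration, text, rk_merge))
        return Hypnogram(stages=np.array(stages, dtype=np.int64), start_time=start_time)
    raise ValueError(f"unknown hypnogram dialect {dialect!r}")


def write_hypnogram_csv(hyp: Hypnogram, path) -> None:
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["epoch", "stage"])
        for i, label in enumerate(hyp.labels):
            writer.writerow([i, label])


def write_hypnogram_edf(hyp: Hypnogram, path) -> None:
    """Write a hypnogram as an annotation-only EDF+ file (run-length TALs)."""
    annotations = []
    stages = hyp.stages
    start = 0
    for i in range(1, len(stages) + 1):
        if i == len(stages) or stages[i] != stages[start]:
            annotations.append(
                (
                    start * EPOCH_SECONDS,
                    (i - start) * EPOCH_SECONDS,
                    STAGES[stages[start]],
                )
            )
            start = i
    _edf.write_edf(path, [], start_time=hyp.start_time, annotations=annotations)


# Hypnograms commonly run a little past the end of the signal; more than this
# many surplus labels is treated as a misalignment rather than scorer overrun.
_MAX_SURPLUS_EPOCHS = 2


def align_labels(rec: Recording, hyp: Hypnogram) -> tuple[Recording, Hypnogram]:
    """Validate/truncate a hypnogram against floor(duration / 30 s)."""
    n_epochs = int(rec.duration // EPOCH_SECONDS)
    n_labels = len(hyp)
    if n_labels == n_epochs:
        return rec, hyp
    if n_epochs < n_labels <= n_epochs + _MAX_SURPLUS_EPOCHS:
        return rec, Hypnogram(
            stages=hyp.stages[:n_epochs], start_time=hyp.start_time
        )
    raise ValueError(
        f"label count {n_labels} does not match the {n_epochs} complete 30-s "
        f"epochs of the {rec.duration:.0f}-s recording"
    )
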