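"""Modality-specific bandpass filtering, 30-s epoching, 9.5-h night standardization.

Each channel is filtered with a zero-phase (forward-backward) Butterworth
bandpass chosen by modality: EEG and EOG 0.3-35 Hz, EMG 10-100 Hz, ECG
0.3-70 Hz, order 4. When the upper edge reaches the Nyquist frequency (EMG at
100 Hz sampling) it is clipped to 0.99 x Nyquist with a warning.

Nights are standardized to exactly 1,140 epochs (9.5 h of 30-s epochs):
longer nights are truncated from the end; shorter nights are pre-padded by
cyclically repeating the night's leading consecutive Wake epochs (signal and
label alike), i.e. the padding extends the pre-sleep Wake period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import EPOCH_SECONDS, Channel, Hypnogram, Recording

__all__ = [
    "FilterSpec",
    "EpochedRecording",
    "DEFAULT_FILTER_BANDS",
    "NIGHT_EPOCHS",
    "filter_spec_for",
    "bandpass",
    "filter_recording",
    "epoch_segment",
    "standardize_night",
]

NIGHT_EPOCHS = 1140  # 9.5 h of 30-s epochs

DEFAULT_FILTER_BANDS: dict[str, tuple[float, float]] = {
    "EEG": (0.3, 35.0),
    "EOG": (0.3, 35.0),
    "EMG": (10.0, 100.0),
    "ECG": (0.3, 70.0),
}


@dataclass
class FilterSpec:
    """Butterworth bandpass for one modality, applied forward-backward."""

    modality: str
    band: tuple[float, float]
    order: int = 4

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"invalid band {self.band}")


def filter_spec_for(modality: str, bands=None, order: int = 4) -> FilterSpec:
    bands = bands or DEFAULT_FILTER_BANDS
    if modality not in bands:
        raise KeyError(f"no filter band configured for modality {modality!r}")
    return FilterSpec(modality=modality, band=bands[modality], order=order)


@dataclass
class EpochedRecording:
    """(T epochs x C channels x S samples) microvolt array on the 30-s grid."""

    data: np.ndarray
    channel_labels: list[str]
    rate: float
    subject_id: str = "S00"
    night_id: str = "N00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be (T, C, S)")
        if self.data.shape[2] != int(EPOCH_SECONDS * self.rate):
            raise ValueError(
                f"samples per epoch {self.data.shape[2]} != 30 s x {self.rate} Hz"
            )
        if self.data.shape[0] < 1:
            raise ValueError("need at least one epoch")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel label count must match data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def bandpass(signal, rate: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth bandpass; same length as the input."""
    x = np.asarray(signal, dtype=float).ravel()
    nyq = rate / 2.0
    low, high = spec.band
    if low >= nyq:
        raise ValueError(
            f"{spec.modality} band {spec.band} lies entirely above Nyquist ({nyq} Hz)"
        )
    if high >= nyq:
        clipped = 0.99 * nyq
        warnings.warn(
            f"{spec.modality} high cutoff {high} Hz >= Nyquist {nyq} Hz; "
            f"clipping to {clipped:.2f} Hz",
            stacklevel=2,
        )
        high = clipped
    sos = sps.butter(spec.order, [low, high], btype="bandpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def filter_recording(rec: Recording, bands=None, order: int = 4) -> Recording:
    """Filter every channel with its modality's band."""
    channels = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # EMG-at-Nyquist clip is expected
        for c in rec.channels:
            spec = filter_spec_for(c.modality, bands=bands, order=order)
            channels.append(
                Channel(
                    label=c.label,
                    samples=bandpass(c.samples, c.rate, spec),
                    rate=c.rate,
                    modality=c.modality,
                )
            )
    return Recording(
        channels=channels,
        start_time=rec.start_time,
        subject_id=rec.subject_id,
        night_id=rec.night_id,
    )


def epoch_segment(rec: Recording) -> EpochedRecording:
    """Cut a recording into non-overlapping 30-s epochs; remainder discarded."""
    rates = {c.rate for c in rec.channels}
    if len(rates) != 1:
        raise ValueError(
            f"epoching needs a single sampling rate, got {sorted(rates)}"
        )
    rate = rates.pop()
    S = int(EPOCH_SECONDS * rate)
    n_samples = rec.channels[0].samples.size
    T = n_samples // S
    if T < 1:
        raise ValueError(
            f"recording of {rec.duration:.1f} s is shorter than one 30-s epoch"
        )
    data = np.stack([c.samples[: T * S].reshape(T, S) for c in rec.channels], axis=1)
    return EpochedRecording(
        data=data,
        channel_labels=rec.channel_labels,
        rate=rate,
        subject_id=rec.subject_id,
        night_id=rec.night_id,
    )


def standardize_night(
    epochs: EpochedRecording, hyp: Hypnogram, target: int = NIGHT_EPOCHS
) -> tuple[EpochedRecording, Hypnogram]:
    """Trim or pad a night to exactly ``target`` epochs (default 1,140).

    Longer nights keep their first ``target`` epochs. Shorter nights are
    padded at the start by cyclically repeating the leading consecutive Wake
    block (signal epochs and W labels); a short night with no leading Wake
    epoch cannot be padded and raises.
    """
    if epochs.n_epochs != len(hyp):
        raise ValueError(
            f"signal has {epochs.n_epochs} epochs but hypnogram has {len(hyp)}"
        )
    data, stages = epochs.data, hyp.stages
    if epochs.n_epochs > target:
        data = data[:target]
        stages = stages[:target]
    elif epochs.n_epochs < target:
        n_wake = 0
        while n_wake < len(stages) and stages[n_wake] == 0:
            n_wake += 1
        if n_wake == 0:
            raise ValueError(
                "night shorter than the standard length has no leading Wake "
                "epochs to pad from"
            )
        need = target - epochs.n_epochs
        pad_idx = np.arange(need) % n_wake
        data = np.concatenate([data[pad_idx], data], axis=0)
        stages = np.concatenate([np.zeros(need, dtype=np.int64), stages])
    out = EpochedRecording(
        data=data,
        channel_labels=list(epochs.channel_labels),
        rate=epochs.rate,
        subject_id=epochs.subject_id,
        night_id=epochs.night_id,
    )
    return out, Hypnogram(stages=stages, start_time=hyp.start_time)
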