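"""Minimal EDF/EDF+ codec (16-bit signals, TAL annotations).

Covers the subset of the European Data Format needed for PSG round trips:
fixed-length ASCII headers, one-second data records of little-endian int16
samples with linear physical scaling, and EDF+ time-stamped annotation lists
(TALs) for hypnogram annotations. The reader is cross-checked against
``mne.io.read_raw_edf`` in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime

import numpy as np

DIG_MIN = -32768
DIG_MAX = 32767
ANNOTATION_LABEL = "EDF Annotations"


@dataclass
class EdfSignal:
    label: str
    samples: np.ndarray  # physical units
    rate: float  # Hz; ignored for annotation signals
    physical_dim: str = "uV"


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"header field {s!r} exceeds {width} ASCII bytes")
    return s.ljust(width).encode("ascii")


def quantization_step(phys_min: float, phys_max: float) -> float:
    return (phys_max - phys_min) / (DIG_MAX - DIG_MIN)


def _phys_range(x: np.ndarray) -> tuple[float, float]:
    amp = float(np.max(np.abs(x))) if x.size else 1.0
    amp = max(amp, 1e-6)
    # Round up to keep the header ASCII-compact and the range symmetric.
    amp = float(np.ceil(amp * 1.0001))
    return -amp, amp


def write_edf(
    path,
    signals: list[EdfSignal],
    start_time: datetime,
    patient_id: str = "X",
    recording_id: str = "X",
    annotations: list[tuple[float, float, str]] | None = None,
) -> None:
    """Write signals (and optional EDF+ annotations) to ``path``.

    Ordinary signals are stored in one-second records, so every rate must be
    a positive integer. ``annotations`` is a list of (onset_s, duration_s,
    text) triples.
    """
    if not signals and not annotations:
        raise ValueError("cannot write an EDF file with no channels")
    for sig in signals:
        if sig.rate <= 0 or sig.rate != int(sig.rate):
            raise ValueError(
                f"channel {sig.label!r}: rate {sig.rate} must be a positive integer "
                "(one-second records)"
            )
    labels = [s.label for s in signals]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel labels")

    if signals:
        n_records = max(
            int(math.ceil(s.samples.size / int(s.rate))) for s in signals
        )
        record_duration = 1.0
    else:
        n_records = 1
        record_duration = max(
            (onset + dur for onset, dur, _ in annotations), default=1.0
        )

    # Build per-record annotation payloads (TALs). Record 0 carries them all.
    ann_payloads = [b"" for _ in range(n_records)]
    has_annotations = annotations is not None
    if has_annotations:
        for rec in range(n_records):
            tal = f"+{rec * record_duration:g}".encode("ascii") + b"\x14\x14\x00"
            ann_payloads[rec] = tal
        for onset, duration, text in annotations:
            tal = (
                f"+{onset:g}".encode("ascii")
                + b"\x15"
                + f"{duration:g}".encode("ascii")
                + b"\x14"
                + text.encode("utf-8")
                + b"\x14\x00"
            )
            ann_payloads[0] += tal
    ann_samples_per_record = (
        max((len(p) + 1) // 2 + 1 for p in ann_payloads) if has_annotations else 0
    )

    phys_ranges = [_phys_range(s.samples) for s in signals]
    ns = len(signals) + (1 if has_annotations else 0)
    header_bytes = 256 * (1 + ns)

    with open(path, "wb") as f:
        f.write(_field("0", 8))
        f.write(_field(patient_id, 80))
        f.write(_field(recording_id, 80))
        f.write(_field(start_time.strftime("%d.%m.%y"), 8))
        f.write(_field(start_time.strftime("%H.%M.%S"), 8))
        f.write(_field(header_bytes, 8))
        f.write(_field("EDF+C" if has_annotations else "", 44))
        f.write(_field(n_records, 8))
        f.write(_field(f"{record_duration:g}", 8))
        f.write(_field(ns, 4))

        all_labels = labels + ([ANNOTATION_LABEL] if has_annotations else [])
        dims = [s.physical_dim for s in signals] + ([""] if has_annotations else [])
        pmins = [f"{r[0]:g}" for r in phys_ranges] + (["0"] if has_annotations else [])
        pmaxs = [f"{r[1]:g}" for r in phys_ranges] + (["1"] if has_annotations else [])
        rates = [int(s.rate) for s in signals] + (
            [ann_samples_per_record] if has_annotations else []
        )
        for label in all_labels:
            f.write(_field(label, 16))
        for _ in all_labels:
            f.write(_field("", 80))  # transducer
        for dim in dims:
            f.write(_field(dim, 8))
        for p in pmins:
            f.write(_field(p, 8))
        for p in pmaxs:
            f.write(_field(p, 8))
        for _ in all_labels:
            f.write(_field(DIG_MIN, 8))
        for _ in all_labels:
            f.write(_field(DIG_MAX, 8))
        for _ in all_labels:
            f.write(_field("", 80))  # prefiltering
        for r in rates:
            f.write(_field(r, 8))
        for _ in all_labels:
            f.write(_field("", 32))  # reserved

        for rec in range(n_records):
            for sig, (pmin, pmax) in zip(signals, phys_ranges):
                spr = int(sig.rate)
                chunk = sig.samples[rec * spr : (rec + 1) * spr]
                if chunk.size < spr:
                    chunk = np.pad(chunk, (0, spr - chunk.size))
                gain = quantization_step(pmin, pmax)
                dig = np.round((chunk - pmin) / gain) + DIG_MIN
                dig = np.clip(dig, DIG_MIN, DIG_MAX).astype("<i2")
                f.write(dig.tobytes())
            if has_annotations:
                payload = ann_payloads[rec]
                buf = payload.ljust(2 * ann_samples_per_record, b"\x00")
                f.write(buf)


def read_edf(path):
    """Read an EDF/EDF+ file.

    Returns ``(signals, annotations, start_time)`` where signals is a list of
    :class:`EdfSignal` (annotation channels excluded) and annotations a list
    of (onset_s, duration_s, text) triples.
    """
    with open(path, "rb") as f:
        header = f.read(256)
        if len(header) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            header.decode("ascii")
        except UnicodeDecodeError as exc:
            raise ValueError(f"{path}: corrupt EDF header (non-ASCII)") from exc

        def hfield(start, width):
            return header[start : start + width].decode("ascii").strip()

        date_s, time_s = hfield(168, 8), hfield(176, 8)
        try:
            start_time = datetime.strptime(date_s + " " + time_s, "%d.%m.%y %H.%M.%S")
        except ValueError:
            start_time = datetime(2000, 1, 1)
        try:
            n_records = int(hfield(236, 8))
            record_duration = float(hfield(244, 8))
            ns = int(hfield(252, 4))
        except ValueError as exc:
            raise ValueError(f"{path}: corrupt EDF header") from exc

        sig_header = f.read(256 * ns)

        # Field offsets within the per-signal header block, bytes from its
        # start: label 16*ns | transducer 80*ns | dim 8*ns | pmin 8*ns |
        # pmax 8*ns | dmin 8*ns | dmax 8*ns | prefilter 80*ns | spr 8*ns |
        # reserved 32*ns.
        def block(offset_bytes, width, i):
            start = offset_bytes + i * width
            return sig_header[start : start + width].decode("ascii").strip()

        labels = [block(0, 16, i) for i in range(ns)]
        dims = [block(96 * ns, 8, i) for i in range(ns)]
        pmin = [float(block(104 * ns, 8, i)) for i in range(ns)]
        pmax = [float(block(112 * ns, 8, i)) for i in range(ns)]
        dmin = [int(float(block(120 * ns, 8, i))) for i in range(ns)]
        dmax = [int(float(block(128 * ns, 8, i))) for i in range(ns)]
        spr = [int(block(216 * ns, 8, i)) for i in range(ns)]

        raw = np.frombuffer(f.read(), dtype="<i2")

    rec_len = sum(spr)
    if n_records < 0:  # unknown length: infer
        n_records = raw.size // rec_len
    raw = raw[: n_records * rec_len].reshape(n_records, rec_len)

    signals: list[EdfSignal] = []
    annotations: list[tuple[float, float, str]] = []
    offset = 0
    for i in range(ns):
        chunk = raw[:, offset : offset + spr[i]]
        offset += spr[i]
        if labels[i] == ANNOTATION_LABEL:
            annotations.extend(_parse_tals(chunk.astype("<i2").tobytes()))
            continue
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = (chunk.reshape(-1).astype(float) - dmin[i]) * gain + pmin[i]
        rate = spr[i] / record_duration
        signals.append(
            EdfSignal(label=labels[i], samples=phys, rate=rate, physical_dim=dims[i])
        )
    return signals, annotations, start_time


def _parse_tals(buf: bytes):
    annotations = []
    for tal in buf.split(b"\x00"):
        if not tal:
            continue
        parts = tal.split(b"\x14")
        if len(parts) < 2:
            continue
        onset_dur = parts[0]
        if b"\x15" in onset_dur:
            onset_b, dur_b = onset_dur.split(b"\x15", 1)
            duration = float(dur_b)
        else:
            onset_b, duration = onset_dur, 0.0
        try:
            onset = float(onset_b)
        except ValueError:
            continue
        for text in parts[1:]:
            if text:
                annotations.append((onset, duration, text.decode("utf-8")))
    return annotations
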