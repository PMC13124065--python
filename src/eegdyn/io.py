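"""Reading recordings, channel selection, resampling and segmentation.

The atomic analysis unit downstream is the :class:`Segment`: a fixed-length,
mean-centered, multichannel epoch with subject/group/condition metadata.
Recordings arrive either as standard EEG files (EDF, BrainVision — read via
MNE) or as a plain numeric channels x samples matrix with a JSON sidecar
holding the sampling rate and channel labels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger(__name__)

#: The standard 19-electrode 10-20 montage used by default for the
#: synchronization analyses (subset of a denser 10-10 montage).
MONTAGE_1020_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)


@dataclass
class Recording:
    """A continuous multichannel recording (channels x samples, microvolts)."""

    samples: np.ndarray
    rate: float
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    group_label: str = ""
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time matrix")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channel rows"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class Segment:
    """One artifact-free, mean-centered epoch cut from a recording."""

    samples: np.ndarray
    rate: float
    channel_labels: tuple[str, ...]
    subject_id: str = ""
    group_label: str = ""
    condition_label: str = ""
    segment_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_labels = tuple(str(c) for c in self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class StudyDesign:
    """Subject x condition design table with ordered group/condition lists."""

    rows: pd.DataFrame  # columns: subject, group, condition[, path]
    groups: tuple[str, ...] = field(default=())
    conditions: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        required = {"subject", "group", "condition"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        dup = self.rows.duplicated(subset=["subject", "condition"])
        if dup.any():
            raise ValueError("duplicate (subject, condition) rows in design")
        if not self.groups:
            self.groups = tuple(pd.unique(self.rows["group"]))
        if not self.conditions:
            self.conditions = tuple(pd.unique(self.rows["condition"]))
        if len(self.groups) < 2:
            raise ValueError("design needs at least 2 groups")
        if len(self.conditions) < 1:
            raise ValueError("design needs at least 1 condition")

    @property
    def n_cells(self) -> int:
        return len(self.groups) * len(self.conditions)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StudyDesign":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# readers / writers


def read_recording(path: str | Path, format_hint: str | None = None, **meta) -> Recording:
    """Read a recording from EDF, BrainVision, or plain matrix + JSON sidecar.

    ``format_hint`` one of {"edf", "brainvision", "plain"}; inferred from the
    file suffix when omitted. ``meta`` may set subject_id/group_label/
    condition_label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format_hint or _infer_format(path)).lower()
    if fmt == "plain":
        return _read_plain(path, **meta)
    if fmt == "edf":
        return _read_mne(path, "edf", **meta)
    if fmt == "brainvision":
        return _read_mne(path, "brainvision", **meta)
    raise ValueError(f"unknown recording format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix == ".vhdr":
        return "brainvision"
    return "plain"


def _read_plain(path: Path, **meta) -> Recording:
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ValueError(f"missing JSON sidecar for plain matrix: {sidecar}")
    with open(sidecar) as fh:
        info = json.load(fh)
    for key in ("rate", "labels"):
        if key not in info:
            raise ValueError(f"sidecar {sidecar} missing required key {key!r}")
    samples = np.loadtxt(path, delimiter=",", ndmin=2)
    if len(info["labels"]) != samples.shape[0]:
        raise ValueError(
            f"sidecar lists {len(info['labels'])} labels but matrix has "
            f"{samples.shape[0]} rows"
        )
    return Recording(samples, float(info["rate"]), tuple(info["labels"]), **meta)


def _read_mne(path: Path, kind: str, **meta) -> Recording:
    import mne  # mne-base; imported lazily to keep base import light

    reader = {"edf": mne.io.read_raw_edf, "brainvision": mne.io.read_raw_brainvision}[kind]
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE holds volts; the pipeline is in microvolts
    return Recording(data, float(raw.info["sfreq"]), tuple(raw.ch_names), **meta)


def write_plain(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV matrix + JSON sidecar; returns the matrix path."""
    path = Path(path)
    np.savetxt(path, rec.samples, delimiter=",")
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"rate": rec.rate, "labels": list(rec.channel_labels)}, fh)
    return path


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a 16-bit EDF file (one data record per second).

    Minimal but standard-conforming European Data Format writer: a 256-byte
    fixed header, one 256-byte signal header per channel, then int16
    little-endian sample records. Physical range is set per channel from the
    data, so quantization error is (phys range)/2^16 per sample.
    """
    path = Path(path)
    rate = rec.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per 1-s record per channel
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one 1-s EDF record")
    nch = rec.n_channels
    data = rec.samples[:, : n_records * spr]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),  # local patient id
            pad("Startdate X", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 * (nch + 1)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),  # record duration, seconds
            pad(str(nch), 4),
        ]
    )

    def sig_field(values: Sequence[str], width: int) -> bytes:
        return b"".join(pad(v, width) for v in values)

    labels = [c[:16] for c in rec.channel_labels]
    header += sig_field(labels, 16)
    header += sig_field(["" for _ in range(nch)], 80)  # transducer
    header += sig_field(["uV" for _ in range(nch)], 8)
    header += sig_field([f"{v:.6g}" for v in phys_min], 8)
    header += sig_field([f"{v:.6g}" for v in phys_max], 8)
    header += sig_field([str(dig_min) for _ in range(nch)], 8)
    header += sig_field([str(dig_max) for _ in range(nch)], 8)
    header += sig_field(["" for _ in range(nch)], 80)  # prefiltering
    header += sig_field([str(spr) for _ in range(nch)], 8)
    header += sig_field(["" for _ in range(nch)], 32)  # reserved

    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec_i in range(n_records):
            block = digital[:, rec_i * spr : (rec_i + 1) * spr]
            fh.write(block.tobytes())  # channel-sequential within record
    return path


# ---------------------------------------------------------------------------
# channel selection / resampling / segmentation


def select_channels(rec: Recording, names: Sequence[str] = MONTAGE_1020_19) -> Recording:
    """Subset and reorder channels to ``names`` (default 19-channel 10-20 set)."""
    lookup = {label: i for i, label in enumerate(rec.channel_labels)}
    missing = [n for n in names if n not in lookup]
    if missing:
        raise KeyError(f"channels not present in recording: {missing}")
    idx = [lookup[n] for n in names]
    return replace(rec, samples=rec.samples[idx], channel_labels=tuple(names))


def downsample(rec: Recording, target_rate: float) -> Recording:
    """Anti-alias filtered decimation to ``target_rate``.

    The decimation ratio must be an integer. A zero-phase FIR low-pass with
    cutoff at 0.8x the target Nyquist precedes subsampling, so phase
    relations between channels are preserved.
    """
    ratio = rec.rate / target_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9 or q < 1:
        raise ValueError(
            f"rate {rec.rate} is not an integer multiple of target {target_rate}"
        )
    if q == 1:
        return replace(rec)
    cutoff = 0.8 * (target_rate / 2.0)
    numtaps = 2 * int(4 * rec.rate / cutoff) + 1
    taps = signal.firwin(numtaps, cutoff, fs=rec.rate)
    filtered = signal.filtfilt(taps, [1.0], rec.samples, axis=1)
    out = filtered[:, ::q]
    return replace(rec, samples=out, rate=target_rate)


def make_segments(
    rec: Recording,
    segment_length_s: float = 10.0,
    artifact_mask: np.ndarray | None = None,
) -> list[Segment]:
    """Cut consecutive non-overlapping mean-centered segments.

    The trailing remainder is dropped. If ``artifact_mask`` (boolean, per
    sample, True = bad) is given, any segment overlapping a masked sample is
    excluded.
    """
    n_t = int(round(segment_length_s * rec.rate))
    n_full = rec.n_samples // n_t
    if n_full == 0:
        warnings.warn(
            f"recording of {rec.duration:.1f}s shorter than one "
            f"{segment_length_s}s segment; returning no segments",
            stacklevel=2,
        )
        return []
    segments: list[Segment] = []
    for k in range(n_full):
        sl = slice(k * n_t, (k + 1) * n_t)
        if artifact_mask is not None and np.any(artifact_mask[sl]):
            continue
        block = rec.samples[:, sl]
        block = block - block.mean(axis=1, keepdims=True)
        segments.append(
            Segment(
                block,
                rec.rate,
                rec.channel_labels,
                subject_id=rec.subject_id,
                group_label=rec.group_label,
                condition_label=rec.condition_label,
                segment_index=k,
            )
        )
    return segments
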