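"""Recording containers, referencing, epoching and on-disk formats.

A :class:`Recording` is a channels x time matrix of amplitudes in microvolts
with a sampling rate and channel labels.  Recordings are read either from EDF
(via :mod:`mne`), from a plain CSV matrix (one row per channel) with a JSON or
YAML sidecar carrying the sampling rate and labels, or from a ``.npy`` matrix
with the same sidecar convention.

Epoching is non-overlapping from t=0; a trailing partial segment is discarded,
which is what makes the channel-epoch bookkeeping exact (e.g. a 6-minute,
58-channel recording at 1-minute epochs yields exactly 58 x 6 = 348
channel-epochs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "Epoch",
    "ClassLabel",
    "read_recording",
    "write_recording",
    "common_average_reference",
    "segment_epochs",
]


class ClassLabel(str, Enum):
    """Three-way data partition: artifact-free signal, recorded signal with
    artifact present, and the artifact source itself."""

    CLEAN = "C"
    RAW = "R"
    NOISE = "N"


@dataclass
class Recording:
    """Multichannel recording: ``data`` is channels x time, in microvolts."""

    channel_labels: list[str]
    sampling_rate: float
    data: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x time matrix")
        n_ch, n_samp = self.data.shape
        if n_ch < 1 or n_samp < 2:
            raise ValueError("need at least 1 channel and 2 samples")
        if len(self.channel_labels) != n_ch:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {n_ch} channels"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class Epoch:
    """A fixed-length segment of a recording.

    ``source_channel`` names the channel for single-channel epochs and is the
    literal string ``"multichannel"`` for channels x time segments.  ``samples``
    is 1-D in the former case and 2-D in the latter.  Epochs are half-open
    intervals [k*L, (k+1)*L) with 0-based time.
    """

    source_channel: str
    start_time: float
    samples: np.ndarray
    sampling_rate: float
    metadata: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.samples.shape[-1] / self.sampling_rate


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous cross-channel mean from every channel.

    The output's column means are zero, making the operation idempotent.
    Re-referencing a single channel is undefined and raises.
    """
    if rec.n_channels < 2:
        raise ValueError("common average reference requires >= 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(
        channel_labels=list(rec.channel_labels),
        sampling_rate=rec.sampling_rate,
        data=data,
        metadata=dict(rec.metadata),
    )


def segment_epochs(
    rec: Recording,
    epoch_seconds: float,
    mode: str = "per_channel",
) -> list[Epoch]:
    """Cut a recording into consecutive non-overlapping epochs from t=0.

    ``mode="per_channel"`` yields one single-channel Epoch per (channel, slot)
    pair; ``mode="multichannel"`` yields one channels x time Epoch per slot.
    A trailing partial segment is discarded.
    """
    if epoch_seconds <= 0:
        raise ValueError("epoch_seconds must be positive")
    if mode not in ("per_channel", "multichannel"):
        raise ValueError(f"unknown mode {mode!r}")
    epoch_len = int(round(epoch_seconds * rec.sampling_rate))
    if epoch_len > rec.n_samples:
        raise ValueError(
            f"epoch of {epoch_seconds} s ({epoch_len} samples) exceeds "
            f"recording length ({rec.n_samples} samples)"
        )
    n_full = rec.n_samples // epoch_len
    epochs: list[Epoch] = []
    for k in range(n_full):
        sl = slice(k * epoch_len, (k + 1) * epoch_len)
        start = k * epoch_len / rec.sampling_rate
        if mode == "per_channel":
            for ch, label in enumerate(rec.channel_labels):
                epochs.append(
                    Epoch(
                        source_channel=label,
                        start_time=start,
                        samples=rec.data[ch, sl].copy(),
                        sampling_rate=rec.sampling_rate,
                        metadata=dict(rec.metadata),
                    )
                )
        else:
            epochs.append(
                Epoch(
                    source_channel="multichannel",
                    start_time=start,
                    samples=rec.data[:, sl].copy(),
                    sampling_rate=rec.sampling_rate,
                    metadata=dict(rec.metadata),
                )
            )
    return epochs


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def _read_sidecar(path: Path) -> dict:
    for ext in (".json", ".yaml", ".yml"):
        side = path.with_suffix(ext)
        if side.exists():
            text = side.read_text()
            if ext == ".json":
                return json.loads(text)
            import yaml

            return yaml.safe_load(text)
    raise FileNotFoundError(
        f"no sidecar ({path.stem}.json/.yaml) with sampling rate found for {path}"
    )


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from EDF, CSV (channels x time) or ``.npy``.

    CSV and npy matrices need a sidecar config (same stem, ``.json`` or
    ``.yaml``) providing at least ``sampling_rate`` and optionally
    ``channel_labels`` and ``metadata``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".edf": "edf", ".csv": "csv", ".npy": "npy"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format of {path}")

    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne returns volts
        rec = Recording(
            channel_labels=list(raw.ch_names),
            sampling_rate=float(raw.info["sfreq"]),
            data=data,
            metadata={"source": str(path)},
        )
    elif format in ("csv", "npy"):
        side = _read_sidecar(path)
        if "sampling_rate" not in side:
            raise ValueError(f"sidecar for {path} lacks 'sampling_rate'")
        if format == "csv":
            rows = []
            with open(path) as fh:
                for line in fh:
                    line = line.strip()
                    if line:
                        rows.append([float(v) for v in line.split(",")])
            if not rows:
                raise ValueError(f"{path} is empty")
            lengths = {len(r) for r in rows}
            if len(lengths) != 1:
                raise ValueError(f"ragged channels in {path}: lengths {sorted(lengths)}")
            data = np.asarray(rows, dtype=float)
        else:
            data = np.load(path)
        labels = side.get("channel_labels")
        if labels is None:
            labels = [f"ch{i}" for i in range(data.shape[0])]
        rec = Recording(
            channel_labels=list(labels),
            sampling_rate=float(side["sampling_rate"]),
            data=data,
            metadata=dict(side.get("metadata", {})),
        )
    else:
        raise ValueError(f"unsupported format {format!r}")
    logger.info(
        "read %s: %d channels, %d samples at %g Hz",
        path, rec.n_channels, rec.n_samples, rec.sampling_rate,
    )
    return rec


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording as a CSV matrix plus a JSON sidecar.

    The CSV uses ``repr``-precision floats so a read-back round-trip is
    bit-identical for finite values.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in rec.data:
            fh.write(",".join(repr(float(v)) for v in row))
            fh.write("\n")
    sidecar = {
        "sampling_rate": rec.sampling_rate,
        "channel_labels": list(rec.channel_labels),
        "metadata": rec.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
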