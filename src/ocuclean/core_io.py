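"""Recording I/O, windowing and splicing.

Recordings come from EDF files (read through MNE, values converted to µV)
or plain delimited text (one column per channel, optional header row,
sampling rate supplied by the caller). Channels are segmented into fixed
non-overlapping windows — 10 s by default, the unit at which contamination
is detected and denoised — and cleaned windows are spliced back in place,
leaving untouched regions bit-identical.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "Segment",
    "read_recording",
    "write_recording",
    "segment_signal",
    "splice_segments",
]

DEFAULT_WINDOW_S = 10.0


@dataclass
class Recording:
    """Multichannel sampled signal: data is (n_channels, n_samples) in µV."""

    data: np.ndarray
    fs: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.labels.index(name)]
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.labels}")


@dataclass
class Segment:
    """One fixed window of one channel.

    label: 0 = clean, 1 = ocular-contaminated, None = unknown.
    """

    samples: np.ndarray
    fs: float
    start_index: int = 0
    channel: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.start_index < 0:
            raise ValueError("start_index must be >= 0")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size


def _read_text(path: Path, fs: float) -> Recording:
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else None

    def _floatable(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    tokens = [t for t in first.replace(",", " ").split() if t]
    has_header = not all(_floatable(t) for t in tokens)
    df = pd.read_csv(
        path,
        sep=delim if delim else r"\s+",
        header=0 if has_header else None,
        engine="python",
    )
    labels = (
        [str(c) for c in df.columns]
        if has_header
        else [f"ch{i}" for i in range(df.shape[1])]
    )
    data = df.to_numpy(dtype=float).T
    return Recording(data=data, fs=fs, labels=labels)


def read_recording(path, fs_override: float | None = None) -> Recording:
    """Read an EDF or delimited-text recording.

    Text input has no embedded sampling rate, so fs_override is mandatory
    for it; for EDF it replaces the header rate if given. EDF voltages are
    returned in µV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        fs = float(fs_override) if fs_override else float(raw.info["sfreq"])
        return Recording(
            data=raw.get_data() * 1e6, fs=fs, labels=list(raw.ch_names)
        )
    if fs_override is None:
        raise ValueError("text input requires fs_override (no embedded rate)")
    return _read_text(path, float(fs_override))


def write_recording(rec: Recording, path) -> None:
    """Write a recording as CSV, one column per channel, header = labels."""
    pd.DataFrame(rec.data.T, columns=rec.labels).to_csv(path, index=False)


def segment_signal(
    rec: Recording, channel: str, window_s: float = DEFAULT_WINDOW_S
) -> list[Segment]:
    """Split one channel into consecutive full windows.

    A trailing partial window is dropped (every downstream operator
    assumes full windows). A recording shorter than one window yields an
    empty list with a warning.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    x = rec.channel(channel)
    win = int(round(window_s * rec.fs))
    n_seg = x.size // win
    if n_seg == 0:
        warnings.warn(
            f"recording ({x.size} samples) shorter than one {window_s} s window"
        )
        return []
    return [
        Segment(
            samples=x[i * win : (i + 1) * win].copy(),
            fs=rec.fs,
            start_index=i * win,
            channel=channel,
        )
        for i in range(n_seg)
    ]


def splice_segments(
    rec: Recording, channel: str, cleaned: list[Segment]
) -> Recording:
    """Replace the given windows of one channel with cleaned samples.

    Windows must lie inside the channel and must not overlap; all other
    samples are copied bit-identically.
    """
    idx = rec.labels.index(channel) if channel in rec.labels else None
    if idx is None:
        raise KeyError(f"no channel named {channel!r}")
    n = rec.n_samples
    spans = sorted(
        ((s.start_index, s.start_index + len(s)) for s in cleaned),
        key=lambda t: t[0],
    )
    for (a0, a1), (b0, _b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError(f"replacement windows overlap at sample {b0}")
    data = rec.data.copy()
    for seg in cleaned:
        a, b = seg.start_index, seg.start_index + len(seg)
        if b > n:
            raise ValueError(
                f"window [{a}, {b}) exceeds channel length {n}"
            )
        data[idx, a:b] = seg.samples
    return Recording(data=data, fs=rec.fs, labels=list(rec.labels))
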