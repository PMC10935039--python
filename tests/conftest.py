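import struct

import numpy as np
import pytest

from ocuclean.core_io import Recording, Segment


def write_minimal_edf(path, channels, fs, labels=None, phys_range=1000.0):
    """Write a minimal valid EDF file (int16 data records, µV units).

    `channels` is a (n_ch, n_samples) array in µV; n_samples must be a
    multiple of fs (1 s data records).
    """
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    n_ch, n_samp = channels.shape
    fs = int(fs)
    assert n_samp % fs == 0, "need whole 1 s records"
    n_rec = n_samp // fs
    labels = labels or [f"EEG ch{i}" for i in range(n_ch)]

    def pad(s, n):
        return s[:n].ljust(n).encode("ascii")

    header_bytes = 256 * (1 + n_ch)
    hdr = b"".join(
        [
            pad("0", 8),
            pad("synthetic test subject", 80),
            pad("synthetic test recording", 80),
            pad("01.01.24", 8),
            pad("00.00.00", 8),
            pad(str(header_bytes), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(n_ch), 4),
        ]
    )
    sig = b""
    for field, width in [
        (labels, 16),
        (["" for _ in range(n_ch)], 80),
        (["uV"] * n_ch, 8),
        ([str(-phys_range)] * n_ch, 8),
        ([str(phys_range)] * n_ch, 8),
        (["-32768"] * n_ch, 8),
        (["32767"] * n_ch, 8),
        (["" for _ in range(n_ch)], 80),
        ([str(fs)] * n_ch, 8),
        (["" for _ in range(n_ch)], 32),
    ]:
        sig += b"".join(pad(str(v), width) for v in field)

    scale = 32767.0 / phys_range
    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for r in range(n_rec):
            for c in range(n_ch):
                block = np.clip(
                    np.round(channels[c, r * fs : (r + 1) * fs] * scale),
                    -32768,
                    32767,
                ).astype("<i2")
                fh.write(block.tobytes())
    return path


@pytest.fixture
def fs():
    return 200.0


@pytest.fixture
def two_tone(fs):
    t = np.arange(2000) / fs
    return np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 40 * t)


@pytest.fixture
def white_noise():
    return np.random.default_rng(1234).standard_normal(2000)


@pytest.fixture
def recording(fs):
    rng = np.random.default_rng(7)
    data = rng.standard_normal((2, 12000))
    return Recording(data=data, fs=fs, labels=["C3", "C4"])


def make_segment(x, fs=200.0, **kw):
    return Segment(np.asarray(x, dtype=float), fs=fs, **kw)
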