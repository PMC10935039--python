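"""Evaluation indices for artifact removal.

With ground truth (semi-simulated data): correlation coefficient, relative
root-mean-square error, mean-square error and peak signal-to-noise ratio
between the pure EEG and the cleaned signal. Without ground truth (real
recordings): band-wise power change before vs after cleaning, and the
standard multi-class staging scores (per-class precision/recall/F1,
accuracy, macro- and weighted-F1) for downstream sleep-stage evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch
from sklearn.metrics import accuracy_score, precision_recall_fscore_support

from .features import DEFAULT_BANDS
from .synth import rms

__all__ = [
    "SimMetrics",
    "BandPowerDelta",
    "cc",
    "rrmse",
    "mse",
    "psnr",
    "sim_metrics",
    "delta_psd",
    "staging_metrics",
    "SLEEP_STAGES",
]

SLEEP_STAGES = ("W", "N1", "N2", "N3", "REM")


@dataclass(frozen=True)
class SimMetrics:
    cc: float
    rrmse: float
    mse: float
    psnr: float


@dataclass(frozen=True)
class BandPowerDelta:
    """Per-band power change P_before - P_after."""

    deltas: dict


def _pair(x, y):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    return x, y


def cc(x_pure, x_clean) -> float:
    """Pearson correlation between the reference and the cleaned signal."""
    x, y = _pair(x_pure, x_clean)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant signal")
    return float(np.corrcoef(x, y)[0, 1])


def rrmse(x_pure, x_clean) -> float:
    """RMS of the error relative to the RMS of the reference."""
    x, y = _pair(x_pure, x_clean)
    denom = rms(x)
    if denom == 0:
        raise ValueError("reference signal has zero RMS")
    return rms(x - y) / denom


def mse(x_pure, x_clean) -> float:
    x, y = _pair(x_pure, x_clean)
    return float(np.mean((x - y) ** 2))


def psnr(x_pure, x_clean, m_bits: int = 8) -> float:
    """10 log10((2^m - 1)^2 / MSE), in dB; +inf for identical signals."""
    err = mse(x_pure, x_clean)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10((2**m_bits - 1) ** 2 / err))


def sim_metrics(x_pure, x_clean, m_bits: int = 8) -> SimMetrics:
    return SimMetrics(
        cc=cc(x_pure, x_clean),
        rrmse=rrmse(x_pure, x_clean),
        mse=mse(x_pure, x_clean),
        psnr=psnr(x_pure, x_clean, m_bits),
    )


def _band_powers(x, fs, bands):
    nperseg = min(int(2 * fs), len(x))
    f, p = welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    out = {}
    for name, (lo, hi) in bands.items():
        if hi > fs / 2:
            raise ValueError(f"band '{name}' upper edge above Nyquist")
        sel = (f >= lo) & (f <= hi)
        out[name] = float(np.trapezoid(p[sel], f[sel]))
    return out


def delta_psd(x_pre, x_post, fs: float, bands=None) -> BandPowerDelta:
    """Band power before minus after cleaning (2 s Hann Welch estimate)."""
    x, y = _pair(x_pre, x_post)
    bands = bands if bands is not None else DEFAULT_BANDS
    p_in = _band_powers(x, fs, bands)
    p_out = _band_powers(y, fs, bands)
    return BandPowerDelta({k: p_in[k] - p_out[k] for k in bands})


def staging_metrics(y_true, y_pred, stages=SLEEP_STAGES) -> dict:
    """Per-class precision/recall/F1 plus ACC, macro-F1 and weighted-F1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    bad = set(y_true) | set(y_pred)
    if not bad <= set(stages):
        raise ValueError(f"unknown stage labels: {sorted(bad - set(stages))}")
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=list(stages), zero_division=0
    )
    present = support > 0
    out = {
        "per_class": {
            s: {"precision": float(p), "recall": float(r), "f1": float(f)}
            for s, p, r, f in zip(stages, prec, rec, f1)
        },
        "acc": float(accuracy_score(y_true, y_pred)),
        "mf1": float(f1[present].mean()) if present.any() else 0.0,
        "wf1": float(np.average(f1[present], weights=support[present]))
        if present.any()
        else 0.0,
    }
    return out
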