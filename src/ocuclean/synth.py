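"""Semi-simulated EEG/EOG generator.

Provides ground-truth material for every stage of the artifact-removal
pipeline: surrogate clean EEG (a sum of band-limited Gaussian processes
with an alpha-dominant, 1/f-like band-power profile), surrogate EOG
(Poisson-timed blink pulses over a slow drift), and their mixture at a
controlled RMS signal-to-noise ratio:

    X_mix = X_pure + theta * X_EOG,    SNR = RMS(X_pure) / RMS(theta * X_EOG)

so theta = RMS(X_pure) / (SNR * RMS(X_EOG)) realizes any requested SNR
exactly. The two surrogate families are tuned so that their approximate
entropy distributions separate at 0.4 (EEG above, EOG below), which is the
property the component-rejection threshold relies on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "MixSpec",
    "rms",
    "gen_pure_eeg",
    "gen_eog",
    "mix",
    "gen_labeled_corpus",
    "write_corpus",
    "EEG_BAND_WEIGHTS",
]

# Relative band powers of the surrogate EEG (eyes-closed resting profile:
# alpha-dominant, moderate delta). Keys are (low Hz, high Hz) -> weight.
EEG_BAND_WEIGHTS: dict[tuple[float, float], float] = {
    (0.5, 4.0): 0.15,   # delta
    (4.0, 8.0): 0.20,   # theta
    (8.0, 13.0): 0.40,  # alpha
    (13.0, 30.0): 0.25, # beta
}


@dataclass(frozen=True)
class MixSpec:
    """Record of one semi-simulated mixture."""

    snr: float
    theta: float
    seed: int | None
    duration_s: float
    fs: float

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")


def rms(x: np.ndarray) -> float:
    """Root mean square, sqrt(mean(x^2))."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty array is undefined")
    return float(np.sqrt(np.mean(x**2)))


def _bandpass(x: np.ndarray, lo: float, hi: float, fs: float) -> np.ndarray:
    sos = butter(4, [lo, hi], btype="band", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def gen_pure_eeg(
    duration_s: float,
    fs: float = 200.0,
    seed: int | None = None,
    band_weights: dict[tuple[float, float], float] | None = None,
) -> np.ndarray:
    """Surrogate clean EEG, normalized to unit SD.

    Independent white-noise drives are band-passed into the classical
    delta/theta/alpha/beta bands and summed with the given relative power
    weights. Deterministic per seed.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    weights = band_weights if band_weights is not None else EEG_BAND_WEIGHTS
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    out = np.zeros(n)
    for (lo, hi), w in weights.items():
        comp = _bandpass(rng.standard_normal(n), lo, hi, fs)
        sd = comp.std()
        if sd > 0:
            out += np.sqrt(w) * comp / sd
    sd = out.std()
    if sd > 0:
        out /= sd
    return out


def _blink_pulse(width_samples: int) -> np.ndarray:
    """Smooth unimodal blink waveform: a squared half-sine (Hann lobe)."""
    t = np.arange(width_samples) / width_samples
    return np.sin(np.pi * t) ** 2


def gen_eog(
    duration_s: float,
    fs: float = 200.0,
    seed: int | None = None,
    blink_rate: float = 12.0,
    drift_amp: float = 1.0,
) -> np.ndarray:
    """Surrogate EOG: Poisson blink train plus a slow (< 1 Hz) drift.

    blink_rate is in events per minute; blink widths are 200-400 ms and
    amplitudes 3-10 (in units of the EEG SD, which gen_pure_eeg fixes
    at 1). With blink_rate = 0 and drift_amp = 0 the output is all zeros.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if blink_rate < 0:
        raise ValueError("blink_rate must be >= 0")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    out = np.zeros(n)
    n_blinks = rng.poisson(blink_rate * duration_s / 60.0)
    for _ in range(n_blinks):
        width = int(round(rng.uniform(0.2, 0.4) * fs))
        amp = rng.uniform(3.0, 10.0)
        start = rng.integers(0, max(n - width, 1))
        stop = min(start + width, n)
        out[start:stop] += amp * _blink_pulse(width)[: stop - start]
    if drift_amp > 0:
        # smooth random drift below 1 Hz: low-passed noise via a slow
        # random-phase harmonic sum (avoids filter warm-up artifacts)
        n_harm = max(1, int(duration_s))  # harmonics up to ~1 Hz
        t = np.arange(n) / fs
        drift = np.zeros(n)
        for h in range(1, n_harm + 1):
            f = h / duration_s
            if f >= 1.0:
                break
            drift += rng.normal() * np.cos(2 * np.pi * f * t) + rng.normal() * np.sin(
                2 * np.pi * f * t
            )
        sd = drift.std()
        if sd > 0:
            out += drift_amp * drift / sd
    return out


def mix(
    pure: np.ndarray,
    eog: np.ndarray,
    snr: float,
    seed: int | None = None,
    fs: float = 200.0,
) -> tuple[np.ndarray, MixSpec]:
    """Mix pure EEG and EOG so the realized RMS SNR equals `snr` exactly."""
    pure = np.asarray(pure, dtype=float)
    eog = np.asarray(eog, dtype=float)
    if pure.shape != eog.shape:
        raise ValueError("pure and eog must have equal length")
    if snr <= 0:
        raise ValueError("snr must be positive")
    r_eog = rms(eog)
    if r_eog == 0:
        raise ValueError("eog has zero RMS; SNR is undefined")
    theta = rms(pure) / (snr * r_eog)
    mixture = pure + theta * eog
    spec = MixSpec(
        snr=snr, theta=theta, seed=seed, duration_s=pure.size / fs, fs=fs
    )
    return mixture, spec


def gen_labeled_corpus(
    n_per_class: int,
    duration_s: float = 10.0,
    fs: float = 200.0,
    seed: int = 0,
    snr_range: tuple[float, float] = (0.5, 2.0),
):
    """Yield (samples, label, meta) tuples for classifier training.

    label 0 = pure surrogate EEG, label 1 = EEG + EOG mixture (theta > 0)
    at an SNR drawn uniformly from snr_range.
    """
    rng = np.random.default_rng(seed)
    for i in range(n_per_class):
        s = int(rng.integers(0, 2**31 - 1))
        yield gen_pure_eeg(duration_s, fs, seed=s), 0, {
            "seed": s, "snr": np.inf, "theta": 0.0,
        }
    for i in range(n_per_class):
        s = int(rng.integers(0, 2**31 - 1))
        snr = float(rng.uniform(*snr_range))
        pure = gen_pure_eeg(duration_s, fs, seed=s)
        eog = gen_eog(duration_s, fs, seed=s + 1)
        mixture, spec = mix(pure, eog, snr, seed=s, fs=fs)
        yield mixture, 1, {"seed": s, "snr": snr, "theta": spec.theta}


def write_corpus(
    out_dir: str,
    n_per_class: int,
    duration_s: float = 10.0,
    fs: float = 200.0,
    seed: int = 0,
    snr_range: tuple[float, float] = (0.5, 2.0),
) -> str:
    """Write a labeled corpus as one CSV per segment plus a manifest CSV.

    Returns the manifest path. Manifest columns: file, label, snr, theta,
    seed.
    """
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    corpus = gen_labeled_corpus(n_per_class, duration_s, fs, seed, snr_range)
    for i, (samples, label, meta) in enumerate(corpus):
        fname = f"segment_{i:05d}.csv"
        np.savetxt(os.path.join(out_dir, fname), samples, fmt="%.8g")
        rows.append(
            {
                "file": fname,
                "label": label,
                "snr": meta["snr"],
                "theta": meta["theta"],
                "seed": meta["seed"],
            }
        )
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
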