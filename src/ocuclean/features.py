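"""Segment features and the SVM contamination classifier.

Each 10 s segment is summarized by time-domain statistics (skewness,
kurtosis, Hjorth activity/mobility/complexity), Welch band powers
(absolute and relative delta/theta/alpha/beta), and nonlinear descriptors
(Shannon entropy, composite multiscale sample entropy, dispersion entropy,
Katz fractal dimension, normalized Lempel-Ziv complexity, rescaled-range
Hurst exponent). Features are ranked by greedy mRMR (mutual-information
relevance minus mean redundancy) and an RBF SVM separates clean segments
(label 0) from ocular-contaminated ones (label 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.signal import welch
from sklearn.metrics import mutual_info_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "FeatureVector",
    "ArtifactClassifier",
    "DEFAULT_BANDS",
    "time_features",
    "psd_features",
    "nonlinear_features",
    "extract_features",
    "mrmr_select",
    "train_classifier",
    "classify_segments",
    "save_classifier",
    "load_classifier",
]

DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

SCHEMA_VERSION = 1


@dataclass
class FeatureVector:
    """Named, ordered feature values for one segment."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __add__(self, other: "FeatureVector") -> "FeatureVector":
        return FeatureVector(
            self.names + other.names, np.concatenate([self.values, other.values])
        )


def _samples(seg) -> np.ndarray:
    return np.asarray(getattr(seg, "samples", seg), dtype=float).ravel()


def _fs(seg, fs: float | None) -> float:
    got = getattr(seg, "fs", fs)
    if got is None:
        raise ValueError("sampling rate required (pass a Segment or fs=)")
    return float(got)


def time_features(seg) -> FeatureVector:
    """Skewness, excess kurtosis and the three Hjorth parameters.

    Constant input maps to 0 for skewness/kurtosis and mobility by
    convention.
    """
    x = _samples(seg)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    var = float(np.var(x))
    if var == 0:
        skew = kurt = mobility = complexity = 0.0
    else:
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))  # excess kurtosis
        d1 = np.diff(x)
        v1 = float(np.var(d1))
        mobility = float(np.sqrt(v1 / var))
        if v1 == 0:
            complexity = 0.0
        else:
            d2 = np.diff(d1)
            mob1 = float(np.sqrt(np.var(d2) / v1))
            complexity = mob1 / mobility if mobility > 0 else 0.0
    return FeatureVector(
        [
            "skewness",
            "kurtosis",
            "hjorth_activity",
            "hjorth_mobility",
            "hjorth_complexity",
        ],
        np.array([skew, kurt, var, mobility, complexity]),
    )


def psd_features(
    seg,
    fs: float | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
) -> FeatureVector:
    """Absolute and relative Welch band powers (2 s Hann, 50% overlap)."""
    x = _samples(seg)
    fs = _fs(seg, fs)
    bands = bands if bands is not None else DEFAULT_BANDS
    for name, (lo, hi) in bands.items():
        if hi > fs / 2:
            raise ValueError(f"band '{name}' upper edge {hi} Hz above Nyquist")
    nperseg = min(int(2 * fs), x.size)
    f, p = welch(x, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    total = float(np.trapezoid(p, f))
    names, vals = [], []
    for name, (lo, hi) in bands.items():
        sel = (f >= lo) & (f <= hi)
        power = float(np.trapezoid(p[sel], f[sel])) if sel.sum() > 1 else 0.0
        names += [f"psd_{name}", f"psd_{name}_rel"]
        vals += [power, power / total if total > 0 else 0.0]
    return FeatureVector(names, np.array(vals))


def _shannon_entropy(x: np.ndarray, bins: int = 16) -> float:
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _sample_entropy(x: np.ndarray, m: int, r: float) -> float:
    """SampEn (no self-matches, Chebyshev distance); inf-safe fallback 0.

    The pairwise |x_i - x_j| matrix is built once; the Chebyshev distance
    at each embedding dimension is its running max over diagonal shifts.
    """
    x = np.asarray(x, dtype=np.float32)
    d0 = np.abs(x[:, None] - x[None, :])
    counts = []
    n_vec_m = x.size - m  # templates comparable at both m and m+1
    d = d0[:n_vec_m, :n_vec_m].copy()
    for k in range(1, m):
        np.maximum(d, d0[k : k + n_vec_m, k : k + n_vec_m], out=d)
    counts.append(float((d <= r).sum() - n_vec_m))
    np.maximum(d, d0[m : m + n_vec_m, m : m + n_vec_m], out=d)
    counts.append(float((d <= r).sum() - n_vec_m))
    if counts[0] == 0 or counts[1] == 0:
        return 0.0
    return float(-np.log(counts[1] / counts[0]))


def _cmse(x: np.ndarray, m: int = 2, r_coef: float = 0.15, scales=(1, 2, 3)) -> float:
    """Composite multiscale sample entropy, averaged over scales.

    At scale s, SampEn is averaged over all s coarse-graining offsets;
    r is fixed at r_coef * SD of the original series.
    """
    r = r_coef * float(np.std(x))
    if r == 0:
        return 0.0
    vals = []
    for s in scales:
        per_offset = []
        for off in range(s):
            cg = x[off:]
            cg = cg[: (cg.size // s) * s].reshape(-1, s).mean(axis=1)
            if cg.size > m + 1:
                per_offset.append(_sample_entropy(cg, m, r))
        if per_offset:
            vals.append(float(np.mean(per_offset)))
    return float(np.mean(vals)) if vals else 0.0


def _dispersion_entropy(x: np.ndarray, m: int = 2, c: int = 6, d: int = 1) -> float:
    """Normalized dispersion entropy with normal-CDF class mapping."""
    sd = x.std()
    if sd == 0:
        return 0.0
    y = stats.norm.cdf(x, loc=x.mean(), scale=sd)
    z = np.clip(np.round(c * y + 0.5).astype(int), 1, c)
    n_pat = x.size - (m - 1) * d
    if n_pat <= 0:
        return 0.0
    pats = np.stack([z[i * d : i * d + n_pat] for i in range(m)], axis=1)
    codes = (pats * (c ** np.arange(m))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(c**m))


def _katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension; 1 for a constant (curve length = diameter)."""
    dists = np.abs(np.diff(x))
    L = float(dists.sum())
    if L == 0:
        return 1.0
    d = float(np.abs(x - x[0]).max())
    if d == 0:
        return 1.0
    n = x.size - 1
    return float(np.log10(n) / (np.log10(n) + np.log10(d / L)))


def _lz_complexity(x: np.ndarray) -> float:
    """Normalized Lempel-Ziv (1976) complexity of the median-binarized
    sequence: c(n) * log2(n) / n. Serves as a Kolmogorov-complexity
    estimate."""
    b = (x > np.median(x)).astype(np.uint8).tobytes()
    n = len(b)
    if n == 0:
        return 0.0
    # LZ76 parsing: each phrase is the shortest prefix-novel substring
    c = 0
    i = 0
    while i < n:
        length = 1
        while i + length <= n and b[: i].find(b[i : i + length]) != -1:
            length += 1
        c += 1
        i += length
    return float(c * np.log2(n) / n)


def _hurst_rs(x: np.ndarray) -> float:
    """Rescaled-range Hurst exponent; 0.5 for a constant by convention."""
    if x.std() == 0:
        return 0.5
    n = x.size
    sizes = np.unique(
        np.floor(n / 2 ** np.arange(0, int(np.log2(n / 16)) + 1)).astype(int)
    )
    sizes = sizes[sizes >= 16]
    if sizes.size < 2:
        return 0.5
    log_rs, log_n = [], []
    for w in sizes:
        rs_vals = []
        for start in range(0, n - w + 1, w):
            seg = x[start : start + w]
            dev = seg - seg.mean()
            z = np.cumsum(dev)
            r = z.max() - z.min()
            s = seg.std()
            if s > 0:
                rs_vals.append(r / s)
        if rs_vals:
            log_rs.append(np.log(np.mean(rs_vals)))
            log_n.append(np.log(w))
    if len(log_rs) < 2:
        return 0.5
    slope = np.polyfit(log_n, log_rs, 1)[0]
    return float(slope)


def nonlinear_features(seg) -> FeatureVector:
    """Entropy, fractal and complexity descriptors of one segment."""
    x = _samples(seg)
    if x.size < 100:
        raise ValueError("need at least 100 samples for nonlinear features")
    return FeatureVector(
        [
            "shannon_entropy",
            "cmse",
            "dispersion_entropy",
            "katz_fd",
            "lz_complexity",
            "hurst",
        ],
        np.array(
            [
                _shannon_entropy(x),
                _cmse(x),
                _dispersion_entropy(x),
                _katz_fd(x),
                _lz_complexity(x),
                _hurst_rs(x),
            ]
        ),
    )


def extract_features(seg, fs: float | None = None) -> FeatureVector:
    """Full feature vector: time + PSD + nonlinear."""
    return time_features(seg) + psd_features(seg, fs=fs) + nonlinear_features(seg)


def _discretize(col: np.ndarray, n_bins: int = 8) -> np.ndarray:
    """Equal-frequency binning for MI estimation."""
    edges = np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, col)


def mrmr_select(
    X: np.ndarray, y: np.ndarray, n_keep: int, n_bins: int = 8
) -> list[int]:
    """Greedy mRMR ranking: argmax MI(f; y) - mean MI(f; selected).

    Features are discretized into equal-frequency bins; the ranking is
    deterministic given the data (ties broken by lowest index).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("mRMR needs both classes present")
    n_feat = X.shape[1]
    if n_keep > n_feat:
        raise ValueError("n_keep exceeds the number of features")
    disc = np.column_stack([_discretize(X[:, j], n_bins) for j in range(n_feat)])
    relevance = np.array(
        [mutual_info_score(disc[:, j], y) for j in range(n_feat)]
    )
    selected: list[int] = []
    remaining = list(range(n_feat))
    red_cache = np.zeros((n_feat, n_feat)) * np.nan
    while len(selected) < n_keep:
        best_j, best_score = None, -np.inf
        for j in remaining:
            if selected:
                reds = []
                for s in selected:
                    if np.isnan(red_cache[j, s]):
                        red_cache[j, s] = red_cache[s, j] = mutual_info_score(
                            disc[:, j], disc[:, s]
                        )
                    reds.append(red_cache[j, s])
                score = relevance[j] - float(np.mean(reds))
            else:
                score = relevance[j]
            if score > best_score + 1e-12:
                best_j, best_score = j, score
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


@dataclass
class ArtifactClassifier:
    """Trained artifact detector: scaler + mRMR selection + RBF SVM."""

    svm: SVC
    selected: list[int]
    scaler: StandardScaler
    feature_names: list[str]
    schema_version: int = SCHEMA_VERSION

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.svm.predict(self.scaler.transform(X)[:, self.selected])


def _feature_matrix(segments, fs: float | None = None):
    fvs = [extract_features(s, fs=fs) for s in segments]
    names = fvs[0].names
    return np.vstack([fv.values for fv in fvs]), names


def train_classifier(
    segments,
    labels,
    n_keep: int = 10,
    fs: float | None = None,
    C: float = 1.0,
    gamma="scale",
) -> ArtifactClassifier:
    """Fit the scaler, mRMR selection and RBF SVM on labeled segments."""
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("training needs both classes present")
    if counts.min() < 10:
        raise ValueError("need at least 10 segments per class")
    X, names = _feature_matrix(segments, fs=fs)
    if n_keep > X.shape[1]:
        raise ValueError("n_keep exceeds the number of extracted features")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    selected = mrmr_select(Xs, labels, n_keep)
    svm = SVC(kernel="rbf", C=C, gamma=gamma).fit(Xs[:, selected], labels)
    return ArtifactClassifier(
        svm=svm, selected=selected, scaler=scaler, feature_names=names
    )


def classify_segments(
    clf: ArtifactClassifier, segments, fs: float | None = None
) -> np.ndarray:
    """Label segments: 1 = ocular-contaminated (denoise), 0 = leave as is."""
    if not isinstance(clf, ArtifactClassifier):
        raise TypeError("clf must be a trained ArtifactClassifier")
    segments = list(segments)
    if not segments:
        return np.array([], dtype=int)
    X, _ = _feature_matrix(segments, fs=fs)
    return clf.predict(X).astype(int)


def save_classifier(clf: ArtifactClassifier, path: str) -> None:
    import joblib

    joblib.dump(
        {"schema_version": clf.schema_version, "classifier": clf}, path
    )


def load_classifier(path: str) -> ArtifactClassifier:
    import joblib

    blob = joblib.load(path)
    if blob.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("unsupported classifier file schema")
    return blob["classifier"]
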