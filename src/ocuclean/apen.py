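"""Approximate-entropy scoring and rejection of artifact components.

After blind source separation, each recovered source is scored with
approximate entropy (ApEn): ocular components (blinks, slow drifts) are
smooth and highly regular, so their ApEn falls well below that of ongoing
EEG. Sources whose ApEn falls below a fixed threshold (default 0.4) are
zeroed and the remaining sources are projected back through the estimated
mixing matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .sobi import SOBIResult, sobi_reconstruct

__all__ = [
    "ApEnParams",
    "ComponentMask",
    "approximate_entropy",
    "classify_components",
    "remove_components",
]


@dataclass(frozen=True)
class ApEnParams:
    """Parameters for ApEn scoring and artifact thresholding.

    m : embedding dimension (number of consecutive samples per template).
    r_coef : similarity radius as a fraction of the series SD.
    threshold : sources with ApEn below this are flagged as ocular artifact.
    """

    m: int = 2
    r_coef: float = 0.15
    threshold: float = 0.4

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not 0.0 < self.r_coef < 1.0:
            raise ValueError("r_coef must lie in (0, 1)")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


@dataclass
class ComponentMask:
    """Per-source ApEn values and the keep/reject decision."""

    apen_values: np.ndarray
    keep: np.ndarray
    threshold: float = 0.4

    def __post_init__(self) -> None:
        self.apen_values = np.asarray(self.apen_values, dtype=float)
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.apen_values.shape != self.keep.shape:
            raise ValueError("apen_values and keep must have equal length")

    @property
    def n_rejected(self) -> int:
        return int((~self.keep).sum())


def _phi(x: np.ndarray, m: int, r: float) -> float:
    """Mean log frequency of template matches at embedding dimension m.

    Matches use the Chebyshev (max-coordinate) distance with strict `< r`
    and include self-matches, so every count is >= 1 whenever r > 0.
    """
    n_vec = x.size - m + 1
    # pairwise |x_i - x_j| once; the m-dim Chebyshev distance is the max
    # over m diagonal shifts of this matrix
    d0 = np.abs(x[:, None] - x[None, :]).astype(np.float32)
    d = d0[:n_vec, :n_vec].copy()
    for k in range(1, m):
        np.maximum(d, d0[k : k + n_vec, k : k + n_vec], out=d)
    counts = (d < r).sum(axis=1)
    return float(np.mean(np.log(counts / n_vec)))


def approximate_entropy(x: np.ndarray, params: ApEnParams | None = None) -> float:
    """ApEn of a 1-D series: Phi_m(r) - Phi_{m+1}(r), r = r_coef * SD.

    A constant series (SD = 0) returns 0 by convention; tiny negative
    floating-point results are clipped to 0.
    """
    if params is None:
        params = ApEnParams()
    x = np.asarray(x, dtype=float).ravel()
    if x.size <= params.m + 1:
        raise ValueError(
            f"series of length {x.size} too short for ApEn with m={params.m}"
        )
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = params.r_coef * sd
    apen = _phi(x, params.m, r) - _phi(x, params.m + 1, r)
    return max(apen, 0.0)


def classify_components(
    sources: np.ndarray, params: ApEnParams | None = None
) -> ComponentMask:
    """Score each source (row) with ApEn; reject those below the threshold.

    All-rejected and none-rejected outcomes are legal but warned about,
    since both usually indicate the segment needed no separation.
    """
    if params is None:
        params = ApEnParams()
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    if sources.shape[0] < 1:
        raise ValueError("need at least one source")
    apens = np.array([approximate_entropy(s, params) for s in sources])
    keep = apens >= params.threshold
    if keep.all():
        warnings.warn("no component fell below the ApEn threshold; nothing removed")
    elif not keep.any():
        warnings.warn("every component fell below the ApEn threshold; all removed")
    return ComponentMask(apen_values=apens, keep=keep, threshold=params.threshold)


def remove_components(res: SOBIResult, mask: ComponentMask) -> np.ndarray:
    """Zero the rejected sources and reconstruct the observations."""
    if mask.keep.size != res.S.shape[0]:
        raise ValueError("mask length does not match the number of sources")
    s_mod = res.S * mask.keep[:, None]
    return sobi_reconstruct(res, s_mod)
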