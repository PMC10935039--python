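"""Second-order blind identification (SOBI).

Separates an instantaneous linear mixture X = A S using only second-order
temporal statistics: the observations are whitened, sample covariance
matrices at a set of positive lags are formed, and a single orthogonal
matrix V that jointly (approximately) diagonalizes them is found by Jacobi
rotation sweeps. Sources with distinct autocorrelation structure are then
identifiable up to permutation, sign and scale — no non-Gaussianity is
needed, which suits narrow-band EEG decompositions well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SOBIResult",
    "whiten",
    "lagged_covariances",
    "joint_diagonalize",
    "sobi_separate",
    "sobi_reconstruct",
]

DEFAULT_LAGS = tuple(range(1, 21))


@dataclass
class SOBIResult:
    """Everything needed to modify sources and map back to observations.

    Q : whitening matrix (cov(Q X) = I).
    V : orthogonal joint diagonalizer of the lagged covariances.
    A_hat : estimated mixing matrix, pinv(Q) @ V.
    C_sep : separation matrix, V.T @ Q (inverse of A_hat).
    S : recovered source time courses, one row per source, ordered by
        decreasing back-projected variance.
    lags : the sample delays used.
    means : per-channel means removed before whitening (restored on
        reconstruction).
    """

    Q: np.ndarray
    V: np.ndarray
    A_hat: np.ndarray
    C_sep: np.ndarray
    S: np.ndarray
    lags: tuple[int, ...]
    means: np.ndarray


def whiten(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Whiten a (channels x samples) array.

    Returns (W, Q) with W = Q (X - mean) and cov(W) = I. Raises on a
    rank-deficient covariance, naming constant channels when they are the
    cause.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_ch, n_s = X.shape
    if n_ch < 2:
        raise ValueError("whitening needs at least 2 channels")
    if n_s <= n_ch:
        raise ValueError("need more samples than channels")
    Xc = X - X.mean(axis=1, keepdims=True)
    variances = Xc.var(axis=1)
    dead = np.flatnonzero(variances <= 1e-30 * max(variances.max(), 1.0))
    if dead.size:
        raise ValueError(
            f"channel(s) {dead.tolist()} are constant; covariance is singular"
        )
    C = Xc @ Xc.T / n_s
    evals, evecs = np.linalg.eigh(C)
    if evals[0] <= 1e-12 * evals[-1]:
        raise ValueError(
            "covariance is rank deficient (duplicated or linearly dependent "
            "channels)"
        )
    Q = (evecs / np.sqrt(evals)).T[::-1]  # rows ordered by decreasing eigenvalue
    return Q @ Xc, Q


def lagged_covariances(W: np.ndarray, lags=DEFAULT_LAGS) -> list[np.ndarray]:
    """Symmetrized sample covariances D(p) = E[W(t+p) W(t)^T] of whitened data."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    n_s = W.shape[1]
    out = []
    for lag in lags:
        if lag < 0 or lag >= n_s / 2:
            raise ValueError(f"lag {lag} too large for {n_s} samples")
        if lag == 0:
            D = W @ W.T / n_s
        else:
            D = W[:, lag:] @ W[:, :-lag].T / (n_s - lag)
        out.append(0.5 * (D + D.T))
    return out


def joint_diagonalize(
    mats, tol: float = 1e-8, max_sweeps: int = 100
) -> np.ndarray:
    """Orthogonal V minimizing the summed off-diagonal energy of V^T M V.

    Jacobi scheme for real symmetric matrices: for each index pair the
    rotation angle has the closed form of Cardoso & Souloumiac's joint
    diagonalization, and sweeps repeat until every angle is below `tol`.
    """
    mats = [np.asarray(M, dtype=float) for M in mats]
    n = mats[0].shape[0]
    for M in mats:
        if M.shape != (n, n):
            raise ValueError("all matrices must be square and of equal size")
        if not np.allclose(M, M.T, atol=1e-10 * max(1.0, np.abs(M).max())):
            raise ValueError("joint diagonalization requires symmetric matrices")
    A = np.stack(mats)  # (n_mats, n, n), rotated in place
    V = np.eye(n)
    for _ in range(max_sweeps):
        biggest = 0.0
        for p in range(n - 1):
            for q in range(p + 1, n):
                ton = A[:, p, p] - A[:, q, q]
                toff = A[:, p, q] + A[:, q, p]
                theta = 0.5 * np.arctan2(
                    np.sum(toff * ton) * 2.0,
                    np.sum(ton * ton) - np.sum(toff * toff),
                ) / 2.0
                # equivalent closed form: maximize sum of (ton*c + toff*s)^2
                c, s = np.cos(theta), np.sin(theta)
                biggest = max(biggest, abs(s))
                if abs(s) < tol:
                    continue
                # rotate rows/cols p,q of every matrix
                Ap = A[:, p, :].copy()
                Aq = A[:, q, :].copy()
                A[:, p, :] = c * Ap + s * Aq
                A[:, q, :] = -s * Ap + c * Aq
                Ap = A[:, :, p].copy()
                Aq = A[:, :, q].copy()
                A[:, :, p] = c * Ap + s * Aq
                A[:, :, q] = -s * Ap + c * Aq
                Vp = V[:, p].copy()
                V[:, p] = c * Vp + s * V[:, q]
                V[:, q] = -s * Vp + c * V[:, q]
        if biggest < tol:
            break
    return V


def sobi_separate(X: np.ndarray, lags=DEFAULT_LAGS) -> SOBIResult:
    """Full SOBI: whiten, form lagged covariances, jointly diagonalize.

    Sources are returned ordered by decreasing variance of their
    back-projection onto the observation channels.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise ValueError(
            "SOBI needs at least 2 observation channels (stack decomposition "
            "modes to separate a single channel)"
        )
    means = X.mean(axis=1)
    W, Q = whiten(X)
    mats = lagged_covariances(W, lags)
    V = joint_diagonalize(mats)
    A_hat = np.linalg.pinv(Q) @ V
    C_sep = V.T @ Q
    S = C_sep @ (X - means[:, None])
    # back-projected energy of source i is ||A[:, i]||^2 * var(S_i)
    energy = np.sum(A_hat**2, axis=0) * S.var(axis=1)
    order = np.argsort(energy)[::-1]
    return SOBIResult(
        Q=Q,
        V=V,
        A_hat=A_hat[:, order],
        C_sep=C_sep[order, :],
        S=S[order, :],
        lags=tuple(lags),
        means=means,
    )


def sobi_reconstruct(res: SOBIResult, S_mod: np.ndarray) -> np.ndarray:
    """Map (possibly modified) sources back to observations: A_hat S + mean."""
    S_mod = np.atleast_2d(np.asarray(S_mod, dtype=float))
    if S_mod.shape != res.S.shape:
        raise ValueError("modified sources must match the shape of res.S")
    return res.A_hat @ S_mod + res.means[:, None]
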