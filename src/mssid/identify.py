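"""Parameter extraction from the transformed second-order statistics.

The future-past cross-covariance factorizes as ``H_w = O_w C_w`` with the
multiscale extended observability matrix ``O_w = [C_z; C_z A; ...; C_y; C_y A;
...]`` and reachability matrix ``C_w = [G_z, A G_z, ..., G_y, A G_y, ...]``.
A rank-n_x truncated SVD splits H_w into the two factors; the observation
matrices and cross-covariances are slices of the factors, and A solves the
joint shift-invariance least-squares problem over both modalities' blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExtendedFactors",
    "factorize_hankel",
    "extract_observation_matrices",
    "estimate_A",
    "extract_G",
    "extract_dz",
    "extended_observability",
    "extended_reachability",
    "fit_multiscale_sid",
]

#: relative singular-value cutoff for pseudoinverses
PINV_RCOND = 1e-12


@dataclass
class ExtendedFactors:
    """Rank-n_x factorization of H_w with the block layout recorded."""

    O_w: np.ndarray  # (h_z n_z + h_y n_y) x n_x
    C_w: np.ndarray  # n_x x (h_z n_z + h_y n_y)
    singular_values: np.ndarray  # full spectrum of H_w, descending
    h_z: int
    h_y: int
    n_z: int
    n_y: int

    @property
    def n_x(self) -> int:
        return self.O_w.shape[1]

    @property
    def O_z(self) -> np.ndarray:
        return self.O_w[: self.h_z * self.n_z]

    @property
    def O_y(self) -> np.ndarray:
        return self.O_w[self.h_z * self.n_z :]

    @property
    def C_wz(self) -> np.ndarray:
        return self.C_w[:, : self.h_z * self.n_z]

    @property
    def C_wy(self) -> np.ndarray:
        return self.C_w[:, self.h_z * self.n_z :]


def extended_observability(
    A: np.ndarray, C_z: np.ndarray, C_y: np.ndarray, h_z: int, h_y: int
) -> np.ndarray:
    """Stack [C_z; C_z A; ...; C_z A^(h_z-1); C_y; ...; C_y A^(h_y-1)]."""
    rows = []
    for C, h in ((np.atleast_2d(C_z), h_z), (np.atleast_2d(C_y), h_y)):
        if C.shape[0] == 0:
            continue
        blk = C
        for _ in range(h):
            rows.append(blk)
            blk = blk @ A
    return np.vstack(rows)


def extended_reachability(
    A: np.ndarray, G_z: np.ndarray, G_y: np.ndarray, h_z: int, h_y: int
) -> np.ndarray:
    """Stack [G_z, A G_z, ..., A^(h_z-1) G_z, G_y, ..., A^(h_y-1) G_y]."""
    cols = []
    for G, h in ((np.atleast_2d(G_z), h_z), (np.atleast_2d(G_y), h_y)):
        if G.shape[1] == 0:
            continue
        blk = G
        for _ in range(h):
            cols.append(blk)
            blk = A @ blk
    return np.hstack(cols)


def factorize_hankel(
    H_w: np.ndarray, n_x: int, h_z: int, h_y: int, n_z: int, n_y: int
) -> ExtendedFactors:
    """SVD-factorize H_w keeping the top n_x singular values.

    ``O_w = U1 K1^(1/2)`` and ``C_w = K1^(1/2) V1'``.  Warns when a horizon
    is at or below the single-modality observability guidance
    ``h > ceil(n_x / n_channels)``.
    """
    H_w = np.asarray(H_w, dtype=float)
    if n_x > min(H_w.shape):
        raise ValueError(
            f"n_x = {n_x} exceeds the Hankel rank bound min{H_w.shape}; "
            "increase the horizons or reduce n_x"
        )
    if n_z and h_z <= int(np.ceil(n_x / n_z)):
        warnings.warn(
            f"h_z = {h_z} is not larger than ceil(n_x/n_z) = {int(np.ceil(n_x / n_z))}; "
            "the spike observability block may be rank deficient",
            RuntimeWarning,
            stacklevel=2,
        )
    if n_y and h_y <= int(np.ceil(n_x / n_y)):
        warnings.warn(
            f"h_y = {h_y} is not larger than ceil(n_x/n_y) = {int(np.ceil(n_x / n_y))}; "
            "the field observability block may be rank deficient",
            RuntimeWarning,
            stacklevel=2,
        )
    U, K, Vt = np.linalg.svd(H_w, full_matrices=False)
    sqrtK = np.sqrt(K[:n_x])
    return ExtendedFactors(
        O_w=U[:, :n_x] * sqrtK,
        C_w=sqrtK[:, None] * Vt[:n_x],
        singular_values=K,
        h_z=h_z if n_z else 0,
        h_y=h_y if n_y else 0,
        n_z=n_z,
        n_y=n_y,
    )


def extract_observation_matrices(f: ExtendedFactors) -> tuple[np.ndarray, np.ndarray]:
    """C_z and C_y are the first n_z / n_y rows of O_z / O_y."""
    return f.O_z[: f.n_z].copy(), f.O_y[: f.n_y].copy()


def estimate_A(f: ExtendedFactors, M: int = 1) -> np.ndarray:
    """Joint shift-invariance least squares for the state transition matrix.

    For single-rate data (M = 1) this solves ``min_A || [O_z_lower;
    O_y_lower] A - [O_z_upper; O_y_upper] ||_F`` where the lower/upper
    submatrices drop the last/first block row of each modality's
    observability factor.

    For multirate data (M > 1) the field block rows of ``O_w`` advance by
    ``A^M`` per block, so the joint least squares estimates ``F = A^M``
    (using M-step shifts of the spike blocks alongside the one-block shifts
    of the field blocks) and A is the principal real M-th root of F.  The
    root is the right branch whenever the mode angles are below pi/M, which
    the slow cortical-range dynamics modeled here satisfy by a wide margin.
    """
    lowers, uppers = [], []
    shift = 1 if (M == 1 or f.n_y == 0) else M
    if f.n_z and f.h_z > shift:
        lowers.append(f.O_z[: (f.h_z - shift) * f.n_z])
        uppers.append(f.O_z[shift * f.n_z :])
    if f.n_y and f.h_y > 1:
        lowers.append(f.O_y[: (f.h_y - 1) * f.n_y])
        uppers.append(f.O_y[f.n_y :])
    if not lowers:
        raise np.linalg.LinAlgError(
            "no shift-invariance blocks available; increase the horizons"
        )
    lower = np.vstack(lowers)
    upper = np.vstack(uppers)
    n_x = f.n_x
    if np.linalg.matrix_rank(lower, tol=None) < n_x:
        raise np.linalg.LinAlgError(
            "shift-invariance system is rank deficient; increase the horizons "
            "h_z/h_y or reduce n_x"
        )
    F = np.linalg.pinv(lower, rcond=PINV_RCOND) @ upper
    if shift == 1:
        return F
    from scipy.linalg import fractional_matrix_power

    A = fractional_matrix_power(F, 1.0 / shift)
    if np.abs(A.imag).max() > 1e-6 * max(1.0, np.abs(A.real).max()):
        warnings.warn(
            "matrix M-th root of the M-step transition has a non-negligible "
            "imaginary part; the identified dynamics may be aliased",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.ascontiguousarray(A.real)


def extract_G(
    f: ExtendedFactors, A: np.ndarray | None = None, M: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """G_z and G_y are the first n_z / n_y columns of C_w's modality blocks.

    In the stride-M multirate layout the first field column block of C_w is
    ``A^{M-1} G_y``; undoing that factor requires the estimated A.
    """
    G_z = f.C_wz[:, : f.n_z].copy()
    G_y = f.C_wy[:, : f.n_y].copy()
    if M > 1 and f.n_y:
        if A is None:
            raise ValueError("A is required to extract G_y from a stride-M layout")
        G_y = np.linalg.solve(np.linalg.matrix_power(A, M - 1), G_y)
    return G_z, G_y


def extract_dz(mu_z: np.ndarray, n_z: int) -> np.ndarray:
    """The log-rate intercept is the anchor-time block of the stacked mean."""
    return np.asarray(mu_z, dtype=float)[:n_z].copy()


def fit_multiscale_sid(data, n_x: int, h_z: int = 10, h_y: int = 10, **kwargs):
    """Fit the full multiscale SID pipeline on a :class:`MultimodalData`.

    Thin functional wrapper over :class:`mssid.estimator.MultiscaleSID`;
    returns the noise-form parameters and the fit diagnostics.
    """
    from .estimator import MultiscaleSID

    est = MultiscaleSID(n_x=n_x, h_z=h_z, h_y=h_y, **kwargs).fit(data)
    return est.params_, est.diagnostics_
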