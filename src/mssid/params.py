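"""Parameter containers for the multiscale dynamical model.

The model couples a latent linear-Gaussian state with two observation
modalities::

    x[t+1] = A x[t] + q[t],            q ~ N(0, Q)
    y[t]   = C_y x[t] + r_y[t],        r_y ~ N(0, R_y)   (continuous features)
    z[t]   = C_z x[t] + d_z            (log firing rate)
    N[t]   ~ Poisson(exp(z[t]))        (spike counts)

Two equivalent parameterizations are used.  The *noise form* carries the
noise covariances ``{A, C_y, C_z, Q, R_y, d_z}`` and is what the multiscale
filter consumes.  The *covariance form* replaces the noise covariances with
second-order observation statistics ``{A, C_z, C_y, G_z, G_y, Lambda0, d_z,
Sigma_x}``, where ``G_z = Cov[x[t+1], z[t]]``, ``G_y = Cov[x[t+1], y[t]]``,
``Lambda0 = Cov[(z[t]; y[t])]`` and ``Sigma_x`` is the stationary state
covariance.  The covariance form is what subspace identification estimates
directly and what model evaluation compares.

The model structurally fixes ``R_z = 0`` (no additive noise on the log rate),
``R_zy = 0`` and ``S = Cov[q, r] = 0``; those blocks are therefore never
stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

__all__ = [
    "MultiscaleParams",
    "CovParams",
    "ValidationReport",
    "validate_params",
    "pset_from_nset",
    "nset_from_pset",
    "symmetrize",
    "stationary_state_covariance",
    "InvalidNoiseError",
    "StationarityError",
]

#: relative tolerance for PSD checks (w.r.t. the largest eigenvalue magnitude)
PSD_RTOL = 1e-8


class StationarityError(ValueError):
    """Raised when A has spectral radius >= 1 and a stationary solve is needed."""


class InvalidNoiseError(ValueError):
    """Raised when covariance-form parameters imply non-PSD noise covariances."""


def symmetrize(m: np.ndarray) -> np.ndarray:
    """Project onto the symmetric matrices; counters floating-point drift."""
    return (m + m.T) / 2.0


def _is_psd(m: np.ndarray, tol: float | None = None) -> bool:
    if m.size == 0:
        return True
    w = np.linalg.eigvalsh(symmetrize(m))
    if tol is None:
        tol = PSD_RTOL * max(1.0, float(np.max(np.abs(w))))
    return bool(w.min() >= -tol)


@dataclass
class MultiscaleParams:
    """Noise-form parameter set of the multiscale model."""

    A: np.ndarray
    C_y: np.ndarray
    C_z: np.ndarray
    Q: np.ndarray
    R_y: np.ndarray
    d_z: np.ndarray
    #: bin width in seconds (metadata only; exp(z) is a per-bin rate)
    bin_width_s: float = 0.010

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        n_x = self.A.shape[0]
        self.C_y = np.asarray(self.C_y, dtype=float).reshape(-1, n_x)
        self.C_z = np.asarray(self.C_z, dtype=float).reshape(-1, n_x)
        self.Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        n_y = self.C_y.shape[0]
        self.R_y = np.asarray(self.R_y, dtype=float).reshape(n_y, n_y)
        self.d_z = np.asarray(self.d_z, dtype=float).reshape(-1)

    @property
    def n_x(self) -> int:
        return self.A.shape[0]

    @property
    def n_y(self) -> int:
        return self.C_y.shape[0]

    @property
    def n_z(self) -> int:
        return self.C_z.shape[0]

    @property
    def C(self) -> np.ndarray:
        """Stacked observation matrix (C_z over C_y)."""
        return np.vstack([self.C_z, self.C_y])


@dataclass
class CovParams:
    """Covariance-form parameter set of the multiscale model."""

    A: np.ndarray
    C_z: np.ndarray
    C_y: np.ndarray
    G_z: np.ndarray
    G_y: np.ndarray
    Lambda0: np.ndarray
    d_z: np.ndarray
    Sigma_x: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        n_x = self.A.shape[0]
        self.C_z = np.asarray(self.C_z, dtype=float).reshape(-1, n_x)
        self.C_y = np.asarray(self.C_y, dtype=float).reshape(-1, n_x)
        self.G_z = np.asarray(self.G_z, dtype=float).reshape(n_x, -1)
        self.G_y = np.asarray(self.G_y, dtype=float).reshape(n_x, -1)
        n_zy = self.C_z.shape[0] + self.C_y.shape[0]
        self.Lambda0 = np.asarray(self.Lambda0, dtype=float).reshape(n_zy, n_zy)
        self.d_z = np.asarray(self.d_z, dtype=float).reshape(-1)
        self.Sigma_x = np.asarray(self.Sigma_x, dtype=float).reshape(n_x, n_x)

    @property
    def n_x(self) -> int:
        return self.A.shape[0]

    @property
    def n_y(self) -> int:
        return self.C_y.shape[0]

    @property
    def n_z(self) -> int:
        return self.C_z.shape[0]

    @property
    def C(self) -> np.ndarray:
        return np.vstack([self.C_z, self.C_y])

    @property
    def Lambda0_zz(self) -> np.ndarray:
        return self.Lambda0[: self.n_z, : self.n_z]

    @property
    def Lambda0_zy(self) -> np.ndarray:
        return self.Lambda0[: self.n_z, self.n_z :]

    @property
    def Lambda0_yy(self) -> np.ndarray:
        return self.Lambda0[self.n_z :, self.n_z :]


@dataclass
class ValidationReport:
    """Report-style result of :func:`validate_params`."""

    passed: bool
    messages: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def validate_params(p: MultiscaleParams, tol: float = PSD_RTOL) -> ValidationReport:
    """Check dimensions, symmetry and positive semidefiniteness of a model.

    Returns a report rather than raising, so callers can surface all problems
    at once.
    """
    msgs: list[str] = []
    n_x, n_y, n_z = p.n_x, p.n_y, p.n_z
    if n_x < 1:
        msgs.append(f"n_x must be >= 1, got {n_x}")
    if n_y + n_z < 1:
        msgs.append("model must have at least one observation channel")
    if p.A.shape != (n_x, n_x):
        msgs.append(f"A has shape {p.A.shape}, expected ({n_x}, {n_x})")
    if p.Q.shape != (n_x, n_x):
        msgs.append(f"Q has shape {p.Q.shape}, expected ({n_x}, {n_x})")
    if p.R_y.shape != (n_y, n_y):
        msgs.append(f"R_y has shape {p.R_y.shape}, expected ({n_y}, {n_y})")
    if p.d_z.shape != (n_z,):
        msgs.append(f"d_z has shape {p.d_z.shape}, expected ({n_z},)")
    for name, m in (("Q", p.Q), ("R_y", p.R_y)):
        if m.size == 0 or m.shape[0] != m.shape[1]:
            continue
        scale = max(1.0, float(np.abs(m).max()))
        if np.abs(m - m.T).max() > tol * scale:
            msgs.append(f"{name} is not symmetric beyond tolerance")
        w = np.linalg.eigvalsh(symmetrize(m))
        bound = tol * max(1.0, float(np.max(np.abs(w))))
        if w.min() < -bound:
            msgs.append(f"{name} has negative eigenvalue {w.min():.3e}")
    return ValidationReport(passed=not msgs, messages=msgs)


def stationary_state_covariance(A: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Solve the discrete Lyapunov equation ``Sigma = A Sigma A' + Q``.

    Uses the direct (Schur-based) solver; requires spectral radius of A < 1.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    rho = float(np.max(np.abs(np.linalg.eigvals(A)))) if A.size else 0.0
    if rho >= 1.0:
        raise StationarityError(
            f"A has spectral radius {rho:.4f} >= 1; no stationary covariance exists"
        )
    return symmetrize(sla.solve_discrete_lyapunov(A, symmetrize(np.atleast_2d(Q))))


def pset_from_nset(p: MultiscaleParams) -> CovParams:
    """Convert noise-form parameters to the equivalent covariance form.

    ``Sigma_x`` solves the discrete Lyapunov equation, then
    ``(G_z G_y) = A Sigma_x C'`` and ``Lambda0 = C Sigma_x C' +
    blockdiag(0, R_y)``.
    """
    Sigma_x = stationary_state_covariance(p.A, p.Q)
    C = p.C
    G = p.A @ Sigma_x @ C.T
    Lambda0 = symmetrize(C @ Sigma_x @ C.T)
    Lambda0[p.n_z :, p.n_z :] += symmetrize(p.R_y)
    return CovParams(
        A=p.A.copy(),
        C_z=p.C_z.copy(),
        C_y=p.C_y.copy(),
        G_z=G[:, : p.n_z],
        G_y=G[:, p.n_z :],
        Lambda0=Lambda0,
        d_z=p.d_z.copy(),
        Sigma_x=Sigma_x,
    )


def nset_from_pset(p: CovParams, tol: float = PSD_RTOL) -> MultiscaleParams:
    """Convert covariance-form parameters back to noise form.

    ``Q = Sigma_x - A Sigma_x A'`` and ``R_y = Lambda0_yy - C_y Sigma_x C_y'``
    must come out PSD; otherwise the covariance form is inconsistent with the
    structural zero-noise constraints and the constrained noise optimization
    has to be solved first.
    """
    Sigma_x = symmetrize(p.Sigma_x)
    Q = symmetrize(Sigma_x - p.A @ Sigma_x @ p.A.T)
    R_y = symmetrize(p.Lambda0_yy - p.C_y @ Sigma_x @ p.C_y.T)
    for name, m in (("Q", Q), ("R_y", R_y)):
        if not _is_psd(m, tol * max(1.0, float(np.abs(m).max()) if m.size else 1.0)):
            raise InvalidNoiseError(
                f"derived {name} is not PSD; solve the constrained noise "
                "optimization (noise_opt.solve_noise_statistics) first"
            )
    return MultiscaleParams(
        A=p.A.copy(), C_y=p.C_y.copy(), C_z=p.C_z.copy(), Q=Q, R_y=R_y, d_z=p.d_z.copy()
    )
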