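"""Valid noise statistics via convex constrained optimization.

Covariance-based subspace identification does not by itself yield positive
semidefinite noise covariances, and the multiscale filter additionally
requires the structural zeros R_z = 0 (no additive log-rate noise),
R_zy = 0 and S = Cov[q, r] = 0.  Writing the noise statistics as affine
functions of the stationary state covariance Sigma_x,

    Q(Sigma_x)   = Sigma_x - A Sigma_x A'
    R(Sigma_x)   = Lambda0 - C Sigma_x C'        (blocks R_z, R_zy, R_y)
    S(Sigma_x)   = (G_z G_y) - A Sigma_x C'

we solve

    min_{Sigma_x}  ||S||_F + ||R_z||_F + ||R_zy||_F
    s.t.           Sigma_x, Q(Sigma_x), R_y(Sigma_x)  PSD,

a convex problem (norms of affine maps; min-eigenvalue constraints are
concave).  The solver first computes the unconstrained least-squares
minimizer in closed form; when that point already satisfies the PSD
constraints (the typical well-estimated case) it is returned directly.
Otherwise a smoothed version of the objective is minimized with
``scipy.optimize.minimize(method="trust-constr")`` under analytic
minimum-eigenvalue constraints, with a penalized quasi-Newton solve on a
Cholesky factorization of Sigma_x as a last-resort fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .params import CovParams, MultiscaleParams, symmetrize

__all__ = ["SdpResult", "solve_noise_statistics", "finalize_model", "NoiseEstimationError"]

#: smoothing of the Frobenius norms at zero
_NORM_DELTA = 1e-14
#: diagonal slack on the PSD constraints, relative to the state-covariance scale
_PSD_SLACK = 1e-9


class NoiseEstimationError(RuntimeError):
    pass


@dataclass
class SdpResult:
    Sigma_x: np.ndarray
    Q: np.ndarray
    R_y: np.ndarray
    objective: float
    status: str  # "least-squares" | "trust-constr" | "fallback"
    #: raw pre-finalization cost terms at the optimum, for diagnostics
    S: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    R_z: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    R_zy: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


def _sym_basis(n: int) -> list[np.ndarray]:
    basis = []
    for i in range(n):
        for j in range(i, n):
            E = np.zeros((n, n))
            E[i, j] = E[j, i] = 1.0
            basis.append(E)
    return basis


def _vech(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    return np.concatenate([M[i, i:] for i in range(n)])


def _unvech(s: np.ndarray, n: int) -> np.ndarray:
    M = np.zeros((n, n))
    k = 0
    for i in range(n):
        M[i, i:] = s[k : k + n - i]
        M[i:, i] = s[k : k + n - i]
        k += n - i
    return M


def _grad_to_vech(G: np.ndarray) -> np.ndarray:
    """Chain rule from a symmetric matrix gradient to the vech parameters."""
    G = symmetrize(G)
    n = G.shape[0]
    out = []
    for i in range(n):
        row = G[i, i:].copy() * 2.0
        row[0] = G[i, i]
        out.append(row)
    return np.concatenate(out)


def _psd_clip(M: np.ndarray) -> np.ndarray:
    if M.size == 0:
        return M
    w, V = np.linalg.eigh(symmetrize(M))
    return symmetrize((V * np.clip(w, 0.0, None)) @ V.T)


def solve_noise_statistics(
    A: np.ndarray,
    C_z: np.ndarray,
    C_y: np.ndarray,
    G_z: np.ndarray,
    G_y: np.ndarray,
    Lambda0: np.ndarray,
    max_iter: int = 400,
) -> SdpResult:
    """Solve the constrained noise-statistics problem for Sigma_x, Q, R_y."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n_x = A.shape[0]
    C_z = np.asarray(C_z, dtype=float).reshape(-1, n_x)
    C_y = np.asarray(C_y, dtype=float).reshape(-1, n_x)
    n_z, n_y = C_z.shape[0], C_y.shape[0]
    C = np.vstack([C_z, C_y])
    G = np.hstack([np.asarray(G_z, dtype=float).reshape(n_x, n_z),
                   np.asarray(G_y, dtype=float).reshape(n_x, n_y)])
    Lambda0 = symmetrize(np.asarray(Lambda0, dtype=float).reshape(n_z + n_y, n_z + n_y))

    def terms(Sig):
        S = G - A @ Sig @ C.T
        R = Lambda0 - C @ Sig @ C.T
        return S, R[:n_z, :n_z], R[:n_z, n_z:], symmetrize(R[n_z:, n_z:])

    def objective_value(Sig):
        S, R_z, R_zy, _ = terms(Sig)
        return (
            np.linalg.norm(S)
            + np.linalg.norm(R_z)
            + np.linalg.norm(R_zy)
        )

    # --- closed-form unconstrained least-squares minimizer -----------------
    basis = _sym_basis(n_x)
    cols = []
    for E in basis:
        S_E = -A @ E @ C.T
        R_E = -C @ E @ C.T
        cols.append(
            np.concatenate([S_E.ravel(), R_E[:n_z, :n_z].ravel(), R_E[:n_z, n_z:].ravel()])
        )
    design = np.column_stack(cols)
    target = -np.concatenate(
        [G.ravel(), Lambda0[:n_z, :n_z].ravel(), Lambda0[:n_z, n_z:].ravel()]
    )
    if design.shape[0] == 0:
        raise NoiseEstimationError("model has no observation channels")
    s_ls, *_ = np.linalg.lstsq(design, target, rcond=None)
    Sigma_ls = _unvech(s_ls, n_x)

    scale = max(1.0, float(np.trace(Sigma_ls)))
    slack = _PSD_SLACK * scale
    feas_tol = 1e-8 * scale

    def min_eigs(Sig):
        out = [float(np.linalg.eigvalsh(symmetrize(Sig)).min())]
        Qm = symmetrize(Sig - A @ Sig @ A.T)
        out.append(float(np.linalg.eigvalsh(Qm).min()))
        if n_y:
            Rym = symmetrize(Lambda0[n_z:, n_z:] - C_y @ Sig @ C_y.T)
            out.append(float(np.linalg.eigvalsh(Rym).min()))
        return np.array(out)

    status = "least-squares"
    Sigma = Sigma_ls
    if np.any(min_eigs(Sigma_ls) < -feas_tol):
        Sigma, status = _constrained_solve(
            A, C, C_y, G, Lambda0, n_z, n_y, Sigma_ls, slack, max_iter,
            objective_value, terms, min_eigs,
        )

    Q = _psd_clip(Sigma - A @ Sigma @ A.T)
    R_y = _psd_clip(Lambda0[n_z:, n_z:] - C_y @ Sigma @ C_y.T)
    Sigma = _psd_clip(Sigma)
    S, R_z, R_zy, _ = terms(Sigma)
    return SdpResult(
        Sigma_x=Sigma,
        Q=Q,
        R_y=R_y,
        objective=objective_value(Sigma),
        status=status,
        S=S,
        R_z=R_z,
        R_zy=R_zy,
    )


def _constrained_solve(
    A, C, C_y, G, Lambda0, n_z, n_y, Sigma0, slack, max_iter,
    objective_value, terms, min_eigs,
):
    """trust-constr solve with analytic gradients; penalized fallback."""
    n_x = A.shape[0]
    C_z = C[:n_z]

    def smooth_obj(s):
        Sig = _unvech(s, n_x)
        S, R_z, R_zy, _ = terms(Sig)
        val, grad = 0.0, np.zeros_like(Sig)
        for M, adj in (
            (S, lambda W: -A.T @ W @ C),
            (R_z, lambda W: -C_z.T @ W @ C_z),
            (R_zy, lambda W: -C_z.T @ W @ C_y),
        ):
            if M.size == 0:
                continue
            nrm = np.sqrt(np.sum(M * M) + _NORM_DELTA)
            val += nrm
            grad += adj(M / nrm)
        return val, _grad_to_vech(grad)

    def eig_con(s, which):
        Sig = _unvech(s, n_x)
        if which == "sigma":
            Ms, push = Sig, lambda vv: vv
        elif which == "q":
            Ms, push = symmetrize(Sig - A @ Sig @ A.T), lambda vv: vv - A.T @ vv @ A
        else:
            Ms = symmetrize(Lambda0[n_z:, n_z:] - C_y @ Sig @ C_y.T)
            push = lambda vv: -C_y.T @ vv @ C_y
        w, V = np.linalg.eigh(Ms)
        v = V[:, 0]
        return w[0], _grad_to_vech(push(np.outer(v, v)))

    cons = []
    for which in ("sigma", "q") + (("ry",) if n_y else ()):
        cons.append(
            optimize.NonlinearConstraint(
                lambda s, w=which: eig_con(s, w)[0],
                lb=-slack,
                ub=np.inf,
                jac=lambda s, w=which: eig_con(s, w)[1],
            )
        )

    # feasible-ish start: clip the LS point's eigenvalues
    w0, V0 = np.linalg.eigh(symmetrize(Sigma0))
    Sigma_start = symmetrize((V0 * np.clip(w0, slack, None)) @ V0.T)
    try:
        res = optimize.minimize(
            smooth_obj,
            _vech(Sigma_start),
            jac=True,
            method="trust-constr",
            constraints=cons,
            options={"maxiter": max_iter, "gtol": 1e-10, "xtol": 1e-12, "verbose": 0},
        )
        Sigma = _unvech(res.x, n_x)
        if np.all(min_eigs(Sigma) > -100 * slack):
            return Sigma, "trust-constr"
    except Exception:
        pass

    # fallback: Sigma = L L' with hinge penalties on Q / R_y eigenvalues
    def penalized(l_flat):
        L = l_flat.reshape(n_x, n_x)
        Sig = L @ L.T
        S, R_z, R_zy, R_ym = terms(Sig)
        val = np.linalg.norm(S) + np.linalg.norm(R_z) + np.linalg.norm(R_zy)
        rho = 1e4
        Qm = symmetrize(Sig - A @ Sig @ A.T)
        val += rho * np.sum(np.clip(-np.linalg.eigvalsh(Qm), 0.0, None) ** 2)
        if n_y:
            val += rho * np.sum(np.clip(-np.linalg.eigvalsh(R_ym), 0.0, None) ** 2)
        return val

    w0c = np.clip(w0, slack, None)
    L0 = V0 * np.sqrt(w0c)
    res = optimize.minimize(penalized, L0.ravel(), method="L-BFGS-B", options={"maxiter": 2000})
    if not np.all(np.isfinite(res.x)):
        raise NoiseEstimationError(
            "noise-statistics optimization failed; the second-order statistics "
            "are likely poorly estimated - use more training data"
        )
    L = res.x.reshape(n_x, n_x)
    return symmetrize(L @ L.T), "fallback"


def finalize_model(
    sdp: SdpResult,
    A: np.ndarray,
    C_z: np.ndarray,
    C_y: np.ndarray,
    d_z: np.ndarray,
) -> tuple[MultiscaleParams, CovParams]:
    """Impose S = R_z = R_zy = 0 exactly and return consistent parameter sets.

    With the optimized Sigma_x the cross-covariances and zero-lag covariance
    are recomputed from the model structure: ``(G_z G_y) = A Sigma_x C'`` and
    ``Lambda0 = C Sigma_x C' + blockdiag(0, R_y)``.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    n_x = A.shape[0]
    C_z = np.asarray(C_z, dtype=float).reshape(-1, n_x)
    C_y = np.asarray(C_y, dtype=float).reshape(-1, n_x)
    n_z = C_z.shape[0]
    C = np.vstack([C_z, C_y])
    Sigma = symmetrize(sdp.Sigma_x)
    Gf = A @ Sigma @ C.T
    Lam = symmetrize(C @ Sigma @ C.T)
    Lam[n_z:, n_z:] += symmetrize(sdp.R_y)
    nset = MultiscaleParams(A=A, C_y=C_y, C_z=C_z, Q=sdp.Q, R_y=sdp.R_y, d_z=d_z)
    pset = CovParams(
        A=A,
        C_z=C_z,
        C_y=C_y,
        G_z=Gf[:, :n_z],
        G_y=Gf[:, n_z:],
        Lambda0=Lam,
        d_z=np.asarray(d_z, dtype=float),
        Sigma_x=Sigma,
    )
    return nset, pset
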