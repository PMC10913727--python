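"""Causal latent-state inference with the multiscale filter (MSF).

The MSF alternates a linear prediction step with a Laplace-approximated
update that combines the Poisson spike likelihood and (when the slow
modality is observed at that bin) the Gaussian feature likelihood in one
joint posterior mode-finding problem:

    x-   = A x[t-1|t-1],   P- = A P[t-1|t-1] A' + Q
    x[t|t] = argmax_x  -1/2 (x - x-)' P-^{-1} (x - x-)
                       + sum_i [ N_ti (C_z x + d_z)_i - exp((C_z x + d_z)_i) ]
                       + [y observed]  -1/2 (y_t - C_y x)' R_y^{-1} (y_t - C_y x)

solved by Newton-Raphson from x-, with P[t|t] the inverse negative Hessian
at the mode.  With no spike channels every update is exactly the Kalman
filter (the problem is quadratic); with no continuous channels it is the
Laplace point-process filter.  Bins where y is missing simply omit the
Gaussian term, so multirate data needs no interpolation at inference time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import MultiscaleParams, StationarityError, pset_from_nset, symmetrize
from .simulate import MultimodalData

__all__ = ["FilterOutput", "msf_filter", "predict_one_step"]

_NEWTON_MAX_ITER = 25
_NEWTON_GTOL = 1e-9


@dataclass
class FilterOutput:
    x_pred: np.ndarray  # (T, n_x) one-step-ahead means x[t|t-1]
    P_pred: np.ndarray  # (T, n_x, n_x)
    x_filt: np.ndarray  # (T, n_x) filtered means x[t|t]
    P_filt: np.ndarray  # (T, n_x, n_x)
    y_pred: np.ndarray  # (T, n_y) = C_y x[t|t-1]
    z_pred: np.ndarray  # (T, n_z) = C_z x[t|t-1] + d_z
    p_event: np.ndarray  # (T, n_z) P(at least one spike) per bin


def predict_one_step(
    p: MultiscaleParams, x_pred: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Observation predictions from one-step-ahead states.

    ``p_event = 1 - exp(-exp(z_pred))`` is the per-bin probability of at
    least one spike under the Poisson model.
    """
    x_pred = np.atleast_2d(np.asarray(x_pred, dtype=float))
    y_pred = x_pred @ p.C_y.T
    z_pred = x_pred @ p.C_z.T + p.d_z
    p_event = 1.0 - np.exp(-np.exp(z_pred))
    return y_pred, z_pred, p_event


def msf_filter(
    p: MultiscaleParams,
    data: MultimodalData,
    x0: np.ndarray | None = None,
    P0: np.ndarray | None = None,
) -> FilterOutput:
    """Run the causal multiscale filter over a multimodal series.

    Initialization is the stationary prior: ``x[1|0] = 0`` and ``P[1|0] =
    Sigma_x`` (unless overridden).  The availability mask of ``data`` is
    authoritative: values stored at missing y bins are never read.
    """
    n_x, n_y, n_z = p.n_x, p.n_y, p.n_z
    T = data.T
    A, Q = p.A, symmetrize(p.Q)
    C_z, d_z, C_y = p.C_z, p.d_z, p.C_y

    if P0 is None:
        try:
            P0 = pset_from_nset(p).Sigma_x
        except StationarityError:
            warnings.warn(
                "A is not stable, so no stationary prior exists; initializing "
                "the filter covariance with Q",
                RuntimeWarning,
                stacklevel=2,
            )
            P0 = Q + 1e-6 * max(1.0, float(np.trace(Q))) * np.eye(n_x)
    if x0 is None:
        x0 = np.zeros(n_x)

    if n_y:
        # information-form Gaussian update terms; tolerates tiny R_y via pinv
        w, V = np.linalg.eigh(symmetrize(p.R_y))
        if np.any(w <= 0):
            Ry_inv = (V / np.maximum(w, 1e-12)) @ V.T
        else:
            Ry_inv = (V / w) @ V.T
        CtRi = C_y.T @ Ry_inv  # n_x x n_y
        CtRiC = symmetrize(CtRi @ C_y)

    x_pred = np.empty((T, n_x))
    P_pred = np.empty((T, n_x, n_x))
    x_filt = np.empty((T, n_x))
    P_filt = np.empty((T, n_x, n_x))

    xp = np.asarray(x0, dtype=float)
    Pp = symmetrize(np.asarray(P0, dtype=float))
    N = data.N
    y = data.y
    mask = data.mask
    n_warn = 0

    for t in range(T):
        x_pred[t] = xp
        P_pred[t] = Pp
        Pp_inv = np.linalg.inv(Pp)
        has_y = bool(mask[t]) and n_y > 0

        # Newton-Raphson on the joint log posterior, initialized at x-
        x = xp.copy()
        converged = n_z == 0  # pure-Gaussian case is solved in one exact step
        for _ in range(_NEWTON_MAX_ITER if n_z else 1):
            grad = -Pp_inv @ (x - xp)
            H = -Pp_inv.copy()
            if n_z:
                lam = np.exp(C_z @ x + d_z)
                grad += C_z.T @ (N[t] - lam)
                H -= (C_z.T * lam) @ C_z
            if has_y:
                grad += CtRi @ (y[t] - C_y @ x)
                H -= CtRiC
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            x = x - step
            if n_z == 0:
                converged = True
                break
            if np.linalg.norm(grad) < _NEWTON_GTOL * max(1.0, np.linalg.norm(x)):
                converged = True
                break
        if n_z:
            lam = np.exp(C_z @ x + d_z)
            grad = -Pp_inv @ (x - xp) + C_z.T @ (N[t] - lam)
            if has_y:
                grad += CtRi @ (y[t] - C_y @ x)
            if np.linalg.norm(grad) < _NEWTON_GTOL * max(1.0, np.linalg.norm(x)) * 1e3:
                converged = True
        if not converged:
            n_warn += 1
            x = xp.copy()  # fall back to the predicted mean
        H = -Pp_inv.copy()
        if n_z:
            lam = np.exp(C_z @ x + d_z)
            H -= (C_z.T * lam) @ C_z
        if has_y:
            H -= CtRiC
        Pf = symmetrize(np.linalg.inv(-H))
        wmin = float(np.linalg.eigvalsh(Pf).min())
        if wmin < -1e-8 * max(1.0, float(np.abs(Pf).max())):
            raise np.linalg.LinAlgError(
                f"filtered covariance lost positive semidefiniteness at bin {t}"
            )
        x_filt[t] = x
        P_filt[t] = Pf

        xp = A @ x
        Pp = symmetrize(A @ Pf @ A.T + Q)

    if n_warn:
        warnings.warn(
            f"Newton update failed to converge at {n_warn} of {T} bins; the "
            "predicted mean was used there",
            RuntimeWarning,
            stacklevel=2,
        )
    y_pred, z_pred, p_event = predict_one_step(p, x_pred)
    return FilterOutput(
        x_pred=x_pred,
        P_pred=P_pred,
        x_filt=x_filt,
        P_filt=P_filt,
        y_pred=y_pred,
        z_pred=z_pred,
        p_event=p_event,
    )
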