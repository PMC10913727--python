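"""Model evaluation: alignment, error metrics, prediction accuracy, decoding.

Learned latent-state models are only identified up to an invertible change of
basis (similarity transform), so parameter comparison first aligns the
learned model to the truth by the transform T minimizing
``|| O_w^learned T - O_w^true ||_F`` over extended observability matrices,
then reports normalized Frobenius errors ``||psi_id - psi_true||_F /
||psi_true||_F``.  Dynamical-mode (eigenvalue) errors use minimum-total-
distance matching, which absorbs both basis changes and mode permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import roc_auc_score

from .identify import extended_observability
from .params import CovParams

__all__ = [
    "EvalReport",
    "align_models",
    "normalized_error",
    "normalized_mode_error",
    "cost_term_norms",
    "prediction_power",
    "prediction_cc",
    "fit_behavior_decoder",
    "predict_behavior",
    "blocked_cv_splits",
    "select_state_dim",
    "evaluate_identification",
]


@dataclass
class EvalReport:
    """Flat container of evaluation results (missing entries stay None)."""

    param_errors: dict[str, float] = field(default_factory=dict)
    mode_error: float | None = None
    mode_error_by_type: dict[str, float] = field(default_factory=dict)
    cost_norms: dict[str, float] = field(default_factory=dict)
    pp: float | None = None
    cc: float | None = None
    behavior_cc: float | None = None

    def as_dict(self) -> dict:
        out: dict = {}
        for k, v in self.param_errors.items():
            out[f"err_{k}"] = v
        if self.mode_error is not None:
            out["mode_error"] = self.mode_error
        for k, v in self.mode_error_by_type.items():
            out[f"mode_error_{k}"] = v
        for k, v in self.cost_norms.items():
            out[f"norm_{k}"] = v
        for k in ("pp", "cc", "behavior_cc"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        return out


# ---------------------------------------------------------------------------
# similarity-transform alignment


def _alignment_horizon(n_x: int, n_z: int, n_y: int) -> int:
    per = min(n for n in (n_z, n_y) if n > 0)
    return min(10, max(2, 2 * int(np.ceil(n_x / per))))


def align_models(learned: CovParams, truth: CovParams) -> CovParams:
    """Re-express the learned model in the basis closest to the true model.

    Finds the invertible T minimizing ``||O_w^learned T - O_w^true||_F`` and
    applies ``A <- T^-1 A T``, ``C <- C T``, ``G <- T^-1 G``,
    ``Sigma_x <- T^-1 Sigma_x T^-T``.  Observation-space behavior (and
    Lambda0) is unchanged.
    """
    if (learned.n_x, learned.n_z, learned.n_y) != (truth.n_x, truth.n_z, truth.n_y):
        raise ValueError("learned and true models must have identical dimensions")
    h = _alignment_horizon(truth.n_x, truth.n_z, truth.n_y)
    O_l = extended_observability(learned.A, learned.C_z, learned.C_y, h, h)
    O_t = extended_observability(truth.A, truth.C_z, truth.C_y, h, h)
    T, *_ = np.linalg.lstsq(O_l, O_t, rcond=None)
    cond = np.linalg.cond(T)
    if cond > 1e8:
        warnings.warn(
            f"alignment transform is ill-conditioned (cond = {cond:.2e}); "
            "reported errors may be unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    Ti = np.linalg.inv(T)
    return CovParams(
        A=Ti @ learned.A @ T,
        C_z=learned.C_z @ T,
        C_y=learned.C_y @ T,
        G_z=Ti @ learned.G_z,
        G_y=Ti @ learned.G_y,
        Lambda0=learned.Lambda0.copy(),
        d_z=learned.d_z.copy(),
        Sigma_x=Ti @ learned.Sigma_x @ Ti.T,
    )


def normalized_error(psi_id: np.ndarray, psi_true: np.ndarray) -> float:
    """``||psi_id - psi_true||_F / ||psi_true||_F``."""
    psi_id = np.asarray(psi_id)
    psi_true = np.asarray(psi_true)
    denom = np.linalg.norm(psi_true)
    if denom == 0:
        raise ValueError("true parameter has zero norm; normalized error undefined")
    return float(np.linalg.norm(psi_id - psi_true) / denom)


def normalized_mode_error(
    A_id: np.ndarray,
    A_true: np.ndarray,
    mode_subset: np.ndarray | None = None,
) -> float:
    """Eigenvalue identification error after optimal matching.

    Eigenvalues of the identified A are assigned to those of the true A by
    minimum total complex distance (Hungarian algorithm), then the error is
    ``||matched difference||_2 / ||true eigenvalues||_2``.  ``mode_subset``
    restricts the true eigenvalues (e.g. to the shared modes); the learned
    eigenvalues are then matched rectangularly so each true one picks its
    best distinct partner.
    """
    ev_id = np.linalg.eigvals(np.atleast_2d(A_id))
    ev_true = np.linalg.eigvals(np.atleast_2d(A_true))
    if mode_subset is not None:
        ev_true = np.asarray(mode_subset, dtype=complex)
        if ev_true.size > ev_id.size:
            raise ValueError("mode subset larger than the identified spectrum")
    elif ev_id.size != ev_true.size:
        raise ValueError("spectra have different sizes")
    cost = np.abs(ev_true[:, None] - ev_id[None, :])
    rows, cols = linear_sum_assignment(cost)
    diff = ev_true[rows] - ev_id[cols]
    return float(np.linalg.norm(diff) / np.linalg.norm(ev_true))


def cost_term_norms(
    R_z: np.ndarray,
    R_zy: np.ndarray,
    S: np.ndarray,
    R_y: np.ndarray,
    Lambda0: np.ndarray,
    G: np.ndarray,
    n_z: int,
) -> dict[str, float]:
    """Normalized Frobenius norms of the optimization cost terms.

    Each raw (pre-finalization) term is normalized by its total covariance:
    R_z by Lambda0_zz, R_zy by Lambda0_zy, S by (G_z G_y), and as a control
    R_y by Lambda0_yy (the control is not in the cost, so it should not
    shrink with more data).
    """
    out = {}
    for name, term, denom in (
        ("R_z", R_z, Lambda0[:n_z, :n_z]),
        ("R_zy", R_zy, Lambda0[:n_z, n_z:]),
        ("S", S, G),
        ("R_y", R_y, Lambda0[n_z:, n_z:]),
    ):
        d = np.linalg.norm(denom)
        if d == 0:
            raise ValueError(f"zero normalization for cost term {name}")
        out[name] = float(np.linalg.norm(term) / d)
    return out


# ---------------------------------------------------------------------------
# prediction metrics


def prediction_power(events: np.ndarray, p_event: np.ndarray) -> float:
    """Spike-event prediction power, ``PP = 2 AUC - 1`` averaged over channels.

    ``events`` holds per-bin counts or indicators; a channel enters with the
    indicator of at least one spike.  Channels with a single class are
    skipped with a warning; if all are single-class an error is raised.
    """
    events = np.atleast_2d(np.asarray(events))
    p_event = np.atleast_2d(np.asarray(p_event, dtype=float))
    if events.shape != p_event.shape:
        raise ValueError("events and p_event must have matching shapes")
    pps = []
    skipped = []
    for i in range(events.shape[1]):
        lab = (events[:, i] >= 1).astype(int)
        if lab.min() == lab.max():
            skipped.append(i)
            continue
        pps.append(2.0 * roc_auc_score(lab, p_event[:, i]) - 1.0)
    if not pps:
        raise ValueError("all spike channels are single-class; PP undefined")
    if skipped:
        warnings.warn(
            f"skipped single-class spike channels {skipped} in PP",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(np.mean(pps))


def prediction_cc(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean per-channel Pearson correlation; missing bins (NaN) are skipped."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError("shapes must match")
    ccs = []
    for i in range(y_true.shape[1]):
        ok = np.isfinite(y_true[:, i]) & np.isfinite(y_pred[:, i])
        a, b = y_true[ok, i], y_pred[ok, i]
        if a.std() == 0 or b.std() == 0:
            raise ValueError(f"channel {i} has zero variance; CC undefined")
        ccs.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(ccs))


# ---------------------------------------------------------------------------
# behavior decoding


def fit_behavior_decoder(x_filt: np.ndarray, behavior: np.ndarray) -> np.ndarray:
    """OLS projection from filtered states (with intercept) to behavior.

    Solves ``L = B X' (X X')^{-1}`` with ``X`` the states stacked over time
    with a prepended constant 1.  Falls back to a small ridge when X X' is
    numerically singular.
    """
    X = np.hstack([np.ones((x_filt.shape[0], 1)), np.asarray(x_filt, dtype=float)]).T
    B = np.atleast_2d(np.asarray(behavior, dtype=float).T)
    XXt = X @ X.T
    try:
        L = np.linalg.solve(XXt, X @ B.T).T
    except np.linalg.LinAlgError:
        warnings.warn(
            "X X' is singular; using ridge-regularized decoder",
            RuntimeWarning,
            stacklevel=2,
        )
        lam = 1e-8 * np.trace(XXt) / XXt.shape[0]
        L = np.linalg.solve(XXt + lam * np.eye(XXt.shape[0]), X @ B.T).T
    return L


def predict_behavior(L: np.ndarray, x_filt: np.ndarray) -> np.ndarray:
    X = np.hstack([np.ones((x_filt.shape[0], 1)), np.asarray(x_filt, dtype=float)])
    return X @ np.asarray(L).T


# ---------------------------------------------------------------------------
# cross-validation and model selection


def blocked_cv_splits(T: int, k: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """k contiguous, disjoint, exhaustive test blocks (remainder in the last)."""
    if T < k:
        raise ValueError("T must be >= k")
    if k < 2:
        raise ValueError("k must be >= 2 (a single fold has an empty training set)")
    size = T // k
    splits = []
    for i in range(k):
        lo = i * size
        hi = (i + 1) * size if i < k - 1 else T
        test = np.arange(lo, hi)
        train = np.concatenate([np.arange(0, lo), np.arange(hi, T)])
        splits.append((train, test))
    return splits


def select_state_dim(
    fit_score_fn,
    T: int,
    candidates,
) -> int:
    """Pick the latent dimension with the best inner-split behavior prediction.

    ``fit_score_fn(n_x, train_idx, test_idx) -> float`` fits on the inner
    training set (first 80% of the data, contiguous) and scores on the inner
    test set (last 20%); the candidate with the highest score wins, ties
    going to the smallest dimension.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidates must be nonempty")
    split = int(round(0.8 * T))
    train_idx = np.arange(0, split)
    test_idx = np.arange(split, T)
    best = None
    errors = []
    for n_x in sorted(candidates):
        try:
            score = fit_score_fn(n_x, train_idx, test_idx)
        except Exception as exc:  # candidate may be infeasible (rank etc.)
            errors.append(f"n_x={n_x}: {exc}")
            continue
        if best is None or score > best[1] + 1e-12:
            best = (n_x, score)
    if best is None:
        raise RuntimeError("all candidate state dimensions failed: " + "; ".join(errors))
    return best[0]


# ---------------------------------------------------------------------------
# convenience: full identification report


def evaluate_identification(
    learned: CovParams, truth: CovParams, mode_info=None
) -> EvalReport:
    """Align and compute all normalized parameter and mode errors."""
    aligned = align_models(learned, truth)
    report = EvalReport()
    report.param_errors = {
        "eig_A": normalized_mode_error(aligned.A, truth.A),
        "C_z": normalized_error(aligned.C_z, truth.C_z) if truth.n_z else np.nan,
        "C_y": normalized_error(aligned.C_y, truth.C_y) if truth.n_y else np.nan,
        "G_z": normalized_error(aligned.G_z, truth.G_z) if truth.n_z else np.nan,
        "G_y": normalized_error(aligned.G_y, truth.G_y) if truth.n_y else np.nan,
        "Lambda0": normalized_error(aligned.Lambda0, truth.Lambda0),
        "d_z": normalized_error(aligned.d_z, truth.d_z) if truth.n_z else np.nan,
    }
    report.mode_error = normalized_mode_error(aligned.A, truth.A)
    if mode_info is not None:
        for mtype in ("shared", "spike-only", "field-only"):
            ev = mode_info.eigenvalues_of(mtype)
            if ev.size:
                report.mode_error_by_type[mtype] = normalized_mode_error(
                    aligned.A, truth.A, mode_subset=ev
                )
    return report
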