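"""Scikit-learn style estimator for multiscale subspace identification.

:class:`MultiscaleSID` learns a latent linear state-space model jointly
driving Poisson spike counts and Gaussian continuous features, using a
single pass of analytical (non-iterative) computations:

1. interpolate the slow continuous modality to full rate (training only),
2. empirical moments of the stacked future-past vectors,
3. moment transformation from count moments to latent log-rate moments,
4. SVD factorization of the future-past cross-covariance H_w,
5. shift-invariance least squares for A; slicing for C_z, C_y, G_z, G_y, d_z,
6. constrained convex optimization for valid PSD noise statistics Q, R_y.

The fitted model supports causal filtering and one-step-ahead prediction of
both modalities through the multiscale filter, which handles the multirate
missingness directly (no interpolation at inference time).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import moments as mom
from .identify import (
    estimate_A,
    extract_G,
    extract_dz,
    extract_observation_matrices,
    factorize_hankel,
)
from .inference import FilterOutput, msf_filter
from .noise_opt import finalize_model, solve_noise_statistics
from .simulate import MultimodalData

__all__ = ["MultiscaleSID"]


def _coerce_data(X, y=None) -> MultimodalData:
    if isinstance(X, MultimodalData):
        return X
    if isinstance(X, tuple) and len(X) in (2, 3):
        return _coerce_data(*X)
    N = np.atleast_2d(np.asarray(X))
    if N.size and (np.any(N < 0) or not np.allclose(N, np.round(N))):
        raise ValueError("count array must contain nonnegative integers")
    N = N.astype(np.int64)
    if y is None:
        yy = np.zeros((N.shape[0], 0))
        mask = np.ones(N.shape[0], dtype=bool)
    else:
        yy = np.atleast_2d(np.asarray(y, dtype=float))
        mask = np.all(np.isfinite(yy), axis=1)
    M = 1
    if y is not None and not mask.all():
        obs = np.flatnonzero(mask)
        steps = np.unique(np.diff(obs))
        if obs[0] != 0 or steps.size != 1:
            raise ValueError(
                "continuous-modality missingness is not a period-M pattern "
                "starting at the first bin; pass a MultimodalData instead"
            )
        M = int(steps[0])
    return MultimodalData(N=N, y=yy, mask=mask, M=M)


class MultiscaleSID(BaseEstimator):
    """Multiscale subspace identification of a joint spike/field model.

    Parameters
    ----------
    n_x : int
        Latent state dimension.
    h_z, h_y : int
        Past/future horizons (stacked lags) for the count and continuous
        modalities.  Identifiability requires roughly
        ``h > ceil(n_x / n_channels)`` per modality.
    interpolate : bool
        Fill period-M missing continuous bins by zero-phase FIR interpolation
        before computing moments.  Required when the data are multirate;
        inference never interpolates.
    zscore : bool
        z-score each continuous channel on the training data first.  The
        learned model then describes the standardized features.
    clip_eps : float
        Relative floor for log arguments in the moment transformation.
    interp_half_len, interp_kaiser_beta :
        Interpolation filter design (original-sample half-length, Kaiser
        window shape).
    sdp_max_iter : int
        Iteration cap for the constrained noise-statistics solve.

    Attributes
    ----------
    params_ : MultiscaleParams
        Noise-form parameter set {A, C_y, C_z, Q, R_y, d_z}.
    cov_params_ : CovParams
        Equivalent covariance-form set {A, C_z, C_y, G_z, G_y, Lambda0, d_z,
        Sigma_x} (finalized, exactly consistent with the structural zeros).
    A_, C_z_, C_y_, Q_, R_y_, d_z_, G_z_, G_y_, Lambda0_, Sigma_x_ : ndarray
        Convenience views of the fitted parameters.
    singular_values_ : ndarray
        Singular-value spectrum of the estimated H_w.
    diagnostics_ : dict
        Stagewise diagnostics: raw (pre-finalization) cost terms S, R_z,
        R_zy, R_y and the raw Lambda0/G estimates, SDP objective and status,
        moment clip fraction, spectral radius of A.
    """

    def __init__(
        self,
        n_x: int = 8,
        h_z: int = 10,
        h_y: int = 10,
        moment_estimator: str = "lag",
        balance_channels: bool = True,
        interpolate: bool = True,
        zscore: bool = False,
        clip_eps: float = mom.CLIP_EPS,
        interp_half_len: int = 4,
        interp_kaiser_beta: float = 5.0,
        sdp_max_iter: int = 400,
    ):
        self.n_x = n_x
        self.h_z = h_z
        self.h_y = h_y
        self.moment_estimator = moment_estimator
        self.balance_channels = balance_channels
        self.interpolate = interpolate
        self.zscore = zscore
        self.clip_eps = clip_eps
        self.interp_half_len = interp_half_len
        self.interp_kaiser_beta = interp_kaiser_beta
        self.sdp_max_iter = sdp_max_iter

    # ------------------------------------------------------------------ fit
    def fit(self, X, y=None):
        """Learn the model from multimodal training data.

        ``X`` may be a :class:`MultimodalData`, a ``(N, y)`` tuple, or the
        count array with the continuous array passed as ``y`` (NaN rows mark
        missing bins of the slow modality).
        """
        data = _coerce_data(X, y)
        if self.n_x < 1:
            raise ValueError("n_x must be >= 1")
        n_z, n_y = data.n_z, data.n_y
        if n_z + n_y < 1:
            raise ValueError("data must contain at least one channel")

        if self.moment_estimator not in ("lag", "stacked"):
            raise ValueError("moment_estimator must be 'lag' or 'stacked'")
        y_work = np.asarray(data.y, dtype=float)
        self.standardizer_ = None
        if n_y and self.zscore:
            y_work, _, self.standardizer_ = mom.standardize_continuous(y_work)

        if self.moment_estimator == "lag":
            # direct stationary lag-covariance estimation; no interpolation
            train = MultimodalData(
                N=data.N, y=y_work, mask=data.mask, M=data.M,
                bin_width_s=data.bin_width_s,
            )
            lm = mom.compute_lag_moments(train, self.h_z, self.h_y)
            tm = mom.assemble_hankel_from_lags(lm, self.clip_eps)
        else:
            if n_y and not data.mask.all():
                if not self.interpolate:
                    raise ValueError(
                        "stacked-moment training requires a full-rate "
                        "continuous modality; the data are multirate (M > 1), "
                        "so enable interpolation"
                    )
                y_work = mom.interpolate_continuous(
                    y_work, data.M, self.interp_half_len, self.interp_kaiser_beta
                )
            train = MultimodalData(
                N=data.N, y=y_work, mask=np.ones(data.T, dtype=bool), M=1,
                bin_width_s=data.bin_width_s,
            )
            em = mom.compute_empirical_moments(train, self.h_z, self.h_y)
            transformed = mom.transform_moments(em, self.clip_eps)
            tm = mom.assemble_hankel(em, transformed)

        # balance channel scales before the SVD so that the rank truncation is
        # not dominated by the larger-variance modality; the extracted factors
        # are unscaled afterwards, so the learned model is unaffected in
        # population (log rates and field features live on very different
        # scales, and an unbalanced truncation buries weak spike-side modes)
        H_w = tm.H_w
        diag0 = np.diag(tm.Lambda0).copy()
        scale = np.ones(n_z + n_y)
        if self.balance_channels:
            ok = diag0 > 0
            scale[ok] = 1.0 / np.sqrt(diag0[ok])
            row = np.concatenate(
                [np.tile(scale[:n_z], self.h_z), np.tile(scale[n_z:], self.h_y)]
            )
            H_w = H_w * row[:, None] * row[None, :]

        factors = factorize_hankel(
            H_w, self.n_x, self.h_z, self.h_y, n_z, n_y
        )
        C_z, C_y = extract_observation_matrices(factors)
        A = estimate_A(factors, M=tm.M)
        G_z_raw, G_y_raw = extract_G(factors, A, M=tm.M)
        if self.balance_channels:
            C_z = C_z / scale[:n_z, None]
            C_y = C_y / scale[n_z:, None]
            G_z_raw = G_z_raw / scale[None, :n_z]
            G_y_raw = G_y_raw / scale[None, n_z:]
        d_z = extract_dz(tm.mu_z, n_z)

        sdp = solve_noise_statistics(
            A, C_z, C_y, G_z_raw, G_y_raw, tm.Lambda0, max_iter=self.sdp_max_iter
        )
        nset, pset = finalize_model(sdp, A, C_z, C_y, d_z)
        nset.bin_width_s = data.bin_width_s

        self.params_ = nset
        self.cov_params_ = pset
        self.factors_ = factors
        self.moments_ = tm
        self.singular_values_ = factors.singular_values
        self.n_features_in_ = n_z + n_y
        rho = float(np.max(np.abs(np.linalg.eigvals(A))))
        self.diagnostics_ = {
            "S_raw": sdp.S,
            "R_z_raw": sdp.R_z,
            "R_zy_raw": sdp.R_zy,
            "R_y": sdp.R_y,
            "Lambda0_raw": tm.Lambda0,
            "G_raw": np.hstack([G_z_raw, G_y_raw]),
            "sdp_objective": sdp.objective,
            "sdp_status": sdp.status,
            "clip_fraction": tm.clip_fraction,
            "spectral_radius": rho,
            "unstable_A": rho >= 1.0,
            "n_samples": data.T,
        }
        return self

    # ------------------------------------------------------------ inference
    def _prepared(self, X, y=None) -> MultimodalData:
        check_is_fitted(self, "params_")
        data = _coerce_data(X, y)
        if self.standardizer_ is not None and data.n_y:
            yz = self.standardizer_.transform(data.y)
            data = MultimodalData(
                N=data.N, y=yz, mask=data.mask, M=data.M, bin_width_s=data.bin_width_s
            )
        return data

    def filter(self, X, y=None) -> FilterOutput:
        """Causal multiscale filtering; missing y bins get spike-only updates."""
        data = self._prepared(X, y)
        return msf_filter(self.params_, data)

    def predict(self, X, y=None) -> np.ndarray:
        """One-step-ahead prediction of the continuous features.

        Returns predictions on the training scale (inverting any z-scoring).
        """
        out = self.filter(X, y)
        y_pred = out.y_pred
        if self.standardizer_ is not None:
            y_pred = self.standardizer_.inverse_transform(y_pred)
        return y_pred

    def predict_event_proba(self, X, y=None) -> np.ndarray:
        """One-step-ahead probability of at least one spike per bin/channel."""
        return self.filter(X, y).p_event

    def score(self, X, y=None) -> float:
        """Mean one-step-ahead Pearson CC over observed continuous bins."""
        from .evaluate import prediction_cc

        data = _coerce_data(X, y)
        y_pred = self.predict(data)
        obs = data.mask
        return prediction_cc(data.y[obs], y_pred[obs])
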