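"""Core model containers, subspace projection, and likelihood evaluation.

The observation model for participant i at location s_v is

    y_i(s_v) = Σ_j x_ij α_j + Σ_j x_ij β_j(s_v) + η_i(s_v) + ε_i(s_v),

with global effects α_j, spatially varying effects β_j ~ GP(0, σ²_β K),
participant deviations η_i ~ GP(0, σ²_η K), and GP noise ε_i ~ GP(0, σ²_ε K).
After the Karhunen–Loève reparameterization (β_j = Ψ Λ^{1/2} θ_{βj}, etc.)
and projection of responses by Φ = Ψ Λ^{-1/2}, the model becomes an
L-dimensional regression with iid N(0, σ²_ε) errors:

    ỹ_i = (x_i^T α)·1_V^T Φ + x_i^T θ_β + θ_{ηi}^T Φη + ε̃_i.

Both inference engines work entirely in this projected space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain import SpatialDomain
from .kernel import LowRankBasis, ProjectionOperators

HALF_CAUCHY_SCALE = 100.0  # weakly informative prior scale A for all SDs


@dataclass
class RegressionDataset:
    """Participant-by-location responses with a design matrix.

    ``Y`` is N×V (image units); ``X`` is N×(J+1) whose first column is the
    all-ones intercept.  Missing values are rejected, not imputed.
    """

    Y: np.ndarray
    X: np.ndarray
    covariate_names: list[str]
    domain: SpatialDomain

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.Y.ndim != 2 or self.X.ndim != 2:
            raise ValueError("Y and X must be matrices")
        if self.Y.shape[0] != self.X.shape[0]:
            raise ValueError("Y and X disagree on the number of participants")
        if self.Y.shape[0] < 2:
            raise ValueError("need at least 2 participants")
        if self.Y.shape[1] != self.domain.n_locations:
            raise ValueError("Y columns must match the spatial domain")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the all-ones intercept")
        if not (np.all(np.isfinite(self.Y)) and np.all(np.isfinite(self.X))):
            raise ValueError("missing or non-finite values are not supported")
        if len(self.covariate_names) != self.X.shape[1]:
            raise ValueError("covariate_names must have J+1 entries")

    @property
    def n_participants(self) -> int:
        return self.Y.shape[0]

    @property
    def n_covariates(self) -> int:
        """J: number of covariates beyond the intercept."""
        return self.X.shape[1] - 1


@dataclass
class TransformedDataset:
    """Responses projected onto the L-dimensional basis subspace."""

    Y_tilde: np.ndarray
    ops: ProjectionOperators

    @property
    def n_participants(self) -> int:
        return self.Y_tilde.shape[0]

    @property
    def L(self) -> int:
        return self.Y_tilde.shape[1]


def project_responses(data: RegressionDataset, ops: ProjectionOperators) -> TransformedDataset:
    """Compute ỹ_i = y_i^T Φ for every participant."""
    if data.Y.shape[1] != ops.Phi.shape[0]:
        raise ValueError("response dimension does not match projection rows")
    return TransformedDataset(Y_tilde=data.Y @ ops.Phi, ops=ops)


@dataclass
class ParameterState:
    """One full set of model parameters (a Gibbs draw, or an initial point).

    Variances carry the half-Cauchy(A) prior through its inverse-gamma
    mixture: σ² ~ IG(1/2, 1/a), a ~ IG(1/2, 1/A²), with A = 100.
    """

    alpha: np.ndarray          # (J+1,)
    theta_beta: np.ndarray     # (J+1, L)
    theta_eta: np.ndarray      # (N, L_eta)
    sigma2_alpha: float
    sigma2_beta: float
    sigma2_eta: float
    sigma2_eps: float
    a_alpha: float
    a_beta: float
    a_eta: float
    a_eps: float
    A: float = HALF_CAUCHY_SCALE

    def __post_init__(self) -> None:
        for name in ("sigma2_alpha", "sigma2_beta", "sigma2_eta", "sigma2_eps",
                     "a_alpha", "a_beta", "a_eta", "a_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def copy(self) -> "ParameterState":
        return ParameterState(
            alpha=self.alpha.copy(),
            theta_beta=self.theta_beta.copy(),
            theta_eta=self.theta_eta.copy(),
            sigma2_alpha=self.sigma2_alpha,
            sigma2_beta=self.sigma2_beta,
            sigma2_eta=self.sigma2_eta,
            sigma2_eps=self.sigma2_eps,
            a_alpha=self.a_alpha,
            a_beta=self.a_beta,
            a_eta=self.a_eta,
            a_eps=self.a_eps,
            A=self.A,
        )


def predicted_projected(
    state: ParameterState, X: np.ndarray, ops: ProjectionOperators
) -> np.ndarray:
    """Model mean of Ỹ (N×L) under the projected model."""
    Xa = X @ state.alpha  # (N,)
    return (
        np.outer(Xa, ops.ones_proj)
        + X @ state.theta_beta
        + state.theta_eta @ ops.Phi_eta
    )


def conditional_loglik(
    state: ParameterState,
    tdata: TransformedDataset,
    X: np.ndarray,
    ops: ProjectionOperators,
) -> float:
    """Gaussian log-likelihood of the projected data given all parameters."""
    if state.sigma2_eps <= 0:
        raise ValueError("sigma2_eps must be positive")
    R = tdata.Y_tilde - predicted_projected(state, X, ops)
    n_terms = R.size
    ssr = float(np.sum(R * R))
    return -0.5 * (n_terms * np.log(2.0 * np.pi * state.sigma2_eps) + ssr / state.sigma2_eps)


def reconstruct_effect(
    alpha_j: float, theta_beta_j: np.ndarray, basis: LowRankBasis
) -> np.ndarray:
    """Voxel-level effect map α_j·1 + Ψ Λ^{1/2} θ_{βj}."""
    return alpha_j + basis.kl_map @ np.asarray(theta_beta_j, dtype=float)


def model_predict(
    state: ParameterState,
    X_new: np.ndarray,
    basis: LowRankBasis,
    include_eta: bool = False,
) -> np.ndarray:
    """Predicted images (rows of X_new × V) from a parameter set.

    The participant-deviation term is added only with ``include_eta`` for
    in-sample rows (X_new must then align with the fitted participants);
    out-of-sample participants get η = 0.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != state.alpha.size:
        raise ValueError("X_new has the wrong number of columns")
    pred = np.outer(X_new @ state.alpha, np.ones(basis.n_locations))
    pred += (X_new @ state.theta_beta) @ basis.kl_map.T
    if include_eta:
        if state.theta_eta.shape[0] != X_new.shape[0]:
            raise ValueError("include_eta requires one X_new row per fitted participant")
        pred += state.theta_eta @ basis.kl_map_eta.T
    return pred


# ---------------------------------------------------------------------------
# Identifiability recentering
#
# The likelihood is exactly invariant under (α_j, θ_{βj}) -> (α_j + δ,
# θ_{βj} − δ·w) with w = Λ^{-1/2} Ψ^T 1_V (= ones_proj), because the
# projected contribution of the pair cancels.  Choosing δ so the
# reconstructed β_j has exact zero voxel mean enforces Σ_v β_j(s_v) = 0
# without breaking conjugacy.  Likewise, subtracting the participant mean of
# θ_η and absorbing it into the spatial intercept θ_{β0} enforces
# Σ_i η_i(s_v) = 0 while leaving every fitted value unchanged.
# ---------------------------------------------------------------------------


def recenter_beta(state: ParameterState, ops: ProjectionOperators) -> None:
    """Move the voxel mean of each reconstructed β_j into α_j (in place)."""
    basis = ops.basis
    V = basis.n_locations
    w = ops.ones_proj  # = Λ^{-1/2} Ψ^T 1_V
    # voxel mean of β_j: (1^T Ψ Λ^{1/2} θ_j) / V;  note 1^T Ψ Λ^{1/2} = w·Λ
    ones_kl = w * basis.eigenvalues  # 1_V^T Ψ Λ^{1/2}
    means = state.theta_beta @ ones_kl / V
    denom = float(ones_kl @ w)  # 1^T Ψ Ψ^T 1
    if denom <= 0:
        return
    delta = means * V / denom
    state.alpha = state.alpha + delta
    state.theta_beta = state.theta_beta - np.outer(delta, w)


def recenter_eta(state: ParameterState, ops: ProjectionOperators) -> None:
    """Subtract the participant mean of θ_η, absorbing it into θ_{β0}."""
    mean_eta = state.theta_eta.mean(axis=0)
    state.theta_eta = state.theta_eta - mean_eta
    state.theta_beta = state.theta_beta.copy()
    state.theta_beta[0] += ops.Phi_eta.T @ mean_eta


def initialize_state(
    tdata: TransformedDataset,
    X: np.ndarray,
    ops: ProjectionOperators,
    variance_scale: float = 1.0,
    A: float = HALF_CAUCHY_SCALE,
) -> ParameterState:
    """Deterministic warm start shared by both inference engines.

    α comes from least squares of voxel-mean responses on X; θ_β from per-l
    ridge solutions; θ_η starts at zero; variances at method-of-moments
    residual estimates (optionally scaled to overdisperse chains);
    auxiliaries at A².
    """
    Yt = tdata.Y_tilde
    N, L = Yt.shape
    J1 = X.shape[1]
    V = ops.Phi.shape[0]
    # α: regress the voxel-mean image value on X
    y_mean = (Yt @ (ops.basis.kl_map.T @ np.ones(V))) / V  # mean over voxels per i
    alpha, *_ = np.linalg.lstsq(X, y_mean, rcond=None)
    resid0 = Yt - np.outer(X @ alpha, ops.ones_proj)
    XtX = X.T @ X
    theta_beta = np.linalg.solve(XtX + 0.1 * np.eye(J1), X.T @ resid0)
    resid = resid0 - X @ theta_beta
    s2 = max(float(np.var(resid)), 1e-6)
    state = ParameterState(
        alpha=alpha,
        theta_beta=theta_beta,
        theta_eta=np.zeros((N, ops.Phi_eta.shape[0])),
        sigma2_alpha=max(float(alpha @ alpha) / J1, 1e-2) * variance_scale,
        sigma2_beta=max(float(np.var(theta_beta)), 1e-2) * variance_scale,
        sigma2_eta=s2 * variance_scale,
        sigma2_eps=s2 * variance_scale,
        a_alpha=A**2,
        a_beta=A**2,
        a_eta=A**2,
        a_eps=A**2,
        A=A,
    )
    recenter_beta(state, ops)
    return state
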