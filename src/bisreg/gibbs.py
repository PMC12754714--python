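"""Conjugate Gibbs sampler for the projected model.

Every block has a closed-form full conditional: Gaussian for α, θ_β (per
basis index, with a shared (J+1)×(J+1) precision), and θ_η (per participant,
with a shared Lη×Lη precision); inverse-gamma for the four variances and the
four half-Cauchy auxiliaries.  Per-iteration cost is O(N·L·Lη + Lη³) after
the one-off projection, independent of V.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .kernel import ProjectionOperators
from .model import (
    ParameterState,
    TransformedDataset,
    conditional_loglik,
    initialize_state,
    predicted_projected,
    recenter_beta,
    recenter_eta,
)

_VAR_FLOOR = 1e-12
_CHAIN_DISPERSION = (0.5, 1.0, 2.0)  # cycled over chains to overdisperse inits


@dataclass
class GibbsConfig:
    n_chains: int = 3
    n_burn: int = 4000
    n_keep: int = 1000
    thin: int = 1
    seed: int = 0
    store_eta: bool = True
    rhat_threshold: float = 1.1


@dataclass
class PosteriorDraws:
    """Kept draws from one or more chains, aligned with a log-likelihood trace."""

    alpha: np.ndarray         # (chains, keep, J+1)
    theta_beta: np.ndarray    # (chains, keep, J+1, L)
    theta_eta: np.ndarray | None  # (chains, keep, N, L_eta) when stored
    variances: dict[str, np.ndarray]  # each (chains, keep)
    loglik: np.ndarray        # (chains, keep)
    n_burn: int
    n_keep: int
    seed: int
    ops: ProjectionOperators = field(repr=False)

    @property
    def n_chains(self) -> int:
        return self.alpha.shape[0]

    def flat(self, name: str) -> np.ndarray:
        """Draws with the chain axis folded into the draw axis."""
        arr = getattr(self, name)
        return arr.reshape((-1,) + arr.shape[2:])


# ---------------------------------------------------------------------------
# Block updates (each mutates ``state`` and returns the drawn block)
# ---------------------------------------------------------------------------


def _draw_mvn_from_precision(
    prec: np.ndarray, lin: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw x ~ N(prec^{-1} lin, prec^{-1}) columnwise via one Cholesky.

    ``lin`` may be a vector or a matrix whose columns are independent
    problems sharing the same precision.
    """
    try:
        C = linalg.cholesky(prec, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(f"singular full-conditional precision: {exc}") from exc
    mean = linalg.cho_solve((C, True), lin)
    z = rng.standard_normal(mean.shape)
    return mean + linalg.solve_triangular(C, z, lower=True, trans="T")


def update_alpha(
    state: ParameterState,
    tdata: TransformedDataset,
    X: np.ndarray,
    ops: ProjectionOperators,
    rng: np.random.Generator,
) -> np.ndarray:
    c = ops.ones_proj
    resid = tdata.Y_tilde - X @ state.theta_beta - state.theta_eta @ ops.Phi_eta
    prec = (float(c @ c) / state.sigma2_eps) * (X.T @ X) + np.eye(X.shape[1]) / state.sigma2_alpha
    lin = X.T @ (resid @ c) / state.sigma2_eps
    state.alpha = _draw_mvn_from_precision(prec, lin, rng)
    return state.alpha


def update_theta_beta(
    state: ParameterState,
    tdata: TransformedDataset,
    X: np.ndarray,
    ops: ProjectionOperators,
    rng: np.random.Generator,
    recenter: bool = True,
) -> np.ndarray:
    resid = (
        tdata.Y_tilde
        - np.outer(X @ state.alpha, ops.ones_proj)
        - state.theta_eta @ ops.Phi_eta
    )
    prec = (X.T @ X) / state.sigma2_eps + np.eye(X.shape[1]) / state.sigma2_beta
    lin = X.T @ resid / state.sigma2_eps  # (J+1, L): independent per column
    state.theta_beta = _draw_mvn_from_precision(prec, lin, rng)
    if recenter:
        recenter_beta(state, ops)
    return state.theta_beta


def update_theta_eta(
    state: ParameterState,
    tdata: TransformedDataset,
    X: np.ndarray,
    ops: ProjectionOperators,
    rng: np.random.Generator,
    recenter: bool = True,
) -> np.ndarray:
    resid = (
        tdata.Y_tilde
        - np.outer(X @ state.alpha, ops.ones_proj)
        - X @ state.theta_beta
    )
    Phi_eta = ops.Phi_eta
    prec = (Phi_eta @ Phi_eta.T) / state.sigma2_eps + np.eye(Phi_eta.shape[0]) / state.sigma2_eta
    lin = Phi_eta @ resid.T / state.sigma2_eps  # (L_eta, N): independent per column
    state.theta_eta = _draw_mvn_from_precision(prec, lin, rng).T
    if recenter:
        recenter_eta(state, ops)
    return state.theta_eta


def _draw_inverse_gamma(
    shape: float, rate: float, rng: np.random.Generator
) -> float:
    return max(float(rate / rng.gamma(shape)), _VAR_FLOOR)


def update_variances(
    state: ParameterState,
    tdata: TransformedDataset,
    X: np.ndarray,
    ops: ProjectionOperators,
    rng: np.random.Generator,
) -> tuple[float, float, float, float]:
    """Inverse-gamma full conditionals: IG(1/2 + m/2, 1/a + Σ(terms²)/2)."""
    state.sigma2_alpha = _draw_inverse_gamma(
        0.5 + state.alpha.size / 2.0,
        1.0 / state.a_alpha + float(state.alpha @ state.alpha) / 2.0,
        rng,
    )
    state.sigma2_beta = _draw_inverse_gamma(
        0.5 + state.theta_beta.size / 2.0,
        1.0 / state.a_beta + float(np.sum(state.theta_beta**2)) / 2.0,
        rng,
    )
    state.sigma2_eta = _draw_inverse_gamma(
        0.5 + state.theta_eta.size / 2.0,
        1.0 / state.a_eta + float(np.sum(state.theta_eta**2)) / 2.0,
        rng,
    )
    R = tdata.Y_tilde - predicted_projected(state, X, ops)
    state.sigma2_eps = _draw_inverse_gamma(
        0.5 + R.size / 2.0,
        1.0 / state.a_eps + float(np.sum(R * R)) / 2.0,
        rng,
    )
    return (state.sigma2_alpha, state.sigma2_beta, state.sigma2_eta, state.sigma2_eps)


def update_auxiliaries(
    state: ParameterState, rng: np.random.Generator
) -> tuple[float, float, float, float]:
    """a | σ² ~ IG(1, 1/A² + 1/σ²) for each variance's auxiliary."""
    inv_A2 = 1.0 / state.A**2
    state.a_alpha = _draw_inverse_gamma(1.0, inv_A2 + 1.0 / state.sigma2_alpha, rng)
    state.a_beta = _draw_inverse_gamma(1.0, inv_A2 + 1.0 / state.sigma2_beta, rng)
    state.a_eta = _draw_inverse_gamma(1.0, inv_A2 + 1.0 / state.sigma2_eta, rng)
    state.a_eps = _draw_inverse_gamma(1.0, inv_A2 + 1.0 / state.sigma2_eps, rng)
    return (state.a_alpha, state.a_beta, state.a_eta, state.a_eps)


def gibbs_iteration(
    state: ParameterState,
    tdata: TransformedDataset,
    X: np.ndarray,
    ops: ProjectionOperators,
    rng: np.random.Generator,
) -> None:
    """One full update cycle: α → θ_β → θ_η → variances → auxiliaries."""
    update_alpha(state, tdata, X, ops, rng)
    update_theta_beta(state, tdata, X, ops, rng)
    update_theta_eta(state, tdata, X, ops, rng)
    # the η recentering shifts θ_β0, so restore the zero-mean-β convention
    recenter_beta(state, ops)
    update_variances(state, tdata, X, ops, rng)
    update_auxiliaries(state, rng)


def run_gibbs(
    tdata: TransformedDataset,
    X: np.ndarray,
    ops: ProjectionOperators,
    config: GibbsConfig,
) -> PosteriorDraws:
    """Run the full sampler for ``config.n_chains`` chains.

    Chains share the deterministic warm start but overdisperse their initial
    variances by chain-indexed factors, and use independent seeded streams.
    """
    N, L = tdata.Y_tilde.shape
    J1 = X.shape[1]
    L_eta = ops.Phi_eta.shape[0]
    C, K = config.n_chains, config.n_keep
    alpha_d = np.empty((C, K, J1))
    tb_d = np.empty((C, K, J1, L))
    te_d = np.empty((C, K, N, L_eta)) if config.store_eta else None
    var_d = {k: np.empty((C, K)) for k in ("sigma2_alpha", "sigma2_beta", "sigma2_eta", "sigma2_eps")}
    ll_d = np.empty((C, K))
    for chain in range(C):
        rng = np.random.default_rng([config.seed, chain])
        scale = _CHAIN_DISPERSION[chain % len(_CHAIN_DISPERSION)]
        state = initialize_state(tdata, X, ops, variance_scale=scale)
        kept = 0
        it = 0
        total = config.n_burn + config.n_keep * config.thin
        while kept < K:
            gibbs_iteration(state, tdata, X, ops, rng)
            it += 1
            if it > config.n_burn and (it - config.n_burn) % config.thin == 0:
                alpha_d[chain, kept] = state.alpha
                tb_d[chain, kept] = state.theta_beta
                if te_d is not None:
                    te_d[chain, kept] = state.theta_eta
                for k in var_d:
                    var_d[k][chain, kept] = getattr(state, k)
                ll_d[chain, kept] = conditional_loglik(state, tdata, X, ops)
                kept += 1
            if it > total:  # pragma: no cover - defensive
                raise RuntimeError("iteration bookkeeping error")
    return PosteriorDraws(
        alpha=alpha_d,
        theta_beta=tb_d,
        theta_eta=te_d,
        variances=var_d,
        loglik=ll_d,
        n_burn=config.n_burn,
        n_keep=K,
        seed=config.seed,
        ops=ops,
    )


def gelman_rubin(traces: np.ndarray) -> float:
    """Potential scale reduction factor R̂ from per-chain scalar traces.

    Standard between/within formulation: with C chains of length K,
    W = mean within-chain variance, B = K·Var(chain means),
    R̂ = sqrt(((K−1)/K·W + B/K) / W).
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    C, K = traces.shape
    if K < 10:
        raise ValueError("chains too short for a meaningful diagnostic")
    W = float(np.mean(np.var(traces, axis=1, ddof=1)))
    if W == 0.0:
        warnings.warn("zero within-chain variance; R-hat undefined")
        return float("inf")
    B = K * float(np.var(np.mean(traces, axis=1), ddof=1))
    var_plus = (K - 1) / K * W + B / K
    return float(np.sqrt(var_plus / W))
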