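"""Posterior summaries: effect maps, evidence measures, activation, PPCs.

The reported quantity per covariate j and location v is the combined
voxel-level effect α_j + β_j(s_v).  Evidence of activation is expressed on
a common [−1, 1] scale: for Bayesian fits Es = 2(P+ − 0.5) with
P+ = Pr(effect > 0 | data); for frequentist baselines Es = ±(1 − p) from
adjusted p-values, signed by the effect direction.  A location counts as
active when |Es| exceeds a threshold (default 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .gibbs import PosteriorDraws
from .kernel import LowRankBasis
from .model import ParameterState
from .vi import VariationalPosterior

_MIN_DRAWS = 50


@dataclass
class EffectSummary:
    """Per-covariate voxel maps; every array is (J+1, V)."""

    mean: np.ndarray
    sd: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    p_plus: np.ndarray
    es: np.ndarray
    active: np.ndarray
    level: float
    covariate_names: list[str] | None = field(default=None)

    @property
    def n_covariates(self) -> int:
        return self.mean.shape[0]


def _draws_effect_matrix(draws: PosteriorDraws, basis: LowRankBasis, j: int, include_global: bool) -> np.ndarray:
    theta = draws.flat("theta_beta")[:, j, :]  # (n_draws, L)
    eff = theta @ basis.kl_map.T
    if include_global:
        eff += draws.flat("alpha")[:, j][:, None]
    return eff


def summarize_effects(
    posterior: PosteriorDraws | VariationalPosterior,
    basis: LowRankBasis,
    level: float = 0.05,
    include_global: bool = True,
    es_threshold: float = 0.95,
    mode: str = "two-sided",
) -> EffectSummary:
    """Summarize the posterior of every voxel-level effect map.

    Sampled posteriors use empirical quantiles and sign frequencies;
    variational posteriors use their Gaussian marginals in closed form.
    """
    V = basis.n_locations
    if isinstance(posterior, PosteriorDraws):
        n_draws = posterior.alpha.shape[0] * posterior.alpha.shape[1]
        if n_draws < _MIN_DRAWS:
            raise ValueError(f"need at least {_MIN_DRAWS} draws, have {n_draws}")
        J1 = posterior.alpha.shape[2]
        mean = np.empty((J1, V))
        sd = np.empty((J1, V))
        lower = np.empty((J1, V))
        upper = np.empty((J1, V))
        p_plus = np.empty((J1, V))
        for j in range(J1):
            eff = _draws_effect_matrix(posterior, basis, j, include_global)
            mean[j] = eff.mean(axis=0)
            sd[j] = eff.std(axis=0, ddof=1)
            lower[j] = np.quantile(eff, level / 2, axis=0)
            upper[j] = np.quantile(eff, 1 - level / 2, axis=0)
            # ties at exactly zero count half, so a null effect gets P+ = 1/2
            p_plus[j] = np.mean(eff > 0, axis=0) + 0.5 * np.mean(eff == 0, axis=0)
    elif isinstance(posterior, VariationalPosterior):
        J1 = posterior.alpha_mean.size
        mean = np.empty((J1, V))
        sd = np.empty((J1, V))
        p_plus = np.empty((J1, V))
        z = stats.norm.ppf(1 - level / 2)
        for j in range(J1):
            mean[j] = posterior.effect_mean(basis, j, include_global)
            sd[j] = np.sqrt(posterior.effect_var(basis, j, include_global))
            with np.errstate(divide="ignore", invalid="ignore"):
                point = 0.5 * (np.sign(mean[j]) + 1.0)  # degenerate marginal
                p_plus[j] = np.where(sd[j] > 0, stats.norm.cdf(mean[j] / sd[j]), point)
        lower = mean - z * sd
        upper = mean + z * sd
    else:
        raise TypeError(f"unsupported posterior object: {type(posterior)!r}")
    es = 2.0 * (p_plus - 0.5)
    summary = EffectSummary(
        mean=mean, sd=sd, lower=lower, upper=upper, p_plus=p_plus, es=es,
        active=np.zeros_like(es, dtype=bool), level=level,
    )
    summary.active = threshold_active(summary, threshold=es_threshold, mode=mode)
    return summary


def evidence_from_pvalue(p, sign):
    """Es = ±(1 − p): adjusted p-values mapped onto the evidence scale.

    ``sign`` is +1/−1 (or an array of signs from the estimated effects).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    s = np.sign(np.asarray(sign, dtype=float))
    s = np.where(s == 0, 1.0, s)
    out = s * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def threshold_active(
    summary: EffectSummary, threshold: float = 0.95, mode: str = "two-sided"
) -> np.ndarray:
    """Boolean activation mask per covariate from the Es maps."""
    if mode == "two-sided":
        return np.abs(summary.es) > threshold
    if mode == "positive-only":
        return summary.es > threshold
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class PPCResult:
    """Pooled-density posterior predictive check on a shared grid."""

    grid: np.ndarray
    observed_density: np.ndarray | None
    replicate_densities: np.ndarray  # (n_rep, grid size)
    replicates: np.ndarray | None = None


def _kde_on_grid(values: np.ndarray, grid: np.ndarray, rng: np.random.Generator, cap: int = 5000) -> np.ndarray:
    flat = np.ravel(values)
    if flat.size > cap:
        flat = rng.choice(flat, size=cap, replace=False)
    if np.std(flat) < 1e-12:  # degenerate: all mass at one value
        edges = np.concatenate([grid, [2 * grid[-1] - grid[-2]]])
        dens, _ = np.histogram(flat, bins=edges, density=True)
        return dens
    return stats.gaussian_kde(flat, bw_method="silverman")(grid)


def _sample_state(posterior, rng: np.random.Generator, n_participants: int, L_eta: int) -> ParameterState:
    if isinstance(posterior, PosteriorDraws):
        n = posterior.alpha.shape[0] * posterior.alpha.shape[1]
        k = int(rng.integers(n))
        alpha = posterior.flat("alpha")[k]
        theta_beta = posterior.flat("theta_beta")[k]
        s2 = {name: float(posterior.variances[name].reshape(-1)[k]) for name in posterior.variances}
        if posterior.theta_eta is not None:
            theta_eta = posterior.flat("theta_eta")[k]
        else:
            theta_eta = rng.standard_normal((n_participants, L_eta)) * np.sqrt(s2["sigma2_eta"])
        return ParameterState(
            alpha=alpha, theta_beta=theta_beta, theta_eta=theta_eta,
            sigma2_alpha=s2["sigma2_alpha"], sigma2_beta=s2["sigma2_beta"],
            sigma2_eta=s2["sigma2_eta"], sigma2_eps=s2["sigma2_eps"],
            a_alpha=1.0, a_beta=1.0, a_eta=1.0, a_eps=1.0,
        )
    if isinstance(posterior, VariationalPosterior):
        J1 = posterior.alpha_mean.size
        La = posterior.theta_beta_mean.shape[1]
        chol_a = np.linalg.cholesky(posterior.alpha_cov)
        alpha = posterior.alpha_mean + chol_a @ rng.standard_normal(J1)
        chol_b = np.linalg.cholesky(posterior.theta_beta_cov)
        theta_beta = posterior.theta_beta_mean + chol_b @ rng.standard_normal((J1, La))
        chol_e = np.linalg.cholesky(posterior.theta_eta_cov)
        theta_eta = posterior.theta_eta_mean + (chol_e @ rng.standard_normal((L_eta, n_participants))).T
        def ig_draw(name):
            s, r = posterior.ig_sigma2[name]
            return max(float(r / rng.gamma(s)), 1e-12)
        return ParameterState(
            alpha=alpha, theta_beta=theta_beta, theta_eta=theta_eta,
            sigma2_alpha=ig_draw("alpha"), sigma2_beta=ig_draw("beta"),
            sigma2_eta=ig_draw("eta"), sigma2_eps=ig_draw("eps"),
            a_alpha=1.0, a_beta=1.0, a_eta=1.0, a_eps=1.0,
        )
    raise TypeError(f"unsupported posterior object: {type(posterior)!r}")


def posterior_predictive_draws(
    posterior: PosteriorDraws | VariationalPosterior,
    X: np.ndarray,
    basis: LowRankBasis,
    n_rep: int,
    rng: np.random.Generator,
    observed: np.ndarray | None = None,
    grid_size: int = 512,
    return_replicates: bool = False,
) -> PPCResult:
    """Replicate datasets from the fitted model and pooled density overlays.

    Each replicate samples one parameter set from the posterior and
    generates y_rep from the observation model, with the participant
    deviations taken from their posterior and the GP noise drawn through
    the low-rank kernel representation.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = X.shape[0]
    L = basis.L
    B = basis.kl_map
    reps = []
    for _ in range(n_rep):
        state = _sample_state(posterior, rng, N, basis.L_eta)
        signal = np.outer(X @ state.alpha, np.ones(basis.n_locations))
        signal += (X @ state.theta_beta) @ B.T
        signal += state.theta_eta @ basis.kl_map_eta.T
        noise = (rng.standard_normal((N, L)) * np.sqrt(state.sigma2_eps)) @ B.T
        reps.append(signal + noise)
    pooled = np.concatenate([r.ravel() for r in reps])
    if observed is not None:
        pooled = np.concatenate([pooled, np.ravel(observed)])
    lo, hi = pooled.min(), pooled.max()
    pad = 0.05 * (hi - lo + 1e-12)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    dens = np.stack([_kde_on_grid(r, grid, rng) for r in reps])
    obs_dens = _kde_on_grid(observed, grid, rng) if observed is not None else None
    return PPCResult(
        grid=grid,
        observed_density=obs_dens,
        replicate_densities=dens,
        replicates=np.stack(reps) if return_replicates else None,
    )
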