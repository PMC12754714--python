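"""Comparison methods and the simulation evaluation harness.

Two baselines bracket the spatial model: a massive-univariate GLM (ordinary
least squares independently at each location, Benjamini–Hochberg adjusted)
and a voxelwise Bayesian multilevel model (BML) that pools information
hierarchically but has no spatial correlation in its priors and a scalar
per-participant deviation.  The harness replicates the four study scenarios
{N ∈ {50, 200}} × {σ_ε ∈ {2, 5}} and scores every method on MSE, TPR, FDR
and interval coverage against the generator truth.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

from .kernel import KernelSpec, LowRankBasis, build_projections
from .model import RegressionDataset, project_responses
from .simulate import SCENARIOS, SimulationTruth, make_truth, simulate_dataset
from .summary import evidence_from_pvalue, summarize_effects
from .vi import CaviConfig, run_cavi

logger = logging.getLogger(__name__)

_VAR_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Massive-univariate GLM
# ---------------------------------------------------------------------------


@dataclass
class GLMResult:
    coef: np.ndarray       # (J+1, V)
    se: np.ndarray
    pvalues: np.ndarray    # two-sided, unadjusted
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    df_resid: int


def glm_fit(data: RegressionDataset, level: float = 0.05) -> GLMResult:
    """Vectorized per-voxel OLS with t-based two-sided inference."""
    X, Y = data.X, data.Y
    N, J1 = X.shape
    if N <= J1:
        raise ValueError("need more participants than design columns")
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < J1:
        raise ValueError("rank-deficient design matrix")
    XtX_inv = linalg.inv(XtX)
    coef = XtX_inv @ (X.T @ Y)  # (J+1, V)
    resid = Y - X @ coef
    df = N - J1
    s2 = np.sum(resid**2, axis=0) / df  # (V,)
    se = np.sqrt(np.outer(np.diag(XtX_inv), s2))
    with np.errstate(divide="ignore", invalid="ignore"):
        # exact fits (se = 0): infinite evidence for nonzero coefficients
        tvals = np.where(se > 0, coef / se, np.where(coef == 0, 0.0, np.inf))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    tcrit = stats.t.ppf(1 - level / 2, df)
    return GLMResult(
        coef=coef,
        se=se,
        pvalues=pvals,
        ci_lower=coef - tcrit * se,
        ci_upper=coef + tcrit * se,
        df_resid=df,
    )


def bh_adjust(pvalues: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (monotone adjusted p-values, rejections)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    reject, p_adj, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return p_adj.reshape(p.shape), reject.reshape(p.shape)


# ---------------------------------------------------------------------------
# Voxelwise Bayesian multilevel model (no spatial prior)
# ---------------------------------------------------------------------------


@dataclass
class BMLConfig:
    n_chains: int = 3
    n_burn: int = 4000
    n_keep: int = 1000
    seed: int = 0
    A: float = 100.0


@dataclass
class BMLResult:
    """Posterior draws of the voxel effects α_j + β_j(s_v)."""

    effect_draws: np.ndarray  # (total kept draws, J+1, V)
    config: BMLConfig = field(repr=False)


def _ig_draw(shape: float, rate: float, rng: np.random.Generator) -> float:
    return max(float(rate / rng.gamma(shape)), _VAR_FLOOR)


def bml_fit(
    data: RegressionDataset,
    config: BMLConfig | None = None,
    fix_sigma2_beta: float | None = None,
) -> BMLResult:
    """Conjugate Gibbs for the voxelwise multilevel model.

    y_i(s_v) = x_i^T α + x_i^T β(s_v) + η_i + ε_i(s_v), with β_j(s_v) iid
    N(0, σ²_{βj}) across voxels (one variance per covariate), scalar
    η_i ~ N(0, σ²_η), iid noise, and the same half-Cauchy/inverse-gamma
    hierarchy on all standard deviations as the spatial model.

    ``fix_sigma2_beta`` pins the β variances (skipping their update); the
    σ²_β → ∞ limit reproduces per-voxel OLS (no pooling), the → 0 limit
    collapses every voxel effect onto the global α (complete pooling).
    """
    config = config or BMLConfig()
    X, Y = data.X, data.Y
    N, J1 = X.shape
    V = data.Y.shape[1]
    XtX = X.T @ X
    total_keep = config.n_chains * config.n_keep
    effect_draws = np.empty((total_keep, J1, V))
    k_out = 0
    for chain in range(config.n_chains):
        rng = np.random.default_rng([config.seed, chain])
        # warm start from OLS
        coef = linalg.lstsq(X, Y)[0]
        alpha = coef.mean(axis=1)
        beta = coef - alpha[:, None]
        eta = np.zeros(N)
        resid = Y - X @ coef
        s2_eps = max(float(np.var(resid)), 1e-6) * (0.5, 1.0, 2.0)[chain % 3]
        s2_alpha = max(float(alpha @ alpha) / J1, 1e-2)
        s2_beta = np.maximum(np.var(beta, axis=1), 1e-4)
        if fix_sigma2_beta is not None:
            s2_beta = np.full(J1, float(fix_sigma2_beta))
        s2_eta = s2_eps
        A2 = config.A**2
        a_alpha = a_eta = a_eps = A2
        a_beta = np.full(J1, A2)
        for it in range(config.n_burn + config.n_keep):
            # β_v | rest — shared (J+1)×(J+1) precision across voxels
            r = Y - (X @ alpha)[:, None] - eta[:, None]
            prec = XtX / s2_eps + np.diag(1.0 / s2_beta)
            C = linalg.cholesky(prec, lower=True)
            mean = linalg.cho_solve((C, True), X.T @ r / s2_eps)
            beta = mean + linalg.solve_triangular(
                C, rng.standard_normal((J1, V)), lower=True, trans="T"
            )
            # recenter: voxel mean of each β_j moves into α_j
            m = beta.mean(axis=1)
            beta -= m[:, None]
            alpha = alpha + m
            # α | rest
            r = Y - X @ beta - eta[:, None]
            prec_a = V * XtX / s2_eps + np.eye(J1) / s2_alpha
            Ca = linalg.cholesky(prec_a, lower=True)
            mean_a = linalg.cho_solve((Ca, True), X.T @ r.sum(axis=1) / s2_eps)
            alpha = mean_a + linalg.solve_triangular(
                Ca, rng.standard_normal(J1), lower=True, trans="T"
            )
            # η_i | rest — scalar per participant
            r = Y - (X @ alpha)[:, None] - X @ beta
            prec_e = V / s2_eps + 1.0 / s2_eta
            mean_e = r.sum(axis=1) / s2_eps / prec_e
            eta = mean_e + rng.standard_normal(N) / np.sqrt(prec_e)
            me = eta.mean()
            eta -= me
            alpha[0] += me
            # variances + auxiliaries
            s2_alpha = _ig_draw(0.5 + J1 / 2, 1 / a_alpha + float(alpha @ alpha) / 2, rng)
            if fix_sigma2_beta is None:
                for j in range(J1):
                    s2_beta[j] = _ig_draw(
                        0.5 + V / 2, 1 / a_beta[j] + float(beta[j] @ beta[j]) / 2, rng
                    )
            s2_eta = _ig_draw(0.5 + N / 2, 1 / a_eta + float(eta @ eta) / 2, rng)
            r = Y - (X @ alpha)[:, None] - X @ beta - eta[:, None]
            s2_eps = _ig_draw(0.5 + r.size / 2, 1 / a_eps + float(np.sum(r * r)) / 2, rng)
            a_alpha = _ig_draw(1.0, 1 / A2 + 1 / s2_alpha, rng)
            for j in range(J1):
                a_beta[j] = _ig_draw(1.0, 1 / A2 + 1 / s2_beta[j], rng)
            a_eta = _ig_draw(1.0, 1 / A2 + 1 / s2_eta, rng)
            a_eps = _ig_draw(1.0, 1 / A2 + 1 / s2_eps, rng)
            if it >= config.n_burn:
                effect_draws[k_out] = alpha[:, None] + beta
                k_out += 1
    return BMLResult(effect_draws=effect_draws, config=config)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def compute_metrics(
    true_effects: np.ndarray,
    estimate: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    es: np.ndarray,
    active_truth: np.ndarray,
    es_threshold: float = 0.95,
) -> dict[str, float]:
    """MSE / TPR / FDR / coverage for one replicate of one method.

    All inputs are (J+1, V) maps; metrics pool covariates and locations.
    FDR uses the max(TP+FP, 1) guard so that no declarations give FDR 0.
    """
    true_effects = np.asarray(true_effects, dtype=float)
    if not (estimate.shape == true_effects.shape == es.shape == active_truth.shape):
        raise ValueError("map shapes disagree")
    declared = np.abs(es) > es_threshold
    tp = int(np.sum(declared & active_truth))
    fp = int(np.sum(declared & ~active_truth))
    fn = int(np.sum(~declared & active_truth))
    return {
        "mse": float(np.mean((estimate - true_effects) ** 2)),
        "tpr": tp / max(tp + fn, 1),
        "fdr": fp / max(tp + fp, 1),
        "coverage": float(np.mean((lower <= true_effects) & (true_effects <= upper))),
    }


METRIC_NAMES = ("mse", "tpr", "fdr", "coverage")


@dataclass
class MetricsReport:
    """Per method × scenario metric means and SDs over replicates."""

    table: pd.DataFrame  # index (scenario, method); columns metric_mean/metric_sd
    n_reps: int
    exclusions: dict[tuple[str, str], int]
    runtime_seconds: float

    def to_frame(self, mse_scale: float = 1.0) -> pd.DataFrame:
        out = self.table.copy()
        out["mse_mean"] *= mse_scale
        out["mse_sd"] *= mse_scale
        return out


def _glm_maps(data: RegressionDataset):
    res = glm_fit(data)
    es = np.empty_like(res.coef)
    for j in range(res.coef.shape[0]):
        p_adj, _ = bh_adjust(res.pvalues[j])
        es[j] = evidence_from_pvalue(p_adj, np.sign(res.coef[j]))
    return res.coef, res.ci_lower, res.ci_upper, es


def _bml_maps(data: RegressionDataset, config: BMLConfig):
    res = bml_fit(data, config)
    d = res.effect_draws
    mean = d.mean(axis=0)
    lower = np.quantile(d, 0.025, axis=0)
    upper = np.quantile(d, 0.975, axis=0)
    p_plus = np.mean(d > 0, axis=0)
    return mean, lower, upper, 2 * (p_plus - 0.5)


def _simba_maps(data: RegressionDataset, basis: LowRankBasis, engine: str, seed: int,
                gibbs_config=None):
    ops = build_projections(basis)
    tdata = project_responses(data, ops)
    if engine == "vi":
        post = run_cavi(tdata, data.X, ops, CaviConfig(max_iter=300, rel_tol=1e-7))
    else:
        from .gibbs import GibbsConfig, run_gibbs

        post = run_gibbs(
            tdata, data.X, ops,
            gibbs_config or GibbsConfig(n_chains=1, n_burn=500, n_keep=500, seed=seed),
        )
    s = summarize_effects(post, basis, include_global=True)
    return s.mean, s.lower, s.upper, s.es


def run_simulation_study(
    scenarios: list[str] | None = None,
    n_reps: int = 20,
    methods: tuple[str, ...] = ("glm", "bml", "vi"),
    seed: int = 0,
    target_voxels: int = 5000,
    L: int | None = None,
    bml_config: BMLConfig | None = None,
    length_scale: float = 0.3,
) -> MetricsReport:
    """Replicate the study scenarios and score every requested method.

    The ground truth of each scenario is fixed (mask, effect regions,
    calibrated amplitudes); replicates differ only by randomization seed.
    A spatial-model basis is built once per scenario and reused; ``L=None``
    selects the rank by the cumulative-variance window + LOOCV grid search
    on the scenario's first replicate.  Failed method fits are logged and
    excluded.
    """
    scenarios = scenarios or list(SCENARIOS)
    rows = []
    exclusions: dict[tuple[str, str], int] = {}
    t0 = time.perf_counter()
    for s_idx, name in enumerate(scenarios):
        cfg = SCENARIOS[name]
        truth = make_truth(
            target_voxels=target_voxels,
            sigma_eps=cfg["sigma_eps"],
            snr=cfg["snr"],
            length_scale=length_scale,
            seed=seed,
        )
        truth_maps = truth.alpha_true[:, None] + truth.beta_maps
        basis = None
        if any(m in methods for m in ("vi", "gibbs")):
            spec = KernelSpec(length_scale=length_scale)
            if L is not None:
                L_scen = L
            else:
                from .selection import choose_L

                sel_data = simulate_dataset(
                    truth, N=cfg["N"],
                    seed=int(np.random.default_rng([seed, s_idx, 9999]).integers(2**31)),
                )
                sel = choose_L(
                    sel_data, truth.domain, spec,
                    L_max=min(truth.domain.n_locations, 2000),
                    grid_size=3, engine="vi", seed=seed,
                    max_folds=min(cfg["N"], 8),
                )
                L_scen = sel.selected_L
                logger.info("scenario %s: selected L = %d", name, L_scen)
            basis = LowRankBasis.build(truth.domain, spec, L=L_scen, seed=seed)
        for rep in range(n_reps):
            rep_seed = int(np.random.default_rng([seed, s_idx, rep]).integers(2**31))
            data = simulate_dataset(truth, N=cfg["N"], seed=rep_seed)
            for method in methods:
                try:
                    if method == "glm":
                        maps = _glm_maps(data)
                    elif method == "bml":
                        maps = _bml_maps(
                            data,
                            bml_config
                            or BMLConfig(n_chains=1, n_burn=300, n_keep=300, seed=rep_seed),
                        )
                    elif method in ("vi", "gibbs"):
                        maps = _simba_maps(data, basis, method, rep_seed)
                    else:
                        raise ValueError(f"unknown method {method!r}")
                except Exception as exc:  # noqa: BLE001 - replicate-level robustness
                    warnings.warn(f"{method} failed on {name} rep {rep}: {exc}")
                    exclusions[(name, method)] = exclusions.get((name, method), 0) + 1
                    continue
                m = compute_metrics(truth_maps, *maps, truth.active_masks)
                m.update(scenario=name, method=method, rep=rep)
                rows.append(m)
    df = pd.DataFrame(rows)
    agg = df.groupby(["scenario", "method"])[list(METRIC_NAMES)].agg(["mean", "std"])
    agg.columns = [f"{a}_{'sd' if b == 'std' else b}" for a, b in agg.columns]
    return MetricsReport(
        table=agg,
        n_reps=n_reps,
        exclusions=exclusions,
        runtime_seconds=time.perf_counter() - t0,
    )
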