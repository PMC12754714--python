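"""Choosing the number of basis functions L.

Likelihoods are not comparable across different L (each L defines a
different projected data space), so information criteria are deliberately
not offered.  Instead: decompose once at an upper bound Lmax, keep the
candidate window where the eigenvalue spectrum explains 80–98% of total
variance, and grid-search that window by leave-one-participant-out
predictive mean squared error (PMSE).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .domain import SpatialDomain
from .kernel import KernelSpec, LowRankBasis, build_projections, select_inducing_points, nystrom_decompose
from .model import RegressionDataset, model_predict, project_responses
from .vi import CaviConfig, run_cavi

logger = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    L_max: int
    eigenvalues: np.ndarray
    candidates: list[int]
    pmse: list[float]
    pmse_per_participant: list[np.ndarray]
    selected_L: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"L": self.candidates, "pmse": self.pmse})


def candidate_L_range(
    eigenvalues: np.ndarray, lo: float = 0.80, hi: float = 0.98
) -> tuple[int, int]:
    """Smallest L reaching each cumulative-variance fraction of the spectrum."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.size == 0:
        raise ValueError("empty eigenvalue spectrum")
    if np.any(lam <= 0) or np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be positive and sorted nonincreasing")
    frac = np.cumsum(lam) / lam.sum()
    L_lo = int(np.searchsorted(frac, lo) + 1)
    L_hi = int(np.searchsorted(frac, hi) + 1)
    return L_lo, L_hi


def _build_basis(
    domain: SpatialDomain, spec: KernelSpec, L: int, seed: int
) -> LowRankBasis:
    return LowRankBasis.build(domain, spec, L=L, seed=seed)


def loocv_pmse(
    data: RegressionDataset,
    domain: SpatialDomain,
    spec: KernelSpec,
    L: int,
    engine: str = "vi",
    seed: int = 0,
    max_folds: int | None = None,
    basis: LowRankBasis | None = None,
    cavi_config: CaviConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Leave-one-participant-out predictive MSE at a candidate L.

    The basis depends only on coordinates, so it is built once and reused
    across folds.  Each fold fits on N−1 participants and predicts the
    held-out image with η = 0 (a new participant has no deviation estimate).
    ``max_folds`` caps the number of held-out participants (a seeded random
    subset) to bound compute on large N; the default uses all participants.
    Returns (grand-mean PMSE, per-fold PMSE).
    """
    N = data.n_participants
    if N < 3:
        raise ValueError("LOOCV needs at least 3 participants")
    if engine not in ("vi", "gibbs"):
        raise ValueError(f"unknown engine {engine!r}")
    if basis is None:
        basis = _build_basis(domain, spec, L, seed)
    ops = build_projections(basis)
    Y_tilde_full = data.Y @ ops.Phi
    folds = np.arange(N)
    if max_folds is not None and max_folds < N:
        folds = np.sort(np.random.default_rng(seed).choice(N, size=max_folds, replace=False))
    pmse_folds = []
    n_failed = 0
    from .model import TransformedDataset  # local to avoid cycle at import time

    for i in folds:
        keep = np.arange(N) != i
        tdata = TransformedDataset(Y_tilde=Y_tilde_full[keep], ops=ops)
        X_train = data.X[keep]
        try:
            if engine == "vi":
                q = run_cavi(tdata, X_train, ops, cavi_config or CaviConfig(max_iter=200, rel_tol=1e-6))
                state = q.mean_state()
            else:
                from .gibbs import GibbsConfig, run_gibbs

                draws = run_gibbs(
                    tdata, X_train, ops,
                    GibbsConfig(n_chains=1, n_burn=200, n_keep=200, seed=seed + int(i)),
                )
                state = _posterior_mean_state(draws)
            pred = model_predict(state, data.X[i : i + 1], basis, include_eta=False)[0]
        except Exception as exc:  # noqa: BLE001 - fold-level robustness by design
            warnings.warn(f"LOOCV fold {i} failed: {exc}")
            n_failed += 1
            continue
        pmse_folds.append(float(np.mean((data.Y[i] - pred) ** 2)))
    if n_failed > 0.2 * len(folds):
        raise RuntimeError(f"{n_failed}/{len(folds)} LOOCV folds failed")
    per_fold = np.asarray(pmse_folds)
    return float(per_fold.mean()), per_fold


def _posterior_mean_state(draws):
    from .model import ParameterState

    return ParameterState(
        alpha=draws.flat("alpha").mean(axis=0),
        theta_beta=draws.flat("theta_beta").mean(axis=0),
        theta_eta=(
            draws.flat("theta_eta").mean(axis=0)
            if draws.theta_eta is not None
            else np.zeros((1, draws.ops.Phi_eta.shape[0]))
        ),
        sigma2_alpha=float(draws.variances["sigma2_alpha"].mean()),
        sigma2_beta=float(draws.variances["sigma2_beta"].mean()),
        sigma2_eta=float(draws.variances["sigma2_eta"].mean()),
        sigma2_eps=float(draws.variances["sigma2_eps"].mean()),
        a_alpha=1.0, a_beta=1.0, a_eta=1.0, a_eps=1.0,
    )


def choose_L(
    data: RegressionDataset,
    domain: SpatialDomain,
    spec: KernelSpec,
    L_max: int | None = None,
    grid_size: int = 5,
    engine: str = "vi",
    seed: int = 0,
    max_folds: int | None = None,
) -> SelectionReport:
    """Cumulative-variance screen then LOOCV grid search; ties → smaller L."""
    V = domain.n_locations
    if L_max is None:
        L_max = min(V, 2000)
    if L_max > V:
        raise ValueError("L_max cannot exceed the number of locations")
    ind = select_inducing_points(domain, L_max, seed=seed)
    _, lam = nystrom_decompose(domain, spec, ind)
    L_lo, L_hi = candidate_L_range(lam)
    candidates = sorted(set(np.linspace(L_lo, L_hi, grid_size).round().astype(int).tolist()))
    pmse, per_part = [], []
    for L in candidates:
        m, folds = loocv_pmse(
            data, domain, spec, L, engine=engine, seed=seed, max_folds=max_folds
        )
        logger.info("LOOCV PMSE at L=%d: %.5f", L, m)
        pmse.append(m)
        per_part.append(folds)
    selected = candidates[int(np.argmin(pmse))]
    return SelectionReport(
        L_max=L_max,
        eigenvalues=lam,
        candidates=candidates,
        pmse=pmse,
        pmse_per_participant=per_part,
        selected_L=selected,
    )
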