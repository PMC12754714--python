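"""Matérn kernels, inducing points, and the Nyström low-rank decomposition.

The spatial prior for every smooth component of the model is a Gaussian
process with a stationary Matérn correlation kernel.  Because a dense V×V
Gram matrix is intractable at whole-brain resolution, the kernel is replaced
by a rank-L Nyström approximation anchored at L inducing locations:

    K_V ≈ K_{V,L} K_L^{-1} K_{V,L}^T = Ψ Λ Ψ^T,

where Ψ has orthonormal columns and Λ holds positive eigenvalues.  Ψ Λ^{1/2}
then acts as a Karhunen–Loève basis: a GP draw is represented by L iid
normal coefficients, which is what makes conjugate inference cheap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, special
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .domain import SpatialDomain

logger = logging.getLogger(__name__)

_JITTER_MAX = 1e-4


@dataclass
class KernelSpec:
    """Stationary unit-variance Matérn kernel settings.

    The correlation at distance t uses the √(2ν) scaling convention,

        u = √(2ν)·t/ρ,    K(t) = 2^{1−ν}/Γ(ν) · u^ν · besselK_ν(u),

    so ``length_scale`` ρ is in normalized coordinate units and ν=1/2, 3/2,
    5/2 reduce to the familiar exponential-family closed forms.  ν defaults
    to 1/2 (the exponential kernel): its slowly decaying spectrum yields a
    basis whose 80–98% cumulative-variance window spans the rank range that
    leave-one-out selection actually favors on imaging-scale masks, whereas
    smoother kernels collapse the window to a few dozen functions.
    """

    length_scale: float = 0.3
    smoothness: float = 0.5
    jitter: float = 1e-8
    family: str = "matern"

    def __post_init__(self) -> None:
        if self.length_scale <= 0:
            raise ValueError("length_scale must be positive")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")
        if self.family != "matern":
            raise ValueError(f"unsupported kernel family: {self.family!r}")


def matern_correlation(dist, spec: KernelSpec):
    """Matérn correlation at the given distance(s); 1 at distance zero."""
    d = np.asarray(dist, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    nu = spec.smoothness
    u = np.sqrt(2.0 * nu) * d / spec.length_scale
    if nu == 0.5:
        out = np.exp(-u)
    elif nu == 1.5:
        out = (1.0 + u) * np.exp(-u)
    elif nu == 2.5:
        out = (1.0 + u + u * u / 3.0) * np.exp(-u)
    else:
        with np.errstate(invalid="ignore", over="ignore"):
            out = (2.0 ** (1.0 - nu) / special.gamma(nu)) * u**nu * special.kv(nu, u)
        out = np.where(u == 0, 1.0, out)
        # roundoff in the Bessel product can exceed 1 by ~1e-15 near u = 0
        out = np.minimum(np.nan_to_num(out, nan=1.0), 1.0)
    if np.ndim(dist) == 0:
        return float(out)
    return out


def gram_matrix(
    rows: np.ndarray, cols: np.ndarray, spec: KernelSpec, jitter_diagonal: bool = False
) -> np.ndarray:
    """Kernel matrix between two coordinate sets.

    The square case (identical sets) is symmetric with unit diagonal, plus
    ``spec.jitter`` on the diagonal when ``jitter_diagonal`` is set.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    cols = np.atleast_2d(np.asarray(cols, dtype=float))
    if rows.shape[1] != cols.shape[1]:
        raise ValueError(
            f"coordinate dimension mismatch: {rows.shape[1]} vs {cols.shape[1]}"
        )
    K = matern_correlation(cdist(rows, cols), spec)
    if jitter_diagonal:
        if K.shape[0] != K.shape[1]:
            raise ValueError("jitter_diagonal requires a square Gram matrix")
        K = K + spec.jitter * np.eye(K.shape[0])
    return K


def select_inducing_points(
    domain: SpatialDomain, L: int, seed: int, method: str = "kmeans"
) -> np.ndarray:
    """Choose L approximately space-filling inducing locations.

    Default is k-means on the (normalized) coordinates with centroids
    snapped to the nearest masked location; duplicate snaps are replaced by
    farthest-point substitution.  ``method="random"`` draws a uniform subset.
    """
    V = domain.n_locations
    if not 1 <= L <= V:
        raise ValueError(f"L must be in [1, {V}], got {L}")
    if L == V:
        return np.arange(V)
    rng = np.random.default_rng(seed)
    if method == "random":
        return np.sort(rng.choice(V, size=L, replace=False))
    if method != "kmeans":
        raise ValueError(f"unknown inducing method: {method!r}")
    km = KMeans(n_clusters=L, n_init=1, random_state=int(seed) % (2**32))
    km.fit(domain.coords)
    snapped = np.argmin(cdist(km.cluster_centers_, domain.coords), axis=1)
    chosen = list(dict.fromkeys(snapped.tolist()))  # preserve order, drop dups
    # farthest-point substitution for collapsed centroids
    while len(chosen) < L:
        dist_to_set = cdist(domain.coords, domain.coords[chosen]).min(axis=1)
        dist_to_set[chosen] = -np.inf
        chosen.append(int(np.argmax(dist_to_set)))
    return np.sort(np.asarray(chosen[:L]))


def _chol_with_jitter(K: np.ndarray, jitter0: float) -> np.ndarray:
    """Cholesky with ×10 jitter escalation up to the module cap."""
    jitter = max(jitter0, 1e-12)
    base = np.eye(K.shape[0])
    while jitter <= _JITTER_MAX:
        try:
            return linalg.cholesky(K + jitter * base, lower=True)
        except linalg.LinAlgError:
            jitter *= 10.0
    cond = np.linalg.cond(K)
    raise linalg.LinAlgError(
        f"Cholesky failed up to jitter {_JITTER_MAX:g}; condition estimate {cond:.3e}"
    )


def nystrom_decompose(
    domain: SpatialDomain, spec: KernelSpec, inducing: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rank-L spectral approximation K_V ≈ Ψ Λ Ψ^T via the Nyström method.

    Computes K_L = R R^T (Cholesky), K̃ = K_{V,L} R^{-T}, thin SVD
    K̃ = Ψ D U^T, and returns (Ψ, Λ = D²) with the numerically zero
    eigenvalue tail (below 1e-10·λ₁) trimmed.
    """
    inducing = np.asarray(inducing, dtype=np.int64)
    if inducing.size == 0 or np.unique(inducing).size != inducing.size:
        raise ValueError("inducing indices must be nonempty and distinct")
    if inducing.min() < 0 or inducing.max() >= domain.n_locations:
        raise ValueError("inducing indices out of range")
    S_L = domain.coords[inducing]
    K_L = gram_matrix(S_L, S_L, spec, jitter_diagonal=True)
    R = _try_chol(K_L, spec)
    K_VL = gram_matrix(domain.coords, S_L, spec)
    Ktilde = linalg.solve_triangular(R, K_VL.T, lower=True).T
    Psi, D, _ = linalg.svd(Ktilde, full_matrices=False)
    eigvals = D**2
    keep = eigvals > 1e-10 * eigvals[0]
    if not np.all(keep):
        logger.info(
            "trimmed %d numerically zero eigenvalues (L %d -> %d)",
            (~keep).sum(),
            eigvals.size,
            keep.sum(),
        )
    return np.ascontiguousarray(Psi[:, keep]), eigvals[keep]


def _try_chol(K_L: np.ndarray, spec: KernelSpec) -> np.ndarray:
    # jitter already on the diagonal from gram_matrix; escalate only on failure
    try:
        return linalg.cholesky(K_L, lower=True)
    except linalg.LinAlgError:
        return _chol_with_jitter(K_L, spec.jitter * 10)


@dataclass
class LowRankBasis:
    """Karhunen–Loève bases for the population (L) and participant (Lη) fields.

    ``Psi`` (V×L) with eigenvalues Λ approximates the shared kernel; the
    participant-deviation field uses a coarser, independently decomposed
    basis ``Psi_eta`` (V×Lη) to prevent overfitting (default Lη = ⌈0.1·L⌉).
    """

    inducing_indices: np.ndarray
    Psi: np.ndarray
    eigenvalues: np.ndarray
    inducing_indices_eta: np.ndarray
    Psi_eta: np.ndarray
    eigenvalues_eta: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.eigenvalues <= 0) or np.any(self.eigenvalues_eta <= 0):
            raise ValueError("eigenvalues must be strictly positive")
        if np.any(np.diff(self.eigenvalues) > 1e-12) or np.any(
            np.diff(self.eigenvalues_eta) > 1e-12
        ):
            raise ValueError("eigenvalues must be sorted nonincreasing")
        if self.L_eta > self.L or self.L > self.Psi.shape[0]:
            raise ValueError("require L_eta <= L <= V")

    @property
    def L(self) -> int:
        return self.eigenvalues.size

    @property
    def L_eta(self) -> int:
        return self.eigenvalues_eta.size

    @property
    def n_locations(self) -> int:
        return self.Psi.shape[0]

    @property
    def kl_map(self) -> np.ndarray:
        """Ψ Λ^{1/2} (V×L): maps basis coefficients to voxel maps."""
        return self.Psi * np.sqrt(self.eigenvalues)

    @property
    def kl_map_eta(self) -> np.ndarray:
        return self.Psi_eta * np.sqrt(self.eigenvalues_eta)

    @classmethod
    def build(
        cls,
        domain: SpatialDomain,
        spec: KernelSpec,
        L: int,
        L_eta: int | None = None,
        seed: int = 0,
        method: str = "kmeans",
    ) -> "LowRankBasis":
        """Select inducing points and decompose both bases."""
        if L_eta is None:
            L_eta = int(np.ceil(0.1 * L))
        ind = select_inducing_points(domain, L, seed=seed, method=method)
        Psi, lam = nystrom_decompose(domain, spec, ind)
        ind_eta = select_inducing_points(domain, L_eta, seed=seed + 1, method=method)
        Psi_eta, lam_eta = nystrom_decompose(domain, spec, ind_eta)
        return cls(ind, Psi, lam, ind_eta, Psi_eta, lam_eta)


@dataclass
class ProjectionOperators:
    """Projections that whiten the low-rank model.

    Φ = Ψ Λ^{-1/2} turns projected GP noise into iid N(0, σ²_ε I_L);
    Φη = Λ̃^{1/2} Ψ̃^T Ψ Λ^{-1/2} is the participant-field design in the
    projected space; ``ones_proj`` caches 1_V^T Φ for the global-effect term.
    """

    Phi: np.ndarray
    Phi_eta: np.ndarray
    ones_proj: np.ndarray
    basis: LowRankBasis = field(repr=False)


def build_projections(basis: LowRankBasis) -> ProjectionOperators:
    if np.any(basis.eigenvalues <= 0):
        raise ValueError("zero eigenvalue in basis; trim before projecting")
    inv_sqrt = 1.0 / np.sqrt(basis.eigenvalues)
    Phi = basis.Psi * inv_sqrt
    Phi_eta = (basis.Psi_eta * np.sqrt(basis.eigenvalues_eta)).T @ Phi
    ones_proj = Phi.sum(axis=0)
    return ProjectionOperators(Phi=Phi, Phi_eta=Phi_eta, ones_proj=ones_proj, basis=basis)


def estimate_length_scale(
    Y: np.ndarray,
    domain: SpatialDomain,
    n_pairs: int = 2000,
    seed: int = 0,
    bounds: tuple[float, float] = (0.02, 1.5),
    smoothness: float = 0.5,
) -> float:
    """Empirical Matérn length scale from pairwise spatial correlations.

    Subsamples location pairs, computes the across-participant correlation
    of voxel-centered images for each pair, and returns the length scale
    whose Matérn correlation curve best fits those (distance, correlation)
    points in least squares.  Pinned to a bound (with a warning) when the
    data carry no, or perfect, spatial correlation.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[0] < 2:
        raise ValueError("Y must be N×V with N >= 2")
    Yc = Y - Y.mean(axis=0)
    sd = Yc.std(axis=0)
    if np.all(sd < 1e-12):
        raise ValueError("degenerate images: constant across participants")
    rng = np.random.default_rng(seed)
    V = Y.shape[1]
    a = rng.integers(0, V, size=n_pairs)
    b = rng.integers(0, V, size=n_pairs)
    ok = (a != b) & (sd[a] > 1e-12) & (sd[b] > 1e-12)
    a, b = a[ok], b[ok]
    if a.size < 10:
        raise ValueError("too few usable location pairs")
    corr = np.einsum("ij,ij->j", Yc[:, a], Yc[:, b]) / (Y.shape[0] * sd[a] * sd[b])
    dist = np.linalg.norm(domain.coords[a] - domain.coords[b], axis=1)
    if np.all(corr > 0.999):
        warnings.warn("pairwise correlations are all ~1; pinning to upper bound")
        return bounds[1]

    def sse(log_rho: float) -> float:
        spec = KernelSpec(length_scale=float(np.exp(log_rho)), smoothness=smoothness)
        return float(np.sum((corr - matern_correlation(dist, spec)) ** 2))

    res = optimize.minimize_scalar(
        sse, bounds=(np.log(bounds[0]), np.log(bounds[1])), method="bounded"
    )
    rho = float(np.exp(res.x))
    if rho <= bounds[0] * 1.02:
        warnings.warn("length-scale estimate pinned to the lower bound")
        return bounds[0]
    if rho >= bounds[1] * 0.98:
        warnings.warn("length-scale estimate pinned to the upper bound")
        return bounds[1]
    return rho
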