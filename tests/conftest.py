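"""Shared fixtures: small synthetic study instances, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from bisreg import (
    GibbsConfig,
    KernelSpec,
    LowRankBasis,
    build_projections,
    make_truth,
    project_responses,
    run_cavi,
    run_gibbs,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def truth():
    """Scaled-down study truth: ~600-voxel slice mask, two-region maps."""
    return make_truth(target_voxels=600, sigma_eps=2.0, snr=0.3, seed=7, noise_rank=150)


@pytest.fixture(scope="session")
def dataset(truth):
    return simulate_dataset(truth, N=40, seed=11)


@pytest.fixture(scope="session")
def basis(truth):
    return LowRankBasis.build(truth.domain, KernelSpec(length_scale=0.3), L=60, seed=0)


@pytest.fixture(scope="session")
def ops(basis):
    return build_projections(basis)


@pytest.fixture(scope="session")
def tdata(dataset, ops):
    return project_responses(dataset, ops)


@pytest.fixture(scope="session")
def fitted_vi(tdata, dataset, ops):
    return run_cavi(tdata, dataset.X, ops)


@pytest.fixture(scope="session")
def fitted_gibbs(tdata, dataset, ops):
    return run_gibbs(
        tdata, dataset.X, ops, GibbsConfig(n_chains=2, n_burn=300, n_keep=300, seed=42)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_identity_ops(V: int, L_eta: int | None = None):
    """A basis where Ψ = I and Λ = I, so projection is the identity map."""
    from bisreg.domain import SpatialDomain
    from bisreg.kernel import ProjectionOperators

    if L_eta is None:
        L_eta = V
    coords = np.linspace(0, 1, V)[:, None]
    domain = SpatialDomain.from_coords(coords, normalize=False)
    b = LowRankBasis(
        inducing_indices=np.arange(V),
        Psi=np.eye(V),
        eigenvalues=np.ones(V),
        inducing_indices_eta=np.arange(L_eta),
        Psi_eta=np.eye(V)[:, :L_eta],
        eigenvalues_eta=np.ones(L_eta),
    )
    return domain, b, build_projections(b)
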