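"""Shared fixtures: small random model instances built from seeded generators."""

import numpy as np
import pytest

from blade import BulkMatrix, SignaturePrior, VariationalState


def make_instance(seed: int, I: int = 3, J: int = 4, T: int = 3,
                  omega_scale: float | None = None, b_offset: float = 0.0):
    """A random (state, bulk, prior) triple with generic O(1) gradients."""
    rng = np.random.default_rng(seed)
    y = rng.lognormal(0.0, 1.0, size=(J, I))
    bulk = BulkMatrix(y, [f"g{j}" for j in range(J)], [f"s{i}" for i in range(I)])
    sd = rng.uniform(0.2, 1.0, size=(J, T))
    alpha0 = rng.uniform(0.5, 3.0)
    prior = SignaturePrior(
        mu0=rng.normal(0.0, 1.0, (J, T)),
        sigma=sd,
        kappa0=rng.uniform(0.3, 2.0),
        alpha0=alpha0,
        beta0=alpha0 * sd**2,
        gamma=rng.uniform(0.5, 2.0, J),
        dirichlet_alpha=rng.uniform(0.8, 3.0),
        s=1.0,
    )
    omega = (
        rng.uniform(0.05, 0.5, (I, J, T))
        if omega_scale is None
        else np.full((I, J, T), omega_scale)
    )
    state = VariationalState(
        nu=rng.normal(0.0, 1.0, (I, J, T)),
        omega=omega,
        B=rng.uniform(0.5, 3.0, (I, T)) + b_offset,
    )
    return state, bulk, prior


@pytest.fixture
def small_instance():
    return make_instance(seed=0)
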