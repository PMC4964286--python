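import numpy as np
import pytest

from latentdx import (
    CrossClassifiedCounts,
    ModelParameters,
    covariance_bounds,
    internal_wind_stroke,
)
from latentdx.priors import PriorSpecification


@pytest.fixture(scope="session")
def stroke_counts() -> CrossClassifiedCounts:
    return internal_wind_stroke()


@pytest.fixture(scope="session")
def elicited_priors() -> PriorSpecification:
    return PriorSpecification.internal_wind()


def _feasible_cov(rng: np.random.Generator, a1: float, a2: float) -> float:
    """Covariance inside the stated bounds AND keeping all 4 cells in [0, 1].

    The stated lower bound (a1-1)(1-a2) also needs C >= -a1*a2 when
    a1 + a2 < 1, so sample from the intersection.
    """
    lo, hi = covariance_bounds(a1, a2)
    lo = max(lo, -a1 * a2)
    return rng.uniform(0.999 * lo, 0.999 * hi)


def random_valid_parameters(rng: np.random.Generator) -> ModelParameters:
    """A uniformly scattered valid parameter vector (covariances inside bounds)."""
    se = tuple(rng.uniform(0.05, 0.95, 3))
    sp = tuple(rng.uniform(0.05, 0.95, 3))
    cp = _feasible_cov(rng, se[0], se[1])
    cn = _feasible_cov(rng, sp[0], sp[1])
    return ModelParameters(
        se=se, sp=sp, prevalence=rng.uniform(0.02, 0.98), cov_pos=cp, cov_neg=cn
    )


def random_counts(rng: np.random.Generator, n_max: int = 400) -> CrossClassifiedCounts:
    """A random 8-cell table with every pattern stratum possible."""
    n = int(rng.integers(8, n_max))
    probs = rng.dirichlet(np.ones(8))
    return CrossClassifiedCounts(tuple(int(c) for c in rng.multinomial(n, probs)))
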