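"""Latent-class model for three binary diagnostic tests without a gold standard.

True condition status D is an unobserved Bernoulli(pi) variable.  Tests 1
and 2 (standardized scales) may err dependently given D; their conditional
covariances are C+ = cov(T1, T2 | D=1) and C- = cov(T1, T2 | D=0).  Test 3
(expert consensus) errs independently of the scales given D.  The joint
probability of a response pattern marginalizes over D:

    p(t1,t2,t3) = pi * P(t1,t2 | D=1) * Se3^t3 (1-Se3)^(1-t3)
                + (1-pi) * P(t1,t2 | D=0) * (1-Sp3)^t3 Sp3^(1-t3)

with

    P(t1,t2 | D=1) = prod_i Se_i^ti (1-Se_i)^(1-ti) + (-1)^(t1+t2) C+
    P(t1,t2 | D=0) = prod_i Sp_i^(1-ti) (1-Sp_i)^ti + (-1)^(t1+t2) C-

The nine parameters are theta = (Se1, Se2, Se3, Sp1, Sp2, Sp3, pi, C+, C-).
The observed 8-cell counts are multinomial over these cell probabilities,
which gives 7 degrees of freedom for 9 parameters: the model is not
identified by the data alone and is completed by informative priors
(see :mod:`latentdx.priors`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data import PATTERNS, CrossClassifiedCounts

PARAM_NAMES: tuple[str, ...] = (
    "Se1", "Se2", "Se3", "Sp1", "Sp2", "Sp3", "prevalence", "cov_pos", "cov_neg",
)


class InvalidParameterError(ValueError):
    """A parameter vector violates the model's constraints."""


def covariance_bounds(a1: float, a2: float) -> tuple[float, float]:
    """Admissible range for the conditional covariance of two binary tests.

    For a pair of accuracies (a1, a2) — either (Se1, Se2) or (Sp1, Sp2) —
    the covariance C of the two test results given the true status must keep
    all four conditional joint probabilities in [0, 1], which is equivalent to

        (a1 - 1)(1 - a2)  <=  C  <=  min(a1, a2) - a1 * a2

    The lower bound is always <= 0 and the upper bound always >= 0, so
    conditional independence (C = 0) is always admissible.
    """
    if not (0.0 <= a1 <= 1.0 and 0.0 <= a2 <= 1.0):
        raise ValueError(f"accuracies must lie in [0, 1], got ({a1}, {a2})")
    return (a1 - 1.0) * (1.0 - a2), min(a1, a2) - a1 * a2


@dataclass(frozen=True)
class ModelParameters:
    """theta = (Se1, Se2, Se3, Sp1, Sp2, Sp3, pi, C+, C-).

    Parameters
    ----------
    se, sp : tuple of 3 floats
        Sensitivities and specificities of the three tests.
    prevalence : float
        P(D = 1).
    cov_pos, cov_neg : float
        Conditional covariances of tests 1 and 2 given D=1 and D=0.
        Each must lie within :func:`covariance_bounds` of the corresponding
        accuracy pair.
    """

    se: tuple[float, float, float]
    sp: tuple[float, float, float]
    prevalence: float
    cov_pos: float = 0.0
    cov_neg: float = 0.0

    def validate(self) -> None:
        """Raise :class:`InvalidParameterError` naming the violated bound."""
        for name, vals in (("Se", self.se), ("Sp", self.sp)):
            for i, v in enumerate(vals, start=1):
                if not 0.0 <= v <= 1.0:
                    raise InvalidParameterError(f"{name}{i}={v} outside [0, 1]")
        if not 0.0 <= self.prevalence <= 1.0:
            raise InvalidParameterError(
                f"prevalence={self.prevalence} outside [0, 1]"
            )
        lo, hi = covariance_bounds(self.se[0], self.se[1])
        if not lo <= self.cov_pos <= hi:
            raise InvalidParameterError(
                f"cov_pos={self.cov_pos} outside [{lo}, {hi}] implied by "
                f"Se1={self.se[0]}, Se2={self.se[1]}"
            )
        lo, hi = covariance_bounds(self.sp[0], self.sp[1])
        if not lo <= self.cov_neg <= hi:
            raise InvalidParameterError(
                f"cov_neg={self.cov_neg} outside [{lo}, {hi}] implied by "
                f"Sp1={self.sp[0]}, Sp2={self.sp[1]}"
            )
        # belt and braces: the four conditional joint probabilities per stratum
        for d in (0, 1):
            for t1 in (0, 1):
                for t2 in (0, 1):
                    q = conditional_joint(self, t1, t2, d, _validate=False)
                    if not -1e-12 <= q <= 1.0 + 1e-12:
                        raise InvalidParameterError(
                            f"P(T1={t1},T2={t2}|D={d})={q} outside [0, 1]"
                        )

    def is_valid(self) -> bool:
        try:
            self.validate()
        except InvalidParameterError:
            return False
        return True

    def to_vector(self) -> np.ndarray:
        """Flat vector in the order (Se1,Se2,Se3,Sp1,Sp2,Sp3,pi,C+,C-)."""
        return np.array(
            [*self.se, *self.sp, self.prevalence, self.cov_pos, self.cov_neg]
        )

    @classmethod
    def from_vector(cls, theta: Sequence[float]) -> "ModelParameters":
        theta = [float(x) for x in theta]
        if len(theta) != 9:
            raise ValueError(f"expected 9 parameters, got {len(theta)}")
        return cls(
            se=tuple(theta[0:3]),
            sp=tuple(theta[3:6]),
            prevalence=theta[6],
            cov_pos=theta[7],
            cov_neg=theta[8],
        )

    def label_swap(self) -> "ModelParameters":
        """The mirror solution: pi -> 1-pi, Se_i <-> 1-Sp_i, C+ <-> C-.

        The observed-data likelihood is invariant under this map — the
        model's intrinsic non-identifiability.  Informative accuracy priors
        are what suppress the mirror mode in practice.
        """
        return ModelParameters(
            se=tuple(1.0 - s for s in self.sp),
            sp=tuple(1.0 - s for s in self.se),
            prevalence=1.0 - self.prevalence,
            cov_pos=self.cov_neg,
            cov_neg=self.cov_pos,
        )


@dataclass(frozen=True)
class CellProbabilityVector:
    """The 8 joint pattern probabilities in canonical order."""

    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.probs) != 8:
            raise ValueError("expected 8 cell probabilities")
        if any(p < -1e-12 or p > 1.0 + 1e-12 for p in self.probs):
            raise ValueError("cell probabilities must lie in [0, 1]")
        if abs(sum(self.probs) - 1.0) > 1e-10:
            raise ValueError(
                f"cell probabilities sum to {sum(self.probs)}, not 1"
            )

    def __getitem__(self, pattern) -> float:
        return self.probs[PATTERNS.index(tuple(pattern))]

    def as_dict(self) -> dict[str, float]:
        return {"".join(map(str, p)): v for p, v in zip(PATTERNS, self.probs)}


# ------------------------------------------------------------------ fast core
# Scalar-arithmetic versions operating on the flat 9-vector; these are the
# sampler's inner loop, so no dataclass construction or numpy overhead.

def _cond4(a1: float, a2: float, c: float) -> tuple[float, float, float, float]:
    """Conditional joint P(T1,T2|D) in order (1,1), (1,0), (0,1), (0,0)."""
    return (
        a1 * a2 + c,
        a1 * (1.0 - a2) - c,
        (1.0 - a1) * a2 - c,
        (1.0 - a1) * (1.0 - a2) + c,
    )


def _cell_probs8(th: Sequence[float]) -> tuple[float, ...]:
    """Eight cell probabilities in canonical pattern order, or None if invalid."""
    se1, se2, se3, sp1, sp2, sp3, pi, cp, cn = th
    a = _cond4(se1, se2, cp)                      # P(t1,t2 | D=1)
    b = _cond4(1.0 - sp1, 1.0 - sp2, cn)          # P(t1,t2 | D=0)
    q = 1.0 - pi
    out = []
    for k in range(4):
        pos = pi * a[k]
        neg = q * b[k]
        out.append(pos * se3 + neg * (1.0 - sp3))  # t3 = 1
        out.append(pos * (1.0 - se3) + neg * sp3)  # t3 = 0
    return tuple(out)


def _theta_valid(th: Sequence[float]) -> bool:
    se1, se2, se3, sp1, sp2, sp3, pi, cp, cn = th
    for x in (se1, se2, se3, sp1, sp2, sp3, pi):
        if not 0.0 <= x <= 1.0:
            return False
    for v in _cond4(se1, se2, cp):
        if not 0.0 <= v <= 1.0:
            return False
    for v in _cond4(1.0 - sp1, 1.0 - sp2, cn):
        if not 0.0 <= v <= 1.0:
            return False
    return True


def _loglik(th: Sequence[float], y: Sequence[float]) -> float:
    """Multinomial log-likelihood (kernel, without the combinatorial constant)."""
    probs = _cell_probs8(th)
    total = 0.0
    for yk, pk in zip(y, probs):
        if yk:
            if pk <= 0.0:
                return -math.inf
            total += yk * math.log(pk)
    return total


# ------------------------------------------------------------ public surface

def conditional_joint(
    params: ModelParameters, t1: int, t2: int, d: int, _validate: bool = True
) -> float:
    """P(T1=t1, T2=t2 | D=d) with the additive covariance correction."""
    if _validate:
        params.validate()
    sign = 1.0 if (t1 + t2) % 2 == 0 else -1.0
    if d == 1:
        se1, se2 = params.se[0], params.se[1]
        base = (se1 if t1 else 1.0 - se1) * (se2 if t2 else 1.0 - se2)
        return base + sign * params.cov_pos
    sp1, sp2 = params.sp[0], params.sp[1]
    base = (1.0 - sp1 if t1 else sp1) * (1.0 - sp2 if t2 else sp2)
    return base + sign * params.cov_neg


def cell_probability(params: ModelParameters, t1: int, t2: int, t3: int) -> float:
    """Joint probability of the response pattern (t1, t2, t3)."""
    params.validate()
    se3, sp3, pi = params.se[2], params.sp[2], params.prevalence
    pos = conditional_joint(params, t1, t2, 1, _validate=False)
    neg = conditional_joint(params, t1, t2, 0, _validate=False)
    return (
        pi * pos * (se3 if t3 else 1.0 - se3)
        + (1.0 - pi) * neg * ((1.0 - sp3) if t3 else sp3)
    )


def cell_probabilities(params: ModelParameters) -> CellProbabilityVector:
    """All eight pattern probabilities, in canonical order; they sum to 1."""
    params.validate()
    return CellProbabilityVector(_cell_probs8(params.to_vector()))


def log_likelihood(params: ModelParameters, data: CrossClassifiedCounts) -> float:
    """Observed-data log-likelihood sum_y Y_t * log p_t (multinomial kernel).

    Returns ``-inf`` (rather than raising) when some cell has a zero
    probability but a positive count, so samplers can treat such states as
    rejected rather than exceptional.
    """
    params.validate()
    return _loglik(params.to_vector(), data.counts)


def default_initial_values() -> ModelParameters:
    """Conventional starting point for the MCMC chains.

    These are the naive (expert-as-gold-standard) accuracy estimates of the
    packaged internal-wind dataset rounded to three decimals, with both
    covariances started at conditional independence.
    """
    return ModelParameters(
        se=(0.748, 0.945, 0.850),
        sp=(0.844, 0.883, 0.935),
        prevalence=0.623,
        cov_pos=0.0,
        cov_neg=0.0,
    )


class LatentClassModel:
    """Three-test latent-class diagnostic accuracy model.

    Parameters
    ----------
    counts : CrossClassifiedCounts
        Observed 2x2x2 pattern counts.
    prior : PriorSpecification, optional
        Joint prior over theta.  Defaults to the weakly informative
        all-uniform specification; note that with only 7 degrees of freedom
        in the data, informative accuracy priors are usually required for a
        well-behaved posterior.

    Examples
    --------
    >>> from latentdx import LatentClassModel, internal_wind_stroke
    >>> from latentdx.priors import PriorSpecification
    >>> model = LatentClassModel(internal_wind_stroke(),
    ...                          PriorSpecification.internal_wind())
    >>> results = model.fit(seed=1)          # doctest: +SKIP
    >>> results.summary()                    # doctest: +SKIP
    """

    def __init__(self, counts: CrossClassifiedCounts, prior=None):
        from .priors import PriorSpecification  # local import: avoid cycle

        if not isinstance(counts, CrossClassifiedCounts):
            raise TypeError("counts must be a CrossClassifiedCounts")
        self.counts = counts
        self.prior = prior if prior is not None else PriorSpecification.uniform()

    @classmethod
    def from_dataframe(cls, df, prior=None) -> "LatentClassModel":
        """Build from a long-format table with columns t1, t2, t3, count."""
        mapping = {
            (int(r["t1"]), int(r["t2"]), int(r["t3"])): int(r["count"])
            for _, r in df.iterrows()
        }
        return cls(CrossClassifiedCounts.from_dict(mapping), prior=prior)

    @classmethod
    def from_file(cls, path, prior=None) -> "LatentClassModel":
        return cls(CrossClassifiedCounts.from_file(path), prior=prior)

    def loglike(self, params: ModelParameters) -> float:
        return log_likelihood(params, self.counts)

    def cell_probabilities(self, params: ModelParameters) -> CellProbabilityVector:
        return cell_probabilities(params)

    def fit(
        self,
        n_chains: int = 3,
        n_iterations: int = 60_000,
        n_burnin: int = 10_000,
        thin: int = 5,
        seed: int = 0,
        initial_values=None,
        proposal_scales=None,
    ):
        """Sample the posterior by Metropolis-within-Gibbs MCMC.

        Returns
        -------
        LatentClassResults
            Posterior medians, 95% equal-tailed credible intervals and
            convergence diagnostics, statsmodels-style.
        """
        from .results import LatentClassResults
        from .sampler import SamplerConfig, sample_posterior

        config = SamplerConfig(
            n_chains=n_chains,
            n_iterations=n_iterations,
            n_burnin=n_burnin,
            thin=thin,
            seed=seed,
            initial_values=initial_values,
            proposal_scales=proposal_scales,
        )
        chains = sample_posterior(self.counts, self.prior, config)
        return LatentClassResults(self, chains, config)

    def simulate(self, params: ModelParameters, n: int, seed: int):
        """Draw a synthetic count table of size n from this model at ``params``."""
        from .simulate import simulate_counts

        return simulate_counts(params, n, seed)
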