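"""Prior elicitation and the joint prior density over the model parameters.

Accuracy priors are Beta(alpha, beta) distributions elicited from expert
statements of the form "the most probable value is m, and we are 95% sure
the quantity is at least q".  The elicitation uses the mode-preserving
parameterization

    alpha = 1 + m * k,    beta = 1 + (1 - m) * k,    k > 0,

whose mode is exactly m for every k; k is then solved so that the beta CDF
at q equals the stated tail probability.  Prevalence takes a uniform prior
on [0, 1] by default.  The conditional covariances C+ and C- take uniform
priors on their admissible ranges, which depend on the current accuracies,
so the joint prior is hierarchical:

    f(theta) = f(Se, Sp, pi) * f(C+ | Se1, Se2) * f(C- | Sp1, Sp2)

and the 1/range normalizers of the two conditional uniforms are part of the
density (omitting them would change the posterior).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import yaml
from scipy import optimize, special, stats

from .model import ModelParameters, covariance_bounds

_K_MAX = 1e6
_K_MIN = 1e-6


@dataclass(frozen=True)
class ElicitationStatement:
    """An expert statement: mode m, and P(X <= percentile_value) = percentile_prob."""

    mode: float
    percentile_value: float
    percentile_prob: float


@dataclass(frozen=True)
class BetaHyperparameters:
    """Shape parameters of a Beta(alpha, beta) prior, with optional provenance."""

    alpha: float
    beta: float
    source: ElicitationStatement | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(
                f"beta shapes must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mode(self) -> float:
        """Mode (alpha-1)/(alpha+beta-2); defined only for alpha, beta > 1."""
        if self.alpha <= 1 or self.beta <= 1:
            raise ValueError("mode is defined only for alpha > 1 and beta > 1")
        return (self.alpha - 1.0) / (self.alpha + self.beta - 2.0)

    def median(self) -> float:
        return float(stats.beta.median(self.alpha, self.beta))

    def interval(self, prob: float = 0.95) -> tuple[float, float]:
        lo, hi = stats.beta.interval(prob, self.alpha, self.beta)
        return float(lo), float(hi)

    def logpdf(self, x: float) -> float:
        if not 0.0 <= x <= 1.0:
            return -math.inf
        return float(stats.beta.logpdf(x, self.alpha, self.beta))


def elicit_beta(
    mode: float, percentile_value: float, percentile_prob: float
) -> BetaHyperparameters:
    """Solve for the beta prior matching a mode and one percentile.

    Parameters
    ----------
    mode : float
        The expert's most probable value, strictly inside (0, 1).
    percentile_value : float
        The quantile the expert bounds, e.g. 0.5 in "95% sure it is at
        least 0.5".
    percentile_prob : float
        The lower-tail probability at ``percentile_value``; a statement
        "95% sure at least q" translates to percentile_prob = 0.05.

    Returns
    -------
    BetaHyperparameters
        With alpha = 1 + mode*k and beta = 1 + (1-mode)*k, so the mode
        constraint holds exactly by construction.

    Notes
    -----
    The beta CDF at fixed q < mode decreases monotonically in k (the
    distribution concentrates around the mode as k grows), so the root in k
    is unique when it exists; it is bracketed on [1e-6, 1e6] and found by
    Brent's method.
    """
    if not 0.0 < mode < 1.0:
        raise ValueError(f"mode must lie strictly inside (0, 1), got {mode}")
    if not 0.0 < percentile_prob < 1.0:
        raise ValueError(
            f"percentile_prob must lie in (0, 1), got {percentile_prob}"
        )
    if not 0.0 < percentile_value < 1.0:
        raise ValueError(
            f"percentile_value must lie in (0, 1), got {percentile_value}"
        )
    below = percentile_value < mode
    if below and percentile_prob >= 0.5:
        raise ValueError(
            "a percentile below the mode must carry a lower-tail probability "
            "< 0.5; check which side of the mode the statement bounds"
        )
    if not below and percentile_prob <= 0.5:
        raise ValueError(
            "a percentile above the mode must carry a lower-tail probability "
            "> 0.5; check which side of the mode the statement bounds"
        )

    def gap(k: float) -> float:
        a = 1.0 + mode * k
        b = 1.0 + (1.0 - mode) * k
        return float(special.betainc(a, b, percentile_value)) - percentile_prob

    g_lo, g_hi = gap(_K_MIN), gap(_K_MAX)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"no beta distribution with mode {mode} puts lower-tail "
            f"probability {percentile_prob} at {percentile_value}; the "
            f"statement is infeasible for k in ({_K_MIN}, {_K_MAX}]"
        )
    k = optimize.brentq(gap, _K_MIN, _K_MAX, xtol=1e-10, rtol=1e-12)
    return BetaHyperparameters(
        alpha=1.0 + mode * k,
        beta=1.0 + (1.0 - mode) * k,
        source=ElicitationStatement(mode, percentile_value, percentile_prob),
    )


_UNIFORM = BetaHyperparameters(1.0, 1.0)


@dataclass(frozen=True)
class PriorSpecification:
    """Joint prior over theta.

    ``se_priors`` and ``sp_priors`` hold one :class:`BetaHyperparameters`
    per test; ``prevalence_prior`` defaults to uniform on [0, 1].  The two
    conditional covariances always take constrained-uniform priors on their
    admissible ranges (no free hyperparameters), so they carry no field.
    """

    se_priors: tuple[BetaHyperparameters, BetaHyperparameters, BetaHyperparameters]
    sp_priors: tuple[BetaHyperparameters, BetaHyperparameters, BetaHyperparameters]
    prevalence_prior: BetaHyperparameters = _UNIFORM

    @classmethod
    def uniform(cls) -> "PriorSpecification":
        """Beta(1,1) on every accuracy and on prevalence."""
        return cls(se_priors=(_UNIFORM,) * 3, sp_priors=(_UNIFORM,) * 3)

    @classmethod
    def internal_wind(cls) -> "PriorSpecification":
        """The elicited priors of the packaged internal-wind analysis.

        Scale sensitivities: mode 0.7, 95% sure at least 0.5
        (≈ Beta(13.322, 6.281)).  Scale specificities: mode 0.8, 95% sure at
        least 0.5 (≈ Beta(7.549, 2.637)).  Expert sensitivity: mode 0.8, 95%
        sure at least 0.7 (≈ Beta(48.283, 12.821)).  Expert specificity:
        mode 0.85, 95% sure at least 0.6 (≈ Beta(10.657, 2.704)).
        Prevalence: uniform on [0, 1].
        """
        return _internal_wind_spec()

    @classmethod
    def from_file(cls, path: str | Path) -> "PriorSpecification":
        """Read a prior configuration from JSON or YAML.

        Each of the keys se1, se2, se3, sp1, sp2, sp3 (and optionally
        ``prevalence``) maps to either ``{"alpha": a, "beta": b}`` or an
        elicitation statement ``{"mode": m, "percentile": q,
        "confidence": c}`` meaning "confidence c that the quantity is at
        least q" (lower-tail probability 1 - c).
        """
        path = Path(path)
        text = path.read_text()
        payload = (
            json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        )
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: prior configuration must be a mapping")

        def parse(key: str, default: BetaHyperparameters) -> BetaHyperparameters:
            if key not in payload:
                return default
            entry = payload[key]
            if "alpha" in entry and "beta" in entry:
                return BetaHyperparameters(float(entry["alpha"]), float(entry["beta"]))
            if {"mode", "percentile", "confidence"} <= set(entry):
                return elicit_beta(
                    float(entry["mode"]),
                    float(entry["percentile"]),
                    1.0 - float(entry["confidence"]),
                )
            raise ValueError(
                f"{path}: entry {key!r} needs either alpha/beta or "
                "mode/percentile/confidence"
            )

        return cls(
            se_priors=tuple(parse(f"se{i}", _UNIFORM) for i in (1, 2, 3)),
            sp_priors=tuple(parse(f"sp{i}", _UNIFORM) for i in (1, 2, 3)),
            prevalence_prior=parse("prevalence", _UNIFORM),
        )

    def accuracy_hyperparameters(self):
        """(alphas, betas) arrays over (Se1,Se2,Se3,Sp1,Sp2,Sp3,prevalence)."""
        hypers = (*self.se_priors, *self.sp_priors, self.prevalence_prior)
        return (
            [h.alpha for h in hypers],
            [h.beta for h in hypers],
        )

    def modes(self) -> ModelParameters:
        """Parameter vector at the prior modes (covariances at 0).

        Prevalence falls back to the prior mean when its prior is flat and
        has no interior mode.
        """
        try:
            prev = self.prevalence_prior.mode
        except ValueError:
            a, b = self.prevalence_prior.alpha, self.prevalence_prior.beta
            prev = a / (a + b)
        return ModelParameters(
            se=tuple(h.mode for h in self.se_priors),
            sp=tuple(h.mode for h in self.sp_priors),
            prevalence=prev,
        )


@lru_cache(maxsize=1)
def _internal_wind_spec() -> "PriorSpecification":
    scale_se = elicit_beta(0.70, 0.5, 0.05)
    scale_sp = elicit_beta(0.80, 0.5, 0.05)
    expert_se = elicit_beta(0.80, 0.7, 0.05)
    expert_sp = elicit_beta(0.85, 0.6, 0.05)
    return PriorSpecification(
        se_priors=(scale_se, scale_se, expert_se),
        sp_priors=(scale_sp, scale_sp, expert_sp),
    )


def prior_log_density(params: ModelParameters, spec: PriorSpecification) -> float:
    """Log joint prior density f(theta); -inf outside the support.

    Sums beta log-densities for the six accuracies and prevalence, and the
    -log(range) normalizers of the two conditional-uniform covariance priors.
    """
    if not params.is_valid():
        return -math.inf
    total = 0.0
    for hyper, x in zip(spec.se_priors, params.se):
        total += hyper.logpdf(x)
    for hyper, x in zip(spec.sp_priors, params.sp):
        total += hyper.logpdf(x)
    total += spec.prevalence_prior.logpdf(params.prevalence)
    lo, hi = covariance_bounds(params.se[0], params.se[1])
    if hi - lo <= 0.0:
        return -math.inf
    total -= math.log(hi - lo)
    lo, hi = covariance_bounds(params.sp[0], params.sp[1])
    if hi - lo <= 0.0:
        return -math.inf
    total -= math.log(hi - lo)
    return total
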