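"""Metropolis-within-Gibbs sampling of the joint posterior and chain summaries.

The target is log L(theta | Y) + log f(theta).  Each iteration sweeps the
nine components in a fixed order with single-site random-walk proposals:

* accuracies and prevalence are proposed on the logit scale (the proposal
  is symmetric in logit space; the change-of-variables Jacobian
  x(1-x) enters the acceptance ratio), which keeps them strictly inside
  (0, 1);
* the covariances C+ and C- are proposed by a random walk on their current
  admissible interval with reflection at the bounds (symmetric, no
  Jacobian);
* an update of Se1 or Se2 (resp. Sp1 or Sp2) moves the admissible interval
  of C+ (resp. C-), so those proposals are joint: the covariance is
  rescaled to preserve its relative position in the interval and the linear
  rescaling's Jacobian (new range / old range) enters the acceptance ratio.
  This keeps every emitted draw inside the valid region without silent
  truncation.

Proposal scales are tuned during burn-in toward a 20-40% acceptance rate
and frozen afterwards, so the post-burn-in chain is a genuine Markov chain.
Per-chain random streams are spawned deterministically from one master seed.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd

from .data import CrossClassifiedCounts
from .model import (
    PARAM_NAMES,
    ModelParameters,
    _cell_probs8,
    _theta_valid,
    default_initial_values,
)
from .priors import PriorSpecification

_IDX_CPOS, _IDX_CNEG = 7, 8
# which covariance (if any) each accuracy update drags along
_COUPLED_COV = {0: _IDX_CPOS, 1: _IDX_CPOS, 3: _IDX_CNEG, 4: _IDX_CNEG}


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run configuration.

    ``initial_values`` may be a single :class:`ModelParameters` (used for
    chain 0, with the remaining chains jittered deterministically on the
    logit scale for overdispersed starts) or a list with one entry per
    chain.  ``proposal_scales`` are initial random-walk standard deviations
    for the nine components (logit scale for the first seven).
    """

    n_chains: int = 3
    n_iterations: int = 60_000
    n_burnin: int = 10_000
    thin: int = 5
    seed: int = 0
    initial_values: object = None
    proposal_scales: Sequence[float] | None = None
    tune: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("need 0 <= n_burnin < n_iterations")

    def resolve_initials(self) -> list[ModelParameters]:
        init = self.initial_values
        if init is None:
            init = default_initial_values()
        if isinstance(init, ModelParameters):
            base = [init] * self.n_chains
        else:
            base = list(init)
            if len(base) != self.n_chains:
                raise ValueError(
                    f"got {len(base)} initial value sets for {self.n_chains} chains"
                )
        for p in base:
            p.validate()
        return base

    def resolve_scales(self) -> np.ndarray:
        if self.proposal_scales is None:
            scales = np.array([0.3] * 7 + [0.05, 0.05])
        else:
            scales = np.asarray(self.proposal_scales, dtype=float)
            if scales.shape != (9,) or np.any(scales <= 0):
                raise ValueError("proposal_scales must be 9 positive reals")
        return scales


@dataclass
class PosteriorChain:
    """Retained draws of one chain (post burn-in, thinned)."""

    draws: np.ndarray  # shape (n_kept, 9), canonical parameter order
    chain_id: int
    acceptance_rates: np.ndarray  # per parameter, post burn-in
    proposal_scales: np.ndarray  # frozen scales actually used after burn-in
    warnings: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.draws, columns=list(PARAM_NAMES))
        df.insert(0, "chain", self.chain_id)
        return df


@dataclass(frozen=True)
class PosteriorSummary:
    """Pooled posterior medians, 95% equal-tailed intervals and diagnostics."""

    table: pd.DataFrame  # index: parameter; median, ci_lower, ci_upper, mcse, rhat, ess
    notes: tuple[str, ...] = ()

    def __getitem__(self, parameter: str) -> pd.Series:
        return self.table.loc[parameter]

    def median(self, parameter: str) -> float:
        return float(self.table.loc[parameter, "median"])

    def interval(self, parameter: str) -> tuple[float, float]:
        row = self.table.loc[parameter]
        return float(row["ci_lower"]), float(row["ci_upper"])


def _covariance_window(th, j):
    """Admissible (lo, hi) for covariance component j at the current accuracies."""
    if j == _IDX_CPOS:
        a1, a2 = th[0], th[1]
    else:
        a1, a2 = th[3], th[4]
    return (a1 - 1.0) * (1.0 - a2), min(a1, a2) - a1 * a2


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    if width <= 0.0:
        return lo
    y = (x - lo) % (2.0 * width)
    return lo + (width - abs(y - width))


def _log_target(th, y, alphas, betas) -> float:
    """log likelihood + log prior (both up to theta-free constants)."""
    if not _theta_valid(th):
        return -math.inf
    probs = _cell_probs8(th)
    total = 0.0
    for yk, pk in zip(y, probs):
        if yk:
            if pk <= 0.0:
                return -math.inf
            total += yk * math.log(pk)
    for i in range(7):
        x = th[i]
        if x <= 0.0 or x >= 1.0:
            return -math.inf
        total += (alphas[i] - 1.0) * math.log(x) + (betas[i] - 1.0) * math.log(1.0 - x)
    lo, hi = _covariance_window(th, _IDX_CPOS)
    if hi - lo <= 0.0:
        return -math.inf
    total -= math.log(hi - lo)
    lo, hi = _covariance_window(th, _IDX_CNEG)
    if hi - lo <= 0.0:
        return -math.inf
    total -= math.log(hi - lo)
    return total


def _run_chain(y, alphas, betas, theta0, scales, config, rng, chain_id):
    n_iter, n_burn, thin = config.n_iterations, config.n_burnin, config.thin
    th = list(theta0)
    logt = _log_target(th, y, alphas, betas)
    if not math.isfinite(logt):
        raise ValueError(
            f"chain {chain_id}: initial values have zero posterior density"
        )
    scales = list(scales)
    n_kept = (n_iter - n_burn + thin - 1) // thin
    kept = np.empty((n_kept, 9))
    k = 0
    acc_post = [0] * 9
    n_post = 0
    acc_win = [0] * 9
    win_size = 100
    # pre-drawn randomness, in fixed consumption order for reproducibility
    normals = rng.standard_normal((n_iter, 9))
    logu = np.log(rng.random((n_iter, 9)))

    for it in range(n_iter):
        z_row = normals[it]
        u_row = logu[it]
        for j in range(9):
            if j < 7:
                x = th[j]
                zeta = math.log(x / (1.0 - x)) + scales[j] * z_row[j]
                if abs(zeta) > 700.0:
                    continue  # overflow-guard: treat as rejected
                xp = 1.0 / (1.0 + math.exp(-zeta))
                if xp <= 0.0 or xp >= 1.0:
                    continue
                prop = th.copy()
                prop[j] = xp
                log_jac = math.log(xp * (1.0 - xp)) - math.log(x * (1.0 - x))
                cov_j = _COUPLED_COV.get(j)
                if cov_j is not None:
                    lo, hi = _covariance_window(th, cov_j)
                    lon, hin = _covariance_window(prop, cov_j)
                    old_w, new_w = hi - lo, hin - lon
                    if old_w <= 0.0 or new_w <= 0.0:
                        continue
                    rel = (th[cov_j] - lo) / old_w
                    prop[cov_j] = lon + rel * new_w
                    log_jac += math.log(new_w / old_w)
            else:
                lo, hi = _covariance_window(th, j)
                if hi - lo <= 0.0:
                    continue
                prop = th.copy()
                prop[j] = _reflect(th[j] + scales[j] * z_row[j], lo, hi)
                log_jac = 0.0
            logt_prop = _log_target(prop, y, alphas, betas)
            if u_row[j] < logt_prop - logt + log_jac:
                th = prop
                logt = logt_prop
                acc_win[j] += 1
                if it >= n_burn:
                    acc_post[j] += 1
        if it >= n_burn:
            n_post += 1
            if (it - n_burn) % thin == 0:
                kept[k] = th
                k += 1
        elif config.tune and (it + 1) % win_size == 0:
            for j in range(9):
                rate = acc_win[j] / win_size
                if rate < 0.20:
                    scales[j] *= 0.8
                elif rate > 0.40:
                    scales[j] *= 1.25
            acc_win = [0] * 9

    rates = np.array([a / max(n_post, 1) for a in acc_post])
    chain_warnings = [
        f"parameter {PARAM_NAMES[j]}: no accepted moves after burn-in"
        for j in range(9)
        if acc_post[j] == 0
    ]
    return PosteriorChain(
        draws=kept[:k],
        chain_id=chain_id,
        acceptance_rates=rates,
        proposal_scales=np.array(scales),
        warnings=chain_warnings,
    )


def sample_posterior(
    data: CrossClassifiedCounts,
    prior: PriorSpecification,
    config: SamplerConfig,
) -> list[PosteriorChain]:
    """Run the configured chains and return their retained draws.

    Deterministic given (data, prior, config): chain streams are spawned
    from ``config.seed`` and randomness is consumed in a fixed order.
    """
    y = tuple(float(c) for c in data.counts)
    alphas, betas = prior.accuracy_hyperparameters()
    initials = config.resolve_initials()
    scales = config.resolve_scales()
    streams = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains = []
    for cid in range(config.n_chains):
        rng = np.random.default_rng(streams[cid])
        theta0 = initials[cid].to_vector()
        if cid > 0 and not isinstance(config.initial_values, (list, tuple)):
            theta0 = _jitter_start(theta0, rng)
        chains.append(
            _run_chain(y, alphas, betas, list(theta0), scales, config, rng, cid)
        )
    return chains


def _jitter_start(theta0, rng, sd: float = 0.5):
    """Overdispersed start: jitter accuracies/prevalence on the logit scale."""
    th = list(theta0)
    for j in range(7):
        z = math.log(th[j] / (1.0 - th[j])) + sd * rng.standard_normal()
        th[j] = 1.0 / (1.0 + math.exp(-z))
    lo, hi = _covariance_window(th, _IDX_CPOS)
    th[_IDX_CPOS] = lo + (hi - lo) * rng.uniform(0.25, 0.75)
    lo, hi = _covariance_window(th, _IDX_CNEG)
    th[_IDX_CNEG] = lo + (hi - lo) * rng.uniform(0.25, 0.75)
    return th


def _stacked(chains: Sequence[PosteriorChain]) -> np.ndarray:
    """Draws as an (n_chains, n_draws, 9) array; chains truncated to equal length."""
    n = min(c.n_draws for c in chains)
    return np.stack([c.draws[:n] for c in chains])


def summarize(chains: Sequence[PosteriorChain]) -> PosteriorSummary:
    """Pooled medians, equal-tailed 95% intervals and convergence diagnostics.

    The potential-scale-reduction statistic is the rank-normalized split-R̂;
    with a single chain the split-chain variant is all that is available and
    a note says so.  Requires at least 100 retained draws in total.
    """
    if len(chains) == 0:
        raise ValueError("at least one chain is required")
    arr = _stacked(chains)
    if arr.shape[0] * arr.shape[1] < 100:
        raise ValueError(
            f"too few retained draws ({arr.shape[0] * arr.shape[1]}) to "
            "summarize; need at least 100"
        )
    pooled = arr.reshape(-1, 9)
    rows = {}
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # arviz warns on 1-chain rhat input
        for i, name in enumerate(PARAM_NAMES):
            x = arr[:, :, i]
            if np.ptp(x) == 0.0:  # constant chain: diagnostics degenerate
                mcse, ess, rhat = 0.0, float(x.size), 1.0
            else:
                mcse = float(az.mcse(x, method="median"))
                ess = float(az.ess(x))
                rhat = float(az.rhat(x))
            rows[name] = {
                "median": float(np.median(pooled[:, i])),
                "ci_lower": float(np.quantile(pooled[:, i], 0.025)),
                "ci_upper": float(np.quantile(pooled[:, i], 0.975)),
                "mcse": mcse,
                "rhat": rhat,
                "ess": ess,
            }
    notes = []
    if len(chains) == 1:
        notes.append("single chain: split-chain R-hat variant used")
    notes.extend(w for c in chains for w in c.warnings)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "parameter"
    return PosteriorSummary(table=table, notes=tuple(notes))


def convergence_report(
    chains: Sequence[PosteriorChain], threshold: float = 1.05
) -> pd.DataFrame:
    """Per-parameter R̂ and effective sample size, with a flag column.

    Parameters whose potential scale reduction exceeds ``threshold``
    (default 1.05) are flagged.
    """
    summary = summarize(chains)
    report = summary.table[["rhat", "ess"]].copy()
    report["flagged"] = report["rhat"] > threshold
    report.attrs["notes"] = list(summary.notes)
    return report


def mirror_mode_fraction(chains: Sequence[PosteriorChain]) -> float:
    """Fraction of pooled draws sitting in the label-swapped mode.

    A draw is counted when Se_i + Sp_i < 1 for all three tests
    simultaneously — the mirror solution that informative accuracy priors
    are meant to suppress.  Reported as a diagnostic.
    """
    pooled = _stacked(chains).reshape(-1, 9)
    flipped = (pooled[:, 0:3] + pooled[:, 3:6]) < 1.0
    return float(np.mean(np.all(flipped, axis=1)))


def chains_to_parameters(chain: PosteriorChain) -> list[ModelParameters]:
    """Materialize a chain's draws as ModelParameters objects."""
    return [ModelParameters.from_vector(row) for row in chain.draws]
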