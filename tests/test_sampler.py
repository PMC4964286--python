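"""MCMC sampler behaviour: validity, determinism, summaries, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from latentdx import (
    CrossClassifiedCounts,
    ModelParameters,
    SamplerConfig,
    sample_posterior,
    summarize,
)
from latentdx.model import PARAM_NAMES
from latentdx.priors import BetaHyperparameters, PriorSpecification
from latentdx.sampler import (
    PosteriorChain,
    convergence_report,
    mirror_mode_fraction,
)

ZERO_DATA = CrossClassifiedCounts((0,) * 8)


def small_config(**kw):
    base = dict(n_chains=2, n_iterations=4000, n_burnin=1000, thin=1, seed=5)
    base.update(kw)
    return SamplerConfig(**base)


class TestSampling:
    def test_every_draw_satisfies_model_constraints(self, stroke_counts,
                                                    elicited_priors):
        chains = sample_posterior(stroke_counts, elicited_priors, small_config())
        for chain in chains:
            for row in chain.draws[::37]:
                ModelParameters.from_vector(row).validate()
            # vectorized full check of the box and covariance constraints
            d = chain.draws
            assert np.all((d[:, :7] > 0) & (d[:, :7] < 1))
            lo = (d[:, 0] - 1) * (1 - d[:, 1])
            hi = np.minimum(d[:, 0], d[:, 1]) - d[:, 0] * d[:, 1]
            assert np.all((d[:, 7] >= lo) & (d[:, 7] <= hi))

    def test_reproducible_given_seed(self, stroke_counts, elicited_priors):
        cfg = small_config(n_iterations=2000, n_burnin=500)
        a = summarize(sample_posterior(stroke_counts, elicited_priors, cfg))
        b = summarize(sample_posterior(stroke_counts, elicited_priors, cfg))
        assert a.table.equals(b.table)

    def test_different_seeds_differ(self, stroke_counts, elicited_priors):
        a = sample_posterior(stroke_counts, elicited_priors,
                             small_config(n_chains=1, seed=1))
        b = sample_posterior(stroke_counts, elicited_priors,
                             small_config(n_chains=1, seed=2))
        assert not np.array_equal(a[0].draws, b[0].draws)

    def test_prior_recovery_with_empty_data(self, elicited_priors):
        """With n=0 the posterior is the prior: Se3 median must match
        the Beta(48.283, 12.821) median from scipy's quantile routine."""
        cfg = SamplerConfig(n_chains=1, n_iterations=50_000, n_burnin=10_000,
                            thin=1, seed=9)
        summary = summarize(sample_posterior(ZERO_DATA, elicited_priors, cfg))
        h = elicited_priors.se_priors[2]
        expected = float(stats.beta.median(h.alpha, h.beta))
        assert summary.median("Se3") == pytest.approx(expected, abs=0.01)
        # prevalence prior is uniform: median 0.5, 95% interval (0.025, 0.975)
        assert summary.median("prevalence") == pytest.approx(0.5, abs=0.02)
        lo, hi = summary.interval("prevalence")
        assert lo == pytest.approx(0.025, abs=0.02)
        assert hi == pytest.approx(0.975, abs=0.02)

    def test_overwhelming_priors_pin_the_accuracies(self, stroke_counts):
        """Near-point-mass accuracy priors dominate any data."""
        m = (0.75, 0.9, 0.8, 0.85, 0.7, 0.95)
        scale = 1e6
        hypers = [BetaHyperparameters(scale * v, scale * (1 - v)) for v in m]
        spec = PriorSpecification(se_priors=tuple(hypers[:3]),
                                  sp_priors=tuple(hypers[3:]))
        cfg = small_config(n_chains=1, initial_values=ModelParameters(
            se=m[:3], sp=m[3:], prevalence=0.5))
        summary = summarize(sample_posterior(stroke_counts, spec, cfg))
        for name, v in zip(("Se1", "Se2", "Se3", "Sp1", "Sp2", "Sp3"), m):
            assert summary.median(name) == pytest.approx(v, abs=0.01)


class TestSummarize:
    def test_constant_chain_degenerates_cleanly(self):
        draws = np.tile(np.linspace(0.1, 0.9, 9), (200, 1))
        chain = PosteriorChain(draws=draws, chain_id=0,
                               acceptance_rates=np.zeros(9),
                               proposal_scales=np.ones(9))
        summary = summarize([chain])
        row = summary["Se1"]
        assert row["median"] == 0.1
        assert row["ci_upper"] - row["ci_lower"] == 0.0
        assert row["mcse"] == 0.0

    def test_quantiles_of_a_uniform_grid(self):
        draws = np.tile(np.linspace(0.2, 0.8, 9), (10_000, 1))
        draws[:, 0] = np.arange(1, 10_001) / 10_000
        chain = PosteriorChain(draws=draws, chain_id=0,
                               acceptance_rates=np.zeros(9),
                               proposal_scales=np.ones(9))
        summary = summarize([chain])
        assert summary.median("Se1") == pytest.approx(0.5, abs=1e-3)
        lo, hi = summary.interval("Se1")
        assert lo == pytest.approx(0.025, abs=1e-3)
        assert hi == pytest.approx(0.975, abs=1e-3)

    def test_too_few_draws_rejected(self):
        chain = PosteriorChain(draws=np.full((50, 9), 0.5), chain_id=0,
                               acceptance_rates=np.zeros(9),
                               proposal_scales=np.ones(9))
        with pytest.raises(ValueError, match="too few"):
            summarize([chain])

    def test_single_chain_notes_split_variant(self):
        rng = np.random.default_rng(3)
        chain = PosteriorChain(draws=rng.random((500, 9)), chain_id=0,
                               acceptance_rates=np.zeros(9),
                               proposal_scales=np.ones(9))
        summary = summarize([chain])
        assert any("split" in note for note in summary.notes)


class TestConvergence:
    def _chain(self, draws, cid):
        return PosteriorChain(draws=draws, chain_id=cid,
                              acceptance_rates=np.zeros(9),
                              proposal_scales=np.ones(9))

    def test_identical_chains_give_unit_statistic(self):
        rng = np.random.default_rng(41)
        draws = rng.random((2000, 9))
        report = convergence_report([self._chain(draws, 0),
                                     self._chain(draws.copy(), 1)])
        assert np.allclose(report["rhat"], 1.0, atol=0.01)
        assert not report["flagged"].any()

    def test_disjoint_chains_flagged(self):
        rng = np.random.default_rng(43)
        a = rng.uniform(0.0, 0.1, (1000, 9))
        b = rng.uniform(0.9, 1.0, (1000, 9))
        report = convergence_report([self._chain(a, 0), self._chain(b, 1)])
        assert (report["rhat"] > 1.5).all()
        assert report["flagged"].all()


class TestMirrorMode:
    def test_informative_priors_suppress_label_swapped_mode(self, stroke_counts,
                                                            elicited_priors):
        chains = sample_posterior(stroke_counts, elicited_priors,
                                  small_config(seed=11))
        assert mirror_mode_fraction(chains) == 0.0


class TestConfigValidation:
    def test_burnin_must_precede_end(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iterations=100, n_burnin=100)

    def test_wrong_number_of_initials_rejected(self, stroke_counts,
                                               elicited_priors):
        cfg = small_config(initial_values=[ModelParameters(
            se=(0.7,) * 3, sp=(0.8,) * 3, prevalence=0.5)])
        with pytest.raises(ValueError, match="initial value"):
            sample_posterior(stroke_counts, elicited_priors, cfg)
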