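"""Cell probabilities, covariance constraints and the observed-data likelihood."""

import math

import numpy as np
import pytest
from scipy import stats

from latentdx import (
    CrossClassifiedCounts,
    InvalidParameterError,
    ModelParameters,
    PATTERNS,
    cell_probabilities,
    cell_probability,
    conditional_joint,
    covariance_bounds,
    default_initial_values,
    log_likelihood,
)

from conftest import random_valid_parameters


def params(se, sp, prev, cp=0.0, cn=0.0):
    return ModelParameters(se=se, sp=sp, prevalence=prev, cov_pos=cp, cov_neg=cn)


class TestConditionalJoint:
    def test_independence_with_symmetric_accuracies(self):
        p = params((0.5, 0.5, 0.5), (0.5, 0.5, 0.5), 0.5)
        assert conditional_joint(p, 1, 1, 1) == pytest.approx(0.25)

    def test_covariance_shifts_discordant_cells_down(self):
        p = params((0.7, 0.9, 0.5), (0.5, 0.5, 0.5), 0.5, cp=0.05)
        assert conditional_joint(p, 1, 0, 1) == pytest.approx(0.7 * 0.1 - 0.05)

    def test_product_of_specificities_when_independent(self):
        p = params((0.5, 0.5, 0.5), (0.8, 0.85, 0.5), 0.5)
        assert conditional_joint(p, 0, 0, 0) == pytest.approx(0.8 * 0.85)

    @pytest.mark.parametrize("d", [0, 1])
    def test_four_outcomes_sum_to_one(self, d):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_valid_parameters(rng)
            total = sum(
                conditional_joint(p, t1, t2, d) for t1 in (0, 1) for t2 in (0, 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_invalid_covariance_raises_naming_bound(self):
        p = params((0.7, 0.9, 0.5), (0.5, 0.5, 0.5), 0.5, cp=0.2)
        with pytest.raises(InvalidParameterError, match="cov_pos"):
            conditional_joint(p, 1, 1, 1)


class TestCovarianceBounds:
    @pytest.mark.parametrize(
        "a1,a2,expected",
        [
            (1.0, 1.0, (0.0, 0.0)),
            (0.7, 0.9, (-0.03, 0.07)),
            (0.5, 0.5, (-0.25, 0.25)),
        ],
    )
    def test_known_bounds(self, a1, a2, expected):
        lo, hi = covariance_bounds(a1, a2)
        assert lo == pytest.approx(expected[0], abs=1e-12)
        assert hi == pytest.approx(expected[1], abs=1e-12)

    def test_bounds_bracket_zero(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a1, a2 = rng.uniform(0, 1, 2)
            lo, hi = covariance_bounds(a1, a2)
            assert lo <= 0.0 <= hi

    def test_admissibility_matches_conditional_table(self):
        """C inside the bounds <=> all four conditional cells lie in [0, 1].

        The equivalence holds for accuracy pairs with a1 + a2 >= 1 (tests at
        least as good as chance, the relevant regime); below that the stated
        lower bound must be tightened by C >= -a1*a2, which the parameter
        validator also enforces.
        """
        rng = np.random.default_rng(13)
        for _ in range(100):
            a1 = rng.uniform(0.5, 0.95)
            a2 = rng.uniform(1.0 - a1, 0.95)
            lo, hi = covariance_bounds(a1, a2)
            for c in (lo + 1e-12, (lo + hi) / 2, hi - 1e-12):
                cells = [a1 * a2 + c, a1 * (1 - a2) - c, (1 - a1) * a2 - c,
                         (1 - a1) * (1 - a2) + c]
                assert all(-1e-9 <= v <= 1 + 1e-9 for v in cells)
            for c in (lo - 1e-6, hi + 1e-6):
                cells = [a1 * a2 + c, a1 * (1 - a2) - c, (1 - a1) * a2 - c,
                         (1 - a1) * (1 - a2) + c]
                assert any(v < 0 or v > 1 for v in cells)

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(ValueError):
            covariance_bounds(1.2, 0.5)


class TestCellProbability:
    def test_perfect_tests_reveal_latent_status(self):
        p = params((1, 1, 1), (1, 1, 1), 0.6)
        assert cell_probability(p, 1, 1, 1) == pytest.approx(0.6)
        assert cell_probability(p, 0, 0, 0) == pytest.approx(0.4)
        for pat in PATTERNS:
            if pat not in ((1, 1, 1), (0, 0, 0)):
                assert cell_probability(p, *pat) == pytest.approx(0.0)

    def test_two_component_mixture_value(self):
        # independent enumeration over D: pi*prod(Se) + (1-pi)*prod(1-Sp)
        p = default_initial_values()
        expected = 0.623 * 0.748 * 0.945 * 0.850 + 0.377 * 0.156 * 0.117 * 0.065
        assert cell_probability(p, 1, 1, 1) == pytest.approx(expected, abs=1e-12)
        assert cell_probability(p, 1, 1, 1) == pytest.approx(0.37476, abs=5e-6)

    def test_normalization_over_random_parameters(self):
        rng = np.random.default_rng(17)
        for _ in range(1000):
            p = random_valid_parameters(rng)
            vec = cell_probabilities(p)
            assert sum(vec.probs) == pytest.approx(1.0, abs=1e-10)
            assert all(v >= -1e-12 for v in vec.probs)

    def test_independence_reduction(self):
        """With C+=C-=0 the mixture equals the plain product-form model."""
        rng = np.random.default_rng(19)
        for _ in range(100):
            q = random_valid_parameters(rng)
            p = ModelParameters(se=q.se, sp=q.sp, prevalence=q.prevalence)
            for t1, t2, t3 in PATTERNS:
                se_term = math.prod(
                    s if t else 1 - s for s, t in zip(p.se, (t1, t2, t3))
                )
                sp_term = math.prod(
                    (1 - s) if t else s for s, t in zip(p.sp, (t1, t2, t3))
                )
                expected = p.prevalence * se_term + (1 - p.prevalence) * sp_term
                assert cell_probability(p, t1, t2, t3) == pytest.approx(
                    expected, abs=1e-12
                )


class TestLogLikelihood:
    def test_single_subject_likelihood_is_log_cell_probability(self):
        data = CrossClassifiedCounts((1, 0, 0, 0, 0, 0, 0, 0))
        p = default_initial_values()
        assert log_likelihood(p, data) == pytest.approx(
            math.log(cell_probability(p, 1, 1, 1))
        )

    def test_matches_multinomial_logpmf_oracle(self, stroke_counts):
        """Independent oracle: scipy's multinomial log-pmf minus its constant."""
        p = default_initial_values()
        probs = np.array(cell_probabilities(p).probs)
        y = np.array(stroke_counts.counts)
        full = stats.multinomial.logpmf(y, n=y.sum(), p=probs)
        const = full - np.sum(y * np.log(probs))
        assert log_likelihood(p, stroke_counts) == pytest.approx(full - const)
        assert log_likelihood(p, stroke_counts) < 0

    def test_zero_probability_with_positive_count_is_neg_inf(self):
        p = params((1, 1, 1), (1, 1, 1), 0.6)
        data = CrossClassifiedCounts((0, 5, 0, 0, 0, 0, 0, 0))
        assert log_likelihood(p, data) == -math.inf

    def test_mirror_symmetry_of_likelihood(self, stroke_counts):
        """Label swap (pi->1-pi, Se_i<->1-Sp_i, C+<->C-) leaves L unchanged."""
        rng = np.random.default_rng(23)
        for _ in range(100):
            p = random_valid_parameters(rng)
            swapped = p.label_swap()
            assert log_likelihood(p, stroke_counts) == pytest.approx(
                log_likelihood(swapped, stroke_counts), rel=1e-10
            )


class TestParameterVector:
    def test_vector_round_trip(self):
        rng = np.random.default_rng(29)
        p = random_valid_parameters(rng)
        assert ModelParameters.from_vector(p.to_vector()) == p

    def test_label_swap_is_involution(self):
        p = default_initial_values()
        assert p.label_swap().label_swap() == p

    @pytest.mark.parametrize(
        "bad,message",
        [
            (dict(se=(1.2, 0.5, 0.5), sp=(0.5,) * 3, prevalence=0.5), "Se1"),
            (dict(se=(0.5,) * 3, sp=(0.5,) * 3, prevalence=-0.1), "prevalence"),
            (
                dict(se=(0.7, 0.9, 0.5), sp=(0.5,) * 3, prevalence=0.5,
                     cov_pos=0.5),
                "cov_pos",
            ),
        ],
    )
    def test_validation_names_offending_field(self, bad, message):
        with pytest.raises(InvalidParameterError, match=message):
            ModelParameters(**bad).validate()
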