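"""Exact-inference engine: worked examples, invariants, degenerate cases."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biasnet import (
    DomainError,
    EvidenceImpossibleError,
    PriorSet,
    UndefinedLLRError,
    bias_direction_prior,
    clamp_prior,
    joint_enumerate,
    logit2,
    posterior_marginals,
    variable_llr,
)
from biasnet.network import (
    VARIABLES,
    posterior_marginals_from_joint,
    variable_llr_from_joint,
)
from biasnet import network as _net
from biasnet.network import testimony_likelihood as prob_testimony_true

GRID = (0.1, 0.3, 0.5, 0.7, 0.9)

interior = st.floats(min_value=0.01, max_value=0.99, allow_nan=False)


def priors_strategy():
    return st.builds(
        PriorSet, h=interior, sl=interior, bi=interior, e=interior, hl=interior
    )


class TestClampPrior:
    @pytest.mark.parametrize(
        "p, expected", [(1.0, 0.99), (0.0, 0.01), (0.73, 0.73), (0.5, 0.5)]
    )
    def test_values(self, p, expected):
        assert clamp_prior(p) == expected

    @pytest.mark.parametrize("p", [-0.1, 1.1, float("nan")])
    def test_domain_error(self, p):
        with pytest.raises(DomainError):
            clamp_prior(p)


class TestBiasDirectionPrior:
    @pytest.mark.parametrize(
        "sl, hl, expected",
        [(1, 1, 1.0), (0, 1, 0.0), (0.7, 0.2, 0.38), (0.5, 0.9, 0.5)],
    )
    def test_values(self, sl, hl, expected):
        # oracle: enumerate the 2x2 match/clash table
        enum = sum(
            (sl if s else 1 - sl) * (hl if h else 1 - hl)
            for s, h in itertools.product((0, 1), repeat=2)
            if s == h
        )
        assert bias_direction_prior(sl, hl) == pytest.approx(expected, abs=1e-12)
        assert bias_direction_prior(sl, hl) == pytest.approx(enum, abs=1e-12)


class TestTestimonyLikelihood:
    def test_impartial_expert_reports_truth(self):
        priors = PriorSet(h=0.5, sl=0.3, bi=0.0, e=1.0, hl=1.0)
        assert prob_testimony_true(True, priors) == 1.0
        assert prob_testimony_true(False, priors) == 0.0

    def test_fully_biased_source_ignores_truth(self):
        priors = PriorSet(h=0.5, sl=0.3, bi=1.0, e=0.7, hl=1.0)
        assert prob_testimony_true(True, priors) == pytest.approx(0.3)
        assert prob_testimony_true(False, priors) == pytest.approx(0.3)

    def test_mixed_case(self):
        priors = PriorSet(h=0.5, sl=0.5, bi=0.5, e=0.5, hl=1.0)
        # 0.5*0.5 + 0.5*(0.5*1 + 0.5*0.5)
        assert prob_testimony_true(True, priors) == pytest.approx(0.625)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(priors=priors_strategy(), h_state=st.booleans())
    def test_matches_enumeration(self, priors, h_state):
        joint = joint_enumerate(priors)
        mask = joint.column("H") == int(h_state)
        oracle = (joint.prior[mask] * joint.p_true[mask]).sum() / joint.prior[
            mask
        ].sum()
        assert prob_testimony_true(h_state, priors) == pytest.approx(
            oracle, abs=1e-12
        )


class TestJointTable:
    def test_uniform_roots(self):
        joint = joint_enumerate(PriorSet(h=0.5, sl=0.5, bi=0.5, e=0.5, hl=0.5))
        assert len(joint.prior) == 32
        np.testing.assert_allclose(joint.prior, 1 / 32)

    def test_clamped_leaning_zeroes_half_the_table(self):
        joint = joint_enumerate(PriorSet(h=0.5, sl=0.5, bi=0.5, e=0.5, hl=1.0))
        assert (joint.prior[joint.column("HL") == 0] == 0).all()

    def test_total_testimony_probability(self):
        joint = joint_enumerate(PriorSet(h=0.5, sl=0.5, bi=0.5, e=0.5, hl=1.0))
        assert joint.weights(True).sum() == pytest.approx(0.5, abs=1e-12)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(priors=priors_strategy())
    def test_masses_normalised_and_cpts_deterministic(self, priors):
        joint = joint_enumerate(priors)
        assert joint.prior.sum() == pytest.approx(1.0, abs=1e-12)
        assert set(np.unique(joint.p_true)) <= {0.0, 0.5, 1.0}
        w = joint.weights(True)
        assert (w / w.sum()).sum() == pytest.approx(1.0, abs=1e-12)


class TestPosteriorMarginals:
    def test_fully_biased_source_uninformative_about_h(self):
        priors = PriorSet(h=0.5, sl=0.4, bi=1.0, e=0.8, hl=1.0)
        assert posterior_marginals(priors, True).h == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_example(self):
        priors = PriorSet(h=0.5, sl=0.5, bi=0.5, e=0.5, hl=1.0)
        assert posterior_marginals(priors, True).h == pytest.approx(0.625)

    def test_bias_attribution_example(self):
        priors = PriorSet(h=0.1, sl=1.0, bi=0.5, e=0.5, hl=1.0)
        # (0.5*1)/(0.5*1 + 0.5*0.3)
        assert posterior_marginals(priors, True).bi == pytest.approx(
            1 / 1.3, abs=1e-9
        )

    def test_no_update_when_likelihoods_equal(self):
        # h = 0.5 and f = 0.5: bias-intensity and expertise posteriors
        # equal their priors
        priors = PriorSet(h=0.5, sl=0.5, bi=0.3, e=0.8, hl=1.0)
        post = posterior_marginals(priors, True)
        assert post.bi == pytest.approx(0.3, abs=1e-12)
        assert post.e == pytest.approx(0.8, abs=1e-12)

    def test_impossible_evidence_raises(self):
        # impartial expert certain the hypothesis is true cannot say FALSE
        priors = PriorSet(h=1.0, sl=0.5, bi=0.0, e=1.0, hl=1.0)
        with pytest.raises(EvidenceImpossibleError):
            posterior_marginals(priors, False)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(priors=priors_strategy(), testimony=st.booleans())
    def test_matches_enumeration(self, priors, testimony):
        fast = posterior_marginals(priors, testimony)
        brute = posterior_marginals_from_joint(priors, testimony)
        for name in VARIABLES:
            assert getattr(fast, name.lower()) == pytest.approx(
                getattr(brute, name.lower()), abs=1e-12
            )


class TestVariableLLR:
    def test_fully_biased_source_gives_zero_h_llr(self):
        priors = PriorSet(h=0.5, sl=0.4, bi=1.0, e=0.8, hl=1.0)
        assert variable_llr(priors, True, "H") == 0.0

    def test_symmetric_example_and_mirror(self):
        priors = PriorSet(h=0.5, sl=0.5, bi=0.5, e=0.5, hl=1.0)
        assert variable_llr(priors, True, "H") == pytest.approx(math.log2(5 / 3))
        assert variable_llr(priors, False, "H") == pytest.approx(-math.log2(5 / 3))

    def test_impartial_nonexpert_gives_zero_h_llr(self):
        priors = PriorSet(h=0.5, sl=0.4, bi=0.0, e=0.0, hl=1.0)
        assert variable_llr(priors, True, "H") == 0.0

    def test_infinite_llr_is_signed_not_capped(self):
        # impartial expert: testimony TRUE impossible under H = False
        priors = PriorSet(h=0.5, sl=0.5, bi=0.0, e=1.0, hl=1.0)
        assert variable_llr(priors, True, "H") == math.inf
        assert variable_llr(priors, False, "H") == -math.inf

    def test_undefined_llr_raises(self):
        # fully biased source against the hypothesis can never say TRUE,
        # under either hypothesis state
        priors = PriorSet(h=0.5, sl=0.0, bi=1.0, e=0.5, hl=1.0)
        with pytest.raises(UndefinedLLRError):
            variable_llr(priors, True, "H")

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        priors=priors_strategy(),
        testimony=st.booleans(),
        target=st.sampled_from(VARIABLES),
    )
    def test_matches_enumeration(self, priors, testimony, target):
        assert variable_llr(priors, testimony, target) == pytest.approx(
            variable_llr_from_joint(priors, testimony, target), abs=1e-12
        )

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        priors=priors_strategy(),
        testimony=st.booleans(),
        target=st.sampled_from(VARIABLES),
    )
    def test_logit_identity(self, priors, testimony, target):
        """logit2(posterior) - logit2(prior) equals the LLR wherever finite."""
        post = posterior_marginals(priors, testimony)
        prior = priors.f if target == "BD" else getattr(priors, target.lower())
        llr = variable_llr(priors, testimony, target)
        lhs = logit2(getattr(post, target.lower())) - logit2(prior)
        if math.isfinite(lhs) and math.isfinite(llr):
            assert lhs == pytest.approx(llr, abs=1e-9)


class TestSymmetries:
    def test_swap_hl_sl(self):
        for h, a, b, bi, e in itertools.product(GRID, GRID, GRID, GRID, GRID):
            p1 = PriorSet(h=h, hl=a, sl=b, bi=bi, e=e)
            p2 = PriorSet(h=h, hl=b, sl=a, bi=bi, e=e)
            assert variable_llr(p1, True, "H") == pytest.approx(
                variable_llr(p2, True, "H"), abs=1e-12
            )
            m1 = posterior_marginals(p1, True)
            m2 = posterior_marginals(p2, True)
            assert m1.hl == pytest.approx(m2.sl, abs=1e-12)
            assert m1.sl == pytest.approx(m2.hl, abs=1e-12)

    def test_complement_negates_h_llr(self):
        for h, sl, bi, e in itertools.product(GRID, GRID, GRID, GRID):
            p1 = PriorSet(h=h, hl=1.0, sl=sl, bi=bi, e=e)
            p2 = PriorSet(h=1 - h, hl=1.0, sl=1 - sl, bi=bi, e=e)
            assert variable_llr(p1, True, "H") == pytest.approx(
                -variable_llr(p2, False, "H"), abs=1e-12
            )


class TestPriorSet:
    def test_clamped_leaves_hl_alone_by_default(self):
        p = PriorSet(h=1.0, sl=0.0, bi=0.5, e=1.0, hl=1.0)
        c = p.clamped()
        assert (c.h, c.sl, c.bi, c.e, c.hl) == (0.99, 0.01, 0.5, 0.99, 1.0)
        assert p.clamped(clamp_hl=True).hl == 0.99

    def test_rejects_out_of_range(self):
        with pytest.raises(DomainError):
            PriorSet(h=1.2, sl=0.5, bi=0.5, e=0.5)

    def test_testimony_coercion(self):
        assert _net.Testimony.coerce("true") is _net.Testimony.TRUE
        assert _net.Testimony.coerce(False) is _net.Testimony.FALSE
        with pytest.raises(DomainError):
            _net.Testimony.coerce("maybe")
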