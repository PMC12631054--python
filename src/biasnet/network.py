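"""Exact inference in the bias-and-expertise source-credibility network.

The network has seven binary variables describing one act of testimony:

* ``H``  — Hypothesis: the state of the world the claim concerns.
* ``HL`` — Hypothesis Leaning: which political side the hypothesis, if
  true, supports (state 1 = pro-Government by convention).
* ``SL`` — Source Leaning: which side the source favours, if biased.
* ``BI`` — Bias Intensity: whether the source is biased (1) or impartial (0).
* ``E``  — Expertise: whether an impartial source reports the ground truth
  (1) or testifies at random (0).
* ``BD`` — Bias Direction: FOR (1) when source and hypothesis leanings
  match, AGAINST (0) when they clash; a deterministic child of SL and HL.
* ``T``  — Testimony: the source's claim that the hypothesis is true or
  false.  A biased source's testimony follows its bias direction only; an
  impartial expert reports the truth; an impartial non-expert says
  true/false with probability one half.

All conditional probability entries are therefore 0, 0.5 or 1; the model
has no free parameters.  The five root variables (H, HL, SL, BI, E) carry
independent marginal priors, and inference conditions on an observed
testimony value.  Because the network is tiny, inference is exact: the
closed-form routines below marginalise analytically, and
:func:`joint_enumerate` provides the brute-force 32-configuration joint
table that doubles as an independent oracle for them.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd

from ._exceptions import (
    DomainError,
    EvidenceImpossibleError,
    UndefinedLLRError,
)

__all__ = [
    "VARIABLES",
    "ROOT_VARIABLES",
    "Testimony",
    "PriorSet",
    "PosteriorSet",
    "JointTable",
    "clamp_prior",
    "bias_direction_prior",
    "testimony_likelihood",
    "conditional_likelihoods",
    "joint_enumerate",
    "posterior_marginals",
    "posterior_marginals_from_joint",
    "variable_llr",
    "variable_llr_from_joint",
    "logit2",
]

#: Variables a posterior or likelihood-ratio query may target.
VARIABLES = ("H", "HL", "SL", "BI", "E", "BD")

#: The five a-priori independent root variables, in enumeration order.
ROOT_VARIABLES = ("H", "HL", "SL", "BI", "E")


class Testimony(Enum):
    """The observed content of the source's claim."""

    TRUE = True
    FALSE = False

    @classmethod
    def coerce(cls, value: "Testimony | bool | str") -> "Testimony":
        if isinstance(value, cls):
            return value
        if isinstance(value, bool):
            return cls(value)
        if isinstance(value, str):
            key = value.strip().upper()
            if key in cls.__members__:
                return cls.__members__[key]
        raise DomainError(f"not a testimony value: {value!r}")


def _check_prob(p: float, name: str) -> float:
    p = float(p)
    if math.isnan(p) or not 0.0 <= p <= 1.0:
        raise DomainError(f"{name} must lie in [0, 1], got {p!r}")
    return p


def clamp_prior(p: float) -> float:
    """Map elicited certainty to the nearest expressible prior.

    Priors of exactly 0 or 1 make likelihood ratios infinite or undefined,
    so they are replaced by 0.01 and 0.99; interior values pass through
    unchanged.
    """
    p = _check_prob(p, "prior")
    if p == 1.0:
        return 0.99
    if p == 0.0:
        return 0.01
    return p


def logit2(p: float) -> float:
    """Base-2 log-odds; ``-inf``/``inf`` at 0 and 1."""
    p = _check_prob(p, "probability")
    if p == 0.0:
        return -math.inf
    if p == 1.0:
        return math.inf
    return math.log2(p / (1.0 - p))


@dataclass(frozen=True)
class PriorSet:
    """Marginal priors on the five root variables.

    Each field is the probability of the variable's "1" state: ``h`` that
    the hypothesis is true, ``hl`` that it leans pro-Government, ``sl``
    that the source leans pro-Government, ``bi`` that the source is
    biased, ``e`` that the source is an expert.  ``hl`` defaults to
    exactly 1, the study convention for hypotheses always phrased in
    their pro-Government polarity.
    """

    h: float
    sl: float
    bi: float
    e: float
    hl: float = 1.0

    def __post_init__(self) -> None:
        for name in ("h", "hl", "sl", "bi", "e"):
            _check_prob(getattr(self, name), name)

    def clamped(self, clamp_hl: bool = False) -> "PriorSet":
        """Return a copy with 0/1 priors pulled to 0.01/0.99.

        ``hl`` is exempt by default: the hypothesis-leaning prior is a
        design constant (exactly 1) that happens never to produce an
        undefined posterior.  Pass ``clamp_hl=True`` to clamp it too (the
        difference is negligible).
        """
        out = replace(
            self,
            h=clamp_prior(self.h),
            sl=clamp_prior(self.sl),
            bi=clamp_prior(self.bi),
            e=clamp_prior(self.e),
        )
        if clamp_hl:
            out = replace(out, hl=clamp_prior(self.hl))
        return out

    @property
    def f(self) -> float:
        """Prior probability that Bias Direction = FOR."""
        return bias_direction_prior(self.sl, self.hl)


@dataclass(frozen=True)
class PosteriorSet:
    """Posterior marginals of every non-testimony variable's "1" state."""

    h: float
    hl: float
    sl: float
    bi: float
    e: float
    bd: float

    def __getitem__(self, target: str) -> float:
        return getattr(self, target.lower())


def bias_direction_prior(sl: float, hl: float) -> float:
    """P(Bias Direction = FOR) = P(source and hypothesis leanings match).

    FOR when both lean side 1 or both lean side 0, hence
    ``sl*hl + (1-sl)*(1-hl)``.
    """
    sl = _check_prob(sl, "sl")
    hl = _check_prob(hl, "hl")
    return sl * hl + (1.0 - sl) * (1.0 - hl)


def testimony_likelihood(h_state: bool, priors: PriorSet) -> float:
    """P(Testimony = TRUE | Hypothesis = ``h_state``), roots marginalised.

    A biased source (probability ``bi``) asserts the hypothesis iff its
    bias direction is FOR (probability ``f``); an impartial source either
    reports the truth (expert, probability ``e``) or flips a fair coin.
    """
    f = priors.f
    truth_report = 1.0 if h_state else 0.0
    return priors.bi * f + (1.0 - priors.bi) * (
        priors.e * truth_report + (1.0 - priors.e) * 0.5
    )


def _p_true_given(priors: PriorSet, target: str, state: int) -> float:
    """P(T = TRUE | target = state) with the other roots at their priors."""
    h, hl, sl, bi, e = priors.h, priors.hl, priors.sl, priors.bi, priors.e
    f = priors.f
    m = e * h + (1.0 - e) * 0.5  # impartial-source branch, H marginalised
    s = float(state)
    if target == "H":
        return bi * f + (1.0 - bi) * (e * s + (1.0 - e) * 0.5)
    if target == "HL":
        f_cond = sl if state else 1.0 - sl
        return bi * f_cond + (1.0 - bi) * m
    if target == "SL":
        f_cond = hl if state else 1.0 - hl
        return bi * f_cond + (1.0 - bi) * m
    if target == "BI":
        return f if state else m
    if target == "E":
        return bi * f + (1.0 - bi) * (h if state else 0.5)
    if target == "BD":
        return bi * s + (1.0 - bi) * m
    raise DomainError(f"unknown target variable {target!r}")


def conditional_likelihoods(
    priors: PriorSet, testimony: Testimony | bool | str, target: str
) -> tuple[float, float]:
    """(P(testimony | target=1), P(testimony | target=0)), closed form."""
    testimony = Testimony.coerce(testimony)
    target = target.upper()
    l1 = _p_true_given(priors, target, 1)
    l0 = _p_true_given(priors, target, 0)
    if testimony is Testimony.FALSE:
        l1, l0 = 1.0 - l1, 1.0 - l0
    return l1, l0


def _prior_of(priors: PriorSet, target: str) -> float:
    if target == "BD":
        return priors.f
    return getattr(priors, target.lower())


def posterior_marginals(
    priors: PriorSet, testimony: Testimony | bool | str
) -> PosteriorSet:
    """Posterior marginals of all six variables given one testimony.

    Uses the analytic one-step Bayes update per variable,
    ``post = prior*L1 / (prior*L1 + (1-prior)*L0)``; agrees with
    brute-force enumeration (:func:`posterior_marginals_from_joint`) to
    machine precision.

    Raises
    ------
    EvidenceImpossibleError
        If the observed testimony has probability zero under the priors
        (cannot happen once h, sl, bi, e are clamped into (0, 1)).
    """
    testimony = Testimony.coerce(testimony)
    out = {}
    for target in VARIABLES:
        l1, l0 = conditional_likelihoods(priors, testimony, target)
        prior = _prior_of(priors, target)
        num = prior * l1
        den = num + (1.0 - prior) * l0
        if den == 0.0:
            raise EvidenceImpossibleError(
                f"testimony {testimony.name} has probability 0 under the priors"
            )
        out[target.lower()] = num / den
    return PosteriorSet(**out)


def variable_llr(
    priors: PriorSet, testimony: Testimony | bool | str, target: str
) -> float:
    """Base-2 log likelihood ratio of the testimony for one variable.

    ``log2(P(testimony | target=1) / P(testimony | target=0))``, the
    amount added to the base-2 logit prior to obtain the logit posterior.
    Signed infinities are returned when exactly one conditional is zero.

    Raises
    ------
    UndefinedLLRError
        If both conditionals are zero (0/0).
    """
    l1, l0 = conditional_likelihoods(priors, testimony, target)
    if l1 == 0.0 and l0 == 0.0:
        raise UndefinedLLRError(
            f"testimony impossible under both states of {target}"
        )
    if l0 == 0.0:
        return math.inf
    if l1 == 0.0:
        return -math.inf
    return math.log2(l1 / l0)


# ---------------------------------------------------------------------------
# Brute-force enumeration: the 32-row joint table over the root variables.
# ---------------------------------------------------------------------------

# all 2^5 root configurations, one row per (H, HL, SL, BI, E)
_CONFIGS = np.array(list(itertools.product((0, 1), repeat=5)), dtype=np.int8)


@dataclass(frozen=True)
class JointTable:
    """Exhaustive joint over the 32 root configurations.

    ``states`` holds one row per configuration of (H, HL, SL, BI, E);
    ``prior`` the product of the independent root priors; ``p_true`` the
    conditional probability of Testimony = TRUE under that configuration
    (always 0, 0.5 or 1, Bias Direction being resolved deterministically
    from SL and HL).
    """

    states: np.ndarray
    prior: np.ndarray
    p_true: np.ndarray

    def column(self, name: str) -> np.ndarray:
        name = name.upper()
        if name == "BD":
            return (self.states[:, 1] == self.states[:, 2]).astype(np.int8)
        return self.states[:, ROOT_VARIABLES.index(name)]

    def weights(self, testimony: Testimony | bool | str) -> np.ndarray:
        """Unnormalised posterior mass of each configuration."""
        testimony = Testimony.coerce(testimony)
        like = self.p_true if testimony is Testimony.TRUE else 1.0 - self.p_true
        return self.prior * like

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(ROOT_VARIABLES))
        df["BD"] = self.column("BD")
        df["prior"] = self.prior
        df["p_true"] = self.p_true
        return df


def joint_enumerate(priors: PriorSet) -> JointTable:
    """Build the 32-configuration joint table for a set of root priors."""
    marginals = np.array(
        [priors.h, priors.hl, priors.sl, priors.bi, priors.e]
    )
    prob = np.where(_CONFIGS == 1, marginals, 1.0 - marginals)
    prior = prob.prod(axis=1)

    h, hl, sl, bi, e = (_CONFIGS[:, i] for i in range(5))
    bd = (hl == sl).astype(float)
    # biased source follows bias direction; impartial expert reports the
    # truth; impartial non-expert testifies at random
    p_true = np.where(bi == 1, bd, np.where(e == 1, h, 0.5)).astype(float)
    return JointTable(states=_CONFIGS, prior=prior, p_true=p_true)


def posterior_marginals_from_joint(
    priors: PriorSet, testimony: Testimony | bool | str
) -> PosteriorSet:
    """Brute-force counterpart of :func:`posterior_marginals`."""
    joint = joint_enumerate(priors)
    w = joint.weights(testimony)
    total = w.sum()
    if total == 0.0:
        raise EvidenceImpossibleError(
            "testimony has probability 0 under the priors"
        )
    post = {
        name.lower(): float(w[joint.column(name) == 1].sum() / total)
        for name in VARIABLES
    }
    return PosteriorSet(**post)


def variable_llr_from_joint(
    priors: PriorSet, testimony: Testimony | bool | str, target: str
) -> float:
    """Brute-force counterpart of :func:`variable_llr`.

    Conditions the joint on each state of the target (renormalising the
    remaining roots) and compares the testimony's probability under each.
    """
    testimony = Testimony.coerce(testimony)
    joint = joint_enumerate(priors)
    like = joint.p_true if testimony is Testimony.TRUE else 1.0 - joint.p_true
    col = joint.column(target)
    conds = []
    for state in (1, 0):
        mask = col == state
        mass = joint.prior[mask].sum()
        if mass == 0.0:
            # target state has prior 0: condition via the closed form
            # (the conditional likelihood does not involve the target's
            # own prior), falling back to the analytic expression
            conds.append(conditional_likelihoods(priors, testimony, target)[0 if state else 1])
        else:
            conds.append(float((joint.prior[mask] * like[mask]).sum() / mass))
    l1, l0 = conds
    if l1 == 0.0 and l0 == 0.0:
        raise UndefinedLLRError(
            f"testimony impossible under both states of {target}"
        )
    if l0 == 0.0:
        return math.inf
    if l1 == 0.0:
        return -math.inf
    return math.log2(l1 / l0)
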