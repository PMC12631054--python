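"""Per-participant model predictions from elicited 0-100 slider judgments.

Two experimental designs are supported:

* **Study 1** (within-subjects, 3 source-leaning x 2 expertise x 2
  testimony): participants rate each source's leaning, bias intensity and
  expertise before hearing its claim; the hypothesis prior is assumed to
  be 0.5 (the listener professes "no idea").  The model predicts the
  posterior belief in the hypothesis.
* **Study 2** (between-subjects, 5 evidence x 2 claim-1 x 2 claim-2, one
  trial each): stage 1 feeds the elicited post-evidence hypothesis prior
  and prior source perceptions into the network and predicts posterior
  perceptions of bias intensity, source leaning and expertise after the
  source's first claim; stage 2 re-enters the *observed* posterior
  perceptions together with the prior for a second hypothesis and
  predicts the posterior belief after the source's second claim.

Every hypothesis is phrased in its pro-Government polarity, so the
hypothesis-leaning prior is fixed at exactly 1 and the testimony mapping
(claim asserts the pro-Government state -> TRUE) carries all polarity
logic.  Sliders are divided by 100 and 0/1 priors clamped to 0.01/0.99.
There are no free parameters anywhere in the pipeline.
"""

from __future__ import annotations

import numbers
import warnings

import pandas as pd

from ._exceptions import DomainError, ValidationError
from .network import PriorSet, Testimony, clamp_prior, posterior_marginals

__all__ = [
    "STUDY1_CONDITIONS",
    "STUDY2_CONDITIONS",
    "STUDY1_COLUMNS",
    "STUDY2_COLUMNS",
    "slider_to_prob",
    "map_testimony",
    "predict_study1_row",
    "predict_study2_stage1_row",
    "predict_study2_stage2_row",
    "predict_study1",
    "predict_study2",
    "predict_trials",
]

STUDY1_CONDITIONS = {
    "expertise": ("High", "Low"),
    "bias": ("ProGov", "Neutral", "AntiGov"),
    "testimony": ("Pro", "Anti"),
}

STUDY2_CONDITIONS = {
    "evidence": (
        "strong-harm",
        "weak-harm",
        "neutral",
        "weak-benefit",
        "strong-benefit",
    ),
    "claim1": ("beneficial", "harmful"),
    "claim2": ("beneficial", "harmful"),
}

#: Required input columns per design (schema version 1).
STUDY1_COLUMNS = (
    "participant_id",
    "expertise",
    "bias",
    "testimony",
    "sl_prior",
    "bi_prior",
    "e_prior",
)
STUDY2_COLUMNS = (
    "participant_id",
    "evidence",
    "claim1",
    "claim2",
    "h_tax_prior",
    "sl_prior",
    "bi_prior",
    "e_prior",
    "sl_posterior_obs",
    "bi_posterior_obs",
    "e_posterior_obs",
    "h_crime_prior",
)

# claim vocabulary -> whether the claim asserts the pro-Government
# hypothesis state (TRUE) or denies it (FALSE)
_TESTIMONY_MAP = {
    "pro": True,
    "beneficial": True,
    "reduced": True,
    "reduced the crime rate": True,
    "anti": False,
    "harmful": False,
    "damaging": False,
    "increased": False,
    "increased the crime rate": False,
}


def slider_to_prob(s: float) -> float:
    """Convert a 0-100 slider judgment to a clamped probability.

    Values are divided by 100; 0 and 100 are clamped to 0.01 and 0.99.
    Non-integer values within range are accepted with a warning (export
    formats vary); out-of-range or non-numeric values raise.
    """
    if isinstance(s, bool) or not isinstance(s, numbers.Real):
        raise ValidationError(f"slider value must be numeric, got {s!r}")
    s = float(s)
    if s != s or not 0.0 <= s <= 100.0:
        raise ValidationError(f"slider value must lie in [0, 100], got {s!r}")
    if s != int(s):
        warnings.warn(
            f"non-integer slider value {s!r} accepted", stacklevel=2
        )
    return clamp_prior(s / 100.0)


def map_testimony(label: str) -> Testimony:
    """Map a claim-direction label onto the testimony variable.

    Claims asserting the pro-Government hypothesis state ("Pro",
    "beneficial", "reduced the crime rate") map to TRUE; claims denying
    it ("Anti", "harmful", "increased the crime rate") to FALSE.
    """
    if not isinstance(label, str):
        raise ValidationError(f"testimony label must be a string, got {label!r}")
    key = label.strip().lower()
    if key not in _TESTIMONY_MAP:
        raise ValidationError(f"unknown testimony label {label!r}")
    return Testimony(_TESTIMONY_MAP[key])


def predict_study1_row(
    sl_prior: float, bi_prior: float, e_prior: float, testimony: str
) -> float:
    """Predicted posterior belief in the hypothesis for one trial.

    The hypothesis prior is assumed flat (0.5); hypothesis leaning fixed
    at 1; source perceptions come from the participant's sliders.
    """
    priors = PriorSet(
        h=0.5,
        hl=1.0,
        sl=slider_to_prob(sl_prior),
        bi=slider_to_prob(bi_prior),
        e=slider_to_prob(e_prior),
    )
    return posterior_marginals(priors, map_testimony(testimony)).h


def predict_study2_stage1_row(
    h_tax_prior: float,
    sl_prior: float,
    bi_prior: float,
    e_prior: float,
    claim1: str,
) -> dict[str, float]:
    """Predicted posterior source perceptions after the first claim."""
    priors = PriorSet(
        h=slider_to_prob(h_tax_prior),
        hl=1.0,
        sl=slider_to_prob(sl_prior),
        bi=slider_to_prob(bi_prior),
        e=slider_to_prob(e_prior),
    )
    post = posterior_marginals(priors, map_testimony(claim1))
    return {
        "bi_posterior_pred": post.bi,
        "sl_posterior_pred": post.sl,
        "e_posterior_pred": post.e,
    }


def predict_study2_stage2_row(
    h_crime_prior: float,
    sl_posterior_obs: float,
    bi_posterior_obs: float,
    e_posterior_obs: float,
    claim2: str,
) -> float:
    """Predicted posterior belief in the second hypothesis.

    The participant's *observed* posterior source perceptions after the
    first claim re-enter the network as fresh independent priors,
    together with the elicited prior for the second (crime) hypothesis.
    """
    priors = PriorSet(
        h=slider_to_prob(h_crime_prior),
        hl=1.0,
        sl=slider_to_prob(sl_posterior_obs),
        bi=slider_to_prob(bi_posterior_obs),
        e=slider_to_prob(e_posterior_obs),
    )
    return posterior_marginals(priors, map_testimony(claim2)).h


def _require_columns(df: pd.DataFrame, columns: tuple[str, ...], study: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{study} table is missing columns: {missing}")


def _check_levels(df: pd.DataFrame, conditions: dict[str, tuple[str, ...]]) -> None:
    for col, levels in conditions.items():
        bad = set(df[col].unique()) - set(levels)
        if bad:
            raise ValidationError(f"unknown {col} labels: {sorted(bad)}")


def predict_study1(trials: pd.DataFrame) -> pd.DataFrame:
    """Predict the hypothesis posterior for every Study-1 trial.

    Returns a copy of the condition/key columns with an added
    ``h_posterior_pred`` column on the probability scale.
    """
    _require_columns(trials, STUDY1_COLUMNS, "Study-1")
    _check_levels(trials, {k: v for k, v in STUDY1_CONDITIONS.items()})
    out = trials.loc[:, [c for c in STUDY1_COLUMNS if c in trials.columns]].copy()
    out["h_posterior_pred"] = [
        predict_study1_row(r.sl_prior, r.bi_prior, r.e_prior, r.testimony)
        for r in trials.itertuples()
    ]
    return out


def predict_study2(trials: pd.DataFrame) -> pd.DataFrame:
    """Run both Study-2 prediction stages for every trial.

    Adds ``bi/sl/e_posterior_pred`` (stage 1, from prior perceptions and
    the first claim) and ``h_crime_posterior_pred`` (stage 2, from
    observed posterior perceptions and the second claim).
    """
    _require_columns(trials, STUDY2_COLUMNS, "Study-2")
    _check_levels(trials, {k: v for k, v in STUDY2_CONDITIONS.items()})
    out = trials.loc[:, [c for c in STUDY2_COLUMNS if c in trials.columns]].copy()
    stage1 = pd.DataFrame(
        [
            predict_study2_stage1_row(
                r.h_tax_prior, r.sl_prior, r.bi_prior, r.e_prior, r.claim1
            )
            for r in trials.itertuples()
        ],
        index=trials.index,
    )
    out = pd.concat([out, stage1], axis=1)
    out["h_crime_posterior_pred"] = [
        predict_study2_stage2_row(
            r.h_crime_prior,
            r.sl_posterior_obs,
            r.bi_posterior_obs,
            r.e_posterior_obs,
            r.claim2,
        )
        for r in trials.itertuples()
    ]
    return out


def predict_trials(trials: pd.DataFrame, study: str) -> pd.DataFrame:
    """Dispatch to the per-study prediction pipeline (``S1`` or ``S2``)."""
    study = study.upper()
    if study == "S1":
        return predict_study1(trials)
    if study == "S2":
        return predict_study2(trials)
    raise ValidationError(f"unknown study label {study!r} (expected S1 or S2)")
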