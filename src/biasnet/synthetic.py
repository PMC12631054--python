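"""Seeded synthetic trial tables with the structure of the two designs.

The published participant tables are not bundled, so this module
generates stand-in data with the same shape and statistical structure:
per-condition prior judgments drawn from two-parameter Beta profiles,
noise-free model posteriors computed through the prediction pipeline,
and observed posterior sliders produced as posterior plus additive
truncated Gaussian response noise rounded to the 0-100 integer scale.

* **Study 1** (within-subjects): each participant rates six sources —
  the 3 leaning x 2 expertise crossing — and hears one claim from each;
  which claim comes from which source alternates between two fixed
  testimony layouts ("streams"), assigned deterministically by
  participant parity.  72 total trials per 12 design cells emerge from
  150 participants as in the original sample-size regime (145 after
  exclusions; the generator default is 150).
* **Study 2** (between-subjects): one trial per participant, randomly
  assigned to one of the 5 evidence x 2 claim-1 x 2 claim-2 cells.  The
  post-evidence hypothesis prior is drawn from an evidence-dependent
  Beta profile; source-perception priors are near-neutral because the
  source is unknown to the listener by design.

Each participant draws from an independent substream keyed by (seed,
participant index), so enlarging a table never perturbs earlier rows.
Hidden ``*_truth`` columns carry the noise-free model posteriors for
recovery testing and equal a fresh run of the prediction module on the
same rows exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .prediction import (
    STUDY2_CONDITIONS,
    predict_study1,
    predict_study2,
)

__all__ = [
    "BetaProfile",
    "GeneratorConfig",
    "default_profiles",
    "generate",
    "STUDY1_SOURCES",
]

#: Study-1 source layout: (expertise, bias) with the claim direction heard
#: in each of the two counterbalancing streams.
STUDY1_SOURCES = (
    # expertise, bias, stream-A testimony, stream-B testimony
    ("High", "AntiGov", "Pro", "Anti"),
    ("High", "ProGov", "Anti", "Pro"),
    ("High", "Neutral", "Pro", "Anti"),
    ("Low", "AntiGov", "Anti", "Pro"),
    ("Low", "ProGov", "Pro", "Anti"),
    ("Low", "Neutral", "Anti", "Pro"),
)


@dataclass(frozen=True)
class BetaProfile:
    """Two-parameter Beta distribution for one elicited prior."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValidationError("Beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def draw_slider(self, rng: np.random.Generator) -> int:
        return int(round(100.0 * rng.beta(self.a, self.b)))


def default_profiles(design: str) -> dict[str, BetaProfile]:
    """Documented default prior profiles per design.

    Study 1: expertise sliders concentrate high for the think-tank head
    and low for the construction worker; leaning sliders concentrate on
    the described side (symmetric for the neutral source); bias
    intensity concentrates above one half for partisan descriptions and
    below for neutral ones.  Study 2: the post-evidence hypothesis prior
    shifts with the evidence level (means 0.15/0.35/0.5/0.65/0.85);
    perceptions of the unknown source stay near-neutral.
    """
    design = design.upper()
    if design == "S1":
        return {
            "e:High": BetaProfile(8, 2),
            "e:Low": BetaProfile(2, 8),
            "sl:ProGov": BetaProfile(8, 2),
            "sl:AntiGov": BetaProfile(2, 8),
            "sl:Neutral": BetaProfile(5, 5),
            "bi:ProGov": BetaProfile(6, 3),
            "bi:AntiGov": BetaProfile(6, 3),
            "bi:Neutral": BetaProfile(3, 6),
        }
    if design == "S2":
        return {
            "h_tax:strong-harm": BetaProfile(1.5, 8.5),
            "h_tax:weak-harm": BetaProfile(3.5, 6.5),
            "h_tax:neutral": BetaProfile(5, 5),
            "h_tax:weak-benefit": BetaProfile(6.5, 3.5),
            "h_tax:strong-benefit": BetaProfile(8.5, 1.5),
            "sl": BetaProfile(5, 5),
            "bi": BetaProfile(5, 5),
            "e": BetaProfile(5, 5),
            "h_crime": BetaProfile(5, 5),
        }
    raise ValidationError(f"unknown design label {design!r} (expected S1 or S2)")


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic table.

    ``noise_sd`` is the standard deviation, on the probability scale, of
    the additive Gaussian response noise applied to the model posterior
    before truncation to [0, 1] and rounding to the integer slider.
    """

    design: str
    n_participants: int
    seed: int
    noise_sd: float = 0.05
    profiles: dict[str, BetaProfile] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design.upper() not in ("S1", "S2"):
            raise ValidationError(f"unknown design label {self.design!r}")
        if self.n_participants < 1:
            raise ValidationError("n_participants must be at least 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    def resolved_profiles(self) -> dict[str, BetaProfile]:
        out = default_profiles(self.design)
        out.update(self.profiles)
        return out


def _participant_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based substream: earlier participants never change when
    # n_participants grows
    return np.random.default_rng([seed, index])


def _noisy_slider(p: float, noise_sd: float, rng: np.random.Generator) -> int:
    if noise_sd > 0:
        p = p + rng.normal(0.0, noise_sd)
    return int(round(100.0 * min(1.0, max(0.0, p))))


def _generate_s1(config: GeneratorConfig) -> pd.DataFrame:
    profiles = config.resolved_profiles()
    rows = []
    for i in range(config.n_participants):
        rng = _participant_rng(config.seed, i)
        stream = "A" if i % 2 == 0 else "B"
        for expertise, bias, testimony_a, testimony_b in STUDY1_SOURCES:
            rows.append(
                {
                    "participant_id": f"S1-{i:04d}",
                    "study": "S1",
                    "stream": stream,
                    "expertise": expertise,
                    "bias": bias,
                    "testimony": testimony_a if stream == "A" else testimony_b,
                    "sl_prior": profiles[f"sl:{bias}"].draw_slider(rng),
                    "bi_prior": profiles[f"bi:{bias}"].draw_slider(rng),
                    "e_prior": profiles[f"e:{expertise}"].draw_slider(rng),
                }
            )
    table = pd.DataFrame(rows)
    preds = predict_study1(table)
    table["h_posterior_truth"] = preds["h_posterior_pred"]
    table["h_posterior_obs"] = [
        _noisy_slider(p, config.noise_sd, _participant_rng(config.seed, 1_000_000 + i))
        for i, p in enumerate(table["h_posterior_truth"])
    ]
    return table


def _generate_s2(config: GeneratorConfig) -> pd.DataFrame:
    profiles = config.resolved_profiles()
    evidence_levels = STUDY2_CONDITIONS["evidence"]
    claims = STUDY2_CONDITIONS["claim1"]
    rows = []
    for i in range(config.n_participants):
        rng = _participant_rng(config.seed, i)
        evidence = evidence_levels[rng.integers(len(evidence_levels))]
        claim1 = claims[rng.integers(2)]
        claim2 = claims[rng.integers(2)]
        rows.append(
            {
                "participant_id": f"S2-{i:04d}",
                "study": "S2",
                "evidence": evidence,
                "claim1": claim1,
                "claim2": claim2,
                "h_tax_prior": profiles[f"h_tax:{evidence}"].draw_slider(rng),
                "sl_prior": profiles["sl"].draw_slider(rng),
                "bi_prior": profiles["bi"].draw_slider(rng),
                "e_prior": profiles["e"].draw_slider(rng),
                "h_crime_prior": profiles["h_crime"].draw_slider(rng),
            }
        )
    table = pd.DataFrame(rows)

    # stage 1: noise-free posterior perceptions, then noisy observed sliders
    stage1_in = table.assign(
        sl_posterior_obs=0, bi_posterior_obs=0, e_posterior_obs=0
    )
    preds = predict_study2(stage1_in)
    for var in ("bi", "sl", "e"):
        table[f"{var}_posterior_truth"] = preds[f"{var}_posterior_pred"]
    noise_rngs = [
        _participant_rng(config.seed, 1_000_000 + i)
        for i in range(len(table))
    ]
    for var in ("bi", "sl", "e"):
        table[f"{var}_posterior_obs"] = [
            _noisy_slider(p, config.noise_sd, rng)
            for p, rng in zip(table[f"{var}_posterior_truth"], noise_rngs)
        ]

    # stage 2 consumes the *observed* posterior perceptions, as the
    # prediction pipeline does
    preds2 = predict_study2(table)
    table["h_crime_posterior_truth"] = preds2["h_crime_posterior_pred"]
    table["h_crime_posterior_obs"] = [
        _noisy_slider(
            p, config.noise_sd, _participant_rng(config.seed, 2_000_000 + i)
        )
        for i, p in enumerate(table["h_crime_posterior_truth"])
    ]
    return table


def generate(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a seeded synthetic trial table for one design.

    Identical configurations reproduce identical tables byte-for-byte.
    Public slider columns are integers in [0, 100]; ``*_truth`` columns
    hold the noise-free model posteriors on the probability scale.
    """
    if config.design.upper() == "S1":
        return _generate_s1(config)
    return _generate_s2(config)
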