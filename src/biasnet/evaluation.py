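"""Model-performance statistics and derived trend variables.

Three statistics judge an observed-vs-predicted posterior table:

* **Pearson r** across all trials (plus the mean of per-participant
  correlations, which respects the non-independence of repeated
  measures; participants whose observed or predicted vector is constant
  have no defined correlation and are excluded and counted);
* **Brier score** — the mean squared difference between observed and
  predicted posteriors, an absolute-accuracy measure;
* **Variance in Means (VM)** — the adjusted-R² percentage of variance
  in per-condition mean observed posteriors explained by per-condition
  mean predictions, a trend-fidelity measure.  Being R²-based, VM is
  invariant to affine rescaling of the predictions: it rewards getting
  the *pattern* across conditions right, not calibration.

The derived variables (`persuasion`, `lean_shift`, `ev_support`,
`flip_code`) re-express raw posteriors in claim-relative coordinates so
that trends across conditions can be compared between observations and
predictions, and :func:`sensitivity_power_r` gives the minimum Pearson
correlation detectable at a given power via the Fisher-z approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._exceptions import UndefinedMetricError, ValidationError

__all__ = [
    "MetricsReport",
    "evaluate_study1_table",
    "evaluate_study2_table",
    "brier",
    "pearson_r",
    "mean_individual_r",
    "variance_in_means",
    "evaluate_table",
    "persuasion",
    "lean_shift",
    "ev_support",
    "flip_code",
    "sensitivity_power_r",
]


@dataclass(frozen=True)
class MetricsReport:
    """Performance statistics for one observed-vs-predicted table."""

    pearson_r: float
    mean_individual_r: float
    brier: float
    vm: float
    n_trials: int
    n_conditions: int
    n_participants_excluded_from_individual_r: int

    def to_dict(self) -> dict:
        return asdict(self)


def _pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or obs.size == 0:
        raise ValidationError(
            f"observed and predicted must be equal-length 1-d vectors, "
            f"got shapes {obs.shape} and {pred.shape}"
        )
    return obs, pred


def brier(observed, predicted) -> float:
    """Mean squared difference between observed and predicted posteriors."""
    obs, pred = _pair(observed, predicted)
    return float(np.mean((obs - pred) ** 2))


def pearson_r(observed, predicted) -> float:
    """Pearson correlation across all trials."""
    obs, pred = _pair(observed, predicted)
    if obs.size < 2 or np.ptp(obs) == 0.0 or np.ptp(pred) == 0.0:
        raise UndefinedMetricError("correlation undefined for constant input")
    return float(stats.pearsonr(obs, pred).statistic)


def mean_individual_r(
    table: pd.DataFrame,
    observed: str = "observed",
    predicted: str = "predicted",
    participant: str = "participant_id",
) -> tuple[float, int]:
    """Mean of per-participant Pearson correlations.

    Participants for whom a correlation is undefined — fewer than two
    trials, or a constant observed or predicted vector (for example an
    estimated posterior of 0.5 in every condition) — are excluded; the
    second return value counts them.
    """
    rs = []
    excluded = 0
    for _, block in table.groupby(participant, sort=False):
        obs = block[observed].to_numpy(dtype=float)
        pred = block[predicted].to_numpy(dtype=float)
        if obs.size < 2 or np.ptp(obs) == 0.0 or np.ptp(pred) == 0.0:
            excluded += 1
            continue
        rs.append(stats.pearsonr(obs, pred).statistic)
    if not rs:
        raise UndefinedMetricError("no participant has a defined correlation")
    return float(np.mean(rs)), excluded


def variance_in_means(observed_means, predicted_means) -> float:
    """Adjusted-R² percentage of variance in condition means explained.

    Ordinary least squares of observed condition means on predicted
    condition means (one regressor plus intercept); returns
    ``100 * (1 - (1 - R²)(n - 1)/(n - 2))`` for ``n`` conditions.
    """
    obs, pred = _pair(observed_means, predicted_means)
    n = obs.size
    if n < 3:
        raise ValidationError("variance_in_means needs at least 3 conditions")
    if np.ptp(pred) == 0.0:
        raise UndefinedMetricError("zero-variance predictor: VM undefined")
    fit = sm.OLS(obs, sm.add_constant(pred)).fit()
    return float(100.0 * fit.rsquared_adj)


def evaluate_table(
    table: pd.DataFrame,
    observed: str = "observed",
    predicted: str = "predicted",
    participant: str = "participant_id",
    condition_cols: list[str] | None = None,
) -> MetricsReport:
    """Compute all performance statistics for one joined table.

    ``condition_cols`` name the design cells over which VM's condition
    means are taken (e.g. the three Study-1 factors, giving 12 cells).
    """
    if condition_cols is None or not condition_cols:
        raise ValidationError("condition_cols must name at least one factor")
    obs = table[observed].to_numpy(dtype=float)
    pred = table[predicted].to_numpy(dtype=float)
    means = table.groupby(condition_cols, sort=True)[[observed, predicted]].mean()
    try:
        mean_r, excluded = mean_individual_r(table, observed, predicted, participant)
    except UndefinedMetricError:
        # e.g. one trial per participant in a between-subjects design
        mean_r, excluded = float("nan"), table[participant].nunique()
    return MetricsReport(
        pearson_r=pearson_r(obs, pred),
        mean_individual_r=mean_r,
        brier=brier(obs, pred),
        vm=variance_in_means(means[observed], means[predicted]),
        n_trials=len(table),
        n_conditions=len(means),
        n_participants_excluded_from_individual_r=excluded,
    )


def _joined_metrics(
    table: pd.DataFrame, obs_slider: str, pred: str, cells: list[str]
) -> MetricsReport:
    work = table[["participant_id", *cells]].copy()
    work["observed"] = table[obs_slider].astype(float) / 100.0
    work["predicted"] = table[pred].astype(float)
    return evaluate_table(work, condition_cols=cells)


def evaluate_study1_table(joined: pd.DataFrame) -> MetricsReport:
    """Metrics for a joined Study-1 table.

    Expects ``h_posterior_obs`` (0-100 slider) and ``h_posterior_pred``
    (probability) columns; VM condition means are taken over the 12
    design cells (3 leanings x 2 expertise x 2 testimony).
    """
    return _joined_metrics(
        joined,
        "h_posterior_obs",
        "h_posterior_pred",
        ["expertise", "bias", "testimony"],
    )


def evaluate_study2_table(joined: pd.DataFrame) -> dict[str, MetricsReport]:
    """Per-variable metrics for a joined Study-2 table.

    Source-perception posteriors use the 10 evidence x claim-1 cells;
    the second-hypothesis posterior uses the full 20-cell design.  With
    one trial per participant the mean individual correlation is
    undefined, so those fields are reported as NaN with every
    participant counted as excluded.
    """
    out = {}
    for var in ("bi", "sl", "e"):
        out[var] = _joined_metrics(
            joined,
            f"{var}_posterior_obs",
            f"{var}_posterior_pred",
            ["evidence", "claim1"],
        )
    out["h_crime"] = _joined_metrics(
        joined,
        "h_crime_posterior_obs",
        "h_crime_posterior_pred",
        ["evidence", "claim1", "claim2"],
    )
    return out


# ---------------------------------------------------------------------------
# Derived trend variables
# ---------------------------------------------------------------------------

_PRO = {"pro", "beneficial", "reduced", "reduced the crime rate"}
_ANTI = {"anti", "harmful", "damaging", "increased", "increased the crime rate"}


def _direction_sign(direction: str) -> float:
    key = str(direction).strip().lower()
    if key in _PRO:
        return 1.0
    if key in _ANTI:
        return -1.0
    raise ValidationError(f"unknown claim direction {direction!r}")


def persuasion(posterior: float, direction: str) -> float:
    """Signed movement of the posterior from 0.5 toward the claim.

    ``posterior - 0.5`` for a pro-Government claim, ``0.5 - posterior``
    for an anti-Government one.
    """
    posterior = float(posterior)
    if not 0.0 <= posterior <= 1.0:
        raise ValidationError(f"posterior must lie in [0, 1], got {posterior!r}")
    return _direction_sign(direction) * (posterior - 0.5)


def lean_shift(prior: float, posterior: float, direction: str) -> float:
    """Signed leaning update in the claim-consistent direction.

    ``posterior - prior`` when the claim is "beneficial" (pro-side),
    ``prior - posterior`` when it is "harmful".
    """
    prior, posterior = float(prior), float(posterior)
    for name, p in (("prior", prior), ("posterior", posterior)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {p!r}")
    return _direction_sign(direction) * (posterior - prior)


_EVIDENCE_SIGN = {
    "strong-harm": (-1.0, 2),
    "weak-harm": (-1.0, 1),
    "neutral": (0.0, 0),
    "weak-benefit": (1.0, 1),
    "strong-benefit": (1.0, 2),
}


def ev_support(evidence: str, claim1: str) -> int:
    """1-5 coding of how strongly the evidence supports the first claim.

    1 = strong conflicting evidence, 2 = weak conflicting, 3 = neutral,
    4 = weak consistent, 5 = strong consistent.
    """
    key = str(evidence).strip().lower()
    if key not in _EVIDENCE_SIGN:
        raise ValidationError(f"unknown evidence level {evidence!r}")
    ev_sign, strength = _EVIDENCE_SIGN[key]
    return int(3 + ev_sign * _direction_sign(claim1) * strength)


def flip_code(claim1: str, claim2: str) -> float:
    """+0.5 if the second claim reverses the first's direction, else -0.5."""
    return 0.5 if _direction_sign(claim1) != _direction_sign(claim2) else -0.5


def sensitivity_power_r(n: int, power: float = 0.80, alpha: float = 0.05) -> float:
    """Minimum detectable two-tailed Pearson correlation at given power.

    Fisher-z approximation: ``tanh((z_{1-alpha/2} + z_{power}) /
    sqrt(n - 3))``.
    """
    n = int(n)
    if n <= 3:
        raise ValidationError("sensitivity_power_r needs n > 3")
    if not (0.0 < power < 1.0 and 0.0 < alpha < 1.0):
        raise ValidationError("power and alpha must lie strictly in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    return float(math.tanh(z / math.sqrt(n - 3)))
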