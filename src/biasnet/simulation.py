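"""Model-behaviour sweeps: likelihood-ratio surfaces over prior grids.

The network's qualitative behaviour is summarised by sweeping each prior
over a grid and recording, at every grid point, the base-2 log
likelihood ratio (LLR) of a TRUE/FALSE testimony for a target variable
together with that variable's posterior.  :func:`check_trends` then
machine-checks the expected qualitative patterns:

* hypothesis updating rises with expertise and falls with bias intensity
  and with claim-consistent bias direction;
* bias intensity is attributed more strongly the less plausible the
  claim, the more so the higher the expertise;
* expertise attributions flip sign at a hypothesis prior of 0.5 and are
  damped by bias intensity and claim-consistent leaning;
* bias *direction* is attributed toward the claim more strongly the less
  plausible the claim and the more intense the bias;
* a source asserting a hypothesis is inferred to share its leaning, the
  more so the more biased (and, for implausible claims, the more expert)
  it is;
* swapping the source- and hypothesis-leaning priors exchanges their
  posteriors and leaves the hypothesis LLR unchanged, and complementing
  the testimony, hypothesis prior and bias-direction prior negates the
  hypothesis LLR exactly.

The exact grids behind the published behaviour plots are not part of the
model; the defaults here (0.1-0.9 in steps of 0.1, degenerate endpoints
excluded so every LLR is finite) are this package's reconstruction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ValidationError
from .network import (
    PriorSet,
    Testimony,
    posterior_marginals,
    variable_llr,
)

__all__ = ["DEFAULT_GRID", "SweepSpec", "run_sweep", "check_trends"]

#: Default prior grid: interior points only, every LLR finite.
DEFAULT_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.1, 0.95, 0.1), 10))

_PRIOR_NAMES = ("h", "hl", "sl", "bi", "e")


@dataclass(frozen=True)
class SweepSpec:
    """Specification of one sweep.

    ``axes`` maps each prior name to either a fixed scalar or an
    iterable grid of values in [0, 1]; unlisted priors default to 0.5
    except ``hl`` which defaults to 1 (the study convention).  At least
    one axis must vary.
    """

    target: str
    testimony: Testimony | bool | str = Testimony.TRUE
    axes: dict = field(default_factory=dict)

    def resolved_axes(self) -> dict[str, np.ndarray]:
        defaults = {"h": 0.5, "hl": 1.0, "sl": 0.5, "bi": 0.5, "e": 0.5}
        out = {}
        for name in _PRIOR_NAMES:
            value = self.axes.get(name, defaults[name])
            arr = np.atleast_1d(np.asarray(value, dtype=float))
            if arr.size == 0:
                raise ValidationError(f"empty grid for axis {name!r}")
            if ((arr < 0) | (arr > 1)).any():
                raise ValidationError(f"axis {name!r} has values outside [0, 1]")
            out[name] = arr
        if all(v.size == 1 for v in out.values()):
            raise ValidationError("at least one sweep axis must vary")
        return out


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate LLR and posterior of the target on the full grid.

    Returns a tidy frame with one row per grid point: the five prior
    columns, ``llr`` (may be +/-inf on degenerate grids) and
    ``posterior``.
    """
    axes = spec.resolved_axes()
    testimony = Testimony.coerce(spec.testimony)
    rows = []
    for values in itertools.product(*(axes[n] for n in _PRIOR_NAMES)):
        priors = PriorSet(**dict(zip(_PRIOR_NAMES, values)))
        rows.append(
            (*values,
             variable_llr(priors, testimony, spec.target),
             posterior_marginals(priors, testimony)[spec.target])
        )
    return pd.DataFrame(rows, columns=[*_PRIOR_NAMES, "llr", "posterior"])


# ---------------------------------------------------------------------------
# Qualitative trend checks
# ---------------------------------------------------------------------------

def _monotone(df: pd.DataFrame, by: str, column: str, sign: int, tol: float) -> bool:
    """Non-strict monotonicity of ``column`` in ``by`` within every other-
    axis stratum."""
    others = [c for c in _PRIOR_NAMES if c != by and df[c].nunique() > 1]
    grouped = df.groupby(others, sort=True) if others else [((), df)]
    for _, block in grouped:
        y = block.sort_values(by)[column].to_numpy()
        if (sign * np.diff(y) < -tol).any():
            return False
    return True


def _grid_sweep(target, testimony, **axes) -> pd.DataFrame:
    return run_sweep(SweepSpec(target=target, testimony=testimony, axes=axes))


def check_trends(
    grid: tuple[float, ...] = DEFAULT_GRID, tol: float = 1e-9
) -> dict[str, bool]:
    """Machine-check every expected qualitative trend on a prior grid.

    Returns a mapping from check name to pass/fail.  All inequalities
    are non-strict with ``tol`` slack, since boundary plateaus (for
    example a bias-direction prior of 0 making the hypothesis LLR
    constant in bias intensity) are legitimate model behaviour.
    """
    g = np.asarray(grid, dtype=float)
    if g.size < 3:
        raise ValidationError("trend checks need a grid of at least 3 points")
    low = g[g < 0.5]
    if low.size == 0:
        raise ValidationError("trend checks need grid points below 0.5")
    report: dict[str, bool] = {}

    # hypothesis updating: up in expertise, down in bias intensity and in
    # claim-consistent leaning (hl = 1 makes f = sl)
    sweep = _grid_sweep("H", True, h=g, sl=g, bi=g, e=g, hl=1.0)
    report["hypothesis_up_in_expertise"] = _monotone(sweep, "e", "llr", +1, tol)
    report["hypothesis_down_in_bias_intensity"] = _monotone(sweep, "bi", "llr", -1, tol)
    report["hypothesis_down_in_consistency"] = _monotone(sweep, "sl", "llr", -1, tol)

    # bias-intensity attribution: down in hypothesis prior when the bias
    # direction is claim-consistent (f > 0.5); expertise amplifies the
    # hypothesis-prior effect
    sweep = _grid_sweep("BI", True, h=g, sl=g[g > 0.5], bi=g, e=g, hl=1.0)
    report["bias_attribution_down_in_h_prior"] = _monotone(sweep, "h", "llr", -1, tol)
    post = sweep.copy()
    post["shift"] = post["posterior"] - post["bi"]
    report["bias_attribution_shift_down_in_h_prior"] = _monotone(post, "h", "shift", -1, tol)
    spread = (
        sweep.groupby(["sl", "bi", "e"])["llr"]
        .agg(lambda v: v.max() - v.min())
        .reset_index(name="spread")
    )
    report["bias_attribution_expertise_amplifies"] = _monotone(
        spread.assign(h=0.5, hl=1.0), "e", "spread", +1, tol
    )

    # expertise attribution at f = 0.5: sign follows the claim's prior
    # plausibility, zero at h = 0.5; damped by bias intensity and by
    # claim-consistent leaning
    sweep = _grid_sweep("E", True, h=g, sl=0.5, bi=g[g < 1.0], e=g, hl=1.0)
    shift = sweep["posterior"] - sweep["e"]
    report["expertise_sign_follows_plausibility"] = bool(
        ((shift > tol) == (sweep["h"] > 0.5)).all()
        and (shift.abs()[np.isclose(sweep["h"], 0.5)] <= tol).all()
    )
    damp = sweep.assign(absshift=shift.abs())
    report["expertise_damped_by_bias_intensity"] = _monotone(damp, "bi", "absshift", -1, tol)
    sweep = _grid_sweep("E", True, h=g, sl=g[g >= 0.5], bi=g, e=g, hl=1.0)
    sweep["absshift"] = (sweep["posterior"] - sweep["e"]).abs()
    report["expertise_damped_by_consistency"] = _monotone(sweep, "sl", "absshift", -1, tol)

    # bias-direction attribution: down in hypothesis prior, up in bias
    # intensity; expertise amplifies (h-prior spread everywhere, bias-
    # intensity spread where the claim is implausible)
    sweep = _grid_sweep("BD", True, h=g, sl=0.5, bi=g, e=g, hl=1.0)
    report["direction_attribution_down_in_h_prior"] = _monotone(sweep, "h", "llr", -1, tol)
    report["direction_attribution_up_in_bias_intensity"] = _monotone(sweep, "bi", "llr", +1, tol)
    spread = (
        sweep.groupby(["bi", "e"])["llr"]
        .agg(lambda v: v.max() - v.min())
        .reset_index(name="spread")
    )
    report["direction_attribution_expertise_amplifies_h_spread"] = _monotone(
        spread.assign(h=0.5, sl=0.5, hl=1.0), "e", "spread", +1, tol
    )
    lowplaus = sweep[sweep["h"] < 0.5]
    spread = (
        lowplaus.groupby(["h", "e"])["llr"]
        .agg(lambda v: v.max() - v.min())
        .reset_index(name="spread")
    )
    report["direction_attribution_expertise_amplifies_bi_spread"] = _monotone(
        spread.assign(sl=0.5, bi=0.5, hl=1.0), "e", "spread", +1, tol
    )

    # leaning attribution: asserting a pro-side hypothesis (hl = 1) moves
    # the leaning posterior toward that side, the more so the higher the
    # bias intensity (and, for implausible claims, the expertise)
    sweep = _grid_sweep("SL", True, h=g, sl=g, bi=g, e=g, hl=1.0)
    sweep["shift"] = sweep["posterior"] - sweep["sl"]
    report["leaning_shift_toward_hypothesis"] = bool((sweep["shift"] >= -tol).all())
    report["leaning_shift_up_in_bias_intensity"] = _monotone(sweep, "bi", "shift", +1, tol)
    report["leaning_shift_up_in_expertise_when_implausible"] = _monotone(
        sweep[sweep["h"] < 0.5], "e", "shift", +1, tol
    )

    # swap symmetry: exchanging hl and sl exchanges their posteriors and
    # leaves the hypothesis LLR unchanged
    ok = True
    for h, a, b, bi, e in itertools.product(low, g, g, g[::2], g[::2]):
        p1 = PriorSet(h=h, hl=a, sl=b, bi=bi, e=e)
        p2 = PriorSet(h=h, hl=b, sl=a, bi=bi, e=e)
        if abs(variable_llr(p1, True, "H") - variable_llr(p2, True, "H")) > tol:
            ok = False
            break
        m1, m2 = posterior_marginals(p1, True), posterior_marginals(p2, True)
        if abs(m1.hl - m2.sl) > tol or abs(m1.sl - m2.hl) > tol:
            ok = False
            break
    report["leaning_swap_symmetry"] = ok

    # complement symmetry: negating testimony, hypothesis prior and bias
    # direction prior negates the hypothesis LLR exactly
    ok = True
    for h, sl, bi, e in itertools.product(g, g, g, g):
        p1 = PriorSet(h=h, hl=1.0, sl=sl, bi=bi, e=e)
        p2 = PriorSet(h=1.0 - h, hl=1.0, sl=1.0 - sl, bi=bi, e=e)
        if abs(variable_llr(p1, True, "H") + variable_llr(p2, False, "H")) > tol:
            ok = False
            break
    report["complement_symmetry"] = ok

    return report
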