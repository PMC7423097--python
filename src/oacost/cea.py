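"""Cost-effectiveness analysis: pain-reduction effects, ICER, and sensitivity.

The effect measure is the 0-10 numeric rating scale (NRS) for pain, where
lower is better.  The incremental cost-effectiveness ratio follows the raw
published arithmetic

    ICER = (cost_A - cost_B) / (effect_A - effect_B)

with post-treatment pain scores entered directly (the change-from-baseline
variant is available as an option).  The reported ICER integer is truncated
toward zero, matching how the published figure was derived from its deltas.

One-way deterministic sensitivity analysis (tornado) and probabilistic
sensitivity analysis (PSA) with a cost-effectiveness acceptability curve are
generic extensions over any evaluation pipeline.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .costing import ValidationError, round_sek

__all__ = [
    "EffectEstimate",
    "Quadrant",
    "ICERResult",
    "percent_reduction",
    "icer",
    "icer_from_estimates",
    "one_way_dsa",
    "psa",
    "PSAResult",
]


@dataclass(frozen=True)
class EffectEstimate:
    """Mean pain before and after a 12-week episode, on the 0-10 NRS."""

    pain_pre: float
    pain_post: float
    horizon_weeks: float = 12.0

    def __post_init__(self) -> None:
        for name in ("pain_pre", "pain_post"):
            v = getattr(self, name)
            if not 0.0 <= v <= 10.0:
                raise ValidationError(f"{name} must be in [0, 10], got {v}")

    @property
    def change(self) -> float:
        """Pain change, post minus pre (negative = improvement)."""
        return self.pain_post - self.pain_pre


class Quadrant(str, enum.Enum):
    """Position of (delta_effect, delta_cost) on the cost-effectiveness plane.

    Pain is a negative outcome, so intervention A is *more effective* when its
    delta_effect (A - B) is negative.  NE = costlier and more effective,
    SW = cheaper and less effective; ties are classified weakly.
    """

    DOMINANT = "dominant"
    DOMINATED = "dominated"
    TRADEOFF_NE = "tradeoff_NE"
    TRADEOFF_SW = "tradeoff_SW"


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_effect: float
    ratio: Optional[float]
    quadrant: Quadrant

    @property
    def reported(self) -> Optional[int]:
        """Whole-SEK ratio, truncated toward zero (publication convention)."""
        if self.ratio is None:
            return None
        return math.trunc(self.ratio)


def percent_reduction(pre: float, post: float, integer: bool = True) -> float:
    """Percent pain reduction, (pre - post) / pre x 100.

    By default the value is rounded half-up to a whole percent, the form in
    which such reductions are reported; pass ``integer=False`` for the exact
    value.
    """
    if pre <= 0:
        raise ValidationError(f"pre-treatment score must be > 0, got {pre}")
    value = (pre - post) / pre * 100.0
    return float(round_sek(value)) if integer else value


def _classify(delta_cost: float, delta_effect: float) -> Quadrant:
    if delta_effect == 0.0:
        return Quadrant.DOMINANT if delta_cost <= 0 else Quadrant.DOMINATED
    if delta_effect < 0:  # A relieves more pain
        return Quadrant.DOMINANT if delta_cost <= 0 else Quadrant.TRADEOFF_NE
    return Quadrant.TRADEOFF_SW if delta_cost <= 0 else Quadrant.DOMINATED


def icer(cost_a: float, cost_b: float, effect_a: float, effect_b: float) -> ICERResult:
    """Incremental cost-effectiveness of A versus B on raw (pain) effects.

    Deltas are A minus B.  The ratio is undefined when the effect delta is
    zero; the dominance quadrant is still classified from the cost sign.
    """
    delta_cost = cost_a - cost_b
    delta_effect = effect_a - effect_b
    ratio = None if delta_effect == 0.0 else delta_cost / delta_effect
    return ICERResult(delta_cost=delta_cost, delta_effect=delta_effect,
                      ratio=ratio, quadrant=_classify(delta_cost, delta_effect))


def icer_from_estimates(cost_a: float, cost_b: float,
                        effect_a: EffectEstimate, effect_b: EffectEstimate,
                        measure: str = "post_score") -> ICERResult:
    """ICER with the effect delta taken from paired pre/post estimates.

    ``measure='post_score'`` (default) divides by the difference of
    post-treatment scores, the published convention; ``'change'`` divides by
    the difference of within-arm changes from baseline.
    """
    if measure == "post_score":
        return icer(cost_a, cost_b, effect_a.pain_post, effect_b.pain_post)
    if measure == "change":
        return icer(cost_a, cost_b, effect_a.change, effect_b.change)
    raise ValidationError(f"unknown effect measure {measure!r}")


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

def one_way_dsa(evaluate: Callable[[Mapping[str, float]], float],
                base_params: Mapping[str, float],
                param_ranges: Mapping[str, tuple[float, float]]) -> pd.DataFrame:
    """One-way deterministic sensitivity analysis (tornado table).

    Re-evaluates *evaluate* at each parameter's low and high bound, holding
    the others at base, and returns rows sorted by decreasing output span.
    Each range must bracket the base value.
    """
    base_output = float(evaluate(dict(base_params)))
    rows = []
    for name, (low, high) in param_ranges.items():
        if name not in base_params:
            raise ValidationError(f"range given for unknown parameter {name!r}")
        base = base_params[name]
        if not low <= base <= high:
            raise ValidationError(
                f"range for {name!r} must bracket the base value: "
                f"{low} <= {base} <= {high} fails")
        lo_out = float(evaluate({**base_params, name: low}))
        hi_out = float(evaluate({**base_params, name: high}))
        rows.append({
            "parameter": name, "low": low, "high": high,
            "output_base": base_output, "output_low": lo_out,
            "output_high": hi_out, "span": abs(hi_out - lo_out),
        })
    table = pd.DataFrame(rows, columns=["parameter", "low", "high", "output_base",
                                        "output_low", "output_high", "span"])
    return table.sort_values("span", ascending=False, kind="stable",
                             ignore_index=True)


def _draw(dist: Sequence, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw *n* samples from a distribution spec tuple.

    Specs: ``("fixed", value)``, ``("gamma", mean, sd)`` (costs),
    ``("normal", mean, sd, low, high)`` (scores, truncated).  A zero sd makes
    the parameter degenerate at its mean without consuming random numbers.
    """
    kind = dist[0]
    if kind == "fixed":
        return np.full(n, float(dist[1]))
    if kind == "gamma":
        _, mean, sd = dist
        if mean < 0 or sd < 0:
            raise ValidationError(f"gamma mean and sd must be >= 0, got {dist}")
        if sd == 0 or mean == 0:
            return np.full(n, float(mean))
        shape = (mean / sd) ** 2
        return rng.gamma(shape, scale=sd**2 / mean, size=n)
    if kind == "normal":
        _, mean, sd, low, high = dist
        if sd < 0:
            raise ValidationError(f"normal sd must be >= 0, got {sd}")
        if low > high:
            raise ValidationError(f"normal bounds inverted: {low} > {high}")
        if sd == 0:
            return np.full(n, float(np.clip(mean, low, high)))
        a, b = (low - mean) / sd, (high - mean) / sd
        return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                                   random_state=rng)
    raise ValidationError(f"unknown distribution kind {kind!r}")


@dataclass(frozen=True)
class PSAResult:
    """Draws (parameters and incremental outcomes) plus the CEAC."""

    draws: pd.DataFrame
    ceac: pd.DataFrame

    @property
    def mean_delta_cost(self) -> float:
        return float(self.draws["delta_cost"].mean())

    @property
    def mean_delta_effect(self) -> float:
        return float(self.draws["delta_effect"].mean())


def psa(param_distributions: Mapping[str, Sequence],
        n_draws: int,
        seed: int,
        evaluate: Callable[[Mapping[str, float]], tuple[float, float]],
        wtp_grid: Optional[Sequence[float]] = None) -> PSAResult:
    """Probabilistic sensitivity analysis over an incremental pipeline.

    *evaluate* maps one parameter draw to ``(delta_cost, delta_effect)``
    (A minus B, pain scale).  The CEAC reports, on a willingness-to-pay grid
    (SEK per pain point averted), the probability that the pain improvement
    ``-delta_effect`` is worth more than the incremental cost.  Reproducible
    for a given integer seed; this is an analytic extension beyond the
    published point estimates.
    """
    if n_draws < 1:
        raise ValidationError(f"n_draws must be >= 1, got {n_draws}")
    rng = np.random.default_rng(seed)
    params = {name: _draw(dist, rng, n_draws)
              for name, dist in param_distributions.items()}
    records = []
    for i in range(n_draws):
        draw = {name: float(values[i]) for name, values in params.items()}
        delta_cost, delta_effect = evaluate(draw)
        records.append({**draw, "delta_cost": float(delta_cost),
                        "delta_effect": float(delta_effect)})
    draws = pd.DataFrame(records)

    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 50_000.0, 51)
    wtp = np.asarray(list(wtp_grid), dtype=float)
    dc = draws["delta_cost"].to_numpy()
    de = draws["delta_effect"].to_numpy()
    prob = [(wtp_i * (-de) - dc >= 0).mean() for wtp_i in wtp]
    ceac = pd.DataFrame({"wtp_sek_per_point": wtp, "probability_cost_effective": prob})
    return PSAResult(draws=draws, ceac=ceac)
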