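"""Patient travel costing and CO2 accounting for clinic-based care.

Face-to-face care requires the patient to travel to the clinic for every
on-site session.  Travel time is valued as leisure time (a fraction of the
gross population wage) and the associated vehicle emissions are monetized at
an emission-rights price.  Digital care has no clinic travel, hence zero
transport cost and zero emissions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from .costing import Role, ValidationError, ValuationContext, value_labour_time

__all__ = [
    "TransportMode",
    "TransportProfile",
    "EmissionPrice",
    "transport_time_cost",
    "episode_emissions",
    "cohort_emissions",
    "emissions_value",
    "effective_emission_price_sek",
    "PUBLISHED_UNRECONCILED",
]

#: Published figures that cannot be reconstructed from the other published
#: inputs; carried as report metadata only and excluded from computation.
#: The total emission value (SEK) is inconsistent with tons x USD price at the
#: published exchange rate, implying an effective price near 4 180 SEK/ton.
PUBLISHED_UNRECONCILED = {
    "total_emission_value_sek": {"value": 555_747.0, "reproducible": False},
}


class TransportMode(str, enum.Enum):
    CAR = "car"
    BUS = "bus"
    NONE = "none"


@dataclass(frozen=True)
class EmissionPrice:
    """Price of one ton of CO2, quoted in USD (EU-ETS convention)."""

    usd_per_ton: float = 220.0

    def __post_init__(self) -> None:
        if self.usd_per_ton < 0:
            raise ValidationError(f"emission price must be >= 0, got {self.usd_per_ton}")


@dataclass(frozen=True)
class TransportProfile:
    """Per-episode clinic travel: time, trip count, and CO2.

    ``emission_tons_per_episode`` is the direct per-episode estimate; an
    optional decomposition ``round_trip_km x kg_co2_per_km x visits`` may be
    supplied and must agree with the direct figure within 1 %.
    ``emission_price_sek_per_ton`` optionally overrides the USD market price
    with a calibrated effective SEK price (the published per-episode emission
    cost line implies one).
    """

    mode: TransportMode = TransportMode.NONE
    round_trip_minutes: float = 0.0
    visits_per_episode: float = 0.0
    emission_tons_per_episode: float = 0.0
    round_trip_km: Optional[float] = None
    kg_co2_per_km: Optional[float] = None
    emission_price_sek_per_ton: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("round_trip_minutes", "visits_per_episode",
                     "emission_tons_per_episode"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("round_trip_km", "kg_co2_per_km", "emission_price_sek_per_ton"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.mode is TransportMode.NONE:
            if self.round_trip_minutes or self.emission_tons_per_episode:
                raise ValidationError(
                    "mode 'none' implies zero travel time and zero emissions")


def transport_time_cost(profile: TransportProfile, ctx: ValuationContext) -> float:
    """Value per-episode travel time at the leisure fraction of the gross wage."""
    if profile.mode is TransportMode.NONE:
        return 0.0
    hours = profile.visits_per_episode * profile.round_trip_minutes / 60.0
    return value_labour_time(hours, ctx.population_gross_hourly_wage,
                             Role.PATIENT_LEISURE, ctx)


def episode_emissions(profile: TransportProfile) -> float:
    """Per-episode travel emissions in tons of CO2.

    Uses the direct parameter; when a km-level decomposition is also given the
    two must agree within 1 % (guarding against inconsistent configs), and the
    decomposition is used when it is the only source.
    """
    if profile.mode is TransportMode.NONE:
        return 0.0
    decomposed: Optional[float] = None
    if profile.round_trip_km is not None and profile.kg_co2_per_km is not None:
        decomposed = (profile.round_trip_km * profile.kg_co2_per_km
                      * profile.visits_per_episode / 1000.0)
    direct = profile.emission_tons_per_episode
    if decomposed is not None and direct > 0:
        if not math.isclose(decomposed, direct, rel_tol=0.01):
            raise ValidationError(
                f"emission decomposition {decomposed:.6f} t disagrees with the "
                f"direct parameter {direct:.6f} t by more than 1%")
        return direct
    if decomposed is not None:
        return decomposed
    return direct


def cohort_emissions(per_episode_tons: float, n_episodes: float) -> float:
    """Total cohort emissions: exactly linear in both arguments."""
    if per_episode_tons < 0 or n_episodes < 0:
        raise ValidationError("per-episode tons and episode count must be >= 0")
    return per_episode_tons * n_episodes


def emissions_value(tons: float, price: EmissionPrice, ctx: ValuationContext) -> float:
    """Monetize *tons* of CO2 in SEK at the USD market price and context FX."""
    if tons < 0:
        raise ValidationError(f"tons must be >= 0, got {tons}")
    return tons * price.usd_per_ton * ctx.sek_per_usd


def effective_emission_price_sek(profile: TransportProfile,
                                 ctx: ValuationContext,
                                 price: EmissionPrice | None = None) -> float:
    """SEK price per ton used for costing: calibrated override or market price."""
    if profile.emission_price_sek_per_ton is not None:
        return profile.emission_price_sek_per_ton
    return (price or EmissionPrice()).usd_per_ton * ctx.sek_per_usd
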