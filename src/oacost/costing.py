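"""Deterministic micro-costing engine for first-line osteoarthritis care episodes.

Implements the identification / quantification / valuation workflow used to cost
a 12-week episode of care from a societal perspective.  Time is valued with the
human-capital method: provider time at the gross physiotherapist wage plus
employer social fees (with a facility surcharge for on-site care), patient care
time at the gross population wage, and patient travel time at a leisure
fraction of the gross wage.  Costs are kept at full floating precision
throughout; whole-SEK rounding happens only in reports (:func:`round_sek`).

All monetary values are SEK of the context's reference year.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "ValidationError",
    "Mode",
    "Domain",
    "Category",
    "Role",
    "MidpointPolicy",
    "ValuationContext",
    "ContactEvent",
    "CareModelSpec",
    "CostItem",
    "CostBreakdown",
    "round_sek",
    "value_labour_time",
    "allocate_group_session",
    "technical_support_unit_cost",
    "amortize_training",
    "build_episode_schedule",
    "cost_model",
    "aggregate_breakdown",
]


class ValidationError(ValueError):
    """An input violates a domain constraint (negative time, zero group, ...)."""


def round_sek(value: float) -> int:
    """Round a monetary value to whole SEK, half away from zero (presentation only).

    Published cost tables are rounded this way; all internal arithmetic stays
    at full precision, so sub-items may differ from a printed subtotal by
    +/- 1 SEK once rounded individually.
    """
    if not math.isfinite(value):
        raise ValidationError(f"cannot round non-finite value {value!r}")
    return int(Decimal(repr(value)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


class Mode(str, enum.Enum):
    """How a care contact is delivered."""

    IN_PERSON = "in_person"
    TELEPHONE = "telephone"
    PLATFORM = "platform"
    SELF_ADMINISTERED = "self_administered"


class Domain(str, enum.Enum):
    """Societal cost domain: health system (A), patient (B), other sectors (C)."""

    SYSTEM = "system"
    PATIENT = "patient"
    OTHER = "other"


class Category(str, enum.Enum):
    CONTACTS = "contacts"
    ADMINISTRATION = "administration"
    TECHNICAL_SUPPORT = "technical_support"
    TRAINING = "training"
    TRANSPORTATION = "transportation"
    DIRECT_FEES = "direct_fees"
    EMISSIONS = "emissions"


#: Stable presentation order of cost lines within a breakdown.
_DOMAIN_ORDER = {Domain.SYSTEM: 0, Domain.PATIENT: 1, Domain.OTHER: 2}
_CATEGORY_ORDER = {
    Category.CONTACTS: 0,
    Category.ADMINISTRATION: 1,
    Category.TECHNICAL_SUPPORT: 2,
    Category.TRAINING: 3,
    Category.TRANSPORTATION: 4,
    Category.DIRECT_FEES: 5,
    Category.EMISSIONS: 6,
}


class Role(str, enum.Enum):
    """Whose time is being valued, selecting the human-capital valuation rule."""

    PROVIDER = "provider"
    PATIENT_LEISURE = "patient_leisure"
    PATIENT_FULL = "patient_full"


class MidpointPolicy(str, enum.Enum):
    """How a published duration range such as ``5-8`` minutes is resolved."""

    MIDPOINT = "midpoint"
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class ValuationContext:
    """All monetary-valuation parameters in one auditable record.

    Parameters
    ----------
    provider_gross_hourly_wage
        Mean gross hourly wage of a physiotherapist, SEK/h.
    population_gross_hourly_wage
        Mean gross hourly wage of the general population, SEK/h.
    social_fee_rate
        Employer non-wage social fees added to provider time.  The legally
        mandatory minimum rate is 0.3142; an alternative convention of 0.501
        exists and may be selected here.
    leisure_fraction
        Fraction of the gross wage at which patient leisure (travel) time is
        valued.
    facility_surcharge
        Surcharge on staff time in facility-based care, covering rent.
    user_fee_ceiling
        Annual cap on patient out-of-pocket fees, SEK; every patient is
        assumed to reach it.
    training_wage_multiplier
        Wage multiplier applied when valuing provider training time.
    fx_usd_per_100_sek, fx_eur_per_100_sek
        Exchange rates expressed as foreign units per 100 SEK.
    """

    provider_gross_hourly_wage: float
    population_gross_hourly_wage: float
    social_fee_rate: float = 0.3142
    leisure_fraction: float = 0.30
    facility_surcharge: float = 0.10
    user_fee_ceiling: float = 1100.0
    training_wage_multiplier: float = 1.5
    fx_usd_per_100_sek: float = 10.2
    fx_eur_per_100_sek: float = 9.43
    reference_year: int = 2018

    def __post_init__(self) -> None:
        for name in ("provider_gross_hourly_wage", "population_gross_hourly_wage",
                     "user_fee_ceiling"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("social_fee_rate", "leisure_fraction", "facility_surcharge"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.training_wage_multiplier < 1.0:
            raise ValidationError(
                f"training_wage_multiplier must be >= 1, got {self.training_wage_multiplier}")
        if self.fx_usd_per_100_sek <= 0 or self.fx_eur_per_100_sek <= 0:
            raise ValidationError("FX rates must be > 0")

    @property
    def sek_per_usd(self) -> float:
        return 100.0 / self.fx_usd_per_100_sek

    @property
    def sek_per_eur(self) -> float:
        return 100.0 / self.fx_eur_per_100_sek


@dataclass(frozen=True)
class ContactEvent:
    """One scheduled care contact, possibly recurring within the episode.

    ``duration_minutes`` gives a point duration; alternatively ``duration_low``
    and ``duration_high`` give a published range resolved at schedule-building
    time by a :class:`MidpointPolicy`.  ``group_size`` is the average number of
    participants sharing a (group-based) session; provider-side session costs
    are divided by it, patient-side time is not.  ``once_per_episode`` marks
    introduction/information sessions whose count is independent of episode
    length.  ``participation_key`` names the participation rate (e.g. exercise
    sessions, co-patient lecture) that the synthetic-cohort generator thins
    attendance by; the deterministic engine costs the full protocol.
    """

    label: str
    mode: Mode
    occurrences_per_episode: int = 1
    duration_minutes: Optional[float] = None
    duration_low: Optional[float] = None
    duration_high: Optional[float] = None
    provider_attends: bool = True
    patient_attends: bool = True
    group_size: float = 1.0
    on_site: bool = False
    once_per_episode: bool = False
    participation_key: Optional[str] = None

    def __post_init__(self) -> None:
        has_point = self.duration_minutes is not None
        has_range = self.duration_low is not None or self.duration_high is not None
        if has_point == has_range:
            raise ValidationError(
                f"contact {self.label!r}: give either duration_minutes or a "
                "duration_low/duration_high range")
        if has_range and (self.duration_low is None or self.duration_high is None):
            raise ValidationError(
                f"contact {self.label!r}: a duration range needs both bounds")
        for name in ("duration_minutes", "duration_low", "duration_high"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"contact {self.label!r}: {name} must be >= 0")
        if has_range and self.duration_low > self.duration_high:
            raise ValidationError(
                f"contact {self.label!r}: duration_low > duration_high")
        if self.occurrences_per_episode < 0:
            raise ValidationError(f"contact {self.label!r}: occurrences must be >= 0")
        if self.group_size < 1:
            raise ValidationError(f"contact {self.label!r}: group_size must be >= 1")
        if self.on_site and self.mode is not Mode.IN_PERSON:
            raise ValidationError(
                f"contact {self.label!r}: on_site requires in_person mode")

    def resolved_minutes(self, policy: MidpointPolicy = MidpointPolicy.MIDPOINT) -> float:
        """Duration in minutes with any published range resolved by *policy*."""
        if self.duration_minutes is not None:
            return self.duration_minutes
        if policy is MidpointPolicy.LOW:
            return float(self.duration_low)
        if policy is MidpointPolicy.HIGH:
            return float(self.duration_high)
        return (self.duration_low + self.duration_high) / 2.0


@dataclass(frozen=True)
class SupportSpec:
    """Stand-by technical/other support, costed as an annual budget per patient."""

    annual_budget: float
    annual_patients: int
    halved: bool = False

    def __post_init__(self) -> None:
        if self.annual_budget < 0:
            raise ValidationError("annual support budget must be >= 0")
        if self.annual_patients < 1:
            raise ValidationError("annual_patients must be >= 1")


@dataclass(frozen=True)
class CareModelSpec:
    """A care model as a contact schedule plus overheads and one-off costs.

    ``admin_system_hours`` / ``admin_patient_hours`` are fixed
    preparation/follow-up hours per episode (valued at the provider and
    population wage respectively).  ``line_scales`` maps ``"domain.category"``
    keys to unitless calibration factors applied to the corresponding computed
    cost line; they default to 1 and exist because the unrounded sub-item
    values behind the published unit-cost table are not public, so exact
    line-level reproduction is a calibration rather than a derivation.
    """

    name: str
    contacts: Sequence[ContactEvent] = ()
    episode_weeks: float = 12.0
    facility_based: bool = False
    admin_system_hours: float = 0.0
    admin_patient_hours: float = 0.0
    training_hours_per_provider: float = 0.0
    episodes_per_provider: float = 1.0
    support: Optional[SupportSpec] = None
    transport: Optional["TransportProfile"] = None  # noqa: F821 (transport module)
    line_scales: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.episode_weeks <= 0:
            raise ValidationError("episode_weeks must be > 0")
        for name in ("admin_system_hours", "admin_patient_hours",
                     "training_hours_per_provider"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.episodes_per_provider < 1:
            raise ValidationError("episodes_per_provider must be >= 1")
        for key, scale in self.line_scales.items():
            if scale < 0:
                raise ValidationError(f"line scale {key!r} must be >= 0")

    def scale(self, domain: Domain, category: Category) -> float:
        return float(self.line_scales.get(f"{domain.value}.{category.value}", 1.0))

    def with_contacts(self, contacts: Sequence[ContactEvent]) -> "CareModelSpec":
        """Copy of this spec with a different realized contact list."""
        return replace(self, contacts=tuple(contacts))


@dataclass(frozen=True)
class CostItem:
    """One valued resource line: a (domain, category) cell of the cost table."""

    domain: Domain
    category: Category
    total: float
    quantity_hours: Optional[float] = None
    unit_value: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.total < 0:
            raise ValidationError(f"cost item total must be >= 0, got {self.total}")
        if (self.quantity_hours is not None and self.unit_value is not None
                and not math.isclose(self.total, self.quantity_hours * self.unit_value,
                                     rel_tol=1e-9, abs_tol=1e-6)):
            raise ValidationError(
                f"cost item {self.label or self.category.value!r}: total "
                f"{self.total} != quantity {self.quantity_hours} x unit "
                f"{self.unit_value}")


@dataclass(frozen=True)
class CostBreakdown:
    """Per-domain aggregation of cost items with the conservation invariant.

    ``total == subtotal_system + subtotal_patient + subtotal_other`` holds
    exactly (same floating-point summation order) by construction.
    """

    model_name: str
    items: tuple[CostItem, ...]
    subtotal_system: float
    subtotal_patient: float
    subtotal_other: float
    total: float

    def subtotal(self, domain: Domain) -> float:
        return {
            Domain.SYSTEM: self.subtotal_system,
            Domain.PATIENT: self.subtotal_patient,
            Domain.OTHER: self.subtotal_other,
        }[domain]


# ---------------------------------------------------------------------------
# Valuation primitives
# ---------------------------------------------------------------------------

def value_labour_time(hours: float, wage: float, role: Role,
                      ctx: ValuationContext, on_site: bool = False) -> float:
    """Value *hours* of a person's time under the human-capital method.

    Provider time carries employer social fees and, when ``on_site`` in a
    facility-based model, the facility surcharge.  Patient leisure time is
    valued at ``leisure_fraction`` of the gross wage; patient care-contact time
    at the full gross wage, net of social fees in both cases.
    """
    if hours < 0:
        raise ValidationError(f"hours must be >= 0, got {hours}")
    if wage < 0:
        raise ValidationError(f"wage must be >= 0, got {wage}")
    role = Role(role)
    if role is Role.PROVIDER:
        value = hours * wage * (1.0 + ctx.social_fee_rate)
        if on_site:
            value *= 1.0 + ctx.facility_surcharge
        return value
    if role is Role.PATIENT_LEISURE:
        return hours * wage * ctx.leisure_fraction
    return hours * wage  # PATIENT_FULL


def allocate_group_session(session_cost: float, group_size: float) -> float:
    """Divide a session's provider-side cost by the average group size.

    The undivided (payer-perspective) figure is simply ``session_cost`` and
    remains available to callers; this helper returns the per-patient share.
    """
    if group_size < 1:
        raise ValidationError(f"group_size must be >= 1, got {group_size}")
    return session_cost / group_size


def technical_support_unit_cost(annual_budget: float, annual_patients: int,
                                halved: bool = False) -> float:
    """Per-episode stand-by support cost: annual budget over annual patients.

    ``halved`` applies the comparator rule that a face-to-face model's support
    cost is assumed to be half of the digital model's.
    """
    if annual_patients < 1:
        raise ValidationError(f"annual_patients must be >= 1, got {annual_patients}")
    if annual_budget < 0:
        raise ValidationError(f"annual_budget must be >= 0, got {annual_budget}")
    unit = annual_budget / annual_patients
    return 0.5 * unit if halved else unit


def amortize_training(training_hours: float, wage: float, ctx: ValuationContext,
                      episodes_per_provider: float) -> float:
    """Per-episode cost of one-off provider training and certification.

    Training time is valued at the gross wage times the training multiplier
    (senior-staff-led instruction) plus social fees, then spread over the
    episodes a trained provider delivers.
    """
    if training_hours < 0:
        raise ValidationError(f"training_hours must be >= 0, got {training_hours}")
    if wage < 0:
        raise ValidationError(f"wage must be >= 0, got {wage}")
    if episodes_per_provider < 1:
        raise ValidationError(
            f"episodes_per_provider must be >= 1, got {episodes_per_provider}")
    return (training_hours * wage * ctx.training_wage_multiplier
            * (1.0 + ctx.social_fee_rate) / episodes_per_provider)


# ---------------------------------------------------------------------------
# Schedule expansion and full model costing
# ---------------------------------------------------------------------------

def build_episode_schedule(
    spec: CareModelSpec,
    midpoint_policy: MidpointPolicy = MidpointPolicy.MIDPOINT,
) -> tuple[int, float, float]:
    """Expand a contact schedule into per-episode totals.

    Returns ``(contact_count, provider_minutes, patient_minutes)`` with
    occurrence counts expanded and duration ranges resolved by
    *midpoint_policy*.  Minutes are raw (unrounded) sums.
    """
    midpoint_policy = MidpointPolicy(midpoint_policy)
    count = 0
    provider_minutes = 0.0
    patient_minutes = 0.0
    for contact in spec.contacts:
        minutes = contact.resolved_minutes(midpoint_policy)
        n = contact.occurrences_per_episode
        count += n
        if contact.provider_attends:
            provider_minutes += minutes * n
        if contact.patient_attends:
            patient_minutes += minutes * n
    return count, provider_minutes, patient_minutes


def _contact_items(spec: CareModelSpec, ctx: ValuationContext,
                   midpoint_policy: MidpointPolicy) -> tuple[float, float]:
    """(system, patient) contact-time cost for the full protocol."""
    system = 0.0
    patient = 0.0
    for contact in spec.contacts:
        hours = contact.resolved_minutes(midpoint_policy) / 60.0
        n = contact.occurrences_per_episode
        if contact.provider_attends:
            session = value_labour_time(
                hours, ctx.provider_gross_hourly_wage, Role.PROVIDER, ctx,
                on_site=contact.on_site)
            system += allocate_group_session(session, contact.group_size) * n
        if contact.patient_attends:
            patient += value_labour_time(
                hours, ctx.population_gross_hourly_wage, Role.PATIENT_FULL, ctx) * n
    return system, patient


def cost_model(spec: CareModelSpec, ctx: ValuationContext,
               midpoint_policy: MidpointPolicy = MidpointPolicy.MIDPOINT) -> CostBreakdown:
    """Cost one episode of care under *spec*, returning a full breakdown.

    Emits one :class:`CostItem` per populated (domain, category) cell:
    provider contact time (group-allocated, facility surcharge when on site),
    administration, stand-by support, amortized training, patient contact and
    administration time, travel time, the capped direct user fee, and the
    monetized CO2 emissions of clinic travel.  All arithmetic is at full
    precision; apply :func:`round_sek` only when presenting.
    """
    from . import transport as _transport  # deferred: transport imports this module

    midpoint_policy = MidpointPolicy(midpoint_policy)
    w_provider = ctx.provider_gross_hourly_wage
    w_pop = ctx.population_gross_hourly_wage
    items: list[CostItem] = []

    sys_contacts, pat_contacts = _contact_items(spec, ctx, midpoint_policy)
    sys_contacts *= spec.scale(Domain.SYSTEM, Category.CONTACTS)
    pat_contacts *= spec.scale(Domain.PATIENT, Category.CONTACTS)
    items.append(CostItem(Domain.SYSTEM, Category.CONTACTS, sys_contacts,
                          label="Contacts/Visits/Sessions"))
    items.append(CostItem(Domain.PATIENT, Category.CONTACTS, pat_contacts,
                          label="Contacts/Visits"))

    admin_rate = value_labour_time(1.0, w_provider, Role.PROVIDER, ctx,
                                   on_site=spec.facility_based)
    sys_admin = (spec.admin_system_hours * admin_rate
                 * spec.scale(Domain.SYSTEM, Category.ADMINISTRATION))
    items.append(CostItem(Domain.SYSTEM, Category.ADMINISTRATION, sys_admin,
                          label="Preparations/Follow-up"))

    if spec.support is not None:
        support = technical_support_unit_cost(
            spec.support.annual_budget, spec.support.annual_patients,
            halved=spec.support.halved)
        support *= spec.scale(Domain.SYSTEM, Category.TECHNICAL_SUPPORT)
        items.append(CostItem(Domain.SYSTEM, Category.TECHNICAL_SUPPORT, support,
                              label="Technical support"))

    training = amortize_training(spec.training_hours_per_provider, w_provider,
                                 ctx, spec.episodes_per_provider)
    training *= spec.scale(Domain.SYSTEM, Category.TRAINING)
    items.append(CostItem(Domain.SYSTEM, Category.TRAINING, training,
                          label="Training of physiotherapists"))

    pat_admin = (spec.admin_patient_hours * w_pop
                 * spec.scale(Domain.PATIENT, Category.ADMINISTRATION))
    items.append(CostItem(Domain.PATIENT, Category.ADMINISTRATION, pat_admin,
                          label="Preparations/Follow-up"))

    if spec.transport is not None and spec.transport.mode is not _transport.TransportMode.NONE:
        travel = _transport.transport_time_cost(spec.transport, ctx)
        travel *= spec.scale(Domain.PATIENT, Category.TRANSPORTATION)
        items.append(CostItem(Domain.PATIENT, Category.TRANSPORTATION, travel,
                              label="Transportation to and from clinic"))
        tons = _transport.episode_emissions(spec.transport)
        price = _transport.effective_emission_price_sek(spec.transport, ctx)
        emissions = tons * price * spec.scale(Domain.OTHER, Category.EMISSIONS)
        items.append(CostItem(Domain.OTHER, Category.EMISSIONS, emissions,
                              label="CO2 emissions"))

    items.append(CostItem(Domain.PATIENT, Category.DIRECT_FEES, ctx.user_fee_ceiling,
                          label="Direct costs (user fees)"))

    return aggregate_breakdown(items, model_name=spec.name)


def aggregate_breakdown(items: Iterable[CostItem], model_name: str = "") -> CostBreakdown:
    """Aggregate cost items into per-domain subtotals and a grand total.

    Items are ordered stably by (domain, category); the grand total is the sum
    of the three subtotals, so conservation holds exactly.
    """
    ordered = sorted(
        items, key=lambda it: (_DOMAIN_ORDER[it.domain], _CATEGORY_ORDER[it.category]))
    subtotals = {Domain.SYSTEM: 0.0, Domain.PATIENT: 0.0, Domain.OTHER: 0.0}
    for item in ordered:
        subtotals[item.domain] += item.total
    return CostBreakdown(
        model_name=model_name,
        items=tuple(ordered),
        subtotal_system=subtotals[Domain.SYSTEM],
        subtotal_patient=subtotals[Domain.PATIENT],
        subtotal_other=subtotals[Domain.OTHER],
        total=subtotals[Domain.SYSTEM] + subtotals[Domain.PATIENT] + subtotals[Domain.OTHER],
    )
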