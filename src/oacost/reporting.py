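"""Config loading/validation and report rendering.

Care models and valuation contexts are YAML (or JSON) documents validated
field-by-field; validation failures name the offending field.  The bundled
``boa.yaml`` and ``ja.yaml`` encode the two study care models and
``valuation.yaml`` the 2018 Swedish valuation context, with calibrated
quantities where the published table's underlying micro-data are not public.

Report writers produce the published-table-shaped two-model comparison
(whole-SEK, half-up — the only place rounding happens) and tidy CSV/JSON
exports that embed the fully resolved parameter set for auditability.
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .costing import (
    CareModelSpec,
    Category,
    ContactEvent,
    CostBreakdown,
    Domain,
    Mode,
    SupportSpec,
    ValidationError,
    ValuationContext,
    round_sek,
)
from .transport import TransportMode, TransportProfile

__all__ = [
    "ConfigError",
    "RunConfig",
    "bundled_path",
    "load_valuation_context",
    "save_valuation_context",
    "load_care_model",
    "save_care_model",
    "load_and_validate",
    "breakdown_to_frame",
    "breakdown_to_dict",
    "render_breakdown_report",
]


class ConfigError(ValidationError):
    """A config file is missing a field or violates the schema."""


# ---------------------------------------------------------------------------
# Loading helpers
# ---------------------------------------------------------------------------

def bundled_path(name: str) -> Path:
    """Path to a bundled fixture config: ``boa``, ``ja`` or ``valuation``."""
    path = resources.files("oacost").joinpath(f"data/{name}.yaml")
    if not path.is_file():
        raise ConfigError(f"no bundled config named {name!r}")
    return Path(str(path))


def _load_document(path: Union[str, Path]) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    doc = (json.loads(text) if path.suffix.lower() == ".json"
           else yaml.safe_load(text))
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    return dict(doc)


def _get(doc: Mapping, field: str, where: str, required: bool = True,
         default: Any = None) -> Any:
    if field not in doc:
        if required:
            raise ConfigError(f"{where}: missing required field {field!r}")
        return default
    return doc[field]


def _number(doc: Mapping, field: str, where: str, required: bool = True,
            default: Any = None) -> Any:
    value = _get(doc, field, where, required, default)
    if value is None:
        return None
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"{where}: field {field!r} must be a number, "
                          f"got {value!r}")
    return float(value)


def load_valuation_context(path: Union[str, Path]) -> ValuationContext:
    """Read and validate a valuation-context config (YAML or JSON)."""
    doc = _load_document(path)
    where = str(path)
    kwargs: dict[str, Any] = {
        "provider_gross_hourly_wage": _number(doc, "provider_gross_hourly_wage", where),
        "population_gross_hourly_wage": _number(doc, "population_gross_hourly_wage", where),
    }
    for field_ in ("social_fee_rate", "leisure_fraction", "facility_surcharge",
                   "user_fee_ceiling", "training_wage_multiplier",
                   "fx_usd_per_100_sek", "fx_eur_per_100_sek"):
        value = _number(doc, field_, where, required=False)
        if value is not None:
            kwargs[field_] = value
    year = _get(doc, "reference_year", where, required=False)
    if year is not None:
        kwargs["reference_year"] = int(year)
    try:
        return ValuationContext(**kwargs)
    except ValidationError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def save_valuation_context(ctx: ValuationContext, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(ctx), sort_keys=False))


def _parse_contact(doc: Mapping, where: str) -> ContactEvent:
    label = _get(doc, "label", where)
    where = f"{where} ({label})"
    mode = _get(doc, "mode", where)
    try:
        mode = Mode(mode)
    except ValueError:
        raise ConfigError(
            f"{where}: field 'mode' must be one of "
            f"{[m.value for m in Mode]}, got {mode!r}") from None
    kwargs: dict[str, Any] = {
        "label": str(label),
        "mode": mode,
        "occurrences_per_episode": int(_number(doc, "occurrences", where,
                                               required=False, default=1)),
    }
    duration = _get(doc, "duration_minutes", where, required=False)
    dur_range = _get(doc, "duration_range", where, required=False)
    if duration is not None:
        kwargs["duration_minutes"] = float(duration)
    elif dur_range is not None:
        if not isinstance(dur_range, Mapping):
            raise ConfigError(f"{where}: field 'duration_range' must be a "
                              "mapping with 'low' and 'high'")
        kwargs["duration_low"] = _number(dur_range, "low", f"{where}.duration_range")
        kwargs["duration_high"] = _number(dur_range, "high", f"{where}.duration_range")
    else:
        raise ConfigError(f"{where}: missing required field 'duration_minutes' "
                          "or 'duration_range'")
    for field_ in ("provider_attends", "patient_attends", "on_site",
                   "once_per_episode"):
        value = _get(doc, field_, where, required=False)
        if value is not None:
            if not isinstance(value, bool):
                raise ConfigError(f"{where}: field {field_!r} must be boolean")
            kwargs[field_] = value
    group = _number(doc, "group_size", where, required=False)
    if group is not None:
        kwargs["group_size"] = group
    key = _get(doc, "participation_key", where, required=False)
    if key is not None:
        kwargs["participation_key"] = str(key)
    try:
        return ContactEvent(**kwargs)
    except ValidationError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def load_care_model(path: Union[str, Path]) -> CareModelSpec:
    """Read and validate a care-model config (YAML or JSON)."""
    doc = _load_document(path)
    where = str(path)
    name = str(_get(doc, "name", where))
    contacts_doc = _get(doc, "contacts", where, required=False, default=[])
    if not isinstance(contacts_doc, Sequence) or isinstance(contacts_doc, str):
        raise ConfigError(f"{where}: field 'contacts' must be a list")
    contacts = tuple(_parse_contact(c, f"{where}: contacts[{i}]")
                     for i, c in enumerate(contacts_doc))

    kwargs: dict[str, Any] = {"name": name, "contacts": contacts}
    value = _number(doc, "episode_weeks", where, required=False)
    if value is not None:
        kwargs["episode_weeks"] = value
    fb = _get(doc, "facility_based", where, required=False)
    if fb is not None:
        kwargs["facility_based"] = bool(fb)

    admin = _get(doc, "admin", where, required=False, default={})
    if admin:
        kwargs["admin_system_hours"] = _number(admin, "system_hours",
                                               f"{where}: admin",
                                               required=False, default=0.0)
        kwargs["admin_patient_hours"] = _number(admin, "patient_hours",
                                                f"{where}: admin",
                                                required=False, default=0.0)
    training = _get(doc, "training", where, required=False, default={})
    if training:
        kwargs["training_hours_per_provider"] = _number(
            training, "hours_per_provider", f"{where}: training")
        kwargs["episodes_per_provider"] = _number(
            training, "episodes_per_provider", f"{where}: training")
    support = _get(doc, "support", where, required=False)
    if support is not None:
        kwargs["support"] = SupportSpec(
            annual_budget=_number(support, "annual_budget", f"{where}: support"),
            annual_patients=int(_number(support, "annual_patients",
                                        f"{where}: support")),
            halved=bool(_get(support, "halved", f"{where}: support",
                             required=False, default=False)),
        )
    transport = _get(doc, "transport", where, required=False)
    if transport is not None:
        twhere = f"{where}: transport"
        mode = _get(transport, "mode", twhere)
        try:
            mode = TransportMode(mode)
        except ValueError:
            raise ConfigError(f"{twhere}: field 'mode' must be one of "
                              f"{[m.value for m in TransportMode]}") from None
        tkwargs: dict[str, Any] = {"mode": mode}
        for field_ in ("round_trip_minutes", "visits_per_episode",
                       "emission_tons_per_episode", "round_trip_km",
                       "kg_co2_per_km", "emission_price_sek_per_ton"):
            value = _number(transport, field_, twhere, required=False)
            if value is not None:
                tkwargs[field_] = value
        try:
            kwargs["transport"] = TransportProfile(**tkwargs)
        except ValidationError as exc:
            raise ConfigError(f"{twhere}: {exc}") from exc
    scales = _get(doc, "line_scales", where, required=False)
    if scales is not None:
        if not isinstance(scales, Mapping):
            raise ConfigError(f"{where}: field 'line_scales' must be a mapping")
        kwargs["line_scales"] = {str(k): float(v) for k, v in scales.items()}
    try:
        return CareModelSpec(**kwargs)
    except ValidationError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def save_care_model(spec: CareModelSpec, path: Union[str, Path]) -> None:
    """Serialize a care model back to YAML (round-trips with the loader)."""
    doc: dict[str, Any] = {
        "name": spec.name,
        "episode_weeks": spec.episode_weeks,
        "facility_based": spec.facility_based,
        "contacts": [],
    }
    for c in spec.contacts:
        cdoc: dict[str, Any] = {"label": c.label, "mode": c.mode.value,
                                "occurrences": c.occurrences_per_episode}
        if c.duration_minutes is not None:
            cdoc["duration_minutes"] = c.duration_minutes
        else:
            cdoc["duration_range"] = {"low": c.duration_low, "high": c.duration_high}
        cdoc.update({"provider_attends": c.provider_attends,
                     "patient_attends": c.patient_attends,
                     "group_size": c.group_size, "on_site": c.on_site,
                     "once_per_episode": c.once_per_episode})
        if c.participation_key is not None:
            cdoc["participation_key"] = c.participation_key
        doc["contacts"].append(cdoc)
    doc["admin"] = {"system_hours": spec.admin_system_hours,
                    "patient_hours": spec.admin_patient_hours}
    doc["training"] = {"hours_per_provider": spec.training_hours_per_provider,
                       "episodes_per_provider": spec.episodes_per_provider}
    if spec.support is not None:
        doc["support"] = dataclasses.asdict(spec.support)
    if spec.transport is not None:
        tdoc = {k: v for k, v in dataclasses.asdict(spec.transport).items()
                if v is not None}
        tdoc["mode"] = spec.transport.mode.value
        doc["transport"] = tdoc
    if spec.line_scales:
        doc["line_scales"] = dict(spec.line_scales)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class RunConfig:
    """A fully resolved analysis run: inputs, output location, switches."""

    model_paths: tuple[Path, ...]
    context_path: Path
    output_dir: Path
    formats: tuple[str, ...] = ("csv", "json")
    scenario_mode: str = "standard"
    log_level: str = "INFO"

    def load(self) -> tuple[list[CareModelSpec], ValuationContext]:
        specs = [load_care_model(p) for p in self.model_paths]
        return specs, load_valuation_context(self.context_path)


def load_and_validate(config_path: Union[str, Path]) -> RunConfig:
    """Load a run config, resolving and validating every referenced file."""
    doc = _load_document(config_path)
    where = str(config_path)
    base = Path(config_path).parent

    def _resolve(p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else base / path

    models = _get(doc, "models", where)
    if not isinstance(models, Sequence) or isinstance(models, str) or not models:
        raise ConfigError(f"{where}: field 'models' must be a non-empty list "
                          "of care-model config paths")
    model_paths = tuple(_resolve(str(p)) for p in models)
    context_path = _resolve(str(_get(doc, "valuation_context", where)))
    output_dir = _resolve(str(_get(doc, "output_dir", where, required=False,
                                   default=".")))
    formats = _get(doc, "formats", where, required=False, default=["csv", "json"])
    for fmt in formats:
        if fmt not in ("csv", "json"):
            raise ConfigError(f"{where}: field 'formats' entries must be "
                              f"'csv' or 'json', got {fmt!r}")
    scenario_mode = str(_get(doc, "scenario_mode", where, required=False,
                             default="standard"))
    if scenario_mode not in ("standard", "as_printed"):
        raise ConfigError(f"{where}: field 'scenario_mode' must be 'standard' "
                          f"or 'as_printed', got {scenario_mode!r}")
    config = RunConfig(
        model_paths=model_paths,
        context_path=context_path,
        output_dir=output_dir,
        formats=tuple(formats),
        scenario_mode=scenario_mode,
        log_level=str(_get(doc, "log_level", where, required=False,
                           default="INFO")),
    )
    config.load()  # validates every referenced file now, not at use time
    return config


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

#: Published-table row labels by (domain, categories merged into the row).
_REPORT_ROWS: list[tuple[str, Domain, tuple[Category, ...]]] = [
    ("Contacts/Visits/Sessions", Domain.SYSTEM, (Category.CONTACTS,)),
    ("Administration", Domain.SYSTEM,
     (Category.ADMINISTRATION, Category.TECHNICAL_SUPPORT)),
    ("Training of physiotherapists", Domain.SYSTEM, (Category.TRAINING,)),
    ("Contacts/Visits", Domain.PATIENT, (Category.CONTACTS,)),
    ("Administration ", Domain.PATIENT, (Category.ADMINISTRATION,)),
    ("Transportation", Domain.PATIENT, (Category.TRANSPORTATION,)),
    ("Direct costs", Domain.PATIENT, (Category.DIRECT_FEES,)),
    ("CO2 emissions", Domain.OTHER, (Category.EMISSIONS,)),
]


def breakdown_to_frame(breakdown: CostBreakdown) -> pd.DataFrame:
    """Tidy (machine-readable) cost inventory: one row per cost item."""
    rows = [{
        "model": breakdown.model_name,
        "domain": item.domain.value,
        "category": item.category.value,
        "label": item.label,
        "quantity_hours": item.quantity_hours,
        "unit_value": item.unit_value,
        "total": item.total,
    } for item in breakdown.items]
    return pd.DataFrame(rows, columns=["model", "domain", "category", "label",
                                       "quantity_hours", "unit_value", "total"])


def breakdown_to_dict(breakdown: CostBreakdown,
                      ctx: Optional[ValuationContext] = None) -> dict:
    """JSON-ready breakdown; embeds the resolved valuation parameters if given."""
    doc = {
        "model": breakdown.model_name,
        "items": [{"domain": it.domain.value, "category": it.category.value,
                   "label": it.label, "total": it.total}
                  for it in breakdown.items],
        "subtotals": {"system": breakdown.subtotal_system,
                      "patient": breakdown.subtotal_patient,
                      "other": breakdown.subtotal_other},
        "total": breakdown.total,
        "rounded_total_sek": round_sek(breakdown.total),
    }
    if ctx is not None:
        doc["valuation_context"] = dataclasses.asdict(ctx)
    return doc


def _sum_categories(breakdown: CostBreakdown, domain: Domain,
                    categories: tuple[Category, ...]) -> Optional[float]:
    totals = [it.total for it in breakdown.items
              if it.domain is domain and it.category in categories]
    return sum(totals) if totals else None


def render_breakdown_report(breakdowns: Sequence[CostBreakdown]) -> pd.DataFrame:
    """Published-table-shaped comparison with whole-SEK half-up rounding.

    One column per model plus, for exactly two models, a ``Difference``
    column (first minus second, computed on the rounded totals as published
    figures are).  Absent lines (e.g. transport under digital care) show as
    missing values.
    """
    if len(breakdowns) == 0:
        raise ValidationError("at least one breakdown is required")
    index: list[str] = []
    columns: dict[str, list] = {b.model_name: [] for b in breakdowns}

    def emit(label: str, values: list) -> None:
        index.append(label)
        for b, v in zip(breakdowns, values):
            columns[b.model_name].append(v)

    for domain, domain_label, sub_label in (
            (Domain.SYSTEM, "A. System", "A: Sub-total"),
            (Domain.PATIENT, "B. Patient", "B: Sub-total"),
            (Domain.OTHER, "C. Other", "C: Sub-total")):
        for label, row_domain, cats in _REPORT_ROWS:
            if row_domain is not domain:
                continue
            values = []
            for b in breakdowns:
                total = _sum_categories(b, domain, cats)
                values.append(pd.NA if total is None else round_sek(total))
            if any(v is not pd.NA for v in values):
                emit(label, values)
        emit(sub_label, [round_sek(b.subtotal(domain)) for b in breakdowns])
    emit("Total", [round_sek(b.total) for b in breakdowns])

    table = pd.DataFrame(columns, index=index, dtype="Int64")
    if len(breakdowns) == 2:
        a, b = breakdowns[0].model_name, breakdowns[1].model_name
        table["Difference"] = table[a] - table[b]
    return table
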