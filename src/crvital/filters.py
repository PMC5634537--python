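"""Rule-based exclusion filters mapping raw media-registry cases to the analysis set.

A news-media registry of people killed during police encounters uses a
broader case definition than the ICD-10 "legal intervention" category, so
cases are excluded when they do not conform to the ICD definition:
vehicle-struck deaths outside pursuits or intentional transport injuries,
domestic violence by officers, in-custody deaths without a clear
law-enforcement mechanism or homicide ruling, deaths falling in the next
calendar year, and friendly fire.

The rules form a fixed cascade so that every record receives exactly one
canonical decision: death-next-year, friendly fire, domestic violence,
the vehicle rule, the custody rule, then inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "EXCLUSION_REASONS",
    "MECHANISMS",
    "FLAG_COLUMNS",
    "FilterDecision",
    "classify_exclusion",
    "apply_filters",
]

MECHANISMS = frozenset(
    {"firearm", "taser", "struck_by_against", "motor_vehicle", "neglect", "other_custody"}
)

#: mechanisms that by themselves establish law-enforcement causation in custody
_CUSTODY_QUALIFYING_MECHANISMS = frozenset({"taser", "neglect"})

FLAG_COLUMNS = (
    "vehicle_pursuit",
    "intentional_vehicle_transport_injury",
    "domestic_violence",
    "friendly_fire",
    "in_custody",
    "chokehold_or_taser",
    "essential_care_withheld",
    "ruled_homicide",
)

EXCLUSION_REASONS = (
    "vehicle_not_pursuit",
    "domestic_violence",
    "custody_no_mechanism",
    "death_next_year",
    "friendly_fire",
)


@dataclass(frozen=True)
class FilterDecision:
    record_id: str
    included: bool
    reason: str

    def __post_init__(self) -> None:
        if self.included != (self.reason == "included"):
            raise ValueError("reason must be 'included' iff included is True")


def _flag(record, name: str) -> bool:
    value = record.get(name, False)
    return bool(value) and not pd.isna(value)


def classify_exclusion(record, study_year: int | None = None) -> FilterDecision:
    """Classify one case through the exclusion cascade.

    ``record`` is a mapping or pandas row with ``record_id``, ``mechanism``,
    ``injury_date``, optional ``death_year`` and the boolean narrative flags
    in :data:`FLAG_COLUMNS`.  ``study_year`` defaults to the injury year.
    """
    record_id = str(record["record_id"])
    mechanism = record.get("mechanism")
    if mechanism is None or pd.isna(mechanism) or mechanism not in MECHANISMS:
        raise ValueError(f"record {record_id}: missing or invalid mechanism {mechanism!r}")
    if study_year is None:
        study_year = pd.Timestamp(record["injury_date"]).year

    death_year = record.get("death_year")
    if death_year is not None and not pd.isna(death_year) and int(death_year) > study_year:
        return FilterDecision(record_id, False, "death_next_year")
    if _flag(record, "friendly_fire"):
        return FilterDecision(record_id, False, "friendly_fire")
    if _flag(record, "domestic_violence"):
        return FilterDecision(record_id, False, "domestic_violence")
    if mechanism == "motor_vehicle" and not (
        _flag(record, "vehicle_pursuit") or _flag(record, "intentional_vehicle_transport_injury")
    ):
        return FilterDecision(record_id, False, "vehicle_not_pursuit")
    if _flag(record, "in_custody"):
        qualifies = (
            mechanism in _CUSTODY_QUALIFYING_MECHANISMS
            or _flag(record, "chokehold_or_taser")
            or _flag(record, "essential_care_withheld")
            or _flag(record, "ruled_homicide")
        )
        if not qualifies:
            return FilterDecision(record_id, False, "custody_no_mechanism")
    return FilterDecision(record_id, True, "included")


def apply_filters(
    records: pd.DataFrame, study_year: int | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter a case table; return the included rows and a per-reason tally.

    The tally is keyed by the five exclusion reasons (zero-filled), so
    ``len(included) + sum(tally.values()) == len(records)``.
    """
    tally = {reason: 0 for reason in EXCLUSION_REASONS}
    if records.empty:
        return records.copy(), tally
    keep = []
    for _, row in records.iterrows():
        decision = classify_exclusion(row, study_year=study_year)
        if decision.included:
            keep.append(True)
        else:
            keep.append(False)
            tally[decision.reason] += 1
    return records.loc[keep].copy(), tally
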