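"""Reading, validating and writing trial adverse-event result records.

The on-disk format is a small, documented XML dialect mirroring the results
section of ClinicalTrials.gov study records (see ``docs/registry_format.md``):

.. code-block:: xml

    <cohort>
      <trial trial_id="T00001" sponsor_type="Industry" intervention="Drug X">
        <arm arm_id="A1" title="Treatment" enrolled="120" mean_age="47.5"
             overall_affected="33">
          <event term="Nausea" serious="false" subjects_affected="12"
                 subjects_at_risk="120" soc="Gastrointestinal disorders"/>
        </arm>
      </trial>
    </cohort>

Counts are per arm, exactly as the registry reports them: every event row
carries its own ``subjects_affected`` / ``subjects_at_risk`` pair, and the
event-level denominator may legitimately differ from the arm enrollment.
``overall_affected`` (number of participants experiencing at least one
event) is optional because registry records do not always publish the
deduplicated arm total; :func:`effective_overall_affected` provides the
documented fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from lxml import etree

from .errors import ParseError, ValidationError

__all__ = [
    "EventRecord",
    "ArmRecord",
    "TrialRecord",
    "read_trial_records",
    "write_trial_records",
    "effective_overall_affected",
]

logger = logging.getLogger(__name__)

_BOOL_TRUE = {"true", "1", "yes"}
_BOOL_FALSE = {"false", "0", "no"}


@dataclass(frozen=True)
class EventRecord:
    """One adverse-event row of an arm's results table."""

    term: str
    serious: bool
    subjects_affected: int
    subjects_at_risk: int
    soc_hint: str | None = None

    def validate(self, context: str = "") -> None:
        where = f"{context}event '{self.term}'" if context else f"event '{self.term}'"
        if not self.term or not self.term.strip():
            raise ValidationError(f"{context}event term is empty")
        if self.subjects_at_risk <= 0:
            raise ValidationError(
                f"{where}: subjects_at_risk must be positive, got {self.subjects_at_risk}"
            )
        if self.subjects_affected < 0:
            raise ValidationError(
                f"{where}: subjects_affected must be non-negative, got {self.subjects_affected}"
            )
        if self.subjects_affected > self.subjects_at_risk:
            raise ValidationError(
                f"{where}: subjects_affected ({self.subjects_affected}) exceeds "
                f"subjects_at_risk ({self.subjects_at_risk})"
            )


@dataclass(frozen=True)
class ArmRecord:
    """A trial arm: the unit at which the registry reports event counts."""

    arm_id: str
    enrolled: int
    title: str = ""
    mean_age: float | None = None
    overall_affected: int | None = None
    events: tuple[EventRecord, ...] = ()

    def validate(self, context: str = "") -> None:
        where = f"{context}arm '{self.arm_id}'"
        if not self.arm_id:
            raise ValidationError(f"{context}arm_id is empty")
        if self.enrolled <= 0:
            raise ValidationError(f"{where}: enrolled must be positive, got {self.enrolled}")
        if self.mean_age is not None and self.mean_age < 0:
            raise ValidationError(f"{where}: mean_age must be non-negative, got {self.mean_age}")
        if self.overall_affected is not None:
            if self.overall_affected < 0:
                raise ValidationError(
                    f"{where}: overall_affected must be non-negative, got {self.overall_affected}"
                )
            if self.overall_affected > self.enrolled:
                raise ValidationError(
                    f"{where}: overall_affected ({self.overall_affected}) exceeds "
                    f"enrolled ({self.enrolled})"
                )
            # A participant counted for any single whole-arm event is affected
            # overall, so the reported total cannot undercut the largest
            # event count taken over the full enrollment.
            floor = max(
                (
                    ev.subjects_affected
                    for ev in self.events
                    if ev.subjects_at_risk == self.enrolled
                ),
                default=0,
            )
            if self.overall_affected < floor:
                raise ValidationError(
                    f"{where}: overall_affected ({self.overall_affected}) is below the "
                    f"largest whole-arm event count ({floor})"
                )
        for ev in self.events:
            ev.validate(context=f"{where}: ")


@dataclass(frozen=True)
class TrialRecord:
    """A clinical trial with one or more arms."""

    trial_id: str
    arms: tuple[ArmRecord, ...]
    sponsor_type: str | None = None
    intervention: str | None = None

    def validate(self) -> None:
        where = f"trial '{self.trial_id}'"
        if not self.trial_id:
            raise ValidationError("trial_id is empty")
        if not self.arms:
            raise ValidationError(f"{where}: arms collection is empty")
        seen: set[str] = set()
        for arm in self.arms:
            if arm.arm_id in seen:
                raise ValidationError(f"{where}: duplicate arm_id '{arm.arm_id}'")
            seen.add(arm.arm_id)
            arm.validate(context=f"{where}: ")


def effective_overall_affected(arm: ArmRecord) -> tuple[int, str]:
    """Number of participants affected by at least one event, with provenance.

    Returns ``(count, "reported")`` when the registry record carries the
    deduplicated arm total, and otherwise ``(count, "lower_bound")`` where the
    count is the maximum ``subjects_affected`` over the arm's events (0 for an
    arm with no events).  The max rule is a true lower bound: participants
    hit by a single event are certainly affected overall, while overlap
    between different events cannot be recovered from arm-level tables.
    """
    if arm.overall_affected is not None:
        return arm.overall_affected, "reported"
    if not arm.events:
        return 0, "lower_bound"
    return max(ev.subjects_affected for ev in arm.events), "lower_bound"


# ---------------------------------------------------------------------------
# XML serialization
# ---------------------------------------------------------------------------


def _parse_bool(raw: str, where: str) -> bool:
    low = raw.strip().lower()
    if low in _BOOL_TRUE:
        return True
    if low in _BOOL_FALSE:
        return False
    raise ValidationError(f"{where}: cannot interpret '{raw}' as a boolean")


def _parse_int(raw: str, where: str) -> int:
    try:
        return int(raw)
    except ValueError as exc:
        raise ValidationError(f"{where}: cannot interpret '{raw}' as an integer") from exc


def _require(elem: etree._Element, attr: str, where: str) -> str:
    value = elem.get(attr)
    if value is None:
        raise ValidationError(f"{where}: missing required attribute '{attr}'")
    return value


def _event_from_xml(elem: etree._Element, where: str) -> EventRecord:
    term = _require(elem, "term", where)
    ewhere = f"{where}: event '{term}'"
    return EventRecord(
        term=term,
        serious=_parse_bool(_require(elem, "serious", ewhere), ewhere),
        subjects_affected=_parse_int(_require(elem, "subjects_affected", ewhere), ewhere),
        subjects_at_risk=_parse_int(_require(elem, "subjects_at_risk", ewhere), ewhere),
        soc_hint=elem.get("soc"),
    )


def _arm_from_xml(elem: etree._Element, where: str) -> ArmRecord:
    arm_id = _require(elem, "arm_id", where)
    awhere = f"{where}: arm '{arm_id}'"
    mean_age = elem.get("mean_age")
    overall = elem.get("overall_affected")
    events = tuple(
        _event_from_xml(child, awhere) for child in elem.iterchildren("event")
    )
    return ArmRecord(
        arm_id=arm_id,
        title=elem.get("title", ""),
        enrolled=_parse_int(_require(elem, "enrolled", awhere), awhere),
        mean_age=float(mean_age) if mean_age is not None else None,
        overall_affected=_parse_int(overall, awhere) if overall is not None else None,
        events=events,
    )


def _trial_from_xml(elem: etree._Element) -> TrialRecord:
    trial_id = _require(elem, "trial_id", "trial")
    where = f"trial '{trial_id}'"
    return TrialRecord(
        trial_id=trial_id,
        sponsor_type=elem.get("sponsor_type"),
        intervention=elem.get("intervention"),
        arms=tuple(_arm_from_xml(child, where) for child in elem.iterchildren("arm")),
    )


def read_trial_records(
    path: str | Path, *, skip_invalid: bool = False
) -> list[TrialRecord]:
    """Parse a cohort document into validated :class:`TrialRecord` objects.

    Every record is validated against the type invariants.  By default an
    invalid record aborts the read with a :class:`ValidationError` naming the
    trial and field.  With ``skip_invalid=True`` invalid records are dropped,
    each with a logged per-record diagnostic, and the valid remainder is
    returned.

    Raises
    ------
    ParseError
        If the document is not well-formed XML (message includes the lxml
        line context).
    ValidationError
        If a record violates an invariant and ``skip_invalid`` is false.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "cohort":
        raise ParseError(f"{path}: expected root element <cohort>, found <{root.tag}>")
    records: list[TrialRecord] = []
    for elem in root.iterchildren("trial"):
        try:
            record = _trial_from_xml(elem)
            record.validate()
        except ValidationError as exc:
            if skip_invalid:
                logger.warning("rejected record at line %s: %s", elem.sourceline, exc)
                continue
            raise
        records.append(record)
    return records


def _format_float(value: float) -> str:
    # repr round-trips exactly; integral ages still read back identically.
    return repr(float(value))


def write_trial_records(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Serialize records to the cohort XML dialect (UTF-8, deterministic).

    ``read_trial_records`` inverts this exactly, and writing the same records
    twice yields byte-identical files.
    """
    root = etree.Element("cohort")
    for trial in records:
        trial.validate()
        t = etree.SubElement(root, "trial", trial_id=trial.trial_id)
        if trial.sponsor_type is not None:
            t.set("sponsor_type", trial.sponsor_type)
        if trial.intervention is not None:
            t.set("intervention", trial.intervention)
        for arm in trial.arms:
            a = etree.SubElement(t, "arm", arm_id=arm.arm_id)
            if arm.title:
                a.set("title", arm.title)
            a.set("enrolled", str(arm.enrolled))
            if arm.mean_age is not None:
                a.set("mean_age", _format_float(arm.mean_age))
            if arm.overall_affected is not None:
                a.set("overall_affected", str(arm.overall_affected))
            for ev in arm.events:
                e = etree.SubElement(a, "event", term=ev.term)
                e.set("serious", "true" if ev.serious else "false")
                e.set("subjects_affected", str(ev.subjects_affected))
                e.set("subjects_at_risk", str(ev.subjects_at_risk))
                if ev.soc_hint is not None:
                    e.set("soc", ev.soc_hint)
    tree = etree.ElementTree(root)
    tree.write(str(path), encoding="utf-8", xml_declaration=True, pretty_print=True)
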