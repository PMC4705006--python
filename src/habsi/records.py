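"""Domain records for the EMR streams the surveillance rules consume.

All timestamps are timezone-naive :class:`datetime.datetime` at minute
resolution (every rule in the pipeline is hour-scale).  ``None`` in a
``*_ts`` field that the schema marks "or open" means the interval is still
open (patient not discharged, device still in place, order still running).

Specimen *log-in* time — the laboratory receipt timestamp — is used
throughout as the proxy for collection time and infection onset.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, datetime

from .organisms import OrganismIsolate

__all__ = [
    "RecordError",
    "Sex",
    "SpecimenType",
    "DeviceType",
    "Classification",
    "PatientStay",
    "Episode",
    "CultureResult",
    "VitalSign",
    "DeviceInterval",
    "AntimicrobialOrder",
    "HabsiEvent",
    "Bundle",
]


class RecordError(ValueError):
    """A record violates its invariants."""


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    U = "U"


class SpecimenType(str, enum.Enum):
    BLOOD = "blood"
    CATHETER_TIP = "catheter_tip"
    URINE = "urine"
    SPUTUM = "sputum"
    WOUND = "wound"
    CSF = "csf"
    OTHER = "other"


class DeviceType(str, enum.Enum):
    CENTRAL_LINE = "central_line"
    URINARY_CATHETER = "urinary_catheter"
    VENTILATOR = "ventilator"
    OTHER = "other"


class Classification(str, enum.Enum):
    """Event labels: primary BSI subtypes, secondary BSI, clinical sepsis."""

    PRIM_CRBSI = "PRIM_CRBSI"
    PRIM_CLABSI = "PRIM_CLABSI"
    PRIM_OTHER = "PRIM_OTHER"
    SEC = "SEC"
    CSEP = "CSEP"


# Vital-sign plausibility bounds enforced (with a warning) at ingest.
TEMP_BOUNDS = (30.0, 45.0)
HR_BOUNDS = (0, 350)
RR_BOUNDS = (0, 150)


@dataclass
class PatientStay:
    """One hospitalization interval with its ward-transfer history."""

    patient_id: str
    stay_id: str
    admission_ts: datetime
    discharge_ts: datetime | None
    birth_date: date
    sex: Sex
    transfers: tuple[tuple[str, datetime], ...]

    def validate(self) -> None:
        if self.discharge_ts is not None and not self.admission_ts < self.discharge_ts:
            raise RecordError(
                f"stay {self.stay_id}: admission {self.admission_ts} not before "
                f"discharge {self.discharge_ts}"
            )
        if self.transfers:
            times = [t for _, t in self.transfers]
            if times != sorted(times):
                raise RecordError(f"stay {self.stay_id}: transfers not sorted by enter time")
            if times[0] != self.admission_ts:
                raise RecordError(
                    f"stay {self.stay_id}: first transfer enter time {times[0]} "
                    f"!= admission {self.admission_ts}"
                )


@dataclass
class Episode:
    """A single hospitalization episode: one or more stays linked across
    re-admissions within the linkage window."""

    episode_id: str
    patient_id: str
    stays: tuple[PatientStay, ...]

    @property
    def start_ts(self) -> datetime:
        return self.stays[0].admission_ts

    @property
    def end_ts(self) -> datetime | None:
        return self.stays[-1].discharge_ts

    def contains(self, ts: datetime) -> bool:
        end = self.end_ts
        return self.start_ts <= ts and (end is None or ts <= end)

    def validate(self) -> None:
        if not self.stays:
            raise RecordError(f"episode {self.episode_id}: no stays")
        if any(s.patient_id != self.patient_id for s in self.stays):
            raise RecordError(f"episode {self.episode_id}: mixed patient ids")
        for a, b in zip(self.stays, self.stays[1:]):
            if a.discharge_ts is None or b.admission_ts < a.discharge_ts:
                raise RecordError(
                    f"episode {self.episode_id}: stays overlap or out of order"
                )


@dataclass
class CultureResult:
    """A culture specimen with its final report and any later revisions.

    ``revisions`` are full replacements of the organism list, in strictly
    increasing revision-time order.  Whether a revision is *applied* is a
    detection-rule concern (the recall-day window), not a record concern.
    """

    specimen_id: str
    patient_id: str
    login_ts: datetime
    specimen_type: SpecimenType
    organisms: tuple[OrganismIsolate, ...]
    report_final_ts: datetime
    revisions: tuple[tuple[datetime, tuple[OrganismIsolate, ...]], ...] = ()

    def validate(self) -> None:
        if self.login_ts > self.report_final_ts:
            raise RecordError(
                f"specimen {self.specimen_id}: log-in after final report"
            )
        rev_times = [t for t, _ in self.revisions]
        if any(b <= a for a, b in zip(rev_times, rev_times[1:])):
            raise RecordError(
                f"specimen {self.specimen_id}: revision times not strictly increasing"
            )


@dataclass
class VitalSign:
    """One nursing observation; at least one measurement must be present."""

    patient_id: str
    ts: datetime
    temperature_c: float | None = None
    heart_rate_bpm: int | None = None
    respiratory_rate_pm: int | None = None

    def validate(self) -> None:
        if (
            self.temperature_c is None
            and self.heart_rate_bpm is None
            and self.respiratory_rate_pm is None
        ):
            raise RecordError(
                f"vital sign for {self.patient_id} at {self.ts}: no measurement present"
            )


@dataclass
class DeviceInterval:
    patient_id: str
    device_type: DeviceType
    start_ts: datetime
    end_ts: datetime | None = None

    def validate(self) -> None:
        if self.end_ts is not None and not self.start_ts < self.end_ts:
            raise RecordError(
                f"device interval for {self.patient_id}: start not before end"
            )

    def overlaps(self, lo: datetime, hi: datetime) -> bool:
        end = self.end_ts
        return self.start_ts <= hi and (end is None or end >= lo)


@dataclass
class AntimicrobialOrder:
    patient_id: str
    drug_code: str
    start_ts: datetime
    end_ts: datetime | None = None

    def validate(self) -> None:
        if self.end_ts is not None and not self.start_ts < self.end_ts:
            raise RecordError(
                f"antimicrobial order for {self.patient_id}: start not before end"
            )


@dataclass
class HabsiEvent:
    """A detected healthcare-associated bloodstream infection event.

    ``confirmation_ts`` is the (human) confirmation date when known; it is an
    input field carried through for delay statistics, never produced by the
    detector itself.
    """

    event_id: str
    patient_id: str
    episode_id: str
    onset_ts: datetime
    organisms: tuple[OrganismIsolate, ...]
    classification: Classification
    source_specimens: tuple[str, ...]
    confirmation_ts: datetime | None = None

    def validate(self) -> None:
        if (self.classification is Classification.CSEP) != (len(self.organisms) == 0):
            raise RecordError(
                f"event {self.event_id}: CSEP iff the organism set is empty"
            )
        if self.confirmation_ts is not None and self.confirmation_ts < self.onset_ts:
            raise RecordError(f"event {self.event_id}: confirmation before onset")


@dataclass
class Bundle:
    """All EMR streams for a surveillance period."""

    stays: list[PatientStay] = field(default_factory=list)
    cultures: list[CultureResult] = field(default_factory=list)
    vitals: list[VitalSign] = field(default_factory=list)
    devices: list[DeviceInterval] = field(default_factory=list)
    abx: list[AntimicrobialOrder] = field(default_factory=list)

    def patient_ids(self) -> set[str]:
        return {s.patient_id for s in self.stays}
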