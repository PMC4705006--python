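"""Flat-table interchange I/O for the EMR streams.

One CSV per stream stands in for the hospital's HL7 feeds.  Schemas (header
rows are mandatory and checked):

``stays.csv``
    patient_id, stay_id, admission_ts, discharge_ts, birth_date, sex, transfers
    — ``transfers`` is ``ward@ISO-TS`` entries joined by ``;``; ``discharge_ts``
    empty means still admitted.
``cultures.csv``
    specimen_id, patient_id, login_ts, specimen_type, organisms,
    report_final_ts, revisions — ``organisms`` is ``|``-joined organism codes
    ('' = no growth); ``revisions`` is ``ISO-TS=CODE|CODE`` entries joined by
    ``;``.
``vitals.csv``
    patient_id, ts, temperature_c, heart_rate_bpm, respiratory_rate_pm
    (blank = not measured).
``devices.csv``
    patient_id, device_type, start_ts, end_ts.
``abx.csv``
    patient_id, drug_code, start_ts, end_ts.
``reference_labels.csv``
    patient_id, habsi, classification, onset_ts — one row per patient in the
    evaluated population; ``habsi`` is 0/1.

Timestamps are ISO-8601 at minute resolution in a single implicit timezone.
Ingest never silently drops a row: every input row is either parsed into a
validated record or rejected with a row-level diagnostic, and
``accepted + rejected == input rows`` per stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

from . import records as rec
from .organisms import DEFAULT_COMMENSAL_CODES, OrganismIsolate, isolates_from_codes
from .records import Bundle, HabsiEvent, RecordError

log = logging.getLogger(__name__)

__all__ = [
    "IngestReport",
    "read_tables",
    "write_bundle",
    "write_line_list",
    "read_line_list",
    "read_reference_labels",
    "write_reference_labels",
]

TS_FMT = "%Y-%m-%dT%H:%M"

STREAM_COLUMNS: dict[str, list[str]] = {
    "stays": ["patient_id", "stay_id", "admission_ts", "discharge_ts", "birth_date", "sex", "transfers"],
    "cultures": ["specimen_id", "patient_id", "login_ts", "specimen_type", "organisms", "report_final_ts", "revisions"],
    "vitals": ["patient_id", "ts", "temperature_c", "heart_rate_bpm", "respiratory_rate_pm"],
    "devices": ["patient_id", "device_type", "start_ts", "end_ts"],
    "abx": ["patient_id", "drug_code", "start_ts", "end_ts"],
}

EVENT_COLUMNS = [
    "event_id", "patient_id", "episode_id", "onset_ts", "organisms",
    "classification", "source_specimens", "confirmation_ts",
]

LABEL_COLUMNS = ["patient_id", "habsi", "classification", "onset_ts"]


def _fmt_ts(ts: datetime | None) -> str:
    return "" if ts is None else ts.strftime(TS_FMT)


def _parse_ts(text: str, *, optional: bool = False) -> datetime | None:
    text = (text or "").strip()
    if not text:
        if optional:
            return None
        raise ValueError("missing timestamp")
    # minute grid: truncate seconds if present
    return datetime.fromisoformat(text).replace(second=0, microsecond=0)


@dataclass
class IngestReport:
    """Row-level accounting of one read_tables call."""

    accepted: dict[str, int] = field(default_factory=dict)
    rejected: dict[str, int] = field(default_factory=dict)
    diagnostics: list[tuple[str, int, str]] = field(default_factory=list)  # (stream, row, message)

    def reject(self, stream: str, row: int, message: str) -> None:
        self.rejected[stream] = self.rejected.get(stream, 0) + 1
        self.diagnostics.append((stream, row, message))
        log.warning("%s row %d rejected: %s", stream, row, message)


def _read_stream(path: Path, stream: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = STREAM_COLUMNS[stream]
    if list(df.columns) != expected:
        raise RecordError(
            f"{path}: header mismatch for {stream}: got {list(df.columns)}, expected {expected}"
        )
    return df


def _parse_stay(row: Mapping[str, str]) -> rec.PatientStay:
    transfers = []
    for entry in filter(None, (row["transfers"] or "").split(";")):
        ward, _, ts = entry.partition("@")
        if not ts:
            raise ValueError(f"bad transfer entry {entry!r}")
        transfers.append((ward, _parse_ts(ts)))
    stay = rec.PatientStay(
        patient_id=row["patient_id"],
        stay_id=row["stay_id"],
        admission_ts=_parse_ts(row["admission_ts"]),
        discharge_ts=_parse_ts(row["discharge_ts"], optional=True),
        birth_date=date.fromisoformat(row["birth_date"]),
        sex=rec.Sex(row["sex"]),
        transfers=tuple(transfers),
    )
    stay.validate()
    return stay


def _parse_culture(row: Mapping[str, str], commensal_codes: frozenset[str]) -> rec.CultureResult:
    revisions = []
    for entry in filter(None, (row["revisions"] or "").split(";")):
        ts, sep, codes = entry.partition("=")
        if not sep:
            raise ValueError(f"bad revision entry {entry!r}")
        revisions.append((_parse_ts(ts), isolates_from_codes(codes, commensal_codes)))
    culture = rec.CultureResult(
        specimen_id=row["specimen_id"],
        patient_id=row["patient_id"],
        login_ts=_parse_ts(row["login_ts"]),
        specimen_type=rec.SpecimenType(row["specimen_type"]),
        organisms=isolates_from_codes(row["organisms"], commensal_codes),
        report_final_ts=_parse_ts(row["report_final_ts"]),
        revisions=tuple(revisions),
    )
    culture.validate()
    return culture


def _parse_vital(row: Mapping[str, str]) -> rec.VitalSign:
    def num(text: str, cast: Callable, bounds: tuple[float, float], what: str):
        text = (text or "").strip()
        if not text:
            return None
        value = cast(float(text))
        lo, hi = bounds
        if not lo <= value <= hi:
            raise ValueError(f"{what} {value} outside plausibility bounds [{lo}, {hi}]")
        return value

    vital = rec.VitalSign(
        patient_id=row["patient_id"],
        ts=_parse_ts(row["ts"]),
        temperature_c=num(row["temperature_c"], float, rec.TEMP_BOUNDS, "temperature"),
        heart_rate_bpm=num(row["heart_rate_bpm"], int, rec.HR_BOUNDS, "heart rate"),
        respiratory_rate_pm=num(row["respiratory_rate_pm"], int, rec.RR_BOUNDS, "respiratory rate"),
    )
    vital.validate()
    return vital


def _parse_device(row: Mapping[str, str]) -> rec.DeviceInterval:
    device = rec.DeviceInterval(
        patient_id=row["patient_id"],
        device_type=rec.DeviceType(row["device_type"]),
        start_ts=_parse_ts(row["start_ts"]),
        end_ts=_parse_ts(row["end_ts"], optional=True),
    )
    device.validate()
    return device


def _parse_abx(row: Mapping[str, str]) -> rec.AntimicrobialOrder:
    order = rec.AntimicrobialOrder(
        patient_id=row["patient_id"],
        drug_code=row["drug_code"],
        start_ts=_parse_ts(row["start_ts"]),
        end_ts=_parse_ts(row["end_ts"], optional=True),
    )
    order.validate()
    return order


def read_tables(
    paths: Mapping[str, Path | str] | Path | str,
    commensal_codes: frozenset[str] = DEFAULT_COMMENSAL_CODES,
) -> tuple[Bundle, IngestReport]:
    """Read the per-stream CSVs into a validated :class:`Bundle`.

    ``paths`` is either a directory containing the conventionally named files
    (``stays.csv`` etc.) or an explicit stream-name -> path mapping.  Streams
    other than ``stays`` may be absent (treated as empty).  A malformed
    header is fatal; a malformed row is rejected with a diagnostic.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {stream: base / f"{stream}.csv" for stream in STREAM_COLUMNS}
    paths = {k: Path(v) for k, v in paths.items()}

    parsers: dict[str, Callable[[Mapping[str, str]], object]] = {
        "stays": _parse_stay,
        "cultures": lambda row: _parse_culture(row, commensal_codes),
        "vitals": _parse_vital,
        "devices": _parse_device,
        "abx": _parse_abx,
    }
    bundle = Bundle()
    targets = {
        "stays": bundle.stays,
        "cultures": bundle.cultures,
        "vitals": bundle.vitals,
        "devices": bundle.devices,
        "abx": bundle.abx,
    }
    report = IngestReport()
    for stream, parser in parsers.items():
        path = paths.get(stream)
        if path is None or (not path.exists() and stream != "stays"):
            report.accepted[stream] = 0
            continue
        df = _read_stream(path, stream)
        n_ok = 0
        for i, row in enumerate(df.to_dict("records")):
            try:
                targets[stream].append(parser(row))
                n_ok += 1
            except (ValueError, KeyError) as exc:
                report.reject(stream, i, str(exc))
        report.accepted[stream] = n_ok
    return bundle, report


# ---------------------------------------------------------------------------
# writing

def _codes(organisms: Iterable[OrganismIsolate]) -> str:
    return "|".join(o.organism_code for o in organisms)


def write_bundle(bundle: Bundle, out_dir: Path | str) -> dict[str, Path]:
    """Write every stream of a bundle as CSV; deterministic row order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames: dict[str, pd.DataFrame] = {}

    frames["stays"] = pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "stay_id": s.stay_id,
                "admission_ts": _fmt_ts(s.admission_ts),
                "discharge_ts": _fmt_ts(s.discharge_ts),
                "birth_date": s.birth_date.isoformat(),
                "sex": s.sex.value,
                "transfers": ";".join(f"{w}@{_fmt_ts(t)}" for w, t in s.transfers),
            }
            for s in sorted(bundle.stays, key=lambda s: (s.patient_id, s.admission_ts, s.stay_id))
        ],
        columns=STREAM_COLUMNS["stays"],
    )
    frames["cultures"] = pd.DataFrame(
        [
            {
                "specimen_id": c.specimen_id,
                "patient_id": c.patient_id,
                "login_ts": _fmt_ts(c.login_ts),
                "specimen_type": c.specimen_type.value,
                "organisms": _codes(c.organisms),
                "report_final_ts": _fmt_ts(c.report_final_ts),
                "revisions": ";".join(f"{_fmt_ts(t)}={_codes(orgs)}" for t, orgs in c.revisions),
            }
            for c in sorted(bundle.cultures, key=lambda c: (c.login_ts, c.patient_id, c.specimen_id))
        ],
        columns=STREAM_COLUMNS["cultures"],
    )
    frames["vitals"] = pd.DataFrame(
        [
            {
                "patient_id": v.patient_id,
                "ts": _fmt_ts(v.ts),
                "temperature_c": "" if v.temperature_c is None else f"{v.temperature_c:.1f}",
                "heart_rate_bpm": "" if v.heart_rate_bpm is None else str(v.heart_rate_bpm),
                "respiratory_rate_pm": "" if v.respiratory_rate_pm is None else str(v.respiratory_rate_pm),
            }
            for v in sorted(bundle.vitals, key=lambda v: (v.ts, v.patient_id))
        ],
        columns=STREAM_COLUMNS["vitals"],
    )
    frames["devices"] = pd.DataFrame(
        [
            {
                "patient_id": d.patient_id,
                "device_type": d.device_type.value,
                "start_ts": _fmt_ts(d.start_ts),
                "end_ts": _fmt_ts(d.end_ts),
            }
            for d in sorted(bundle.devices, key=lambda d: (d.start_ts, d.patient_id, d.device_type.value))
        ],
        columns=STREAM_COLUMNS["devices"],
    )
    frames["abx"] = pd.DataFrame(
        [
            {
                "patient_id": a.patient_id,
                "drug_code": a.drug_code,
                "start_ts": _fmt_ts(a.start_ts),
                "end_ts": _fmt_ts(a.end_ts),
            }
            for a in sorted(bundle.abx, key=lambda a: (a.start_ts, a.patient_id, a.drug_code))
        ],
        columns=STREAM_COLUMNS["abx"],
    )

    written = {}
    for stream, frame in frames.items():
        path = out_dir / f"{stream}.csv"
        frame.to_csv(path, index=False, lineterminator="\n")
        written[stream] = path
    return written


def write_line_list(events: Iterable[HabsiEvent], path: Path | str) -> None:
    """Write detected events as a CSV line list.

    Rows are ordered by (onset_ts, patient_id, event_id) and columns are
    fixed, so output is byte-identical across runs on equal input.
    """
    rows = [
        {
            "event_id": e.event_id,
            "patient_id": e.patient_id,
            "episode_id": e.episode_id,
            "onset_ts": _fmt_ts(e.onset_ts),
            "organisms": _codes(e.organisms),
            "classification": e.classification.value,
            "source_specimens": ";".join(e.source_specimens),
            "confirmation_ts": _fmt_ts(e.confirmation_ts),
        }
        for e in sorted(events, key=lambda e: (e.onset_ts, e.patient_id, e.event_id))
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def read_line_list(
    path: Path | str, commensal_codes: frozenset[str] = DEFAULT_COMMENSAL_CODES
) -> list[HabsiEvent]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != EVENT_COLUMNS:
        raise RecordError(f"{path}: header mismatch for events line list")
    events = []
    for row in df.to_dict("records"):
        event = HabsiEvent(
            event_id=row["event_id"],
            patient_id=row["patient_id"],
            episode_id=row["episode_id"],
            onset_ts=_parse_ts(row["onset_ts"]),
            organisms=isolates_from_codes(row["organisms"], commensal_codes),
            classification=rec.Classification(row["classification"]),
            source_specimens=tuple(filter(None, row["source_specimens"].split(";"))),
            confirmation_ts=_parse_ts(row["confirmation_ts"], optional=True),
        )
        event.validate()
        events.append(event)
    return events


def write_reference_labels(labels: pd.DataFrame, path: Path | str) -> None:
    """Write a patient-level reference-standard label table."""
    out = labels.loc[:, LABEL_COLUMNS].sort_values("patient_id", kind="stable")
    out.to_csv(path, index=False, lineterminator="\n")


def read_reference_labels(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != LABEL_COLUMNS:
        raise RecordError(f"{path}: header mismatch for reference labels")
    df["habsi"] = df["habsi"].astype(int)
    return df
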