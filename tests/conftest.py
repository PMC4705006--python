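"""Shared builders for hand-constructed EMR fixtures.

Everything is constructed programmatically; timestamps use a compact
``ts("2012-10-03 08:00")`` helper.
"""

from __future__ import annotations

from datetime import date, datetime

import pytest

from habsi.organisms import isolate
from habsi.records import (
    AntimicrobialOrder,
    Bundle,
    CultureResult,
    DeviceInterval,
    DeviceType,
    PatientStay,
    Sex,
    SpecimenType,
    VitalSign,
)


def ts(text: str) -> datetime:
    return datetime.fromisoformat(text)


def mk_stay(
    pid: str,
    adm: str,
    dis: str | None,
    stay_id: str | None = None,
    birth: str = "1960-01-01",
    ward: str = "W01",
) -> PatientStay:
    admission = ts(adm)
    return PatientStay(
        patient_id=pid,
        stay_id=stay_id or f"{pid}-A",
        admission_ts=admission,
        discharge_ts=None if dis is None else ts(dis),
        birth_date=date.fromisoformat(birth),
        sex=Sex.M,
        transfers=((ward, admission),),
    )


def mk_culture(
    pid: str,
    sid: str,
    login: str,
    codes: list[str],
    stype: SpecimenType = SpecimenType.BLOOD,
    final: str | None = None,
    revisions: tuple = (),
) -> CultureResult:
    login_ts = ts(login)
    return CultureResult(
        specimen_id=sid,
        patient_id=pid,
        login_ts=login_ts,
        specimen_type=SpecimenType(stype),
        organisms=tuple(isolate(c) for c in codes),
        report_final_ts=ts(final) if final else login_ts.replace(hour=23, minute=59),
        revisions=tuple((ts(t), tuple(isolate(c) for c in cc)) for t, cc in revisions),
    )


def mk_vital(pid: str, when: str, temp=None, hr=None, rr=None) -> VitalSign:
    return VitalSign(pid, ts(when), temp, hr, rr)


def mk_abx(pid: str, start: str, end: str | None = None) -> AntimicrobialOrder:
    return AntimicrobialOrder(pid, "CEFTR", ts(start), None if end is None else ts(end))


def mk_line(pid: str, start: str, end: str | None = None) -> DeviceInterval:
    return DeviceInterval(
        pid, DeviceType.CENTRAL_LINE, ts(start), None if end is None else ts(end)
    )


@pytest.fixture()
def hand_bundle() -> tuple[Bundle, dict]:
    """Twelve hand-built patients with rule-by-rule expected outcomes.

    Returns the bundle and the expected patient -> (n_events, classification
    of first event) map computed by applying the documented rules by hand.
    """
    b = Bundle()

    def add(*records):
        for r in records:
            if isinstance(r, PatientStay):
                b.stays.append(r)
            elif isinstance(r, CultureResult):
                b.cultures.append(r)
            elif isinstance(r, VitalSign):
                b.vitals.append(r)
            elif isinstance(r, DeviceInterval):
                b.devices.append(r)
            elif isinstance(r, AntimicrobialOrder):
                b.abx.append(r)

    # A: pathogen blood culture at 72 h + fever -> one PRIM_OTHER event
    add(
        mk_stay("A", "2012-10-01 00:00", "2012-10-10 00:00"),
        mk_culture("A", "A-S1", "2012-10-04 00:00", ["ECOLI"]),
        mk_vital("A", "2012-10-04 01:00", temp=38.9),
        mk_abx("A", "2012-10-04 06:00", "2012-10-11 06:00"),
    )
    # B: pathogen at 24 h -> community onset, no event; fever+abx near the
    # grown culture keep the sepsis pathway shut too
    add(
        mk_stay("B", "2012-10-01 00:00", "2012-10-08 00:00"),
        mk_culture("B", "B-S1", "2012-10-02 00:00", ["KPNEU"]),
        mk_vital("B", "2012-10-02 01:00", temp=39.0),
        mk_abx("B", "2012-10-02 04:00", "2012-10-09 04:00"),
    )
    # C: commensal in two draws one day apart + fever -> one event
    add(
        mk_stay("C", "2012-10-01 00:00", "2012-10-12 00:00"),
        mk_culture("C", "C-S1", "2012-10-04 08:00", ["CONS"]),
        mk_culture("C", "C-S2", "2012-10-05 08:00", ["CONS"]),
        mk_vital("C", "2012-10-04 10:00", temp=38.4),
    )
    # D: single commensal draw, no corroboration -> no event
    add(
        mk_stay("D", "2012-10-01 00:00", "2012-10-09 00:00"),
        mk_culture("D", "D-S1", "2012-10-04 08:00", ["CONS"]),
        mk_vital("D", "2012-10-04 10:00", temp=38.4),
    )
    # E: fever day 5, new antimicrobial same day, no cultures -> CSEP
    add(
        mk_stay("E", "2012-10-01 00:00", "2012-10-10 00:00"),
        mk_vital("E", "2012-10-05 09:00", temp=38.6),
        mk_abx("E", "2012-10-05 15:00", "2012-10-12 15:00"),
    )
    # F: two different pathogens two hours apart -> one polymicrobial event
    add(
        mk_stay("F", "2012-10-01 00:00", "2012-10-10 00:00"),
        mk_culture("F", "F-S1", "2012-10-04 00:00", ["ECOLI"]),
        mk_culture("F", "F-S2", "2012-10-04 02:00", ["KPNEU"]),
    )
    # G: same organism day 3 and day 10 -> persistent BSI, one event
    add(
        mk_stay("G", "2012-10-01 00:00", "2012-10-15 00:00"),
        mk_culture("G", "G-S1", "2012-10-04 00:00", ["SAURE"]),
        mk_culture("G", "G-S2", "2012-10-11 00:00", ["SAURE"]),
    )
    # H: same organism day 3 and day 25 -> gap beyond 14 d, two events
    add(
        mk_stay("H", "2012-10-01 00:00", "2012-11-05 00:00"),
        mk_culture("H", "H-S1", "2012-10-04 00:00", ["SAURE"]),
        mk_culture("H", "H-S2", "2012-10-26 00:00", ["SAURE"]),
    )
    # I: central line in place + concordant catheter tip -> PRIM_CRBSI
    add(
        mk_stay("I", "2012-10-01 00:00", "2012-10-12 00:00"),
        mk_line("I", "2012-10-01 06:00", "2012-10-12 00:00"),
        mk_culture("I", "I-S1", "2012-10-05 00:00", ["SAURE"]),
        mk_culture("I", "I-S2", "2012-10-06 00:00", ["SAURE"], stype=SpecimenType.CATHETER_TIP),
    )
    # J: central line, no tip culture -> PRIM_CLABSI
    add(
        mk_stay("J", "2012-10-01 00:00", "2012-10-12 00:00"),
        mk_line("J", "2012-10-01 06:00", "2012-10-12 00:00"),
        mk_culture("J", "J-S1", "2012-10-05 00:00", ["PAERU"]),
    )
    # K: matching organism in urine two days before onset -> SEC
    add(
        mk_stay("K", "2012-10-01 00:00", "2012-10-12 00:00"),
        mk_culture("K", "K-S1", "2012-10-06 00:00", ["ECOLI"]),
        mk_culture("K", "K-S2", "2012-10-04 00:00", ["ECOLI"], stype=SpecimenType.URINE),
    )
    # L: re-admission within 2 days; culture 12 h after the second admission
    # is healthcare-associated because the episode clock starts at the first
    add(
        mk_stay("L", "2012-10-01 00:00", "2012-10-04 00:00", stay_id="L-A"),
        mk_stay("L", "2012-10-06 00:00", "2012-10-14 00:00", stay_id="L-B"),
        mk_culture("L", "L-S1", "2012-10-06 12:00", ["ECOLI"]),
    )

    expected = {
        "A": (1, "PRIM_OTHER"),
        "B": (0, None),
        "C": (1, "PRIM_OTHER"),
        "D": (0, None),
        "E": (1, "CSEP"),
        "F": (1, "PRIM_OTHER"),
        "G": (1, "PRIM_OTHER"),
        "H": (2, "PRIM_OTHER"),
        "I": (1, "PRIM_CRBSI"),
        "J": (1, "PRIM_CLABSI"),
        "K": (1, "SEC"),
        "L": (1, "PRIM_OTHER"),
    }
    return b, expected
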