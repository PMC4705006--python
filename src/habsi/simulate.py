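"""Synthetic EMR cohort generator with planted ground truth.

The generator emits the same flat-table streams the detector consumes
(stays, cultures, vitals, devices, antimicrobial orders) plus a
patient-level reference-standard label file, for a one-month surveillance
period by default.  Planted HABSI cases satisfy the documented detection
rules *by construction* — timing (onset at least 48 h into the episode),
signs, organisms, corroborating draws, devices — so on a clean
configuration the pipeline must recover the labels exactly; planted
negatives are the clinically realistic near-misses the rules exist to
reject:

* community-onset BSI (positive blood culture within 48 h of admission),
* single-draw commensal contaminants (no corroborating second draw),
* fever without an antimicrobial response (and antimicrobials without
  fever) among ordinary inpatients,
* laboratory reports revised *after* the recall day, which the detector
  deliberately never re-reads (a false-positive mechanism),
* persistent-BSI repeat draws, which must be absorbed rather than
  double-counted.

Two further error-mode knobs degrade true cases into misses: withholding
the corroborating second commensal draw, or keeping fever at or below the
38.0 degC criterion (antipyretic-style miss).  Raising these produces
false negatives only; raising the post-recall revision rate produces false
positives only.

Organism frequencies, ward structure and vital-sign noise are simple
categorical/Gaussian models: the goal is rule coverage with realistic
timing, not epidemiological realism.  Baseline vitals are drawn strictly
below every screening threshold, so each detection is attributable to a
planted mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta

import numpy as np
import pandas as pd

from .organisms import DEFAULT_COMMENSAL_CODES, isolate
from .records import (
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

__all__ = ["CohortConfig", "generate"]

PATHOGEN_CODES = ["ECOLI", "KPNEU", "SAURE", "PAERU", "ABAUM", "EFAEC", "CALBI"]
COMMENSAL_CODES = sorted(DEFAULT_COMMENSAL_CODES)
WARDS = [f"W{k:02d}" for k in range(1, 13)]
ABX_DRUGS = ["CEFTR", "VANCO", "MEROP", "PIPTA", "LEVOF"]


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort.

    Rates with a stated source: the HABSI rate defaults to 14.7 episodes
    per 1000 patients (the hospital-wide pooled mean the system surveys)
    and ``single_draw_prob`` to 0.0123 (1.23% of blood specimens arriving
    from a single draw).  Error-mode probabilities default to off; the
    contaminant rate defaults to 2% of patients, a typical blood-culture
    contamination burden.
    """

    n_patients: int = 10_000
    period_start: date = date(2012, 10, 1)
    period_days: int = 31
    habsi_rate_per_1000_patients: float = 14.7
    contamination_prob: float = 0.02
    single_draw_prob: float = 0.0123
    revision_after_recall_prob: float = 0.0
    readmit_prob: float = 0.05
    subtype_mix: dict = field(
        default_factory=lambda: {
            "PRIM_CRBSI": 0.15,
            "PRIM_CLABSI": 0.20,
            "PRIM_OTHER": 0.35,
            "SEC": 0.20,
            "CSEP": 0.10,
        }
    )
    # fraction of primary culture-based cases due to a common commensal
    commensal_positive_frac: float = 0.20
    # error modes (false negatives): see module docstring
    commensal_single_draw_prob: float = 0.0
    fever_miss_prob: float = 0.0
    # planted-negative scenario rates
    community_onset_prob: float = 0.01
    fever_no_abx_prob: float = 0.03
    abx_only_prob: float = 0.25
    persistent_repeat_prob: float = 0.30
    infant_frac: float = 0.05
    seed: int = 0

    @property
    def period(self) -> tuple[date, date]:
        return self.period_start, self.period_start + timedelta(days=self.period_days - 1)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.period_days < 8:
            raise ValueError("period must span at least 8 days to fit onset timing")
        if not 0 <= self.habsi_rate_per_1000_patients <= 1000:
            raise ValueError("habsi_rate_per_1000_patients must be in [0, 1000]")
        probs = {
            "contamination_prob": self.contamination_prob,
            "single_draw_prob": self.single_draw_prob,
            "revision_after_recall_prob": self.revision_after_recall_prob,
            "readmit_prob": self.readmit_prob,
            "commensal_positive_frac": self.commensal_positive_frac,
            "commensal_single_draw_prob": self.commensal_single_draw_prob,
            "fever_miss_prob": self.fever_miss_prob,
            "community_onset_prob": self.community_onset_prob,
            "fever_no_abx_prob": self.fever_no_abx_prob,
            "abx_only_prob": self.abx_only_prob,
            "persistent_repeat_prob": self.persistent_repeat_prob,
            "infant_frac": self.infant_frac,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if abs(sum(self.subtype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("subtype_mix must sum to 1")
        neg_total = (
            self.community_onset_prob
            + self.contamination_prob
            + self.fever_no_abx_prob
            + self.revision_after_recall_prob
        )
        if neg_total > 1.0:
            raise ValueError("planted-negative scenario probabilities exceed 1")


class _PatientBuilder:
    """Accumulates one patient's records with deterministic ids."""

    def __init__(self, bundle: Bundle, pid: str):
        self.bundle = bundle
        self.pid = pid
        self._n_spec = 0

    def specimen_id(self) -> str:
        self._n_spec += 1
        return f"{self.pid}-S{self._n_spec:02d}"

    def culture(
        self,
        login: datetime,
        stype: SpecimenType,
        codes: list[str],
        final_delay_h: float = 48.0,
        revisions: tuple = (),
    ) -> str:
        sid = self.specimen_id()
        self.bundle.cultures.append(
            CultureResult(
                specimen_id=sid,
                patient_id=self.pid,
                login_ts=_minute(login),
                specimen_type=stype,
                organisms=tuple(isolate(c) for c in codes),
                report_final_ts=_minute(login + timedelta(hours=final_delay_h)),
                revisions=revisions,
            )
        )
        return sid

    def vital(self, ts: datetime, temp: float, hr: int, rr: int) -> None:
        self.bundle.vitals.append(
            VitalSign(self.pid, _minute(ts), round(temp, 1), int(hr), int(rr))
        )

    def abx(self, start: datetime, days: float) -> None:
        self.bundle.abx.append(
            AntimicrobialOrder(
                self.pid, "CEFTR", _minute(start), _minute(start + timedelta(days=days))
            )
        )


def _minute(ts: datetime) -> datetime:
    return ts.replace(second=0, microsecond=0)


def generate(config: CohortConfig) -> tuple[Bundle, pd.DataFrame]:
    """Generate a seeded, reproducible cohort and its truth labels.

    Returns the EMR bundle and a label table with one row per patient:
    ``patient_id, habsi, classification, onset_ts`` (classification and
    onset empty for negatives).  The same config (including seed) always
    yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bundle = Bundle()
    labels: list[dict] = []
    p_pos = config.habsi_rate_per_1000_patients / 1000.0
    subtypes = sorted(config.subtype_mix)
    subtype_p = np.array([config.subtype_mix[s] for s in subtypes])
    period_start_dt = datetime.combine(config.period_start, time(0, 0))
    width = max(5, len(str(config.n_patients)))

    for i in range(config.n_patients):
        pid = f"P{i + 1:0{width}d}"
        b = _PatientBuilder(bundle, pid)
        infant = rng.random() < config.infant_frac
        positive = rng.random() < p_pos
        subtype = str(rng.choice(subtypes, p=subtype_p)) if positive else ""

        # admission leaves >= 7 days of period for onset and follow-up
        adm_day = int(rng.integers(0, max(1, config.period_days - 7)))
        admission = period_start_dt + timedelta(
            days=adm_day, hours=int(rng.integers(0, 24)), minutes=int(rng.integers(0, 60))
        )
        if infant:
            birth = admission.date() - timedelta(days=int(rng.integers(10, 300)))
        else:
            birth = admission.date() - timedelta(days=int(rng.integers(18 * 365, 90 * 365)))
        sex = Sex.F if rng.random() < 0.5 else Sex.M

        if positive:
            label_row = _build_positive(b, rng, config, admission, birth, sex, subtype, infant)
        else:
            label_row = _build_negative(b, rng, config, admission, birth, sex)
        labels.append(label_row)

    label_df = pd.DataFrame(labels, columns=["patient_id", "habsi", "classification", "onset_ts"])
    return bundle, label_df


def _stay(
    b: _PatientBuilder,
    rng: np.random.Generator,
    admission: datetime,
    los_days: float,
    birth: date,
    sex: Sex,
    split_for_readmit: bool,
    split_day: float | None = None,
    gap_days: int = 1,
) -> tuple[datetime, list[tuple[datetime, datetime]]]:
    """Emit one or two linked stays; returns (episode end, in-stay intervals)."""
    ward = WARDS[int(rng.integers(0, len(WARDS)))]
    discharge = admission + timedelta(days=los_days)
    if not split_for_readmit:
        b.bundle.stays.append(
            PatientStay(
                b.pid, f"{b.pid}-A", _minute(admission), _minute(discharge),
                birth, sex, ((ward, _minute(admission)),),
            )
        )
        return discharge, [(admission, discharge)]
    split_day = split_day if split_day is not None else los_days / 2
    d1 = admission + timedelta(days=split_day)
    readmit = d1 + timedelta(days=gap_days)
    d2 = readmit + timedelta(days=max(2.0, los_days - split_day))
    b.bundle.stays.append(
        PatientStay(b.pid, f"{b.pid}-A", _minute(admission), _minute(d1), birth, sex,
                    ((ward, _minute(admission)),))
    )
    b.bundle.stays.append(
        PatientStay(b.pid, f"{b.pid}-B", _minute(readmit), _minute(d2), birth, sex,
                    ((ward, _minute(readmit)),))
    )
    return d2, [(admission, d1), (readmit, d2)]


def _baseline_vitals(
    b: _PatientBuilder, rng: np.random.Generator,
    intervals: list[tuple[datetime, datetime]], infant: bool,
) -> None:
    """12-hourly observations, all strictly below the screening thresholds."""
    for lo, hi in intervals:
        t = lo + timedelta(hours=6)
        while t < hi:
            temp = min(37.7, 36.8 + rng.normal(0, 0.25))
            temp = max(36.1, temp)
            if infant:
                hr = int(np.clip(rng.normal(130, 12), 95, 175))
                rr = int(np.clip(rng.normal(35, 5), 22, 55))
            else:
                hr = int(np.clip(rng.normal(74, 6), 55, 88))
                rr = int(np.clip(rng.normal(15, 2), 10, 19))
            b.vital(t, temp, hr, rr)
            t += timedelta(hours=12)


def _fever_burst(
    b: _PatientBuilder, rng: np.random.Generator, around: datetime,
    infant: bool, peak: tuple[float, float] = (38.6, 39.8),
) -> None:
    for off_h in (0.0, 5.0, 11.0):
        temp = rng.uniform(*peak)
        hr = int(rng.uniform(185, 210)) if infant else int(rng.uniform(95, 130))
        rr = int(rng.uniform(62, 75)) if infant else int(rng.uniform(22, 30))
        b.vital(around + timedelta(hours=off_h), temp, hr, rr)


def _build_positive(
    b, rng, config: CohortConfig, admission: datetime, birth: date, sex: Sex,
    subtype: str, infant: bool,
) -> dict:
    readmit = rng.random() < config.readmit_prob
    gap = int(rng.integers(1, 3))
    if readmit:
        # onset early in the *second* stay: healthcare-associated only
        # because the episode clock starts at the first admission
        onset_offset_h = (3.0 + gap) * 24 + rng.uniform(6, 36)
    else:
        onset_offset_h = 48.0 + rng.uniform(0, 72)
    onset = admission + timedelta(hours=onset_offset_h)
    follow_days = rng.uniform(5, 10)
    los = onset_offset_h / 24 + follow_days
    end, intervals = _stay(
        b, rng, admission, los, birth, sex, readmit,
        split_day=3.0 if readmit else None, gap_days=gap,
    )
    _baseline_vitals(b, rng, intervals, infant)

    commensal_case = subtype in ("PRIM_OTHER", "PRIM_CLABSI") and rng.random() < config.commensal_positive_frac
    fever_missed = commensal_case and rng.random() < config.fever_miss_prob
    second_draw_withheld = commensal_case and rng.random() < config.commensal_single_draw_prob

    if subtype == "CSEP":
        _fever_burst(b, rng, onset, infant)
        b.culture(onset + timedelta(hours=1), SpecimenType.BLOOD, [])
        b.culture(onset + timedelta(hours=1, minutes=50), SpecimenType.BLOOD, [])
        b.abx(onset + timedelta(hours=6), 7)
        return _label(b.pid, 1, subtype, onset)

    code = (
        COMMENSAL_CODES[int(rng.integers(0, len(COMMENSAL_CODES)))]
        if commensal_case
        else PATHOGEN_CODES[int(rng.integers(0, len(PATHOGEN_CODES)))]
    )
    if fever_missed:
        # sustained rise that never crosses the strict 38.0 criterion, with
        # heart/respiratory rates below the screening thresholds too
        for off_h in (0.0, 5.0, 11.0):
            t = onset - timedelta(hours=2) + timedelta(hours=off_h)
            if infant:
                b.vital(t, rng.uniform(37.6, 38.0), int(rng.uniform(130, 170)), int(rng.uniform(30, 55)))
            else:
                b.vital(t, rng.uniform(37.6, 38.0), int(rng.uniform(70, 88)), int(rng.uniform(12, 19)))
    else:
        _fever_burst(b, rng, onset - timedelta(hours=2), infant)
    b.culture(onset, SpecimenType.BLOOD, [code])
    if not second_draw_withheld:
        b.culture(onset + timedelta(minutes=50), SpecimenType.BLOOD, [code])
    b.abx(onset + timedelta(hours=4), 7)

    if subtype == "SEC":
        off_h = rng.uniform(1, 48) * (1 if rng.random() < 0.5 else -1)
        sec_login = max(admission + timedelta(hours=1), onset + timedelta(hours=off_h))
        b.culture(sec_login, SpecimenType.URINE, [code])
    elif subtype in ("PRIM_CRBSI", "PRIM_CLABSI"):
        line_start = intervals[-1][0] if readmit else admission
        b.bundle.devices.append(
            DeviceInterval(b.pid, DeviceType.CENTRAL_LINE, _minute(line_start), _minute(end))
        )
        if subtype == "PRIM_CRBSI":
            b.culture(onset + timedelta(days=2), SpecimenType.CATHETER_TIP, [code])

    if not commensal_case and rng.random() < config.persistent_repeat_prob:
        # repeat growth of the same organism inside the persistent window,
        # before discharge so the detector actually sees it
        repeat_days = rng.uniform(3.0, max(3.5, follow_days - 1.0))
        b.culture(onset + timedelta(days=repeat_days), SpecimenType.BLOOD, [code])

    detected_truth = 1  # planted infections are real regardless of system misses
    return _label(b.pid, detected_truth, subtype, onset)


def _build_negative(
    b, rng, config: CohortConfig, admission: datetime, birth: date, sex: Sex
) -> dict:
    u = rng.random()
    p_co = config.community_onset_prob
    p_cont = config.contamination_prob
    p_fev = config.fever_no_abx_prob
    p_rev = config.revision_after_recall_prob
    if u < p_co:
        scenario = "community_onset"
    elif u < p_co + p_cont:
        scenario = "contaminant"
    elif u < p_co + p_cont + p_fev:
        scenario = "fever_no_abx"
    elif u < p_co + p_cont + p_fev + p_rev:
        scenario = "recall_revision"
    else:
        scenario = "plain"

    los = 2.0 + float(rng.exponential(3.0))
    if scenario in ("contaminant", "recall_revision", "fever_no_abx"):
        los = max(los, 5.0)
    los = min(los, 20.0)
    readmit = scenario == "plain" and los > 5 and rng.random() < config.readmit_prob
    end, intervals = _stay(b, rng, admission, los, birth, sex, readmit)
    infant = (admission.date() - birth).days <= 365
    _baseline_vitals(b, rng, intervals, infant)

    if scenario == "community_onset":
        login = admission + timedelta(hours=rng.uniform(4, 40))
        code = PATHOGEN_CODES[int(rng.integers(0, len(PATHOGEN_CODES)))]
        b.culture(login, SpecimenType.BLOOD, [code])
        b.culture(login + timedelta(minutes=50), SpecimenType.BLOOD, [code])
        _fever_burst(b, rng, login - timedelta(hours=2), infant)
        b.abx(login + timedelta(hours=4), 7)
    elif scenario == "contaminant":
        login = admission + timedelta(hours=rng.uniform(49, 90))
        code = COMMENSAL_CODES[int(rng.integers(0, len(COMMENSAL_CODES)))]
        b.culture(login, SpecimenType.BLOOD, [code])
        if rng.random() < config.abx_only_prob:
            b.abx(admission + timedelta(hours=rng.uniform(2, 24)), 5)
    elif scenario == "fever_no_abx":
        _fever_burst(b, rng, admission + timedelta(hours=rng.uniform(49, 80)), infant)
    elif scenario == "recall_revision":
        login = admission + timedelta(hours=rng.uniform(49, 90))
        code = PATHOGEN_CODES[int(rng.integers(0, len(PATHOGEN_CODES)))]
        commensal = COMMENSAL_CODES[int(rng.integers(0, len(COMMENSAL_CODES)))]
        final = login + timedelta(hours=48)
        # corrected after the recall day: contaminant, not a pathogen
        revision_ts = final + timedelta(days=7 + 2)
        b.bundle.cultures.append(
            CultureResult(
                specimen_id=b.specimen_id(),
                patient_id=b.pid,
                login_ts=_minute(login),
                specimen_type=SpecimenType.BLOOD,
                organisms=(isolate(code),),
                report_final_ts=_minute(final),
                revisions=((_minute(revision_ts), (isolate(commensal),)),),
            )
        )
        _fever_burst(b, rng, login - timedelta(hours=2), infant)
        b.abx(login + timedelta(hours=4), 7)
    else:
        if rng.random() < config.abx_only_prob:
            start = admission + timedelta(hours=rng.uniform(2, max(3.0, los * 24 - 24)))
            b.abx(start, min(5.0, max(1.0, los - 1)))
        if rng.random() < 0.10:
            b.bundle.devices.append(
                DeviceInterval(b.pid, DeviceType.CENTRAL_LINE, _minute(admission), _minute(end))
            )

    if rng.random() < config.single_draw_prob:
        # stray single no-growth follow-up draw
        b.culture(admission + timedelta(hours=rng.uniform(1, los * 24 - 1)), SpecimenType.BLOOD, [])
    return _label(b.pid, 0, "", None)


def _label(pid: str, habsi: int, classification: str, onset: datetime | None) -> dict:
    return {
        "patient_id": pid,
        "habsi": habsi,
        "classification": classification,
        "onset_ts": "" if onset is None else _minute(onset).strftime("%Y-%m-%dT%H:%M"),
    }
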