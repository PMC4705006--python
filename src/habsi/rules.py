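"""Candidate detection: the daily-screening rules.

The screening logic mirrors how the surveillance system watches the hospital
data streams.  A bloodstream-infection candidate arises on one of two
pathways:

* **culture pathway** — a blood culture confirmed positive (a recognized
  pathogen in any draw, or a common skin commensal corroborated across
  separate draws with a concurrent sign of infection), whose specimen log-in
  is 48 hours or more after admission of the hospitalization episode
  ("hospital-acquired" rule; the clock starts at the first admission of a
  merged episode);

* **clinical-sepsis pathway** — infection signs (fever strictly above
  38.0 degC, hypothermia, tachycardia or tachypnea against age-band
  thresholds) with a new antimicrobial order started shortly after, and no
  confirmed positive culture anywhere that would explain or localize the
  picture.

Laboratory report revisions are applied only within the *recall window*
(``recall_days`` after the final report); later revisions are deliberately
ignored, reproducing the false-positive mechanism of a system that stops
re-reading old reports after its recall day.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta

from .config import RulesConfig
from .organisms import OrganismIsolate
from .records import (
    Bundle,
    CultureResult,
    Episode,
    RecordError,
    SpecimenType,
    VitalSign,
)

__all__ = [
    "SignFlags",
    "Candidate",
    "is_healthcare_associated",
    "screen_signs",
    "effective_organisms",
    "confirm_organisms",
    "detect_candidates",
]


@dataclass(frozen=True)
class SignFlags:
    """Vital-sign screening flags over a time window."""

    fever: bool = False
    hypothermia: bool = False
    tachycardia: bool = False
    tachypnea: bool = False
    window: tuple[datetime, datetime] | None = None

    @property
    def any(self) -> bool:
        return self.fever or self.hypothermia or self.tachycardia or self.tachypnea


@dataclass
class Candidate:
    """A pre-deduplication HABSI signal.

    ``organisms`` empty if and only if the candidate came through the
    clinical-sepsis pathway.
    """

    patient_id: str
    episode_id: str
    onset_ts: datetime
    source_specimens: tuple[str, ...]
    organisms: tuple[OrganismIsolate, ...]
    signs: SignFlags

    @property
    def is_sepsis_pathway(self) -> bool:
        return len(self.organisms) == 0


def is_healthcare_associated(
    login_ts: datetime, episode: Episode, config: RulesConfig = RulesConfig()
) -> bool:
    """Hospital-acquired rule: specimen log-in >= ``min_hai_hours`` (48 h,
    inclusive) after the first admission of the merged episode."""
    if not episode.contains(login_ts):
        raise RecordError(
            f"log-in {login_ts} outside episode {episode.episode_id} "
            f"[{episode.start_ts}, {episode.end_ts}] — mis-joined data"
        )
    return login_ts - episode.start_ts >= timedelta(hours=config.min_hai_hours)


def screen_signs(
    vitals: list[VitalSign],
    window: tuple[datetime, datetime],
    config: RulesConfig = RulesConfig(),
    age_days: int | None = None,
) -> SignFlags:
    """Screen vital signs within ``window`` (inclusive ends).

    Fever is strictly above ``fever_c`` — a reading of exactly 38.0 degC is
    *not* fever.  Heart- and respiratory-rate thresholds are age-banded:
    patients up to ``infant_age_days`` old use pediatric cut-offs.  Absent
    vitals simply leave every flag false.
    """
    lo, hi = window
    infant = age_days is not None and age_days <= config.infant_age_days
    hr_thr = config.infant_hr_bpm if infant else config.adult_hr_bpm
    rr_thr = config.infant_rr_pm if infant else config.adult_rr_pm
    fever = hypo = tachy = tachyp = False
    for v in vitals:
        if not lo <= v.ts <= hi:
            continue
        if v.temperature_c is not None:
            if v.temperature_c > config.fever_c:
                fever = True
            if v.temperature_c < config.hypothermia_c:
                hypo = True
        if v.heart_rate_bpm is not None and v.heart_rate_bpm > hr_thr:
            tachy = True
        if v.respiratory_rate_pm is not None and v.respiratory_rate_pm > rr_thr:
            tachyp = True
    return SignFlags(fever, hypo, tachy, tachyp, window)


def effective_organisms(
    culture: CultureResult,
    config: RulesConfig = RulesConfig(),
    as_of_ts: datetime | None = None,
) -> tuple[OrganismIsolate, ...]:
    """Organism list after applying in-window report revisions.

    Revisions are applied in order, but only those no later than
    ``recall_days`` after the final report (and, when screening as of a
    given day, no later than that day).  Later revisions never reach the
    detector — the recall-day semantics.
    """
    cutoff = culture.report_final_ts + timedelta(days=config.recall_days)
    organisms = culture.organisms
    for rev_ts, rev_orgs in culture.revisions:
        if rev_ts > cutoff:
            break
        if as_of_ts is not None and rev_ts > as_of_ts:
            break
        organisms = rev_orgs
    return organisms


@dataclass(frozen=True)
class _ConfirmedDraw:
    specimen_id: str
    login_ts: datetime
    organisms: tuple[OrganismIsolate, ...]
    corroborating: tuple[str, ...] = ()  # extra specimens backing a commensal


def confirm_organisms(
    blood_cultures: list[CultureResult],
    vitals: list[VitalSign],
    config: RulesConfig = RulesConfig(),
    as_of_ts: datetime | None = None,
    age_days: int | None = None,
) -> list[_ConfirmedDraw]:
    """Confirm organism-positive blood draws within one episode.

    A recognized (non-commensal) pathogen in any finalized blood culture
    confirms that draw outright.  A common skin commensal is confirmed only
    when the same commensal grows in at least two separate draws logged in
    within ``commensal_window_days`` of each other *and* at least one
    vital-sign flag is raised within +/- ``sign_window_hours`` of the first
    draw of the pair; the corroborated draws are reported as one confirmed
    draw anchored at the first log-in.

    Returns one entry per confirmed draw group, sorted by log-in time; every
    confirmed specimen appears in exactly one entry.
    """
    finalized = sorted(
        (c for c in blood_cultures
         if c.specimen_type is SpecimenType.BLOOD
         and (as_of_ts is None or c.report_final_ts <= as_of_ts)),
        key=lambda c: (c.login_ts, c.specimen_id),
    )
    eff = {c.specimen_id: effective_organisms(c, config, as_of_ts) for c in finalized}

    confirmed: list[_ConfirmedDraw] = []
    claimed: set[str] = set()

    # pathogen-positive draws: each stands alone
    for c in finalized:
        pathogens = tuple(o for o in eff[c.specimen_id] if not o.commensal)
        if pathogens:
            confirmed.append(_ConfirmedDraw(c.specimen_id, c.login_ts, pathogens))
            claimed.add(c.specimen_id)

    # commensal chains: same organism, successive log-ins within the window,
    # anchored by a sign flag near the first draw
    by_code: dict[str, list[CultureResult]] = {}
    for c in finalized:
        if c.specimen_id in claimed:
            continue
        for o in eff[c.specimen_id]:
            if o.commensal:
                by_code.setdefault(o.organism_code, []).append(c)
    window = timedelta(hours=config.sign_window_hours)
    for code in sorted(by_code):
        draws = [c for c in by_code[code] if c.specimen_id not in claimed]
        i = 0
        while i < len(draws):
            chain = [draws[i]]
            j = i + 1
            while j < len(draws):
                gap = (draws[j].login_ts.date() - chain[0].login_ts.date()).days
                if gap <= config.commensal_window_days:
                    chain.append(draws[j])
                    j += 1
                else:
                    break
            if len(chain) >= 2:
                first = chain[0]
                flags = screen_signs(
                    vitals,
                    (first.login_ts - window, first.login_ts + window),
                    config,
                    age_days,
                )
                if flags.any:
                    org = next(o for o in eff[first.specimen_id] if o.organism_code == code)
                    confirmed.append(
                        _ConfirmedDraw(
                            first.specimen_id,
                            first.login_ts,
                            (org,),
                            corroborating=tuple(c.specimen_id for c in chain[1:]),
                        )
                    )
                    claimed.update(c.specimen_id for c in chain)
            i = j
    confirmed.sort(key=lambda d: (d.login_ts, d.specimen_id))
    return confirmed


def nonblood_positive(
    culture: CultureResult,
    config: RulesConfig = RulesConfig(),
    as_of_ts: datetime | None = None,
) -> bool:
    """A non-blood culture counts as confirmed positive when it grew at
    least one recognized (non-commensal) pathogen."""
    if culture.specimen_type is SpecimenType.BLOOD:
        return False
    if as_of_ts is not None and culture.report_final_ts > as_of_ts:
        return False
    return any(not o.commensal for o in effective_organisms(culture, config, as_of_ts))


def _age_days(episode: Episode) -> int:
    return (episode.start_ts.date() - episode.stays[0].birth_date).days


def detect_candidates(
    bundle: Bundle,
    episodes: list[Episode],
    config: RulesConfig = RulesConfig(),
    as_of_ts: datetime | None = None,
) -> list[Candidate]:
    """Run the screening rules over every episode and emit candidates.

    Culture-pathway candidates: one per confirmed, healthcare-associated
    blood draw group, onset at the first qualifying specimen log-in.

    Sepsis-pathway candidates: a raised sign flag at least 48 h into the
    episode, a new antimicrobial order within ``csep_abx_hours`` after the
    sign, no blood culture with any organism growth within
    +/- ``csep_blood_window_hours`` and no confirmed positive non-blood
    culture within +/- ``csep_nonblood_window_days``; consecutive qualifying
    sign times within ``csep_blood_window_hours`` collapse into one
    candidate with onset at the earliest sign.
    """
    cultures_by_patient: dict[str, list[CultureResult]] = {}
    for c in bundle.cultures:
        cultures_by_patient.setdefault(c.patient_id, []).append(c)
    vitals_by_patient: dict[str, list[VitalSign]] = {}
    for v in bundle.vitals:
        vitals_by_patient.setdefault(v.patient_id, []).append(v)
    abx_by_patient: dict[str, list] = {}
    for a in bundle.abx:
        abx_by_patient.setdefault(a.patient_id, []).append(a)

    candidates: list[Candidate] = []
    for episode in sorted(episodes, key=lambda e: (e.patient_id, e.start_ts)):
        pid = episode.patient_id
        cultures = [
            c for c in cultures_by_patient.get(pid, []) if episode.contains(c.login_ts)
        ]
        vitals = [v for v in vitals_by_patient.get(pid, []) if episode.contains(v.ts)]
        age = _age_days(episode)

        blood = [c for c in cultures if c.specimen_type is SpecimenType.BLOOD]
        confirmed = confirm_organisms(blood, vitals, config, as_of_ts, age)
        sign_window = timedelta(hours=config.sign_window_hours)
        for draw in confirmed:
            if not is_healthcare_associated(draw.login_ts, episode, config):
                continue
            flags = screen_signs(
                vitals,
                (draw.login_ts - sign_window, draw.login_ts + sign_window),
                config,
                age,
            )
            candidates.append(
                Candidate(
                    patient_id=pid,
                    episode_id=episode.episode_id,
                    onset_ts=draw.login_ts,
                    source_specimens=(draw.specimen_id, *draw.corroborating),
                    organisms=draw.organisms,
                    signs=flags,
                )
            )

        candidates.extend(
            _sepsis_candidates(
                episode, vitals, cultures,
                abx_by_patient.get(pid, []), config, as_of_ts, age,
            )
        )
    candidates.sort(key=lambda c: (c.patient_id, c.onset_ts, c.source_specimens))
    return candidates


def _sepsis_candidates(
    episode: Episode,
    vitals: list[VitalSign],
    cultures: list[CultureResult],
    abx: list,
    config: RulesConfig,
    as_of_ts: datetime | None,
    age_days: int,
) -> list[Candidate]:
    if as_of_ts is not None:
        vitals = [v for v in vitals if v.ts <= as_of_ts]
        abx = [a for a in abx if a.start_ts <= as_of_ts]
    blood_window = timedelta(hours=config.csep_blood_window_hours)
    abx_window = timedelta(hours=config.csep_abx_hours)
    nb_window = timedelta(days=config.csep_nonblood_window_days)
    ha_offset = timedelta(hours=config.min_hai_hours)
    # clinical sepsis requires blood cultures with *no growth at all* nearby:
    # any organism in a blood draw — even an unconfirmed contaminant —
    # points away from the culture-negative sepsis picture
    blood_growth_times = [
        c.login_ts
        for c in cultures
        if c.specimen_type is SpecimenType.BLOOD
        and (as_of_ts is None or c.report_final_ts <= as_of_ts)
        and effective_organisms(c, config, as_of_ts)
    ]
    nonblood_times = [
        c.login_ts for c in cultures if nonblood_positive(c, config, as_of_ts)
    ]
    abx_starts = sorted(a.start_ts for a in abx)

    qualifying: list[datetime] = []
    for v in sorted(vitals, key=lambda v: v.ts):
        flags = screen_signs([v], (v.ts, v.ts), config, age_days)
        if not flags.any:
            continue
        if v.ts - episode.start_ts < ha_offset:
            continue
        if any(abs(t - v.ts) <= blood_window for t in blood_growth_times):
            continue
        if any(abs(t - v.ts) <= nb_window for t in nonblood_times):
            continue
        if not any(v.ts <= t <= v.ts + abx_window for t in abx_starts):
            continue
        qualifying.append(v.ts)

    out: list[Candidate] = []
    run_start: datetime | None = None
    prev: datetime | None = None
    for t in qualifying + [None]:  # type: ignore[list-item]
        if t is not None and prev is not None and t - prev <= blood_window:
            prev = t
            continue
        if run_start is not None:
            flags = screen_signs(
                vitals, (run_start, run_start + blood_window), config, age_days
            )
            out.append(
                Candidate(
                    patient_id=episode.patient_id,
                    episode_id=episode.episode_id,
                    onset_ts=run_start,
                    source_specimens=(),
                    organisms=(),
                    signs=flags,
                )
            )
        run_start = t
        prev = t
    return out
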