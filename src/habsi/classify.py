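"""Event deduplication and PRIM/SEC/CSEP classification.

Two criteria collapse candidate signals into single infection events, to
eliminate duplicate counting:

* **polymicrobial** — candidates of the same pathway whose onsets fall
  within ``polymicrobial_hours`` (default 48 h) are one event with the union
  organism set;
* **persistent BSI** — a later candidate sharing an organism with an open
  event, within ``persistent_days`` (default 14 d) of the event's most
  recent isolate, is the same continuing infection, not a new one.

Classification precedence is total and deterministic:
CSEP > SEC > PRIM_CRBSI > PRIM_CLABSI > PRIM_OTHER.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

from .config import RulesConfig
from .linkage import link_stays
from .records import (
    Bundle,
    Classification,
    CultureResult,
    DeviceInterval,
    DeviceType,
    Episode,
    HabsiEvent,
    SpecimenType,
)
from .rules import Candidate, detect_candidates, nonblood_positive

__all__ = ["merge_events", "classify", "run_pipeline", "PipelineResult"]


@dataclass
class _ProtoEvent:
    """A merged event before classification."""

    candidates: list[Candidate]
    onset_ts: datetime
    last_onset_ts: datetime  # most recent absorbed onset (persistent window)

    @property
    def organisms(self) -> tuple:
        seen = {}
        for c in self.candidates:
            for o in c.organisms:
                seen.setdefault(o.organism_code, o)
        return tuple(seen[k] for k in sorted(seen))

    @property
    def source_specimens(self) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.candidates:
            out.extend(c.source_specimens)
        return tuple(dict.fromkeys(out))

    @property
    def is_sepsis(self) -> bool:
        return self.candidates[0].is_sepsis_pathway


def merge_events(
    candidates: list[Candidate], config: RulesConfig = RulesConfig()
) -> list[_ProtoEvent]:
    """Merge one episode's candidates chronologically.

    Replays candidates in onset order.  A candidate joins an existing event
    of the same pathway if its onset is within ``polymicrobial_hours`` of
    the event onset (polymicrobial merge), or if it shares an organism with
    the event and falls within ``persistent_days`` of the event's most
    recent absorbed onset (persistent BSI).  Otherwise it opens a new event.
    Every candidate lands in exactly one event, so the operation conserves
    candidates and is idempotent on its own output.
    """
    poly = timedelta(hours=config.polymicrobial_hours)
    persist = timedelta(days=config.persistent_days)
    events: list[_ProtoEvent] = []
    for cand in sorted(candidates, key=lambda c: (c.onset_ts, c.source_specimens)):
        target = None
        for ev in events:
            if ev.is_sepsis != cand.is_sepsis_pathway:
                continue
            if abs(cand.onset_ts - ev.onset_ts) <= poly:
                target = ev
                break
            ev_codes = {o.organism_code for o in ev.organisms}
            if (
                ev_codes & {o.organism_code for o in cand.organisms}
                and cand.onset_ts - ev.last_onset_ts <= persist
            ):
                target = ev
                break
        if target is None:
            events.append(_ProtoEvent([cand], cand.onset_ts, cand.onset_ts))
        else:
            target.candidates.append(cand)
            target.last_onset_ts = max(target.last_onset_ts, cand.onset_ts)
    return events


def classify(
    proto: _ProtoEvent,
    non_blood_cultures: list[CultureResult],
    devices: list[DeviceInterval],
    config: RulesConfig = RulesConfig(),
    as_of_ts: datetime | None = None,
) -> Classification:
    """Assign the event label.

    Sepsis-pathway events are CSEP.  A culture-based event is SEC when a
    confirmed positive non-blood culture within the secondary window carries
    a matching organism (genus+species) — catheter tips are excluded from
    this check, since a colonized tip is laboratory evidence about the line,
    not an infected body site.  With a central line in place during the
    lookback window the event is PRIM_CRBSI when a concordant catheter-tip
    culture exists, else PRIM_CLABSI; otherwise PRIM_OTHER.
    """
    if proto.is_sepsis:
        return Classification.CSEP
    onset = proto.onset_ts
    sec_window = timedelta(days=config.secondary_window_days)
    names = {o.genus_species.strip().lower() for o in proto.organisms}

    def matches(culture: CultureResult) -> bool:
        if abs(culture.login_ts - onset) > sec_window:
            return False
        if not nonblood_positive(culture, config, as_of_ts):
            return False
        from .rules import effective_organisms

        return any(
            o.genus_species.strip().lower() in names
            for o in effective_organisms(culture, config, as_of_ts)
        )

    if any(
        matches(c)
        for c in non_blood_cultures
        if c.specimen_type is not SpecimenType.CATHETER_TIP
    ):
        return Classification.SEC

    lookback_lo = onset - timedelta(hours=config.line_lookback_hours)
    line_in_place = any(
        d.device_type is DeviceType.CENTRAL_LINE and d.overlaps(lookback_lo, onset)
        for d in devices
    )
    if line_in_place:
        tip_match = any(
            matches(c)
            for c in non_blood_cultures
            if c.specimen_type is SpecimenType.CATHETER_TIP
        )
        return Classification.PRIM_CRBSI if tip_match else Classification.PRIM_CLABSI
    return Classification.PRIM_OTHER


@dataclass
class PipelineResult:
    events: list[HabsiEvent]
    funnel: dict = field(default_factory=dict)


def run_pipeline(
    bundle: Bundle,
    config: RulesConfig = RulesConfig(),
    episodes: list[Episode] | None = None,
    as_of_ts: datetime | None = None,
) -> PipelineResult:
    """Full detection: link episodes, screen candidates, merge, classify.

    Deterministic in its inputs; emits a funnel report with the counts at
    every stage (episodes screened, blood specimens, candidates by pathway,
    events absorbed by each dedup criterion, events by final class).
    """
    if episodes is None:
        episodes = link_stays(bundle.stays, config.readmit_gap_days)
    candidates = detect_candidates(bundle, episodes, config, as_of_ts)

    cultures_by_patient: dict[str, list[CultureResult]] = {}
    for c in bundle.cultures:
        cultures_by_patient.setdefault(c.patient_id, []).append(c)
    devices_by_patient: dict[str, list[DeviceInterval]] = {}
    for d in bundle.devices:
        devices_by_patient.setdefault(d.patient_id, []).append(d)

    by_episode: dict[str, list[Candidate]] = {}
    for cand in candidates:
        by_episode.setdefault(cand.episode_id, []).append(cand)

    episode_by_id = {e.episode_id: e for e in episodes}
    events: list[HabsiEvent] = []
    n_absorbed = 0
    class_counts = {c.value: 0 for c in Classification}
    for episode_id in sorted(by_episode):
        episode = episode_by_id[episode_id]
        pid = episode.patient_id
        protos = merge_events(by_episode[episode_id], config)
        n_absorbed += sum(len(p.candidates) - 1 for p in protos)
        non_blood = [
            c
            for c in cultures_by_patient.get(pid, [])
            if c.specimen_type is not SpecimenType.BLOOD and episode.contains(c.login_ts)
        ]
        for proto in protos:
            label = classify(proto, non_blood, devices_by_patient.get(pid, []), config, as_of_ts)
            class_counts[label.value] += 1
            events.append(
                HabsiEvent(
                    event_id="",  # assigned after global ordering
                    patient_id=pid,
                    episode_id=episode_id,
                    onset_ts=proto.onset_ts,
                    organisms=proto.organisms,
                    classification=label,
                    source_specimens=proto.source_specimens,
                )
            )
    events.sort(key=lambda e: (e.onset_ts, e.patient_id, e.source_specimens))
    for k, event in enumerate(events, start=1):
        event.event_id = f"EV{k:05d}"
        event.validate()

    funnel = {
        "patients": len(bundle.patient_ids()),
        "episodes": len(episodes),
        "blood_specimens": sum(
            1 for c in bundle.cultures if c.specimen_type is SpecimenType.BLOOD
        ),
        "candidates": len(candidates),
        "candidates_culture": sum(1 for c in candidates if not c.is_sepsis_pathway),
        "candidates_sepsis": sum(1 for c in candidates if c.is_sepsis_pathway),
        "candidates_absorbed": n_absorbed,
        "events": len(events),
        "events_by_class": class_counts,
    }
    return PipelineResult(events=events, funnel=funnel)
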