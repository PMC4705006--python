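"""Episode linkage and census denominators.

Re-admissions within ``gap_days`` calendar days of the previous discharge are
linked to that stay and counted as a single hospitalization episode; the
default window of 2 days is the administrative linkage rule the surveillance
system runs with.  The gap is measured on calendar dates, inclusive: a
discharge on the 5th followed by re-admission on the 7th (gap of exactly 2
days) merges.

Patient-days use the standard census convention: the admission day counts,
the discharge day does not, so a stay admitted on day 1 and discharged on
day 4 contributes 3 patient-days.
"""

from __future__ import annotations

from datetime import date, timedelta

from .records import Episode, PatientStay, RecordError

__all__ = ["link_stays", "patient_days"]


def link_stays(stays: list[PatientStay], gap_days: int = 2) -> list[Episode]:
    """Partition stays into hospitalization episodes.

    Within each patient, stays are sorted by admission time; consecutive
    stays whose calendar-date gap (re-admission date minus discharge date)
    is <= ``gap_days`` are merged transitively into one episode.  Linking is
    idempotent and every stay lands in exactly one episode.

    Raises :class:`RecordError` on overlapping stays for one patient — that
    is mis-joined source data, not a linkage question.
    """
    if gap_days < 0:
        raise ValueError("gap_days must be >= 0")
    by_patient: dict[str, list[PatientStay]] = {}
    for stay in stays:
        by_patient.setdefault(stay.patient_id, []).append(stay)

    episodes: list[Episode] = []
    for patient_id in sorted(by_patient):
        ordered = sorted(by_patient[patient_id], key=lambda s: s.admission_ts)
        groups: list[list[PatientStay]] = []
        for stay in ordered:
            prev = groups[-1][-1] if groups else None
            if prev is not None:
                if prev.discharge_ts is None or stay.admission_ts < prev.discharge_ts:
                    raise RecordError(
                        f"patient {patient_id}: stays {prev.stay_id} and "
                        f"{stay.stay_id} overlap"
                    )
                gap = (stay.admission_ts.date() - prev.discharge_ts.date()).days
                if gap <= gap_days:
                    groups[-1].append(stay)
                    continue
            groups.append([stay])
        for k, group in enumerate(groups, start=1):
            episodes.append(
                Episode(
                    episode_id=f"{patient_id}-E{k:02d}",
                    patient_id=patient_id,
                    stays=tuple(group),
                )
            )
    for episode in episodes:
        episode.validate()
    return episodes


def patient_days(
    episodes: list[Episode], period: tuple[date, date], open_end: date | None = None
) -> int:
    """Total patient-days contributed by ``episodes`` within ``period``.

    ``period`` is an inclusive (first_day, last_day) date interval.  Each
    stay contributes its occupied dates [admission_date, discharge_date)
    clipped to the period; a still-open stay is clipped at ``open_end``
    (default: the period's last day, which then counts as occupied).
    """
    first, last = period
    if last < first:
        raise ValueError("period end before start")
    if open_end is None:
        open_end = last
    total = 0
    for episode in episodes:
        for stay in episode.stays:
            start = stay.admission_ts.date()
            # discharge day itself is not occupied
            stop = (
                stay.discharge_ts.date() - timedelta(days=1)
                if stay.discharge_ts is not None
                else open_end
            )
            lo = max(start, first)
            hi = min(stop, last)
            if hi >= lo:
                total += (hi - lo).days + 1
    return total
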