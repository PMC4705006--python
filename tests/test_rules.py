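"""Detection-rule boundaries: the 48-h clock, strict fever, commensal
corroboration, the recall window, and the sepsis pathway."""

from __future__ import annotations

import pytest

from habsi.config import RulesConfig
from habsi.linkage import link_stays
from habsi.records import Bundle, RecordError, SpecimenType
from habsi.rules import (
    confirm_organisms,
    detect_candidates,
    effective_organisms,
    is_healthcare_associated,
    screen_signs,
)

from conftest import mk_abx, mk_culture, mk_stay, mk_vital, ts

CFG = RulesConfig()


def _episode(adm="2012-10-01 00:00", dis="2012-10-20 00:00", pid="P"):
    return link_stays([mk_stay(pid, adm, dis)])[0]


class TestHealthcareAssociated:
    def test_exactly_48_hours_is_associated(self):
        assert is_healthcare_associated(ts("2012-10-03 00:00"), _episode())

    def test_one_minute_short_is_not(self):
        assert not is_healthcare_associated(ts("2012-10-02 23:59"), _episode())

    def test_clock_starts_at_first_admission_of_merged_episode(self):
        episode = link_stays(
            [
                mk_stay("P", "2012-10-01 00:00", "2012-10-04 00:00", stay_id="S1"),
                mk_stay("P", "2012-10-06 00:00", "2012-10-14 00:00", stay_id="S2"),
            ]
        )[0]
        login = ts("2012-10-06 01:00")  # 1 h into the re-admission
        assert is_healthcare_associated(login, episode)
        # oracle: elapsed minutes from first admission
        assert (login - episode.start_ts).total_seconds() / 3600 >= 48

    def test_login_outside_episode_signals_misjoined_data(self):
        with pytest.raises(RecordError, match="outside episode"):
            is_healthcare_associated(ts("2012-12-01 00:00"), _episode())


class TestScreenSigns:
    WINDOW = (ts("2012-10-03 00:00"), ts("2012-10-05 00:00"))

    def test_fever_is_strictly_above_38(self):
        assert screen_signs([mk_vital("P", "2012-10-04 00:00", temp=38.1)], self.WINDOW).fever
        assert not screen_signs(
            [mk_vital("P", "2012-10-04 00:00", temp=38.0)], self.WINDOW
        ).fever

    def test_no_vitals_all_flags_false(self):
        flags = screen_signs([], self.WINDOW)
        assert not flags.any

    def test_age_banded_rate_thresholds(self):
        v = [mk_vital("P", "2012-10-04 00:00", hr=120, rr=30)]
        adult = screen_signs(v, self.WINDOW, CFG, age_days=40 * 365)
        infant = screen_signs(v, self.WINDOW, CFG, age_days=100)
        assert adult.tachycardia and adult.tachypnea
        assert not infant.tachycardia and not infant.tachypnea

    def test_hypothermia_below_36(self):
        assert screen_signs([mk_vital("P", "2012-10-04 00:00", temp=35.5)], self.WINDOW).hypothermia


class TestConfirmOrganisms:
    FEVER = [mk_vital("P", "2012-10-04 09:00", temp=38.6)]

    def test_single_commensal_draw_not_confirmed(self):
        draws = [mk_culture("P", "S1", "2012-10-04 08:00", ["CONS"])]
        assert confirm_organisms(draws, self.FEVER) == []

    def test_pathogen_single_draw_confirmed(self):
        draws = [mk_culture("P", "S1", "2012-10-04 08:00", ["ECOLI"])]
        confirmed = confirm_organisms(draws, [])
        assert len(confirmed) == 1
        assert confirmed[0].organisms[0].organism_code == "ECOLI"

    def test_commensal_pair_with_fever_confirmed_once(self):
        draws = [
            mk_culture("P", "S1", "2012-10-04 08:00", ["CONS"]),
            mk_culture("P", "S2", "2012-10-05 08:00", ["CONS"]),
        ]
        confirmed = confirm_organisms(draws, self.FEVER)
        assert len(confirmed) == 1
        assert confirmed[0].specimen_id == "S1"
        assert confirmed[0].corroborating == ("S2",)

    def test_commensal_pair_without_signs_not_confirmed(self):
        draws = [
            mk_culture("P", "S1", "2012-10-04 08:00", ["CONS"]),
            mk_culture("P", "S2", "2012-10-05 08:00", ["CONS"]),
        ]
        assert confirm_organisms(draws, []) == []

    def test_commensal_draws_too_far_apart_not_confirmed(self):
        draws = [
            mk_culture("P", "S1", "2012-10-04 08:00", ["CONS"]),
            mk_culture("P", "S2", "2012-10-08 08:00", ["CONS"]),
        ]
        assert confirm_organisms(draws, self.FEVER) == []

    def test_draw_pair_enumeration_oracle(self):
        # oracle: enumerate all draw pairs; confirmation iff some same-code
        # pair is within the window and a sign sits near the earlier draw
        draws = [
            mk_culture("P", "S1", "2012-10-03 08:00", ["CONS"]),
            mk_culture("P", "S2", "2012-10-04 07:00", ["MICRO"]),
            mk_culture("P", "S3", "2012-10-05 06:00", ["CONS"]),
        ]
        pairs = [
            (a, b)
            for a in draws
            for b in draws
            if a.specimen_id < b.specimen_id
            and {o.organism_code for o in a.organisms}
            & {o.organism_code for o in b.organisms}
            and (b.login_ts.date() - a.login_ts.date()).days <= 2
        ]
        assert len(pairs) == 1  # S1+S3 share CONS within 2 days
        fever_near_first = [mk_vital("P", "2012-10-03 12:00", temp=38.6)]
        confirmed = confirm_organisms(draws, fever_near_first)
        assert [c.specimen_id for c in confirmed] == ["S1"]
        assert confirmed[0].corroborating == ("S3",)
        # with the sign outside +/-24 h of the first draw, nothing confirms
        assert confirm_organisms(draws, self.FEVER) == []


class TestRecallWindow:
    def test_revision_within_recall_window_applies(self):
        culture = mk_culture(
            "P", "S1", "2012-10-04 08:00", ["ECOLI"],
            final="2012-10-06 08:00",
            revisions=(("2012-10-10 08:00", ["CONS"]),),
        )
        orgs = effective_organisms(culture)
        assert [o.organism_code for o in orgs] == ["CONS"]

    def test_revision_after_recall_day_is_ignored(self):
        culture = mk_culture(
            "P", "S1", "2012-10-04 08:00", ["ECOLI"],
            final="2012-10-06 08:00",
            revisions=(("2012-10-20 08:00", ["CONS"]),),
        )
        orgs = effective_organisms(culture)
        assert [o.organism_code for o in orgs] == ["ECOLI"]


class TestDetectCandidates:
    def _run(self, bundle):
        episodes = link_stays(bundle.stays)
        return detect_candidates(bundle, episodes)

    def test_pathogen_at_72h_with_fever_one_candidate(self):
        b = Bundle(
            stays=[mk_stay("P", "2012-10-01 00:00", "2012-10-10 00:00")],
            cultures=[mk_culture("P", "S1", "2012-10-04 00:00", ["ECOLI"])],
            vitals=[mk_vital("P", "2012-10-04 01:00", temp=38.9)],
        )
        cands = self._run(b)
        assert len(cands) == 1
        assert cands[0].onset_ts == ts("2012-10-04 00:00")
        assert not cands[0].is_sepsis_pathway

    def test_pathogen_at_24h_no_candidate(self):
        b = Bundle(
            stays=[mk_stay("P", "2012-10-01 00:00", "2012-10-10 00:00")],
            cultures=[mk_culture("P", "S1", "2012-10-02 00:00", ["ECOLI"])],
        )
        assert self._run(b) == []

    def test_clinical_sepsis_pathway(self):
        b = Bundle(
            stays=[mk_stay("P", "2012-10-01 00:00", "2012-10-10 00:00")],
            vitals=[mk_vital("P", "2012-10-05 09:00", temp=38.7)],
            abx=[mk_abx("P", "2012-10-05 15:00", "2012-10-12 15:00")],
        )
        cands = self._run(b)
        assert len(cands) == 1
        assert cands[0].is_sepsis_pathway
        assert cands[0].onset_ts == ts("2012-10-05 09:00")
        assert cands[0].organisms == ()

    def test_sepsis_blocked_by_grown_blood_culture_even_unconfirmed(self):
        b = Bundle(
            stays=[mk_stay("P", "2012-10-01 00:00", "2012-10-10 00:00")],
            cultures=[mk_culture("P", "S1", "2012-10-05 08:00", ["CONS"])],
            vitals=[mk_vital("P", "2012-10-05 09:00", temp=38.7)],
            abx=[mk_abx("P", "2012-10-05 15:00", "2012-10-12 15:00")],
        )
        assert self._run(b) == []

    def test_sepsis_blocked_by_positive_nonblood_culture(self):
        b = Bundle(
            stays=[mk_stay("P", "2012-10-01 00:00", "2012-10-10 00:00")],
            cultures=[
                mk_culture("P", "S1", "2012-10-04 08:00", ["ECOLI"], stype=SpecimenType.URINE)
            ],
            vitals=[mk_vital("P", "2012-10-05 09:00", temp=38.7)],
            abx=[mk_abx("P", "2012-10-05 15:00", "2012-10-12 15:00")],
        )
        assert self._run(b) == []

    def test_sepsis_requires_antimicrobial_response(self):
        b = Bundle(
            stays=[mk_stay("P", "2012-10-01 00:00", "2012-10-10 00:00")],
            vitals=[mk_vital("P", "2012-10-05 09:00", temp=38.7)],
        )
        assert self._run(b) == []

    def test_removing_vitals_never_removes_pathogen_candidates(self):
        b = Bundle(
            stays=[mk_stay("P", "2012-10-01 00:00", "2012-10-12 00:00")],
            cultures=[
                mk_culture("P", "S1", "2012-10-04 00:00", ["ECOLI"]),
                mk_culture("P", "S2", "2012-10-05 08:00", ["CONS"]),
                mk_culture("P", "S3", "2012-10-06 08:00", ["CONS"]),
            ],
            vitals=[mk_vital("P", "2012-10-05 09:00", temp=38.9)],
            abx=[mk_abx("P", "2012-10-05 15:00")],
        )
        with_vitals = self._run(b)
        b_stripped = Bundle(stays=b.stays, cultures=b.cultures, abx=b.abx)
        without = self._run(b_stripped)
        pathogen_keys = lambda cands: {
            (c.onset_ts, c.source_specimens)
            for c in cands
            if any(not o.commensal for o in c.organisms)
        }
        assert pathogen_keys(without) == pathogen_keys(with_vitals)
        assert len(without) <= len(with_vitals)

    def test_confirmed_specimens_partition_across_candidates(self):
        b = Bundle(
            stays=[mk_stay("P", "2012-10-01 00:00", "2012-10-15 00:00")],
            cultures=[
                mk_culture("P", "S1", "2012-10-04 00:00", ["ECOLI"]),
                mk_culture("P", "S2", "2012-10-04 01:00", ["ECOLI"]),
                mk_culture("P", "S3", "2012-10-06 08:00", ["CONS"]),
                mk_culture("P", "S4", "2012-10-07 08:00", ["CONS"]),
            ],
            vitals=[mk_vital("P", "2012-10-06 09:00", temp=38.9)],
        )
        cands = self._run(b)
        seen = [s for c in cands for s in c.source_specimens]
        assert sorted(seen) == sorted(set(seen))  # no specimen claimed twice
        assert set(seen) == {"S1", "S2", "S3", "S4"}
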