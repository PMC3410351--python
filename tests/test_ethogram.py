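import math

import pytest

from flycourt import (
    CourtshipSession,
    Element,
    EventRecord,
    GeneratorConfig,
    ParseError,
    ValidationError,
    generate_sessions,
    read_sessions,
    total_time,
    write_sessions,
)


def _write(tmp_path, text, name="sessions.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER = "couple_id,genotype,element,start_s,end_s\n"


class TestReadSessions:
    def test_minimal_file(self, tmp_path):
        path = _write(tmp_path, HEADER + "c1,control,orientation,0.00,10.00\n")
        sessions = read_sessions(path)
        assert len(sessions) == 1
        (s,) = sessions
        assert s.couple_id == "c1"
        assert s.genotype == "control"
        assert s.events == [EventRecord(Element.ORIENTATION, 0.0, 10.0)]

    def test_two_copulations_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER
            + "c1,control,copulation,100.00,100.00\n"
            + "c1,control,copulation,200.00,200.00\n",
        )
        with pytest.raises(ValidationError, match="c1.*copulation"):
            read_sessions(path)

    def test_bad_element_names_line(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER
            + "c1,control,orientation,0.00,10.00\n"
            + "c1,control,waggle,0.00,10.00\n",
        )
        with pytest.raises(ParseError, match=":3"):
            read_sessions(path)

    def test_bad_number_names_line(self, tmp_path):
        path = _write(tmp_path, HEADER + "c1,control,orientation,zero,10.00\n")
        with pytest.raises(ParseError, match=":2"):
            read_sessions(path)

    def test_bad_header_rejected(self, tmp_path):
        path = _write(tmp_path, "couple,genotype,element,start,end\nc1,control,nse,1,1\n")
        with pytest.raises(ParseError, match="header"):
            read_sessions(path)

    def test_unknown_genotype_rejected(self, tmp_path):
        path = _write(tmp_path, HEADER + "c1,mystery,orientation,0.00,10.00\n")
        with pytest.raises(ValidationError, match="genotype"):
            read_sessions(path)

    def test_conflicting_genotype_rejected(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER
            + "c1,control,orientation,0.00,10.00\n"
            + "c1,a30p,vibration,0.00,5.00\n",
        )
        with pytest.raises(ValidationError, match="conflicting genotype"):
            read_sessions(path)

    def test_sessions_and_events_ordered(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER
            + "c2,a30p,orientation,5.00,10.00\n"
            + "c1,control,vibration,20.00,25.00\n"
            + "c1,control,orientation,0.00,10.00\n",
        )
        sessions = read_sessions(path)
        assert [s.couple_id for s in sessions] == ["c1", "c2"]
        assert [e.start_s for e in sessions[0].events] == [0.0, 20.0]


class TestInvariants:
    def test_same_element_overlap_rejected(self):
        s = CourtshipSession(
            "c1",
            "control",
            events=[
                EventRecord(Element.ORIENTATION, 0, 10),
                EventRecord(Element.ORIENTATION, 5, 15),
            ],
        )
        with pytest.raises(ValidationError, match="overlap"):
            s.validate()

    def test_cross_element_overlap_allowed(self):
        s = CourtshipSession(
            "c1",
            "control",
            events=[
                EventRecord(Element.ORIENTATION, 0, 10),
                EventRecord(Element.VIBRATION, 5, 15),
            ],
        )
        s.validate()

    def test_touching_bouts_allowed(self):
        s = CourtshipSession(
            "c1",
            "control",
            events=[
                EventRecord(Element.NSE, 3.0, 3.0),
                EventRecord(Element.NSE, 3.0, 3.0),
                EventRecord(Element.LICKING, 1.0, 2.0),
                EventRecord(Element.LICKING, 2.0, 3.0),
            ],
        )
        s.validate()

    def test_event_after_cap_rejected(self):
        s = CourtshipSession(
            "c1", "control", events=[EventRecord(Element.ORIENTATION, 0, 700)]
        )
        with pytest.raises(ValidationError, match="cap"):
            s.validate()

    def test_event_after_copulation_rejected(self):
        s = CourtshipSession(
            "c1",
            "control",
            events=[
                EventRecord(Element.COPULATION, 300, 300),
                EventRecord(Element.ORIENTATION, 350, 360),
            ],
        )
        with pytest.raises(ValidationError, match="session ended"):
            s.validate()

    def test_negative_start_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            EventRecord(Element.NSE, -1.0, 0.0)

    def test_end_before_start_rejected(self):
        with pytest.raises(ValidationError, match="precedes"):
            EventRecord(Element.ORIENTATION, 10.0, 5.0)


class TestTotalTime:
    def test_no_copulation_is_cap(self):
        s = CourtshipSession("c1", "control", events=[])
        assert total_time(s) == 600.0

    def test_copulation_truncates(self):
        s = CourtshipSession(
            "c1",
            "control",
            events=[
                EventRecord(Element.ORIENTATION, 0, 100),
                EventRecord(Element.COPULATION, 354.95, 354.95),
            ],
        )
        assert total_time(s) == 354.95
        assert total_time(s) <= s.observation_cap_s

    def test_ritual_time_from_first_act(self):
        from flycourt.ethogram import ritual_time

        s = CourtshipSession(
            "c1",
            "control",
            events=[
                EventRecord(Element.NSE, 10, 10),
                EventRecord(Element.ORIENTATION, 50, 80),
                EventRecord(Element.COPULATION, 400, 400),
            ],
        )
        assert ritual_time(s) == 400.0
        assert ritual_time(s, from_first_act=True) == 350.0
        nse_only = CourtshipSession(
            "c2", "control", events=[EventRecord(Element.NSE, 10, 10)]
        )
        assert ritual_time(nse_only, from_first_act=True) == 0.0

    def test_invariant_under_event_reordering(self):
        events = [
            EventRecord(Element.ORIENTATION, 0, 100),
            EventRecord(Element.COPULATION, 412.5, 412.5),
            EventRecord(Element.NSE, 50, 50),
        ]
        t = total_time(CourtshipSession("c1", "control", events=events))
        t_rev = total_time(
            CourtshipSession("c1", "control", events=list(reversed(events)))
        )
        assert t == t_rev == 412.5


class TestRoundTrip:
    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        write_sessions([], path)
        assert path.read_text() == HEADER  # universal-newline read
        assert read_sessions(path) == []

    def test_synthetic_cohort_round_trips(self, tmp_path):
        sessions = generate_sessions(GeneratorConfig(n_per_group=28, seed=3))
        path = tmp_path / "cohort.csv"
        write_sessions(sessions, path)
        back = read_sessions(path)
        assert len(back) == len(sessions) == 56
        for orig, rec in zip(sessions, back):
            assert rec.couple_id == orig.couple_id
            assert rec.genotype == orig.genotype
            assert rec.events == orig.events
            assert math.isclose(rec.total_time_s, orig.total_time_s)

    def test_write_read_write_is_stable(self, tmp_path):
        sessions = generate_sessions(GeneratorConfig(n_per_group=5, seed=9))
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_sessions(sessions, p1)
        write_sessions(read_sessions(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()
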