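import datetime as dt
import logging

import numpy as np
import pandas as pd
import pytest

from hsb import (
    CodedEvent,
    DateInterval,
    ascertainment_window,
    build_cohort,
    flag_all,
    flag_marker,
    gp_visit_summary,
    qualifies,
)
from hsb.ascertain import MarkerFlags

INDEX = dt.date(2019, 9, 1)


class TestAscertainmentWindow:
    def test_breast_screen_past_upper_age(self, catalogue):
        m = catalogue["breast_screen"]
        std = ascertainment_window(1945, m, INDEX, "standard")
        res = ascertainment_window(1945, m, INDEX, "restricted")
        assert std == DateInterval(dt.date(2013, 1, 1), INDEX)
        assert res == DateInterval(dt.date(2013, 1, 1), dt.date(2017, 1, 1))

    def test_fixed_lookback_same_for_everyone(self, catalogue):
        m = catalogue["psa_test"]
        for yob in (1920, 1945, 1953):
            assert ascertainment_window(yob, m, INDEX, "standard") == DateInterval(
                dt.date(2016, 9, 1), INDEX)

    def test_still_eligible_window_ends_at_index(self, catalogue):
        m = catalogue["bowel_screen"]
        w = ascertainment_window(1953, m, INDEX, "standard")
        assert w == DateInterval(dt.date(2016, 9, 1), INDEX)
        # restricted equals standard while still age-eligible at index
        assert ascertainment_window(1953, m, INDEX, "restricted") == w

    def test_restricted_subset_of_standard(self, catalogue):
        for m in catalogue:
            for yob in range(1919, 1954, 4):
                std = ascertainment_window(yob, m, INDEX, "standard")
                res = ascertainment_window(yob, m, INDEX, "restricted")
                if res is None:
                    continue
                assert std is not None
                assert std.start <= res.start and res.end <= std.end


class TestQualifies:
    def _window(self):
        return DateInterval(dt.date(2014, 9, 1), INDEX)

    def test_acs_primary_position_only(self, catalogue, codelists):
        m = catalogue["acs_hospital_visit"]
        codes = codelists.codes(m.name, m.sources, "narrow")
        ev = CodedEvent("p", dt.date(2018, 1, 1), "hes_diagnosis", "ACSJ18001", 2)
        assert not qualifies(ev, m, codes, self._window())
        assert qualifies(CodedEvent("p", dt.date(2018, 1, 1), "hes_diagnosis", "ACSJ18001", 1),
                         m, codes, self._window())

    def test_out_of_hours_consultations_excluded(self, catalogue):
        m = catalogue["gp_visits"]
        w = DateInterval(dt.date(2018, 9, 1), INDEX)
        ooh = CodedEvent("p", dt.date(2019, 1, 1), "consultation", "CONSULT",
                         consultation_type="out_of_hours")
        gp = CodedEvent("p", dt.date(2019, 1, 1), "consultation", "CONSULT",
                        consultation_type="nurse")
        assert not qualifies(ooh, m, frozenset(), w)
        assert qualifies(gp, m, frozenset(), w)

    def test_window_boundaries_half_open(self, catalogue, codelists):
        m = catalogue["blood_pressure"]
        codes = codelists.codes(m.name, m.sources, "narrow")
        w = DateInterval(dt.date(2018, 9, 1), INDEX)
        at_start = CodedEvent("p", w.start, "clinical", "BPMEAS001")
        at_end = CodedEvent("p", w.end, "clinical", "BPMEAS001")
        assert qualifies(at_start, m, codes, w)
        assert not qualifies(at_end, m, codes, w)


def _cohort(rows):
    return build_cohort(pd.DataFrame(rows), INDEX)


def _events(rows):
    df = pd.DataFrame(rows, columns=[
        "patient_id", "date", "source", "code", "diag_position", "consultation_type"])
    df["date"] = pd.to_datetime(df["date"])
    df["diag_position"] = df["diag_position"].astype("Int64")
    return df


@pytest.fixture()
def tiny_cohort():
    return _cohort([
        {"patient_id": "p1", "year_of_birth": 1945, "sex": "female", "reg_start": dt.date(2000, 1, 1)},
        {"patient_id": "p2", "year_of_birth": 1950, "sex": "male", "reg_start": dt.date(2000, 1, 1)},
        {"patient_id": "p3", "year_of_birth": 1930, "sex": "female", "reg_start": dt.date(2000, 1, 1)},
    ])


class TestFlagMarker:
    def test_flags_are_binary_not_counts(self, tiny_cohort, catalogue, codelists):
        events = _events([
            ("p1", "2019-01-01", "clinical", "BPMEAS001", None, None),
            ("p1", "2019-02-01", "clinical", "BPMEAS002", None, None),
        ])
        col = flag_marker(tiny_cohort, events, catalogue["blood_pressure"], codelists)
        assert col.tolist() == [1, 0, 0]

    def test_vaccination_recorded_only_as_prescription_counts(
            self, tiny_cohort, catalogue, codelists):
        events = _events([("p2", "2018-10-15", "prescription", "FLURX0001", None, None)])
        col = flag_marker(tiny_cohort, events, catalogue["influenza_vaccination"], codelists)
        assert col.tolist() == [0, 1, 0]

    def test_event_outside_window_does_not_count(self, tiny_cohort, catalogue, codelists):
        # breast screen for yob 1930: E = 2002-01-01, window starts 1998-01-01
        events = _events([("p3", "1997-06-01", "clinical", "BRSCR001", None, None)])
        col = flag_marker(tiny_cohort, events, catalogue["breast_screen"], codelists)
        assert col.tolist() == [0, 0, 0]

    def test_broad_fallback_warns_and_uses_narrow(
            self, tiny_cohort, catalogue, codelists, caplog):
        events = _events([("p1", "2019-01-01", "clinical", "BPMEAS001", None, None)])
        with caplog.at_level(logging.WARNING, logger="hsb.ascertain"):
            col = flag_marker(tiny_cohort, events, catalogue["blood_pressure"],
                              codelists, variant="broad")
        assert "falling back" in caplog.text
        assert col.tolist() == [1, 0, 0]


class TestFlagAll:
    def test_shape_and_columns(self, small_sim, small_cohort, catalogue, codelists):
        mf = flag_all(small_cohort, small_sim.events, catalogue, codelists)
        assert mf.markers == catalogue.names
        assert len(mf.flags) == small_cohort.n
        assert ((mf.gp_visit_count >= 1).astype(int) == mf.flags["gp_visits"]).all()

    def test_restricted_flags_never_exceed_standard(
            self, small_sim, small_cohort, catalogue, codelists):
        std = flag_all(small_cohort, small_sim.events, catalogue, codelists, "standard")
        res = flag_all(small_cohort, small_sim.events, catalogue, codelists, "restricted")
        assert (res.flags <= std.flags).all().all()

    def test_narrow_flags_never_exceed_broad(
            self, small_sim, small_cohort, catalogue, codelists):
        narrow = flag_all(small_cohort, small_sim.events, catalogue, codelists, variant="narrow")
        broad = flag_all(small_cohort, small_sim.events, catalogue, codelists, variant="broad")
        assert (narrow.flags <= broad.flags).all().all()
        assert broad.flags.to_numpy().sum() > narrow.flags.to_numpy().sum()

    def test_noise_events_never_change_flags(
            self, small_sim, small_cohort, catalogue, codelists):
        base = flag_all(small_cohort, small_sim.events, catalogue, codelists)
        rng = np.random.default_rng(7)
        pids = small_cohort.patients["patient_id"].sample(300, random_state=1).to_numpy()
        noise = pd.DataFrame({
            "patient_id": pids,
            "date": pd.Timestamp(INDEX) - pd.to_timedelta(rng.integers(1, 3000, 300), "D"),
            "source": rng.choice(["clinical", "prescription", "hes_procedure"], 300),
            "code": [f"ZZX{i}" for i in range(300)],
            "diag_position": pd.array([pd.NA] * 300, dtype="Int64"),
            "consultation_type": [None] * 300,
        })
        noisy = flag_all(small_cohort, pd.concat([small_sim.events, noise]),
                         catalogue, codelists)
        pd.testing.assert_frame_equal(base.flags, noisy.flags)
        assert (base.gp_visit_count == noisy.gp_visit_count).all()

    def test_truth_recovery_with_zero_leak(self, catalogue, codelists):
        from conftest import strict_config
        from hsb.simulate import simulate

        res = simulate(strict_config(800, seed=5))
        cohort = build_cohort(res.patients)
        mf = flag_all(cohort, res.events, catalogue, codelists)
        truth = res.truth.set_index("patient_id")
        for m in mf.markers:
            assert (mf.flags[m] == truth[m].reindex(mf.flags.index)).all(), m
        assert (mf.gp_visit_count == truth["gp_visit_count"].reindex(mf.flags.index)).all()


class TestGpVisitSummary:
    def _flags(self, counts):
        idx = pd.Index([f"p{i}" for i in range(len(counts))], name="patient_id")
        flags = pd.DataFrame({"gp_visits": [1 if c else 0 for c in counts]}, index=idx)
        return MarkerFlags(flags, pd.Series(counts, index=idx), "standard", "narrow", INDEX)

    def test_constant_counts(self):
        out = gp_visit_summary(self._flags([7, 7, 7]), by_age_band=False)
        row = out.iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (7, 7, 7)

    def test_linear_interpolation_quartiles(self):
        out = gp_visit_summary(self._flags(list(range(1, 10))), by_age_band=False)
        row = out.iloc[0]
        assert (row["q1"], row["median"], row["q3"]) == (3, 5, 7)

    def test_empty_counts_yield_no_rows(self):
        out = gp_visit_summary(self._flags([]), by_age_band=False)
        assert out.empty
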