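"""Data model, CSV round-trips, device-default cleaning and alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnoscore.epoch_data import (AlignmentError, EpochFormatError,
                                   EpochValidationError, align_series,
                                   clean_default_runs, read_activity_csv,
                                   read_hypnogram_csv, read_sleepwake_csv,
                                   write_activity_csv, write_hypnogram_csv,
                                   write_sleepwake_csv)
from .conftest import T0, make_activity, make_hypnogram, make_sleepwake


class TestActivityCSV:
    def test_identity_readback(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("timestamp,count\n"
                     "2020-01-01T22:00:00,0\n"
                     "2020-01-01T22:01:00,5\n"
                     "2020-01-01T22:02:00,20\n")
        s = read_activity_csv(p)
        assert len(s) == 3
        assert not s.missing_mask.any()
        np.testing.assert_array_equal(s.counts, [0, 5, 20])
        assert s.start_time == T0

    def test_gap_becomes_missing_epoch(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("timestamp,count\n"
                     "2020-01-01T22:00:00,1\n"
                     "2020-01-01T22:02:00,2\n")
        s = read_activity_csv(p)
        assert len(s) == 3
        np.testing.assert_array_equal(s.missing_mask, [False, True, False])

    @pytest.mark.parametrize("rows,err", [
        ("2020-01-01T22:00:00,1\nnot-a-time,2\n", EpochFormatError),
        ("2020-01-01T22:00:00,-3\n", EpochValidationError),
        ("2020-01-01T22:00:00,1\n2020-01-01T22:00:00,2\n", EpochValidationError),
    ], ids=["bad-timestamp", "negative-count", "duplicate-timestamp"])
    def test_malformed_inputs_rejected(self, tmp_path, rows, err):
        p = tmp_path / "a.csv"
        p.write_text("timestamp,count\n" + rows)
        with pytest.raises(err):
            read_activity_csv(p)

    @settings(deadline=None, max_examples=25)
    @given(counts=st.lists(st.floats(0, 1e4, allow_nan=False), min_size=1, max_size=50),
           gaps=st.sets(st.integers(0, 49)))
    def test_roundtrip_is_identity(self, tmp_path_factory, counts, gaps):
        n = len(counts)
        missing = np.zeros(n, dtype=bool)
        for g in gaps:
            if g < n:
                missing[g] = True
        if missing.all() or missing[0] or missing[-1]:
            # leading/trailing missing epochs are unrepresentable in a file
            missing[0] = missing[-1] = False
        s = make_activity(counts, missing)
        p = tmp_path_factory.mktemp("rt") / "a.csv"
        write_activity_csv(s, p)
        back = read_activity_csv(p, participant_id=s.participant_id)
        assert back.start_time == s.start_time
        np.testing.assert_array_equal(back.missing_mask, s.missing_mask)
        np.testing.assert_allclose(back.counts[~missing], s.counts[~missing], rtol=1e-12)


class TestOtherReaders:
    def test_hypnogram_roundtrip_and_aliases(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("timestamp,stage\n"
                     "2020-01-01T22:00:00,w\n"
                     "2020-01-01T22:00:30,n2\n"
                     "2020-01-01T22:01:00,R\n")
        h = read_hypnogram_csv(p)
        np.testing.assert_array_equal(h.stages, ["W", "N2", "REM"])
        p2 = tmp_path / "h2.csv"
        write_hypnogram_csv(h, p2)
        np.testing.assert_array_equal(read_hypnogram_csv(p2).stages, h.stages)

    def test_hypnogram_rejects_gaps_and_bad_stage(self, tmp_path):
        p = tmp_path / "h.csv"
        p.write_text("timestamp,stage\n2020-01-01T22:00:00,W\n2020-01-01T22:01:30,N2\n")
        with pytest.raises(EpochValidationError):
            read_hypnogram_csv(p)
        p.write_text("timestamp,stage\n2020-01-01T22:00:00,W\n2020-01-01T22:00:30,N9\n")
        with pytest.raises(EpochValidationError):
            read_hypnogram_csv(p)

    def test_sleepwake_roundtrip(self, tmp_path):
        s = make_sleepwake("SWSS")
        p = tmp_path / "s.csv"
        write_sleepwake_csv(s, p)
        back = read_sleepwake_csv(p)
        np.testing.assert_array_equal(back.states, s.states)
        p.write_text("timestamp,state\n2020-01-01T22:00:00,maybe\n")
        with pytest.raises(EpochFormatError):
            read_sleepwake_csv(p)


class TestCleanDefaultRuns:
    def test_long_run_removed_short_counts_kept(self):
        s = make_activity([20, 20, 20, 20, 20, 7, 0, 3])
        cleaned, removed = clean_default_runs(s, min_run=5)
        assert removed == 5
        np.testing.assert_array_equal(
            cleaned.missing_mask, [True] * 5 + [False] * 3)
        np.testing.assert_array_equal(cleaned.counts, s.counts)

    def test_short_run_untouched(self):
        s = make_activity([0, 20, 0])
        cleaned, removed = clean_default_runs(s, min_run=2)
        assert removed == 0
        assert not cleaned.missing_mask.any()

    def test_all_default_series_fully_removed(self):
        s = make_activity([20.0] * 7)
        cleaned, removed = clean_default_runs(s)
        assert removed == 7
        assert cleaned.missing_mask.all()

    def test_run_interrupted_by_missing_epoch_not_merged(self):
        # a missing epoch splits two 3-runs: neither reaches min_run=5
        missing = np.array([False] * 3 + [True] + [False] * 3)
        s = make_activity([20] * 7, missing)
        cleaned, removed = clean_default_runs(s, min_run=5)
        assert removed == 0

    @settings(deadline=None, max_examples=50)
    @given(counts=st.lists(st.sampled_from([0.0, 7.0, 20.0]), min_size=1, max_size=40),
           min_run=st.integers(1, 6))
    def test_idempotent_and_value_preserving(self, counts, min_run):
        s = make_activity(counts)
        once, n1 = clean_default_runs(s, min_run=min_run)
        twice, n2 = clean_default_runs(once, min_run=min_run)
        np.testing.assert_array_equal(once.missing_mask, twice.missing_mask)
        assert n2 == 0
        np.testing.assert_array_equal(once.counts, s.counts)


class TestAlignSeries:
    def test_identical_ranges_pair_everything(self):
        a = make_activity([1, 2, 3])
        b = make_sleepwake("SWS")
        t = align_series(a, b)
        assert len(t) == 3
        np.testing.assert_array_equal(t["a"], [1, 2, 3])

    def test_partial_overlap_intersects_intervals(self):
        # a spans 22:00-06:00, b spans 23:00-07:00 -> pairs 23:00-05:59
        a = make_activity(np.arange(480), start=T0)
        b = make_sleepwake([1] * 480, start=T0 + pd.Timedelta(hours=1))
        t = align_series(a, b)
        assert len(t) == 420
        assert t["timestamp"].iloc[0] == T0 + pd.Timedelta(hours=1)
        assert t["a"].iloc[0] == 60

    def test_missing_epoch_excluded_and_symmetry(self):
        missing = np.array([False, True, False, False])
        a = make_activity([1, 2, 3, 4], missing)
        b = make_sleepwake("SSWS")
        t = align_series(a, b)
        assert len(t) == 3
        assert 2 not in t["a"].to_numpy()
        t2 = align_series(b, a)
        assert len(t2) == len(t)
        np.testing.assert_array_equal(t2["timestamp"], t["timestamp"])

    def test_no_overlap_raises_with_ranges(self):
        a = make_activity([1, 2], start=T0)
        b = make_sleepwake("SS", start=T0 + pd.Timedelta(hours=5))
        with pytest.raises(AlignmentError, match="no overlap"):
            align_series(a, b)

    def test_subminute_offset_rejected_unless_rounded(self):
        a = make_activity([1, 2, 3], start=T0)
        b = make_sleepwake("SWS", start=T0 + pd.Timedelta(seconds=20))
        with pytest.raises(AlignmentError, match="offset"):
            align_series(a, b)
        t = align_series(a, b, round_offsets=True)
        assert len(t) == 3
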