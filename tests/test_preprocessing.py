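"""Preprocessing chain, linking/median assignment, splits and normalization."""
from datetime import date, datetime, timedelta

import numpy as np
import pytest

from conftest import make_ecg, make_lab
from ecglyte.records import (
    INDEPENDENT_LEADS,
    TWELVE_LEADS,
    LeadMismatchError,
    PatientRecord,
)
from ecglyte.preprocessing import (
    DatasetSplits,
    TemporalSplitEmptyError,
    TraceTooLongError,
    fit_normalizer,
    link_ecg_lab,
    preprocess_trace,
    reduce_leads,
    select_eval_ecgs,
    split_patients,
)


class TestPreprocessTrace:
    def test_short_trace_zero_padded_to_target(self, rng):
        rec = make_ecg(trace=rng.standard_normal((8, 4000)).astype(np.float32), fs=400)
        out = preprocess_trace(rec, target_fs=400, target_len=4096)
        assert out.trace.shape == (8, 4096)
        assert np.all(out.trace[:, 4000:] == 0)

    def test_dc_offset_removed(self):
        rec = make_ecg(trace=np.full((8, 2000), 5.0, dtype=np.float32), fs=400)
        out = preprocess_trace(rec, target_fs=400, target_len=2048)
        assert np.abs(out.trace[:, :2000].mean()) < 1e-3 * 5.0

    def test_notch_suppresses_mains(self):
        t = np.arange(2000) / 400.0
        trace = np.tile(np.sin(2 * np.pi * 50 * t), (8, 1)).astype(np.float32)
        rec = make_ecg(trace=trace, fs=400)
        out = preprocess_trace(rec, target_fs=400, target_len=2048, notch_freq=50.0)
        rms_in = np.sqrt(np.mean(trace.astype(float) ** 2))
        rms_out = np.sqrt(np.mean(out.trace[:, :2000].astype(float) ** 2))
        assert rms_out <= 0.10 * rms_in

    def test_resampling_changes_rate_and_length(self, rng):
        rec = make_ecg(trace=rng.standard_normal((8, 1024)).astype(np.float32), fs=256)
        out = preprocess_trace(rec, target_fs=128, target_len=1024)
        assert out.fs == 128
        assert out.trace.shape == (8, 1024)
        assert np.all(out.trace[:, 512:] == 0)  # 512 resampled samples, rest pad

    def test_too_long_trace_raises(self, rng):
        rec = make_ecg(trace=rng.standard_normal((8, 5000)).astype(np.float32), fs=400)
        with pytest.raises(TraceTooLongError):
            preprocess_trace(rec, target_fs=400, target_len=4096)

    def test_roughly_idempotent_on_ecg_like_trace(self, patient):
        """A second pass changes an already-filtered ECG only marginally
        (residual: filter transients and the notch transition band)."""
        from ecglyte.synthetic import DEFAULT_NOISE, STRONG_EFFECT, synthesize_ecg

        rec = synthesize_ecg(4.5, patient, STRONG_EFFECT, DEFAULT_NOISE,
                             fs=400, duration=5.0, seed=3)
        once = preprocess_trace(rec, target_fs=400, target_len=2000)
        twice = preprocess_trace(once, target_fs=400, target_len=2000)
        denom = np.linalg.norm(once.trace)
        assert np.linalg.norm(twice.trace - once.trace) / denom < 0.05


class TestReduceLeads:
    def test_identity_on_eight_leads(self, rng):
        rec = make_ecg(trace=rng.standard_normal((8, 64)).astype(np.float32))
        out = reduce_leads(rec)
        assert np.array_equal(out.trace, rec.trace)

    def test_permuted_twelve_leads_reordered(self, rng):
        trace = rng.standard_normal((12, 64)).astype(np.float32)
        perm = np.array([5, 0, 11, 3, 8, 1, 9, 2, 10, 4, 6, 7])
        labels = tuple(TWELVE_LEADS[i] for i in perm)
        rec = make_ecg(trace=trace[perm], leads=labels)
        out = reduce_leads(rec)
        assert out.lead_labels == INDEPENDENT_LEADS
        for i, name in enumerate(INDEPENDENT_LEADS):
            assert np.array_equal(out.trace[i], trace[TWELVE_LEADS.index(name)])

    def test_missing_lead_raises(self, rng):
        rec = make_ecg(trace=rng.standard_normal((7, 64)).astype(np.float32),
                       leads=INDEPENDENT_LEADS[:7])
        with pytest.raises(LeadMismatchError):
            reduce_leads(rec)


class TestLinking:
    T0 = datetime(2013, 5, 1, 12, 0)

    def test_lab_just_outside_window_excluded(self):
        ecg = make_ecg(t=self.T0)
        lab = make_lab(t=self.T0 + timedelta(minutes=61))
        assert link_ecg_lab([ecg], [lab]) == []

    def test_lab_exactly_on_boundary_included(self):
        ecg = make_ecg(t=self.T0)
        lab = make_lab(t=self.T0 + timedelta(minutes=60))
        assert len(link_ecg_lab([ecg], [lab])) == 1

    def test_odd_count_median(self):
        ecg = make_ecg(t=self.T0)
        labs = [make_lab(f"L{i}", value=v, t=self.T0) for i, v in enumerate([3.5, 4.0, 5.0])]
        assert link_ecg_lab([ecg], labs)[0].target == 4.0

    def test_even_count_median_is_midmean(self):
        ecg = make_ecg(t=self.T0)
        labs = [make_lab(f"L{i}", value=v, t=self.T0)
                for i, v in enumerate([3.5, 4.0, 5.0, 9.0])]
        assert link_ecg_lab([ecg], labs)[0].target == 4.5

    def test_toy_cohort_matches_hand_enumeration(self):
        """6 ECGs / 9 labs across 3 patients against a hand-worked table."""
        m = lambda mins: self.T0 + timedelta(minutes=mins)
        ecgs = [
            make_ecg("E1", "A", t=m(0)),
            make_ecg("E2", "A", t=m(100)),
            make_ecg("E3", "B", t=m(0)),
            make_ecg("E4", "B", t=m(200)),
            make_ecg("E5", "C", t=m(0)),
            make_ecg("E6", "C", t=m(30)),
        ]
        labs = [
            # patient A: labs at -30 (3.0) and +50 (5.0); E1 window catches both,
            # E2 (t=100) catches only the +50 lab.
            make_lab("L1", "A", 3.0, m(-30)),
            make_lab("L2", "A", 5.0, m(50)),
            # patient B: one lab at +90 -> E3 excluded, E4 (t=200) excluded too.
            make_lab("L3", "B", 4.2, m(90)),
            # patient C: labs 3.9 (0), 4.1 (+20), 7.0 (+85); E5 catches first two,
            # E6 (t=30) catches all three.
            make_lab("L4", "C", 3.9, m(0)),
            make_lab("L5", "C", 4.1, m(20)),
            make_lab("L6", "C", 7.0, m(85)),
            # extra labs far outside any window
            make_lab("L7", "A", 9.0, m(500)),
            make_lab("L8", "B", 9.0, m(-500)),
            make_lab("L9", "C", 9.0, m(700)),
        ]
        linked = {x.ecg_id: x for x in link_ecg_lab(ecgs, labs)}
        assert set(linked) == {"E1", "E2", "E5", "E6"}
        assert linked["E1"].target == 4.0 and linked["E1"].n_labs_in_window == 2
        assert linked["E2"].target == 5.0
        assert linked["E5"].target == 4.0  # median of {3.9, 4.1}
        assert linked["E6"].target == 4.1  # median of {3.9, 4.1, 7.0}

    def test_mixed_analytes_rejected(self):
        labs = [make_lab("L1", analyte="potassium"), make_lab("L2", analyte="sodium")]
        with pytest.raises(ValueError):
            link_ecg_lab([make_ecg()], labs)


class TestEvalSelection:
    T0 = datetime(2013, 5, 1, 12, 0)

    def _setup(self, times, split_set):
        ecgs = [make_ecg(f"E{i}", "P0", t=self.T0 + timedelta(hours=h))
                for i, h in enumerate(times)]
        labs = [make_lab(f"L{i}", "P0", 4.0, e.acquisition_time) for i, e in enumerate(ecgs)]
        linked = link_ecg_lab(ecgs, labs)
        splits = DatasetSplits(**{split_set: {e.ecg_id for e in ecgs}})
        return linked, ecgs, splits

    def test_only_first_ecg_kept_in_test(self):
        linked, ecgs, splits = self._setup([2, 0, 5], "random_test")
        kept = select_eval_ecgs(linked, ecgs, splits)
        assert [x.ecg_id for x in kept] == ["E1"]  # earliest acquisition

    def test_single_ecg_unchanged(self):
        linked, ecgs, splits = self._setup([1], "val")
        assert len(select_eval_ecgs(linked, ecgs, splits)) == 1

    def test_training_keeps_all_ecgs(self):
        linked, ecgs, splits = self._setup([0, 1, 2], "train")
        assert len(select_eval_ecgs(linked, ecgs, splits)) == 3

    def test_toy_split_matches_enumeration(self):
        ecgs, labs = [], []
        for p in range(5):
            for j in range(2):
                t = self.T0 + timedelta(hours=j)
                ecgs.append(make_ecg(f"E{p}{j}", f"P{p}", t=t))
                labs.append(make_lab(f"L{p}{j}", f"P{p}", 4.0, t))
        linked = link_ecg_lab(ecgs, labs)
        splits = DatasetSplits(
            train={"E00", "E01"},
            val={"E10", "E11"},
            random_test={"E20", "E21", "E30", "E31"},
            temporal_test={"E40", "E41"},
        )
        kept = {x.ecg_id for x in select_eval_ecgs(linked, ecgs, splits)}
        assert kept == {"E00", "E01", "E10", "E20", "E30", "E40"}


class TestSplits:
    @staticmethod
    def _patients(n, n_post):
        out = []
        for i in range(n):
            d = date(2017, 3, 1) if i < n_post else date(2014, 6, 1)
            out.append(PatientRecord(f"P{i:04d}", 50.0, "male", d))
        return out

    def test_partitions_patient_disjoint(self):
        pats = self._patients(200, 30)
        ecgs = [make_ecg(f"E{i}", p.patient_id, t=datetime(2015, 1, 1))
                for i, p in enumerate(pats)]
        s = split_patients(pats, ecgs, seed=1)
        groups = {"train", "val"}, {"random_test"}, {"temporal_test"}
        sets = [
            {p for p, part in s.patient_partition.items() if part in g}
            for g in groups
        ]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])

    def test_scarce_post_cutoff_patients_all_temporal(self):
        pats = self._patients(300, 10)
        ecgs = []
        s = split_patients(pats, ecgs, seed=0)
        temporal = {p for p, part in s.patient_partition.items() if part == "temporal_test"}
        assert temporal == {f"P{i:04d}" for i in range(10)}

    def test_realized_fractions_close_to_nominal(self):
        pats = self._patients(1000, 200)
        ecgs = [make_ecg(f"E{i}", p.patient_id, t=datetime(2015, 1, 1))
                for i, p in enumerate(pats)]
        s = split_patients(pats, ecgs, seed=3)
        counts = {"dev": 0, "random_test": 0, "temporal_test": 0}
        for part in s.patient_partition.values():
            counts["dev" if part in ("train", "val") else part] += 1
        assert abs(counts["dev"] / 1000 - 0.70) < 0.02
        assert abs(counts["temporal_test"] / 1000 - 0.10) < 0.02
        assert abs(counts["random_test"] / 1000 - 0.20) < 0.02

    def test_post_cutoff_ecgs_removed_from_dev_and_random(self):
        pats = self._patients(50, 10)
        ecgs = []
        for i, p in enumerate(pats):
            ecgs.append(make_ecg(f"A{i}", p.patient_id, t=datetime(2015, 1, 1)))
            ecgs.append(make_ecg(f"B{i}", p.patient_id, t=datetime(2017, 6, 1)))
        s = split_patients(pats, ecgs, seed=2)
        post_ids = {f"B{i}" for i in range(50)}
        for part in ("train", "val", "random_test"):
            assert not getattr(s, part) & post_ids
        assert s.n_removed_post_cutoff > 0

    def test_no_post_cutoff_patients_raises(self):
        pats = self._patients(20, 0)
        with pytest.raises(TemporalSplitEmptyError):
            split_patients(pats, [], seed=0)


class TestNormalizer:
    def test_two_point_targets(self):
        norm = fit_normalizer([2.0, 4.0])
        assert norm.mean == 3.0 and norm.sd == 1.0  # population convention
        np.testing.assert_allclose(norm.apply([2.0, 4.0]), [-1.0, 1.0])

    def test_constant_targets_rejected(self):
        with pytest.raises(ValueError):
            fit_normalizer([4.0, 4.0, 4.0])

    def test_round_trip_identity(self, rng):
        norm = fit_normalizer(rng.normal(4, 0.5, 100))
        x = rng.normal(4, 1, 50)
        np.testing.assert_allclose(norm.invert(norm.apply(x)), x, rtol=1e-12)
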