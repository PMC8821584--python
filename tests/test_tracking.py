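"""Nearest-neighbour linking, morphology measurement and group statistics."""

import numpy as np
import pytest
from scipy import stats

from viaphase.evaluate import NucleusRecord
from viaphase.ground_truth import BACKGROUND, DEAD, LIVE, SemanticMap
from viaphase.optics import OpticsConfig, PhaseMap
from viaphase.tracking import (Track, TrackPoint, group_stats, link_tracks,
                               measure_track, normalize_series, track_series,
                               tracks_table)


def frame_with_disks(centers, cls=LIVE, shape=(128, 128), r=6):
    labels = np.full(shape, BACKGROUND, dtype=np.uint8)
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    for cy, cx in centers:
        labels[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = cls
    return SemanticMap(labels)


def synthetic_track(series, cls=LIVE):
    """A track whose normalised 'area' series is prescribed directly."""
    points = []
    for f, v in enumerate(series):
        rec = NucleusRecord(1, np.array([[0, 0]]), (0.0, 0.0), 1, cls)
        points.append(TrackPoint(f, rec, area_um2=float(v), dry_mass_pg=float(v)))
    return Track(0, points)


class TestLinkTracks:
    def test_stationary_object_single_track(self):
        frames = [frame_with_disks([(64, 64)]) for _ in range(5)]
        tracks = link_tracks(frames, max_disp_px=10, min_len=5)
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 1, 2, 3, 4]

    def test_slow_drift_is_followed(self):
        frames = [frame_with_disks([(40 + 4 * f, 40 + 3 * f)]) for f in range(6)]
        tracks = link_tracks(frames, max_disp_px=10, min_len=6)
        assert len(tracks) == 1

    def test_no_identity_swap_beyond_max_disp(self):
        """Two objects that jump past each other farther than max_disp
        produce four short tracks rather than crossing identities."""
        a0, b0 = (30, 30), (30, 98)
        frames = [frame_with_disks([a0, b0]),
                  frame_with_disks([a0, b0]),
                  frame_with_disks([(30, 98), (30, 30)])]  # swapped positions
        # positions are identical sets, so linking keeps each identity put
        tracks = link_tracks(frames, max_disp_px=15, min_len=1)
        assert len(tracks) == 2
        # now make them truly jump out of range mid-movie
        frames = [frame_with_disks([(30, 30)]) for _ in range(2)] + \
                 [frame_with_disks([(98, 98)]) for _ in range(2)]
        tracks = link_tracks(frames, max_disp_px=15, min_len=1)
        assert len(tracks) == 2
        assert sorted(len(t) for t in tracks) == [2, 2]

    def test_min_len_filter(self):
        frames = [frame_with_disks([(64, 64)]) for _ in range(3)]
        assert link_tracks(frames, max_disp_px=5, min_len=5) == []

    def test_deterministic_and_relabel_invariant(self):
        frames = [frame_with_disks([(30, 30), (90, 90)]),
                  frame_with_disks([(33, 31), (88, 92)])]
        t1 = link_tracks(frames, max_disp_px=10, min_len=2)
        t2 = link_tracks(frames, max_disp_px=10, min_len=2)
        c1 = sorted(tuple(p.nucleus.centroid for p in t.points) for t in t1)
        c2 = sorted(tuple(p.nucleus.centroid for p in t.points) for t in t2)
        assert c1 == c2

    def test_empty_frame_list(self):
        with pytest.raises(ValueError):
            link_tracks([])


class TestMeasureTrack:
    def test_uniform_disk_mass_and_area(self):
        labels = np.full((64, 64), BACKGROUND, dtype=np.uint8)
        labels[10:20, 10:20] = LIVE  # 100 px square "nucleus"
        sem = SemanticMap(labels)
        phases = [PhaseMap(np.ones((64, 64)), pixel_size_um=0.325)]
        tracks = link_tracks([sem], max_disp_px=5, min_len=1)
        tr = measure_track(tracks[0], phases, [sem], OpticsConfig())
        assert tr.points[0].area_um2 == pytest.approx(100 * 0.325**2)
        assert tr.points[0].dry_mass_pg == pytest.approx(4.623, abs=5e-4)

    def test_zero_phase_zero_mass(self):
        sem = frame_with_disks([(32, 32)], shape=(64, 64))
        phases = [PhaseMap(np.zeros((64, 64)), pixel_size_um=0.325)]
        tr = measure_track(link_tracks([sem], 5, 1)[0], phases, [sem])
        assert tr.points[0].dry_mass_pg == 0.0
        assert tr.points[0].area_um2 > 0

    def test_doubling_area_doubles_mass(self):
        labels = np.full((64, 64), BACKGROUND, dtype=np.uint8)
        labels[10:20, 10:20] = LIVE
        small = SemanticMap(labels.copy())
        labels[10:20, 30:50] = LIVE  # second region, same track? no - separate
        pm = PhaseMap(np.ones((64, 64)), pixel_size_um=0.325)
        tr_small = measure_track(link_tracks([small], 5, 1)[0], [pm], [small])
        big_labels = np.full((64, 64), BACKGROUND, dtype=np.uint8)
        big_labels[10:30, 10:20] = LIVE  # 200 px
        big = SemanticMap(big_labels)
        tr_big = measure_track(link_tracks([big], 5, 1)[0], [pm], [big])
        assert tr_big.points[0].area_um2 == pytest.approx(2 * tr_small.points[0].area_um2)
        assert tr_big.points[0].dry_mass_pg == pytest.approx(2 * tr_small.points[0].dry_mass_pg)

    def test_frame_out_of_range(self):
        sem = frame_with_disks([(32, 32)], shape=(64, 64))
        tr = link_tracks([sem], 5, 1)[0]
        tr.points[0].frame = 3
        with pytest.raises(IndexError):
            measure_track(tr, [PhaseMap(np.zeros((64, 64)))], [sem])


class TestNormalizeSeries:
    def test_constant_series(self):
        assert np.allclose(normalize_series([5, 5, 5]), 1.0)

    def test_hand_division(self):
        assert np.allclose(normalize_series([10, 12, 9]), [1.0, 1.2, 0.9])

    def test_idempotent(self):
        once = normalize_series([4.0, 6.0, 2.0])
        assert np.allclose(normalize_series(once), once)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_series([0.0, 1.0])


class TestGroupStats:
    def test_identical_groups_p_one(self, rng):
        tracks = [synthetic_track([10.0, 10.0 + i, 9.0 + i]) for i in range(5)]
        clones = [synthetic_track([10.0, 10.0 + i, 9.0 + i]) for i in range(5)]
        gs = group_stats(tracks, clones, "area")
        assert np.allclose(gs["welch_p"], 1.0)
        assert np.allclose(gs["t_stat"], 0.0)

    def test_sem_matches_hand_formula(self):
        vals = [1.0, 1.2, 0.8, 1.1, 0.9]
        tracks = [synthetic_track([1.0, v]) for v in vals]
        other = [synthetic_track([1.0, v + 1]) for v in vals]
        gs = group_stats(tracks, other, "area")
        arr = np.array(vals)
        sem = arr.std(ddof=1) / np.sqrt(len(arr))
        assert gs.loc[1, "sem_a"] == pytest.approx(sem)
        assert gs.loc[1, "n_a"] == 5

    def test_welch_reduces_to_student_for_equal_variances(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 12)
        tracks_a = [synthetic_track([1.0, v + 2]) for v in a]
        tracks_b = [synthetic_track([1.0, v + 2]) for v in b]
        gs = group_stats(tracks_a, tracks_b, "area")
        # equal sizes: Welch's statistic equals Student's exactly
        sa = np.array([(v + 2) / 1.0 for v in a])
        sb = np.array([(v + 2) / 1.0 for v in b])
        student = stats.ttest_ind(sa, sb, equal_var=True)
        assert gs.loc[1, "t_stat"] == pytest.approx(student.statistic, abs=1e-9)

    def test_large_shift_detected(self, rng):
        a = [synthetic_track([1.0, 1.0 + rng.normal(0, 0.01)]) for _ in range(10)]
        b = [synthetic_track([1.0, 1.5 + rng.normal(0, 0.01)]) for _ in range(10)]
        gs = group_stats(a, b, "area")
        assert gs.loc[1, "welch_p"] < 1e-6

    def test_insufficient_tracks_rejected(self):
        with pytest.raises(ValueError):
            group_stats([synthetic_track([1, 2])], [synthetic_track([1, 2])] * 3, "area")


class TestTracksTable:
    def test_schema_and_times(self):
        frames = [frame_with_disks([(64, 64)]) for _ in range(3)]
        tracks = link_tracks(frames, 5, 3)
        pm = [PhaseMap(np.ones((128, 128)), pixel_size_um=0.325)] * 3
        for t in tracks:
            measure_track(t, pm, frames)
        df = tracks_table(tracks, frame_interval_min=30)
        assert list(df["t_hours"]) == [0.0, 0.5, 1.0]
        assert set(df["class"]) == {"live"}
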