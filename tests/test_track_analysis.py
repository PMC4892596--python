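"""Run/tumble segmentation and motility estimators on constructed and sampled data."""

import math

import numpy as np
import pandas as pd
import pytest

from chemorace.tables import TrackTable
from chemorace.track_analysis import (
    mean_run_speed,
    mean_run_time,
    normalized_run_time,
    segment_runs,
    turn_angle_stats,
)

FRAME_DT = 0.1


def _table(tracks, meta=None):
    """Build a TrackTable from a list of (n, 2) or (n, 3) position arrays."""
    rows = []
    for tid, X in enumerate(tracks):
        X = np.asarray(X, dtype=float)
        for i in range(len(X)):
            rows.append((tid, i * FRAME_DT, *X[i]))
    cols = ["track_id", "t", "x", "y"] + (["z"] if np.asarray(tracks[0]).shape[1] == 3 else [])
    md = {"frame_dt": FRAME_DT}
    md.update(meta or {})
    return TrackTable(pd.DataFrame(rows, columns=cols), md)


def _straight_track(n=100, v=15.0):
    t = np.arange(n) * FRAME_DT
    return np.column_stack([v * t, np.zeros(n)])


class TestSegmentation:
    def test_constant_velocity_is_one_run(self):
        seg = segment_runs(_table([_straight_track()]))
        assert len(seg.segments) == 1
        assert seg.segments[0].label == "run"
        assert not seg.tumbles()

    def test_inserted_stop_gives_one_tumble(self):
        # 0.3 s stop in the middle of a straight run
        X = _straight_track(100)
        stop = slice(50, 53)
        X[stop.stop:] -= X[stop.stop] - X[stop.start]
        seg = segment_runs(_table([X]))
        tums = seg.tumbles()
        assert len(tums) == 1
        assert tums[0].t0 <= 50 * FRAME_DT <= tums[0].t1

    def test_stationary_jitter_mostly_tumble(self, rng):
        noise = 0.3
        X = rng.normal(0.0, noise, (200, 2))
        seg = segment_runs(_table([X], {"loc_noise_sd": noise}))
        frames = sum(s.n_frames for s in seg.segments)
        tumble_frames = sum(s.n_frames for s in seg.tumbles())
        assert tumble_frames / frames >= 0.9

    def test_segments_tile_track(self, rng):
        X = np.cumsum(rng.normal(0, 1.0, (300, 2)), axis=0)
        seg = segment_runs(_table([X]))
        spans = sorted((s.i0, s.i1) for s in seg.segments)
        assert spans[0][0] == 0
        assert spans[-1][1] == 299
        for (a, b), (c, d) in zip(spans[:-1], spans[1:]):
            assert b == c  # no gaps, no overlap

    def test_short_tracks_skipped(self):
        seg = segment_runs(_table([_straight_track(3), _straight_track(50)]))
        assert seg.n_skipped == 1
        assert seg.n_tracks == 1

    def test_invariance_under_rotation_and_translation(self, rng):
        X = np.cumsum(rng.normal(0, 1.0, (200, 2)), axis=0)
        th = 0.77
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        X2 = X @ R.T + np.array([123.0, -456.0])
        lab1 = [(s.i0, s.i1, s.label) for s in segment_runs(_table([X])).segments]
        lab2 = [(s.i0, s.i1, s.label) for s in segment_runs(_table([X2])).segments]
        assert lab1 == lab2


class TestRunTime:
    def test_exact_runs_fixture(self):
        # runs of exactly 2 s separated by 0.3 s stops
        blocks = []
        xcur = 0.0
        for _ in range(6):
            run = xcur + 15.0 * FRAME_DT * np.arange(20)
            xcur = run[-1]
            blocks.append(run)
            blocks.append(np.full(3, xcur))
        x = np.concatenate(blocks)
        X = np.column_stack([x, np.zeros_like(x)])
        seg = segment_runs(_table([X]))
        mean, sem, n = mean_run_time(seg)
        assert mean == pytest.approx(2.0, abs=2 * FRAME_DT)
        assert sem == pytest.approx(0.0, abs=1e-9) or math.isnan(sem)

    @staticmethod
    def _labelled_exponential_segments(tau, n_tracks=60, T=60.0, dwell=0.2,
                                       dt=0.1, seed=7):
        """Sampling oracle: exponential runs, fixed dwells, conservative
        frame labels (any tumble-contaminated frame is dropped, as the
        tumble filter does)."""
        from chemorace.track_analysis import RunTumbleSegments, Segment

        rng = np.random.default_rng(seed)
        segs = []
        for tid in range(n_tracks):
            t, state, events = 0.0, "run", []
            while t < T:
                dur = rng.exponential(tau) if state == "run" else dwell
                events.append((t, min(t + dur, T), state))
                t += dur
                state = "tumble" if state == "run" else "run"
            nf = int(T / dt)
            labels = []
            for i in range(nf):
                a, b = i * dt, (i + 1) * dt
                overlap = sum(
                    max(0.0, min(b, e) - max(a, s))
                    for s, e, lab in events if lab == "tumble"
                )
                labels.append(overlap > 1e-9)
            i0 = 0
            for i in range(1, nf + 1):
                if i == nf or labels[i] != labels[i0]:
                    segs.append(Segment(
                        tid, i0, i, "tumble" if labels[i0] else "run",
                        i0 * dt, i * dt, censored=(i0 == 0 or i == nf),
                    ))
                    i0 = i
        return RunTumbleSegments(segs, dt, n_tracks, 0)

    @pytest.mark.parametrize("tau", [0.5, 1.15, 2.4])
    def test_exponential_recovery(self, tau):
        # estimator is unbiased within 3 SE on exponential run data at 10 Hz,
        # including the pileup and boundary corrections (a crisply labelled
        # tumble spans ~2 frames plus boundary partials)
        seg = self._labelled_exponential_segments(tau)
        mean, sem, n = mean_run_time(seg, frames_per_tumble=3.0)
        assert n > 500
        assert abs(mean - tau) < 3 * sem

    def test_full_pipeline_closure(self):
        # generator-to-estimator closure through segmentation at the default
        # 10 Hz acquisition; the residual instrument bias stays below 10%
        from chemorace.synthetic_data import GeneratorConfig, generate_homogeneous_assay

        cfg = GeneratorConfig(seed=17, n_tracks=150, duration=50.0)
        tracks = generate_homogeneous_assay("aspartate", 0.0, cfg)
        mean, sem, n = mean_run_time(segment_runs(tracks))
        truth = tracks.metadata["truth"]["mean_run_time_s"]
        assert mean == pytest.approx(truth, rel=0.10)
        assert n > 500

    def test_normalization_is_division(self):
        seg = segment_runs(_table([_straight_track()]))
        # fabricate: single censored run -> nan; use the arithmetic contract
        fold, _ = normalized_run_time(seg, baseline_s=1.15)
        assert math.isnan(fold)  # no interior runs in a single straight track
        with pytest.raises(ValueError):
            normalized_run_time(seg, baseline_s=0.0)


class TestRunSpeed:
    def test_exact_speed_no_noise(self):
        # purely planar fixture: pitch_max = 0 metadata means no projection
        # correction, so per-track speeds are exact and the population SD
        # reflects the spread of the three tracks
        tracks = [_straight_track(v=v) for v in (12.0, 15.0, 18.0)]
        tab = _table(tracks, {"pitch_max": 0.0})
        seg = segment_runs(tab)
        mean, sd, n = mean_run_speed(seg, tab, loc_noise_sd=0.0)
        assert n == 3
        assert mean == pytest.approx(15.0, rel=1e-9)
        assert sd == pytest.approx(3.0, rel=1e-6)

    def test_speed_recovery_3d(self):
        # 3-D tracks need no projection correction: exact recovery
        from chemorace.synthetic_data import GeneratorConfig, generate_homogeneous_assay

        cfg = GeneratorConfig(seed=19, n_tracks=120, duration=40.0, keep_z=True)
        tracks = generate_homogeneous_assay("aspartate", 0.0, cfg)
        seg = segment_runs(tracks)
        mean, sd, n = mean_run_speed(seg, tracks)
        truth = tracks.metadata["truth"]["u_mean"]
        se = sd / math.sqrt(n)
        assert abs(mean - truth) < 3 * se + 0.3

    def test_stops_do_not_bias_speed(self):
        # inserting stops leaves the run-speed estimate unchanged
        X = _straight_track(120, v=15.0)
        Xs = X.copy()
        Xs[60:63] = Xs[59]
        Xs[63:] -= Xs[63] - Xs[59]
        t1 = _table([X], {"pitch_max": 0.0})  # planar fixture: no correction
        t2 = _table([Xs], {"pitch_max": 0.0})
        s1 = mean_run_speed(segment_runs(t1), t1, loc_noise_sd=0.0)[0]
        s2 = mean_run_speed(segment_runs(t2), t2, loc_noise_sd=0.0)[0]
        assert s2 == pytest.approx(s1, rel=1e-6)
        assert s1 == pytest.approx(15.0, rel=1e-6)


class TestTurnAngles:
    def test_deterministic_right_angles(self):
        # straight run, stop, straight run at 90 degrees: cos = 0
        a = _straight_track(40, v=15.0)
        stop = np.tile(a[-1], (3, 1))
        b = a[-1] + np.column_stack([np.zeros(40), 15.0 * FRAME_DT * np.arange(1, 41)])
        X = np.vstack([a, stop, b])
        tab = _table([X])
        seg = segment_runs(tab)
        cosm, se, n = turn_angle_stats(seg, tab)
        assert n == 1
        assert cosm == pytest.approx(0.0, abs=1e-9)

    def test_no_tumbles_flagged(self):
        tab = _table([_straight_track()])
        seg = segment_runs(tab)
        cosm, se, n = turn_angle_stats(seg, tab)
        assert n == 0 and math.isnan(cosm)

    def test_generator_cosine_recovered(self):
        from chemorace.synthetic_data import GeneratorConfig, generate_homogeneous_assay

        cfg = GeneratorConfig(seed=29, n_tracks=150, duration=40.0, keep_z=True)
        tracks = generate_homogeneous_assay("aspartate", 0.0, cfg)
        seg = segment_runs(tracks)
        cosm, se, n = turn_angle_stats(seg, tracks)
        assert n > 1000
        assert cosm == pytest.approx(0.3, abs=0.05)
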