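"""Track kinetics: velocities, pauses, summaries, event/arrival metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from axotrack import (KineticsConfig, SimTrackConfig, Track, TrackSet,
                      detect_pauses, event_frequency, first_arrival_time,
                      instantaneous_velocity, population_summary,
                      simulate_tracks, track_summary)

from conftest import constant_speed_track, make_track


class TestInstantaneousVelocity:
    def test_constant_retrograde_speed_everywhere(self):
        tr = constant_speed_track(-2.0)
        v = instantaneous_velocity(tr)
        assert v == pytest.approx(np.full(len(tr), -2.0))

    def test_window_three_uses_one_second_baseline_at_2hz(self):
        # the central difference at 2 Hz spans t_{i+1} - t_{i-1} = 1.0 s
        tr = make_track([0, 1, 1, 2, 2, 3, 3, 4], frame_rate=2.0)
        v = instantaneous_velocity(tr, KineticsConfig(velocity_window=3))
        assert v[1] == pytest.approx((tr.x[2] - tr.x[0]) / 1.0)
        assert v[3] == pytest.approx((tr.x[4] - tr.x[2]) / 1.0)

    def test_window_larger_than_track_rejected(self):
        tr = make_track([0, 1, 2])
        with pytest.raises(ValueError, match="velocity window"):
            instantaneous_velocity(tr, KineticsConfig(velocity_window=5))

    def test_stationary_noisy_track_reads_below_pause_threshold(self, rng):
        """With 0.05 µm localization noise the windowed velocity stays
        below the 0.1 µm/s pause threshold in >= 95% of frames."""
        below = total = 0
        cfg = KineticsConfig(velocity_window=5)
        for _ in range(1000):
            x = rng.normal(0, 0.05, size=40)
            v = instantaneous_velocity(make_track(x), cfg)
            below += int(np.sum(np.abs(v) < cfg.pause_speed_threshold))
            total += v.size
        assert below / total >= 0.95


class TestPauses:
    def test_constant_motion_has_no_pauses(self):
        assert detect_pauses(constant_speed_track(1.0)) == []

    def test_ten_second_slow_segment_is_one_pause(self):
        t = np.arange(0, 34.5, 0.5)
        x = np.where(t < 10, 100 - 2 * t,
                     np.where(t < 20, 80 - 0.05 * (t - 10),
                              79.5 - 2 * (t - 20)))
        events = detect_pauses(make_track(x))
        assert len(events) == 1
        assert events[0].duration == pytest.approx(10.0, abs=0.5)

    def test_pause_recovery_on_synthetic_tracks(self):
        """Percent pausing recovered within 2 points of generator truth."""
        cfg = SimTrackConfig(n_tracks=500, n_movies=10, seed=42,
                             direction_mix=(1.0, 0.0, 0.0),
                             pause_entry_rate=0.05, pause_mean_duration=4.0)
        ts = simulate_tracks(cfg)
        pop = population_summary(ts)
        motile = pop.per_track[pop.per_track.passed_motile_filter]
        gt = ts.ground_truth.set_index("track_id")
        truth = 100.0 * gt.loc[motile.track_id, "true_pause_fraction"].mean()
        measured = motile.percent_pausing.mean()
        assert measured == pytest.approx(truth, abs=2.0)


class TestTrackSummary:
    def test_retrograde_net_speed_and_run_length(self):
        tr = constant_speed_track(-2.0, n=61, x0=100.0)  # 100 -> 40 over 30 s
        s = track_summary(tr)
        assert s.mean_speed == pytest.approx(2.0)
        assert s.run_length == pytest.approx(60.0)
        assert s.direction == "retrograde"
        assert s.passed_motile_filter

    def test_sub_threshold_displacement_is_stationary(self):
        tr = constant_speed_track(0.2, n=81)  # 8 µm net over 40 s
        s = track_summary(tr)
        assert s.run_length == pytest.approx(8.0)
        assert not s.passed_motile_filter
        assert s.direction == "stationary"

    def test_speed_averages_over_paused_time(self):
        t = np.arange(0, 30.5, 0.5)
        x = np.where(t <= 20, 2.0 * t, 40.0)  # 40 µm in 20 s then 10 s pause
        s = track_summary(make_track(x))
        assert s.mean_speed == pytest.approx(40.0 / 30.0, rel=1e-6)
        assert s.percent_pausing == pytest.approx(33.3, abs=4.0)

    def test_zero_duration_rejected(self):
        tr = make_track([0.0, 5.0])
        tr.t = np.array([1.0, 1.0])
        with pytest.raises(ValueError, match="duration"):
            track_summary(tr)

    def test_net_speed_never_exceeds_path_speed(self):
        tr = make_track(np.array([0, 10, 5, 15, 10, 20, 30, 40.0]))
        s = track_summary(tr)
        assert s.mean_speed <= s.path_speed + 1e-12


class TestPopulation:
    def test_mean_and_sem_of_three_tracks(self):
        tracks = [constant_speed_track(v, n=41, track_id=i)
                  for i, v in enumerate((1.0, 2.0, 3.0))]
        pop = population_summary(TrackSet(tracks=tracks, frame_rate=2.0))
        agg = pop.aggregates.set_index("metric")
        assert agg.loc["mean_speed", "mean_over_tracks"] == pytest.approx(2.0)
        assert agg.loc["mean_speed", "sem_over_tracks"] == pytest.approx(0.577, abs=5e-3)

    def test_direction_fractions_on_noiseless_tracks(self):
        tracks = [constant_speed_track(-2.0, track_id=i) for i in range(8)]
        tracks += [constant_speed_track(2.0, track_id=8 + i) for i in range(2)]
        pop = population_summary(TrackSet(tracks=tracks, frame_rate=2.0))
        assert pop.direction_fractions["retrograde"] == pytest.approx(0.8)
        assert pop.direction_fractions["anterograde"] == pytest.approx(0.2)

    def test_speed_recovery_against_generator(self):
        """Population net speed within 3 SE of the configured 1.76 µm/s
        (pauses disabled so net and run speed coincide)."""
        cfg = SimTrackConfig(n_tracks=500, n_movies=10, seed=7,
                             direction_mix=(1.0, 0.0, 0.0),
                             pause_entry_rate=0.0)
        ts = simulate_tracks(cfg)
        pop = population_summary(ts)
        agg = pop.aggregates.set_index("metric")
        mean = agg.loc["mean_speed", "mean_over_tracks"]
        se = agg.loc["mean_speed", "sem_over_tracks"]
        assert mean == pytest.approx(1.76, abs=3 * se)

    def test_all_filtered_out_is_explicit(self):
        tracks = [constant_speed_track(0.05, track_id=0)]
        pop = population_summary(TrackSet(tracks=tracks, frame_rate=2.0))
        assert pop.status == "all tracks filtered out"
        assert pop.n_motile == 0


class TestEventFrequency:
    def test_six_motile_tracks_in_two_minutes(self):
        tracks = [constant_speed_track(-2.0, track_id=i) for i in range(6)]
        ts = TrackSet(tracks=tracks, frame_rate=2.0, movie_duration=120.0)
        assert event_frequency(ts) == pytest.approx(3.0)

    def test_no_motile_tracks_is_zero(self):
        tracks = [constant_speed_track(0.05, track_id=0)]
        ts = TrackSet(tracks=tracks, frame_rate=2.0, movie_duration=120.0)
        assert event_frequency(ts) == 0.0

    def test_poisson_flux_recovered_over_movies(self, rng):
        """20 movies with Poisson(rate x duration) motile events per movie:
        the per-movie-averaged estimate is within 3 SE of the rate."""
        minutes, rate = 4.0, 3.0
        tracks, tid = [], 0
        for m in range(20):
            for _ in range(rng.poisson(rate * minutes)):
                tracks.append(constant_speed_track(
                    -2.0, n=41, track_id=tid, movie=f"movie{m}"))
                tid += 1
        ts = TrackSet(tracks=tracks, frame_rate=2.0,
                      movie_duration=60 * minutes)
        freq = event_frequency(ts)
        per_movie = np.array([sum(t.movie == m for t in tracks) / minutes
                              for m in ts.movies])
        se = per_movie.std(ddof=1) / np.sqrt(per_movie.size)
        assert freq == pytest.approx(per_movie.mean())
        assert freq == pytest.approx(rate, abs=3 * max(se, np.sqrt(rate / (20 * minutes))))


class TestFirstArrival:
    def test_single_track_entering_at_180s(self):
        frames = np.arange(360, 421)
        t = frames / 2.0
        x = 110.0 - 2.0 * (t - 180.0)
        tr = Track(track_id=0, frames=frames, t=t, x=x)
        ts = TrackSet(tracks=[tr], frame_rate=2.0, label_onset=True)
        assert first_arrival_time(ts) == pytest.approx(3.0)

    def test_empty_set_not_observed(self):
        ts = TrackSet(tracks=[], frame_rate=2.0, label_onset=True)
        assert first_arrival_time(ts) is None

    def test_stable_binding_simulation_arrives_under_five_minutes(self):
        cfg = SimTrackConfig(
            n_tracks=40, seed=5, direction_mix=(1.0, 0.0, 0.0),
            speed_mean=1.76, speed_sd=0.0, pause_entry_rate=0.0,
            localization_sd=0.0, visible_length_mean=1e6,
            label_onset=True, movie_duration=600.0)
        ts = simulate_tracks(cfg)
        arrival = first_arrival_time(ts)
        assert arrival is not None
        assert arrival < 5.0


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 2 ** 31 - 1))
def test_coordinate_flip_swaps_directions_only(seed):
    """Negating x swaps retrograde/anterograde and preserves magnitudes."""
    rng = np.random.default_rng(seed)
    x = np.cumsum(rng.normal(-0.6, 0.5, size=50))
    tr = make_track(x)
    s, sf = track_summary(tr), track_summary(tr.flipped())
    swap = {"retrograde": "anterograde", "anterograde": "retrograde",
            "stationary": "stationary"}
    assert sf.direction == swap[s.direction]
    assert sf.mean_speed == pytest.approx(s.mean_speed)
    assert sf.run_length == pytest.approx(s.run_length)
    assert sf.percent_pausing == pytest.approx(s.percent_pausing)
    assert sf.n_pauses == s.n_pauses
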