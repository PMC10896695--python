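"""Generators: configured laws, determinism, geometry and ground truth."""

import numpy as np
import pytest

from axotrack import (AxonGeometry, SimTraceConfig, SimTrackConfig,
                      render_kymograph, simulate_bleach_traces,
                      simulate_dual_channel, simulate_tracks)
from axotrack.tracks import TrackSet

from conftest import constant_speed_track


def retro_cfg(**kw):
    base = dict(direction_mix=(1.0, 0.0, 0.0), seed=1)
    base.update(kw)
    return SimTrackConfig(**base)


class TestGeometry:
    def test_window_must_lie_inside_groove(self):
        with pytest.raises(ValueError, match="window"):
            AxonGeometry(groove_length=100.0, window_start=0.0, window_end=110.0)

    def test_defaults_are_groove_500_window_110(self):
        geo = AxonGeometry()
        assert geo.groove_length == 500.0
        assert geo.window_width == pytest.approx(110.0)


class TestTrackSimulation:
    def test_noiseless_kinematics_exact(self):
        cfg = retro_cfg(n_tracks=1, speed_mean=2.0, speed_sd=0.0,
                        pause_entry_rate=0.0, localization_sd=0.0)
        ts = simulate_tracks(cfg)
        assert len(ts) == 1
        dx = np.diff(ts[0].x)
        assert dx == pytest.approx(np.full(len(dx), -1.0))  # -1 µm per frame at 2 Hz

    def test_frame_interval_half_second_at_2hz(self):
        ts = simulate_tracks(retro_cfg(n_tracks=20, seed=3))
        for tr in ts:
            assert np.diff(tr.t) == pytest.approx(np.full(len(tr) - 1, 0.5))

    def test_speed_law_recovered_at_1000_tracks(self):
        cfg = retro_cfg(n_tracks=1000, speed_mean=1.76, speed_sd=0.5, seed=99)
        ts = simulate_tracks(cfg)
        speeds = ts.ground_truth["speed"].to_numpy()
        se = speeds.std(ddof=1) / np.sqrt(speeds.size)
        assert speeds.mean() == pytest.approx(1.76, abs=3 * se)

    def test_positions_confined_to_window(self):
        cfg = retro_cfg(n_tracks=100, seed=5, localization_sd=0.0)
        geo = cfg.geometry
        for tr in simulate_tracks(cfg):
            assert np.all(tr.x >= geo.window_start - 1e-9)
            assert np.all(tr.x <= geo.window_end + 1e-9)

    def test_retrograde_tracks_decrease_anterograde_increase(self):
        cfg = SimTrackConfig(n_tracks=200, seed=8, localization_sd=0.0,
                             pause_entry_rate=0.0,
                             direction_mix=(0.5, 0.5, 0.0))
        ts = simulate_tracks(cfg)
        gt = ts.ground_truth.set_index("track_id")
        for tr in ts:
            net = tr.x[-1] - tr.x[0]
            if gt.loc[tr.track_id, "direction"] == "retrograde":
                assert net < 0
            else:
                assert net > 0

    def test_label_onset_starts_at_distal_end(self):
        cfg = retro_cfg(n_tracks=50, seed=2, label_onset=True,
                        movie_duration=600.0)
        ts = simulate_tracks(cfg)
        assert np.all(ts.ground_truth["start_x"] == cfg.geometry.groove_length)
        assert np.all(ts.ground_truth["start_time"] == 0.0)

    def test_seed_determinism(self):
        a = simulate_tracks(retro_cfg(n_tracks=30, seed=17))
        b = simulate_tracks(retro_cfg(n_tracks=30, seed=17))
        c = simulate_tracks(retro_cfg(n_tracks=30, seed=18))
        pa, pb, pc = (s.to_spots_frame() for s in (a, b, c))
        assert pa.equals(pb)
        assert not pa.equals(pc)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="frame_rate"):
            SimTrackConfig(frame_rate=0.0)
        with pytest.raises(ValueError, match="direction_mix"):
            SimTrackConfig(direction_mix=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError, match="speed_min"):
            SimTrackConfig(speed_min=5.0, speed_max=1.0)


class TestTraceSimulation:
    def test_forced_stoichiometry_two_steps(self):
        cfg = SimTraceConfig(n_traces=20, molecule_count_pmf={1: 1.0},
                             copies_per_molecule=2, labeling_efficiency=1.0,
                             noise_sd=0.0, seed=4)
        trs = simulate_bleach_traces(cfg)
        assert np.all(trs.ground_truth["n_fluorophores"] == 2)
        for tr in trs:
            assert len(np.unique(np.round(tr.values, 6))) <= 3  # <= 2 drops

    def test_partial_labeling_spans_one_to_seven(self):
        cfg = SimTraceConfig(
            n_traces=2000, molecule_count_pmf={1: 0.3, 2: 0.2, 3: 0.2, 4: 0.3},
            copies_per_molecule=2, labeling_efficiency=0.8, seed=12)
        counts = set(simulate_bleach_traces(cfg).ground_truth["n_fluorophores"])
        assert {1, 2, 3, 4, 5, 6, 7}.issubset(counts)  # odd counts from partial labeling

    def test_modal_fluorophore_count_matches_binomial_mixture(self):
        # analytic enumeration of the binomial mixture says the mode is 2
        from scipy.stats import binom
        pmf = {1: 0.6, 2: 0.25, 3: 0.15}
        law = {k: sum(w * binom.pmf(k, n * 2, 0.9) for n, w in pmf.items())
               for k in range(0, 8)}
        assert max(law, key=law.get) == 2
        cfg = SimTraceConfig(n_traces=300, molecule_count_pmf=pmf,
                             copies_per_molecule=2, labeling_efficiency=0.9,
                             seed=6)
        counts = simulate_bleach_traces(cfg).ground_truth["n_fluorophores"]
        assert counts.mode().iloc[0] == 2

    def test_pmf_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimTraceConfig(molecule_count_pmf={1: 0.5, 2: 0.4})
        with pytest.raises(ValueError, match="non-empty"):
            SimTraceConfig(molecule_count_pmf={})

    def test_trace_determinism(self):
        a = simulate_bleach_traces(SimTraceConfig(n_traces=5, seed=9))
        b = simulate_bleach_traces(SimTraceConfig(n_traces=5, seed=9))
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.values, tb.values)


class TestDualChannel:
    def test_zero_fraction_shares_nothing(self):
        sa, sb = simulate_dual_channel(retro_cfg(n_tracks=30),
                                       retro_cfg(n_tracks=30, seed=2),
                                       coloc_fraction=0.0, seed=3)
        assert (sa.ground_truth["partner_id"] == -1).all()
        assert (sb.ground_truth["partner_id"] == -1).all()

    def test_full_fraction_zero_noise_identical_positions(self):
        cfg_a = retro_cfg(n_tracks=20, localization_sd=0.0)
        cfg_b = retro_cfg(n_tracks=0, localization_sd=0.0, seed=2)
        sa, sb = simulate_dual_channel(cfg_a, cfg_b, coloc_fraction=1.0, seed=3)
        assert len(sb) == len(sa)
        pairs = sa.ground_truth.set_index("track_id")["partner_id"]
        b_by_id = {tr.track_id: tr for tr in sb}
        for tr in sa:
            partner = b_by_id[pairs.loc[tr.track_id]]
            assert np.array_equal(tr.x, partner.x)

    def test_pair_count_is_deterministic_fraction(self):
        cfg_a = retro_cfg(n_tracks=500, n_movies=5)
        cfg_b = retro_cfg(n_tracks=100, seed=2, n_movies=5)
        sa, sb = simulate_dual_channel(cfg_a, cfg_b, coloc_fraction=0.10, seed=3)
        n_pairs = int((sa.ground_truth["partner_id"] >= 0).sum())
        assert n_pairs == round(0.10 * len(sa))

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="coloc_fraction"):
            simulate_dual_channel(retro_cfg(), retro_cfg(), coloc_fraction=1.5)


class TestKymograph:
    def test_static_spot_is_vertical_line(self):
        geo = AxonGeometry(groove_length=100, window_start=0, window_end=20)
        tr = constant_speed_track(0.0, n=21, x0=10.0)
        img = render_kymograph(TrackSet(tracks=[tr], frame_rate=2.0,
                                        movie_duration=10.0), geo)
        cols = img.argmax(axis=1)
        assert np.all(cols == cols[0])

    def test_moving_spot_slope_equals_speed(self):
        geo = AxonGeometry(groove_length=100, window_start=0, window_end=60)
        tr = constant_speed_track(2.0, n=41, x0=5.0)
        ts = TrackSet(tracks=[tr], frame_rate=2.0, movie_duration=20.0)
        img = render_kymograph(ts, geo, pixel_size=0.1)
        cols = img.argmax(axis=1)
        # µm per second along the ridge
        slope = np.polyfit(np.arange(len(cols)) / 2.0, cols * 0.1, 1)[0]
        assert slope == pytest.approx(2.0, rel=0.05)

    def test_empty_trackset_is_background_only(self):
        geo = AxonGeometry()
        ts = TrackSet(tracks=[], frame_rate=2.0, movie_duration=5.0)
        img = render_kymograph(ts, geo)
        assert np.all(img == 0.0)

    def test_nonpositive_psf_rejected(self):
        ts = TrackSet(tracks=[constant_speed_track(1.0)], frame_rate=2.0,
                      movie_duration=30.0)
        with pytest.raises(ValueError, match="psf_sd"):
            render_kymograph(ts, AxonGeometry(), psf_sd=0.0)
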