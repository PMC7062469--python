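"""Synthetic generators: determinism, closed-form moments, round-trips."""

import numpy as np
import pytest

from spineglia import contact, io as sio, synth
from spineglia.synth import SynthConfig


class TestDeterminism:
    def test_contact_movie_byte_identical_for_same_seed(self):
        cfg = SynthConfig(seed=42, image_size_px=128)
        a = synth.make_contact_movie(cfg, n_spines=5, n_frames=4)
        b = synth.make_contact_movie(cfg, n_spines=5, n_frames=4)
        assert a.microglia_mask.tobytes() == b.microglia_mask.tobytes()
        assert a.dendrite.tobytes() == b.dendrite.tobytes()
        for sa, sb in zip(a.spines, b.spines):
            assert np.array_equal(sa.polygon, sb.polygon)

    def test_different_seed_differs(self):
        a = synth.make_contact_movie(SynthConfig(seed=1, image_size_px=128), 5, n_frames=4)
        b = synth.make_contact_movie(SynthConfig(seed=2, image_size_px=128), 5, n_frames=4)
        assert a.microglia_mask.tobytes() != b.microglia_mask.tobytes()

    def test_calcium_dataset_deterministic(self):
        cfg = SynthConfig(seed=5, n_odors=3, n_repeats=2)
        a = synth.make_calcium_dataset(cfg, n_mice=1, n_dendrites_per_mouse=2)
        b = synth.make_calcium_dataset(cfg, n_mice=1, n_dendrites_per_mouse=2)
        for k in a.traces:
            assert np.array_equal(a.traces[k], b.traces[k])


class TestContactMovie:
    def test_empty_microglia_channel_gives_zero_coverage(self):
        cfg = SynthConfig(seed=0, image_size_px=128)
        m = synth.make_contact_movie(cfg, n_spines=5, n_frames=4, n_processes=0)
        series = contact.score_movie(m.microglia_mask, m.spines, 3.0)
        for s in series.values():
            assert np.all(s.coverage == 0.0)

    def test_spine_polygons_inside_image(self):
        m = synth.make_contact_movie(SynthConfig(seed=3, image_size_px=128), 20, n_frames=2)
        for sp in m.spines:
            sp.raster_indices((128, 128))  # raises if out of bounds

    def test_bias_elevates_mushroom_coverage(self):
        cfg = SynthConfig(seed=9, image_size_px=128)
        biased = synth.make_contact_movie(cfg, 20, bias=5.0, n_frames=8)
        series = contact.score_movie(biased.microglia_mask, biased.spines, 3.0)
        mush = np.mean(
            [series[s.spine_id].coverage.mean() for s in biased.spines
             if s.spine_class == "mushroom"]
        )
        filo = np.mean(
            [series[s.spine_id].coverage.mean() for s in biased.spines
             if s.spine_class == "filopodial"]
        )
        assert mush > 3 * filo
        assert any(v.size for v in biased.true_contact_frames.values())

    def test_invalid_args_rejected(self):
        cfg = SynthConfig(seed=0, image_size_px=64)
        with pytest.raises(ValueError):
            synth.make_contact_movie(cfg, n_spines=0)
        with pytest.raises(ValueError):
            synth.make_contact_movie(cfg, n_spines=2, bias=-1)

    def test_threshold_segment_contract(self, rng):
        stack = rng.uniform(0, 100, size=(3, 16, 16))
        mask = synth.threshold_segment(stack, 50.0)
        assert mask.dtype == bool and mask.shape == stack.shape


class TestCalciumDataset:
    def test_window_mean_matches_closed_form_kernel_average(self):
        # responders carry amp_sd_units x noise_sd x kernel, so the mean
        # dF/F_sigma over the analysis window is amp_sd_units x the
        # window-average of the kernel, up to Monte-Carlo error
        cfg = SynthConfig(seed=4, n_odors=1, n_repeats=2)
        ds = synth.make_calcium_dataset(
            cfg, n_mice=1, n_dendrites_per_mouse=1000, p_respond=1.0,
            amp_sd_units=2.0, noise_sd=1.0,
        )
        fs = ds.frame_rate_hz
        onset = ds.odor_onset_frame
        n_win = int(5 * fs)
        t_rel = (np.arange(ds.n_frames) - onset) / fs
        kernel_avg = synth.gcamp_kernel(t_rel)[onset : onset + n_win].mean()
        got = np.mean(
            [
                ((f - f[:onset].mean()) / ds.noise_sd)[onset : onset + n_win].mean()
                for k, f in ds.traces.items()
                if k[2] != "blank"
            ]
        )
        assert got == pytest.approx(2.0 * kernel_avg, abs=0.05)

    def test_blank_trials_present_per_repeat_set(self):
        cfg = SynthConfig(seed=1, n_odors=2, n_repeats=3)
        ds = synth.make_calcium_dataset(cfg, n_mice=1, n_dendrites_per_mouse=1)
        blanks = [k for k in ds.traces if k[2] == "blank"]
        assert len(blanks) == 3

    def test_p_respond_zero_has_no_true_amplitudes(self):
        cfg = SynthConfig(seed=2, n_odors=5, n_repeats=2)
        ds = synth.make_calcium_dataset(cfg, 1, 3, p_respond=0.0)
        assert all(v == 0.0 for v in ds.true_amplitude.values())

    def test_bleach_drift_is_monotone_decay(self):
        cfg = SynthConfig(seed=3, n_odors=1, n_repeats=1)
        ds = synth.make_calcium_dataset(
            cfg, 1, 1, p_respond=0.0, bleach_tau_s=30.0, noise_sd=1e-9
        )
        (f,) = [v for k, v in ds.traces.items() if k[2] == "blank"]
        assert np.all(np.diff(f) < 0)

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            synth.make_calcium_dataset(SynthConfig(seed=0), 1, 1, noise_sd=0.0)


class TestRcTestPulse:
    def test_closed_form_peak_and_steady_state(self):
        p = synth.make_rc_testpulse(10.0, 500.0, 14.0, noise_pa=0.0)
        i = p.mean_current()
        on = int(round(p.step_onset_s * p.sample_rate_hz))
        # |I_peak| = |dV|/Rs = 10 mV / 10 MOhm = 1000 pA
        assert abs(i[on]) == pytest.approx(1000.0, rel=1e-9)
        # steady state = |dV|/(Rs+Rm) = 10 mV / 510 MOhm
        off = on + int(round(p.step_duration_s * p.sample_rate_hz))
        assert abs(i[off - 10 : off].mean()) == pytest.approx(1e4 / 510, rel=1e-3)

    def test_open_circuit_limit_steady_state_near_zero(self):
        p = synth.make_rc_testpulse(10.0, 1e9, 14.0, noise_pa=0.0)
        i = p.mean_current()
        on = int(round(p.step_onset_s * p.sample_rate_hz))
        off = on + int(round(p.step_duration_s * p.sample_rate_hz))
        assert abs(i[off - 10 : off].mean()) < 1e-3  # pA

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            synth.make_rc_testpulse(0.0, 500.0, 14.0)


class TestHierarchicalValues:
    def test_degenerate_sds_collapse_to_group_means(self):
        a, b = synth.make_hierarchical_values(3, 5, 0.0, 0.0, effect=1.0,
                                              grand_mean=2.0, seed=0)
        assert np.all(a.pooled() == 2.0)
        assert np.all(b.pooled() == 1.0)

    def test_treated_shifted_down_by_effect(self):
        a, b = synth.make_hierarchical_values(20, 200, 0.1, 1.0, effect=0.5, seed=1)
        assert a.pooled().mean() - b.pooled().mean() == pytest.approx(0.5, abs=0.1)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            synth.make_hierarchical_values(3, 5, -1.0, 1.0)


class TestEventTrain:
    def test_rate_recovery_within_5pct(self):
        train = synth.make_event_train(30.0, 300.0, seed=2)
        assert len(train) / (train.duration_ms / 1e3) == pytest.approx(30.0, rel=0.05)

    def test_zero_rate_gives_empty_train(self):
        assert len(synth.make_event_train(0.0, 100.0, seed=0)) == 0

    def test_doublet_fraction_flagged_in_ground_truth(self):
        train = synth.make_event_train(10.0, 100.0, doublet_fraction=0.1, seed=3)
        n_primary = int((~train.is_doublet).sum())
        frac = train.is_doublet.sum() / n_primary
        assert frac == pytest.approx(0.1, abs=0.03)

    def test_times_sorted(self):
        train = synth.make_event_train(20.0, 50.0, doublet_fraction=0.2, seed=4)
        assert np.all(np.diff(train.times_ms) >= 0)


class TestRoundTrips:
    def test_contact_movie_tiff_and_roi_json(self, tmp_path):
        m = synth.make_contact_movie(SynthConfig(seed=0, image_size_px=64), 4, n_frames=3)
        sio.write_contact_movie(tmp_path / "m.tif", m)
        dend, mask = sio.read_contact_movie(tmp_path / "m.tif")
        assert np.array_equal(dend, m.dendrite)
        assert np.array_equal(mask, m.microglia_mask)
        sio.write_rois(tmp_path / "r.json", m.spines)
        back = sio.read_rois(tmp_path / "r.json")
        assert [s.spine_id for s in back] == [s.spine_id for s in m.spines]
        assert all(
            np.array_equal(a.polygon, b.polygon) for a, b in zip(back, m.spines)
        )

    def test_trace_csv_and_hdf5_round_trip(self, tmp_path):
        cfg = SynthConfig(seed=6, n_odors=2, n_repeats=2)
        ds = synth.make_calcium_dataset(cfg, 1, 2)
        sio.write_traces_csv(tmp_path / "t.csv", ds)
        got_csv = sio.read_traces_csv(tmp_path / "t.csv")
        sio.write_traces_hdf5(tmp_path / "t.h5", ds)
        got_h5 = sio.read_traces_hdf5(tmp_path / "t.h5")
        assert set(got_csv) == set(ds.traces) == set(got_h5)
        for k in ds.traces:
            assert got_csv[k] == pytest.approx(ds.traces[k], rel=1e-12)
            assert np.array_equal(got_h5[k], ds.traces[k])
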