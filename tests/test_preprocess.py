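"""Preprocessing: filter analytics, epoching contracts, RANSAC recovery, PSD."""

import numpy as np
import pytest

from tinnigraph.containers import EpochSet, RawRecording
from tinnigraph.preprocess import (RansacParams, apply_filter, average_psd,
                                   butterworth_prototype_gain, compute_psd,
                                   define_events, design_bandpass,
                                   detect_bad_channels, make_epochs,
                                   ransac_clean, remove_bad_channels)
from tinnigraph.synth import ArtifactSpec, inject_artifacts


class TestFilterDesign:
    @pytest.mark.parametrize("order", [2, 4, 6])
    def test_band_edges_at_minus_3db(self, order):
        spec = design_bandpass(order, 1.0, 40.0, fs=256.0)
        grid = np.linspace(1.0, 40.0, 2000)
        peak = spec.magnitude(grid).max()
        edges = spec.magnitude(np.array([1.0, 40.0]))
        edge_db = 20 * np.log10(edges / peak)
        assert np.allclose(edge_db, -20 * np.log10(np.sqrt(2)), atol=0.1)

    def test_prototype_gain_at_cutoff_is_inv_sqrt2(self):
        assert butterworth_prototype_gain(10.0, 10.0, 4) == pytest.approx(
            1.0 / np.sqrt(2.0), abs=1e-15)

    def test_default_order_is_four(self):
        assert design_bandpass().order == 4

    def test_high_cut_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            design_bandpass(4, 1.0, 130.0, fs=256.0)


class TestApplyFilter:
    def _rec(self, x, fs):
        return RawRecording(data=np.atleast_2d(x), fs=fs)

    def test_dc_suppressed(self):
        spec = design_bandpass(4, 1.0, 40.0, fs=256.0)
        out = apply_filter(self._rec(np.ones(2560), 256.0), spec)
        assert np.abs(out.data).max() < 0.01

    def test_inband_tone_passes_with_unit_gain(self):
        fs = 256.0
        t = np.arange(int(10 * fs)) / fs
        spec = design_bandpass(4, 1.0, 40.0, fs=fs)
        out = apply_filter(self._rec(np.sin(2 * np.pi * 10 * t), fs), spec)
        steady = out.data[0, int(2 * fs):-int(2 * fs)]
        assert np.abs(steady).max() == pytest.approx(1.0, rel=0.02)

    def test_stopband_tone_attenuated_20db(self):
        fs = 512.0
        t = np.arange(int(10 * fs)) / fs
        spec = design_bandpass(4, 1.0, 40.0, fs=fs)
        out = apply_filter(self._rec(np.sin(2 * np.pi * 100 * t), fs), spec)
        steady = out.data[0, int(2 * fs):-int(2 * fs)]
        assert 20 * np.log10(np.abs(steady).max()) < -20.0

    def test_zero_phase_no_lag(self):
        fs = 256.0
        t = np.arange(int(8 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        spec = design_bandpass(4, 1.0, 40.0, fs=fs)
        y = apply_filter(self._rec(x, fs), spec).data[0]
        xc = np.correlate(x[512:-512], y[512:-512], mode="full")
        lag = np.argmax(xc) - (len(x) - 1024 - 1)
        assert lag == 0

    def test_fs_mismatch_rejected(self, clean_recording):
        spec = design_bandpass(4, 1.0, 40.0, fs=128.0)
        with pytest.raises(ValueError, match="fs"):
            apply_filter(clean_recording, spec)

    def test_filtered_flag_set(self, clean_recording, bandpass):
        assert apply_filter(clean_recording, bandpass).filtered


class TestBadChannels:
    def test_flat_channel_flagged(self, clean_recording):
        rec, _ = inject_artifacts(clean_recording,
                                  ArtifactSpec(flat_channel_ids=[3]), seed=0)
        report = detect_bad_channels(rec)
        assert report.flat[3] and "flat" in report.reasons(3)

    def test_noisy_channel_flagged(self, clean_recording):
        rec, _ = inject_artifacts(clean_recording,
                                  ArtifactSpec(noisy_channel_ids=[5]), seed=0)
        report = detect_bad_channels(rec)
        assert report.hf_noise[5]

    def test_clean_recording_unflagged(self, clean_recording):
        assert detect_bad_channels(clean_recording).bad_channels == []

    def test_removal_reduces_channels(self, clean_recording):
        rec, _ = inject_artifacts(clean_recording,
                                  ArtifactSpec(flat_channel_ids=[3]), seed=0)
        reduced, _ = remove_bad_channels(rec, detect_bad_channels(rec))
        assert reduced.n_channels == clean_recording.n_channels - 1


class TestEventsAndEpochs:
    def test_events_sorted_passthrough(self):
        rec = RawRecording(data=np.zeros((2, 1024)), fs=256.0,
                           markers=[(512, 2), (256, 1)])
        events = define_events(rec)
        assert [(e.sample, e.marker_id) for e in events] == [(256, 1), (512, 2)]
        assert events[0].time == 1.0

    def test_no_markers_empty_list(self):
        rec = RawRecording(data=np.zeros((2, 256)), fs=256.0)
        assert define_events(rec) == []

    def test_epoch_count_and_content(self, clean_recording, bandpass):
        filtered = apply_filter(clean_recording, bandpass)
        events = define_events(filtered)
        ep = make_epochs(filtered, events, 0.0, 1.0)
        assert ep.n_epochs == 10  # 20 s recording, markers every 2 s
        s0 = events[3].sample
        assert np.array_equal(ep.data[3], filtered.data[:, s0:s0 + 256])

    def test_out_of_bounds_event_dropped(self):
        rec = RawRecording(data=np.random.default_rng(0).normal(size=(2, 512)),
                           fs=256.0, markers=[(10, 1), (256, 1)])
        from tinnigraph.preprocess import define_events as de
        ep = make_epochs(rec, de(rec), tmin=-1.0, tmax=0.0)
        assert ep.n_epochs == 1

    def test_window_longer_than_recording_rejected(self):
        rec = RawRecording(data=np.zeros((2, 256)), fs=256.0, markers=[(0, 1)])
        with pytest.raises(ValueError, match="longer"):
            make_epochs(rec, define_events(rec), 0.0, 2.0)

    def test_contiguous_epochs_reconstruct_signal(self):
        rng = np.random.default_rng(1)
        rec = RawRecording(data=rng.normal(size=(3, 1024)), fs=256.0,
                           markers=[(i * 256, 1) for i in range(4)])
        ep = make_epochs(rec, define_events(rec), 0.0, 1.0)
        rebuilt = np.concatenate(list(ep.data), axis=1)
        assert np.array_equal(rebuilt, rec.data)


class TestRansac:
    def test_clean_epochs_not_rejected(self, clean_epochs):
        out = ransac_clean(clean_epochs)
        assert out.rejected.sum() == 0

    def test_blink_epochs_flagged(self, clean_recording, bandpass):
        rng = np.random.default_rng(3)
        bad = sorted(rng.choice(10, size=3, replace=False))
        spec = ArtifactSpec(blink_times_s=[2.0 * b + 0.5 for b in bad],
                            blink_multiplier=10.0)
        rec, _ = inject_artifacts(clean_recording, spec, seed=1)
        filtered = apply_filter(rec, bandpass)
        ep = make_epochs(filtered, define_events(filtered), 0.0, 1.0)
        out = ransac_clean(ep)
        flagged = set(np.flatnonzero(out.rejected))
        assert flagged == set(bad)

    def test_same_seed_same_rejections(self, clean_epochs):
        a = ransac_clean(clean_epochs, RansacParams(seed=9))
        b = ransac_clean(clean_epochs, RansacParams(seed=9))
        assert np.array_equal(a.rejected, b.rejected)

    def test_rejection_monotone_in_amplitude(self, clean_recording, bandpass):
        counts = []
        for mult in (2.0, 5.0, 10.0):
            spec = ArtifactSpec(blink_times_s=[0.5, 4.5, 8.5],
                                blink_multiplier=mult)
            rec, _ = inject_artifacts(clean_recording, spec, seed=4)
            filtered = apply_filter(rec, bandpass)
            ep = make_epochs(filtered, define_events(filtered), 0.0, 1.0)
            counts.append(int(ransac_clean(ep).rejected.sum()))
        assert counts == sorted(counts)

    def test_too_few_channels_rejected(self):
        ep = EpochSet(data=np.zeros((6, 3, 256)), fs=256.0, tmin=0, tmax=1)
        with pytest.raises(ValueError, match="channels"):
            ransac_clean(ep)

    def test_rejected_epochs_kept_in_array(self, clean_epochs):
        out = ransac_clean(clean_epochs)
        assert out.n_epochs == clean_epochs.n_epochs


class TestPsd:
    def test_pure_tone_peak_bin(self):
        fs = 256.0
        t = np.arange(256) / fs
        x = np.sin(2 * np.pi * 10 * t)
        ep = EpochSet(data=np.tile(x, (1, 1, 1)), fs=fs, tmin=0, tmax=1)
        sd = compute_psd(ep)
        assert sd.freqs[np.argmax(sd.power[0, 0])] == pytest.approx(10.0, abs=1.0)

    def test_parseval_white_noise(self, rng):
        fs = 256.0
        x = rng.standard_normal((1, 1, 2048))
        ep = EpochSet(data=x, fs=fs, tmin=0, tmax=8)
        sd = compute_psd(ep, segment_seconds=8.0)
        total = np.trapezoid(sd.power[0, 0], sd.freqs)
        assert total == pytest.approx(x.var(), rel=0.1)

    def test_zero_signal_zero_psd(self):
        ep = EpochSet(data=np.zeros((1, 2, 256)), fs=256.0, tmin=0, tmax=1)
        sd = compute_psd(ep)
        assert np.all(sd.power == 0)

    def test_segment_longer_than_epoch_capped(self):
        ep = EpochSet(data=np.zeros((1, 2, 128)), fs=256.0, tmin=0, tmax=0.5)
        sd = compute_psd(ep, segment_seconds=1.0)  # capped at epoch length
        assert sd.power.shape[-1] == 65

    def test_periodogram_method(self):
        ep = EpochSet(data=np.zeros((1, 2, 256)), fs=256.0, tmin=0, tmax=1)
        sd = compute_psd(ep, method="periodogram")
        assert sd.power.shape[-1] == 129


class TestAveragePsd:
    def test_two_channel_mean(self):
        from tinnigraph.containers import SpectralDensity
        p = np.ones((1, 1, 5))
        sd = SpectralDensity(freqs=np.arange(5.0),
                             power=np.concatenate([p, 3 * p], axis=1))
        assert np.allclose(average_psd(sd).power, 2.0)

    def test_single_channel_identity(self):
        from tinnigraph.containers import SpectralDensity
        sd = SpectralDensity(freqs=np.arange(5.0),
                             power=np.random.default_rng(0).random((2, 1, 5)))
        assert np.array_equal(average_psd(sd).power, sd.power)

    def test_matches_elementwise_loop(self, rng):
        from tinnigraph.containers import SpectralDensity
        power = rng.random((3, 4, 6))
        sd = SpectralDensity(freqs=np.arange(6.0), power=power)
        out = average_psd(sd).power[:, 0]
        # independent brute-force mean
        expect = np.empty((3, 6))
        for e in range(3):
            for f in range(6):
                expect[e, f] = sum(power[e, c, f] for c in range(4)) / 4
        assert np.allclose(out, expect)
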