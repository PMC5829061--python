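"""EEG conditioning: resampling, filtering, ocular rejection, epoching."""

import numpy as np
import pytest

from hbci.config import FilterSpec
from hbci.data import ChannelInfo, ContinuousRecording, EventMarker
from hbci.eeg import bandpass, downsample, epoch, remove_eog
from hbci.pipeline import preprocess_eeg
from hbci.config import PipelineConfig
from hbci.simulate import SimulationConfig, build_schedule, simulate_eeg


def _rec(data, rate, events=(), modality="EEG"):
    chans = [ChannelInfo(f"ch{i}", modality) for i in range(data.shape[0])]
    return ContinuousRecording(data=data, rate=rate, channels=chans,
                               events=list(events), unit="uV")


class TestDownsample:
    def test_sine_amplitude_preserved(self):
        rate = 2048.0
        t = np.arange(int(10 * rate)) / rate
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        out = downsample(_rec(x, rate), 200.0)
        assert out.rate == 200.0
        core = out.data[0][200:-200]  # away from filter edges
        assert abs(core.max() - 1.0) < 0.01

    def test_tone_above_target_nyquist_removed(self):
        rate = 2048.0
        t = np.arange(int(10 * rate)) / rate
        x = np.sin(2 * np.pi * 150 * t)[None, :]
        out = downsample(_rec(x, rate), 200.0)
        p_in = np.mean(x**2)
        p_out = np.mean(out.data[0][200:-200] ** 2)
        assert p_out < 1e-3 * p_in

    def test_tone_below_target_nyquist_kept(self):
        rate = 2048.0
        t = np.arange(int(10 * rate)) / rate
        x = np.sin(2 * np.pi * 90 * t)[None, :]
        out = downsample(_rec(x, rate), 200.0)
        p_ratio = np.mean(out.data[0][400:-400] ** 2) / np.mean(x**2)
        assert 0.9 < p_ratio < 1.1

    def test_event_onset_rescaled(self):
        x = np.zeros((1, 4096))
        out = downsample(_rec(x, 2048.0, [EventMarker(2048, "MA")]), 200.0)
        assert out.events[0].onset_sample == 200

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="below"):
            downsample(_rec(np.zeros((1, 100)), 100.0), 200.0)


class TestBandpass:
    def test_dc_rejected(self):
        x = np.full((1, 4000), 7.0)
        out = bandpass(_rec(x, 200.0), FilterSpec(0.1, 50))
        assert np.abs(out.data).max() < 1e-3

    def test_passband_tone_unit_gain_zero_lag(self):
        rate = 200.0
        t = np.arange(int(60 * rate)) / rate
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        out = bandpass(_rec(x, rate), FilterSpec(0.1, 50))
        core = slice(2000, -2000)
        gain = out.data[0][core].std() / x[0][core].std()
        assert 0.95 < gain < 1.05
        lag = np.argmax(np.correlate(out.data[0][core], x[0][core], "full"))
        assert lag == len(x[0][core]) - 1  # zero-lag peak

    def test_stopband_tone_attenuated(self):
        rate = 200.0
        t = np.arange(int(30 * rate)) / rate
        x = np.sin(2 * np.pi * 60 * t)[None, :]
        out = bandpass(_rec(x, rate), FilterSpec(0.1, 50))
        assert out.data[0].std() < 0.4 * x[0].std()

    def test_edge_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_rec(np.zeros((1, 100)), 100.0), FilterSpec(0.1, 50.0))


class TestRemoveEOG:
    def _mixed(self, g=0.7, seed=0):
        rng = np.random.default_rng(seed)
        n = 6000
        clean = rng.standard_normal((3, n))
        eog = np.convolve(rng.standard_normal(n), np.ones(40) / 40, "same") * 5
        data = np.vstack([clean + np.outer([g, g / 2, g / 4], eog), eog[None]])
        chans = [ChannelInfo(f"ch{i}", "EEG") for i in range(3)]
        chans.append(ChannelInfo("VEOG", "EOG"))
        return ContinuousRecording(data, 200.0, chans), clean, eog

    def test_planted_mixture_removed(self):
        rec, clean, eog = self._mixed()
        out = remove_eog(rec, ["VEOG"])
        assert out.n_channels == 3
        for row in out.data:
            r = np.corrcoef(row, eog)[0, 1]
            assert abs(r) < 0.05

    def test_zero_eog_leaves_eeg_untouched(self):
        rec, clean, _ = self._mixed()
        data = rec.data.copy()
        data[3] = 0.0
        data[:3] = clean
        rec2 = ContinuousRecording(data, rec.rate, rec.channels)
        out = remove_eog(rec2, ["VEOG"])
        assert np.allclose(out.data, clean)

    def test_missing_eog_channel_errors(self):
        rec = _rec(np.random.default_rng(0).standard_normal((2, 100)), 100.0)
        with pytest.raises(ValueError, match="no EOG channel"):
            remove_eog(rec, [])

    def test_blink_power_reduced_on_simulated_frontals(self):
        cfg = SimulationConfig(n_trials_per_class=2, blink_rate_hz=0.5, seed=8)
        sched = build_schedule(cfg, np.random.default_rng(8))
        rec = simulate_eeg(cfg, sched, np.random.default_rng(9))
        out = remove_eog(rec, ["VEOG"])
        frontal = [i for i, c in enumerate(rec.channels) if c.region == "frontal"]
        from hbci.nirs import _sos_bandpass

        low_in = _sos_bandpass(rec.data[frontal], rec.rate, FilterSpec(0.01, 4.0))
        low_out = _sos_bandpass(out.data[: len(frontal)], rec.rate,
                                FilterSpec(0.01, 4.0))
        assert np.mean(low_out**2) < np.mean(low_in**2)


class TestEpoch:
    def _event_rec(self, rate=200.0, dur=60.0, onsets=((30.0, "MA"),)):
        n = int(dur * rate)
        data = np.arange(2 * n, dtype=float).reshape(2, n)
        events = [EventMarker(int(t * rate), lab) for t, lab in onsets]
        return _rec(data, rate, events)

    def test_shape_90_trials_6000_samples(self, strong_epochs):
        eeg_epochs, _ = strong_epochs
        assert eeg_epochs.data.shape == (90, 21, 6000)
        assert eeg_epochs.time_axis[0] == pytest.approx(-5.0)

    def test_empty_window_rejected(self):
        rec = self._event_rec()
        with pytest.raises(ValueError, match="empty"):
            epoch(rec, (0.0, 0.0))

    def test_single_event_exact_samples(self):
        rec = self._event_rec(rate=200.0, dur=60.0, onsets=((30.0, "MI"),))
        eps = epoch(rec, (-5.0, 25.0))
        assert eps.data.shape == (1, 2, 6000)
        onset = 30 * 200
        assert np.array_equal(eps.data[0, 0], rec.data[0, onset - 1000: onset + 5000])
        assert eps.labels[0] == "MI"

    def test_out_of_bounds_window_names_trial(self):
        rec = self._event_rec(onsets=((0.5, "MA"),))
        with pytest.raises(ValueError, match="trial 0"):
            epoch(rec, (-5.0, 25.0))

    def test_adjacent_windows_tile_the_recording(self):
        """Epoching contiguous half-open windows loses and duplicates nothing."""
        rec = self._event_rec(rate=100.0, dur=30.0, onsets=((10.0, "IS"),))
        parts = [epoch(rec, (a, a + 2.0)).data[0] for a in (-4.0, -2.0, 0.0, 2.0)]
        tiled = np.concatenate(parts, axis=1)
        onset = 1000
        assert np.array_equal(tiled, rec.data[:, onset - 400: onset + 400])


def test_preprocess_eeg_drops_eog_and_keeps_trials(small_session):
    eeg_rec, _ = small_session
    eps = preprocess_eeg(eeg_rec, PipelineConfig())
    assert eps.n_trials == 18
    assert all(c.modality == "EEG" for c in eps.channels)
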