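import numpy as np
import pandas as pd
import pytest

from confclust.eegproc import (
    ContinuousRecording,
    baseline_correct,
    derive_eog,
    exclude_participants_by_variance,
    extract_epochs,
    preprocess_continuous,
    preprocess_epochs,
    read_edf,
    reject_artifact_epochs,
    rereference_common_average,
    trim_amplitude_percentiles,
    write_edf,
)
from confclust.epochs import EpochArray, default_times


def make_epochs(data, participants=None, fs=128.0, window=(-1.0, 2.0), channels=None):
    data = np.asarray(data, dtype=float)
    n_tr, n_ch, n_t = data.shape
    if channels is None:
        channels = [f"ch{i}" for i in range(n_ch)]
    times = default_times(fs, window)[:n_t]
    meta = pd.DataFrame({
        "participant": participants if participants is not None else ["p0"] * n_tr,
    })
    return EpochArray(data=data, times=times, channels=channels, metadata=meta)


class TestContinuousFiltering:
    def _record(self, freq=None, fs=512.0, duration=120.0, dc=0.0):
        t = np.arange(0, duration, 1 / fs)
        sig = np.full_like(t, dc)
        if freq is not None:
            sig = sig + np.sin(2 * np.pi * freq * t)
        return ContinuousRecording(data=np.vstack([sig, sig]), fs=fs,
                                   channels=["Cz", "Pz"])

    @staticmethod
    def _amplitude(rec, freq):
        x = rec.data[0] - rec.data[0].mean()
        n = x.size
        spec = np.abs(np.fft.rfft(x * np.hanning(n)))
        freqs = np.fft.rfftfreq(n, 1 / rec.fs)
        return spec[np.argmin(np.abs(freqs - freq))]

    def test_output_rate_is_128(self):
        out = preprocess_continuous(self._record(freq=10.0))
        assert out.fs == 128.0

    def test_60hz_attenuated_20db(self):
        rec = self._record(freq=60.0)
        out = preprocess_continuous(rec)
        # compare against a 10 Hz reference processed identically
        ref = preprocess_continuous(self._record(freq=10.0))
        ratio = self._amplitude(out, 60.0) / self._amplitude(ref, 10.0)
        assert ratio < 10 ** (-20 / 20)

    def test_dc_removed(self):
        out = preprocess_continuous(self._record(dc=55.0))
        inner = out.data[0][4000:-4000]  # clear of filtfilt edge transients
        assert np.max(np.abs(inner)) < 0.5

    def test_passband_10hz_preserved(self):
        rec = self._record(freq=10.0)
        out = preprocess_continuous(rec)
        inner = out.data[0][4000:-4000]
        assert np.percentile(np.abs(inner), 99) == pytest.approx(1.0, rel=0.05)

    def test_low_sampling_rate_rejected(self):
        t = np.arange(0, 10, 1 / 128)
        rec = ContinuousRecording(data=np.zeros((1, t.size)), fs=128.0, channels=["Cz"])
        with pytest.raises(ValueError, match=">= 256"):
            preprocess_continuous(rec)

    def test_missing_montage_channels_rejected(self):
        rec = self._record(freq=10.0)
        with pytest.raises(ValueError, match="missing montage channels"):
            preprocess_continuous(rec, montage=["Cz", "Pz", "Oz"])


class TestEog:
    def _rec(self, af7, af8, afz, fpz):
        data = np.vstack([af7, af8, afz, fpz])
        return ContinuousRecording(data=data, fs=128.0,
                                   channels=["AF7", "AF8", "AFz", "Fpz"])

    def test_equal_channels_zero(self):
        x = np.random.default_rng(0).normal(size=100)
        h, v = derive_eog(self._rec(x, x, x, x))
        np.testing.assert_allclose(h, 0.0)
        np.testing.assert_allclose(v, 0.0)

    def test_constant_offset(self):
        x = np.zeros(50)
        h, _ = derive_eog(self._rec(x, x + 1.0, x, x))
        np.testing.assert_allclose(h, 1.0)

    def test_blink_template_recovered(self):
        blink = np.exp(-0.5 * ((np.arange(100) - 50) / 8.0) ** 2) * 80
        zero = np.zeros(100)
        _, v = derive_eog(self._rec(zero, zero, zero, blink))
        np.testing.assert_allclose(v, blink)

    def test_missing_channel_rejected(self):
        rec = ContinuousRecording(data=np.zeros((2, 10)), fs=128.0,
                                  channels=["AF7", "AF8"])
        with pytest.raises(ValueError):
            derive_eog(rec)


class TestRereference:
    def test_single_channel_zeroed(self):
        ep = make_epochs(np.random.default_rng(0).normal(size=(3, 1, 20)))
        out = rereference_common_average(ep)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_antisymmetric_pair_unchanged(self):
        base = np.random.default_rng(1).normal(size=(4, 1, 30))
        data = np.concatenate([base, -base], axis=1)
        out = rereference_common_average(make_epochs(data))
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_mean_zero_everywhere(self):
        ep = make_epochs(np.random.default_rng(2).normal(size=(5, 7, 40)))
        out = rereference_common_average(ep)
        assert np.max(np.abs(out.data.mean(axis=1))) < 1e-10

    def test_idempotent(self):
        ep = make_epochs(np.random.default_rng(3).normal(size=(5, 6, 40)))
        once = rereference_common_average(ep)
        twice = rereference_common_average(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)


class TestBaseline:
    def test_constant_becomes_zero(self):
        ep = make_epochs(np.full((4, 3, 385), 7.5))
        out = baseline_correct(ep)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_cross_trial_scalar(self):
        # two trials with baseline-window means 1 and 3 -> both shifted by -2
        times = default_times()
        ep = make_epochs(np.zeros((2, 1, times.size)))
        mask = ep.time_mask(-0.7, -0.2)
        ep.data[0, 0, :] = 1.0
        ep.data[1, 0, :] = 3.0
        out = baseline_correct(ep)
        np.testing.assert_allclose(out.data[0, 0, mask], -1.0)
        np.testing.assert_allclose(out.data[1, 0, mask], 1.0)

    def test_trialwise_differences_preserved(self):
        rng = np.random.default_rng(4)
        ep = make_epochs(rng.normal(size=(6, 2, 385)))
        mask = ep.time_mask(-0.7, -0.2)
        before = ep.data[:, :, mask].mean(axis=2)
        out = baseline_correct(ep)
        after = out.data[:, :, mask].mean(axis=2)
        np.testing.assert_allclose(after - after.mean(axis=0),
                                   before - before.mean(axis=0), atol=1e-10)

    def test_idempotent(self):
        ep = make_epochs(np.random.default_rng(5).normal(size=(4, 2, 385)))
        once = baseline_correct(ep)
        twice = baseline_correct(once)
        np.testing.assert_allclose(twice.data, once.data, atol=1e-10)

    def test_per_participant_scalars(self):
        data = np.zeros((4, 1, 385))
        data[:2] = 1.0   # participant a
        data[2:] = 5.0   # participant b
        ep = make_epochs(data, participants=["a", "a", "b", "b"])
        out = baseline_correct(ep)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_empty_window_rejected(self):
        ep = make_epochs(np.zeros((2, 1, 385)))
        with pytest.raises(ValueError):
            baseline_correct(ep, window=(5.0, 6.0))


class TestTrim:
    def _epochs_with_metric(self, n, participants=None):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(n, 2, 50))
        data[:, 0, 0] = np.arange(n)  # strictly increasing max amplitude
        return make_epochs(data, participants=participants)

    def test_100_trials_keep_98(self):
        out, dropped = trim_amplitude_percentiles(self._epochs_with_metric(100))
        assert out.n_trials == 98
        assert dropped["p0"] == 2

    def test_300_trials_keep_294(self):
        out, _ = trim_amplitude_percentiles(self._epochs_with_metric(300))
        assert out.n_trials == 294

    def test_ties_broken_by_trial_index(self):
        data = np.ones((100, 1, 10))
        ep = make_epochs(data)
        out, _ = trim_amplitude_percentiles(ep)
        assert out.n_trials == 98
        # stable sort: first and last by index are dropped
        kept = out.metadata.index
        assert len(kept) == 98


class TestArtifactSurrogate:
    def test_ptp_rejection(self):
        data = np.zeros((5, 2, 50))
        data[2, 0, 10] = 200.0
        ep = make_epochs(data)
        out, report = reject_artifact_epochs(ep, ptp_threshold=150.0)
        assert out.n_trials == 4
        assert report["n_dropped"] == 1

    def test_eog_rejection(self):
        ep = make_epochs(np.zeros((4, 2, 50)))
        eog = np.zeros((4, 50))
        eog[1] = 300.0
        out, report = reject_artifact_epochs(ep, eog=eog, eog_threshold=120.0)
        assert out.n_trials == 3
        assert report["n_eog"] == 1


class TestVarianceExclusion:
    def _cohort(self, n=6, n_ch=16, bad=None, bad_count=0, scale=10.0):
        rng = np.random.default_rng(7)
        out = {}
        for i in range(n):
            data = rng.normal(size=(20, n_ch, 64))
            if bad == i:
                data[:, :bad_count, :] *= scale
            out[f"p{i}"] = make_epochs(data, participants=[f"p{i}"] * 20)
        return out

    def test_homogeneous_cohort_empty(self):
        assert exclude_participants_by_variance(self._cohort()) == []

    def test_twelve_bad_channels_excluded(self):
        cohort = self._cohort(bad=2, bad_count=12)
        assert exclude_participants_by_variance(cohort) == ["p2"]

    def test_exactly_ten_bad_channels_retained(self):
        cohort = self._cohort(bad=2, bad_count=10)
        assert exclude_participants_by_variance(cohort) == []


class TestPipelineOrderAndAccounting:
    def test_retention_accounting_balances(self, small_epochs):
        out, logs = preprocess_epochs(small_epochs)
        for log in logs:
            assert log["n_input"] == (log["n_retained"] + log["n_artifact"]
                                      + log["n_trimmed"])
        total = sum(log["n_retained"] for log in logs)
        assert total == out.n_trials

    def test_output_is_rereferenced_and_baselined(self, small_epochs):
        out, _ = preprocess_epochs(small_epochs)
        assert np.max(np.abs(out.data.mean(axis=1))) < 1e-9
        # baseline scalars are computed before the percentile trim (canonical
        # order: reref -> artifact -> baseline -> trim), so the post-trim
        # baseline means are only near zero
        mask = out.time_mask(-0.7, -0.2)
        for pid, sub in out.metadata.groupby("participant"):
            rows = out.metadata.index.get_indexer(sub.index)
            means = out.data[rows][:, :, mask].mean(axis=(0, 2))
            np.testing.assert_allclose(means, 0.0, atol=0.1)


class TestEdf:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        data = rng.normal(0, 30.0, size=(4, 2560))
        rec = ContinuousRecording(data=data, fs=256.0,
                                  channels=["Cz", "Pz", "AFz", "Fpz"])
        path = tmp_path / "test.edf"
        write_edf(path, rec)
        back = read_edf(path)
        assert back.channels == rec.channels
        assert back.fs == 256.0
        # 16-bit quantization over the physical range
        np.testing.assert_allclose(back.data[:, :2560], data, atol=0.01)

    def test_epoch_extraction_from_edf(self, tmp_path):
        fs = 512.0
        t = np.arange(0, 60, 1 / fs)
        sig = np.sin(2 * np.pi * 10 * t) * 20
        rec = ContinuousRecording(data=np.vstack([sig, sig]), fs=fs,
                                  channels=["Cz", "Pz"])
        path = tmp_path / "cont.edf"
        write_edf(path, rec)
        proc = preprocess_continuous(read_edf(path))
        onsets = np.array([10.0, 20.0, 30.0])
        epochs = extract_epochs(proc, onsets)
        assert epochs.n_trials == 3
        assert epochs.data.shape[2] == default_times().size
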