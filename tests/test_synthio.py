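"""Generator contracts: determinism, SNR arithmetic, scenario structure,
ERP placement, and confidence-sample invariants."""

import numpy as np
import pytest

from hybridstd import synthio
from hybridstd.eegprep import STANDARD_60, build_partition


class TestEEGDataset:
    def test_same_seed_gives_bit_identical_epochs(self):
        a = synthio.gen_eeg_dataset(10, 10, seed=7)
        b = synthio.gen_eeg_dataset(10, 10, seed=7)
        for ea, eb in zip(a, b):
            np.testing.assert_array_equal(ea.data, eb.data)
            assert ea.label == eb.label

    def test_epoch_geometry_and_labels(self):
        eps = synthio.gen_eeg_dataset(3, 4, srate=100.0, seed=0)
        assert len(eps) == 7
        assert sum(e.label == "target" for e in eps) == 3
        for e in eps:
            assert e.data.shape == (60, 100)
            assert e.channel_labels == list(STANDARD_60)

    def test_snr_zero_removes_class_difference(self):
        eps = synthio.gen_eeg_dataset(40, 40, snr_scale=0.0, seed=1)
        tgt = np.stack([e.data for e in eps if e.label == "target"])
        non = np.stack([e.data for e in eps if e.label == "nontarget"])
        # grand averages are indistinguishable: the class difference stays
        # within sampling noise of the two means everywhere
        diff = tgt.mean(axis=0) - non.mean(axis=0)
        sem = np.sqrt(tgt.var(axis=0) / len(tgt) + non.var(axis=0) / len(non))
        assert np.abs(diff / sem).max() < 5.5

    def test_grand_average_peaks_in_temporal_region_window(self):
        # strong effect size: the averaged evoked response on temporal
        # channels must peak inside the 100-400 ms window
        eps = synthio.gen_eeg_dataset(60, 1, snr_scale=5.0, seed=2)
        part = build_partition(list(STANDARD_60))
        tgt = np.stack([e.data for e in eps if e.label == "target"])
        grand = tgt.mean(axis=0)[part.region_order["T"], :].mean(axis=0)
        peak_ms = np.argmax(np.abs(grand)) * 10.0  # 100 Hz -> 10 ms/sample
        assert 100.0 <= peak_ms <= 400.0

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            synthio.gen_eeg_dataset(0, 5, seed=0)
        with pytest.raises(ValueError):
            synthio.gen_eeg_dataset(5, 5, srate=-1.0, seed=0)


class TestTargetClips:
    def test_length_and_determinism(self):
        a = synthio.gen_target_clip(1, 3.0, seed=1)
        assert len(a) == 132300
        np.testing.assert_array_equal(a, synthio.gen_target_clip(1, 3.0, seed=1))

    def test_unit_rms(self):
        for t in range(1, 7):
            clip = synthio.gen_target_clip(t, 1.0, seed=3)
            assert np.sqrt((clip ** 2).mean()) == pytest.approx(1.0, rel=1e-9)

    def test_types_have_distinct_dominant_frequencies(self):
        peaks = []
        for t in (1, 2):
            clip = synthio.gen_target_clip(t, 1.0, seed=5)
            spec = np.abs(np.fft.rfft(clip))
            peaks.append(np.fft.rfftfreq(len(clip), 1 / 44100)[np.argmax(spec)])
        assert abs(peaks[0] - peaks[1]) > 20.0

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError):
            synthio.gen_target_clip(7, 1.0, seed=0)


class TestMixAtSnr:
    @pytest.mark.parametrize("snr_db", [0.0, -10.0, -13.63, 6.0])
    def test_snr_round_trip(self, snr_db):
        rng = np.random.default_rng(0)
        target = synthio.gen_target_clip(2, 1.0, seed=0)
        noise = synthio.gen_background_noise(1.0, seed=1)
        mixed = synthio.mix_at_snr(target, noise, snr_db)
        scaled = mixed - noise  # exact reconstruction of the component
        measured = 20 * np.log10(np.sqrt((scaled ** 2).mean())
                                 / np.sqrt((noise ** 2).mean()))
        assert measured == pytest.approx(snr_db, abs=0.01)

    def test_zero_snr_equalizes_rms(self):
        target = synthio.gen_target_clip(1, 1.0, seed=0)
        noise = 2.5 * synthio.gen_background_noise(1.0, seed=1)
        scaled = synthio.mix_at_snr(target, noise, 0.0) - noise
        assert np.sqrt((scaled ** 2).mean()) == pytest.approx(
            np.sqrt((noise ** 2).mean()), rel=1e-9)

    def test_silent_noise_rejected(self):
        with pytest.raises(ValueError):
            synthio.mix_at_snr(np.ones(100), np.zeros(100), 0.0)


class TestScenario:
    def test_default_scenario_structure(self):
        sc = synthio.gen_scenario(seed=3)
        assert len(sc.events) == 12          # 6 types x 2 SNRs
        assert len(sc.waveform) == int(300.0 * 44100)
        onsets = [e[0] for e in sc.events]
        assert onsets == sorted(onsets)
        for (o1, d1, *_), (o2, *_rest) in zip(sc.events, sc.events[1:]):
            assert o2 >= o1 + d1             # non-overlapping
        for o, d, t, s in sc.events:
            assert 0 <= o and o + d <= sc.duration_s
            assert t in range(1, 7) and s in (-10.0, 0.0)

    def test_seed_determinism(self):
        a = synthio.gen_scenario(seed=5)
        b = synthio.gen_scenario(seed=5)
        assert a.events == b.events
        np.testing.assert_array_equal(a.waveform, b.waveform)

    def test_event_local_snr_is_respected(self):
        cfg = synthio.ScenarioConfig(duration_s=120.0)
        sc = synthio.gen_scenario(cfg, seed=2)
        noise = synthio.gen_background_noise(120.0, seed=2 + 1)
        for onset, dur, _, snr in sc.events:
            i0 = int(round(onset * 44100))
            n = int(round(dur * 44100))
            comp = sc.waveform[i0:i0 + n] - noise[i0:i0 + n]
            measured = 20 * np.log10(
                np.sqrt((comp ** 2).mean())
                / np.sqrt((noise[i0:i0 + n] ** 2).mean()))
            assert measured == pytest.approx(snr, abs=0.2)

    def test_infeasible_duration_raises(self):
        with pytest.raises(RuntimeError):
            synthio.gen_scenario(synthio.ScenarioConfig(duration_s=30.0),
                                 seed=0)

    def test_wav_json_round_trip(self, tmp_path):
        sc = synthio.gen_scenario(
            synthio.ScenarioConfig(duration_s=60.0, types=(1, 2),
                                   snrs_db=(0.0,)), seed=4)
        stem = str(tmp_path / "scene")
        synthio.write_scenario(stem, sc)
        back = synthio.read_scenario(stem)
        assert back.events == sc.events
        assert len(back.waveform) == len(sc.waveform)
        # 16-bit quantisation error only
        peak = np.abs(sc.waveform).max()
        np.testing.assert_allclose(back.waveform * peak / 0.9, sc.waveform,
                                   atol=peak / 3000)


class TestConfidenceSamples:
    def test_empty_counts_give_empty_list(self):
        assert synthio.gen_confidence_samples(0, 0, 0, seed=0) == []

    def test_probabilities_sum_to_one_and_match_prediction(self):
        samples = synthio.gen_confidence_samples(50, 50, 50, seed=1)
        for s in samples:
            assert s.p1 + s.p2 == pytest.approx(1.0, abs=1e-12)
            assert s.predicted_label == (0 if s.p1 >= 0.5 else 1)

    def test_noise_band_mean_matches_configuration(self):
        # Monte-Carlo mean over several seeds
        means = []
        for seed in range(5):
            samples = synthio.gen_confidence_samples(1000, 0, 0, seed=seed)
            means.append(np.mean([s.p1 for s in samples]))
        assert np.mean(means) == pytest.approx(0.85, abs=0.05)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            synthio.gen_confidence_samples(-1, 0, 0, seed=0)


@pytest.mark.parametrize("seed", [0, 1])
def test_decoder_accuracy_monotone_in_effect_size(seed):
    """Validation accuracy of the decoder is non-decreasing in the
    generator's evoked-component scale (2-point tolerance, fixed seed)."""
    from hybridstd import trisdanet as tn
    accs = []
    for snr in (0.0, 0.5, 1.0, 2.0):
        data = synthio.gen_eeg_dataset(120, 120, snr_scale=snr, seed=seed)
        _, hist = tn.train(data, tn.TrainConfig(epochs=10, seed=seed))
        accs.append(hist["best_val_acc"])
    for lo, hi in zip(accs, accs[1:]):
        assert hi >= lo - 0.02, accs


def test_eeg_stream_determinism_and_shape():
    a = synthio.gen_eeg_stream(20.0, [5.0], 3.0, seed=9)
    b = synthio.gen_eeg_stream(20.0, [5.0], 3.0, seed=9)
    np.testing.assert_array_equal(a, b)
    assert a.shape == (60, 2000)


def test_eeg_dataset_file_round_trip(tmp_path):
    eps = synthio.gen_eeg_dataset(3, 3, seed=1)
    path = str(tmp_path / "ds.npz")
    synthio.save_eeg_dataset(path, eps)
    back = synthio.load_eeg_dataset(path)
    assert len(back) == 6
    for a, b in zip(eps, back):
        np.testing.assert_array_equal(a.data, b.data)
        assert a.label == b.label
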