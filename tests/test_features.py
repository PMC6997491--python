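"""Spectral stacks: channel derivation, STFT geometry, normalization, modes."""

import numpy as np
import pytest

from somnistage import (
    ChannelMeta,
    FeatureSet,
    PSGRecord,
    QCReport,
    assemble_sequence,
    build_sequence_dataset,
    compute_spectrogram,
    compute_stacks,
    derive_analysis_channels,
    stack_channels,
)
from somnistage.features import CHANNEL_ORDER, HOP, N_BINS, N_FRAMES, WINDOW_LENGTH, flatten_stack
from somnistage.record import ROLES


def _record(c3=10.0, c4=30.0, n_epochs=2, fs=100.0):
    spe = int(fs * 30)
    channels = {
        "C3": np.full(n_epochs * spe, c3),
        "C4": np.full(n_epochs * spe, c4),
        "EOG-L": np.full(n_epochs * spe, 1.0),
        "EOG-R": np.full(n_epochs * spe, 2.0),
        "EMG": np.full(n_epochs * spe, 3.0),
    }
    meta = {r: ChannelMeta(r, fs, 250.0) for r in ROLES}
    return PSGRecord(channels, meta)


class TestDeriveAnalysisChannels:
    def test_eeg_is_mean_of_c3_c4(self):
        out = derive_analysis_channels(_record(), QCReport())
        assert np.allclose(out["EEG"], 20.0)

    def test_dropped_eog_falls_back_to_survivor(self):
        qc = QCReport(dropped_channels={"EOG-L": 200.0})
        out = derive_analysis_channels(_record(), qc)
        assert np.allclose(out["EOG-L"], 2.0) and np.allclose(out["EOG-R"], 2.0)

    def test_dropped_c4_gives_eeg_equal_c3(self):
        qc = QCReport(dropped_channels={"C4": 200.0})
        out = derive_analysis_channels(_record(), qc)
        assert np.array_equal(out["EEG"], _record().channels["C3"])

    @pytest.mark.parametrize(
        "dropped,msg",
        [({"C3", "C4"}, "C3 and C4"), ({"EOG-L", "EOG-R"}, "EOG"), ({"EMG"}, "EMG")],
    )
    def test_unusable_records_rejected_with_reason(self, dropped, msg):
        qc = QCReport(dropped_channels={r: 200.0 for r in dropped})
        with pytest.raises(ValueError, match=msg):
            derive_analysis_channels(_record(), qc)


class TestComputeSpectrogram:
    def test_geometry_is_32_frames_by_32_bins(self, rng):
        assert compute_spectrogram(rng.normal(size=3000)).shape == (32, 32)
        assert (3000 - WINDOW_LENGTH) // HOP + 1 == N_FRAMES

    def test_all_zero_epoch_maps_to_all_zero_spectrum(self):
        assert np.array_equal(compute_spectrogram(np.zeros(3000)), np.zeros((32, 32)))

    def test_pure_10hz_tone_peaks_at_bin_13_every_frame(self):
        t = np.arange(3000) / 100.0
        s = compute_spectrogram(np.sin(2 * np.pi * 10 * t))
        # bin = round(10 / (100/128)) = 13; normalization puts 1.0 there
        assert np.all(np.argmax(s, axis=1) == 13)
        assert np.all(s.max(axis=1) == 1.0)

    def test_matches_direct_dft_of_one_windowed_frame(self, rng):
        """Oracle: hand-evaluated DFT of the first Hamming-windowed frame."""
        x = rng.normal(size=3000)
        frame = x[:WINDOW_LENGTH] * np.hamming(WINDOW_LENGTH)
        k = np.arange(WINDOW_LENGTH)
        mags = np.array(
            [np.abs(np.sum(frame * np.exp(-2j * np.pi * f * k / WINDOW_LENGTH)))
             for f in range(N_BINS)]
        )
        expected = (mags - mags.min()) / (mags.max() - mags.min())
        np.testing.assert_allclose(compute_spectrogram(x)[0], expected, atol=1e-9)

    def test_normalization_attains_0_and_1_per_frame(self, rng):
        s = compute_spectrogram(rng.normal(size=3000))
        assert np.allclose(s.min(axis=1), 0.0) and np.allclose(s.max(axis=1), 1.0)

    @pytest.mark.parametrize("freq", [3.0, 7.5, 12.0, 18.0, 23.0])
    def test_energy_locality_for_pure_tones(self, freq):
        t = np.arange(3000) / 100.0
        s = compute_spectrogram(np.sin(2 * np.pi * freq * t))
        expected_bin = round(freq * 128 / 100)
        assert np.sum(np.argmax(s, axis=1) == expected_bin) >= 30

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="3000"):
            compute_spectrogram(np.zeros(2999))


class TestStackAndFlatten:
    def test_stack_recovers_inputs_in_channel_order(self):
        spectra = {name: np.full((32, 32), i / 10) for i, name in enumerate(CHANNEL_ORDER)}
        stack = stack_channels(spectra)
        assert stack.shape == (32, 32, 4)
        for i, name in enumerate(CHANNEL_ORDER):
            assert np.allclose(stack[:, :, i], i / 10)

    def test_flatten_column_index_is_32_channel_plus_bin(self, rng):
        stack = rng.random((32, 32, 4))
        flat = flatten_stack(stack)
        assert flat.shape == (32, 128)
        assert flat[5, 32 * 2 + 7] == stack[5, 7, 2]

    def test_shape_mismatch_rejected(self):
        spectra = {name: np.zeros((32, 32)) for name in CHANNEL_ORDER}
        spectra["EMG"] = np.zeros((31, 32))
        with pytest.raises(ValueError, match="EMG"):
            stack_channels(spectra)


def _feature_set(n_epochs=6, missing=()):
    stacks, kept = [], []
    for k in range(n_epochs):
        if k in missing:
            continue
        stacks.append(np.full((32, 32, 4), (k + 1) / 10.0))
        kept.append(k)
    mask = np.array([k not in missing for k in range(n_epochs)])
    return FeatureSet(np.array(stacks), np.array(kept), mask, labels=np.array(kept) % 5)


class TestAssembleSequence:
    def test_mode1_is_the_reshaped_target_stack(self):
        fs = _feature_set()
        seq = assemble_sequence(fs, 3, mode=1)
        assert seq.shape == (32, 128)
        assert np.allclose(seq, 0.4)

    def test_mode3_final_rows_are_target_epoch(self):
        fs = _feature_set()
        seq = assemble_sequence(fs, 4, mode=3)
        assert seq.shape == (96, 128)
        assert np.allclose(seq[64:], 0.5)
        assert np.allclose(seq[:32], 0.3)

    def test_mode2_concatenation_matches_manual_fixture(self):
        stacks = np.stack([np.zeros((32, 32, 4)), np.full((32, 32, 4), 0.7)])
        fs = FeatureSet(stacks, np.array([0, 1]), np.ones(2, bool), np.array([0, 1]))
        seq = assemble_sequence(fs, 1, mode=2)
        assert np.all(seq[:32] == 0.0) and np.all(seq[32:] == 0.7)

    def test_insufficient_history_returns_none(self):
        fs = _feature_set()
        assert assemble_sequence(fs, 1, mode=3) is None

    def test_qc_gap_breaks_consecutiveness(self):
        fs = _feature_set(missing={2})
        assert assemble_sequence(fs, 3, mode=2) is None
        assert assemble_sequence(fs, 4, mode=2) is not None

    def test_mode_nesting_property(self):
        """The mode-i input's last 32(i-1) rows equal the mode-(i-1) input."""
        fs = _feature_set(8)
        for mode in (2, 3, 4):
            big = assemble_sequence(fs, 6, mode=mode)
            small = assemble_sequence(fs, 6, mode=mode - 1)
            assert np.array_equal(big[32:], small) or np.array_equal(
                big[-small.shape[0]:], small
            )


class TestDatasetBuild:
    def test_labels_are_target_epoch_stages(self):
        fs = _feature_set(6)
        X, y, idx = build_sequence_dataset(fs, mode=3)
        assert X.shape == (4, 96, 128)
        assert idx.tolist() == [2, 3, 4, 5]
        assert y.tolist() == [2, 3, 4, 0]

    def test_roundtrip_save_load(self, tmp_path):
        fs = _feature_set(6)
        fs.save(tmp_path / "f.npz")
        back = FeatureSet.load(tmp_path / "f.npz")
        assert np.array_equal(back.stacks, fs.stacks)
        assert np.array_equal(back.labels, fs.labels)
        assert np.array_equal(back.qc_mask, fs.qc_mask)


def test_compute_stacks_values_in_unit_interval(short_night):
    from somnistage import run_qc

    filtered, qc = run_qc(short_night)
    feats = compute_stacks(filtered, qc)
    assert feats.stacks.shape == (20, 32, 32, 4)
    assert feats.stacks.min() >= 0.0 and feats.stacks.max() <= 1.0
    assert np.array_equal(feats.labels, short_night.hypnogram)
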