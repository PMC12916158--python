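"""The synthetic AEP generator: determinism, effect recoverability, invariants."""

import numpy as np
import pytest

from eegmtl import ParameterError, SynthConfig, generate_dataset, subject_signature
from eegmtl.records import DEVICES, LANGUAGES
from eegmtl.synthetic import generate_trial


class TestSubjectSignature:
    def test_deterministic_for_same_seed_and_index(self):
        cfg = SynthConfig(n_subjects=5, seed=3)
        a = subject_signature(2, cfg)
        b = subject_signature(2, cfg)
        assert a.peak_hz == b.peak_hz
        np.testing.assert_array_equal(a.mixing, b.mixing)
        np.testing.assert_array_equal(a.template_jitter, b.template_jitter)

    def test_all_pairs_of_mixing_vectors_differ(self):
        cfg = SynthConfig(n_subjects=8, seed=0)
        sigs = [subject_signature(i, cfg) for i in range(8)]
        for i in range(8):
            for j in range(i + 1, 8):
                cos = float(sigs[i].mixing @ sigs[j].mixing)
                assert cos < 1.0 - 1e-6

    def test_peak_frequencies_stay_in_alpha_band(self):
        cfg = SynthConfig(n_subjects=2, seed=1)
        for i in (0, 1):
            assert 8.0 <= subject_signature(i, cfg).peak_hz <= 13.0

    def test_out_of_range_index_rejected(self):
        cfg = SynthConfig(n_subjects=4)
        with pytest.raises(ParameterError):
            subject_signature(4, cfg)
        with pytest.raises(ParameterError):
            subject_signature(-1, cfg)


class TestGenerateDataset:
    def test_grid_size_and_unique_trial_ids(self, tiny_synth_config):
        recs = generate_dataset(tiny_synth_config)
        c = tiny_synth_config
        assert len(recs) == c.n_subjects * 2 * 2 * c.n_trials_per_cell
        assert len({r.trial_id for r in recs}) == len(recs)
        langs = {r.language for r in recs}
        devs = {r.device for r in recs}
        assert langs == set(LANGUAGES) and devs == set(DEVICES)

    def test_bit_identical_across_calls(self, tiny_synth_config):
        a = generate_dataset(tiny_synth_config)
        b = generate_dataset(tiny_synth_config)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_trial_independent_of_generation_order(self, tiny_synth_config):
        direct = generate_trial(tiny_synth_config, 1, "native", "bone", 1)
        from_grid = [
            r
            for r in generate_dataset(tiny_synth_config)
            if r.trial_id == direct.trial_id
        ][0]
        np.testing.assert_array_equal(direct.samples, from_grid.samples)

    def test_language_effect_recoverable_by_thresholding(self):
        """With tiny noise and a large late-component effect, the mean late
        amplitude separates native from non-native trials perfectly."""
        cfg = SynthConfig(
            n_subjects=4,
            n_trials_per_cell=4,
            trial_length=1000,
            noise_sd=1e-3,
            subject_effect=0.0,
            device_effect=0.0,
            language_effect=2.0,
            seed=5,
        )
        recs = generate_dataset(cfg)
        fs = cfg.sampling_rate

        def late_energy(rec):
            vals = []
            onset = 0.0
            while (onset + 0.55) * fs < rec.n_samples:
                a, b = int((onset + 0.25) * fs), int((onset + 0.55) * fs)
                vals.append(np.mean(np.abs(rec.samples[:, a:b])))
                onset += cfg.stimulus_interval_s
            return np.mean(vals)

        native = [late_energy(r) for r in recs if r.language == "native"]
        other = [late_energy(r) for r in recs if r.language == "non_native"]
        threshold = (np.mean(native) + np.mean(other)) / 2
        assert all(v > threshold for v in native)
        assert all(v < threshold for v in other)

    def test_zero_effects_make_labels_uninformative(self):
        """With all effects at 0 the per-condition means coincide: the signal
        distribution is identical across labels by construction."""
        cfg = SynthConfig(
            n_subjects=3,
            n_trials_per_cell=2,
            trial_length=800,
            subject_effect=0.0,
            language_effect=0.0,
            device_effect=0.0,
            seed=2,
        )
        recs = generate_dataset(cfg)
        grand = np.mean([r.samples.mean() for r in recs])
        for lang in LANGUAGES:
            m = np.mean([r.samples.mean() for r in recs if r.language == lang])
            assert m == pytest.approx(grand, abs=0.05)

    def test_subject_identity_recoverable_from_spectra(self):
        """Nearest-class-mean on trial spectra identifies subjects when the
        subject effect is strong and noise small."""
        cfg = SynthConfig(
            n_subjects=6,
            n_trials_per_cell=2,
            trial_length=1000,
            subject_effect=2.0,
            noise_sd=0.1,
            seed=11,
        )
        recs = generate_dataset(cfg)

        def spectrum(rec):
            return np.abs(np.fft.rfft(rec.samples, axis=-1)).ravel()

        feats = np.array([spectrum(r) for r in recs])
        labels = np.array([r.subject_id for r in recs])
        correct = 0
        for i in range(len(recs)):  # leave-one-out nearest class mean
            mask = np.arange(len(recs)) != i
            classes = {}
            for s in np.unique(labels[mask]):
                classes[s] = feats[mask][labels[mask] == s].mean(axis=0)
            pred = min(classes, key=lambda s: np.linalg.norm(feats[i] - classes[s]))
            correct += pred == labels[i]
        assert correct / len(recs) > 0.95

    def test_pink_noise_mode_has_low_frequency_dominance(self):
        cfg = SynthConfig(
            n_subjects=2,
            n_trials_per_cell=1,
            trial_length=2000,
            subject_effect=0.0,
            language_effect=0.0,
            device_effect=0.0,
            noise_sd=1.0,
            noise_color="pink",
            seed=0,
        )
        rec = generate_dataset(cfg)[0]
        # compare band power below/above 20 Hz, excluding evoked band overlap
        spec = np.abs(np.fft.rfft(rec.samples[0])) ** 2
        f = np.fft.rfftfreq(rec.n_samples, 1 / cfg.sampling_rate)
        low = spec[(f > 1) & (f < 10)].mean()
        high = spec[(f > 50) & (f < 90)].mean()
        assert low > 5 * high

    def test_invalid_configs_rejected(self):
        with pytest.raises(ParameterError):
            SynthConfig(n_subjects=1)
        with pytest.raises(ParameterError):
            SynthConfig(noise_sd=0.0)
        with pytest.raises(ParameterError):
            SynthConfig(language_effect=-1.0)
        with pytest.raises(ParameterError):
            SynthConfig(noise_color="blue")


def test_generated_recordings_pass_through_pipeline(tmp_path, tiny_synth_config):
    """Written datasets read back identically through the io layer."""
    from eegmtl import load_dataset, write_dataset

    manifest = write_dataset(tiny_synth_config, tmp_path / "data")
    back = load_dataset(manifest, tiny_synth_config.channels)
    orig = generate_dataset(tiny_synth_config)
    assert len(back) == len(orig)
    by_id = {r.trial_id: r for r in back}
    for r in orig:
        np.testing.assert_array_equal(by_id[r.trial_id].samples, r.samples)
        assert by_id[r.trial_id].labels == r.labels


def test_language_accuracy_monotone_in_effect_size():
    """A fixed threshold pipeline's language accuracy is non-decreasing in
    the language effect (checked at 3 effect levels x 3 seeds, ties allowed)."""
    from eegmtl.records import LANGUAGES

    def late_energy(rec, cfg):
        fs = cfg.sampling_rate
        vals, onset = [], 0.0
        while (onset + 0.55) * fs < rec.n_samples:
            a, b = int((onset + 0.25) * fs), int((onset + 0.55) * fs)
            vals.append(np.mean(np.abs(rec.samples[:, a:b])))
            onset += cfg.stimulus_interval_s
        return np.mean(vals)

    def pipeline_accuracy(effect, seed):
        cfg = SynthConfig(
            n_subjects=4, n_trials_per_cell=6, trial_length=1000,
            language_effect=effect, seed=seed,
        )
        recs = generate_dataset(cfg)
        feats = np.array([late_energy(r, cfg) for r in recs])
        y = np.array([r.language == "native" for r in recs])
        train = np.arange(len(recs)) % 2 == 0   # alternate trials
        thr = (feats[train & y].mean() + feats[train & ~y].mean()) / 2
        test = ~train
        return np.mean((feats[test] > thr) == y[test])

    for seed in (0, 1, 2):
        accs = [pipeline_accuracy(e, seed) for e in (0.1, 0.6, 1.5)]
        assert accs[0] <= accs[1] + 1e-9
        assert accs[1] <= accs[2] + 1e-9
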