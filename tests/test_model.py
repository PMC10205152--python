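"""CV scheme, Fisher z, delta-z, visual TRF combination, nested CV."""

import numpy as np
import pytest
from scipy.optimize import brentq

import speechtrf as st
from speechtrf.errors import ConfigError, DataError
from speechtrf.model import PredictionAccuracy


class TestCVScheme:
    def test_fifteen_trials_give_folds_of_three(self):
        scheme = st.make_cv_scheme(15, seed=0)
        assert sorted(len(f) for f in scheme.folds) == [3] * 5

    def test_five_trials_give_singletons(self):
        scheme = st.make_cv_scheme(5, seed=1)
        assert sorted(len(f) for f in scheme.folds) == [1] * 5

    def test_folds_partition_trials(self):
        scheme = st.make_cv_scheme(17, seed=2)
        flat = sorted(t for f in scheme.folds for t in f)
        assert flat == list(range(17))

    def test_rotations_never_touch_the_test_fold(self):
        scheme = st.make_cv_scheme(15, seed=3)
        for fold in range(5):
            test = set(scheme.folds[fold])
            rotations = scheme.rotations(fold)
            assert len(rotations) == 4
            vals = []
            for train, val in rotations:
                assert not (set(train) | set(val)) & test
                assert not set(train) & set(val)
                vals.append(tuple(val))
            # each remaining fold serves as validation exactly once
            assert sorted(vals) == sorted(
                tuple(scheme.folds[i]) for i in range(5) if i != fold
            )

    def test_too_few_trials_rejected(self):
        with pytest.raises(ConfigError):
            st.make_cv_scheme(4, seed=0)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert st.fisher_z(0.0) == 0.0

    def test_odd_symmetry(self):
        r = np.linspace(-0.95, 0.95, 11)
        assert np.allclose(st.fisher_z(-r), -st.fisher_z(r), atol=1e-14)

    def test_half_matches_numerical_tanh_inverse(self):
        z_oracle = brentq(lambda z: np.tanh(z) - 0.5, 0, 5, xtol=1e-12)
        assert st.fisher_z(0.5) == pytest.approx(z_oracle, abs=1e-9)

    def test_domain_error_and_cap(self):
        with pytest.raises(DataError):
            st.fisher_z(1.5)
        with pytest.warns(UserWarning):
            assert st.fisher_z(1.0, cap=8.0) == 8.0
        with pytest.warns(UserWarning):
            assert st.fisher_z(-1.0, cap=8.0) == -8.0


class TestDeltaZ:
    def _acc(self, z, label=""):
        z = np.asarray(z, dtype=float)
        return PredictionAccuracy(
            r=np.tanh(z), z=z, channel_names=("c0", "c1"), label=label
        )

    def test_identical_models_give_zero(self):
        a = self._acc([0.2, 0.4])
        assert np.allclose(st.delta_z(a, a), 0.0)

    def test_antisymmetry(self):
        a, b = self._acc([0.5, 0.1]), self._acc([0.2, 0.3])
        assert np.allclose(st.delta_z(a, b), -st.delta_z(b, a))

    def test_channel_mismatch_rejected(self):
        a = self._acc([0.1, 0.2])
        b = PredictionAccuracy(
            r=np.zeros(2), z=np.zeros(2), channel_names=("x", "y")
        )
        with pytest.raises(DataError):
            st.delta_z(a, b)


class TestCombineVisualTRF:
    def test_axis_extends_to_1000_ms_for_500_ms_stimulus(self, basis100):
        onset = np.zeros(basis100.n_lags)
        offset = np.zeros(basis100.n_lags)
        _, lags = st.combine_visual_trf(
            onset, offset, basis100.lag_samples, fs=100.0, stimulus_duration=0.5
        )
        assert lags[0] == -10 and lags[-1] == 100  # -100 .. 1000 ms
        assert lags[-1] / 100.0 == pytest.approx(1.0)

    def test_zero_offset_yields_padded_onset(self, basis100):
        rng = np.random.default_rng(0)
        onset = rng.standard_normal(basis100.n_lags)
        combined, lags = st.combine_visual_trf(
            onset, np.zeros_like(onset), basis100.lag_samples, fs=100.0
        )
        assert np.array_equal(combined[: onset.size], onset)
        assert np.all(combined[onset.size :] == 0)

    def test_overlap_is_elementwise_sum(self, basis100):
        rng = np.random.default_rng(1)
        onset = rng.standard_normal(basis100.n_lags)
        offset = rng.standard_normal(basis100.n_lags)
        combined, lags = st.combine_visual_trf(
            onset, offset, basis100.lag_samples, fs=100.0, stimulus_duration=0.5
        )
        shift = 50
        for i, lag in enumerate(lags):
            expected = 0.0
            if i < onset.size:
                expected += onset[i]
            if 0 <= i - shift < offset.size:
                expected += offset[i - shift]
            assert combined[i] == pytest.approx(expected, abs=1e-14)

    def test_shape_mismatch_rejected(self, basis100):
        with pytest.raises(DataError):
            st.combine_visual_trf(
                np.zeros(10), np.zeros(11), basis100.lag_samples, fs=100.0
            )


class TestNestedCV:
    def _simulated(self, basis, rng, n_channels=2, T=6000, n_trials=6):
        bounds = [
            (i * (T // n_trials), (i + 1) * (T // n_trials)) for i in range(n_trials)
        ]
        x = np.zeros((1, T))
        x[0, rng.choice(T, 240, replace=False)] = 1.0
        t = basis.lags
        kernel = np.exp(-0.5 * ((t - 0.15) / 0.05) ** 2)[None, :]
        eeg = st.synthesize_eeg(
            {"p": x}, {"p": kernel}, basis.lag_samples, 100.0,
            noise_sigma=0.3, trial_bounds=bounds, seed=11, n_channels=n_channels,
        )
        return eeg, x, bounds

    def test_fold_prediction_equals_average_of_model_predictions(self, basis100):
        """Predicting with averaged coefficients is identical (by linearity)
        to averaging the four rotation models' predictions."""
        rng = np.random.default_rng(5)
        eeg, x, bounds = self._simulated(basis100, rng)
        scheme = st.make_cv_scheme(len(bounds), seed=0)
        model = st.BoostingTRF(
            eeg.data, {"p": x}, fs=100, trial_bounds=bounds, basis=basis100,
            scheme=scheme,
        )
        res = model.fit()
        fold = 0
        test_trials = list(scheme.folds[fold])
        fold_fits = res.fits[:4]
        avg_of_preds = np.mean([f.predict(test_trials) for f in fold_fits], axis=0)
        te = model._samples(test_trials)
        assert np.allclose(res.predicted[:, te], avg_of_preds, atol=1e-10)

    def test_signal_yields_positive_z(self, basis100):
        rng = np.random.default_rng(6)
        eeg, x, bounds = self._simulated(basis100, rng)
        res = st.BoostingTRF(
            eeg.data, {"p": x}, fs=100, trial_bounds=bounds, basis=basis100,
            scheme=st.make_cv_scheme(len(bounds), seed=1),
        ).fit()
        assert np.all(res.accuracy.z > 0)
        # delta z of the only signal predictor vs itself is zero
        assert np.allclose(st.delta_z(res.accuracy, res.accuracy), 0.0)

    def test_summary_mentions_structure(self, basis100):
        rng = np.random.default_rng(7)
        eeg, x, bounds = self._simulated(basis100, rng)
        res = st.BoostingTRF(
            eeg.data, {"p": x}, fs=100, trial_bounds=bounds, basis=basis100,
            scheme=st.make_cv_scheme(len(bounds), seed=1),
        ).fit()
        text = res.summary()
        assert "models fitted: 20" in text
        assert "-100..500 ms" in text
        assert "p" in res.kernels

    def test_scheme_trial_count_mismatch_rejected(self, basis100):
        rng = np.random.default_rng(8)
        eeg, x, bounds = self._simulated(basis100, rng)
        with pytest.raises(ConfigError):
            st.BoostingTRF(
                eeg.data, {"p": x}, fs=100, trial_bounds=bounds, basis=basis100,
                scheme=st.make_cv_scheme(7, seed=0),
            )
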