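"""Decoder families: softmax and both loss functions, CNN builders,
classical baselines, fit/predict contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_
from hypothesis.extra import numpy as hnp

from eegspeech import decoders as dec
from eegspeech import nn


class TestSoftmax:
    def test_equal_logits_give_uniform(self):
        p = dec.softmax(np.zeros(6))
        assert np.allclose(p, 1 / 6)

    @settings(deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            np.float64, (3, 6),
            elements=st_.floats(-50, 50, allow_nan=False),
        )
    )
    def test_rows_sum_to_one(self, logits):
        p = dec.softmax(logits)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p >= 0)

    def test_matches_extended_precision_evaluation(self):
        """Direct evaluation in extended precision agrees to < 1e-12."""
        logits = np.array([10.0, 0, 0, 0, 0, 0])
        p1 = dec.softmax(logits)[0]
        ld = np.longdouble
        num = np.exp(ld(10.0))
        oracle = num / (num + 5 * np.exp(ld(0.0)))
        assert abs(p1 - float(oracle)) < 1e-12

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            dec.softmax(np.array([np.nan, 0.0]))


class TestLosses:
    def test_perfect_one_hot_prediction_is_zero(self):
        probs = np.eye(4)[[0, 1, 3]]
        y = np.array([0, 1, 3])
        assert dec.nll_loss(probs, y) == pytest.approx(0.0, abs=1e-12)
        assert dec.ce_loss(probs, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_six_class_nll_is_ln6(self):
        probs = np.full((10, 6), 1 / 6)
        y = np.zeros(10, dtype=int)
        assert dec.nll_loss(probs, y) == pytest.approx(np.log(6), abs=1e-12)

    def test_two_trial_hand_computed_nll(self):
        probs = np.array([[0.5, 0.5, 0.0], [0.25, 0.5, 0.25]])
        y = np.array([0, 0])
        expected = -(np.log(0.5) + np.log(0.25)) / 2
        assert dec.nll_loss(probs, y) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 5, 6])
    def test_uniform_ce_matches_direct_formula(self, k):
        probs = np.full((4, k), 1 / k)
        y = np.arange(4) % k
        # one true class at 1/k, k-1 others at 1/k each
        expected = -(np.log(1 / k) + (k - 1) * np.log(1 - 1 / k))
        assert dec.ce_loss(probs, y) == pytest.approx(expected, abs=1e-12)

    def test_ce_dominates_true_class_nll_term(self):
        rng = np.random.default_rng(0)
        probs = dec.softmax(rng.standard_normal((20, 6)))
        y = rng.integers(0, 6, 20)
        assert dec.ce_loss(probs, y) >= dec.nll_loss(probs, y) - 1e-12

    def test_zero_probability_clamped_with_warning(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        y = np.array([1, 1])
        with pytest.warns(UserWarning, match="clamped"):
            loss = dec.nll_loss(probs, y)
        assert np.isfinite(loss)


class TestShrinkageLDA:
    def test_matches_sklearn_at_fixed_shrinkage(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(0)
        x = rng.standard_normal((90, 8))
        y = rng.integers(0, 3, 90)
        x[y == 1] += 1.0
        for s in (0.1, 0.5, 0.9):
            ours = dec.ShrinkageLDA(shrinkage=s).fit(x, y)
            ref = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=s).fit(x, y)
            assert np.allclose(ours.coef_, ref.coef_, atol=1e-8)
            assert np.allclose(ours.intercept_, ref.intercept_, atol=1e-8)

    def test_auto_shrinkage_predictions_agree_with_sklearn(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(1)
        x = rng.standard_normal((120, 10))
        y = rng.integers(0, 4, 120)
        x[y == 1] += 0.8
        x[y == 2, :3] -= 0.8
        ours = dec.ShrinkageLDA().fit(x, y)
        ref = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto").fit(x, y)
        xt = rng.standard_normal((300, 10))
        assert np.mean(ours.predict(xt) == ref.predict(xt)) > 0.9


class TestBuilders:
    def test_deep_cnn_has_four_convolutional_blocks(self):
        spec = dec.DecoderSpec(family="deep_cnn", n_classes=6)
        net = dec.build_cnn(spec, 0)
        pools = [l for l in net.layers if isinstance(l, nn.PoolTime)]
        assert len(pools) == 4  # one initial block + three identical blocks
        convs = [l for l in net.layers if isinstance(l, nn.Conv2d)]
        assert len(convs) == 5  # temporal + spatial, then one per block

    @pytest.mark.parametrize("family", dec.CNN_FAMILIES)
    def test_dropout_probability_is_half_everywhere(self, family):
        net = dec.build_cnn(dec.DecoderSpec(family=family, n_classes=6), 0)
        drops = [l for l in net.layers if isinstance(l, nn.Dropout)]
        assert len(drops) >= 1
        assert all(d.p == 0.5 for d in drops)

    def test_parameter_counts_ordered(self):
        counts = {
            f: dec.build_cnn(dec.DecoderSpec(family=f, n_classes=6), 0)
            .n_parameters()
            for f in dec.CNN_FAMILIES
        }
        assert counts["eegnet"] < counts["shallow_cnn"] < counts["deep_cnn"]

    def test_unknown_activation_lists_valid_values(self):
        spec = dec.DecoderSpec(
            family="eegnet", hp={"activation": "gelu"}, n_classes=6
        )
        with pytest.raises(ValueError, match="leaky_relu"):
            dec.build_cnn(spec, 0)

    def test_unknown_hp_key_rejected(self):
        with pytest.raises(ValueError, match="schema"):
            dec.DecoderSpec(family="svm", hp={"lr": 0.1})

    def test_grid_schema_closure(self):
        """Every value of every declared grid dimension is constructible."""
        for family in dec.CNN_FAMILIES:
            grid = dec.DEFAULT_GRIDS[family]
            for act in grid["activation"]:
                nn.Activation(act)
            for loss in grid["loss"]:
                assert loss in nn.LOSSES
            dec.build_cnn(
                dec.DecoderSpec(
                    family=family,
                    hp={"activation": grid["activation"][-1]},
                    n_classes=6,
                ),
                0,
            )
        for family in ("svm", "rdf", "rlda"):
            for name, values in dec.DEFAULT_GRIDS[family].items():
                for v in values:
                    dec.DecoderSpec(family=family, hp={name: v})


class TestFitPredict:
    def test_linear_svm_separable_toy(self):
        x = np.array([[0.0, 0], [0, 1], [4, 0], [4, 1]] * 3)
        y = np.array([0, 0, 1, 1] * 3)
        spec = dec.DecoderSpec(
            family="svm", hp={"kernel": "linear", "C": 1.0}, n_classes=2
        )
        trained = dec.fit(spec, x, y, seed=0)
        assert np.all(dec.predict(trained, x).labels_hat == y)

    def test_random_forest_seeded_determinism(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((60, 30))
        y = rng.integers(0, 3, 60)
        spec = dec.DecoderSpec(family="rdf", hp={"trees": 50}, n_classes=3)
        a = dec.predict(dec.fit(spec, x, y, 5), x).probs
        b = dec.predict(dec.fit(spec, x, y, 5), x).probs
        assert np.array_equal(a, b)

    def test_shallow_cnn_learns_band_power_signal(self, twoclass_128):
        """Spec'd training regime on strongly separable two-class data:
        held-out accuracy above the 3-SD binomial chance band."""
        trials, y, train, test = twoclass_128
        spec = dec.DecoderSpec(
            family="shallow_cnn",
            hp={"lr": 0.01, "epochs": 20, "activation": "square", "loss": "nll"},
            n_classes=2,
            input_shape=(6, 512),
        )
        trained = dec.fit(spec, trials.data[train], y[train], seed=0)
        acc = np.mean(
            dec.predict(trained, trials.data[test]).labels_hat == y[test]
        )
        n = len(test)
        assert acc > 0.5 + 3 * np.sqrt(0.25 / n)

    @pytest.mark.parametrize("family,epochs", [("eegnet", 8), ("deep_cnn", 15)])
    def test_other_cnns_learn_band_power_signal(self, twoclass_128, family, epochs):
        trials, y, train, test = twoclass_128
        spec = dec.DecoderSpec(
            family=family,
            hp={"lr": 0.01, "epochs": epochs, "activation": "elu", "loss": "nll"},
            n_classes=2,
            input_shape=(6, 512),
        )
        trained = dec.fit(spec, trials.data[train], y[train], seed=0)
        acc = np.mean(
            dec.predict(trained, trials.data[test]).labels_hat == y[test]
        )
        assert acc > 0.5 + 3 * np.sqrt(0.25 / len(test))

    def test_cnn_fit_seeded_determinism(self, twoclass_128):
        trials, y, train, test = twoclass_128
        spec = dec.DecoderSpec(
            family="eegnet",
            hp={"lr": 0.01, "epochs": 2, "activation": "elu", "loss": "ce"},
            n_classes=2,
            input_shape=(6, 512),
        )
        sub = train[:64]
        a = dec.fit(spec, trials.data[sub], y[sub], seed=3)
        b = dec.fit(spec, trials.data[sub], y[sub], seed=3)
        pa = dec.predict(a, trials.data[test]).probs
        pb = dec.predict(b, trials.data[test]).probs
        assert np.array_equal(pa, pb)

    def test_non_finite_loss_raises_divergence_error(self):
        """A non-finite forward pass is reported as divergence, not as
        a silent bad fit (the grid search layer maps it to accuracy 0)."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((64, 6, 512))
        x[0, 0, 0] = np.inf
        y = rng.integers(0, 2, 64)
        spec = dec.DecoderSpec(
            family="shallow_cnn",
            hp={"lr": 0.01, "epochs": 2, "activation": "square", "loss": "nll"},
            n_classes=2,
            input_shape=(6, 512),
        )
        with pytest.raises(nn.DivergenceError):
            dec.fit(spec, x, y, seed=0)

    def test_rlda_pipeline_fits_raw_trials(self, signal_trialset_128):
        trials = signal_trialset_128
        y = trials.encoded_labels()
        spec = dec.DecoderSpec(
            family="rlda", hp={"nsf": 2, "miql": 6, "nof": 8}, n_classes=6
        )
        trained = dec.fit(spec, trials.data, y, seed=0)
        pb = dec.predict(trained, trials.data)
        assert pb.probs.shape == (trials.n_trials, 6)
        # strong band-power classes: training accuracy far above chance
        assert np.mean(pb.labels_hat == y) > 0.5

    def test_prediction_rows_sum_to_one_and_duplicates_agree(
        self, signal_trialset_128
    ):
        trials = signal_trialset_128
        y = trials.encoded_labels()
        spec = dec.DecoderSpec(family="rlda", n_classes=6)
        trained = dec.fit(spec, trials.data, y, seed=0)
        batch = np.concatenate([trials.data[:3], trials.data[:3]])
        pb = dec.predict(trained, batch)
        assert np.allclose(pb.probs.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(pb.probs[:3], pb.probs[3:])
        assert np.array_equal(pb.labels_hat, pb.probs.argmax(axis=1))

    def test_shape_mismatch_rejected(self, twoclass_128):
        trials, y, train, _ = twoclass_128
        rwe = np.random.default_rng(0).random((40, 30))
        spec = dec.DecoderSpec(family="svm", n_classes=2)
        trained = dec.fit(spec, rwe, y[train][:40], seed=0)
        with pytest.raises(ValueError, match="shape|match"):
            dec.predict(trained, rwe[:, :10])
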