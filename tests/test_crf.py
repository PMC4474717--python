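import itertools
import math

import numpy as np
import pytest

from disomcs import crf
from disomcs.annotation import STATES
from disomcs.features import FeatureMatrix


def random_instance(rng, length, offsets=(-1, 0, 1), scale=0.5):
    tmpl = crf.TemplateSpec(offsets)
    fm = FeatureMatrix(rng.normal(size=(length, 12)))
    x = crf.expand_features(fm, tmpl)
    model = crf.CRFModel(
        state_weights=rng.normal(size=(3, tmpl.n_expanded)) * scale,
        transitions=rng.normal(size=(3, 3)) * scale,
        template=tmpl,
    )
    return model, x


def enumerate_paths(model, x):
    """Brute-force log-partition, marginals and best path over all 3^L paths."""
    length = x.shape[0]
    paths = ["".join(p) for p in itertools.product(STATES, repeat=length)]
    scores = np.array([crf.path_score(model, x, p) for p in paths])
    m = scores.max()
    log_z = m + math.log(np.exp(scores - m).sum())
    probs = np.exp(scores - log_z)
    marg = np.zeros((length, 3))
    for path, pr in zip(paths, probs):
        for pos, lab in enumerate(path):
            marg[pos, STATES.index(lab)] += pr
    return log_z, marg, paths[int(np.argmax(scores))], scores.max()


class TestExpandFeatures:
    def test_offset_zero_is_row_plus_bias(self):
        fm = FeatureMatrix(np.arange(24, dtype=float).reshape(2, 12))
        x = crf.expand_features(fm, crf.TemplateSpec((0,)))
        np.testing.assert_array_equal(x[:, :12], fm.values)
        np.testing.assert_array_equal(x[:, 12], 1.0)

    def test_boundary_zero_padding(self):
        fm = FeatureMatrix(np.ones((3, 12)))
        x = crf.expand_features(fm)  # offsets -4..+4
        # at position 0 every negative offset block is padding
        for k, off in enumerate(crf.TemplateSpec().offsets):
            block = x[0, k * 12 : (k + 1) * 12]
            expected = 1.0 if 0 <= off < 3 else 0.0
            np.testing.assert_array_equal(block, expected)

    def test_interior_window_copies_rows(self):
        rng = np.random.default_rng(1)
        fm = FeatureMatrix(rng.normal(size=(9, 12)))
        tmpl = crf.TemplateSpec((-2, -1, 0, 1, 2))
        x = crf.expand_features(fm, tmpl)
        p = 4
        for k, off in enumerate(tmpl.offsets):
            np.testing.assert_array_equal(x[p, k * 12 : (k + 1) * 12], fm.values[p + off])

    def test_template_must_contain_zero(self):
        with pytest.raises(ValueError):
            crf.TemplateSpec((-1, 1))


class TestForwardBackward:
    def test_uniform_model(self):
        tmpl = crf.TemplateSpec((0,))
        model = crf.CRFModel.zeros(tmpl)
        x = crf.expand_features(FeatureMatrix(np.zeros((7, 12))), tmpl)
        log_z, marg, _ = crf.forward_backward(model, x)
        assert log_z == pytest.approx(7 * math.log(3))
        np.testing.assert_allclose(marg.values, 1 / 3, atol=1e-12)

    def test_single_position_is_softmax(self):
        rng = np.random.default_rng(2)
        model, x = random_instance(rng, 1)
        log_z, marg, _ = crf.forward_backward(model, x)
        s = x @ model.state_weights.T
        expected = np.exp(s - s.max())
        expected /= expected.sum()
        np.testing.assert_allclose(marg.values[0], expected[0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(2, 7))
        model, x = random_instance(rng, length)
        log_z, marg, _ = crf.forward_backward(model, x)
        bz, bmarg, bpath, bscore = enumerate_paths(model, x)
        assert log_z == pytest.approx(bz, abs=1e-9)
        np.testing.assert_allclose(marg.values, bmarg, atol=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_forward_and_backward_logz_agree(self, seed):
        rng = np.random.default_rng(100 + seed)
        model, x = random_instance(rng, int(rng.integers(2, 40)), scale=1.5)
        log_z, marg, _ = crf.forward_backward(model, x)
        assert log_z == pytest.approx(crf.backward_log_z(model, x), abs=1e-8)
        np.testing.assert_allclose(marg.values.sum(axis=1), 1.0, atol=1e-9)


class TestViterbi:
    def test_all_zero_weights_tie_break_toward_order(self):
        tmpl = crf.TemplateSpec((0,))
        model = crf.CRFModel.zeros(tmpl)
        x = crf.expand_features(FeatureMatrix(np.zeros((6, 12))), tmpl)
        assert crf.viterbi(model, x) == "OOOOOO"

    @pytest.mark.parametrize("seed", range(8))
    def test_path_score_matches_enumeration_maximum(self, seed):
        rng = np.random.default_rng(200 + seed)
        model, x = random_instance(rng, int(rng.integers(2, 7)))
        path = crf.viterbi(model, x)
        _, _, _, best = enumerate_paths(model, x)
        assert crf.path_score(model, x, path) == pytest.approx(best, abs=1e-9)

    def test_zero_transitions_reduce_to_per_position_argmax(self):
        rng = np.random.default_rng(3)
        tmpl = crf.TemplateSpec((0,))
        fm = FeatureMatrix(rng.normal(size=(20, 12)) * 5)
        x = crf.expand_features(fm, tmpl)
        model = crf.CRFModel(
            rng.normal(size=(3, tmpl.n_expanded)), np.zeros((3, 3)), tmpl
        )
        scores = x @ model.state_weights.T
        expected = "".join(STATES[i] for i in np.argmax(scores, axis=1))
        assert crf.viterbi(model, x) == expected


class TestTraining:
    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        tmpl = crf.TemplateSpec((-1, 0, 1))
        fm = FeatureMatrix(rng.normal(size=(6, 12)))
        x = crf.expand_features(fm, tmpl)
        ds = [(x, rng.integers(0, 3, size=6))]
        w = rng.normal(size=3 * tmpl.n_expanded + 9) * 0.3
        _, g = crf.objective(w, ds, tmpl, 10.0)
        eps = 1e-6
        num = np.zeros_like(w)
        for i in range(len(w)):
            wp, wm = w.copy(), w.copy()
            wp[i] += eps
            wm[i] -= eps
            num[i] = (crf.objective(wp, ds, tmpl, 10.0)[0] - crf.objective(wm, ds, tmpl, 10.0)[0]) / (2 * eps)
        rel = np.abs(num - g).max() / max(1.0, np.abs(g).max())
        assert rel < 1e-4

    def test_zero_iterations_returns_zero_model(self):
        fm = FeatureMatrix(np.zeros((4, 12)))
        model, log = crf.train([(fm, "OODD")], crf.TrainConfig(max_iter=0))
        assert (model.state_weights == 0).all() and (model.transitions == 0).all()
        assert log["n_iter"] == 0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            crf.train([])

    def test_separable_set_fits_to_high_accuracy(self):
        # features literally contain the one-hot label, so the task is separable
        rng = np.random.default_rng(5)
        dataset = []
        for _ in range(20):
            length = int(rng.integers(10, 25))
            y = rng.integers(0, 3, size=length)
            vals = np.zeros((length, 12))
            vals[np.arange(length), y] = 1.0
            dataset.append((FeatureMatrix(vals), "".join(STATES[i] for i in y)))
        model, log = crf.train(dataset, crf.TrainConfig(max_iter=100))
        correct = total = 0
        for fm, labels in dataset:
            path = crf.predict_path(model, fm)
            correct += sum(a == b for a, b in zip(path, labels))
            total += len(labels)
        assert correct / total >= 0.99
        # accepted line-search iterates never decrease the penalized likelihood
        traj = log["objective_trajectory"]
        assert all(b >= a - 1e-9 for a, b in zip(traj, traj[1:]))

    def test_training_is_deterministic(self, tmp_path):
        rng = np.random.default_rng(6)
        fm = FeatureMatrix(rng.normal(size=(15, 12)))
        ds = [(fm, "OOONNNDDDOOONNN")]
        m1, _ = crf.train(ds, crf.TrainConfig(max_iter=30))
        m2, _ = crf.train(ds, crf.TrainConfig(max_iter=30))
        crf.save_model(m1, tmp_path / "a.json")
        crf.save_model(m2, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()


class TestSerialization:
    def test_bit_exact_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        model, _ = random_instance(rng, 3)
        path = tmp_path / "model.json"
        crf.save_model(model, path)
        back = crf.load_model(path)
        np.testing.assert_array_equal(back.state_weights, model.state_weights)
        np.testing.assert_array_equal(back.transitions, model.transitions)
        assert back.template == model.template

    def test_version_checked(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text('{"format_version": 99}')
        with pytest.raises(ValueError):
            crf.load_model(path)
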