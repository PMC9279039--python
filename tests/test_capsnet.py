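import numpy as np
import pytest

from capsfmri.capsnet.autodiff import Adam, Tensor, conv2d, softmax
from capsfmri.capsnet.model import (
    CapsNetClassifier,
    CapsNetConfig,
    margin_loss,
    route,
    squash,
)
from oracles import (
    margin_loss_closed_form,
    margin_loss_grad_closed_form,
    route_direct,
)


class TestAutodiff:
    def _fd_check(self, f, x0, atol=1e-6):
        """Finite-difference gradient check of scalar-valued f at x0."""
        x = Tensor(x0.copy(), requires_grad=True)
        f(x).backward()
        analytic = x.grad
        h = 1e-6
        fd = np.zeros_like(x0)
        for idx in np.ndindex(x0.shape):
            xp, xm = x0.copy(), x0.copy()
            xp[idx] += h
            xm[idx] -= h
            fd[idx] = (f(Tensor(xp)).data - f(Tensor(xm)).data) / (2 * h)
        np.testing.assert_allclose(analytic, fd, atol=atol)

    def test_elementwise_and_reduction_gradients(self, rng):
        x0 = rng.normal(size=(3, 4))

        def f(x):
            return ((x * x + 2.0 * x).relu().sum(axis=1) ** 2).mean()

        self._fd_check(f, x0)

    def test_matmul_and_softmax_gradients(self, rng):
        x0 = rng.normal(size=(4, 3))
        w = Tensor(rng.normal(size=(3, 2)))

        def f(x):
            return (softmax(x @ w, axis=1) ** 2).sum()

        self._fd_check(f, x0)

    def test_conv2d_gradients(self, rng):
        x0 = rng.normal(size=(2, 3, 6, 6))
        w = Tensor(rng.normal(size=(4, 3, 3, 3)), requires_grad=True)
        b = Tensor(rng.normal(size=4), requires_grad=True)

        def f(x):
            return (conv2d(x, w, b, stride=2) ** 2).sum()

        self._fd_check(f, x0, atol=1e-5)
        # kernel gradient too
        w.grad = None
        x = Tensor(x0)
        loss = (conv2d(x, w, b, stride=2) ** 2).sum()
        loss.backward()
        h = 1e-6
        idx = (1, 2, 0, 1)
        wp = w.data.copy()
        wp[idx] += h
        wm = w.data.copy()
        wm[idx] -= h
        fd = (
            (conv2d(x, Tensor(wp), b, stride=2) ** 2).sum().data
            - (conv2d(x, Tensor(wm), b, stride=2) ** 2).sum().data
        ) / (2 * h)
        assert w.grad[idx] == pytest.approx(float(fd), abs=1e-5)

    def test_adam_descends_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            loss = (p * p).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 0.1


class TestSquash:
    def test_zero_vector_maps_to_zero(self):
        np.testing.assert_array_equal(squash(np.zeros(8)), np.zeros(8))

    def test_unit_vector_has_norm_half(self):
        v = np.zeros(8)
        v[0] = 1.0
        assert np.linalg.norm(squash(v)) == pytest.approx(0.5, abs=1e-6)

    def test_large_vector_saturates_below_one(self):
        v = np.full(4, 500.0)
        n = np.linalg.norm(squash(v))
        assert 1 - 1e-5 < n < 1.0

    def test_direction_preserved(self, rng):
        v = rng.normal(size=6)
        out = squash(v)
        cos = out @ v / (np.linalg.norm(out) * np.linalg.norm(v))
        assert cos == pytest.approx(1.0)


class TestRouting:
    def test_coupling_coefficients_sum_to_one_every_iteration(self, rng):
        votes = rng.normal(size=(10, 3, 8))
        _, couplings = route(votes, iters=4, return_couplings=True)
        assert len(couplings) == 4
        for c in couplings:
            np.testing.assert_allclose(c.sum(axis=1), 1.0, atol=1e-8)

    @pytest.mark.parametrize("iters", [1, 2, 5])
    def test_single_capsule_single_class_returns_squashed_vote(self, rng, iters):
        vote = rng.normal(size=(1, 1, 6))
        out = route(vote, iters=iters)
        np.testing.assert_allclose(out[0], squash(vote[0, 0]), atol=1e-12)

    def test_identical_votes_preserve_direction(self, rng):
        common = rng.normal(size=(2, 8))
        votes = np.broadcast_to(common, (7, 2, 8)).copy()
        out = route(votes, iters=3)
        for c in range(2):
            cos = out[c] @ common[c] / (
                np.linalg.norm(out[c]) * np.linalg.norm(common[c])
            )
            assert cos == pytest.approx(1.0)

    def test_matches_direct_iteration_oracle(self, rng):
        votes = rng.normal(size=(6, 2, 5))
        np.testing.assert_allclose(route(votes, 3), route_direct(votes, 3), atol=1e-10)


class TestMarginLoss:
    def test_inactive_hinges_give_zero(self):
        assert margin_loss(np.array([0.9, 0.1]), 0) == 0.0

    def test_zero_scores_give_081(self):
        assert margin_loss(np.array([0.0, 0.0]), 0) == pytest.approx(0.81)

    def test_hand_evaluated_two_class_case(self):
        assert margin_loss(np.array([0.5, 0.6]), 0) == pytest.approx(0.285)

    def test_matches_closed_form_on_random_scores(self, rng):
        for _ in range(50):
            scores = rng.uniform(0, 1, size=rng.integers(2, 6))
            k = int(rng.integers(0, scores.size))
            assert margin_loss(scores, k) == pytest.approx(
                margin_loss_closed_form(scores, k), abs=1e-12
            )

    def test_nonnegative_and_zero_iff_margins_met(self, rng):
        for _ in range(100):
            scores = rng.uniform(0, 1, size=3)
            k = int(rng.integers(0, 3))
            loss = margin_loss(scores, k)
            assert loss >= 0.0
            met = scores[k] >= 0.9 and all(
                s <= 0.1 for i, s in enumerate(scores) if i != k
            )
            assert (loss == 0.0) == met

    def test_score_out_of_range_is_error(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            margin_loss(np.array([1.2, 0.0]), 0)

    def test_gradient_matches_analytic_on_50_points(self, rng):
        """Finite-difference gradient of the margin loss w.r.t. the scores
        agrees with the closed-form analytic gradient within 1e-5."""
        h = 1e-7
        for _ in range(50):
            scores = rng.uniform(0.01, 0.99, size=4)
            k = int(rng.integers(0, 4))
            analytic = margin_loss_grad_closed_form(scores, k)
            for p in range(4):
                sp, sm = scores.copy(), scores.copy()
                sp[p] += h
                sm[p] -= h
                fd = (margin_loss(sp, k) - margin_loss(sm, k)) / (2 * h)
                assert fd == pytest.approx(analytic[p], abs=1e-5)


def _toy_dataset(n_per_class=8, seed=0):
    """Two classes of 1x8x8 images separated by a bright quadrant."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            img = rng.normal(0, 0.3, size=(1, 8, 8))
            if label:
                img[0, :4, :4] += 2.0
            X.append(img)
            y.append(label)
    return np.stack(X), np.array(y)


TOY_CFG = dict(
    conv1_channels=8, conv1_kernel=3, primary_channels=4, primary_dim=4,
    primary_kernel=3, primary_stride=2, class_dim=8,
)


class TestClassifier:
    def test_training_reduces_loss(self):
        X, y = _toy_dataset()
        model = CapsNetClassifier(CapsNetConfig(epochs=10, seed=0, **TOY_CFG)).fit(X, y)
        assert model.history[-1]["loss"] < model.history[0]["loss"]

    def test_training_is_deterministic(self):
        X, y = _toy_dataset()
        cfg = CapsNetConfig(epochs=3, seed=1, **TOY_CFG)
        m1 = CapsNetClassifier(cfg).fit(X, y)
        m2 = CapsNetClassifier(cfg).fit(X, y)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k].data, m2.params[k].data)

    def test_scores_in_unit_interval_and_repeatable(self):
        X, y = _toy_dataset()
        model = CapsNetClassifier(CapsNetConfig(epochs=3, seed=0, **TOY_CFG)).fit(X, y)
        s1 = model.predict_scores(X)
        s2 = model.predict_scores(X)
        np.testing.assert_array_equal(s1, s2)
        assert s1.min() >= 0.0 and s1.max() < 1.0

    def test_fit_quality_on_separable_set(self):
        X, y = _toy_dataset(n_per_class=10)
        model = CapsNetClassifier(CapsNetConfig(epochs=25, seed=0, **TOY_CFG)).fit(X, y)
        assert (model.predict(X) == y).mean() >= 0.95

    def test_single_class_rejected(self):
        X, y = _toy_dataset()
        with pytest.raises(ValueError, match="two classes"):
            CapsNetClassifier(CapsNetConfig(**TOY_CFG)).fit(X, np.zeros_like(y))

    def test_shape_mismatch_rejected(self):
        X, y = _toy_dataset()
        model = CapsNetClassifier(CapsNetConfig(epochs=1, seed=0, **TOY_CFG)).fit(X, y)
        with pytest.raises(ValueError, match="shape"):
            model.predict(np.zeros((2, 1, 9, 9)))

    def test_save_load_round_trip(self, tmp_path):
        X, y = _toy_dataset()
        model = CapsNetClassifier(CapsNetConfig(epochs=2, seed=0, **TOY_CFG)).fit(X, y)
        model.save(tmp_path / "m.npz")
        back = CapsNetClassifier.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(back.predict_scores(X), model.predict_scores(X))
        assert back.history == model.history

    def test_argmax_tie_breaks_to_lower_class(self):
        from capsfmri.capsnet.model import Prediction

        scores = np.array([0.4, 0.4])
        assert int(scores.argmax()) == 0
        p = Prediction(class_scores=scores, predicted_class=int(scores.argmax()))
        assert p.predicted_class == 0

    def test_kernel_too_large_for_input(self):
        cfg = CapsNetConfig(conv1_kernel=9, primary_kernel=9)
        with pytest.raises(ValueError, match="does not fit"):
            CapsNetClassifier(cfg)._build((1, 12, 12))
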