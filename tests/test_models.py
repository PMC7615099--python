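"""Model-family contracts: augmentation, normalisation, the ordinal
log-barrier loss (against closed forms and finite differences), and
training behaviour of both classifiers on planted-signal fixtures."""

import numpy as np
import pandas as pd
import pytest

from urbansense import models as md
from urbansense.classes_splits import SplitPlan


class TestAugment:
    def test_disabled_is_identity(self, rng):
        img = rng.uniform(size=(16, 16, 3))
        assert np.array_equal(md.augment(img, rng, enabled=False), img)

    def test_constant_image_invariant(self, rng):
        img = np.full((20, 20, 3), 0.37)
        out = md.augment(img, rng)
        assert out.shape == img.shape
        assert np.allclose(out, 0.37, atol=1e-6)

    def test_flip_frequency_and_shape(self, rng):
        # left-bright/right-dark image: flipping swaps the halves
        img = np.zeros((16, 16, 3))
        img[:, :8] = 1.0
        flips = 0
        n = 400
        for _ in range(n):
            out = md.augment(img, rng)
            flips += out[:, :4].mean() < out[:, -4:].mean()
        p = flips / n
        assert abs(p - 0.5) < 4 * np.sqrt(0.25 / n)


class TestNormalizer:
    def test_training_set_becomes_zero_mean_unit_sd(self, rng):
        X = rng.uniform(0.2, 0.9, size=(40, 8, 8, 3))
        norm = md.Normalizer.fit(X)
        Z = norm.transform(X)
        assert np.allclose(Z.mean(axis=(0, 1, 2)), 0, atol=1e-9)
        assert np.allclose(Z.std(axis=(0, 1, 2)), 1, atol=1e-9)

    def test_constant_channel_guarded(self, rng):
        X = rng.uniform(size=(10, 8, 8, 3))
        X[..., 2] = 0.5
        Z = md.Normalizer.fit(X).transform(X)
        assert np.allclose(Z[..., 2], 0.0)

    def test_train_statistics_applied_to_shifted_holdout(self, rng):
        X = rng.uniform(0.0, 0.5, size=(50, 8, 8, 3))
        holdout = rng.uniform(0.4, 0.9, size=(50, 8, 8, 3))
        Z = md.Normalizer.fit(X).transform(holdout)
        assert abs(Z.mean()) > 0.5  # distribution shift visible


def random_simplex(rng, k):
    p = rng.dirichlet(np.ones(k))
    return p


class TestOrdinalLoss:
    def test_lambda_zero_is_cross_entropy(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 12))
            p = random_simplex(rng, k)
            y = int(rng.integers(0, k))
            assert md.ordinal_loss(p, y, barrier_weight=0.0) == pytest.approx(
                -np.log(p[y]), rel=1e-12
            )

    def test_uniform_prediction_gives_log_k(self):
        for k in (2, 5, 10, 11):
            p = np.full(k, 1.0 / k)
            assert md.ordinal_loss(p, 0, barrier_weight=0.0) == pytest.approx(np.log(k))

    def test_barrier_vanishes_for_strict_unimodal_profile_as_t_grows(self):
        p = np.array([0.05, 0.15, 0.45, 0.25, 0.10])
        y = 2
        ce = -np.log(p[y])
        loss_t = md.ordinal_loss(p, y, barrier_weight=1.0, barrier_t=200.0)
        assert loss_t == pytest.approx(ce, abs=0.05)
        # and the barrier shrinks monotonically in t
        losses = [md.ordinal_loss(p, y, 1.0, t) for t in (5.0, 20.0, 200.0)]
        assert losses[0] > losses[1] > losses[2]

    def test_unimodality_violation_costs_more_than_rearrangement(self):
        # rising flank below y=2 is violated by (0.25, 0.05); its monotone
        # rearrangement keeps p_y fixed
        bad = np.array([0.25, 0.05, 0.50, 0.20])
        good = np.array([0.05, 0.25, 0.50, 0.20])
        for lam in (0.01, 0.1, 1.0):
            assert md.ordinal_loss(bad, 2, lam) > md.ordinal_loss(good, 2, lam)

    def test_class_order_matters(self):
        p = np.array([0.1, 0.2, 0.5, 0.15, 0.05])
        reordered = p[[2, 0, 1, 4, 3]]
        l1 = md.ordinal_loss(p, 2, 0.5)
        l2 = md.ordinal_loss(reordered, 0, 0.5)  # same p_y, classes permuted
        assert l1 != pytest.approx(l2)

    def test_finite_on_simplex_boundary_neighbourhood(self):
        p = np.array([1e-9, 1.0 - 2e-9, 1e-9])
        assert np.isfinite(md.ordinal_loss(p, 1, 1.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            md.ordinal_loss(np.array([0.5, 0.6]), 0)
        with pytest.raises(ValueError):
            md.ordinal_loss(np.array([0.5, 0.5]), 2)

    def test_gradient_matches_finite_differences(self, rng):
        k, n = 5, 3
        logits = rng.normal(size=(n, k))
        y = rng.integers(0, k, n)
        loss, grad = md._loss_grad_logits(logits, y, 0.3, 5.0)
        eps = 1e-6
        for i in range(n):
            for j in range(k):
                z = logits.copy()
                z[i, j] += eps
                lp, _ = md._loss_grad_logits(z, y, 0.3, 5.0)
                z[i, j] -= 2 * eps
                lm, _ = md._loss_grad_logits(z, y, 0.3, 5.0)
                assert grad[i, j] == pytest.approx((lp - lm) / (2 * eps), rel=1e-4, abs=1e-7)


class TestConvNetGradients:
    def test_backprop_matches_finite_differences(self, rng):
        net = md.TinyConvNet(n_classes=4, input_size=8, channels=(2, 3), rng=rng)
        X = rng.normal(size=(2, 8, 8, 3))
        y = np.array([1, 3])

        def loss_of(params):
            saved = net.params
            net.params = params
            logits = net.forward(X)
            out, _ = md._loss_grad_logits(logits, y, 0.2, 5.0)
            net.params = saved
            return out

        logits = net.forward(X, cache=True)
        _, dlogits = md._loss_grad_logits(logits, y, 0.2, 5.0)
        grads = net.backward(dlogits)
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for name, g in grads.items():
            flat_idx = check_rng.choice(g.size, size=min(5, g.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, g.shape)
                pp = {k: v.copy() for k, v in net.params.items()}
                pp[name][idx] += eps
                lp = loss_of(pp)
                pp[name][idx] -= 2 * eps
                lm = loss_of(pp)
                num = (lp - lm) / (2 * eps)
                assert g[idx] == pytest.approx(num, rel=2e-3, abs=1e-6), name


def class_images(n, k, seed, noise=0.08, size=16):
    """Images whose red level deterministically encodes the class."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, k, n)
    imgs = rng.uniform(0.2, 0.4, (n, size, size, 3))
    imgs[..., 0] += (y / (k - 1) * 0.5)[:, None, None]
    imgs += rng.normal(0, noise, imgs.shape)
    return np.clip(imgs, 0, 1), y


def image_fixture(n=600, k=6, seed=0):
    X, y = class_images(n, k, seed)
    ids = [f"r{i}" for i in range(n)]
    labels = pd.Series(y, index=ids)
    plan = SplitPlan("1a", ids[: int(n * 2 / 3)], ids[int(n * 2 / 3) : int(n * 5 / 6)],
                     ids[int(n * 5 / 6) :])
    images = {i: X[j] for j, i in enumerate(ids)}
    return images, X, y, labels, plan, ids


class TestTrainCNN:
    def test_learns_planted_red_tint_signal(self):
        images, X, y, labels, plan, ids = image_fixture()
        cfg = md.TrainConfig(family="cnn", seed=0, epochs=8, input_size=16)
        model = md.train_cnn(images, labels, plan, cfg)
        test_idx = [ids.index(r) for r in plan.test_ids]
        acc = (model.predict(X[test_idx]) == y[test_idx]).mean()
        assert acc > 0.6  # null is ~1/6

    def test_shuffled_labels_fall_to_null(self):
        images, X, y, labels, plan, ids = image_fixture()
        rng = np.random.default_rng(1)
        shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        cfg = md.TrainConfig(family="cnn", seed=0, epochs=5, input_size=16)
        model = md.train_cnn(images, shuffled, plan, cfg)
        test_idx = [ids.index(r) for r in plan.test_ids]
        acc = (model.predict(X[test_idx]) == shuffled.loc[plan.test_ids].to_numpy()).mean()
        assert abs(acc - 1 / 6) < 0.15

    def test_same_seed_reproduces_training_curve(self):
        images, X, y, labels, plan, ids = image_fixture(n=300)
        cfg = md.TrainConfig(family="cnn", seed=3, epochs=3, input_size=16)
        m1 = md.train_cnn(images, labels, plan, cfg)
        m2 = md.train_cnn(images, labels, plan, cfg)
        assert m1.history == m2.history
        assert np.array_equal(m1.predict_proba(X[:10]), m2.predict_proba(X[:10]))

    def test_barrier_increases_unimodal_prediction_fraction(self):
        images, X, y, labels, plan, ids = image_fixture()
        test_idx = [ids.index(r) for r in plan.test_ids]

        def unimodal_fraction(lam):
            cfg = md.TrainConfig(
                family="cnn", seed=0, epochs=8, input_size=16, barrier_weight=lam
            )
            model = md.train_cnn(images, labels, plan, cfg)
            P = model.predict_proba(X[test_idx])
            def is_unimodal(p):
                kk = p.argmax()
                return (np.diff(p[: kk + 1]) >= -1e-12).all() and (
                    np.diff(p[kk:]) <= 1e-12
                ).all()
            return np.mean([is_unimodal(p) for p in P])

        assert unimodal_fraction(0.1) >= unimodal_fraction(0.0)


def count_fixture(n=1200, k=5, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, k, n)
    X = pd.DataFrame(
        {
            "car": (y * 3 + rng.poisson(1.0, n)) if informative else rng.poisson(3, n),
            "person": rng.poisson(2.0, n),
            "taxi": rng.poisson(1.0, n),
        },
        index=[f"r{i}" for i in range(n)],
    )
    labels = pd.Series(y, index=X.index)
    ids = list(X.index)
    plan = SplitPlan("1a", ids[:800], ids[800:1000], ids[1000:])
    return X, labels, plan


class TestTrainGBM:
    def test_perfectly_informative_feature_learned(self):
        X, labels, plan = count_fixture()
        model = md.train_gbm(X, labels, plan, md.TrainConfig(seed=0))
        acc = (model.predict(X.loc[plan.test_ids]) == labels.loc[plan.test_ids]).mean()
        assert acc > 0.9

    def test_uninformative_features_stay_at_null(self):
        X, labels, plan = count_fixture(informative=False)
        model = md.train_gbm(X, labels, plan, md.TrainConfig(seed=0))
        acc = (model.predict(X.loc[plan.test_ids]) == labels.loc[plan.test_ids]).mean()
        assert abs(acc - 0.2) < 0.12

    def test_deterministic_given_seed(self):
        X, labels, plan = count_fixture()
        m1 = md.train_gbm(X, labels, plan, md.TrainConfig(seed=5))
        m2 = md.train_gbm(X, labels, plan, md.TrainConfig(seed=5))
        assert np.array_equal(
            m1.predict_proba(X.loc[plan.test_ids]), m2.predict_proba(X.loc[plan.test_ids])
        )

    def test_single_class_labels_refused(self):
        X, labels, plan = count_fixture()
        with pytest.raises(ValueError):
            md.train_gbm(X, labels * 0, plan, md.TrainConfig(seed=0))

    def test_probabilities_cover_full_scheme_even_with_absent_classes(self):
        X, labels, plan = count_fixture(k=3)
        model = md.train_gbm(X, labels, plan, md.TrainConfig(seed=0), n_classes=10)
        P = model.predict_proba(X.loc[plan.test_ids])
        assert P.shape[1] == 10
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.allclose(P[:, 3:], 0.0)
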