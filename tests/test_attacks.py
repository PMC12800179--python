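"""FGSM/PGD contracts: epsilon-ball containment, clipping, equivalences."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affetds._exceptions import NumericalError, ParameterError
from affetds.attacks import AttackConfig, adversarial_augment, fgsm_attack, pgd_attack
from affetds.data import ImageSample


class LogisticToyModel:
    """p(manipulated) = sigmoid(w . x + b): gradients are known analytically.

    For cross-entropy J and true label y, dJ/dx = (p - y) * w, so the
    gradient sign per pixel is sign(p - y) * sign(w). Accepts single images
    (H, W) or batches (N, H, W), per the gradient-model contract.
    """

    def __init__(self, weights, bias=0.0):
        self.w = np.asarray(weights, dtype=np.float64)
        self.b = float(bias)

    def _scores(self, pixels):
        x = np.asarray(pixels, dtype=np.float64)
        batched = x.ndim == 3
        x = x if batched else x[None]
        z = np.tensordot(x, self.w, axes=([1, 2], [0, 1])) + self.b
        return 1.0 / (1.0 + np.exp(-z)), batched

    def predict_proba(self, pixels):
        p, batched = self._scores(pixels)
        return p if batched else float(p[0])

    def loss_and_gradient(self, pixels, labels):
        p, batched = self._scores(pixels)
        y = np.atleast_1d(np.asarray(labels, dtype=np.float64))
        loss = float(np.mean(-(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12))))
        grad = (p - y)[:, None, None] * self.w / len(y)
        return loss, grad if batched else grad[0]


class BrokenModel(LogisticToyModel):
    def loss_and_gradient(self, pixels, labels):
        grad = np.full_like(np.asarray(pixels, dtype=float), np.nan)
        return 1.0, grad


@pytest.fixture
def toy_model():
    return LogisticToyModel(weights=np.full((4, 4), 0.8))


class TestFgsm:
    def test_zero_epsilon_is_identity(self, toy_model, rng):
        x = rng.random((4, 4))
        assert np.array_equal(fgsm_attack(toy_model, x, 1, 0.0), x)

    def test_logistic_gradient_sign_hand_computed(self, toy_model):
        # true label "real" (y=0), positive weights: dJ/dx = p*w > 0 per
        # pixel, so the attack adds +eps everywhere (clip permitting)
        x = np.full((4, 4), 0.4)
        adv = fgsm_attack(toy_model, x, 0, 0.05)
        assert np.allclose(adv, 0.45)

    def test_clip_binds_at_upper_bound(self, toy_model):
        x = np.ones((4, 4))
        adv = fgsm_attack(toy_model, x, 0, 0.3)
        assert np.array_equal(adv, x)

    def test_negative_epsilon_rejected(self, toy_model):
        with pytest.raises(ParameterError):
            fgsm_attack(toy_model, np.zeros((2, 2)), 0, -0.1)

    def test_nonfinite_gradient_signalled(self):
        model = BrokenModel(np.ones((2, 2)))
        with pytest.raises(NumericalError):
            fgsm_attack(model, np.zeros((2, 2)), 0, 0.1)

    @settings(max_examples=30, deadline=None)
    @given(
        eps=st.floats(0.0, 0.3),
        seed=st.integers(0, 10_000),
        label=st.integers(0, 1),
    )
    def test_ball_and_range_containment(self, eps, seed, label):
        gen = np.random.default_rng(seed)
        model = LogisticToyModel(gen.normal(size=(5, 5)))
        x = gen.random((5, 5))
        adv = fgsm_attack(model, x, label, eps)
        assert np.max(np.abs(adv - x)) <= eps + 1e-9
        assert adv.min() >= 0.0 and adv.max() <= 1.0


class TestPgd:
    def test_zero_epsilon_identity(self, toy_model, rng):
        x = rng.random((4, 4))
        cfg = AttackConfig(epsilon=0.0, alpha=0.01, iterations=5, seed=1)
        assert np.array_equal(pgd_attack(toy_model, x, 1, cfg), x)

    def test_zero_iterations_is_seeded_init_only(self, toy_model, rng):
        x = rng.random((4, 4)) * 0.5 + 0.25
        cfg = AttackConfig(epsilon=0.1, alpha=0.05, iterations=0, seed=42)
        expected = np.clip(
            np.clip(x + np.random.default_rng(42).uniform(-0.1, 0.1, x.shape), x - 0.1, x + 0.1),
            0.0,
            1.0,
        )
        assert np.allclose(pgd_attack(toy_model, x, 0, cfg), expected)

    def test_equals_fgsm_with_one_step_and_no_init(self, rng):
        gen = np.random.default_rng(7)
        model = LogisticToyModel(gen.normal(size=(6, 6)))
        x = gen.random((6, 6))
        for eps in (0.01, 0.1):
            cfg = AttackConfig(epsilon=eps, alpha=eps, iterations=1, seed=0)
            pgd = pgd_attack(model, x, 1, cfg, random_init=False)
            fgsm = fgsm_attack(model, x, 1, eps)
            assert np.allclose(pgd, fgsm)

    @settings(max_examples=20, deadline=None)
    @given(
        eps=st.floats(0.0, 0.2),
        alpha=st.floats(0.0, 0.1),
        k=st.integers(0, 6),
        seed=st.integers(0, 9999),
    )
    def test_exhaustive_pixel_ball_check(self, eps, alpha, k, seed):
        gen = np.random.default_rng(seed)
        model = LogisticToyModel(gen.normal(size=(4, 4)))
        x = gen.random((4, 4))
        cfg = AttackConfig(epsilon=eps, alpha=alpha, iterations=k, seed=seed)
        adv = pgd_attack(model, x, 0, cfg)
        # brute-force per-pixel scan of both containment contracts
        for i in range(4):
            for j in range(4):
                assert abs(adv[i, j] - x[i, j]) <= eps + 1e-9
                assert 0.0 <= adv[i, j] <= 1.0


class TestAdversarialAugment:
    def _samples(self, n_per_class):
        out = []
        for i in range(n_per_class):
            out.append(ImageSample(f"r{i}", np.full((4, 4), 0.4), "real"))
            mask = np.zeros((4, 4), dtype=bool)
            mask[1, 1] = True
            out.append(ImageSample(f"m{i}", np.full((4, 4), 0.6), "manipulated", mask))
        return out

    def test_zero_fraction_returns_input(self, toy_model):
        samples = self._samples(3)
        out = adversarial_augment(toy_model, samples, AttackConfig(), fraction=0.0)
        assert [s.id for s in out] == [s.id for s in samples]

    def test_full_fraction_both_methods_triples_count(self, toy_model):
        samples = self._samples(4)
        out = adversarial_augment(
            toy_model, samples, AttackConfig(iterations=2), methods=("fgsm", "pgd"), fraction=1.0
        )
        assert len(out) == 3 * len(samples)

    def test_adversarial_copies_keep_source_labels(self, toy_model):
        samples = self._samples(3)
        out = adversarial_augment(toy_model, samples, AttackConfig(iterations=1), fraction=1.0)
        by_id = {s.id: s for s in samples}
        for adv in out[len(samples) :]:
            source_id = adv.id.rsplit("+", 1)[0]
            assert adv.label == by_id[source_id].label
            assert "+" in adv.provenance

    def test_bad_fraction_rejected(self, toy_model):
        with pytest.raises(ParameterError):
            adversarial_augment(toy_model, self._samples(2), AttackConfig(), fraction=1.5)


class TestCnnAttackIntegration:
    """Attacks against the real CNN contract (not just the toy model)."""

    def test_ball_containment_on_cnn(self, tiny_cnn, rng):
        x = rng.random((32, 32))
        cfg = AttackConfig(epsilon=0.05, alpha=0.02, iterations=3, seed=2)
        adv = pgd_attack(tiny_cnn, x, 1, cfg)
        assert np.max(np.abs(adv - x)) <= 0.05 + 1e-9
        assert adv.min() >= 0 and adv.max() <= 1

    def test_fgsm_increases_loss_on_cnn(self, tiny_cnn, rng):
        x = rng.random((32, 32))
        loss_before, _ = tiny_cnn.loss_and_gradient(x, 1)
        adv = fgsm_attack(tiny_cnn, x, 1, 0.1)
        loss_after, _ = tiny_cnn.loss_and_gradient(adv, 1)
        assert loss_after >= loss_before - 1e-6
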