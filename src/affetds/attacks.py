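"""Adversarial example crafting: FGSM, PGD, and training-set augmentation.

Both attacks perturb pixels within an infinity-norm ball of radius epsilon
around the clean image and keep intensities in [0, 1]:

* FGSM takes the single step ``x' = clip(x + eps * sign(dJ/dx), 0, 1)``.
* PGD starts from a seeded uniform point in the ball and iterates
  ``x' <- clip(clip(x' + alpha * sign(dJ/dx'), x - eps, x + eps), 0, 1)``,
  recomputing the gradient at the current iterate each step.

Any model exposing the :class:`GradientModel` contract can be attacked; in
this package that is the image CNN (the SVM is not gradient-capable, so
adversarial images are crafted against the CNN and then flow through feature
extraction into SVM training as well).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np

from ._exceptions import NumericalError, ParameterError
from .data import ImageSample


@runtime_checkable
class GradientModel(Protocol):
    """Classifier contract required by the attacks.

    ``predict_proba`` returns the probability of "manipulated" per input;
    ``loss_and_gradient`` returns the scalar (mean) cross-entropy loss and
    its gradient with respect to every input pixel (same shape as the
    input). Both must accept a single image ``(H, W)`` or a batch
    ``(N, H, W)``.
    """

    def predict_proba(self, pixels: np.ndarray) -> np.ndarray: ...

    def loss_and_gradient(self, pixels: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]: ...


@dataclass
class AttackConfig:
    """Perturbation budget and iteration schedule.

    epsilon: infinity-norm budget in intensity units ([0,1] scale).
    alpha: per-iteration step size (PGD).
    iterations: PGD step count k.
    seed: RNG seed for the PGD random start.
    """

    epsilon: float = 0.03
    alpha: float = 0.007
    iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ParameterError(f"epsilon must be >= 0, got {self.epsilon}")
        if self.alpha < 0:
            raise ParameterError(f"alpha must be >= 0, got {self.alpha}")
        if not isinstance(self.iterations, (int, np.integer)) or self.iterations < 0:
            raise ParameterError(f"iterations must be a nonnegative integer, got {self.iterations}")


def _checked_gradient(model: GradientModel, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    _, grad = model.loss_and_gradient(x, y)
    grad = np.asarray(grad, dtype=np.float64)
    if grad.shape != x.shape:
        raise NumericalError(f"gradient shape {grad.shape} != input shape {x.shape}")
    if not np.all(np.isfinite(grad)):
        raise NumericalError("non-finite gradient; refusing to craft the attack")
    return grad


def fgsm_attack(model: GradientModel, x: np.ndarray, y: np.ndarray | int, epsilon: float) -> np.ndarray:
    """Single-step signed-gradient attack, clipped to [0, 1].

    ``sign(0) = 0`` (pixels with zero gradient are left alone). The result
    deviates from ``x`` by at most ``epsilon`` per pixel.
    """
    if epsilon < 0:
        raise ParameterError(f"epsilon must be >= 0, got {epsilon}")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    if epsilon == 0:
        return x.copy()
    grad = _checked_gradient(model, x, y)
    return np.clip(x + epsilon * np.sign(grad), 0.0, 1.0)


def pgd_attack(
    model: GradientModel,
    x: np.ndarray,
    y: np.ndarray | int,
    config: AttackConfig,
    random_init: bool = True,
) -> np.ndarray:
    """Iterated projected signed-gradient attack.

    Starts at a seeded uniform point of the epsilon-ball (unless
    ``random_init`` is off), then takes ``iterations`` steps of size
    ``alpha``, projecting back onto the ball and the valid intensity range
    after each step. With ``iterations=1``, ``alpha=epsilon`` and no random
    start this reduces exactly to FGSM.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y)
    eps = config.epsilon
    if eps == 0:
        return x.copy()
    if random_init:
        rng = np.random.default_rng(config.seed)
        x_adv = x + rng.uniform(-eps, eps, size=x.shape)
    else:
        x_adv = x.copy()
    x_adv = np.clip(np.clip(x_adv, x - eps, x + eps), 0.0, 1.0)
    for _ in range(config.iterations):
        grad = _checked_gradient(model, x_adv, y)
        x_adv = x_adv + config.alpha * np.sign(grad)
        x_adv = np.clip(np.clip(x_adv, x - eps, x + eps), 0.0, 1.0)
    return x_adv


def adversarial_augment(
    model: GradientModel,
    samples: Sequence[ImageSample],
    config: AttackConfig,
    methods: Iterable[str] = ("fgsm", "pgd"),
    fraction: float = 1.0,
) -> list[ImageSample]:
    """Append attack-perturbed copies (original labels kept) to a sample list.

    A seeded random subset of size ``round(fraction * n)`` per class is
    perturbed with each requested method. Copies keep the source label — the
    point of adversarial training is that a perturbed forgery is still a
    forgery — and record the attack in their provenance.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError(f"fraction must be in [0, 1], got {fraction}")
    methods = list(methods)
    unknown = [m for m in methods if m not in ("fgsm", "pgd")]
    if unknown:
        raise ParameterError(f"unknown attack methods: {unknown}")

    rng = np.random.default_rng(config.seed)
    chosen: list[int] = []
    labels = [s.label for s in samples]
    for label in sorted(set(labels)):
        idx = [i for i, lab in enumerate(labels) if lab == label]
        n_pick = int(np.floor(fraction * len(idx) + 0.5))
        picked = rng.permutation(len(idx))[:n_pick]
        chosen.extend(idx[i] for i in picked)
    chosen.sort()

    out = list(samples)
    label_codes = {"real": 0, "manipulated": 1}
    chunk = 16  # images perturbed per gradient call
    for method in methods:
        for start in range(0, len(chosen), chunk):
            group = chosen[start : start + chunk]
            x = np.stack([samples[i].pixels for i in group])
            y = np.array([label_codes[samples[i].label] for i in group])
            if method == "fgsm":
                adv = fgsm_attack(model, x, y, config.epsilon)
            else:
                per_cfg = AttackConfig(
                    epsilon=config.epsilon,
                    alpha=config.alpha,
                    iterations=config.iterations,
                    seed=int(rng.integers(0, 2**31)),
                )
                adv = pgd_attack(model, x, y, per_cfg)
            for row, i in enumerate(group):
                src = samples[i]
                out.append(
                    ImageSample(
                        id=f"{src.id}+{method}",
                        pixels=adv[row],
                        label=src.label,
                        mask=src.mask,
                        provenance=f"{src.provenance}+{method}",
                    )
                )
    return out
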