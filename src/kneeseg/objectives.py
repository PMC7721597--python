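"""Adversarial and pixel-wise training objectives.

The conditional-GAN value function is the standard binary cross-entropy game:
the discriminator minimises −[E log D(x,y) + E log(1 − D(x,G(x)))] and the
generator minimises the non-saturating term −E log D(x,G(x)).  The generator
additionally carries a λ-weighted pixel loss (L1, L2 or element-wise SmoothL1
a.k.a. Huber with δ=1) against the ground-truth label map, and the pixel-loss
kind may be switched once at a fixed epoch while weights and optimiser state
persist (e.g. L2 for the first half of training, L1 for the second).

Setting λ = 0 trains on the adversarial term alone; disabling the adversarial
term entirely turns the generator into a plain U-Net regressor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PIXEL_LOSS_KINDS = ("L1", "L2", "SmoothL1")
#: clamp margin applied to scores before logarithms
SCORE_EPS = 1e-7


@dataclass(frozen=True)
class ObjectiveConfig:
    pixel_loss: str = "L1"            # {L1, L2, SmoothL1, none}
    lambda_weight: float = 100.0      # λ; studied values 0, 0.01, 1, 100, 10000
    adversarial: bool = True          # False = plain U-Net training
    switch_epoch: int | None = None
    second_phase_pixel_loss: str | None = None
    epochs: int | None = None         # used to validate switch_epoch if known

    def __post_init__(self):
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be non-negative")
        if (self.pixel_loss == "none") != (self.lambda_weight == 0):
            raise ValueError("pixel_loss='none' iff lambda_weight=0")
        if self.pixel_loss not in PIXEL_LOSS_KINDS + ("none",):
            raise ValueError(f"unknown pixel loss {self.pixel_loss!r}")
        if self.second_phase_pixel_loss is not None \
                and self.second_phase_pixel_loss not in PIXEL_LOSS_KINDS:
            raise ValueError(
                f"unknown second-phase pixel loss {self.second_phase_pixel_loss!r}")
        if self.switch_epoch is not None:
            if self.second_phase_pixel_loss is None:
                raise ValueError("switch_epoch set without second_phase_pixel_loss")
            if self.switch_epoch <= 0:
                raise ValueError("switch_epoch must lie strictly inside training")
            if self.epochs is not None and self.switch_epoch >= self.epochs:
                raise ValueError("switch_epoch must lie strictly inside training")


def _clamp(s: np.ndarray | float) -> np.ndarray:
    s = np.asarray(s, dtype=np.float64)
    if s.min() < 0 or s.max() > 1:
        raise ValueError("discriminator scores must lie in [0, 1]")
    return np.clip(s, SCORE_EPS, 1.0 - SCORE_EPS)


def adversarial_losses(d_real, d_fake) -> tuple[float, float]:
    """(generator term, discriminator term) from patch score maps in (0,1).

    Expectations are arithmetic means over the patch score map and batch.
    The generator term is the non-saturating −E log D(x, G(x)).
    """
    d_real = _clamp(d_real)
    d_fake = _clamp(d_fake)
    disc_term = float(-(np.log(d_real).mean() + np.log(1.0 - d_fake).mean()))
    gen_term = float(-np.log(d_fake).mean())
    return gen_term, disc_term


def pixel_loss(kind: str, y: np.ndarray, g: np.ndarray) -> float:
    """Mean pixel-wise error between target ``y`` and generated ``g``.

    L1 = mean |d|; L2 = mean d²; SmoothL1 = mean of the element-wise Huber
    value (0.5·d² where |d| < 1, |d| − 0.5 elsewhere).
    """
    if y.shape != g.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {g.shape}")
    d = np.asarray(y, dtype=np.float64) - np.asarray(g, dtype=np.float64)
    if kind == "L1":
        return float(np.abs(d).mean())
    if kind == "L2":
        return float((d ** 2).mean())
    if kind == "SmoothL1":
        a = np.abs(d)
        return float(np.where(a < 1.0, 0.5 * d ** 2, a - 0.5).mean())
    raise ValueError(f"unknown pixel loss {kind!r}")


def pixel_loss_grad(kind: str, y: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Gradient of ``pixel_loss`` with respect to the generated image ``g``."""
    if y.shape != g.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {g.shape}")
    d = np.asarray(g, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    n = d.size
    if kind == "L1":
        return np.sign(d) / n
    if kind == "L2":
        return 2.0 * d / n
    if kind == "SmoothL1":
        return np.where(np.abs(d) < 1.0, d, np.sign(d)) / n
    raise ValueError(f"unknown pixel loss {kind!r}")


def total_generator_loss(cfg: ObjectiveConfig, adv_term: float,
                         pixel_term: float) -> float:
    """Combined generator objective: adversarial term + λ · pixel term."""
    if not cfg.adversarial:
        return float(pixel_term)
    if cfg.lambda_weight == 0:
        return float(adv_term)
    return float(adv_term + cfg.lambda_weight * pixel_term)


def active_objective(cfg: ObjectiveConfig, epoch: int) -> str:
    """Effective pixel-loss kind at a (0-based) epoch, honouring the switch."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    if cfg.switch_epoch is None or epoch < cfg.switch_epoch:
        return cfg.pixel_loss
    if cfg.second_phase_pixel_loss is None:
        raise ValueError("switch configured without second_phase_pixel_loss")
    return cfg.second_phase_pixel_loss
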