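"""Training, transfer learning, inference and evaluation orchestration.

Training follows the paired image-to-image recipe: per slice (batch size 1),
one discriminator update on a real (source, label) pair and the current fake
pair, then one generator update on the adversarial term plus the λ-weighted
pixel loss; Adam with lr 2e-4, β₁ 0.5, β₂ 0.999.  Plain U-Net mode drops the
discriminator and trains the generator on the pixel loss alone.  Augmentation
is "jitter": upscale by bicubic interpolation (labels: nearest neighbour, so
colour codes are never interpolated) and randomly crop back to training size,
source and label sharing one offset.

All randomness derives from the configured seed through counter-based
``SeedSequence`` keys (network init, per-epoch shuffles, per-iteration
jitter), so a run is reproducible and a checkpoint resumes bit-compatibly.

The object-oriented surface mirrors the usual modelling-package shape:
``SegmentationModel(...).fit()`` returns a ``TrainingResult`` carrying the
checkpoint, the per-iteration loss log, ``summary()``, ``segment()`` and
``evaluate()``.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from . import objectives as obj
from .data import SlicePair, group_by_subject, load_dataset
from .label_codec import (
    DEFAULT_SCHEME,
    LabelImage,
    LabelScheme,
    filter_dataset,
    is_noise_only,
)
from .metrics import MetricsReport, evaluate_subject
from .networks import (
    GeneratorSpec,
    PatchDiscriminator,
    UNetGenerator,
    build_discriminator,
    build_generator,
    instantiate_discriminator,
)
from .nn import Adam

LOG_COLUMNS = ("phase", "epoch", "iter", "pixel_kind",
               "L_cGAN_G", "L_pixel", "L_D_real", "L_D_fake")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 1
    jitter_resize: int = 68
    crop_size: int = 64
    seed: int = 0
    mode: str = "cgan"                    # {cgan, unet}
    pretrain_epochs: int | None = None
    pretrain_dataset: str | None = None

    def __post_init__(self):
        if self.jitter_resize <= self.crop_size:
            raise ValueError("jitter_resize must exceed crop_size")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.mode not in ("cgan", "unet"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def jitter(source: np.ndarray, label: LabelImage, crop_size: int, resize: int,
           rng: np.random.Generator) -> tuple[np.ndarray, LabelImage]:
    """Resize up (source bicubic, label nearest) then crop at one shared offset."""
    if resize <= crop_size:
        raise ValueError("resize must exceed crop_size")
    if source.shape != label.data.shape[:2]:
        raise ValueError("source and label are not congruent")
    src = _sk_resize(source, (resize, resize), order=3, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    lab = _sk_resize(label.data, (resize, resize, 3), order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True).astype(np.uint8)
    max_off = resize - crop_size
    oy = int(rng.integers(0, max_off + 1))
    ox = int(rng.integers(0, max_off + 1))
    src = src[oy:oy + crop_size, ox:ox + crop_size]
    lab = lab[oy:oy + crop_size, ox:ox + crop_size]
    return src, LabelImage(lab, subject_id=label.subject_id,
                           slice_index=label.slice_index)


def _to_net_source(source: np.ndarray) -> np.ndarray:
    """Grayscale [0,1] → (1,1,H,W) in [−1,1]."""
    return (2.0 * source - 1.0)[None, None]


def _to_net_label(label: np.ndarray) -> np.ndarray:
    """uint8 (H,W,3) → (1,3,H,W) in [−1,1]."""
    return (label.astype(np.float64) / 127.5 - 1.0).transpose(2, 0, 1)[None]


def _from_net_label(g: np.ndarray) -> np.ndarray:
    """(1,3,H,W) in [−1,1] → uint8 (H,W,3), rounded half-up."""
    arr = (g[0].transpose(1, 2, 0) + 1.0) * 127.5
    return np.clip(np.floor(arr + 0.5), 0, 255).astype(np.uint8)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# Checkpoint
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    """Complete training state: weights, optimiser moments, configs, history."""

    gen_spec: GeneratorSpec
    objective: obj.ObjectiveConfig
    train_config: TrainConfig
    epoch: int
    gen_state: dict[str, np.ndarray]
    opt_g_state: dict[str, np.ndarray]
    disc_variant: str | None = None
    disc_state: dict[str, np.ndarray] | None = None
    opt_d_state: dict[str, np.ndarray] | None = None
    loss_history: list[dict] = field(default_factory=list)

    def state_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for key in sorted(self.gen_state):
            h.update(np.ascontiguousarray(self.gen_state[key]).tobytes())
        if self.disc_state:
            for key in sorted(self.disc_state):
                h.update(np.ascontiguousarray(self.disc_state[key]).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        meta = {
            "gen_spec": asdict(self.gen_spec),
            "objective": asdict(self.objective),
            "train_config": asdict(self.train_config),
            "epoch": self.epoch,
            "disc_variant": self.disc_variant,
            "loss_history": self.loss_history,
        }
        arrays = {f"g_{k}": v for k, v in self.gen_state.items()}
        arrays.update({f"og_{k}": v for k, v in self.opt_g_state.items()})
        if self.disc_state is not None:
            arrays.update({f"d_{k}": v for k, v in self.disc_state.items()})
            arrays.update({f"od_{k}": v for k, v in self.opt_d_state.items()})
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            arrays = {k: npz[k] for k in npz.files if k != "meta"}
        gen_state = {k[2:]: v for k, v in arrays.items() if k.startswith("g_")}
        opt_g = {k[3:]: v for k, v in arrays.items() if k.startswith("og_")}
        disc_state = {k[2:]: v for k, v in arrays.items() if k.startswith("d_")
                      and not k.startswith("d_meta")}
        opt_d = {k[3:]: v for k, v in arrays.items() if k.startswith("od_")}
        return cls(
            gen_spec=GeneratorSpec(**meta["gen_spec"]),
            objective=obj.ObjectiveConfig(**meta["objective"]),
            train_config=TrainConfig(**meta["train_config"]),
            epoch=int(meta["epoch"]),
            gen_state=gen_state,
            opt_g_state=opt_g,
            disc_variant=meta["disc_variant"],
            disc_state=disc_state or None,
            opt_d_state=opt_d or None,
            loss_history=meta["loss_history"],
        )


# ---------------------------------------------------------------------------
# Training session
# ---------------------------------------------------------------------------

class _Session:
    """Networks + optimisers, either freshly initialised or restored."""

    def __init__(self, gen_spec: GeneratorSpec, disc_variant: str | None,
                 objective: obj.ObjectiveConfig, cfg: TrainConfig,
                 checkpoint: Checkpoint | None = None):
        self.gen_spec = gen_spec
        self.disc_variant = disc_variant
        self.objective = objective
        self.cfg = cfg
        self.generator: UNetGenerator = build_generator(
            gen_spec, rng=_rng(cfg.seed, 0))
        self.opt_g = Adam(self.generator.parameters(), lr=cfg.learning_rate,
                          beta1=cfg.beta1, beta2=cfg.beta2)
        self.discriminator: PatchDiscriminator | None = None
        self.opt_d: Adam | None = None
        if cfg.mode == "cgan":
            if disc_variant is None:
                raise ValueError("cgan mode needs a discriminator variant")
            spec = build_discriminator(disc_variant)
            self.discriminator = instantiate_discriminator(
                spec, source_channels=gen_spec.in_channels,
                label_channels=gen_spec.out_channels, rng=_rng(cfg.seed, 1))
            self.opt_d = Adam(self.discriminator.parameters(),
                              lr=cfg.learning_rate, beta1=cfg.beta1,
                              beta2=cfg.beta2)
        self.loss_history: list[dict] = []
        self.epoch = 0
        if checkpoint is not None:
            self.generator.load_state_dict(checkpoint.gen_state)
            self.opt_g.load_state_dict(checkpoint.opt_g_state)
            if self.discriminator is not None and checkpoint.disc_state:
                self.discriminator.load_state_dict(checkpoint.disc_state)
                self.opt_d.load_state_dict(checkpoint.opt_d_state)
            self.epoch = checkpoint.epoch
            self.loss_history = list(checkpoint.loss_history)

    def checkpoint(self) -> Checkpoint:
        return Checkpoint(
            gen_spec=self.gen_spec,
            objective=self.objective,
            train_config=self.cfg,
            epoch=self.epoch,
            gen_state=self.generator.state_dict(),
            opt_g_state=self.opt_g.state_dict(),
            disc_variant=self.disc_variant,
            disc_state=(self.discriminator.state_dict()
                        if self.discriminator else None),
            opt_d_state=self.opt_d.state_dict() if self.opt_d else None,
            loss_history=list(self.loss_history),
        )

    # -- one optimisation iteration on a single augmented pair ------------
    def _iteration(self, x: np.ndarray, y: np.ndarray, pixel_kind: str
                   ) -> dict[str, float]:
        cfg, objective = self.cfg, self.objective
        g_out = self.generator.forward(x)
        losses: dict[str, float] = {}

        if cfg.mode == "cgan":
            disc, opt_d = self.discriminator, self.opt_d
            # --- discriminator: real pair up, fake pair down ---
            opt_d.zero_grad()
            z_real = disc.forward(np.concatenate([x, y], axis=1))
            n = z_real.size
            s_real = _sigmoid(z_real)
            disc.backward((s_real - 1.0) / n)
            z_fake = disc.forward(np.concatenate([x, g_out], axis=1))
            s_fake = _sigmoid(z_fake)
            disc.backward(s_fake / n)
            opt_d.step()
            losses["L_D_real"] = float(-np.log(np.clip(s_real, obj.SCORE_EPS,
                                                       None)).mean())
            losses["L_D_fake"] = float(-np.log(np.clip(1 - s_fake, obj.SCORE_EPS,
                                                       None)).mean())
            # --- generator: non-saturating adversarial + λ·pixel ---
            self.opt_g.zero_grad()
            z_fake2 = disc.forward(np.concatenate([x, g_out], axis=1))
            s_fake2 = _sigmoid(z_fake2)
            g_in = disc.backward((s_fake2 - 1.0) / z_fake2.size)
            g_grad = g_in[:, x.shape[1]:]  # gradient w.r.t. the label channels
            losses["L_cGAN_G"] = float(-np.log(np.clip(s_fake2, obj.SCORE_EPS,
                                                       None)).mean())
            if objective.lambda_weight > 0:
                losses["L_pixel"] = obj.pixel_loss(pixel_kind, y, g_out)
                g_grad = g_grad + objective.lambda_weight * obj.pixel_loss_grad(
                    pixel_kind, y, g_out)
            else:
                losses["L_pixel"] = float("nan")
            self.generator.backward(g_grad)
            self.opt_g.step()
        else:
            self.opt_g.zero_grad()
            losses["L_pixel"] = obj.pixel_loss(pixel_kind, y, g_out)
            losses["L_cGAN_G"] = float("nan")
            losses["L_D_real"] = float("nan")
            losses["L_D_fake"] = float("nan")
            self.generator.backward(obj.pixel_loss_grad(pixel_kind, y, g_out))
            self.opt_g.step()
        return losses

    def run_epochs(self, pairs: list[SlicePair], end_epoch: int,
                   phase: str = "train") -> None:
        cfg = self.cfg
        if not pairs:
            raise ValueError("empty training set (after noise-only filtering)")
        size = pairs[0].source.shape[0]
        if cfg.crop_size != self.gen_spec.input_size:
            raise ValueError("crop_size must equal the generator input_size")
        if size != self.gen_spec.input_size:
            raise ValueError(
                f"dataset slices are {size}px but the generator expects "
                f"{self.gen_spec.input_size}px")
        self.generator.set_training(True)
        if self.discriminator is not None:
            self.discriminator.set_training(True)
        while self.epoch < end_epoch:
            epoch = self.epoch
            pixel_kind = obj.active_objective(self.objective, epoch) \
                if self.objective.pixel_loss != "none" else "none"
            order = _rng(cfg.seed, 3, epoch).permutation(len(pairs))
            for it, idx in enumerate(order):
                pair = pairs[int(idx)]
                src, lab = jitter(pair.source, pair.label, cfg.crop_size,
                                  cfg.jitter_resize, _rng(cfg.seed, 2, epoch, it))
                x = _to_net_source(src)
                y = _to_net_label(lab.data)
                losses = self._iteration(x, y, pixel_kind)
                row = {"phase": phase, "epoch": epoch, "iter": it,
                       "pixel_kind": pixel_kind, **losses}
                self.loss_history.append(row)
            self.epoch = epoch + 1


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def train(pairs: list[SlicePair], gen_spec: GeneratorSpec,
          disc_variant: str | None, objective: obj.ObjectiveConfig,
          cfg: TrainConfig, *, checkpoint: Checkpoint | None = None,
          end_epoch: int | None = None, phase: str = "train",
          keep_noise_only: bool = False) -> Checkpoint:
    """Train (or resume) and return the final checkpoint with its loss log."""
    usable = filter_dataset([(p.source, p.label) for p in pairs],
                            keep_noise_only=keep_noise_only)
    usable = [SlicePair(source=s, label=l) for s, l in usable]
    session = _Session(gen_spec, disc_variant, objective, cfg,
                       checkpoint=checkpoint)
    session.run_epochs(usable, end_epoch if end_epoch is not None else cfg.epochs,
                       phase=phase)
    return session.checkpoint()


def transfer_train(pretrain_pairs: list[SlicePair],
                   finetune_pairs: list[SlicePair],
                   gen_spec: GeneratorSpec, disc_variant: str | None,
                   objective: obj.ObjectiveConfig, cfg: TrainConfig
                   ) -> Checkpoint:
    """Pretrain on one dataset, then fine-tune the same weights on another.

    Runs ``cfg.pretrain_epochs`` epochs on the pretraining set followed by
    ``cfg.epochs − pretrain_epochs`` on the fine-tuning set; both phases are
    tagged in the loss log.  ``pretrain_epochs = 0`` reduces to plain training.
    """
    pre = cfg.pretrain_epochs if cfg.pretrain_epochs is not None else 20
    if not 0 <= pre <= cfg.epochs:
        raise ValueError("pretrain_epochs must lie in [0, epochs]")
    if pre == 0:
        return train(finetune_pairs, gen_spec, disc_variant, objective, cfg,
                     phase="finetune")
    ckpt = train(pretrain_pairs, gen_spec, disc_variant, objective, cfg,
                 end_epoch=pre, phase="pretrain")
    return train(finetune_pairs, gen_spec, disc_variant, objective, cfg,
                 checkpoint=ckpt, end_epoch=cfg.epochs, phase="finetune")


class _CheckpointSegmenter:
    """Runs the restored generator on source slices."""

    def __init__(self, checkpoint: Checkpoint):
        self.generator = build_generator(checkpoint.gen_spec,
                                         rng=np.random.default_rng(0))
        self.generator.load_state_dict(checkpoint.gen_state)
        # batch-size-1 batch norm acts as instance norm; inference keeps the
        # per-image statistics rather than the running averages
        self.generator.set_training(True)

    def predict(self, source: np.ndarray) -> np.ndarray:
        g = self.generator.forward(_to_net_source(source))
        return _from_net_label(g)


def segment(checkpoint: Checkpoint | _CheckpointSegmenter,
            sources: list[np.ndarray], subject_id: str = "",
            start_index: int = 0) -> list[LabelImage]:
    """Generator forward pass per slice (augmentation-free), order preserved."""
    seg = checkpoint if hasattr(checkpoint, "predict") \
        else _CheckpointSegmenter(checkpoint)
    out = []
    for k, src in enumerate(sources):
        pred = seg.predict(src)
        out.append(LabelImage(pred, subject_id=subject_id,
                              slice_index=start_index + k))
    return out


def evaluate(checkpoint: Checkpoint | _CheckpointSegmenter,
             test_pairs: list[SlicePair],
             scheme: LabelScheme = DEFAULT_SCHEME,
             include_noise_only: bool = False,
             which: tuple[str, ...] = ("dsc", "voe", "asd"),
             spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
             ) -> MetricsReport:
    """Segment the test set, stack per-subject 3D volumes and score them."""
    if not include_noise_only:
        test_pairs = [p for p in test_pairs if not is_noise_only(p.label)]
    seg = checkpoint if hasattr(checkpoint, "predict") \
        else _CheckpointSegmenter(checkpoint)
    report = MetricsReport()
    for subject, pairs in group_by_subject(test_pairs).items():
        preds = [seg.predict(p.source) for p in pairs]
        pred_vol = np.stack(preds, axis=0)
        truth_vol = np.stack([p.label.data for p in pairs], axis=0)
        report.per_subject[subject] = evaluate_subject(
            pred_vol, truth_vol, scheme=scheme, which=which, spacing=spacing)
    return report


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class SegmentationModel:
    """A segmentation network plus its training recipe, bound to a dataset.

    Parameters
    ----------
    train_pairs : list of SlicePair or path to a dataset directory
    gen_spec : generator architecture
    disc_variant : PatchGAN variant name, or None in unet mode
    objective, config : loss and optimisation settings
    """

    def __init__(self, train_pairs, gen_spec: GeneratorSpec,
                 objective: obj.ObjectiveConfig, config: TrainConfig,
                 disc_variant: str | None = "patch_70"):
        if isinstance(train_pairs, (str, Path)):
            train_pairs = load_dataset(train_pairs, split="train")
        self.train_pairs = train_pairs
        self.gen_spec = gen_spec
        self.objective = objective
        self.config = config
        self.disc_variant = disc_variant if config.mode == "cgan" else None

    @classmethod
    def from_dataset(cls, root: str | Path, gen_spec: GeneratorSpec,
                     objective: obj.ObjectiveConfig, config: TrainConfig,
                     disc_variant: str | None = "patch_70"):
        return cls(load_dataset(root, split="train"), gen_spec, objective,
                   config, disc_variant=disc_variant)

    def fit(self, pretrain_pairs=None) -> "TrainingResult":
        if pretrain_pairs is not None or self.config.pretrain_dataset:
            if pretrain_pairs is None:
                pretrain_pairs = load_dataset(self.config.pretrain_dataset,
                                              split="train")
            ckpt = transfer_train(pretrain_pairs, self.train_pairs,
                                  self.gen_spec, self.disc_variant,
                                  self.objective, self.config)
        else:
            ckpt = train(self.train_pairs, self.gen_spec, self.disc_variant,
                         self.objective, self.config)
        return TrainingResult(self, ckpt)


class TrainingResult:
    """Fitted segmentation network: checkpoint, loss log and evaluation."""

    def __init__(self, model: SegmentationModel, checkpoint: Checkpoint):
        self.model = model
        self.checkpoint = checkpoint
        self._segmenter = _CheckpointSegmenter(checkpoint)

    @property
    def loss_log(self) -> pd.DataFrame:
        return pd.DataFrame(self.checkpoint.loss_history, columns=LOG_COLUMNS)

    def save_loss_log(self, path: str | Path) -> None:
        self.loss_log.to_csv(path, index=False)

    def segment(self, sources: list[np.ndarray], subject_id: str = "") \
            -> list[LabelImage]:
        return segment(self._segmenter, sources, subject_id=subject_id)

    def evaluate(self, test_pairs, scheme: LabelScheme = DEFAULT_SCHEME,
                 include_noise_only: bool = False,
                 which: tuple[str, ...] = ("dsc", "voe", "asd")) -> MetricsReport:
        if isinstance(test_pairs, (str, Path)):
            test_pairs = load_dataset(test_pairs, split="test")
        return evaluate(self._segmenter, test_pairs, scheme=scheme,
                        include_noise_only=include_noise_only, which=which)

    def plot_losses(self, path: str | Path | None = None):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        log = self.loss_log
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        step = np.arange(len(log))
        axes[0].plot(step, log["L_cGAN_G"], label="adversarial (G)", lw=0.7)
        axes[0].plot(step, log["L_pixel"], label="pixel", lw=0.7)
        axes[0].set_title("generator losses")
        axes[1].plot(step, log["L_D_real"], label="D real", lw=0.7)
        axes[1].plot(step, log["L_D_fake"], label="D fake", lw=0.7)
        axes[1].axhline(np.log(2), ls="--", c="gray", lw=0.7,
                        label="log 2 equilibrium")
        axes[1].set_title("discriminator losses")
        for ax in axes:
            ax.set_xlabel("iteration")
            ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def summary(self) -> str:
        cfg, objective = self.model.config, self.model.objective
        spec = self.model.gen_spec
        log = self.loss_log
        buf = io.StringIO()
        print("Segmentation training summary", file=buf)
        print("=" * 60, file=buf)
        print(f"mode:            {cfg.mode}", file=buf)
        print(f"generator:       n_down={spec.n_down}, "
              f"min_channels={spec.min_channels}, input={spec.input_size}px, "
              f"max_channels={spec.max_channels}", file=buf)
        if self.model.disc_variant:
            print(f"discriminator:   {self.model.disc_variant}", file=buf)
        print(f"objective:       pixel={objective.pixel_loss}, "
              f"lambda={objective.lambda_weight}, "
              f"switch={objective.switch_epoch}", file=buf)
        print(f"epochs trained:  {self.checkpoint.epoch}", file=buf)
        print(f"iterations:      {len(log)}", file=buf)
        if len(log):
            last = log[log["epoch"] == log["epoch"].max()]
            with pd.option_context("display.float_format", "{:.4f}".format):
                means = last[["L_cGAN_G", "L_pixel", "L_D_real",
                              "L_D_fake"]].mean()
                print("final-epoch mean losses:", file=buf)
                print(means.to_string(), file=buf)
        return buf.getvalue()
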