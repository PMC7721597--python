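"""U-Net generator and PatchGAN discriminator architectures.

The generator is the classic image-to-image U-Net: ``n_down`` stride-2 4×4
convolutions halve the spatial size down to a bottleneck of
``input_size / 2**n_down`` pixels, and a mirror-symmetric decoder of stride-2
4×4 transposed convolutions doubles it back, with skip concatenations between
encoder/decoder layers of equal spatial size.  Channel widths start at
``min_channels`` and double per level, capped at
``channel_cap_factor × min_channels`` (cap factor 8, so minima 16/32/64/128
reach maxima 128/256/512/1024).

The discriminator is a conditional PatchGAN: a fully convolutional stack
scoring N×N input patches, where N is the receptive field of one output unit.
Four studied variants are provided — a 1×1 PixelGAN and 34×34 / 70×70 /
286×286 PatchGANs — and ``receptive_field`` computes N analytically with the
backward recurrence r ← r·s + (k − s) from r = 1 over the reversed layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

DISCRIMINATOR_VARIANTS = ("pixel_1", "patch_34", "patch_70", "patch_286")


@dataclass(frozen=True)
class ConvLayerSpec:
    kernel: int
    stride: int
    out_channels: int
    norm: str = "batch"          # {batch, none}
    activation: str = "leaky_relu"  # {leaky_relu, relu, tanh, sigmoid, none}
    direction: str = "down"      # {down, up}

    def __post_init__(self):
        if self.kernel < 1 or self.stride < 1 or self.out_channels < 1:
            raise ValueError("kernel, stride and out_channels must be >= 1")
        if self.norm not in ("batch", "none"):
            raise ValueError(f"unknown norm {self.norm!r}")
        if self.activation not in ("leaky_relu", "relu", "tanh", "sigmoid", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def padding(self) -> int:
        # 1 px zero-padding on 4×4 convolutions keeps the halving arithmetic
        # exact; 1×1 convolutions need none.
        return 1 if self.kernel == 4 else 0


@dataclass(frozen=True)
class GeneratorSpec:
    n_down: int = 9
    min_channels: int = 64
    input_size: int = 512
    in_channels: int = 1
    out_channels: int = 3
    channel_cap_factor: int = 8

    def __post_init__(self):
        if self.min_channels < 1:
            raise ValueError("min_channels must be >= 1")
        if self.n_down < 1:
            raise ValueError("n_down must be >= 1")
        if self.input_size % (2 ** self.n_down) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.n_down}")

    @property
    def max_channels(self) -> int:
        return self.channel_cap_factor * self.min_channels

    @property
    def encoder_channels(self) -> tuple[int, ...]:
        return tuple(min(self.min_channels * 2 ** i, self.max_channels)
                     for i in range(self.n_down))

    @property
    def bottleneck_size(self) -> int:
        return self.input_size // 2 ** self.n_down


@dataclass(frozen=True)
class DiscriminatorSpec:
    layers: tuple[ConvLayerSpec, ...]
    conditional: bool = True

    def __post_init__(self):
        if not self.layers:
            raise ValueError("discriminator needs at least one layer")
        if self.layers[-1].out_channels != 1:
            raise ValueError("final discriminator layer must have out_channels 1")
        if any(l.direction != "down" for l in self.layers):
            raise ValueError("discriminator layers must all be direction=down")


def build_discriminator(variant: str) -> DiscriminatorSpec:
    """Declarative layer stack for one of the four studied variants.

    Channel widths start at 64 and double per strided layer, capped at 512.
    The first layer and the output layer omit normalisation.
    """
    if variant == "pixel_1":
        plan = [(1, 1), (1, 1)]
    elif variant == "patch_34":
        plan = [(4, 2)] * 2 + [(4, 1)]
    elif variant == "patch_70":
        plan = [(4, 2)] * 3 + [(4, 1)]
    elif variant == "patch_286":
        plan = [(4, 2)] * 5 + [(4, 1)]
    else:
        raise ValueError(f"unknown discriminator variant {variant!r}; "
                         f"choose one of {DISCRIMINATOR_VARIANTS}")
    layers = []
    ch = 64
    for i, (k, s) in enumerate(plan):
        layers.append(ConvLayerSpec(
            kernel=k, stride=s, out_channels=ch,
            norm="none" if i == 0 else "batch", activation="leaky_relu"))
        if s > 1 or k == 1:  # double per strided layer (and across the PixelGAN stack)
            ch = min(ch * 2, 512)
    k_out = plan[-1][0]
    layers.append(ConvLayerSpec(kernel=k_out, stride=1, out_channels=1,
                                norm="none", activation="none"))
    return DiscriminatorSpec(layers=tuple(layers), conditional=True)


def receptive_field(spec: DiscriminatorSpec) -> int:
    """Input-pixel footprint of one output unit (padding-agnostic)."""
    r = 1
    for layer in reversed(spec.layers):
        r = r * layer.stride + (layer.kernel - layer.stride)
    return r


def empirical_receptive_field(spec: DiscriminatorSpec, input_size: int = 512,
                              seed: int = 0) -> int:
    """Measure the receptive field on an instantiated network.

    Builds a single-channel linear convolution chain with the spec's kernels,
    strides and paddings and strictly positive weights (so contributions never
    cancel), then backpropagates a delta from one central output unit and
    measures the spatial extent of the nonzero input gradient.
    """
    rng = np.random.default_rng(seed)
    chain = []
    for layer in spec.layers:
        conv = nn.Conv2d(1, 1, layer.kernel, layer.stride, layer.padding, rng=rng)
        conv.weight.value = np.abs(conv.weight.value) + 0.5
        conv.bias.value[...] = 0.0
        chain.append(conv)
    x = np.zeros((1, 1, input_size, input_size))
    h = x
    for conv in chain:
        h = conv.forward(h)
    if h.shape[2] < 1:
        raise ValueError("input_size too small for this layer stack")
    gy = np.zeros_like(h)
    gy[0, 0, h.shape[2] // 2, h.shape[3] // 2] = 1.0
    g = gy
    for conv in reversed(chain):
        g = conv.backward(g)
    rows = np.nonzero(g[0, 0].any(axis=1))[0]
    cols = np.nonzero(g[0, 0].any(axis=0))[0]
    extent_r = int(rows.max() - rows.min() + 1)
    extent_c = int(cols.max() - cols.min() + 1)
    if extent_r != extent_c:
        raise RuntimeError("anisotropic footprint; increase input_size")
    return extent_r


# ---------------------------------------------------------------------------
# Instantiated networks (numpy backend)
# ---------------------------------------------------------------------------

class _StatefulNet:
    """Shared parameter/state bookkeeping for generator and discriminator."""

    def _modules(self) -> list[nn.Sequential]:  # pragma: no cover
        raise NotImplementedError

    def parameters(self) -> list[nn.Parameter]:
        return [p for m in self._modules() for p in m.parameters()]

    def set_training(self, flag: bool) -> None:
        for m in self._modules():
            m.set_training(flag)

    def _bn_layers(self) -> list[nn.BatchNorm2d]:
        out = []
        for m in self._modules():
            out.extend(l for l in m.layers if isinstance(l, nn.BatchNorm2d))
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, p in enumerate(self.parameters()):
            state[f"p{i}"] = p.value.copy()
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn{i}_mean"] = bn.running_mean.copy()
            state[f"bn{i}_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"p{i}"]
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean[...] = state[f"bn{i}_mean"]
            bn.running_var[...] = state[f"bn{i}_var"]


class UNetGenerator(_StatefulNet):
    """Encoder–decoder with skip connections, built from a GeneratorSpec."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator | None = None,
                 dropout: float = 0.0):
        rng = rng or np.random.default_rng()
        self.spec = spec
        ch = spec.encoder_channels
        n = spec.n_down

        self.encoder: list[nn.Sequential] = []
        in_ch = spec.in_channels
        for i in range(n):
            blocks: list[nn.Layer] = [nn.Conv2d(in_ch, ch[i], 4, 2, 1, rng=rng)]
            # no norm on the first layer (raw image statistics) nor at the
            # bottleneck (spatial size can be 1×1, degenerate batch statistics)
            if 0 < i < n - 1:
                blocks.append(nn.BatchNorm2d(ch[i]))
            blocks.append(nn.LeakyReLU(0.2))
            self.encoder.append(nn.Sequential(*blocks))
            in_ch = ch[i]

        self.decoder: list[nn.Sequential] = []
        for j in range(n):
            dec_in = ch[n - 1] if j == 0 else 2 * ch[n - 1 - j]
            if j < n - 1:
                dec_out = ch[n - 2 - j]
                blocks = [nn.ConvTranspose2d(dec_in, dec_out, 4, 2, 1, rng=rng),
                          nn.BatchNorm2d(dec_out)]
                if dropout > 0 and j < 3:
                    blocks.append(nn.Dropout(dropout, rng=rng))
                blocks.append(nn.ReLU())
            else:
                blocks = [nn.ConvTranspose2d(dec_in, spec.out_channels, 4, 2, 1,
                                             rng=rng),
                          nn.Tanh()]
            self.decoder.append(nn.Sequential(*blocks))
        self._enc_acts: list[np.ndarray] | None = None

    def _modules(self):
        return self.encoder + self.decoder

    def forward(self, x: np.ndarray) -> np.ndarray:
        acts = []
        h = x
        for enc in self.encoder:
            h = enc.forward(h)
            acts.append(h)
        self._enc_acts = acts
        n = len(self.encoder)
        d = acts[-1]
        for j, dec in enumerate(self.decoder):
            if j > 0:
                d = np.concatenate([d, acts[n - 1 - j]], axis=1)
            d = dec.forward(d)
        return d

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n = len(self.encoder)
        skip_grads: list[np.ndarray | None] = [None] * n
        g = gy
        for j in range(n - 1, -1, -1):
            g = self.decoder[j].backward(g)
            if j > 0:
                ch_d = g.shape[1] // 2
                skip_grads[n - 1 - j] = g[:, ch_d:]
                g = g[:, :ch_d]
        # g is now the gradient reaching the bottleneck activation
        genc = g
        for i in range(n - 1, -1, -1):
            if skip_grads[i] is not None:
                genc = genc + skip_grads[i]
            genc = self.encoder[i].backward(genc)
        return genc

    __call__ = forward


class PatchDiscriminator(_StatefulNet):
    """Conditional patch discriminator instantiated from a DiscriminatorSpec.

    ``forward`` returns raw per-patch logits; ``scores`` maps them through a
    sigmoid into (0, 1).
    """

    def __init__(self, spec: DiscriminatorSpec, in_channels: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.spec = spec
        self.in_channels = in_channels
        blocks: list[nn.Layer] = []
        ch_in = in_channels
        for layer in spec.layers:
            blocks.append(nn.Conv2d(ch_in, layer.out_channels, layer.kernel,
                                    layer.stride, layer.padding, rng=rng))
            if layer.norm == "batch":
                blocks.append(nn.BatchNorm2d(layer.out_channels))
            if layer.activation == "leaky_relu":
                blocks.append(nn.LeakyReLU(0.2))
            elif layer.activation == "relu":
                blocks.append(nn.ReLU())
            elif layer.activation == "tanh":
                blocks.append(nn.Tanh())
            elif layer.activation == "sigmoid":
                blocks.append(nn.Sigmoid())
            ch_in = layer.out_channels
        self.net = nn.Sequential(*blocks)

    def _modules(self):
        return [self.net]

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.net.backward(gy)

    def scores(self, x: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.forward(x)))

    __call__ = forward


def build_generator(spec: GeneratorSpec, rng: np.random.Generator | None = None,
                    dropout: float = 0.0) -> UNetGenerator:
    """Instantiate the U-Net generator described by ``spec``."""
    return UNetGenerator(spec, rng=rng, dropout=dropout)


def instantiate_discriminator(spec: DiscriminatorSpec, source_channels: int = 1,
                              label_channels: int = 3,
                              rng: np.random.Generator | None = None
                              ) -> PatchDiscriminator:
    in_ch = source_channels + label_channels if spec.conditional else label_channels
    return PatchDiscriminator(spec, in_channels=in_ch, rng=rng)


def discriminator_forward(disc: PatchDiscriminator, source: np.ndarray,
                          label: np.ndarray) -> tuple[np.ndarray, float]:
    """Score a (source, label) pair: per-patch scores in (0,1) and their mean.

    ``source`` is (N,Cs,H,W), ``label`` (N,Cl,H,W); the conditional input is
    the channel-wise concatenation.
    """
    if source.shape[0] != label.shape[0] or source.shape[2:] != label.shape[2:]:
        raise ValueError("source and label shapes are incompatible")
    x = np.concatenate([source, label], axis=1) if disc.spec.conditional else label
    score_map = disc.scores(x)
    return score_map, float(score_map.mean())


# ---------------------------------------------------------------------------
# Layer tables for inspection / the CLI `arch` subcommand
# ---------------------------------------------------------------------------

def discriminator_table(spec: DiscriminatorSpec) -> str:
    rows = ["idx  kernel  stride  out_ch  norm   activation"]
    for i, l in enumerate(spec.layers):
        rows.append(f"{i:<4d} {l.kernel:<7d} {l.stride:<7d} {l.out_channels:<7d} "
                    f"{l.norm:<6s} {l.activation}")
    rows.append(f"receptive field: {receptive_field(spec)} px")
    return "\n".join(rows)


def generator_table(spec: GeneratorSpec) -> str:
    ch = spec.encoder_channels
    rows = [f"U-Net generator: input {spec.input_size}px, "
            f"bottleneck {spec.bottleneck_size}px, max channels {spec.max_channels}",
            "stage        out_ch  spatial"]
    size = spec.input_size
    for i, c in enumerate(ch):
        size //= 2
        rows.append(f"down {i:<7d} {c:<7d} {size}")
    for j in range(spec.n_down):
        size *= 2
        out = ch[spec.n_down - 2 - j] if j < spec.n_down - 1 else spec.out_channels
        rows.append(f"up   {j:<7d} {out:<7d} {size}")
    return "\n".join(rows)
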