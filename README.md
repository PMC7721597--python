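# kneeseg

Multi-tissue semantic segmentation of sagittal knee MR slices with a
conditional GAN (U-Net generator + PatchGAN discriminator) or a plain U-Net,
together with the colour-coded label scheme, volumetric accuracy metrics and
transfer-learning protocol that the approach relies on.  A synthetic knee
phantom generator makes every experiment runnable at desk scale on one CPU —
no MRI data download required.

## Who this is for

Researchers in musculoskeletal image analysis who want a tested, inspectable
reference implementation of adversarial image-to-image segmentation of up to
ten knee tissues — femur, tibia, patella, their cartilages, two medial
muscles, and both cruciate ligaments — including the details that are easy to
get subtly wrong: label encoding/decoding tolerances, receptive-field
arithmetic, loss switching mid-training, and surface-distance metrics.

## The model

The generator G maps a grayscale slice x to a 3-channel label map G(x); the
conditional discriminator D scores (x, label) pairs patch-wise.  Training
solves

    G* = arg min_G max_D  L_cGAN(G, D) + λ · L_pix(G)

with the value function

    L_cGAN(G, D) = E_{x,y}[log D(x, y)] + E_x[log(1 − D(x, G(x)))]

and a pixel loss L_pix ∈ {L1, L2, SmoothL1} weighted by λ ∈ {0, 0.01, 1, 100,
10000}.  Setting the adversarial term aside trains the same U-Net as a plain
regressor.  The pixel-loss kind can be switched once at a fixed epoch with
weights and optimiser state carried across (e.g. L2 for the first half, L1
for the second).

Tissues are colour-coded: bones in the blue channel (femur 50, tibia 100,
patella 150), cartilages in green (50/100/150), muscles in red (100/200),
ACL blue 200 and PCL green 200.  Predictions decode to Boolean masks by
keeping pixels within ±20 colour-scale units of each tissue's code, 2D
predictions stack into 3D volumes, and accuracy is reported per tissue as
DSC, VOE and average surface distance (ASD, mm), mean ± std across subjects.

The discriminator's patch size is its receptive field, computed analytically
by the backward recurrence r ← r·s + (k − s) from r = 1 over the reversed
layer stack: 1×1 (PixelGAN), 34×34, 70×70 (default) and 286×286 variants.

The networks run on a small numpy layer library included in `kneeseg.nn`
(im2col convolutions, transposed convolutions, batch norm, Adam) with
hand-written backward passes — no GPU framework needed.

## Worked example

```python
import numpy as np
from kneeseg import (GeneratorSpec, ObjectiveConfig, PhantomConfig,
                     SegmentationModel, TrainConfig, generate_dataset)

generate_dataset(PhantomConfig(seed=1), "phantoms")   # 10 subjects, 80/20 split

model = SegmentationModel.from_dataset(
    "phantoms",
    GeneratorSpec(n_down=5, min_channels=16, input_size=64),
    ObjectiveConfig(pixel_loss="L1", lambda_weight=100.0, adversarial=False),
    TrainConfig(epochs=10, learning_rate=2e-3, mode="unet", seed=7,
                crop_size=64, jitter_resize=68),
    disc_variant=None,
)
result = model.fit()
print(result.summary())
report = result.evaluate("phantoms", which=("dsc",))
for tissue, m in report.aggregate().items():
    print(f"{tissue:22s} DSC {m['dsc'][0]:.3f} ± {m['dsc'][1]:.3f}")
```

prints (about two minutes on one CPU):

```
Segmentation training summary
============================================================
mode:            unet
generator:       n_down=5, min_channels=16, input=64px, max_channels=128
objective:       pixel=L1, lambda=100.0, switch=None
epochs trained:  10
iterations:      640
final-epoch mean losses:
L_cGAN_G      NaN
L_pixel    0.0259
L_D_real      NaN
L_D_fake      NaN

femur                  DSC 0.868 ± 0.003
tibia                  DSC 0.910 ± 0.001
patella                DSC 0.616 ± 0.021
acl                    DSC 0.000 ± 0.000
femoral_cartilage      DSC 0.000 ± 0.000
tibial_cartilage       DSC 0.000 ± 0.000
patellar_cartilage     DSC 0.000 ± 0.000
pcl                    DSC 0.000 ± 0.000
vastus_medialis        DSC 0.481 ± 0.104
medial_gastrocnemius   DSC 0.488 ± 0.024
```

Ten epochs suffice for the two large bones (DSC ≈ 0.87–0.91 held out); small
structures — the 3–4 px patella, thin cartilage shells, ligaments — need far
longer training, exactly the size-dependent ordering seen on real knee MRI.

The same experiments are available from the shell:

```
kneeseg synth --out phantoms --seed 1
kneeseg train --data phantoms --config cfg.yaml --out ckpt.npz --seed 7
kneeseg segment --checkpoint ckpt.npz --images phantoms/images --out pred/
kneeseg evaluate --checkpoint ckpt.npz --data phantoms --out metrics.csv
kneeseg arch --variant patch_70          # layer table + receptive field
```

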