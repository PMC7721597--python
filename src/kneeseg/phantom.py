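"""Synthetic sagittal knee "phantom" slices with paired colour-coded labels.

Each subject is a short stack of 2D slices containing procedural stand-ins for
the ten annotated tissue classes: femur and tibia (large ellipses whose radii
taper toward the stack ends, emulating a 3D bone), a patella disc anterior to
the femur on central slices, 1–3 px cartilage shells on each bone's articular
edge, two posterior muscle blobs, and two thin oblique cruciate-ligament bands
in the joint gap on central slices.  Source intensities are tissue-dependent
means plus Gaussian noise, modulated by a smooth multiplicative bias field
(a sum of low-frequency cosine modes) that mimics RF coil non-uniformity.
A configurable fraction of slices at the stack periphery contains pure noise
with all-zero labels, mirroring how real acquisitions extend past the joint.

The geometry is deliberately procedural rather than anatomical: its purpose is
to exercise every class of the label scheme and give the networks a learnable
multi-tissue task at desk scale, not to simulate MR physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .data import SlicePair, write_dataset
from .label_codec import DEFAULT_SCHEME, LabelImage, LabelScheme, TissueMask, encode_labels

#: per-tissue (mean, std) source intensities on a [0, 1] scale; bones are the
#: unique brightest class so a noise-free threshold recovers them exactly.
DEFAULT_INTENSITIES: dict[str, tuple[float, float]] = {
    "femur": (0.85, 0.02),
    "tibia": (0.85, 0.02),
    "patella": (0.85, 0.02),
    "femoral_cartilage": (0.55, 0.03),
    "tibial_cartilage": (0.55, 0.03),
    "patellar_cartilage": (0.55, 0.03),
    "vastus_medialis": (0.40, 0.03),
    "medial_gastrocnemius": (0.40, 0.03),
    "acl": (0.25, 0.03),
    "pcl": (0.25, 0.03),
}

BACKGROUND_MEAN = 0.08


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 64
    n_subjects: int = 10
    slices_per_subject: int = 10
    seed: int = 0
    tissue_intensity: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITIES))
    background_noise_std: float = 0.03
    bias_field_amplitude: float = 0.15
    noise_only_fraction: float = 0.2
    geometry_jitter: float = 0.05
    geometry_scale: float = 1.0
    scheme: LabelScheme = DEFAULT_SCHEME

    def __post_init__(self):
        if self.image_size & (self.image_size - 1):
            raise ValueError("image_size must be a power of two")
        if self.slices_per_subject < 3:
            raise ValueError("need at least 3 slices per subject")
        if not 0 <= self.noise_only_fraction < 1:
            raise ValueError("noise_only_fraction must lie in [0, 1)")
        if not 0 <= self.bias_field_amplitude < 1:
            raise ValueError("bias_field_amplitude must lie in [0, 1)")
        for name, (mean, std) in self.tissue_intensity.items():
            if not 0.0 <= mean <= 1.0:
                raise ValueError(f"intensity mean for {name!r} outside [0, 1]")
        bone_mean, bone_std = self.tissue_intensity["femur"]
        if bone_mean - BACKGROUND_MEAN <= 2 * (bone_std + self.background_noise_std):
            raise ValueError("bone and background intensities are not separable")


def subject_seeds(cfg: PhantomConfig) -> list[int]:
    """Counter-based fan-out: one independent child seed per subject."""
    root = np.random.SeedSequence(cfg.seed)
    return [int(child.generate_state(1)[0]) for child in root.spawn(cfg.n_subjects)]


def _ellipse(size: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return ((yy - cy) / max(ry, 1e-9)) ** 2 + ((xx - cx) / max(rx, 1e-9)) ** 2 <= 1.0


def _dilate(mask: np.ndarray, px: int) -> np.ndarray:
    from scipy import ndimage
    return ndimage.binary_dilation(mask, iterations=px)


def _band(size: int, y0: float, x0: float, y1: float, x1: float,
          half_width: float) -> np.ndarray:
    """Thin oblique band: pixels within half_width of the segment (y0,x0)-(y1,x1)."""
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = y1 - y0, x1 - x0
    length2 = dy * dy + dx * dx
    t = np.clip(((yy - y0) * dy + (xx - x0) * dx) / length2, 0.0, 1.0)
    dist2 = (yy - (y0 + t * dy)) ** 2 + (xx - (x0 + t * dx)) ** 2
    return dist2 <= half_width ** 2


def _bias_field(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude·f, f a sum of 2–4 cosine modes."""
    if amplitude == 0:
        return np.ones((size, size))
    yy, xx = np.mgrid[0:size, 0:size] / size
    n_modes = rng.integers(2, 5)
    f = np.zeros((size, size))
    for _ in range(n_modes):
        fy, fx = rng.uniform(0.5, 1.5, size=2)
        py, px = rng.uniform(0, 2 * np.pi, size=2)
        f += np.cos(2 * np.pi * fy * yy + py) * np.cos(2 * np.pi * fx * xx + px)
    f /= np.abs(f).max()
    return 1.0 + amplitude * f


def _slice_masks(cfg: PhantomConfig, geom: dict[str, float], k: int,
                 n_anatomy: int) -> dict[str, np.ndarray]:
    """Boolean masks of all tissues present on anatomy slice k of n_anatomy."""
    s = cfg.image_size
    # bone radii taper toward the stack ends (ellipsoid cross-section profile)
    u = 2.0 * (k + 0.5) / n_anatomy - 1.0
    taper = float(np.sqrt(max(1.0 - 0.8 * u * u, 0.05)))
    central = abs(u) < 0.5

    g = geom
    femur = _ellipse(s, g["fem_cy"], g["fem_cx"], g["fem_ry"] * taper,
                     g["fem_rx"] * taper)
    tibia = _ellipse(s, g["tib_cy"], g["tib_cx"], g["tib_ry"] * taper,
                     g["tib_rx"] * taper)
    tibia &= ~femur  # blue channel: bones must stay disjoint
    masks: dict[str, np.ndarray] = {"femur": femur, "tibia": tibia}

    yy, xx = np.mgrid[0:s, 0:s]
    bones = femur | tibia

    # cartilage shells on the articular (joint-facing) edges
    fem_shell = _dilate(femur, 2) & ~bones & (yy > g["fem_cy"])
    tib_shell = _dilate(tibia, 2) & ~bones & (yy < g["tib_cy"])
    tib_shell &= ~fem_shell  # green channel disjointness where shells meet
    masks["femoral_cartilage"] = fem_shell
    masks["tibial_cartilage"] = tib_shell

    if central:
        patella = _ellipse(s, g["pat_cy"], g["pat_cx"], g["pat_r"], g["pat_r"])
        patella &= ~bones
        masks["patella"] = patella
        pat_shell = _dilate(patella, 1) & ~patella & ~bones & (xx > g["pat_cx"])
        pat_shell &= ~(fem_shell | tib_shell)
        masks["patellar_cartilage"] = pat_shell
        bones = bones | patella

        # oblique cruciate bands inside the joint gap, opposite obliquities
        gap_top, gap_bot = g["fem_cy"] + 2, g["tib_cy"] - 2
        acl = _band(s, gap_top, g["fem_cx"] - 6, gap_bot, g["fem_cx"] + 4, 1.2)
        pcl = _band(s, gap_top, g["fem_cx"] + 8, gap_bot, g["fem_cx"] - 2, 1.2)
        acl &= ~bones          # blue channel: keep clear of bones
        pcl &= ~acl
        carts = masks["femoral_cartilage"] | masks["tibial_cartilage"] \
            | masks["patellar_cartilage"]
        pcl &= ~carts          # green channel: keep clear of cartilage
        masks["acl"] = acl
        masks["pcl"] = pcl

    # posterior muscle blobs (posterior = large column index)
    vm = _ellipse(s, g["vm_cy"], g["vm_cx"], g["vm_ry"] * taper, g["vm_rx"] * taper)
    gm = _ellipse(s, g["gm_cy"], g["gm_cx"], g["gm_ry"] * taper, g["gm_rx"] * taper)
    vm &= ~bones
    gm &= ~bones & ~vm  # red channel disjointness
    masks["vastus_medialis"] = vm
    masks["medial_gastrocnemius"] = gm
    return masks


def _subject_geometry(cfg: PhantomConfig, rng: np.random.Generator) -> dict[str, float]:
    s = cfg.image_size
    j = cfg.geometry_jitter
    sc = cfg.geometry_scale

    def jit(base: float, scale: float = 1.0) -> float:
        return base * scale * (1.0 + rng.uniform(-j, j))

    return {
        "fem_cy": jit(0.28 * s), "fem_cx": jit(0.46 * s),
        "fem_ry": jit(0.15 * s, sc), "fem_rx": jit(0.19 * s, sc),
        "tib_cy": jit(0.72 * s), "tib_cx": jit(0.50 * s),
        "tib_ry": jit(0.13 * s, sc), "tib_rx": jit(0.20 * s, sc),
        "pat_cy": jit(0.38 * s), "pat_cx": jit(0.12 * s),
        "pat_r": jit(0.055 * s, sc),
        "vm_cy": jit(0.16 * s), "vm_cx": jit(0.84 * s),
        "vm_ry": jit(0.11 * s, sc), "vm_rx": jit(0.09 * s, sc),
        "gm_cy": jit(0.84 * s), "gm_cx": jit(0.84 * s),
        "gm_ry": jit(0.11 * s, sc), "gm_rx": jit(0.09 * s, sc),
    }


def _noise_slice_flags(cfg: PhantomConfig) -> list[bool]:
    n = cfg.slices_per_subject
    n_noise = int(round(cfg.noise_only_fraction * n))
    head = n_noise // 2
    tail = n_noise - head
    return [True] * head + [False] * (n - n_noise) + [True] * tail


def generate_subject(cfg: PhantomConfig, subject_seed: int,
                     subject_id: str = "subj") -> list[SlicePair]:
    """Deterministically render one subject's paired (source, label) slices."""
    rng = np.random.default_rng(subject_seed)
    geom = _subject_geometry(cfg, rng)
    flags = _noise_slice_flags(cfg)
    n_anatomy = sum(1 for f in flags if not f)
    s = cfg.image_size

    pairs: list[SlicePair] = []
    anatomy_idx = 0
    for slice_index, noise_only in enumerate(flags):
        bias = _bias_field(s, cfg.bias_field_amplitude, rng)
        source = rng.normal(BACKGROUND_MEAN, cfg.background_noise_std, (s, s))
        if noise_only:
            label = LabelImage(np.zeros((s, s, 3), dtype=np.uint8),
                               subject_id=subject_id, slice_index=slice_index)
        else:
            masks = _slice_masks(cfg, geom, anatomy_idx, n_anatomy)
            anatomy_idx += 1
            # paint faint-to-bright so brighter tissues overwrite at overlaps
            order = sorted(masks, key=lambda t: cfg.tissue_intensity[t][0])
            for tissue in order:
                mean, std = cfg.tissue_intensity[tissue]
                m = masks[tissue]
                source[m] = mean + rng.normal(0.0, std, int(m.sum()))
            label = encode_labels(
                {t: TissueMask(m, spacing=(1.0, 1.0), tissue_name=t)
                 for t, m in masks.items()},
                scheme=cfg.scheme, subject_id=subject_id, slice_index=slice_index)
        source = np.clip(source * bias, 0.0, 1.0)
        pairs.append(SlicePair(source=source, label=label))
    return pairs


def generate_dataset(cfg: PhantomConfig, out_dir: str | Path,
                     test_fraction: float = 0.2) -> Path:
    """Write a full phantom dataset (PNGs + manifest) with a subject-level split."""
    out_dir = Path(out_dir)
    seeds = subject_seeds(cfg)
    subjects: dict[str, list[SlicePair]] = {}
    for i, seed in enumerate(seeds):
        sid = f"subj{i:02d}"
        subjects[sid] = generate_subject(cfg, seed, subject_id=sid)
    n_test = max(1, int(round(test_fraction * cfg.n_subjects)))
    ids = list(subjects)
    splits = {sid: ("test" if i >= cfg.n_subjects - n_test else "train")
              for i, sid in enumerate(ids)}
    return write_dataset(out_dir, subjects, splits)


def perturb_domain(cfg: PhantomConfig, shift: float) -> PhantomConfig:
    """Related-but-different appearance domain for transfer experiments.

    Intensity means move by ``shift`` and geometry radii rescale by
    ``1 + shift``; raises if any mean would leave [0, 1].
    """
    new_intensity = {}
    for name, (mean, std) in cfg.tissue_intensity.items():
        new_mean = mean + shift
        if not 0.0 <= new_mean <= 1.0:
            raise ValueError(f"shift {shift} pushes {name!r} mean outside [0, 1]")
        new_intensity[name] = (new_mean, std)
    return replace(cfg, tissue_intensity=new_intensity,
                   geometry_scale=cfg.geometry_scale * (1.0 + shift))
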