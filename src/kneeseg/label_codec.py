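"""Colour-coded label maps for multi-tissue knee segmentation.

Each tissue is assigned one RGB channel and one 8-bit code: bones live in the
blue channel (femur 50, tibia 100, patella 150), cartilages in the green
channel (femoral 50, tibial 100, patellar 150), the two medial muscles in the
red channel (vastus medialis 100, medial gastrocnemius 200) and the cruciate
ligaments re-use blue (ACL 200) and green (PCL 200).  Networks are trained to
paint these codes; predictions are decoded back to Boolean tissue masks by
keeping pixels within ±tolerance (default 20) colour-scale units of the code.

Because different channels are written independently, tissues in different
channels may legitimately overlap (e.g. bone and its cartilage shell at a
shared boundary pixel); two tissues sharing one channel must never overlap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

CHANNELS = ("red", "green", "blue")


@dataclass(frozen=True)
class LabelScheme:
    """Tissue → (channel, code) table with a decode tolerance."""

    entries: tuple[tuple[str, str, int], ...]
    tolerance: int = 20

    def __post_init__(self):
        per_channel: dict[str, list[int]] = {}
        names = set()
        for name, channel, code in self.entries:
            if channel not in CHANNELS:
                raise ValueError(f"unknown channel {channel!r}")
            if not 1 <= code <= 255:
                raise ValueError(f"code {code} outside [1, 255] for {name!r}")
            if name in names:
                raise ValueError(f"duplicate tissue {name!r}")
            names.add(name)
            per_channel.setdefault(channel, []).append(code)
        for channel, codes in per_channel.items():
            codes = sorted(codes)
            for a, b in zip(codes, codes[1:]):
                if b - a <= 2 * self.tolerance:
                    raise ValueError(
                        f"codes {a} and {b} in {channel} channel are within "
                        f"2×tolerance ({2 * self.tolerance}); decoding would be ambiguous")

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(name for name, _, _ in self.entries)

    def lookup(self, tissue_name: str) -> tuple[int, int]:
        """Return (channel index, code) for a tissue."""
        for name, channel, code in self.entries:
            if name == tissue_name:
                return CHANNELS.index(channel), code
        raise KeyError(f"tissue {tissue_name!r} not in scheme")


#: Default scheme: the 10 knee-joint tissue classes across three channels.
DEFAULT_SCHEME = LabelScheme(entries=(
    ("femur", "blue", 50),
    ("tibia", "blue", 100),
    ("patella", "blue", 150),
    ("acl", "blue", 200),
    ("femoral_cartilage", "green", 50),
    ("tibial_cartilage", "green", 100),
    ("patellar_cartilage", "green", 150),
    ("pcl", "green", 200),
    ("vastus_medialis", "red", 100),
    ("medial_gastrocnemius", "red", 200),
))


@dataclass
class TissueMask:
    """Boolean raster (2D slice or 3D slice-stack) with physical spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, ...]
    tissue_name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise ValueError("spacing must give one value per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")


@dataclass
class LabelImage:
    """3-channel 8-bit label raster (H, W, 3)."""

    data: np.ndarray
    subject_id: str = ""
    slice_index: int = 0

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3 or data.shape[-1] != 3:
            raise ValueError("label image must have shape (H, W, 3)")
        if data.dtype != np.uint8:
            if data.min() < 0 or data.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            data = data.astype(np.uint8)
        self.data = data
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")


def encode_labels(masks: dict[str, TissueMask],
                  scheme: LabelScheme = DEFAULT_SCHEME,
                  subject_id: str = "", slice_index: int = 0) -> LabelImage:
    """Write per-tissue Boolean masks into one colour-coded label image.

    Channels are written independently, so tissues in different channels may
    overlap spatially; two masks sharing a channel must be disjoint.
    """
    shapes = {m.data.shape for m in masks.values()}
    if len(shapes) > 1:
        raise ValueError(f"masks have inconsistent shapes: {sorted(shapes)}")
    if not masks:
        raise ValueError("no masks given")
    shape = shapes.pop()
    if len(shape) != 2:
        raise ValueError("encode_labels expects 2D slices")
    out = np.zeros(shape + (3,), dtype=np.uint8)
    claimed = np.zeros(shape + (3,), dtype=bool)
    for name, mask in masks.items():
        ch, code = scheme.lookup(name)
        overlap = claimed[..., ch] & mask.data
        if overlap.any():
            raise ValueError(
                f"mask {name!r} overlaps another tissue in the same channel "
                f"at {int(overlap.sum())} pixel(s); ground truth is inconsistent")
        claimed[..., ch] |= mask.data
        out[..., ch][mask.data] = code
    return LabelImage(out, subject_id=subject_id, slice_index=slice_index)


def decode_tissue_mask(label: LabelImage, tissue_name: str,
                       scheme: LabelScheme = DEFAULT_SCHEME,
                       spacing: tuple[float, float] = (1.0, 1.0)) -> TissueMask:
    """Boolean mask of pixels within ±tolerance of the tissue's colour code."""
    ch, code = scheme.lookup(tissue_name)
    values = label.data[..., ch].astype(np.int16)
    mask = np.abs(values - code) <= scheme.tolerance
    return TissueMask(mask, spacing=spacing, tissue_name=tissue_name)


def is_noise_only(label: LabelImage) -> bool:
    """True iff the slice carries no annotation at all (every channel 0)."""
    return not label.data.any()


def filter_dataset(pairs: list[tuple[np.ndarray, LabelImage]],
                   keep_noise_only: bool = False):
    """Drop (source, label) pairs whose label is all-background, keeping order."""
    if keep_noise_only:
        return list(pairs)
    return [(src, lab) for src, lab in pairs if not is_noise_only(lab)]


def stack_slices(slices: list[TissueMask], slice_spacing: float) -> TissueMask:
    """Stack ordered congruent 2D masks into a 3D volume (leading axis = slice)."""
    if not slices:
        raise ValueError("cannot stack an empty slice list")
    shapes = {s.data.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")
    spacings = {s.spacing for s in slices}
    if len(spacings) > 1:
        raise ValueError("inconsistent in-plane spacings")
    if slice_spacing <= 0:
        raise ValueError("slice spacing must be positive")
    vol = np.stack([s.data for s in slices], axis=0)
    in_plane = slices[0].spacing
    return TissueMask(vol, spacing=(float(slice_spacing),) + in_plane,
                      tissue_name=slices[0].tissue_name)


# ---------------------------------------------------------------------------
# PNG / NIfTI interchange
# ---------------------------------------------------------------------------

_FNAME_RE = re.compile(r"^(?P<subject>.+)_(?P<slice>\d{4})\.png$")


def pair_filename(subject_id: str, slice_index: int) -> str:
    return f"{subject_id}_{slice_index:04d}.png"


def parse_pair_filename(name: str) -> tuple[str, int]:
    m = _FNAME_RE.match(name)
    if not m:
        raise ValueError(f"filename {name!r} does not match <subject>_<slice:04d>.png")
    return m.group("subject"), int(m.group("slice"))


def save_label_png(label: LabelImage, path: str | Path) -> None:
    Image.fromarray(label.data, mode="RGB").save(path)


def load_label_png(path: str | Path) -> LabelImage:
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.uint8)
    subject, idx = parse_pair_filename(path.name)
    return LabelImage(arr, subject_id=subject, slice_index=idx)


def save_source_png(image: np.ndarray, path: str | Path) -> None:
    """Save a grayscale source slice given as floats in [0, 1]."""
    arr = np.clip(np.rint(np.asarray(image) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_source_png(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
    return arr / 255.0


def save_mask_nifti(mask: TissueMask, path: str | Path) -> None:
    """Export a 3D Boolean mask with voxel spacing in the NIfTI header."""
    if mask.data.ndim != 3:
        raise ValueError("NIfTI export expects a 3D mask")
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine=np.diag(
        list(mask.spacing) + [1.0]))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def load_mask_nifti(path: str | Path, tissue_name: str = "") -> TissueMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TissueMask(data, spacing=spacing, tissue_name=tissue_name)
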