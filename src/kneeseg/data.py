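"""Paired image/label dataset layout shared by the phantom generator and the
training pipeline.

A dataset directory holds grayscale source slices under ``images/`` and
RGB colour-coded label maps under ``labels/``, both 8-bit PNG named
``<subject>_<slice:04d>.png``, plus a tab-separated ``manifest.tsv`` with one
row per slice: subject id, slice index, noise-only flag and train/test split.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .label_codec import (
    LabelImage,
    is_noise_only,
    load_label_png,
    load_source_png,
    pair_filename,
    save_label_png,
    save_source_png,
)

MANIFEST_COLUMNS = ("subject", "slice", "noise_only", "split")


@dataclass
class SlicePair:
    source: np.ndarray          # float64 grayscale in [0, 1]
    label: LabelImage

    @property
    def subject_id(self) -> str:
        return self.label.subject_id

    @property
    def slice_index(self) -> int:
        return self.label.slice_index


def write_dataset(root: str | Path, subjects: dict[str, list[SlicePair]],
                  splits: dict[str, str]) -> Path:
    """Write paired PNGs and the manifest; returns the manifest path."""
    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    (root / "labels").mkdir(parents=True, exist_ok=True)
    manifest = root / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(MANIFEST_COLUMNS)
        for subject, pairs in subjects.items():
            for pair in pairs:
                name = pair_filename(subject, pair.slice_index)
                save_source_png(pair.source, root / "images" / name)
                save_label_png(pair.label, root / "labels" / name)
                writer.writerow([subject, pair.slice_index,
                                 int(is_noise_only(pair.label)),
                                 splits[subject]])
    return manifest


def read_manifest(root: str | Path) -> list[dict]:
    root = Path(root)
    rows = []
    with open(root / "manifest.tsv", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append({"subject": row["subject"], "slice": int(row["slice"]),
                         "noise_only": bool(int(row["noise_only"])),
                         "split": row["split"]})
    return rows


def load_dataset(root: str | Path, split: str | None = None) -> list[SlicePair]:
    """Load (source, label) pairs, ordered by subject then slice index."""
    root = Path(root)
    rows = [r for r in read_manifest(root)
            if split is None or r["split"] == split]
    rows.sort(key=lambda r: (r["subject"], r["slice"]))
    pairs = []
    for r in rows:
        name = pair_filename(r["subject"], r["slice"])
        source = load_source_png(root / "images" / name)
        label = load_label_png(root / "labels" / name)
        pairs.append(SlicePair(source=source, label=label))
    return pairs


def group_by_subject(pairs: list[SlicePair]) -> dict[str, list[SlicePair]]:
    out: dict[str, list[SlicePair]] = {}
    for p in pairs:
        out.setdefault(p.subject_id, []).append(p)
    for subject in out:
        out[subject].sort(key=lambda p: p.slice_index)
    return out
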