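"""Volumetric segmentation accuracy metrics: DSC, VOE and symmetric ASD.

DSC = 2|X∩Y| / (|X| + |Y|) in [0, 1], 1 best.
VOE = 1 − |X∩Y| / |X∪Y| in [0, 1], 0 best; identically 1 − DSC/(2 − DSC).
ASD = symmetric average surface distance in mm: the mean, over both surfaces,
of each boundary voxel's Euclidean distance (voxel centre to voxel centre,
scaled by spacing) to the nearest boundary voxel of the other mask.

Surfaces are mask voxels with at least one face-adjacent neighbour outside
the mask (4-connected in 2D, 6-connected in 3D); raster borders count as
outside.  Empty-mask conventions: DSC(∅,∅)=1, VOE(∅,∅)=0, DSC(∅,·)=0,
and ASD is undefined (reported absent) when either mask is empty — matching
how a total segmentation failure scores 0.000.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .label_codec import DEFAULT_SCHEME, LabelScheme, TissueMask, decode_tissue_mask


def _check_congruent(x: TissueMask, y: TissueMask) -> None:
    if x.data.shape != y.data.shape:
        raise ValueError(f"mask shapes differ: {x.data.shape} vs {y.data.shape}")


def dsc(x: TissueMask, y: TissueMask) -> float:
    """Sørensen–Dice similarity coefficient."""
    _check_congruent(x, y)
    nx = int(x.data.sum())
    ny = int(y.data.sum())
    if nx == 0 and ny == 0:
        return 1.0
    inter = int((x.data & y.data).sum())
    return 2.0 * inter / (nx + ny)


def voe(x: TissueMask, y: TissueMask) -> float:
    """Volumetric overlap error."""
    _check_congruent(x, y)
    union = int((x.data | y.data).sum())
    if union == 0:
        return 0.0
    inter = int((x.data & y.data).sum())
    return 1.0 - inter / union


def surface_mask(mask: TissueMask) -> np.ndarray:
    """Boolean raster of boundary voxels (face adjacency, border = outside)."""
    if not mask.data.any():
        raise ValueError("surface of an empty mask is undefined")
    structure = ndimage.generate_binary_structure(mask.data.ndim, 1)
    interior = ndimage.binary_erosion(mask.data, structure=structure,
                                      border_value=0)
    return mask.data & ~interior


def extract_surface(mask: TissueMask) -> np.ndarray:
    """Physical (mm) coordinates of boundary voxel centres, shape (n, ndim)."""
    coords = np.argwhere(surface_mask(mask)).astype(np.float64)
    return coords * np.asarray(mask.spacing)


def asd(x: TissueMask, y: TissueMask) -> float:
    """Symmetric average surface distance in mm.

    Computed with Euclidean distance transforms of each surface (sampled at
    the voxel spacing), which equals the all-pairs nearest-distance between
    boundary voxel centres.
    """
    _check_congruent(x, y)
    if x.spacing != y.spacing:
        raise ValueError("masks must share one voxel spacing")
    if not x.data.any() or not y.data.any():
        raise ValueError("ASD is undefined for empty masks")
    sx = surface_mask(x)
    sy = surface_mask(y)
    dist_to_y = ndimage.distance_transform_edt(~sy, sampling=x.spacing)
    dist_to_x = ndimage.distance_transform_edt(~sx, sampling=x.spacing)
    total = dist_to_y[sx].sum() + dist_to_x[sy].sum()
    return float(total / (sx.sum() + sy.sum()))


@dataclass
class MetricsReport:
    """Per-tissue metrics for a set of test subjects plus mean ± std rows.

    ``per_subject`` maps subject id → tissue → {metric: value}; ASD entries
    are ``None`` where undefined.  Aggregation uses the unweighted mean and
    the population standard deviation across subjects.
    """

    per_subject: dict[str, dict[str, dict[str, float | None]]] = field(
        default_factory=dict)

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for tissue_map in self.per_subject.values():
            for t in tissue_map:
                if t not in seen:
                    seen.append(t)
        return seen

    def aggregate(self) -> dict[str, dict[str, tuple[float, float] | None]]:
        """tissue → metric → (mean, population std), skipping absent values."""
        out: dict[str, dict[str, tuple[float, float] | None]] = {}
        for tissue in self.tissues:
            out[tissue] = {}
            metric_names = sorted({m for s in self.per_subject.values()
                                   for m in s.get(tissue, {})})
            for metric in metric_names:
                vals = [s[tissue][metric] for s in self.per_subject.values()
                        if tissue in s and s[tissue].get(metric) is not None]
                if not vals:
                    out[tissue][metric] = None
                else:
                    arr = np.asarray(vals, dtype=np.float64)
                    out[tissue][metric] = (float(arr.mean()),
                                           float(arr.std(ddof=0)))
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: subject, tissue, metric, value (+ aggregate rows)."""
        rows = []
        for subject, tissue_map in self.per_subject.items():
            for tissue, metric_map in tissue_map.items():
                for metric, value in metric_map.items():
                    rows.append({"subject": subject, "tissue": tissue,
                                 "metric": metric, "value": value})
        for tissue, metric_map in self.aggregate().items():
            for metric, ms in metric_map.items():
                mean, std = ms if ms is not None else (np.nan, np.nan)
                rows.append({"subject": "mean", "tissue": tissue,
                             "metric": metric, "value": mean})
                rows.append({"subject": "std", "tissue": tissue,
                             "metric": metric, "value": std})
        return pd.DataFrame(rows)


def evaluate_masks(pred: dict[str, TissueMask], truth: dict[str, TissueMask],
                   which: tuple[str, ...] = ("dsc", "voe", "asd")
                   ) -> dict[str, dict[str, float | None]]:
    """Per-tissue metrics between two tissue→mask maps (one subject)."""
    out: dict[str, dict[str, float | None]] = {}
    for tissue in truth:
        p, t = pred[tissue], truth[tissue]
        metrics: dict[str, float | None] = {}
        if "dsc" in which:
            metrics["dsc"] = dsc(p, t)
        if "voe" in which:
            metrics["voe"] = voe(p, t)
        if "asd" in which:
            if p.data.any() and t.data.any():
                metrics["asd"] = asd(p, t)
            else:
                metrics["asd"] = None
        out[tissue] = metrics
    return out


def evaluate_subject(pred_volume: np.ndarray, truth_volume: np.ndarray,
                     scheme: LabelScheme = DEFAULT_SCHEME,
                     which: tuple[str, ...] = ("dsc", "voe", "asd"),
                     spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
                     ) -> dict[str, dict[str, float | None]]:
    """Decode every tissue from stacked (S,H,W,3) label volumes and score them."""
    if pred_volume.shape != truth_volume.shape:
        raise ValueError("prediction and truth volumes must be congruent")
    from .label_codec import LabelImage  # local import avoids cycle at module load

    def decode_all(vol: np.ndarray) -> dict[str, TissueMask]:
        masks = {}
        for tissue in scheme.tissues:
            slices = [decode_tissue_mask(LabelImage(vol[k]), tissue, scheme).data
                      for k in range(vol.shape[0])]
            masks[tissue] = TissueMask(np.stack(slices, axis=0), spacing=spacing,
                                       tissue_name=tissue)
        return masks

    return evaluate_masks(decode_all(pred_volume), decode_all(truth_volume),
                          which=which)
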