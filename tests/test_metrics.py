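"""DSC/VOE/ASD: worked examples, identities, and a brute-force surface oracle."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from kneeseg.label_codec import TissueMask, encode_labels
from kneeseg.metrics import (
    MetricsReport,
    asd,
    dsc,
    evaluate_subject,
    extract_surface,
    surface_mask,
    voe,
)


def mask3(arr, spacing=(1.0, 1.0, 1.0)):
    return TissueMask(np.asarray(arr, dtype=bool), spacing)


def brute_force_surface(data):
    """Independent oracle: voxels with a face-adjacent outside neighbour."""
    out = np.zeros_like(data)
    for idx in np.argwhere(data):
        for axis in range(data.ndim):
            for step in (-1, 1):
                nb = list(idx)
                nb[axis] += step
                if not (0 <= nb[axis] < data.shape[axis]) \
                        or not data[tuple(nb)]:
                    out[tuple(idx)] = True
    return out


def brute_force_asd(x, y, spacing):
    """Independent oracle: all-pairs nearest distances between surfaces."""
    sx = np.argwhere(brute_force_surface(x)) * np.asarray(spacing)
    sy = np.argwhere(brute_force_surface(y)) * np.asarray(spacing)
    d = cdist(sx, sy)
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(sx) + len(sy))


class TestOverlap:
    def test_identical_and_disjoint(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[:2] = True
        b = ~a
        assert dsc(mask3(a), mask3(a)) == 1.0
        assert dsc(mask3(a), mask3(b)) == 0.0
        assert voe(mask3(a), mask3(a)) == 0.0
        assert voe(mask3(a), mask3(b)) == 1.0

    def test_worked_examples(self):
        # |X| = |Y| = 4, |X∩Y| = 2 → DSC = 2·2/8 = 0.5
        x = np.zeros((1, 2, 4), dtype=bool)
        y = np.zeros((1, 2, 4), dtype=bool)
        x[0, 0, :4] = True
        y[0, 0, 2:] = True
        y[0, 1, :2] = True
        assert x.sum() == y.sum() == 4 and (x & y).sum() == 2
        assert dsc(mask3(x), mask3(y)) == pytest.approx(0.5)
        # intersect 2, union 6 → VOE = 1 − 2/6 = 2/3
        assert (x | y).sum() == 6
        assert voe(mask3(x), mask3(y)) == pytest.approx(2 / 3)

    def test_empty_conventions(self):
        e = mask3(np.zeros((3, 3, 3)))
        f = mask3(np.ones((3, 3, 3)))
        assert dsc(e, e) == 1.0
        assert voe(e, e) == 0.0
        assert dsc(e, f) == 0.0
        assert dsc(f, e) == 0.0

    def test_symmetry_and_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = mask3(rng.random((6, 6, 6)) < 0.4)
            y = mask3(rng.random((6, 6, 6)) < 0.4)
            d, v = dsc(x, y), voe(x, y)
            assert d == pytest.approx(dsc(y, x))
            assert v == pytest.approx(voe(y, x))
            assert v == pytest.approx(1 - d / (2 - d))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dsc(mask3(np.zeros((2, 2, 2))), mask3(np.zeros((3, 3, 3))))

    def test_dsc_invariant_to_stacking(self):
        rng = np.random.default_rng(1)
        xs = [rng.random((5, 5)) < 0.4 for _ in range(4)]
        ys = [rng.random((5, 5)) < 0.4 for _ in range(4)]
        pooled_inter = sum((a & b).sum() for a, b in zip(xs, ys))
        pooled_sizes = sum(a.sum() + b.sum() for a, b in zip(xs, ys))
        stacked = dsc(mask3(np.stack(xs)), mask3(np.stack(ys)))
        assert stacked == pytest.approx(2 * pooled_inter / pooled_sizes)


class TestSurface:
    def test_solid_cube_has_26_surface_voxels(self):
        cube = np.zeros((5, 5, 5), dtype=bool)
        cube[1:4, 1:4, 1:4] = True
        surf = surface_mask(mask3(cube))
        assert surf.sum() == 26  # all but the centre voxel
        np.testing.assert_array_equal(surf, brute_force_surface(cube))

    def test_single_voxel_and_rod(self):
        single = np.zeros((3, 3, 3), dtype=bool)
        single[1, 1, 1] = True
        assert surface_mask(mask3(single)).sum() == 1
        rod = np.zeros((1, 1, 7), dtype=bool)
        rod[0, 0, :] = True
        assert surface_mask(mask3(rod)).sum() == 7

    def test_physical_coordinates_scale_with_spacing(self):
        single = np.zeros((3, 3, 3), dtype=bool)
        single[1, 2, 1] = True
        coords = extract_surface(mask3(single, spacing=(2.0, 0.5, 1.0)))
        np.testing.assert_allclose(coords, [[2.0, 1.0, 1.0]])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            surface_mask(mask3(np.zeros((3, 3, 3))))


class TestASD:
    def test_identical_masks_have_zero_asd(self):
        rng = np.random.default_rng(2)
        m = mask3(rng.random((6, 6, 6)) < 0.5)
        if not m.data.any():
            pytest.skip("degenerate draw")
        assert asd(m, m) == 0.0

    @pytest.mark.parametrize("k,s", [(1, 1.0), (3, 1.0), (2, 0.5)])
    def test_parallel_planes_closed_form(self, k, s):
        # two 1-voxel-thick planes k slices apart at spacing s → ASD = k·s
        x = np.zeros((k + 2, 4, 4), dtype=bool)
        y = np.zeros_like(x)
        x[0] = True
        y[k] = True
        assert asd(mask3(x, (s, 1, 1)), mask3(y, (s, 1, 1))) \
            == pytest.approx(k * s)

    def test_345_triangle(self):
        x = np.zeros((5, 6, 2), dtype=bool)
        y = np.zeros_like(x)
        x[0, 0, 0] = True
        y[3, 4, 0] = True
        assert asd(mask3(x), mask3(y)) == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            shape = tuple(rng.integers(4, 9, size=3))
            spacing = tuple(rng.choice([0.5, 1.0, 2.0], size=3))
            x = rng.random(shape) < 0.35
            y = rng.random(shape) < 0.35
            if not x.any() or not y.any():
                continue
            ours = asd(mask3(x, spacing), mask3(y, spacing))
            oracle = brute_force_asd(x, y, spacing)
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_empty_mask_undefined(self):
        with pytest.raises(ValueError):
            asd(mask3(np.zeros((3, 3, 3))), mask3(np.ones((3, 3, 3))))


class TestEvaluation:
    def _volume(self, masks_per_slice):
        labels = [encode_labels(m).data for m in masks_per_slice]
        return np.stack(labels)

    def test_perfect_prediction(self):
        rng = np.random.default_rng(4)
        slices = []
        for _ in range(3):
            fem = rng.random((8, 8)) < 0.3
            slices.append({"femur": TissueMask(fem, (1, 1), "femur")})
        vol = self._volume(slices)
        result = evaluate_subject(vol, vol, which=("dsc", "voe", "asd"))
        assert result["femur"]["dsc"] == 1.0
        assert result["femur"]["voe"] == 0.0
        assert result["femur"]["asd"] == 0.0

    def test_missed_tissue_scores_zero_dsc_and_absent_asd(self):
        fem = np.zeros((8, 8), dtype=bool)
        fem[2:5, 2:5] = True
        truth = self._volume([{"femur": TissueMask(fem, (1, 1), "femur")}])
        pred = np.zeros_like(truth)
        result = evaluate_subject(pred, truth)
        assert result["femur"]["dsc"] == 0.0
        assert result["femur"]["asd"] is None

    def test_aggregation_mean_and_population_std(self):
        report = MetricsReport(per_subject={
            "a": {"femur": {"dsc": 0.8}},
            "b": {"femur": {"dsc": 1.0}},
        })
        mean, std = report.aggregate()["femur"]["dsc"]
        assert mean == pytest.approx(0.9)
        assert std == pytest.approx(0.1)  # population form, not n−1

    def test_report_frame_has_aggregate_rows(self):
        report = MetricsReport(per_subject={
            "a": {"femur": {"dsc": 0.8, "asd": None}},
        })
        frame = report.to_frame()
        assert set(frame["subject"]) == {"a", "mean", "std"}
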