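"""Metric correctness against exhaustive brute-force oracles on small masks."""

import math

import numpy as np
import pytest

from scaseg import (
    LabelVolume, MetricConfig, boundary_metrics, evaluate_batch,
    evaluate_case, overlap_metrics, surface_voxels,
)

# ----------------------------------------------------------------- oracles


def oracle_overlap(pred, truth):
    tp = fp = fn = tn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif t:
            fn += 1
        else:
            tn += 1
    nan = float("nan")
    return {
        "dsc": 2 * tp / (2 * tp + fp + fn) if tp + fp + fn else nan,
        "iou": tp / (tp + fp + fn) if tp + fp + fn else nan,
        "sensitivity": tp / (tp + fn) if tp + fn else nan,
        "specificity": tn / (tn + fp) if tn + fp else nan,
        "precision": tp / (tp + fp) if tp + fp else nan,
    }


def oracle_surface(mask):
    out = []
    shape = mask.shape
    for idx in np.ndindex(shape):
        if not mask[idx]:
            continue
        for ax in range(3):
            for d in (-1, 1):
                nb = list(idx)
                nb[ax] += d
                if not (0 <= nb[ax] < shape[ax]) or not mask[tuple(nb)]:
                    out.append(idx)
                    break
            else:
                continue
            break
    return sorted(out)


def oracle_boundary(pred, truth, spacing, tol, pct):
    sp = oracle_surface(pred)
    st = oracle_surface(truth)
    if not sp or not st:
        return None
    dist = lambda a, b: math.sqrt(sum(((x - y) * s) ** 2
                                      for x, y, s in zip(a, b, spacing)))
    pooled = [min(dist(a, b) for b in st) for a in sp]
    pooled += [min(dist(b, a) for a in sp) for b in st]
    pooled = np.asarray(pooled)
    return {
        "hd95_mm": float(np.percentile(pooled, pct)),
        "asd_mm": float(pooled.mean()),
        "nsd": float(np.mean(pooled <= tol)),
    }


def random_mask_pair(rng):
    shape = tuple(rng.integers(2, 7, 3))
    p = rng.random() * 0.6 + 0.2
    pred = rng.random(shape) < p
    truth = rng.random(shape) < p
    return pred, truth


# ------------------------------------------------------------------- tests


class TestOverlapMetrics:
    def test_identical_masks_all_one(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        out = overlap_metrics(m, m)
        for k in ("dsc", "iou", "sensitivity", "specificity", "precision"):
            assert out[k] == 1.0

    def test_shifted_cube_hand_count(self):
        # 2x2x2 cubes overlapping in a 1x2x2 slab: TP=4, FP=4, FN=4
        a = np.zeros((5, 4, 4), bool)
        b = np.zeros((5, 4, 4), bool)
        a[0:2, 0:2, 0:2] = True
        b[1:3, 0:2, 0:2] = True
        out = overlap_metrics(a, b)
        assert out["dsc"] == pytest.approx(0.5)
        assert out["iou"] == pytest.approx(1 / 3)

    def test_disjoint_masks_zero(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        out = overlap_metrics(a, b)
        for k in ("dsc", "iou", "sensitivity", "precision"):
            assert out[k] == 0.0

    def test_empty_truth_marks_sensitivity_missing(self):
        a = np.zeros((3, 3, 3), bool)
        a[0, 0, 0] = True
        out = overlap_metrics(a, np.zeros((3, 3, 3), bool))
        assert math.isnan(out["sensitivity"])
        out2 = overlap_metrics(np.zeros((3, 3, 3), bool), a)
        assert math.isnan(out2["precision"])


class TestSurfaceVoxels:
    def test_solid_cube_surface(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        surf = surface_voxels(m)
        assert len(surf) == 26  # all but the center voxel
        assert (2, 2, 2) not in {tuple(s) for s in surf}

    def test_single_voxel_is_its_own_surface(self):
        m = np.zeros((3, 3, 3), bool)
        m[1, 1, 1] = True
        assert [tuple(s) for s in surface_voxels(m)] == [(1, 1, 1)]

    def test_full_grid_surface_is_boundary(self):
        m = np.ones((4, 5, 6), bool)
        surf = {tuple(s) for s in surface_voxels(m)}
        boundary = {idx for idx in np.ndindex(m.shape)
                    if 0 in idx or idx[0] == 3 or idx[1] == 4 or idx[2] == 5}
        assert surf == boundary


class TestBoundaryMetrics:
    def test_identical_masks(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3, 1:3, 1:3] = True
        out = boundary_metrics(m, m)
        assert out["hd95_mm"] == 0.0
        assert out["asd_mm"] == 0.0
        assert out["nsd"] == 1.0

    def test_two_voxels_three_apart(self):
        a = np.zeros((6, 3, 3), bool)
        b = np.zeros((6, 3, 3), bool)
        a[1, 1, 1] = True
        b[4, 1, 1] = True
        out = boundary_metrics(a, b, spacing=(1, 1, 1))
        assert out["hd95_mm"] == pytest.approx(3.0)
        assert out["asd_mm"] == pytest.approx(3.0)
        assert out["nsd"] == 0.0

    def test_empty_mask_marks_missing(self):
        a = np.zeros((3, 3, 3), bool)
        b = np.ones((3, 3, 3), bool)
        out = boundary_metrics(a, b)
        assert all(math.isnan(v) for v in out.values())

    def test_scale_equivariance(self, rng):
        for _ in range(10):
            pred, truth = random_mask_pair(rng)
            if not pred.any() or not truth.any():
                continue
            base = boundary_metrics(pred, truth, (1, 1, 1), MetricConfig())
            scaled = boundary_metrics(pred, truth, (2.5, 2.5, 2.5),
                                      MetricConfig(nsd_tolerance_mm=2.5))
            assert scaled["hd95_mm"] == pytest.approx(2.5 * base["hd95_mm"])
            assert scaled["asd_mm"] == pytest.approx(2.5 * base["asd_mm"])
            assert scaled["nsd"] == pytest.approx(base["nsd"])

    def test_symmetry_under_swap(self, rng):
        for _ in range(10):
            pred, truth = random_mask_pair(rng)
            if not pred.any() or not truth.any():
                continue
            a = boundary_metrics(pred, truth)
            b = boundary_metrics(truth, pred)
            for k in a:
                assert a[k] == pytest.approx(b[k])


class TestOracleEquivalence:
    def test_hundred_seeded_random_pairs(self):
        rng = np.random.default_rng(2024)
        cfg = MetricConfig()
        spacing = (0.8, 1.0, 1.2)
        checked = 0
        while checked < 100:
            pred, truth = random_mask_pair(rng)
            ours = overlap_metrics(pred, truth)
            ref = oracle_overlap(pred, truth)
            for k in ref:
                if math.isnan(ref[k]):
                    assert math.isnan(ours[k])
                else:
                    assert ours[k] == pytest.approx(ref[k]), k
            assert [tuple(s) for s in surface_voxels(pred)] == oracle_surface(pred)
            ref_b = oracle_boundary(pred, truth, spacing,
                                    cfg.nsd_tolerance_mm, cfg.hd_percentile)
            if ref_b is not None:
                ours_b = boundary_metrics(pred, truth, spacing, cfg)
                for k in ref_b:
                    assert ours_b[k] == pytest.approx(ref_b[k]), k
            checked += 1


class TestEvaluateCase:
    def _labels(self, data):
        return LabelVolume(np.asarray(data, dtype=np.int16), spacing=(0.8, 0.8, 0.8))

    def test_perfect_prediction(self, rng):
        data = rng.integers(0, 4, (8, 8, 8))
        truth = self._labels(data)
        report = evaluate_case(self._labels(data), truth)
        for v in report.dsc_per_structure.values():
            assert v == 1.0
        assert report.full["dsc_full"] == 1.0
        assert report.full["hd95_mm"] == 0.0

    def test_missing_structure_reported_as_missing(self, rng):
        data = rng.integers(0, 3, (8, 8, 8))  # no mesencephalon (code 3)
        report = evaluate_case(self._labels(data), self._labels(data))
        assert math.isnan(report.dsc_per_structure["mesencephalon"])
        assert report.dsc_per_structure["pons"] == 1.0

    def test_dsc_iou_identity_on_union(self, rng):
        pred = self._labels(rng.integers(0, 4, (8, 8, 8)))
        truth = self._labels(rng.integers(0, 4, (8, 8, 8)))
        report = evaluate_case(pred, truth)
        dsc, iou = report.full["dsc_full"], report.full["iou"]
        assert dsc == pytest.approx(2 * iou / (1 + iou))

    def test_spacing_mismatch_rejected(self, rng):
        data = rng.integers(0, 4, (4, 4, 4)).astype(np.int16)
        with pytest.raises(ValueError, match="spacing"):
            evaluate_case(LabelVolume(data, spacing=(1, 1, 1)),
                          LabelVolume(data, spacing=(0.8, 0.8, 0.8)))

    def test_batch_appends_mean_and_sd_rows(self, rng):
        data = rng.integers(0, 4, (6, 6, 6))
        lab = self._labels(data)
        df = evaluate_batch([("a", lab, lab), ("b", lab, lab)])
        assert list(df["case"]) == ["a", "b", "mean", "sd"]
        assert df.loc[df["case"] == "mean", "dsc_full"].item() == 1.0
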