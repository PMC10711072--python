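"""Feature extraction: areas, percentiles, thresholds, SMWI weighting."""

import numpy as np
import pytest

from nigraquant.datatypes import (DegenerateMaskError, GeometryError, MaskSet,
                                  ThresholdPolicy, VolumeImage)
from nigraquant.features import (compute_smwi, contrast_range,
                                 extract_feature_vector, mask_area,
                                 mean_intensity_in_mask,
                                 nm_high_signal_threshold, thresholded_area)

DIMS = (0.5, 0.5, 1.0)


def _vol(data, modality="NM", dims=DIMS):
    return VolumeImage(np.asarray(data, dtype=float), dims, modality)


def _flat_mask(shape, n_true):
    m = np.zeros(shape, dtype=bool)
    m.ravel()[:n_true] = True
    return m


class TestMaskArea:
    def test_voxel_count_times_inplane_area(self):
        m = _flat_mask((10, 10, 1), 100)
        assert mask_area(m, DIMS) == pytest.approx(25.0)

    def test_additive_over_disjoint_masks(self, rng):
        a = np.zeros((8, 8, 3), dtype=bool)
        b = np.zeros((8, 8, 3), dtype=bool)
        a[:4][rng.random((4, 8, 3)) < 0.5] = True
        b[4:][rng.random((4, 8, 3)) < 0.5] = True
        assert mask_area(a | b, DIMS) == pytest.approx(
            mask_area(a, DIMS) + mask_area(b, DIMS))

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateMaskError):
            mask_area(np.zeros((4, 4, 1), dtype=bool), DIMS)


class TestMeanIntensity:
    def test_constant_volume(self):
        v = _vol(np.full((4, 4, 2), 7.5))
        assert mean_intensity_in_mask(v, np.ones((4, 4, 2), bool)) == 7.5

    def test_simple_values(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [1.0, 2.0, 3.0]
        assert mean_intensity_in_mask(_vol(data), np.ones((3, 1, 1), bool)) == 2.0

    def test_mask_outside_grid_raises(self):
        with pytest.raises(GeometryError):
            mean_intensity_in_mask(_vol(np.zeros((2, 2, 1))),
                                   np.ones((3, 3, 1), bool))


def _percentile_oracle(values, q):
    """Order-statistic percentile with linear interpolation, from scratch."""
    v = sorted(values)
    h = (len(v) - 1) * q / 100.0
    lo, hi = int(np.floor(h)), int(np.ceil(h))
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestContrastRange:
    def test_constant_values_give_unity(self):
        v = _vol(np.full((5, 5, 1), 3.3))
        assert contrast_range(v, np.ones((5, 5, 1), bool)) == pytest.approx(1.0)

    def test_matches_sort_based_oracle(self):
        vals = np.arange(1.0, 101.0)
        v = _vol(vals.reshape(10, 10, 1))
        expected = (_percentile_oracle(vals, 90)
                    / _percentile_oracle(vals, 10))
        got = contrast_range(v, np.ones((10, 10, 1), bool))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_random_values_match_oracle(self, rng):
        vals = rng.gamma(3.0, 2.0, size=77) + 0.5
        v = _vol(np.pad(vals, (0, 4)).reshape(9, 9, 1))
        mask = np.zeros(81, bool)
        mask[:77] = True
        got = contrast_range(v, mask.reshape(9, 9, 1))
        assert got == pytest.approx(_percentile_oracle(vals, 90)
                                    / _percentile_oracle(vals, 10))

    def test_invariant_to_positive_rescaling(self, rng):
        vals = rng.uniform(1, 5, size=50)
        mask = np.ones((50, 1, 1), bool)
        r1 = contrast_range(_vol(vals.reshape(50, 1, 1)), mask)
        r2 = contrast_range(_vol((7.3 * vals).reshape(50, 1, 1)), mask)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_nonpositive_p10_rejected(self):
        vals = np.concatenate([[-1.0] * 20, np.ones(30)])
        with pytest.raises(ValueError, match="10th percentile"):
            contrast_range(_vol(vals.reshape(50, 1, 1)),
                           np.ones((50, 1, 1), bool))

    def test_too_few_voxels_rejected(self):
        with pytest.raises(DegenerateMaskError):
            contrast_range(_vol(np.ones((3, 1, 1))), np.ones((3, 1, 1), bool))


def _masks_with_background(bg_values):
    shape = (10, 10, 1)
    sn = np.zeros(shape, bool)
    sn[0, :3, 0] = True
    bg = np.zeros(shape, bool)
    bg.ravel()[-len(bg_values):] = True
    data = np.zeros(shape)
    data[bg] = bg_values
    data[sn] = 999.0
    return _vol(data), MaskSet(sn, bg, (0, 0, 0))


class TestNMThreshold:
    def test_fixed_rule_mean_plus_k_sd(self):
        bg = np.array([90.0, 110.0] * 8)  # mean 100, sd 10
        vol, masks = _masks_with_background(bg)
        got = nm_high_signal_threshold(vol, masks, ThresholdPolicy(nm_k=3.0))
        assert got == pytest.approx(100.0 + 3.0 * 10.0)
        got0 = nm_high_signal_threshold(vol, masks, ThresholdPolicy(nm_k=0.0))
        assert got0 == pytest.approx(100.0)

    def test_zero_background_variance_warns(self):
        vol, masks = _masks_with_background(np.full(12, 50.0))
        with pytest.warns(UserWarning, match="zero background variance"):
            got = nm_high_signal_threshold(vol, masks, ThresholdPolicy())
        assert got == 50.0

    def test_auc_sweep_beats_grid_neighbours(self, rng):
        """Sweep cutoff maximises group-separation AUC over its grid."""
        from nigraquant.stats import empirical_auc

        shape = (6, 6, 1)
        mask = np.ones(shape, bool)
        bgm = np.zeros(shape, bool)
        cohort, labels = [], []
        sn = np.zeros(shape, bool)
        sn[:, :5, :] = True
        bgm = ~sn
        for i in range(30):
            patient = i % 2 == 1
            base = rng.normal(100 if patient else 130, 15, shape)
            vol = _vol(base)
            cohort.append((vol, MaskSet(sn, bgm, (0, 0, 0))))
            labels.append("patient" if patient else "control")
        policy = ThresholdPolicy(optimization_mode="auc_sweep")
        cutoff = nm_high_signal_threshold(cohort[0][0], cohort[0][1], policy,
                                          calibration=(cohort, labels))
        in_mask = [v.data[m.sn_mask] for v, m in cohort]
        y = np.array(labels) == "patient"

        def auc_at(c):
            areas = np.array([(v > c).sum() for v in in_mask], dtype=float)
            return empirical_auc(-areas, y)

        grid = np.unique(np.percentile(np.concatenate(in_mask),
                                       np.linspace(2, 98, 49)))
        assert auc_at(cutoff) >= max(auc_at(c) for c in grid) - 1e-12


class TestThresholdedArea:
    def test_counts_below_cutoff(self):
        data = np.array([60.0, 65.0, 75.0, 80.0]).reshape(4, 1, 1)
        got = thresholded_area(_vol(data, "QSM"), np.ones((4, 1, 1), bool),
                               70.0, "below", DIMS)
        assert got == pytest.approx(0.5)

    def test_all_fail_gives_zero(self):
        data = np.full((4, 1, 1), 90.0)
        got = thresholded_area(_vol(data, "QSM"), np.ones((4, 1, 1), bool),
                               70.0, "below", DIMS)
        assert got == 0.0

    def test_partition_property(self, rng):
        """below + above partition the mask for tie-free values."""
        data = rng.normal(size=(7, 5, 3))
        mask = rng.random((7, 5, 3)) < 0.6
        mask.ravel()[0] = True
        v = _vol(data)
        cut = float(data.mean())  # not an observed value, so no ties
        below = thresholded_area(v, mask, cut, "below", DIMS)
        above = thresholded_area(v, mask, cut, "above", DIMS)
        assert below + above == pytest.approx(mask_area(mask, DIMS))
        assert below <= mask_area(mask, DIMS)


class TestComputeSMWI:
    def test_weight_one_below_chi_low(self):
        qsm = _vol(np.full((3, 3, 1), 70.0), "QSM")
        mag = _vol(np.full((3, 3, 1), 50.0), "SWI_MAG")
        out = compute_smwi(qsm, mag)
        assert np.allclose(out.data, 50.0)
        assert out.modality == "SMWI"

    def test_weight_zero_above_chi_high(self):
        qsm = _vol(np.full((3, 3, 1), 200.0), "QSM")
        mag = _vol(np.full((3, 3, 1), 50.0), "SWI_MAG")
        assert np.allclose(compute_smwi(qsm, mag).data, 0.0)

    def test_midpoint_power(self):
        qsm = _vol(np.full((2, 2, 1), 120.0), "QSM")
        mag = _vol(np.full((2, 2, 1), 80.0), "SWI_MAG")
        out = compute_smwi(qsm, mag, chi_low=70, chi_high=170, power=4)
        assert np.allclose(out.data, 80.0 * 0.5**4)

    def test_monotone_nonincreasing_in_chi(self, rng):
        chis = np.sort(rng.uniform(0, 250, size=40))
        mag = _vol(np.full((40, 1, 1), 100.0), "SWI_MAG")
        out = compute_smwi(_vol(chis.reshape(40, 1, 1), "QSM"), mag)
        assert (np.diff(out.data.ravel()) <= 1e-12).all()
        assert (out.data <= 100.0 + 1e-12).all()

    def test_grid_mismatch_rejected(self):
        qsm = _vol(np.zeros((3, 3, 1)), "QSM")
        mag = _vol(np.zeros((4, 3, 1)), "SWI_MAG")
        with pytest.raises(GeometryError):
            compute_smwi(qsm, mag)


class TestExtraction:
    def test_round_trip_zero_noise(self, rendered_bundles):
        """Noiseless phantom extraction reproduces generator truth."""
        import warnings

        for b in rendered_bundles:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # flat noiseless background
                fv = extract_feature_vector(b.volumes, b.masks)
            for k, truth in b.truth_features.as_dict().items():
                if k == "composite":
                    continue
                assert getattr(fv, k) == pytest.approx(truth, rel=1e-9), k

    def test_permutation_invariance(self, rendered_bundles):
        """Shuffling in-mask voxel order leaves every feature unchanged.

        One permutation per grid, applied jointly to the co-registered
        volumes on that grid (QSM and its magnitude companion must move
        together, since SMWI is their voxel-wise product).
        """
        b = rendered_bundles[0]
        perm_volumes = {}
        rng = np.random.default_rng(0)
        perms = {grid: rng.permutation(int(ms.sn_mask.sum()))
                 for grid, ms in b.masks.items()}
        for mod, vol in b.volumes.items():
            grid = "NM" if mod == "NM" else "QSM"
            m = b.masks[grid].sn_mask
            data = vol.data.copy()
            data[m] = data[m][perms[grid]]
            perm_volumes[mod] = VolumeImage(data, vol.voxel_dims, vol.modality)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fv0 = extract_feature_vector(b.volumes, b.masks)
            fv1 = extract_feature_vector(perm_volumes, b.masks)
        for k, v in fv0.as_dict().items():
            if k == "composite":
                continue
            assert getattr(fv1, k) == pytest.approx(v, rel=1e-9), k

    def test_missing_modality_rejected(self, rendered_bundles):
        b = rendered_bundles[0]
        with pytest.raises(KeyError):
            extract_feature_vector({"NM": b.volumes["NM"]}, b.masks)
        vols = {"NM": b.volumes["NM"], "QSM": b.volumes["QSM"]}
        with pytest.raises(KeyError, match="SMWI"):
            extract_feature_vector(vols, b.masks)
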