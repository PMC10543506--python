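"""Thresholding, artifact masking, and connected-component foci counting."""

import numpy as np
import pytest

from octfoci import (
    BinaryMask,
    DetectionConfig,
    FormatError,
    PhantomConfig,
    build_artifact_mask,
    count_foci,
    detect_eye,
    generate_volume,
    threshold_slab,
    truth_slab_counts,
)
from octfoci.foci_detector import ArtifactMask

from conftest import flat_config


def otsu_sweep_oracle(image: np.ndarray) -> np.ndarray:
    """Exhaustive between-class-variance sweep: returns the optimal foreground."""
    vals = np.unique(image)
    best_fg, best_var = None, -1.0
    for cut in vals[:-1]:
        fg = image > cut
        w1, w0 = fg.mean(), 1 - fg.mean()
        if w1 == 0 or w0 == 0:
            continue
        var = w0 * w1 * (image[fg].mean() - image[~fg].mean()) ** 2
        if var > best_var:
            best_var, best_fg = var, fg
    return best_fg


class TestThresholdSlab:
    def test_zeros_give_empty_mask(self):
        bm = threshold_slab(np.zeros((8, 8)), method="otsu")
        assert not bm.mask.any()
        assert bm.threshold is None

    def test_two_level_otsu_exact(self):
        """Otsu on a two-level image recovers exactly the bright spots,
        matching an exhaustive between-class-variance sweep."""
        rng = np.random.default_rng(1)
        image = np.full((32, 32), 100, dtype=np.uint16)
        spots = rng.choice(32 * 32, size=20, replace=False)
        image.ravel()[spots] = 1000
        bm = threshold_slab(image, method="otsu")
        expected = otsu_sweep_oracle(image)
        assert np.array_equal(bm.mask, expected)
        assert bm.mask.sum() == 20

    def test_mean_k_sd_with_k0_is_mean_cut(self):
        rng = np.random.default_rng(2)
        image = rng.normal(100, 10, (16, 16))
        bm = threshold_slab(image, method="mean_k_sd", k_sd=0.0)
        assert np.array_equal(bm.mask, image >= image.mean())
        assert bm.threshold == pytest.approx(image.mean())

    def test_exclusion_changes_computed_threshold(self):
        rng = np.random.default_rng(4)
        image = rng.normal(100.0, 5.0, (10, 10))
        image[0] = 10_000.0  # artifact row
        exclude = np.zeros((10, 10), bool)
        exclude[0] = True
        with_excl = threshold_slab(image, "mean_k_sd", k_sd=2.0, exclude=exclude)
        without = threshold_slab(image, "mean_k_sd", k_sd=2.0)
        assert with_excl.threshold < without.threshold

    def test_threshold_monotonicity_of_area(self):
        """Raising the threshold never increases total foreground area."""
        rng = np.random.default_rng(3)
        image = rng.integers(0, 1000, (32, 32))
        areas = [
            int((image >= thr).sum()) for thr in np.linspace(0, 1000, 21)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))


class TestCountFoci:
    def make_mask(self, shape=(32, 32)):
        return np.zeros(shape, dtype=bool)

    def test_empty_mask_zero_count(self):
        table, n = count_foci(BinaryMask(self.make_mask(), slab=1))
        assert n == 0 and len(table) == 0

    def test_min_area_rule_drops_small_components(self):
        """A 2-px component is discarded, a 5-px one kept (>= 3 px rule)."""
        mask = self.make_mask()
        mask[2, 2:4] = True                 # 2 px
        mask[10, 10:13] = True              # 3 px across
        mask[10, 11] = mask[11, 11] = True  # grow to 5-px plus shape
        mask[20, 20:25] = True              # 5 px
        table, n = count_foci(BinaryMask(mask, slab=1), min_area=3)
        assert n == 2
        assert (table["area_px"] >= 3).all()

    def test_seven_programmatic_components(self):
        mask = self.make_mask()
        for i in range(7):
            b, a = 4 * (i // 3) + 2, 8 * (i % 3) + 2
            mask[b:b + 2, a:a + 2] = True  # 4-px squares, disjoint
        table, n = count_foci(BinaryMask(mask, slab=2), min_area=3)
        assert n == 7
        assert table["area_px"].tolist() == [4] * 7

    def test_connectivity_4_components_nest_in_8(self):
        """Each 4-connected component lies inside exactly one 8-connected one."""
        rng = np.random.default_rng(5)
        mask = rng.random((40, 40)) < 0.3
        from skimage.measure import label

        lab4 = label(mask, connectivity=1)
        lab8 = label(mask, connectivity=2)
        for comp in range(1, lab4.max() + 1):
            parents = np.unique(lab8[lab4 == comp])
            assert len(parents) == 1

    def test_diagonal_pair_counts_depend_on_connectivity(self):
        mask = self.make_mask()
        mask[5, 5] = mask[6, 6] = mask[4, 4] = True  # diagonal chain, 3 px
        _, n8 = count_foci(BinaryMask(mask, slab=1), min_area=3, connectivity=8)
        _, n4 = count_foci(BinaryMask(mask, slab=1), min_area=3, connectivity=4)
        assert n8 == 1 and n4 == 0  # 4-connectivity splits it into 1-px bits

    def test_artifact_exclusion_monotone(self):
        """Enlarging the artifact mask never increases the count."""
        rng = np.random.default_rng(6)
        mask = rng.random((32, 32)) < 0.1
        base = BinaryMask(mask, slab=1)
        counts = []
        art = np.zeros((32, 32), bool)
        for rows in (0, 8, 16, 32):
            art2 = art.copy()
            art2[:rows] = True
            counts.append(count_foci(base, ArtifactMask(art2), min_area=1)[1])
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(FormatError):
            count_foci(BinaryMask(self.make_mask()), ArtifactMask(np.zeros((2, 2), bool)))


class TestArtifactMask:
    def test_clean_phantom_gives_empty_mask(self):
        vol, surf, _ = generate_volume(flat_config(seed=3))
        art = build_artifact_mask(vol, surf)
        assert not art.mask.any()

    def test_drusen_bump_is_masked(self):
        """A drusen elevation above the cutoff is covered by the drusen mask."""
        cfg = PhantomConfig(n_drusen=1, n_vessels=0, speckle_sigma=0.0,
                            drusen_max_elev_px=10.0, seed=12)
        vol, surf, _ = generate_volume(cfg)
        art = build_artifact_mask(vol, surf)
        assert art.drusen_px > 0
        # the masked region contains the maximum-elevation position
        from scipy import ndimage

        smooth = ndimage.gaussian_filter(surf.z_rpe, sigma=10.0, mode="nearest")
        peak = np.unravel_index(np.argmax(smooth - surf.z_rpe), surf.shape)
        assert art.mask[peak]

    def test_vessels_are_masked(self):
        cfg = PhantomConfig(n_drusen=0, n_vessels=3, speckle_sigma=0.0, seed=13)
        vol, surf, _ = generate_volume(cfg)
        art = build_artifact_mask(vol, surf)
        assert art.vessel_px > 0
        assert art.mask.mean() < 0.35

    def test_user_mask_dimension_mismatch(self):
        vol, surf, _ = generate_volume(flat_config(seed=3))
        with pytest.raises(FormatError):
            build_artifact_mask(vol, surf, user_mask=np.zeros((2, 2), bool))


class TestDetectEye:
    def test_noise_free_counts_equal_ledger(self, clean_detection):
        cfg = PhantomConfig(foci_per_slab={1: 3, 2: 4, 3: 2}, n_drusen=0,
                            n_vessels=0, speckle_sigma=0.0, seed=21)
        vol, surf, ledger = generate_volume(cfg)
        counts, lesions, _, _ = detect_eye(vol, surf, clean_detection)
        assert np.array_equal(counts.counts, truth_slab_counts(ledger, 5))
        assert counts.total == counts.counts.sum()

    def test_zero_foci_zero_counts(self, clean_detection):
        vol, surf, _ = generate_volume(flat_config(seed=22))
        counts, lesions, _, _ = detect_eye(vol, surf, clean_detection)
        assert counts.total == 0 and len(lesions) == 0

    def test_total_user_mask_suppresses_all_counts(self, clean_detection):
        cfg = PhantomConfig(foci_per_slab={1: 3, 2: 2}, n_drusen=0, n_vessels=0,
                            speckle_sigma=0.0, seed=23)
        vol, surf, _ = generate_volume(cfg)
        full = np.ones((vol.n_bscans, vol.n_ascans), dtype=bool)
        counts, _, _, _ = detect_eye(vol, surf, clean_detection, user_mask=full)
        assert counts.total == 0

    def test_invalid_config_rejected(self, clean_phantom):
        _, vol, surf, _ = clean_phantom
        with pytest.raises(Exception):
            detect_eye(vol, surf, DetectionConfig(connectivity=6))
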