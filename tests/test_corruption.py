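"""Corruption masks: samplers, area rule, rotations, banks, application."""

import numpy as np
import pytest
from scipy.stats import chisquare

from inpaintseg.corruption import (
    MaskBank,
    PredictionMask,
    RestorationMask,
    apply_prediction,
    apply_restoration,
    build_mask_bank,
    build_prediction_mask,
    build_restoration_mask,
    draw_mask,
    load_mask_bank,
    rotate_mask,
    sample_anchors_poisson,
    sample_anchors_random,
    save_mask_bank,
)


def _pairwise_min_dist(anchors):
    pts = np.asarray(anchors, dtype=float)
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min()


def _rects_disjoint(anchors, k):
    """Brute-force axis-aligned rectangle intersection over all pairs."""
    pts = np.asarray(anchors)
    dr = np.abs(pts[:, None, 0] - pts[None, :, 0])
    dc = np.abs(pts[:, None, 1] - pts[None, :, 1])
    overlap = (dr < k) & (dc < k)
    np.fill_diagonal(overlap, False)
    return not overlap.any()


class TestRandomSampler:
    def test_degenerate_domain_single_anchor(self):
        gen = sample_anchors_random((16, 16), 16, np.random.default_rng(0))
        assert all(next(gen) == (0, 0) for _ in range(20))

    def test_anchors_in_bounds(self):
        rng = np.random.default_rng(1)
        gen = sample_anchors_random((40, 60), 8, rng)
        for _ in range(500):
            r, c = next(gen)
            assert 0 <= r <= 32 and 0 <= c <= 52

    def test_empirical_uniformity_chi_square(self):
        # 1e5 draws over the 17x17 anchor lattice of a 24x24 image with K=8
        rng = np.random.default_rng(2)
        gen = sample_anchors_random((24, 24), 8, rng)
        counts = np.zeros((17, 17))
        for _ in range(100_000):
            r, c = next(gen)
            counts[r, c] += 1
        _, p = chisquare(counts.ravel())
        assert p > 0.01

    def test_patch_too_large_is_an_error(self):
        with pytest.raises(ValueError):
            next(sample_anchors_random((16, 16), 17, np.random.default_rng(0)))


class TestPoissonSampler:
    def test_min_center_distance_k_sqrt2(self):
        rng = np.random.default_rng(3)
        pts = sample_anchors_poisson((512, 512), 64, rng, 16)
        assert _pairwise_min_dist(pts) >= 64 * np.sqrt(2) - 1e-9  # 90.50...

    def test_patches_pairwise_disjoint_brute_force(self):
        rng = np.random.default_rng(4)
        for k in (16, 32):
            pts = sample_anchors_poisson((256, 256), k, rng, (256 * 256 // 4) // k**2)
            assert _rects_disjoint(pts, k)

    def test_sixteen_disjoint_64_patches_are_exactly_quarter_area(self):
        rng = np.random.default_rng(5)
        mask = build_prediction_mask((512, 512), 64, "poisson", rng)
        assert len(mask.anchors) == 16
        assert mask.covered_fraction == 0.25

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError):
            sample_anchors_poisson((64, 64), 32, np.random.default_rng(0), 2)


class TestAreaRule:
    @pytest.mark.parametrize("sampler", ["random", "poisson"])
    def test_prediction_coverage_at_least_quarter(self, sampler):
        rng = np.random.default_rng(6)
        mask = build_prediction_mask((512, 512), 32, sampler, rng)
        assert mask.covered_fraction >= 0.25

    def test_random_overshoot_below_one_patch_area(self):
        h = w = 128
        k = 16
        rng = np.random.default_rng(7)
        for _ in range(1000):
            mask = build_prediction_mask((h, w), k, "random", rng)
            assert 0.25 <= mask.covered_fraction < 0.25 + k * k / (h * w)

    @pytest.mark.parametrize("sampler", ["random", "poisson"])
    def test_restoration_coverage_and_pair_disjointness(self, sampler):
        rng = np.random.default_rng(8)
        mask = build_restoration_mask((512, 512), 32, sampler, rng)
        assert mask.covered_fraction >= 0.25
        k = mask.patch_size
        for (r1, c1), (r2, c2) in mask.pairs:
            assert abs(r1 - r2) >= k or abs(c1 - c2) >= k

    def test_poisson_restoration_eight_pairs_at_k64(self):
        rng = np.random.default_rng(9)
        mask = build_restoration_mask((512, 512), 64, "poisson", rng)
        assert len(mask.pairs) == 8
        assert mask.covered_fraction == 0.25


class TestApply:
    def test_prediction_zeroes_only_masked_pixels(self, mri_arrays):
        images, _ = mri_arrays
        rng = np.random.default_rng(10)
        mask = build_prediction_mask((64, 64), 16, "random", rng)
        out = apply_prediction(images[0], mask)
        cov = mask.covered
        assert np.all(out[..., cov] == 0)
        assert np.array_equal(out[..., ~cov], images[0][..., ~cov])

    def test_prediction_on_all_zero_image_is_fixed_point(self):
        mask = build_prediction_mask((64, 64), 16, "random", np.random.default_rng(0))
        z = np.zeros((64, 64), dtype=np.float32)
        assert np.array_equal(apply_prediction(z, mask), z)

    def test_multichannel_corruption_identical_across_channels(self):
        rng = np.random.default_rng(11)
        img = rng.normal(size=(3, 64, 64)).astype(np.float32)
        pmask = build_prediction_mask((64, 64), 16, "poisson", rng)
        out = apply_prediction(img, pmask)
        zero_sets = [set(zip(*np.nonzero(out[c] == 0))) for c in range(3)]
        assert zero_sets[0] >= set(zip(*np.nonzero(pmask.covered)))
        rmask = build_restoration_mask((64, 64), 16, "random", rng)
        rout = apply_restoration(img, rmask)
        changed = [rout[c] != img[c] for c in range(3)]
        # pixels the swap moved are the same coordinates in every channel
        assert np.array_equal(changed[0], changed[1])
        assert np.array_equal(changed[0], changed[2])

    def test_restoration_preserves_pixel_multiset_exactly(self):
        rng = np.random.default_rng(12)
        img = rng.normal(size=(64, 64)).astype(np.float32)
        mask = build_restoration_mask((64, 64), 8, "random", rng)
        out = apply_restoration(img, mask)
        assert np.array_equal(np.sort(out.ravel()), np.sort(img.ravel()))

    def test_restoration_twice_with_disjoint_pairs_is_identity(self):
        rng = np.random.default_rng(13)
        img = rng.normal(size=(64, 64)).astype(np.float32)
        mask = build_restoration_mask((64, 64), 16, "poisson", rng)  # all disjoint
        assert np.array_equal(apply_restoration(apply_restoration(img, mask), mask), img)

    def test_constant_image_is_fixed_point_of_restoration(self):
        mask = build_restoration_mask((64, 64), 16, "random", np.random.default_rng(1))
        c = np.full((64, 64), 3.5, dtype=np.float32)
        assert np.array_equal(apply_restoration(c, mask), c)

    def test_shape_mismatch_rejected(self):
        mask = build_prediction_mask((64, 64), 16, "random", np.random.default_rng(0))
        with pytest.raises(ValueError):
            apply_prediction(np.zeros((32, 32)), mask)


class TestRotation:
    def test_four_quarter_turns_identity(self):
        rng = np.random.default_rng(14)
        mask = build_prediction_mask((64, 64), 16, "random", rng)
        out = mask
        for _ in range(4):
            out = rotate_mask(out, 1)
        assert out.anchors == mask.anchors

    def test_half_turn_coordinate_algebra(self):
        mask = PredictionMask(8, ((3, 5),), (32, 32))
        rot = rotate_mask(mask, 2)
        assert rot.anchors == ((32 - 3 - 8, 32 - 5 - 8),)

    def test_rotation_matches_np_rot90_on_covered_grid(self):
        rng = np.random.default_rng(15)
        mask = build_prediction_mask((64, 64), 16, "poisson", rng)
        for q in (1, 2, 3):
            rot = rotate_mask(mask, q)
            assert np.array_equal(rot.covered, np.rot90(mask.covered, q))
            assert rot.n_covered == mask.n_covered

    def test_restoration_rotation_preserves_pairing(self):
        rng = np.random.default_rng(16)
        mask = build_restoration_mask((64, 64), 16, "random", rng)
        rot = rotate_mask(mask, 2)
        assert len(rot.pairs) == len(mask.pairs)
        assert np.array_equal(rot.covered, np.rot90(mask.covered, 2))

    def test_non_square_quarter_turn_rejected(self):
        mask = PredictionMask(8, ((0, 0),), (32, 64))
        with pytest.raises(ValueError):
            rotate_mask(mask, 1)
        assert rotate_mask(mask, 2).image_shape == (32, 64)


class TestMaskBank:
    def test_effective_size_arithmetic(self):
        bank = build_mask_bank("prediction", "random", 16, (64, 64), n_base=5, rng=0)
        assert len(bank) == 5
        assert bank.effective_size == 20

    def test_same_seed_identical_bank(self):
        a = build_mask_bank("restoration", "random", 16, (64, 64), n_base=4, rng=3)
        b = build_mask_bank("restoration", "random", 16, (64, 64), n_base=4, rng=3)
        assert all(x.pairs == y.pairs for x, y in zip(a.base_masks, b.base_masks))

    def test_draw_frequencies_uniform_over_variants(self):
        # 2 base masks x 4 rotations = 8 variants, each with probability 1/8
        bank = build_mask_bank("prediction", "random", 16, (32, 32), n_base=2, rng=4)
        rng = np.random.default_rng(17)
        counts = {}
        n = 100_000
        for _ in range(n):
            m = draw_mask(bank, rng)
            counts[m.anchors] = counts.get(m.anchors, 0) + 1
        assert len(counts) == 8
        p = 1 / 8
        sigma = np.sqrt(p * (1 - p) / n)
        for c in counts.values():
            assert abs(c / n - p) <= 3 * sigma

    def test_drawn_mask_satisfies_invariants(self):
        bank = build_mask_bank("restoration", "poisson", 16, (64, 64), n_base=3, rng=5)
        rng = np.random.default_rng(18)
        for _ in range(20):
            m = draw_mask(bank, rng)
            assert isinstance(m, RestorationMask)
            assert m.covered_fraction >= 0.25

    def test_empty_bank_rejected(self):
        bank = MaskBank("prediction", "random", 16, (64, 64), ())
        with pytest.raises(ValueError):
            draw_mask(bank, np.random.default_rng(0))

    def test_serialization_round_trip_bit_exact(self, tmp_path):
        for task in ("prediction", "restoration"):
            bank = build_mask_bank(task, "random", 16, (64, 64), n_base=3, rng=6)
            path = tmp_path / f"{task}.json"
            save_mask_bank(bank, path)
            loaded = load_mask_bank(path)
            assert loaded.task == bank.task
            assert loaded.patch_size == bank.patch_size
            assert loaded.image_shape == bank.image_shape
            for a, b in zip(bank.base_masks, loaded.base_masks):
                assert np.array_equal(a.covered, b.covered)
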