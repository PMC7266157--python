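"""BrdU quantification: pixel-sum identities, segmentation against truth
masks, planted-ratio recovery through the full image path, and the
Kruskal-Wallis test against closed-form and permutation oracles."""

import itertools

import numpy as np
import pytest
from scipy import stats

from asarscan.simulate import simulate_brdu_image
from asarscan.timing import (
    ChromosomeMeasurement,
    IndeterminateHomologsError,
    brdu_ratio,
    identify_homologs,
    kruskal_wallis,
    measure_cell_image,
    measure_chromosome,
    segment_chromosomes,
)


def _meas(homolog, area, mean_brdu, cell="c1"):
    return ChromosomeMeasurement(cell, homolog, area, mean_brdu, 100.0)


class TestMeasurement:
    def test_mean_times_area_is_pixel_sum_identity(self, rng):
        """total_brdu = mean x area equals the pixel sum to machine precision."""
        grid = rng.random((80, 80)) * 100
        mask = rng.random((80, 80)) > 0.6
        m = measure_chromosome(mask, grid, grid)
        assert m.total_brdu == pytest.approx(float(grid[mask].sum()), rel=1e-12)

    def test_uniform_arithmetic(self):
        grid = np.full((64, 64), 10.0)
        mask = np.zeros((64, 64), dtype=bool)
        mask[:10, :10] = True
        assert measure_chromosome(mask, grid, grid).total_brdu == pytest.approx(1000.0)

    def test_empty_mask_and_shape_mismatch_rejected(self):
        grid = np.zeros((64, 64))
        with pytest.raises(ValueError, match="empty"):
            measure_chromosome(np.zeros((64, 64), dtype=bool), grid, grid)
        with pytest.raises(ValueError, match="shapes"):
            measure_chromosome(np.ones((32, 32), dtype=bool), grid, grid)


class TestSegmentation:
    def test_blank_grid_no_masks(self):
        assert segment_chromosomes(np.zeros((64, 64))) == []

    def test_two_planted_bodies_iou(self):
        img = simulate_brdu_image(1.0, noise_sd=0.0, seed=1)
        masks = segment_chromosomes(img.dapi)
        assert len(masks) == 2
        for mask in masks:
            ious = []
            for truth in img.masks.values():
                inter = (mask & truth).sum()
                union = (mask | truth).sum()
                ious.append(inter / union)
            assert max(ious) >= 0.95

    def test_deterministic_labels(self):
        img = simulate_brdu_image(1.5, noise_sd=2.0, seed=2)
        a = segment_chromosomes(img.dapi)
        b = segment_chromosomes(img.dapi)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestHomologIdentification:
    def _blob_image(self, left_signal, right_signal):
        cen = np.zeros((64, 128))
        cen[28:36, 28:36] = left_signal
        cen[28:36, 92:100] = right_signal
        masks = [np.zeros((64, 128), dtype=bool), np.zeros((64, 128), dtype=bool)]
        masks[0][10:54, 20:44] = True
        masks[1][10:54, 84:108] = True
        return masks, cen

    def test_larger_centromere_is_6a(self):
        masks, cen = self._blob_image(200, 100)
        assert identify_homologs(masks, cen) == {0: "6A", 1: "6B"}
        masks, cen = self._blob_image(100, 200)
        assert identify_homologs(masks, cen) == {0: "6B", 1: "6A"}

    def test_equal_blobs_indeterminate(self):
        masks, cen = self._blob_image(150, 150)
        with pytest.raises(IndeterminateHomologsError):
            identify_homologs(masks, cen)

    def test_simulated_cells_assigned_correctly(self):
        """Across noisy simulated cells the centromere-size rule matches the
        truth masks."""
        correct = 0
        n = 50
        for seed in range(n):
            img = simulate_brdu_image(1.0, noise_sd=2.5, seed=seed)
            masks = segment_chromosomes(img.dapi)
            labels = identify_homologs(masks, img.centromere)
            a_idx = next(i for i, h in labels.items() if h == "6A")
            iou = (masks[a_idx] & img.masks["6A"]).sum() / (
                masks[a_idx] | img.masks["6A"]
            ).sum()
            correct += iou > 0.5
        assert correct / n >= 0.99


class TestBrdURatio:
    def test_equal_totals_unit_ratio(self):
        r = brdu_ratio([_meas("6A", 100, 10.0), _meas("6B", 50, 20.0)])
        assert r.ratio == pytest.approx(1.0)

    def test_reciprocal_under_homolog_swap(self):
        a = _meas("6A", 100, 10.0)
        b = _meas("6B", 100, 25.0)
        r = brdu_ratio([a, b]).ratio
        swapped = brdu_ratio(
            [_meas("6A", 100, 25.0), _meas("6B", 100, 10.0)]
        ).ratio
        assert swapped == pytest.approx(1 / r)

    def test_missing_homolog_rejected(self):
        with pytest.raises(ValueError):
            brdu_ratio([_meas("6A", 100, 10.0)])

    @pytest.mark.parametrize("ratio", [0.5, 2.0])
    def test_full_image_path_recovers_planted_ratio_noiseless(self, ratio):
        img = simulate_brdu_image(ratio, noise_sd=0.0, seed=3)
        r = measure_cell_image(img.dapi, img.brdu, img.centromere)
        assert abs(r.ratio - ratio) <= 0.02

    def test_noisy_cells_median_recovers_ratio(self):
        """Planted ratio 2.0 at 5% noise: median over 20 cells within 0.1."""
        ratios = []
        for seed in range(20):
            img = simulate_brdu_image(2.0, noise_sd=2.5, seed=100 + seed)
            ratios.append(measure_cell_image(img.dapi, img.brdu, img.centromere).ratio)
        assert abs(np.median(ratios) - 2.0) <= 0.1


def kw_oracle(groups):
    """Closed-form tie-corrected H over mid-ranks."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset : offset + len(g)]
        h += r.sum() ** 2 / len(g)
        offset += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - ((counts**3 - counts).sum()) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_identical_constant_groups_degenerate(self):
        res = kruskal_wallis([[5.0, 5.0, 5.0], [5.0, 5.0]])
        assert (res.h_statistic, res.p_value) == (0.0, 1.0)

    def test_small_instance_closed_form(self):
        """H for {1,2,3} vs {4,5,6} by direct evaluation of the rank formula:
        R1=6, R2=15, H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 3.857142..."""
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.h_statistic == pytest.approx(12 / 42 * (12 + 75) - 21)
        assert res.h_statistic == pytest.approx(kw_oracle([np.array([1., 2, 3]), np.array([4., 5, 6])]))

    def test_random_data_with_ties_matches_formula(self, rng):
        for _ in range(10):
            groups = [rng.integers(0, 6, size=rng.integers(3, 9)).astype(float)
                      for _ in range(3)]
            if len(np.unique(np.concatenate(groups))) < 2:
                continue
            res = kruskal_wallis(groups)
            assert res.h_statistic == pytest.approx(kw_oracle(groups), rel=1e-10)
            assert res.p_value == pytest.approx(
                stats.chi2.sf(res.h_statistic, res.df), rel=1e-10
            )

    def test_p_within_monte_carlo_error_of_permutation_oracle(self, rng):
        """Chi-square p close to the permutation distribution on a small
        3-group instance."""
        groups = [
            np.array([1.0, 2.0, 6.0, 7.0]),
            np.array([3.0, 5.0, 9.0, 10.0]),
            np.array([4.0, 8.0, 11.0, 12.0]),
        ]
        res = kruskal_wallis(groups)
        pooled = np.concatenate(groups)
        n_perm = 20_000
        count = 0
        for _ in range(n_perm):
            rng.shuffle(pooled)
            h = kw_oracle([pooled[:4], pooled[4:8], pooled[8:]])
            count += h >= res.h_statistic - 1e-12
        p_perm = count / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(res.p_value - p_perm) <= max(5 * se, 0.02)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.random(6) for _ in range(3)]
        a = kruskal_wallis(groups).h_statistic
        b = kruskal_wallis([np.exp(5 * g) for g in groups]).h_statistic
        assert a == pytest.approx(b, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])
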