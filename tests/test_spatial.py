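import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.signal import convolve2d

from tslniche import (
    ChannelStack,
    LabelVolume,
    SpatialParams,
    SynthImageParams,
    dc_density,
    expand_labels_membrane,
    kde_density_map,
    nfat_localization,
    normalize_weights,
    simulate_ln_image,
)

DIMS = (2.0, 1.0, 1.0)  # 1 µm xy so sigma in µm == sigma in px


def gaussian_kernel_2d(sigma, truncate=4.0):
    r = int(truncate * sigma + 0.5)
    ax = np.arange(-r, r + 1)
    k1 = np.exp(-(ax**2) / (2 * sigma**2))
    k = np.outer(k1, k1)
    return k / k.sum()


def dc_density_oracle(vol, sigma, truncate=4.0):
    """Direct dense per-slice convolution with a sampled, unit-sum kernel."""
    k = gaussian_kernel_2d(sigma, truncate)
    return np.stack([convolve2d(sl, k, mode="same", boundary="symm") for sl in vol])


class TestDcDensity:
    def test_uniform_field_preserved(self):
        labels = np.zeros((3, 30, 30), dtype=np.int32)
        labels[1, 10, 10] = 1
        labels[2, 20, 20] = 2
        stack = ChannelStack(np.full((1, 3, 30, 30), 7.5), ["XCR1"], DIMS)
        dens = dc_density(stack, "XCR1", LabelVolume(labels, DIMS), sigma=3.0)
        np.testing.assert_allclose(dens.to_numpy(), 7.5, atol=1e-9)

    def test_impulse_matches_kernel_entry(self):
        vol = np.zeros((1, 101, 101))
        vol[0, 50, 50] = 1.0  # unit impulse
        labels = np.zeros((1, 101, 101), dtype=np.int32)
        labels[0, 60, 50] = 1  # nucleus 10 px away in-plane
        stack = ChannelStack(vol[None], ["XCR1"], DIMS)
        dens = dc_density(stack, "XCR1", LabelVolume(labels, DIMS), sigma=10.0)
        oracle = dc_density_oracle(vol, 10.0)
        assert dens.iloc[0] == pytest.approx(oracle[0, 60, 50], abs=1e-10)

    def test_impulse_in_other_slice_contributes_nothing(self):
        vol = np.zeros((2, 21, 21))
        vol[0, 10, 10] = 1.0
        labels = np.zeros((2, 21, 21), dtype=np.int32)
        labels[1, 10, 10] = 1  # directly above the impulse, next slice
        stack = ChannelStack(vol[None], ["XCR1"], DIMS)
        dens = dc_density(stack, "XCR1", LabelVolume(labels, DIMS), sigma=3.0)
        assert dens.iloc[0] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_convolution(self, seed):
        rng = np.random.default_rng(seed)
        vol = rng.uniform(0, 1, (3, 32, 32))
        labels = np.zeros((3, 32, 32), dtype=np.int32)
        for lab in range(1, 5):
            z, y, x = rng.integers(0, 3), rng.integers(1, 30), rng.integers(1, 30)
            labels[z, y : y + 2, x : x + 2] = lab
        sigma = float(rng.uniform(1.0, 3.0))
        stack = ChannelStack(vol[None], ["XCR1"], DIMS)
        nuc = LabelVolume(labels, DIMS)
        dens = dc_density(stack, "XCR1", nuc, sigma)
        oracle = dc_density_oracle(vol, sigma)
        for cid in nuc.ids():
            expected = oracle[labels == cid].mean()
            assert dens.loc[cid] == pytest.approx(expected, abs=1e-8)

    def test_missing_channel_rejected(self):
        stack = ChannelStack(np.zeros((1, 2, 4, 4)), ["A"], DIMS)
        with pytest.raises(KeyError):
            dc_density(stack, "XCR1", LabelVolume(np.zeros((2, 4, 4), np.int32), DIMS))

    def test_clustered_cells_register_higher_density(self):
        """Niche-resident cells sit in denser cDC1 regions than dispersed ones."""
        params = SynthImageParams(
            volume_shape=(40, 224, 224), n_dc=10, n_tcells=200, noise_sd=0.0,
            seed=17, max_retries=3000,
        )
        stack, nuc, truth = simulate_ln_image(params)
        dens = dc_density(stack, "XCR1", nuc, 3.6)
        merged = truth.set_index("cell_id").join(dens)
        clustered = merged.loc[merged.clustered, "dc_density"]
        dispersed = merged.loc[~merged.clustered, "dc_density"]
        stat = stats.mannwhitneyu(clustered, dispersed, alternative="greater")
        assert clustered.mean() > dispersed.mean()
        assert stat.pvalue < 0.01


class TestNfatLocalization:
    def _cell(self, nuc_val, mem_val):
        """One 3x3 nucleus with a 1-px membrane rim on a single slice."""
        nuc = np.zeros((1, 9, 9), dtype=np.int32)
        nuc[0, 3:6, 3:6] = 1
        mem = np.zeros_like(nuc)
        mem[0, 2:7, 2:7] = 1
        mem[nuc > 0] = 0
        vol = np.zeros((1, 9, 9))
        vol[nuc > 0] = nuc_val
        vol[mem > 0] = mem_val
        stack = ChannelStack(vol[None], ["NFAT1"], DIMS)
        return stack, LabelVolume(nuc, DIMS), LabelVolume(mem, DIMS)

    def test_uniform_signal_is_nuclear_by_convention(self):
        res = nfat_localization(*self._cell(5.0, 5.0), "NFAT1", low_expr_threshold=0.0)
        assert res.nfat_ratio.iloc[0] == pytest.approx(1.0)
        assert res.nfat_class.iloc[0] == "nuclear"

    def test_ratio_arithmetic(self):
        res = nfat_localization(*self._cell(20.0, 10.0), "NFAT1", low_expr_threshold=0.0)
        assert res.nfat_ratio.iloc[0] == pytest.approx(2.0)
        assert res.nfat_class.iloc[0] == "nuclear"

    def test_membrane_class(self):
        res = nfat_localization(*self._cell(4.0, 10.0), "NFAT1", low_expr_threshold=0.0)
        assert res.nfat_ratio.iloc[0] == pytest.approx(0.4)
        assert res.nfat_class.iloc[0] == "membrane"

    def test_low_expressors_excluded(self):
        res = nfat_localization(*self._cell(0.2, 0.1), "NFAT1", low_expr_threshold=1.0)
        assert res.nfat_class.iloc[0] == "excluded"

    def test_zero_membrane_gives_inf_sentinel(self):
        res = nfat_localization(*self._cell(5.0, 0.0), "NFAT1", low_expr_threshold=0.0)
        assert np.isinf(res.nfat_ratio.iloc[0])
        assert res.nfat_class.iloc[0] == "nuclear"
        assert res.flagged.iloc[0]

    def test_middle_slice_selection_known_areas(self):
        # per-slice nuclear areas {3, 5, 9, 5, 3}: slice 2 is the largest
        areas = [3, 5, 9, 5, 3]
        nuc = np.zeros((5, 10, 10), dtype=np.int32)
        rng = np.random.default_rng(0)
        for z, a in enumerate(areas):
            ys, xs = np.unravel_index(rng.choice(100, a, replace=False), (10, 10))
            nuc[z, ys, xs] = 1
        mem = np.zeros_like(nuc)
        mem[:, 0, :] = 1  # arbitrary rim somewhere else
        vol = rng.uniform(1, 10, (5, 10, 10))
        stack = ChannelStack(vol[None], ["NFAT1"], DIMS)
        res = nfat_localization(
            stack, LabelVolume(nuc, DIMS), LabelVolume(mem, DIMS), "NFAT1",
            low_expr_threshold=0.0,
        )
        assert res.mid_z.iloc[0] == 2
        # exhaustive oracle over the selected slice
        expected_n = vol[2][nuc[2] > 0].mean()
        expected_m = vol[2][mem[2] > 0].mean()
        assert res.nuclear_slice_mean.iloc[0] == pytest.approx(expected_n)
        assert res.nfat_ratio.iloc[0] == pytest.approx(expected_n / expected_m)

    def test_reproduces_generator_truth_noise_free(self, quantified):
        stack, nuc, mem, _, truth = quantified
        res = nfat_localization(stack, nuc, mem, "NFAT1", low_expr_threshold=0.0)
        merged = truth.merge(res, on="cell_id")
        expected = np.where(merged.nfat_nuclear, "nuclear", "membrane")
        assert (merged.nfat_class.to_numpy() == expected).all()


class TestKdeDensityMap:
    def test_single_point_peak_closed_form(self):
        grid = kde_density_map(np.array([[100.0, 100.0, 100.0]]), np.array([1.0]))
        peak = grid.values.max()
        assert peak == pytest.approx((2 * np.pi * 36.0) ** -1.5, abs=1e-10)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 50, (20, 3))
        w = rng.uniform(0, 1, 20)
        g1 = kde_density_map(pts, w)
        g2 = kde_density_map(pts, 2 * w)
        np.testing.assert_allclose(g2.values, 2 * g1.values, rtol=1e-12)

    def test_grid_mass_matches_total_weight(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(40, 60, (30, 3))
        w = rng.uniform(0.1, 1.0, 30)
        params = SpatialParams()
        grid = kde_density_map(pts, w, params)
        mass = grid.values.sum() * params.kde_grid_interval**3
        assert mass == pytest.approx(w.sum(), rel=0.01)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 40, (15, 3))
        w = rng.uniform(0, 1, 15)
        shift = np.array([30.0, -20.0, 10.0])  # multiples of the grid interval
        g1 = kde_density_map(pts, w)
        g2 = kde_density_map(pts + shift, w)
        assert g1.values.shape == g2.values.shape
        np.testing.assert_allclose(g1.values, g2.values, atol=1e-10)

    def test_z_slab_sum_is_plain_node_sum(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 100, (10, 3))
        grid = kde_density_map(pts, np.ones(10))
        full = grid.sum_z()
        np.testing.assert_allclose(full, grid.values.sum(axis=0), rtol=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            kde_density_map(np.zeros((1, 3)), np.array([-1.0]))


class TestNormalizeWeights:
    def test_min_max_scaling(self):
        np.testing.assert_allclose(
            normalize_weights(np.array([10.0, 20.0, 30.0])), [0.0, 0.5, 1.0]
        )

    def test_constant_input_all_ones_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize_weights(np.array([5.0, 5.0]))
        np.testing.assert_array_equal(out, [1.0, 1.0])

    def test_output_in_unit_interval(self):
        rng = np.random.default_rng(6)
        out = normalize_weights(rng.normal(0, 100, 500))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_weights(np.array([]))
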