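"""Block-design GLM pipeline: regressors, filtering, inference, clustering."""

import collections

import numpy as np
import pytest
from scipy import stats as sps

from adedbs import esfmri as fx
from adedbs import simulate as sim
from adedbs.errors import DesignError, ParameterError


class TestRegressor:
    def test_zero_on_period_gives_zero_regressor(self):
        reg = fx.build_regressor(fx.StimProtocol(on_s=0.0, off_s=34.0, repeats=3))
        assert np.all(reg == 0)

    def test_block_arithmetic_at_tr2(self):
        # 8 s ON / 26 s OFF x 10 at TR 2 s: 4 ON then 13 OFF samples per cycle
        reg = fx.build_regressor(fx.StimProtocol(), mode="shifted_boxcar", shift_s=0.0)
        assert reg.size == 170
        cycle = reg[:17]
        assert np.array_equal(cycle, np.r_[np.ones(4), np.zeros(13)])
        assert np.array_equal(reg, np.tile(cycle, 10))

    def test_default_shift_delays_by_one_sample(self):
        reg0 = fx.build_regressor(fx.StimProtocol(), shift_s=0.0)
        reg2 = fx.build_regressor(fx.StimProtocol(), shift_s=2.0)
        assert np.array_equal(reg2[1:], reg0[:-1])

    def test_non_multiple_shift_rounded_with_warning(self):
        with pytest.warns(UserWarning, match="rounded"):
            reg = fx.build_regressor(fx.StimProtocol(), shift_s=1.2)
        assert np.array_equal(reg, fx.build_regressor(fx.StimProtocol(), shift_s=2.0))

    def test_hrf_regressor_peak_normalized_and_additive(self):
        reg = fx.build_regressor(fx.StimProtocol(), mode="hrf_convolved")
        assert reg.max() == pytest.approx(1.0, abs=1e-6)
        # convolution linearity: per-cycle mass is conserved across repeats
        r5 = fx.build_regressor(fx.StimProtocol(repeats=5), mode="hrf_convolved")
        r10 = fx.build_regressor(fx.StimProtocol(repeats=10), mode="hrf_convolved")
        assert r10.sum() == pytest.approx(2 * r5.sum(), rel=0.02)


class TestPreprocess:
    def test_linear_ramp_removed(self):
        t = np.arange(64, dtype=float)
        bold = np.zeros((2, 2, 1, 64)) + (3.0 + 0.5 * t)
        out = fx.preprocess(bold, tr=2.0, spatial_sigma=0.0)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_band_pass_rejects_out_of_band_sine(self):
        n, tr = 200, 1.0
        t = np.arange(n) * tr
        sine = np.sin(2 * np.pi * 0.25 * t)  # above the 0.2 Hz edge
        bold = np.broadcast_to(sine, (2, 2, 1, n)).copy()
        out = fx.preprocess(bold, tr=tr, spatial_sigma=0.0)
        assert np.abs(out).max() <= 0.1 * np.abs(sine).max()

    def test_in_band_sine_preserved(self):
        n, tr = 200, 1.0
        t = np.arange(n) * tr
        sine = np.sin(2 * np.pi * 0.1 * t)
        bold = np.broadcast_to(sine, (1, 1, 1, n)).copy()
        out = fx.preprocess(bold, tr=tr, spatial_sigma=0.0)[0, 0, 0]
        # amplitude preserved up to the small linear component the detrend removes
        gain = np.dot(out, sine) / np.dot(sine, sine)
        assert gain == pytest.approx(1.0, abs=0.01)
        assert np.corrcoef(out, sine)[0, 1] > 0.995

    def test_constant_image_invariant_under_smoothing(self):
        vol = np.full((8, 8, 3), 7.0)
        assert np.allclose(fx.smooth_inplane(vol), 7.0)

    def test_short_run_rejected(self):
        with pytest.raises(ParameterError):
            fx.preprocess(np.zeros((2, 2, 1, 10)), tr=2.0)


class TestGlm:
    def test_noise_free_voxel_flagged_saturated(self):
        reg = fx.build_regressor(fx.StimProtocol(), shift_s=0.0)
        bold = np.broadcast_to(2.5 * reg, (1, 1, 1, reg.size)).copy()
        stat = fx.glm_fit(bold, reg)
        assert stat.saturated[0, 0, 0]
        assert stat.t[0, 0, 0] == fx.T_SATURATED
        assert stat.beta[0, 0, 0] == pytest.approx(2.5)

    def test_constant_regressor_rejected(self):
        with pytest.raises(DesignError):
            fx.glm_fit(np.zeros((1, 1, 1, 30)), np.ones(30))

    def test_null_false_positive_rate_calibrated(self):
        rng = np.random.default_rng(12)
        n_vox = 100_000
        reg = fx.build_regressor(fx.StimProtocol(), mode="hrf_convolved")
        noise = rng.standard_normal((n_vox, 1, 1, reg.size))
        stat = fx.glm_fit(noise, reg)
        fpr = float((stat.p < 0.001).mean())
        se = np.sqrt(0.001 * 0.999 / n_vox)
        assert abs(fpr - 0.001) <= 3 * se

    def test_effect_estimate_unbiased(self):
        rng = np.random.default_rng(5)
        reg = fx.build_regressor(fx.StimProtocol(), shift_s=0.0)
        n_vox = 4000
        bold = 1.0 * reg + rng.standard_normal((n_vox, 1, 1, reg.size))
        stat = fx.glm_fit(bold, reg)
        se_mean = 1.0 / np.sqrt(n_vox * np.sum((reg - reg.mean()) ** 2))
        assert abs(stat.beta.mean() - 1.0) <= 4 * se_mean


def bfs_max_cluster(mask2d):
    """Independent exhaustive connected-component enumeration (4-adjacency)."""
    seen = np.zeros_like(mask2d, dtype=bool)
    best = 0
    for start in map(tuple, np.argwhere(mask2d)):
        if seen[start]:
            continue
        queue = collections.deque([start])
        seen[start] = True
        size = 0
        while queue:
            cx, cy = queue.popleft()
            size += 1
            for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                nb = (cx + dx, cy + dy)
                if (
                    0 <= nb[0] < mask2d.shape[0]
                    and 0 <= nb[1] < mask2d.shape[1]
                    and mask2d[nb]
                    and not seen[nb]
                ):
                    seen[nb] = True
                    queue.append(nb)
        best = max(best, size)
    return best


class TestClusterThreshold:
    def test_alpha_near_one_gives_single_voxel_threshold(self):
        k = fx.mc_cluster_threshold((6, 6), smoothing_sigma=0.0, voxel_p=0.05,
                                    alpha=0.999, n_sim=200, seed=1)
        assert k == 1

    def test_matches_enumeration_oracle_on_small_grid(self):
        seed, n_sim, voxel_p = 3, 1500, 0.01
        k = fx.mc_cluster_threshold((8, 8), smoothing_sigma=0.0, voxel_p=voxel_p,
                                    alpha=0.05, n_sim=n_sim, seed=seed)
        rng = np.random.default_rng(seed)  # identical noise stream
        z = sps.norm.isf(voxel_p)
        maxima = np.array(
            [bfs_max_cluster(rng.standard_normal((8, 8, 1))[:, :, 0] >= z) for _ in range(n_sim)]
        )
        k_oracle = 1
        while np.mean(maxima >= k_oracle) > 0.05:
            k_oracle += 1
        assert k == k_oracle

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ParameterError):
            fx.mc_cluster_threshold((8, 8), alpha=1.5, n_sim=10)


class TestClusterFilter:
    def make_stat(self, mask):
        p = np.where(mask, 1e-5, 0.5)
        return fx.StatMap(
            t=np.where(mask, 10.0, 0.0), df=100, beta=p * 0, p=p,
            mask=np.ones(mask.shape, bool), saturated=np.zeros(mask.shape, bool),
        )

    def test_empty_mask_allowed(self):
        out = fx.cluster_filter(self.make_stat(np.zeros((10, 10, 3), bool)))
        assert not out.any()

    def test_thirteen_voxel_cluster_removed_at_minimum_fourteen(self):
        mask = np.zeros((10, 10, 3), bool)
        mask[2:4, 2:4, :] = True  # 12 voxels
        mask[4, 2, 0] = True  # 13th
        out = fx.cluster_filter(self.make_stat(mask), min_cluster=14)
        assert not out.any()
        mask[4, 3, 0] = True  # 14th
        out = fx.cluster_filter(self.make_stat(mask), min_cluster=14)
        assert out.sum() == 14

    def test_seeded_blob_retained_exactly(self):
        mask = np.zeros((16, 16, 4), bool)
        mask[5:10, 5:9, 1] = True  # 20-voxel blob
        out = fx.cluster_filter(self.make_stat(mask), min_cluster=14)
        assert out.sum() == 20
        assert np.array_equal(out, mask)


class TestGroupMaps:
    def test_probability_counting(self):
        shape = (4, 4, 2)
        masks = [np.zeros(shape, bool) for _ in range(6)]
        for m in masks:
            m[0, 0, 0] = True
        for m in masks[:3]:
            m[1, 1, 1] = True
        pmap = fx.probability_map(masks)
        assert pmap.p_active[0, 0, 0] == 1.0
        assert pmap.p_active[1, 1, 1] == 0.5
        assert pmap.p_active[2, 2, 0] == 0.0
        counts = pmap.p_active * pmap.n_subjects
        assert np.allclose(counts, np.round(counts))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            fx.probability_map([np.zeros((4, 4, 2), bool), np.zeros((4, 4, 3), bool)])

    def test_roi_fractions(self):
        atlas = sim.make_roi_atlas((10, 10, 2), {1: (0, 5, 0, 5, 0, 2), 2: (5, 10, 5, 10, 0, 2)})
        mask = np.zeros((10, 10, 2), bool)
        mask[atlas == 1] = True
        out = fx.roi_activation_volume(mask, atlas)
        assert out[1] == 1.0 and out[2] == 0.0

    def test_random_mask_fraction_matches_density(self):
        rng = np.random.default_rng(2)
        atlas = sim.make_roi_atlas((20, 20, 4), {1: (0, 20, 0, 20, 0, 4)})
        d = 0.3
        mask = rng.random((20, 20, 4)) < d
        frac = fx.roi_activation_volume(mask, atlas)[1]
        n = 20 * 20 * 4
        assert abs(frac - d) <= 4 * np.sqrt(d * (1 - d) / n)


class TestEndToEndRecovery:
    def test_seeded_rois_recovered_nonseeded_quiet(self):
        grid = (32, 32, 6)
        atlas = sim.make_roi_atlas(
            grid, {1: (6, 12, 6, 12, 1, 4), 2: (20, 27, 20, 27, 2, 5), 3: (4, 9, 24, 29, 0, 3)}
        )
        datasets = [
            sim.generate_bold_dataset(
                sim.BoldSimParams(grid=grid, active_rois={1: 1.0, 2: 1.0}, seed=40 + s), atlas
            )
            for s in range(6)
        ]
        pmap, fracs = fx.group_analysis(datasets)
        assert fracs[1] >= 0.8 and fracs[2] >= 0.8
        assert fracs[3] <= 0.05
        assert pmap.p_active[atlas == 3].mean() <= 0.05
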