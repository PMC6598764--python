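"""Density projection, normalized cross-correlation, line profile, period."""

import numpy as np
import pytest

from hepnem.layered import (
    FlatImageError,
    estimate_period,
    layered_analysis,
    line_profile,
    normalized_crosscorr,
    project_density,
)
from hepnem.synthetic import LobuleConfig, generate_layered_grid
from hepnem.types import CorrelationProfile, DensityGrid, DensityImage


def direct_sum_crosscorr_oracle(s: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Literal double-sum implementation of the normalized cross-correlation."""
    mu_s, mu_h = s.mean(), h.mean()
    sd_s, sd_h = s.std(), h.std()
    n, m = s.shape
    out = np.zeros((2 * n - 1, 2 * m - 1))
    for k in range(-(n - 1), n):
        for l in range(-(m - 1), m):
            acc = 0.0
            for i in range(n):
                for j in range(m):
                    ii, jj = i + k, j + l
                    hc = h[ii, jj] - mu_h if (0 <= ii < n and 0 <= jj < m) else 0.0
                    acc += (s[i, j] - mu_s) * hc
            out[k + n - 1, l + m - 1] = acc / ((s.size + h.size) * sd_s * sd_h)
    return out


class TestProjectDensity:
    def test_constant_grid(self):
        grid = DensityGrid(values=np.full((4, 5, 6), 2.5), voxel_size=0.5)
        img = project_density(grid, "z")
        assert img.values.shape == (4, 5)
        np.testing.assert_allclose(img.values, 2.5)
        assert img.pixel_size == 0.5

    def test_single_voxel(self):
        values = np.zeros((3, 4, 10))
        values[1, 2, 7] = 1.0
        img = project_density(DensityGrid(values=values), "z")
        assert img.values[1, 2] == pytest.approx(1.0 / 10)
        assert img.values.sum() == pytest.approx(1.0 / 10)

    def test_mass_conservation(self, rng):
        values = rng.uniform(size=(6, 7, 8))
        img = project_density(DensityGrid(values=values), "z")
        assert img.values.sum() * 8 == pytest.approx(values.sum())

    @pytest.mark.parametrize("axis,shape", [("x", (7, 8)), ("y", (6, 8)), ("z", (6, 7))])
    def test_projection_axes(self, axis, shape, rng):
        img = project_density(DensityGrid(values=rng.uniform(size=(6, 7, 8))), axis)
        assert img.values.shape == shape


class TestNormalizedCrossCorr:
    def test_self_correlation_zero_lag_is_half(self, rng):
        v = rng.uniform(size=(16, 16))
        img = DensityImage(values=v, pixel_size=0.3)
        corr = normalized_crosscorr(img, img)
        assert corr.values[corr.zero_index] == pytest.approx(0.5, abs=1e-12)
        assert corr.values.shape == (31, 31)

    def test_overlap_mode_zero_lag_is_one(self, rng):
        v = rng.uniform(size=(16, 16))
        img = DensityImage(values=v, pixel_size=0.3)
        corr = normalized_crosscorr(img, img, mode="overlap")
        assert corr.values[corr.zero_index] == pytest.approx(1.0, abs=1e-9)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(12)
        a = DensityImage(values=rng.normal(size=(100, 100)), pixel_size=0.3)
        b = DensityImage(values=rng.normal(size=(100, 100)), pixel_size=0.3)
        corr = normalized_crosscorr(a, b)
        assert abs(corr.values[corr.zero_index]) < 0.05

    def test_matches_direct_sum_oracle_with_shift(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(size=(32, 32))
        k0, l0 = 5, -3
        h = np.zeros_like(s)
        # H equals S shifted by (k0, l0): H[n+k0, m+l0] = S[n, m]
        h[
            max(0, k0) : 32 + min(0, k0), max(0, l0) : 32 + min(0, l0)
        ] = s[max(0, -k0) : 32 - max(0, k0), max(0, -l0) : 32 - max(0, l0)]
        si = DensityImage(values=s, pixel_size=0.3)
        hi = DensityImage(values=h, pixel_size=0.3)
        corr = normalized_crosscorr(si, hi)
        oracle = direct_sum_crosscorr_oracle(s, h)
        np.testing.assert_allclose(corr.values, oracle, atol=1e-10)
        peak = np.unravel_index(np.argmax(corr.values), corr.values.shape)
        assert (peak[0] - corr.zero_index[0], peak[1] - corr.zero_index[1]) == (k0, l0)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(4)
        s = DensityImage(values=rng.uniform(size=(20, 24)), pixel_size=0.3)
        h = DensityImage(values=rng.uniform(size=(20, 24)), pixel_size=0.3)
        c_sh = normalized_crosscorr(s, h).values
        c_hs = normalized_crosscorr(h, s).values
        np.testing.assert_allclose(c_sh, c_hs[::-1, ::-1], atol=1e-10)

    def test_flat_image_rejected(self):
        img = DensityImage(values=np.ones((8, 8)), pixel_size=0.3)
        with pytest.raises(FlatImageError):
            normalized_crosscorr(img, img)


class TestLineProfile:
    def test_axis_aligned_profile_equals_binned_row_means(self, rng):
        v = rng.uniform(size=(10, 10))
        img = DensityImage(values=v, pixel_size=0.3)
        corr = normalized_crosscorr(img, img)
        prof = line_profile(corr, [1.0, 0.0], bin_size=1.5)
        # oracle: bin rows of the correlation array by k distance, average
        k = (np.arange(corr.values.shape[0]) - corr.zero_index[0]) * 0.3
        bins = np.rint(k / 1.5).astype(int)
        for b, lag in enumerate(prof.lags):
            rows = corr.values[bins == int(round(lag / 1.5))]
            assert prof.values[b] == pytest.approx(rows.mean(), abs=1e-12)

    def test_constant_array_gives_constant_profile(self):
        from hepnem.layered import CrossCorrelation

        corr = CrossCorrelation(
            values=np.full((21, 21), 0.3), zero_index=(10, 10), pixel_size=0.3
        )
        prof = line_profile(corr, [0.0, 1.0])
        np.testing.assert_allclose(prof.values, 0.3, atol=1e-12)

    def test_separable_array(self):
        from hepnem.layered import CrossCorrelation

        f = np.cos(np.linspace(0, 4 * np.pi, 41))
        g = np.exp(-np.abs(np.linspace(-2, 2, 41)))
        corr = CrossCorrelation(
            values=np.outer(f, g), zero_index=(20, 20), pixel_size=0.3
        )
        prof = line_profile(corr, [1.0, 0.0], bin_size=0.3)  # one entry per bin
        k = np.rint(prof.lags / 0.3).astype(int) + 20
        np.testing.assert_allclose(prof.values, f[k] * g.mean(), atol=1e-12)

    def test_lags_symmetric_and_increasing(self, rng):
        img = DensityImage(values=rng.uniform(size=(30, 30)), pixel_size=0.3)
        prof = line_profile(normalized_crosscorr(img, img), [0.6, 0.8])
        prof.validate()


class TestEstimatePeriod:
    @staticmethod
    def _profile(values, bin_size=1.5):
        n = (len(values) - 1) // 2
        lags = (np.arange(len(values)) - n) * bin_size
        return CorrelationProfile(lags=lags, values=values, bin_size=bin_size)

    def test_cosine_profile_recovers_wavelength(self):
        lags = (np.arange(81) - 40) * 1.5
        prof = self._profile(np.cos(2 * np.pi * lags / 24.0))
        est = estimate_period(prof)
        assert est.significant
        assert est.period == pytest.approx(24.0, abs=0.75)

    def test_white_noise_profile_no_period(self):
        rng = np.random.default_rng(8)
        prof = self._profile(rng.normal(scale=0.05, size=81))
        est = estimate_period(prof)
        assert est.period is None

    def test_default_layered_grids_recover_spacing(self):
        cfg = LobuleConfig(seed=5, voxel_size=0.6)
        grids = generate_layered_grid(cfg)
        res = layered_analysis(
            grids.sinusoid, grids.hepatocyte, grids.layer_normal, n_null=100, seed=2
        )
        # period = hepatocyte diameter + sinusoid diameter
        assert res.estimate.significant
        assert res.estimate.period == pytest.approx(
            cfg.layer_spacing, abs=res.profile.bin_size
        )
        assert res.control_estimate.period is None

    def test_period_invariant_under_grid_rotation(self):
        est = {}
        for angle in (0.0, 30.0):
            cfg = LobuleConfig(seed=6, voxel_size=0.6, layer_angle_deg=angle)
            grids = generate_layered_grid(cfg)
            res = layered_analysis(
                grids.sinusoid,
                grids.hepatocyte,
                grids.layer_normal,
                n_null=60,
                seed=3,
            )
            est[angle] = res.estimate.period
        assert est[0.0] is not None and est[30.0] is not None
        assert abs(est[0.0] - est[30.0]) <= 1.5 * 2  # within one bin each
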