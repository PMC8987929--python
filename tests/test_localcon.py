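"""Coherence ReHo, fALFF and Z-scored maps."""

from itertools import combinations

import numpy as np
import pytest
from scipy import signal

from fuskit.core import PixelMap, PowerDopplerMovie
from fuskit.localcon import (
    SpectralConfig,
    band_coherence,
    falff_map,
    group_reho_stat_map,
    reho_map,
    zscore_map,
)


class TestBandCoherence:
    def test_self_coherence_is_one(self, rng):
        x = rng.standard_normal(512)
        assert band_coherence(x, x, 2.8) == pytest.approx(1.0, abs=1e-10)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(512)
        assert band_coherence(x, 3.0 * x + 5.0, 2.8) == pytest.approx(1.0, abs=1e-9)
        assert band_coherence(x, -2.0 * x, 2.8) == pytest.approx(1.0, abs=1e-9)

    def test_matches_direct_welch_recomputation(self, rng):
        """Independent oracle: the band coherence recomputed from raw
        scipy Welch/CSD outputs matches the operation to 1e-10."""
        cfg = SpectralConfig(welch_window=128)
        x, y = rng.standard_normal(512), rng.standard_normal(512)
        freqs, sxy = signal.csd(
            x, y, fs=1 / 2.8, window="hann", nperseg=128, noverlap=64, detrend="linear"
        )
        _, sxx = signal.welch(
            x, fs=1 / 2.8, window="hann", nperseg=128, noverlap=64, detrend="linear"
        )
        _, syy = signal.welch(
            y, fs=1 / 2.8, window="hann", nperseg=128, noverlap=64, detrend="linear"
        )
        sel = (freqs >= 0.01) & (freqs <= 0.08)
        oracle = abs(sxy[sel].mean()) ** 2 / (sxx[sel].mean() * syy[sel].mean())
        assert band_coherence(x, y, 2.8, cfg) == pytest.approx(oracle, abs=1e-10)

    def test_independent_noise_bias_is_bounded(self, rng):
        cfg = SpectralConfig(welch_window=128)
        vals = [
            band_coherence(rng.standard_normal(512), rng.standard_normal(512), 2.8, cfg)
            for _ in range(200)
        ]
        assert np.mean(vals) < 0.2

    def test_band_without_bins_rejected(self, rng):
        cfg = SpectralConfig(band=(0.0101, 0.0102), welch_window=32)
        x = rng.standard_normal(256)
        with pytest.raises(ValueError, match="no frequency bin"):
            band_coherence(x, x, 2.8, cfg)


class TestRehoMap:
    def test_identical_cluster_series_give_one(self, rng):
        series = rng.standard_normal(256)
        data = 5 + np.tile(series[:, None, None], (1, 5, 5))
        movie = PowerDopplerMovie(data, dt=2.8)
        rm = reho_map(movie)
        assert np.allclose(rm.values[rm.mask], 1.0, atol=1e-9)

    def test_equals_bruteforce_pair_enumeration(self, rng):
        """Map value at each interior pixel equals the mean of the 36
        explicitly enumerated pairwise coherences of its 3x3 cluster."""
        cfg = SpectralConfig(welch_window=64)
        data = rng.standard_normal((256, 8, 8))
        movie = PowerDopplerMovie(data + 10, dt=2.8)
        rm = reho_map(movie, cfg)
        for ci, cj in [(3, 3), (4, 2), (1, 6)]:
            members = [(ci + di, cj + dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
            cohs = [
                band_coherence(data[:, a[0], a[1]], data[:, b[0], b[1]], 2.8, cfg)
                for a, b in combinations(members, 2)
            ]
            assert len(cohs) == 36
            assert rm.values[ci, cj] == pytest.approx(np.mean(cohs), abs=1e-10)

    def test_shared_latent_raises_reho(self, rng):
        """A cluster sharing an in-band latent (SNR 2) scores above an
        independent-noise cluster in >= 95% of seeded runs."""
        from fuskit.filters import BAND_PRESETS, temporal_filter

        cfg = SpectralConfig(welch_window=64)
        wins = 0
        n_runs = 50
        for rep in range(n_runs):
            r = np.random.default_rng(rep)
            latent = temporal_filter(r.standard_normal(256), 2.8, BAND_PRESETS["reho"])
            latent /= latent.std()
            data = r.standard_normal((256, 3, 7))
            data[:, :, :3] += 2.0 * latent[:, None, None]  # SNR 2 cluster on the left
            movie = PowerDopplerMovie(data + 20, dt=2.8)
            rm = reho_map(movie, cfg)
            if rm.values[1, 1] > rm.values[1, 5]:
                wins += 1
        assert wins >= 0.95 * n_runs

    def test_small_clusters_masked_out(self, rng):
        data = rng.standard_normal((256, 5, 5)) + 10
        mask = np.zeros((5, 5), bool)
        mask[0, 0] = True
        mask[4, 4] = True  # isolated pixels: cluster of 1
        movie = PowerDopplerMovie(data, dt=2.8, mask=mask)
        rm = reho_map(movie)
        assert not rm.mask.any()

    def test_values_in_unit_interval(self, rng):
        data = rng.standard_normal((256, 6, 6)) + 10
        rm = reho_map(PowerDopplerMovie(data, dt=2.8))
        vals = rm.values[rm.mask]
        assert (vals >= 0).all() and (vals <= 1).all()


class TestZScore:
    def test_constant_map_rejected(self):
        pm = PixelMap(values=np.ones((4, 4)), mask=np.ones((4, 4), bool))
        with pytest.raises(ValueError, match="zero standard deviation"):
            zscore_map(pm)

    def test_three_value_hand_computation(self):
        pm = PixelMap(
            values=np.array([[1.0, 2.0, 3.0]]), mask=np.ones((1, 3), bool)
        )
        z = zscore_map(pm)
        assert np.allclose(z.values[0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_idempotence(self, rng):
        pm = PixelMap(values=rng.standard_normal((6, 6)), mask=np.ones((6, 6), bool))
        once = zscore_map(pm)
        twice = zscore_map(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_mean_zero_sd_one_contract(self, rng):
        mask = rng.random((8, 8)) > 0.3
        pm = PixelMap(values=rng.standard_normal((8, 8)) * 4 + 2, mask=mask)
        z = zscore_map(pm)
        assert z.values[mask].mean() == pytest.approx(0.0, abs=1e-6)
        assert z.values[mask].std() == pytest.approx(1.0, abs=1e-6)


class TestFalff:
    def test_in_band_tone(self):
        # 0.04 Hz on an exact frequency bin (dt=2.5 s, 400 frames)
        t = np.arange(400) * 2.5
        data = 10 + np.tile(np.sin(2 * np.pi * 0.04 * t)[:, None, None], (1, 3, 3))
        fm = falff_map(PowerDopplerMovie(data, dt=2.5))
        assert fm.values[fm.mask].min() >= 0.95

    def test_out_of_band_tone(self):
        t = np.arange(400) * 2.8
        data = 10 + np.tile(np.sin(2 * np.pi * 0.15 * t)[:, None, None], (1, 3, 3))
        fm = falff_map(PowerDopplerMovie(data, dt=2.8))
        assert fm.values[fm.mask].max() <= 0.1

    def test_white_noise_matches_bandwidth_fraction(self):
        dt = 2.8
        expected = 0.07 / (0.5 / dt)  # band width over positive-frequency extent
        vals = []
        for seed in range(50):
            r = np.random.default_rng(seed)
            movie = PowerDopplerMovie(10 + r.standard_normal((300, 4, 4)), dt=dt)
            fm = falff_map(movie)
            vals.append(fm.values[fm.mask].mean())
        assert np.mean(vals) == pytest.approx(expected, rel=0.30)

    def test_zero_series_masked(self):
        data = np.zeros((300, 3, 3))
        data[:, 0, 0] = np.random.default_rng(0).standard_normal(300)
        fm = falff_map(PowerDopplerMovie(data + 0.0, dt=2.8))
        assert fm.mask[0, 0]
        assert not fm.mask[2, 2]


class TestGroupRehoStats:
    def _zmaps(self, rng, n, effect=0.0, shape=(20, 20)):
        maps = []
        region = np.zeros(shape, bool)
        region[4:10, 4:10] = True
        for _ in range(n):
            vals = rng.standard_normal(shape)
            vals[region] += effect
            pm = PixelMap(values=vals, mask=np.ones(shape, bool))
            maps.append(zscore_map(pm))
        return maps, region

    def test_null_maps_calibrated(self):
        """Null cohorts: the false-positive pixel fraction stays of the order
        of the p < 0.001 threshold, and most runs flag no pixel at all (the
        union bound 1 - N*p >= 0.86 at 144 pixels caps how often any pixel
        can fire)."""
        silent, fractions = 0, []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            maps, _ = self._zmaps(rng, n=7, shape=(12, 12))
            _, sig = group_reho_stat_map(maps, fwhm_mm=0.3, pixel_size=0.1)
            fractions.append(sig.mean())
            silent += sig.sum() == 0
        assert np.mean(fractions) < 0.005
        assert silent >= 13

    def test_programmed_homogeneity_detected(self):
        rng = np.random.default_rng(42)
        maps, region = self._zmaps(rng, n=7, effect=2.5)
        zmap, sig = group_reho_stat_map(maps, fwhm_mm=0.3, pixel_size=0.1)
        assert sig[region].mean() >= 0.5

    def test_t_to_z_order_preserved_across_pixels(self):
        from fuskit.filters import gaussian_smooth

        rng = np.random.default_rng(3)
        maps, _ = self._zmaps(rng, n=5, effect=0.5)
        zmap, _ = group_reho_stat_map(maps, fwhm_mm=0.3, pixel_size=0.1)
        stack = np.stack(
            [gaussian_smooth(m.values, 0.3, 0.1, m.mask) for m in maps]
        )
        t = stack.mean(0) / (stack.std(0, ddof=1) / np.sqrt(5))
        order_t = np.argsort(t[zmap.mask])
        order_z = np.argsort(zmap.values[zmap.mask])
        assert np.array_equal(order_t, order_z)
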