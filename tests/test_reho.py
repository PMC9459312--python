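import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

import dreho
from dreho.reho import (
    NeighborhoodSpec,
    SmoothSpec,
    WindowSpec,
    dreho_map,
    gaussian_smooth,
    kendall_w,
    normalize_by_global_mean,
    reho_map,
    sliding_windows,
    zscore_map,
)
from dreho.volume import ScalarMap, Volume4D

from conftest import make_volume


def brute_force_w(series):
    """Independent Kendall's W implementation straight from the definition."""
    series = np.asarray(series, float)
    k, n = series.shape
    ranks = np.array([rankdata(s) for s in series])
    r = ranks.sum(axis=0)
    s = ((r - r.mean()) ** 2).sum()
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        # a mid-rank shared by t series corresponds to a tie group of size t
        ties += sum(c**3 - c for c in counts)
    return 12 * s / (k**2 * (n**3 - n) - k * ties)


class TestKendallW:
    def test_identical_series_give_one(self):
        s = np.arange(10, dtype=float)
        assert kendall_w(np.tile(s, (27, 1))) == pytest.approx(1.0)

    def test_hand_worked_three_by_four(self):
        # two series ranked (1,2,3,4), one reversed -> W = 1/9
        series = np.array([[1, 2, 3, 4], [10, 20, 30, 40], [4, 3, 2, 1]], float)
        assert kendall_w(series) == pytest.approx(1 / 9)
        assert brute_force_w(series) == pytest.approx(1 / 9)

    def test_null_mean_is_one_over_k(self, rng):
        k, n, draws = 9, 12, 3000
        ws = [kendall_w(rng.standard_normal((k, n))) for _ in range(draws)]
        se = np.std(ws) / np.sqrt(draws)
        assert abs(np.mean(ws) - 1 / k) < 3 * se

    @pytest.mark.parametrize("k,n", [(2, 5), (3, 4), (5, 8), (4, 6)])
    def test_matches_brute_force_with_ties(self, rng, k, n):
        for _ in range(20):
            series = rng.integers(0, 4, size=(k, n)).astype(float)  # many ties
            if np.all(series.std(axis=1) == 0):
                continue
            assert kendall_w(series) == pytest.approx(brute_force_w(series), abs=1e-12)

    def test_monotone_invariance(self, rng):
        """W is a rank statistic: strictly monotone transforms do not change it."""
        series = rng.standard_normal((5, 10))
        transformed = np.exp(series * 2.0) + 5.0
        assert kendall_w(transformed) == pytest.approx(kendall_w(series), abs=1e-12)

    def test_all_constant_returns_zero(self):
        assert kendall_w(np.ones((3, 5))) == 0.0

    def test_too_few_series_rejected(self):
        with pytest.raises(ValueError):
            kendall_w(np.ones((1, 5)))


class TestSlidingWindows:
    def test_230_length_30_step_1(self):
        assert len(sliding_windows(230, WindowSpec(30, 1))) == 201

    def test_230_length_25_step_1(self):
        assert len(sliding_windows(230, WindowSpec(25, 1))) == 206

    def test_windows_are_half_open_and_cover(self):
        wins = sliding_windows(10, WindowSpec(4, 3))
        assert wins == [(0, 4), (3, 7), (6, 10)]

    def test_too_long_window_errors(self):
        with pytest.raises(ValueError):
            sliding_windows(20, WindowSpec(30, 1))

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(10, 11)


class TestRehoMap:
    def test_shared_series_gives_one_everywhere(self, rng):
        vol = make_volume(rng, shape=(5, 5, 4), n_t=15)
        vol.data[:] = vol.data[0, 0, 0]
        m = reho_map(vol)
        np.testing.assert_allclose(m.in_mask, 1.0)

    def test_null_mean_matches_one_over_k_map(self, rng):
        """Independent noise: E[W] = 1/K voxelwise, K varying at boundaries."""
        from scipy import ndimage

        vol = make_volume(rng, shape=(10, 10, 8), n_t=40)
        m = reho_map(vol)
        k_map = ndimage.correlate(
            vol.mask.astype(float), np.ones((3, 3, 3)), mode="constant"
        )
        expected = (1.0 / k_map[vol.mask]).mean()
        assert abs(m.in_mask.mean() - expected) < 0.01

    def test_matches_per_voxel_brute_force(self, rng):
        shape = (6, 6, 6)
        mask = rng.random(shape) > 0.25
        vol = make_volume(rng, shape=shape, n_t=12, mask=mask)
        m = reho_map(vol, NeighborhoodSpec(27))
        for i, j, k in itertools.product(range(6), repeat=3):
            if not mask[i, j, k]:
                continue
            nb = [
                vol.data[a, b, c]
                for a in range(max(0, i - 1), min(6, i + 2))
                for b in range(max(0, j - 1), min(6, j + 2))
                for c in range(max(0, k - 1), min(6, k + 2))
                if mask[a, b, c]
            ]
            if len(nb) >= 2:
                assert m.data[i, j, k] == pytest.approx(
                    kendall_w(np.array(nb)), abs=1e-10
                )

    @pytest.mark.parametrize("connectivity", [7, 19])
    def test_reduced_neighborhoods_match_brute_force(self, rng, connectivity):
        from scipy import ndimage

        struct = ndimage.generate_binary_structure(3, 1 if connectivity == 7 else 2)
        shape = (5, 5, 4)
        vol = make_volume(rng, shape=shape, n_t=10)
        m = reho_map(vol, NeighborhoodSpec(connectivity))
        offsets = np.argwhere(struct) - 1
        for i, j, k in [(2, 2, 2), (0, 0, 0), (4, 2, 1)]:
            nb = []
            for di, dj, dk in offsets:
                a, b, c = i + di, j + dj, k + dk
                if 0 <= a < 5 and 0 <= b < 5 and 0 <= c < 4:
                    nb.append(vol.data[a, b, c])
            assert m.data[i, j, k] == pytest.approx(kendall_w(np.array(nb)), abs=1e-10)

    def test_empty_mask_rejected(self, rng):
        vol = make_volume(rng, shape=(4, 4, 4), n_t=10, mask=np.zeros((4, 4, 4), bool))
        with pytest.raises(ValueError):
            reho_map(vol)


class TestDrehoMap:
    def test_matches_brute_force_loop(self, rng):
        vol = make_volume(rng, shape=(5, 5, 4), n_t=18)
        ws = WindowSpec(6, 2)
        m = dreho_map(vol, ws=ws)
        wins = sliding_windows(18, ws)
        per_window = [
            reho_map(vol.with_data(vol.data[..., s:e])).data for s, e in wins
        ]
        expected = np.std(per_window, axis=0, ddof=1)
        np.testing.assert_allclose(
            m.data[vol.mask], expected[vol.mask], atol=1e-10
        )

    def test_single_window_errors(self, rng):
        vol = make_volume(rng, shape=(3, 3, 3), n_t=10)
        with pytest.raises(ValueError):
            dreho_map(vol, ws=WindowSpec(10, 1))

    def test_modulated_mixing_raises_variability(self, rng):
        """Amplitude-modulated shared signal must out-vary stationary mixing."""
        n_t, reps = 120, 12
        t = np.arange(n_t)
        diffs = []
        for rep in range(reps):
            shared = rng.standard_normal(n_t)
            stat_mean = mod_mean = 0.0
            for case in ("stationary", "modulated"):
                a = 0.5 + (0.35 * np.sin(2 * np.pi * t / 50) if case == "modulated" else 0.0)
                data = np.sqrt(1 - a**2) * rng.standard_normal((3, 3, 3, n_t)) + a * shared
                vol = make_volume(rng, shape=(3, 3, 3), n_t=n_t)
                vol = vol.with_data(data)
                sd = dreho_map(vol, ws=WindowSpec(30, 5)).data[1, 1, 1]
                if case == "stationary":
                    stat_mean = sd
                else:
                    mod_mean = sd
            diffs.append(mod_mean - stat_mean)
        assert np.mean(diffs) > 0
        assert np.mean(diffs) > 2 * np.std(diffs) / np.sqrt(reps)

    def test_cv_is_sd_over_mean(self, rng):
        vol = make_volume(rng, shape=(4, 4, 3), n_t=20)
        ws = WindowSpec(8, 4)
        sd = dreho_map(vol, ws=ws, metric="sd")
        cv = dreho_map(vol, ws=ws, metric="cv")
        wins = sliding_windows(20, ws)
        mean_w = np.mean(
            [reho_map(vol.with_data(vol.data[..., s:e])).data for s, e in wins], axis=0
        )
        np.testing.assert_allclose(
            cv.data[vol.mask], (sd.data / mean_w)[vol.mask], atol=1e-10
        )


class TestNormalization:
    def test_mean_division_gives_unit_mean(self, rng):
        m = ScalarMap(rng.random((5, 5, 5)) + 0.5, np.eye(4), np.ones((5, 5, 5), bool))
        out = normalize_by_global_mean(m)
        assert out.in_mask.mean() == pytest.approx(1.0)

    def test_constant_map_becomes_ones(self):
        m = ScalarMap(np.full((4, 4, 4), 3.7), np.eye(4), np.ones((4, 4, 4), bool))
        np.testing.assert_allclose(normalize_by_global_mean(m).in_mask, 1.0)

    def test_zero_map_rejected(self):
        m = ScalarMap(np.zeros((4, 4, 4)), np.eye(4), np.ones((4, 4, 4), bool))
        with pytest.raises(ValueError):
            normalize_by_global_mean(m)

    def test_zscore_moments(self, rng):
        m = ScalarMap(rng.random((5, 5, 5)), np.eye(4), rng.random((5, 5, 5)) > 0.3)
        out = zscore_map(m)
        assert out.in_mask.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.in_mask.std() == pytest.approx(1.0)

    def test_zscore_affine_invariance(self, rng):
        m = ScalarMap(rng.random((5, 5, 5)), np.eye(4), np.ones((5, 5, 5), bool))
        shifted = m.with_data(4.0 * m.data + 11.0)
        np.testing.assert_allclose(
            zscore_map(shifted).data, zscore_map(m).data, atol=1e-10
        )

    def test_zscore_constant_map_rejected(self):
        m = ScalarMap(np.full((3, 3, 3), 2.0), np.eye(4), np.ones((3, 3, 3), bool))
        with pytest.raises(ValueError):
            zscore_map(m)


class TestSmoothing:
    def test_sigma_conversion(self):
        # 6 mm FWHM on 3 mm voxels: sigma = 6 / 2.3548 / 3 = 0.8493 voxels
        from dreho.reho import FWHM_TO_SIGMA

        assert 6.0 * FWHM_TO_SIGMA / 3.0 == pytest.approx(0.8493, abs=2e-4)

    def test_constant_map_preserved(self, rng):
        mask = rng.random((8, 8, 8)) > 0.4
        m = ScalarMap(np.full((8, 8, 8), 2.5), np.diag([3.0, 3, 3, 1]), mask)
        out = gaussian_smooth(m, SmoothSpec(6.0))
        np.testing.assert_allclose(out.data[mask], 2.5, atol=1e-10)

    def test_fwhm_zero_is_identity(self, rng):
        m = ScalarMap(rng.random((5, 5, 5)), np.diag([3.0, 3, 3, 1]), np.ones((5, 5, 5), bool))
        np.testing.assert_array_equal(gaussian_smooth(m, SmoothSpec(0.0)).data, m.data)

    def test_smoothing_reduces_variance(self, rng):
        m = ScalarMap(rng.standard_normal((12, 12, 12)), np.diag([3.0, 3, 3, 1]),
                      np.ones((12, 12, 12), bool))
        out = gaussian_smooth(m, SmoothSpec(6.0))
        assert out.in_mask.std() < 0.5 * m.in_mask.std()


class TestStepSizeProperty:
    def test_non_overlapping_windows_vary_more(self, rng):
        """step=length (independent windows) gives larger dReHo-sd on noise
        than step=1 (heavily overlapping, smoothed W trajectory)."""
        vals = {1: [], 10: []}
        for rep in range(8):
            vol = make_volume(np.random.default_rng(rep), shape=(4, 4, 3), n_t=60)
            for step in (1, 10):
                m = dreho_map(vol, ws=WindowSpec(10, step))
                vals[step].append(m.in_mask.mean())
        assert np.mean(vals[10]) > np.mean(vals[1])


class TestKendallWProperties:
    """Hypothesis property tests of the concordance statistic."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    @given(
        hnp.arrays(
            float,
            st.tuples(st.integers(2, 6), st.integers(3, 10)),
            elements=st.floats(-50, 50, allow_nan=False),
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_w_in_unit_interval_and_matches_oracle(self, series):
        import numpy as np

        w = kendall_w(series)
        assert 0.0 <= w <= 1.0 + 1e-12
        with np.errstate(invalid="ignore"):
            expected = brute_force_w(series)
        if np.isnan(expected):  # every series constant: W undefined, 0 by contract
            assert w == 0.0
        else:
            assert w == pytest.approx(expected, abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        import numpy as np

        local = np.random.default_rng(seed)
        series = local.standard_normal((4, 8))
        transformed = np.tanh(series) * 3.0 + 1.0  # strictly monotone
        assert kendall_w(transformed) == pytest.approx(kendall_w(series), abs=1e-12)


def test_full_chain_reproducible(rng):
    """reho-over-windows -> sd -> normalize -> smooth is bit-identical on rerun."""
    def chain(seed):
        vol = make_volume(np.random.default_rng(seed), shape=(6, 6, 5), n_t=40)
        m = dreho_map(vol, ws=WindowSpec(12, 4))
        m = normalize_by_global_mean(m)
        return gaussian_smooth(m, SmoothSpec(6.0)).data

    np.testing.assert_array_equal(chain(7), chain(7))
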