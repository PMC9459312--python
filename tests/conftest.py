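import numpy as np
import pytest

from dreho.volume import Volume4D


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(rng, shape=(6, 6, 6), n_t=20, tr=2.0, mask=None):
    data = rng.standard_normal(shape + (n_t,))
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return Volume4D(data=data, affine=np.diag([3.0, 3.0, 3.0, 1.0]), tr_seconds=tr, mask=mask)


@pytest.fixture
def small_volume(rng):
    return make_volume(rng)


def region_windowed_w_sd(volume, region_mask, length=30, step=5, n_discard=10):
    """Across-window sd of Kendall's W over a region's voxel series.

    A cheap region-level surrogate for the voxelwise dReHo map: the region's
    in-mask voxels form one neighborhood set, preprocessed per the standard
    temporal pipeline, and W is computed per sliding window.
    """
    from dreho.prep import bandpass_series
    from dreho.reho import WindowSpec, kendall_w, sliding_windows

    series = volume.data[region_mask & volume.mask][:, n_discard:]
    t = np.arange(series.shape[1], dtype=float)
    t_c = t - t.mean()
    slope = (series * t_c).sum(axis=1, keepdims=True) / (t_c**2).sum()
    series = series - slope * t_c
    series = bandpass_series(series, volume.tr_seconds, 0.01, 0.08)
    wins = sliding_windows(series.shape[1], WindowSpec(length, step))
    ws = [kendall_w(series[:, s:e]) for s, e in wins]
    return float(np.std(ws, ddof=1))
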