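"""Regional homogeneity (Kendall's W) maps, static and dynamic.

Static ReHo assigns each voxel the Kendall coefficient of concordance W of
the time series in its neighborhood (7, 19 or 27 voxels including the
center). Dynamic ReHo (dReHo) recomputes ReHo inside overlapping sliding
windows and summarizes each voxel by the across-window variability
(standard deviation by default, coefficient of variation optionally).

Kendall's W for K series of length n, with mid-rank tie correction:

    W = 12 S / (K^2 (n^3 - n) - K * sum_j T_j)

where R_i is the across-series rank sum at time i, S = sum_i (R_i - Rbar)^2,
and T_j = sum over tie groups of (t^3 - t) for series j. The engine exploits
the mid-rank identity T_j = (n^3 - n) - 12 * sum_i (r_ij - (n+1)/2)^2 so that
both S and the tie term reduce to box-filterable quantities, which is what
makes whole-brain windowed maps tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .volume import ScalarMap, Volume4D

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# 3x3x3 footprints for the three standard ReHo cluster sizes
_STRUCTURES = {
    7: ndimage.generate_binary_structure(3, 1),   # faces
    19: ndimage.generate_binary_structure(3, 2),  # faces + edges
    27: ndimage.generate_binary_structure(3, 3),  # full cube
}


@dataclass
class NeighborhoodSpec:
    """Voxel neighborhood: 7 (faces), 19 (faces+edges) or 27 (full cube)."""

    connectivity: int = 27

    def __post_init__(self) -> None:
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be one of 7, 19, 27")

    @property
    def structure(self) -> np.ndarray:
        return _STRUCTURES[self.connectivity].astype(np.float64)


@dataclass
class WindowSpec:
    """Sliding-window schedule in repetition-time (TR) units."""

    length_tr: int = 30
    step_tr: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.step_tr <= self.length_tr):
            raise ValueError("require 1 <= step <= length")
        if self.length_tr < 2:
            raise ValueError("window length must be >= 2")

    def check_min_frequency(self, tr_seconds: float, f_min_hz: float) -> bool:
        """Guidance check: window should span at least one period of f_min."""
        return self.length_tr * tr_seconds >= 1.0 / f_min_hz


@dataclass
class SmoothSpec:
    """Isotropic Gaussian smoothing kernel, FWHM in millimetres."""

    fwhm_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.fwhm_mm < 0:
            raise ValueError("fwhm must be >= 0")


def sliding_windows(n_timepoints: int, ws: WindowSpec) -> list[tuple[int, int]]:
    """Half-open [start, end) index pairs: [i*step, i*step+length)."""
    if ws.length_tr > n_timepoints:
        raise ValueError(
            f"window length {ws.length_tr} exceeds series length {n_timepoints}"
        )
    n_windows = (n_timepoints - ws.length_tr) // ws.step_tr + 1
    return [(i * ws.step_tr, i * ws.step_tr + ws.length_tr) for i in range(n_windows)]


# ---------------------------------------------------------------------------
# Kendall's W


def kendall_w(series_set: np.ndarray) -> float:
    """Kendall's coefficient of concordance for a (K, n) set of series.

    Tie-corrected with mid-ranks. Returns a value in (0, 1]; 1 iff all K
    series share one strict rank ordering. A zero-variance series is handled
    through mid-ranks (all ranks (n+1)/2); if every series is constant the
    statistic is undefined and 0.0 is returned.
    """
    series = np.asarray(series_set, dtype=np.float64)
    if series.ndim != 2:
        raise ValueError("series_set must be 2D (K, n)")
    k, n = series.shape
    if k < 2 or n < 2:
        raise ValueError("need K >= 2 series of length n >= 2")
    ranks = rankdata(series, axis=1)
    rank_sums = ranks.sum(axis=0)
    s = ((rank_sums - rank_sums.mean()) ** 2).sum()
    centered = ranks - (n + 1) / 2.0
    ties = (n**3 - n) - 12.0 * (centered**2).sum(axis=1)
    denom = k**2 * (n**3 - n) - k * ties.sum()
    if denom <= 0:
        return 0.0
    return float(12.0 * s / denom)


def _window_view(data: np.ndarray, windows: list[tuple[int, int]], step: int) -> np.ndarray:
    """(..., T) -> strided view (..., n_windows, L) for equal-length windows."""
    length = windows[0][1] - windows[0][0]
    from numpy.lib.stride_tricks import sliding_window_view

    view = sliding_window_view(data, length, axis=-1)  # (..., T-L+1, L)
    return view[..., ::step, :]


def _midranks(seg: np.ndarray, may_have_ties: bool = True) -> np.ndarray:
    """Mid-ranks along the last axis; fast argsort path when tie-free."""
    if may_have_ties:
        return rankdata(seg, axis=-1)
    order = np.argsort(seg, axis=-1)
    ranks = np.empty(seg.shape, dtype=np.float64)
    ladder = np.broadcast_to(
        np.arange(1, seg.shape[-1] + 1, dtype=np.float64), seg.shape
    )
    np.put_along_axis(ranks, order, ladder, axis=-1)
    return ranks


def _series_have_ties(data: np.ndarray) -> bool:
    """True if any voxel's full time series contains a repeated value.

    Ties inside any window imply a repeat in the full series, so one sorted
    pass over the series decides whether the cheap tie-free rank path is safe
    for every window.
    """
    srt = np.sort(data, axis=-1)
    return bool((np.diff(srt, axis=-1) == 0).any())


def _neighbor_sum(arr: np.ndarray, structure: np.ndarray, extra_axes: int) -> np.ndarray:
    """Sum over the 3x3x3 footprint on the first three axes, zero-padded."""
    if structure.all():  # full cube separates into three box filters
        out = arr
        for axis in range(3):
            out = ndimage.correlate1d(
                out, np.ones(3), axis=axis, mode="constant", cval=0.0
            )
        return out
    weights = structure.reshape(structure.shape + (1,) * extra_axes)
    return ndimage.correlate(arr, weights, mode="constant", cval=0.0)


def _windowed_w(
    data: np.ndarray,
    mask: np.ndarray,
    structure: np.ndarray,
    windows: list[tuple[int, int]],
    step: int,
    max_chunk_elements: int = 30_000_000,
) -> np.ndarray:
    """Kendall's W per voxel per window.

    Returns (x, y, z, n_windows); zeros outside the mask. Neighborhoods are
    clipped to the mask (K reduced at edges), never zero-padded.
    """
    x, y, z, _ = data.shape
    n_windows = len(windows)
    length = windows[0][1] - windows[0][0]
    maskf = mask.astype(np.float64)
    k_map = _neighbor_sum(maskf, structure, extra_axes=0)
    k_map *= maskf  # only defined inside the mask

    view = _window_view(data, windows, step)  # (x,y,z,n_windows,L)
    out = np.zeros((x, y, z, n_windows), dtype=np.float64)
    may_have_ties = _series_have_ties(data)

    chunk = max(1, int(max_chunk_elements // max(1, x * y * z * length)))
    for lo in range(0, n_windows, chunk):
        hi = min(lo + chunk, n_windows)
        seg = np.ascontiguousarray(view[..., lo:hi, :])
        ranks = _midranks(seg, may_have_ties)
        ranks *= maskf[..., None, None]
        rank_sums = _neighbor_sum(ranks, structure, extra_axes=2)
        # Rbar = K (L+1)/2 exactly: every series contributes mean rank (L+1)/2
        rank_sums -= k_map[..., None, None] * (length + 1) / 2.0
        s = (rank_sums**2).sum(axis=-1)
        centered = ranks - maskf[..., None, None] * (length + 1) / 2.0
        tie = maskf[..., None] * (length**3 - length) - 12.0 * (centered**2).sum(axis=-1)
        tie_sum = _neighbor_sum(tie, structure, extra_axes=1)
        denom = k_map[..., None] ** 2 * (length**3 - length) - k_map[..., None] * tie_sum
        with np.errstate(divide="ignore", invalid="ignore"):
            w = np.where(denom > 0, 12.0 * s / np.where(denom > 0, denom, 1.0), 0.0)
        out[..., lo:hi] = w * maskf[..., None]
    return out


def reho_map(vol: Volume4D, nb: NeighborhoodSpec | None = None) -> ScalarMap:
    """Static ReHo: Kendall's W of each voxel's in-mask neighborhood."""
    nb = nb or NeighborhoodSpec()
    if not vol.mask.any():
        raise ValueError("empty mask")
    w = _windowed_w(
        vol.data, vol.mask, nb.structure, [(0, vol.n_volumes)], step=1
    )[..., 0]
    return ScalarMap(data=w, affine=vol.affine, mask=vol.mask, label="reho")


def dreho_map(
    vol: Volume4D,
    nb: NeighborhoodSpec | None = None,
    ws: WindowSpec | None = None,
    metric: str = "sd",
) -> ScalarMap:
    """Dynamic ReHo: across-window variability of windowed ReHo.

    ``metric`` is ``"sd"`` (sample standard deviation across windows, the
    default) or ``"cv"`` (sd divided by the across-window mean).
    """
    nb = nb or NeighborhoodSpec()
    ws = ws or WindowSpec()
    if metric not in ("sd", "cv"):
        raise ValueError("metric must be 'sd' or 'cv'")
    if not vol.mask.any():
        raise ValueError("empty mask")
    windows = sliding_windows(vol.n_volumes, ws)
    if len(windows) < 2:
        raise ValueError("need at least 2 windows for a variability map")
    w = _windowed_w(vol.data, vol.mask, nb.structure, windows, ws.step_tr)
    sd = w.std(axis=-1, ddof=1)
    if metric == "cv":
        mean = w.mean(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            data = np.where(mean != 0, sd / np.where(mean != 0, mean, 1.0), 0.0)
        label = "dreho_cv"
    else:
        data, label = sd, "dreho_sd"
    data = np.where(vol.mask, data, 0.0)
    return ScalarMap(data=data, affine=vol.affine, mask=vol.mask, label=label)


def windowed_reho_series(
    vol: Volume4D, nb: NeighborhoodSpec, ws: WindowSpec
) -> np.ndarray:
    """Per-voxel ReHo for every window, shape (x, y, z, n_windows)."""
    windows = sliding_windows(vol.n_volumes, ws)
    return _windowed_w(vol.data, vol.mask, nb.structure, windows, ws.step_tr)


# ---------------------------------------------------------------------------
# Normalization and smoothing


def normalize_by_global_mean(m: ScalarMap) -> ScalarMap:
    """Divide every in-mask voxel by the in-mask (whole-brain) mean."""
    mean = m.in_mask.mean()
    scale = np.abs(m.in_mask).max() if m.in_mask.size else 0.0
    if not np.isfinite(mean) or np.abs(mean) <= 1e-12 * max(scale, 1.0):
        raise ValueError("in-mask mean is (numerically) zero; cannot normalize")
    data = np.where(m.mask, m.data / mean, 0.0)
    return m.with_data(data, label="normalized")


def zscore_map(m: ScalarMap) -> ScalarMap:
    """Standardize in-mask voxels to mean 0, sd 1 (population sd)."""
    vals = m.in_mask
    sd = vals.std()
    if sd <= 0:
        raise ValueError("zero in-mask variance; cannot z-score")
    data = np.where(m.mask, (m.data - vals.mean()) / sd, 0.0)
    return m.with_data(data, label="zscored")


def normalize_map(m: ScalarMap, how: str = "mean-div") -> ScalarMap:
    """Apply the configured normalization: mean-div, zscore, or both."""
    if how == "mean-div":
        return normalize_by_global_mean(m)
    if how == "zscore":
        return zscore_map(m)
    if how == "both":
        return zscore_map(normalize_by_global_mean(m))
    raise ValueError("how must be 'mean-div', 'zscore' or 'both'")


def gaussian_smooth(m: ScalarMap, sp: SmoothSpec | None = None) -> ScalarMap:
    """Separable Gaussian smoothing with mask-renormalized kernel weights.

    sigma per axis = fwhm_mm * voxel-size / (2 sqrt(2 ln 2)); kernel weights
    are renormalized over the in-mask support so a constant map is preserved
    and no signal bleeds in from outside the mask.
    """
    sp = sp or SmoothSpec()
    if sp.fwhm_mm == 0:
        return m.with_data(m.data.copy(), label="smoothed")
    sigma_vox = sp.fwhm_mm * FWHM_TO_SIGMA / m.voxel_size_mm
    maskf = m.mask.astype(np.float64)
    num = ndimage.gaussian_filter(m.data * maskf, sigma=sigma_vox, mode="constant")
    den = ndimage.gaussian_filter(maskf, sigma=sigma_vox, mode="constant")
    with np.errstate(divide="ignore", invalid="ignore"):
        data = np.where(m.mask, num / np.where(den > 0, den, 1.0), 0.0)
    return m.with_data(data, label="smoothed")
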