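"""Temporal preprocessing and head-motion screening.

The fixed per-subject order is: discard initial volumes → linear detrend →
ideal band-pass filter (0.01–0.08 Hz by default). Motion screening consumes a
six-parameter rigid-body trace and excludes a subject when any translation
exceeds 1.5 mm or any axis rotation exceeds 1.5 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import Volume4D


@dataclass
class PrepConfig:
    """Preprocessing parameters.

    Defaults mirror the standard resting-state recipe: drop the first 10
    volumes (scanner equilibration), band-pass 0.01–0.08 Hz, and exclude
    subjects moving more than 1.5 mm / 1.5 degrees.
    """

    n_discard: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    max_translation_mm: float = 1.5
    max_rotation_deg: float = 1.5
    detrend: bool = True
    # also null the in-band leakage of a linear trend, so detrend + filter
    # form an exact projection (the pipeline is idempotent after one pass)
    null_trend_leakage: bool = True

    def validate(self, tr_seconds: float) -> None:
        nyquist = 1.0 / (2.0 * tr_seconds)
        if not (0 <= self.band_low_hz < self.band_high_hz):
            raise ValueError("require 0 <= band_low < band_high")
        if self.band_high_hz >= nyquist:
            raise ValueError(
                f"band_high {self.band_high_hz} Hz >= Nyquist {nyquist} Hz"
            )


def discard_initial_volumes(vol: Volume4D, n_discard: int) -> Volume4D:
    """Drop the first ``n_discard`` volumes (magnetic-saturation frames)."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if vol.n_volumes <= n_discard:
        raise ValueError(
            f"cannot discard {n_discard} of {vol.n_volumes} volumes: nothing left"
        )
    return vol.with_data(vol.data[..., n_discard:])


def detrend(vol: Volume4D) -> Volume4D:
    """Remove the per-voxel least-squares linear trend, keeping the mean.

    The temporal mean is re-added after trend removal so intensities stay on
    their original scale (the band-pass removes the mean later anyway).
    """
    data = vol.data
    if data.shape[-1] < 3:
        raise ValueError("detrend needs at least 3 time points")
    t = np.arange(data.shape[-1], dtype=np.float64)
    t_c = t - t.mean()
    denom = (t_c**2).sum()
    mean = data.mean(axis=-1, keepdims=True)
    slope = (data * t_c).sum(axis=-1, keepdims=True) / denom
    return vol.with_data(data - slope * t_c)


def bandpass_filter(vol: Volume4D, config: PrepConfig) -> Volume4D:
    """Ideal (brick-wall) frequency-domain band-pass.

    Fourier components with frequency strictly outside
    [band_low, band_high] are zeroed (the DC term always is, since
    band_low > 0 or by explicit removal), then the series is inverse
    transformed.
    """
    config.validate(vol.tr_seconds)
    data = bandpass_series(
        vol.data, vol.tr_seconds, config.band_low_hz, config.band_high_hz
    )
    if config.detrend and config.null_trend_leakage:
        n = data.shape[-1]
        ramp = np.arange(n, dtype=np.float64) - (n - 1) / 2.0
        ramp_b = bandpass_series(
            ramp, vol.tr_seconds, config.band_low_hz, config.band_high_hz
        )
        norm = np.linalg.norm(ramp_b)
        if norm > 0:
            ramp_b = ramp_b / norm
            data = data - np.einsum("...t,t->...", data, ramp_b)[..., None] * ramp_b
    return vol.with_data(data)


def bandpass_series(
    data: np.ndarray, tr_seconds: float, low_hz: float, high_hz: float
) -> np.ndarray:
    """Ideal band-pass along the last axis of an arbitrary array."""
    n = data.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    spec = np.fft.rfft(data, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


# ---------------------------------------------------------------------------
# Motion


def framewise_displacement(trace: np.ndarray, sphere_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style framewise displacement per frame (first frame = 0).

    Sum of absolute frame-to-frame differences of the six parameters, with
    rotations converted from degrees to arc length on a 50 mm sphere.
    """
    trace = _check_trace(trace)
    diffs = np.abs(np.diff(trace, axis=0))
    diffs[:, 3:] = np.deg2rad(diffs[:, 3:]) * sphere_radius_mm
    fd = np.concatenate([[0.0], diffs.sum(axis=1)])
    return fd


def motion_screen(trace: np.ndarray, config: PrepConfig | None = None) -> tuple[bool, float]:
    """Screen a subject's motion trace.

    Returns
    -------
    retained : bool
        False iff any |translation| > max_translation_mm or any axis
        |rotation| > max_rotation_deg at any frame.
    motion_summary : float
        Mean framewise displacement (mm), the scalar entered as a nuisance
        covariate in the group design.
    """
    config = config or PrepConfig()
    trace = _check_trace(trace)
    max_t = np.abs(trace[:, :3]).max()
    max_r = np.abs(trace[:, 3:]).max()
    retained = (max_t <= config.max_translation_mm) and (max_r <= config.max_rotation_deg)
    return retained, float(framewise_displacement(trace).mean())


def _check_trace(trace: np.ndarray) -> np.ndarray:
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError("motion trace must be a (n_volumes, 6) array")
    if trace.shape[0] == 0:
        raise ValueError("motion trace is empty")
    return trace


def preprocess(vol: Volume4D, config: PrepConfig | None = None) -> Volume4D:
    """Full temporal pipeline: discard → detrend → band-pass."""
    config = config or PrepConfig()
    out = discard_initial_volumes(vol, config.n_discard)
    if config.detrend:
        out = detrend(out)
    return bandpass_filter(out, config)
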