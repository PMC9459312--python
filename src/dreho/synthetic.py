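"""Synthetic two-group resting-state studies with known dynamic-coherence effects.

The generator emulates the structure of a clinical OSA-vs-control study: a
covariate table whose per-group means and SDs follow a configurable schema
(defaulting to published moderate/severe-OSA demographics), six-parameter
head-motion traces, and 4D scans in which the only group difference is the
*temporal modulation depth* of within-neighborhood coherence inside known
spherical regions.

Signal model per voxel v inside an effect region r:

    x_v(t) = sqrt(1 - a(t)^2) * eps_v(t) + a(t) * s_r(t)

where eps_v and s_r are independent band-limited (0.01-0.08 Hz) unit-variance
noise and a(t) = clip(a0 + d * sin(2 pi t TR / period + phi), 0, 0.95). The
instantaneous inter-voxel correlation is a(t)^2, so windowed Kendall's W
tracks the envelope; its across-window variability grows with the modulation
depth d. Patients and controls differ only in d (by the region's sign times
its amplitude), which is what the downstream map/inference stages must
recover. Outside regions the same model runs with the region share replaced
by purely private noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .prep import bandpass_series, framewise_displacement
from .volume import Volume4D, _default_affine

# Per-variable (patient mean, patient sd, control mean, control sd) and the
# variable's hard range. Defaults follow the published moderate/severe
# OSA (n=79) vs healthy-control (n=84) demographics table.
DEFAULT_COVARIATE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "age": (38.5, 9.3, 45.3, 12.1),
    "education": (12.8, 3.0, 11.2, 3.1),
    "bmi": (27.2, 3.5, 21.1, 1.7),
    "total_sleep_time": (387.5, 98.4, 407.3, 22.9),
    "sleep_period_time": (460.9, 71.6, 441.8, 22.3),
    "sleep_efficiency": (83.6, 17.8, 92.2, 3.5),
    "ahi": (54.0, 21.7, 2.2, 1.2),
    "sao2_below_90": (41.2, 48.1, 0.63, 1.3),
    "nadir_sao2": (68.1, 12.4, 93.8, 3.6),
    "mean_sao2": (92.0, 4.1, 96.9, 2.1),
    "odi": (49.9, 24.6, 1.8, 1.1),
    "moca_total": (24.4, 3.3, 28.0, 1.4),
    "moca_visuospatial": (3.9, 0.9, 4.7, 0.5),
    "moca_naming": (2.9, 0.3, 2.9, 0.2),
    "moca_delayed_memory": (2.6, 1.5, 4.3, 0.6),
    "moca_attention": (5.1, 1.3, 5.5, 0.5),
    "moca_language": (2.2, 0.8, 2.7, 0.4),
    "moca_abstraction": (1.5, 0.5, 1.9, 0.2),
    "moca_orientation": (5.7, 0.7, 5.9, 0.3),
    "ess": (11.5, 4.4, 1.4, 1.3),
}

# Hard ranges enforced on generated values. Only ranges a censored-normal
# family can honour together with the published means/SDs are imposed: the
# integer-valued MoCA subscores hug their scale maxima so tightly (e.g.
# naming 2.9 +/- 0.3 on a 0-3 scale) that no truncated/censored normal
# reproduces both moments, so subscores are only bounded below; the
# scale-level constraints (percentages, total score, ESS, AHI) are kept.
VARIABLE_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (18.0, 90.0),
    "education": (0.0, 25.0),
    "bmi": (12.0, 60.0),
    "total_sleep_time": (0.0, 720.0),
    "sleep_period_time": (0.0, 720.0),
    "sleep_efficiency": (0.0, 100.0),
    "ahi": (0.0, np.inf),
    "sao2_below_90": (0.0, 100.0),
    "nadir_sao2": (0.0, 100.0),
    "mean_sao2": (0.0, 100.0),
    "odi": (0.0, np.inf),
    "moca_total": (0.0, 30.0),
    "moca_visuospatial": (0.0, np.inf),
    "moca_naming": (0.0, np.inf),
    "moca_delayed_memory": (0.0, np.inf),
    "moca_attention": (0.0, np.inf),
    "moca_language": (0.0, np.inf),
    "moca_abstraction": (0.0, np.inf),
    "moca_orientation": (0.0, np.inf),
    "ess": (0.0, 24.0),
}


@dataclass
class EffectRegion:
    """A spherical region with group-dependent coherence-modulation depth."""

    center: tuple[int, int, int]
    radius: int
    sign: int                 # +1: patients more variable; -1: less
    amplitude: float          # group difference in modulation depth

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if not (0 <= self.amplitude < 1):
            raise ValueError("amplitude must lie in [0, 1)")


@dataclass
class CohortSpec:
    """Generative description of a two-group synthetic study."""

    n_patients: int = 79
    n_controls: int = 84
    grid_shape: tuple[int, int, int] = (24, 24, 16)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_volumes: int = 240
    tr_seconds: float = 2.0
    # None -> one positive and one negative sphere placed relative to the grid
    effect_regions: list[EffectRegion] | None = None
    covariate_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS)
    )
    coupling: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    # signal-model knobs
    base_mixing: float = 0.45        # a0, time-mean coupling to the shared signal
    base_depth: float = 0.20         # control-group modulation depth d
    depth_jitter_sd: float = 0.04    # between-subject depth variation
    envelope_period_s: float = 100.0
    envelope_phase: str = "random"   # "random": per subject; "fixed": aligned
    shared_signal: str = "noise"     # "noise": band-limited noise; "tone": fixed sinusoid
    band_hz: tuple[float, float] = (0.01, 0.08)
    white_noise_sd: float = 0.3      # out-of-band noise on top of band signal
    drift_per_volume: float = 0.005  # linear scanner-drift slope scale
    mean_intensity: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        if self.effect_regions is None:
            nx, ny, nz = self.grid_shape
            radius = 2
            self.effect_regions = [
                EffectRegion(
                    center=(nx // 3, ny // 3, nz // 2), radius=radius,
                    sign=+1, amplitude=0.25,
                ),
                EffectRegion(
                    center=(2 * nx // 3, 2 * ny // 3, nz // 2), radius=radius,
                    sign=-1, amplitude=0.15,
                ),
            ]
        for name, (_, sd_p, _, sd_c) in self.covariate_params.items():
            if sd_p < 0 or sd_c < 0:
                raise ValueError(f"{name}: sd must be >= 0")
        shape = np.array(self.grid_shape)
        for r in self.effect_regions:
            c = np.array(r.center)
            if ((c - r.radius) < 0).any() or ((c + r.radius) >= shape).any():
                raise ValueError(f"effect region at {r.center} leaves the grid")

    @property
    def affine(self) -> np.ndarray:
        return _default_affine(self.voxel_size_mm)

    def make_mask(self) -> np.ndarray:
        """Ellipsoidal brain-like mask inscribed in the grid."""
        shape = np.array(self.grid_shape, dtype=float)
        center = (shape - 1) / 2.0
        semi = shape * 0.48
        ijk = np.indices(self.grid_shape).astype(float)
        dist = sum(((ijk[d] - center[d]) / semi[d]) ** 2 for d in range(3))
        return dist <= 1.0

    def region_masks(self) -> list[np.ndarray]:
        ijk = np.indices(self.grid_shape).astype(float)
        masks = []
        for r in self.effect_regions:
            dist = sum((ijk[d] - r.center[d]) ** 2 for d in range(3))
            masks.append(dist <= r.radius**2)
        return masks

    def ground_truth_effect(self) -> np.ndarray:
        """Map of the patient-minus-control modulation-depth difference."""
        gt = np.zeros(self.grid_shape)
        for r, rmask in zip(self.effect_regions, self.region_masks()):
            gt[rmask] = r.sign * r.amplitude
        return gt


@dataclass
class SubjectRecord:
    """Clinical/polysomnographic covariates for one participant."""

    subject_id: str
    group: str  # "patient" | "control"
    index: int  # cohort-wide position, keys the per-subject random stream
    values: dict[str, float]
    effect_z: float = 0.0        # standardized depth jitter, couples covariates
    motion_summary: float = 0.0  # mean framewise displacement, mm

    def __getattr__(self, name):
        values = object.__getattribute__(self, "values")
        if name in values:
            return values[name]
        raise AttributeError(name)


def cohort_dataframe(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"subject_id": r.subject_id, "group": r.group, **r.values,
               "motion_summary": r.motion_summary}
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clinical table


from functools import lru_cache


def _clipped_normal_moments(mu: float, sigma: float, lo: float, hi: float):
    """Mean and sd of clip(N(mu, sigma), lo, hi) (censored normal)."""
    a = (lo - mu) / sigma if np.isfinite(lo) else -np.inf
    b = (hi - mu) / sigma if np.isfinite(hi) else np.inf
    phi_a, phi_b = stats.norm.pdf(a), stats.norm.pdf(b)
    cdf_a, cdf_b = stats.norm.cdf(a), stats.norm.cdf(b)
    mid = cdf_b - cdf_a
    m = mu * mid + sigma * (phi_a - phi_b)
    m2 = (
        mu**2 * mid
        + 2 * mu * sigma * (phi_a - phi_b)
        + sigma**2 * (mid + (a * phi_a if np.isfinite(a) else 0.0)
                      - (b * phi_b if np.isfinite(b) else 0.0))
    )
    if np.isfinite(lo):
        m += lo * cdf_a
        m2 += lo**2 * cdf_a
    if np.isfinite(hi):
        m += hi * (1.0 - cdf_b)
        m2 += hi**2 * (1.0 - cdf_b)
    var = m2 - m**2
    return m, np.sqrt(max(var, 0.0))


@lru_cache(maxsize=None)
def _clipnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Underlying (mu, sigma) whose [lo,hi]-censored normal has the target
    mean and sd; falls back to the naive parameters when the solve fails.

    Censoring (a point mass at the bound, as real polysomnographic
    percentages have at 0 or 100) reaches moment combinations a rejection-
    truncated normal cannot, e.g. coefficient of variation above 1 against a
    bound."""
    if sd == 0:
        return mean, 0.0
    a0, b0 = (lo - mean) / sd, (hi - mean) / sd
    if a0 < -6 and b0 > 6:  # clipping negligible
        return mean, sd

    def residual(params):
        mu, log_sigma = params
        sigma = np.exp(np.clip(log_sigma, -20, 20))
        with np.errstate(all="ignore"):
            m, s = _clipped_normal_moments(mu, sigma, lo, hi)
        if not (np.isfinite(m) and np.isfinite(s) and s > 0):
            return [1e3, 1e3]
        return [(m - mean) / sd, (s - sd) / sd]

    # the solution can sit well outside [lo, hi] when the target mean hugs a
    # bound, so try several starting points
    starts = [(mean, np.log(sd))]
    for k in (1.0, 3.0, 6.0):
        for s in (2.0, 4.0, 8.0):
            starts += [(mean - k * sd, np.log(s * sd)), (mean + k * sd, np.log(s * sd))]
    best = None
    with np.errstate(all="ignore"):
        for x0 in starts:
            res = optimize.least_squares(residual, x0, method="lm")
            if best is None or res.cost < best.cost:
                best = res
            if res.cost < 1e-16:
                break
    if best is None or not np.all(np.isfinite(best.x)) or best.cost > 1e-6:
        return mean, sd
    return float(best.x[0]), float(np.exp(best.x[1]))


def generate_clinical_table(spec: CohortSpec, rng=None) -> list[SubjectRecord]:
    """Draw per-group covariates as range-censored Gaussians, moment-matched
    so per-group sample means and SDs converge to ``covariate_params``.

    Covariates named in ``spec.coupling`` are instead linearly coupled to the
    subject's standardized injected-effect jitter z with the named target
    correlation: value = mu + sd (rho z + sqrt(1-rho^2) z'). Deterministic
    given the spec's seed.
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence((spec.seed, 11))
    )
    records: list[SubjectRecord] = []
    groups = [("patient", spec.n_patients), ("control", spec.n_controls)]
    index = 0
    for group, n in groups:
        sel = slice(0, 2) if group == "patient" else slice(2, 4)
        effect_z = rng.standard_normal(n)
        draws: dict[str, np.ndarray] = {}
        for name, params in spec.covariate_params.items():
            mean, sd = params[sel][0], params[sel][1]
            if name in spec.coupling:
                rho = spec.coupling[name]
                if not (-1 <= rho <= 1):
                    raise ValueError(f"coupling for {name} must be in [-1, 1]")
                noise = rng.standard_normal(n)
                vals = mean + sd * (rho * effect_z + np.sqrt(1 - rho**2) * noise)
            elif sd == 0:
                vals = np.full(n, mean)
            else:
                lo, hi = VARIABLE_BOUNDS.get(name, (-np.inf, np.inf))
                mu, sigma = _clipnorm_params(mean, sd, lo, hi)
                if sigma == 0:
                    vals = np.full(n, mu)
                else:
                    vals = mu + sigma * rng.standard_normal(n)
            lo, hi = VARIABLE_BOUNDS.get(name, (-np.inf, np.inf))
            draws[name] = np.clip(vals, lo, hi)
        motion = rng.lognormal(mean=np.log(0.08), sigma=0.4, size=n)
        prefix = "p" if group == "patient" else "c"
        for i in range(n):
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{prefix}{i:03d}",
                    group=group,
                    index=index,
                    values={k: float(v[i]) for k, v in draws.items()},
                    effect_z=float(effect_z[i]),
                    motion_summary=float(motion[i]),
                )
            )
            index += 1
    return records


# ---------------------------------------------------------------------------
# Scans and motion


def _band_noise(rng, shape_t: tuple, tr: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise along the last axis."""
    x = rng.standard_normal(shape_t)
    x = bandpass_series(x, tr, band[0], band[1])
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def subject_depths(record: SubjectRecord, spec: CohortSpec) -> list[float]:
    """This subject's modulation depth in each effect region."""
    depths = []
    for region in spec.effect_regions:
        d = spec.base_depth
        if record.group == "patient":
            d += region.sign * region.amplitude
        d += spec.depth_jitter_sd * record.effect_z
        depths.append(float(np.clip(d, 0.0, 0.9)))
    return depths


@dataclass
class SimulatedScan:
    subject_id: str
    volume: Volume4D
    motion_trace: np.ndarray
    ground_truth_effect: np.ndarray


def generate_scan(record: SubjectRecord, spec: CohortSpec) -> SimulatedScan:
    """Simulate one subject's 4D scan under the coherence-modulation model."""
    seq = np.random.SeedSequence((spec.seed, 101, record.index))
    rng = np.random.default_rng(seq)
    nx, ny, nz = spec.grid_shape
    nt = spec.n_volumes
    tr = spec.tr_seconds
    mask = spec.make_mask()

    data = _band_noise(rng, (nx, ny, nz, nt), tr, spec.band_hz)

    t = np.arange(nt) * tr
    depths = subject_depths(record, spec)
    for region, rmask, depth in zip(
        spec.effect_regions, spec.region_masks(), depths
    ):
        if spec.shared_signal == "tone":
            f0 = np.sqrt(spec.band_hz[0] * spec.band_hz[1])  # band center (geometric)
            shared = np.sqrt(2.0) * np.sin(2 * np.pi * f0 * t)
        else:
            shared = _band_noise(rng, (nt,), tr, spec.band_hz)
        phase = rng.uniform(0, 2 * np.pi) if spec.envelope_phase == "random" else 0.0
        env = np.sin(2 * np.pi * t / spec.envelope_period_s + phase)
        a = np.clip(spec.base_mixing + depth * env, 0.0, 0.95)
        vox = rmask & mask
        data[vox] = np.sqrt(1 - a**2) * data[vox] + a * shared

    drift = rng.normal(0, spec.drift_per_volume, size=(nx, ny, nz, 1)) * np.arange(nt)
    data = (
        spec.mean_intensity
        + data
        + spec.white_noise_sd * rng.standard_normal(data.shape)
        + drift
    )
    data[~mask] = 0.0

    vol = Volume4D(data=data, affine=spec.affine, tr_seconds=tr, mask=mask)
    trace = generate_motion_trace(record, spec, exceed_threshold=False)
    return SimulatedScan(
        subject_id=record.subject_id,
        volume=vol,
        motion_trace=trace,
        ground_truth_effect=spec.ground_truth_effect(),
    )


def generate_motion_trace(
    record: SubjectRecord, spec: CohortSpec, exceed_threshold: bool = False
) -> np.ndarray:
    """Smooth random-walk six-parameter trace (mm, mm, mm, deg, deg, deg).

    With ``exceed_threshold`` the trace is rescaled so at least one
    translation exceeds 1.5 mm; otherwise every parameter stays strictly
    below 1.5 mm / 1.5 degrees.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 202, record.index)))
    nt = spec.n_volumes
    steps = rng.standard_normal((nt, 6))
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(9) / 9.0
    for j in range(6):
        walk[:, j] = np.convolve(walk[:, j], kernel, mode="same")
    walk -= walk[0]  # first frame is the reference
    peak = np.abs(walk).max(axis=0)
    peak = np.where(peak > 0, peak, 1.0)
    targets = rng.uniform(0.1, 1.2, size=6)  # strictly below the 1.5 thresholds
    trace = walk / peak * targets
    if exceed_threshold:
        axis = int(rng.integers(0, 3))
        trace[:, axis] *= 1.8 / np.abs(trace[:, axis]).max()
    return trace


def generate_cohort(spec: CohortSpec):
    """Full study: (records, scans). Motion summaries are filled from the
    generated traces so the clinical table matches the scans."""
    records = generate_clinical_table(spec)
    scans = []
    for rec in records:
        scan = generate_scan(rec, spec)
        rec.motion_summary = float(framewise_displacement(scan.motion_trace).mean())
        scans.append(scan)
    return records, scans
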