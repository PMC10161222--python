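"""Synthetic confocal FCS / FRET-FCS data with known ground truth.

The trace simulator is a minimal physical model of a confocal FCS
recording: point particles perform Brownian motion (per-bin Gaussian
displacements of std sqrt(2 D dt) per axis) in a periodic box much larger
than the observation volume; the detection profile is the usual 3D
Gaussian exp(-2(x^2+y^2)/w0^2 - 2 z^2/z0^2); each detection channel
accumulates Poisson counts around the profile-weighted brightness sum plus
a background rate.  All channels share particle positions, so a species
with brightness in two channels produces genuinely cross-correlated
signals — the operational surrogate for FRET-positive co-assembled
oligomers.  Optional two-state triplet blinking modulates brightness with
the stationary dark fraction and relaxation time of the correlation
model's triplet term.

Faster stand-ins for the higher-level study data are also provided:
analytic correlation curves with heteroscedastic noise (for fitter tests),
sigmoidal time-lapse aggregation series emulating repeated short
measurements at each time point, and 4-parameter-logistic dose–response
tables of molecular brightness versus compound concentration.

Every stochastic operation takes an explicit seed (or Generator); there is
no hidden global random state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .correlator import CorrelationCurve, PhotonTrace
from .fcs_model import (
    DiffusionComponent,
    FcsModelParams,
    diffusion_time_for,
    evaluate_model,
)
from .fitting import MeasurementSeries

__all__ = [
    "SpeciesSpec",
    "SimulationConfig",
    "AggregationScenario",
    "simulate_trace",
    "simulate_curve",
    "simulate_timelapse",
    "simulate_dose_response",
    "four_parameter_logistic",
    "expected_count_rate",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing fluorescent species.

    brightness holds the peak molecular brightness per detection channel
    (counts/s per particle at the center of the observation volume);
    mean_copies is the mean occupancy of the *effective* observation
    volume V_eff = pi^(3/2) w0^2 z0, i.e. the N an FCS fit reports.
    """

    label: str
    diffusion_coefficient: float
    mean_copies: float
    brightness: tuple[float, ...]
    oligomer_size: int = 1
    triplet_fraction: float = 0.0
    triplet_time: float = 5e-6

    def __post_init__(self) -> None:
        if not self.diffusion_coefficient > 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.mean_copies < 0:
            raise ValueError("mean copies must be non-negative")
        if any(b < 0 for b in self.brightness):
            raise ValueError("brightness must be non-negative")
        if self.oligomer_size < 1 or self.oligomer_size != int(self.oligomer_size):
            raise ValueError("oligomer size must be an integer >= 1")
        if not 0 <= self.triplet_fraction < 1:
            raise ValueError("triplet fraction must be in [0, 1)")
        object.__setattr__(self, "brightness", tuple(self.brightness))


@dataclass(frozen=True)
class SimulationConfig:
    """Geometry and acquisition settings for the trace simulator."""

    species: tuple[SpeciesSpec, ...]
    bin_time: float = 1e-4
    duration: float = 10.0
    lateral_radius: float = 0.25
    axial_radius: float = 1.25
    box: tuple[float, float, float] | None = None
    background: tuple[float, ...] = (0.0,)
    channels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("at least one species is required")
        object.__setattr__(self, "species", tuple(self.species))
        if not self.bin_time > 0:
            raise ValueError("bin time must be positive")
        if not self.duration >= self.bin_time:
            raise ValueError("duration must cover at least one bin")
        if not (self.lateral_radius > 0 and self.axial_radius > 0):
            raise ValueError("observation-volume radii must be positive")
        box = self.box
        if box is None:
            box = (
                10.0 * self.lateral_radius,
                10.0 * self.lateral_radius,
                10.0 * self.axial_radius,
            )
        object.__setattr__(self, "box", tuple(float(v) for v in box))
        radii = (self.lateral_radius, self.lateral_radius, self.axial_radius)
        if any(edge < 10.0 * r for edge, r in zip(self.box, radii)):
            warnings.warn(
                "simulation box smaller than 10x the observation-volume "
                "radii; periodic images may bias the correlation",
                stacklevel=2,
            )
        n_ch = len(self.background)
        for sp in self.species:
            if len(sp.brightness) != n_ch:
                raise ValueError(
                    f"species {sp.label!r} has {len(sp.brightness)} brightness "
                    f"values for {n_ch} channels"
                )
        object.__setattr__(self, "background", tuple(self.background))
        channels = self.channels
        if channels is None:
            channels = tuple(chr(ord("A") + i) for i in range(n_ch))
        if len(channels) != n_ch:
            raise ValueError("channel labels do not match channel count")
        object.__setattr__(self, "channels", tuple(channels))
        tau_min = min(
            diffusion_time_for(sp.diffusion_coefficient, self.lateral_radius)
            for sp in self.species
        )
        if self.bin_time > tau_min / 10.0:
            warnings.warn(
                f"bin time {self.bin_time:g} s does not resolve the fastest "
                f"diffusion time {tau_min:g} s (want < tau_D/10)",
                stacklevel=2,
            )

    @property
    def effective_volume(self) -> float:
        return math.pi**1.5 * self.lateral_radius**2 * self.axial_radius

    @property
    def box_volume(self) -> float:
        return self.box[0] * self.box[1] * self.box[2]

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_time))


def expected_count_rate(config: SimulationConfig, channel: int = 0) -> float:
    """Closed-form mean detected rate (counts/s) for one channel.

    Per particle the box-averaged profile integral is the product over
    axes of w sqrt(pi/2) erf(L / (w sqrt(2))) / L; the species term is
    that times its peak brightness and mean box population.
    """
    w = (config.lateral_radius, config.lateral_radius, config.axial_radius)
    geom = 1.0
    for wa, L in zip(w, config.box):
        geom *= wa * math.sqrt(math.pi / 2.0) * erf(L / (wa * math.sqrt(2.0))) / L
    rate = config.background[channel]
    for sp in config.species:
        n_box = sp.mean_copies * config.box_volume / config.effective_volume
        rate += sp.brightness[channel] * n_box * geom
    return rate


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit seed (or Generator) is required")
    return np.random.default_rng(seed)


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency normally
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


# Particles outside the normalized ellipsoidal radius u^2 > _R2_SAFE emit
# < exp(-2 * _R2_SAFE) ~ 1.5e-8 of their peak rate; they are propagated in
# single multi-bin Gaussian jumps sized so that reaching the emitting
# region mid-jump is a > _JUMP_SIGMA-sigma event per axis.
_R2_SAFE = 9.0
_JUMP_SIGMA = 4.0


@_njit(cache=True, fastmath=True)
def _species_profile(
    seed, n_bins, n_part, sigma, lx, ly, lz, w0, z0,
    triplet_fraction, p_bright_to_dark, p_dark_to_bright,
):  # pragma: no cover - exercised through simulate_trace
    np.random.seed(seed)
    out = np.zeros(n_bins)
    iw = 2.0 / (w0 * w0)
    iz = 2.0 / (z0 * z0)
    wmin = min(w0, z0)
    u_safe = math.sqrt(_R2_SAFE)
    blink = triplet_fraction > 0.0
    for _ in range(n_part):
        x = np.random.uniform(-lx / 2.0, lx / 2.0)
        y = np.random.uniform(-ly / 2.0, ly / 2.0)
        z = np.random.uniform(-lz / 2.0, lz / 2.0)
        bright = True
        if blink:
            bright = np.random.random() >= triplet_fraction
        t = 0
        while t < n_bins:
            r2 = (x * x + y * y) / (w0 * w0) + (z * z) / (z0 * z0)
            if r2 < _R2_SAFE:
                if bright:
                    out[t] += math.exp(-(x * x + y * y) * iw - z * z * iz)
                if blink:
                    u = np.random.random()
                    if bright:
                        bright = u >= p_bright_to_dark
                    else:
                        bright = u < p_dark_to_bright
                step = sigma
                k = 1
            else:
                # far from the volume: one Gaussian jump of k bins
                d = (math.sqrt(r2) - u_safe) * wmin
                k = int((d / (_JUMP_SIGMA * sigma)) ** 2)
                if k < 1:
                    k = 1
                if k > n_bins - t:
                    k = n_bins - t
                step = sigma * math.sqrt(k)
                if blink and k > 1:
                    # triplet equilibrates while undetected
                    bright = np.random.random() >= triplet_fraction
            x += np.random.normal(0.0, step)
            y += np.random.normal(0.0, step)
            z += np.random.normal(0.0, step)
            # minimal-image wrap (volume sits at the box center)
            x -= lx * math.floor(x / lx + 0.5)
            y -= ly * math.floor(y / ly + 0.5)
            z -= lz * math.floor(z / lz + 0.5)
            t += k
    return out


def _species_profile_numpy(
    seed, n_bins, n_part, sigma, lx, ly, lz, w0, z0,
    triplet_fraction, p_bd, p_db,
):
    """Chunked vectorized fallback (no far-field skipping)."""
    rng = np.random.default_rng(seed)
    box = np.array([lx, ly, lz])
    pos = rng.uniform(-box / 2.0, box / 2.0, size=(n_part, 3))
    out = np.zeros(n_bins)
    blink = triplet_fraction > 0.0
    if blink:
        bright = rng.random(n_part) >= triplet_fraction
    chunk = int(np.clip(2e7 // max(n_part, 1), 256, n_bins))
    start = 0
    while start < n_bins:
        c = min(chunk, n_bins - start)
        steps = rng.normal(0.0, sigma, size=(c, n_part, 3))
        np.cumsum(steps, axis=0, out=steps)
        traj = steps + pos
        traj -= box * np.floor(traj / box + 0.5)
        pos = traj[-1].copy()
        prof = np.exp(
            -2.0 * (traj[:, :, 0] ** 2 + traj[:, :, 1] ** 2) / w0**2
            - 2.0 * traj[:, :, 2] ** 2 / z0**2
        )
        if blink:
            for i in range(c):
                u = rng.random(n_part)
                bright = np.where(bright, u >= p_bd, u < p_db)
                prof[i] *= bright
        out[start : start + c] = prof.sum(axis=1)
        start += c
    return out


def simulate_trace(
    config: SimulationConfig,
    seed: int | np.random.Generator | None = None,
) -> PhotonTrace:
    """Simulate a binned photon-count trace; bit-reproducible given seed."""
    rng = _as_rng(seed)
    n_bins = config.n_bins
    n_ch = len(config.background)
    lam = np.zeros((n_bins, n_ch))
    kernel = _species_profile if _HAVE_NUMBA else _species_profile_numpy

    for sp in config.species:
        n_box_mean = sp.mean_copies * config.box_volume / config.effective_volume
        n_part = int(rng.poisson(n_box_mean))
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        if n_part == 0 or not any(sp.brightness):
            continue
        step_std = math.sqrt(2.0 * sp.diffusion_coefficient * config.bin_time)
        relax = 1.0 - math.exp(-config.bin_time / sp.triplet_time)
        profile_sum = kernel(
            kernel_seed,
            n_bins,
            n_part,
            step_std,
            config.box[0],
            config.box[1],
            config.box[2],
            config.lateral_radius,
            config.axial_radius,
            sp.triplet_fraction,
            sp.triplet_fraction * relax,
            (1.0 - sp.triplet_fraction) * relax,
        )
        for ch in range(n_ch):
            if sp.brightness[ch]:
                lam[:, ch] += sp.brightness[ch] * profile_sum

    lam += np.asarray(config.background)
    counts = rng.poisson(lam * config.bin_time).astype(np.int64)
    meta = {"simulated": True, "n_species": len(config.species)}
    return PhotonTrace(
        bin_time=config.bin_time,
        counts=counts,
        channels=config.channels,
        metadata=meta,
    )


def simulate_curve(
    params: FcsModelParams,
    lags: np.ndarray,
    noise_level: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> CorrelationCurve:
    """Analytic correlation curve with optional heteroscedastic noise.

    The per-lag noise std is noise_level * (G(tau) - 1 + 0.05 * G(0+)
    amplitude): proportional to the decaying correlation amplitude with a
    small floor so the baseline is not noise-free.  noise_level = 0
    reproduces :func:`fcscreen.fcs_model.evaluate_model` exactly.
    """
    if noise_level < 0:
        raise ValueError("noise level must be non-negative")
    g = evaluate_model(params, lags)
    amp0 = (1.0 / params.n_particles) / (1.0 - params.triplet_fraction)
    sigma = noise_level * ((g - 1.0) + 0.05 * amp0)
    if noise_level > 0:
        rng = _as_rng(seed)
        g = g + rng.standard_normal(g.shape) * sigma
    return CorrelationCurve(
        lags=np.asarray(lags, dtype=float),
        g=g,
        se=sigma,
        channel_pair=("A", "A"),
        metadata={"simulated": True, "noise_level": noise_level},
    )


def default_lag_grid(
    n_per_decade: int = 12, lo: float = 1e-6, hi: float = 1.0
) -> np.ndarray:
    """Logarithmic lag grid spanning the usual FCS range."""
    n = int(round(n_per_decade * math.log10(hi / lo))) + 1
    return np.geomspace(lo, hi, n)


@dataclass(frozen=True)
class AggregationScenario:
    """Sigmoidal growth of ThT-positive aggregate signal over hours.

    theta(t) = 1 / (1 + exp(-growth_rate (t - lag_time))) rises from the
    lag phase through exponential growth to plateau; fluorescence
    intensity follows baseline + plateau_intensity * theta and the
    aggregate diffusion time ramps from tau_start to tau_end on the same
    sigmoid.  Repeated short measurements at each time point emulate the
    study design of consecutive 10 s recordings.
    """

    time_points_h: tuple[float, ...]
    lag_time_h: float = 8.0
    growth_rate_per_h: float = 0.8
    plateau_intensity: float = 2.0e4
    baseline_intensity: float = 200.0
    tau_start_s: float = 3e-4
    tau_end_s: float = 5e-3
    monomer_tau_s: float = 1.5e-4
    aggregate_fraction_max: float = 0.8
    mean_particles: float = 5.0
    repeats: int = 30
    measurement_s: float = 10.0
    intensity_cv: float = 0.10
    curve_noise: float = 0.02

    def __post_init__(self) -> None:
        if not self.time_points_h:
            raise ValueError("at least one time point is required")
        tp = tuple(float(t) for t in self.time_points_h)
        if len(set(tp)) != len(tp):
            raise ValueError("overlapping (duplicate) time points")
        if any(np.diff(tp) <= 0):
            raise ValueError("time points must be strictly increasing")
        object.__setattr__(self, "time_points_h", tp)
        if self.lag_time_h < 0:
            raise ValueError("lag time must be non-negative")
        if not self.plateau_intensity > 0:
            raise ValueError("plateau intensity must be positive")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not 0 < self.aggregate_fraction_max <= 1:
            raise ValueError("aggregate fraction must be in (0, 1]")

    def growth_fraction(self, t_h: float) -> float:
        return 1.0 / (
            1.0 + math.exp(-self.growth_rate_per_h * (t_h - self.lag_time_h))
        )


def simulate_timelapse(
    scenario: AggregationScenario,
    seed: int | np.random.Generator | None = None,
    condition: str = "control",
    structure_parameter: float = 5.0,
) -> list[MeasurementSeries]:
    """Repeated-measurement series at each time point of a growth scenario.

    Each repeat carries a count rate (lognormal-free Gaussian scatter with
    the scenario's coefficient of variation, floored at one count/s) and a
    noisy two-component correlation curve whose slow component tracks the
    aggregate growth sigmoid.
    """
    rng = _as_rng(seed)
    lags = default_lag_grid()
    out: list[MeasurementSeries] = []
    for t in scenario.time_points_h:
        theta = scenario.growth_fraction(t)
        intensity = (
            scenario.baseline_intensity + scenario.plateau_intensity * theta
        )
        tau_agg = (
            scenario.tau_start_s
            + (scenario.tau_end_s - scenario.tau_start_s) * theta
        )
        f_agg = scenario.aggregate_fraction_max * theta
        params = FcsModelParams(
            n_particles=scenario.mean_particles,
            components=(
                DiffusionComponent(1.0 - f_agg, scenario.monomer_tau_s),
                DiffusionComponent(f_agg, tau_agg),
            ),
            structure_parameter=structure_parameter,
        )
        rates = np.maximum(
            rng.normal(
                intensity, scenario.intensity_cv * intensity, scenario.repeats
            ),
            1.0,
        )
        curves = [
            simulate_curve(params, lags, scenario.curve_noise, rng)
            for _ in range(scenario.repeats)
        ]
        out.append(
            MeasurementSeries(
                time_h=float(t),
                condition=condition,
                curves=curves,
                count_rates=tuple(float(r) for r in rates),
                measurement_s=scenario.measurement_s,
            )
        )
    return out


def four_parameter_logistic(
    concentration: np.ndarray,
    top: float,
    bottom: float,
    ic50: float,
    hill: float,
) -> np.ndarray:
    """Descending 4PL: top at c = 0, bottom at saturating c, midpoint IC50."""
    c = np.asarray(concentration, dtype=float)
    out = np.full(c.shape, float(top))
    nz = c > 0
    out[nz] = bottom + (top - bottom) / (1.0 + (c[nz] / ic50) ** hill)
    return out


def simulate_dose_response(
    ic50: float,
    hill: float = 1.0,
    top: float = 1.3,
    bottom: float = 0.2,
    concentrations: np.ndarray | None = None,
    noise: float = 0.05,
    n_replicates: int = 3,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Replicated CPP-versus-concentration table on a 4PL ground truth.

    Defaults mirror a brightness-reduction (inhibition) experiment: CPP
    falls from `top` to `bottom` counts/s/particle (kHz scale) as compound
    concentration (nM) rises past the IC50.  Gaussian noise is relative to
    the local curve value.
    """
    if not ic50 > 0:
        raise ValueError("IC50 must be positive")
    if top < bottom:
        raise ValueError(
            "top < bottom: this generator models a descending response; "
            "swap asymptotes rather than inverting the orientation"
        )
    if concentrations is None:
        concentrations = np.round(np.geomspace(ic50 / 30, ic50 * 30, 8), 3)
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations < 0):
        raise ValueError("concentrations must be non-negative")
    truth = four_parameter_logistic(concentrations, top, bottom, ic50, hill)
    rows = []
    if noise > 0 or n_replicates > 0:
        rng = _as_rng(seed) if noise > 0 else None
    for conc, mu in zip(concentrations, truth):
        for rep in range(n_replicates):
            val = mu
            if noise > 0:
                val = mu * (1.0 + noise * rng.standard_normal())
            rows.append(
                {"concentration": float(conc), "replicate": rep, "cpp": float(val)}
            )
    return pd.DataFrame(rows)
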