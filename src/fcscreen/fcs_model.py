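"""Closed-form confocal FCS model functions and derived quantities.

The normalized autocorrelation of fluorescence fluctuations from a 3D
Gaussian observation volume, with an optional triplet-state (dark blinking)
term and one or two freely diffusing components, is

    G(tau) = 1 + (1/N) * T(tau) * sum_i f_i * g_i(tau)

    T(tau)   = 1 + F/(1-F) * exp(-tau / tau_triplet)
    g_i(tau) = (1 + tau/tau_Di)^-1 * (1 + tau/(s^2 tau_Di))^-1/2

where N is the mean number of molecules in the effective observation
volume, F the triplet fraction, s the structure parameter (axial/lateral
1/e^2 radius ratio) and tau_Di the diffusion time of component i
(fractions f_i sum to one).  The baseline convention (G -> 1 at large lag,
as produced by hardware/vendor correlators) is held in ``BASELINE`` so an
alternative convention is a one-line change.

Everything here is a pure function of parameters; fitting, simulation and
the CLI all validate against this module.  Units are seconds and
micrometers internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BASELINE",
    "DiffusionComponent",
    "FcsModelParams",
    "CalibrationResult",
    "evaluate_model",
    "weighted_diffusion_time",
    "calibrate_volume",
    "diffusion_time_for",
]

#: Correlation baseline at infinite lag (uncorrelated limit).
BASELINE = 1.0

#: Tolerance on the sum of component fractions.
FRACTION_SUM_TOL = 1e-9


@dataclass(frozen=True)
class DiffusionComponent:
    """One diffusing species in the correlation model.

    Parameters
    ----------
    fraction : float
        Amplitude fraction of this component, in [0, 1].  Across a model's
        components the fractions sum to one.
    diffusion_time : float
        Mean dwell time tau_D in the observation volume, seconds (> 0).
    """

    fraction: float
    diffusion_time: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(
                f"component fraction must be in [0, 1], got {self.fraction}"
            )
        if not self.diffusion_time > 0.0:
            raise ValueError(
                f"diffusion time must be positive, got {self.diffusion_time}"
            )


@dataclass(frozen=True)
class FcsModelParams:
    """Full parameter set of the triplet + n-component diffusion model."""

    n_particles: float
    components: tuple[DiffusionComponent, ...]
    triplet_fraction: float = 0.0
    triplet_time: float = 5e-6
    structure_parameter: float = 5.0

    def __post_init__(self) -> None:
        if not self.n_particles > 0.0:
            raise ValueError(f"N must be positive, got {self.n_particles}")
        if not 0.0 <= self.triplet_fraction < 1.0:
            raise ValueError(
                f"triplet fraction must be in [0, 1), got {self.triplet_fraction}"
            )
        if not self.triplet_time > 0.0:
            raise ValueError(
                f"triplet time must be positive, got {self.triplet_time}"
            )
        if not self.structure_parameter > 1.0:
            raise ValueError(
                "structure parameter must exceed 1, "
                f"got {self.structure_parameter}"
            )
        comps = tuple(self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) not in (1, 2):
            raise ValueError(
                f"model supports 1 or 2 components, got {len(comps)}"
            )
        fsum = sum(c.fraction for c in comps)
        if abs(fsum - 1.0) > FRACTION_SUM_TOL:
            raise ValueError(
                f"component fractions must sum to 1, got {fsum!r}"
            )
        tau_min = min(c.diffusion_time for c in comps)
        if self.triplet_fraction > 0.0 and self.triplet_time >= tau_min:
            warnings.warn(
                "triplet time is not shorter than the fastest diffusion "
                f"time ({self.triplet_time:g} s >= {tau_min:g} s); triplet "
                "and diffusion decays will be entangled",
                stacklevel=2,
            )

    @property
    def diffusion_times(self) -> tuple[float, ...]:
        return tuple(c.diffusion_time for c in self.components)

    @property
    def fractions(self) -> tuple[float, ...]:
        return tuple(c.fraction for c in self.components)


def _check_lags(lags: np.ndarray) -> np.ndarray:
    lags = np.asarray(lags, dtype=float)
    if lags.ndim != 1 or lags.size == 0:
        raise ValueError("lags must be a nonempty 1-D array")
    bad = np.flatnonzero(lags <= 0.0)
    if bad.size:
        raise ValueError(
            f"lag times must be strictly positive; offending index {bad[0]} "
            f"(value {lags[bad[0]]!r})"
        )
    if np.any(np.diff(lags) <= 0.0):
        idx = int(np.flatnonzero(np.diff(lags) <= 0.0)[0]) + 1
        raise ValueError(
            f"lag times must be strictly increasing; offending index {idx}"
        )
    return lags


def evaluate_model(params: FcsModelParams, lags: np.ndarray) -> np.ndarray:
    """Evaluate G(tau) on a grid of strictly increasing positive lags.

    Returns an array of correlation amplitudes with the ``BASELINE``
    (G -> 1) convention; G(tau -> 0) -> 1 + (1/N)/(1 - F_triplet).
    """
    lags = _check_lags(lags)
    F = params.triplet_fraction
    if F > 0.0:
        triplet = 1.0 + F / (1.0 - F) * np.exp(-lags / params.triplet_time)
    else:
        triplet = 1.0
    s2 = params.structure_parameter**2
    diff = np.zeros_like(lags)
    for comp in params.components:
        x = lags / comp.diffusion_time
        diff += comp.fraction / ((1.0 + x) * np.sqrt(1.0 + x / s2))
    return BASELINE + triplet * diff / params.n_particles


def weighted_diffusion_time(params: FcsModelParams) -> float:
    """Fraction-weighted mean diffusion time, tau_w = sum_i f_i tau_Di.

    Characterizes the average aggregate size when the curve mixes fast
    (monomer/small oligomer) and slow (aggregate) components.  The simple
    fraction weighting is used; brightness weighting is deliberately not.
    """
    if not params.components:
        raise ValueError("model has no diffusion components")
    return math.fsum(c.fraction * c.diffusion_time for c in params.components)


@dataclass(frozen=True)
class CalibrationResult:
    """Observation-volume geometry from a reference-dye measurement.

    lateral_radius (w0) and axial_radius (z0) are 1/e^2 radii in μm;
    effective_volume is in femtoliters (μm^3 == fL).
    """

    lateral_radius: float
    axial_radius: float
    structure_parameter: float
    effective_volume: float
    reference_dye: str
    reference_diffusion_coefficient: float
    reference_diffusion_time: float = field(repr=False, default=0.0)

    def diffusion_time_for(self, diffusion_coefficient: float) -> float:
        """Expected tau_D (s) of a species with coefficient D (μm²/s)."""
        if not diffusion_coefficient > 0.0:
            raise ValueError("diffusion coefficient must be positive")
        return self.lateral_radius**2 / (4.0 * diffusion_coefficient)

    def diffusion_coefficient_for(self, diffusion_time: float) -> float:
        """Inverse mapping: D (μm²/s) from a fitted tau_D (s)."""
        if not diffusion_time > 0.0:
            raise ValueError("diffusion time must be positive")
        return self.lateral_radius**2 / (4.0 * diffusion_time)


def calibrate_volume(
    fitted_diffusion_time: float,
    fitted_structure_parameter: float,
    reference_diffusion_coefficient: float,
    reference_dye: str = "rhodamine 6G",
) -> CalibrationResult:
    """Observation-volume calibration from a reference dye of known D.

    Uses the standard confocal relations w0 = sqrt(4 D_ref tau_D,ref),
    z0 = s w0 and V_eff = pi^(3/2) w0^2 z0.  The dye measurement supplies
    tau_D,ref and s; D_ref comes from the literature (e.g. rhodamine 6G
    414 μm²/s, ATTO488 400 μm²/s, Cy5 360 μm²/s).
    """
    if not fitted_diffusion_time > 0.0:
        raise ValueError("fitted diffusion time must be positive")
    if not reference_diffusion_coefficient > 0.0:
        raise ValueError("reference diffusion coefficient must be positive")
    if not fitted_structure_parameter > 0.0:
        raise ValueError("structure parameter must be positive")
    if fitted_structure_parameter <= 1.0:
        warnings.warn(
            "structure parameter <= 1 is physically implausible for a "
            "confocal volume (axial radius shorter than lateral)",
            stacklevel=2,
        )
    w0 = math.sqrt(
        4.0 * reference_diffusion_coefficient * fitted_diffusion_time
    )
    z0 = fitted_structure_parameter * w0
    v_eff = math.pi**1.5 * w0**2 * z0
    return CalibrationResult(
        lateral_radius=w0,
        axial_radius=z0,
        structure_parameter=fitted_structure_parameter,
        effective_volume=v_eff,
        reference_dye=reference_dye,
        reference_diffusion_coefficient=reference_diffusion_coefficient,
        reference_diffusion_time=fitted_diffusion_time,
    )


def diffusion_time_for(
    diffusion_coefficient: float, lateral_radius: float
) -> float:
    """tau_D = w0^2 / (4 D) for 3D diffusion through a Gaussian volume."""
    if not (diffusion_coefficient > 0.0 and lateral_radius > 0.0):
        raise ValueError("diffusion coefficient and radius must be positive")
    return lateral_radius**2 / (4.0 * diffusion_coefficient)
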