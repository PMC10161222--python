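"""FRET-FCS molecular-brightness readouts and dose–response analysis.

Molecular brightness is expressed as counts per particle,
CPP = CR / N, the ratio of the detected count rate in the acceptor
channel to the number of FRET-positive particles from the acceptor-channel
autocorrelation fit.  CPP scales with the number of fluorophores per
diffusing particle and hence with oligomer size, independent of
concentration.

Dose–response curves of CPP versus compound concentration are fitted with
the four-parameter logistic (descending orientation)

    CPP(c) = bottom + (top - bottom) / (1 + (c / IC50)^h)

with free Hill slope h; IC50 is reported in the concentration units of the
input (nM in the screening workflow).

A deterministic rule classifies a compound's effect on the time-lapse
aggregation trajectories relative to the control: ``inhibition`` when the
treated endpoint median falls below the control's endpoint lower
quartile, ``acceleration`` when the treated series reaches half-plateau
earlier than the control by more than one time-point spacing, otherwise
``no_effect``.  The thresholds are heuristics exposed through
:class:`ClassificationConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd

from .fitting import SeriesFitSummary

__all__ = [
    "BrightnessResult",
    "DoseResponseResult",
    "ClassificationConfig",
    "EffectCall",
    "cpp",
    "fit_dose_response",
    "classify_effect",
]


@dataclass(frozen=True)
class BrightnessResult:
    """Counts-per-particle over one or more repeats."""

    count_rate: tuple[float, ...]
    particle_number: tuple[float, ...]
    cpp: tuple[float, ...]
    mean: float
    sd: float


def cpp(
    count_rate: float | Sequence[float],
    particle_number: float | Sequence[float],
) -> BrightnessResult:
    """Molecular brightness CPP = CR / N, per repeat plus mean ± SD.

    ``count_rate`` in counts/s and ``particle_number`` dimensionless; both
    may be scalars or matching sequences of repeats.  The SD uses the
    n - 1 denominator (0 for a single repeat).
    """
    cr = np.atleast_1d(np.asarray(count_rate, dtype=float))
    n = np.atleast_1d(np.asarray(particle_number, dtype=float))
    if cr.shape != n.shape:
        if cr.size == 1:
            cr = np.full(n.shape, cr[0])
        elif n.size == 1:
            n = np.full(cr.shape, n[0])
        else:
            raise ValueError("count rate and particle number shapes differ")
    if np.any(n <= 0):
        raise ValueError("particle number must be positive")
    vals = cr / n
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return BrightnessResult(
        count_rate=tuple(cr),
        particle_number=tuple(n),
        cpp=tuple(vals),
        mean=float(vals.mean()),
        sd=sd,
    )


@dataclass(frozen=True)
class DoseResponseResult:
    """Fitted 4PL parameters for a CPP-versus-concentration table."""

    ic50: float
    hill: float
    top: float
    bottom: float
    stderr: dict[str, float | None]
    concentrations: tuple[float, ...]
    converged: bool
    extrapolated: bool
    poor_fit: bool
    reduced_chi_square: float

    def predict(self, concentration: np.ndarray) -> np.ndarray:
        c = np.asarray(concentration, dtype=float)
        out = np.full(c.shape, self.top)
        nz = c > 0
        out[nz] = self.bottom + (self.top - self.bottom) / (
            1.0 + (c[nz] / self.ic50) ** self.hill
        )
        return out


def fit_dose_response(
    table: pd.DataFrame,
    concentration_col: str = "concentration",
    value_col: str = "cpp",
) -> DoseResponseResult:
    """Fit a descending 4PL to replicate CPP values per concentration.

    Needs at least 4 distinct concentrations.  A warning is issued when
    the tested range does not bracket the fitted IC50 by a factor of ten
    on both sides (wide-confidence-interval regime); an IC50 outside the
    tested range sets the ``extrapolated`` flag.  Non-monotone
    concentration means beyond their standard errors set ``poor_fit`` but
    do not abort the fit.
    """
    conc = np.asarray(table[concentration_col], dtype=float)
    vals = np.asarray(table[value_col], dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    uniq = np.unique(conc)
    if uniq.size < 4:
        raise ValueError(
            f"need >= 4 distinct concentrations, got {uniq.size}"
        )
    means = np.array([vals[conc == c].mean() for c in uniq])
    sems = np.array(
        [
            vals[conc == c].std(ddof=1) / np.sqrt((conc == c).sum())
            if (conc == c).sum() > 1
            else 0.0
            for c in uniq
        ]
    )
    # poor-fit heuristic: a rise between successive concentration means
    # larger than twice the joined SEs contradicts a descending response
    rises = np.diff(means)
    tol = 2.0 * np.hypot(sems[:-1], sems[1:])
    poor_fit = bool(np.any(rises > np.maximum(tol, 1e-12)))

    pos = uniq[uniq > 0]
    top0 = float(means[0])
    bottom0 = float(means[-1])
    mid = (top0 + bottom0) / 2.0
    below = np.flatnonzero(means <= mid)
    ic50_0 = float(uniq[below[0]]) if below.size and uniq[below[0]] > 0 else (
        float(np.sqrt(pos[0] * pos[-1]))
    )

    p = lmfit.Parameters()
    span = max(abs(top0 - bottom0), abs(top0), 1e-9)
    p.add("top", value=top0, min=top0 - 10 * span, max=top0 + 10 * span)
    p.add("bottom", value=bottom0, min=bottom0 - 10 * span,
          max=bottom0 + 10 * span)
    p.add("log_ic50", value=np.log10(ic50_0),
          min=np.log10(pos[0]) - 3.0, max=np.log10(pos[-1]) + 3.0)
    p.add("hill", value=1.0, min=0.05, max=10.0)

    def residual(pars):
        ic50 = 10.0 ** pars["log_ic50"].value
        h = pars["hill"].value
        model = np.full(conc.shape, pars["top"].value)
        nz = conc > 0
        model[nz] = pars["bottom"].value + (
            pars["top"].value - pars["bottom"].value
        ) / (1.0 + (conc[nz] / ic50) ** h)
        return model - vals

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = lmfit.minimize(
            residual, p, method="leastsq", xtol=1e-13, ftol=1e-13,
            max_nfev=20000,
        )
    ic50 = float(10.0 ** res.params["log_ic50"].value)
    err = {k: res.params[k].stderr for k in res.params}
    ic50_err = None
    if err.get("log_ic50") is not None:
        ic50_err = float(ic50 * np.log(10.0) * err["log_ic50"])
    stderr = {
        "ic50": ic50_err,
        "hill": err.get("hill"),
        "top": err.get("top"),
        "bottom": err.get("bottom"),
    }
    extrapolated = not (pos[0] <= ic50 <= pos[-1])
    if not (pos[0] <= ic50 / 10.0 and pos[-1] >= 10.0 * ic50):
        warnings.warn(
            "tested concentrations do not span IC50/10 .. 10*IC50; "
            "confidence intervals will be wide",
            stacklevel=2,
        )
    return DoseResponseResult(
        ic50=ic50,
        hill=float(res.params["hill"].value),
        top=float(res.params["top"].value),
        bottom=float(res.params["bottom"].value),
        stderr=stderr,
        concentrations=tuple(float(c) for c in uniq),
        converged=bool(res.success),
        extrapolated=extrapolated,
        poor_fit=poor_fit,
        reduced_chi_square=float(res.redchi),
    )


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds of the compound-effect decision rule (heuristics)."""

    #: treated median below this control quantile => inhibition evidence
    endpoint_quantile: float = 25.0
    #: number of trailing time points that must all show inhibition
    #: evidence (requiring > 1 suppresses single-point sampling flukes)
    endpoint_points: int = 2
    #: acceleration if t_half advances by more than this many grid spacings
    acceleration_spacings: float = 1.0
    #: minimum number of aligned time points
    min_points: int = 3


@dataclass(frozen=True)
class EffectCall:
    """Classification outcome with the quantities the rule compared."""

    label: str
    endpoint_treated_median: float
    endpoint_control_quantile: float
    t_half_control: float
    t_half_treated: float
    spacing: float


def _metric_arrays(
    summaries: Sequence[SeriesFitSummary], metric: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = np.array([s.time_h for s in summaries])
    if metric == "count_rate":
        med = np.array([s.count_rate_median for s in summaries])
        q25 = np.array([s.count_rate_q25 for s in summaries])
    elif metric == "tau_w":
        med = np.array([s.tau_w_median for s in summaries])
        q25 = np.array([s.tau_w_q25 for s in summaries])
    else:
        raise ValueError("metric must be 'count_rate' or 'tau_w'")
    return t, med, q25


def _t_half(t: np.ndarray, med: np.ndarray) -> float:
    """First (interpolated) time the median crosses half its total rise."""
    lo, hi = float(med.min()), float(med.max())
    if hi <= lo:
        return float(t[-1])
    half = lo + 0.5 * (hi - lo)
    above = np.flatnonzero(med >= half)
    i = int(above[0])
    if i == 0:
        return float(t[0])
    f = (half - med[i - 1]) / (med[i] - med[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def classify_effect(
    control: Sequence[SeriesFitSummary],
    treated: Sequence[SeriesFitSummary],
    metric: str = "count_rate",
    config: ClassificationConfig = ClassificationConfig(),
) -> EffectCall:
    """Classify a compound as no_effect / inhibition / acceleration.

    Both trajectories must share the same time grid with at least
    ``config.min_points`` points.
    """
    if len(control) < config.min_points or len(treated) < config.min_points:
        raise ValueError(
            f"need >= {config.min_points} time points for classification"
        )
    tc, med_c, q25_c = _metric_arrays(control, metric)
    tt, med_t, _ = _metric_arrays(treated, metric)
    if tc.shape != tt.shape or not np.allclose(tc, tt):
        raise ValueError("control and treated time grids are not aligned")

    def control_quantile(idx: int) -> float:
        summary = control[idx]
        if metric == "tau_w":
            values = [f.weighted_diffusion_time for f in summary.fits]
        else:
            values = list(summary.kept_count_rates)
        if values:
            return float(
                np.percentile(values, config.endpoint_quantile, method="linear")
            )
        return float(q25_c[idx])

    k = min(max(config.endpoint_points, 1), len(control))
    tail = range(len(control) - k, len(control))
    end_quant = control_quantile(len(control) - 1)
    spacing = float(np.median(np.diff(tc)))
    t_half_c = _t_half(tc, med_c)
    t_half_t = _t_half(tt, med_t)

    if all(med_t[i] < control_quantile(i) for i in tail):
        label = "inhibition"
    elif t_half_t < t_half_c - config.acceleration_spacings * spacing:
        label = "acceleration"
    else:
        label = "no_effect"
    return EffectCall(
        label=label,
        endpoint_treated_median=float(med_t[-1]),
        endpoint_control_quantile=end_quant,
        t_half_control=t_half_c,
        t_half_treated=t_half_t,
        spacing=spacing,
    )
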