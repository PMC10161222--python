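"""Nonlinear least-squares estimation of FCS model parameters.

Curves are fitted with Levenberg–Marquardt (via lmfit) to the triplet +
1/2-component 3D-diffusion model of :mod:`fcscreen.fcs_model`.  The
structure parameter comes from dye calibration and is fixed by default.
Residuals are inverse-variance weighted when the curve carries a complete
set of positive per-lag standard errors, unweighted otherwise.

Start values are derived from the curve itself: N from the short-lag
amplitude (G(0) - 1 ~ 1/N), diffusion times from the lag at which the
correlation amplitude has decayed to half.  Two-component results are
canonicalized to ascending diffusion time so "first" and "second"
component are well defined.

:func:`fit_series` applies the same fit to every repeat of a measurement
series (e.g. 30 consecutive 10 s recordings at one aggregation time
point) and summarizes count rate and weighted diffusion time by median
and 25–75 quartiles (linear-interpolation quantile convention); failed
fits are excluded and counted, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .correlator import CorrelationCurve, PhotonTrace
from .fcs_model import (
    DiffusionComponent,
    FcsModelParams,
    evaluate_model,
    weighted_diffusion_time,
)

__all__ = [
    "FitResult",
    "MeasurementSeries",
    "SeriesFitSummary",
    "fit_curve",
    "fit_series",
]

DEFAULT_BOUNDS = {
    "n_particles": (1e-3, 1e5),
    "tau_d": (1e-7, 10.0),
    "triplet_fraction": (0.0, 0.5),
    "triplet_time": (1e-7, 5e-5),
    "fraction": (0.0, 1.0),
}


@dataclass(frozen=True)
class FitResult:
    """Estimated model parameters with uncertainties and diagnostics."""

    params: FcsModelParams
    stderr: dict[str, float | None]
    reduced_chi_square: float
    converged: bool
    fixed: dict[str, float]
    message: str = ""
    n_function_evals: int = 0

    @property
    def weighted_diffusion_time(self) -> float:
        return weighted_diffusion_time(self.params)


@dataclass(frozen=True)
class MeasurementSeries:
    """Repeated short measurements at one time point of an experiment.

    Repeats may be raw photon traces and/or precomputed correlation
    curves; count rates are per-repeat mean detected rates (counts/s).
    """

    time_h: float
    condition: str
    curves: tuple[CorrelationCurve, ...] = ()
    traces: tuple[PhotonTrace, ...] = ()
    count_rates: tuple[float, ...] = ()
    measurement_s: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "curves", tuple(self.curves))
        object.__setattr__(self, "traces", tuple(self.traces))
        object.__setattr__(self, "count_rates", tuple(self.count_rates))
        if not (self.curves or self.traces):
            raise ValueError("a measurement series needs curves or traces")
        if self.count_rates and self.curves and len(self.count_rates) != len(
            self.curves
        ):
            raise ValueError("count rates do not match repeats")

    @property
    def n_repeats(self) -> int:
        return len(self.curves) if self.curves else len(self.traces)


@dataclass(frozen=True)
class SeriesFitSummary:
    """Median / quartile summary of one measurement series."""

    time_h: float
    condition: str
    n_repeats: int
    n_excluded: int
    count_rate_median: float
    count_rate_q25: float
    count_rate_q75: float
    tau_w_median: float
    tau_w_q25: float
    tau_w_q75: float
    fits: tuple[FitResult, ...] = field(repr=False, default=())
    kept_count_rates: tuple[float, ...] = field(repr=False, default=())


def _start_values(curve: CorrelationCurve, n_components: int) -> dict:
    g = curve.g
    lags = curve.lags
    amp = max(float(np.max(g[: max(3, g.size // 10)])) - 1.0, 1e-6)
    n0 = float(np.clip(1.0 / amp, *DEFAULT_BOUNDS["n_particles"]))
    half = 1.0 + amp / 2.0
    below = np.flatnonzero(g <= half)
    tau_half = float(lags[below[0]]) if below.size else float(lags[g.size // 2])
    tau_half = float(np.clip(tau_half, lags[0], lags[-1]))
    out = {"n_particles": n0}
    if n_components == 1:
        out["tau_d1"] = tau_half
    else:
        out["tau_d1"] = tau_half / 4.0
        out["tau_d2"] = tau_half * 4.0
        out["f1"] = 0.5
    return out


def _build_params(
    values: dict[str, float],
    structure_parameter: float,
    n_components: int,
) -> FcsModelParams:
    if n_components == 1:
        comps = (DiffusionComponent(1.0, values["tau_d1"]),)
    else:
        f1 = values["f1"]
        comps = (
            DiffusionComponent(f1, values["tau_d1"]),
            DiffusionComponent(1.0 - f1, values["tau_d2"]),
        )
    return FcsModelParams(
        n_particles=values["n_particles"],
        components=comps,
        triplet_fraction=values.get("triplet_fraction", 0.0),
        triplet_time=values.get("triplet_time", 5e-6),
        structure_parameter=structure_parameter,
    )


def fit_curve(
    curve: CorrelationCurve,
    n_components: int = 2,
    triplet: bool = True,
    structure_parameter: float = 5.0,
    fixed: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    start: dict[str, float] | None = None,
) -> FitResult:
    """Fit the correlation model to one curve.

    Parameters named ``n_particles, triplet_fraction, triplet_time,
    f1, tau_d1, tau_d2`` may be fixed to given values, re-bounded, or
    given explicit start values.  The structure parameter is always fixed
    (calibration input).  Non-convergence is flagged on the result, never
    silent.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if curve.lags.size < 10:
        raise ValueError("need at least 10 lag points to fit")
    if curve.lags[-1] / curve.lags[0] < 1e3:
        warnings.warn(
            "lag grid spans fewer than 3 decades; diffusion and triplet "
            "times may not be separable",
            stacklevel=2,
        )
    fixed = dict(fixed or {})
    b = {**DEFAULT_BOUNDS, **(bounds or {})}
    s0 = _start_values(curve, n_components)
    s0.update(start or {})

    p = lmfit.Parameters()
    lag_lo, lag_hi = float(curve.lags[0]), float(curve.lags[-1])
    tau_lo = max(b["tau_d"][0], lag_lo / 2.0)
    tau_hi = min(b["tau_d"][1], 10.0 * lag_hi)

    def add(name, value, lo, hi):
        p.add(
            name,
            value=float(np.clip(fixed.get(name, value), lo, hi)),
            min=lo,
            max=hi,
            vary=name not in fixed,
        )

    add("n_particles", s0["n_particles"], *b["n_particles"])
    add("tau_d1", s0["tau_d1"], tau_lo, tau_hi)
    if n_components == 2:
        add("tau_d2", s0["tau_d2"], tau_lo, tau_hi)
        add("f1", s0.get("f1", 0.5), *b["fraction"])
    if triplet:
        add("triplet_fraction", s0.get("triplet_fraction", 0.05),
            *b["triplet_fraction"])
        add("triplet_time", s0.get("triplet_time", 5e-6), *b["triplet_time"])

    se = curve.se
    use_weights = (
        se is not None and np.all(np.isfinite(se)) and np.all(se > 0)
    )
    weights = 1.0 / se if use_weights else None

    def residual(pars):
        v = {k: pars[k].value for k in pars}
        model = evaluate_model(
            _build_params(v, structure_parameter, n_components), curve.lags
        )
        r = model - curve.g
        return r * weights if weights is not None else r

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = lmfit.minimize(
            residual, p, method="leastsq", xtol=1e-12, ftol=1e-12,
            max_nfev=20000,
        )

    v = {k: result.params[k].value for k in result.params}
    err = {k: result.params[k].stderr for k in result.params}
    if n_components == 2 and v["tau_d1"] > v["tau_d2"]:
        v["tau_d1"], v["tau_d2"] = v["tau_d2"], v["tau_d1"]
        v["f1"] = 1.0 - v["f1"]
        err["tau_d1"], err["tau_d2"] = err.get("tau_d2"), err.get("tau_d1")
    if n_components == 2 and v["tau_d2"] > 0:
        ratio = v["tau_d1"] / v["tau_d2"]
        if ratio > 0.5:
            warnings.warn(
                f"two-component fit is ill-conditioned: tau_d1/tau_d2 = "
                f"{ratio:.2f} > 0.5",
                stacklevel=2,
            )
    if not triplet:
        v["triplet_fraction"] = 0.0
    with warnings.catch_warnings():
        # the triplet-vs-diffusion timescale advisory is not useful on
        # fitted outputs (the fit already happened)
        warnings.simplefilter("ignore")
        params = _build_params(v, structure_parameter, n_components)
    return FitResult(
        params=params,
        stderr=err,
        reduced_chi_square=float(result.redchi),
        converged=bool(result.success),
        fixed={**fixed, "structure_parameter": structure_parameter},
        message=str(result.message),
        n_function_evals=int(result.nfev),
    )


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    # linear-interpolation quantile convention, pinned
    q25, med, q75 = np.percentile(values, [25.0, 50.0, 75.0], method="linear")
    return float(med), float(q25), float(q75)


def fit_series(
    series: MeasurementSeries,
    n_components: int = 2,
    triplet: bool = True,
    structure_parameter: float = 5.0,
    **fit_kwargs,
) -> SeriesFitSummary:
    """Fit every repeat of a series and summarize by median and quartiles.

    Repeats whose fit raises or fails to converge (or whose curve data are
    not finite) are excluded from the summary and counted in
    ``n_excluded``.  If all repeats fail, an error naming the time point
    is raised.
    """
    if not series.curves:
        raise ValueError(
            "fit_series needs correlation curves; correlate traces first"
        )
    fits: list[FitResult] = []
    kept_idx: list[int] = []
    n_excluded = 0
    for i, curve in enumerate(series.curves):
        try:
            if not np.all(np.isfinite(curve.g)):
                raise ValueError("non-finite correlation amplitudes")
            res = fit_curve(
                curve,
                n_components=n_components,
                triplet=triplet,
                structure_parameter=structure_parameter,
                **fit_kwargs,
            )
        except Exception:
            n_excluded += 1
            continue
        if not res.converged:
            n_excluded += 1
            continue
        fits.append(res)
        kept_idx.append(i)
    if not fits:
        raise RuntimeError(
            f"all {series.n_repeats} repeats failed to fit at time point "
            f"{series.time_h} h ({series.condition})"
        )
    tau_w = np.array([f.weighted_diffusion_time for f in fits])
    tw_med, tw_q25, tw_q75 = _quartiles(tau_w)
    if series.count_rates:
        rates = np.asarray(series.count_rates, dtype=float)[kept_idx]
        cr_med, cr_q25, cr_q75 = _quartiles(rates)
        kept_rates = tuple(float(r) for r in rates)
    else:
        cr_med = cr_q25 = cr_q75 = float("nan")
        kept_rates = ()
    return SeriesFitSummary(
        time_h=series.time_h,
        condition=series.condition,
        n_repeats=series.n_repeats,
        n_excluded=n_excluded,
        count_rate_median=cr_med,
        count_rate_q25=cr_q25,
        count_rate_q75=cr_q75,
        tau_w_median=tw_med,
        tau_w_q25=tw_q25,
        tau_w_q75=tw_q75,
        fits=tuple(fits),
        kept_count_rates=kept_rates,
    )
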