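"""End-to-end ThT-FCS screening workflow.

Takes, per experimental condition, a time series of measurement sets
(each time point holding repeated short recordings — the study design is
30 consecutive 10 s measurements), runs correlation fits on every repeat,
summarizes count rate and weighted diffusion time as median with 25–75
quartile bands, and classifies each treated condition against the control
trajectory.  The result is a :class:`ScreeningReport` carrying the
trajectories, the classifications, the parameters used and a provenance
block (config digest, seed, package version) so a rerun with the same
inputs reproduces the report exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .brightness_fret import ClassificationConfig, EffectCall, classify_effect
from .correlator import autocorrelate, count_rate
from .fitting import MeasurementSeries, SeriesFitSummary, fit_series

__all__ = ["ScreeningReport", "run_timelapse", "config_digest"]

from . import __version__ as _pkg_version


def config_digest(config: Mapping) -> str:
    """Stable SHA-256 digest of a JSON-serializable config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class ScreeningReport:
    """Outcome of one screening run: trajectories + classifications."""

    conditions: tuple[str, ...]
    summaries: dict[str, tuple[SeriesFitSummary, ...]]
    classifications: dict[str, EffectCall | None]
    parameters: dict
    provenance: dict = field(default_factory=dict)

    def trajectory(self, condition: str) -> pd.DataFrame:
        """Per-time-point summary table for one condition."""
        rows = [
            {
                "time_h": s.time_h,
                "count_rate_median": s.count_rate_median,
                "count_rate_q25": s.count_rate_q25,
                "count_rate_q75": s.count_rate_q75,
                "tau_w_median_s": s.tau_w_median,
                "tau_w_q25_s": s.tau_w_q25,
                "tau_w_q75_s": s.tau_w_q75,
                "n_repeats": s.n_repeats,
                "n_excluded": s.n_excluded,
            }
            for s in self.summaries[condition]
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        """Machine-readable summary (JSON-serializable)."""
        out = {
            "conditions": list(self.conditions),
            "parameters": self.parameters,
            "provenance": self.provenance,
            "classifications": {
                cond: (None if call is None else {
                    "label": call.label,
                    "endpoint_treated_median": call.endpoint_treated_median,
                    "endpoint_control_quantile": call.endpoint_control_quantile,
                    "t_half_control": call.t_half_control,
                    "t_half_treated": call.t_half_treated,
                })
                for cond, call in self.classifications.items()
            },
            "trajectories": {
                cond: self.trajectory(cond).to_dict(orient="list")
                for cond in self.conditions
            },
        }
        return out


def _ensure_curves(series: MeasurementSeries) -> MeasurementSeries:
    """Correlate raw traces if the series does not carry curves yet."""
    if series.curves:
        return series
    curves = tuple(autocorrelate(tr) for tr in series.traces)
    rates = series.count_rates or tuple(count_rate(tr) for tr in series.traces)
    return MeasurementSeries(
        time_h=series.time_h,
        condition=series.condition,
        curves=curves,
        traces=series.traces,
        count_rates=rates,
        measurement_s=series.measurement_s,
    )


def run_timelapse(
    series_by_condition: Mapping[str, Sequence[MeasurementSeries]],
    control: str | None = "control",
    n_components: int = 2,
    triplet: bool = True,
    structure_parameter: float = 5.0,
    classify: bool = True,
    metric: str = "count_rate",
    classification: ClassificationConfig = ClassificationConfig(),
    seed: int | None = None,
) -> ScreeningReport:
    """Run the full screening chain on measurement series per condition.

    When ``classify`` is true, a control condition must be present; every
    other condition is called no_effect / inhibition / acceleration
    against it.  The run is deterministic given its inputs.
    """
    conditions = tuple(series_by_condition)
    if classify and (control is None or control not in series_by_condition):
        raise ValueError(
            f"classification requested but control condition "
            f"{control!r} is missing (have {list(conditions)})"
        )
    summaries: dict[str, tuple[SeriesFitSummary, ...]] = {}
    for cond, series_list in series_by_condition.items():
        fitted = tuple(
            fit_series(
                _ensure_curves(s),
                n_components=n_components,
                triplet=triplet,
                structure_parameter=structure_parameter,
            )
            for s in series_list
        )
        summaries[cond] = fitted

    classifications: dict[str, EffectCall | None] = {}
    if classify:
        ctrl = summaries[control]
        for cond in conditions:
            if cond == control:
                classifications[cond] = None
            else:
                classifications[cond] = classify_effect(
                    ctrl, summaries[cond], metric=metric, config=classification
                )
    else:
        classifications = {cond: None for cond in conditions}

    parameters = {
        "n_components": n_components,
        "triplet": triplet,
        "structure_parameter": structure_parameter,
        "metric": metric,
        "control": control if classify else None,
        "classification": {
            "endpoint_quantile": classification.endpoint_quantile,
            "acceleration_spacings": classification.acceleration_spacings,
            "min_points": classification.min_points,
        },
    }
    provenance = {
        "package": "fcscreen",
        "version": _pkg_version,
        "seed": seed,
        "config_digest": config_digest(parameters),
    }
    return ScreeningReport(
        conditions=conditions,
        summaries=summaries,
        classifications=classifications,
        parameters=parameters,
        provenance=provenance,
    )
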