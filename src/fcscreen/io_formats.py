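"""On-disk formats: delimited-text readers/writers and config validation.

Everything is plain UTF-8 tab-separated text with a '#'-prefixed header
block of ``key = value`` lines, '.' decimal separator and no thousands
separators.  Each writer embeds a ``format`` field like
``fcscreen-trace/1.0``; readers reject unknown major versions.  Floats
are written with 17 significant digits so read(write(x)) is bitwise
stable.

Formats
-------
trace  : bin index + integer photon counts per channel
         (header: bin_time_s, channels, duration_s)
curve  : lag_s, G, se columns (header: channel_pair, estimator metadata)
fits   : one row per measurement (N, triplet, components, tau_w, chi2)
table  : generic TSV for dose–response and viability tables
config : YAML mapping for pipeline/CLI settings, with full-report
         validation (all violations listed, not just the first)
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .correlator import CorrelationCurve, PhotonTrace
from .fitting import FitResult

__all__ = [
    "FormatError",
    "read_trace",
    "write_trace",
    "read_curve",
    "write_curve",
    "write_fit_table",
    "read_table",
    "write_table",
    "read_config",
    "validate_config",
    "ValidationReport",
]

FORMAT_VERSIONS = {
    "fcscreen-trace": 1,
    "fcscreen-curve": 1,
    "fcscreen-fits": 1,
    "fcscreen-table": 1,
}

def _fmt(v: float) -> str:
    """Shortest exact decimal representation (round-trips bitwise)."""
    return repr(float(v))


class FormatError(ValueError):
    """File-format violation with a machine-readable error code."""

    def __init__(self, code: str, message: str):
        super().__init__(f"[{code}] {message}")
        self.code = code


def _check_format(value: str, expected: str) -> None:
    try:
        name, version = value.rsplit("/", 1)
        major = int(version.split(".")[0])
    except (ValueError, AttributeError):
        raise FormatError(
            "malformed-header", f"unparseable format field {value!r}"
        ) from None
    if name != expected:
        raise FormatError(
            "wrong-format", f"expected {expected} file, found {name!r}"
        )
    if major != FORMAT_VERSIONS[expected]:
        raise FormatError(
            "unsupported-version",
            f"{name} major version {major} is not supported "
            f"(reader understands {FORMAT_VERSIONS[expected]}.x)",
        )


def _read_header(path: str | os.PathLike) -> tuple[dict[str, str], int]:
    header: dict[str, str] = {}
    n_header = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if not body or "=" not in body:
                continue
            key, _, value = body.partition("=")
            header[key.strip()] = value.strip()
    return header, n_header


def write_trace(trace: PhotonTrace, path: str | os.PathLike) -> None:
    """Write a photon trace as a TSV with commented header."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# format = fcscreen-trace/{FORMAT_VERSIONS['fcscreen-trace']}.0\n")
        fh.write(f"# bin_time_s = {_fmt(trace.bin_time)}\n")
        fh.write(f"# channels = {','.join(trace.channels)}\n")
        fh.write(f"# duration_s = {_fmt(trace.duration)}\n")
        for key, value in sorted(trace.metadata.items()):
            fh.write(f"# meta.{key} = {value}\n")
        fh.write("# columns = bin\t" + "\t".join(trace.channels) + "\n")
        buf = io.StringIO()
        idx = np.arange(trace.n_bins)
        np.savetxt(
            buf,
            np.column_stack([idx, trace.counts]),
            fmt="%d",
            delimiter="\t",
        )
        fh.write(buf.getvalue())


def read_trace(path: str | os.PathLike) -> PhotonTrace:
    """Read and validate a photon-trace file."""
    header, n_header = _read_header(path)
    if "format" not in header:
        raise FormatError("malformed-header", f"{path}: missing format field")
    _check_format(header["format"], "fcscreen-trace")
    for key in ("bin_time_s", "channels", "duration_s"):
        if key not in header:
            raise FormatError(
                "malformed-header", f"{path}: missing header key {key!r}"
            )
    bin_time = float(header["bin_time_s"])
    if bin_time <= 0:
        raise FormatError("malformed-header", "bin_time_s must be positive")
    channels = tuple(c.strip() for c in header["channels"].split(","))
    try:
        body = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype=np.int64
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(
            "truncated-body", f"{path}: unreadable body ({exc})"
        ) from None
    if body.shape[1] != len(channels) + 1:
        raise FormatError(
            "truncated-body",
            f"{path}: {body.shape[1] - 1} count columns for "
            f"{len(channels)} channels",
        )
    counts = body.iloc[:, 1:].to_numpy()
    neg = np.flatnonzero((counts < 0).any(axis=1))
    if neg.size:
        line_no = n_header + int(neg[0]) + 1
        raise FormatError(
            "negative-count", f"{path}: negative count at line {line_no}"
        )
    duration = float(header["duration_s"])
    if abs(duration - counts.shape[0] * bin_time) > bin_time:
        raise FormatError(
            "duration-mismatch",
            f"{path}: header duration {duration} s differs from body "
            f"({counts.shape[0]} bins x {bin_time} s) by more than one bin",
        )
    metadata = {
        k[len("meta.") :]: v for k, v in header.items() if k.startswith("meta.")
    }
    return PhotonTrace(
        bin_time=bin_time, counts=counts, channels=channels, metadata=metadata
    )


def write_curve(curve: CorrelationCurve, path: str | os.PathLike) -> None:
    """Write a correlation curve (lag_s, G, se) at full float precision."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# format = fcscreen-curve/{FORMAT_VERSIONS['fcscreen-curve']}.0\n")
        fh.write(f"# channel_pair = {curve.channel_pair[0]},{curve.channel_pair[1]}\n")
        for key, value in sorted(curve.metadata.items()):
            fh.write(f"# meta.{key} = {value}\n")
        fh.write("# columns = lag_s\tG\tse\n")
        se = curve.se if curve.se is not None else np.full(curve.lags.size, np.nan)
        for lag, g, s in zip(curve.lags, curve.g, se):
            fh.write(f"{_fmt(lag)}\t{_fmt(g)}\t{_fmt(s)}\n")


def read_curve(path: str | os.PathLike) -> CorrelationCurve:
    """Read and validate a correlation-curve file."""
    header, _ = _read_header(path)
    if "format" not in header:
        raise FormatError("malformed-header", f"{path}: missing format field")
    _check_format(header["format"], "fcscreen-curve")
    body = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["lag_s", "G", "se"], dtype=float,
        float_precision="round_trip",
    )
    pair = tuple(header.get("channel_pair", "A,A").split(","))
    if len(pair) != 2:
        raise FormatError("malformed-header", "channel_pair must name two channels")
    se = body["se"].to_numpy()
    if np.any(se[np.isfinite(se)] < 0):
        raise FormatError("invalid-se", f"{path}: negative standard error")
    metadata = {
        k[len("meta.") :]: v for k, v in header.items() if k.startswith("meta.")
    }
    lags = body["lag_s"].to_numpy()
    if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
        raise FormatError(
            "invalid-lags", f"{path}: lags must be positive and increasing"
        )
    return CorrelationCurve(
        lags=lags, g=body["G"].to_numpy(), se=se,
        channel_pair=(pair[0], pair[1]), metadata=metadata,
    )


FIT_COLUMNS = [
    "measurement", "n_particles", "triplet_fraction", "triplet_time_s",
    "f1", "tau_d1_s", "f2", "tau_d2_s", "tau_w_s", "red_chi2", "converged",
]


def fit_result_row(result: FitResult, measurement: int = 0) -> dict:
    p = result.params
    comps = p.components
    f2, tau2 = (comps[1].fraction, comps[1].diffusion_time) if len(comps) == 2 \
        else (float("nan"), float("nan"))
    return {
        "measurement": measurement,
        "n_particles": p.n_particles,
        "triplet_fraction": p.triplet_fraction,
        "triplet_time_s": p.triplet_time,
        "f1": comps[0].fraction,
        "tau_d1_s": comps[0].diffusion_time,
        "f2": f2,
        "tau_d2_s": tau2,
        "tau_w_s": result.weighted_diffusion_time,
        "red_chi2": result.reduced_chi_square,
        "converged": result.converged,
    }


def write_fit_table(
    results: list[FitResult], path: str | os.PathLike
) -> pd.DataFrame:
    """Write one row per fitted measurement; returns the DataFrame."""
    df = pd.DataFrame(
        [fit_result_row(r, i) for i, r in enumerate(results)],
        columns=FIT_COLUMNS,
    )
    write_table(df, path, kind="fits")
    return df


def write_table(
    df: pd.DataFrame, path: str | os.PathLike, kind: str = "table"
) -> None:
    """Generic TSV writer with format header (dose–response, viability...)."""
    name = f"fcscreen-{kind}" if not kind.startswith("fcscreen-") else kind
    version = FORMAT_VERSIONS.get(name, 1)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# format = {name}/{version}.0\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_fmt)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a generic TSV table written by :func:`write_table`."""
    header, _ = _read_header(path)
    if "format" in header:
        name = header["format"].rsplit("/", 1)[0]
        if name in FORMAT_VERSIONS:
            _check_format(header["format"], name)
    return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")


# --- configuration ---------------------------------------------------------

KNOWN_CONFIG_KEYS = {
    "structure_parameter", "n_components", "triplet", "repeats",
    "measurement_s", "seed", "conditions", "control", "thresholds",
    "bin_time_s", "duration_s", "metric",
}


@dataclass
class ValidationReport:
    """All violations found in a config, not just the first."""

    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def raise_if_failed(self) -> None:
        if self.errors:
            raise FormatError(
                "invalid-config", "; ".join(self.errors)
            )


def read_config(path: str | os.PathLike) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("invalid-config", f"{path}: config must be a mapping")
    return cfg


def validate_config(
    cfg: dict, strict: bool = True, fitting_requested: bool = True
) -> ValidationReport:
    """Validate a pipeline config, reporting every violation.

    Unknown keys are errors in strict mode, warnings otherwise.  A fit
    without a calibrated structure parameter is a hard error; a structure
    parameter <= 1 is physically implausible and warned about.
    """
    rep = ValidationReport()
    unknown = sorted(set(cfg) - KNOWN_CONFIG_KEYS)
    for key in unknown:
        msg = f"unknown config key {key!r}"
        (rep.errors if strict else rep.warnings).append(msg)
    if fitting_requested and "structure_parameter" not in cfg:
        rep.errors.append(
            "structure_parameter is required when fitting is requested "
            "(determine it from a calibration-dye measurement)"
        )
    s = cfg.get("structure_parameter")
    if s is not None:
        if not isinstance(s, (int, float)) or s <= 0:
            rep.errors.append("structure_parameter must be a positive number")
        elif s <= 1:
            rep.warnings.append(
                f"structure_parameter = {s} is physically implausible "
                "(expect > 1 for a confocal volume)"
            )
    nc = cfg.get("n_components")
    if nc is not None and nc not in (1, 2):
        rep.errors.append("n_components must be 1 or 2")
    for key in ("repeats", "seed"):
        v = cfg.get(key)
        if v is not None and (not isinstance(v, int) or v < (1 if key == "repeats" else 0)):
            rep.errors.append(f"{key} must be a non-negative integer")
    for key in ("measurement_s", "bin_time_s", "duration_s"):
        v = cfg.get(key)
        if v is not None and (not isinstance(v, (int, float)) or v <= 0):
            rep.errors.append(f"{key} must be a positive number")
    return rep
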