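"""Cell-viability computation and condition comparison.

Viability is the percentage of live cells among all cells counted in the
field of view, CV = 100 * (total - dead) / total.  Counting at least 2000
cells per sample keeps the binomial counting error on CV below about one
percentage point; smaller counts trigger a warning.

Conditions (replicate CV values, typically three independent
experiments) are compared against a reference condition — e.g. the
peptide alone — with a two-sided Welch t-test (unequal variances);
p-values are reported per comparison, without multiplicity adjustment,
matching the per-comparison significance thresholds this style of
figure annotates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ViabilityCount",
    "cell_viability",
    "compare_conditions",
    "MIN_RECOMMENDED_CELLS",
]

MIN_RECOMMENDED_CELLS = 2000


@dataclass(frozen=True)
class ViabilityCount:
    """Manually counted whole and dead cells for one sample."""

    total: int
    dead: int
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.total < 1 or self.total != int(self.total):
            raise ValueError("total cell count must be a positive integer")
        if self.dead < 0 or self.dead != int(self.dead):
            raise ValueError("dead cell count must be a non-negative integer")
        if self.dead > self.total:
            raise ValueError(
                f"dead cells ({self.dead}) exceed total cells ({self.total})"
            )
        if self.total < MIN_RECOMMENDED_CELLS:
            warnings.warn(
                f"only {self.total} cells counted; at least "
                f"{MIN_RECOMMENDED_CELLS} are recommended for stable "
                "viability estimates",
                stacklevel=2,
            )


def cell_viability(count: ViabilityCount) -> float:
    """Cell viability in percent: CV = 100 * (total - dead) / total."""
    return 100.0 * (count.total - count.dead) / count.total


def compare_conditions(
    groups: Mapping[str, Sequence[float]],
    reference: str,
) -> pd.DataFrame:
    """Per-condition mean/SD and Welch t-test against the reference.

    ``groups`` maps condition label to replicate CV values (>= 2 each).
    Returns a DataFrame with columns condition, n, mean, sd, t, p; the
    reference row carries NaN t and p.  SDs use the n - 1 denominator and
    p-values are two-sided and unadjusted.
    """
    if reference not in groups:
        raise ValueError(f"reference condition {reference!r} not in groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(
                f"condition {label!r} has {len(vals)} replicate(s); need >= 2"
            )
    ref = np.asarray(groups[reference], dtype=float)
    rows = []
    for label, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if label == reference:
            t_stat, p_val = np.nan, np.nan
        else:
            t_stat, p_val = stats.ttest_ind(v, ref, equal_var=False)
        rows.append(
            {
                "condition": label,
                "n": v.size,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)),
                "t": float(t_stat),
                "p": float(p_val),
            }
        )
    return pd.DataFrame(rows)
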