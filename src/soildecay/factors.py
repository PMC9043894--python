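"""Factor-influence ranking from fitted degradation parameters.

The early-stage influence of a factor is measured through DT50 (from the
first-order fits) and the late-stage influence through the plateau y0
(from the plateau fits): for every level of a factor, average the metric
over the conditions at that level, take the range (max minus min) of the
level means, and rank the factors by range, descending.

Sterilization is a special two-level factor: it was run as a separate
paired experiment, so its level means are computed only over condition
pairs that exist in both the sterilized and nonsterilized arms; the other
three factors are evaluated on the nonsterilized conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

__all__ = [
    "EARLY",
    "LATE",
    "FACTORS",
    "FactorInfluence",
    "level_means",
    "influence_range",
    "factor_influences",
    "rank_factors",
]

EARLY = "early"
LATE = "late"
STAGES = (EARLY, LATE)

#: factor name -> measurement-table column holding its levels
FACTOR_COLUMNS = {
    "temperature": "temperature_C",
    "water_content": "water_content_pct",
    "soil_type": "soil_site",
    "sterilization": "sterilized",
}
FACTORS = tuple(FACTOR_COLUMNS)

#: stage -> (metric name, model kind the metric is read from, column)
STAGE_METRIC = {
    EARLY: ("dt50", "first_order", "dt50_days"),
    LATE: ("y0", "plateau", "y0"),
}


@dataclass
class FactorInfluence:
    """Per-level metric means, their range, and the resulting rank."""

    factor: str
    stage: str
    level_means: dict
    range: float
    rank: int | None = None
    tie: bool = False


def _metric_frame(fits: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Select the converged fits of the single model kind carrying ``metric``."""
    if metric == "dt50":
        kind, col = "first_order", "dt50_days"
    elif metric == "y0":
        kind, col = "plateau", "y0"
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'dt50' or 'y0'")
    sub = fits[fits["model_kind"] == kind]
    if sub.empty:
        raise ValueError(f"no {kind} fits available for metric {metric!r}")
    if not sub["converged"].astype(bool).all():
        raise ValueError(f"metric {metric!r} requires all {kind} fits converged")
    return sub.rename(columns={col: "__metric__"})


def level_means(fits: pd.DataFrame, factor: str, metric: str) -> dict:
    """Mean metric per level of ``factor`` over the fitted conditions.

    ``fits`` is the per-condition fit-results table (one row per
    condition and model kind) carrying the condition columns.
    """
    if factor not in FACTOR_COLUMNS:
        raise ValueError(f"unknown factor {factor!r}")
    col = FACTOR_COLUMNS[factor]
    sub = _metric_frame(fits, metric)
    if col not in sub.columns:
        raise KeyError(f"fit table lacks condition column {col!r}")
    grouped = sub.groupby(col)["__metric__"]
    means = grouped.mean()
    if means.empty:
        raise ValueError(f"no levels found for factor {factor!r}")
    counts = grouped.count()
    if counts.nunique() > 1:
        warnings.warn(
            f"unbalanced levels for factor {factor!r}: "
            + ", ".join(f"{k}={v}" for k, v in counts.items()),
            stacklevel=2,
        )
    return {k: float(v) for k, v in means.items()}


def influence_range(means: Mapping) -> float:
    """Max minus min of the per-level means (needs at least two levels)."""
    if len(means) < 2:
        raise ValueError("influence range needs at least two levels")
    vals = [float(v) for v in means.values()]
    return max(vals) - min(vals)


def _sterilization_slice(fits: pd.DataFrame) -> pd.DataFrame:
    """Restrict to condition pairs present in both sterilization arms."""
    keys = ["soil_site", "temperature_C", "water_content_pct"]
    flags = fits.groupby(keys)["sterilized"].nunique()
    paired = flags[flags == 2].index
    if len(paired) == 0:
        raise ValueError("no paired sterilized/nonsterilized conditions")
    idx = fits.set_index(keys).index
    return fits[idx.isin(paired)]


def factor_influences(fits: pd.DataFrame, stage: str) -> list[FactorInfluence]:
    """Influence of every factor at one stage (early: DT50, late: y0)."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    _, _, _ = STAGE_METRIC[stage]
    metric = STAGE_METRIC[stage][0]
    out = []
    nonsterile = fits[~fits["sterilized"].astype(bool)]
    for factor in FACTORS:
        if factor == "sterilization":
            sub = _sterilization_slice(fits)
        else:
            sub = nonsterile
        means = level_means(sub, factor, metric)
        out.append(
            FactorInfluence(
                factor=factor,
                stage=stage,
                level_means=means,
                range=influence_range(means),
            )
        )
    return out


def rank_factors(influences: list[FactorInfluence]) -> list[FactorInfluence]:
    """Sort by range descending; ties break alphabetically and are flagged."""
    ordered = sorted(influences, key=lambda fi: (-fi.range, fi.factor))
    ranges = [fi.range for fi in ordered]
    has_tie = len(set(ranges)) < len(ranges)
    if has_tie:
        warnings.warn("tied influence ranges; ties broken alphabetically",
                      stacklevel=2)
    for pos, fi in enumerate(ordered, start=1):
        fi.rank = pos
        fi.tie = has_tie and ranges.count(fi.range) > 1
    return ordered
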