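"""Synthetic measurement-table generator for the factorial degradation design.

The default design mirrors the reference experiment: 4 soil sites x 3
temperatures x 3 water contents = 36 conditions, each sampled in
triplicate on an 18-point schedule running from 0 h to 96 d, giving
36 * 18 * 3 = 1944 records.  A separately run sterilized condition
(Gongzhuling soil, 35 degC, 50% water content) can be appended.

Ground-truth decay curves are plateau-model parameter sets; sites other
than Gongzhuling have no published per-condition fits and are synthesized
by scaling the Gongzhuling decay rates and plateaus to match the published
per-site mean DT50 and mean y0 ratios (documented stand-ins, not measured
data).

The noise model is truncated additive Gaussian with a proportional
standard deviation and a floor::

    y = max(0, mu(t) + e),  e ~ Normal(0, max(noise_floor_sd, noise_cv * mu(t)))

Each (condition, replicate) pair draws from its own child generator
derived from the master seed, so adding conditions never reshuffles the
noise of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import reference
from .models import PlateauParams, eval_plateau

__all__ = [
    "Condition",
    "SamplingSchedule",
    "SimulationConfig",
    "DEFAULT_SCHEDULE",
    "default_truth_set",
    "simulate_dataset",
]

#: Long-format measurement table column order.
MEASUREMENT_COLUMNS = [
    "condition_id",
    "soil_site",
    "temperature_C",
    "water_content_pct",
    "sterilized",
    "replicate",
    "time_days",
    "concentration_ng_per_g",
]


@dataclass(frozen=True, order=True)
class Condition:
    """One factorial cell: soil site, temperature, water content, sterilized."""

    soil_site: str
    temperature_C: float
    water_content_pct: float
    sterilized: bool = False

    def __post_init__(self) -> None:
        if not self.soil_site:
            raise ValueError("soil_site label must be non-empty")
        if not self.temperature_C > 0:
            raise ValueError("temperature_C must be positive")
        if not self.water_content_pct > 0:
            raise ValueError("water_content_pct must be positive")

    @property
    def condition_id(self) -> str:
        flag = "S" if self.sterilized else "N"
        return (
            f"{self.soil_site}-T{self.temperature_C:g}"
            f"-W{self.water_content_pct:g}-{flag}"
        )


@dataclass(frozen=True)
class SamplingSchedule:
    """Ordered sampling times in days, starting at 0 and strictly increasing."""

    times_days: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times_days, dtype=float)
        if t.size < 2:
            raise ValueError("schedule needs at least two time points")
        if t[0] != 0.0:
            raise ValueError("schedule must start at time 0")
        if not np.all(np.diff(t) > 0):
            raise ValueError("schedule times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_days)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times_days, dtype=float)


# 18-point default schedule; sub-day samples are exact fractions of a day
# (0 h, 4 h, 8 h, 12 h, 16 h, 20 h, 24 h, then 1.5 d ... 96 d).
DEFAULT_SCHEDULE = SamplingSchedule(
    (
        0.0,
        4.0 / 24.0,
        8.0 / 24.0,
        12.0 / 24.0,
        16.0 / 24.0,
        20.0 / 24.0,
        1.0,
        1.5,
        2.0,
        3.0,
        4.0,
        7.0,
        11.0,
        16.0,
        21.0,
        32.0,
        64.0,
        96.0,
    )
)


def default_truth_set(
    sites: tuple[str, ...] = reference.SITES,
    include_sterilized: bool = False,
) -> dict[Condition, PlateauParams]:
    """Plateau-model ground truth for every condition of the default design.

    Gongzhuling conditions use the reference per-condition fits verbatim.
    Other sites reuse the Gongzhuling curves with the decay rate scaled by
    the ratio of published mean DT50 values (DT50 is inversely
    proportional to b) and the plateau scaled by the ratio of published
    mean y0 values.  With ``include_sterilized`` the separately run
    sterilized condition is appended (36 + 1 entries for all four sites).
    """
    ref_dt50 = reference.MEAN_DT50_BY_SITE["Gongzhuling"]
    ref_y0 = reference.MEAN_Y0_BY_SITE["Gongzhuling"]
    truth: dict[Condition, PlateauParams] = {}
    for site in sites:
        b_scale = ref_dt50 / reference.MEAN_DT50_BY_SITE[site]
        y0_scale = reference.MEAN_Y0_BY_SITE[site] / ref_y0
        for (temp, water), p in reference.PLATEAU_GONGZHULING.items():
            cond = Condition(site, temp, water)
            if site == "Gongzhuling":
                truth[cond] = p
            else:
                truth[cond] = PlateauParams(
                    y0=p.y0 * y0_scale, a=p.a, b=p.b * b_scale
                )
    if include_sterilized:
        cond = Condition("Gongzhuling", 35.0, 50.0, sterilized=True)
        truth[cond] = reference.PLATEAU_STERILIZED
    return truth


@dataclass
class SimulationConfig:
    """Ground truth, schedule, replication, noise model, and seed."""

    truth: Mapping[Condition, PlateauParams] = field(
        default_factory=default_truth_set
    )
    schedule: SamplingSchedule = DEFAULT_SCHEDULE
    replicates: int = 3
    noise_cv: float = 0.10
    noise_floor_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.truth:
            raise ValueError("truth set must not be empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.noise_floor_sd < 0:
            raise ValueError("noise_floor_sd must be >= 0")

    def to_dict(self) -> dict:
        """JSON/YAML-serializable provenance record."""
        return {
            "schedule_days": [float(t) for t in self.schedule.times_days],
            "replicates": int(self.replicates),
            "noise_cv": float(self.noise_cv),
            "noise_floor_sd": float(self.noise_floor_sd),
            "seed": int(self.seed),
            "conditions": {
                c.condition_id: {"y0": p.y0, "a": p.a, "b": p.b}
                for c, p in sorted(
                    self.truth.items(), key=lambda kv: kv[0].condition_id
                )
            },
        }


def _child_rng(seed: int, condition_id: str, replicate: int) -> np.random.Generator:
    # CRC32 of the condition id keeps child streams stable when the
    # condition set changes.
    key = zlib.crc32(condition_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, replicate]))


def simulate_dataset(config: SimulationConfig) -> pd.DataFrame:
    """Draw one long-format measurement table from ``config``.

    Identical configs (including seed) give bit-identical tables.  Rows
    are ordered by (condition_id, replicate, time_days).
    """
    times = config.schedule.as_array()
    rows: list[pd.DataFrame] = []
    for cond in sorted(config.truth, key=lambda c: c.condition_id):
        p = config.truth[cond]
        mu = eval_plateau(p, times)
        sd = np.maximum(config.noise_floor_sd, config.noise_cv * mu)
        for rep in range(1, config.replicates + 1):
            rng = _child_rng(config.seed, cond.condition_id, rep)
            y = np.maximum(0.0, mu + rng.standard_normal(times.size) * sd)
            rows.append(
                pd.DataFrame(
                    {
                        "condition_id": cond.condition_id,
                        "soil_site": cond.soil_site,
                        "temperature_C": cond.temperature_C,
                        "water_content_pct": cond.water_content_pct,
                        "sterilized": cond.sterilized,
                        "replicate": rep,
                        "time_days": times,
                        "concentration_ng_per_g": y,
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    return table[MEASUREMENT_COLUMNS]
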