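"""Derived traits from raw plot observations.

Striga-infested maize trials record emerged parasite counts at several
weeks after planting (WAP), visual damage ratings on a 1-9 scale, and
ear weight per plot.  Three derived quantities feed the downstream
analysis:

* **AUSNPC** — area under the *Striga* number progress curve, the
  trapezoid-rule integral of emerged-parasite counts over time
  (count x days), analogous to the AUDPC of plant pathology;
* **SDR** — the average of the two damage ratings;
* **GY** — grain yield in t/ha from plot ear weight, assuming a fixed
  shelling fraction and adjusting to a common grain-moisture basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = [
    "StrigaCountSeries",
    "YieldInput",
    "ausnpc",
    "average_sdr",
    "grain_yield",
    "derive_traits",
    "DEFAULT_WAP_SCHEDULE",
    "DAYS_PER_WEEK",
    "DEFAULT_PLOT_AREA_M2",
]

#: Observation schedule for emerged-Striga counts, in weeks after planting.
DEFAULT_WAP_SCHEDULE = (8, 10, 12)

#: Weeks-after-planting to days-after-planting conversion.
DAYS_PER_WEEK = 7

#: One 4 m row spaced 0.75 m apart.
DEFAULT_PLOT_AREA_M2 = 3.0


@dataclass(frozen=True)
class StrigaCountSeries:
    """Emerged *Striga* counts ``counts`` observed at days ``times``."""

    times: tuple
    counts: tuple

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if times.shape != counts.shape or times.ndim != 1:
            raise DomainError("times and counts must be 1-d and equally long")
        if len(times) < 2:
            raise DomainError("need at least 2 time points for an area")
        if not np.all(np.diff(times) > 0):
            raise DomainError("times must be strictly increasing")
        if np.any(counts < 0):
            raise DomainError("counts must be nonnegative")


@dataclass(frozen=True)
class YieldInput:
    """Plot-level inputs for the grain-yield conversion.

    ear_weight is kg per plot; moisture the percent grain moisture at
    harvest; plot_area in m2.  Yield is adjusted to ``target_moisture``
    percent and a ``shelling_fraction`` of grain per ear weight.
    """

    ear_weight: float
    moisture: float
    plot_area: float = DEFAULT_PLOT_AREA_M2
    shelling_fraction: float = 0.80
    target_moisture: float = 12.5

    def __post_init__(self):
        if self.ear_weight < 0:
            raise DomainError("ear_weight must be nonnegative")
        if self.plot_area <= 0:
            raise DomainError("plot_area must be positive")
        if not (0 <= self.moisture < 100):
            raise DomainError("moisture must be in [0, 100)")
        if not (0 <= self.target_moisture < 100):
            raise DomainError("target_moisture must be in [0, 100)")


def ausnpc(series: StrigaCountSeries) -> float:
    """Area under the *Striga* number progress curve (count x days).

    Trapezoid rule over consecutive observations:
    ``sum_i (y_i + y_{i-1})/2 * (t_i - t_{i-1})``.
    """
    times = np.asarray(series.times, dtype=float)
    counts = np.asarray(series.counts, dtype=float)
    return float(np.trapezoid(counts, times))


def average_sdr(sdr1, sdr2):
    """Average *Striga* damage rating from the 10- and 12-WAP scores.

    Both ratings must lie on the 1 (healthy) to 9 (totally scorched)
    scale.  Accepts scalars or arrays.
    """
    a = np.asarray(sdr1, dtype=float)
    b = np.asarray(sdr2, dtype=float)
    for r in (a, b):
        valid = (r >= 1) & (r <= 9)
        if not np.all(valid | np.isnan(r)):
            raise DomainError("damage ratings must be within [1, 9]")
    out = (a + b) / 2.0
    return float(out) if out.ndim == 0 else out


def grain_yield(inp: YieldInput) -> float:
    """Grain yield in t/ha from plot ear weight.

    ear_weight * shelling_fraction * (100 - moisture)/(100 - target)
    scaled from the plot to a hectare and from kg to tonnes.
    """
    moisture_factor = (100.0 - inp.moisture) / (100.0 - inp.target_moisture)
    kg_per_plot = inp.ear_weight * inp.shelling_fraction * moisture_factor
    return kg_per_plot * (10_000.0 / inp.plot_area) / 1_000.0


def derive_traits(
    phenotypes: pd.DataFrame,
    wap_schedule=DEFAULT_WAP_SCHEDULE,
    plot_area: float = DEFAULT_PLOT_AREA_M2,
    shelling_fraction: float = 0.80,
    target_moisture: float = 12.5,
) -> pd.DataFrame:
    """Add AUSNPC, SDR and GY columns to a plot-level phenotype table.

    Expects columns ``STR{w}WAP`` for each w in ``wap_schedule``,
    ``SDR1``/``SDR2``, ``EarWeight`` (kg/plot) and optionally
    ``Moisture`` (percent; rows without it use the target moisture,
    i.e. no adjustment).  Rows with missing inputs get missing outputs.
    """
    out = phenotypes.copy()
    str_cols = [f"STR{w}WAP" for w in wap_schedule]
    days = np.asarray(wap_schedule, dtype=float) * DAYS_PER_WEEK

    if all(c in out.columns for c in str_cols):
        counts = out[str_cols].to_numpy(dtype=float)
        area = np.trapezoid(counts, days, axis=1)
        area[np.isnan(counts).any(axis=1)] = np.nan
        out["AUSNPC"] = area

    if "SDR1" in out.columns and "SDR2" in out.columns:
        out["SDR"] = average_sdr(out["SDR1"].to_numpy(), out["SDR2"].to_numpy())

    if "EarWeight" in out.columns:
        moisture = (
            out["Moisture"].to_numpy(dtype=float)
            if "Moisture" in out.columns
            else np.full(len(out), target_moisture)
        )
        moisture = np.where(np.isnan(moisture), target_moisture, moisture)
        factor = (100.0 - moisture) / (100.0 - target_moisture)
        out["GY"] = (
            out["EarWeight"].to_numpy(dtype=float)
            * shelling_fraction
            * factor
            * (10_000.0 / plot_area)
            / 1_000.0
        )
    return out
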