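"""Thermal-vulnerability margins and acclimation plasticity metrics.

Warming tolerance is the margin between an organism's critical thermal
maximum and the hottest temperature it is exposed to (``CTmax - env_max``);
cooling tolerance the margin on the cold side (``env_min - CTmin``). Both
are computed at two scales: macroclimate (capital WT / CT, from monthly
air-temperature extremes) and microclimate (lowercase wt / ct, from pond
dataloggers), always over the larval phenology window.

Plasticity of a critical limit across acclimation treatments is summarized
as a plasticity range (difference of treatment means) and as the
Acclimation Response Ratio, ARR = (mean_high - mean_low) / delta_T, the
change in tolerance per degree of acclimation. CTmin trials in which the
water froze before the endpoint carry only the information "CTmin below
the freezing point" and are censored out, which restricts CTmin plasticity
analysis to the warm (20-27 degC) treatments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ToleranceSummary",
    "warming_tolerance",
    "cooling_tolerance",
    "vulnerability_table",
    "tolerance_summaries",
    "plasticity_range",
    "arr",
    "arr_ols",
    "censor_ctmin_trials",
]

PLASTICITY_PAIRS = {"CTmax": (27.0, 6.0), "CTmin": (27.0, 20.0)}
DEFAULT_CTMIN_TREATMENTS = frozenset({20.0, 27.0})


@dataclass(frozen=True)
class ToleranceSummary:
    """Per-population summary of one critical thermal limit."""

    population: str
    trait: str
    n: int
    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


def warming_tolerance(ctmax: float, env_max: float) -> float:
    """CTmax minus the maximum exposure temperature (may be negative)."""
    return float(ctmax) - float(env_max)


def cooling_tolerance(ctmin: float, env_min: float) -> float:
    """Minimum exposure temperature minus CTmin (may be negative)."""
    return float(env_min) - float(ctmin)


def tolerance_summaries(traits: pd.DataFrame, value_col: str = "value_c") -> list[ToleranceSummary]:
    """Per-population n/mean/SE for each trait in a TraitTable."""
    out = []
    for (pop, trait), grp in traits.groupby(["population", "trait"]):
        v = grp[value_col].to_numpy(dtype=float)
        se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        out.append(ToleranceSummary(pop, trait, len(v), float(v.mean()), se))
    return out


def vulnerability_table(
    tolerances: list[ToleranceSummary] | pd.DataFrame,
    climate: pd.DataFrame,
) -> pd.DataFrame:
    """Apply the four margin identities per population.

    WT = CTmax - TMAX, wt = CTmax - tmax, CT = TMIN - CTmin,
    ct = tmin - CTmin. ``climate`` is a ClimateSummary frame (columns
    population, TMAX, tmax, TMIN, tmin); populations missing a trait mean
    or a climate row are omitted with a logged reason. Output is sorted by
    population.
    """
    if isinstance(tolerances, pd.DataFrame):
        tol_df = tolerances
    else:
        tol_df = pd.DataFrame([t.__dict__ for t in tolerances])
    ctmax = tol_df[tol_df["trait"] == "CTmax"].set_index("population")["mean"]
    ctmin = tol_df[tol_df["trait"] == "CTmin"].set_index("population")["mean"]
    clim = climate.set_index("population")
    rows = []
    for pop in sorted(set(clim.index) | set(ctmax.index) | set(ctmin.index)):
        if pop not in clim.index or pop not in ctmax.index or pop not in ctmin.index:
            logger.warning("population %s omitted from vulnerability table "
                           "(missing trait mean or climate summary)", pop)
            continue
        c = clim.loc[pop]
        rows.append(
            {
                "population": pop,
                "WT": warming_tolerance(ctmax[pop], c["TMAX"]),
                "wt": warming_tolerance(ctmax[pop], c["tmax"]),
                "CT": cooling_tolerance(ctmin[pop], c["TMIN"]),
                "ct": cooling_tolerance(ctmin[pop], c["tmin"]),
            }
        )
    if not rows:
        raise ValueError("no population has both tolerance means and a climate summary")
    return pd.DataFrame(rows).reset_index(drop=True)


def plasticity_range(means: Mapping[float, float], trait: str = "CTmax") -> float:
    """Difference of treatment means over the trait's canonical pair.

    CTmax: mean at 27 degC minus mean at 6 degC; CTmin: 27 minus 20
    (the cold CTmin treatments being censored by freezing).
    """
    try:
        high, low = PLASTICITY_PAIRS[trait]
    except KeyError:
        raise ValueError(f"unknown trait {trait!r}; expected CTmax or CTmin") from None
    for t in (high, low):
        if t not in means:
            raise ValueError(f"missing acclimation treatment {t:g} degC for {trait}")
    return float(means[high]) - float(means[low])


def arr(mean_high: float, mean_low: float, delta_t: float, ndigits: int = 3) -> float:
    """Acclimation Response Ratio: (mean_high - mean_low) / delta_t.

    The two-point slope between the extreme treatment means, reported to
    ``ndigits`` decimals (3 by default, the field's reporting convention).
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be > 0")
    return round((float(mean_high) - float(mean_low)) / float(delta_t), ndigits)


def arr_ols(means: Mapping[float, float]) -> float:
    """OLS slope of treatment means on acclimation temperature.

    A regression-based ARR variant using every treatment, not just the
    extremes; provided for sensitivity, not comparability with the
    two-point convention.
    """
    if len(means) < 2:
        raise ValueError("need >= 2 treatments")
    t = np.array(sorted(means))
    y = np.array([means[k] for k in t])
    return float(np.polyfit(t, y, 1)[0])


def censor_ctmin_trials(
    table: pd.DataFrame,
    allowed_treatments: frozenset[float] | set[float] = DEFAULT_CTMIN_TREATMENTS,
) -> pd.DataFrame:
    """Drop unusable CTmin acclimation rows.

    Removes CTmin rows whose acclimation temperature is outside
    ``allowed_treatments`` and any row flagged ``censored`` (freezing
    reached before the endpoint, so the true CTmin is below the recorded
    value). Counts removed by reason live in ``.attrs['removed']``.
    """
    is_ctmin = table["trait"] == "CTmin"
    out_of_range = is_ctmin & ~table["acclimation_c"].isin(list(allowed_treatments))
    censored = table.get("censored", pd.Series(False, index=table.index)).fillna(False).astype(bool)
    drop = out_of_range | censored
    kept = table.loc[~drop].reset_index(drop=True)
    if kept.empty:
        raise ValueError("censoring removed every row")
    kept.attrs["removed"] = {
        "out_of_range": int(out_of_range.sum()),
        "censored": int((censored & ~out_of_range).sum()),
    }
    return kept
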