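"""Stratified survey expansion to minimum swept-area biomass estimates.

Catch-per-tow means are combined with area-proportional stratum weights,
then scaled by (q * A / a) — catchability times total area over area swept
per tow — with the variance scaled by the square of the same constant.
95% confidence bands are mean +/- 1.96 sd.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: Normal 97.5% quantile used for the 95% confidence band.
CI_MULTIPLIER = 1.96


@dataclass(frozen=True)
class StratumRecord:
    """Summary of one survey stratum: area, tow count, and catch-per-tow
    mean and sample variance."""

    stratum_id: str
    area: float
    n_tows: int
    mean_catch: float
    var_catch: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"stratum {self.stratum_id!r}: area must be positive")
        if self.n_tows < 1:
            raise ValueError(f"stratum {self.stratum_id!r}: need at least one tow")
        if self.var_catch < 0:
            raise ValueError(f"stratum {self.stratum_id!r}: negative variance")


@dataclass(frozen=True)
class SweptAreaEstimate:
    """Swept-area biomass estimate with variance and 95% confidence band."""

    mean_biomass: float
    variance: float
    ci_low: float
    ci_high: float
    q: float
    total_area: float
    swept_area: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("negative variance")
        if not (self.ci_low <= self.mean_biomass <= self.ci_high):
            raise ValueError("confidence band does not bracket the mean")


def stratified_mean_variance(strata: Sequence[StratumRecord]) -> tuple[float, float]:
    """Area-weighted stratified mean catch rate and variance of the mean.

    Weights are W_h = area_h / total area; the variance of the stratified
    mean is sum of W_h^2 * s_h^2 / n_h.
    """
    if not strata:
        raise ValueError("need at least one stratum")
    areas = np.array([s.area for s in strata], dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("zero total area")
    w = areas / total
    means = np.array([s.mean_catch for s in strata])
    variances = np.array([s.var_catch for s in strata])
    n = np.array([s.n_tows for s in strata], dtype=float)
    mean = float(np.sum(w * means))
    var = float(np.sum(w**2 * variances / n))
    return mean, var


def expand_to_swept_area(
    mean_per_tow: float,
    variance: float,
    q: float = 1.0,
    total_area: float = 1.0,
    swept_area: float = 1.0,
) -> SweptAreaEstimate:
    """Expand a stratified mean catch rate to a swept-area biomass estimate.

    The mean scales by (q * A / a) and the variance by its square; q = 1
    gives a minimum biomass estimate.
    """
    if q <= 0 or total_area <= 0 or swept_area <= 0:
        raise ValueError("q, total area and swept area must all be positive")
    if variance < 0:
        raise ValueError("negative input variance")
    scale = q * total_area / swept_area
    biomass = mean_per_tow * scale
    var_out = variance * scale**2
    half_width = CI_MULTIPLIER * np.sqrt(var_out)
    return SweptAreaEstimate(
        mean_biomass=biomass,
        variance=var_out,
        ci_low=biomass - half_width,
        ci_high=biomass + half_width,
        q=q,
        total_area=total_area,
        swept_area=swept_area,
    )


STRATA_COLUMNS = ["stratum_id", "area", "n_tows", "mean_catch", "var_catch"]


def read_strata_csv(path) -> list[StratumRecord]:
    df = pd.read_csv(path, dtype={"stratum_id": str})
    missing = [c for c in STRATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        StratumRecord(
            stratum_id=row.stratum_id,
            area=float(row.area),
            n_tows=int(row.n_tows),
            mean_catch=float(row.mean_catch),
            var_catch=float(row.var_catch),
        )
        for row in df.itertuples(index=False)
    ]
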