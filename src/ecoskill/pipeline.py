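"""Orchestration: period definitions, skill tables over a whole dataset,
hindcast-vs-forecast quantile comparison, and PCA of the skill metrics.

Biomass and landings series are z-scored over their full record before
pairing, so hindcast and forecast metrics share one scale.  Indicator
series are computed from raw inputs, then themselves standardized before
scoring so that all categories report comparable error magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as sm
from .indicators import EcosystemDataset, compute_all_indicators
from .timeseries import (
    DegenerateSeriesError,
    InsufficientOverlapError,
    PeriodDefinition,
    SkillTable,
    TimeSeries,
    align_pair,
    standardize,
)

log = logging.getLogger(__name__)

QUANTILE_CUTS = (40.0, 60.0)
MIN_REFERENCE_SIZE = 5


def define_periods(
    hindcast_start: int = 1964,
    hindcast_end: int = 2004,
    spinup_years: int = 10,
    forecast_start: int = 2005,
    forecast_end: int = 2013,
    decade_length: int = 10,
) -> list[PeriodDefinition]:
    """Default analysis windows: the full hindcast, a no-spin-up hindcast,
    four decadal hindcasts, and the forecast."""
    if forecast_start <= hindcast_end:
        raise ValueError("forecast must start after the hindcast ends")
    periods = [
        PeriodDefinition("full_hindcast", hindcast_start, hindcast_end),
        PeriodDefinition("no_spinup", hindcast_start + spinup_years, hindcast_end),
    ]
    start = hindcast_start
    while start + decade_length - 1 < hindcast_end:
        periods.append(
            PeriodDefinition(f"decade_{start}", start, start + decade_length - 1)
        )
        start += decade_length
    periods.append(PeriodDefinition("forecast", forecast_start, forecast_end))
    return periods


def _score_pair_rows(
    obs: TimeSeries,
    mod: TimeSeries,
    periods: list[PeriodDefinition],
    category: str,
) -> list[tuple]:
    rows = []
    for period in periods:
        try:
            pair = align_pair(obs, mod, period)
            scores = sm.compute_all_metrics(pair, period=period.name)
        except InsufficientOverlapError as err:
            log.info("skipping %s in %s: %s", obs.series_id, period.name, err)
            scores = [
                sm.SkillScore(obs.series_id, code, period.name, float("nan"), 0,
                              reason=str(err))
                for code in sm.METRIC_CODES
            ]
        for s in scores:
            rows.append((s.series_id, category, s.metric, s.period, s.value, s.n))
    return rows


def run_assessment(
    dataset: EcosystemDataset,
    periods: list[PeriodDefinition] | None = None,
    standardize_direct: bool = True,
) -> SkillTable:
    """Score every observed/modeled pair in the dataset over every period.

    Biomass and landings series are standardized (full record) before
    pairing when ``standardize_direct`` is set.  The 22 indicators are
    computed on raw inputs for each source, standardized, then paired and
    scored.  Cells that cannot be computed are carried as flagged-missing
    NaN rows, never dropped.
    """
    if periods is None:
        periods = define_periods()
    rows: list[tuple] = []

    for category, table in (("biomass", dataset.biomass), ("landings", dataset.landings)):
        gids = sorted({gid for (_, gid) in table})
        for gid in gids:
            obs = table.get(("observed", gid))
            mod = table.get(("modeled", gid))
            if obs is None or mod is None:
                log.info("no %s pair for %s", category, gid)
                continue
            if standardize_direct:
                try:
                    obs, mod = standardize(obs), standardize(mod)
                except DegenerateSeriesError as err:
                    log.info("cannot standardize %s: %s", gid, err)
                    continue
            rows.extend(_score_pair_rows(obs, mod, periods, category))

    obs_ind = {r.code: r for r in compute_all_indicators(dataset, "observed")}
    mod_ind = {r.code: r for r in compute_all_indicators(dataset, "modeled")}
    for code in obs_ind:
        ro, rm = obs_ind[code], mod_ind[code]
        if not (ro.computed and rm.computed):
            reason = ro.reason or rm.reason
            log.info("indicator %s flagged missing: %s", code, reason)
            for period in periods:
                for mcode in sm.METRIC_CODES:
                    rows.append((code, "indicator", mcode, period.name, float("nan"), 0))
            continue
        try:
            obs_s, mod_s = standardize(ro.series), standardize(rm.series)
        except DegenerateSeriesError as err:
            log.info("cannot standardize indicator %s: %s", code, err)
            for period in periods:
                for mcode in sm.METRIC_CODES:
                    rows.append((code, "indicator", mcode, period.name, float("nan"), 0))
            continue
        rows.extend(_score_pair_rows(obs_s, mod_s, periods, "indicator"))

    if not rows:
        raise ValueError("dataset produced no skill rows")
    frame = pd.DataFrame(rows, columns=["series_id", "category", "metric",
                                        "period", "value", "n"])
    return SkillTable(frame)


@dataclass
class QuantileComparison:
    """Percentile of each forecast cell within its hindcast reference
    distribution, with 40/60 classes and summary percentages."""

    cells: pd.DataFrame  # columns: series_id, category, metric, percentile, class
    summary: dict[str, float] = field(default_factory=dict)

    CLASSES = ("below_40", "mid_40_60", "above_60")


def _percent_rank(value: float, reference: np.ndarray) -> float:
    """Mean percent rank of ``value`` within ``reference`` (ties split)."""
    less = np.sum(reference < value)
    equal = np.sum(reference == value)
    return 100.0 * (less + 0.5 * equal) / len(reference)


def _classify(percentile: float) -> str:
    lo, hi = QUANTILE_CUTS
    if percentile < lo:
        return "below_40"
    if percentile > hi:
        return "above_60"
    return "mid_40_60"


def compare_hindcast_forecast(
    table: SkillTable,
    hindcast_period: str = "full_hindcast",
    forecast_period: str = "forecast",
) -> QuantileComparison:
    """Rank each series' forecast skill within the hindcast skill
    distribution of the same metric and data category.

    Values are orientation-corrected first so larger always means better.
    The reference distribution for a (series, metric) cell is the hindcast
    values of that metric across all series of the same category; fewer
    than ``MIN_REFERENCE_SIZE`` reference values is an error.
    """
    f = table.frame
    for period in (hindcast_period, forecast_period):
        if period not in set(f["period"]):
            raise ValueError(f"period {period!r} not present in table")
    oriented = f.copy()
    oriented["value"] = [
        sm.orient_for_comparison(m, v) for m, v in zip(f["metric"], f["value"])
    ]
    hind = oriented[oriented.period == hindcast_period]
    fore = oriented[oriented.period == forecast_period]

    records = []
    for row in fore.itertuples(index=False):
        if not np.isfinite(row.value):
            continue
        ref = hind[
            (hind.metric == row.metric) & (hind.category == row.category)
        ]["value"].dropna().to_numpy()
        if len(ref) < MIN_REFERENCE_SIZE:
            raise ValueError(
                f"reference too small for metric {row.metric!r} in category "
                f"{row.category!r} ({len(ref)} values, need {MIN_REFERENCE_SIZE})"
            )
        pct = _percent_rank(row.value, ref)
        records.append(
            (row.series_id, row.category, row.metric, pct, _classify(pct))
        )
    cells = pd.DataFrame(
        records, columns=["series_id", "category", "metric", "percentile", "class"]
    )
    if cells.empty:
        raise ValueError("no finite forecast cells to compare")
    counts = cells["class"].value_counts()
    n = len(cells)
    summary = {
        cls: 100.0 * counts.get(cls, 0) / n for cls in QuantileComparison.CLASSES
    }
    summary["same_or_better"] = summary["mid_40_60"] + summary["above_60"]
    return QuantileComparison(cells=cells, summary=summary)


@dataclass
class PCAResult:
    """Loadings, scores and explained variance of a correlation-scaled PCA
    of the skill-metric matrix."""

    loadings: pd.DataFrame  # columns x components
    scores: pd.DataFrame  # rows (series) x components
    variance_explained: np.ndarray
    dropped_columns: list[str] = field(default_factory=list)


def pca_of_metrics(
    table: SkillTable,
    category: str,
    hindcast_period: str = "full_hindcast",
    forecast_period: str = "forecast",
) -> PCAResult:
    """PCA of the series-by-metric matrix (7 metrics x hindcast/forecast).

    Columns are centered and scaled to unit variance and decomposed by
    singular values.  Rows with any missing cell are dropped; zero-variance
    columns are dropped with a warning.  Signs follow a deterministic
    convention: the largest-magnitude loading of each component is
    positive.
    """
    f = table.frame
    sub = f[
        (f.category == category) & (f.period.isin([hindcast_period, forecast_period]))
    ].copy()
    if sub.empty:
        raise ValueError(f"no rows for category {category!r}")
    suffix = {hindcast_period: "_h", forecast_period: "_f"}
    sub["column"] = sub["metric"] + sub["period"].map(suffix)
    wide = sub.pivot(index="series_id", columns="column", values="value")
    order = [
        m + s for s in ("_h", "_f") for m in sm.METRIC_CODES if m + s in wide.columns
    ]
    wide = wide[order].dropna(axis=0, how="any")
    if len(wide) < 3:
        raise ValueError(
            f"fewer than 3 complete series rows for category {category!r}"
        )
    dropped = [c for c in wide.columns if wide[c].std(ddof=1) == 0]
    if dropped:
        log.warning("dropping zero-variance columns %s", dropped)
        wide = wide.drop(columns=dropped)

    X = wide.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest |loading| per component made positive
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    var = s**2
    var_explained = var / var.sum() if var.sum() > 0 else var
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    loadings = pd.DataFrame(vt.T, index=wide.columns, columns=comp_names)
    scores = pd.DataFrame(u * s, index=wide.index, columns=comp_names)
    return PCAResult(
        loadings=loadings,
        scores=scores,
        variance_explained=var_explained,
        dropped_columns=dropped,
    )
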