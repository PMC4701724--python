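"""The seven skill metrics computed on an observed/modeled pair.

Error convention is observed minus predicted throughout, so a model that
overshoots yields a negative average error.  Undefined metrics (constant
vectors) surface as flagged scores, never as silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .timeseries import DegenerateSeriesError, PairedSeries

#: Metric codes in canonical reporting order.
METRIC_CODES = ("AE", "AAE", "RMSE", "MEF", "S", "P", "K")

#: Correlation variants within the suite.
CORRELATION_CODES = ("S", "P", "K")

#: Orientation of each metric: how a raw value maps to "better".
ORIENTATION = {
    "AE": "zero_best",
    "AAE": "lower_better",
    "RMSE": "lower_better",
    "MEF": "higher_better",
    "S": "higher_better",
    "P": "higher_better",
    "K": "higher_better",
}

#: Hard bounds where they exist ((lo, hi), either side may be infinite).
BOUNDS = {
    "AE": (-math.inf, math.inf),
    "AAE": (0.0, math.inf),
    "RMSE": (0.0, math.inf),
    "MEF": (-math.inf, 1.0),
    "S": (-1.0, 1.0),
    "P": (-1.0, 1.0),
    "K": (-1.0, 1.0),
}


@dataclass(frozen=True)
class SkillScore:
    """One metric value for one series over one period.

    ``value`` is NaN when the metric is undefined on the pair; ``reason``
    then says why.
    """

    series_id: str
    metric: str
    period: str
    value: float
    n: int
    reason: str = ""

    @property
    def defined(self) -> bool:
        return np.isfinite(self.value)


def average_error(pair: PairedSeries) -> float:
    """Mean of (obs - mod); positive and negative errors cancel."""
    return float(np.mean(pair.obs - pair.mod))


def average_absolute_error(pair: PairedSeries) -> float:
    """Mean of |obs - mod|."""
    return float(np.mean(np.abs(pair.obs - pair.mod)))


def rmse(pair: PairedSeries) -> float:
    """Root mean squared error of (obs - mod)."""
    return float(np.sqrt(np.mean((pair.obs - pair.mod) ** 2)))


def modeling_efficiency(pair: PairedSeries) -> float:
    """1 - SSE/SSO: positive when the model beats predicting the observed
    mean, 1 for a perfect fit.

    Raises :class:`DegenerateSeriesError` when the observations are
    constant (SSO = 0).
    """
    obs, mod = pair.obs, pair.mod
    sso = float(np.sum((obs - obs.mean()) ** 2))
    if sso == 0:
        raise DegenerateSeriesError(
            f"MEF undefined for {pair.series_id!r}: constant observations"
        )
    sse = float(np.sum((mod - obs) ** 2))
    return 1.0 - sse / sso


def correlation(pair: PairedSeries, kind: str) -> float:
    """Correlation between obs and mod: ``"P"`` Pearson, ``"S"`` Spearman
    (average ranks), ``"K"`` Kendall tau-b.
    """
    if kind not in CORRELATION_CODES:
        raise ValueError(f"unknown correlation kind {kind!r}")
    obs, mod = pair.obs, pair.mod
    if np.ptp(obs) == 0 or np.ptp(mod) == 0:
        raise DegenerateSeriesError(
            f"correlation undefined for {pair.series_id!r}: constant vector"
        )
    if kind == "P":
        r = stats.pearsonr(obs, mod).statistic
    elif kind == "S":
        r = stats.spearmanr(obs, mod).statistic
    else:
        r = stats.kendalltau(obs, mod, variant="b").statistic
    return float(r)


_METRIC_FUNCS = {
    "AE": average_error,
    "AAE": average_absolute_error,
    "RMSE": rmse,
    "MEF": modeling_efficiency,
    "S": lambda p: correlation(p, "S"),
    "P": lambda p: correlation(p, "P"),
    "K": lambda p: correlation(p, "K"),
}


def compute_all_metrics(pair: PairedSeries, period: str = "") -> list[SkillScore]:
    """Score all seven metrics on a pair, one :class:`SkillScore` per code.

    Metrics whose preconditions fail yield a flagged NaN score rather than
    being dropped, so every call returns exactly seven entries.
    """
    scores = []
    for code in METRIC_CODES:
        try:
            value = _METRIC_FUNCS[code](pair)
            reason = ""
        except DegenerateSeriesError as err:
            value, reason = float("nan"), str(err)
        scores.append(
            SkillScore(
                series_id=pair.series_id,
                metric=code,
                period=period,
                value=value,
                n=pair.n,
                reason=reason,
            )
        )
    return scores


def orient_for_comparison(metric: str, value: float) -> float:
    """Map a raw metric value onto a common larger-is-better scale.

    MEF and the correlations pass through, AAE and RMSE are negated, and
    AE becomes minus its magnitude (sign carries no skill information).
    """
    if metric not in ORIENTATION:
        raise ValueError(f"unknown metric {metric!r}")
    if ORIENTATION[metric] == "higher_better":
        return value
    if ORIENTATION[metric] == "lower_better":
        return -value
    return -abs(value)
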