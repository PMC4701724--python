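"""Ecosystem indicators derived from raw biomass, landings and primary
production plus group metadata.

All indicators are computed on raw (un-normalized) series.  Sums are in the
input units; ratios are dimensionless.  An indicator's annual series covers
the years where all of its inputs exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .timeseries import GroupMetadata, TimeSeries

#: Defaults for the depletion proxy behind Proportion Overfished.
DEFAULT_DEPLETION_THRESHOLD = 0.2
DEFAULT_END_WINDOW = 3


@dataclass
class EcosystemDataset:
    """Per-group biomass and landings series for both sources, optional
    primary production, and the group-metadata table.

    Biomass and landings series are keyed by ``(source, group_id)``; the
    series_id of a group series is its group_id.
    """

    biomass: dict[tuple[str, str], TimeSeries] = field(default_factory=dict)
    landings: dict[tuple[str, str], TimeSeries] = field(default_factory=dict)
    primary_production: dict[str, TimeSeries] = field(default_factory=dict)
    metadata: dict[str, GroupMetadata] = field(default_factory=dict)

    @classmethod
    def from_series(
        cls,
        series: Iterable[TimeSeries],
        metadata: Mapping[str, GroupMetadata],
    ) -> "EcosystemDataset":
        ds = cls(metadata=dict(metadata))
        for s in series:
            if s.category == "biomass":
                ds.biomass[(s.source, s.series_id)] = s
            elif s.category == "landings":
                ds.landings[(s.source, s.series_id)] = s
            elif s.category == "primary_production":
                ds.primary_production[s.source] = s
            else:
                raise ValueError(
                    f"series {s.series_id!r}: category {s.category!r} is not a "
                    "dataset input"
                )
        for source, gid in list(ds.biomass) + list(ds.landings):
            if gid not in ds.metadata:
                raise ValueError(f"group {gid!r} has series but no metadata")
        return ds

    def all_series(self) -> list[TimeSeries]:
        return (
            list(self.biomass.values())
            + list(self.landings.values())
            + list(self.primary_production.values())
        )

    def groups(self, source: str, category: str) -> list[str]:
        table = self.biomass if category == "biomass" else self.landings
        return sorted(gid for (src, gid) in table if src == source)

    def _frame(self, table, source: str) -> pd.DataFrame:
        """Year-by-group value frame (NaN for gap years)."""
        cols = {
            gid: pd.Series(ts.values, index=ts.years)
            for (src, gid), ts in sorted(table.items())
            if src == source
        }
        return pd.DataFrame(cols)

    def biomass_frame(self, source: str) -> pd.DataFrame:
        return self._frame(self.biomass, source)

    def landings_frame(self, source: str) -> pd.DataFrame:
        return self._frame(self.landings, source)


class MissingInputError(ValueError):
    """Raised when an indicator's required inputs are absent."""


@dataclass(frozen=True)
class IndicatorDefinition:
    code: str
    description: str
    required_inputs: frozenset[str]
    func: Callable[[EcosystemDataset, str], pd.Series]


@dataclass(frozen=True)
class IndicatorResult:
    """One registry entry evaluated on a dataset: a series, or a flagged
    miss with the reason."""

    code: str
    series: TimeSeries | None
    reason: str = ""

    @property
    def computed(self) -> bool:
        return self.series is not None


def _select(meta: Mapping[str, GroupMetadata], pred) -> list[str]:
    return sorted(gid for gid, m in meta.items() if pred(m))


def _sum_over(frame: pd.DataFrame, groups: Sequence[str], what: str) -> pd.Series:
    groups = [g for g in groups if g in frame.columns]
    if not groups:
        raise MissingInputError(f"no {what} series present")
    sub = frame[groups].dropna(axis=0, how="any")
    if sub.empty:
        raise MissingInputError(f"no common years across {what} series")
    return sub.sum(axis=1)


def _ratio(num: pd.Series, den: pd.Series) -> pd.Series:
    common = num.index.intersection(den.index)
    den_c = den.loc[common]
    if (den_c == 0).all() or common.empty:
        raise MissingInputError("all-zero or empty denominator series")
    keep = den_c != 0
    return num.loc[common][keep] / den_c[keep]


def _pp_series(ds: EcosystemDataset, source: str) -> pd.Series:
    if source not in ds.primary_production:
        raise MissingInputError(f"no primary production series for {source!r}")
    ts = ds.primary_production[source].dropna()
    return pd.Series(ts.values, index=ts.years)


def _weighted_mean_tl(
    frame: pd.DataFrame, meta: Mapping[str, GroupMetadata], what: str
) -> pd.Series:
    groups = [
        g for g in frame.columns if g in meta and np.isfinite(meta[g].trophic_level)
    ]
    if not groups:
        raise MissingInputError(f"no trophic levels available for {what}")
    sub = frame[groups].dropna(axis=0, how="any")
    if sub.empty:
        raise MissingInputError(f"no common years across {what} series")
    tl = np.array([meta[g].trophic_level for g in groups])
    weights = sub.to_numpy()
    totals = weights.sum(axis=1)
    if (totals == 0).all():
        raise MissingInputError("all-zero weights for mean trophic level")
    keep = totals != 0
    mtl = (weights[keep] * tl).sum(axis=1) / totals[keep]
    return pd.Series(mtl, index=sub.index[keep])


def _total_biomass(ds, source):
    frame = ds.biomass_frame(source)
    return _sum_over(frame, list(frame.columns), "biomass")


def _total_catch(ds, source):
    frame = ds.landings_frame(source)
    commercial = _select(ds.metadata, lambda m: m.is_commercial)
    return _sum_over(frame, commercial, "commercial landings")


def _fish_biomass(ds, source):
    return _sum_over(
        ds.biomass_frame(source), _select(ds.metadata, lambda m: m.is_fish), "fish biomass"
    )


def _guild_biomass(ds, source, guild):
    return _sum_over(
        ds.biomass_frame(source),
        _select(ds.metadata, lambda m: m.guild == guild),
        f"{guild} biomass",
    )


def _guild_catch(ds, source, guild):
    return _sum_over(
        ds.landings_frame(source),
        _select(ds.metadata, lambda m: m.guild == guild),
        f"{guild} landings",
    )


def _fish_catch(ds, source):
    # "no scallops or lobster": non-fish commercial groups are excluded
    # via the is_fish flag, not by name.
    return _sum_over(
        ds.landings_frame(source),
        _select(ds.metadata, lambda m: m.is_fish and m.is_commercial),
        "commercial fish landings",
    )


def _teps_biomass(ds, source):
    return _sum_over(
        ds.biomass_frame(source), _select(ds.metadata, lambda m: m.is_tep), "TEP biomass"
    )


def _value(ds, source):
    frame = ds.landings_frame(source)
    groups = [g for g in frame.columns if g in ds.metadata]
    if not groups:
        raise MissingInputError("no landings series present")
    sub = frame[groups].dropna(axis=0, how="any")
    if sub.empty:
        raise MissingInputError("no common years across landings series")
    prices = np.array([ds.metadata[g].price_per_ton for g in groups])
    return pd.Series((sub.to_numpy() * prices).sum(axis=1), index=sub.index)


def proportion_overfished_series(
    ds: EcosystemDataset,
    source: str,
    depletion_threshold: float = DEFAULT_DEPLETION_THRESHOLD,
) -> pd.Series:
    """Annual fraction of commercial groups whose biomass is below
    ``depletion_threshold`` times that group's full-series maximum."""
    commercial = _select(ds.metadata, lambda m: m.is_commercial)
    frame = ds.biomass_frame(source)
    commercial = [g for g in commercial if g in frame.columns]
    if not commercial:
        raise MissingInputError("no commercial groups with biomass series")
    sub = frame[commercial].dropna(axis=0, how="any")
    if sub.empty:
        raise MissingInputError("no common years across commercial biomass series")
    maxima = sub.max(axis=0)
    if (maxima <= 0).any():
        raise MissingInputError("nonpositive biomass maximum in a commercial series")
    rel = sub / maxima
    return (rel < depletion_threshold).mean(axis=1)


def proportion_overfished(
    ds: EcosystemDataset,
    source: str,
    depletion_threshold: float = DEFAULT_DEPLETION_THRESHOLD,
    end_window: int = DEFAULT_END_WINDOW,
) -> float:
    """Fraction of commercial groups depleted at the end of the record.

    A group counts as depleted when its mean biomass over the final
    ``end_window`` years, relative to its full-series maximum, is below
    ``depletion_threshold``.
    """
    if not 0 < depletion_threshold <= 1:
        raise ValueError("depletion threshold must be in (0, 1]")
    commercial = _select(ds.metadata, lambda m: m.is_commercial)
    frame = ds.biomass_frame(source)
    commercial = [g for g in commercial if g in frame.columns]
    if not commercial:
        raise MissingInputError("no commercial groups with biomass series")
    flags = []
    for g in commercial:
        col = frame[g].dropna()
        peak = col.max()
        if peak <= 0:
            raise MissingInputError(f"nonpositive biomass maximum for {g!r}")
        tail = col.iloc[-end_window:]
        flags.append(tail.mean() / peak < depletion_threshold)
    return float(np.mean(flags))


def _build_registry() -> dict[str, IndicatorDefinition]:
    B = frozenset({"biomass"})
    L = frozenset({"landings"})
    PP = frozenset({"primary_production"})

    defs = [
        ("total_biomass", "Total biomass of all modeled groups", B, _total_biomass),
        ("total_catch", "Total catch of commercial fish and benthos", L, _total_catch),
        ("catch_biomass", "Total catch as proportion of total biomass", B | L,
         lambda d, s: _ratio(_total_catch(d, s), _total_biomass(d, s))),
        ("fish_biomass", "Total biomass of fish species", B, _fish_biomass),
        ("demersal_pelagic_ratio",
         "Demersal fish biomass as a proportion of pelagic fish biomass", B,
         lambda d, s: _ratio(_guild_biomass(d, s, "demersal_fish"),
                             _guild_biomass(d, s, "pelagic_fish"))),
        ("teps", "Biomass of threatened, endangered and protected species", B,
         _teps_biomass),
        ("seal_biomass", "Total biomass of seals", B,
         lambda d, s: _guild_biomass(d, s, "mammal_seal")),
        ("whale_biomass", "Total biomass of whales", B,
         lambda d, s: _guild_biomass(d, s, "mammal_whale")),
        ("demersal_catch", "Demersal fish catch (weight)", L,
         lambda d, s: _guild_catch(d, s, "demersal_fish")),
        ("pelagic_catch", "Pelagic fish catch (weight)", L,
         lambda d, s: _guild_catch(d, s, "pelagic_fish")),
        ("mtl_system", "Mean trophic level of all species in the system", B,
         lambda d, s: _weighted_mean_tl(
             d.biomass_frame(s).dropna(axis=0, how="any"), d.metadata, "biomass")),
        ("mtl_catch", "Mean trophic level of species in the catch", L,
         lambda d, s: _weighted_mean_tl(
             d.landings_frame(s).dropna(axis=0, how="any"), d.metadata, "landings")),
        ("biomass_pp", "Total biomass as proportion of primary production", B | PP,
         lambda d, s: _ratio(_total_biomass(d, s), _pp_series(d, s))),
        ("demersal_biomass_pp",
         "Demersal fish biomass as proportion of primary production", B | PP,
         lambda d, s: _ratio(_guild_biomass(d, s, "demersal_fish"), _pp_series(d, s))),
        ("pelagic_biomass_pp",
         "Pelagic fish biomass as proportion of primary production", B | PP,
         lambda d, s: _ratio(_guild_biomass(d, s, "pelagic_fish"), _pp_series(d, s))),
        ("catch_pp", "Fisheries catch as proportion of primary production", L | PP,
         lambda d, s: _ratio(_total_catch(d, s), _pp_series(d, s))),
        ("demersal_catch_pp",
         "Demersal fish catch as proportion of primary production", L | PP,
         lambda d, s: _ratio(_guild_catch(d, s, "demersal_fish"), _pp_series(d, s))),
        ("pelagic_catch_pp",
         "Pelagic fish catch as proportion of primary production", L | PP,
         lambda d, s: _ratio(_guild_catch(d, s, "pelagic_fish"), _pp_series(d, s))),
        ("fish_catch", "Catch of commercial fish (non-fish groups excluded)", L,
         _fish_catch),
        ("fish_catch_fish_biomass",
         "Commercial fish catch as proportion of total fish biomass", B | L,
         lambda d, s: _ratio(_fish_catch(d, s), _fish_biomass(d, s))),
        ("proportion_overfished",
         "Proportion of commercial species with low relative biomass", B,
         lambda d, s: proportion_overfished_series(d, s)),
        ("value", "Total value of the catch", L, _value),
    ]
    return {
        code: IndicatorDefinition(code, desc, req, func)
        for code, desc, req, func in defs
    }


#: Registry of indicator definitions, one per indicator code.
INDICATOR_REGISTRY: dict[str, IndicatorDefinition] = _build_registry()


def compute_indicator(code: str, ds: EcosystemDataset, source: str) -> TimeSeries:
    """Evaluate one registry indicator for one source.

    Raises ``KeyError`` for unknown codes and
    :class:`MissingInputError` when the required inputs are absent.
    """
    if code not in INDICATOR_REGISTRY:
        raise KeyError(f"unknown indicator code {code!r}")
    values = INDICATOR_REGISTRY[code].func(ds, source)
    values = values.sort_index()
    return TimeSeries(
        series_id=code,
        category="indicator",
        source=source,
        years=values.index.to_numpy(dtype=int),
        values=values.to_numpy(dtype=float),
    )


def compute_all_indicators(ds: EcosystemDataset, source: str) -> list[IndicatorResult]:
    """Evaluate every registry indicator; absent inputs yield a flagged
    result, never a silent drop, so the output always has one entry per
    registry code."""
    results = []
    for code in INDICATOR_REGISTRY:
        try:
            results.append(IndicatorResult(code, compute_indicator(code, ds, source)))
        except MissingInputError as err:
            results.append(IndicatorResult(code, None, reason=str(err)))
    return results
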