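"""Time-series containers, long-format CSV I/O, pairing and standardization.

The long-format dialect is UTF-8, comma-separated, ``.`` decimal, empty cell
= missing.  Series files carry the columns ``series_id, category, source,
year, value, units``; group-metadata files carry ``group_id, name, guild,
is_fish, is_commercial, is_tep, trophic_level, price_per_ton``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CATEGORIES = frozenset({"biomass", "landings", "primary_production", "indicator"})
SOURCES = frozenset({"observed", "modeled"})
GUILDS = frozenset(
    {
        "demersal_fish",
        "pelagic_fish",
        "benthos",
        "mammal_seal",
        "mammal_whale",
        "seabird",
        "other",
    }
)

#: Minimum number of paired points required for any skill computation.
MIN_PAIRED_POINTS = 3


class DegenerateSeriesError(ValueError):
    """Raised when an operation requires variation and the series has none."""


class InsufficientOverlapError(ValueError):
    """Raised when two series share fewer paired years than the minimum."""


@dataclass(frozen=True)
class TimeSeries:
    """One annual series with source and category labels.

    ``years`` are strictly increasing integers; ``values`` is the same
    length and may contain NaN to mark gap years.
    """

    series_id: str
    category: str
    source: str
    years: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        if years.ndim != 1 or values.ndim != 1:
            raise ValueError("years and values must be one-dimensional")
        if len(years) != len(values):
            raise ValueError(
                f"series {self.series_id!r}: {len(years)} years vs {len(values)} values"
            )
        if len(years) > 1 and not np.all(np.diff(years) > 0):
            raise ValueError(f"series {self.series_id!r}: years must be strictly increasing")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.years)

    def dropna(self) -> "TimeSeries":
        """Return a copy with gap (NaN) years removed."""
        keep = np.isfinite(self.values)
        return replace(self, years=self.years[keep], values=self.values[keep])

    def clip_period(self, period: "PeriodDefinition") -> "TimeSeries":
        keep = (self.years >= period.start_year) & (self.years <= period.end_year)
        return replace(self, years=self.years[keep], values=self.values[keep])


@dataclass(frozen=True)
class PairedSeries:
    """Aligned observed/modeled values over common years; the unit of skill
    computation."""

    series_id: str
    years: np.ndarray
    obs: np.ndarray
    mod: np.ndarray
    category: str = "biomass"

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        obs = np.asarray(self.obs, dtype=float)
        mod = np.asarray(self.mod, dtype=float)
        if not (len(years) == len(obs) == len(mod)):
            raise ValueError("years, obs and mod must have equal length")
        if len(years) < MIN_PAIRED_POINTS:
            raise InsufficientOverlapError(
                f"series {self.series_id!r}: {len(years)} paired points "
                f"(minimum {MIN_PAIRED_POINTS})"
            )
        if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(mod))):
            raise ValueError("paired series may not contain missing values")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "obs", obs)
        object.__setattr__(self, "mod", mod)

    @property
    def n(self) -> int:
        return len(self.years)


@dataclass(frozen=True)
class GroupMetadata:
    """Per-group ecological attributes feeding the indicator computations."""

    group_id: str
    name: str
    guild: str
    is_fish: bool
    is_commercial: bool
    is_tep: bool
    trophic_level: float
    price_per_ton: float

    def __post_init__(self) -> None:
        if self.guild not in GUILDS:
            raise ValueError(f"group {self.group_id!r}: unknown guild {self.guild!r}")
        if np.isfinite(self.trophic_level) and self.trophic_level < 1:
            raise ValueError(f"group {self.group_id!r}: trophic level must be >= 1")
        if self.price_per_ton < 0:
            raise ValueError(f"group {self.group_id!r}: negative price")


@dataclass(frozen=True)
class PeriodDefinition:
    """Inclusive year range used to window skill computations."""

    name: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ValueError(f"period {self.name!r}: start after end")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


SERIES_COLUMNS = ["series_id", "category", "source", "year", "value", "units"]


def read_timeseries_csv(path) -> list[TimeSeries]:
    """Read a long-format series CSV into a list of :class:`TimeSeries`.

    Rows with an empty value cell become gaps (the year is absent from the
    series).  Duplicate ``(series_id, source, year)`` rows and unknown
    category/source labels are hard errors.
    """
    df = pd.read_csv(path, dtype={"series_id": str, "units": str},
                     float_precision="round_trip")
    missing_cols = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    if df.empty:
        return []
    bad_cat = set(df["category"]) - CATEGORIES
    if bad_cat:
        raise ValueError(f"{path}: unknown category values {sorted(bad_cat)}")
    bad_src = set(df["source"]) - SOURCES
    if bad_src:
        raise ValueError(f"{path}: unknown source values {sorted(bad_src)}")
    df["year"] = df["year"].astype(int)
    dup = df.duplicated(subset=["series_id", "category", "source", "year"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate (series_id, category, source, year) = "
            f"({row.series_id!r}, {row.category!r}, {row.source!r}, {row.year})"
        )
    out: list[TimeSeries] = []
    for (sid, cat, src), grp in df.groupby(["series_id", "category", "source"],
                                           sort=True):
        grp = grp.sort_values("year")
        grp = grp[grp["value"].notna()]  # missing value -> gap year
        if grp.empty:
            continue
        units = grp["units"].iloc[0]
        out.append(
            TimeSeries(
                series_id=sid,
                category=cat,
                source=src,
                years=grp["year"].to_numpy(),
                values=grp["value"].to_numpy(dtype=float),
                units="" if pd.isna(units) else str(units),
            )
        )
    return out


def write_timeseries_csv(series: Iterable[TimeSeries], path) -> None:
    rows = []
    for s in series:
        for y, v in zip(s.years, s.values):
            rows.append((s.series_id, s.category, s.source, int(y), v, s.units))
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


METADATA_COLUMNS = [
    "group_id",
    "name",
    "guild",
    "is_fish",
    "is_commercial",
    "is_tep",
    "trophic_level",
    "price_per_ton",
]

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


def _parse_flag(raw, column: str) -> bool:
    if isinstance(raw, (bool, np.bool_)):
        return bool(raw)
    text = str(raw).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(f"cannot parse boolean {raw!r} in column {column!r}")


def read_metadata_csv(path) -> dict[str, GroupMetadata]:
    """Read a group-metadata CSV keyed by ``group_id``."""
    df = pd.read_csv(path, dtype={"group_id": str, "name": str, "guild": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    if df["group_id"].duplicated().any():
        dup_id = df.loc[df["group_id"].duplicated(), "group_id"].iloc[0]
        raise ValueError(f"{path}: duplicate group_id {dup_id!r}")
    out: dict[str, GroupMetadata] = {}
    for row in df.itertuples(index=False):
        out[row.group_id] = GroupMetadata(
            group_id=row.group_id,
            name=row.name,
            guild=row.guild,
            is_fish=_parse_flag(row.is_fish, "is_fish"),
            is_commercial=_parse_flag(row.is_commercial, "is_commercial"),
            is_tep=_parse_flag(row.is_tep, "is_tep"),
            trophic_level=float(row.trophic_level),
            price_per_ton=float(row.price_per_ton),
        )
    return out


def write_metadata_csv(metadata: Mapping[str, GroupMetadata], path) -> None:
    rows = [
        (
            m.group_id,
            m.name,
            m.guild,
            m.is_fish,
            m.is_commercial,
            m.is_tep,
            m.trophic_level,
            m.price_per_ton,
        )
        for m in metadata.values()
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def align_pair(
    obs: TimeSeries, mod: TimeSeries, period: PeriodDefinition | None = None
) -> PairedSeries:
    """Pair two series over the intersection of their non-missing years.

    The year set is the intersection of the parents' finite-valued years,
    optionally clipped to ``period`` (inclusive).  Fewer than
    ``MIN_PAIRED_POINTS`` common years raises
    :class:`InsufficientOverlapError`.
    """
    if obs.series_id != mod.series_id:
        raise ValueError(
            f"series_id mismatch: {obs.series_id!r} vs {mod.series_id!r}"
        )
    if obs.units != mod.units:
        raise ValueError(
            f"series {obs.series_id!r}: unit mismatch {obs.units!r} vs {mod.units!r}"
        )
    a, b = obs.dropna(), mod.dropna()
    if period is not None:
        a, b = a.clip_period(period), b.clip_period(period)
    common = np.intersect1d(a.years, b.years)
    if len(common) < MIN_PAIRED_POINTS:
        raise InsufficientOverlapError(
            f"series {obs.series_id!r}: insufficient overlap "
            f"({len(common)} common years, minimum {MIN_PAIRED_POINTS})"
        )
    obs_vals = a.values[np.searchsorted(a.years, common)]
    mod_vals = b.values[np.searchsorted(b.years, common)]
    return PairedSeries(
        series_id=obs.series_id,
        years=common,
        obs=obs_vals,
        mod=mod_vals,
        category=obs.category,
    )


def standardize(series: TimeSeries) -> TimeSeries:
    """Z-score a series over its full non-missing record (sample sd, ddof=1).

    The output is dimensionless with mean 0 and sample sd 1 on the
    non-missing years; gap years stay gaps.  Constant series raise
    :class:`DegenerateSeriesError`.
    """
    finite = np.isfinite(series.values)
    vals = series.values[finite]
    if len(vals) < 2:
        raise DegenerateSeriesError(
            f"series {series.series_id!r}: fewer than 2 non-missing values"
        )
    sd = np.std(vals, ddof=1)
    if sd == 0:
        raise DegenerateSeriesError(f"degenerate series {series.series_id!r}: zero sd")
    out = np.full_like(series.values, np.nan)
    out[finite] = (vals - vals.mean()) / sd
    return replace(series, values=out, units="")


SKILL_COLUMNS = ["series_id", "category", "metric", "period", "value", "n"]


@dataclass
class SkillTable:
    """Skill value per (series x metric x period), held as a tidy frame.

    ``value`` is NaN for flagged-undefined cells; ``n`` is the paired-point
    count behind the cell (0 when the pairing itself failed).
    """

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SKILL_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in SKILL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"skill table missing columns {missing}")
        self.frame = self.frame[SKILL_COLUMNS].reset_index(drop=True)
        keys = self.frame[["series_id", "category", "metric", "period"]]
        if keys.duplicated().any():
            row = self.frame[keys.duplicated()].iloc[0]
            raise ValueError(
                "duplicate skill key "
                f"({row.series_id!r}, {row.category!r}, {row.metric!r}, "
                f"{row.period!r})"
            )

    def __len__(self) -> int:
        return len(self.frame)

    def value(self, series_id: str, metric: str, period: str,
              category: str | None = None) -> float:
        f = self.frame
        sel = f[
            (f.series_id == series_id) & (f.metric == metric) & (f.period == period)
        ]
        if category is not None:
            sel = sel[sel.category == category]
        if sel.empty:
            raise KeyError((series_id, metric, period))
        if len(sel) > 1:
            raise KeyError(
                f"ambiguous key {(series_id, metric, period)}: pass category"
            )
        return float(sel["value"].iloc[0])


def write_skill_table(table: SkillTable, path) -> None:
    if len(table) == 0:
        raise ValueError("refusing to write an empty skill table")
    table.frame.to_csv(path, index=False, float_format="%.17g")


def read_skill_table(path) -> SkillTable:
    df = pd.read_csv(path, dtype={"series_id": str, "category": str,
                                  "metric": str, "period": str},
                     float_precision="round_trip")
    df["n"] = df["n"].astype(int)
    return SkillTable(df)
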