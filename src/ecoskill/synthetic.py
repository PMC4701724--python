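"""Synthetic inputs: conceptual mismatch scenarios and full ecosystems.

Two generators live here.  ``generate_scenario`` builds a single
observed/modeled pair exhibiting one stylized form of (mis)fit — perfect
fit, scale mismatch, inverse variation, lack of correlation, trend
mismatch, or a combination.  ``generate_ecosystem`` builds a whole
multi-group dataset with known ground truth: latent biomass follows a
logistic-growth-with-harvest recursion, observations add lognormal error,
landings track harvest, and the modeled series are distortions of the
truth controlled by a per-group skill knob.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .indicators import EcosystemDataset
from .survey import expand_to_swept_area
from .timeseries import GroupMetadata, PairedSeries, TimeSeries

SCENARIO_KINDS = (
    "perfect",
    "scale_mismatch",
    "inverse",
    "uncorrelated",
    "trend_mismatch",
    "combined",
)

SKILL_LEVELS = ("high", "medium", "noise_only")


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one conceptual mismatch scenario."""

    kind: str
    length: int = 40
    noise_sd: float = 0.0
    scale_factor: float = 2.0
    seed: int = 0
    # base-signal shape: offset + slope*t + amp*sin(2*pi*t/cycle)
    offset: float = 10.0
    slope: float = 0.08
    amplitude: float = 1.5
    cycle: float = 12.0
    start_year: int = 1964

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.length < 10:
            raise ValueError("scenario length must be at least 10 years")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


def _base_signal(t: np.ndarray, spec: ScenarioSpec, slope: float | None = None,
                 phase: float = 0.0) -> np.ndarray:
    slope = spec.slope if slope is None else slope
    return (
        spec.offset
        + slope * t
        + spec.amplitude * np.sin(2 * np.pi * t / spec.cycle + phase)
    )


def generate_scenario(spec: ScenarioSpec) -> PairedSeries:
    """Simulate one observed/modeled pair for a mismatch scenario.

    The observed series is the base signal plus Gaussian noise; the
    modeled series is derived from the base according to ``spec.kind``.
    Identical specs (including seed) produce identical output.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.length, dtype=float)
    base = _base_signal(t, spec)
    obs = base + rng.normal(0.0, spec.noise_sd, size=spec.length)

    if spec.kind == "perfect":
        mod = base.copy()
    elif spec.kind == "scale_mismatch":
        mod = spec.scale_factor * base
    elif spec.kind == "inverse":
        mod = 2 * base.mean() - base  # reflect about the base mean
    elif spec.kind == "uncorrelated":
        slope = rng.normal(0.0, abs(spec.slope) if spec.slope else 0.1)
        phase = rng.uniform(0.0, 2 * np.pi)
        mod = _base_signal(t, spec, slope=slope, phase=phase)
    elif spec.kind == "trend_mismatch":
        mod = _base_signal(t, spec, slope=-spec.slope)
    else:  # combined: trend mismatch compounded with scale mismatch
        mod = spec.scale_factor * _base_signal(t, spec, slope=-spec.slope)

    years = spec.start_year + np.arange(spec.length)
    return PairedSeries(
        series_id=f"scenario_{spec.kind}", years=years, obs=obs, mod=mod
    )


#: Default guild mix (proportions; seal/whale/seabird get one group each).
DEFAULT_GUILD_MIX: dict[str, float] = {
    "demersal_fish": 0.35,
    "pelagic_fish": 0.25,
    "benthos": 0.20,
    "other": 0.20,
}

#: Observed-data onsets emulating differential monitoring start years.
DEFAULT_ONSETS: dict[str, int] = {
    "mammal_seal": 1981,
    "mammal_whale": 1990,
    "primary_production": 1998,
}


@dataclass(frozen=True)
class EcosystemConfig:
    """Knobs for one synthetic ecosystem realization."""

    n_groups: int = 30
    guild_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GUILD_MIX)
    )
    start_year: int = 1964
    end_year: int = 2013
    forecast_split: int = 2004
    skill_level: str | Mapping[str, str] = "high"
    obs_cv: float = 0.3
    process_sd: float = 0.1
    missing_onsets: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ONSETS)
    )
    harvest_rate_range: tuple[float, float] = (0.05, 0.30)
    env_amplitude: float = 0.45
    env_cycle: float = 20.0
    harvest_ramp: bool = False
    total_area: float = 293_000.0
    tow_footprint: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 5:
            raise ValueError("need at least 5 groups")
        if self.start_year >= self.end_year:
            raise ValueError("empty year range")
        if not self.start_year <= self.forecast_split < self.end_year:
            raise ValueError("forecast split must fall inside the year range")
        lo, hi = self.harvest_rate_range
        if not (0 <= lo <= hi):
            raise ValueError("bad harvest-rate range")
        if hi >= 1:
            raise ValueError("infeasible harvest rate (must be < 1)")
        levels = (
            {self.skill_level}
            if isinstance(self.skill_level, str)
            else set(self.skill_level.values())
        )
        unknown = levels - set(SKILL_LEVELS)
        if unknown:
            raise ValueError(f"unknown skill levels {sorted(unknown)}")

    def skill_for(self, group_id: str) -> str:
        if isinstance(self.skill_level, str):
            return self.skill_level
        return self.skill_level.get(group_id, "high")


@dataclass
class GroundTruth:
    """Latent states and parameters behind one synthetic ecosystem."""

    true_biomass: dict[str, np.ndarray]
    true_landings: dict[str, np.ndarray]
    params: dict[str, dict]
    obs_ci_low: dict[str, np.ndarray]
    obs_ci_high: dict[str, np.ndarray]
    years: np.ndarray
    config: EcosystemConfig


def _guild_counts(config: EcosystemConfig) -> list[str]:
    """Deterministic guild label per group: one seal, whale and seabird
    group, the rest split by the configured proportions."""
    fixed = ["mammal_seal", "mammal_whale", "seabird"]
    remaining = config.n_groups - len(fixed)
    if remaining < len(config.guild_mix):
        raise ValueError("too few groups for the guild mix")
    mix = dict(config.guild_mix)
    total = sum(mix.values())
    counts = {g: int(round(p / total * remaining)) for g, p in mix.items()}
    # fix rounding drift on the largest guild
    drift = remaining - sum(counts.values())
    largest = max(counts, key=counts.get)
    counts[largest] += drift
    labels = fixed[:]
    for guild in sorted(counts):
        labels.extend([guild] * counts[guild])
    return labels[: config.n_groups]


_SIGMA = lambda cv: np.sqrt(np.log1p(cv**2))


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative lognormal error with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = _SIGMA(cv)
    return rng.lognormal(-0.5 * sigma**2, sigma, size=size)


def _logistic_trajectory(
    rng: np.random.Generator,
    n_years: int,
    r: float,
    K: float,
    b0: float,
    harvest: float,
    process_sd: float,
    env_amp: float = 0.35,
    env_cycle: float = 20.0,
    env_phase: float = 0.0,
    harvest_ramp: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Logistic growth with proportional harvest and lognormal process
    noise; returns (biomass, catch) with biomass floored at 1% of K.

    Carrying capacity oscillates (environmental forcing) and harvest
    ramps up over the record, so trajectories carry persistent trends and
    cycles rather than settling at equilibrium.
    """
    biomass = np.empty(n_years)
    catch = np.empty(n_years)
    t = np.arange(n_years)
    K_t = K * (1 + env_amp * np.sin(2 * np.pi * t / env_cycle + env_phase))
    ramp = 0.5 + t / max(n_years - 1, 1) if harvest_ramp else np.ones(n_years)
    b = b0
    for i in range(n_years):
        biomass[i] = b
        c = min(harvest * ramp[i], 0.9) * b
        catch[i] = c
        growth = r * b * (1 - b / K_t[i])
        shock = rng.lognormal(-0.5 * process_sd**2, process_sd) if process_sd else 1.0
        b = max((b + growth - c) * shock, 0.01 * K)
    return biomass, catch


def generate_ecosystem(
    config: EcosystemConfig,
) -> tuple[EcosystemDataset, GroundTruth]:
    """Build one synthetic ecosystem with its ground-truth record.

    Observed biomass is truth times lognormal observation error, with 95%
    confidence bands attached through the swept-area expansion; landings
    are harvest times truth (never exceeding truth); modeled series are
    truth distorted per the group's skill level.
    """
    rng = np.random.default_rng(config.seed)
    years = np.arange(config.start_year, config.end_year + 1)
    n_years = len(years)
    guilds = _guild_counts(config)

    metadata: dict[str, GroupMetadata] = {}
    series: list[TimeSeries] = []
    truth_b: dict[str, np.ndarray] = {}
    truth_l: dict[str, np.ndarray] = {}
    params: dict[str, dict] = {}
    ci_low: dict[str, np.ndarray] = {}
    ci_high: dict[str, np.ndarray] = {}

    tl_by_guild = {
        "demersal_fish": (3.2, 4.6),
        "pelagic_fish": (3.0, 4.2),
        "benthos": (2.0, 3.0),
        "mammal_seal": (4.5, 5.0),
        "mammal_whale": (3.4, 4.2),
        "seabird": (3.8, 4.5),
        "other": (2.5, 4.0),
    }

    for i, guild in enumerate(guilds):
        gid = f"g{i:02d}_{guild}"
        is_fish = guild in ("demersal_fish", "pelagic_fish")
        is_mammal_or_bird = guild in ("mammal_seal", "mammal_whale", "seabird")
        is_commercial = bool(is_fish or (guild in ("benthos", "other") and i % 2 == 0))
        tl_lo, tl_hi = tl_by_guild[guild]
        metadata[gid] = GroupMetadata(
            group_id=gid,
            name=gid.replace("_", " "),
            guild=guild,
            is_fish=is_fish,
            is_commercial=is_commercial,
            is_tep=is_mammal_or_bird,
            trophic_level=float(rng.uniform(tl_lo, tl_hi)),
            price_per_ton=float(rng.uniform(500, 5000)) if is_commercial else 0.0,
        )

        r = rng.uniform(0.3, 0.8)
        K = float(np.exp(rng.normal(np.log(1e5), 0.5)))
        b0 = K * rng.uniform(0.4, 0.9)
        harvest = (
            float(rng.uniform(*config.harvest_rate_range)) if is_commercial else 0.0
        )
        env_phase = float(rng.uniform(0.0, 2 * np.pi))
        biomass, catch = _logistic_trajectory(
            rng, n_years, r, K, b0, harvest, config.process_sd,
            env_amp=config.env_amplitude, env_cycle=config.env_cycle,
            env_phase=env_phase, harvest_ramp=config.harvest_ramp,
        )
        truth_b[gid] = biomass
        truth_l[gid] = catch
        params[gid] = {"r": r, "K": K, "b0": b0, "harvest": harvest}

        # observation layer: lognormal error + swept-area CIs
        obs_b = biomass * _lognormal_noise(rng, config.obs_cv, n_years)
        scale = config.total_area / config.tow_footprint
        lo = np.empty(n_years)
        hi = np.empty(n_years)
        for j, ob in enumerate(obs_b):
            est = expand_to_swept_area(
                mean_per_tow=ob / scale,
                variance=(config.obs_cv * ob / scale) ** 2,
                q=1.0,
                total_area=config.total_area,
                swept_area=config.tow_footprint,
            )
            lo[j], hi[j] = est.ci_low, est.ci_high
        ci_low[gid], ci_high[gid] = lo, hi

        # modeled layer: truth distorted per the skill knob
        level = config.skill_for(gid)
        if level == "high":
            mod_b = biomass * _lognormal_noise(rng, 0.05, n_years)
        elif level == "medium":
            drift = np.linspace(1.0, 1.4, n_years)
            mod_b = biomass * drift * _lognormal_noise(rng, 0.25, n_years)
        else:  # noise_only: an independent trajectory, unrelated to truth
            r2 = rng.uniform(0.3, 0.8)
            b02 = K * rng.uniform(0.4, 0.9)
            mod_b, _ = _logistic_trajectory(
                rng, n_years, r2, K, b02, harvest, max(config.process_sd, 0.15),
                env_amp=config.env_amplitude, env_cycle=config.env_cycle,
                env_phase=float(rng.uniform(0.0, 2 * np.pi)),
                harvest_ramp=config.harvest_ramp,
            )

        onset = config.missing_onsets.get(guild, config.start_year)
        obs_keep = years >= onset

        series.append(
            TimeSeries(gid, "biomass", "observed",
                       years[obs_keep], obs_b[obs_keep], units="t")
        )
        series.append(TimeSeries(gid, "biomass", "modeled", years, mod_b, units="t"))

        if is_commercial:
            obs_l = np.minimum(
                catch * _lognormal_noise(rng, config.obs_cv / 2, n_years), biomass
            )
            if level == "high":
                mod_l = catch * _lognormal_noise(rng, 0.05, n_years)
            elif level == "medium":
                mod_l = catch * _lognormal_noise(rng, 0.25, n_years)
            else:
                mod_l = params[gid]["harvest"] * mod_b
            mod_l = np.minimum(mod_l, biomass)
            series.append(
                TimeSeries(gid, "landings", "observed",
                           years[obs_keep], obs_l[obs_keep], units="t")
            )
            series.append(
                TimeSeries(gid, "landings", "modeled", years, mod_l, units="t")
            )
            truth_l[gid] = np.minimum(truth_l[gid], biomass)

    # primary production: seasonal-cycle-free smooth series with a mild trend
    t = np.arange(n_years, dtype=float)
    pp_true = 5e6 * (1 + 0.1 * np.sin(2 * np.pi * t / 9)) * (1 + 0.002 * t)
    pp_obs = pp_true * _lognormal_noise(rng, 0.1, n_years)
    pp_mod = pp_true * _lognormal_noise(rng, 0.1, n_years)
    pp_onset = config.missing_onsets.get("primary_production", config.start_year)
    pp_keep = years >= pp_onset
    series.append(
        TimeSeries("pp", "primary_production", "observed",
                   years[pp_keep], pp_obs[pp_keep], units="t")
    )
    series.append(
        TimeSeries("pp", "primary_production", "modeled", years, pp_mod, units="t")
    )

    dataset = EcosystemDataset.from_series(series, metadata)
    truth = GroundTruth(
        true_biomass=truth_b,
        true_landings=truth_l,
        params=params,
        obs_ci_low=ci_low,
        obs_ci_high=ci_high,
        years=years,
        config=config,
    )
    return dataset, truth


def perfect_dataset(config: EcosystemConfig) -> EcosystemDataset:
    """Ecosystem whose modeled series equal the observed ones exactly —
    the fixed point every skill metric should score as ideal."""
    dataset, _ = generate_ecosystem(config)
    mirrored: list[TimeSeries] = []
    for ts in dataset.all_series():
        if ts.source == "observed":
            mirrored.append(ts)
            mirrored.append(replace(ts, source="modeled"))
    return EcosystemDataset.from_series(mirrored, dataset.metadata)
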