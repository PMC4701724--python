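import numpy as np
import pytest

from ecoskill import (
    INDICATOR_REGISTRY,
    EcosystemDataset,
    GroupMetadata,
    compute_all_indicators,
    compute_indicator,
    proportion_overfished,
)
from ecoskill.indicators import MissingInputError

from conftest import make_series


def meta(gid, guild="demersal_fish", is_fish=True, is_commercial=True,
         is_tep=False, tl=4.0, price=0.0):
    return GroupMetadata(gid, gid, guild, is_fish, is_commercial, is_tep, tl, price)


def dataset(series, metadata):
    return EcosystemDataset.from_series(series, metadata)


def constant(gid, value, category="biomass", source="observed", n=5, units="t"):
    return make_series([value] * n, series_id=gid, category=category,
                       source=source, units=units)


@pytest.fixture
def two_guild_ds():
    series = [
        constant("dem", 10.0),
        constant("pel", 5.0),
    ]
    metadata = {
        "dem": meta("dem", "demersal_fish"),
        "pel": meta("pel", "pelagic_fish"),
    }
    return dataset(series, metadata)


class TestRegistry:
    def test_exactly_22_indicators(self):
        assert len(INDICATOR_REGISTRY) == 22

    def test_six_pp_ratio_indicators(self):
        pp_codes = [c for c, d in INDICATOR_REGISTRY.items()
                    if "primary_production" in d.required_inputs]
        assert len(pp_codes) == 6

    def test_unknown_code_error(self, two_guild_ds):
        with pytest.raises(KeyError, match="unknown indicator"):
            compute_indicator("not_a_code", two_guild_ds, "observed")


class TestSingleIndicators:
    def test_demersal_pelagic_ratio(self, two_guild_ds):
        ts = compute_indicator("demersal_pelagic_ratio", two_guild_ds, "observed")
        np.testing.assert_allclose(ts.values, 2.0)

    def test_demersal_pelagic_symmetry(self):
        ds = dataset(
            [constant("dem", 7.0), constant("pel", 7.0)],
            {"dem": meta("dem", "demersal_fish"), "pel": meta("pel", "pelagic_fish")},
        )
        ts = compute_indicator("demersal_pelagic_ratio", ds, "observed")
        np.testing.assert_allclose(ts.values, 1.0)

    def test_mtl_catch_weighted_mean(self):
        ds = dataset(
            [constant("a", 10.0, category="landings"),
             constant("b", 10.0, category="landings"),
             constant("a", 100.0), constant("b", 100.0)],
            {"a": meta("a", tl=4.0), "b": meta("b", "pelagic_fish", tl=3.0)},
        )
        ts = compute_indicator("mtl_catch", ds, "observed")
        np.testing.assert_allclose(ts.values, 3.5)

    def test_mtl_system_single_species(self):
        ds = dataset([constant("a", 42.0)], {"a": meta("a", tl=4.2)})
        ts = compute_indicator("mtl_system", ds, "observed")
        np.testing.assert_allclose(ts.values, 4.2)

    def test_value_price_weighted(self):
        ds = dataset(
            [constant("a", 2.0, category="landings"),
             constant("b", 3.0, category="landings")],
            {"a": meta("a", price=10.0), "b": meta("b", price=1.0)},
        )
        ts = compute_indicator("value", ds, "observed")
        np.testing.assert_allclose(ts.values, 23.0)

    def test_catch_biomass_ratio(self):
        ds = dataset(
            [constant("a", 50.0), constant("a", 5.0, category="landings")],
            {"a": meta("a")},
        )
        ts = compute_indicator("catch_biomass", ds, "observed")
        np.testing.assert_allclose(ts.values, 0.1)

    def test_fish_catch_excludes_nonfish(self):
        ds = dataset(
            [constant("cod", 4.0, category="landings"),
             constant("scallop", 9.0, category="landings"),
             constant("cod", 10.0), constant("scallop", 10.0)],
            {"cod": meta("cod"),
             "scallop": meta("scallop", "benthos", is_fish=False, tl=2.1)},
        )
        fish = compute_indicator("fish_catch", ds, "observed")
        total = compute_indicator("total_catch", ds, "observed")
        np.testing.assert_allclose(fish.values, 4.0)
        np.testing.assert_allclose(total.values, 13.0)

    def test_teps_sums_flagged_groups(self):
        ds = dataset(
            [constant("whale", 6.0), constant("cod", 10.0)],
            {"whale": meta("whale", "mammal_whale", is_fish=False,
                           is_commercial=False, is_tep=True, tl=3.8),
             "cod": meta("cod")},
        )
        ts = compute_indicator("teps", ds, "observed")
        np.testing.assert_allclose(ts.values, 6.0)


class TestProportionOverfished:
    def _ds(self, finals):
        # each group ramps from max=10 down to its final relative level
        series, metadata = [], {}
        for i, rel in enumerate(finals):
            gid = f"g{i}"
            values = [10.0, 10.0, 10 * rel, 10 * rel, 10 * rel]
            series.append(make_series(values, series_id=gid, units="t"))
            metadata[gid] = meta(gid)
        return dataset(series, metadata)

    def test_half_depleted(self):
        ds = self._ds([0.1, 0.5, 0.15, 0.9])
        assert proportion_overfished(ds, "observed", 0.2, 3) == 0.5

    def test_flat_at_maximum_gives_zero(self):
        ds = self._ds([1.0, 1.0, 1.0])
        assert proportion_overfished(ds, "observed", 0.2, 3) == 0.0

    def test_threshold_one_boundary(self):
        ds = self._ds([0.5, 0.9, 0.3])
        assert proportion_overfished(ds, "observed", 1.0, 3) == 1.0

    def test_no_commercial_groups_error(self):
        ds = dataset(
            [constant("seal", 5.0)],
            {"seal": meta("seal", "mammal_seal", is_fish=False,
                          is_commercial=False, is_tep=True, tl=4.8)},
        )
        with pytest.raises(MissingInputError, match="commercial"):
            proportion_overfished(ds, "observed")


class TestComputeAllIndicators:
    def test_full_dataset_yields_22(self, small_ecosystem):
        ds, _ = small_ecosystem
        results = compute_all_indicators(ds, "observed")
        assert len(results) == 22
        assert all(r.computed for r in results)

    def test_missing_pp_flags_six(self, small_ecosystem):
        ds, _ = small_ecosystem
        stripped = EcosystemDataset(
            biomass=ds.biomass, landings=ds.landings,
            primary_production={}, metadata=ds.metadata)
        results = compute_all_indicators(stripped, "observed")
        missing = [r for r in results if not r.computed]
        assert len(missing) == 6
        assert all("primary production" in r.reason for r in missing)
        assert sum(r.computed for r in results) == 16

    def test_identical_inputs_identical_outputs(self, small_ecosystem):
        ds, _ = small_ecosystem
        mirrored = EcosystemDataset(
            biomass={("modeled" if s == "observed" else "observed", g): ts
                     for (s, g), ts in ds.biomass.items()},
            landings={("modeled" if s == "observed" else "observed", g): ts
                      for (s, g), ts in ds.landings.items()},
            primary_production={("modeled" if s == "observed" else "observed"): ts
                                for s, ts in ds.primary_production.items()},
            metadata=ds.metadata,
        )
        for robs, rmod in zip(compute_all_indicators(ds, "observed"),
                              compute_all_indicators(mirrored, "modeled")):
            assert robs.code == rmod.code
            np.testing.assert_array_equal(robs.series.values, rmod.series.values)


class TestIndicatorProperties:
    def test_total_biomass_additivity(self, small_ecosystem):
        ds, _ = small_ecosystem
        total = compute_indicator("total_biomass", ds, "modeled")
        fish = compute_indicator("fish_biomass", ds, "modeled")
        frame = ds.biomass_frame("modeled")
        nonfish = [g for g in frame.columns if not ds.metadata[g].is_fish]
        rest = frame[nonfish].sum(axis=1)
        common = total.years
        np.testing.assert_allclose(
            total.values,
            fish.values + rest.loc[common].to_numpy(),
            rtol=1e-9,
        )

    def test_mtl_bounded_by_contributing_tls(self, small_ecosystem):
        ds, _ = small_ecosystem
        tls = [m.trophic_level for m in ds.metadata.values()]
        for code in ("mtl_system", "mtl_catch"):
            ts = compute_indicator(code, ds, "observed")
            assert np.all(ts.values >= min(tls) - 1e-12)
            assert np.all(ts.values <= max(tls) + 1e-12)

    def test_ratio_indicators_scale_invariant(self, small_ecosystem):
        ds, _ = small_ecosystem
        scaled = EcosystemDataset(
            biomass={k: make_series(3 * ts.values, series_id=ts.series_id,
                                    category=ts.category, source=ts.source,
                                    start_year=int(ts.years[0]), units=ts.units)
                     for k, ts in ds.biomass.items()},
            landings={k: make_series(3 * ts.values, series_id=ts.series_id,
                                     category=ts.category, source=ts.source,
                                     start_year=int(ts.years[0]), units=ts.units)
                      for k, ts in ds.landings.items()},
            primary_production={k: make_series(3 * ts.values, series_id=ts.series_id,
                                               category=ts.category, source=ts.source,
                                               start_year=int(ts.years[0]),
                                               units=ts.units)
                                for k, ts in ds.primary_production.items()},
            metadata=ds.metadata,
        )
        for code in ("catch_biomass", "demersal_pelagic_ratio", "biomass_pp",
                     "catch_pp", "fish_catch_fish_biomass", "mtl_system",
                     "mtl_catch", "proportion_overfished"):
            a = compute_indicator(code, ds, "observed")
            b = compute_indicator(code, scaled, "observed")
            np.testing.assert_allclose(a.values, b.values, rtol=1e-9)

    def test_all_zero_denominator_error(self):
        ds = dataset(
            [constant("dem", 10.0), constant("pel", 0.0)],
            {"dem": meta("dem", "demersal_fish"),
             "pel": meta("pel", "pelagic_fish")},
        )
        with pytest.raises(MissingInputError):
            compute_indicator("demersal_pelagic_ratio", ds, "observed")
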