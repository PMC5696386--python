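"""Synthetic landscape / observation generator."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichekde.synth import (
    HABITAT_CLASSES,
    DesignError,
    InvalidConfigError,
    LandscapeConfig,
    SiteYearSpec,
    SpeciesParams,
    StudyDesign,
    UnsatisfiablePreferenceError,
    child_seed,
    default_design,
    generate_landscape,
    generate_observations,
    generate_study,
)

MIX = (0.35, 0.15, 0.05, 0.20, 0.15, 0.05, 0.05)


class TestLandscape:
    def test_degenerate_mix_labels_every_field_cereal(self):
        cfg = LandscapeConfig(habitat_mix=(1, 0, 0, 0, 0, 0, 0), seed=3)
        land = generate_landscape(cfg)
        assert (land.labels == 0).all()
        assert land.cover_proportions()[0] == pytest.approx(1.0)

    def test_realized_cover_converges_to_mix(self):
        # 4 km extent, 100 m fields: cereal cover within 0.35 +/- 0.03
        # per seed at binomial tolerance (1600 fields -> SD ~ 0.012)
        covers = []
        for seed in range(50):
            cfg = LandscapeConfig(width_m=4000, height_m=4000, field_size_m=100,
                                  habitat_mix=MIX, seed=seed)
            covers.append(generate_landscape(cfg).cover_proportions()[0])
        covers = np.asarray(covers)
        # +/-0.03 is ~2.5 binomial SDs at 1600 fields: allow the expected
        # handful of borderline seeds but require the bulk inside
        assert (np.abs(covers - 0.35) < 0.03).sum() >= 46
        assert abs(covers.mean() - 0.35) < 0.005

    def test_same_seed_identical_labelling(self):
        cfg = LandscapeConfig(habitat_mix=MIX, seed=11)
        a = generate_landscape(cfg)
        b = generate_landscape(cfg)
        np.testing.assert_array_equal(a.labels, b.labels)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"width_m": 0},
            {"height_m": -100},
            {"field_size_m": 0},
            {"habitat_mix": (0.5, 0.5)},
            {"habitat_mix": (0.5, 0.6, 0, 0, 0, 0, -0.1)},
            {"habitat_mix": (0.2,) * 7},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidConfigError):
            LandscapeConfig(**kwargs)

    def test_class_at_outside_extent_is_minus_one(self, mixed_landscape):
        assert mixed_landscape.class_at(-1.0, 50.0)[0] == -1
        assert mixed_landscape.class_at(50.0, 1e9)[0] == -1


class TestObservations:
    def test_cereal_only_preference_places_all_points_in_cereal(self, mixed_landscape):
        params = SpeciesParams(
            species="little_bustard", n_points=150,
            preference=(1, 0, 0, 0, 0, 0, 0),
        )
        obs = generate_observations(mixed_landscape, params, seed=5)
        codes = mixed_landscape.class_at(obs["x_m"].to_numpy(), obs["y_m"].to_numpy())
        assert (codes == 0).all()
        assert (obs["count"] == 1).all()  # LB males are single birds

    def test_zero_points_gives_empty_set(self, mixed_landscape):
        params = SpeciesParams(species="great_bustard", n_points=0)
        obs = generate_observations(mixed_landscape, params, seed=1)
        assert len(obs) == 0

    def test_unsatisfiable_preference_raises(self):
        land = generate_landscape(LandscapeConfig(habitat_mix=(1, 0, 0, 0, 0, 0, 0)))
        params = SpeciesParams(
            species="little_bustard", n_points=10,
            preference=(0, 1, 1, 1, 1, 1, 1),
        )
        with pytest.raises(UnsatisfiablePreferenceError):
            generate_observations(land, params, seed=0)

    def test_great_bustard_flock_sizes(self, mixed_landscape):
        params = SpeciesParams(species="great_bustard", n_points=400,
                               group_size_mean=4.0)
        obs = generate_observations(mixed_landscape, params, seed=9)
        assert (obs["count"] >= 1).all()
        assert obs["count"].mean() == pytest.approx(4.0, abs=0.5)

    def test_uniform_preference_matches_availability(self, mixed_landscape):
        # chi-square goodness of fit against realized cover, not rejected
        # at alpha = 0.01 in >= 48/50 seeds
        probs = mixed_landscape.cover_proportions()
        params = SpeciesParams(species="little_bustard", n_points=300)
        ok = 0
        for seed in range(50):
            obs = generate_observations(mixed_landscape, params, seed=seed)
            codes = mixed_landscape.class_at(obs["x_m"].to_numpy(), obs["y_m"].to_numpy())
            counts = np.bincount(codes, minlength=7)
            p = stats.chisquare(counts, f_exp=300 * probs).pvalue
            ok += p > 0.01
        assert ok >= 48

    def test_clustering_reduces_nearest_neighbour_distance(self, mixed_landscape):
        base = dict(species="little_bustard", n_points=200)
        d = {}
        for scale in (0.0, 300.0):
            params = SpeciesParams(clustering_m=scale, **base)
            obs = generate_observations(mixed_landscape, params, seed=21)
            pts = obs[["x_m", "y_m"]].to_numpy()
            dist = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
            np.fill_diagonal(dist, np.inf)
            d[scale] = dist.min(axis=1).mean()
        assert d[300.0] < d[0.0]


@pytest.fixture(scope="module")
def gb_field(mixed_landscape):
    params = SpeciesParams(species="great_bustard", n_points=40,
                           group_size_mean=4.0, clustering_m=250.0)
    return generate_observations(mixed_landscape, params, seed=77)


class TestDisplacement:
    def _cereal_use(self, land, gamma, gb, seeds):
        vals = []
        for seed in seeds:
            params = SpeciesParams(
                species="little_bustard", n_points=120,
                preference=(1.0, 0.1, 1.5, 2.0, 2.0, 0.2, 0.05),
                displacement_gamma=gamma,
            )
            obs = generate_observations(land, params, competitor=gb, seed=seed)
            codes = land.class_at(obs["x_m"].to_numpy(), obs["y_m"].to_numpy())
            vals.append((codes == 0).mean())
        return float(np.mean(vals))

    def test_displacement_lowers_cereal_use(self, mixed_landscape, gb_field):
        seeds = range(100)
        off = self._cereal_use(mixed_landscape, 0.0, gb_field, seeds)
        on = self._cereal_use(mixed_landscape, 0.5, gb_field, seeds)
        assert on < off

    def test_monotone_in_gamma_and_competitor_density(self, mixed_landscape, gb_field):
        seeds = range(40)
        # gamma grid at fixed competitor field
        use = [self._cereal_use(mixed_landscape, g, gb_field, seeds)
               for g in (0.0, 0.5, 2.0)]
        assert use[0] >= use[1] - 0.01 and use[1] >= use[2] - 0.01
        # competitor-density grid at fixed gamma (scale flock sizes)
        dens_use = []
        for mult in (0, 1, 3):
            gb = gb_field.copy()
            gb["count"] = gb["count"] * mult
            gb = gb[gb["count"] > 0]
            dens_use.append(self._cereal_use(mixed_landscape, 0.5, gb, seeds))
        assert dens_use[0] >= dens_use[1] - 0.01 >= dens_use[2] - 0.02


class TestStudyDesign:
    def test_default_design_structure(self):
        design = default_design(0)
        assert len(design.site_years) == 26
        sites = {sy.site for sy in design.site_years}
        assert len(sites) == 9
        gb_free = {
            s for s in sites
            if all(
                p.n_points == 0
                for sy in design.site_years if sy.site == s
                for p in sy.species_params if p.species == "great_bustard"
            )
        }
        assert len(gb_free) == 3
        for sy in design.site_years:
            lb = next(p for p in sy.species_params if p.species == "little_bustard")
            assert 10 <= lb.n_points <= 174

    def test_default_study_counts(self):
        study = generate_study(default_design(4))
        obs = study.observations
        assert len(study.landscapes) == 26
        by = obs.groupby(["site", "year", "species"]).size()
        gb_birds = obs[obs.species == "great_bustard"].groupby(["site", "year"])["count"].sum()
        assert gb_birds.max() <= 174
        lb_per_sy = by.xs("little_bustard", level="species")
        assert lb_per_sy.between(10, 174).all()
        # exactly 3 sites with zero GB observations in all their years
        gb_by_site = (
            obs[obs.species == "great_bustard"].groupby("site").size()
            .reindex(sorted({s for s, _ in study.landscapes}), fill_value=0)
        )
        assert (gb_by_site == 0).sum() == 3

    def test_duplicate_site_year_rejected(self):
        sy = default_design(0).site_years
        with pytest.raises(DesignError):
            StudyDesign(site_years=(sy[0], sy[0]), master_seed=0)

    def test_single_site_year_design(self):
        design = StudyDesign(site_years=(default_design(0).site_years[0],))
        study = generate_study(design)
        assert len(study.landscapes) == 1

    def test_master_seed_reproducibility_byte_identical(self):
        a = generate_study(default_design(123)).observations.to_csv(index=False)
        b = generate_study(default_design(123)).observations.to_csv(index=False)
        assert a == b

    def test_different_master_seeds_differ(self):
        a = generate_study(default_design(1)).observations
        b = generate_study(default_design(2)).observations
        assert not a.equals(b)

    def test_child_seed_stable_and_bounded(self):
        s = child_seed(42, "S1", 2010, "land")
        assert s == child_seed(42, "S1", 2010, "land")
        assert 0 <= s < 2**31 - 1
        assert s != child_seed(42, "S1", 2011, "land")
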