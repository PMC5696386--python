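import numpy as np
import pytest

from nichekde.synth import (
    HABITAT_CLASSES,
    Landscape,
    LandscapeConfig,
    SiteYearSpec,
    SpeciesParams,
    StudyDesign,
    generate_landscape,
)

MIX_EXAMPLE = (0.35, 0.15, 0.05, 0.20, 0.15, 0.05, 0.05)

LB_PREF = (1.0, 0.1, 1.5, 2.0, 2.0, 0.2, 0.05)
GB_PREF = (1.0, 1.0, 1.2, 1.0, 0.8, 0.3, 0.05)


def small_design(master_seed=0, gb_points=(12, 12, 2, 0)):
    """Small two-site study; one entry per site-year, sites alternate A/B
    and years advance every second entry."""
    site_years = []
    for i, n_gb in enumerate(gb_points):
        site = "AB"[i % 2]
        year = 2010 + i // 2
        lb = SpeciesParams(species="little_bustard", n_points=40,
                           preference=LB_PREF, clustering_m=300.0)
        gb = SpeciesParams(species="great_bustard", n_points=n_gb,
                           group_size_mean=4.0, preference=GB_PREF,
                           clustering_m=250.0)
        site_years.append(
            SiteYearSpec(site=site, year=year,
                         landscape=LandscapeConfig(width_m=3000, height_m=3000),
                         species_params=(lb, gb))
        )
    return StudyDesign(site_years=tuple(site_years), master_seed=master_seed)


@pytest.fixture(scope="session")
def mixed_landscape() -> Landscape:
    """A 3 km mosaic with every habitat class present."""
    return generate_landscape(
        LandscapeConfig(width_m=3000, height_m=3000, field_size_m=100,
                        habitat_mix=MIX_EXAMPLE, seed=42)
    )


@pytest.fixture()
def halfplane_landscape() -> Landscape:
    """Left half cereal, right half young fallow, 100 m fields."""
    labels = np.zeros((20, 20), dtype=np.int8)
    labels[:, 10:] = HABITAT_CLASSES.index("young_fallow")
    return Landscape(labels=labels, field_size_m=100.0, width_m=2000.0, height_m=2000.0)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
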