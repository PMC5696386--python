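"""Synthetic farmland landscapes and bustard observation sets.

This module emulates the kind of data the analysis consumes: a mosaic of
rectangular agricultural fields labelled with one of seven habitat classes,
and two species of steppe birds observed on it —

* little bustard (*Tetrax tetrax*): displaying males, one bird per
  observation, loosely clustered (exploded-lek structure), preferring
  semi-permanent substrates (fallows, natural vegetation, legumes) with
  cereal as a secondary habitat;
* great bustard (*Otis tarda*): mixed-sex flocks, strong conspecific
  attraction, little marked preference among the main agrarian habitats.

An optional density-dependent displacement mechanism suppresses the little
bustard's cereal weight where local great bustard density is high and
transfers the suppressed preference mass to the species' primary habitat
(natural vegetation), mimicking asymmetric interspecific competition that
pushes birds out of the shared secondary habitat and back into their
preferred one.  The exponential form ``w_cereal * exp(-gamma * D_local)``
is a synthetic stand-in: no quantitative interaction kernel is available
for these species, only the qualitative fact of displacement out of
cereals toward the primary habitat.

All randomness flows through :class:`numpy.random.Generator` objects seeded
deterministically, so any study is byte-reproducible from one master seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

HABITAT_CLASSES: tuple[str, ...] = (
    "cereal",
    "ploughed",
    "legume",
    "young_fallow",
    "natural_vegetation",
    "dry_woody",
    "other",
)
N_HABITATS = len(HABITAT_CLASSES)

SPECIES = ("little_bustard", "great_bustard")

#: radius (m) within which competitor individuals count toward local density
LOCAL_DENSITY_RADIUS_M = 500.0

OBS_COLUMNS = ["site", "year", "species", "x_m", "y_m", "count"]


class InvalidConfigError(ValueError):
    """A landscape / species / design configuration violates an invariant."""


class UnsatisfiablePreferenceError(ValueError):
    """Every habitat present in the landscape has zero preference weight."""


class DesignError(ValueError):
    """A study design is inconsistent (e.g. duplicate site-year keys)."""


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LandscapeConfig:
    """Rectangular mosaic of fields with a fixed habitat class mixture.

    Parameters
    ----------
    width_m, height_m
        Landscape extent in metres.
    field_size_m
        Mean field edge length; the tessellation is a regular grid of
        square fields of this size.
    habitat_mix
        Seven nonnegative proportions over :data:`HABITAT_CLASSES`,
        summing to 1.  The default mix puts cereal + ploughed at ~50% of
        the surface, as in extensive Iberian cereal farmland.
    seed
        Integer seed controlling the field labelling.
    """

    width_m: float = 4000.0
    height_m: float = 4000.0
    #: typical dryland parcel (2.25 ha); a 100 m-radius buffer then spans
    #: only one or a few fields, as in real parcel mosaics
    field_size_m: float = 150.0
    habitat_mix: tuple[float, ...] = (0.35, 0.15, 0.05, 0.20, 0.15, 0.05, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.width_m > 0 and self.height_m > 0):
            raise InvalidConfigError("landscape extent must be positive")
        if not self.field_size_m > 0:
            raise InvalidConfigError("field_size_m must be positive")
        mix = np.asarray(self.habitat_mix, dtype=float)
        if mix.shape != (N_HABITATS,):
            raise InvalidConfigError(
                f"habitat_mix must have exactly {N_HABITATS} entries"
            )
        if (mix < 0).any():
            raise InvalidConfigError("habitat_mix proportions must be nonnegative")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise InvalidConfigError("habitat_mix must sum to 1 (tol 1e-9)")


@dataclass(frozen=True)
class SpeciesParams:
    """Sampling model for one species' observations on a landscape.

    ``preference`` holds relative per-unit-area habitat weights (not
    probabilities); sampling probability is proportional to the weight of
    the habitat under each candidate location.  ``clustering_m > 0``
    switches on a Thomas-process structure (Gaussian scatter of points
    around Poisson parents).  ``displacement_gamma`` only acts for the
    little bustard: the cereal weight is multiplied by
    ``exp(-gamma * local_competitor_density)`` (density in
    individuals / km^2 inside a 500 m radius) and the suppressed
    preference mass is added to the natural-vegetation weight.
    """

    species: str
    n_points: int
    group_size_mean: float = 1.0
    preference: tuple[float, ...] = (1.0,) * N_HABITATS
    clustering_m: float = 0.0
    displacement_gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise InvalidConfigError(f"unknown species {self.species!r}")
        if self.n_points < 0:
            raise InvalidConfigError("n_points must be >= 0")
        if self.group_size_mean < 1:
            raise InvalidConfigError("group_size_mean must be >= 1")
        pref = np.asarray(self.preference, dtype=float)
        if pref.shape != (N_HABITATS,):
            raise InvalidConfigError(
                f"preference must have exactly {N_HABITATS} weights"
            )
        if (pref < 0).any() or not pref.any():
            raise InvalidConfigError("preference weights must be nonnegative, not all zero")
        if self.displacement_gamma < 0:
            raise InvalidConfigError("displacement_gamma must be >= 0")
        if self.displacement_gamma > 0 and self.species != "little_bustard":
            raise InvalidConfigError(
                "displacement_gamma applies to the little bustard only"
            )


@dataclass(frozen=True)
class SiteYearSpec:
    site: str
    year: int
    landscape: LandscapeConfig
    species_params: tuple[SpeciesParams, ...]


@dataclass(frozen=True)
class StudyDesign:
    """A multi-site, multi-year study layout plus a master seed."""

    site_years: tuple[SiteYearSpec, ...]
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.site_years) == 0:
            raise DesignError("a study design needs at least one site-year")
        keys = [(sy.site, sy.year) for sy in self.site_years]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise DesignError(f"duplicate (site, year) keys in design: {dupes}")


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Landscape:
    """A rectangular grid of square fields, each with one habitat class.

    ``labels[j, i]`` is the integer habitat code of the field in column i
    (x direction) and row j (y direction); codes index
    :data:`HABITAT_CLASSES`.  Coordinates are planar metres with the
    origin at the lower-left corner.
    """

    labels: np.ndarray  # (ny, nx) int8
    field_size_m: float
    width_m: float
    height_m: float

    @property
    def nx(self) -> int:
        return self.labels.shape[1]

    @property
    def ny(self) -> int:
        return self.labels.shape[0]

    def in_extent(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= 0) & (x <= self.width_m) & (y >= 0) & (y <= self.height_m)

    def class_at(self, x, y) -> np.ndarray:
        """Integer habitat code under each (x, y); -1 outside the extent."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        inside = self.in_extent(x, y)
        i = np.clip((x / self.field_size_m).astype(int), 0, self.nx - 1)
        j = np.clip((y / self.field_size_m).astype(int), 0, self.ny - 1)
        out = np.where(inside, self.labels[j, i], -1)
        return out.astype(np.int16)

    def cover_proportions(self) -> np.ndarray:
        """Realized area fraction of each habitat class (exact, since the
        grid tiles the extent up to boundary truncation of the last
        row/column, which carries the same class distribution)."""
        # area-weight fields clipped at the extent boundary
        xs = np.minimum((np.arange(self.nx) + 1) * self.field_size_m, self.width_m) - np.arange(
            self.nx
        ) * self.field_size_m
        ys = np.minimum((np.arange(self.ny) + 1) * self.field_size_m, self.height_m) - np.arange(
            self.ny
        ) * self.field_size_m
        areas = np.outer(ys, xs)
        total = areas.sum()
        props = np.array(
            [areas[self.labels == k].sum() for k in range(N_HABITATS)], dtype=float
        )
        return props / total

    def field_polygons(self):
        """Yield (shapely box, habitat code) per field, clipped to extent."""
        from shapely.geometry import box

        fs = self.field_size_m
        for j in range(self.ny):
            for i in range(self.nx):
                x0, y0 = i * fs, j * fs
                x1 = min(x0 + fs, self.width_m)
                y1 = min(y0 + fs, self.height_m)
                yield box(x0, y0, x1, y1), int(self.labels[j, i])


def generate_landscape(cfg: LandscapeConfig) -> Landscape:
    """Tessellate the extent into square fields and label them i.i.d.
    from ``habitat_mix``.  Deterministic given ``cfg.seed``."""
    nx = max(1, int(np.ceil(cfg.width_m / cfg.field_size_m)))
    ny = max(1, int(np.ceil(cfg.height_m / cfg.field_size_m)))
    rng = np.random.default_rng(cfg.seed)
    labels = rng.choice(N_HABITATS, size=(ny, nx), p=np.asarray(cfg.habitat_mix))
    return Landscape(
        labels=labels.astype(np.int8),
        field_size_m=cfg.field_size_m,
        width_m=cfg.width_m,
        height_m=cfg.height_m,
    )


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------


def _local_density_per_km2(
    x: np.ndarray, y: np.ndarray, competitor: pd.DataFrame | None
) -> np.ndarray:
    """Competitor individuals within LOCAL_DENSITY_RADIUS_M, per km^2."""
    if competitor is None or len(competitor) == 0:
        return np.zeros_like(np.asarray(x, dtype=float))
    cx = competitor["x_m"].to_numpy(dtype=float)
    cy = competitor["y_m"].to_numpy(dtype=float)
    cw = competitor["count"].to_numpy(dtype=float)
    d2 = (x[:, None] - cx[None, :]) ** 2 + (y[:, None] - cy[None, :]) ** 2
    within = d2 <= LOCAL_DENSITY_RADIUS_M**2
    counts = within @ cw
    area_km2 = np.pi * (LOCAL_DENSITY_RADIUS_M / 1000.0) ** 2
    return counts / area_km2


def generate_observations(
    landscape: Landscape,
    params: SpeciesParams,
    competitor: pd.DataFrame | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample ``params.n_points`` observation locations on the landscape.

    Locations are drawn with probability proportional to the effective
    habitat weight of the containing field (rejection sampling); with
    ``clustering_m > 0`` candidate locations come from a Thomas cluster
    process instead of a uniform proposal.  Individual counts are 1 for
    the little bustard and shifted-Poisson (mean ``group_size_mean``)
    flocks for the great bustard.

    Returns a DataFrame with columns species, x_m, y_m, count.
    """
    pref = np.asarray(params.preference, dtype=float)
    present = np.unique(landscape.labels)
    if not pref[present].any():
        raise UnsatisfiablePreferenceError(
            "every habitat present in the landscape has zero preference weight"
        )
    rng = np.random.default_rng(seed)
    n = params.n_points
    if n == 0:
        return pd.DataFrame(
            {"species": pd.Series([], dtype=str)}
            | {c: pd.Series([], dtype=float) for c in ("x_m", "y_m")}
            | {"count": pd.Series([], dtype=int)}
        )

    use_displacement = (
        params.displacement_gamma > 0 and params.species == "little_bustard"
    )
    # Displaced birds resettle in the primary habitat (natural
    # vegetation, code 4): a candidate that would have settled in cereal
    # is displaced with probability 1 - exp(-gamma * local GB density)
    # and then placed in a uniformly chosen natural-vegetation field.
    # Pro-rata redistribution instead of resettlement would split the
    # displaced birds evenly between fallows and natural vegetation and
    # erase the directional niche shift displacement is meant to encode.
    nv_fields = None
    if use_displacement and pref[4] > 0:
        jj, ii = np.where(landscape.labels == 4)
        if len(ii) > 0:
            nv_fields = (ii, jj)

    # Thomas-process parents (cluster centres); each accepted point keeps
    # its parent so rejected proposals are redrawn around the same centre.
    if params.clustering_m > 0:
        mean_per_parent = 5.0
        n_parents = max(1, int(np.round(n / mean_per_parent)))
        px = rng.uniform(0, landscape.width_m, n_parents)
        py = rng.uniform(0, landscape.height_m, n_parents)
        parent_of = rng.integers(0, n_parents, size=n)
    else:
        parent_of = None

    xs = np.empty(n)
    ys = np.empty(n)
    pending = np.arange(n)
    w_max = pref.max()
    max_rounds = 2000
    for _ in range(max_rounds):
        m = len(pending)
        if m == 0:
            break
        if parent_of is None:
            cand_x = rng.uniform(0, landscape.width_m, m)
            cand_y = rng.uniform(0, landscape.height_m, m)
        else:
            p = parent_of[pending]
            cand_x = px[p] + rng.normal(0, params.clustering_m, m)
            cand_y = py[p] + rng.normal(0, params.clustering_m, m)
            oob = ~landscape.in_extent(cand_x, cand_y)
            if oob.any():
                # out-of-extent cluster offspring: re-anchor to a fresh parent
                parent_of[pending[oob]] = rng.integers(0, len(px), oob.sum())
        inside = landscape.in_extent(cand_x, cand_y)
        codes = landscape.class_at(cand_x, cand_y)
        w = np.where(inside, pref[np.clip(codes, 0, N_HABITATS - 1)], 0.0)
        accept = rng.uniform(0, w_max, m) < w
        displaced = np.zeros(m, dtype=bool)
        if use_displacement:
            in_cereal = accept & (codes == 0)
            if in_cereal.any():
                dens = _local_density_per_km2(cand_x, cand_y, competitor)
                stay_p = np.exp(-params.displacement_gamma * dens)
                pushed = in_cereal & (rng.uniform(0, 1, m) >= stay_p)
                if nv_fields is not None:
                    displaced = pushed
                else:
                    # no primary habitat mapped: displaced birds are
                    # simply rejected and resample pro rata
                    accept &= ~pushed
        if displaced.any():
            k = int(displaced.sum())
            fi = rng.integers(0, len(nv_fields[0]), k)
            fs = landscape.field_size_m
            cand_x[displaced] = np.minimum(
                (nv_fields[0][fi] + rng.uniform(0, 1, k)) * fs, landscape.width_m
            )
            cand_y[displaced] = np.minimum(
                (nv_fields[1][fi] + rng.uniform(0, 1, k)) * fs, landscape.height_m
            )
        idx = pending[accept]
        xs[idx] = cand_x[accept]
        ys[idx] = cand_y[accept]
        pending = pending[~accept]
    else:
        raise UnsatisfiablePreferenceError(
            "rejection sampling failed to place all points; preference weights "
            "may be (almost) zero on the available habitat"
        )

    if params.species == "little_bustard":
        counts = np.ones(n, dtype=int)
    else:
        counts = 1 + rng.poisson(params.group_size_mean - 1.0, size=n)
    return pd.DataFrame(
        {
            "species": params.species,
            "x_m": xs,
            "y_m": ys,
            "count": counts.astype(int),
        }
    )


# ---------------------------------------------------------------------------
# study-level generation
# ---------------------------------------------------------------------------


def child_seed(master_seed: int, site: str, year: int, tag: str = "") -> int:
    """Stable per-site-year seed derived from the master seed (< 2^31)."""
    h = hashlib.sha256(f"{master_seed}|{site}|{year}|{tag}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass(frozen=True)
class StudyData:
    """One generated study: a landscape per site-year plus a tidy
    observation table (columns: site, year, species, x_m, y_m, count)."""

    design: StudyDesign
    landscapes: dict
    observations: pd.DataFrame

    def site_years(self) -> list[tuple[str, int]]:
        return [(sy.site, sy.year) for sy in self.design.site_years]


def generate_study(design: StudyDesign) -> StudyData:
    """Generate landscapes and both species' observations per site-year.

    The great bustard is always generated first within a site-year so it
    can act as the competitor field for the little bustard's displacement
    term.  Fully reproducible from ``design.master_seed``.
    """
    landscapes: dict = {}
    frames: list[pd.DataFrame] = []
    for sy in design.site_years:
        lcfg = replace(sy.landscape, seed=child_seed(design.master_seed, sy.site, sy.year, "land"))
        land = generate_landscape(lcfg)
        landscapes[(sy.site, sy.year)] = land
        params_by_species = {p.species: p for p in sy.species_params}
        gb_obs = None
        ordered = [s for s in ("great_bustard", "little_bustard") if s in params_by_species]
        for sp in ordered:
            p = params_by_species[sp]
            obs = generate_observations(
                land,
                p,
                competitor=gb_obs if sp == "little_bustard" else None,
                seed=child_seed(design.master_seed, sy.site, sy.year, sp),
            )
            if sp == "great_bustard":
                gb_obs = obs
            obs = obs.copy()
            obs.insert(0, "site", sy.site)
            obs.insert(1, "year", sy.year)
            frames.append(obs)
    observations = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=OBS_COLUMNS)
    )
    observations = observations[OBS_COLUMNS]
    return StudyData(design=design, landscapes=landscapes, observations=observations)


# ---------------------------------------------------------------------------
# default design: 9 sites, 26 site-years, 3 great-bustard-free sites
# ---------------------------------------------------------------------------

#: little bustard preference: semi-permanent substrates first, cereal second
LB_PREFERENCE = (1.0, 0.10, 1.5, 2.0, 2.0, 0.20, 0.05)
#: great bustard: weak preferences among main agrarian habitats
GB_PREFERENCE = (1.0, 1.0, 1.2, 1.0, 0.8, 0.30, 0.05)

LB_CLUSTERING_M = 400.0
GB_CLUSTERING_M = 250.0
GB_GROUP_SIZE_MEAN = 4.0
#: calibrated so a typical flock (4 birds => 5.1 birds/km^2 within 500 m)
#: suppresses local cereal use by ~92%, i.e. little bustards essentially
#: cease to use cereal inside the interaction radius of foraging great
#: bustards, as described for these species
DEFAULT_DISPLACEMENT_GAMMA = 0.5

# (site, years, extent_m, LB points per year, GB individuals per year)
# Magnitudes follow the field protocol this package emulates: LB observations 10-174,
# GB individuals 0-142 per site-year; three sites never hold great bustards;
# one further site-year has zero great bustards, and several sympatric
# site-years keep GB below the 10-individual niche gate.
_DEFAULT_SITES = (
    ("S1", (2010, 2011, 2012), 4200, (45, 50, 48), (60, 65, 58)),
    ("S2", (2010, 2011), 3500, (15, 14), (115, 125)),
    ("S3", (2010,), 3200, (12,), (40,)),
    ("S4", (2006,), 9000, (22,), (140,)),
    ("S5", (2007, 2008, 2009, 2010, 2011), 4800, (40, 44, 42, 38, 41), (5, 42, 46, 8, 3)),
    ("S6", (2007, 2008, 2009, 2010, 2011), 4900, (52, 55, 50, 57, 54), (5, 4, 6, 0, 4)),
    ("S7", (2010, 2011), 5400, (35, 42), (0, 0)),
    ("S8", (2008, 2009, 2010, 2011), 4400, (70, 75, 72, 68), (0, 0, 0, 0)),
    ("S9", (2008, 2010, 2011), 6700, (120, 128, 134), (0, 0, 0)),
)


def _site_year_mix(rng: np.random.Generator) -> tuple[float, ...]:
    """Habitat mix for one site-year.

    Cereal cover and the split of the unsown rotational land between
    ploughed management and young fallow vary across site-years (they
    are alternative states of the same 2-year-rotation substrate), and
    legumes are grown in only some sites and years.  Natural vegetation,
    woody cultures and minor substrates are stable.  Cereal + ploughed
    average ~50% of the surface.
    """
    cereal = rng.uniform(0.26, 0.40)
    legume = 0.05 if rng.uniform() < 0.6 else 0.0
    natveg, woody, other = 0.10, 0.05, 0.05
    unsown = 1.0 - cereal - legume - natveg - woody - other
    split = rng.uniform(0.25, 0.75)
    ploughed = unsown * split
    young_fallow = unsown * (1.0 - split)
    return (cereal, ploughed, legume, young_fallow, natveg, woody, other)


def default_design(
    master_seed: int = 0, displacement_gamma: float = DEFAULT_DISPLACEMENT_GAMMA
) -> StudyDesign:
    """The default 26-site-year, 9-site study design.

    Three sites (S7-S9) never hold great bustards and one S6 year has
    none, so 16 site-years are sympatric and 10 allopatric.  Set
    ``displacement_gamma=0`` for the no-competition null.
    """
    site_years = []
    for site, years, extent, lb_counts, gb_birds in _DEFAULT_SITES:
        for year, n_lb, n_gb_birds in zip(years, lb_counts, gb_birds):
            mix_rng = np.random.default_rng(child_seed(master_seed, site, year, "mix"))
            lcfg = LandscapeConfig(
                width_m=extent, height_m=extent, field_size_m=150.0,
                habitat_mix=_site_year_mix(mix_rng),
            )
            lb = SpeciesParams(
                species="little_bustard",
                n_points=n_lb,
                preference=LB_PREFERENCE,
                clustering_m=LB_CLUSTERING_M,
                displacement_gamma=displacement_gamma,
            )
            n_gb_points = int(np.round(n_gb_birds / GB_GROUP_SIZE_MEAN))
            gb = SpeciesParams(
                species="great_bustard",
                n_points=n_gb_points,
                group_size_mean=GB_GROUP_SIZE_MEAN,
                preference=GB_PREFERENCE,
                clustering_m=GB_CLUSTERING_M,
            )
            site_years.append(
                SiteYearSpec(site=site, year=year, landscape=lcfg, species_params=(lb, gb))
            )
    return StudyDesign(site_years=tuple(site_years), master_seed=master_seed)
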