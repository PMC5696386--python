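"""Pipeline configuration with validation and YAML round-tripping.

Defaults follow the published field protocol: 100 m buffers, at least 30
random availability points, 95% highest-density regions, and a gate of 10
observed birds (five per niche dimension) before a KDE is estimated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

VALID_AXIS_PAIRS = ("PC1-PC2", "PC1-PC3", "PC2-PC3")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass(frozen=True)
class PipelineConfig:
    buffer_radius_m: float = 100.0
    raster_cell_m: float = 10.0
    min_random_points: int = 30
    grid_resolution: int = 151
    grid_padding: float = 0.15
    hdr_level: float = 0.95
    axis_pairs: tuple[str, ...] = VALID_AXIS_PAIRS
    #: minimum weighted individuals for a species' site-year KDE
    min_observations: int = 10
    #: minimum observation points for the plug-in bandwidth (5 per dimension)
    min_points: int = 10
    pca_mode: str = "covariance"
    n_axes: int = 3
    compute_overlap: bool = True
    overlap_mode: str = "full"
    #: manual KDE exclusions: (site, year, axis_pair) triples
    exclusions: tuple[tuple[str, int, str], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.hdr_level <= 1:
            raise ConfigError(f"hdr_level must be in (0, 1], got {self.hdr_level}")
        if self.grid_padding < 0:
            raise ConfigError("grid_padding must be >= 0")
        if self.grid_resolution < 32:
            raise ConfigError("grid_resolution must be >= 32")
        if self.buffer_radius_m <= 0 or self.raster_cell_m <= 0:
            raise ConfigError("buffer radius and raster cell must be positive")
        if self.min_random_points < 1:
            raise ConfigError("min_random_points must be >= 1")
        if self.pca_mode not in ("covariance", "correlation"):
            raise ConfigError("pca_mode must be 'covariance' or 'correlation'")
        if self.overlap_mode not in ("full", "hdr_union"):
            raise ConfigError("overlap_mode must be 'full' or 'hdr_union'")
        if not 1 <= self.n_axes <= 7:
            raise ConfigError("n_axes must be between 1 and 7")
        for ap in self.axis_pairs:
            i, j = axis_pair_indices(ap)
            if j >= self.n_axes:
                raise ConfigError(f"axis pair {ap} needs more axes than n_axes={self.n_axes}")
        for exc in self.exclusions:
            if len(exc) != 3 or exc[2] not in self.axis_pairs:
                raise ConfigError(f"malformed exclusion {exc!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["axis_pairs"] = list(self.axis_pairs)
        d["exclusions"] = [list(e) for e in self.exclusions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "axis_pairs" in d:
            d["axis_pairs"] = tuple(d["axis_pairs"])
        if "exclusions" in d:
            d["exclusions"] = tuple(tuple(e) for e in d["exclusions"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def axis_pair_indices(axis_pair: str) -> tuple[int, int]:
    """'PC1-PC3' -> (0, 2)."""
    try:
        a, b = axis_pair.split("-")
        i, j = int(a[2:]) - 1, int(b[2:]) - 1
    except Exception as e:  # noqa: BLE001
        raise ConfigError(f"malformed axis pair {axis_pair!r}") from e
    if not (0 <= i < j):
        raise ConfigError(f"axis pair {axis_pair!r} must name increasing axes")
    return i, j


def axis_pair_slug(axis_pair: str) -> str:
    return axis_pair.replace("-", "_").lower()
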