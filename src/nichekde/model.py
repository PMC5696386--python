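"""End-to-end niche-shift analysis as a model/results pair.

:class:`NicheShiftModel` holds the raw inputs (observation table,
landscape per site-year, configuration); :meth:`NicheShiftModel.fit` runs
the whole chain — used-area delimitation, availability sampling, buffer
composition, pooled PCA, shared-grid weighted KDEs with their 95%
highest-density regions, niche statistics, and the three mixed-model
designs — and returns a :class:`NicheShiftResults` carrying every table
the analysis produces plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference, kde, nichespace, spatial, synth
from .config import PipelineConfig, axis_pair_indices, axis_pair_slug


@dataclass
class GateDecision:
    site: str
    year: int
    species: str
    axis_pair: str
    reason: str


class NicheShiftModel:
    """Habitat-niche shift analysis for two potentially competing species.

    Parameters
    ----------
    observations
        Tidy table with columns site, year, species, x_m, y_m, count.
    landscapes
        Mapping (site, year) -> :class:`nichekde.synth.Landscape`.
    config
        :class:`nichekde.config.PipelineConfig`; defaults follow the
        field protocol the synthetic generator emulates.
    """

    def __init__(
        self,
        observations: pd.DataFrame,
        landscapes: dict,
        config: PipelineConfig | None = None,
    ):
        missing = [c for c in synth.OBS_COLUMNS if c not in observations.columns]
        if missing:
            raise ValueError(f"observation table lacks columns: {missing}")
        self.observations = observations.reset_index(drop=True)
        self.landscapes = landscapes
        self.config = config or PipelineConfig()
        keys = {(s, y) for s, y in zip(observations["site"], observations["year"])}
        lacking = sorted(k for k in keys if k not in landscapes)
        if lacking:
            raise ValueError(f"no landscape provided for site-years: {lacking}")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_study(cls, study: synth.StudyData, config: PipelineConfig | None = None):
        return cls(study.observations, study.landscapes, config)

    @classmethod
    def from_design(
        cls, design: synth.StudyDesign, config: PipelineConfig | None = None
    ):
        return cls.from_study(synth.generate_study(design), config)

    @classmethod
    def from_csv(
        cls,
        observations_path,
        landscape_paths: dict,
        config: PipelineConfig | None = None,
    ):
        from .io import read_landscape, read_observations

        obs = read_observations(observations_path)
        landscapes = {key: read_landscape(p) for key, p in landscape_paths.items()}
        return cls(obs, landscapes, config)

    # -- fitting ----------------------------------------------------------

    def fit(self, models: bool = True, store_densities: bool = False):
        """Run the full pipeline; ``models=False`` stops after the niche
        metrics (useful for partial runs and small fixtures)."""
        cfg = self.config
        site_years = sorted(
            {(s, int(y)) for s, y in zip(self.observations["site"], self.observations["year"])}
        )

        # 1. spatial stage: MCP, availability points, buffer composition
        comp_frames, mcps, density_rows = [], {}, []
        for site, year in site_years:
            obs = self.observations[
                (self.observations["site"] == site) & (self.observations["year"] == year)
            ]
            comp, mcp = spatial.composition_rows(
                obs,
                self.landscapes[(site, year)],
                site,
                year,
                seed=synth.child_seed(cfg.seed, site, year, "availability"),
                radius=cfg.buffer_radius_m,
                cell=cfg.raster_cell_m,
                min_random=cfg.min_random_points,
            )
            comp_frames.append(comp)
            mcps[(site, year)] = mcp
            lb_d = inference.site_density(obs, mcp.area_km2, "little_bustard")
            gb_d = inference.site_density(obs, mcp.area_km2, "great_bustard")
            density_rows.append(
                {
                    "site": site,
                    "year": year,
                    "mcp_area_km2": mcp.area_km2,
                    "lb_density": lb_d,
                    "gb_density": gb_d,
                    "gb_present": gb_d > 0,
                }
            )
        compositions = pd.concat(comp_frames, ignore_index=True)
        records = pd.DataFrame(density_rows)

        # 2. pooled ordination
        space = nichespace.fit_habitat_pca(
            compositions, k=cfg.n_axes, mode=cfg.pca_mode
        )
        scores = nichespace.project(space, compositions)

        # 3. KDEs per axis pair on a shared grid
        gate_log: list[GateDecision] = []
        metric_rows: list[dict] = []
        overlap_rows: list[dict] = []
        densities: dict = {}
        grids: dict[str, kde.Grid2D] = {}
        for ap in cfg.axis_pairs:
            i, j = axis_pair_indices(ap)
            ap_scores = scores[:, [i, j]]
            grid = kde.make_common_grid(
                ap_scores, resolution=cfg.grid_resolution, padding_fraction=cfg.grid_padding
            )
            grids[ap] = grid
            for site, year in site_years:
                in_sy = (compositions["site"] == site) & (compositions["year"] == year)
                groups = {
                    "little_bustard": in_sy & (compositions["origin"] == "bird_LB"),
                    "environment": in_sy & (compositions["origin"] == "random"),
                }
                if cfg.compute_overlap:
                    groups["great_bustard"] = in_sy & (compositions["origin"] == "bird_GB")
                fitted = {}
                for label, mask in groups.items():
                    pts = ap_scores[mask.to_numpy()]
                    wts = compositions.loc[mask, "weight"].to_numpy(dtype=float)
                    reason = self._gate_reason(label, site, year, ap, pts, wts)
                    if reason is not None:
                        gate_log.append(GateDecision(site, year, label, ap, reason))
                        continue
                    H = kde.plugin_bandwidth(
                        pts, wts, min_points=cfg.min_points,
                        context=f"{site} {year} {label} {ap}",
                    )
                    dg = kde.evaluate_kde(
                        pts, wts, H, grid, level=cfg.hdr_level,
                        axis_pair=ap, key=(site, year, label),
                    )
                    fitted[label] = dg
                    diag = kde.kde_diagnostics(dg)
                    pos = kde.niche_position(dg)
                    metric_rows.append(
                        {
                            "site": site,
                            "year": year,
                            "species": label,
                            "axis_pair": ap,
                            "breadth": kde.niche_breadth(dg),
                            "pos_dim1": pos[0],
                            "pos_dim2": pos[1],
                            "n_obs": dg.n_obs,
                            "total_weight": dg.total_weight,
                            **diag,
                        }
                    )
                    if store_densities:
                        densities[(site, year, label, ap)] = dg
                if cfg.compute_overlap:
                    if "little_bustard" in fitted and "great_bustard" in fitted:
                        ov = kde.niche_overlap(
                            fitted["little_bustard"],
                            fitted["great_bustard"],
                            mode=cfg.overlap_mode,
                        )
                        overlap_rows.append(
                            {"site": site, "year": year, "axis_pair": ap, "overlap": ov}
                        )

        metrics = pd.DataFrame(metric_rows)
        overlaps = pd.DataFrame(overlap_rows, columns=["site", "year", "axis_pair", "overlap"])

        # 4. wide site-year record table
        records = self._merge_metrics(records, metrics, overlaps)

        results = NicheShiftResults(
            model=self,
            config=cfg,
            niche_space=space,
            compositions=compositions,
            mcps=mcps,
            grids=grids,
            metrics=metrics,
            overlaps=overlaps,
            records=records,
            gate_log=pd.DataFrame([g.__dict__ for g in gate_log]),
            densities=densities,
        )
        if models:
            results.run_models()
        results._finalize_manifest()
        return results

    def _gate_reason(self, label, site, year, ap, pts, wts):
        cfg = self.config
        if (site, int(year), ap) in {(s, int(y), a) for s, y, a in cfg.exclusions}:
            return "manual_exclusion"
        if label == "environment":
            return None if len(pts) >= cfg.min_points else "too_few_random_points"
        if wts.sum() < cfg.min_observations:
            return f"fewer_than_{cfg.min_observations}_individuals"
        if len(pts) < cfg.min_points:
            return f"fewer_than_{cfg.min_points}_observation_points"
        return None

    @staticmethod
    def _merge_metrics(records, metrics, overlaps):
        out = records.copy()
        for _, row in metrics.iterrows():
            slug = axis_pair_slug(row["axis_pair"])
            prefix = {"little_bustard": "lb", "environment": "env", "great_bustard": "gb"}[
                row["species"]
            ]
            sel = (out["site"] == row["site"]) & (out["year"] == row["year"])
            out.loc[sel, f"{prefix}_breadth_{slug}"] = row["breadth"]
            out.loc[sel, f"{prefix}_pos1_{slug}"] = row["pos_dim1"]
            out.loc[sel, f"{prefix}_pos2_{slug}"] = row["pos_dim2"]
        for _, row in overlaps.iterrows():
            slug = axis_pair_slug(row["axis_pair"])
            sel = (out["site"] == row["site"]) & (out["year"] == row["year"])
            out.loc[sel, f"overlap_{slug}"] = row["overlap"]
        return out


@dataclass
class NicheShiftResults:
    """Everything the fitted analysis produced."""

    model: NicheShiftModel
    config: PipelineConfig
    niche_space: nichespace.NicheSpace
    compositions: pd.DataFrame
    mcps: dict
    grids: dict
    metrics: pd.DataFrame
    overlaps: pd.DataFrame
    records: pd.DataFrame
    gate_log: pd.DataFrame
    densities: dict = field(default_factory=dict)
    presence_results: dict = field(default_factory=dict)
    density_results: dict = field(default_factory=dict)
    overlap_results: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    # -- statistical stage -------------------------------------------------

    def run_models(
        self,
        axis_pairs=None,
        responses=("breadth", "pos_dim1", "pos_dim2"),
        compute_lrt: bool = True,
    ) -> None:
        cfg = self.config
        axis_pairs = list(axis_pairs or cfg.axis_pairs)
        self.presence_results = inference.shift_analysis_presence(
            self.records, axis_pairs, responses=responses, compute_lrt=compute_lrt
        )
        self.density_results = inference.shift_analysis_density(
            self.records, axis_pairs, responses=responses, compute_lrt=False
        )
        if cfg.compute_overlap and len(self.overlaps):
            pairs_with_overlap = [
                ap
                for ap in axis_pairs
                if f"overlap_{axis_pair_slug(ap)}" in self.records.columns
            ]
            if pairs_with_overlap:
                self.overlap_results = inference.overlap_analysis(
                    self.records, pairs_with_overlap, compute_lrt=False
                )

    # -- tables ------------------------------------------------------------

    @property
    def presence_table(self) -> pd.DataFrame:
        return inference.results_table(self.presence_results, "presence_vs_absence")

    @property
    def density_table(self) -> pd.DataFrame:
        return inference.results_table(self.density_results, "density_dependence")

    @property
    def overlap_table(self) -> pd.DataFrame:
        return inference.results_table(self.overlap_results, "overlap_vs_gb_density")

    def site_year_table(self) -> pd.DataFrame:
        """Study-layout summary: densities and MCP size per site-year."""
        cols = ["site", "year", "mcp_area_km2", "lb_density", "gb_density", "gb_present"]
        return self.records[cols].copy()

    # -- manifest / persistence ---------------------------------------------

    def _finalize_manifest(self) -> None:
        hasher = hashlib.md5()
        for df in (self.records, self.metrics, self.overlaps):
            hasher.update(df.to_csv(index=False).encode())
        self.manifest = {
            "config": self.config.to_dict(),
            "n_site_years": int(len(self.records)),
            "n_sympatric": int(self.records["gb_present"].sum()),
            "grid_hashes": {ap: g.hash() for ap, g in self.grids.items()},
            "explained_variance_pct": [
                round(float(v), 6) for v in self.niche_space.explained_variance_pct
            ],
            "gate_decisions": int(len(self.gate_log)),
            "content_hash": hasher.hexdigest(),
        }

    def save(self, outdir) -> None:
        """Write all artefact tables + manifest to a directory."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.compositions.to_csv(out / "compositions.csv", index=False)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.overlaps.to_csv(out / "overlaps.csv", index=False)
        self.records.to_csv(out / "records.csv", index=False)
        self.gate_log.to_csv(out / "gate_log.csv", index=False)
        self.niche_space.to_table().to_csv(out / "pca_loadings.csv")
        for name, table in (
            ("models_presence.csv", self.presence_results),
            ("models_density.csv", self.density_results),
            ("models_overlap.csv", self.overlap_results),
        ):
            if table:
                inference.results_table(table, name.removesuffix(".csv")).to_csv(
                    out / name, index=False
                )
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        buf = _io.StringIO()
        rec = self.records
        print("Habitat-niche shift analysis", file=buf)
        print("=" * 60, file=buf)
        print(
            f"site-years: {len(rec)}  "
            f"(sympatric {int(rec['gb_present'].sum())}, "
            f"allopatric {int((~rec['gb_present']).sum())})",
            file=buf,
        )
        ev = self.niche_space.explained_variance_pct
        print(
            "PCA explained variance (%): "
            + "  ".join(f"PC{i + 1} {v:.1f}" for i, v in enumerate(ev)),
            file=buf,
        )
        if len(self.overlaps):
            print("mean niche overlap by axis pair:", file=buf)
            for ap, v in self.overlaps.groupby("axis_pair")["overlap"].mean().items():
                n = int((self.overlaps["axis_pair"] == ap).sum())
                print(f"  {ap}: {v:.3f}  (n={n})", file=buf)
        for title, results in (
            ("presence/absence (ecological release)", self.presence_results),
            ("density dependence (sympatric)", self.density_results),
            ("overlap ~ GB density", self.overlap_results),
        ):
            if not results:
                continue
            print(f"\n{title}", file=buf)
            tbl = inference.results_table(results, title)
            with pd.option_context("display.width", 120, "display.precision", 3):
                cols = [c for c in ("niche", "response", "term", "estimate", "se", "t", "chi2", "p_wald", "p_lrt", "n") if c in tbl.columns]
                print(tbl[cols].to_string(index=False), file=buf)
        if len(self.gate_log):
            print(f"\ngate decisions ({len(self.gate_log)}):", file=buf)
            for _, g in self.gate_log.iterrows():
                print(
                    f"  {g['site']} {g['year']} {g['species']} {g['axis_pair']}: {g['reason']}",
                    file=buf,
                )
        return buf.getvalue()

    def plot_density(self, site, year, species, axis_pair, ax=None):
        """Diagnostic plot of one stored KDE with its HDR contour."""
        key = (site, year, species, axis_pair)
        if key not in self.densities:
            raise KeyError(
                "density not stored; refit with store_densities=True"
            )
        import matplotlib.pyplot as plt

        dg = self.densities[key]
        if ax is None:
            _, ax = plt.subplots()
        g = dg.grid
        ax.imshow(
            dg.density, origin="lower", extent=(g.xmin, g.xmax, g.ymin, g.ymax),
            aspect="auto", cmap="viridis",
        )
        ax.contour(
            g.x_centers, g.y_centers, dg.hdr_mask.astype(float), levels=[0.5],
            colors="white", linewidths=1.0,
        )
        px, py = kde.niche_position(dg)
        ax.plot(px, py, "ws", markersize=6, markerfacecolor="none")
        i, j = axis_pair.split("-")
        ax.set_xlabel(i)
        ax.set_ylabel(j)
        ax.set_title(f"{species} {site} {year} ({axis_pair})")
        return ax
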