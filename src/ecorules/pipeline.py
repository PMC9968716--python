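"""End-to-end orchestration: climate -> scaling -> ladders -> path models.

A run is described by a :class:`RunConfig` (buildable from YAML): either a
synthetic scenario block or paths to trees/traits/rasters/ranges.  The run
extracts per-species climate, builds the shape table, fits the Bergmann,
Allen and temperature candidate ladders, ranks the causal path models, and
(optionally) repeats the coefficient-level analyses across a set of trees,
reporting per-term coefficient quantiles.  All outputs are plain TSV/CSV
plus a JSON provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model_selection, path_analysis, scaling, spatial, synth
from .phylo import GLSContext, Phylogeny, read_trees
from .pgls import DesignSpec, fit_pgls

log = logging.getLogger("ecorules")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (scenario xor file inputs)."""

    # synthetic-scenario mode
    scenario: synth.SyntheticScenario | None = None
    simulate_world: bool = False
    grid_shape: tuple[int, int] = (90, 180)
    # file mode
    trees_path: str | None = None
    trees_format: str = "nexus"
    traits_path: str | None = None
    raster_paths: dict = field(default_factory=dict)   # var -> path
    ranges_path: str | None = None
    # analysis options
    scaling_method: str = "residual"
    climate_metric: str = "max_temp_all_months"
    climate_cols: list[str] | None = None
    response_transform: str = "reflect_log"
    controls: tuple[str, ...] = ()
    subset_by: str | None = None          # e.g. "migration"
    subset_min_size: int = 50
    n_trees: int = 1
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if (self.scenario is None) == (self.traits_path is None):
            raise ValueError(
                "exactly one of scenario or file inputs must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "scenario" in raw and raw["scenario"] is not None:
            sc = raw["scenario"]
            if isinstance(sc, dict):
                if "coefficients" in sc:
                    sc["coefficients"] = {
                        tuple(k.split("->")): (tuple(v) if isinstance(v, list)
                                               else v)
                        for k, v in sc["coefficients"].items()}
                raw["scenario"] = synth.SyntheticScenario(**sc)
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        if "controls" in raw:
            raw["controls"] = tuple(raw["controls"])
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        if d.get("scenario") is not None:
            d["scenario"]["coefficients"] = {
                "->".join(k): v
                for k, v in d["scenario"]["coefficients"].items()}
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Tables and provenance from one pipeline run."""

    tables: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            if isinstance(table, pd.DataFrame):
                table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        (outdir / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, default=str))


# ---------------------------------------------------------------------------


def _load_inputs(config: RunConfig):
    """Return (trees, traits, climate table or None)."""
    if config.scenario is not None:
        sc = config.scenario
        rng = sc.rng("trees")
        trees = [synth.simulate_tree(sc.n_tips, sc.birth_rate, rng)
                 for _ in range(max(1, config.n_trees))]
        traits, truth = synth.simulate_traits(trees[0], sc)
        climate = None
        if config.simulate_world:
            world = synth.simulate_world(traits, sc,
                                         grid_shape=config.grid_shape)
            filt = spatial.filter_ranges(world.ranges)
            agg = spatial.aggregate_season(filt.ranges)
            climate = spatial.species_climate(world.stacks, agg,
                                              crs=world.ranges.crs)
        return trees, traits, climate
    trees = read_trees(config.trees_path, config.trees_format)
    traits = pd.read_csv(config.traits_path,
                         sep="\t" if str(config.traits_path).endswith(".tsv")
                         else ",")
    traits, rejected = scaling.prepare_log_traits(traits)
    if len(rejected):
        log.warning("dropped %d trait rows with non-positive measurements",
                    len(rejected))
    climate = None
    if config.raster_paths and config.ranges_path:
        stacks = {var: spatial.MonthlyRasterStack.from_file(p)
                  for var, p in config.raster_paths.items()}
        ranges = spatial.RangePolygonSet.from_geojson(config.ranges_path)
        filt = spatial.filter_ranges(ranges)
        agg = spatial.aggregate_season(filt.ranges)
        climate = spatial.species_climate(stacks, agg, crs=ranges.crs)
    return trees, traits, climate


def _analysis_frame(config: RunConfig, tree: Phylogeny,
                    traits: pd.DataFrame, climate: pd.DataFrame | None
                    ) -> tuple[pd.DataFrame, list[str], GLSContext]:
    """Join traits with climate, prune to common species, build shapes."""
    df = traits.copy()
    if climate is not None:
        df = df.merge(climate, on="species", how="inner")
        cols = config.climate_cols or [c for c in spatial.METRICS
                                       if c in df.columns]
    else:
        cols = config.climate_cols or ["temperature"]
    df = df.dropna(subset=cols)
    common = sorted(set(df["species"]) & set(tree.tip_labels))
    if len(common) < len(tree.tip_labels) or len(common) < len(df):
        log.info("pruning to %d species shared by tree and data", len(common))
    tree = tree.prune_to(common) if len(common) < len(tree.tip_labels) else tree
    df = df[df["species"].isin(common)].reset_index(drop=True)
    ctx = GLSContext.from_tree(tree)
    shapes = scaling.shape_table(df, ctx, method=config.scaling_method)
    df = df.merge(shapes.drop(columns=["scaling_method"]), on="species")
    if "range_area_m2" in df.columns:
        df["log_range_area"] = np.log(df["range_area_m2"])
    return df, cols, ctx


def run(config: RunConfig) -> RunReport:
    """Execute the full analysis and return a report of tables."""
    report = RunReport()
    report.provenance = {"config_hash": config.config_hash(),
                         "seed": config.seed,
                         "scaling_method": config.scaling_method}
    trees, traits, climate = _load_inputs(config)
    df, climate_cols, ctx = _analysis_frame(config, trees[0], traits, climate)
    report.tables["species_data"] = df.drop(
        columns=[c for c in ("geometry",) if c in df.columns])

    # transformed temperature response
    metric = config.climate_metric if climate is not None else "temperature"
    transformed, meta = spatial.transform_response(
        df[metric].to_numpy(), method=config.response_transform)
    df["temp_response"] = transformed
    report.provenance["response_transform"] = meta

    try:
        lat_col = "abs_latitude" if "abs_latitude" in df.columns else None
        for family in ("bergmann", "allen_beak", "allen_tarsus"):
            cset = model_selection.build_phenotype_candidates(
                family, climate_cols, latitude_col=lat_col)
            ranked = model_selection.rank_models(cset, df, ctx,
                                                 controls=config.controls)
            report.tables[f"ladder_{family}"] = \
                model_selection.ladder_table(ranked)
        cset = model_selection.build_temperature_candidates()
        ranked = model_selection.rank_models(cset, df, ctx,
                                             controls=config.controls)
        report.tables["ladder_temperature"] = \
            model_selection.ladder_table(ranked)
    except Exception as exc:
        report.errors.append({"stage": "model_selection", "error": str(exc)})
        log.exception("model selection failed")

    try:
        if metric != "temperature":
            path_df = (df.drop(columns=["temperature"], errors="ignore")
                       .rename(columns={metric: "temperature"}))
        else:
            path_df = df
        for direction in ("phenotype_response", "temperature_response"):
            results = [path_analysis.fit_paths(dag, path_df, ctx)
                       for dag in path_analysis.candidate_dags(direction)]
            report.tables[f"paths_{direction}"] = \
                path_analysis.rank_paths(results)
            report.tables[f"path_coefficients_{direction}"] = pd.concat(
                [r.coefficients.assign(model=r.label) for r in results],
                ignore_index=True)
    except Exception as exc:
        report.errors.append({"stage": "path_analysis", "error": str(exc)})
        log.exception("path analysis failed")

    if config.subset_by:
        try:
            report.tables["subset_ladders"] = subset_analyses(
                config, df, ctx, climate_cols)
        except Exception as exc:
            report.errors.append({"stage": "subsets", "error": str(exc)})

    if config.n_trees > 1 and len(trees) >= config.n_trees:
        report.tables["tree_robustness"] = _tree_robustness(
            config, trees[:config.n_trees], traits, climate)

    if config.outdir:
        report.write(config.outdir)
    return report


def subset_analyses(config: RunConfig, df: pd.DataFrame, ctx,
                    climate_cols: list[str]) -> pd.DataFrame:
    """Refit the Bergmann ladder within each subset (e.g. migration class).

    Subsets below ``subset_min_size`` species are skipped with a log entry.
    """
    out = []
    for value, grp in df.groupby(config.subset_by):
        if len(grp) < config.subset_min_size:
            log.info("skipping subset %s=%s (n=%d below threshold)",
                     config.subset_by, value, len(grp))
            continue
        sub_ctx = model_selection._prune_context_tree(ctx, grp["species"])
        lat = "abs_latitude" if "abs_latitude" in grp.columns else None
        cset = model_selection.build_phenotype_candidates(
            "bergmann", climate_cols, latitude_col=lat)
        ranked = model_selection.rank_models(cset, grp, sub_ctx)
        tbl = model_selection.ladder_table(ranked)
        tbl.insert(0, "subset", value)
        out.append(tbl)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)


def _tree_robustness(config: RunConfig, trees, traits, climate
                     ) -> pd.DataFrame:
    """Refit the focal coefficient model on each tree; report quantiles.

    The focal model is the Bergmann regression of log mass on the chosen
    climate metric (or generated temperature); one coefficient row per
    term per tree, summarised with the median and 2.5/97.5% quantiles.
    """
    metric = ("temperature" if config.scenario is not None
              else config.climate_metric)
    rows = []
    for i, tree in enumerate(trees):
        if config.scenario is not None:
            sc_i = replace(config.scenario,
                           seed=int((config.scenario.seed + 7919 * (i + 1))
                                    % 2**31))
            traits_i, _ = synth.simulate_traits(tree, sc_i)
            df = traits_i
        else:
            df = traits
        common = sorted(set(df["species"]) & set(tree.tip_labels))
        t = tree.prune_to(common) if len(common) < len(tree.tip_labels) \
            else tree
        sub = df[df["species"].isin(common)]
        spec = DesignSpec(response="log_mass", fixed_terms=(metric,))
        fit = fit_pgls(sub, spec, t)
        for term, b in fit.beta.items():
            rows.append({"tree": i, "term": term, "estimate": float(b),
                         "lambda": fit.lambda_hat})
    per_tree = pd.DataFrame(rows)
    summary = (per_tree.groupby("term")["estimate"]
               .agg(median="median",
                    q025=lambda s: s.quantile(0.025),
                    q975=lambda s: s.quantile(0.975),
                    n_trees="count")
               .reset_index())
    summary.attrs["per_tree"] = per_tree
    return summary
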