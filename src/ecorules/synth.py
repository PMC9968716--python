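"""Synthetic trees, traits, rasters and range polygons.

The generator emulates the statistical structure of a global avian
comparative dataset: a Yule phylogeny; species temperature as a
lambda-model (phylogenetically correlated) trait; log body mass, log beak
and log tarsus lengths produced by a chosen causal structure among
{temperature, log_mass, log_beak, log_tarsus}; categorical migratory
habits; and toy monthly temperature rasters (latitudinal gradient plus a
hemisphere-phased seasonal cycle) overlaid with blob-shaped seasonal range
polygons placed so each species' range climate matches its generated
temperature.

Default allometric coefficients are the fitted global avian values
(log beak = 1.4345 + 0.3362 log mass; log tarsus = 2.1141 + 0.2883 log
mass, natural logs, mm vs g); the default mass distribution is centred on
the avian median of 35.5 g.  All outputs are deterministic under
(scenario, seed): one root seed spawns independent sub-streams per stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

from .phylo import GLSContext, Phylogeny
from .spatial import MonthlyRasterStack, RangePolygonSet

VERTICES = ("temperature", "log_mass", "log_beak", "log_tarsus")

#: Printed allometric coefficients (natural-log scale, mm vs g).
BEAK_INTERCEPT, BEAK_SLOPE = 1.4345, 0.3362
TARSUS_INTERCEPT, TARSUS_SLOPE = 2.1141, 0.2883

#: Median avian body mass (g) used to centre the synthetic mass distribution.
MASS_MEDIAN_G = 35.5

_DEF_COEFS = {
    # Bergmann: warmer ranges -> smaller bodies (log-mass per degree C)
    ("temperature", "log_mass"): -0.07,
    # Allen on beaks: warmer ranges -> relatively longer beaks
    ("temperature", "log_beak"): 0.012,
    # inverse Allen on tarsi (the avian pattern): shorter tarsi when warm
    ("temperature", "log_tarsus"): -0.008,
    # allometry (intercept, slope) on raw log mass
    ("log_mass", "log_beak"): (BEAK_INTERCEPT, BEAK_SLOPE),
    ("log_mass", "log_tarsus"): (TARSUS_INTERCEPT, TARSUS_SLOPE),
    # temperature-as-response direction: effects of standardized-ish traits
    ("log_mass", "temperature"): -0.8,
    ("log_beak", "temperature"): 2.0,
    ("log_tarsus", "temperature"): -1.5,
}

_DEF_LAMBDA = {"temperature": 0.9, "log_mass": 0.9,
               "log_beak": 0.8, "log_tarsus": 0.8}

# residual SDs chosen so allometry explains roughly 72-73% of appendage
# variance and temperature roughly 10% of log-mass variance, matching the
# regimes of the global avian dataset
_DEF_NOISE = {"temperature": 8.0, "log_mass": 1.8,
              "log_beak": 0.39, "log_tarsus": 0.34}


@dataclass
class SyntheticScenario:
    """Full generative description of one synthetic study."""

    n_tips: int = 500
    birth_rate: float = 1.0
    causal_model: str = "mixed"          # null_allometry|bergmann|allen|mixed
    direction: str = "phenotype_response"  # or temperature_response
    coefficients: dict = field(default_factory=lambda: dict(_DEF_COEFS))
    lambda_per_trait: dict = field(default_factory=lambda: dict(_DEF_LAMBDA))
    noise_sd: dict = field(default_factory=lambda: dict(_DEF_NOISE))
    temperature_mean: float = 18.0
    mass_median_g: float = MASS_MEDIAN_G
    migration_probs: tuple = (0.6, 0.25, 0.15)  # resident, partial, full
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.migration_probs) - 1.0) > 1e-9:
            raise ValueError("migration_probs must sum to 1")
        from .path_analysis import candidate_dags
        labels = {d.label for d in candidate_dags(self.direction)}
        if self.causal_model not in labels:
            raise ValueError(f"unknown causal model {self.causal_model!r}")

    def rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible sub-stream for one generation stage."""
        import zlib
        ss = np.random.SeedSequence(
            [int(self.seed), zlib.crc32(stage.encode()) % (2**31)])
        return np.random.default_rng(ss)

    def dag(self):
        from .path_analysis import candidate_dags
        for d in candidate_dags(self.direction):
            if d.label == self.causal_model:
                return d
        raise AssertionError


# ---------------------------------------------------------------------------
# Yule tree
# ---------------------------------------------------------------------------


class _Lineage:
    __slots__ = ("start", "children", "label")

    def __init__(self, start: float):
        self.start = start
        self.children: list["_Lineage"] = []
        self.label: str | None = None


def simulate_tree(n_tips: int, birth_rate: float = 1.0,
                  seed: int | np.random.Generator = 0) -> Phylogeny:
    """Pure-birth (Yule) tree with all tips extant (ultrametric)."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    root = _Lineage(0.0)
    left, right = _Lineage(0.0), _Lineage(0.0)
    root.children = [left, right]
    active = [left, right]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = rng.integers(k)
        parent = active.pop(i)
        a, b = _Lineage(t), _Lineage(t)
        parent.children = [a, b]
        active.extend([a, b])
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    order = rng.permutation(n_tips)
    for idx, leaf in zip(order, active):
        leaf.label = f"s{idx + 1:04d}"

    def newick(node: _Lineage, end: float) -> str:
        if not node.children:
            return f"{node.label}:{end - node.start:.10g}"
        split = node.children[0].start
        inner = ",".join(newick(c, end) for c in node.children)
        return f"({inner}):{split - node.start:.10g}"

    split = root.children[0].start
    s = "(" + ",".join(newick(c, t_end) for c in root.children) + ");"
    return Phylogeny.from_newick(s)


# ---------------------------------------------------------------------------
# Trait simulation under a causal DAG
# ---------------------------------------------------------------------------


def _lambda_noise(ctx: GLSContext, lam: float, sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw one lambda-model trait deviation with unit-depth scaling.

    The covariance is ``sd^2 * (lam*C + (1-lam)diag(C)) / depth`` so the
    marginal (tip) standard deviation equals ``sd`` on ultrametric trees.
    """
    z = rng.standard_normal(ctx.n)
    if ctx.ultrametric:
        v = (lam * ctx.w + (1 - lam) * ctx.depth) / ctx.depth
        return sd * (ctx.U @ (np.sqrt(np.clip(v, 0, None)) * z))
    V = (lam * ctx.C + (1 - lam) * np.diag(ctx.d)) / ctx.d.mean()
    from scipy import linalg
    L = linalg.cholesky(V, lower=True)
    return sd * (L @ z)


def simulate_traits(tree: Phylogeny, scenario: SyntheticScenario,
                    ctx: GLSContext | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Simulate the four focal traits plus migratory habit on a tree.

    Traits are generated in topological order of the scenario's causal DAG:
    exogenous traits are lambda-model draws around their scenario means;
    each downstream trait adds its parents' contributions (allometric edges
    use the printed intercept+slope on raw log mass; all other edges use
    coefficient x mean-centred parent; ``"a*b"`` keys add interaction
    terms) plus lambda-model residual noise.  Returns the trait table and a
    truth record of the generating values.
    """
    ctx = ctx or GLSContext.from_tree(tree)
    dag = scenario.dag()
    rng = scenario.rng("traits")
    means = {"temperature": scenario.temperature_mean,
             "log_mass": math.log(scenario.mass_median_g),
             "log_beak": BEAK_INTERCEPT
             + BEAK_SLOPE * math.log(scenario.mass_median_g),
             "log_tarsus": TARSUS_INTERCEPT
             + TARSUS_SLOPE * math.log(scenario.mass_median_g)}
    for key in scenario.coefficients:
        parent = key[0]
        if "*" not in parent and parent not in VERTICES:
            raise ValueError(f"coefficient references unknown vertex {parent!r}")
    values: dict[str, np.ndarray] = {}
    used_edges = {}
    for v in dag.topological_order():
        parents = dag.parents(v)
        lam = scenario.lambda_per_trait.get(v, 1.0)
        sd = scenario.noise_sd.get(v, 1.0)
        x = means[v] + _lambda_noise(ctx, lam, sd, rng)
        for p in parents:
            coef = scenario.coefficients.get((p, v))
            if coef is None:
                raise ValueError(f"no coefficient for edge {p} -> {v}")
            if isinstance(coef, tuple):  # allometric intercept + slope
                b0, b1 = coef
                x = x - means[v] + b0 + b1 * values[p]
            else:
                x = x + coef * (values[p] - values[p].mean())
            used_edges[f"{p}->{v}"] = coef
        # optional interaction contributions, e.g. ("log_mass*temperature",
        # "log_beak") adds coef * centred(log_mass) * centred(temperature)
        for key, coef in scenario.coefficients.items():
            src, dst = key
            if dst != v or "*" not in src:
                continue
            terms = src.split("*")
            if not all(t in values for t in terms):
                raise ValueError(
                    f"interaction {src!r} references traits not yet generated")
            prod = np.ones(ctx.n)
            for t in terms:
                prod = prod * (values[t] - values[t].mean())
            x = x + coef * prod
            used_edges[f"{src}->{v}"] = coef
        values[v] = x
    for v in VERTICES:  # vertices outside the DAG are exogenous draws
        if v not in values:
            lam = scenario.lambda_per_trait.get(v, 1.0)
            sd = scenario.noise_sd.get(v, 1.0)
            values[v] = means[v] + _lambda_noise(ctx, lam, sd, rng)
    habit = rng.choice(["resident", "partial_migrant", "full_migrant"],
                       size=ctx.n, p=scenario.migration_probs)
    df = pd.DataFrame({"species": ctx.labels, **{v: values[v] for v in VERTICES},
                       "migration": habit})
    df["mass_g"] = np.exp(df["log_mass"])
    df["beak_mm"] = np.exp(df["log_beak"])
    df["tarsus_mm"] = np.exp(df["log_tarsus"])
    truth = {"scenario": {k: v for k, v in asdict(scenario).items()
                          if k not in ("coefficients",)},
             "edges": used_edges,
             "means": means}
    return df, truth


# ---------------------------------------------------------------------------
# Synthetic world: rasters + seasonal range polygons
# ---------------------------------------------------------------------------

#: climate field parameters: equatorial annual mean, lapse per degree
#: latitude, max seasonal amplitude at the poles, Tmax/Tmin half-spread
T_EQUATOR = 28.0
LAT_LAPSE = 0.55
SEASON_AMP = 15.0
DIURNAL_SPREAD = 6.0


def _annual_mean_field(lat: np.ndarray) -> np.ndarray:
    return T_EQUATOR - LAT_LAPSE * np.abs(lat)


def _monthly_anomaly(lat: np.ndarray, month: int) -> np.ndarray:
    """Seasonal cycle: northern peak in July, southern in January."""
    phase = math.cos(2.0 * math.pi * (month - 6) / 12.0)
    amp = SEASON_AMP * np.abs(lat) / 90.0
    return np.where(lat >= 0, amp * phase, -amp * phase)


def latitude_for_temperature(t: float) -> float:
    """Invert the annual-mean field: |latitude| with mean temperature t."""
    return float(np.clip((T_EQUATOR - t) / LAT_LAPSE, 0.0, 85.0))


@dataclass
class SyntheticWorld:
    """Raster stacks, seasonal range polygons and the generating truth."""

    stacks: dict            # variable -> MonthlyRasterStack
    ranges: RangePolygonSet
    truth: pd.DataFrame     # per-species noise-free climate metrics


def simulate_world(species: Sequence[str] | pd.DataFrame,
                   scenario: SyntheticScenario,
                   grid_shape: tuple[int, int] = (90, 180),
                   pixel_noise_sd: float = 0.3,
                   seed: int | None = None) -> SyntheticWorld:
    """Build monthly Tmin/Tavg/Tmax rasters and blob-shaped seasonal ranges.

    ``species`` is either a list of names (ranges placed at random
    latitudes) or a trait table with ``species``, ``temperature`` and
    ``migration`` columns, in which case each species' range is centred at
    the latitude whose annual-mean field temperature equals its generated
    temperature, and migrants receive displaced breeding/winter ranges.
    """
    nrow, ncol = grid_shape
    if nrow < 20 or ncol < 20:
        raise ValueError("grid must be at least 20 x 20")
    rng = (np.random.default_rng(seed) if seed is not None
           else scenario.rng("world"))
    dx, dy = 360.0 / ncol, 180.0 / nrow
    lat_centers = 90.0 - (np.arange(nrow) + 0.5) * dy
    lat_grid = np.repeat(lat_centers[:, None], ncol, axis=1)
    stacks = {}
    clean = {}
    for var, offset in (("Tmin", -DIURNAL_SPREAD), ("Tavg", 0.0),
                        ("Tmax", DIURNAL_SPREAD)):
        layers = np.empty((12, nrow, ncol))
        noiseless = np.empty((12, nrow, ncol))
        for m in range(12):
            base = _annual_mean_field(lat_grid) + _monthly_anomaly(lat_grid, m)
            noiseless[m] = base + offset
            layers[m] = noiseless[m] + rng.normal(0.0, pixel_noise_sd,
                                                  size=(nrow, ncol))
        stacks[var] = MonthlyRasterStack(
            variable=var, data=layers, west=-180.0, north=90.0,
            dx=dx, dy=dy, nodata=-9999.0, crs="synthetic-planar-degrees")
        clean[var] = MonthlyRasterStack(
            variable=var, data=noiseless, west=-180.0, north=90.0,
            dx=dx, dy=dy, nodata=-9999.0, crs="synthetic-planar-degrees")

    if isinstance(species, pd.DataFrame):
        table = species
        names = table["species"].tolist()
        temps = table["temperature"].to_numpy(dtype=float)
        habits = table["migration"].tolist() if "migration" in table \
            else ["resident"] * len(names)
    else:
        names = list(species)
        temps = rng.uniform(-10.0, 27.0, size=len(names))
        habits = ["resident"] * len(names)

    records = []
    for name, t, habit in zip(names, temps, habits):
        absl = latitude_for_temperature(t)
        hemi = 1.0 if rng.random() < 0.5 else -1.0
        lat_c = hemi * absl
        lon_c = rng.uniform(-150.0, 150.0)
        radius = rng.uniform(4.0, 10.0)

        def blob(lat0: float) -> "Point":
            lat0 = float(np.clip(lat0, -88.0, 88.0))
            g = Point(lon_c, lat0).buffer(radius, quad_segs=12)
            return g.intersection(box(-180.0, -90.0, 180.0, 90.0))

        if habit == "resident":
            seasons = [("year_round", blob(lat_c))]
        elif habit == "partial_migrant":
            seasons = [("year_round", blob(lat_c)),
                       ("breeding", blob(lat_c + hemi * 8.0))]
        else:  # full migrant: breed poleward, winter equatorward
            seasons = [("breeding", blob(lat_c + hemi * 8.0)),
                       ("winter", blob(lat_c - hemi * 8.0))]
        for season, geom in seasons:
            records.append({"species": name, "season": season,
                            "presence": "extant", "origin": "native",
                            "geometry": geom})
    frame = pd.DataFrame.from_records(records)
    ranges = RangePolygonSet(frame=frame, crs="synthetic-planar-degrees")

    # truth: the pipeline's own climate metrics on the noise-free fields
    from . import spatial
    agg = spatial.aggregate_season(ranges)
    truth = spatial.species_climate(clean, agg, crs=ranges.crs)
    truth = truth.rename(columns={c: f"true_{c}" for c in truth.columns
                                  if c != "species"})
    return SyntheticWorld(stacks=stacks, ranges=ranges, truth=truth)
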