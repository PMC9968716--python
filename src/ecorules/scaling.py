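"""Allometric null models and the three relative-appendage-size scalings.

Beak and tarsus lengths scale with body mass as power laws,
``length = a * mass^b`` (equivalently ``ln length = ln a + b ln mass``).
Against body mass — a volumetric measure — a linear measure scales
isometrically with exponent 1/3.  The primary "relative appendage length"
is the phylogenetic residual from the log-log PGLS allometric fit; log
length/mass ratios (which assume isometry) and phylogenetic-PCA axes are
provided as parallel scalings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pgls import DesignSpec, PGLSFit, fit_pgls, phylo_residuals
from .phylo import as_context, phylo_pca

APPENDAGES = ("beak", "tarsus")


def isometric_exponent(measure_dims: int = 1, reference_dims: int = 3) -> float:
    """Exponent for geometric (isometric) scaling of one measure on another.

    A 1-dimensional length against a 3-dimensional mass gives 1/3.
    """
    if measure_dims <= 0 or reference_dims <= 0:
        raise ValueError("dimensionalities must be positive")
    return measure_dims / reference_dims


def prepare_log_traits(traits: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add natural-log columns from raw measurements, rejecting bad rows.

    Expects ``mass_g``, ``beak_mm``, ``tarsus_mm`` (any subset); rows with
    non-positive values are dropped and reported.
    """
    df = traits.copy()
    raw_cols = {"mass_g": "log_mass", "beak_mm": "log_beak",
                "tarsus_mm": "log_tarsus"}
    bad = pd.Series(False, index=df.index)
    for raw, logged in raw_cols.items():
        if raw in df.columns:
            vals = pd.to_numeric(df[raw], errors="coerce")
            bad |= ~(vals > 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                df[logged] = np.log(vals)
    report = df.loc[bad, [c for c in ("species", *raw_cols) if c in df]]
    return df.loc[~bad].copy(), report.copy()


@dataclass
class AllometricModel:
    """A fitted log-log allometry of one appendage against body mass."""

    appendage: str
    intercept: float       # log mm at 1 g
    slope: float           # allometric exponent
    lambda_hat: float = float("nan")
    fit: PGLSFit | None = None

    @property
    def normalized_constant(self) -> float:
        """The multiplier a in ``length = a * mass^slope`` (mm at 1 g)."""
        return math.exp(self.intercept)

    def predict_log_length(self, log_mass) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(log_mass, dtype=float)

    def predict_length(self, mass_g) -> np.ndarray:
        mass = np.asarray(mass_g, dtype=float)
        return self.normalized_constant * mass ** self.slope


def fit_allometry(traits: pd.DataFrame, tree,
                  lambda_mode: str | float = "ML"
                  ) -> dict[str, AllometricModel]:
    """PGLS of log appendage length on log body mass, per appendage."""
    ctx = as_context(tree)
    out = {}
    for app in APPENDAGES:
        spec = DesignSpec(response=f"log_{app}", fixed_terms=("log_mass",),
                          name=f"allometry_{app}")
        fit = fit_pgls(traits, spec, ctx, lambda_mode=lambda_mode)
        out[app] = AllometricModel(
            appendage=app,
            intercept=float(fit.beta["(Intercept)"]),
            slope=float(fit.beta["log_mass"]),
            lambda_hat=fit.lambda_hat,
            fit=fit,
        )
    return out


def residual_shape(traits: pd.DataFrame, tree,
                   lambda_mode: str | float = "ML") -> pd.DataFrame:
    """Primary shape table: phylogenetic residuals as relative lengths."""
    models = fit_allometry(traits, tree, lambda_mode=lambda_mode)
    df = traits.set_index("species") if "species" in traits.columns else traits
    out = pd.DataFrame({
        "species": phylo_residuals(models["beak"].fit).index,
        "body_size": df["log_mass"].to_numpy(),
        "rel_beak": phylo_residuals(models["beak"].fit).to_numpy(),
        "rel_tarsus": phylo_residuals(models["tarsus"].fit).to_numpy(),
    })
    out["scaling_method"] = "residual"
    out.attrs["allometry"] = {
        app: {"intercept": m.intercept, "slope": m.slope,
              "lambda_hat": m.lambda_hat}
        for app, m in models.items()}
    return out


def ratio_shape(traits: pd.DataFrame) -> pd.DataFrame:
    """Log length-to-mass ratios (isometry-assuming parallel scaling)."""
    df = traits.set_index("species") if "species" in traits.columns else traits
    out = pd.DataFrame({
        "species": df.index.astype(str),
        "body_size": df["log_mass"].to_numpy(),
        "rel_beak": (df["log_beak"] - df["log_mass"]).to_numpy(),
        "rel_tarsus": (df["log_tarsus"] - df["log_mass"]).to_numpy(),
    })
    out["scaling_method"] = "ratio"
    return out


def ppca_shape(traits: pd.DataFrame, tree) -> pd.DataFrame:
    """Phylogenetic-PCA scaling: PC1 = body size, PC2/PC3 = shape axes.

    Log traits are standardized (mean 0, SD 1) before the phylogenetic PCA
    so that body size loads evenly on all three measurements.
    """
    df = traits.set_index("species") if "species" in traits.columns else traits
    cols = ["log_mass", "log_beak", "log_tarsus"]
    X = df[cols].astype(float)
    X = (X - X.mean()) / X.std(ddof=1)
    res = phylo_pca(X, tree)
    scores = pd.DataFrame(res.scores, index=res.labels,
                          columns=[f"PC{i+1}" for i in range(len(cols))])
    scores = scores.loc[df.index.astype(str)]
    out = pd.DataFrame({
        "species": scores.index,
        "body_size": scores["PC1"].to_numpy(),
        "rel_beak": scores["PC2"].to_numpy(),
        "rel_tarsus": scores["PC3"].to_numpy(),
    })
    out["scaling_method"] = "ppca"
    out.attrs["loadings"] = pd.DataFrame(
        res.loadings, index=cols,
        columns=[f"PC{i+1}" for i in range(len(cols))])
    out.attrs["eigenvalues"] = res.eigenvalues
    return out


def shape_table(traits: pd.DataFrame, tree,
                method: str = "residual") -> pd.DataFrame:
    """Dispatch on scaling method: residual (primary), ratio or ppca."""
    if method == "residual":
        return residual_shape(traits, tree)
    if method == "ratio":
        return ratio_shape(traits)
    if method == "ppca":
        return ppca_shape(traits, tree)
    raise ValueError(f"unknown scaling method {method!r}")
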