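"""Candidate model ladders and AIC ranking.

Families mirror the comparative design: "bergmann" predicts log body mass
from single temperature metrics (or latitude); the two "allen" families
predict log appendage length from the allometric null extended by single
temperature metrics and mass-by-temperature interactions; the
"temperature" family predicts the (transformed) environmental temperature
from all combinations of body size and the two relative appendage lengths
up to the full-factorial three-way interaction.  Support classes follow
the conventional Akaike rules: dAIC < 2 most likely, < 7 somewhat likely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pgls import CategoricalCoding, DesignSpec, fit_pgls
from .phylo import as_context

FAMILIES = ("bergmann", "allen_beak", "allen_tarsus", "temperature")

MIGRATION_CODING = CategoricalCoding(
    levels=("resident", "partial_migrant", "full_migrant"),
    reference="resident")

AIC_TIE_TOL = 1e-6


@dataclass
class CandidateSet:
    """An ordered ladder of model specifications for one response."""

    response: str
    family: str
    candidates: list[DesignSpec] = field(default_factory=list)

    def __post_init__(self):
        names = [c.name or c.formula() for c in self.candidates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate candidate specs in set")
        if not any(len(c.fixed_terms) == 0 or
                   c.fixed_terms == (self._null_terms(),)
                   for c in self.candidates):
            raise ValueError("candidate set must contain a null model")

    def _null_terms(self):
        return "log_mass" if self.family.startswith("allen") else None


def build_phenotype_candidates(family: str,
                               climate_cols: list[str],
                               latitude_col: str | None = "abs_latitude"
                               ) -> CandidateSet:
    """Ladders for the phenotype responses.

    bergmann: {null, latitude, one model per climate metric};
    allen_beak / allen_tarsus: {allometric null, +latitude, +each metric as
    fixed term, +each metric crossed with log mass}.  One climate metric
    per model (the metrics are tightly correlated).
    """
    if family not in {"bergmann", "allen_beak", "allen_tarsus"}:
        raise ValueError(f"unknown phenotype family {family!r}")
    if not climate_cols:
        raise ValueError("no climate metric columns supplied")
    cands: list[DesignSpec] = []
    if family == "bergmann":
        response = "log_mass"
        cands.append(DesignSpec(response, name="null"))
        if latitude_col:
            cands.append(DesignSpec(response, (latitude_col,),
                                    name="latitude"))
        for col in climate_cols:
            cands.append(DesignSpec(response, (col,), name=col))
    else:
        response = "log_beak" if family == "allen_beak" else "log_tarsus"
        base = ("log_mass",)
        cands.append(DesignSpec(response, base, name="allometric_null"))
        if latitude_col:
            cands.append(DesignSpec(response, base + (latitude_col,),
                                    name="latitude"))
        for col in climate_cols:
            cands.append(DesignSpec(response, base + (col,), name=col))
        for col in climate_cols:
            cands.append(DesignSpec(response, base + (col,),
                                    interactions=(("log_mass", col),),
                                    name=f"log_mass x {col}"))
    return CandidateSet(response=response, family=family, candidates=cands)


def build_temperature_candidates(response: str = "temp_response",
                                 terms: tuple[str, str, str] =
                                 ("body_size", "rel_beak", "rel_tarsus")
                                 ) -> CandidateSet:
    """Ladder for the environmental-temperature response.

    All subsets of the three phenotype terms as fixed effects, every
    combination of two-way interactions among the included terms, and the
    full-factorial three-way model as the maximal element.
    """
    cands: list[DesignSpec] = [DesignSpec(response, name="null")]
    for k in range(1, 4):
        for combo in itertools.combinations(terms, k):
            cands.append(DesignSpec(response, combo,
                                    name=" + ".join(combo)))
    for k in range(2, 4):
        for combo in itertools.combinations(terms, k):
            pairs = list(itertools.combinations(combo, 2))
            for r in range(1, len(pairs) + 1):
                for inter in itertools.combinations(pairs, r):
                    name = (" + ".join(combo) + " | "
                            + ", ".join(":".join(p) for p in inter))
                    cands.append(DesignSpec(response, combo,
                                            interactions=inter, name=name))
    cands.append(DesignSpec(response, terms,
                            interactions=tuple(
                                itertools.combinations(terms, 2)) + (terms,),
                            name="three_way_full_factorial"))
    return CandidateSet(response=response, family="temperature",
                        candidates=cands)


def rank_models(candidate_set: CandidateSet, data: pd.DataFrame, tree,
                controls: tuple[str, ...] = (),
                lambda_mode: str | float = "ML") -> pd.DataFrame:
    """Fit every candidate on the shared complete-case rows and rank by AIC.

    ``controls`` ("migration", "log_range_area") enter every candidate as
    additive fixed effects.  All candidates are fit on the intersection of
    complete cases across every variable any candidate uses, so AICs are
    comparable.  Ties below 1e-6 go to the model with fewer parameters,
    then input order.
    """
    ctx = as_context(tree)
    used: set[str] = set()
    for spec in candidate_set.candidates:
        used |= spec.variables()
    used |= set(controls)
    cols = [c for c in used if c in data.columns]
    missing = used - set(cols)
    if missing:
        raise ValueError(f"variables absent from data: {sorted(missing)}")
    if "species" in data.columns:
        data = data.set_index(data["species"].astype(str))
    complete = data[cols].notna().all(axis=1)
    sub = data.loc[complete]
    if len(sub) < ctx.n:
        ctx = as_context(
            _prune_context_tree(ctx, sub.index))
    rows = []
    for order, spec in enumerate(candidate_set.candidates):
        spec2 = _with_controls(spec, controls)
        fit = fit_pgls(sub, spec2, ctx, lambda_mode=lambda_mode)
        rows.append({"model": spec.name or spec.formula(),
                     "formula": spec2.formula(),
                     "order": order, "aic": fit.aic, "r2": fit.r2,
                     "lambda": fit.lambda_hat, "loglik": fit.loglik,
                     "k": fit.k, "n": fit.n, "fit": fit})
    table = pd.DataFrame(rows)
    table = table.sort_values(["aic", "k", "order"],
                              key=lambda s: np.round(s / AIC_TIE_TOL)
                              * AIC_TIE_TOL if s.name == "aic" else s)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    table["support"] = np.select(
        [table["delta_aic"] < 2.0, table["delta_aic"] < 7.0],
        ["most_likely", "somewhat_likely"], default="unsupported")
    return table.reset_index(drop=True)


def _with_controls(spec: DesignSpec, controls: tuple[str, ...]) -> DesignSpec:
    if not controls:
        return spec
    cat = dict(spec.categorical)
    extra = []
    for c in controls:
        if c in spec.fixed_terms:
            continue
        extra.append(c)
        if c == "migration":
            cat[c] = MIGRATION_CODING
    return DesignSpec(response=spec.response,
                      fixed_terms=spec.fixed_terms + tuple(extra),
                      interactions=spec.interactions,
                      categorical=cat, center=spec.center,
                      name=spec.name)


def _prune_context_tree(ctx, labels):
    from .phylo import PhyloCovariance
    keep = [str(x).strip() for x in labels]
    idx = [ctx.index[k] for k in keep]
    sub = ctx.C[np.ix_(idx, idx)]
    return PhyloCovariance(labels=keep, matrix=sub)


def ladder_table(table: pd.DataFrame) -> pd.DataFrame:
    """Presentation columns of a ranked ladder (drops fit objects)."""
    cols = ["model", "formula", "aic", "delta_aic", "r2", "lambda",
            "support", "k", "n"]
    return table[cols].copy()
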