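"""Phylogenetic path analysis: d-separation tests, Fisher's C and CICc.

A candidate causal model is a DAG over {temperature, log_mass, log_beak,
log_tarsus}.  Its d-separation basis set contains one conditional
independence claim per non-adjacent vertex pair, conditioned on the union
of both vertices' parents; each claim is tested by the two-tailed PGLS
p-value of the independent variable.  Fisher's C = -2 sum(ln p) follows a
chi-square with 2k df under the correct model, and models are ranked by
the small-sample C-statistic information criterion
CICc = C + 2 q n / (n - 1 - q), with q the number of estimated parameters
(edges plus one intercept per vertex with parents).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .pgls import DesignSpec, fit_pgls
from .phylo import as_context

DEFAULT_VERTICES = ("temperature", "log_mass", "log_beak", "log_tarsus")

P_FLOOR = 1e-300


class DAGError(ValueError):
    pass


@dataclass(frozen=True)
class CausalDAG:
    """A directed acyclic model over trait/temperature variables."""

    label: str
    edges: tuple[tuple[str, str], ...]
    vertices: tuple[str, ...] = DEFAULT_VERTICES
    direction: str = "phenotype_response"

    def __post_init__(self):
        for a, b in self.edges:
            if a not in self.vertices or b not in self.vertices:
                raise DAGError(f"edge ({a}, {b}) uses unknown vertices")
        if self.topological_order() is None:
            raise DAGError(f"model {self.label!r} is cyclic")

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(a for a, b in self.edges if b == v)

    def children(self, v: str) -> tuple[str, ...]:
        return tuple(b for a, b in self.edges if a == v)

    def adjacent(self, x: str, y: str) -> bool:
        return (x, y) in self.edges or (y, x) in self.edges

    def topological_order(self) -> tuple[str, ...] | None:
        indeg = {v: 0 for v in self.vertices}
        for _, b in self.edges:
            indeg[b] += 1
        queue = [v for v in self.vertices if indeg[v] == 0]
        out = []
        while queue:
            v = queue.pop(0)
            out.append(v)
            for c in self.children(v):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        return tuple(out) if len(out) == len(self.vertices) else None

    def reachable(self, src: str, dst: str) -> bool:
        seen, stack = set(), [src]
        while stack:
            v = stack.pop()
            if v == dst:
                return True
            if v in seen:
                continue
            seen.add(v)
            stack.extend(self.children(v))
        return False

    @property
    def n_parameters(self) -> int:
        """q: edges plus one intercept per vertex with parents."""
        with_parents = {b for _, b in self.edges}
        return len(self.edges) + len(with_parents)


def candidate_dags(direction: str,
                   temperature: str = "temperature",
                   mass: str = "log_mass",
                   appendages: tuple[str, ...] = ("log_beak", "log_tarsus")
                   ) -> list[CausalDAG]:
    """The four causal candidates for either response framing.

    phenotype_response (appendage lengths as final responses): allometry
    (mass -> appendages) always; Bergmann adds temperature -> mass; Allen
    adds temperature -> appendages; the mixed model has both.
    temperature_response: allometry always; Bergmann adds mass ->
    temperature; Allen adds appendages -> temperature; mixed has both, with
    temperature as a sink.
    """
    allo = tuple((mass, a) for a in appendages)
    verts = (temperature, mass, *appendages)
    if direction == "phenotype_response":
        berg = ((temperature, mass),)
        allen = tuple((temperature, a) for a in appendages)
    elif direction == "temperature_response":
        berg = ((mass, temperature),)
        allen = tuple((a, temperature) for a in appendages)
    else:
        raise DAGError(f"unknown direction {direction!r}")
    mk = lambda label, extra: CausalDAG(label=label, edges=allo + extra,
                                        vertices=verts, direction=direction)
    return [mk("null_allometry", ()),
            mk("bergmann", berg),
            mk("allen", allen),
            mk("mixed", berg + allen)]


# ---------------------------------------------------------------------------
# Basis set
# ---------------------------------------------------------------------------


@dataclass
class DSepClaim:
    """One conditional-independence claim implied by a DAG."""

    x: str                         # regressed-on (independent) variable
    y: str                         # regression child
    conditioning: tuple[str, ...]
    p_value: float | None = None

    def statement(self) -> str:
        cond = ", ".join(self.conditioning) or "{}"
        return f"{self.x} _||_ {self.y} | {{{cond}}}"


def basis_set(dag: CausalDAG) -> list[DSepClaim]:
    """One claim per non-adjacent pair, conditioning on both parent sets.

    The regression child is the causally downstream member of the pair (or
    the later vertex in topological order when neither is an ancestor of
    the other) — the directed-separation convention of phylogenetic
    path-analysis tooling.
    """
    topo = dag.topological_order()
    if topo is None:
        raise DAGError("cannot build a basis set for a cyclic model")
    rank = {v: i for i, v in enumerate(topo)}
    claims = []
    for i, a in enumerate(topo):
        for b in topo[i + 1:]:
            if dag.adjacent(a, b):
                continue
            if dag.reachable(a, b):
                x, y = a, b
            elif dag.reachable(b, a):
                x, y = b, a
            else:
                x, y = (a, b) if rank[a] < rank[b] else (b, a)
            cond = tuple(sorted((set(dag.parents(a)) | set(dag.parents(b)))
                                - {x, y}))
            claims.append(DSepClaim(x=x, y=y, conditioning=cond))
    return claims


def test_claims(claims: list[DSepClaim], data: pd.DataFrame, tree,
                lambda_mode: str | float = "ML") -> list[DSepClaim]:
    """PGLS conditional-independence tests: p of x in ``y ~ x + cond``."""
    ctx = as_context(tree)
    out = []
    for claim in claims:
        spec = DesignSpec(response=claim.y,
                          fixed_terms=(claim.x, *claim.conditioning))
        fit = fit_pgls(data, spec, ctx, lambda_mode=lambda_mode,
                       compute_r2=False)
        out.append(replace(claim, p_value=float(fit.p[claim.x])))
    return out


# ---------------------------------------------------------------------------
# Fisher's C and CIC
# ---------------------------------------------------------------------------


def fisher_c(p_values) -> tuple[float, int, float]:
    """Fisher's C = -2 sum(ln p); df = 2k; upper-tail chi-square p."""
    ps = np.asarray(list(p_values), dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(ps == 0):
        warnings.warn("p-value of 0 clamped to machine minimum")
        ps = np.clip(ps, P_FLOOR, 1.0)
    C = float(-2.0 * np.sum(np.log(ps)))
    df = 2 * len(ps)
    p = float(stats.chi2.sf(C, df=df)) if df > 0 else 1.0
    return C, df, p


def cic(C: float, n: int, q: int, small_sample: bool = True) -> float:
    """C-statistic information criterion.

    ``small_sample=True`` gives CICc = C + 2 q n / (n - 1 - q); otherwise
    the plain C + 2q.
    """
    if q >= n - 1:
        raise ValueError(f"q = {q} must be below n - 1 = {n - 1}")
    if small_sample:
        return float(C + 2.0 * q * n / (n - 1.0 - q))
    return float(C + 2.0 * q)


# ---------------------------------------------------------------------------
# Full path fit
# ---------------------------------------------------------------------------


@dataclass
class PathResult:
    """Fisher's C, CICc and standardized path coefficients for one DAG."""

    dag: CausalDAG
    C: float
    c_df: int
    c_p: float
    q: int
    cic: float
    n: int
    claims: list[DSepClaim] = field(default_factory=list)
    coefficients: pd.DataFrame | None = None   # edge, estimate, se, p
    delta_cic: float = float("nan")

    @property
    def label(self) -> str:
        return self.dag.label


def fit_paths(dag: CausalDAG, data: pd.DataFrame, tree,
              lambda_mode: str | float = "ML",
              small_sample: bool = True,
              standardized: bool = True) -> PathResult:
    """Fit one causal model: d-sep tests plus per-edge PGLS coefficients.

    Variables are standardized to mean 0, SD 1 (unless ``standardized``
    is False) so edge coefficients are comparable effect sizes.
    """
    ctx = as_context(tree)
    df = data.copy()
    if "species" in df.columns:
        df = df.set_index(df["species"].astype(str))
    cols = list(dag.vertices)
    if standardized:
        for c in cols:
            v = df[c].astype(float)
            df[c] = (v - v.mean()) / v.std(ddof=1)
    claims = test_claims(basis_set(dag), df, ctx, lambda_mode=lambda_mode)
    C, c_df, c_p = fisher_c([c.p_value for c in claims])
    n = ctx.n
    q = dag.n_parameters
    rows = []
    for child in dag.topological_order():
        parents = dag.parents(child)
        if not parents:
            continue
        spec = DesignSpec(response=child, fixed_terms=parents)
        fit = fit_pgls(df, spec, ctx, lambda_mode=lambda_mode,
                       compute_r2=False)
        for p_ in parents:
            rows.append({"edge": f"{p_} -> {child}",
                         "parent": p_, "child": child,
                         "estimate": float(fit.beta[p_]),
                         "se": float(fit.se[p_]),
                         "p": float(fit.p[p_]),
                         "lambda": fit.lambda_hat})
    coefs = pd.DataFrame(rows)
    return PathResult(dag=dag, C=C, c_df=c_df, c_p=c_p, q=q,
                      cic=cic(C, n, q, small_sample=small_sample), n=n,
                      claims=claims, coefficients=coefs)


def rank_paths(results: list[PathResult]) -> pd.DataFrame:
    """Ascending-CIC table with delta CIC; requires identical data (n)."""
    if not results:
        raise ValueError("no path results to rank")
    ns = {r.n for r in results}
    if len(ns) > 1:
        raise ValueError(f"results fit on different n: {sorted(ns)}")
    order = sorted(range(len(results)), key=lambda i: (results[i].cic, i))
    best = results[order[0]].cic
    rows = []
    for i in order:
        r = results[i]
        r.delta_cic = r.cic - best
        rows.append({"model": r.label, "C": r.C, "df": r.c_df, "p": r.c_p,
                     "q": r.q, "cic": r.cic, "delta_cic": r.delta_cic,
                     "n": r.n})
    return pd.DataFrame(rows)
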