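"""Phylogenetic generalized least squares under the Pagel-lambda model.

The regression error covariance is ``sigma^2 * V(lambda)`` where
``V(lambda)`` multiplies the off-diagonal phylogenetic covariance by lambda.
Lambda is estimated jointly with the coefficients by maximum likelihood
(profiled analytically over beta and sigma^2), matching the convention of
phylolm-style comparative regressions.  AIC counts lambda and sigma^2 among
the parameters.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylo import GLSContext, GLSProblem, PhyloError, as_context

INTERCEPT = "(Intercept)"


@dataclass(frozen=True)
class CategoricalCoding:
    """Treatment coding for a categorical term: dummies vs a reference level."""

    levels: tuple[str, ...]
    reference: str

    def __post_init__(self):
        if self.reference not in self.levels:
            raise ValueError(
                f"reference {self.reference!r} not among levels {self.levels}")


@dataclass
class DesignSpec:
    """A model specification: response, fixed terms and interactions.

    Interaction members must also appear as fixed terms (hierarchical,
    full-factorial expansion).  Categorical terms are treatment-coded against
    a named reference level.
    """

    response: str
    fixed_terms: tuple[str, ...] = ()
    interactions: tuple[tuple[str, ...], ...] = ()
    categorical: Mapping[str, CategoricalCoding] = field(default_factory=dict)
    center: bool = False
    name: str | None = None

    def __post_init__(self):
        self.fixed_terms = tuple(self.fixed_terms)
        self.interactions = tuple(tuple(t) for t in self.interactions)
        if len(set(self.fixed_terms)) != len(self.fixed_terms):
            raise ValueError("duplicate fixed terms")
        if len(set(self.interactions)) != len(self.interactions):
            raise ValueError("duplicate interaction terms")
        for tup in self.interactions:
            if len(tup) < 2:
                raise ValueError(f"interaction {tup} needs >= 2 members")
            for t in tup:
                if t not in self.fixed_terms:
                    raise ValueError(
                        f"interaction member {t!r} missing from fixed terms")

    # -- formula sugar -----------------------------------------------------

    @classmethod
    def from_formula(cls, formula: str,
                     categorical: Mapping[str, CategoricalCoding] | None = None,
                     center: bool = False) -> "DesignSpec":
        """Parse ``"y ~ a + b*c"`` style formulas.

        ``*`` expands to main effects plus all interactions among its
        members; ``:`` denotes a bare interaction (members must also appear
        as main effects elsewhere in the formula); ``1`` is the intercept-only
        model.
        """
        lhs, _, rhs = formula.partition("~")
        response = lhs.strip()
        if not response:
            raise ValueError(f"formula {formula!r} lacks a response")
        fixed: list[str] = []
        inters: list[tuple[str, ...]] = []
        for raw in rhs.split("+"):
            term = raw.strip()
            if term in {"", "1"}:
                continue
            if "*" in term:
                members = [x.strip() for x in term.split("*")]
                for m in members:
                    if m not in fixed:
                        fixed.append(m)
                for k in range(2, len(members) + 1):
                    for combo in itertools.combinations(members, k):
                        if combo not in inters:
                            inters.append(combo)
            elif ":" in term:
                combo = tuple(x.strip() for x in term.split(":"))
                if combo not in inters:
                    inters.append(combo)
            else:
                if term not in fixed:
                    fixed.append(term)
        return cls(response=response, fixed_terms=tuple(fixed),
                   interactions=tuple(inters),
                   categorical=dict(categorical or {}), center=center)

    def formula(self) -> str:
        parts = list(self.fixed_terms)
        parts += [":".join(t) for t in self.interactions]
        rhs = " + ".join(parts) if parts else "1"
        return f"{self.response} ~ {rhs}"

    def variables(self) -> set[str]:
        return {self.response, *self.fixed_terms}

    # -- design matrix -----------------------------------------------------

    def _term_columns(self, data: pd.DataFrame, term: str) -> pd.DataFrame:
        if term in self.categorical:
            coding = self.categorical[term]
            col = data[term].astype(str)
            unknown = set(col.unique()) - set(coding.levels)
            if unknown:
                raise ValueError(
                    f"unknown levels {sorted(unknown)} in categorical {term!r}")
            out = {}
            for lev in coding.levels:
                if lev == coding.reference:
                    continue
                out[f"{term}[{lev}]"] = (col == lev).astype(float)
            return pd.DataFrame(out, index=data.index)
        vals = pd.to_numeric(data[term], errors="raise").astype(float)
        if self.center:
            vals = vals - vals.mean()
        return vals.to_frame(term)

    def build_design(self, data: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
        """Return (X, y) with an intercept column first."""
        missing = self.variables() - set(data.columns)
        if missing:
            raise ValueError(f"variables missing from data: {sorted(missing)}")
        y = pd.to_numeric(data[self.response], errors="raise").astype(float)
        blocks = [pd.DataFrame({INTERCEPT: np.ones(len(data))},
                               index=data.index)]
        term_cols: dict[str, pd.DataFrame] = {}
        for term in self.fixed_terms:
            cols = self._term_columns(data, term)
            term_cols[term] = cols
            blocks.append(cols)
        for tup in self.interactions:
            grids = [term_cols[t] for t in tup]
            for combo in itertools.product(*[g.columns for g in grids]):
                prod = np.ones(len(data))
                for g, c in zip(grids, combo):
                    prod = prod * g[c].to_numpy()
                blocks.append(pd.DataFrame({":".join(combo): prod},
                                           index=data.index))
        X = pd.concat(blocks, axis=1)
        if not np.isfinite(X.to_numpy()).all() or not np.isfinite(y).all():
            raise ValueError("non-finite values in design or response")
        return X, y


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------


@dataclass
class PGLSFit:
    """A fitted phylogenetic regression under the lambda model."""

    spec: DesignSpec
    beta: pd.Series
    se: pd.Series
    t: pd.Series
    p: pd.Series
    lambda_hat: float
    sigma2_hat: float
    loglik: float
    aic: float
    r2: float
    residuals: pd.Series      # raw scale: y - X beta
    fitted: pd.Series
    n: int
    k_coef: int
    k: int                    # coefficients + lambda + sigma^2
    rss_v: float              # V(lambda_hat)^-1 weighted RSS
    X: pd.DataFrame = field(repr=False, default=None)
    ctx: GLSContext = field(repr=False, default=None)

    @property
    def response(self) -> str:
        return self.spec.response

    def summary_row(self) -> dict:
        return {
            "model": self.spec.name or self.spec.formula(),
            "loglik": self.loglik, "aic": self.aic, "r2": self.r2,
            "lambda": self.lambda_hat, "n": self.n, "k": self.k,
        }


def _check_rank(X: pd.DataFrame):
    M = X.to_numpy()
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        # name the offending columns by greedy QR-style elimination
        bad = []
        keep: list[int] = []
        for j in range(M.shape[1]):
            if np.linalg.matrix_rank(M[:, keep + [j]]) > len(keep):
                keep.append(j)
            else:
                bad.append(X.columns[j])
        raise np.linalg.LinAlgError(
            f"rank-deficient design; collinear columns: {bad}")


def fit_pgls(data: pd.DataFrame, spec: DesignSpec, tree,
             lambda_mode: str | float = "ML",
             species_col: str = "species",
             compute_r2: bool = True,
             r2_method: str = "rss") -> PGLSFit:
    """Fit a PGLS model.

    ``tree`` may be a :class:`Phylogeny`, :class:`PhyloCovariance` or a
    pre-built :class:`GLSContext` (reuse a context when fitting many models
    on the same tree).  ``lambda_mode`` is ``"ML"`` or a fixed value in
    [0, 1].  Rows are matched to tips via ``species_col`` (or the index).
    """
    ctx = as_context(tree)
    if species_col in data.columns:
        labels = data[species_col].astype(str).str.strip()
        data = data.set_index(labels.rename("species"))
    labels = [str(x).strip() for x in data.index]
    if len(labels) != ctx.n or set(labels) != set(ctx.labels):
        raise PhyloError(
            f"data species ({len(labels)}) do not match tree tips "
            f"({ctx.n}); prune the tree or subset the data first")
    X, y = spec.build_design(data)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"n = {n} too small for {p} coefficients")
    _check_rank(X)
    order = ctx.align(labels)
    Xo = np.empty((n, p))
    yo = np.empty(n)
    Xo[order] = X.to_numpy()
    yo[order] = y.to_numpy()
    prob = GLSProblem(ctx, Xo, yo)
    if lambda_mode == "ML":
        core = prob.fit_ml()
    else:
        lam = float(lambda_mode)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"fixed lambda {lam} outside [0, 1]")
        core = prob.fit(lam)
    dof = n - p
    sigma2_err = core.rss / dof
    cov = sigma2_err * core.xtvx_inv
    se = np.sqrt(np.diag(cov))
    tvals = core.beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=dof)
    fitted_o = Xo @ core.beta
    resid_o = yo - fitted_o
    # back to input row order
    fitted = np.empty(n)
    resid = np.empty(n)
    fitted = fitted_o[order]
    resid = resid_o[order]
    k = p + 2
    aic = -2.0 * core.loglik + 2.0 * k
    fit = PGLSFit(
        spec=spec,
        beta=pd.Series(core.beta, index=X.columns),
        se=pd.Series(se, index=X.columns),
        t=pd.Series(tvals, index=X.columns),
        p=pd.Series(pvals, index=X.columns),
        lambda_hat=float(core.lam),
        sigma2_hat=float(core.sigma2_ml),
        loglik=float(core.loglik),
        aic=float(aic),
        r2=float("nan"),
        residuals=pd.Series(resid, index=data.index, name="residual"),
        fitted=pd.Series(fitted, index=data.index, name="fitted"),
        n=n, k_coef=p, k=k, rss_v=float(core.rss),
        X=X, ctx=ctx,
    )
    if compute_r2:
        if p == 1:
            fit.r2 = 0.0
        else:
            null_spec = DesignSpec(response=spec.response, name="null")
            null = fit_pgls(data, null_spec, ctx, lambda_mode=lambda_mode,
                            compute_r2=False)
            fit.r2 = r_squared(fit, null, method=r2_method)
    return fit


def r_squared(fit: PGLSFit, null_fit: PGLSFit, method: str = "rss") -> float:
    """Coefficient of determination of a PGLS fit against a null fit.

    ``"rss"``: 1 - RSS_V(fit)/RSS_V(null), each residual sum of squares
    weighted by its own fitted V; ``"loglik"``: likelihood-based pseudo-R2
    ``1 - exp(-2/n (llfit - llnull))``.  Clipped to [0, 1].
    """
    if fit.response != null_fit.response:
        raise ValueError(
            f"response mismatch: {fit.response!r} vs {null_fit.response!r}")
    if method == "rss":
        r2 = 1.0 - fit.rss_v / null_fit.rss_v
    elif method == "loglik":
        r2 = 1.0 - math.exp(-2.0 / fit.n * (fit.loglik - null_fit.loglik))
    else:
        raise ValueError(f"unknown r2 method {method!r}")
    return float(np.clip(r2, 0.0, 1.0))


def phylo_residuals(fit: PGLSFit) -> pd.Series:
    """Raw (not V-whitened) per-species residuals ``y - X beta``."""
    return fit.residuals


def predict_profile(fit: PGLSFit, focal: str,
                    quantiles: Sequence[float] = (0.1, 0.5, 0.9),
                    moderator: str | None = None,
                    fixed: Mapping[str, float] | None = None,
                    n_grid: int = 25,
                    grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Deterministic predicted-response curves along a focal term.

    One curve per quantile of ``moderator`` (other continuous terms held at
    their observed means unless pinned in ``fixed``; categorical terms at the
    reference level).  Returns a tidy frame with columns ``focal value``,
    ``quantile``, ``moderator value`` and ``predicted``.
    """
    if focal not in fit.spec.fixed_terms:
        raise ValueError(f"{focal!r} is not a term of the model")
    cols = fit.X
    data_focal = cols[focal].to_numpy()
    if grid is None:
        grid = np.linspace(data_focal.min(), data_focal.max(), n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
        if (grid.min() < data_focal.min() - 1e-12
                or grid.max() > data_focal.max() + 1e-12):
            warnings.warn("profile grid extrapolates beyond the observed "
                          "range of the focal term")
    fixed = dict(fixed or {})
    base = {}
    for c in cols.columns:
        if c == INTERCEPT or ":" in c:
            continue
        if "[" in c:  # categorical dummy -> reference level
            base[c] = 0.0
        else:
            base[c] = fixed.get(c, float(cols[c].mean()))
    if moderator is not None:
        mod_vals = [float(np.quantile(cols[moderator].to_numpy(), q))
                    for q in quantiles]
        mod_iter = list(zip(quantiles, mod_vals))
    else:
        mod_iter = [(None, None)]
    rows = []
    for q, mv in mod_iter:
        for g in grid:
            point = dict(base)
            point[focal] = float(g)
            if moderator is not None:
                point[moderator] = mv
            pred = 0.0
            for c, b in fit.beta.items():
                if c == INTERCEPT:
                    pred += b
                elif ":" in c:
                    val = 1.0
                    for part in c.split(":"):
                        val *= point.get(part, 0.0)
                    pred += b * val
                else:
                    pred += b * point.get(c, 0.0)
            rows.append({"focal": focal, "value": float(g),
                         "quantile": q, "moderator_value": mv,
                         "predicted": float(pred)})
    return pd.DataFrame(rows)
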