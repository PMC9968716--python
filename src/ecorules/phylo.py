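"""Tree I/O, phylogenetic covariance, Pagel's lambda and phylogenetic PCA.

The phylogenetic covariance matrix ``C`` has entries ``C[i, j]`` equal to the
shared root-to-MRCA path length of tips *i* and *j* (so ``C[i, i]`` is the
root-to-tip depth of tip *i*).  Pagel's lambda rescales the off-diagonal
entries, interpolating between phylogenetic independence (``lam = 0``) and the
full Brownian-motion covariance (``lam = 1``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy import linalg, optimize, stats


class PhyloError(ValueError):
    """Raised for invalid trees, labels or trait joins."""


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """A rooted tree with branch lengths and unique tip labels.

    Thin wrapper around a :class:`dendropy.Tree` providing the covariance
    construction and label bookkeeping the comparative analyses need.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label.strip() for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise PhyloError(f"duplicate tip labels: {dupes}")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise PhyloError(
                    f"negative branch length {edge.length} on edge to "
                    f"{edge.head_node}"
                )
        self.tip_labels: list[str] = labels

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick",
                                     preserve_underscores=True)
        except Exception as exc:
            kind = ("duplicate tip labels"
                    if "Duplicate" in type(exc).__name__
                    or "duplicate" in str(exc).lower() else "parse error")
            raise PhyloError(f"{kind}: {exc}") from exc
        return cls(tree)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick",
                                    suppress_rooting=True).strip()

    # -- basic structure ---------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip label."""
        out = {}
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            out[leaf.taxon.label.strip()] = d
        return out

    def prune_to(self, labels: Sequence[str]) -> "Phylogeny":
        """Prune the tree to the given tip labels (exact string match)."""
        keep = {str(x).strip() for x in labels}
        missing = keep - set(self.tip_labels)
        if missing:
            raise PhyloError(f"labels not in tree: {sorted(missing)[:5]} ...")
        tree = self._tree.clone(depth=1)
        taxa = [t for t in tree.taxon_namespace if t.label.strip() in keep]
        tree.retain_taxa(taxa)
        return Phylogeny(tree)

    def vcv(self) -> "PhyloCovariance":
        """Brownian-motion covariance: shared path lengths among tips."""
        labels = self.tip_labels
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))
        # depth of each node from root, then fill blocks at internal nodes
        depth = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depth[node] = 0.0
            else:
                depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                i = index[node.taxon.label.strip()]
                C[i, i] = depth[node]
                node._tipset = [i]
            else:
                kids = [c._tipset for c in node.child_nodes()]
                d = depth[node]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        ia = np.asarray(kids[a])
                        ib = np.asarray(kids[b])
                        C[np.ix_(ia, ib)] = d
                        C[np.ix_(ib, ia)] = d
                node._tipset = [i for k in kids for i in k]
        for node in self._tree.postorder_node_iter():
            if hasattr(node, "_tipset"):
                del node._tipset
        return PhyloCovariance(labels=list(labels), matrix=C, lam=1.0)


def read_trees(path: str | Path, format: str = "newick") -> list[Phylogeny]:
    """Read all trees from a Newick or Nexus file, preserving order."""
    format = format.lower()
    if format not in {"newick", "nexus"}:
        raise ValueError(f"unknown tree format {format!r}")
    try:
        trees = dendropy.TreeList.get(path=str(path), schema=format,
                                      preserve_underscores=True)
    except Exception as exc:  # dendropy raises many parse error types
        raise PhyloError(f"could not parse {path} as {format}: {exc}") from exc
    return [Phylogeny(t) for t in trees]


# ---------------------------------------------------------------------------
# Covariance + lambda transform
# ---------------------------------------------------------------------------


@dataclass
class PhyloCovariance:
    """n-by-n shared-path-length matrix bound to a tip-label order."""

    labels: list[str]
    matrix: np.ndarray
    lam: float = 1.0

    def __post_init__(self):
        C = np.asarray(self.matrix, dtype=float)
        if C.shape[0] != C.shape[1] or C.shape[0] != len(self.labels):
            raise PhyloError("covariance shape does not match label count")
        self.matrix = C


def lambda_transform(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply the off-diagonal entries of ``C`` by ``lam``."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    M = C.matrix
    out = lam * M + (1.0 - lam) * np.diag(np.diag(M))
    return PhyloCovariance(labels=list(C.labels), matrix=out, lam=lam)


# ---------------------------------------------------------------------------
# GLS context: the likelihood engine shared by signal, PGLS and path tests
# ---------------------------------------------------------------------------


class GLSContext:
    """Pre-factorised phylogenetic covariance for repeated lambda-model fits.

    For ultrametric trees (constant tip depth ``T``) the lambda-transformed
    covariance ``V(lam) = lam*C + (1-lam)*diag(C)`` shares the eigenbasis of
    ``C``, so one symmetric eigendecomposition serves every lambda: each
    profile-likelihood evaluation is then O(n p^2).  Non-ultrametric trees
    fall back to a Cholesky factorisation per lambda value.
    """

    def __init__(self, cov: PhyloCovariance):
        self.labels = list(cov.labels)
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        self.C = cov.matrix
        self.d = np.diag(self.C).copy()
        self.n = len(self.labels)
        t = float(self.d.mean())
        self.ultrametric = bool(np.allclose(self.d, t, rtol=1e-8, atol=1e-10))
        self.depth = t
        if self.ultrametric:
            w, U = linalg.eigh(self.C)
            self.w = np.clip(w, 0.0, None)
            self.U = U
        else:
            self.w = None
            self.U = None

    @classmethod
    def from_tree(cls, tree: Phylogeny) -> "GLSContext":
        return cls(tree.vcv())

    def align(self, labels: Sequence[str]) -> np.ndarray:
        """Row indices of ``labels`` in this context's tip order."""
        try:
            return np.asarray([self.index[str(x).strip()] for x in labels])
        except KeyError as exc:
            raise PhyloError(f"tip label {exc} not in tree") from exc


def as_context(tree) -> GLSContext:
    if isinstance(tree, GLSContext):
        return tree
    if isinstance(tree, Phylogeny):
        return GLSContext.from_tree(tree)
    if isinstance(tree, PhyloCovariance):
        return GLSContext(tree)
    raise TypeError(f"expected Phylogeny, PhyloCovariance or GLSContext, "
                    f"got {type(tree)}")


@dataclass
class _CoreFit:
    beta: np.ndarray
    xtvx_inv: np.ndarray
    rss: float            # V^-1-weighted residual sum of squares
    sigma2_ml: float
    loglik: float
    lam: float


class GLSProblem:
    """One (X, y) pair bound to a :class:`GLSContext`.

    Provides the profiled Gaussian log-likelihood of the lambda model, with
    beta and sigma^2 maximised analytically at each lambda.
    """

    def __init__(self, ctx: GLSContext, X: np.ndarray, y: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if X.shape[0] != ctx.n or y.shape[0] != ctx.n:
            raise ValueError("X/y rows must match the tree context tip count")
        self.ctx = ctx
        self.X = X
        self.y = y
        if ctx.ultrametric:
            self.Xr = ctx.U.T @ X
            self.yr = ctx.U.T @ y

    def fit(self, lam: float) -> _CoreFit:
        ctx = self.ctx
        n = ctx.n
        if ctx.ultrametric:
            v = lam * ctx.w + (1.0 - lam) * ctx.depth
            if np.any(v <= 0):
                v = np.clip(v, 1e-12, None)
            wi = 1.0 / v
            Xw = self.Xr * wi[:, None]
            xtvx = Xw.T @ self.Xr
            xtvy = Xw.T @ self.yr
            logdet = float(np.sum(np.log(v)))
            try:
                xtvx_inv = linalg.inv(xtvx)
            except linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "singular design under GLS weighting") from exc
            beta = xtvx_inv @ xtvy
            resid = self.yr - self.Xr @ beta
            rss = float(np.sum(resid * resid * wi))
        else:
            V = lam * ctx.C + (1.0 - lam) * np.diag(ctx.d)
            try:
                L = linalg.cholesky(V, lower=True)
            except linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "lambda-transformed covariance not positive definite"
                ) from exc
            logdet = float(2.0 * np.sum(np.log(np.diag(L))))
            Xs = linalg.solve_triangular(L, self.X, lower=True)
            ys = linalg.solve_triangular(L, self.y, lower=True)
            xtvx = Xs.T @ Xs
            xtvx_inv = linalg.inv(xtvx)
            beta = xtvx_inv @ (Xs.T @ ys)
            resid = ys - Xs @ beta
            rss = float(resid @ resid)
        sigma2 = max(rss / n, 1e-300)
        ll = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + n + logdet)
        return _CoreFit(beta=beta, xtvx_inv=xtvx_inv, rss=rss,
                        sigma2_ml=sigma2, loglik=ll, lam=lam)

    def loglik(self, lam: float) -> float:
        return self.fit(lam).loglik

    def fit_ml(self, xatol: float = 1e-8) -> _CoreFit:
        """Maximise the profile likelihood over lambda in [0, 1]."""
        res = optimize.minimize_scalar(
            lambda lam: -self.loglik(lam),
            bounds=(0.0, 1.0), method="bounded",
            options={"xatol": xatol},
        )
        candidates = [self.fit(float(res.x)), self.fit(0.0), self.fit(1.0)]
        return max(candidates, key=lambda f: f.loglik)


# ---------------------------------------------------------------------------
# Phylogenetic signal (Pagel's lambda, intercept-only model)
# ---------------------------------------------------------------------------


@dataclass
class SignalEstimate:
    """ML Pagel's lambda for one trait with a likelihood-ratio test vs 0."""

    lambda_hat: float
    loglik_at_hat: float
    loglik_at_zero: float
    lr_p: float


def pagel_signal(trait, tree, labels: Sequence[str] | None = None) -> SignalEstimate:
    """Estimate Pagel's lambda for a single trait by maximum likelihood.

    ``trait`` may be a mapping/Series indexed by tip label, or an array with
    ``labels`` supplied.  The likelihood-ratio p-value compares the ML fit
    against lambda = 0 using chi-square with 1 df.
    """
    ctx = as_context(tree)
    if labels is None:
        if hasattr(trait, "index"):
            labels = list(trait.index)
            values = np.asarray(trait, dtype=float)
        elif isinstance(trait, dict):
            labels = list(trait)
            values = np.asarray([trait[k] for k in labels], dtype=float)
        else:
            raise PhyloError("labels required when trait has no index")
    else:
        values = np.asarray(trait, dtype=float)
    if len(labels) != ctx.n:
        raise PhyloError(
            f"trait has {len(labels)} values but tree has {ctx.n} tips")
    order = ctx.align(labels)
    y = np.empty(ctx.n)
    y[order] = values
    if np.std(y) == 0:
        raise PhyloError("trait is constant: lambda is unidentifiable")
    prob = GLSProblem(ctx, np.ones((ctx.n, 1)), y)
    best = prob.fit_ml()
    ll0 = prob.loglik(0.0)
    lr = max(0.0, 2.0 * (best.loglik - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return SignalEstimate(lambda_hat=float(best.lam),
                          loglik_at_hat=float(best.loglik),
                          loglik_at_zero=float(ll0), lr_p=p)


# ---------------------------------------------------------------------------
# Phylogenetic PCA (GLS-centred, phylogeny-weighted covariance)
# ---------------------------------------------------------------------------


@dataclass
class PhyloPCA:
    """Result of a phylogenetic principal component analysis."""

    labels: list[str]
    trait_names: list[str]
    scores: np.ndarray       # n x m, per-tip component scores
    loadings: np.ndarray     # m x m, columns are eigenvectors
    eigenvalues: np.ndarray  # length m, non-increasing
    gls_mean: np.ndarray     # ancestral (GLS) trait means


def phylo_pca(traits, tree) -> PhyloPCA:
    """Phylogeny-weighted PCA of a per-tip trait matrix.

    Traits are centred on their GLS (ancestral-state) means and the
    evolutionary covariance ``(X - 1a)' C^-1 (X - 1a) / (n - 1)`` is
    eigendecomposed; scores are projections of the centred traits.
    """
    ctx = as_context(tree)
    import pandas as pd
    if isinstance(traits, pd.DataFrame):
        names = list(traits.columns)
        labels = list(traits.index)
        X = traits.to_numpy(dtype=float)
    else:
        raise PhyloError("phylo_pca expects a DataFrame indexed by species")
    if np.isnan(X).any():
        raise PhyloError("missing trait values: drop or impute before "
                         "phylogenetic PCA")
    if X.shape[1] < 2:
        raise PhyloError("need at least two traits")
    order = ctx.align(labels)
    Xo = np.empty_like(X)
    Xo[order] = X
    Cinv = linalg.inv(ctx.C)
    one = np.ones(ctx.n)
    a = (one @ Cinv @ Xo) / (one @ Cinv @ one)
    Xc = Xo - a
    R = Xc.T @ Cinv @ Xc / (ctx.n - 1)
    evals, evecs = linalg.eigh(R)
    idx = np.argsort(evals)[::-1]
    evals = np.clip(evals[idx], 0.0, None)
    evecs = evecs[:, idx]
    # sign convention: largest-magnitude loading of each component positive
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    scores = Xc @ evecs
    return PhyloPCA(labels=[ctx.labels[i] for i in range(ctx.n)],
                    trait_names=names,
                    scores=scores, loadings=evecs, eigenvalues=evals,
                    gls_mean=a)
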