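"""Phylogenetic logistic regression for binary tip traits.

Model: for tips i of a rooted phylogeny, logit P(y_i = 1) = b0 + b1 x_i,
with residual dependence among tips decaying with patristic distance d_ij as
exp(-alpha * d_ij); alpha >= 0 is the phylogenetic-signal parameter (large
alpha = independence, small alpha = strong shared history).  Coefficients
are estimated by iterated GEE-style estimating equations with a working
correlation R(alpha) = exp(-alpha * D); alpha is chosen by maximizing a
scale-profiled Gaussian working likelihood of the standardized residuals.
Inference on the slope uses a parametric bootstrap: binary tip data are
re-simulated from the fitted model on the same tree (via a Gaussian copula
that preserves the logit marginals and the distance-decaying correlation),
refit, and the two-sided p-value for b1 is taken from the replicate
distribution's tail beyond zero.  The bootstrap route is preferred to
asymptotic standard errors because the per-phylum sample sizes here are
small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import expit, ndtri
from scipy.stats import norm

from .trait_db import normalize_taxon_id

logger = logging.getLogger(__name__)

__all__ = [
    "Phylogeny",
    "PhyloLogitFit",
    "read_newick",
    "select_top_traits",
    "phylo_logistic",
    "simulate_binary_on_tree",
]

_MU_EPS = 1e-9
_BETA_CAP = 30.0


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths, plus tip clade annotations.

    ``clades`` maps tips to clade labels (e.g. class, family) parsed from
    internal node labels of the form ``rank=value`` and propagated to all
    descendant tips; absent annotations yield empty strings.
    """

    tree: dendropy.Tree
    tips: list[str]
    distances: pd.DataFrame  # patristic distances, tips x tips
    clades: pd.DataFrame  # tips x annotation ranks

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def prune_to(self, tips: Sequence[str]) -> "Phylogeny":
        keep = [t for t in self.tips if t in set(tips)]
        tree = self.tree.clone(depth=1)
        tree.retain_taxa_with_labels(keep)
        return Phylogeny(
            tree,
            keep,
            self.distances.loc[keep, keep],
            self.clades.loc[keep],
        )


def _patristic_matrix(tree: dendropy.Tree, tips: list[str]) -> pd.DataFrame:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(tips)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[tips[i]], taxa[tips[j]])
    return pd.DataFrame(D, index=tips, columns=tips)


def read_newick(path: str | Path, annotation_ranks: Sequence[str] = ("class", "family")) -> Phylogeny:
    """Parse a Newick tree; tip names are normalized for database matching.

    Branch lengths must be present on all non-root edges (zero lengths are
    accepted); duplicate tip names are an error.  Internal node labels of
    the form ``rank=value`` (several may be joined with ``;``) annotate all
    descendant tips with that clade label.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip names in {path}: {exc}") from exc
    for taxon in tree.taxon_namespace:
        taxon.label = normalize_taxon_id(taxon.label)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(tips)) != len(tips):
        dupes = sorted({t for t in tips if tips.count(t) > 1})
        raise ValueError(f"duplicate tip names: {dupes[:5]}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")

    clades = pd.DataFrame("", index=tips, columns=list(annotation_ranks))
    for node in tree.preorder_node_iter():
        label = getattr(node, "label", None)
        if not label or node.is_leaf():
            continue
        for part in str(label).split(";"):
            if "=" not in part:
                continue
            rank, value = part.split("=", 1)
            rank = rank.strip().lower()
            if rank in clades.columns:
                for leaf in node.leaf_iter():
                    clades.loc[leaf.taxon.label, rank] = value.strip()

    return Phylogeny(tree, tips, _patristic_matrix(tree, tips), clades)


def select_top_traits(importances: pd.DataFrame | pd.Series, k: int = 5) -> list[str]:
    """The k highest-importance traits; ties broken lexicographically.

    Accepts an importance table with a ``mean`` column or a plain Series of
    scores indexed by trait.
    """
    if isinstance(importances, pd.DataFrame):
        scores = importances["mean"]
    else:
        scores = importances
    order = sorted(scores.index, key=lambda t: (-float(scores[t]), str(t)))
    return order[: max(k, 0)]


class _CorrelationGrid:
    """Per-alpha working-correlation factorizations, shared across refits."""

    def __init__(self, D: np.ndarray, alphas: Sequence[float]):
        self.D = D
        self.alphas = np.asarray(alphas, dtype=float)
        self.factors = []
        n = len(D)
        for a in self.alphas:
            R = np.exp(-a * D)
            R[np.diag_indices(n)] = 1.0 + 1e-8
            self.factors.append((linalg.cho_factor(R, lower=True), R))

    def solve(self, k: int, b: np.ndarray) -> np.ndarray:
        return linalg.cho_solve(self.factors[k][0], b)

    def logdet(self, k: int) -> float:
        c = self.factors[k][0][0]
        return 2.0 * float(np.sum(np.log(np.diag(c))))

    def chol(self, k: int) -> np.ndarray:
        return np.tril(self.factors[k][0][0])


def _default_alpha_grid(D: np.ndarray) -> np.ndarray:
    off = D[np.triu_indices(len(D), k=1)]
    scale = float(np.mean(off)) if off.size else 1.0
    scale = max(scale, 1e-9)
    rel = np.array([0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 64.0, 1e6])
    return rel / scale


def _gee_fit(X: np.ndarray, y: np.ndarray, grid: _CorrelationGrid, k: int,
             beta0: np.ndarray | None = None,
             max_iter: int = 50, tol: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Fisher scoring for the GEE estimating equation at fixed alpha index k."""
    n, q = X.shape
    beta = np.zeros(q) if beta0 is None else beta0.copy()
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        a = mu * (1.0 - mu)
        sa = np.sqrt(a)
        # U = X' A^{1/2} R^{-1} A^{-1/2} (y - mu);  I = X' A^{1/2} R^{-1} A^{1/2} X
        Xs = X * sa[:, None]
        Rinv_Xs = grid.solve(k, Xs)
        U = Xs.T @ grid.solve(k, (y - mu) / sa)
        info = Xs.T @ Rinv_Xs
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(q), U)
        except np.linalg.LinAlgError:
            break
        beta_new = beta + step
        nrm = np.linalg.norm(beta_new)
        if nrm > _BETA_CAP:  # quasi-separation guard
            beta_new *= _BETA_CAP / nrm
        if np.linalg.norm(beta_new - beta) < tol * (1 + np.linalg.norm(beta)):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    return beta, converged


def _working_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                    grid: _CorrelationGrid, k: int) -> float:
    """Scale-profiled Gaussian working log-likelihood of standardized residuals."""
    n = len(y)
    mu = np.clip(expit(X @ beta), _MU_EPS, 1.0 - _MU_EPS)
    u = (y - mu) / np.sqrt(mu * (1.0 - mu))
    quad = float(u @ grid.solve(k, u))
    quad = max(quad, 1e-12)
    return -0.5 * grid.logdet(k) - 0.5 * n * np.log(quad / n)


@dataclass
class PhyloLogitFit:
    """Fitted single-trait phylogenetic logistic regression."""

    intercept: float
    coefficient: float
    alpha_phy: float
    p_boot: float | None
    n_boot: int
    converged: bool
    n_tips: int
    boot_coefficients: np.ndarray = field(default_factory=lambda: np.array([]))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        """Percentile bootstrap interval for the slope."""
        if self.boot_coefficients.size == 0:
            return (float("nan"), float("nan"))
        lo = (1 - level) / 2
        return (
            float(np.quantile(self.boot_coefficients, lo)),
            float(np.quantile(self.boot_coefficients, 1 - lo)),
        )


def _fit_alpha_profile(
    X: np.ndarray, y: np.ndarray, grid: _CorrelationGrid
) -> tuple[np.ndarray, int, bool]:
    best = None
    for k in range(len(grid.alphas)):
        beta, conv = _gee_fit(X, y, grid, k)
        ll = _working_loglik(X, y, beta, grid, k)
        if best is None or ll > best[0]:
            best = (ll, beta, k, conv)
    _, beta, k, conv = best
    return beta, k, conv


def phylo_logistic(
    tree: Phylogeny,
    y: pd.Series | Sequence[int],
    x: pd.Series | Sequence[float],
    nboot: int = 10_000,
    seed: int = 0,
    alpha_grid: Sequence[float] | None = None,
) -> PhyloLogitFit:
    """Fit the phylogenetic logistic model and bootstrap the slope's p-value.

    ``y`` (binary) and ``x`` (numeric) are aligned to the tree's tips; tips
    missing from either are pruned before fitting.  The parametric bootstrap
    simulates tip data from the fitted model (nboot replicates, deterministic
    given ``seed``), refits each with the phylogenetic-signal parameter held
    at its point estimate, and reports the two-sided tail probability of the
    slope replicates beyond zero, floored at 1/(nboot+1).  ``nboot=0`` skips
    the bootstrap.
    """
    y = pd.Series(y, index=tree.tips if not isinstance(y, pd.Series) else None)
    x = pd.Series(x, index=tree.tips if not isinstance(x, pd.Series) else None)
    tips = [t for t in tree.tips if t in y.index and t in x.index
            and pd.notna(y[t]) and pd.notna(x[t])]
    if len(tips) < len(tree.tips):
        tree = tree.prune_to(tips)
    yv = y.loc[tips].to_numpy(dtype=float)
    xv = x.loc[tips].to_numpy(dtype=float)
    if len(np.unique(yv)) < 2:
        raise ValueError("response has a single class")
    if np.ptp(xv) == 0:
        raise ValueError("predictor is constant; slope inestimable")

    D = tree.distances.loc[tips, tips].to_numpy(dtype=float)
    grid = _CorrelationGrid(D, alpha_grid if alpha_grid is not None
                            else _default_alpha_grid(D))
    X = np.column_stack([np.ones(len(tips)), xv])
    beta, k_hat, converged = _fit_alpha_profile(X, yv, grid)
    alpha_hat = float(grid.alphas[k_hat])
    if not converged:
        logger.warning("phylogenetic logistic fit did not fully converge")

    p_boot = None
    boot_b1 = np.array([])
    if nboot > 0:
        rng = np.random.default_rng(seed)
        L = grid.chol(k_hat)
        mu = np.clip(expit(X @ beta), _MU_EPS, 1.0 - _MU_EPS)
        b1s = np.empty(nboot)
        for b in range(nboot):
            ystar = _copula_binary(mu, L, rng)
            if len(np.unique(ystar)) < 2:
                b1s[b] = 0.0
                continue
            bstar, _ = _gee_fit(X, ystar, grid, k_hat, beta0=beta)
            b1s[b] = bstar[1]
        n_le = int((b1s <= 0).sum())
        n_ge = int((b1s >= 0).sum())
        p_boot = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (nboot + 1))
        boot_b1 = b1s

    return PhyloLogitFit(
        intercept=float(beta[0]),
        coefficient=float(beta[1]),
        alpha_phy=alpha_hat,
        p_boot=p_boot,
        n_boot=nboot,
        converged=converged,
        n_tips=len(tips),
        boot_coefficients=boot_b1,
    )


def _copula_binary(mu: np.ndarray, L: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Correlated Bernoulli draws with the given marginals via Gaussian copula."""
    z = L @ rng.standard_normal(len(mu))
    z /= np.sqrt((L**2).sum(axis=1))
    return (norm.cdf(z) < mu).astype(float)


def simulate_binary_on_tree(
    tree: Phylogeny,
    beta0: float,
    beta1: float,
    x: pd.Series | Sequence[float],
    alpha_phy: float,
    seed: int = 0,
) -> pd.Series:
    """Simulate correlated binary tip values under the phylogenetic logit model.

    Marginally P(y_i = 1) = logit^-1(beta0 + beta1 x_i); the latent Gaussian
    copula has correlation exp(-alpha_phy * d_ij), so tips joined by short
    paths are more concordant than independent draws, and alpha_phy -> inf
    recovers independent Bernoulli tips.
    """
    x = pd.Series(x, index=tree.tips if not isinstance(x, pd.Series) else None)
    xv = x.loc[tree.tips].to_numpy(dtype=float)
    D = tree.distances.to_numpy(dtype=float)
    R = np.exp(-alpha_phy * D)
    R[np.diag_indices(len(R))] = 1.0 + 1e-8
    L = np.linalg.cholesky(R)
    mu = np.clip(expit(beta0 + beta1 * xv), _MU_EPS, 1.0 - _MU_EPS)
    rng = np.random.default_rng(seed)
    y = _copula_binary(mu, L, rng)
    return pd.Series(y.astype(int), index=tree.tips)
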