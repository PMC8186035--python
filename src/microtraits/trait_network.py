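"""Trait co-occurrence network: sparse partial correlations, signed clustering,
and the bipartite cluster-site association graph.

The network is estimated by the graphical lasso over abundance-weighted
trait profiles (traits standardized across samples), with the penalty chosen
by the extended Bayesian information criterion

    EBIC(lambda) = -2 loglik + |E| log n + 4 |E| gamma log p,

where |E| is the number of edges of the estimated precision matrix, n the
number of samples and p the number of traits.  Edges carry partial
correlations.  Communities are found by minimizing a signed spin-glass
(Potts) energy in which positive edge weight inside a cluster and negative
weight between clusters lower the energy, relative to a configuration null
model applied separately to the positive and negative subgraphs; the
optimizer is simulated annealing with geometric cooling, deterministic given
its seed.  Finally, each body site is regressed (L1-penalized logistic
regression, penalty chosen by cross-validated misclassification) on all
trait profiles, and the cluster-site edge weight is the mean of the retained
coefficients of that cluster's traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.covariance import graphical_lasso
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .community_profiles import SampleMetadata, TraitProfileMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PartialCorrelationNetwork",
    "TraitClusters",
    "ClusterSiteNetwork",
    "AnnealSchedule",
    "fit_glasso_ebic",
    "signed_potts_energy",
    "spin_glass_communities",
    "site_cluster_network",
]


@dataclass
class PartialCorrelationNetwork:
    """Sparse partial-correlation graph over expanded traits."""

    partial_corr: pd.DataFrame  # p x p, zero off-diagonal where no edge
    precision: pd.DataFrame
    lambda_selected: float
    gamma_ebic: float
    n_samples: int
    ebic_path: pd.DataFrame  # columns lambda, n_edges, loglik, ebic

    @property
    def nodes(self) -> pd.Index:
        return self.partial_corr.index

    @property
    def n_nodes(self) -> int:
        return len(self.partial_corr)

    def edges(self) -> pd.DataFrame:
        """Tidy edge list (node_a, node_b, weight) over the upper triangle."""
        pc = self.partial_corr
        rows = []
        names = list(pc.index)
        arr = pc.to_numpy()
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if arr[i, j] != 0:
                    rows.append(
                        {"node_a": names[i], "node_b": names[j],
                         "weight": float(arr[i, j])}
                    )
        return pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.partial_corr.index)
        for _, row in self.edges().iterrows():
            g.add_edge(row["node_a"], row["node_b"], weight=row["weight"])
        return g

    def weight_matrix(self) -> np.ndarray:
        w = self.partial_corr.to_numpy().copy()
        np.fill_diagonal(w, 0.0)
        return w


def _constrained_mle(S: np.ndarray, support: np.ndarray,
                     n: int) -> tuple[np.ndarray, float]:
    """Gaussian MLE of the precision matrix with off-support entries fixed at 0.

    Convex in the free entries; solved by L-BFGS on the negative profile
    log-likelihood -log det K + tr(S K), gradient (S - K^{-1}) on the free
    entries.  Returns the precision matrix and n/2 (log det K - tr(S K)).
    """
    from scipy.optimize import minimize

    p = len(S)
    iu = np.triu_indices(p, k=1)
    free_edges = [(i, j) for i, j in zip(*iu) if support[i, j]]

    def unpack(x: np.ndarray) -> np.ndarray:
        K = np.diag(np.exp(x[:p]))
        for k, (i, j) in enumerate(free_edges):
            K[i, j] = K[j, i] = x[p + k]
        return K

    def objective(x: np.ndarray):
        K = unpack(x)
        try:
            # Cholesky doubles as the positive-definiteness check; a positive
            # determinant alone does not keep the iterate inside the PD cone,
            # where the objective is unbounded below
            L = np.linalg.cholesky(K)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(x)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        G = S - np.linalg.inv(K)
        val = -logdet + float(np.trace(S @ K))
        g = np.empty_like(x)
        g[:p] = np.diag(G) * np.exp(x[:p])
        for k, (i, j) in enumerate(free_edges):
            g[p + k] = 2.0 * G[i, j]
        return val, g

    x0 = np.zeros(p + len(free_edges))
    bounds = [(-15.0, 15.0)] * p + [(-1e4, 1e4)] * len(free_edges)
    res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"maxiter": 500})
    K = unpack(res.x)
    return K, -(n / 2.0) * float(res.fun)


def _standardize(values: pd.DataFrame) -> pd.DataFrame:
    """Mean-impute then z-score columns; constant columns are dropped."""
    x = values.copy()
    x = x.fillna(x.mean())
    sd = x.std(ddof=1)
    keep = sd[sd > 0].index
    dropped = [c for c in x.columns if c not in keep]
    if dropped:
        logger.warning("dropping %d constant trait columns", len(dropped))
    x = x[keep]
    return (x - x.mean()) / x.std(ddof=1)


def fit_glasso_ebic(
    profiles: TraitProfileMatrix | pd.DataFrame,
    gamma_ebic: float = 0.5,
    lambda_path: Sequence[float] | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> PartialCorrelationNetwork:
    """Graphical lasso with EBIC model selection.

    ``profiles`` may be a TraitProfileMatrix (traits x samples; transposed
    internally) or a samples x variables DataFrame.  Missing cells are
    mean-imputed and every column standardized before fitting.  When no
    explicit ``lambda_path`` is given, ``n_lambda`` log-spaced values from
    lambda_max (smallest penalty giving the empty graph) down to
    ``lambda_min_ratio * lambda_max`` are used.  Penalties whose fit fails
    to converge are dropped with a warning.
    """
    if isinstance(profiles, TraitProfileMatrix):
        data = profiles.values.T
    else:
        data = profiles
    X = _standardize(data)
    # exactly collinear columns (e.g. dummy groups of one categorical trait
    # whose profiles sum to 1) make the Gaussian model unidentifiable; drop
    # the redundant ones by pivoted QR
    from scipy.linalg import qr as _qr

    _, Rm, piv = _qr(X.to_numpy(), mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rm))
    rank = int((diag > max(diag.max(), 1e-12) * 1e-8).sum())
    if rank < X.shape[1]:
        redundant = sorted(X.columns[piv[rank:]])
        logger.warning("dropping %d linearly dependent trait columns: %s",
                       len(redundant), redundant[:6])
        X = X[sorted(X.columns[piv[:rank]], key=list(X.columns).index)]
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for network inference")
    S = np.cov(X.to_numpy(), rowvar=False, ddof=0)
    S = np.atleast_2d(S)

    if lambda_path is None:
        lam_max = float(np.max(np.abs(S - np.diag(np.diag(S)))))
        lam_max = max(lam_max, 1e-3)
        lambda_path = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    lambda_path = np.asarray(sorted(lambda_path, reverse=True), dtype=float)

    rows = []
    fits: dict[bytes, np.ndarray] = {}
    seen: set[bytes] = set()
    for lam in lambda_path:
        try:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                _, theta_pen = graphical_lasso(S, alpha=float(lam), max_iter=200)
        except Exception as exc:  # non-convergence at this penalty
            logger.warning("graphical lasso failed at lambda=%.4g: %s", lam, exc)
            continue
        support = np.abs(theta_pen) > 1e-10
        np.fill_diagonal(support, False)
        key = support.tobytes()
        n_edges = int(support[np.triu_indices(p, k=1)].sum())
        if key in seen:
            # same candidate model as a previous lambda; reuse its refit
            prev = next(r for r in rows if r["_key"] == key)
            rows.append({**prev, "lambda": float(lam)})
            continue
        seen.add(key)
        # the lasso path proposes the support; the likelihood entering EBIC
        # is that of the support-constrained (unshrunk) Gaussian MLE
        theta, loglik = _constrained_mle(S, support, n)
        ebic = (
            -2.0 * loglik
            + n_edges * np.log(n)
            + 4.0 * n_edges * gamma_ebic * np.log(p)
        )
        rows.append(
            {"lambda": float(lam), "n_edges": n_edges,
             "loglik": float(loglik), "ebic": float(ebic), "_key": key}
        )
        fits[key] = theta
    if not rows:
        raise RuntimeError("graphical lasso failed on the whole penalty path")

    path = pd.DataFrame(rows)
    best = path.loc[path["ebic"].idxmin()]
    theta = fits[best["_key"]]
    path = path.drop(columns=["_key"])
    d = np.sqrt(np.diag(theta))
    pcorr = -theta / np.outer(d, d)
    np.fill_diagonal(pcorr, 0.0)
    pcorr[np.abs(pcorr) < 1e-10] = 0.0

    cols = list(X.columns)
    return PartialCorrelationNetwork(
        partial_corr=pd.DataFrame(pcorr, index=cols, columns=cols),
        precision=pd.DataFrame(theta, index=cols, columns=cols),
        lambda_selected=float(best["lambda"]),
        gamma_ebic=gamma_ebic,
        n_samples=n,
        ebic_path=path,
    )


@dataclass
class TraitClusters:
    """Partition of the network's non-isolated nodes into trait suites."""

    assignment: pd.Series  # node -> cluster id (int); isolated nodes absent
    energy: float
    gamma_sg: float
    seed: int

    @property
    def clusters(self) -> dict[int, list[str]]:
        return {
            int(c): sorted(self.assignment.index[self.assignment == c])
            for c in sorted(self.assignment.unique())
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cluster_id": self.assignment.values, "trait": self.assignment.index}
        ).sort_values(["cluster_id", "trait"], ignore_index=True)


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric-cooling schedule for the Potts annealer."""

    t_start: float = 1.0
    t_end: float = 5e-3
    cooling: float = 0.95
    sweeps_per_temp: int = 15
    n_restarts: int = 3


def _signed_modularity_matrix(weights: np.ndarray, gamma: float) -> np.ndarray:
    """Pairwise gain matrix B of the signed spin-glass objective.

    B_ij = (w+_ij - gamma e+_ij) - (w-_ij - gamma e-_ij), where w+/w- are the
    positive/negative parts of the weights and e+/e- are configuration-model
    expectations s_i s_j / (2 W) on each subgraph.  Diagonal is zeroed.
    """
    w = np.asarray(weights, dtype=float)
    wp = np.clip(w, 0, None)
    wn = np.clip(-w, 0, None)
    B = np.zeros_like(w)
    for part, sign in ((wp, +1.0), (wn, -1.0)):
        total = part.sum() / 2.0
        if total <= 0:
            continue
        s = part.sum(axis=1)
        B += sign * (part - gamma * np.outer(s, s) / (2.0 * total))
    np.fill_diagonal(B, 0.0)
    return B


def signed_potts_energy(
    weights: np.ndarray, assignment: np.ndarray, gamma: float = 1.0
) -> float:
    """Energy of a partition under the signed spin-glass objective.

    H = - sum_{i<j, same cluster} B_ij with B the signed modularity matrix:
    positive weight inside clusters and negative weight between clusters
    lower the energy, relative to configuration-model expectations.
    """
    assignment = np.asarray(assignment)
    B = _signed_modularity_matrix(weights, gamma)
    same = assignment[:, None] == assignment[None, :]
    np.fill_diagonal(same, False)
    return -float((B * same).sum() / 2.0)


def spin_glass_communities(
    net: PartialCorrelationNetwork | np.ndarray,
    gamma_sg: float = 1.0,
    seed: int = 0,
    schedule: AnnealSchedule | None = None,
    node_names: Sequence[str] | None = None,
) -> TraitClusters:
    """Signed spin-glass community detection by simulated annealing.

    Isolated nodes (no incident edge) are excluded from the partition.
    The annealer proposes single-node moves to existing or new clusters and
    accepts by the Metropolis rule under geometric cooling; the best state
    over all restarts is returned.  Deterministic given ``seed``.
    """
    schedule = schedule or AnnealSchedule()
    if isinstance(net, PartialCorrelationNetwork):
        w_full = net.weight_matrix()
        names = list(net.nodes)
    else:
        w_full = np.asarray(net, dtype=float)
        names = list(node_names) if node_names is not None else [
            str(i) for i in range(len(w_full))
        ]

    if not np.isfinite(w_full).all():
        logger.warning("non-finite edge weights zeroed before clustering")
        w_full = np.where(np.isfinite(w_full), w_full, 0.0)
    degree = np.abs(w_full).sum(axis=1)
    active = np.where(degree > 0)[0]
    if active.size == 0:
        return TraitClusters(pd.Series(dtype=int), 0.0, gamma_sg, seed)
    w = w_full[np.ix_(active, active)]
    n = len(active)
    rng = np.random.default_rng(seed)
    B = _signed_modularity_matrix(w, gamma_sg)

    best_assign = None
    best_energy = np.inf
    for _ in range(schedule.n_restarts):
        assign = rng.integers(0, max(2, min(n, 8)), size=n)
        energy = signed_potts_energy(w, assign, gamma_sg)
        t = schedule.t_start
        while t > schedule.t_end:
            for _ in range(schedule.sweeps_per_temp * n):
                i = int(rng.integers(n))
                old = assign[i]
                choices = np.unique(assign)
                new_label = int(choices.max()) + 1  # allow opening a cluster
                options = [c for c in choices if c != old] + [new_label]
                new = options[int(rng.integers(len(options)))]
                # moving i changes only its same-cluster neighbourhood sums
                row = B[i]
                gain_old = float(row[assign == old].sum()) - float(row[i])
                gain_new = float(row[assign == new].sum())
                delta = gain_old - gain_new  # H change of moving i old -> new
                if delta <= 0 or rng.random() < np.exp(-delta / t):
                    assign[i] = new
                    energy += delta
            t *= schedule.cooling
        energy = signed_potts_energy(w, assign, gamma_sg)  # re-sync accumulation
        if energy < best_energy:
            best_energy = energy
            best_assign = assign.copy()

    # relabel clusters consecutively by first appearance
    relabel: dict[int, int] = {}
    labels = []
    for a in best_assign:
        if a not in relabel:
            relabel[a] = len(relabel) + 1
        labels.append(relabel[a])
    assignment = pd.Series(labels, index=[names[i] for i in active], dtype=int)
    return TraitClusters(assignment, float(best_energy), gamma_sg, seed)


@dataclass
class ClusterSiteNetwork:
    """Bipartite cluster-site graph from per-site sparse logistic models."""

    edges: pd.DataFrame  # columns cluster, site, weight
    lambda_by_site: dict[str, float]
    coefficients: pd.DataFrame  # traits x sites retained coefficients

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for _, row in self.edges.iterrows():
            g.add_node(f"cluster:{row['cluster']}", bipartite="cluster")
            g.add_node(f"site:{row['site']}", bipartite="site")
            g.add_edge(
                f"cluster:{row['cluster']}", f"site:{row['site']}",
                weight=float(row["weight"]),
            )
        return g


def site_cluster_network(
    profiles: TraitProfileMatrix,
    meta: SampleMetadata,
    clusters: TraitClusters,
    cv_folds: int = 10,
    seed: int = 0,
    c_path: Sequence[float] | None = None,
) -> ClusterSiteNetwork:
    """Per-site L1 logistic regressions summarized as a bipartite network.

    Each body site is modeled as a binary outcome over samples with the
    standardized trait profiles as predictors.  The inverse penalty C is
    chosen by minimizing cross-validated misclassification error; the edge
    weight between a cluster and a site is the mean of that cluster's
    retained (nonzero) coefficients, and the edge is absent when none are
    retained.
    """
    X = _standardize(profiles.values.T)  # samples x traits
    sites = meta.site_of().reindex(X.index)
    if c_path is None:
        c_path = np.geomspace(1e-2, 1e2, 13)

    edge_rows = []
    lam_by_site: dict[str, float] = {}
    coef_cols: dict[str, pd.Series] = {}
    for site in sorted(sites.dropna().unique()):
        y = (sites == site).astype(int).to_numpy()
        n_pos = int(y.sum())
        if n_pos == 0 or n_pos == len(y):
            continue
        k = min(cv_folds, n_pos, len(y) - n_pos)
        if k < cv_folds:
            logger.warning("site %s: reducing CV folds to %d", site, k)
        if k < 2:
            continue
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        errs = []
        for C in c_path:
            fold_err = []
            for tr, te in cv.split(X, y):
                m = LogisticRegression(
                    penalty="l1", C=float(C), solver="liblinear",
                    max_iter=2000, random_state=seed,
                )
                m.fit(X.iloc[tr], y[tr])
                fold_err.append(float((m.predict(X.iloc[te]) != y[te]).mean()))
            errs.append(np.mean(fold_err))
        best_c = float(c_path[int(np.argmin(errs))])
        lam_by_site[site] = 1.0 / best_c
        final = LogisticRegression(
            penalty="l1", C=best_c, solver="liblinear",
            max_iter=2000, random_state=seed,
        )
        final.fit(X, y)
        coefs = pd.Series(final.coef_[0], index=X.columns)
        coef_cols[site] = coefs
        for cluster_id, members in clusters.clusters.items():
            present = [m for m in members if m in coefs.index]
            retained = coefs.loc[present]
            retained = retained[retained != 0]
            if len(retained):
                edge_rows.append(
                    {"cluster": cluster_id, "site": site,
                     "weight": float(retained.mean())}
                )

    edges = pd.DataFrame(edge_rows, columns=["cluster", "site", "weight"])
    coefficients = pd.DataFrame(coef_cols)
    return ClusterSiteNetwork(edges, lam_by_site, coefficients)
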