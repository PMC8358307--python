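"""Covariate-adjusted Spearman association networks and bootstrap stability.

Nodes are the 28 analysis variables (26 neurophysiological parameters plus
MMSE and DBD-13); an edge between two variables is their partial Spearman
correlation given age and gender.  The partial Spearman is computed by
rank-transforming every column (average ranks for ties), residualizing the
two variable rank vectors on the covariate ranks by least squares, and
taking the product-moment correlation of the residuals; the p-value comes
from the t statistic with ``n - 2 - k`` degrees of freedom.  Edges with
p > 0.05 are removed, negative correlations are folded to positive (the
edge weight is |rho|; the signed value is kept as metadata), and no
multiplicity correction is applied, deliberately retaining weak clinical
edges.

Four association modes are supported: ``pre`` and ``post`` (one session's
variables), ``changes`` (post minus pre of every variable), and
``prediction`` (pre-treatment neurophysiological variables against the
change in the clinical scores).

Stability is quantified by a subject-level bootstrap: each iteration
resamples subjects with replacement and recomputes every (unthresholded)
edge weight; percentile confidence intervals summarize the per-edge weight
distributions.  The *variability* network compares the pre and post
bootstrap ensembles edge by edge with a Wilcoxon signed-rank test paired by
iteration (both ensembles share one resample matrix, so each iteration
resamples the same subjects in both sessions); its edge weight is the
magnitude of the standardized test statistic, and only the strongest
``top_fraction`` of edges is retained.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVariableError, InputError, PairingError
from .tables import ANALYSIS_VARIABLES, SCORES, ParameterTable

__all__ = [
    "Edge",
    "AssociationNetwork",
    "BootstrapEnsemble",
    "partial_spearman",
    "build_association_network",
    "bootstrap_networks",
    "edge_confidence_intervals",
    "variability_network",
    "export_network",
]

MODES = ("pre", "post", "changes", "prediction")
CLINICAL = set(SCORES) | {f"{s} Var" for s in SCORES}


@dataclass(frozen=True)
class Edge:
    u: str
    v: str
    weight: float
    rho_signed: float
    p_value: float


@dataclass
class AssociationNetwork:
    """Weighted variable-association graph for one analysis mode."""

    mode: str
    nodes: list[str]
    edges: list[Edge]
    alpha: float = 0.05
    flags: list[str] = field(default_factory=list)

    @property
    def node_class(self) -> dict[str, str]:
        return {
            n: "cognitive/behavioral" if n in CLINICAL else "neurophysiological"
            for n in self.nodes
        }

    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.nodes}
        for e in self.edges:
            deg[e.u] += 1
            deg[e.v] += 1
        return deg

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(mode=self.mode)
        classes = self.node_class
        for n in self.nodes:
            g.add_node(n, node_class=classes[n])
        for e in self.edges:
            g.add_edge(e.u, e.v, weight=e.weight, rho_signed=e.rho_signed,
                       p_value=e.p_value)
        return g


@dataclass
class BootstrapEnsemble:
    """Per-edge weight distributions over subject resamples."""

    mode: str
    nodes: list[str]
    edge_index: list[tuple[str, str]]
    resample_matrix: np.ndarray  # iterations x n_subjects
    weights: np.ndarray  # iterations x n_edges, |rho| with nan for degenerate
    seed: int

    @property
    def n_iterations(self) -> int:
        return self.resample_matrix.shape[0]


# ------------------------------------------------------------------ core math

def _rank(a: np.ndarray) -> np.ndarray:
    """Column-wise average ranks."""
    return stats.rankdata(a, axis=0)


def _residualize(y: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Residuals of columns of y on [1, c] by least squares."""
    design = np.column_stack([np.ones(len(y)), c])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def _partial_rank_corr_matrix(
    values: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, int]:
    """All-pairs partial Spearman rho and p for the columns of ``values``.

    Returns (rho matrix, p matrix, k) where k is the number of covariates.
    Constant columns yield nan rows/columns rather than raising.
    """
    n = values.shape[0]
    r = _rank(values)
    if covariates is not None and covariates.size:
        k = covariates.shape[1]
        resid = _residualize(r, _rank(covariates))
    else:
        k = 0
        resid = r - r.mean(axis=0)
    sd = resid.std(axis=0)
    ok = sd > 1e-12
    z = np.zeros_like(resid)
    z[:, ok] = (resid[:, ok] - resid[:, ok].mean(axis=0)) / sd[ok]
    rho = (z.T @ z) / n
    rho = np.clip(rho, -1.0, 1.0)
    rho[~ok, :] = np.nan
    rho[:, ~ok] = np.nan

    df = n - 2 - k
    if df <= 0:
        raise InputError(f"need n >= k + 4 samples (n={n}, k={k})")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt(df / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(rho) >= 1.0 - 1e-12, 0.0, p)
    return rho, p, k


def _permutation_p(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None,
    rho_obs: float, seed: int = 0, n_resamples: int = 20000,
) -> float:
    """Permutation p for the partial Spearman: permute y, refit, compare |rho|.

    Full enumeration when n! is tractable (n <= 8), otherwise seeded
    Monte-Carlo with ``n_resamples`` draws.
    """
    n = len(y)
    cols = np.column_stack([x, y])
    exact = math.factorial(n) <= 40320
    if exact:
        perms = itertools.permutations(range(n))
        total = hits = 0
        for perm in perms:
            cols[:, 1] = y[list(perm)]
            rho, _, _ = _partial_rank_corr_matrix(cols, covariates)
            hits += abs(rho[0, 1]) >= abs(rho_obs) - 1e-12
            total += 1
        return hits / total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_resamples):
        cols[:, 1] = rng.permutation(y)
        rho, _, _ = _partial_rank_corr_matrix(cols, covariates)
        hits += abs(rho[0, 1]) >= abs(rho_obs) - 1e-12
    return (hits + 1) / (n_resamples + 1)


def partial_spearman(
    x,
    y,
    covariates=None,
    method: str = "t",
    seed: int = 0,
) -> tuple[float, float]:
    """Covariate-adjusted Spearman correlation of x and y.

    Ranks x, y and the covariates (average ranks for ties), residualizes the
    x and y ranks on the covariate ranks, and correlates the residuals.
    ``method="t"`` gives the two-sided t-approximation p-value with
    ``n - 2 - k`` degrees of freedom; ``method="permutation"`` permutes y
    (exact enumeration for n <= 8, seeded Monte-Carlo above that).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InputError("x and y must have equal length")
    cov = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != x.size:
            cov = cov.T
        if cov.shape[0] != x.size:
            raise InputError("covariates must have one row per observation")
    k = 0 if cov is None else cov.shape[1]
    if x.size < k + 4:
        raise InputError(f"need n >= k + 4 samples (n={x.size}, k={k})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateVariableError("constant variable: correlation undefined")
    rho, p, _ = _partial_rank_corr_matrix(np.column_stack([x, y]), cov)
    rho_xy = float(rho[0, 1])
    if method == "t":
        return rho_xy, float(p[0, 1])
    if method == "permutation":
        return rho_xy, float(_permutation_p(x, y, cov, rho_xy, seed=seed))
    raise InputError(f"unknown method {method!r}")


# ------------------------------------------------------------- network builds

def _mode_frame(table: ParameterTable, mode: str) -> pd.DataFrame:
    if mode == "pre" or mode == "post":
        return table.session_values(mode)
    if mode == "changes":
        changes = table.change_values()
        return changes.rename(columns={v: f"{v} Var" for v in changes.columns})
    if mode == "prediction":
        pre = table.session_values("pre")
        neuro = pre[[v for v in ANALYSIS_VARIABLES if v not in SCORES]]
        changes = table.change_values()[list(SCORES)]
        changes = changes.rename(columns={s: f"{s} Var" for s in SCORES})
        return pd.concat([neuro, changes], axis=1)
    raise InputError(f"unknown network mode {mode!r}; expected one of {MODES}")


def build_association_network(
    table: ParameterTable,
    mode: str,
    covariate_adjust: bool = True,
    alpha: float = 0.05,
) -> AssociationNetwork:
    """Point-estimate association network for one mode.

    Every pair of the mode's 28 variables is tested with the partial
    Spearman correlation (age and gender as covariates unless
    ``covariate_adjust`` is False); pairs with p > ``alpha`` are dropped and
    the surviving edges carry weight |rho|.
    """
    frame = _mode_frame(table, mode)
    cov = table.covariates().to_numpy() if covariate_adjust else None
    values = frame.to_numpy(dtype=float)
    rho, p, _ = _partial_rank_corr_matrix(values, cov)
    nodes = list(frame.columns)
    edges = []
    for i, j in itertools.combinations(range(len(nodes)), 2):
        if np.isnan(rho[i, j]):
            continue  # degenerate variable: edge recorded as absent
        if p[i, j] < alpha:
            edges.append(
                Edge(nodes[i], nodes[j], abs(float(rho[i, j])),
                     float(rho[i, j]), float(p[i, j]))
            )
    return AssociationNetwork(mode=mode, nodes=nodes, edges=edges, alpha=alpha)


def bootstrap_networks(
    table: ParameterTable,
    mode: str,
    n_iterations: int = 2000,
    seed: int = 0,
    resample_matrix: np.ndarray | None = None,
) -> BootstrapEnsemble:
    """Subject-level bootstrap of all edge weights for one mode.

    Each iteration draws ``n_subjects`` subjects with replacement and
    recomputes every pairwise covariate-adjusted |rho| without the
    significance threshold, so confidence intervals are not truncated.
    Iterations in which a variable is constant record ``nan`` for the
    affected edges.  Passing an explicit ``resample_matrix`` overrides the
    seeded draw (e.g. the identity resample for a degenerate bootstrap).
    """
    if n_iterations < 1:
        raise InputError("n_iterations must be >= 1")
    frame = _mode_frame(table, mode)
    values = frame.to_numpy(dtype=float)
    cov = table.covariates().to_numpy()
    n = len(values)
    if resample_matrix is None:
        rng = np.random.default_rng(seed)
        resample_matrix = rng.integers(0, n, size=(n_iterations, n))
    else:
        resample_matrix = np.asarray(resample_matrix, dtype=int)
        if resample_matrix.shape != (n_iterations, n):
            raise InputError("resample_matrix must be n_iterations x n_subjects")
    nodes = list(frame.columns)
    pairs = list(itertools.combinations(range(len(nodes)), 2))
    weights = np.empty((n_iterations, len(pairs)))
    iu = tuple(np.array(p) for p in zip(*pairs))
    for it in range(n_iterations):
        idx = resample_matrix[it]
        rho, _, _ = _partial_rank_corr_matrix(values[idx], cov[idx])
        weights[it] = np.abs(rho[iu])
    return BootstrapEnsemble(
        mode=mode,
        nodes=nodes,
        edge_index=[(nodes[i], nodes[j]) for i, j in pairs],
        resample_matrix=resample_matrix,
        weights=weights,
        seed=seed,
    )


def edge_confidence_intervals(
    ensemble: BootstrapEnsemble, level: float = 0.95
) -> pd.DataFrame:
    """Percentile CIs of each edge's bootstrapped |rho| (nan-aware)."""
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nan edges
        for j, (u, v) in enumerate(ensemble.edge_index):
            w = ensemble.weights[:, j]
            valid = w[np.isfinite(w)]
            if valid.size:
                lo, hi, med = (np.percentile(valid, lo_q),
                               np.percentile(valid, hi_q),
                               np.median(valid))
            else:
                lo = hi = med = np.nan
            rows.append(
                {"node1": u, "node2": v, "median": med, "ci_low": lo,
                 "ci_high": hi, "n_valid": valid.size}
            )
    return pd.DataFrame(rows)


def _paired_wilcoxon_z(pre: np.ndarray, post: np.ndarray) -> tuple[float, float]:
    """Standardized Wilcoxon signed-rank statistic and two-sided p."""
    ok = np.isfinite(pre) & np.isfinite(post)
    d = post[ok] - pre[ok]
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    res = stats.wilcoxon(d, correction=False, method="approx")
    return float(res.zstatistic), float(res.pvalue)


def variability_network(
    ensemble_pre: BootstrapEnsemble,
    ensemble_post: BootstrapEnsemble,
    top_fraction: float = 0.05,
) -> AssociationNetwork:
    """Edge-wise paired comparison of the pre vs post bootstrap ensembles.

    For each edge the 2 x n_iterations bootstrapped weights are compared
    with a Wilcoxon signed-rank test paired by iteration index; the edge
    weight is |z|, the magnitude of the standardized statistic.  Exactly
    ``ceil(top_fraction * n_edges)`` strongest edges are retained, ties
    broken by smaller p then lexicographic node pair.  Requires both
    ensembles to share nodes, iteration count and resample matrix (the
    pairing that makes a signed-rank test well-posed).
    """
    if ensemble_pre.nodes != ensemble_post.nodes:
        raise PairingError("ensembles have different node sets")
    if ensemble_pre.edge_index != ensemble_post.edge_index:
        raise PairingError("ensembles have different edge indexing")
    if ensemble_pre.resample_matrix.shape != ensemble_post.resample_matrix.shape or \
            not np.array_equal(ensemble_pre.resample_matrix, ensemble_post.resample_matrix):
        raise PairingError("ensembles must share one resample matrix")
    if not 0 < top_fraction <= 1:
        raise InputError("top_fraction must be in (0, 1]")

    candidates = []
    for j, (u, v) in enumerate(ensemble_pre.edge_index):
        z, p = _paired_wilcoxon_z(
            ensemble_pre.weights[:, j], ensemble_post.weights[:, j]
        )
        candidates.append(Edge(u, v, abs(z), z, p))
    n_keep = math.ceil(top_fraction * len(candidates))
    candidates.sort(key=lambda e: (-e.weight, e.p_value, (e.u, e.v)))
    kept = candidates[:n_keep]
    flags = []
    if kept and max(e.weight for e in kept) == 0.0:
        flags.append("degenerate-top-set")
    return AssociationNetwork(
        mode="variability", nodes=list(ensemble_pre.nodes), edges=kept, flags=flags
    )


# ------------------------------------------------------------------- export

def export_network(network: AssociationNetwork, path: str | Path, fmt: str) -> Path:
    """Write a network as GEXF or as CSV node/edge lists.

    ``gexf`` emits a graph-tool-loadable file with node class attributes and
    edge weights; ``edge-csv`` emits ``node1,node2,weight,rho_signed,p_value``
    rows sorted by descending weight; ``node-csv`` emits node, class, degree.
    """
    path = Path(path)
    if fmt == "gexf":
        nx.write_gexf(network.to_graph(), path)
    elif fmt == "edge-csv":
        rows = [
            {"node1": e.u, "node2": e.v, "weight": e.weight,
             "rho_signed": e.rho_signed, "p_value": e.p_value}
            for e in sorted(network.edges, key=lambda e: -e.weight)
        ]
        pd.DataFrame(
            rows, columns=["node1", "node2", "weight", "rho_signed", "p_value"]
        ).to_csv(path, index=False, float_format="%.12g")
    elif fmt == "node-csv":
        deg = network.degree()
        classes = network.node_class
        pd.DataFrame(
            [{"node": n, "node_class": classes[n], "degree": deg[n]}
             for n in network.nodes]
        ).to_csv(path, index=False)
    else:
        raise InputError(f"unknown export format {fmt!r}")
    return path
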