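"""Moran's Eigenvector Maps: neighbour graphs, spatial weights, eigenbases,
and parsimony-driven model selection.

A spatial weighting matrix W is built from a neighbour graph (minimum
spanning tree, relative neighbourhood graph, Gabriel graph or Delaunay
triangulation — a hierarchy of increasing connectivity whose edge sets nest)
and an edge-weighting scheme (binary, f1 = 1/d, or f2 = 1 - d/d_max).
Eigenvectors of the double-centred W with positive eigenvalues model positive
spatial autocorrelation and serve as orthogonal spatial predictors.  Among
the 12 graph x scheme candidates, the most parsimonious regression of a
dissimilarity matrix's principal coordinates on a nested sequence of
eigenvectors (ranked by individual explanatory power, added one at a time)
is chosen by the corrected Akaike information criterion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import squareform, pdist

from .core_data import DistMatrix, SiteTable

__all__ = ["NeighbourGraph", "WeightScheme", "MemBasis", "MemSelection",
           "GRAPH_TYPES", "WEIGHT_KINDS", "build_graph", "weight_matrix",
           "mem_eigenvectors", "select_eigenvectors", "select_mem_model",
           "aicc"]

GRAPH_TYPES = ("mst", "rng", "gabriel", "delaunay")
WEIGHT_KINDS = ("binary", "f1", "f2")

#: eigenvalues above this are treated as genuinely positive
POSITIVE_EIG_TOL = 1e-10
#: AICc differences below this are ties, resolved toward fewer eigenvectors
AICC_TIE_TOL = 0.01


@dataclass
class NeighbourGraph:
    n: int
    edges: list[tuple[int, int, float]]  # (i, j, euclidean length), i < j
    graph_type: str

    def edge_set(self) -> set[tuple[int, int]]:
        return {(i, j) for i, j, _ in self.edges}

    def adjacency(self) -> np.ndarray:
        A = np.zeros((self.n, self.n))
        for i, j, _ in self.edges:
            A[i, j] = A[j, i] = 1.0
        return A


@dataclass(frozen=True)
class WeightScheme:
    kind: str  # binary | f1 | f2

    def __post_init__(self):
        if self.kind not in WEIGHT_KINDS:
            raise ValueError(f"unknown weighting scheme {self.kind!r}")


@dataclass
class MemBasis:
    """Positive-eigenvalue spatial eigenvectors (unit norm, zero sum)."""

    eigenvectors: np.ndarray      # n x k, columns sorted by descending eigenvalue
    eigenvalues: np.ndarray       # k positive reals, descending
    graph_type: str = ""
    weight_kind: str = ""

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[1]


@dataclass
class MemSelection:
    graph_type: str
    weight_kind: str
    retained: list[int]           # indices into the winning basis (0-based)
    aicc: float
    r2: float
    basis: MemBasis
    aicc_path: list[dict] = field(default_factory=list)
    all_candidates: list[dict] = field(default_factory=list)


def _delaunay_edges(pts: np.ndarray) -> set[tuple[int, int]]:
    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise ValueError(
            "Delaunay triangulation failed (collinear/degenerate points?); "
            "consider jittering the coordinates"
        ) from e
    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for i, j in itertools.combinations(simplex, 2):
            edges.add((min(i, j), max(i, j)))
    return edges


def build_graph(sites: SiteTable, graph_type: str) -> NeighbourGraph:
    """Neighbour graph over site coordinates.

    mst: spanning tree of minimum total length; rng: edge (i,j) unless some k
    is closer to both ends than they are to each other; gabriel: edge unless
    some k lies inside the circle with diameter ij; delaunay: triangulation
    edges.
    """
    if graph_type not in GRAPH_TYPES:
        raise ValueError(f"unknown graph type {graph_type!r}")
    pts = sites.coords()
    n = len(pts)
    if n < 3:
        raise ValueError("neighbour graphs need at least 3 sites")
    D = squareform(pdist(pts))
    edges: set[tuple[int, int]] = set()
    if graph_type == "mst":
        T = minimum_spanning_tree(D).tocoo()
        edges = {(min(i, j), max(i, j)) for i, j in zip(T.row, T.col)}
    elif graph_type in ("rng", "gabriel"):
        for i in range(n):
            for j in range(i + 1, n):
                others = np.delete(np.arange(n), [i, j])
                if graph_type == "rng":
                    blocked = np.any(np.maximum(D[i, others], D[j, others]) < D[i, j])
                else:
                    blocked = np.any(D[i, others] ** 2 + D[j, others] ** 2 < D[i, j] ** 2)
                if not blocked:
                    edges.add((i, j))
    else:
        edges = _delaunay_edges(pts)
    edge_list = sorted((i, j, float(D[i, j])) for i, j in edges)
    return NeighbourGraph(n, edge_list, graph_type)


def weight_matrix(g: NeighbourGraph, scheme: WeightScheme) -> np.ndarray:
    """Symmetric n x n spatial weighting matrix for one graph + scheme."""
    W = np.zeros((g.n, g.n))
    if not g.edges:
        return W
    d_max = max(d for _, _, d in g.edges)
    for i, j, d in g.edges:
        if scheme.kind == "binary":
            w = 1.0
        elif scheme.kind == "f1":
            if d <= 0:
                raise ValueError("f1 weighting requires strictly positive edge lengths")
            w = 1.0 / d
        else:  # f2
            w = 1.0 - d / d_max
        W[i, j] = W[j, i] = w
    return W


def mem_eigenvectors(W: np.ndarray, graph_type: str = "",
                     weight_kind: str = "") -> MemBasis:
    """Positive-eigenvalue eigenvectors of the double-centred weight matrix.

    Omega = H W H with H = I - 11'/n; columns are unit-norm, sum to zero, and
    are sorted by descending eigenvalue.  Moran's I of each eigenvector
    (under the same W) is a monotone function of its eigenvalue, so the
    leading vectors describe the broadest positively autocorrelated patterns.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n) or not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("weight matrix must be square and symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("weight matrix must have a zero diagonal")
    H = np.eye(n) - np.ones((n, n)) / n
    omega = H @ W @ H
    eigvals, eigvecs = np.linalg.eigh(omega)
    keep = eigvals > POSITIVE_EIG_TOL
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    # deterministic sign: largest-magnitude element positive
    for k in range(eigvecs.shape[1]):
        j = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] *= -1
    return MemBasis(eigvecs, eigvals, graph_type, weight_kind)


def aicc(rss: float, n: int, p: int) -> float:
    """Corrected AIC for a least-squares model: n ln(RSS/n) + 2p + 2p(p+1)/(n-p-1)."""
    if n - p - 1 <= 0:
        raise ValueError("AICc undefined for n - p - 1 <= 0")
    if rss <= 0:
        rss = np.finfo(float).tiny
    return n * np.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def _response_axes(beta: DistMatrix) -> np.ndarray:
    """Positive-eigenvalue principal coordinates of the dissimilarity matrix,
    scaled by the square roots of their eigenvalues so that pooled residual
    sums of squares weight each axis by the inertia it carries."""
    from .cap_ordination import pcoa
    axes, _eigvals, _neg = pcoa(beta)
    return axes


def _path_rss(Y: np.ndarray, basis: MemBasis, order: list[int]) -> list[float]:
    """RSS pooled over response axes for the nested models along ``order``,
    starting from the intercept-only model (step 0)."""
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    rss = [float(np.sum(Yc**2))]
    for step in range(1, len(order) + 1):
        X = basis.eigenvectors[:, order[:step]]
        # eigenvectors are centred and orthonormal: projection is X X' Yc
        fitted = X @ (X.T @ Yc)
        rss.append(float(np.sum((Yc - fitted) ** 2)))
    return rss


def select_eigenvectors(Y: np.ndarray, basis: MemBasis) -> tuple[list[int], float, list[dict]]:
    """AICc-guided selection of eigenvectors for a (possibly multivariate)
    response.

    Eigenvectors are ranked by individual explanatory power, entered one at a
    time, and the nested model with the lowest AICc along that path is
    retained (ties within 0.01 go to the smaller model).  Returns (retained
    indices, best AICc, path records).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = Y.shape[0]
    if basis.k == 0:
        Yc = Y - Y.mean(axis=0)
        a = aicc(float(np.sum(Yc**2)), n, 1)
        return [], a, [{"p": 1, "indices": [], "aicc": a}]
    Yc = Y - Y.mean(axis=0)
    tss = float(np.sum(Yc**2))
    # rank by individual R^2 (orthonormal basis: R^2_k = ||v_k' Yc||^2 / TSS)
    proj = basis.eigenvectors.T @ Yc          # k x q
    indiv = np.sum(proj**2, axis=1) / tss
    order = list(np.argsort(indiv)[::-1])
    rss_path = _path_rss(Y, basis, order)
    path = []
    for step, rss in enumerate(rss_path):
        p = step + 1  # intercept + step eigenvectors
        if n - p - 1 <= 0:
            break
        path.append({"p": p, "indices": sorted(order[:step]),
                     "aicc": aicc(rss, n, p), "r2": 1 - rss / tss})
    best = min(path, key=lambda rec: rec["aicc"])
    # parsimony tie-break: smallest model within the tolerance of the minimum
    for rec in path:  # path is ordered by increasing model size
        if rec["aicc"] <= best["aicc"] + AICC_TIE_TOL:
            best = rec
            break
    return list(best["indices"]), float(best["aicc"]), path


def select_mem_model(beta: DistMatrix, sites: SiteTable) -> MemSelection:
    """Choose the most parsimonious spatial model among the 12 candidates.

    For each graph type x weighting scheme: build the positive-eigenvalue
    basis, run the AICc forward path against the principal coordinates of
    ``beta``, and record the path minimum.  The overall winner is the
    candidate with the lowest best-AICc.
    """
    if beta.labels != sites.site_ids:
        raise ValueError("beta matrix and site table must be aligned (same site order)")
    Y = _response_axes(beta)
    candidates = []
    for gt in GRAPH_TYPES:
        graph = build_graph(sites, gt)
        for wk in WEIGHT_KINDS:
            W = weight_matrix(graph, WeightScheme(wk))
            basis = mem_eigenvectors(W, gt, wk)
            retained, best_aicc, path = select_eigenvectors(Y, basis)
            r2 = next(rec["r2"] for rec in path
                      if rec["indices"] == sorted(retained)) if path else 0.0
            candidates.append({"graph_type": gt, "weight_kind": wk,
                               "retained": retained, "aicc": best_aicc,
                               "r2": r2, "basis": basis, "path": path})
    winner = min(candidates,
                 key=lambda c: (c["aicc"], len(c["retained"]), c["graph_type"],
                                c["weight_kind"]))
    return MemSelection(
        graph_type=winner["graph_type"], weight_kind=winner["weight_kind"],
        retained=winner["retained"], aicc=winner["aicc"], r2=winner["r2"],
        basis=winner["basis"], aicc_path=winner["path"],
        all_candidates=[{k: v for k, v in c.items() if k not in ("basis", "path")}
                        for c in candidates],
    )


def morans_i(vec: np.ndarray, W: np.ndarray) -> float:
    """Moran's I spatial autocorrelation of one variable under weights W."""
    z = vec - vec.mean()
    s0 = W.sum()
    if s0 == 0:
        raise ValueError("weight matrix has no edges")
    n = len(vec)
    return n / s0 * float(z @ W @ z) / float(z @ z)
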