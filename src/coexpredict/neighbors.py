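"""Gene-gene distances and neighbor constructions.

Three neighborhood definitions are used by the predictors:

* standard k-nearest neighbors (k genes of smallest combined distance);
* mutual nearest neighbors: j is a neighbor of a target i only if each lies
  in the other's top-K distance list, with a floor of the target's top
  ``fallback`` neighbors so no target ends up isolated;
* dense subnet: of a target's top-K neighbors, the m with the highest degree
  inside the subgraph of the global K-NN graph induced by those K genes.

All distances are Euclidean over the concatenated profiles of the strains
with complete data.  Prediction targets are prohibited from serving as
neighbors (their prediction-strain values are the unknowns), which every
construction enforces via the ``forbidden`` set.  Ties in distance are broken
by dataset gene order, making every construction deterministic.

Top-K membership (used by the mutual and dense-subnet constructions) is
evaluated on the full gene set — geometry only, excluding a gene itself —
while forbidden genes are filtered when the returned neighbor set is chosen.
Removing targets from every candidate pool instead would make the mutual set
of a target empty by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import ExpressionDataset

__all__ = [
    "DistanceMatrix",
    "NeighborGraph",
    "strain_distance",
    "combined_distance_matrix",
    "knn_neighbors",
    "mutual_knn_neighbors",
    "dense_subnet_neighbors",
    "build_neighbor_graph",
]


def strain_distance(
    ds: ExpressionDataset, i: str, j: str, strain: str, replicates: str = "mean"
) -> float:
    """Euclidean distance between two genes' profiles within one strain."""
    a = ds.profile(i, strain, replicates=replicates)
    b = ds.profile(j, strain, replicates=replicates)
    return float(np.linalg.norm(a - b))


class DistanceMatrix:
    """Symmetric gene x gene Euclidean distance matrix over complete strains."""

    def __init__(self, genes: Sequence[str], values: np.ndarray, *, validate: bool = True):
        self.genes = tuple(genes)
        self.values = np.asarray(values, dtype=float)
        self._index = {g: i for i, g in enumerate(self.genes)}
        if validate:
            if self.values.shape != (len(self.genes),) * 2:
                raise ValueError("distance matrix shape does not match gene list")
            if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
                raise ValueError("distances must be finite and non-negative")
            if np.any(np.diagonal(self.values) != 0):
                raise ValueError("distance matrix diagonal must be zero")
            if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
                raise ValueError("distance matrix must be symmetric")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"unknown gene identifier {gene!r}") from None

    def distance(self, i: str, j: str) -> float:
        return float(self.values[self.index(i), self.index(j)])


def combined_distance_matrix(
    ds: ExpressionDataset, exclude: str | None = None, replicates: str = "mean"
) -> DistanceMatrix:
    """Distance over the concatenation of all complete strains' profiles.

    Equivalently ``sqrt(sum_s d_s^2)`` over the per-strain distances; the
    prediction strain (``exclude``) never contributes.
    """
    if exclude is None:
        exclude = ds.prediction_strain
    if exclude != ds.prediction_strain:
        raise ValueError(
            f"excluded strain must be the prediction strain {ds.prediction_strain!r}"
        )
    if len(ds.complete_strains) < 1:
        raise ValueError("need at least one complete strain to compute distances")
    profiles = ds.complete_profiles(replicates=replicates)
    dm = squareform(pdist(profiles, metric="euclidean"))
    np.fill_diagonal(dm, 0.0)
    return DistanceMatrix(ds.genes, dm, validate=False)


# ---------------------------------------------------------------------------
# ranking helpers


def _ordered_indices(row: np.ndarray, self_idx: int, banned: np.ndarray | None = None) -> np.ndarray:
    """All gene indices ordered by (distance, dataset order), self/banned last."""
    d = row.copy()
    d[self_idx] = np.inf
    if banned is not None:
        d[banned] = np.inf
    return np.argsort(d, kind="stable")  # stable => ties fall back to gene order


def _top_lists(values: np.ndarray, K: int) -> list[np.ndarray]:
    """Top-K index lists for every gene over the full set (excluding self)."""
    n = values.shape[0]
    order = np.argsort(values, kind="stable", axis=1)
    out = []
    for i in range(n):
        row = order[i]
        row = row[row != i][:K]
        out.append(row)
    return out


def _forbidden_array(D: DistanceMatrix, forbidden) -> np.ndarray:
    idx = sorted({D.index(g) for g in forbidden})
    return np.asarray(idx, dtype=int)


def knn_neighbors(
    D: DistanceMatrix, gene: str, k: int, forbidden: Sequence[str] = ()
) -> list[str]:
    """The k nearest eligible genes, ascending by distance."""
    if k < 1:
        raise ValueError("k must be >= 1")
    gi = D.index(gene)
    banned = _forbidden_array(D, set(forbidden) - {gene})
    eligible = D.n_genes - 1 - banned.size
    if eligible < k:
        raise ValueError(f"k={k} exceeds the {eligible} eligible genes for {gene!r}")
    order = _ordered_indices(D.values[gi], gi, banned)
    return [D.genes[j] for j in order[:k]]


def mutual_knn_neighbors(
    D: DistanceMatrix,
    gene: str,
    K: int = 20,
    fallback: int = 3,
    forbidden: Sequence[str] = (),
    _top: list[np.ndarray] | None = None,
) -> list[str]:
    """Mutual top-K neighbors of a target, floored at its top ``fallback``.

    Returns ``M_i | T_i`` ordered by distance to ``gene``, where ``M_i`` is
    the set of eligible genes j with j in top-K(i) and i in top-K(j), and
    ``T_i`` the target's ``fallback`` nearest eligible genes.
    """
    if not (K >= fallback >= 1):
        raise ValueError("need K >= fallback >= 1")
    gi = D.index(gene)
    top = _top if _top is not None else _top_lists(D.values, K)
    banned_set = set(_forbidden_array(D, set(forbidden) - {gene}).tolist())
    mutual = [j for j in top[gi] if j not in banned_set and gi in top[j]]
    floor = knn_neighbors(D, gene, fallback, forbidden)
    floor_idx = [D.index(g) for g in floor]
    chosen = set(mutual) | set(floor_idx)
    order = _ordered_indices(D.values[gi], gi)
    return [D.genes[j] for j in order if j in chosen][: len(chosen)]


def dense_subnet_neighbors(
    D: DistanceMatrix,
    gene: str,
    K: int = 20,
    m: int = 10,
    forbidden: Sequence[str] = (),
    _top: list[np.ndarray] | None = None,
) -> list[str]:
    """The m best-connected genes within the target's top-K neighborhood.

    The global K-NN graph (undirected: an edge exists if either endpoint
    lists the other in its top-K) is induced on the target's K nearest
    eligible genes; candidates are ranked by degree in that subgraph, ties
    broken by distance to the target, then gene order.
    """
    if K < m:
        raise ValueError("need K >= m")
    candidates = knn_neighbors(D, gene, K, forbidden)  # raises if pool too small
    cand_idx = [D.index(g) for g in candidates]
    top = _top if _top is not None else _top_lists(D.values, K)

    graph = nx.Graph()
    graph.add_nodes_from(cand_idx)
    cand_set = set(cand_idx)
    for a in cand_idx:
        for b in top[a]:
            if b in cand_set and b != a:
                graph.add_edge(a, b)

    gi = D.index(gene)
    ranked = sorted(cand_idx, key=lambda j: (-graph.degree(j), D.values[gi, j], j))
    return [D.genes[j] for j in ranked[:m]]


@dataclass
class NeighborGraph:
    """Per-target neighbor lists with distances and construction metadata."""

    construction: str
    params: dict
    neighbors: Mapping[str, tuple[str, ...]]
    distances: Mapping[str, tuple[float, ...]] = field(default_factory=dict)

    def export_edges(self, path) -> None:
        """Write (gene_a, gene_b, distance) TSV for inspection."""
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tdistance\n")
            for g, nbrs in self.neighbors.items():
                dists = self.distances.get(g, (float("nan"),) * len(nbrs))
                for nb, d in zip(nbrs, dists):
                    fh.write(f"{g}\t{nb}\t{d:.17g}\n")


def build_neighbor_graph(
    D: DistanceMatrix,
    targets: Sequence[str],
    construction: str,
    forbidden: Sequence[str] | None = None,
    **params,
) -> NeighborGraph:
    """Neighborhoods for every target under one construction.

    ``forbidden`` defaults to the target set itself: no target may serve as
    a neighbor of another.  Callers with additional masked genes (e.g. a
    holdout round on a dataset whose true targets are already hidden) pass
    the wider set.  The global top-K lists needed by the mutual and
    dense-subnet constructions are computed once and shared.
    """
    forbidden = tuple(targets) if forbidden is None else tuple(set(forbidden) | set(targets))
    if construction == "knn":
        k = params.get("k", 10)
        fn = lambda g: knn_neighbors(D, g, k, forbidden)
    elif construction == "mutual":
        K, fb = params.get("K", 20), params.get("fallback", 3)
        top = _top_lists(D.values, K)
        fn = lambda g: mutual_knn_neighbors(D, g, K, fb, forbidden, _top=top)
    elif construction == "dense":
        K, m = params.get("K", 20), params.get("m", 10)
        top = _top_lists(D.values, K)
        fn = lambda g: dense_subnet_neighbors(D, g, K, m, forbidden, _top=top)
    else:
        raise ValueError(f"unknown construction {construction!r}")

    neighbors, distances = {}, {}
    for g in targets:
        nbrs = tuple(fn(g))
        neighbors[g] = nbrs
        gi = D.index(g)
        distances[g] = tuple(float(D.values[gi, D.index(nb)]) for nb in nbrs)
    return NeighborGraph(construction, dict(params), neighbors, distances)
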