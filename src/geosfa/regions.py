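"""District contiguity structure and Gaussian Markov random field (GMRF)
machinery for the structured spatial inefficiency effect.

Districts are neighbours if they share a common border.  The intrinsic
GMRF (ICAR) prior penalizes squared differences of the effect between
contiguous districts; its precision structure K has K_ii = degree(i),
K_ij = -1 for neighbours.  K annihilates component-wise constants, so
draws are identified by a sum-to-zero constraint per connected
component.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve


@dataclass
class RegionGraph:
    """Ordered region identifiers with a symmetric contiguity relation.

    ``edges`` holds each undirected edge once as an (m, 2) array of
    region indices; ``coarse_map`` optionally maps each region to a
    coarser (NUTS2-style) region identifier.
    """

    regions: list
    edges: np.ndarray
    coarse_map: dict | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.regions = list(self.regions)
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("region ids not unique")
        if len(self.regions) == 0:
            raise ValueError("empty region graph")
        self._index = {r: i for i, r in enumerate(self.regions)}
        e = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if np.any(e[:, 0] == e[:, 1]):
            raise ValueError("self-edges are not allowed")
        if e.size and (e.min() < 0 or e.max() >= len(self.regions)):
            raise ValueError("edge endpoint out of range")
        # deduplicate, store each undirected edge once with i < j
        e = np.unique(np.sort(e, axis=1), axis=0) if e.size else e
        self.edges = e

    # -- basic structure ----------------------------------------------------
    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def index_of(self, region_ids) -> np.ndarray:
        try:
            return np.array([self._index[r] for r in region_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"region id {exc.args[0]!r} not in graph") from exc

    @property
    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_regions, dtype=int)
        if self.edges.size:
            np.add.at(d, self.edges[:, 0], 1)
            np.add.at(d, self.edges[:, 1], 1)
        return d

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_regions))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def components(self) -> np.ndarray:
        """Connected-component label per region."""
        labels = np.full(self.n_regions, -1, dtype=int)
        for k, comp in enumerate(nx.connected_components(self.to_networkx())):
            labels[list(comp)] = k
        return labels

    @property
    def n_components(self) -> int:
        return int(self.components().max()) + 1

    def precision_matrix(self) -> sp.csr_matrix:
        """ICAR structure matrix K (row sums zero, rank n - #components)."""
        n = self.n_regions
        if not self.edges.size:
            return sp.csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([i, j, np.arange(n)])
        cols = np.concatenate([j, i, np.arange(n)])
        vals = np.concatenate([-np.ones(2 * len(i)), self.degrees.astype(float)])
        return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def neighbor_lists(self) -> list[np.ndarray]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_regions)]
        for a, b in self.edges:
            nbrs[a].append(b)
            nbrs[b].append(a)
        return [np.array(x, dtype=int) for x in nbrs]

    def coloring(self) -> np.ndarray:
        """Greedy proper coloring (parallel single-site MCMC updates)."""
        col = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        return np.array([col[i] for i in range(self.n_regions)], dtype=int)

    # -- coarse level -------------------------------------------------------
    def coarsen(self) -> "RegionGraph":
        """Aggregate to the coarse level implied by ``coarse_map``;
        coarse regions are adjacent if any member districts are."""
        if self.coarse_map is None:
            raise ValueError("no coarse_map on this graph")
        coarse_ids = sorted({self.coarse_map[r] for r in self.regions})
        cidx = {c: i for i, c in enumerate(coarse_ids)}
        memb = np.array([cidx[self.coarse_map[r]] for r in self.regions])
        ce = {(min(a, b), max(a, b))
              for a, b in ((memb[i], memb[j]) for i, j in self.edges)
              if a != b}
        edges = np.array(sorted(ce), dtype=int).reshape(-1, 2)
        return RegionGraph(coarse_ids, edges)

    def coarse_index(self) -> np.ndarray:
        """Per-region index into the coarsened graph's ordering."""
        coarse = self.coarsen()
        return coarse.index_of([self.coarse_map[r] for r in self.regions])


# ---------------------------------------------------------------------------
# construction

def build_graph_from_edgelist(path, regions: list | None = None,
                              coarse_map: dict | None = None,
                              sep: str | None = None) -> RegionGraph:
    """Two-column delimited text, one edge per line.

    With ``regions`` given (the full ordered district list, including
    isolated districts that appear in no edge), every edge endpoint must
    be among them; otherwise the region set is taken from the edges.
    """
    pairs = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep) if sep else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected two region ids")
            pairs.append((parts[0], parts[1]))
    if not pairs:
        raise ValueError(f"{path}: empty edge list")
    seen = {r for p in pairs for r in p}
    if regions is None:
        regions = sorted(seen)
    else:
        dangling = seen - set(regions)
        if dangling:
            raise ValueError(f"{path}: edge endpoints not in the declared "
                             f"region list: {sorted(dangling)[:5]}")
    idx = {r: i for i, r in enumerate(regions)}
    edges = np.array([[idx[a], idx[b]] for a, b in pairs], dtype=int)
    return RegionGraph(regions, edges, coarse_map=coarse_map)


def build_graph_from_polygons(path, id_property: str = "id",
                              coarse_property: str | None = None) -> RegionGraph:
    """Derive rook contiguity from a GeoJSON FeatureCollection: regions
    are neighbours when their polygons share a boundary of nonzero
    length (point touches do not count)."""
    from shapely.geometry import shape
    from shapely.strtree import STRtree

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"]
    ids = [f["properties"][id_property] for f in feats]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region ids in polygon file")
    geoms = [shape(f["geometry"]) for f in feats]
    tree = STRtree(geoms)
    edges = set()
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.intersection(geoms[j])
            if inter.length > 0:
                edges.add((i, j))
    coarse_map = None
    if coarse_property is not None:
        coarse_map = {ids[i]: feats[i]["properties"][coarse_property]
                      for i in range(len(ids))}
    return RegionGraph(ids, np.array(sorted(edges), dtype=int).reshape(-1, 2),
                       coarse_map=coarse_map)


# ---------------------------------------------------------------------------
# GMRF primitives

def gmrf_quadform(f: np.ndarray, graph: RegionGraph) -> float:
    """f'Kf = sum over edges of (f_i - f_j)^2; zero iff f is constant on
    each connected component."""
    f = np.asarray(f, dtype=float)
    if f.shape != (graph.n_regions,):
        raise ValueError(
            f"effect vector length {f.shape} != n_regions {graph.n_regions}")
    if not graph.edges.size:
        return 0.0
    d = f[graph.edges[:, 0]] - f[graph.edges[:, 1]]
    return float(d @ d)


def _center_per_component(f: np.ndarray, labels: np.ndarray) -> np.ndarray:
    out = f.copy()
    for k in range(labels.max() + 1):
        m = labels == k
        out[m] -= out[m].mean()
    return out


def sample_structured_effect(data_precision: np.ndarray,
                             data_linear: np.ndarray,
                             graph: RegionGraph,
                             tau2: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Joint draw of the structured effect from its Gaussian full
    conditional given per-region Gaussian likelihood contributions.

    The full conditional has precision Q = K/tau2 + diag(data_precision)
    and mean solving Q m = data_linear; the draw is re-centered to sum
    to zero within each connected component (ICAR identification).
    Regions without data (zero precision entries) are informed by their
    neighbours only.
    """
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    n = graph.n_regions
    dp = np.asarray(data_precision, dtype=float)
    dl = np.asarray(data_linear, dtype=float)
    if dp.shape != (n,) or dl.shape != (n,):
        raise ValueError("data term length mismatch with graph")
    Q = (graph.precision_matrix() / tau2).toarray()
    Q[np.diag_indices(n)] += dp
    try:
        cf = cho_factor(Q)
    except np.linalg.LinAlgError as exc:
        comps = graph.components()
        empty = [k for k in range(comps.max() + 1)
                 if not np.any(dp[comps == k] > 0)]
        raise np.linalg.LinAlgError(
            f"singular full-conditional precision (components without any "
            f"data: {empty}); the ICAR prior is improper along component "
            f"constants") from exc
    mean = cho_solve(cf, dl)
    # draw: mean + L^-T z with Q = L L'
    L = np.linalg.cholesky(Q)
    z = rng.standard_normal(n)
    draw = mean + np.linalg.solve(L.T, z)
    return _center_per_component(draw, graph.components())


def sample_icar(graph: RegionGraph, tau2: float,
                rng: np.random.Generator) -> np.ndarray:
    """Draw from the intrinsic GMRF prior under the per-component
    sum-to-zero constraint (spectral construction on the non-null
    eigenpairs of K).  Isolated regions get 0."""
    K = graph.precision_matrix().toarray()
    w, V = np.linalg.eigh(K)
    pos = w > 1e-9 * max(w.max(), 1.0)
    z = rng.standard_normal(int(pos.sum()))
    f = (V[:, pos] * (np.sqrt(tau2 / w[pos]) * z)).sum(axis=1)
    return _center_per_component(f, graph.components())


def make_lattice_graph(g: int, coarse_block: int | None = None) -> RegionGraph:
    """g x g rook-adjacency lattice (2 g (g-1) edges); optionally with a
    coarse map aggregating ``coarse_block`` x ``coarse_block`` tiles."""
    if g < 2:
        raise ValueError("lattice size must be >= 2")
    regions = [f"d{r:02d}{c:02d}" for r in range(g) for c in range(g)]
    edges = []
    for r in range(g):
        for c in range(g):
            i = r * g + c
            if c + 1 < g:
                edges.append((i, i + 1))
            if r + 1 < g:
                edges.append((i, i + g))
    coarse_map = None
    if coarse_block:
        coarse_map = {f"d{r:02d}{c:02d}": f"n{r // coarse_block}{c // coarse_block}"
                      for r in range(g) for c in range(g)}
    return RegionGraph(regions, np.array(edges, dtype=int),
                       coarse_map=coarse_map)


def export_choropleth_geojson(graph: RegionGraph, values: dict[str, np.ndarray],
                              path, geometries: dict | None = None) -> None:
    """Write posterior spatial means as GeoJSON properties.  Without
    supplied geometries, lattice graphs get unit-square polygons so the
    export is always renderable."""
    feats = []
    for i, r in enumerate(graph.regions):
        if geometries is not None and r in geometries:
            geom = geometries[r]
        elif isinstance(r, str) and len(r) == 5 and r.startswith("d"):
            row, col = int(r[1:3]), int(r[3:5])
            geom = {"type": "Polygon", "coordinates": [[
                [col, -row], [col + 1, -row], [col + 1, -row - 1],
                [col, -row - 1], [col, -row]]]}
        else:
            geom = None
        props = {"id": str(r)}
        for name, arr in values.items():
            props[name] = float(arr[i])
        feats.append({"type": "Feature", "geometry": geom, "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
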