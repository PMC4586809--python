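"""Areal adjacency structures and contiguity rules.

Neighbourhood graphs drive both the intrinsic CAR (ICAR) priors and the
spatially varying disparity coefficient.  Graphs can be built from polygon
geometry with queen or rook contiguity, read from a plain edge list, or
generated synthetically (see :mod:`arealdisp.simulate`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse
from shapely.geometry import shape


class GraphError(ValueError):
    pass


@dataclass
class AdjacencyGraph:
    """Symmetric, irreflexive neighbour structure over a fixed area list.

    ``areas`` fixes the ordering used by all vectorized code downstream;
    ``neighbors`` maps each area id to the set of its neighbours.
    """

    areas: list
    neighbors: dict
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        areaset = set(self.areas)
        if len(areaset) != len(self.areas):
            raise GraphError("duplicate area ids")
        for a in self.areas:
            self.neighbors.setdefault(a, set())
        for a, nbs in self.neighbors.items():
            if a not in areaset:
                raise GraphError(f"neighbor list for unknown area {a!r}")
            if a in nbs:
                raise GraphError(f"self-loop at {a!r}")
            for b in nbs:
                if b not in areaset:
                    raise GraphError(f"edge to unknown area {b!r}")
                if a not in self.neighbors.get(b, set()):
                    raise GraphError(f"asymmetric edge {a!r}-{b!r}")
        isolated = [a for a in self.areas if not self.neighbors[a]]
        if isolated:
            self.warnings.append(f"isolated areas (no neighbours): {isolated[:10]}")

    # -- basic structure ---------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.areas)

    def degree(self, area) -> int:
        return len(self.neighbors[area])

    def degrees(self) -> np.ndarray:
        return np.array([len(self.neighbors[a]) for a in self.areas], dtype=np.int64)

    def edges(self) -> list[tuple]:
        out = []
        index = {a: i for i, a in enumerate(self.areas)}
        for a in self.areas:
            for b in self.neighbors[a]:
                if index[a] < index[b]:
                    out.append((a, b))
        return out

    def edge_index(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer index pairs (i, j), i < j, one per undirected edge."""
        index = {a: i for i, a in enumerate(self.areas)}
        pairs = [(index[a], index[b]) for a, b in self.edges()]
        if not pairs:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        arr = np.array(pairs, dtype=np.int64)
        return arr[:, 0], arr[:, 1]

    def adjacency_matrix(self) -> sparse.csr_matrix:
        i, j = self.edge_index()
        n = self.n_areas
        data = np.ones(len(i))
        W = sparse.coo_matrix((data, (i, j)), shape=(n, n))
        W = W + W.T
        return W.tocsr()

    def laplacian(self) -> np.ndarray:
        """Dense graph Laplacian D - W (the ICAR structure matrix)."""
        W = self.adjacency_matrix().toarray()
        return np.diag(W.sum(axis=1)) - W

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.areas)
        g.add_edges_from(self.edges())
        return g

    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())

    def coloring(self) -> list[np.ndarray]:
        """Greedy proper colouring as boolean masks over the area order.

        Areas within one colour class are mutually non-adjacent, so their
        ICAR full conditionals are independent given the rest — the masks
        drive vectorized single-site MCMC updates.
        """
        colors = nx.greedy_color(self.to_networkx(), strategy="largest_first")
        k = max(colors.values(), default=0) + 1
        masks = []
        order = np.array([colors[a] for a in self.areas])
        for c in range(k):
            masks.append(order == c)
        return masks

    def bind(self, panel_areas: list) -> "AdjacencyGraph":
        """Check area ids match a panel's and return the graph reordered."""
        if set(panel_areas) != set(self.areas):
            extra = set(self.areas) - set(panel_areas)
            missing = set(panel_areas) - set(self.areas)
            raise GraphError(
                f"graph/panel area mismatch (graph-only: {sorted(extra)[:5]}, "
                f"panel-only: {sorted(missing)[:5]})"
            )
        return AdjacencyGraph(list(panel_areas), {a: set(self.neighbors[a]) for a in self.areas})

    def to_edge_list(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in self.edges():
                fh.write(f"{a} {b}\n")
            for a in self.areas:
                if not self.neighbors[a]:
                    fh.write(f"{a} .\n")


def read_adjacency(path, areas: list | None = None) -> AdjacencyGraph:
    """Read a two-column whitespace edge list; ``a .`` declares an isolate.

    Edges are symmetrized; self-loops are dropped with a warning.
    """
    neighbors: dict = {}
    seen: list = []
    warnings = []

    def _touch(a):
        if a not in neighbors:
            neighbors[a] = set()
            seen.append(a)

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 2:
                raise GraphError(f"line {lineno}: expected two columns, got {parts}")
            a, b = parts
            _touch(a)
            if b == ".":
                continue
            _touch(b)
            if a == b:
                warnings.append(f"line {lineno}: self-loop {a!r} dropped")
                continue
            neighbors[a].add(b)
            neighbors[b].add(a)
    if areas is not None:
        unknown = set(seen) - set(areas)
        if unknown:
            raise GraphError(f"edge-list areas not in panel: {sorted(unknown)[:5]}")
        for a in areas:
            _touch(a)
        seen = list(areas)
    g = AdjacencyGraph(seen, neighbors)
    g.warnings.extend(warnings)
    return g


def build_contiguity(geometries: dict, rule: str = "queen", snap: float = 1e-9) -> AdjacencyGraph:
    """Build a contiguity graph from ``{area_id: shapely polygon}``.

    queen: areas sharing at least one boundary point are neighbours.
    rook:  a shared boundary segment of positive length is required.
    Coordinates are snapped to a grid of spacing ``snap`` before comparing
    vertices, so exactly shared vertices are found deterministically.
    """
    if rule not in ("queen", "rook"):
        raise GraphError(f"unknown contiguity rule {rule!r}")
    areas = list(geometries)
    geoms = {}
    for a, g in geometries.items():
        if g is None or g.is_empty:
            raise GraphError(f"empty geometry for area {a!r}")
        if g.area <= 0:
            raise GraphError(f"degenerate (zero-area) geometry for area {a!r}")
        geoms[a] = g

    def _vertices(g):
        pts = set()
        boundary = g.boundary
        lines = getattr(boundary, "geoms", [boundary])
        for line in lines:
            for x, y in line.coords:
                pts.add((round(x / snap) * snap, round(y / snap) * snap))
        return pts

    verts = {a: _vertices(g) for a in areas}
    neighbors: dict = {a: set() for a in areas}
    for i, a in enumerate(areas):
        for b in areas[i + 1 :]:
            ga, gb = geoms[a], geoms[b]
            # cheap bounding-box reject
            ax0, ay0, ax1, ay1 = ga.bounds
            bx0, by0, bx1, by1 = gb.bounds
            if ax1 < bx0 - snap or bx1 < ax0 - snap or ay1 < by0 - snap or by1 < ay0 - snap:
                continue
            rook_touch = ga.boundary.intersection(gb.boundary).length > 0
            if rule == "rook":
                touch = rook_touch
            else:
                touch = rook_touch or bool(verts[a] & verts[b])
            if touch:
                neighbors[a].add(b)
                neighbors[b].add(a)
    return AdjacencyGraph(areas, neighbors)


def read_geojson(path) -> dict:
    """Read a GeoJSON FeatureCollection into ``{area_id: geometry}``."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise GraphError("expected a GeoJSON FeatureCollection")
    out = {}
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if "area_id" not in props:
            raise GraphError("every feature needs an 'area_id' property")
        out[props["area_id"]] = shape(feat["geometry"])
    return out
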