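"""The bone graph: a region-connectivity model of a binarized skeleton.

Every connected bone region of every transaxial slice becomes a node;
two regions on *adjacent* slices are linked by a paired down-link and
up-link whenever their (x, y) pixel sets overlap.  Each directed edge
carries the overlap weight

    w_ij = |R(i)| * |R(i) n R(j)| / |R(i) u R(j)|**2

which lies in [0, 1], equals 1 for identical regions and 0 for disjoint
ones.  Spine extraction is a greedy graph clustering seeded at the neck:
a growing cluster C1 absorbs a neighbouring cluster when its similarity
to C1 balances its similarity to everything else (cost d < 0.5), and
otherwise decomposes the neighbour's image region watershed-style — the
C1-side region is dilated into it, the remainder is eroded, and the
resulting reference regions are grown synchronously until their meeting
fronts form dam pixels that split the region.  The loop ends when C1 is
completely disconnected from all remaining clusters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .errors import NonConvergenceError
from .preprocess import SliceRegion

__all__ = [
    "BoneGraph",
    "ClusterState",
    "edge_weight",
    "build_graph",
    "cluster_similarity",
    "cost_distance",
    "reference_regions",
    "split_region_by_dams",
    "extract_cluster",
    "square_element",
]


def square_element(size: int = 3) -> np.ndarray:
    """Odd-sized square structuring element (all ones)."""
    if size < 1 or size % 2 == 0:
        raise ValueError("structuring element size must be odd and >= 1")
    return np.ones((size, size), dtype=bool)


# ---------------------------------------------------------------------------
# Edge weight and graph construction
# ---------------------------------------------------------------------------

def edge_weight(Ri, Rj) -> float:
    """Directed overlap weight of region i with region j.

    ``w_ij = |R(i)| * |R(i) n R(j)| / |R(i) u R(j)|**2`` — 0 for disjoint
    pixel sets, 1 when they are identical.
    """
    Ri, Rj = set(Ri), set(Rj)
    if not Ri or not Rj:
        raise ValueError("edge_weight requires two non-empty pixel sets")
    inter = len(Ri & Rj)
    if inter == 0:
        return 0.0
    union = len(Ri | Rj)
    return len(Ri) * inter / union ** 2


class BoneGraph:
    """Bone graph over per-slice regions with paired directed edges.

    Backed by a :class:`networkx.DiGraph`; node keys are region ids,
    each node stores its :class:`~spectspine.preprocess.SliceRegion`.
    An edge pair exists iff the two regions lie on adjacent slices and
    their (x, y) pixel sets overlap; both directed weights are stored.
    """

    def __init__(self) -> None:
        self.g = nx.DiGraph()

    # -- basic queries ----------------------------------------------------
    def __contains__(self, node_id) -> bool:
        return node_id in self.g

    def __len__(self) -> int:
        return self.g.number_of_nodes()

    @property
    def node_ids(self):
        return list(self.g.nodes)

    def region(self, node_id) -> SliceRegion:
        return self.g.nodes[node_id]["region"]

    def slice_of(self, node_id) -> int:
        return self.region(node_id).z

    def nodes_in_slice(self, z: int) -> list:
        return sorted(n for n in self.g.nodes if self.slice_of(n) == z)

    def slices(self) -> list[int]:
        return sorted({self.slice_of(n) for n in self.g.nodes})

    def weight(self, u, v) -> float:
        """Directed weight w_uv; 0 when the edge does not exist."""
        data = self.g.get_edge_data(u, v)
        return 0.0 if data is None else data["weight"]

    def sym_weight(self, u, v) -> float:
        """Symmetrized weight (w_uv + w_vu) / 2."""
        return 0.5 * (self.weight(u, v) + self.weight(v, u))

    def neighbors(self, u) -> list:
        """Adjacent nodes (edge pairing makes adjacency symmetric)."""
        return sorted(set(self.g.successors(u)) | set(self.g.predecessors(u)))

    def down_neighbors(self, u) -> list:
        zu = self.slice_of(u)
        return [v for v in self.neighbors(u) if self.slice_of(v) == zu + 1]

    def up_neighbors(self, u) -> list:
        zu = self.slice_of(u)
        return [v for v in self.neighbors(u) if self.slice_of(v) == zu - 1]

    # -- construction and editing ----------------------------------------
    def add_region(self, region: SliceRegion, connect: bool = True) -> None:
        if region.region_id in self.g:
            raise ValueError(f"duplicate node id {region.region_id!r}")
        self.g.add_node(region.region_id, region=region)
        if connect:
            self._connect(region.region_id)

    def _connect(self, node_id) -> None:
        """(Re)compute edges of one node to both adjacent slices."""
        region = self.region(node_id)
        for z in (region.z - 1, region.z + 1):
            for other_id in self.nodes_in_slice(z):
                other = self.region(other_id)
                if _bbox_disjoint(region.bbox, other.bbox):
                    continue
                if region.pixels & other.pixels:
                    self.g.add_edge(node_id, other_id,
                                    weight=edge_weight(region.pixels,
                                                       other.pixels))
                    self.g.add_edge(other_id, node_id,
                                    weight=edge_weight(other.pixels,
                                                       region.pixels))

    def remove_node(self, node_id) -> None:
        self.g.remove_node(node_id)

    def cut(self, u, v) -> None:
        """Remove the paired edges between u and v."""
        if self.g.has_edge(u, v):
            self.g.remove_edge(u, v)
        if self.g.has_edge(v, u):
            self.g.remove_edge(v, u)

    def copy(self) -> "BoneGraph":
        out = BoneGraph()
        out.g = self.g.copy()
        return out

    def check_edge_pairing(self) -> bool:
        """True iff every directed edge has its reverse and weights are
        in [0, 1] and endpoints lie on adjacent slices."""
        for u, v, data in self.g.edges(data=True):
            if not self.g.has_edge(v, u):
                return False
            if not 0 <= data["weight"] <= 1:
                return False
            if abs(self.slice_of(u) - self.slice_of(v)) != 1:
                return False
        return True

    def export_edge_list(self, path) -> None:
        """Plain-text dump: one node line and one edge-pair line each."""
        lines = []
        for n in sorted(self.g.nodes):
            r = self.region(n)
            lines.append(f"node\t{n}\t{r.z}\t{r.area}\t"
                         f"{r.centroid[0]:.3f}\t{r.centroid[1]:.3f}")
        seen = set()
        for u, v in sorted(self.g.edges):
            if (v, u) in seen:
                continue
            seen.add((u, v))
            lines.append(f"edge\t{u}\t{v}\t{self.weight(u, v):.6f}\t"
                         f"{self.weight(v, u):.6f}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _bbox_disjoint(a, b) -> bool:
    return a[2] < b[0] or b[2] < a[0] or a[3] < b[1] or b[3] < a[1]


def build_graph(slices: list[list[SliceRegion]]) -> BoneGraph:
    """Build the bone graph from per-slice region lists (cranial first)."""
    graph = BoneGraph()
    for regions in slices:
        for region in regions:
            graph.add_region(region, connect=False)
    for z_regions, next_regions in zip(slices, slices[1:]):
        for rm in z_regions:
            for rn in next_regions:
                if _bbox_disjoint(rm.bbox, rn.bbox):
                    continue
                if rm.pixels & rn.pixels:
                    graph.g.add_edge(rm.region_id, rn.region_id,
                                     weight=edge_weight(rm.pixels, rn.pixels))
                    graph.g.add_edge(rn.region_id, rm.region_id,
                                     weight=edge_weight(rn.pixels, rm.pixels))
    return graph


# ---------------------------------------------------------------------------
# Cluster similarity and cost
# ---------------------------------------------------------------------------

def cluster_similarity(A, B, graph: BoneGraph) -> float:
    """Similarity S(A, B): sum of symmetrized edge weights across the cut.

    Each unordered connected pair (i in A, j in B) contributes
    ``(w_ij + w_ji) / 2`` once, making S symmetric and additive over
    disjoint unions.
    """
    A, B = set(A), set(B)
    if A & B:
        raise ValueError("clusters must be disjoint")
    total = 0.0
    small, large = (A, B) if len(A) <= len(B) else (B, A)
    for i in small:
        for j in graph.neighbors(i):
            if j in large:
                total += graph.sym_weight(i, j)
    return total


def cost_distance(S_1i: float, S_other: float) -> float:
    """Merge/split cost d = |S_1i - S_other| / max(S_1i, S_other).

    ``S_1i`` is the similarity of cluster C_i to the growing cluster C1;
    ``S_other`` is its total similarity to every other cluster.  A value
    below 0.5 indicates C_i sits evenly on C1's frontier and should be
    merged; d >= 0.5 flags an unbalanced (branching) cluster to split.
    """
    if S_1i <= 0:
        raise ValueError("cost_distance requires S_1i > 0")
    S_other = max(float(S_other), 0.0)
    return abs(S_1i - S_other) / max(S_1i, S_other)


# ---------------------------------------------------------------------------
# Region decomposition (reference regions + dam splitting)
# ---------------------------------------------------------------------------

def _sets_to_grids(sets, pad):
    """Rasterize pixel sets onto a common padded grid.

    Returns (grids, (x0, y0)) where grids[k][y, x] indexes local coords.
    """
    all_pixels = set().union(*sets)
    xs = [p[0] for p in all_pixels]
    ys = [p[1] for p in all_pixels]
    x0, y0 = min(xs) - pad, min(ys) - pad
    w = max(xs) - x0 + 1 + pad
    h = max(ys) - y0 + 1 + pad
    grids = []
    for s in sets:
        grid = np.zeros((h, w), dtype=bool)
        for x, y in s:
            grid[y - y0, x - x0] = True
        grids.append(grid)
    return grids, (x0, y0)


def _grid_to_set(grid, origin) -> frozenset:
    x0, y0 = origin
    ys, xs = np.nonzero(grid)
    return frozenset((int(x) + x0, int(y) + y0) for x, y in zip(xs, ys))


def reference_regions(M, Rx, B: np.ndarray | None = None) -> list[frozenset]:
    """Assemble the reference regions used to decompose region M.

    ``Rx`` is the pixel projection of the C1-side neighbour.  The
    reference set is the dilated projection clipped to M, plus every
    connected component of the eroded remainder ``(M - Rx) eroded B``
    (made disjoint from the first member by subtraction).  ``B`` defaults
    to a 5x5 square.  Empty members are dropped; the result may
    legitimately be a single region.
    """
    M = set(M)
    if not M:
        raise ValueError("M must be non-empty")
    Rx = set(Rx)
    if B is None:
        B = square_element(5)
    pad = max(B.shape) // 2 + 1
    (m_grid, rx_grid), origin = _sets_to_grids([M, Rx or {next(iter(M))}],
                                               pad)
    if not Rx:
        rx_grid[:] = False
    dilated = ndimage.binary_dilation(rx_grid, structure=B) & m_grid
    remainder = m_grid & ~rx_grid
    eroded = ndimage.binary_erosion(remainder, structure=B,
                                    border_value=0)
    eroded &= ~dilated  # keep members pairwise disjoint
    refs = []
    if dilated.any():
        refs.append(_grid_to_set(dilated, origin))
    labels, n = ndimage.label(eroded, structure=square_element(3))
    comps = []
    for lab in range(1, n + 1):
        comp = _grid_to_set(labels == lab, origin)
        if comp:
            comps.append(comp)
    refs.extend(sorted(comps, key=lambda s: sorted(s)))
    return refs


def split_region_by_dams(M, refs, growth: np.ndarray | None = None):
    """Partition M by growing the reference regions synchronously.

    Every reference region is dilated one morphological step per round,
    restricted to M; pixels reached by two or more fronts in the same
    round become dam pixels (which block further growth).  When growth
    stops, the dams are removed and the grown regions — one per
    reference, plus one per pocket left unreachable behind a dam — are
    the parts.  (The grown regions themselves are returned rather than
    the connected components of M minus the dams: a meeting front is a
    4-connected barrier with diagonal gaps, so under 8-connectivity the
    dam pixels alone would not always disconnect the parts.)

    Returns
    -------
    (parts, dams)
        ``parts`` — list of connected pixel frozensets, pairwise
        disjoint, whose union is M minus the dams; ``dams`` — frozenset
        of dam pixels.
    """
    M = set(M)
    refs = [set(r) for r in refs]
    if not refs:
        raise ValueError("at least one reference region is required")
    for r in refs:
        if not r <= M:
            raise ValueError("reference regions must be subsets of M")
    for a, b in itertools.combinations(refs, 2):
        if a & b:
            raise ValueError("reference regions must be pairwise disjoint")
    if growth is None:
        growth = square_element(3)
    (m_grid, *ref_grids), origin = _sets_to_grids([M, *refs], 1)
    labels = np.zeros(m_grid.shape, dtype=np.int32)
    for k, rg in enumerate(ref_grids, start=1):
        labels[rg] = k
    dam = np.zeros(m_grid.shape, dtype=bool)
    while True:
        free = m_grid & (labels == 0) & ~dam
        if not free.any():
            break
        fronts = []
        for k in range(1, len(refs) + 1):
            grown = ndimage.binary_dilation(labels == k, structure=growth)
            fronts.append(grown & free)
        count = np.sum(fronts, axis=0)
        newly_single = count == 1
        newly_dam = count >= 2
        if not (newly_single.any() or newly_dam.any()):
            break  # pockets unreachable past dams stay unlabeled
        for k, front in enumerate(fronts, start=1):
            labels[front & newly_single] = k
        dam |= newly_dam
    parts = []
    for k in range(1, len(refs) + 1):
        part = _grid_to_set(labels == k, origin)
        if part:
            parts.append(part)
    unreached = m_grid & (labels == 0) & ~dam
    if unreached.any():
        comp_labels, n = ndimage.label(unreached, structure=growth)
        for lab in range(1, n + 1):
            parts.append(_grid_to_set(comp_labels == lab, origin))
    parts = sorted(parts, key=lambda s: sorted(s))
    return parts, _grid_to_set(dam, origin)


# ---------------------------------------------------------------------------
# Iterative cluster extraction
# ---------------------------------------------------------------------------

@dataclass
class ClusterState:
    """Evolving partition of bone-graph nodes around the spine cluster C1.

    All clusters other than C1 are singletons throughout the procedure,
    so the partition is fully described by the C1 membership set.
    """

    graph: BoneGraph
    c1_label: str = "C1"
    c1_nodes: set = field(default_factory=set)
    merge_log: list = field(default_factory=list)

    @property
    def assignment(self) -> dict:
        out = {}
        for n in self.graph.node_ids:
            out[n] = self.c1_label if n in self.c1_nodes else f"C[{n}]"
        return out

    def log(self, event: str, **info) -> None:
        self.merge_log.append({"event": event, **info})

    def export_merge_log(self, path) -> None:
        import json
        with open(path, "w") as fh:
            for rec in self.merge_log:
                fh.write(json.dumps(rec, default=str) + "\n")

    def residual_similarity(self) -> float:
        """Sum of S(C1, C_i) over all remaining clusters (0 at the end)."""
        total = 0.0
        for u in self.c1_nodes:
            for v in self.graph.neighbors(u):
                if v not in self.c1_nodes:
                    total += self.graph.sym_weight(u, v)
        return total


def _frontier_key(graph):
    def key(node_id):
        return (graph.slice_of(node_id), str(node_id))
    return key


def extract_cluster(graph: BoneGraph, seed, *,
                    merge_floor: float = 0.05,
                    cap_factor: int = 10,
                    ref_element: np.ndarray | None = None,
                    growth_element: np.ndarray | None = None,
                    mutate: bool = False) -> ClusterState:
    """Grow the spine cluster C1 from a seed node by merge/split rounds.

    Repeatedly examines every cluster C_i with positive similarity
    ``S_1i`` to C1: its cost ``d_i`` (see :func:`cost_distance`) decides
    between merging it into C1 (d < 0.5) and decomposing its image
    region via :func:`reference_regions` + :func:`split_region_by_dams`,
    after which the affected graph neighbourhood is rebuilt.  A split
    that cannot change the topology (single reference region, or a
    single surviving part) is resolved at the chain terminals: the node
    is merged when its symmetrized similarity to C1 exceeds
    ``merge_floor``, otherwise its edges to C1 are cut.  The procedure
    stops when C1 is disconnected from every remaining cluster.

    Parameters
    ----------
    graph
        Bone graph; left untouched unless ``mutate=True`` (a copy is
        modified and returned inside the state).
    seed
        Node id to seed C1 with (normally the neck reference node).
    merge_floor
        Minimum symmetrized similarity to C1 for a terminal node to be
        absorbed rather than cut off.
    cap_factor
        Iteration cap = ``cap_factor * |V|`` events; exceeding it raises
        :class:`~spectspine.errors.NonConvergenceError`.

    Returns
    -------
    ClusterState
        With ``c1_nodes`` the extracted spine nodes, the (possibly
        rebuilt) graph, and a full merge/split/cut event log.
    """
    if seed not in graph:
        raise ValueError(f"seed node {seed!r} not in graph")
    if not mutate:
        graph = graph.copy()
    if ref_element is None:
        ref_element = square_element(5)
    if growth_element is None:
        growth_element = square_element(3)
    state = ClusterState(graph=graph, c1_nodes={seed})
    state.log("seed", node=seed, slice=graph.slice_of(seed))
    cap = max(1, cap_factor * len(graph))
    events = 0
    split_serial = 0
    key = _frontier_key(graph)

    def s1_of(v) -> float:
        return sum(graph.sym_weight(v, u)
                   for u in graph.neighbors(v) if u in state.c1_nodes)

    while True:
        frontier = sorted(
            {v for u in state.c1_nodes for v in graph.neighbors(u)
             if v not in state.c1_nodes and graph.sym_weight(u, v) > 0},
            key=key)
        if not frontier:
            break
        progressed = False
        for v in frontier:
            if v not in graph or v in state.c1_nodes:
                continue
            s1 = s1_of(v)
            if s1 <= 0:
                continue
            s_other = sum(graph.sym_weight(v, j)
                          for j in graph.neighbors(v)
                          if j not in state.c1_nodes)
            d = cost_distance(s1, s_other)
            events += 1
            if events > cap:
                raise NonConvergenceError(
                    f"clustering exceeded {cap} events", state.merge_log)
            if d < 0.5:
                state.c1_nodes.add(v)
                state.log("merge", node=v, d=round(d, 6), S1=round(s1, 6))
                progressed = True
                continue
            # --- split path -------------------------------------------
            c1_neighbors = [u for u in graph.neighbors(v)
                            if u in state.c1_nodes]
            # strongest C1-side neighbour; smallest id on ties
            x = min(c1_neighbors,
                    key=lambda u: (-graph.sym_weight(v, u), str(u)))
            M = graph.region(v).pixels
            Rx = graph.region(x).pixels
            refs = reference_regions(M, Rx, ref_element)
            parts = []
            if len(refs) >= 2:
                parts, dams = split_region_by_dams(M, refs, growth_element)
            if len(parts) >= 2:
                z = graph.slice_of(v)
                graph.remove_node(v)
                new_ids = []
                for part in parts:
                    split_serial += 1
                    rid = f"{v}/{split_serial}"
                    graph.add_region(
                        SliceRegion(region_id=rid, z=z, pixels=part))
                    new_ids.append(rid)
                state.log("split", node=v, d=round(d, 6),
                          n_parts=len(parts), n_dams=len(dams),
                          new_nodes=new_ids)
                progressed = True
                break  # topology changed: recompute the frontier
            # --- no topology change: terminal rule --------------------
            if s1 > merge_floor:
                state.c1_nodes.add(v)
                state.log("terminal-merge", node=v, d=round(d, 6),
                          S1=round(s1, 6))
            else:
                for u in c1_neighbors:
                    graph.cut(v, u)
                state.log("cut", node=v, d=round(d, 6), S1=round(s1, 6))
            progressed = True
        if not progressed:
            break
    state.log("stop", residual=state.residual_similarity(),
              c1_size=len(state.c1_nodes))
    return state
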