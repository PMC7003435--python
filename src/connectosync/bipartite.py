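"""Barber-modularity bipartite module detection via LPAb+ label propagation.

Significant TTC gene pairs form a binary bipartite graph: genes of one region
on the bottom side, genes of the other on the top side, one edge per
significant pair.  Barber's bipartite modularity

    Q_B = (1/m) * sum_ij (A_ij - k_i * d_j / m) * delta(label_i, label_j)

compares within-module edges to a degree-preserving bipartite null.  LPAb+
maximizes Q_B in two stages: a bottom-up label-propagation sweep in which
each node adopts the neighbouring label with the largest local Q_B gain, and
a top-down stage greedily merging module pairs while any merge increases
Q_B.  The procedure restarts from several seeded node orders and returns the
best labeling.  Modules with more than a configured number of internal edges
(1000 in the original study) are kept and their genes pooled per tissue.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BipartiteGraph:
    """Binary bipartite graph between two gene sets.

    ``bottom`` / ``top`` hold the node names; ``edges`` the (bottom index,
    top index) pairs.  Degree vectors and adjacency lists are precomputed.
    """

    bottom: list[str]
    top: list[str]
    edges: np.ndarray  # (m, 2) int array of (bottom_idx, top_idx)
    adj_bottom: list[np.ndarray] = field(repr=False, default_factory=list)
    adj_top: list[np.ndarray] = field(repr=False, default_factory=list)
    deg_bottom: np.ndarray = field(repr=False, default=None)
    deg_top: np.ndarray = field(repr=False, default=None)

    @classmethod
    def from_edges(cls, edge_list) -> "BipartiteGraph":
        """Build from (gene_a, gene_b) pairs; duplicates collapse to one edge."""
        pairs = sorted({(str(a), str(b)) for a, b in edge_list})
        bottom = sorted({a for a, _ in pairs})
        top = sorted({b for _, b in pairs})
        bi = {g: i for i, g in enumerate(bottom)}
        ti = {g: i for i, g in enumerate(top)}
        edges = np.array([(bi[a], ti[b]) for a, b in pairs], dtype=np.int64)
        g = cls(bottom=bottom, top=top, edges=edges)
        g._index()
        return g

    @classmethod
    def from_ttc(cls, ttc_result) -> "BipartiteGraph":
        return cls.from_edges(
            zip(ttc_result.pairs.gene_a, ttc_result.pairs.gene_b)
        )

    def _index(self) -> None:
        nb, nt = len(self.bottom), len(self.top)
        self.deg_bottom = np.bincount(self.edges[:, 0], minlength=nb)
        self.deg_top = np.bincount(self.edges[:, 1], minlength=nt)
        self.adj_bottom = [np.empty(0, dtype=np.int64) for _ in range(nb)]
        self.adj_top = [np.empty(0, dtype=np.int64) for _ in range(nt)]
        order = np.argsort(self.edges[:, 0], kind="stable")
        for i, grp in itertools.groupby(order, key=lambda e: self.edges[e, 0]):
            self.adj_bottom[i] = self.edges[list(grp), 1]
        order = np.argsort(self.edges[:, 1], kind="stable")
        for j, grp in itertools.groupby(order, key=lambda e: self.edges[e, 1]):
            self.adj_top[j] = self.edges[list(grp), 0]

    @property
    def m(self) -> int:
        return len(self.edges)


@dataclass
class Labeling:
    """Module labels for both sides plus the achieved Barber modularity."""

    bottom_labels: np.ndarray
    top_labels: np.ndarray
    qb: float

    def as_dict(self, graph: BipartiteGraph) -> dict[tuple[str, str], int]:
        out = {}
        for name, lab in zip(graph.bottom, self.bottom_labels):
            out[("bottom", name)] = int(lab)
        for name, lab in zip(graph.top, self.top_labels):
            out[("top", name)] = int(lab)
        return out


def barber_modularity(
    graph: BipartiteGraph,
    bottom_labels: np.ndarray,
    top_labels: np.ndarray,
) -> float:
    """Q_B of a labeling, by the degree-null formula.

    The adjacency term sums over edges with co-labeled endpoints; the null
    term sums k_i * d_j / m over all co-labeled (bottom, top) node pairs,
    which reduces to a per-label product of degree sums.
    """
    if graph.m == 0:
        raise ValueError("modularity undefined for an empty graph")
    bl = np.asarray(bottom_labels)
    tl = np.asarray(top_labels)
    if bl.shape[0] != len(graph.bottom) or tl.shape[0] != len(graph.top):
        raise ValueError("labeling does not cover all nodes")
    m = graph.m
    within = np.sum(bl[graph.edges[:, 0]] == tl[graph.edges[:, 1]])
    labels = np.union1d(bl, tl)
    remap = {l: i for i, l in enumerate(labels)}
    kb = np.zeros(len(labels))
    kt = np.zeros(len(labels))
    np.add.at(kb, [remap[l] for l in bl], graph.deg_bottom)
    np.add.at(kt, [remap[l] for l in tl], graph.deg_top)
    null = float(np.sum(kb * kt)) / m
    return (within - null) / m


def _propagate(
    graph: BipartiteGraph,
    bl: np.ndarray,
    tl: np.ndarray,
    rng: np.random.Generator,
    max_sweeps: int,
) -> None:
    """Stage 1: node-by-node label adoption maximizing the local Q_B gain.

    For a bottom node i considering label L, the local contribution is
    (#neighbours with label L) - k_i * D_L / m, with D_L the top-side degree
    sum of L (and symmetrically for top nodes).  Moves with strictly positive
    gain are accepted; ties on gain resolve to the smallest label id, which
    makes the sweep deterministic given the node order.
    """
    m = graph.m
    n_labels = len(graph.bottom) + len(graph.top)
    K = np.zeros(n_labels)  # bottom degree sum per label
    D = np.zeros(n_labels)  # top degree sum per label
    np.add.at(K, bl, graph.deg_bottom)
    np.add.at(D, tl, graph.deg_top)

    nb = len(graph.bottom)
    node_ids = np.arange(nb + len(graph.top))
    for _ in range(max_sweeps):
        changed = 0
        order = rng.permutation(node_ids)
        for node in order:
            if node < nb:
                i = node
                neigh = graph.adj_bottom[i]
                if neigh.size == 0:
                    continue
                cur = bl[i]
                cand = np.unique(tl[neigh])
                counts = np.array(
                    [np.sum(tl[neigh] == c) for c in cand], dtype=float
                )
                gains = counts - graph.deg_bottom[i] * D[cand] / m
                cur_gain = (
                    np.sum(tl[neigh] == cur)
                    - graph.deg_bottom[i] * D[cur] / m
                )
                best = np.max(gains)
                if best > cur_gain + 1e-12:
                    new = int(cand[gains >= best - 1e-12].min())
                    K[cur] -= graph.deg_bottom[i]
                    K[new] += graph.deg_bottom[i]
                    bl[i] = new
                    changed += 1
            else:
                j = node - nb
                neigh = graph.adj_top[j]
                if neigh.size == 0:
                    continue
                cur = tl[j]
                cand = np.unique(bl[neigh])
                counts = np.array(
                    [np.sum(bl[neigh] == c) for c in cand], dtype=float
                )
                gains = counts - graph.deg_top[j] * K[cand] / m
                cur_gain = (
                    np.sum(bl[neigh] == cur) - graph.deg_top[j] * K[cur] / m
                )
                best = np.max(gains)
                if best > cur_gain + 1e-12:
                    new = int(cand[gains >= best - 1e-12].min())
                    D[cur] -= graph.deg_top[j]
                    D[new] += graph.deg_top[j]
                    tl[j] = new
                    changed += 1
        if changed == 0:
            break


def _merge_modules(
    graph: BipartiteGraph, bl: np.ndarray, tl: np.ndarray
) -> None:
    """Stage 2: greedily merge module pairs while any merge increases Q_B.

    Merging labels (a, b) changes Q_B by
    [E_cross(a, b) - (K_a * D_b + K_b * D_a) / m] / m, where E_cross counts
    edges between the two modules and K/D are per-label degree sums.  Only
    pairs sharing at least one edge are candidates; best gain first, ties to
    the smallest label pair.
    """
    m = graph.m
    while True:
        eb = bl[graph.edges[:, 0]]
        et = tl[graph.edges[:, 1]]
        cross = {}
        for a, b in zip(eb, et):
            if a != b:
                key = (min(a, b), max(a, b))
                cross[key] = cross.get(key, 0) + 1
        if not cross:
            return
        K = {}
        D = {}
        for lab, deg in zip(bl, graph.deg_bottom):
            K[lab] = K.get(lab, 0) + deg
        for lab, deg in zip(tl, graph.deg_top):
            D[lab] = D.get(lab, 0) + deg
        best_gain, best_pair = 0.0, None
        for (a, b), e in sorted(cross.items()):
            gain = (
                e
                - (K.get(a, 0) * D.get(b, 0) + K.get(b, 0) * D.get(a, 0)) / m
            ) / m
            if gain > best_gain + 1e-15:
                best_gain, best_pair = gain, (a, b)
        if best_pair is None:
            return
        a, b = best_pair
        bl[bl == b] = a
        tl[tl == b] = a


def lpab_plus(
    graph: BipartiteGraph,
    n_restarts: int = 5,
    seed: int = 0,
    max_sweeps: int = 100,
) -> Labeling:
    """Two-stage LPAb+ maximization of Barber modularity.

    Each restart initializes every node with a unique label, runs the
    propagation stage with a restart-specific node order (child RNG stream
    ``[seed, restart]``), then the merge stage.  The labeling with the
    highest Q_B wins; ties go to the earliest restart.  Accepted moves never
    decrease Q_B.
    """
    if graph.m < 1:
        raise ValueError("LPAb+ requires at least one edge")
    nb, nt = len(graph.bottom), len(graph.top)
    best: Labeling | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        bl = np.arange(nb)
        tl = np.arange(nb, nb + nt)
        _propagate(graph, bl, tl, rng, max_sweeps)
        _merge_modules(graph, bl, tl)
        qb = barber_modularity(graph, bl, tl)
        if best is None or qb > best.qb + 1e-12:
            best = Labeling(bottom_labels=bl, top_labels=tl, qb=qb)
    return best


@dataclass
class Module:
    label: int
    genes_bottom: list[str]
    genes_top: list[str]
    n_edges: int


@dataclass
class ModuleSet:
    modules: list[Module]
    pooled_bottom: list[str]
    pooled_top: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mod in self.modules:
            for g in mod.genes_bottom:
                rows.append({"node": g, "side": "bottom", "module": mod.label})
            for g in mod.genes_top:
                rows.append({"node": g, "side": "top", "module": mod.label})
        return pd.DataFrame(rows)


def select_modules(
    labeling: Labeling, graph: BipartiteGraph, min_edges: int = 1000
) -> ModuleSet:
    """Keep modules with strictly more than ``min_edges`` internal edges and
    pool their member genes per side (deduplicated, sorted)."""
    eb = labeling.bottom_labels[graph.edges[:, 0]]
    et = labeling.top_labels[graph.edges[:, 1]]
    within = eb == et
    edge_counts: dict[int, int] = {}
    for lab in eb[within]:
        edge_counts[int(lab)] = edge_counts.get(int(lab), 0) + 1

    modules = []
    for lab in sorted(edge_counts):
        if edge_counts[lab] <= min_edges:
            continue
        genes_b = [
            g
            for g, l in zip(graph.bottom, labeling.bottom_labels)
            if l == lab
        ]
        genes_t = [
            g for g, l in zip(graph.top, labeling.top_labels) if l == lab
        ]
        modules.append(
            Module(
                label=lab,
                genes_bottom=genes_b,
                genes_top=genes_t,
                n_edges=edge_counts[lab],
            )
        )
    pooled_b = sorted({g for mod in modules for g in mod.genes_bottom})
    pooled_t = sorted({g for mod in modules for g in mod.genes_top})
    return ModuleSet(
        modules=modules, pooled_bottom=pooled_b, pooled_top=pooled_t
    )
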