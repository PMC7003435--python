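"""Pathway-interaction analysis across region-pair binding classes.

For each region pair, the binarized pathway associations of its two sides
are crossed into a pathway x pathway interaction adjacency (symmetrized by
element-wise max, so the diagonal marks pathways associated on both sides).
Interaction proportions per binding class (not-bound, tract-bound,
AD-tract-bound) are compared cell-wise against the not-bound reference with
a 2x2 chi-square test (no continuity correction); cells with nominal p <
0.05 form the interaction graph whose node degrees rank hub pathways.  The
symmetric-synchronization Fisher test asks, per pathway, whether symmetric
(both-side) association concentrates in a binding class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from connectosync.pathway_enrichment import EnrichmentMatrix, PathwayDB
from connectosync.reach_probability import (
    AD_TRACT_BOUND,
    NOT_BOUND,
    TRACT_BOUND,
    RegionPairClasses,
)


def interaction_adjacency(
    enrichment: EnrichmentMatrix, pair_id: str, pathway_ids: list[str]
) -> np.ndarray:
    """Binary pathway x pathway adjacency for one region pair.

    M[p, q] = 1 iff p is associated with side ROI1 and q with side ROI2,
    symmetrized with the transpose (region-pair orientation is arbitrary).
    """
    res = enrichment.results
    sub = res[res.pair_id == pair_id]
    idx = {p: i for i, p in enumerate(pathway_ids)}
    side1 = np.zeros(len(pathway_ids), dtype=bool)
    side2 = np.zeros(len(pathway_ids), dtype=bool)
    for row in sub.itertuples():
        if not row.significant:
            continue
        i = idx[row.pathway]
        if row.side == "ROI1":
            side1[i] = True
        else:
            side2[i] = True
    M = np.outer(side1, side2)
    return np.maximum(M, M.T).astype(np.int8)


def all_adjacencies(
    enrichment: EnrichmentMatrix, pathway_ids: list[str]
) -> dict[str, np.ndarray]:
    pair_ids = sorted(enrichment.results.pair_id.unique())
    return {
        pid: interaction_adjacency(enrichment, pid, pathway_ids)
        for pid in pair_ids
    }


@dataclass
class GroupProportions:
    """Element-wise interaction counts and proportions per binding class."""

    counts: dict[str, np.ndarray]
    sizes: dict[str, int]

    def proportions(self, group: str) -> np.ndarray:
        if self.sizes.get(group, 0) == 0:
            warnings.warn(f"empty group {group!r}: proportions undefined")
            return np.full_like(
                next(iter(self.counts.values()), np.zeros((0, 0))),
                np.nan,
                dtype=float,
            )
        return self.counts[group] / self.sizes[group]


def group_proportions(
    adjacencies: dict[str, np.ndarray], classes: RegionPairClasses
) -> GroupProportions:
    """Mean interaction adjacency per binding class (pairs as pair ids)."""
    klass_of = {
        f"{r.region_a}|{r.region_b}": r.klass
        for r in classes.pairs.itertuples()
    }
    shape = next(iter(adjacencies.values())).shape
    counts = {
        g: np.zeros(shape, dtype=np.int64)
        for g in (NOT_BOUND, TRACT_BOUND, AD_TRACT_BOUND)
    }
    sizes = {g: 0 for g in counts}
    for pid, adj in adjacencies.items():
        g = klass_of[pid]
        counts[g] += adj
        sizes[g] += 1
    return GroupProportions(counts=counts, sizes=sizes)


def chisq_2x2(a, b, c, d):
    """Vectorized Pearson chi-square on 2x2 tables, no continuity correction.

    Closed form n*(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); degenerate margins
    give p = 1.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    p = np.where(denom > 0, stats.chi2.sf(chi2, df=1), 1.0)
    return chi2, p


def chisq_compare(
    props: GroupProportions, group: str, reference: str = NOT_BOUND
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-wise chi-square of interaction presence: group vs reference.

    Each pathway-pair cell contributes a 2x2 count table
    (present/absent x group/reference).  Returns (p matrix, -log10 p).
    """
    n_g, n_r = props.sizes[group], props.sizes[reference]
    if min(n_g, n_r) < 2:
        raise ValueError("group sizes must be at least 2")
    a = props.counts[group]
    b = n_g - a
    c = props.counts[reference]
    d = n_r - c
    _, p = chisq_2x2(a, b, c, d)
    # cells with no interaction anywhere are uninformative
    p = np.where((a + c) == 0, 1.0, p)
    return p, -np.log10(np.maximum(p, 1e-300))


@dataclass
class InteractionGraph:
    graph: nx.Graph
    degrees: pd.Series  # pathway -> incident edges (self-loop counts once)
    group: str = ""

    def top_nodes(self, k: int = 10) -> pd.Series:
        return self.degrees.sort_values(ascending=False).head(k)


def build_graph(
    p_matrix: np.ndarray,
    pathway_ids: list[str],
    alpha: float = 0.05,
    group: str = "",
) -> InteractionGraph:
    """Interaction graph: edge (p, q) iff the cell p-value < alpha.

    Degrees count distinct incident edges with a self-loop contributing 1,
    ranked descending in the ``degrees`` series (isolated pathways keep 0).
    """
    if not np.allclose(p_matrix, p_matrix.T):
        raise ValueError("p matrix must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(pathway_ids)
    ii, jj = np.nonzero(p_matrix < alpha)
    for i, j in zip(ii, jj):
        if i <= j:
            g.add_edge(pathway_ids[i], pathway_ids[j])
    degrees = pd.Series(
        {p: len(list(g.neighbors(p))) for p in pathway_ids}, name="degree"
    ).sort_values(ascending=False)
    return InteractionGraph(graph=g, degrees=degrees, group=group)


def symmetric_sync_test(
    sync: pd.DataFrame,
    classes: RegionPairClasses,
    group: str,
    reference: str = NOT_BOUND,
) -> pd.Series:
    """Per-pathway Fisher test of symmetric synchronization vs reference.

    ``sync`` is the output of ``synchronization_type``.  For each pathway the
    2x2 table crosses (pair in group vs pair in reference) with (pathway
    symmetric in pair vs not); the one-sided (greater) Fisher p asks whether
    symmetric synchronization concentrates in the group.  Pathways never
    symmetric anywhere get p = 1.
    """
    klass_of = {
        f"{r.region_a}|{r.region_b}": r.klass
        for r in classes.pairs.itertuples()
    }
    sync = sync.copy()
    sync["klass"] = sync.pair_id.map(klass_of)
    in_group = sync.klass == group
    in_ref = sync.klass == reference
    n_group = sync.loc[in_group, "pair_id"].nunique()
    n_ref = sync.loc[in_ref, "pair_id"].nunique()
    if n_group == 0:
        warnings.warn(f"empty group {group!r}: all p set to 1")
    out = {}
    for pathway, sub in sync.groupby("pathway"):
        sym = sub["sync"] == "symmetric"
        a = int((sym & (sub.klass == group)).sum())
        c = int((sym & (sub.klass == reference)).sum())
        if (a + c) == 0 or n_group == 0:
            out[pathway] = 1.0
            continue
        table = [[a, n_group - a], [c, n_ref - c]]
        out[pathway] = float(
            stats.fisher_exact(table, alternative="greater")[1]
        )
    return pd.Series(out, name=f"fisher_p_{group}").sort_values()


def ward_clustering(neglog10: np.ndarray, n_clusters: int = 3) -> np.ndarray:
    """Optional Ward agglomerative clustering of a -log10 p matrix (report
    only; memberships are configuration-dependent and not asserted)."""
    from sklearn.cluster import AgglomerativeClustering

    model = AgglomerativeClustering(n_clusters=n_clusters, linkage="ward")
    return model.fit_predict(neglog10)
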