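"""Community detection on weighted association networks.

Communities — the clusters of preferentially associating whales within which
centrality is later measured — are found per sampling period by short-random-
walk agglomeration (walktrap, 4-step walks) on the SRI weights, cutting the
merge dendrogram at maximum weighted Newman modularity.  Robustness is
quantified two ways: bootstrap consistency of co-assignment across resampled
encounters (r_com), and a data-stream-permutation test of whether the network
is more modular than expected under random group membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import numpy as np

from .association import AssociationMatrix, compute_sri

__all__ = [
    "CommunityPartition",
    "detect_communities",
    "modularity",
    "bootstrap_community_consistency",
    "modularity_null_test",
]


@dataclass
class CommunityPartition:
    period: str
    assignment: dict
    modularity: float
    sizes: dict = field(default_factory=dict)
    large_flags: dict = field(default_factory=dict)
    degenerate: bool = False
    min_community_size: int = 5

    def __post_init__(self):
        if not self.sizes:
            for com in self.assignment.values():
                self.sizes[com] = self.sizes.get(com, 0) + 1
        if not self.large_flags:
            self.large_flags = {
                c: s >= self.min_community_size for c, s in self.sizes.items()
            }

    def members(self, community) -> list:
        return sorted(n for n, c in self.assignment.items() if c == community)

    def co_assigned_pairs(self) -> set:
        pairs = set()
        for c in self.sizes:
            mem = self.members(c)
            for i, a in enumerate(mem):
                for b in mem[i + 1 :]:
                    pairs.add((a, b))
        return pairs


def _graph_from_matrix(matrix: AssociationMatrix) -> ig.Graph:
    w = matrix.weights
    iu = np.triu_indices(matrix.n_nodes, k=1)
    mask = w[iu] > 0
    edges = list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
    g = ig.Graph(n=matrix.n_nodes, edges=edges)
    g.es["weight"] = w[iu][mask].tolist()
    return g


def detect_communities(
    matrix: AssociationMatrix, steps: int = 4, min_community_size: int = 5
) -> CommunityPartition:
    """Partition one period's network by weighted walktrap agglomeration.

    The dendrogram is cut at the modularity maximum.  Detection runs per
    connected component (community structure cannot span components); nodes
    with no associations become singleton communities.  Community ids are
    relabelled 0..K-1 by smallest member node, so the result is invariant to
    node order up to identical labels.  A network with no edges at all is
    returned as all-singletons and flagged degenerate.
    """
    if matrix.n_nodes == 0:
        raise ValueError("cannot detect communities on an empty matrix")
    g = _graph_from_matrix(matrix)
    membership = np.full(matrix.n_nodes, -1, dtype=int)
    next_id = 0
    for comp in sorted(g.connected_components(), key=min):
        comp = sorted(comp)
        if len(comp) == 1:
            membership[comp[0]] = next_id
            next_id += 1
            continue
        sub = g.induced_subgraph(comp)
        dendro = sub.community_walktrap(weights="weight", steps=steps)
        clust = dendro.as_clustering()
        for local_c in range(len(clust)):
            for local_v in clust[local_c]:
                membership[comp[local_v]] = next_id + local_c
        next_id += len(clust)
    # relabel by smallest member node id for label determinism
    order = {}
    for i in np.argsort(np.asarray(matrix.nodes, dtype=object)):
        order.setdefault(membership[i], len(order))
    assignment = {matrix.nodes[i]: order[membership[i]] for i in range(matrix.n_nodes)}
    degenerate = g.ecount() == 0
    q = float("nan") if degenerate else modularity(matrix, assignment)
    return CommunityPartition(
        period=matrix.period,
        assignment=assignment,
        modularity=q,
        degenerate=degenerate,
        min_community_size=min_community_size,
    )


def modularity(matrix: AssociationMatrix, assignment: dict) -> float:
    """Weighted Newman modularity Q = sum_c [W_c/W - (k_c / 2W)^2].

    W is the total edge weight, W_c the weight internal to community c, and
    k_c the summed strength of c's members.  Defined only for W > 0.
    """
    missing = set(matrix.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment does not cover nodes: {sorted(missing)}")
    w = matrix.weights
    total = w.sum() / 2.0
    if total <= 0:
        raise ValueError("modularity undefined for a network with zero total weight")
    labels = np.array([assignment[n] for n in matrix.nodes])
    strength = w.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        mask = labels == c
        w_c = w[np.ix_(mask, mask)].sum() / 2.0
        k_c = strength[mask].sum()
        q += w_c / total - (k_c / (2.0 * total)) ** 2
    return float(q)


def _resample_encounters(encounters, period: str, rng: np.random.Generator):
    sub = encounters[encounters["period"].astype(str) == str(period)]
    enc_ids = sub["encounter"].unique()
    draw = rng.choice(enc_ids, size=len(enc_ids), replace=True)
    parts = []
    groups = dict(tuple(sub.groupby("encounter")))
    for i, e in enumerate(draw):
        block = groups[e].copy()
        block["encounter"] = f"b{i}"
        parts.append(block)
    import pandas as pd

    return pd.concat(parts, ignore_index=True)


def bootstrap_community_consistency(
    encounters,
    period: str,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    steps: int = 4,
) -> float:
    """Bootstrap consistency of community co-assignment (r_com).

    Encounters of the period are resampled with replacement (the encounter is
    the census's sampling unit), the network rebuilt and communities
    re-detected; r_com is the mean, over replicates, of the proportion of
    originally co-assigned dyads (both members present in the replicate) that
    remain co-assigned.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    sub = encounters[encounters["period"].astype(str) == str(period)]
    if sub["encounter"].nunique() < 2:
        raise ValueError("bootstrap needs at least two encounters in the period")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    original = detect_communities(compute_sri(encounters, period), steps=steps)
    base_pairs = original.co_assigned_pairs()
    if not base_pairs:
        return 1.0
    props = []
    for _ in range(n_boot):
        boot = _resample_encounters(encounters, period, rng)
        part = detect_communities(compute_sri(boot, period), steps=steps)
        seen = set(part.assignment)
        pairs = [(a, b) for a, b in base_pairs if a in seen and b in seen]
        if not pairs:
            continue
        kept = sum(part.assignment[a] == part.assignment[b] for a, b in pairs)
        props.append(kept / len(pairs))
    return float(np.mean(props)) if props else float("nan")


def modularity_null_test(
    encounters,
    period: str,
    n_perm: int,
    seed: int | None = None,
    burn_in: int = 1000,
    spacing: int = 100,
    steps: int = 4,
):
    """Is the period's network more modular than random group membership?

    The null is generated by data-stream (checkerboard-swap) permutations
    that preserve every whale's sighting count and every group's size; the
    statistic is the best-partition modularity, compared one-sidedly (ge)
    with the counting-rule p-value.
    """
    from .permutation import DatastreamPermuter, permutation_test

    def stat(enc):
        return detect_communities(compute_sri(enc, period), steps=steps).modularity

    permuter = DatastreamPermuter(
        encounters, periods=[str(period)], burn_in=burn_in, spacing=spacing
    )
    return permutation_test(stat, permuter, encounters, n_perm=n_perm, seed=seed, direction="ge")
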