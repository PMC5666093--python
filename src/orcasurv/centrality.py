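"""Within-community social position: normalized degree and rank-normalized closeness.

Both measures are computed inside a whale's community only, since the
biologically relevant social environment is the cluster of preferred
associates rather than the whole population.  Degree is the unweighted count
of same-community associates, normalized by (community size − 1).  Closeness
is the inverse mean weighted path length to all same-community members, with
edge lengths 1/SRI so that stronger associates are fewer "steps" away;
because closeness is highly skewed it is rank-transformed (average ranks on
ties) and min–max normalized to [0, 1] before analysis.  Communities smaller
than ``min_community_size`` (default 5) carry too little structure and are
excluded entirely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.stats import rankdata

from .association import AssociationMatrix
from .communities import CommunityPartition

__all__ = ["centrality_table", "community_degree", "community_closeness"]

CENTRALITY_COLUMNS = [
    "period",
    "individual",
    "community",
    "community_size",
    "degree_raw",
    "degree_norm",
    "closeness_raw",
    "closeness_rank_norm",
    "component_excluded",
]


def _community_blocks(matrix: AssociationMatrix, partition: CommunityPartition):
    missing = set(matrix.nodes) - set(partition.assignment)
    if missing:
        raise ValueError(f"partition does not cover matrix nodes: {sorted(missing)}")
    labels = np.array([partition.assignment[n] for n in matrix.nodes])
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        yield int(c), idx


def _closeness_within(w: np.ndarray, min_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Raw closeness on edge lengths 1/SRI, per connected component.

    Average path length is undefined across disconnected parts of a
    community, so closeness is computed within each connected component;
    members of components smaller than ``min_size`` get NaN and are flagged.
    Returns (closeness_raw, excluded_flag).
    """
    m = w.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, 0.0)
    dist = dijkstra(np.where(np.isfinite(lengths), lengths, 0.0), directed=False)
    closeness = np.full(m, np.nan)
    excluded = np.zeros(m, dtype=bool)
    reach = np.isfinite(dist)
    for i in range(m):
        comp = reach[i]
        n_comp = int(comp.sum())
        if n_comp < min_size:
            excluded[i] = True
            continue
        total = dist[i, comp].sum()
        closeness[i] = (n_comp - 1) / total if total > 0 else np.nan
    return closeness, excluded


def _rank_normalize(values: np.ndarray) -> np.ndarray:
    """Average-rank then min-max normalize: (rank − 1)/(m − 1); highest
    closeness maps to 1.  A single defined value gets the midpoint 0.5."""
    out = np.full(len(values), np.nan)
    ok = np.isfinite(values)
    m = int(ok.sum())
    if m == 0:
        return out
    if m == 1:
        out[ok] = 0.5
        return out
    ranks = rankdata(values[ok], method="average")
    out[ok] = (ranks - 1.0) / (m - 1.0)
    return out


def centrality_table(
    matrix: AssociationMatrix,
    partition: CommunityPartition,
    min_community_size: int = 5,
    rank_scope: str = "community",
) -> pd.DataFrame:
    """Degree and closeness centrality for every member of a large community.

    Parameters
    ----------
    rank_scope : {"community", "network"}
        Whether closeness ranks are taken within each community (default,
        consistent with all other within-community computation) or across the
        whole period network.
    """
    if rank_scope not in ("community", "network"):
        raise ValueError("rank_scope must be 'community' or 'network'")
    rows = []
    for c, idx in _community_blocks(matrix, partition):
        size = len(idx)
        if size < min_community_size:
            continue
        w = matrix.weights[np.ix_(idx, idx)]
        degree_raw = (w > 0).sum(axis=1)
        closeness_raw, excluded = _closeness_within(w, min_community_size)
        rank_norm = (
            _rank_normalize(closeness_raw) if rank_scope == "community" else None
        )
        for j, i in enumerate(idx):
            rows.append(
                {
                    "period": matrix.period,
                    "individual": matrix.nodes[i],
                    "community": c,
                    "community_size": size,
                    "degree_raw": int(degree_raw[j]),
                    "degree_norm": degree_raw[j] / (size - 1),
                    "closeness_raw": closeness_raw[j],
                    "closeness_rank_norm": rank_norm[j] if rank_norm is not None else np.nan,
                    "component_excluded": bool(excluded[j]),
                }
            )
    table = pd.DataFrame(rows, columns=CENTRALITY_COLUMNS)
    if rank_scope == "network" and not table.empty:
        table["closeness_rank_norm"] = _rank_normalize(table["closeness_raw"].to_numpy())
    return table


def community_degree(matrix, partition, min_community_size: int = 5) -> pd.DataFrame:
    """Degree columns of the centrality table."""
    t = centrality_table(matrix, partition, min_community_size)
    return t[["period", "individual", "community", "community_size", "degree_raw", "degree_norm"]]


def community_closeness(matrix, partition, min_community_size: int = 5, rank_scope="community"):
    """Closeness columns of the centrality table."""
    t = centrality_table(matrix, partition, min_community_size, rank_scope)
    return t[
        [
            "period",
            "individual",
            "community",
            "community_size",
            "closeness_raw",
            "closeness_rank_norm",
            "component_excluded",
        ]
    ]
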