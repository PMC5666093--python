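"""Reading, validation, and export of the three input tables and of networks.

Input schema (CSV, UTF-8, header row):

* encounters: ``period,encounter,group,individual`` — one row per individual
  per group sighting.  Period ids are strings so pooled two-year periods
  ("1976-1977") live in the same column as single years ("1996").
* individuals: ``id,sex,first_period,last_period,fate`` with
  ``sex in {M,F,U}`` and ``fate in {died,censored}``.
* salmon: ``year,index`` — one row per year, index a non-negative real.
  Years without an index may simply be absent; such periods are excluded
  from salmon-stratified analyses only.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ReferentialIntegrityError",
    "read_dataset",
    "write_dataset",
    "validate_encounters",
    "validate_registry",
    "validate_salmon",
    "write_network",
    "read_network",
]

ENCOUNTER_COLUMNS = ["period", "encounter", "group", "individual"]
REGISTRY_COLUMNS = ["id", "sex", "first_period", "last_period", "fate"]
SALMON_COLUMNS = ["year", "index"]

SEXES = {"M", "F", "U"}
FATES = {"died", "censored"}


class SchemaError(ValueError):
    """A table violates its documented schema."""


class ReferentialIntegrityError(ValueError):
    """Cross-references between tables do not resolve."""


def validate_registry(registry: pd.DataFrame) -> pd.DataFrame:
    missing = set(REGISTRY_COLUMNS) - set(registry.columns)
    if missing:
        raise SchemaError(f"individual registry missing columns: {sorted(missing)}")
    registry = registry.copy()
    for col in REGISTRY_COLUMNS:
        registry[col] = registry[col].astype(str)
    if registry["id"].duplicated().any():
        dupes = registry.loc[registry["id"].duplicated(), "id"].tolist()
        raise SchemaError(f"duplicate individual ids: {dupes}")
    bad_sex = set(registry["sex"]) - SEXES
    if bad_sex:
        raise SchemaError(f"unknown sex categories: {sorted(bad_sex)}")
    bad_fate = set(registry["fate"]) - FATES
    if bad_fate:
        raise SchemaError(f"unknown fate categories: {sorted(bad_fate)}")
    return registry


def validate_encounters(encounters: pd.DataFrame, registry: pd.DataFrame | None = None) -> pd.DataFrame:
    missing = set(ENCOUNTER_COLUMNS) - set(encounters.columns)
    if missing:
        raise SchemaError(f"encounter table missing columns: {sorted(missing)}")
    encounters = encounters.copy()
    for col in ENCOUNTER_COLUMNS:
        encounters[col] = encounters[col].astype(str)
    # A whale may appear in at most one group of an encounter: the field
    # grouping protocol merges chained associations, so a second membership
    # would double-count the dyadic numerator.
    dup = encounters.duplicated(subset=["period", "encounter", "individual"])
    if dup.any():
        rows = encounters.loc[dup, ["period", "encounter", "individual"]].head()
        raise SchemaError(
            "individual appears more than once within an encounter:\n" + rows.to_string()
        )
    if registry is not None:
        unknown = set(encounters["individual"]) - set(registry["id"])
        if unknown:
            raise ReferentialIntegrityError(
                f"encounter rows reference individuals absent from the registry: {sorted(unknown)}"
            )
    return encounters


def validate_salmon(salmon: pd.DataFrame) -> pd.DataFrame:
    missing = set(SALMON_COLUMNS) - set(salmon.columns)
    if missing:
        raise SchemaError(f"salmon table missing columns: {sorted(missing)}")
    salmon = salmon.copy()
    try:
        salmon["year"] = salmon["year"].astype(int)
        salmon["index"] = salmon["index"].astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"salmon table is not numeric: {exc}") from exc
    if salmon["year"].duplicated().any():
        raise SchemaError("salmon series has duplicate years")
    if (salmon["index"] < 0).any() or salmon["index"].isna().any():
        raise SchemaError("salmon indices must be non-negative reals")
    return salmon.sort_values("year").reset_index(drop=True)


def read_dataset(
    encounters_path: str | Path,
    individuals_path: str | Path,
    salmon_path: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and cross-validate the encounter, registry and salmon CSVs.

    Returns ``(encounters, registry, salmon)`` with string-typed identifier
    columns, periods sorted, and all encounter individuals resolved against
    the registry.
    """
    registry = validate_registry(pd.read_csv(individuals_path, dtype=str))
    encounters = pd.read_csv(encounters_path, dtype=str)
    encounters = validate_encounters(encounters, registry)
    encounters = encounters.sort_values(ENCOUNTER_COLUMNS, kind="stable").reset_index(drop=True)
    salmon = validate_salmon(pd.read_csv(salmon_path))
    return encounters, registry, salmon


def write_dataset(
    encounters: pd.DataFrame,
    registry: pd.DataFrame,
    salmon: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the three tables as CSVs; inverse of :func:`read_dataset`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "encounters": outdir / "encounters.csv",
        "individuals": outdir / "individuals.csv",
        "salmon": outdir / "salmon.csv",
    }
    encounters.sort_values(ENCOUNTER_COLUMNS, kind="stable").to_csv(paths["encounters"], index=False)
    registry[REGISTRY_COLUMNS].to_csv(paths["individuals"], index=False)
    salmon[SALMON_COLUMNS].to_csv(paths["salmon"], index=False)
    return paths


def _network_graph(matrix, partition=None, centrality=None, registry=None) -> nx.Graph:
    g = nx.Graph(period=str(matrix.period))
    for node in matrix.nodes:
        g.add_node(node)
    if partition is not None:
        extra = set(partition.assignment) - set(matrix.nodes)
        if extra:
            raise ValueError(
                f"partition assigns nodes absent from the association matrix: {sorted(extra)}"
            )
        for node, com in partition.assignment.items():
            g.nodes[node]["community"] = int(com)
    if registry is not None:
        sex = dict(zip(registry["id"], registry["sex"]))
        for node in matrix.nodes:
            if node in sex:
                g.nodes[node]["sex"] = sex[node]
    if centrality is not None:
        for _, row in centrality.iterrows():
            if row["individual"] in g:
                g.nodes[row["individual"]]["degree_norm"] = float(row["degree_norm"])
                if np.isfinite(row.get("closeness_rank_norm", np.nan)):
                    g.nodes[row["individual"]]["closeness_rank_norm"] = float(
                        row["closeness_rank_norm"]
                    )
    idx = {n: i for i, n in enumerate(matrix.nodes)}
    w = matrix.weights
    for a in matrix.nodes:
        for b in matrix.nodes:
            if a < b and w[idx[a], idx[b]] > 0:
                g.add_edge(a, b, sri=float(w[idx[a], idx[b]]))
    return g


def write_network(
    matrix,
    partition=None,
    graphml_path: str | Path | None = None,
    csv_path: str | Path | None = None,
    centrality: pd.DataFrame | None = None,
    registry: pd.DataFrame | None = None,
) -> nx.Graph:
    """Export one period's association network.

    GraphML carries the SRI as edge attribute ``sri`` and node attributes
    ``sex``, ``community`` and centrality values where available (openable in
    Gephi); the CSV dialect is a plain ``node_a,node_b,sri`` edge list.
    """
    g = _network_graph(matrix, partition, centrality, registry)
    if graphml_path is not None:
        nx.write_graphml(g, Path(graphml_path))
    if csv_path is not None:
        rows = [
            {"node_a": a, "node_b": b, "sri": d["sri"]}
            for a, b, d in sorted(g.edges(data=True))
        ]
        pd.DataFrame(rows, columns=["node_a", "node_b", "sri"]).to_csv(csv_path, index=False)
    return g


def read_network(graphml_path: str | Path):
    """Read a written GraphML file back into an association matrix."""
    from .association import AssociationMatrix

    g = nx.read_graphml(Path(graphml_path))
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for a, b, d in g.edges(data=True):
        w[idx[a], idx[b]] = w[idx[b], idx[a]] = float(d["sri"])
    return AssociationMatrix(period=g.graph.get("period", ""), nodes=nodes, weights=w)


def dump_json(obj, path: str | Path) -> None:
    """Deterministic JSON dump (sorted keys) used for all result documents."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
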