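"""Ingredient-target-pathway/disease association network assembly,
degree-based filtering, multi-cluster Venn comparison and graph export."""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import networkx as nx
import pandas as pd

from .datatypes import EnrichmentResult

__all__ = [
    "assemble_network",
    "compare_clusters",
    "export_network",
    "import_network",
    "ClusterComparison",
]

NODE_KINDS = ("ingredient", "target", "pathway", "disease")
EXPORT_FORMATS = ("graphml", "node-link-json", "edge-tsv")


def _node_key(kind: str, name: str) -> str:
    return f"{kind}:{name}"


def assemble_network(
    ingredient_targets: Mapping[str, Collection[str]],
    enrichment_results: Sequence[EnrichmentResult] = (),
    min_compounds: int = 0,
    simplified: bool = False,
    p_adj_cutoff: float = 0.05,
    clusters: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Build the typed association network.

    * ingredient--target edges from the potential-target lists;
    * target--pathway / target--disease edges from enrichment results
      (``pathway``/``go_*`` categories become ``pathway`` nodes,
      ``disease`` becomes ``disease`` nodes);
    * targets linked by **more than** ``min_compounds`` ingredients are
      kept (strictly greater), others removed before term nodes attach;
    * ``simplified=True`` keeps only term nodes with
      ``p_adjusted <= p_adj_cutoff``;
    * node ``degree`` attributes describe the *filtered* graph: target
      degree = number of linking ingredients, term degree = number of
      mapped (kept) targets;
    * ``clusters`` maps ingredient -> cluster name; targets carry the
      sorted, comma-joined clusters of their linking ingredients.

    Orphan pathway/disease nodes never appear.  Node insertion order is
    deterministic, so exports are byte-stable.
    """
    if min_compounds < 0:
        raise ValueError("min_compounds must be >= 0")
    clusters = clusters or {}

    target_links: dict[str, set[str]] = {}
    for ing in sorted(ingredient_targets):
        for t in ingredient_targets[ing]:
            target_links.setdefault(t, set()).add(ing)
    kept_targets = {t for t, ings in target_links.items() if len(ings) > min_compounds}

    g = nx.Graph()
    for ing in sorted(ingredient_targets):
        tgts = sorted(set(ingredient_targets[ing]) & kept_targets)
        attrs = {"kind": "ingredient", "name": ing, "degree": len(tgts)}
        if ing in clusters:
            attrs["cluster"] = clusters[ing]
        g.add_node(_node_key("ingredient", ing), **attrs)
    for t in sorted(kept_targets):
        ings = sorted(target_links[t])
        cl = sorted({clusters[i] for i in ings if i in clusters})
        g.add_node(
            _node_key("target", t),
            kind="target",
            name=t,
            degree=len(ings),
            cluster=",".join(cl),
        )
        for ing in ings:
            g.add_edge(
                _node_key("ingredient", ing),
                _node_key("target", t),
                edge_type="ingredient-target",
            )

    for res in sorted(enrichment_results, key=lambda r: (r.category, r.term_id)):
        if simplified and res.p_adjusted > p_adj_cutoff:
            continue
        kind = "disease" if res.category == "disease" else "pathway"
        mapped = sorted(set(res.mapped_targets) & kept_targets)
        if not mapped:
            continue  # no orphan term nodes
        key = _node_key(kind, res.term_id)
        g.add_node(
            key,
            kind=kind,
            name=res.term_id,
            term_name=res.term_name,
            category=res.category,
            degree=len(mapped),
            p_adjusted=res.p_adjusted,
            significant=res.significant,
        )
        for t in mapped:
            g.add_edge(_node_key("target", t), key, edge_type=f"target-{kind}")
    return g


@dataclass(frozen=True)
class ClusterComparison:
    """Venn partition of 2-5 cluster target sets.

    ``regions`` maps a sorted tuple of cluster names (the clusters a
    region belongs to, exclusively) to the sorted member ids.
    """

    cluster_names: tuple[str, ...]
    regions: dict[tuple[str, ...], tuple[str, ...]]

    def counts(self) -> dict[tuple[str, ...], int]:
        return {k: len(v) for k, v in self.regions.items()}

    def to_table(self) -> pd.DataFrame:
        rows = [
            {"clusters": "&".join(k), "count": len(v), "members": "|".join(v)}
            for k, v in sorted(self.regions.items(), key=lambda kv: (len(kv[0]), kv[0]))
        ]
        return pd.DataFrame(rows, columns=["clusters", "count", "members"])


def compare_clusters(cluster_targets: Mapping[str, Collection[str]]) -> ClusterComparison:
    """Full ``2^c - 1`` region Venn partition of 2-5 cluster target sets:
    each region holds the ids in exactly that subset of clusters."""
    names = tuple(sorted(cluster_targets))
    if not (2 <= len(names) <= 5):
        raise ValueError(
            f"{len(names)} clusters given; compare 2-5 clusters "
            "(use pairwise comparisons beyond that)"
        )
    sets = {c: set(cluster_targets[c]) for c in names}
    regions: dict[tuple[str, ...], tuple[str, ...]] = {}
    for mask in range(1, 2 ** len(names)):
        inside = tuple(c for i, c in enumerate(names) if mask >> i & 1)
        outside = [c for c in names if c not in inside]
        members = set.intersection(*(sets[c] for c in inside))
        for c in outside:
            members -= sets[c]
        regions[inside] = tuple(sorted(members))
    return ClusterComparison(cluster_names=names, regions=regions)


def export_network(net: nx.Graph, path, fmt: str) -> None:
    """Write the network as GraphML, node-link JSON or a per-edge TSV,
    with stable element ordering."""
    if fmt not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {fmt!r}; supported: {EXPORT_FORMATS}")
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(net.nodes(data=True)))
    ordered.add_edges_from(
        sorted((min(u, v), max(u, v), d) for u, v, d in net.edges(data=True))
    )
    if fmt == "graphml":
        nx.write_graphml(ordered, path)
    elif fmt == "node-link-json":
        data = nx.node_link_data(ordered, edges="links")
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        rows = []
        for u, v, d in ordered.edges(data=True):
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "edge_type": d.get("edge_type", ""),
                    "cluster": ordered.nodes[u].get("cluster", ""),
                }
            )
        pd.DataFrame(rows, columns=["source", "target", "edge_type", "cluster"]).to_csv(
            path, sep="\t", index=False
        )


def import_network(path, fmt: str) -> nx.Graph:
    """Re-load a network exported by :func:`export_network` (graphml or
    node-link-json)."""
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "node-link-json":
        with open(path) as fh:
            return nx.node_link_graph(json.load(fh), edges="links")
    raise ValueError(f"cannot import format {fmt!r}")
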