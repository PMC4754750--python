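"""Readers/writers for the plain-text exchange formats.

All tables are TSV; similarity matrices use an id header row/column with
``NA`` for missing; gene sets use GMT (term TAB description TAB
members...); sequences use FASTA (via Biopython).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

from .datatypes import (
    GeneSet,
    GeneSetCollection,
    InteractionSet,
    SimilarityMatrix,
    interaction_set,
)

__all__ = [
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_interactions",
    "write_interactions",
    "read_feature_table",
    "write_feature_table",
    "read_gmt",
    "write_gmt",
    "read_fasta_sequences",
    "read_edge_list",
    "write_edge_list",
    "read_term_membership",
    "read_fingerprints",
    "read_expression_signatures",
    "read_id_list",
]


def read_similarity_matrix(path, measure_name: str) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise ValueError(f"{path}: row ids differ from column ids")
    return SimilarityMatrix(measure_name, ids, df.to_numpy(dtype=float))


def write_similarity_matrix(matrix: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.entity_ids, columns=matrix.entity_ids)
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_interactions(path, role: str = "GSP") -> InteractionSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: need at least two columns (compound, protein)")
    pairs = list(zip(df[cols[0]], df[cols[1]]))
    return interaction_set(role, pairs)


def write_interactions(interactions: InteractionSet, path, source: str | None = None) -> None:
    rows = interactions.sorted_pairs
    df = pd.DataFrame(rows, columns=["compound_id", "protein_id"])
    if source is not None:
        df["source"] = source
    df.to_csv(path, sep="\t", index=False)


def read_known_targets(path) -> set[tuple[str, str]]:
    """Known-target table: compound_id TAB protein_id [TAB source]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    return set(zip(df[cols[0]], df[cols[1]]))


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA",
                               float_format="%.10g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["compound_id"] = df["compound_id"].astype(str)
    df["protein_id"] = df["protein_id"].astype(str)
    return df.set_index(["compound_id", "protein_id"])


def read_gmt(path, category: str, universe: Iterable[str] | None = None) -> GeneSetCollection:
    terms: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term_id, name, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if term_id in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term {term_id!r}")
            terms[term_id] = GeneSet(term_id, name, frozenset(members))
    return GeneSetCollection(
        category=category,
        terms=terms,
        universe=frozenset(universe) if universe is not None else frozenset(),
    )


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for term_id in sorted(collection.terms):
            t = collection.terms[term_id]
            fh.write("\t".join([t.term_id, t.name, *sorted(t.members)]) + "\n")


def read_fasta_sequences(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_edge_list(path) -> nx.Graph:
    """Undirected PPI edge list (two id columns, optional header);
    self-loops and duplicates dropped."""
    g = nx.Graph()
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    for a, b in zip(df[0], df[1]):
        if a != b:
            g.add_edge(a, b)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted((min(u, v), max(u, v)) for u, v in g.edges()):
            fh.write(f"{u}\t{v}\n")


def read_term_membership(path) -> dict[str, frozenset[str]]:
    """entity_id TAB term rows -> entity -> term set."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    out: dict[str, set[str]] = {}
    for e, t in zip(df[0], df[1]):
        out.setdefault(e, set()).add(t)
    return {e: frozenset(s) for e, s in out.items()}


def read_fingerprints(path) -> dict[str, np.ndarray]:
    """id TAB bit-string (e.g. ``0101...``) or hex string prefixed ``0x``."""
    out: dict[str, np.ndarray] = {}
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    for cid, bits in zip(df[0], df[1]):
        if bits.startswith("0x"):
            n = (len(bits) - 2) * 4
            val = int(bits, 16)
            arr = np.array([(val >> (n - 1 - i)) & 1 for i in range(n)], dtype=np.int8)
        else:
            arr = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
            if not np.isin(arr, (0, 1)).all():
                raise ValueError(f"bad fingerprint string for {cid!r}")
            arr = arr.astype(np.int8)
        out[cid] = arr
    return out


def read_expression_signatures(path) -> dict[str, np.ndarray]:
    """TSV matrix: rows = compound ids, columns = genes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {str(i): df.loc[i].to_numpy(dtype=float) for i in df.index}


def read_id_list(path) -> list[str]:
    """One id per line; blank lines and ``#`` comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out
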