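"""Synthetic universes with planted structure.

Drugs and proteins are assigned to latent modules; every similarity
measure is drawn around a high within-module mean and a low
between-module mean, and positives are sampled from within-module
drug-protein combinations -- so similarity-product features genuinely
predict the planted interactions.  A secondary generator emits raw
records (fingerprints, ATC codes, sequences, a PPI graph ...) so the
similarity operations themselves can be exercised end-to-end.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .datatypes import (
    DRUG_MEASURES,
    PROTEIN_MEASURES,
    CompoundRecord,
    GeneSet,
    GeneSetCollection,
    InteractionSet,
    ProteinRecord,
    SimilarityMatrix,
    interaction_set,
)

__all__ = ["UniverseSpec", "Universe", "generate_universe", "generate_gene_sets",
           "generate_raw_records"]


@dataclass
class UniverseSpec:
    """Parameters of the planted-module synthetic universe."""

    n_drugs: int = 60
    n_proteins: int = 80
    n_modules: int = 4
    within_sim: tuple[float, float] = (0.65, 0.12)  # mean, sd
    between_sim: tuple[float, float] = (0.30, 0.12)
    availability: dict = field(default_factory=dict)  # measure -> rate in (0,1]
    gsp_fraction: float = 0.5
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0 <= self.within_sim[0] <= 1 and 0 <= self.between_sim[0] <= 1):
            raise ValueError("similarity means must lie in [0, 1]")
        if self.within_sim[0] <= self.between_sim[0]:
            raise ValueError(
                "within-module similarity mean must exceed between-module mean; "
                "otherwise there is no planted signal"
            )
        if not (0 < self.gsp_fraction <= 1):
            raise ValueError("gsp_fraction must be in (0, 1]")
        if self.n_modules < 1 or self.n_drugs < self.n_modules or self.n_proteins < self.n_modules:
            raise ValueError("need at least one drug and protein per module")


@dataclass
class Universe:
    drug_ids: list[str]
    protein_ids: list[str]
    drug_modules: dict[str, int]
    protein_modules: dict[str, int]
    drug_sims: dict[str, SimilarityMatrix]
    prot_sims: dict[str, SimilarityMatrix]
    gsp: InteractionSet
    spec: UniverseSpec


def _module_matrix(
    rng: np.random.Generator,
    modules: np.ndarray,
    within: tuple[float, float],
    between: tuple[float, float],
    availability_rate: float,
) -> np.ndarray:
    n = len(modules)
    same = modules[:, None] == modules[None, :]
    mean = np.where(same, within[0], between[0])
    sd = np.where(same, within[1], between[1])
    raw = rng.normal(mean, sd)
    v = np.clip(np.triu(raw, 1), 0.0, 1.0)
    v = v + v.T
    np.fill_diagonal(v, 1.0)
    if availability_rate < 1.0:
        missing = rng.random(n) >= availability_rate
        v[missing, :] = np.nan
        v[:, missing] = np.nan
    return v


def generate_universe(spec: UniverseSpec | None = None) -> Universe:
    """Generate drugs/proteins in latent modules, one similarity matrix
    per measure (independent noise), and a within-module positive set.

    Fully reproducible under ``spec.seed``; refuses specs whose positive
    set would be smaller than 10 pairs.
    """
    spec = spec or UniverseSpec()
    rng = np.random.default_rng(spec.seed)
    drug_ids = [f"D{i:04d}" for i in range(1, spec.n_drugs + 1)]
    protein_ids = [f"P{i:04d}" for i in range(1, spec.n_proteins + 1)]
    drug_mod = np.sort(rng.integers(0, spec.n_modules, size=spec.n_drugs))
    prot_mod = np.sort(rng.integers(0, spec.n_modules, size=spec.n_proteins))
    # guarantee every module is populated on both sides
    for m in range(spec.n_modules):
        drug_mod[m] = m
        prot_mod[m] = m
    drug_mod = np.sort(drug_mod)
    prot_mod = np.sort(prot_mod)

    drug_sims = {}
    for measure in DRUG_MEASURES:
        rate = spec.availability.get(measure, 1.0)
        v = _module_matrix(rng, drug_mod, spec.within_sim, spec.between_sim, rate)
        drug_sims[measure] = SimilarityMatrix(measure, drug_ids, v)
    prot_sims = {}
    for measure in PROTEIN_MEASURES:
        rate = spec.availability.get(measure, 1.0)
        v = _module_matrix(rng, prot_mod, spec.within_sim, spec.between_sim, rate)
        prot_sims[measure] = SimilarityMatrix(measure, protein_ids, v)

    within_pairs = [
        (d, p)
        for i, d in enumerate(drug_ids)
        for j, p in enumerate(protein_ids)
        if drug_mod[i] == prot_mod[j]
    ]
    n_pos = int(round(spec.gsp_fraction * len(within_pairs)))
    if n_pos < 10:
        raise ValueError(
            f"gsp_fraction {spec.gsp_fraction} yields only {n_pos} positives; "
            "too few to train"
        )
    idx = rng.choice(len(within_pairs), size=n_pos, replace=False)
    gsp = interaction_set("GSP", (within_pairs[i] for i in idx))

    return Universe(
        drug_ids=drug_ids,
        protein_ids=protein_ids,
        drug_modules=dict(zip(drug_ids, drug_mod.tolist())),
        protein_modules=dict(zip(protein_ids, prot_mod.tolist())),
        drug_sims=drug_sims,
        prot_sims=prot_sims,
        gsp=gsp,
        spec=spec,
    )


def generate_gene_sets(
    proteins: Sequence[str],
    n_terms: int = 30,
    planted_term_size: int = 20,
    seed: int = 0,
    category: str = "pathway",
) -> tuple[GeneSetCollection, str]:
    """Random gene sets of varied size over the protein universe plus one
    designated planted term; returns ``(collection, planted_term_id)`` so
    tests can assert recovery."""
    proteins = list(proteins)
    if planted_term_size > len(proteins):
        raise ValueError("planted term larger than the protein universe")
    rng = np.random.default_rng(seed)
    terms: dict[str, GeneSet] = {}
    planted_id = "TERM0000"
    members = rng.choice(proteins, size=planted_term_size, replace=False)
    terms[planted_id] = GeneSet(planted_id, "planted term", frozenset(map(str, members)))
    for i in range(1, n_terms):
        tid = f"TERM{i:04d}"
        size = int(rng.integers(5, max(6, len(proteins) // 2)))
        size = min(size, len(proteins))
        members = rng.choice(proteins, size=size, replace=False)
        terms[tid] = GeneSet(tid, f"decoy term {i}", frozenset(map(str, members)))
    collection = GeneSetCollection(
        category=category, terms=terms, universe=frozenset(map(str, proteins))
    )
    return collection, planted_id


_AA = "ACDEFGHIKLMNPQRSTVWY"


def generate_raw_records(
    n_drugs: int = 8,
    n_proteins: int = 10,
    seed: int = 0,
    fp_length: int = 64,
    n_groups: int = 12,
    n_side_effects: int = 20,
    n_genes: int = 15,
    seq_length: int = 50,
    n_go_terms: int = 25,
) -> tuple[list[CompoundRecord], list[ProteinRecord], nx.Graph]:
    """Small random raw-data universe (no planted structure) for
    exercising the similarity operations and file formats end-to-end."""
    rng = np.random.default_rng(seed)
    se_vocab = [f"SE{i:03d}" for i in range(n_side_effects)]
    go_vocab = [f"GO:{i:07d}" for i in range(1, n_go_terms + 1)]
    letters = string.ascii_uppercase

    compounds = []
    for i in range(n_drugs):
        fp = rng.integers(0, 2, size=fp_length)
        if fp.sum() == 0:
            fp[0] = 1
        atc = frozenset(
            f"{letters[int(rng.integers(26))]}"
            f"{int(rng.integers(100)):02d}"
            f"{letters[int(rng.integers(26))]}"
            f"{letters[int(rng.integers(26))]}"
            f"{int(rng.integers(100)):02d}"
            for _ in range(int(rng.integers(1, 3)))
        )
        compounds.append(
            CompoundRecord(
                compound_id=f"D{i + 1:04d}",
                fingerprint=fp,
                functional_groups=rng.integers(0, 5, size=n_groups),
                side_effects=frozenset(
                    map(str, rng.choice(se_vocab, size=int(rng.integers(1, 6)), replace=False))
                ),
                atc_codes=atc,
                expression_signature=rng.normal(size=n_genes),
            )
        )
    proteins = []
    for i in range(n_proteins):
        seq = "".join(rng.choice(list(_AA), size=seq_length))
        proteins.append(
            ProteinRecord(
                protein_id=f"P{i + 1:04d}",
                sequence=seq,
                go_terms=frozenset(
                    map(str, rng.choice(go_vocab, size=int(rng.integers(1, 8)), replace=False))
                ),
                in_network=True,
            )
        )
    ppi = nx.gnp_random_graph(n_proteins, 0.3, seed=int(rng.integers(2**31)))
    ppi = nx.relabel_nodes(ppi, {i: proteins[i].protein_id for i in range(n_proteins)})
    return compounds, proteins, ppi
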