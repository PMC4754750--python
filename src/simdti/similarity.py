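"""Pairwise similarity measures and feature-table construction.

Six drug-drug measures (fingerprint Tanimoto, functional-group weighted
Tanimoto, side-effect Jaccard, ATC level-prefix, rescaled expression
correlation, ingested text-mining scores) and three protein-protein
measures (normalized Smith-Waterman, interaction-network closeness, GO
Jaccard).  All return values in ``[0, 1]`` or ``NaN`` for missing data.

The per-pair classification feature for one drug measure and one protein
measure is the maximum, over reference positive interactions, of
``drug_sim * protein_sim`` -- the query pair itself is never used as its
own reference.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .datatypes import (
    ALL_FEATURES,
    ATC_PATTERN,
    CompoundRecord,
    InteractionSet,
    ProteinRecord,
    SimilarityMatrix,
    feature_name,
)

__all__ = [
    "tanimoto_similarity",
    "functional_group_similarity",
    "set_similarity",
    "atc_similarity",
    "expression_similarity",
    "sequence_similarity",
    "network_closeness",
    "compound_similarity_matrices",
    "protein_similarity_matrices",
    "rescale_text_mining",
    "build_feature_table",
]


def tanimoto_similarity(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient of two equal-length bit vectors."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint lengths differ: {a.size} vs {b.size}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        warnings.warn("both fingerprints all-zero; similarity defined as 0")
        return 0.0
    return float(np.count_nonzero(a & b) / union)


def functional_group_similarity(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """Weighted (min/max) Tanimoto on non-negative count vectors."""
    a = np.asarray(g_a, dtype=float)
    b = np.asarray(g_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"group vocabulary lengths differ: {a.size} vs {b.size}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("count vectors must be non-negative")
    denom = np.maximum(a, b).sum()
    if denom == 0:
        warnings.warn("both count vectors zero; similarity defined as 0")
        return 0.0
    return float(np.minimum(a, b).sum() / denom)


def set_similarity(s_a: Iterable[str], s_b: Iterable[str]) -> float:
    """Jaccard index of two term sets; both-empty is *missing* (NaN)."""
    sa, sb = set(s_a), set(s_b)
    union = sa | sb
    if not union:
        return float("nan")
    return len(sa & sb) / len(union)


def _atc_levels(code: str) -> tuple[str, str, str, str, str]:
    # anatomical | therapeutic | pharmacological | chemical subgroup | substance
    return (code[0], code[1:3], code[3], code[4], code[5:7])


def atc_similarity(codes_a: Iterable[str], codes_b: Iterable[str]) -> float:
    """Max over code cross-pairs of (shared leading ATC levels)/5.

    Either set empty -> missing (NaN).
    """
    ca, cb = set(codes_a), set(codes_b)
    if not ca or not cb:
        return float("nan")
    for code in ca | cb:
        if not ATC_PATTERN.match(code):
            raise ValueError(f"bad ATC code {code!r}")
    best = 0
    for x in ca:
        lx = _atc_levels(x)
        for y in cb:
            ly = _atc_levels(y)
            match = 0
            for u, v in zip(lx, ly):
                if u != v:
                    break
                match += 1
            best = max(best, match)
    return best / 5.0


def expression_similarity(sig_a: np.ndarray, sig_b: np.ndarray) -> float:
    """Pearson correlation of expression signatures mapped onto [0, 1]
    via ``(r + 1) / 2``.  Constant vectors -> missing."""
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("signature lengths differ")
    if a.size < 3:
        raise ValueError("signatures must have length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    return min(1.0, max(0.0, (r + 1.0) / 2.0))


_ALIGNER_CACHE: dict[tuple, Align.PairwiseAligner] = {}


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    key = (matrix, gap_open, gap_extend)
    if key not in _ALIGNER_CACHE:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(matrix)
        aligner.open_gap_score = -gap_open
        aligner.extend_gap_score = -gap_extend
        _ALIGNER_CACHE[key] = aligner
    return _ALIGNER_CACHE[key]


def sequence_similarity(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Normalized Smith-Waterman: ``SW(a,b) / sqrt(SW(a,a) * SW(b,b))``.

    Self-similarity is 1 by construction; empty sequence -> missing.
    """
    if not seq_a or not seq_b:
        return float("nan")
    aligner = _aligner(matrix, gap_open, gap_extend)
    ab = aligner.score(seq_a, seq_b)
    if ab <= 0:
        return 0.0
    aa = aligner.score(seq_a, seq_a)
    bb = aligner.score(seq_b, seq_b)
    return float(min(1.0, ab / np.sqrt(aa * bb)))


def network_closeness(
    prot_a: str, prot_b: str, ppi: nx.Graph, decay: float = 0.5
) -> float:
    """Shortest-path decay proximity: 1 for self, ``decay**d`` for
    distance ``d``, 0 when disconnected, missing when absent from graph."""
    if prot_a not in ppi or prot_b not in ppi:
        return float("nan")
    if prot_a == prot_b:
        return 1.0
    try:
        d = nx.shortest_path_length(ppi, prot_a, prot_b)
    except nx.NetworkXNoPath:
        return 0.0
    return float(decay**d)


def rescale_text_mining(matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Rescale a raw (non-negative) text-mining association matrix into
    [0, 1] by dividing by its maximum; the diagonal is forced to 1 for
    entities with data."""
    v = matrix.values.copy()
    finite = ~np.isnan(v)
    if finite.any():
        m = v[finite].max()
        if m > 0:
            v = v / m
    avail = ~np.isnan(np.diag(v))
    v[np.diag_indices_from(v)] = np.where(avail, 1.0, np.nan)
    return SimilarityMatrix("text_mining", matrix.entity_ids, v)


def _pairwise_matrix(ids, fn, available) -> np.ndarray:
    n = len(ids)
    out = np.full((n, n), np.nan)
    for i in range(n):
        if not available[i]:
            continue
        out[i, i] = 1.0
        for j in range(i + 1, n):
            if not available[j]:
                continue
            out[i, j] = out[j, i] = fn(i, j)
    return out


def compound_similarity_matrices(
    compounds: Sequence[CompoundRecord],
    measures: Sequence[str] = ("fp2", "functional_group", "side_effect", "atc", "expression"),
) -> dict[str, SimilarityMatrix]:
    """Compute drug-drug similarity matrices from raw records.

    ``text_mining`` cannot be computed from records (scores are ingested
    precomputed via :func:`rescale_text_mining`).
    """
    ids = [c.compound_id for c in compounds]
    out: dict[str, SimilarityMatrix] = {}
    fns = {
        "fp2": lambda i, j: tanimoto_similarity(
            compounds[i].fingerprint, compounds[j].fingerprint
        ),
        "functional_group": lambda i, j: functional_group_similarity(
            compounds[i].functional_groups, compounds[j].functional_groups
        ),
        "side_effect": lambda i, j: set_similarity(
            compounds[i].side_effects, compounds[j].side_effects
        ),
        "atc": lambda i, j: atc_similarity(
            compounds[i].atc_codes, compounds[j].atc_codes
        ),
        "expression": lambda i, j: expression_similarity(
            compounds[i].expression_signature, compounds[j].expression_signature
        ),
    }
    for m in measures:
        if m == "text_mining":
            raise ValueError("text_mining similarities are ingested, not computed")
        avail = [c.availability[m] for c in compounds]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[m] = SimilarityMatrix(m, ids, _pairwise_matrix(ids, fns[m], avail))
    return out


def protein_similarity_matrices(
    proteins: Sequence[ProteinRecord],
    ppi: nx.Graph | None = None,
    measures: Sequence[str] = ("sequence", "closeness", "go"),
    decay: float = 0.5,
) -> dict[str, SimilarityMatrix]:
    """Compute protein-protein similarity matrices from raw records."""
    ids = [p.protein_id for p in proteins]
    out: dict[str, SimilarityMatrix] = {}
    for m in measures:
        if m == "sequence":
            avail = [bool(p.sequence) for p in proteins]
            fn = lambda i, j: sequence_similarity(proteins[i].sequence, proteins[j].sequence)
            values = _pairwise_matrix(ids, fn, avail)
        elif m == "go":
            avail = [bool(p.go_terms) for p in proteins]
            fn = lambda i, j: set_similarity(proteins[i].go_terms, proteins[j].go_terms)
            values = _pairwise_matrix(ids, fn, avail)
        elif m == "closeness":
            if ppi is None:
                raise ValueError("closeness requires a PPI graph")
            values = _closeness_matrix(ids, ppi, decay)
        else:
            raise ValueError(f"unknown protein measure {m!r}")
        out[m] = SimilarityMatrix(m, ids, values)
    return out


def _closeness_matrix(ids: Sequence[str], ppi: nx.Graph, decay: float) -> np.ndarray:
    n = len(ids)
    idx = {e: i for i, e in enumerate(ids)}
    out = np.full((n, n), np.nan)
    for a in ids:
        i = idx[a]
        if a not in ppi:
            continue
        row = np.zeros(n)  # disconnected -> 0
        mask = np.zeros(n, dtype=bool)
        for e in ids:
            if e in ppi:
                mask[idx[e]] = True
        lengths = nx.single_source_shortest_path_length(ppi, a)
        for b, d in lengths.items():
            j = idx.get(b)
            if j is not None:
                row[j] = 1.0 if d == 0 else decay**d
        out[i, mask] = row[mask]
        out[i, i] = 1.0
    return out


def _product_tensor(
    pairs: Sequence[tuple[str, str]],
    refs: Sequence[tuple[str, str]],
    drug_sim: SimilarityMatrix,
    prot_sim: SimilarityMatrix,
) -> np.ndarray:
    """(n_pairs, n_refs) matrix of drug_sim(d, d') * prot_sim(t, t')."""
    pair_drugs = [d for d, _ in pairs]
    pair_prots = [t for _, t in pairs]
    ref_drugs = [d for d, _ in refs]
    ref_prots = [t for _, t in refs]

    return drug_sim.submatrix(pair_drugs, ref_drugs) * prot_sim.submatrix(
        pair_prots, ref_prots
    )


def _exclusion_mask(
    pairs: Sequence[tuple[str, str]],
    refs: Sequence[tuple[str, str]],
    policy: str,
) -> np.ndarray:
    """(n_pairs, n_refs) boolean mask; True = reference forbidden for pair."""
    ref_arr_d = np.array([d for d, _ in refs], dtype=object)
    ref_arr_t = np.array([t for _, t in refs], dtype=object)
    mask = np.zeros((len(pairs), len(refs)), dtype=bool)
    for i, (d, t) in enumerate(pairs):
        same_d = ref_arr_d == d
        same_t = ref_arr_t == t
        if policy == "pair":
            mask[i] = same_d & same_t
        elif policy == "drug":
            mask[i] = same_d
        elif policy == "protein":
            mask[i] = same_t
        elif policy == "either":
            mask[i] = same_d | same_t
        else:
            raise ValueError(f"bad exclusion policy {policy!r}")
    return mask


def build_feature_table(
    pairs: Sequence[tuple[str, str]],
    gsp: InteractionSet,
    drug_sims: Mapping[str, SimilarityMatrix],
    prot_sims: Mapping[str, SimilarityMatrix],
    exclude: Iterable[tuple[str, str]] = (),
    exclusion_policy: str = "pair",
    exclude_self: bool = True,
) -> pd.DataFrame:
    """Per-pair feature values against a reference positive set.

    For each drug measure ``i`` and protein measure ``j`` the feature of a
    pair ``(d, t)`` is ``max over (d', t') in GSP`` of
    ``S_i(d, d') * S_j(t, t')``, never using the query pair (or, under
    stricter policies, any reference sharing its drug/protein) as its own
    reference.  Missing source data propagates to missing features.

    Returns a DataFrame indexed by ``(compound_id, protein_id)`` with one
    column per available feature; missing values are ``NaN``.
    ``exclude_self=False`` disables query-pair exclusion (leakage mode,
    for diagnostics only).
    """
    refs = [p for p in gsp.sorted_pairs if p not in set(exclude)]
    if not refs:
        raise ValueError("reference positive set empty after exclusions")
    pairs = list(pairs)
    self_mask = (
        _exclusion_mask(pairs, refs, exclusion_policy)
        if exclude_self
        else np.zeros((len(pairs), len(refs)), dtype=bool)
    )
    columns: dict[str, np.ndarray] = {}
    for dm, dsim in drug_sims.items():
        for pm, psim in prot_sims.items():
            prod = _product_tensor(pairs, refs, dsim, psim)
            prod[self_mask] = np.nan
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                columns[feature_name(dm, pm)] = np.nanmax(prod, axis=1)
    index = pd.MultiIndex.from_tuples(pairs, names=["compound_id", "protein_id"])
    order = [f for f in ALL_FEATURES if f in columns]
    return pd.DataFrame(columns, index=index)[order]
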