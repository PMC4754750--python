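"""Core value types shared across the pipeline.

Conventions used throughout the package:

* entity ids are opaque, case-sensitive strings;
* similarity scores live in ``[0, 1]``; *missing* data is represented by
  ``NaN`` (never by ``0`` -- absence of evidence is not evidence of
  dissimilarity);
* feature names are ``"<drug_measure>-<protein_measure>"`` strings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

DRUG_MEASURES = (
    "fp2",
    "functional_group",
    "side_effect",
    "atc",
    "expression",
    "text_mining",
)
PROTEIN_MEASURES = ("sequence", "closeness", "go")

#: the full 6 x 3 feature vocabulary, in deterministic order
ALL_FEATURES = tuple(
    f"{d}-{p}" for d in DRUG_MEASURES for p in PROTEIN_MEASURES
)

#: features derived from chemical structure only (fallback model when a
#: query compound has nothing but structure data)
STRUCTURE_FEATURES = (
    "fp2-closeness",
    "functional_group-sequence",
    "functional_group-go",
)

ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")


def feature_name(drug_measure: str, protein_measure: str) -> str:
    if drug_measure not in DRUG_MEASURES:
        raise ValueError(f"unknown drug measure: {drug_measure!r}")
    if protein_measure not in PROTEIN_MEASURES:
        raise ValueError(f"unknown protein measure: {protein_measure!r}")
    return f"{drug_measure}-{protein_measure}"


def split_feature_name(name: str) -> tuple[str, str]:
    drug_measure, _, protein_measure = name.partition("-")
    if f"{drug_measure}-{protein_measure}" not in ALL_FEATURES:
        raise ValueError(f"unknown feature name: {name!r}")
    return drug_measure, protein_measure


@dataclass
class CompoundRecord:
    """One compound's per-source raw descriptors.

    A source whose field is empty/``None`` is unavailable; availability is
    derived, never stored inconsistently.
    """

    compound_id: str
    fingerprint: np.ndarray | None = None  # bit vector (0/1 ints)
    functional_groups: np.ndarray | None = None  # non-negative counts
    side_effects: frozenset[str] | None = None
    atc_codes: frozenset[str] | None = None
    expression_signature: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.fingerprint is not None:
            self.fingerprint = np.asarray(self.fingerprint, dtype=np.int8)
            if not np.isin(self.fingerprint, (0, 1)).all():
                raise ValueError(f"{self.compound_id}: fingerprint must be 0/1")
        if self.functional_groups is not None:
            self.functional_groups = np.asarray(self.functional_groups, dtype=np.int64)
            if (self.functional_groups < 0).any():
                raise ValueError(f"{self.compound_id}: negative group counts")
        if self.side_effects is not None:
            self.side_effects = frozenset(self.side_effects)
        if self.atc_codes is not None:
            self.atc_codes = frozenset(self.atc_codes)
            for code in self.atc_codes:
                if not ATC_PATTERN.match(code):
                    raise ValueError(f"{self.compound_id}: bad ATC code {code!r}")
        if self.expression_signature is not None:
            self.expression_signature = np.asarray(
                self.expression_signature, dtype=float
            )

    @property
    def availability(self) -> dict[str, bool]:
        return {
            "fp2": self.fingerprint is not None and self.fingerprint.size > 0,
            "functional_group": self.functional_groups is not None
            and self.functional_groups.size > 0,
            "side_effect": bool(self.side_effects),
            "atc": bool(self.atc_codes),
            "expression": self.expression_signature is not None
            and self.expression_signature.size > 0,
        }


@dataclass
class ProteinRecord:
    """One protein's raw data: sequence, GO annotation, PPI membership."""

    protein_id: str
    sequence: str | None = None
    go_terms: frozenset[str] | None = None
    in_network: bool = False

    def __post_init__(self) -> None:
        if self.sequence is not None:
            bad = set(self.sequence.upper()) - AMINO_ACIDS
            if bad:
                raise ValueError(
                    f"{self.protein_id}: non-amino-acid letters {sorted(bad)}"
                )
            self.sequence = self.sequence.upper()
        if self.go_terms is not None:
            self.go_terms = frozenset(self.go_terms)

    @property
    def availability(self) -> dict[str, bool]:
        return {
            "sequence": bool(self.sequence),
            "go": bool(self.go_terms),
            "closeness": self.in_network,
        }


class SimilarityMatrix:
    """A named measure's symmetric pairwise scores with an explicit
    missing mask (``NaN`` entries).

    Entities lacking the underlying source carry an all-``NaN`` row/column
    (including the diagonal); every entity with data has diagonal 1.
    """

    def __init__(
        self,
        measure_name: str,
        entity_ids: Sequence[str],
        values: np.ndarray,
        validate: bool = True,
    ):
        self.measure_name = measure_name
        self.entity_ids = list(entity_ids)
        self.values = np.asarray(values, dtype=float)
        self._index = {e: i for i, e in enumerate(self.entity_ids)}
        if len(self._index) != len(self.entity_ids):
            raise ValueError("duplicate entity ids")
        if validate:
            self._validate()

    def _validate(self) -> None:
        v = self.values
        n = len(self.entity_ids)
        if v.shape != (n, n):
            raise ValueError(f"shape {v.shape} != ({n}, {n})")
        finite = ~np.isnan(v)
        if not np.array_equal(finite, finite.T) or not np.allclose(
            v[finite & finite.T], v.T[finite & finite.T], atol=1e-9
        ):
            raise ValueError(f"{self.measure_name}: matrix not symmetric")
        vals = v[finite]
        if vals.size and (vals.min() < -1e-9 or vals.max() > 1 + 1e-9):
            raise ValueError(f"{self.measure_name}: values outside [0, 1]")
        diag = np.diag(v)
        avail = ~np.isnan(diag)
        if avail.any() and not np.allclose(diag[avail], 1.0, atol=1e-9):
            raise ValueError(f"{self.measure_name}: available diagonal != 1")

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._index

    def index_of(self, entity_id: str) -> int:
        return self._index[entity_id]

    def get(self, a: str, b: str) -> float:
        """Pairwise score; ``NaN`` if either entity is unknown or lacks data."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return float("nan")
        return float(self.values[ia, ib])

    def is_available(self, entity_id: str) -> bool:
        i = self._index.get(entity_id)
        return i is not None and not np.isnan(self.values[i, i])

    def rows(self, ids: Sequence[str]) -> np.ndarray:
        """Sub-matrix of rows for ``ids`` (NaN rows for unknown ids)."""
        idx = np.fromiter(
            (self._index.get(e, -1) for e in ids), dtype=np.int64, count=len(ids)
        )
        out = self.values[np.clip(idx, 0, None)]
        out[idx < 0] = np.nan
        return out

    def submatrix(self, row_ids: Sequence[str], col_ids: Sequence[str]) -> np.ndarray:
        """Rectangular block of scores (NaN for unknown ids)."""
        ridx = np.fromiter(
            (self._index.get(e, -1) for e in row_ids), dtype=np.int64, count=len(row_ids)
        )
        cidx = np.fromiter(
            (self._index.get(e, -1) for e in col_ids), dtype=np.int64, count=len(col_ids)
        )
        out = self.values[np.ix_(np.clip(ridx, 0, None), np.clip(cidx, 0, None))]
        out[ridx < 0, :] = np.nan
        out[:, cidx < 0] = np.nan
        return out


@dataclass(frozen=True)
class InteractionSet:
    """Labeled compound-protein pairs (golden-standard positives/negatives
    or an independent test set)."""

    role: str  # "GSP" | "GSN" | "test"
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.role not in ("GSP", "GSN", "test"):
            raise ValueError(f"bad role {self.role!r}")
        object.__setattr__(self, "pairs", frozenset(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.sorted_pairs)

    @property
    def sorted_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.pairs)

    @property
    def drugs(self) -> set[str]:
        return {d for d, _ in self.pairs}

    @property
    def proteins(self) -> set[str]:
        return {p for _, p in self.pairs}


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.term_id}: empty gene set")
        object.__setattr__(self, "members", frozenset(self.members))


@dataclass
class GeneSetCollection:
    """Term -> member-set mapping for one category, plus the background
    universe used by the hypergeometric test (defaults to the union of all
    member sets)."""

    category: str  # pathway | go_bp | go_mf | go_cc | disease | ...
    terms: dict[str, GeneSet]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(
                *(t.members for t in self.terms.values())
            ) if self.terms else frozenset()
        for t in self.terms.values():
            extra = t.members - self.universe
            if extra:
                raise ValueError(
                    f"term {t.term_id} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's enrichment test outcome."""

    term_id: str
    term_name: str
    category: str
    k: int  # targets mapped to the term
    K: int  # term size
    n: int  # target-set size within the universe
    N: int  # universe size
    p_raw: float
    p_adjusted: float
    mapped_targets: tuple[str, ...]
    significant: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError("invalid contingency counts")
        if not (0.0 < self.p_raw <= 1.0):
            raise ValueError("p_raw outside (0, 1]")
        if self.p_adjusted < self.p_raw - 1e-12 or self.p_adjusted > 1 + 1e-12:
            raise ValueError("p_adjusted must satisfy p_raw <= p_adj <= 1")


@dataclass
class PredictionConfig:
    """User-tunable knobs of the predictor, recorded for provenance."""

    score_cutoff: float = 0.0
    n_bins: int = 20
    pseudocount: float = 1.0
    n_selected_features: int = 8
    exclusion_policy: str = "pair"  # pair | drug | protein | either
    seed: int = 0
    features: Sequence[str] | None = None  # restrict to a subset (e.g. structure-only)

    def __post_init__(self) -> None:
        if self.score_cutoff < 0:
            raise ValueError("score_cutoff must be >= 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.exclusion_policy not in ("pair", "drug", "protein", "either"):
            raise ValueError(f"bad exclusion policy {self.exclusion_policy!r}")
        if self.features is not None:
            self.features = tuple(self.features)
            for f in self.features:
                split_feature_name(f)

    def to_dict(self) -> dict:
        return {
            "score_cutoff": self.score_cutoff,
            "n_bins": self.n_bins,
            "pseudocount": self.pseudocount,
            "n_selected_features": self.n_selected_features,
            "exclusion_policy": self.exclusion_policy,
            "seed": self.seed,
            "features": list(self.features) if self.features else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PredictionConfig":
        return cls(**dict(d))


@dataclass(frozen=True)
class RankedTargets:
    """Descending-score ranking of candidate proteins for one compound.

    Known targets are flagged regardless of score and survive any cutoff.
    """

    compound_id: str
    entries: tuple[tuple[str, float, bool], ...]  # (protein, score, is_known)
    unscorable: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        scores = [s for _, s, _ in self.entries]
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError("entries must be sorted by non-increasing score")


def interaction_set(role: str, pairs: Iterable[tuple[str, str]]) -> InteractionSet:
    return InteractionSet(role=role, pairs=frozenset(pairs))
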