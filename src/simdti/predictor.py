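"""Likelihood-ratio predictor: negative-set sampling, per-feature LR
estimation on equal-width bins, greedy mRMR feature selection and max-LR
scoring/ranking of candidate targets."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    InteractionSet,
    PredictionConfig,
    RankedTargets,
    SimilarityMatrix,
    interaction_set,
)
from .similarity import build_feature_table

__all__ = [
    "sample_gsn",
    "estimate_lr",
    "mrmr_select",
    "score_pair",
    "score_pairs",
    "rank_targets",
    "apply_cutoff",
    "LRModel",
    "train_model",
]

MODEL_FORMAT_VERSION = 1


def sample_gsn(
    gsp: InteractionSet,
    drugs: Iterable[str] | None = None,
    proteins: Iterable[str] | None = None,
    seed: int = 0,
    size: int | None = None,
    forbidden: Iterable[tuple[str, str]] = (),
) -> InteractionSet:
    """Sample a negative set of ``size`` (default ``len(gsp)``) random
    drug-protein combinations, excluding the positives (and any extra
    ``forbidden`` pairs).

    Drugs and proteins default to the entities appearing in the positive
    set.  Reproducible under ``seed``.
    """
    drug_pool = sorted(set(drugs) if drugs is not None else gsp.drugs)
    prot_pool = sorted(set(proteins) if proteins is not None else gsp.proteins)
    size = len(gsp) if size is None else size
    banned = set(gsp.pairs) | set(forbidden)
    n_possible = len(drug_pool) * len(prot_pool) - len(
        {p for p in banned if p[0] in set(drug_pool) and p[1] in set(prot_pool)}
    )
    if n_possible < size:
        raise ValueError(
            f"cannot sample {size} negatives: only {n_possible} "
            "non-positive combinations available"
        )
    rng = np.random.default_rng(seed)
    chosen: set[tuple[str, str]] = set()
    # rejection sampling; dense fallback if the free space is tight
    if n_possible < 2 * size:
        all_pairs = [
            (d, t) for d in drug_pool for t in prot_pool if (d, t) not in banned
        ]
        idx = rng.choice(len(all_pairs), size=size, replace=False)
        chosen = {all_pairs[i] for i in idx}
    else:
        while len(chosen) < size:
            d = drug_pool[int(rng.integers(len(drug_pool)))]
            t = prot_pool[int(rng.integers(len(prot_pool)))]
            if (d, t) not in banned and (d, t) not in chosen:
                chosen.add((d, t))
    return interaction_set("GSN", chosen)


def bin_index(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Map values in [0, 1] onto equal-width bin indices; value 1 falls in
    the last bin.  NaN maps to -1."""
    v = np.asarray(values, dtype=float)
    idx = np.full(v.shape, -1, dtype=np.int64)
    ok = ~np.isnan(v)
    idx[ok] = np.minimum((v[ok] * n_bins).astype(np.int64), n_bins - 1)
    return idx


@dataclass
class LRModel:
    """Trained per-feature bin likelihood ratios plus the selected-feature
    list used by the max-LR score."""

    n_bins: int
    pseudocount: float
    features: tuple[str, ...]  # features with estimated LRs, in table order
    lr: dict[str, np.ndarray]  # feature -> (n_bins,) LR values
    pos_counts: dict[str, np.ndarray]
    neg_counts: dict[str, np.ndarray]
    selected_features: tuple[str, ...] = ()
    seed: int | None = None
    n_gsp: int = 0
    n_gsn: int = 0

    def __post_init__(self) -> None:
        edges = self.bin_edges
        for f in self.features:
            arr = np.asarray(self.lr[f], dtype=float)
            if arr.shape != (self.n_bins,):
                raise ValueError(f"{f}: LR array shape {arr.shape}")
            if not np.isfinite(arr).all() or (arr < 0).any():
                raise ValueError(f"{f}: LR values must be finite and >= 0")
            self.lr[f] = arr
        unknown = set(self.selected_features) - set(self.features)
        if unknown:
            raise ValueError(f"selected features not in model: {sorted(unknown)}")

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)

    def feature_lr(self, feature: str, value: float) -> float:
        """LR of one feature value; NaN input -> NaN."""
        if np.isnan(value):
            return float("nan")
        b = int(bin_index(np.array([value]), self.n_bins)[0])
        return float(self.lr[feature][b])

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "n_bins": self.n_bins,
            "pseudocount": self.pseudocount,
            "features": list(self.features),
            "lr": {f: self.lr[f].tolist() for f in self.features},
            "pos_counts": {f: self.pos_counts[f].tolist() for f in self.features},
            "neg_counts": {f: self.neg_counts[f].tolist() for f in self.features},
            "selected_features": list(self.selected_features),
            "seed": self.seed,
            "n_gsp": self.n_gsp,
            "n_gsn": self.n_gsn,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "LRModel":
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {d.get('format_version')!r}")
        return cls(
            n_bins=int(d["n_bins"]),
            pseudocount=float(d["pseudocount"]),
            features=tuple(d["features"]),
            lr={f: np.asarray(v, dtype=float) for f, v in d["lr"].items()},
            pos_counts={f: np.asarray(v) for f, v in d["pos_counts"].items()},
            neg_counts={f: np.asarray(v) for f, v in d["neg_counts"].items()},
            selected_features=tuple(d["selected_features"]),
            seed=d.get("seed"),
            n_gsp=int(d.get("n_gsp", 0)),
            n_gsn=int(d.get("n_gsn", 0)),
        )

    @classmethod
    def from_json(cls, path) -> "LRModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _smoothed_lr(
    pos: np.ndarray, neg: np.ndarray, alpha: float, n_bins: int
) -> np.ndarray:
    n_pos, n_neg = pos.sum(), neg.sum()
    p_pos = (pos + alpha) / (n_pos + alpha * n_bins)
    p_neg = (neg + alpha) / (n_neg + alpha * n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.where(p_neg > 0, p_pos / p_neg, np.inf)
    if not np.isfinite(lr).all():
        raise ValueError("non-finite LR; use pseudocount > 0 with empty bins")
    return lr


def estimate_lr(
    features: pd.DataFrame,
    gsp: InteractionSet,
    gsn: InteractionSet,
    n_bins: int = 20,
    pseudocount: float = 1.0,
) -> LRModel:
    """Estimate per-feature, per-bin likelihood ratios.

    ``LR_b = ((c+_b + a)/(n+ + aB)) / ((c-_b + a)/(n- + aB))`` where the
    counts come from the feature values of positive/negative pairs that
    are non-missing for that feature.  Features missing for every pair are
    dropped with a warning.
    """
    pos_idx = [p for p in gsp.sorted_pairs if p in features.index]
    neg_idx = [p for p in gsn.sorted_pairs if p in features.index]
    if len(pos_idx) < len(gsp) or len(neg_idx) < len(gsn):
        raise ValueError("feature table does not cover all GSP/GSN pairs")
    lr: dict[str, np.ndarray] = {}
    pos_counts: dict[str, np.ndarray] = {}
    neg_counts: dict[str, np.ndarray] = {}
    kept: list[str] = []
    for f in features.columns:
        pv = features.loc[pos_idx, f].to_numpy()
        nv = features.loc[neg_idx, f].to_numpy()
        pb = bin_index(pv, n_bins)
        nb = bin_index(nv, n_bins)
        cp = np.bincount(pb[pb >= 0], minlength=n_bins).astype(float)
        cn = np.bincount(nb[nb >= 0], minlength=n_bins).astype(float)
        if cp.sum() == 0 and cn.sum() == 0:
            warnings.warn(f"feature {f!r} missing for all pairs; dropped")
            continue
        kept.append(f)
        pos_counts[f] = cp
        neg_counts[f] = cn
        lr[f] = _smoothed_lr(cp, cn, pseudocount, n_bins)
    if not kept:
        raise ValueError("no usable features")
    return LRModel(
        n_bins=n_bins,
        pseudocount=pseudocount,
        features=tuple(kept),
        lr=lr,
        pos_counts=pos_counts,
        neg_counts=neg_counts,
        n_gsp=len(gsp),
        n_gsn=len(gsn),
    )


def _mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """MI (nats) between two discrete integer-coded variables."""
    joint = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy().astype(float)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


def mrmr_select(
    features: pd.DataFrame,
    labels: Sequence[int],
    k: int,
    n_bins: int = 20,
    discretize: bool = True,
) -> list[str]:
    """Greedy minimum-redundancy / maximum-relevance (MID difference form).

    Features are discretized onto the LR bins (missing as its own
    category).  The first pick maximizes MI with the labels; each next
    pick maximizes ``MI(f; label) - mean MI(f; selected)``.  Ties break by
    feature name.  Returns ``min(k, available)`` names in selection order.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    y = np.asarray(labels)
    if len(y) != len(features):
        raise ValueError("labels length mismatch")
    cols: dict[str, np.ndarray] = {}
    for f in features.columns:
        v = features[f].to_numpy()
        cols[f] = bin_index(v, n_bins) if discretize else np.asarray(v)
        if len(np.unique(cols[f])) < 2:
            del cols[f]  # degenerate: constant after discretization
    if not cols:
        raise ValueError("no non-degenerate features")
    names = sorted(cols)
    relevance = {f: _mutual_information(cols[f], y) for f in names}
    redundancy: dict[tuple[str, str], float] = {}

    def red(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in redundancy:
            redundancy[key] = _mutual_information(cols[key[0]], cols[key[1]])
        return redundancy[key]

    selected: list[str] = []
    while len(selected) < min(k, len(names)):
        best, best_score = None, -np.inf
        for f in names:
            if f in selected:
                continue
            score = relevance[f]
            if selected:
                score -= np.mean([red(f, s) for s in selected])
            if score > best_score + 1e-12 or (
                abs(score - best_score) <= 1e-12 and (best is None or f < best)
            ):
                best, best_score = f, score
        selected.append(best)
    return selected


def train_model(
    features: pd.DataFrame,
    gsp: InteractionSet,
    gsn: InteractionSet,
    config: PredictionConfig,
) -> LRModel:
    """Estimate LRs and run mRMR selection in one step.

    ``config.features`` restricts the candidate features (e.g. the
    structure-only subset); LRs are then estimated on that subset.
    """
    table = features
    if config.features is not None:
        avail = [f for f in config.features if f in features.columns]
        if not avail:
            raise ValueError("none of the requested features are in the table")
        table = features[avail]
    model = estimate_lr(
        table, gsp, gsn, n_bins=config.n_bins, pseudocount=config.pseudocount
    )
    pairs = gsp.sorted_pairs + gsn.sorted_pairs
    labels = np.array([1] * len(gsp) + [0] * len(gsn))
    sub = table.loc[pairs, list(model.features)]
    k = min(config.n_selected_features, len(model.features))
    model.selected_features = tuple(
        mrmr_select(sub, labels, k, n_bins=config.n_bins)
    )
    model.seed = config.seed
    return model


def score_pair(
    pair: tuple[str, str],
    model: LRModel,
    features: pd.DataFrame | Mapping[str, float],
) -> float:
    """Max-LR score of one pair: the maximum likelihood ratio over the
    selected, non-missing features.  All-missing -> NaN (unscorable)."""
    if isinstance(features, pd.DataFrame):
        row = features.loc[pair]
    else:
        row = features
    sel = model.selected_features or model.features
    lrs = [
        model.feature_lr(f, float(row[f]))
        for f in sel
        if f in model.features and not np.isnan(float(row[f]))
    ]
    if not lrs:
        return float("nan")
    return max(lrs)


def score_pairs(features: pd.DataFrame, model: LRModel) -> np.ndarray:
    """Vectorized max-LR scores for every row of a feature table."""
    sel = [f for f in (model.selected_features or model.features) if f in features.columns]
    if not sel:
        return np.full(len(features), np.nan)
    out = np.full(len(features), -np.inf)
    any_avail = np.zeros(len(features), dtype=bool)
    for f in sel:
        b = bin_index(features[f].to_numpy(), model.n_bins)
        ok = b >= 0
        vals = np.where(ok, model.lr[f][np.clip(b, 0, None)], -np.inf)
        out = np.maximum(out, vals)
        any_avail |= ok
    out[~any_avail] = np.nan
    return out


def rank_targets(
    compound: str,
    candidates: Sequence[str],
    model: LRModel,
    gsp: InteractionSet,
    drug_sims: Mapping[str, SimilarityMatrix],
    prot_sims: Mapping[str, SimilarityMatrix],
    known: Iterable[tuple[str, str]] = (),
    exclusion_policy: str = "pair",
) -> RankedTargets:
    """Score every candidate protein for one compound and rank descending,
    ties broken by protein id.  Known targets (from a user-supplied
    table) are flagged and always retained."""
    if not candidates:
        raise ValueError("candidate list is empty")
    if not any(compound in sim and sim.is_available(compound) for sim in drug_sims.values()):
        raise ValueError(
            f"compound {compound!r} absent from every drug similarity matrix"
        )
    known_prots = {t for d, t in known if d == compound}
    pairs = [(compound, t) for t in sorted(set(candidates) | known_prots)]
    table = build_feature_table(
        pairs, gsp, drug_sims, prot_sims, exclusion_policy=exclusion_policy
    )
    scores = score_pairs(table, model)
    entries = []
    unscorable = []
    for (c, t), s in zip(pairs, scores):
        if np.isnan(s):
            if t in known_prots:
                entries.append((t, float("-inf"), True))
            else:
                unscorable.append(t)
        else:
            entries.append((t, float(s), t in known_prots))
    entries.sort(key=lambda e: (-e[1], e[0]))
    # unscorable known targets sort to the bottom but keep a NaN score
    entries = [
        (t, (float("nan") if s == float("-inf") else s), k) for t, s, k in entries
    ]
    return RankedTargets(
        compound_id=compound, entries=tuple(entries), unscorable=tuple(sorted(unscorable))
    )


def apply_cutoff(ranked: RankedTargets, score_cutoff: float) -> list[tuple[str, float, bool]]:
    """Potential targets: predictions with score strictly above the cutoff,
    unioned with all known targets (whatever their score)."""
    out = []
    for t, s, k in ranked.entries:
        if k or (not np.isnan(s) and s > score_cutoff):
            out.append((t, s, k))
    return out
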