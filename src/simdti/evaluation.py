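"""Cross-validation and ROC/AUC evaluation of the predictor.

Two schemes: leave-one-interaction-out (every labeled pair held out in
turn; the held-out positive is also removed from the feature-reference
set) and leave-one-drug-out (all of one drug's labeled pairs held out
together, simulating prediction for a compound with no known targets),
plus a train-once independent-test protocol.  Scores of all folds are
pooled into a single ROC curve.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import InteractionSet, PredictionConfig, SimilarityMatrix
from .predictor import (
    LRModel,
    _smoothed_lr,
    bin_index,
    mrmr_select,
    sample_gsn,
    score_pairs,
    train_model,
)
from .similarity import _exclusion_mask, _product_tensor, build_feature_table
from .datatypes import ALL_FEATURES, feature_name

__all__ = ["roc_auc", "loio_cv", "lodo_cv", "independent_test", "EvaluationResult"]


@dataclass
class EvaluationResult:
    scheme: str  # loio | lodo | independent | roc
    scores: np.ndarray
    labels: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    n_folds: int = 0
    skipped_folds: int = 0
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "auc": self.auc,
            "n_folds": self.n_folds,
            "skipped_folds": self.skipped_folds,
            "n_scored": int(len(self.scores)),
            "config": self.config,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def roc_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_auc(scores: Sequence[float], labels: Sequence[int], scheme: str = "roc") -> EvaluationResult:
    """ROC curve by threshold sweep and AUC via the Mann-Whitney statistic
    (tied score pairs count 1/2).

    Tied scores collapse to a single ROC point; the curve starts at (0,0)
    and ends at (1,1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if np.isnan(s).any():
        raise ValueError("NaN scores are not rankable; filter unscorable pairs first")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # Mann-Whitney AUC with average ranks (ties count 1/2)
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    # threshold sweep, descending; one point per distinct score
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    distinct = np.r_[np.nonzero(np.diff(s_sorted))[0], len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos, 1.0]
    fpr = np.r_[0.0, fps[distinct] / n_neg, 1.0]
    thresholds = np.r_[np.inf, s_sorted[distinct], -np.inf]
    # drop a duplicated terminal point
    if len(tpr) > 2 and tpr[-2] == 1.0 and fpr[-2] == 1.0:
        tpr, fpr, thresholds = tpr[:-1], fpr[:-1], thresholds[:-1]
    return EvaluationResult(
        scheme=scheme,
        scores=s,
        labels=y,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=float(auc),
    )


class _FoldEngine:
    """Precomputed similarity-product tensors for fast exact refitting of
    features and LR counts when pairs or reference columns are held out."""

    def __init__(
        self,
        gsp: InteractionSet,
        gsn: InteractionSet,
        drug_sims: Mapping[str, SimilarityMatrix],
        prot_sims: Mapping[str, SimilarityMatrix],
        config: PredictionConfig,
        exclude_self: bool = True,
    ):
        self.gsp = gsp
        self.gsn = gsn
        self.config = config
        self.pos_pairs = gsp.sorted_pairs
        self.neg_pairs = gsn.sorted_pairs
        self.pairs = self.pos_pairs + self.neg_pairs
        self.labels = np.r_[np.ones(len(self.pos_pairs)), np.zeros(len(self.neg_pairs))].astype(int)
        self.refs = self.pos_pairs  # reference columns = GSP, sorted
        wanted = set(config.features) if config.features is not None else None
        self.feature_names: list[str] = []
        self.tensors: dict[str, np.ndarray] = {}
        self.raw_tensors: dict[str, np.ndarray] = {}
        mask = _exclusion_mask(self.pairs, self.refs, config.exclusion_policy)
        for dm, dsim in drug_sims.items():
            for pm, psim in prot_sims.items():
                name = feature_name(dm, pm)
                if wanted is not None and name not in wanted:
                    continue
                raw = _product_tensor(self.pairs, self.refs, dsim, psim)
                t = raw.copy()
                if exclude_self:
                    t[mask] = np.nan
                self.feature_names.append(name)
                self.tensors[name] = t
                self.raw_tensors[name] = raw
        self.feature_names = [f for f in ALL_FEATURES if f in self.tensors]
        self.ref_drugs = np.array([d for d, _ in self.refs], dtype=object)

    def features_with_columns_masked(self, col_mask: np.ndarray | None) -> pd.DataFrame:
        """Feature table with the given reference columns removed."""
        cols: dict[str, np.ndarray] = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            for f in self.feature_names:
                t = self.tensors[f]
                sub = t if col_mask is None else t[:, ~col_mask]
                cols[f] = (
                    np.nanmax(sub, axis=1) if sub.shape[1] else np.full(len(self.pairs), np.nan)
                )
        idx = pd.MultiIndex.from_tuples(self.pairs, names=["compound_id", "protein_id"])
        return pd.DataFrame(cols, index=idx)

    def lr_from_rows(
        self, feats: pd.DataFrame, row_mask: np.ndarray
    ) -> dict[str, np.ndarray]:
        """Per-feature LR arrays from the rows selected by ``row_mask``."""
        cfg = self.config
        y = self.labels[row_mask]
        out: dict[str, np.ndarray] = {}
        for f in self.feature_names:
            b = bin_index(feats[f].to_numpy()[row_mask], cfg.n_bins)
            cp = np.bincount(b[(b >= 0) & (y == 1)], minlength=cfg.n_bins).astype(float)
            cn = np.bincount(b[(b >= 0) & (y == 0)], minlength=cfg.n_bins).astype(float)
            out[f] = _smoothed_lr(cp, cn, cfg.pseudocount, cfg.n_bins)
        return out

    def select_features(self, feats: pd.DataFrame) -> list[str]:
        k = min(self.config.n_selected_features, len(self.feature_names))
        try:
            return mrmr_select(feats, self.labels, k, n_bins=self.config.n_bins)
        except ValueError:
            return list(self.feature_names)

    @staticmethod
    def max_lr_scores(
        feats: pd.DataFrame,
        lr: Mapping[str, np.ndarray],
        selected: Sequence[str],
        rows: np.ndarray,
        n_bins: int,
    ) -> np.ndarray:
        sub = feats.iloc[rows] if rows is not None else feats
        out = np.full(len(sub), -np.inf)
        avail = np.zeros(len(sub), dtype=bool)
        for f in selected:
            if f not in lr:
                continue
            b = bin_index(sub[f].to_numpy(), n_bins)
            ok = b >= 0
            out = np.maximum(out, np.where(ok, lr[f][np.clip(b, 0, None)], -np.inf))
            avail |= ok
        out[~avail] = np.nan
        return out


def _top2(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row (top value, its column, runner-up value); NaN as -inf."""
    t = np.where(np.isnan(matrix), -np.inf, matrix)
    n_cols = t.shape[1]
    if n_cols == 1:
        v1 = t[:, 0]
        return v1, np.zeros(len(t), dtype=np.int64), np.full(len(t), -np.inf)
    part = np.argpartition(-t, 1, axis=1)[:, :2]
    rows = np.arange(len(t))[:, None]
    vals = t[rows, part]
    first = np.argmax(vals, axis=1)
    v1 = vals[np.arange(len(t)), first]
    i1 = part[np.arange(len(t)), first]
    v2 = vals[np.arange(len(t)), 1 - first]
    return v1, i1, v2


def loio_cv(
    gsp: InteractionSet,
    gsn: InteractionSet,
    drug_sims: Mapping[str, SimilarityMatrix],
    prot_sims: Mapping[str, SimilarityMatrix],
    config: PredictionConfig | None = None,
    per_fold_selection: bool = False,
    exclude_self: bool = True,
) -> EvaluationResult:
    """Leave-one-interaction-out cross-validation.

    Every pair of ``GSP | GSN`` is held out in turn: it is removed from
    its own set for LR estimation and, when positive, from the feature
    reference set, so the remaining pairs' features are exactly those of
    a model trained without it.  All (score, label) pairs are pooled into
    one ROC/AUC.

    ``exclude_self=False`` disables query-pair exclusion everywhere
    (deliberate-leakage diagnostic: every positive scores its own
    reference product of 1).  ``per_fold_selection`` reruns mRMR inside
    every fold (slow); by default selection runs once on the full data.
    """
    if len(gsp) == 0 or len(gsn) == 0:
        raise ValueError("GSP and GSN must be non-empty")
    if len(gsp) < 2:
        raise ValueError("need at least two positives to leave one out")
    config = config or PredictionConfig()
    eng = _FoldEngine(gsp, gsn, drug_sims, prot_sims, config,
                      exclude_self=exclude_self)
    n_pos = len(eng.pos_pairs)
    n_bins, alpha = config.n_bins, config.pseudocount
    full_feats = eng.features_with_columns_masked(None)
    selected_full = eng.select_features(full_feats)

    # per-feature top-2 over reference columns + baseline bin counts
    v1: dict[str, np.ndarray] = {}
    i1: dict[str, np.ndarray] = {}
    v2: dict[str, np.ndarray] = {}
    bins0: dict[str, np.ndarray] = {}
    bins2: dict[str, np.ndarray] = {}
    counts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    y = eng.labels
    for f in eng.feature_names:
        a, b, c = _top2(eng.tensors[f])
        v1[f], i1[f], v2[f] = a, b, c
        fb = np.where(np.isinf(a), -1, np.minimum((np.clip(a, 0, 1) * n_bins).astype(np.int64), n_bins - 1))
        fb[np.isinf(a)] = -1
        bins0[f] = fb
        sb = np.where(np.isinf(c), -1, np.minimum((np.clip(c, 0, 1) * n_bins).astype(np.int64), n_bins - 1))
        sb[np.isinf(c)] = -1
        bins2[f] = sb
        cp = np.bincount(fb[(fb >= 0) & (y == 1)], minlength=n_bins).astype(float)
        cn = np.bincount(fb[(fb >= 0) & (y == 0)], minlength=n_bins).astype(float)
        counts[f] = (cp, cn)

    def _lr_at(f: str, b: int, cp: np.ndarray, cn: np.ndarray) -> float:
        p_pos = (cp[b] + alpha) / (cp.sum() + alpha * n_bins)
        p_neg = (cn[b] + alpha) / (cn.sum() + alpha * n_bins)
        if p_neg <= 0:
            raise ValueError("zero negative density; use pseudocount > 0")
        return p_pos / p_neg

    scores: list[float] = []
    labels: list[int] = []
    skipped = 0
    n_folds = len(eng.pairs)
    for i, pair in enumerate(eng.pairs):
        positive = i < n_pos
        selected = selected_full
        if per_fold_selection:
            col_mask = None
            if positive and exclude_self:
                col_mask = np.zeros(len(eng.refs), dtype=bool)
                col_mask[i] = True
            feats = eng.features_with_columns_masked(col_mask)
            row_mask = np.ones(len(eng.pairs), dtype=bool)
            row_mask[i] = False
            selected = mrmr_select(
                feats.iloc[np.nonzero(row_mask)[0]], y[row_mask],
                min(config.n_selected_features, len(eng.feature_names)),
                n_bins=config.n_bins,
            )
        best = -np.inf
        scorable = False
        for f in selected:
            cp, cn = counts[f]
            applied: list[tuple[np.ndarray, int, float]] = []

            def adj(arr: np.ndarray, b: int, amt: float) -> None:
                if b >= 0:
                    arr[b] += amt
                    applied.append((arr, b, amt))

            if positive and exclude_self:
                # removing reference column i shifts rows whose max sat there
                for q in np.nonzero(i1[f] == i)[0]:
                    if q == i or bins0[f][q] < 0:
                        continue
                    arr = cp if y[q] == 1 else cn
                    adj(arr, bins0[f][q], -1.0)
                    adj(arr, bins2[f][q], +1.0)
                test_bin = int(bins0[f][i])  # own column already self-masked
            elif positive and not exclude_self:
                test_bin = int(bins0[f][i])  # leakage: own column stays in
            else:
                test_bin = int(bins0[f][i])
            # held-out pair leaves its own class counts
            adj(cp if positive else cn, int(bins0[f][i]), -1.0)
            if test_bin >= 0:
                best = max(best, _lr_at(f, test_bin, cp, cn))
                scorable = True
            for arr, b, amt in reversed(applied):
                arr[b] -= amt
        if not scorable:
            skipped += 1
            warnings.warn(f"fold for pair {pair} unscorable; skipped")
            continue
        scores.append(float(best))
        labels.append(int(y[i]))

    result = roc_auc(scores, labels, scheme="loio")
    result.n_folds = n_folds
    result.skipped_folds = skipped
    result.config = {**config.to_dict(), "per_fold_selection": per_fold_selection,
                     "exclude_self": exclude_self}
    return result


def lodo_cv(
    gsp: InteractionSet,
    gsn: InteractionSet,
    drug_sims: Mapping[str, SimilarityMatrix],
    prot_sims: Mapping[str, SimilarityMatrix],
    config: PredictionConfig | None = None,
) -> EvaluationResult:
    """Leave-one-drug-out cross-validation: one fold per distinct drug in
    ``GSP | GSN``; all of that drug's labeled pairs are held out together
    and its positives removed from the reference set ("ab initio"
    prediction)."""
    drugs = sorted(gsp.drugs | gsn.drugs)
    if len(drugs) < 2:
        raise ValueError("need at least two distinct drugs")
    config = config or PredictionConfig()
    eng = _FoldEngine(gsp, gsn, drug_sims, prot_sims, config)
    full_feats = eng.features_with_columns_masked(None)
    selected = eng.select_features(full_feats)
    pair_drugs = np.array([d for d, _ in eng.pairs], dtype=object)

    scores: list[float] = []
    labels: list[int] = []
    skipped = 0
    for drug in drugs:
        col_mask = eng.ref_drugs == drug
        if col_mask.all():
            skipped += 1
            continue
        test_rows = np.nonzero(pair_drugs == drug)[0]
        if len(test_rows) == 0:
            continue
        feats = eng.features_with_columns_masked(col_mask)
        row_mask = pair_drugs != drug
        lr = eng.lr_from_rows(feats, row_mask)
        s = _FoldEngine.max_lr_scores(feats, lr, selected, test_rows, config.n_bins)
        for j, v in zip(test_rows, s):
            if np.isnan(v):
                skipped += 1
                continue
            scores.append(float(v))
            labels.append(int(eng.labels[j]))
    result = roc_auc(scores, labels, scheme="lodo")
    result.n_folds = len(drugs)
    result.skipped_folds = skipped
    result.config = config.to_dict()
    return result


def independent_test(
    train_gsp: InteractionSet,
    train_gsn: InteractionSet,
    test_pos: InteractionSet,
    drug_sims: Mapping[str, SimilarityMatrix],
    prot_sims: Mapping[str, SimilarityMatrix],
    config: PredictionConfig | None = None,
    drugs_disjoint: bool = False,
    negative_seed: int = 1,
) -> EvaluationResult:
    """Train once on the training sets, score an independent positive set
    plus freshly sampled negatives (excluded from train GSP/GSN and the
    test positives).

    ``drugs_disjoint=True`` additionally requires that no test drug occurs
    in training, and errors naming offenders otherwise.
    """
    overlap = test_pos.pairs & train_gsp.pairs
    if overlap:
        raise ValueError(f"test positives present in training GSP: {sorted(overlap)[:5]}")
    if drugs_disjoint:
        shared = test_pos.drugs & (train_gsp.drugs | train_gsn.drugs)
        if shared:
            raise ValueError(f"test drugs present in training: {sorted(shared)[:5]}")
    config = config or PredictionConfig()
    train_feats = build_feature_table(
        train_gsp.sorted_pairs + train_gsn.sorted_pairs,
        train_gsp,
        drug_sims,
        prot_sims,
        exclusion_policy=config.exclusion_policy,
    )
    model = train_model(train_feats, train_gsp, train_gsn, config)
    test_neg = sample_gsn(
        test_pos,
        proteins=train_gsp.proteins | test_pos.proteins,
        seed=negative_seed,
        forbidden=train_gsp.pairs | train_gsn.pairs,
    )
    test_pairs = test_pos.sorted_pairs + test_neg.sorted_pairs
    test_feats = build_feature_table(
        test_pairs, train_gsp, drug_sims, prot_sims,
        exclusion_policy=config.exclusion_policy,
    )
    s = score_pairs(test_feats, model)
    y = np.r_[np.ones(len(test_pos)), np.zeros(len(test_neg))].astype(int)
    ok = ~np.isnan(s)
    result = roc_auc(s[ok], y[ok], scheme="independent")
    result.n_folds = 1
    result.skipped_folds = int((~ok).sum())
    result.config = {**config.to_dict(), "drugs_disjoint": drugs_disjoint,
                     "negative_seed": negative_seed}
    return result
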