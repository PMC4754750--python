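import itertools
import json
import math

import numpy as np
import pandas as pd
import pytest

from simdti.datatypes import PredictionConfig, SimilarityMatrix, interaction_set
from simdti.predictor import (
    LRModel,
    apply_cutoff,
    bin_index,
    estimate_lr,
    mrmr_select,
    rank_targets,
    sample_gsn,
    score_pair,
    score_pairs,
    train_model,
)
from simdti.similarity import build_feature_table


def _feature_frame(values: dict[str, list[float]], pairs) -> pd.DataFrame:
    idx = pd.MultiIndex.from_tuples(pairs, names=["compound_id", "protein_id"])
    return pd.DataFrame(values, index=idx)


class TestSampleGsn:
    def test_same_size_as_gsp(self, small_universe):
        gsn = sample_gsn(small_universe.gsp, seed=5)
        assert len(gsn) == len(small_universe.gsp)

    def test_never_overlaps_gsp(self, small_universe):
        for seed in range(10):
            gsn = sample_gsn(small_universe.gsp, seed=seed)
            assert not (gsn.pairs & small_universe.gsp.pairs)

    def test_entities_from_gsp(self, small_universe):
        gsn = sample_gsn(small_universe.gsp, seed=2)
        assert gsn.drugs <= small_universe.gsp.drugs
        assert gsn.proteins <= small_universe.gsp.proteins

    def test_deterministic(self, small_universe):
        a = sample_gsn(small_universe.gsp, seed=9)
        b = sample_gsn(small_universe.gsp, seed=9)
        assert a.pairs == b.pairs

    def test_insufficient_space(self):
        gsp = interaction_set("GSP", [("d1", "t1"), ("d1", "t2"), ("d2", "t1")])
        # only one non-positive combination exists for 2 drugs x 2 proteins
        with pytest.raises(ValueError, match="cannot sample"):
            sample_gsn(gsp, seed=0)

    def test_dense_fallback_exact(self):
        gsp = interaction_set("GSP", [("d1", "t1"), ("d2", "t2")])
        gsn = sample_gsn(gsp, seed=0)  # free space is exactly 2 pairs
        assert gsn.pairs == {("d1", "t2"), ("d2", "t1")}


class TestEstimateLr:
    def test_frequency_ratio(self):
        # bin 1 of 2: 3/10 positives vs 1/10 negatives, vanishing smoothing
        pos_pairs = [(f"d{i}", f"t{i}") for i in range(10)]
        neg_pairs = [(f"e{i}", f"u{i}") for i in range(10)]
        pos_vals = [0.8] * 3 + [0.2] * 7
        neg_vals = [0.8] * 1 + [0.2] * 9
        feats = _feature_frame(
            {"fp2-sequence": pos_vals + neg_vals}, pos_pairs + neg_pairs
        )
        gsp = interaction_set("GSP", pos_pairs)
        gsn = interaction_set("GSN", neg_pairs)
        model = estimate_lr(feats, gsp, gsn, n_bins=2, pseudocount=1e-9)
        assert model.lr["fp2-sequence"][1] == pytest.approx(3.0, rel=1e-6)
        assert model.lr["fp2-sequence"][0] == pytest.approx(7 / 9, rel=1e-6)

    def test_uninformative_feature_near_one(self, rng):
        n = 4000
        vals = rng.random(n)
        pos_pairs = [(f"d{i}", f"t{i}") for i in range(n // 2)]
        neg_pairs = [(f"e{i}", f"u{i}") for i in range(n // 2)]
        feats = _feature_frame({"fp2-sequence": list(vals)}, pos_pairs + neg_pairs)
        model = estimate_lr(
            feats,
            interaction_set("GSP", pos_pairs),
            interaction_set("GSN", neg_pairs),
            n_bins=10,
            pseudocount=1.0,
        )
        assert np.all(model.lr["fp2-sequence"] > 0.5)
        assert np.all(model.lr["fp2-sequence"] < 2.0)

    def test_empty_bin_smoothing_finite(self):
        pos_pairs = [(f"d{i}", f"t{i}") for i in range(4)]
        neg_pairs = [(f"e{i}", f"u{i}") for i in range(4)]
        feats = _feature_frame(
            {"fp2-sequence": [0.9] * 4 + [0.1] * 4}, pos_pairs + neg_pairs
        )
        model = estimate_lr(
            feats,
            interaction_set("GSP", pos_pairs),
            interaction_set("GSN", neg_pairs),
            n_bins=20,
            pseudocount=1.0,
        )
        assert np.isfinite(model.lr["fp2-sequence"]).all()

    def test_all_missing_feature_dropped(self):
        pos_pairs = [("d1", "t1"), ("d2", "t2")]
        neg_pairs = [("e1", "u1"), ("e2", "u2")]
        feats = _feature_frame(
            {
                "fp2-sequence": [0.5, 0.6, 0.2, 0.1],
                "atc-go": [np.nan] * 4,
            },
            pos_pairs + neg_pairs,
        )
        with pytest.warns(UserWarning, match="dropped"):
            model = estimate_lr(
                feats,
                interaction_set("GSP", pos_pairs),
                interaction_set("GSN", neg_pairs),
                n_bins=4,
                pseudocount=1.0,
            )
        assert model.features == ("fp2-sequence",)

    def test_missing_table_rows_rejected(self):
        feats = _feature_frame({"fp2-sequence": [0.5]}, [("d1", "t1")])
        with pytest.raises(ValueError, match="cover"):
            estimate_lr(
                feats,
                interaction_set("GSP", [("d1", "t1"), ("d9", "t9")]),
                interaction_set("GSN", []),
            )

    def test_bin_index_boundaries(self):
        idx = bin_index(np.array([0.0, 0.999, 1.0, np.nan]), 10)
        assert list(idx) == [0, 9, 9, -1]


def _mi_oracle(x, y):
    """Exhaustive discrete mutual information (nats)."""
    x, y = np.asarray(x), np.asarray(y)
    n = len(x)
    mi = 0.0
    for vx in np.unique(x):
        for vy in np.unique(y):
            pxy = np.mean((x == vx) & (y == vy))
            if pxy == 0:
                continue
            px, py = np.mean(x == vx), np.mean(y == vy)
            mi += pxy * math.log(pxy / (px * py))
    return mi


def _greedy_mrmr_oracle(cols: dict[str, np.ndarray], y, k):
    names = sorted(cols)
    selected = []
    while len(selected) < min(k, len(names)):
        best, best_score = None, -np.inf
        for f in names:
            if f in selected:
                continue
            score = _mi_oracle(cols[f], y)
            if selected:
                score -= np.mean([_mi_oracle(cols[f], cols[s]) for s in selected])
            if score > best_score + 1e-12 or (
                abs(score - best_score) <= 1e-12 and (best is None or f < best)
            ):
                best, best_score = f, score
        selected.append(best)
    return selected


class TestMrmr:
    def test_single_feature(self):
        pairs = [(f"d{i}", f"t{i}") for i in range(6)]
        feats = _feature_frame({"fp2-sequence": [0.1, 0.2, 0.9, 0.8, 0.85, 0.15]}, pairs)
        assert mrmr_select(feats, [0, 0, 1, 1, 1, 0], k=1) == ["fp2-sequence"]

    def test_redundant_copy_deferred(self):
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        a = [0.0, 0.0, 0.0, 0.9, 0.9, 0.9, 0.9, 0.9]  # strong
        b = [0.0, 0.0, 0.9, 0.0, 0.9, 0.9, 0.0, 0.9]  # weaker, independent
        pairs = [(f"d{i}", f"t{i}") for i in range(8)]
        feats = _feature_frame(
            {"atc-go": a, "atc-sequence": list(a), "fp2-go": b}, pairs
        )
        picked = mrmr_select(feats, y, k=2)
        # the exact copy of the first pick is penalized by redundancy
        assert picked[0] in ("atc-go", "atc-sequence")
        assert picked[1] == "fp2-go"

    def test_matches_exhaustive_oracle(self, rng):
        for trial in range(10):
            n = 40
            y = rng.integers(0, 2, n)
            cols = {
                name: rng.integers(0, 2, n).astype(float) * 0.9
                for name in ["atc-go", "fp2-go", "expression-go", "side_effect-go"]
            }
            feats = _feature_frame(
                {k: list(v) for k, v in cols.items()},
                [(f"d{i}", f"t{i}") for i in range(n)],
            )
            try:
                got = mrmr_select(feats, y, k=4, n_bins=20)
            except ValueError:
                continue  # all-degenerate draw
            binned = {k: bin_index(v, 20) for k, v in cols.items()
                      if len(np.unique(bin_index(v, 20))) >= 2}
            expected = _greedy_mrmr_oracle(binned, y, 4)
            assert got == expected

    def test_default_count_contract(self, small_universe, small_gsn, config):
        uni = small_universe
        pairs = uni.gsp.sorted_pairs + small_gsn.sorted_pairs
        feats = build_feature_table(pairs, uni.gsp, uni.drug_sims, uni.prot_sims)
        model = train_model(feats, uni.gsp, small_gsn, config)
        assert len(model.selected_features) == 8
        assert set(model.selected_features) <= set(feats.columns)

    def test_invalid_k(self):
        feats = _feature_frame({"fp2-go": [0.1, 0.9]}, [("d1", "t1"), ("d2", "t2")])
        with pytest.raises(ValueError):
            mrmr_select(feats, [0, 1], k=0)


def _toy_model():
    return LRModel(
        n_bins=2,
        pseudocount=1.0,
        features=("fp2-sequence", "atc-go", "fp2-go"),
        lr={
            "fp2-sequence": np.array([0.4, 2.0]),
            "atc-go": np.array([0.2, 5.0]),
            "fp2-go": np.array([0.9, 1.2]),
        },
        pos_counts={f: np.array([1.0, 1.0]) for f in ("fp2-sequence", "atc-go", "fp2-go")},
        neg_counts={f: np.array([1.0, 1.0]) for f in ("fp2-sequence", "atc-go", "fp2-go")},
        selected_features=("fp2-sequence", "atc-go", "fp2-go"),
    )


class TestScorePair:
    def test_max_of_feature_lrs(self):
        model = _toy_model()
        row = {"fp2-sequence": 0.8, "atc-go": 0.9, "fp2-go": 0.1}
        # LRs: 2.0, 5.0, 0.9 -> max 5.0
        assert score_pair(("d", "t"), model, row) == pytest.approx(5.0)

    def test_degenerate_single_feature(self):
        model = _toy_model()
        row = {"fp2-sequence": 0.1, "atc-go": np.nan, "fp2-go": np.nan}
        assert score_pair(("d", "t"), model, row) == pytest.approx(0.4)

    def test_all_missing_unscorable(self):
        model = _toy_model()
        row = {f: np.nan for f in model.features}
        assert math.isnan(score_pair(("d", "t"), model, row))

    def test_invariant_to_feature_order_and_missing(self):
        model = _toy_model()
        row = {"fp2-sequence": 0.8, "atc-go": 0.9, "fp2-go": np.nan}
        reordered = {"fp2-go": np.nan, "atc-go": 0.9, "fp2-sequence": 0.8}
        assert score_pair(("d", "t"), model, row) == score_pair(("d", "t"), model, reordered)

    def test_restricted_feature_subset(self):
        model = _toy_model()
        model.selected_features = ("fp2-go",)
        row = {"fp2-sequence": 0.9, "atc-go": 0.9, "fp2-go": 0.9}
        assert score_pair(("d", "t"), model, row) == pytest.approx(1.2)

    def test_score_pairs_matches_scalar(self):
        model = _toy_model()
        pairs = [("d1", "t1"), ("d2", "t2"), ("d3", "t3")]
        feats = _feature_frame(
            {
                "fp2-sequence": [0.8, 0.1, np.nan],
                "atc-go": [0.9, np.nan, np.nan],
                "fp2-go": [0.1, np.nan, np.nan],
            },
            pairs,
        )
        vec = score_pairs(feats, model)
        for i, p in enumerate(pairs):
            scalar = score_pair(p, model, feats)
            if math.isnan(scalar):
                assert math.isnan(vec[i])
            else:
                assert vec[i] == pytest.approx(scalar)


class TestRankAndCutoff:
    def test_tie_break_by_protein_id(self):
        model = _toy_model()
        dsim = SimilarityMatrix("fp2", ["d1", "d2"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        pv = np.eye(3) * 0 + 0.6
        np.fill_diagonal(pv, 1.0)
        psim = SimilarityMatrix("sequence", ["t1", "t2", "t3"], pv)
        gsp = interaction_set("GSP", [("d1", "t1")])
        model.selected_features = ("fp2-sequence",)
        ranked = rank_targets(
            "d2", ["t3", "t2"], model, gsp, {"fp2": dsim}, {"sequence": psim}
        )
        # t2 and t3 both score sim 0.9*0.6 -> same bin, tie broken by id
        assert [e[0] for e in ranked.entries] == ["t2", "t3"]

    def test_empty_known_table(self):
        model = _toy_model()
        model.selected_features = ("fp2-sequence",)
        dsim = SimilarityMatrix("fp2", ["d1", "d2"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        psim = SimilarityMatrix("sequence", ["t1", "t2"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        gsp = interaction_set("GSP", [("d1", "t1")])
        ranked = rank_targets("d2", ["t1", "t2"], model, gsp, {"fp2": dsim}, {"sequence": psim})
        assert all(not e[2] for e in ranked.entries)

    def test_unknown_compound_raises(self):
        model = _toy_model()
        dsim = SimilarityMatrix("fp2", ["d1"], np.array([[1.0]]))
        psim = SimilarityMatrix("sequence", ["t1"], np.array([[1.0]]))
        gsp = interaction_set("GSP", [("d1", "t1")])
        with pytest.raises(ValueError, match="absent"):
            rank_targets("dX", ["t1"], model, gsp, {"fp2": dsim}, {"sequence": psim})

    def test_cutoff_union_semantics(self):
        from simdti.datatypes import RankedTargets

        ranked = RankedTargets(
            compound_id="d1",
            entries=(("t1", 5.0, False), ("t2", 2.0, True), ("t3", 0.5, False)),
        )
        kept = apply_cutoff(ranked, score_cutoff=3.0)
        # t2 is below cutoff but known -> retained
        assert [t for t, _, _ in kept] == ["t1", "t2"]

    def test_cutoff_zero_keeps_all_scorable(self):
        from simdti.datatypes import RankedTargets

        ranked = RankedTargets(
            compound_id="d1",
            entries=(("t1", 5.0, False), ("t2", 0.1, False)),
        )
        assert len(apply_cutoff(ranked, 0.0)) == 2

    def test_cutoff_above_max_empty(self):
        from simdti.datatypes import RankedTargets

        ranked = RankedTargets(
            compound_id="d1", entries=(("t1", 5.0, False),)
        )
        assert apply_cutoff(ranked, 10.0) == []

    def test_whole_universe_ranking(self, small_universe, small_gsn, config):
        uni = small_universe
        pairs = uni.gsp.sorted_pairs + small_gsn.sorted_pairs
        feats = build_feature_table(pairs, uni.gsp, uni.drug_sims, uni.prot_sims)
        model = train_model(feats, uni.gsp, small_gsn, config)
        compound = uni.drug_ids[0]
        ranked = rank_targets(
            compound, uni.protein_ids, model, uni.gsp, uni.drug_sims, uni.prot_sims
        )
        assert len(ranked.entries) + len(ranked.unscorable) == len(uni.protein_ids)
        scores = [s for _, s, _ in ranked.entries if not math.isnan(s)]
        assert scores == sorted(scores, reverse=True)


class TestModelSerialization:
    def test_round_trip(self, tmp_path, small_universe, small_gsn, config):
        uni = small_universe
        pairs = uni.gsp.sorted_pairs + small_gsn.sorted_pairs
        feats = build_feature_table(pairs, uni.gsp, uni.drug_sims, uni.prot_sims)
        model = train_model(feats, uni.gsp, small_gsn, config)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = LRModel.from_json(path)
        assert loaded.selected_features == model.selected_features
        for f in model.features:
            np.testing.assert_array_equal(loaded.lr[f], model.lr[f])

    def test_version_guard(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps({"format_version": 99}))
        with pytest.raises(ValueError, match="format"):
            LRModel.from_json(path)

    def test_deterministic_training(self, small_universe, config, tmp_path):
        uni = small_universe
        out = []
        for _ in range(2):
            gsn = sample_gsn(uni.gsp, seed=config.seed)
            pairs = uni.gsp.sorted_pairs + gsn.sorted_pairs
            feats = build_feature_table(pairs, uni.gsp, uni.drug_sims, uni.prot_sims)
            model = train_model(feats, uni.gsp, gsn, config)
            p = tmp_path / f"m{len(out)}.json"
            model.to_json(p)
            out.append(p.read_bytes())
        assert out[0] == out[1]
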