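import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import histokey as hk
from histokey.scoring import (
    classify_shape_heuristic,
    compute_scores,
    impact_score,
    label_patches,
    load_reference_clusters,
    select_key_features,
    weight_from_impact,
)
from histokey.tiling import Patch


def oracle_scores(clusters, labels, k):
    """Exhaustive hand-count implementation of the rate/impact calculus."""
    n_plus = sum(1 for l in labels if l == 1)
    n_minus = sum(1 for l in labels if l == 0)
    out = {}
    for kk in range(k):
        pos = sum(1 for c, l in zip(clusters, labels) if c == kk and l == 1)
        neg = sum(1 for c, l in zip(clusters, labels) if c == kk and l == 0)
        rp, rm = pos / n_plus, neg / n_minus
        I = 0.5 if rp + rm == 0 else rp / (rp + rm)
        out[kk] = (rp, rm, I, 1 + abs(0.5 - I))
    return out


class TestLabelPatches:
    def test_labels_inherited_from_slides(self):
        df = pd.DataFrame({"slide_id": ["a"] * 5 + ["b"] * 5, "cluster": range(10)})
        out = label_patches(df, {"a": 1, "b": 0})
        assert out["label"].tolist() == [1] * 5 + [0] * 5

    def test_missing_slide_raises_with_name(self):
        df = pd.DataFrame({"slide_id": ["a", "zz"]})
        with pytest.raises(ValueError, match="zz"):
            label_patches(df, {"a": 1})

    def test_unlabeled_slide_rejected(self):
        df = pd.DataFrame({"slide_id": ["a"]})
        with pytest.raises(ValueError, match="no response label"):
            label_patches(df, {"a": None})


class TestComputeScores:
    def test_worked_toy_example(self):
        """n+=4, n-=2; cluster A: 3 pos + 1 neg; cluster B: 1 pos + 1 neg."""
        clusters = [0, 0, 0, 0, 1, 1]
        labels = [1, 1, 1, 0, 1, 0]
        a, b = compute_scores(clusters, labels, k=2)
        assert a.r_plus == pytest.approx(0.75)
        assert a.r_minus == pytest.approx(0.5)
        assert a.impact == pytest.approx(0.6)
        assert a.weight == pytest.approx(1.1)
        assert b.impact == pytest.approx(1 / 3)
        assert b.weight == pytest.approx(1 + 1 / 6)

    def test_balanced_cluster_is_neutral(self):
        (s,) = compute_scores([0, 0], [1, 0], k=1)
        assert s.impact == 0.5 and s.weight == 1.0 and s.polarity == "neutral"

    def test_empty_cluster_flagged_neutral(self):
        scores = compute_scores([0, 0], [1, 0], k=2)
        assert scores[1].empty and scores[1].impact == 0.5 and scores[1].weight == 1.0

    def test_single_label_input_rejected(self):
        with pytest.raises(ValueError, match="both labels"):
            compute_scores([0, 1], [1, 1], k=2)

    @settings(max_examples=40, deadline=None)
    @given(
        n=st.integers(4, 50),
        k=st.integers(2, 5),
        seed=st.integers(0, 10_000),
    )
    def test_matches_hand_count_oracle(self, n, k, seed):
        rng = np.random.default_rng(seed)
        clusters = rng.integers(0, k, size=n)
        labels = np.r_[1, 0, rng.integers(0, 2, size=n - 2)]  # both labels present
        scores = compute_scores(clusters, labels, k=k)
        expect = oracle_scores(list(clusters), list(labels), k)
        for s in scores:
            rp, rm, I, W = expect[s.cluster_id]
            assert s.r_plus == pytest.approx(rp)
            assert s.r_minus == pytest.approx(rm)
            assert s.impact == pytest.approx(I)
            assert s.weight == pytest.approx(W)

    @settings(max_examples=30, deadline=None)
    @given(n=st.integers(4, 60), k=st.integers(2, 6), seed=st.integers(0, 10_000))
    def test_conservation_and_weight_bounds(self, n, k, seed):
        """Sum of r+ and of r- over clusters is 1; W always in [1, 1.5]."""
        rng = np.random.default_rng(seed)
        clusters = rng.integers(0, k, size=n)
        labels = np.r_[1, 0, rng.integers(0, 2, size=n - 2)]
        scores = compute_scores(clusters, labels, k=k)
        assert sum(s.r_plus for s in scores) == pytest.approx(1.0)
        assert sum(s.r_minus for s in scores) == pytest.approx(1.0)
        assert all(1.0 <= s.weight <= 1.5 for s in scores)

    def test_impact_invariant_to_duplication(self, rng):
        clusters = rng.integers(0, 3, size=30)
        labels = np.r_[1, 0, rng.integers(0, 2, size=28)]
        once = compute_scores(clusters, labels, k=3)
        twice = compute_scores(np.tile(clusters, 2), np.tile(labels, 2), k=3)
        for a, b in zip(once, twice):
            assert a.impact == pytest.approx(b.impact)

    def test_moving_positive_patch_in_never_decreases_impact(self, rng):
        clusters = rng.integers(0, 3, size=40)
        labels = np.r_[1, 0, rng.integers(0, 2, size=38)]
        base = compute_scores(clusters, labels, k=3)
        # move one positive patch from another cluster into cluster 0
        donor = next(i for i in range(40) if labels[i] == 1 and clusters[i] != 0)
        moved = clusters.copy()
        moved[donor] = 0
        after = compute_scores(moved, labels, k=3)
        assert after[0].impact >= base[0].impact - 1e-12


class TestKeyFeatureSelection:
    def test_shape_clusters_excluded(self):
        scores = compute_scores([0, 0, 1, 1, 2, 2], [1, 1, 0, 0, 1, 0], k=3)
        fm = select_key_features(
            scores, key_threshold=1.1, morphology={0: "shape", 1: "histology", 2: "histology"}
        )
        # cluster 0 (all positive) exceeds threshold but is shape; cluster 1 is key
        assert fm.scores[0].weight > 1.1 and not fm.scores[0].is_key
        assert fm.scores[1].is_key
        assert not fm.scores[2].is_key  # neutral, W = 1

    def test_threshold_at_upper_bound_selects_nothing(self):
        scores = compute_scores([0, 0, 1, 1], [1, 1, 0, 0], k=2)
        fm = select_key_features(scores, key_threshold=1.5)
        assert fm.key_clusters == []

    def test_threshold_one_selects_all_non_neutral_histology(self):
        scores = compute_scores([0, 0, 1, 1, 2, 2], [1, 1, 0, 0, 1, 0], k=3)
        fm = select_key_features(scores, key_threshold=1.0)
        assert fm.key_clusters == [0, 1]

    def test_unknown_cluster_annotation_rejected(self):
        scores = compute_scores([0, 1], [1, 0], k=2)
        with pytest.raises(ValueError, match="unknown clusters"):
            select_key_features(scores, morphology={9: "shape"})


class TestShapeHeuristic:
    def _patch(self, blank_frac, seed=0):
        rng = np.random.default_rng(seed)
        px = rng.integers(100, 200, size=(128, 128, 3)).astype(np.uint8)
        n_blank = int(round(blank_frac * 128))
        px[:n_blank] = 255
        return Patch("s", (0, 0), px)

    def test_half_blank_cluster_is_shape(self):
        members = [self._patch(0.5, s) for s in range(5)]
        assert classify_shape_heuristic(members) == "shape"

    def test_full_tissue_cluster_is_histology(self):
        members = [self._patch(0.0, s) for s in range(5)]
        assert classify_shape_heuristic(members) == "histology"

    def test_no_pixels_falls_back_to_histology(self, caplog):
        assert classify_shape_heuristic([]) == "histology"


class TestReferenceTable:
    def test_reference_polarity_split(self):
        ref = load_reference_clusters()
        assert len(ref) == 38
        assert (ref.impact_score > 0.5).sum() == 25
        assert (ref.impact_score < 0.5).sum() == 13

    def test_reference_key_set(self):
        ref = load_reference_clusters()
        W = weight_from_impact(ref.impact_score)
        over = ref[W > 1.1]
        assert len(over) == 8
        key = over[over.morphology_class != "shape"].cluster.tolist()
        assert key == [33, 15, 9, 2, 27, 30]


def test_impact_feature_model_estimator(rng):
    """Estimator wraps clustering + scoring; transform yields slide vectors."""
    centers = np.array([[0.0] * 6, [30.0] * 6])
    X = np.vstack([c + rng.normal(size=(20, 6)) for c in centers])
    y = np.r_[np.ones(20), np.zeros(20)].astype(int)
    sids = np.array(["s1"] * 10 + ["s2"] * 10 + ["s3"] * 10 + ["s4"] * 10)
    fm = hk.ImpactFeatureModel(n_clusters=2, random_state=0).fit(X, y, slide_ids=sids)
    assert fm.scores_.shape[0] == 2
    assert set(fm.scores_["polarity"]) == {"positive", "negative"}
    vectors = fm.transform(X, sids)
    assert vectors.shape == (4, 2)
    # unweighted occupancy fractions sum to 1 per slide
    unweighted = vectors.values / fm.weights_
    np.testing.assert_allclose(unweighted.sum(axis=1), 1.0)
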