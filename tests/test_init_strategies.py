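"""Initialization strategies: K-means diversity vs an exhaustive oracle,
the MC-dropout variance formula, hybrid composition, nested random draws."""

import numpy as np
import pytest
from oracle_utils import oracle_diversity as _oracle_diversity

from coldstart_al.encoders import EmbeddingMatrix
from coldstart_al.init_strategies import (
    MCDropoutConfig,
    QueryResult,
    UncertaintyScores,
    diversity_init,
    hybrid_init,
    mc_dropout_variance,
    random_init,
    uncertainty_init,
)


def _em(vectors, ids=None):
    vectors = np.asarray(vectors, dtype=float)
    if ids is None:
        ids = [f"p{i:02d}" for i in range(vectors.shape[0])]
    return EmbeddingMatrix(ids=ids, vectors=vectors, encoder_name="fixture")


class TestDiversityInit:
    def test_two_well_separated_groups(self):
        # two clusters; nearest-to-centroid members are the corner points
        pts = [(0, 0), (1, 0), (0, 1), (10, 10), (11, 10), (10, 11)]
        result = diversity_init(_em(pts), budget=2, seed=0, standardize=False)
        assert set(result.selected_ids) == {"p00", "p03"}

    def test_budget_one_returns_sample_nearest_global_mean(self, rng):
        vectors = rng.normal(size=(12, 3))
        result = diversity_init(_em(vectors), budget=1, seed=0, standardize=False)
        nearest = int(np.argmin(np.linalg.norm(vectors - vectors.mean(axis=0), axis=1)))
        assert result.selected_ids == [f"p{nearest:02d}"]

    def test_budget_equals_pool_returns_everything(self, rng):
        vectors = rng.normal(size=(6, 2))
        result = diversity_init(_em(vectors), budget=6, seed=0)
        assert sorted(result.selected_ids) == [f"p{i:02d}" for i in range(6)]

    def test_budget_exceeding_pool_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds pool size"):
            diversity_init(_em(rng.normal(size=(4, 2))), budget=5)

    @pytest.mark.parametrize("n,k", [(5, 2), (6, 2), (7, 3), (8, 3)])
    def test_matches_exhaustive_min_sse_oracle(self, n, k):
        # small continuous instances: the global SSE optimum is unique a.s.
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            vectors = rng.normal(size=(n, 2))
            em = _em(vectors)
            result = diversity_init(em, budget=k, seed=seed, standardize=False)
            assert set(result.selected_ids) == _oracle_diversity(vectors, em.ids, k)

    def test_determinism(self, tiny_embeddings):
        a = diversity_init(tiny_embeddings, budget=5, seed=3)
        b = diversity_init(tiny_embeddings, budget=5, seed=3)
        assert a.selected_ids == b.selected_ids


class _SequenceStub:
    """Estimator stub whose successive MC passes return preset outputs."""

    def __init__(self, outputs):
        self.outputs = list(outputs)
        self.calls = 0

    def mc_forward(self, images, dropout_p, rng):
        out = np.asarray(self.outputs[self.calls % len(self.outputs)], dtype=float)
        self.calls += 1
        return out


class TestMCDropoutVariance:
    def test_printed_formula_on_two_passes(self):
        # passes 0 and 1 for one scalar output: var = ((0-.5)^2 + (1-.5)^2)/2
        stub = _SequenceStub([np.array([[0.0]]), np.array([[1.0]])])
        scores = mc_dropout_variance(stub, np.zeros((1, 4, 4)), MCDropoutConfig(n_passes=2))
        assert scores.variance[0] == pytest.approx(0.25)

    def test_population_not_sample_variance(self):
        # three passes 0, 1, 2: population variance 2/3 (sample variance would be 1)
        stub = _SequenceStub([np.array([[v]]) for v in (0.0, 1.0, 2.0)])
        scores = mc_dropout_variance(stub, np.zeros((1, 4, 4)), MCDropoutConfig(n_passes=3))
        assert scores.variance[0] == pytest.approx(2.0 / 3.0)

    def test_single_pass_gives_zero(self):
        stub = _SequenceStub([np.array([[3.7, -1.0]])])
        scores = mc_dropout_variance(stub, np.zeros((1, 4, 4)), MCDropoutConfig(n_passes=1))
        assert scores.variance[0] == 0.0

    def test_zero_dropout_gives_zero_variance(self, rng):
        from coldstart_al.models import TrainingConfig, train_uncertainty_estimator

        images = rng.random((6, 16, 16))
        est, _ = train_uncertainty_estimator(
            images, rng.random((6, 3)),
            TrainingConfig(learning_rate=1e-4, loss="mean_squared_error", max_epochs=2, seed=0),
        )
        scores = mc_dropout_variance(
            est, images, MCDropoutConfig(n_passes=5, dropout_probability=0.0, seed=1)
        )
        assert np.allclose(scores.variance, 0.0)

    def test_aggregation_modes_and_nonnegativity(self, rng):
        passes = [rng.normal(size=(4, 3)) for _ in range(6)]
        mean_s = mc_dropout_variance(
            _SequenceStub(passes), np.zeros((4, 2, 2)), MCDropoutConfig(n_passes=6)
        )
        sum_s = mc_dropout_variance(
            _SequenceStub(passes), np.zeros((4, 2, 2)),
            MCDropoutConfig(n_passes=6, aggregation="sum_over_dims"),
        )
        assert np.all(mean_s.variance >= 0)
        assert np.allclose(sum_s.variance, 3 * mean_s.variance)

    def test_invalid_config(self):
        with pytest.raises(ValueError, match="n_passes"):
            MCDropoutConfig(n_passes=0)


class TestUncertaintyInit:
    def test_selection_follows_stub_variances(self):
        em = _em(np.zeros((3, 2)), ids=["a", "b", "c"])
        scores = UncertaintyScores(ids=["a", "b", "c"], variance=np.array([3.0, 1.0, 2.0]))
        result = uncertainty_init(np.zeros((3, 4, 4)), em, budget=2, scores=scores)
        assert result.selected_ids == ["a", "c"]

    def test_budget_equals_pool_orders_by_descending_variance(self):
        em = _em(np.zeros((3, 2)), ids=["a", "b", "c"])
        scores = UncertaintyScores(ids=["a", "b", "c"], variance=np.array([1.0, 3.0, 2.0]))
        result = uncertainty_init(np.zeros((3, 4, 4)), em, budget=3, scores=scores)
        assert result.selected_ids == ["b", "c", "a"]

    def test_ties_break_by_smallest_id(self):
        em = _em(np.zeros((3, 2)), ids=["c", "a", "b"])
        scores = UncertaintyScores(ids=["c", "a", "b"], variance=np.ones(3))
        result = uncertainty_init(np.zeros((3, 4, 4)), em, budget=2, scores=scores)
        assert result.selected_ids == ["a", "b"]

    def test_end_to_end_determinism(self, tiny_dataset, tiny_embeddings, fast_estimator, fast_mc):
        runs = [
            uncertainty_init(
                tiny_dataset.images, tiny_embeddings, 4, fast_estimator, fast_mc
            ).selected_ids
            for _ in range(2)
        ]
        assert runs[0] == runs[1]


class TestHybridInit:
    def test_planted_clusters_with_stub_variances(self):
        pts = np.array([(0, 0), (0.5, 0), (0, 0.5), (10, 10), (10.5, 10), (10, 10.5)])
        em = _em(pts)
        # highest variance: p02 in the low cluster, p04 in the high cluster
        scores = UncertaintyScores(ids=em.ids, variance=np.array([0.1, 0.2, 0.9, 0.1, 0.8, 0.2]))
        result = hybrid_init(
            np.zeros((6, 4, 4)), em, budget=2, seed=0, standardize=False, scores=scores
        )
        assert set(result.selected_ids) == {"p02", "p04"}

    def test_constant_variances_pick_one_per_diversity_cluster(self, rng):
        for seed in range(5):
            vectors = np.random.default_rng(seed).normal(size=(10, 2))
            em = _em(vectors)
            scores = UncertaintyScores(ids=em.ids, variance=np.ones(10))
            div = diversity_init(em, budget=3, seed=seed, standardize=False)
            hyb = hybrid_init(
                np.zeros((10, 4, 4)), em, budget=3, seed=seed, standardize=False, scores=scores
            )
            labels = np.asarray(div.diagnostics["cluster_labels"])
            id_index = {s: i for i, s in enumerate(em.ids)}
            div_clusters = sorted(labels[id_index[s]] for s in div.selected_ids)
            hyb_clusters = sorted(labels[id_index[s]] for s in hyb.selected_ids)
            assert div_clusters == hyb_clusters == [0, 1, 2]

    def test_budget_equals_pool(self):
        em = _em(np.arange(8, dtype=float).reshape(4, 2))
        scores = UncertaintyScores(ids=em.ids, variance=np.arange(4.0))
        result = hybrid_init(np.zeros((4, 4, 4)), em, budget=4, seed=0, scores=scores)
        assert sorted(result.selected_ids) == em.ids


class TestRandomInit:
    def test_nesting_within_each_rep(self):
        ids = [f"s{i:03d}" for i in range(60)]
        reps = random_init(ids, [10, 20, 30, 40, 50], n_reps=20, seed=4)
        assert len(reps) == 20
        for per_budget in reps:
            previous = set()
            for budget in (10, 20, 30, 40, 50):
                current = set(per_budget[budget].selected_ids)
                assert len(current) == budget
                assert previous <= current
                previous = current

    def test_reps_are_distinct_draws(self):
        ids = [f"s{i:03d}" for i in range(40)]
        reps = random_init(ids, [10], n_reps=50, seed=0)
        distinct = {tuple(r[10].selected_ids) for r in reps}
        assert len(distinct) == 50

    def test_budget_equal_pool(self):
        ids = ["a", "b", "c"]
        reps = random_init(ids, [3], n_reps=3, seed=1)
        for rep in reps:
            assert sorted(rep[3].selected_ids) == ids

    def test_budget_exceeding_pool_rejected(self):
        with pytest.raises(ValueError, match="exceeds pool size"):
            random_init(["a", "b"], [3], n_reps=1, seed=0)


class TestQueryResult:
    def test_size_must_match_budget(self):
        with pytest.raises(ValueError, match="budget"):
            QueryResult(selected_ids=["a"], strategy="x", budget=2)

    def test_ids_must_be_unique(self):
        with pytest.raises(ValueError, match="unique"):
            QueryResult(selected_ids=["a", "a"], strategy="x", budget=2)
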