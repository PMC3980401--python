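import numpy as np
import pytest

from skinmil import (Bag, build_locality_matrix, fit_citation, generate_bags,
                     predict_citation, predict_citation_pruned)
from skinmil.citation_knn import kmedoids
from skinmil.mil_core import ahd


def random_bags(rng, n, dim=2, shift=None):
    bags, labels = [], []
    for i in range(n):
        x = rng.normal(size=(int(rng.integers(1, 5)), dim))
        lab = int(rng.integers(0, 2))
        if shift is not None and lab == 1:
            x = x + shift
        bags.append(Bag(f"b{i}", x))
        labels.append(lab)
    labels = np.array(labels)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return bags, labels


def brute_force_citation(train_bags, labels, test, R, C):
    """Reference + citer vote by exhaustive enumeration (oracle)."""
    n = len(train_bags)
    d_test = np.array([ahd(b, test) for b in train_bags])
    order = np.lexsort((np.arange(n), d_test))
    votes = list(labels[order[:R]])
    for i in range(n):
        closer = sum(
            1 for j in range(n)
            if j != i and ahd(train_bags[i], train_bags[j]) < d_test[i])
        if closer < C:
            votes.append(labels[i])
    pos = sum(votes)
    return 1 if pos > len(votes) - pos else 0


class TestFitCitation:
    def test_model_stores_all_training_bags(self, rng):
        bags, labels = random_bags(rng, 10)
        model = fit_citation(bags, labels, R=3)
        assert model.n == 10
        assert model.C == 5

    def test_too_few_bags_for_r_rejected(self, rng):
        bags, labels = random_bags(rng, 4)
        with pytest.raises(ValueError, match="R\\+1"):
            fit_citation(bags, labels, R=4)

    def test_single_class_training_rejected(self, rng):
        bags, _ = random_bags(rng, 6)
        with pytest.raises(ValueError, match="both classes"):
            fit_citation(bags, np.ones(6, dtype=int), R=2)

    def test_refit_gives_identical_predictions(self, rng):
        bags, labels = random_bags(rng, 12)
        tests = [Bag(f"t{i}", rng.normal(size=(2, 2))) for i in range(10)]
        p1 = [predict_citation(fit_citation(bags, labels, R=3), t) for t in tests]
        p2 = [predict_citation(fit_citation(bags, labels, R=3), t) for t in tests]
        assert p1 == p2


class TestPredictCitation:
    def test_vote_matches_exhaustive_oracle(self, rng):
        for _ in range(40):
            bags, labels = random_bags(rng, 8)
            test = Bag("t", rng.normal(size=(int(rng.integers(1, 4)), 2)))
            model = fit_citation(bags, labels, R=3, C=5)
            assert predict_citation(model, test) == brute_force_citation(
                bags, labels, test, R=3, C=5)

    def test_clone_of_positive_bag_in_positive_cluster(self, rng):
        bags, labels = random_bags(rng, 12, shift=np.array([8.0, 8.0]))
        model = fit_citation(bags, labels, R=3)
        pos_bag = bags[int(np.nonzero(labels == 1)[0][0])]
        assert predict_citation(model, Bag("t", pos_bag.instances.copy())) == 1

    def test_all_negative_neighbourhood_votes_zero(self, rng):
        bags, labels = random_bags(rng, 12, shift=np.array([8.0, 8.0]))
        model = fit_citation(bags, labels, R=3)
        far_negative = Bag("t", rng.normal(size=(3, 2)) - 20.0)
        assert predict_citation(model, far_negative) == 0

    def test_invariant_to_training_order(self, rng):
        bags, labels = random_bags(rng, 10)
        test = Bag("t", rng.normal(size=(3, 2)))
        perm = rng.permutation(10)
        m1 = fit_citation(bags, labels, R=3)
        m2 = fit_citation([bags[i] for i in perm], labels[perm], R=3)
        assert predict_citation(m1, test) == predict_citation(m2, test)


class TestLocalityMatrix:
    def test_every_bag_its_own_medoid_when_s_equals_n(self, rng):
        bags, labels = random_bags(rng, 8)
        model = fit_citation(bags, labels, R=2)
        lm = build_locality_matrix(model, s=8, K=8, seed=0)
        assert np.array_equal(np.sort(lm.medoid_ids), np.arange(8))
        dist = model.train_distances()
        for r, mid in enumerate(lm.medoid_ids):
            expected = np.lexsort((np.arange(8), dist[mid]))
            assert np.array_equal(lm.rows[r], expected)

    def test_single_cluster_row_is_global_sort(self, rng):
        bags, labels = random_bags(rng, 9)
        model = fit_citation(bags, labels, R=2)
        lm = build_locality_matrix(model, s=1, K=4, seed=0)
        assert lm.rows.shape == (1, 4)
        dist = model.train_distances()
        mid = lm.medoid_ids[0]
        assert np.array_equal(lm.rows[0],
                              np.lexsort((np.arange(9), dist[mid]))[:4])

    def test_rows_match_brute_force_sort(self, rng):
        bags, labels = random_bags(rng, 12)
        model = fit_citation(bags, labels, R=3)
        lm = build_locality_matrix(model, s=3, K=5, seed=1)
        dist = model.train_distances()
        for r, mid in enumerate(lm.medoid_ids):
            order = sorted(range(12), key=lambda j: (dist[mid, j], j))
            assert list(lm.rows[r]) == order[:5]

    def test_s_larger_than_n_rejected(self, rng):
        bags, labels = random_bags(rng, 6)
        model = fit_citation(bags, labels, R=2)
        with pytest.raises(ValueError):
            build_locality_matrix(model, s=7, K=3)

    def test_build_cost_is_quadratic_in_ahd_calls(self, rng):
        bags, labels = random_bags(rng, 15)
        model = fit_citation(bags, labels, R=3)
        build_locality_matrix(model, s=4, K=6, seed=0)
        n = model.n
        assert model.calculator.n_calls <= n * n

    def test_kmedoids_partitions_clear_clusters(self, rng):
        a = rng.normal(size=(5, 2))
        b = rng.normal(size=(5, 2)) + 30.0
        pts = np.vstack([a, b])
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        medoids = kmedoids(dist, 2, seed=0)
        assign = np.argmin(dist[:, medoids], axis=1)
        assert len(set(assign[:5])) == 1 and len(set(assign[5:])) == 1
        assert assign[0] != assign[5]


class TestPrunedPrediction:
    def test_exactness_limit_q1_k_equals_n(self, rng):
        bags, labels = random_bags(rng, 12)
        model = fit_citation(bags, labels, R=3)
        build_locality_matrix(model, s=4, K=12, seed=0)
        for _ in range(50):
            test = Bag("t", rng.normal(size=(2, 2)))
            assert (predict_citation_pruned(model, test, q=1.0)
                    == predict_citation(model, test))

    def test_candidate_set_bounded_by_kept_rows(self, rng):
        bags, labels = random_bags(rng, 16)
        model = fit_citation(bags, labels, R=3)
        lm = build_locality_matrix(model, s=4, K=5, seed=0)
        q = 0.5
        n_keep = int(np.ceil(q * lm.s))
        candidates = np.unique(lm.rows[:n_keep].ravel())
        assert candidates.size <= n_keep * lm.K

    def test_half_pruning_agrees_on_clustered_data(self, rng):
        # two well-separated bag clusters: pruning should rarely change votes
        bags, labels = random_bags(rng, 30, shift=np.array([10.0, 10.0]))
        model = fit_citation(bags, labels, R=3)
        build_locality_matrix(model, s=6, K=10, seed=0)
        agree = 0
        n_cases = 60
        for i in range(n_cases):
            lab = i % 2
            x = rng.normal(size=(3, 2)) + (10.0 if lab else 0.0)
            test = Bag(f"t{i}", x)
            agree += (predict_citation_pruned(model, test, q=0.5)
                      == predict_citation(model, test))
        assert agree / n_cases >= 0.95

    def test_unbuilt_locality_matrix_rejected(self, rng):
        bags, labels = random_bags(rng, 8)
        model = fit_citation(bags, labels, R=2)
        with pytest.raises(ValueError, match="locality"):
            predict_citation_pruned(model, Bag("t", np.zeros((1, 2))), q=0.5)


def test_learner_recovers_planted_mil_structure():
    ds = generate_bags(30, 30, dim=5, separation=6.0, witness_rate=0.3, seed=7)
    from skinmil import split_train_test
    train, test = split_train_test(ds, 0.6, seed=7)
    model = fit_citation(train.bags, train.labels("t1"), R=3)
    pred = np.array([predict_citation(model, b) for b in test.bags])
    assert (pred == test.labels("t1")).mean() >= 0.9
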