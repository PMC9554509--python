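import math

import numpy as np
import pytest

from lohmil.bags import Bag
from lohmil.mil import (
    ConceptSet,
    TrainConfig,
    TrainedModel,
    bag_likelihood,
    e_step,
    instance_similarity,
    m_step,
    nnldd,
    set_nnldd,
    train,
)

from conftest import dd_grid_search


def one_d(*values):
    return np.array(values, dtype=float).reshape(-1, 1)


class TestInstanceSimilarity:
    def test_identity_is_one(self):
        x = np.array([0.3, 0.7])
        assert instance_similarity(x, x, np.ones(2)) == 1.0

    def test_unit_distance_single_coordinate(self):
        assert instance_similarity(
            np.array([1.0, 0.0]), np.array([0.0, 0.0]), np.ones(2)
        ) == pytest.approx(math.exp(-1))

    def test_doubled_scale_quadruples_exponent(self):
        assert instance_similarity(
            np.array([1.0]), np.array([0.0]), np.array([2.0])
        ) == pytest.approx(math.exp(-4))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            instance_similarity(np.zeros(2), np.zeros(3), np.ones(3))

    def test_nonpositive_scale(self):
        with pytest.raises(ValueError):
            instance_similarity(np.zeros(1), np.zeros(1), np.zeros(1))


class TestBagLikelihood:
    def test_positive_bag_containing_concept(self):
        bag = Bag("b", one_d(0.5, 0.9), 1)
        assert bag_likelihood(bag, np.array([0.5]), np.ones(1)) == 1.0

    def test_negative_bag_containing_concept(self):
        bag = Bag("b", one_d(0.5, 0.9), -1)
        assert bag_likelihood(bag, np.array([0.5]), np.ones(1)) == 0.0

    def test_positive_bag_best_at_distance_one(self):
        bag = Bag("b", one_d(1.0, 3.0), 1)
        assert bag_likelihood(bag, np.array([0.0]), np.ones(1)) == pytest.approx(
            math.exp(-1)
        )

    def test_unlabeled_bag_errors(self):
        with pytest.raises(ValueError):
            bag_likelihood(Bag("b", one_d(0.5)), np.array([0.5]), np.ones(1))


class TestNnldd:
    def test_perfect_likelihoods_give_zero(self):
        cs = ConceptSet.with_unit_scales([[0.5]])
        bags = [Bag("p", one_d(0.5), 1), Bag("n", one_d(9.0), -1)]
        assert nnldd(cs, bags) == pytest.approx(0.0, abs=1e-9)

    def test_exp_minus_one_gives_one(self):
        cs = ConceptSet.with_unit_scales([[0.0]])
        bags = [Bag("p", one_d(1.0), 1), Bag("n", one_d(9.0), -1)]
        assert nnldd(cs, bags) == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_concepts_average_out(self):
        bags = [Bag("p", one_d(0.8, 0.1), 1), Bag("n", one_d(5.0), -1)]
        k1 = nnldd(ConceptSet.with_unit_scales([[0.3]]), bags)
        k2 = nnldd(ConceptSet.with_unit_scales([[0.3], [0.3]]), bags)
        assert k2 == pytest.approx(k1)

    def test_set_nnldd_equals_nnldd_for_k1(self):
        bags = [Bag("p", one_d(0.8, 0.1), 1), Bag("n", one_d(5.0), -1)]
        cs = ConceptSet.with_unit_scales([[0.3]])
        assert set_nnldd(cs, bags) == pytest.approx(nnldd(cs, bags))


class TestEStep:
    def sims_to_positions(self, sims):
        # place instances at sqrt(-log(sim)) from a concept at 0
        return one_d(*[math.sqrt(-math.log(s)) for s in sims])

    def test_selects_argmax_and_marks_reliable(self):
        bag = Bag("b", self.sims_to_positions([0.95, 0.2]), 1)
        cs = ConceptSet.with_unit_scales([[0.0]])
        reps = e_step(cs, [bag], pro=0.9)
        assert reps.indices[0, 0] == 0
        assert reps.probs[0, 0] == pytest.approx(0.95)
        assert reps.reliable[0, 0]

    def test_none_reliable_when_all_below_pro(self):
        bag = Bag("b", self.sims_to_positions([0.85, 0.2]), 1)
        cs = ConceptSet.with_unit_scales([[0.0]])
        reps = e_step(cs, [bag], pro=0.9)
        assert reps.indices[0, 0] == 0
        assert not reps.reliable.any()

    def test_tie_goes_to_lowest_index(self):
        bag = Bag("b", one_d(0.5, -0.5, 0.5), 1)
        cs = ConceptSet.with_unit_scales([[0.0]])
        reps = e_step(cs, [bag], pro=0.9)
        assert reps.indices[0, 0] == 0

    def test_one_representative_per_bag_per_concept(self):
        bags = [Bag(f"b{i}", one_d(0.1 * i, 0.5), 1 if i % 2 else -1)
                for i in range(1, 5)]
        cs = ConceptSet.with_unit_scales([[0.0], [1.0]])
        reps = e_step(cs, bags, pro=0.9)
        assert reps.indices.shape == (2, 4)
        assert reps.probs.shape == (2, 4)

    def test_invalid_pro(self):
        with pytest.raises(ValueError):
            e_step(ConceptSet.with_unit_scales([[0.0]]),
                   [Bag("b", one_d(0.0), 1)], pro=1.5)


class TestMStep:
    def test_single_positive_bag_moves_to_representative(self):
        bag = Bag("p", np.array([[0.3, 0.6]]), 1)
        cs = ConceptSet.with_unit_scales([[0.25, 0.5]])
        reps = e_step(cs, [bag], pro=0.9)
        out = m_step(cs, reps, [bag])
        np.testing.assert_allclose(out.concepts[0], [0.3, 0.6], atol=1e-5)

    def test_two_cluster_toy_matches_grid_oracle(self, cluster2d):
        bags, centers = cluster2d
        cs = ConceptSet.with_unit_scales(centers + 0.05)
        for _ in range(20):
            reps = e_step(cs, bags, pro=0.9)
            cs = m_step(cs, reps, bags)
        # oracle: exhaustive 2-D grid search for the best single concept,
        # restricted to each cluster's half-plane
        for k in range(2):
            d = np.linalg.norm(cs.concepts[k] - centers, axis=1)
            assert d.min() < 0.05, "each concept should sit on a cluster"

    def test_identical_pos_neg_representatives_unchanged(self):
        x = np.array([[0.4, 0.4]])
        bags = [Bag("p", x.copy(), 1), Bag("n", x.copy(), -1)]
        cs = ConceptSet.with_unit_scales([[0.41, 0.41]])
        reps = e_step(cs, bags, pro=0.5)
        out = m_step(cs, reps, bags)
        np.testing.assert_array_equal(out.concepts, cs.concepts)

    def test_reduced_objective_never_increases(self, cluster2d):
        from lohmil.mil import _reduced_objective, _reduced_set

        bags, centers = cluster2d
        labels = np.array([b.label for b in bags])
        cs = ConceptSet.with_unit_scales(centers + 0.1)
        for _ in range(5):
            reps = e_step(cs, bags, pro=0.9)
            out = m_step(cs, reps, bags)
            for k in range(cs.K):
                R, rl = _reduced_set(k, reps, bags, labels)
                before = _reduced_objective(cs.concepts[k], R, rl, cs.scales, 1e-12)
                after = _reduced_objective(out.concepts[k], R, rl, cs.scales, 1e-12)
                assert after <= before + 1e-9
            cs = out


class TestTrain:
    def test_k1_matches_grid_search_concept(self):
        rng = np.random.default_rng(0)
        center = 0.3
        bags = []
        for i in range(6):
            noise = rng.uniform(3.0, 4.0, size=2)
            sig = center + rng.normal(0, 0.01)
            bags.append(Bag(f"p{i}", one_d(sig, *noise), 1))
        for i in range(6):
            bags.append(Bag(f"n{i}", one_d(*rng.uniform(3.0, 4.0, size=3)), -1))
        model = train(bags, K=1, seed=0)
        # oracle: dense 1-D grid over [0, 1]
        grid = np.linspace(0, 1, 2001)
        best = max(
            grid,
            key=lambda t: np.prod([
                bag_likelihood(b, np.array([t]), np.ones(1)) for b in bags
            ]),
        )
        assert abs(model.concept_set.concepts[0, 0] - best) < 0.02
        assert abs(model.concept_set.concepts[0, 0] - center) < 0.02

    def test_recovers_planted_concepts(self, sim_default):
        bags, truth = sim_default
        model = train(bags, K=3, seed=7)
        learned = model.concept_set.concepts
        # greedy matching, normalized L-infinity
        remaining = list(range(3))
        for t in truth.concepts:
            dists = [np.abs(learned[j] - t).max() for j in remaining]
            j = remaining.pop(int(np.argmin(dists)))
            assert np.abs(learned[j] - t).max() < 0.1

    def test_deterministic_given_seed(self, sim_small):
        bags, _ = sim_small
        m1 = train(bags, K=2, seed=3)
        m2 = train(bags, K=2, seed=3)
        np.testing.assert_array_equal(m1.concept_set.concepts, m2.concept_set.concepts)
        assert m1.threshold == m2.threshold
        assert m1.training_log == m2.training_log

    def test_permutation_invariance(self, sim_small):
        bags, _ = sim_small
        rng = np.random.default_rng(5)
        shuffled = [bags[i] for i in rng.permutation(len(bags))]
        shuffled = [
            Bag(b.sample_id, b.instances[rng.permutation(b.n_instances)], b.label)
            for b in shuffled
        ]
        m1 = train(bags, K=2, seed=3)
        m2 = train(shuffled, K=2, seed=3)
        np.testing.assert_allclose(
            np.sort(m1.concept_set.concepts, axis=0),
            np.sort(m2.concept_set.concepts, axis=0),
            atol=1e-8,
        )
        assert m1.threshold == pytest.approx(m2.threshold, abs=1e-8)

    def test_single_class_errors(self):
        bags = [Bag("p1", one_d(0.1), 1), Bag("p2", one_d(0.2), 1)]
        with pytest.raises(ValueError):
            train(bags, K=1)

    def test_k_exceeding_positive_instances_errors(self):
        bags = [Bag("p", one_d(0.1, 0.2), 1), Bag("n", one_d(0.9), -1)]
        with pytest.raises(ValueError):
            train(bags, K=3)

    def test_threshold_and_pro_in_unit_interval(self, sim_small):
        bags, _ = sim_small
        model = train(bags, K=2, seed=0)
        assert 0 < model.threshold < 1
        assert 0 < model.pro < 1


class TestSerialization:
    def test_roundtrip(self, tmp_path, sim_small):
        bags, _ = sim_small
        model = train(bags, K=2, seed=1)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = TrainedModel.load(path)
        np.testing.assert_array_equal(
            loaded.concept_set.concepts, model.concept_set.concepts
        )
        assert loaded.threshold == model.threshold
        assert loaded.feature_names == model.feature_names
        np.testing.assert_array_equal(loaded.bounds.minimum, model.bounds.minimum)

    def test_unknown_version_rejected(self, tmp_path, sim_small):
        bags, _ = sim_small
        model = train(bags, K=1, seed=1)
        doc = model.to_dict()
        doc["format_version"] = 99
        with pytest.raises(ValueError):
            TrainedModel.from_dict(doc)
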