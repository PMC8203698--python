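import numpy as np
import pytest

from carepath.config import PipelineConfig
from carepath.markov import ClusterModel, fit_markov
from carepath.predict import (
    PredictorEnsemble,
    fit_ensemble,
    knn_estimate,
    predict_cost,
)
from carepath.simgen import SimConfig, simulate_dataset
from carepath.tpd import TPDParams
from conftest import make_seq

PARAMS = TPDParams(epsilon=0.01)


def toy_cluster(cid, members, totals):
    vocab = sorted({(a.activity, a.cost) for s in members for a in s.actions})
    return ClusterModel(
        cluster_id=cid,
        member_ids=[s.patient_id for s in members],
        member_sequences=members,
        member_total_costs=np.asarray(totals, dtype=float),
        chain=fit_markov(members, vocab, beta=0.5),
    )


class TestKnnEstimate:
    def test_k1_returns_nearest_members_cost(self):
        members = [make_seq("m1", [("A", 5.0)]), make_seq("m2", [("B", 9.0)])]
        c = toy_cluster(0, members, [100.0, 900.0])
        query = make_seq("q", [("A", 5.0)])
        est, ids = knn_estimate(query, c, k=1, params=PARAMS, delta=1e-6)
        assert est == pytest.approx(100.0)
        assert ids == ("m1",)

    def test_equidistant_neighbors_average(self):
        members = [make_seq("m1", [("A", 4.0)]), make_seq("m2", [("A", 6.0)])]
        c = toy_cluster(0, members, [10.0, 20.0])
        query = make_seq("q", [("A", 5.0)])  # TPD w2*1 to both
        est, _ = knn_estimate(query, c, k=2, params=PARAMS, delta=1e-6)
        assert est == pytest.approx(15.0)

    def test_exact_match_dominates_by_inverse_distance(self):
        members = [
            make_seq("m1", [("A", 5.0)]),
            make_seq("m2", [("A", 50.0)]),
            make_seq("m3", [("B", 5.0)]),
        ]
        c = toy_cluster(0, members, [100.0, 500.0, 900.0])
        query = make_seq("q", [("A", 5.0)])  # TPD 0 to m1, 0.3*45 to m2, 0.7*eps to m3
        est, ids = knn_estimate(query, c, k=3, params=PARAMS, delta=1e-6)
        assert ids[0] == "m1"
        d = np.array([0.0, 13.5, 0.007]) + 1e-6
        w = 1.0 / d
        expected = np.dot(w, [100.0, 500.0, 900.0]) / w.sum()
        assert est == pytest.approx(expected, rel=1e-9)
        assert est == pytest.approx(100.0, rel=2e-3)  # exact match still dominates

    def test_k_truncated_to_cluster_size(self):
        members = [make_seq(f"m{i}", [("A", float(i))]) for i in range(4)]
        c = toy_cluster(0, members, [10.0, 20.0, 30.0, 40.0])
        _, ids = knn_estimate(make_seq("q", [("A", 0.0)]), c, k=10, params=PARAMS, delta=1e-3)
        assert len(ids) == 4

    def test_tie_broken_by_member_index(self):
        members = [make_seq("m1", [("A", 4.0)]), make_seq("m2", [("A", 6.0)])]
        c = toy_cluster(0, members, [10.0, 20.0])
        _, ids = knn_estimate(make_seq("q", [("A", 5.0)]), c, k=1, params=PARAMS, delta=1e-6)
        assert ids == ("m1",)

    def test_nonpositive_delta_rejected(self):
        members = [make_seq("m1", [("A", 4.0)])]
        c = toy_cluster(0, members, [10.0])
        with pytest.raises(ValueError, match="delta"):
            knn_estimate(make_seq("q", [("A", 5.0)]), c, k=1, params=PARAMS, delta=0.0)


class TestPredictCost:
    @pytest.fixture
    def two_cluster_ensemble(self):
        from carepath.discretize import fit_quantiles

        a_members = [make_seq("a1", [("A", 1.0), ("A", 1.0)]), make_seq("a2", [("A", 1.0)])]
        b_members = [make_seq("b1", [("B", 9.0), ("B", 9.0)]), make_seq("b2", [("B", 9.0)])]
        disc = fit_quantiles([1.0, 1.0, 1.0, 9.0, 9.0, 9.0], 2)
        return PredictorEnsemble(
            discretizer=disc,
            tpd_params=PARAMS,
            clusters=[
                toy_cluster(0, a_members, [2.0, 1.0]),
                toy_cluster(1, b_members, [18.0, 9.0]),
            ],
            knn_k=1,
            knn_weight_delta=1e-6,
        )

    def test_hand_computed_two_cluster_blend(self, two_cluster_ensemble):
        """Full spreadsheet check of the three prediction phases.

        Query [A 1, A 1] (costs already at the segment means 1 and 9):
        cluster 0: member a1 = [A1, A1] at TPD 0 -> k=1 estimate 2.
        cluster 1: b1 = [B9, B9] needs two substitutions, TPD
          2*0.7*(8+0.01) = 11.214; b2 = [B9] needs one substitution plus
          one deletion, 0.7*(8.01) + 0.7*1 = 6.307 -> nearest is b2,
          estimate 9.
        chain weights: both clusters have single-action vocabularies
        (N=1); cluster 0 scores probability 1 per step and cluster 1
        scores the unseen-activity floor 1/N = 1 per step, so the
        normalized weights are [0.5, 0.5].
        final = 0.5*2 + 0.5*9 = 5.5.
        """
        res = predict_cost(make_seq("q", [("A", 1.0), ("A", 1.0)]), two_cluster_ensemble)
        np.testing.assert_allclose(res.per_cluster_estimates, [2.0, 9.0])
        np.testing.assert_allclose(res.cluster_weights, [0.5, 0.5])
        assert res.final_cost == pytest.approx(5.5, rel=1e-9)

    def test_final_is_dot_of_weights_and_estimates(self, two_cluster_ensemble):
        res = predict_cost(make_seq("q", [("A", 1.0), ("B", 9.0)]), two_cluster_ensemble)
        assert res.final_cost == pytest.approx(
            float(np.dot(res.cluster_weights, res.per_cluster_estimates)), rel=1e-9
        )
        assert res.per_cluster_estimates.min() <= res.final_cost <= res.per_cluster_estimates.max()

    def test_single_cluster_weight_is_one(self):
        from carepath.discretize import fit_quantiles

        members = [make_seq("m1", [("A", 1.0)]), make_seq("m2", [("A", 1.0), ("A", 1.0)])]
        ens = PredictorEnsemble(
            discretizer=fit_quantiles([1.0, 1.0, 1.0], 1),
            tpd_params=PARAMS,
            clusters=[toy_cluster(0, members, [1.0, 2.0])],
            knn_k=1,
            knn_weight_delta=1e-6,
        )
        res = predict_cost(make_seq("q", [("A", 1.0)]), ens)
        np.testing.assert_allclose(res.cluster_weights, [1.0])
        assert res.final_cost == pytest.approx(res.per_cluster_estimates[0])


@pytest.fixture(scope="module")
def fitted():
    cfg = SimConfig.well_separated(seed=5, n_patients_per_cluster=30)
    ds, labels, _ = simulate_dataset(cfg)
    ens = fit_ensemble(ds, PipelineConfig(min_cluster_size=10))
    return ds, ens


class TestPipelineInvariants:
    def test_prediction_is_convex_combination_of_training_totals(self, fitted):
        ds, ens = fitted
        totals = ds.total_costs()
        for seq in ds.sequences[::7]:
            res = predict_cost(seq, ens)
            assert totals.min() - 1e-9 <= res.final_cost <= totals.max() + 1e-9

    def test_every_training_sequence_in_exactly_one_cluster(self, fitted):
        ds, ens = fitted
        seen = [pid for c in ens.clusters for pid in c.member_ids]
        assert sorted(seen) == sorted(ds.patient_ids)

    def test_training_member_recovers_its_own_total(self, fitted):
        # k=1, no smoothing advantage needed: TPD 0 to itself dominates
        ds, ens = fitted
        import dataclasses

        ens1 = dataclasses.replace(ens, knn_k=1)
        for seq in ds.sequences[::11]:
            res = predict_cost(seq, ens1)
            best = res.per_cluster_estimates[res.top_cluster]
            assert best == pytest.approx(seq.total_cost, rel=1e-3)
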