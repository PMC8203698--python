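import numpy as np
import pytest

from carepath.core import (
    Action,
    Dataset,
    EventLogError,
    TreatmentSequence,
    load_model,
    read_event_log,
    save_model,
    write_event_log,
)


class TestDomainTypes:
    def test_action_rejects_negative_cost_and_empty_activity(self):
        with pytest.raises(ValueError):
            Action("CONS", -1.0)
        with pytest.raises(ValueError):
            Action("", 5.0)

    def test_sequence_requires_at_least_one_action(self):
        with pytest.raises(ValueError):
            TreatmentSequence("p1", ())

    def test_dataset_rejects_duplicate_patient_ids(self, seq_factory):
        s = seq_factory("p1", [("A", 1)])
        with pytest.raises(ValueError, match="duplicate"):
            Dataset([s, seq_factory("p1", [("B", 2)])])

    def test_alphabet_is_union_of_observed_activities(self, toy_dataset):
        assert toy_dataset.activity_alphabet == {"CONS", "LABO", "RADI", "QUIR"}


class TestEventLogIO:
    def test_single_patient_grouping(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text(
            "patient_id,visit_time,activity,cost\n"
            "p1,1,CONS,80\np1,2,LABO,45.5\np1,3,RADI,210\n"
        )
        ds = read_event_log(p)
        assert len(ds) == 1
        assert len(ds.sequences[0]) == 3
        assert ds.sequences[0].activities == ("CONS", "LABO", "RADI")

    def test_interleaved_patients_are_time_sorted(self, tmp_path):
        # rows out of order within patients; expected order fixed by hand
        p = tmp_path / "log.csv"
        p.write_text(
            "patient_id,visit_time,activity,cost\n"
            "a,3,RADI,210\nb,1,CONS,75\na,1,CONS,80\nb,2,QUIR,2500\na,2,LABO,45\n"
        )
        ds = read_event_log(p)
        assert ds.patient_ids == ["a", "b"]
        assert ds.sequences[0].activities == ("CONS", "LABO", "RADI")
        assert ds.sequences[1].activities == ("CONS", "QUIR")

    def test_tied_visit_times_keep_file_order(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text(
            "patient_id,visit_time,activity,cost\n"
            "a,1,FIRST,1\na,1,SECOND,2\na,1,THIRD,3\n"
        )
        ds = read_event_log(p)
        assert ds.sequences[0].activities == ("FIRST", "SECOND", "THIRD")

    def test_negative_cost_names_row(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text("patient_id,visit_time,activity,cost\na,1,CONS,80\na,2,LABO,-1\n")
        with pytest.raises(EventLogError, match="row 1"):
            read_event_log(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text("patient_id,visit_time,activity\na,1,CONS\n")
        with pytest.raises(EventLogError, match="cost"):
            read_event_log(p)

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "log.csv"
        p.write_text("patient_id,visit_time,activity,cost\n")
        with pytest.raises(EventLogError, match="no rows|empty"):
            read_event_log(p)

    def test_round_trip(self, toy_dataset, tmp_path):
        p = tmp_path / "out.csv"
        write_event_log(toy_dataset, p)
        back = read_event_log(p)
        assert back.patient_ids == toy_dataset.patient_ids
        for s1, s2 in zip(back, toy_dataset):
            assert s1.actions == s2.actions

    def test_lossy_rounding_warns(self, seq_factory, tmp_path):
        ds = Dataset([seq_factory("p", [("A", 12.345)])])
        p = tmp_path / "out.csv"
        with pytest.warns(UserWarning, match="lossy"):
            write_event_log(ds, p, decimals=2)
        assert read_event_log(p).sequences[0].actions[0].cost == 12.35


class TestModelIO:
    @pytest.fixture
    def fitted(self):
        from carepath import PipelineConfig, SimConfig, fit_ensemble, simulate_dataset

        cfg = SimConfig.well_separated(seed=3, n_patients_per_cluster=25)
        ds, _, _ = simulate_dataset(cfg)
        return ds, fit_ensemble(ds, PipelineConfig(min_cluster_size=8))

    def test_round_trip_preserves_predictions(self, fitted, tmp_path):
        from carepath import predict_cost

        ds, ensemble = fitted
        path = tmp_path / "model.json"
        save_model(ensemble, path)
        back = load_model(path)
        for seq in ds.sequences[:5]:
            a = predict_cost(seq, ensemble)
            b = predict_cost(seq, back)
            assert b.final_cost == pytest.approx(a.final_cost, rel=1e-9)
            np.testing.assert_allclose(b.cluster_weights, a.cluster_weights, rtol=1e-12)

    def test_round_trip_preserves_probabilities(self, fitted, tmp_path):
        _, ensemble = fitted
        path = tmp_path / "model.json"
        save_model(ensemble, path)
        back = load_model(path)
        for c1, c2 in zip(ensemble.clusters, back.clusters):
            np.testing.assert_allclose(
                c2.chain.transition_matrix, c1.chain.transition_matrix, atol=1e-12
            )
            np.testing.assert_allclose(c2.chain.initial_probs, c1.chain.initial_probs, atol=1e-12)
        np.testing.assert_allclose(
            back.discretizer.segment_means, ensemble.discretizer.segment_means, atol=1e-12
        )

    def test_corrupted_file_is_parse_error(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text("{not json")
        with pytest.raises(EventLogError, match="corrupted"):
            load_model(path)

    def test_version_mismatch_is_explicit(self, fitted, tmp_path):
        import json

        _, ensemble = fitted
        path = tmp_path / "model.json"
        save_model(ensemble, path)
        doc = json.loads(path.read_text())
        doc["schema_version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(EventLogError, match="version"):
            load_model(path)

    def test_unseen_activity_query_is_handled(self, fitted, seq_factory):
        from carepath import predict_cost

        _, ensemble = fitted
        res = predict_cost(seq_factory("new", [("UNKNOWN_ACT", 50.0)]), ensemble)
        assert np.isfinite(res.final_cost)
        assert res.cluster_weights.sum() == pytest.approx(1.0)
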