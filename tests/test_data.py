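"""Instrument/cohort validation and file round-trips."""
import numpy as np
import pandas as pd
import pytest

import netoutcome as no
from netoutcome.data import ItemDescriptor, SymptomScale


class TestSymptomScale:
    def test_default_instrument_shape(self, scale):
        assert scale.n_items == 17
        maxes = [it.max_score for it in scale.items]
        assert maxes.count(2) == 4 and maxes.count(4) == 13
        assert all(it.min_score == 0 for it in scale.items)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(no.ValidationError):
            SymptomScale((ItemDescriptor("a"), ItemDescriptor("a")))

    def test_bad_score_range_rejected(self):
        with pytest.raises(no.ValidationError):
            ItemDescriptor("x", max_score=3)


class TestCohortValidation:
    def test_out_of_range_score_names_row_and_item(self, scale):
        scores = np.zeros((3, 17))
        scores[1, no.SUICIDALITY] = 5
        with pytest.raises(no.ValidationError, match="row 1.*suicidality"):
            no.CohortTable(scores, np.zeros(3), scale)

    def test_nonbinary_outcome_rejected(self, scale):
        with pytest.raises(no.ValidationError, match="outcome"):
            no.CohortTable(np.zeros((2, 17)), np.array([0, 2]), scale)

    def test_empty_cohort_rejected(self, scale):
        with pytest.raises(no.ValidationError, match="empty"):
            no.CohortTable(np.zeros((0, 17)), np.zeros(0), scale)


class TestCohortIO:
    def test_round_trip_preserves_every_value(self, scale, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        no.write_cohort(small_cohort, path)
        back = no.load_cohort(path, scale)
        assert back.n_patients == small_cohort.n_patients
        np.testing.assert_array_equal(back.scores, small_cohort.scores)
        np.testing.assert_array_equal(back.outcome, small_cohort.outcome)

    def test_161_row_file_loads_161_patients(self, scale, tmp_path):
        model = no.default_study_model(1)
        coh = no.sample_cohort(model, scale, no.SimulationConfig(n_patients=161, seed=4))
        path = tmp_path / "c.csv"
        no.write_cohort(coh, path)
        assert no.load_cohort(path, scale).n_patients == 161

    def test_complete_case_dropping_counts_and_is_order_independent(
        self, scale, small_cohort, tmp_path
    ):
        df = small_cohort.to_dataframe().astype(float)
        df.loc[3, "guilt"] = np.nan
        df.loc[10, "remission"] = np.nan
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        df.to_csv(p1, index=False)
        df.sample(frac=1, random_state=0).to_csv(p2, index=False)
        t1 = no.load_cohort(p1, scale)
        t2 = no.load_cohort(p2, scale)
        assert t1.n_dropped == t2.n_dropped == 2
        assert t1.n_patients == small_cohort.n_patients - 2
        key = lambda t: np.lexsort(np.column_stack([t.scores, t.outcome]).T)
        np.testing.assert_array_equal(
            np.sort(t1.scores, axis=0), np.sort(t2.scores, axis=0)
        )

    def test_empty_file_rejected(self, scale, tmp_path):
        path = tmp_path / "empty.csv"
        pd.DataFrame(columns=scale.labels + ["remission"]).to_csv(path, index=False)
        with pytest.raises(no.ValidationError, match="empty"):
            no.load_cohort(path, scale)

    def test_unknown_column_is_schema_error(self, scale, small_cohort, tmp_path):
        df = small_cohort.to_dataframe()
        df["extra"] = 1
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with pytest.raises(no.SchemaError, match="extra"):
            no.load_cohort(path, scale)

    def test_out_of_range_in_file_names_the_row(self, scale, small_cohort, tmp_path):
        df = small_cohort.to_dataframe()
        df.loc[0, "suicidality"] = 5
        path = tmp_path / "c.csv"
        df.to_csv(path, index=False)
        with pytest.raises(no.ValidationError, match="suicidality"):
            no.load_cohort(path, scale)


class TestNetworkIO:
    @pytest.mark.parametrize("fmt", ["json", "graphml"])
    def test_fitted_model_round_trips(self, default_network, tmp_path, fmt):
        path = tmp_path / f"net.{fmt}"
        no.write_network(default_network, path, fmt)
        back = no.read_network(path, fmt)
        assert back.node_labels == default_network.node_labels
        np.testing.assert_allclose(
            back.adjacency, default_network.adjacency, rtol=1e-12, atol=0
        )
        np.testing.assert_allclose(
            back.predictability, default_network.predictability, rtol=1e-12, atol=0
        )

    def test_negative_edge_sign_preserved(self, tmp_path):
        from netoutcome.estimate import NetworkModel

        adj = np.zeros((18, 18))
        adj[0, 1] = adj[1, 0] = -0.3
        model = NetworkModel(
            node_labels=[f"n{i}" for i in range(18)],
            node_types=["continuous"] * 17 + ["categorical"],
            adjacency=adj,
            sign_undefined=np.zeros((18, 18), dtype=bool),
            nodewise_fits=None,
            predictability=np.zeros(18),
            smallest_retained_weight=0.3,
        )
        path = tmp_path / "net.json"
        no.write_network(model, path, "json")
        back = no.read_network(path, "json")
        assert back.adjacency[0, 1] == -0.3

    def test_empty_network_has_nodes_but_no_edges(self, tmp_path):
        from netoutcome.estimate import NetworkModel

        model = NetworkModel(
            node_labels=[f"n{i}" for i in range(18)],
            node_types=["continuous"] * 17 + ["categorical"],
            adjacency=np.zeros((18, 18)),
            sign_undefined=np.zeros((18, 18), dtype=bool),
            nodewise_fits=None,
            predictability=np.zeros(18),
            smallest_retained_weight=None,
        )
        path = tmp_path / "net.json"
        no.write_network(model, path, "json")
        import json

        rec = json.loads(path.read_text())
        assert len(rec["nodes"]) == 18 and rec["edges"] == []
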