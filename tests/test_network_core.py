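import numpy as np
import pandas as pd
import pytest

from trophinet import (
    BipartiteNetwork,
    InteractionRecord,
    TraitTable,
    apply_mapping,
    build_network,
    read_edge_list,
    read_matrix,
    read_traits,
    write_edge_list,
    write_matrix,
    write_traits,
)
from trophinet.structure_metrics import connectance


class TestInteractionRecord:
    def test_rank_defaults_to_main_and_ids_are_trimmed(self):
        r = InteractionRecord(" s1 ", "r1 ")
        assert (r.consumer_id, r.resource_id, r.rank) == ("s1", "r1", "main")

    @pytest.mark.parametrize(
        "args", [("", "r1"), ("s1", ""), ("s1", "r1", "tertiary")]
    )
    def test_invalid_records_rejected(self, args):
        with pytest.raises(ValueError):
            InteractionRecord(*args)


class TestBuildNetwork:
    def test_single_record_gives_1x1_identity(self):
        net = build_network([InteractionRecord("s1", "r1")], include_secondary=False)
        assert net.consumers == ["s1"] and net.resources == ["r1"]
        assert net.A.tolist() == [[1]]

    def test_secondary_filtering_keeps_resources_with_main_links(self):
        # r2 keeps s2's main link, so the filtered network is 2x2 diagonal
        records = [
            InteractionRecord("s1", "r1", "main"),
            InteractionRecord("s1", "r2", "secondary"),
            InteractionRecord("s2", "r2", "main"),
        ]
        net = build_network(records, include_secondary=False)
        assert net.consumers == ["s1", "s2"]
        assert net.resources == ["r1", "r2"]
        assert net.A.tolist() == [[1, 0], [0, 1]]

    def test_duplicate_records_are_idempotent(self, toy_records):
        net1 = build_network(toy_records)
        net2 = build_network(toy_records + toy_records + [toy_records[0]])
        assert net1 == net2

    def test_first_appearance_order(self, toy_records):
        net = build_network(toy_records)
        assert net.consumers == ["s1", "s2", "s3"]
        assert net.resources == ["r1", "r2", "r3"]

    def test_empty_record_list_rejected(self):
        with pytest.raises(ValueError):
            build_network([])


class TestBipartiteNetwork:
    def test_rejects_nonbinary_and_empty_rows(self):
        with pytest.raises(ValueError):
            BipartiteNetwork(["a"], ["x"], np.array([[2]]))
        with pytest.raises(ValueError):
            BipartiteNetwork(["a", "b"], ["x"], np.array([[1], [0]]))

    def test_remove_consumers_drops_emptied_columns(self):
        A = np.array([[1, 1], [1, 0]])
        net = BipartiteNetwork(["a", "b"], ["x", "y"], A)
        sub = net.remove_consumers(["a"])
        assert sub.consumers == ["b"] and sub.resources == ["x"]
        with pytest.raises(KeyError):
            net.remove_consumers(["nope"])


class TestRoundTrips:
    def test_edge_list_round_trip(self, toy_records, tmp_path):
        p = tmp_path / "edges.csv"
        write_edge_list(toy_records, p)
        assert read_edge_list(p) == toy_records

    def test_edge_list_without_rank_column_defaults_to_main(self, tmp_path):
        p = tmp_path / "edges.csv"
        p.write_text("consumer,resource\ns1,r1\ns2,r1\ns2,r2\n")
        records = read_edge_list(p)
        assert len(records) == 3 and all(r.rank == "main" for r in records)

    def test_edge_list_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError):
            read_edge_list(p)

    def test_matrix_round_trip_bit_exact(self, toy_records, tmp_path):
        net = build_network(toy_records)
        p = tmp_path / "matrix.csv"
        write_matrix(net, p)
        assert read_matrix(p) == net

    def test_traits_round_trip(self, tmp_path):
        traits = TraitTable(
            pd.DataFrame(
                {
                    "family": ["F1", "F2"],
                    "body_mass_g": [10.0, 2500.0],
                    "lifestyle": ["arboreal", "terrestrial"],
                },
                index=pd.Index(["s1", "s2"], name="species"),
            )
        )
        p = tmp_path / "traits.csv"
        write_traits(traits, p)
        back = read_traits(p)
        pd.testing.assert_frame_equal(back.data, traits.data)


class TestTraitTable:
    def test_rejects_bad_mass_and_lifestyle(self):
        base = dict(family=["F"], body_mass_g=[5.0], lifestyle=["arboreal"])
        with pytest.raises(ValueError):
            TraitTable(pd.DataFrame({**base, "body_mass_g": [-1.0]}, index=["s"]))
        with pytest.raises(ValueError):
            TraitTable(pd.DataFrame({**base, "lifestyle": ["flying"]}, index=["s"]))

    def test_check_covers_flags_missing_consumers(self, toy_records):
        net = build_network(toy_records)
        traits = TraitTable(
            pd.DataFrame(
                {"family": ["F"], "body_mass_g": [1.0], "lifestyle": ["aquatic"]},
                index=pd.Index(["s1"], name="species"),
            )
        )
        with pytest.raises(ValueError, match="s2"):
            traits.check_covers(net)


class TestApplyMapping:
    def test_identity_mapping_is_noop(self, toy_records):
        net = build_network(toy_records)
        out = apply_mapping(net, {r: r for r in net.resources})
        assert out == net

    def test_columns_are_ored(self):
        net = BipartiteNetwork(["a", "b"], ["x", "y"], np.eye(2, dtype=int))
        out = apply_mapping(net, {"x": "z", "y": "z"})
        assert out.resources == ["z"]
        assert out.A.tolist() == [[1], [1]]

    def test_consumer_degrees_stay_positive_and_connectance_grows(self, combined_default):
        net, _ = combined_default
        # coarsen resources 3:1
        mapping = {r: f"coarse_{i % 9}" for i, r in enumerate(net.resources)}
        out = apply_mapping(net, mapping)
        assert (out.consumer_degrees >= 1).all()
        assert connectance(out) >= connectance(net)

    def test_missing_resource_rejected(self, toy_records):
        net = build_network(toy_records)
        with pytest.raises(KeyError):
            apply_mapping(net, {"r1": "z"})
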