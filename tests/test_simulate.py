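import numpy as np
import pytest

from poma import io
from poma.diffexpr import select_de_genes
from poma.network import build_reference_network
from poma.scores import nod
from poma.simulate import (
    read_manifest,
    simulate_expression,
    simulate_network,
    simulate_study,
)


class TestSimulateExpression:
    def test_seed_determinism(self):
        a, ma = simulate_expression(100, 5, 5, 10, 4.0, 0.2, seed=7)
        b, mb = simulate_expression(100, 5, 5, 10, 4.0, 0.2, seed=7)
        assert a.values.equals(b.values)
        assert ma == mb

    def test_null_simulation_type_one_calibration(self):
        # with no planted genes, the flagged fraction is bounded by the
        # t-test level intersected with the fold-change filter's attrition
        matrix, manifest = simulate_expression(2000, 20, 20, 0, 4.0, 0.2, seed=1)
        assert manifest["planted_de"] == {}
        flagged = [r for r in select_de_genes(matrix) if r.is_de]
        assert len(flagged) / 2000 <= 0.05

    def test_planted_split_up_and_down(self):
        _, manifest = simulate_expression(50, 3, 3, 10, 4.0, 0.2, seed=2)
        fcs = list(manifest["planted_de"].values())
        assert fcs.count(4.0) == 5 and fcs.count(0.25) == 5

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_expression(10, 3, 3, 20, 4.0, 0.2, seed=0)
        with pytest.raises(ValueError):
            simulate_expression(10, 3, 3, 2, 0.5, 0.2, seed=0)


class TestSimulateNetwork:
    def make(self, **kw):
        params = dict(
            n_mirna=30, n_gene=200, mean_degree=5.0, n_outliers=4,
            outlier_exclusive_targets=5, tf_frac=0.1, disease_frac=0.1,
            outlier_tf_boost=3.0, outlier_disease_boost=3.0, seed=11,
        )
        params.update(kw)
        return simulate_network(**params)

    def test_exclusive_targets_guarantee_nod(self):
        interactions, _, _, manifest = self.make()
        net = build_reference_network(interactions)
        for m, info in manifest["planted_outliers"].items():
            assert nod(net, m) >= 5
            for g in info["exclusive_targets"]:
                assert net.graph.in_degree(g) == 1

    def test_in_degree_one_count_equals_nod_sum(self):
        interactions, _, _, _ = self.make()
        net = build_reference_network(interactions)
        total = sum(nod(net, m) for m in net.mirna_nodes)
        singles = sum(1 for g in net.gene_nodes if net.graph.in_degree(g) == 1)
        assert total == singles

    def test_unit_boosts_leave_planted_fractions_at_background(self):
        interactions, tf, dz, manifest = self.make(
            outlier_tf_boost=1.0, outlier_disease_boost=1.0
        )
        fracs = [info["tf_fraction"] for info in manifest["planted_outliers"].values()]
        assert np.mean(fracs) < 0.25  # near tf_frac, not boosted

    def test_seed_determinism(self):
        a = self.make()[0]
        b = self.make()[0]
        assert a.records.equals(b.records)

    def test_infeasible_planting_is_error(self):
        with pytest.raises(ValueError, match="infeasible"):
            self.make(n_gene=25, n_outliers=5, outlier_exclusive_targets=5)


class TestSimulateStudy:
    def test_toy_byte_identical_across_runs_and_seeds(self, tmp_path):
        p1 = simulate_study("toy", 1, tmp_path / "a")
        p2 = simulate_study("toy", 99, tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_default_files_parse_through_io(self, default_study):
        matrix = io.read_expression(
            default_study["expression"], default_study["annotation"]
        )
        interactions = io.read_interactions(
            [default_study["interactions_validated"], default_study["interactions_predicted"]]
        )
        tf = io.read_gene_set(default_study["tf_genes"], "tf")
        dz = io.read_gene_set(default_study["disease_genes"], "disease")
        assoc = io.read_mirna_list(default_study["associated_mirnas"])
        manifest = read_manifest(default_study["manifest"])
        assert len(matrix.gene_ids) == 1000
        assert set(manifest["planted_outliers"]) <= interactions.mirnas
        assert len(tf) == 100 and len(dz) == 100
        assert set(manifest["planted_outliers"]) <= assoc.members

    def test_manifest_round_trips(self, tmp_path):
        paths = simulate_study("default", 5, tmp_path)
        manifest = read_manifest(paths["manifest"])
        from poma.simulate import write_manifest

        write_manifest(manifest, tmp_path / "copy.json")
        assert read_manifest(tmp_path / "copy.json") == manifest

    def test_stress_preset_generates_and_parses(self, tmp_path):
        paths = simulate_study("stress", 2, tmp_path)
        s = io.read_interactions(
            [paths["interactions_validated"], paths["interactions_predicted"]]
        )
        assert len(s.mirnas) == 2000

    def test_unknown_preset_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            simulate_study("huge", 1, tmp_path)
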