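"""Reaction network assembly, level changes, edge significance classes."""

import numpy as np
import pandas as pd
import pytest

import networkx as nx

from lipidsig.pathway import (
    PathwayError,
    annotate_edges,
    build_network,
    classify_edge,
    export_network,
    level_change,
    load_reactions,
)
from lipidsig.synthetic import SynthSpec, generate
from conftest import make_profiles

DIAG8 = ["OA"] * 4 + ["RA"] * 4


class TestReactionTable:
    def test_default_table_stoichiometry(self):
        table = load_reactions()
        deltas = {"elongation": (2, 0), "chain_shortening": (-2, 0),
                  "desaturation": (0, 1)}
        from lipidsig.names import parse_fa_name

        for _, row in table.iterrows():
            s = parse_fa_name(row["substrate"])
            p = parse_fa_name(row["product"])
            dc, db = deltas[row["kind"]]
            assert (p.carbons - s.carbons, p.double_bonds - s.double_bonds) == (
                dc, db,
            )

    def test_invalid_reaction_rejected(self, tmp_path):
        bad = tmp_path / "r.tsv"
        bad.write_text("substrate\tproduct\tkind\n14:0\t18:0\telongation\n")
        with pytest.raises(PathwayError, match="stoichiometry"):
            load_reactions(bad)


class TestBuildNetwork:
    def test_two_measured_neighbours(self):
        net = build_network({"14:0", "16:0"})
        assert net.has_edge("14:0", "16:0")
        assert not net.edges["14:0", "16:0"]["effective"]

    def test_effective_edge_bridges_unmeasured_c24_loop(self):
        """22:5n-3 -> 22:6n-3 goes through unmeasured 24:5n-3/24:6n-3."""
        measured = {"18:3n-3", "20:5n-3", "22:5n-3", "22:6n-3"}
        net = build_network(measured)
        e = net.edges["22:5n-3", "22:6n-3"]
        assert e["effective"]
        assert e["path"] == "22:5n-3|24:5n-3|24:6n-3|22:6n-3"

    def test_effective_edge_deltas_sum_along_chain(self, study_profiles):
        acyl = [lab for lab, nm in study_profiles.parsed_names().items()
                if not nm.is_dma]
        net = build_network(acyl)
        from lipidsig.names import parse_fa_name

        for u, v, data in net.edges(data=True):
            if not data["effective"]:
                continue
            chain = data["path"].split("|")
            total = (
                parse_fa_name(v).carbons - parse_fa_name(u).carbons,
                parse_fa_name(v).double_bonds - parse_fa_name(u).double_bonds,
            )
            step_sum = (0, 0)
            for a, b in zip(chain, chain[1:]):
                step_sum = (
                    step_sum[0] + parse_fa_name(b).carbons - parse_fa_name(a).carbons,
                    step_sum[1]
                    + parse_fa_name(b).double_bonds
                    - parse_fa_name(a).double_bonds,
                )
            assert step_sum == total

    def test_no_measured_fas_gives_hollow_network(self):
        net = build_network(set())
        assert net.number_of_nodes() > 0
        assert not any(d["measured"] for _, d in net.nodes(data=True))
        assert not any(d["effective"] for *_, d in net.edges(data=True))

    def test_orphan_measured_fa_warns(self):
        with pytest.warns(UserWarning, match="19:0"):
            net = build_network({"19:0", "14:0", "16:0"})
        assert net.nodes["19:0"]["measured"]
        assert net.degree("19:0") == 0

    def test_no_self_loops(self, study_profiles):
        acyl = [lab for lab, nm in study_profiles.parsed_names().items()
                if not nm.is_dma]
        net = build_network(acyl)
        assert not list(nx.selfloop_edges(net))


class TestLevelChange:
    def test_equal_means_give_zero(self):
        pm = make_profiles({"14:0": [40.0] * 8, "16:0": [60.0] * 8}, DIAG8)
        lc = level_change(pm)
        assert np.allclose(lc, 0.0)

    def test_direct_arithmetic(self):
        pm = make_profiles(
            {"14:0": [1.0] * 4 + [1.5] * 4, "16:0": [99.0] * 4 + [98.5] * 4},
            DIAG8,
        )
        lc = level_change(pm, ref="OA", alt="RA")
        assert lc["14:0"] == pytest.approx(0.5, abs=1e-12)

    def test_reference_against_itself_is_zero(self, study_profiles):
        lc = level_change(study_profiles, ref="OA", alt="OA")
        assert np.allclose(lc, 0.0, atol=1e-15)

    def test_label_exchange_maps_scores(self, study_profiles):
        lc = level_change(study_profiles, ref="OA", alt="RA")
        swapped = level_change(study_profiles, ref="RA", alt="OA")
        assert np.allclose(swapped, -lc / (1 + lc), atol=1e-12)

    def test_zero_reference_mean_reported_missing(self):
        pm = make_profiles(
            {"14:0": [0.0] * 4 + [1.0] * 4, "16:0": [100.0] * 4 + [99.0] * 4},
            DIAG8,
        )
        with pytest.warns(UserWarning, match="14:0"):
            lc = level_change(pm)
        assert np.isnan(lc["14:0"])


class TestAnnotateEdges:
    def test_duplicated_column_is_sig_both(self):
        x = np.array([1, 2, 3, 5, 2, 3, 4, 6.0])
        pm = make_profiles(
            {"14:0": x, "16:0": x * 2, "18:0": 100 - 3 * x}, DIAG8
        )
        net = build_network({"14:0", "16:0"})
        ann = annotate_edges(net, pm).set_index(["substrate", "product"])
        row = ann.loc[("14:0", "16:0")]
        assert row["class"] == "sig_both"
        assert row["r_OA"] == pytest.approx(1.0)

    def test_classify_edge_is_pure_in_pvalues(self):
        assert classify_edge(0.01, 0.01) == "sig_both"
        assert classify_edge(0.01, 0.5) == "sig_OA_only"
        assert classify_edge(0.5, 0.01) == "sig_RA_only"
        assert classify_edge(0.5, 0.5) == "sig_neither"
        assert classify_edge(0.05, 0.05) == "sig_both"  # threshold inclusive

    def test_label_exchange_swaps_one_sided_classes(self, study_profiles):
        net = build_network(
            [lab for lab, nm in study_profiles.parsed_names().items()
             if not nm.is_dma]
        )
        a = annotate_edges(net, study_profiles, ref="OA", alt="RA")
        b = annotate_edges(net, study_profiles, ref="RA", alt="OA")
        merged = a.merge(b, on=["substrate", "product"], suffixes=("_a", "_b"))
        swap = {"sig_OA_only": "sig_OA_only", "sig_RA_only": "sig_RA_only",
                "sig_both": "sig_both", "sig_neither": "sig_neither"}
        assert (merged["class_a"].map(swap) == merged["class_b"]).all()

    def test_planted_ra_edge_detected(self):
        """A substrate -> product correlation of 0.9 planted in RA samples
        only is classified sig_RA_only in >= 90% of seeded replicates."""
        hits = 0
        n_rep = 50
        net = build_network({"14:0", "16:0"})
        for seed in range(n_rep):
            z, _ = generate(
                SynthSpec(seed=seed, n_groups=1, vars_per_group=2, rho=0.0,
                          effect=(0.0,), closure=False,
                          var_names=["14:0", "16:0"],
                          edge_effects=[("14:0", "16:0", "RA", 0.9)])
            )
            ann = annotate_edges(net, z).set_index(["substrate", "product"])
            hits += ann.loc[("14:0", "16:0"), "class"] == "sig_RA_only"
        assert hits / n_rep >= 0.9

    def test_missing_endpoint_skipped_with_warning(self):
        pm = make_profiles(
            {"14:0": [1, 2, 3, 5, 2, 3, 4, 6.0],
             "16:0": [99, 98, 97, 95, 98, 97, 96, 94.0]},
            DIAG8,
        )
        net = build_network({"14:0", "16:0", "18:0"})
        with pytest.warns(UserWarning, match="skip"):
            ann = annotate_edges(net, pm)
        assert set(zip(ann["substrate"], ann["product"])) == {("14:0", "16:0")}


class TestExport:
    def test_empty_network_valid_graphml(self, tmp_path):
        net = nx.DiGraph()
        paths = export_network(net, prefix=str(tmp_path / "empty"))
        back = nx.read_graphml(paths["graphml"])
        assert back.number_of_nodes() == 0

    def test_round_trip_preserves_attributes(self, tmp_path, study_profiles):
        acyl = [lab for lab, nm in study_profiles.parsed_names().items()
                if not nm.is_dma]
        net = build_network(acyl)
        lc = level_change(study_profiles)
        ann = annotate_edges(net, study_profiles)
        paths = export_network(net, ann, lc, prefix=str(tmp_path / "net"))
        back = nx.read_graphml(paths["graphml"])
        assert back.number_of_nodes() == net.number_of_nodes()
        assert back.number_of_edges() == net.number_of_edges()
        for node in net.nodes:
            assert back.nodes[node]["measured"] == net.nodes[node]["measured"]
        classes = nx.get_edge_attributes(back, "class")
        assert sorted(classes.values()) == sorted(ann["class"])
        edge_table = pd.read_csv(paths["edges"], sep="\t")
        assert len(edge_table) == len(ann)

    def test_n6_chain_present_and_annotated(self, study_profiles, tmp_path):
        """The 18:3n-6 -> 20:3n-6 -> 20:4n-6 route is in the network and
        carries within-diagnosis correlations."""
        acyl = [lab for lab, nm in study_profiles.parsed_names().items()
                if not nm.is_dma]
        net = build_network(acyl)
        assert net.has_edge("18:3n-6", "20:3n-6")
        assert net.has_edge("20:3n-6", "20:4n-6")
        ann = annotate_edges(net, study_profiles).set_index(
            ["substrate", "product"]
        )
        for edge in [("18:3n-6", "20:3n-6"), ("20:3n-6", "20:4n-6")]:
            row = ann.loc[edge]
            assert np.isfinite(row["r_OA"]) and np.isfinite(row["r_RA"])
            assert row["class"] in {
                "sig_OA_only", "sig_RA_only", "sig_both", "sig_neither"
            }
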