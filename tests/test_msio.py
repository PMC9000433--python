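"""I/O layer: peak tables, mzML, Newick and GraphML round trips."""

import io

import numpy as np
import pytest

from strainselect import (
    Dendrogram,
    MAN,
    newick_string,
    read_mzml,
    read_peaklist_table,
    write_graphml,
    write_newick,
    write_peaklist_table,
)
from strainselect.msio import PeakTableParseError

from conftest import write_mzml


class TestPeakTable:
    def test_reader_sorts_by_mz(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("500.1,10\n300.2,5\n")
        pl = read_peaklist_table(p, "A", "r1")
        assert [(pk.mz, pk.intensity) for pk in pl.peaks] == [(300.2, 5), (500.1, 10)]
        assert pl.isolate_id == "A" and pl.replicate_id == "r1"

    def test_duplicate_mz_keeps_max_intensity(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("300.2,5\n300.2,7\n")
        pl = read_peaklist_table(p, "A", "r1")
        assert [(pk.mz, pk.intensity) for pk in pl.peaks] == [(300.2, 7)]

    def test_malformed_field_names_line(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("abc,5\n")
        with pytest.raises(PeakTableParseError, match="line 1"):
            read_peaklist_table(p, "A", "r1")

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("")
        with pytest.raises(PeakTableParseError, match="no peaks"):
            read_peaklist_table(p, "A", "r1")

    @pytest.mark.parametrize("delim", [",", "\t", ";"])
    def test_delimiter_autodetect_and_header(self, tmp_path, delim):
        p = tmp_path / "a.txt"
        p.write_text(f"mz{delim}intensity{delim}snr\n400.5{delim}12{delim}3\n")
        pl = read_peaklist_table(p, "A", "r1")
        assert [(pk.mz, pk.intensity) for pk in pl.peaks] == [(400.5, 12)]

    def test_write_read_round_trip(self, tmp_path):
        p = tmp_path / "a.csv"
        src = read_peaklist_table(
            self._write(tmp_path, "src.csv", "300.123456,5.5\n1200.654321,88\n"),
            "A",
            "r1",
        )
        write_peaklist_table(src.peaks, p)
        back = read_peaklist_table(p, "A", "r1")
        for a, b in zip(src.peaks, back.peaks):
            assert b.mz == pytest.approx(a.mz, rel=1e-6)
            assert b.intensity == pytest.approx(a.intensity, rel=1e-6)

    @staticmethod
    def _write(tmp_path, name, text):
        f = tmp_path / name
        f.write_text(text)
        return f


class TestMzml:
    def test_naming_pattern_assigns_isolate_and_replicate(self, tmp_path):
        p = tmp_path / "x.mzml"
        write_mzml(
            p,
            [
                ("A_r1", [300.5, 500.2], [10, 20], True),
                ("A_r2", [300.6], [11], True),
                ("A_r3", [300.4], [9], True),
            ],
        )
        pls = read_mzml(p)
        assert [pl.isolate_id for pl in pls] == ["A", "A", "A"]
        assert [pl.replicate_id for pl in pls] == ["r1", "r2", "r3"]
        assert pls[0].mz == [300.5, 500.2]

    def test_empty_mzml_yields_empty_sequence(self, tmp_path):
        p = tmp_path / "x.mzml"
        write_mzml(p, [])
        assert read_mzml(p) == []

    def test_profile_spectra_rejected_without_force(self, tmp_path):
        p = tmp_path / "x.mzml"
        write_mzml(p, [("B_r1", [300.5], [10], False)])
        with pytest.raises(ValueError, match="profile spectra not supported"):
            read_mzml(p)
        assert len(read_mzml(p, force_centroid=True)) == 1

    def test_unmatched_spectrum_ids_listed(self, tmp_path):
        p = tmp_path / "x.mzml"
        write_mzml(p, [("nounderscore", [300.5], [10], True)])
        with pytest.raises(ValueError, match="nounderscore"):
            read_mzml(p)

    def test_invalid_xml_is_a_format_error(self, tmp_path):
        p = tmp_path / "x.mzml"
        p.write_text("this is not xml <<<")
        with pytest.raises(ValueError, match="invalid mzML"):
            read_mzml(p)


def _dendro(leaves, merges):
    return Dendrogram(
        leaves=leaves,
        linkage_matrix=np.array(merges, dtype=float),
        linkage_method="average",
        distance_metric="cosine",
    )


class TestNewick:
    def test_two_leaf_tree(self):
        d = _dendro(["A", "B"], [[0, 1, 0.4, 2]])
        assert newick_string(d) == "(A:0.4,B:0.4);"

    def test_single_leaf_tree(self):
        d = _dendro(["A"], np.empty((0, 4)))
        assert newick_string(d) == "A;"

    def test_round_trip_through_independent_parser(self, tmp_path):
        # ((A,B) at 0.1, C) at 0.9: root-to-leaf distance 0.9 everywhere
        from Bio import Phylo

        d = _dendro(["A", "B", "C"], [[0, 1, 0.1, 2], [3, 2, 0.9, 3]])
        out = tmp_path / "t.nwk"
        write_newick(d, out)
        tree = Phylo.read(str(out), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["A", "B", "C"]
        # topology: A and B are siblings, C attaches at the root
        a = next(t for t in tree.get_terminals() if t.name == "A")
        b = next(t for t in tree.get_terminals() if t.name == "B")
        assert tree.common_ancestor([a, b]) is not tree.root
        for leaf in tree.get_terminals():
            depth = sum(c.branch_length for c in tree.get_path(leaf))
            assert depth == pytest.approx(0.9, rel=1e-6)


class TestGraphml:
    def test_node_and_edge_counts(self, tmp_path):
        man = MAN(
            group_id=1,
            isolate_nodes={"A"},
            feature_nodes={0, 1},
            edges={("A", 0), ("A", 1)},
        )
        out = tmp_path / "m.graphml"
        write_graphml(man, out)
        import networkx as nx

        g = nx.read_graphml(str(out))
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2

    def test_empty_network_is_valid_graphml(self, tmp_path):
        man = MAN(group_id=1, isolate_nodes=set(), feature_nodes=set(), edges=set())
        out = tmp_path / "m.graphml"
        write_graphml(man, out)
        import networkx as nx

        g = nx.read_graphml(str(out))
        assert g.number_of_nodes() == 0

    def test_round_trip_preserves_bipartite_adjacency(self, tmp_path, rng):
        import networkx as nx

        from conftest import random_feature_sets

        sets = random_feature_sets(rng, 6, 10)
        edges = {(iso, f) for iso, feats in sets.items() for f in feats}
        man = MAN(
            group_id=3,
            isolate_nodes=set(sets),
            feature_nodes={f for _, f in edges},
            edges=edges,
        )
        out = tmp_path / "m.graphml"
        write_graphml(man, out)
        g = nx.read_graphml(str(out))
        back = set()
        for u, v in g.edges():
            iso, feat = (u, v) if g.nodes[u]["node_type"] == "isolate" else (v, u)
            back.add((iso, g.nodes[feat]["feature_id"]))
        assert back == edges
        types = {d["node_type"] for _, d in g.nodes(data=True)}
        assert types == {"isolate", "feature"}
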