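"""Character coding, binary expansion and reduced-median networks.

The key correctness property: on homoplasy-free (pairwise compatible)
binary matrices the construction must reproduce the unique perfect
phylogeny.  The oracle generates such matrices directly from a random tree
(each character is planted on one edge), so the expected edge splits are
known by construction, independently of the implementation.
"""

import itertools
import re

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from chlorotype import markers as mk
from chlorotype import network as cnet


def random_compatible_matrix(rng, n_haps, n_chars):
    """Binary matrix whose columns are planted on edges of a random tree.

    Returns (DataFrame, list of expected nontrivial splits as frozensets of
    haplotype labels on the derived side).
    """
    labels = [f"h{i}" for i in range(n_haps)]
    # random rooted tree by sequential attachment; edges = (child, parent)
    parents = {}
    nodes = [0]
    for child in range(1, n_haps):
        parents[child] = int(rng.choice(nodes))
        nodes.append(child)

    def below(node):
        out = {node}
        for child, parent in parents.items():
            if parent == node:
                out |= below(child)
        return out

    cols = {}
    splits = set()
    for c in range(n_chars):
        edge_child = int(rng.integers(1, n_haps))
        carriers = below(edge_child)
        cols[f"c{c}"] = [1 if i in carriers else 0 for i in range(n_haps)]
        if 1 <= len(carriers) <= n_haps - 1:
            splits.add(frozenset(labels[i] for i in carriers))
    df = pd.DataFrame(cols, index=labels)
    informative = {s for s in splits if 1 <= len(s) <= len(labels) - 1}
    return df, informative


def observed_splits(net: cnet.MedianNetwork):
    """Bipartitions of observed haplotypes induced by deleting each edge."""
    out = set()
    for u, v in net.graph.edges:
        g = net.graph.copy()
        g.remove_edge(u, v)
        comps = list(nx.connected_components(g))
        side = next(c for c in comps if u in c)
        haps = {h for h, node in net.observed.items() if node in side}
        out.add(frozenset(haps))
    return out


class TestEncoding:
    def _panel(self):
        return mk.Panel([
            mk.MarkerLocus(id=1, kind="ssr", motif="T", anchor=(100, 8),
                           size_range=(98, 110)),
            mk.MarkerLocus(id=8, kind="indel", gel_scored=True),
            mk.MarkerLocus(id=54, kind="mixed", motif="T", anchor=(230, 10),
                           size_range=(231, 239)),
            mk.MarkerLocus(id="CAPS-XapI", kind="caps"),
        ])

    PROFILES = {
        "E1.1": {1: 104, 8: "absent", 54: (233, 0), "CAPS-XapI": "cut"},
        "E1.2": {1: 105, 8: "absent", 54: (233, 1), "CAPS-XapI": "uncut"},
        "E3.1": {1: 104, 8: "present", 54: (234, 1), "CAPS-XapI": "cut"},
    }

    def test_ssr_locus_becomes_ordered_repeat_counts(self):
        m = cnet.encode_matrix(self.PROFILES, self._panel())
        assert m.kinds["1"] == cnet.ORDERED
        assert m.data["1"].tolist() == [12, 13, 12]  # anchor 100 <-> 8 repeats

    def test_indel_locus_becomes_binary(self):
        m = cnet.encode_matrix(self.PROFILES, self._panel())
        assert m.kinds["8"] == cnet.BINARY
        assert m.data["8"].tolist() == [0, 0, 1]

    def test_mixed_locus_emits_two_characters(self):
        m = cnet.encode_matrix(self.PROFILES, self._panel())
        assert m.kinds["54:ssr"] == cnet.ORDERED
        assert m.kinds["54:indel"] == cnet.BINARY

    def test_caps_excluded_by_default_included_on_request(self):
        m = cnet.encode_matrix(self.PROFILES, self._panel())
        assert "CAPS-XapI" not in m.data.columns
        m2 = cnet.encode_matrix(self.PROFILES, self._panel(), include_caps=True)
        assert m2.kinds["CAPS-XapI"] == cnet.BINARY

    def test_motif_inconsistent_size_rejected(self):
        panel = mk.Panel([mk.MarkerLocus(id=1, kind="ssr", motif="AT",
                                         anchor=(100, 6), size_range=(98, 110))])
        profiles = {"a": {1: 100}, "b": {1: 101}}
        with pytest.raises(ValueError, match="inconsistent"):
            cnet.encode_matrix(profiles, panel)


class TestBinaryExpansion:
    def test_three_state_ladder(self):
        m = cnet.CodedMatrix(pd.DataFrame({"s": [3, 4, 5]}, index=list("xyz")),
                             {"s": cnet.ORDERED}, {"s": 1.0})
        binary, _w, exp = cnet.binary_expand(m)
        assert list(binary.columns) == ["s>=4", "s>=5"]
        assert exp.back_map["s>=4"] == ("s", 4)

    def test_binary_matrix_identity_expansion(self):
        df = pd.DataFrame({"b": [0, 1]}, index=["x", "y"])
        m = cnet.CodedMatrix(df, {"b": cnet.BINARY}, {"b": 1.0})
        binary, _w, exp = cnet.binary_expand(m)
        assert binary.equals(df)

    def test_distance_preservation_exhaustive(self, rng):
        """Hamming distance on the expansion equals the summed absolute
        ordered-state difference, for all pairs (8 haplotypes)."""
        data = pd.DataFrame({
            "s1": rng.integers(8, 14, size=8),
            "s2": rng.integers(3, 7, size=8),
            "b": rng.integers(0, 2, size=8),
        }, index=[f"h{i}" for i in range(8)])
        m = cnet.CodedMatrix(data, {"s1": cnet.ORDERED, "s2": cnet.ORDERED,
                                    "b": cnet.BINARY},
                             {c: 1.0 for c in data.columns})
        binary, _w, _e = cnet.binary_expand(m)
        for a, b in itertools.combinations(data.index, 2):
            manhattan = (data.loc[a] - data.loc[b]).abs().sum()
            hamming = (binary.loc[a] != binary.loc[b]).sum()
            assert manhattan == hamming


class TestReducedMedian:
    def test_single_haplotype(self):
        df = pd.DataFrame({"c": [1]}, index=["only"])
        net = cnet.reduced_median(df)
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_two_haplotypes_one_edge(self):
        df = pd.DataFrame({"c": [0, 1]}, index=["a", "b"])
        net = cnet.reduced_median(df)
        assert net.graph.number_of_edges() == 1
        (_u, _v, d), = net.graph.edges(data=True)
        assert d["characters"] == ["c"]

    def test_compatible_five_haplotypes_equal_perfect_phylogeny(self):
        df = pd.DataFrame({
            "c1": [0, 0, 1, 1, 1], "c2": [0, 0, 0, 1, 1],
            "c3": [1, 0, 0, 0, 0], "c4": [0, 0, 0, 0, 1],
        }, index=[f"h{i}" for i in range(1, 6)])
        net = cnet.reduced_median(df)
        g = net.graph
        assert nx.is_connected(g)
        assert g.number_of_edges() == g.number_of_nodes() - 1  # a tree
        everyone = frozenset(df.index)

        def canon(s):
            return min(s, everyone - s, key=sorted)

        expected = {canon(frozenset(df.index[df[c] == 1])) for c in df.columns}
        assert {canon(s) for s in observed_splits(net)} == expected

    def test_exhaustive_perfect_phylogeny_oracle(self):
        """Random compatible matrices (<=8 haplotypes x <=12 characters):
        the network must be the perfect phylogeny tree, edge set and all."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            n_haps = int(rng.integers(3, 9))
            n_chars = int(rng.integers(2, 13))
            df, expected = random_compatible_matrix(rng, n_haps, n_chars)
            net = cnet.reduced_median(df, r=2.0)
            g = net.graph
            assert nx.is_connected(g)
            assert g.number_of_edges() == g.number_of_nodes() - 1
            got = {s for s in observed_splits(net)
                   if 1 <= len(s) <= n_haps - 1}
            # identical haplotypes merge; compare informative splits only
            informative = set()
            for s in expected:
                comp = frozenset(df.index) - s
                if s and comp:
                    informative.add(min(s, comp, key=sorted))
            got_norm = {min(s, frozenset(df.index) - s, key=sorted)
                        for s in got}
            assert got_norm == informative

    def test_every_observed_haplotype_is_a_node_once(self, rng):
        df, _ = random_compatible_matrix(rng, 6, 8)
        net = cnet.reduced_median(df)
        for h in df.index:
            assert h in net.observed
        all_labels = [h for _n, d in net.graph.nodes(data=True)
                      for h in d["labels"]]
        assert sorted(all_labels) == sorted(df.index)

    def test_weight_scaling_invariance(self, rng):
        df, _ = random_compatible_matrix(rng, 6, 8)
        w1 = {c: 1.0 for c in df.columns}
        w7 = {c: 7.0 for c in df.columns}
        n1 = cnet.reduced_median(df, weights=w1)
        n7 = cnet.reduced_median(df, weights=w7)
        assert nx.is_isomorphic(n1.graph, n7.graph)

    def test_balanced_conflict_yields_reticulation(self):
        # all four gametes, equal frequencies: neither character dominates
        df = pd.DataFrame({"c1": [0, 0, 1, 1], "c2": [0, 1, 0, 1]},
                          index=["a", "b", "c", "d"])
        net = cnet.reduced_median(df, frequencies={h: 1.0 for h in df.index})
        g = net.graph
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 4
        assert len(nx.cycle_basis(g)) == 1  # one parallelogram

    def test_asymmetric_conflict_resolved_by_splitting(self):
        # same gametes but c1's variant is rare: treated as two independent
        # mutations of c1, giving a tree instead of a cycle
        df = pd.DataFrame({"c1": [0, 0, 1, 1], "c2": [0, 1, 0, 1]},
                          index=["a", "b", "c", "d"])
        freqs = {"a": 10.0, "b": 10.0, "c": 1.0, "d": 1.0}
        net = cnet.reduced_median(df, frequencies=freqs, r=2.0)
        g = net.graph
        assert g.number_of_edges() == g.number_of_nodes() - 1

    def test_reduction_parameter_validated(self):
        df = pd.DataFrame({"c": [0, 1]}, index=["a", "b"])
        with pytest.raises(ValueError):
            cnet.reduced_median(df, r=0.5)

    def test_edge_labels_decode_to_single_steps(self):
        m = cnet.CodedMatrix(
            pd.DataFrame({"s": [11, 12, 13, 13], "b": [0, 0, 0, 1]},
                         index=["w", "x", "y", "z"]),
            {"s": cnet.ORDERED, "b": cnet.BINARY},
            {"s": 1.0, "b": 1.0},
        )
        binary, w, exp = cnet.binary_expand(m)
        net = cnet.reduced_median(binary, w, expansion=exp)
        for _u, _v, d in net.graph.edges(data=True):
            assert set(d["characters"]) <= {"s", "b"}
            assert len(d["characters"]) == 1


class TestExportAndLineages:
    def _net(self):
        df = pd.DataFrame({"c1": [0, 1, 1], "c2": [0, 0, 1]},
                          index=["E1.1", "E1.2", "E2.1"])
        return cnet.reduced_median(df)

    def test_graphml_round_trip_isomorphic(self, tmp_path):
        net = self._net()
        path = tmp_path / "net.graphml"
        cnet.network_export(net, "graphml", path)
        back = nx.read_graphml(path)
        assert nx.is_isomorphic(back, net.graph)

    def test_dot_output_parses(self, tmp_path):
        net = self._net()
        path = tmp_path / "net.dot"
        cnet.network_export(net, "dot", path)
        text = path.read_text()
        assert text.startswith("graph") and text.rstrip().endswith("}")
        body = text.splitlines()[1:-1]
        stmt = re.compile(r'^\s*"[^"]+"(\s*--\s*"[^"]+")?\s*\[[^\]]*\];$')
        assert all(stmt.match(line) for line in body if line.strip())

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            cnet.network_export(self._net(), "gexf", tmp_path / "x")

    def test_three_clade_lineages_connected(self):
        df = pd.DataFrame({
            "L1": [1, 1, 0, 0, 0, 0], "L2": [0, 0, 1, 1, 0, 0],
            "L3": [0, 0, 0, 0, 1, 1],
            "d1": [0, 1, 0, 0, 0, 0], "d2": [0, 0, 0, 1, 0, 0],
            "d3": [0, 0, 0, 0, 0, 1],
        }, index=["E1.1", "E1.2", "E2.1", "E2.2", "E3.1", "E3.2"])
        net = cnet.reduced_median(df)
        lineage_of = {h: h.split(".")[0] for h in df.index}
        cnet.annotate_lineages(net, lineage_of)
        report = cnet.lineage_clusters(net, lineage_of)
        assert all(v["connected"] for v in report["lineages"].values())
        assert report["homoplastic_characters"] == []

    def test_homoplastic_character_flagged(self):
        df = pd.DataFrame({"c1": [0, 0, 1, 1], "c2": [0, 1, 0, 1]},
                          index=["a", "b", "c", "d"])
        net = cnet.reduced_median(df)
        report = cnet.lineage_clusters(net, {h: "X" for h in df.index})
        assert set(report["homoplastic_characters"]) == {"c1", "c2"}
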