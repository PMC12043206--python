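import networkx as nx
import numpy as np
import pytest

from core_responder import netshift as ns
from core_responder.io_model import TaxonomyTable


def _graph(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestNeshScores:
    def test_identical_networks_all_zero(self):
        g = _graph([(1, 2), (2, 3), (3, 4)])
        report = ns.nesh_scores(g, g.copy())
        assert (report.table["nesh"] == 0).all()
        assert (report.edges["status"] == "shared").all()
        assert ns.identify_drivers(report) == set()

    def test_full_turnover_scores_one(self):
        # node 1 has no control neighbors and an entirely novel case
        # neighborhood: |B \ A| = |A u B| -> NESH = 1
        control = _graph([(2, 3)], nodes=[1, 2, 3])
        case = _graph([(1, 3), (1, 2)], nodes=[1, 2, 3])
        report = ns.nesh_scores(control, case)
        row = report.table.set_index("node")
        assert row.loc[1, "nesh"] == pytest.approx(1.0)
        # a swapped-but-nonempty neighborhood scores the case-specific
        # fraction, not 1
        control2 = _graph([(1, 2)], nodes=[1, 2, 3])
        case2 = _graph([(1, 3)], nodes=[1, 2, 3])
        row2 = ns.nesh_scores(control2, case2).table.set_index("node")
        assert row2.loc[1, "nesh"] == pytest.approx(0.5)  # {2} -> {3}

    def test_toy_pair_matches_set_arithmetic(self):
        control = _graph([(1, 2), (1, 3), (2, 3), (4, 5)], nodes=range(1, 7))
        case = _graph([(1, 2), (1, 4), (2, 3), (4, 5), (5, 6)], nodes=range(1, 7))
        report = ns.nesh_scores(control, case)
        scores = dict(zip(report.table["node"], report.table["nesh"]))
        # brute-force oracle on enumerated neighbor sets
        for v in range(1, 7):
            a, b = set(control[v]), set(case[v])
            expected = len(b - a) / len(a | b) if a | b else 0.0
            assert scores[v] == pytest.approx(expected), f"node {v}"
        edges = report.edges.set_index(["taxon_a", "taxon_b"])["status"]
        assert edges.loc[(1, 3)] == "control_only"
        assert edges.loc[(1, 4)] == "case_only"
        assert edges.loc[(1, 2)] == "shared"

    def test_no_common_nodes_warns_empty(self):
        with pytest.warns(UserWarning, match="no nodes"):
            report = ns.nesh_scores(_graph([(1, 2)]), _graph([(3, 4)]))
        assert len(report.table) == 0

    def test_scaled_all_equal_is_zero(self):
        g = _graph([(1, 2), (2, 3)])
        report = ns.nesh_scores(g, g.copy())
        assert (report.table["scaled_nesh"] == 0).all()

    def test_complement_symmetry(self):
        # swapping control and case maps NESH(v) to |A \ B| / |A u B|
        rng = np.random.default_rng(0)
        for seed in range(5):
            gc = nx.gnp_random_graph(12, 0.3, seed=seed)
            gd = nx.gnp_random_graph(12, 0.3, seed=seed + 100)
            fwd = ns.nesh_scores(gc, gd).table.set_index("node")["nesh"]
            for v in gc.nodes:
                a, b = set(gc[v]), set(gd[v])
                swapped_expected = len(a - b) / len(a | b) if a | b else 0.0
                got = ns.nesh_scores(gd, gc).table.set_index("node")["nesh"][v]
                assert got == pytest.approx(swapped_expected)
                union = a | b
                if union:
                    assert fwd[v] + swapped_expected <= 1 + len(a & b) / len(union) + 1e-12

    def test_relabeling_invariance(self):
        gc = nx.gnp_random_graph(10, 0.3, seed=1)
        gd = nx.gnp_random_graph(10, 0.3, seed=2)
        mapping = {i: f"n{i}" for i in gc.nodes}
        r1 = ns.nesh_scores(gc, gd)
        ns.identify_drivers(r1)
        r2 = ns.nesh_scores(nx.relabel_nodes(gc, mapping), nx.relabel_nodes(gd, mapping))
        ns.identify_drivers(r2)
        assert {mapping[v] for v in r1.drivers} == r2.drivers


class TestIdentifyDrivers:
    def test_max_nesh_and_rising_betweenness_is_driver(self):
        # node 1 gains a bridging position (3-4 and 3-5 route through it)
        # and has the largest neighborhood turnover -> scaled NESH 1
        control = _graph([(1, 2), (3, 4), (4, 5)], nodes=range(1, 6))
        case = _graph([(1, 3), (1, 4), (4, 5)], nodes=range(1, 6))
        report = ns.nesh_scores(control, case)
        drivers = ns.identify_drivers(report, tau=1.0)
        assert 1 in drivers

    def test_no_bias_on_matched_random_graphs(self):
        counts = {v: 0 for v in range(12)}
        n_seeds = 40
        for seed in range(n_seeds):
            gc = nx.gnp_random_graph(12, 0.35, seed=seed)
            gd = nx.gnp_random_graph(12, 0.35, seed=seed + 1000)
            report = ns.nesh_scores(gc, gd)
            for v in ns.identify_drivers(report):
                counts[v] += 1
        rates = np.array(list(counts.values())) / n_seeds
        assert rates.max() - rates.min() < 0.5  # no node systematically favored


class TestCoreDrivers:
    @staticmethod
    def _report(drivers):
        import pandas as pd

        rep = ns.DriverReport("", pd.DataFrame(), pd.DataFrame())
        rep.drivers = set(drivers)
        return rep

    def test_four_of_ten_is_core_boundary(self):
        reports = {f"E{i:02d}": self._report(["GenusA"] if i <= 4 else []) for i in range(1, 11)}
        out = ns.core_drivers(reports, min_ecotypes=4)
        assert out.loc[out["genus"] == "GenusA", "is_core"].item()

    def test_three_of_ten_not_core(self):
        reports = {f"E{i:02d}": self._report(["GenusA"] if i <= 3 else []) for i in range(1, 11)}
        out = ns.core_drivers(reports, min_ecotypes=4)
        assert not out.loc[out["genus"] == "GenusA", "is_core"].item()

    def test_everywhere_driver_ranks_first(self):
        reports = {
            f"E{i:02d}": self._report(["GenusA"] + (["GenusB"] if i <= 2 else []))
            for i in range(1, 11)
        }
        out = ns.core_drivers(reports, min_ecotypes=4)
        assert out.iloc[0]["genus"] == "GenusA"
        assert out.iloc[0]["n_ecotypes"] == 10

    def test_bulk_overlap_flag(self):
        reports = {f"E{i:02d}": self._report(["GenusA"]) for i in range(1, 5)}
        reports["bulk"] = self._report(["GenusA", "GenusZ"])
        out = ns.core_drivers(reports, min_ecotypes=4)
        assert out.loc[out["genus"] == "GenusA", "in_bulk"].item()
        assert "GenusZ" not in set(out["genus"])  # bulk never counts as an ecotype

    def test_genus_aggregation_with_taxonomy(self):
        import pandas as pd

        tax = TaxonomyTable(
            pd.DataFrame(
                {
                    "kingdom": ["Bacteria"] * 2,
                    "phylum": ["P"] * 2,
                    "class": ["C"] * 2,
                    "order": ["O"] * 2,
                    "family": ["F"] * 2,
                    "genus": ["Massilia", "Massilia"],
                    "species": ["", ""],
                },
                index=["ASV1", "ASV2"],
            )
        )
        reports = {
            "E01": self._report(["ASV1"]),
            "E02": self._report(["ASV2"]),
            "E03": self._report(["ASV1", "ASV2"]),
            "E04": self._report(["ASV1"]),
        }
        out = ns.core_drivers(reports, taxonomy=tax, min_ecotypes=4)
        row = out.set_index("genus").loc["Massilia"]
        assert row["n_ecotypes"] == 4 and row["is_core"]
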