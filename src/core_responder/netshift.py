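"""Control-vs-case network comparison: neighbor-shift scores and driver taxa.

For a node v with control/case neighbor sets A and B (both restricted to the
nodes shared by the two networks), NESH(v) = |B \\ A| / |A u B| — 0 for an
unchanged neighborhood, 1 for a fully novel one. Scaled NESH is a min-max
rescaling over common nodes. A node is a driver when its betweenness rises
from control to case and its scaled NESH reaches the threshold (default:
the mean scaled NESH).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


def _as_graph(netlike) -> nx.Graph:
    if isinstance(netlike, nx.Graph):
        return netlike
    return netlike.graph


@dataclass
class DriverReport:
    ecotype: str
    table: pd.DataFrame  # per common node
    edges: pd.DataFrame  # union edge list with status {case_only, control_only, shared}
    drivers: set = field(default_factory=set)


def nesh_scores(control, case, ecotype: str = "") -> DriverReport:
    """Score every node common to both networks; classify union edges."""
    gc, gd = _as_graph(control), _as_graph(case)
    common = sorted(set(gc.nodes) & set(gd.nodes))
    if not common:
        warnings.warn("control and case networks share no nodes", stacklevel=2)
        empty = pd.DataFrame(
            columns=[
                "node", "degree_control", "degree_case", "betweenness_control",
                "betweenness_case", "nesh", "scaled_nesh",
            ]
        )
        return DriverReport(ecotype, empty, pd.DataFrame(columns=["taxon_a", "taxon_b", "status"]))
    common_set = set(common)
    bet_c = nx.betweenness_centrality(gc, normalized=True)
    bet_d = nx.betweenness_centrality(gd, normalized=True)
    rows = []
    for v in common:
        a = set(gc[v]) & common_set
        b = set(gd[v]) & common_set
        union = a | b
        nesh = len(b - a) / len(union) if union else 0.0
        rows.append(
            {
                "node": v,
                "degree_control": gc.degree(v),
                "degree_case": gd.degree(v),
                "betweenness_control": bet_c[v],
                "betweenness_case": bet_d[v],
                "nesh": nesh,
            }
        )
    table = pd.DataFrame(rows)
    lo, hi = table["nesh"].min(), table["nesh"].max()
    table["scaled_nesh"] = 0.0 if hi == lo else (table["nesh"] - lo) / (hi - lo)

    edge_rows = []
    ec = {tuple(sorted(e)) for e in gc.edges}
    ed = {tuple(sorted(e)) for e in gd.edges}
    for a_, b_ in sorted(ec | ed):
        status = "shared" if (a_, b_) in ec and (a_, b_) in ed else (
            "control_only" if (a_, b_) in ec else "case_only"
        )
        edge_rows.append({"taxon_a": a_, "taxon_b": b_, "status": status})
    edges = pd.DataFrame(edge_rows, columns=["taxon_a", "taxon_b", "status"])
    return DriverReport(ecotype, table, edges)


def identify_drivers(report: DriverReport, tau=None) -> set:
    """Drivers: betweenness_case > betweenness_control and scaled NESH >= tau."""
    t = report.table
    if len(t) == 0:
        report.drivers = set()
        return set()
    if tau is None:
        tau = float(t["scaled_nesh"].mean())
    is_driver = (t["betweenness_case"] > t["betweenness_control"]) & (t["scaled_nesh"] >= tau)
    report.table = t.assign(is_driver=is_driver)
    report.drivers = set(t.loc[is_driver.to_numpy(), "node"])
    return report.drivers


def core_drivers(
    reports: dict,
    taxonomy=None,
    min_ecotypes: int = 4,
    bulk_key: str = "bulk",
) -> pd.DataFrame:
    """Aggregate drivers at genus level and flag cross-ecotype core drivers.

    ``reports`` maps ecotype -> DriverReport (drivers already identified);
    the entry under ``bulk_key`` is excluded from the count and only feeds
    the ``in_bulk`` overlap column. Without a taxonomy the node ids are
    treated as genus labels directly.
    """
    def genus_of(node):
        if taxonomy is None:
            return node
        return taxonomy.label_at(node, "genus")

    counts: dict = {}
    bulk_genera: set = set()
    for eco, report in reports.items():
        genera = {genus_of(v) for v in report.drivers}
        if eco == bulk_key:
            bulk_genera = genera
            continue
        for g in genera:
            counts.setdefault(g, set()).add(eco)
    rows = [
        {
            "genus": g,
            "n_ecotypes": len(ecos),
            "ecotypes": ",".join(sorted(ecos)),
            "is_core": len(ecos) >= min_ecotypes,
            "in_bulk": g in bulk_genera,
        }
        for g, ecos in counts.items()
    ]
    out = pd.DataFrame(rows, columns=["genus", "n_ecotypes", "ecotypes", "is_core", "in_bulk"])
    return out.sort_values(
        ["n_ecotypes", "genus"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def write_comparison_graphml(report: DriverReport, path) -> None:
    """Union graph with edge status and node driver flags, GraphML."""
    g = nx.Graph()
    if len(report.table):
        for _, row in report.table.iterrows():
            g.add_node(
                row["node"],
                nesh=float(row["nesh"]),
                scaled_nesh=float(row["scaled_nesh"]),
                is_driver=bool(row.get("is_driver", False)),
            )
    for _, row in report.edges.iterrows():
        g.add_edge(row["taxon_a"], row["taxon_b"], status=row["status"])
    nx.write_graphml(g, path)
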