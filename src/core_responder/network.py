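"""Co-occurrence network construction, topology metrics, and cohesion.

One network per (ecotype, treatment) context: Spearman correlations on the
abundance-filtered taxa, BH adjustment over all tested pairs, and retention
of pairs with |rho| >= rho_min and q < q_max (sign kept). Modularity uses
the deterministic greedy agglomerative partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_adjust
from .io_model import RelativeAbundanceTable, StudyDesign


@dataclass
class CooccurrenceNetwork:
    graph: nx.Graph
    ecotype: str = ""
    treatment: str = ""
    candidates: list = field(default_factory=list)  # taxa that passed the filters

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def n_edges(self):
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": a, "taxon_b": b, **attrs}
            for a, b, attrs in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho", "q", "sign"])


@dataclass
class NetworkMetrics:
    n_nodes: int
    n_edges: int
    connectance: float
    average_degree: float
    modularity: float
    degree: dict
    betweenness: dict
    modules: dict  # node -> module index

    def summary(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "connectance": self.connectance,
            "average_degree": self.average_degree,
            "modularity": self.modularity,
        }


def _spearman_matrices(x: np.ndarray):
    """Spearman rho and p for all column pairs (average ranks for ties)."""
    if x.shape[1] == 2:
        rho, p = stats.spearmanr(x[:, 0], x[:, 1])
        return np.array([[1.0, rho], [rho, 1.0]]), np.array([[0.0, p], [p, 0.0]])
    rho, p = stats.spearmanr(x)
    return np.asarray(rho), np.asarray(p)


def build_network(
    table: RelativeAbundanceTable,
    design: StudyDesign,
    ecotype: str,
    treatment: str,
    abund_min: float = 0.002,
    min_prev: int = 2,
    rho_min: float = 0.9,
    q_max: float = 0.05,
    positive_only: bool = False,
    samples=None,
) -> CooccurrenceNetwork:
    """Context network for one ecotype x treatment.

    Candidate taxa need mean relative abundance > abund_min within the
    context and presence in >= min_prev samples. ``samples`` overrides the
    design lookup (used by subset analyses).
    """
    if samples is None:
        samples = design.samples_for(ecotype=ecotype, treatment=treatment)
    if len(samples) < 4:
        raise ValueError(f"context {ecotype}/{treatment} has fewer than 4 samples")
    rows = [table.sample_ids.index(s) for s in samples]
    x = table.values[rows, :]
    eligible = (x.mean(axis=0) > abund_min) & ((x > 0).sum(axis=0) >= min_prev)
    taxa = [t for t, e in zip(table.taxon_ids, eligible) if e]
    graph = nx.Graph()
    if len(taxa) < 2:
        warnings.warn(
            f"context {ecotype}/{treatment}: fewer than 2 eligible taxa, empty network",
            stacklevel=2,
        )
        return CooccurrenceNetwork(graph, ecotype, treatment, taxa)
    xs = x[:, eligible]
    rho, p = _spearman_matrices(xs)
    iu = np.triu_indices(len(taxa), 1)
    pvals = p[iu]
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    q = bh_adjust(pvals)
    r = rho[iu]
    strong = r >= rho_min if positive_only else np.abs(r) >= rho_min
    keep = strong & (q < q_max) & ~np.isnan(r)
    for (i, j, rho_ij, q_ij) in zip(iu[0][keep], iu[1][keep], r[keep], q[keep]):
        graph.add_edge(
            taxa[i],
            taxa[j],
            rho=float(rho_ij),
            q=float(q_ij),
            sign="positive" if rho_ij >= 0 else "negative",
        )
    return CooccurrenceNetwork(graph, ecotype, treatment, taxa)


def topology(net: CooccurrenceNetwork) -> NetworkMetrics:
    """Connectance, average degree, betweenness, and greedy-partition modularity.

    The graph is rebuilt with sorted node and edge order before partitioning
    so ties in the agglomeration always break the same way.
    """
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes))
    g.add_edges_from(sorted(tuple(sorted(e)) for e in net.graph.edges))
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return NetworkMetrics(0, 0, float("nan"), float("nan"), float("nan"), {}, {}, {})
    connectance = e / (n * (n - 1) / 2) if n > 1 else float("nan")
    average_degree = 2 * e / n
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=True)
    if e == 0:
        q = float("nan")
        modules = {v: 0 for v in g.nodes}
    else:
        communities = nx.community.greedy_modularity_communities(g)
        communities = sorted((sorted(c) for c in communities), key=lambda c: c[0])
        q = nx.community.modularity(g, communities)
        modules = {v: k for k, comm in enumerate(communities) for v in comm}
    return NetworkMetrics(
        n_nodes=n,
        n_edges=e,
        connectance=float(connectance),
        average_degree=float(average_degree),
        modularity=float(q),
        degree=degree,
        betweenness=betweenness,
        modules=modules,
    )


@dataclass
class CohesionResult:
    positive: float
    negative: float
    total: float
    per_sample: pd.DataFrame  # columns positive, negative
    connectedness: pd.DataFrame  # per-taxon positive/negative connectedness


def cohesion(
    table: RelativeAbundanceTable,
    samples,
    n_null: int = 200,
    seed=None,
) -> CohesionResult:
    """Abundance-weighted community connectedness (stability proxy).

    Pairwise Pearson correlations on relative abundances are null-corrected
    by subtracting the mean correlation over ``n_null`` tables in which each
    taxon's values are independently shuffled across samples. Per taxon,
    positive (negative) connectedness is the mean of the positive (negative)
    corrected correlations with all other taxa; per sample, cohesion is the
    abundance-weighted sum of connectedness. Network-level values are means
    over the context samples; total = positive + |negative|.
    """
    rows = [table.sample_ids.index(s) for s in samples]
    if len(rows) < 4:
        raise ValueError("cohesion needs at least 4 samples")
    x = table.values[rows, :]
    keep = x.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} constant taxa from cohesion", stacklevel=2
        )
    x = x[:, keep]
    n_samples, n_taxa = x.shape
    if n_taxa < 2:
        raise ValueError("cohesion needs at least 2 varying taxa")
    obs = np.corrcoef(x, rowvar=False)
    rng = np.random.default_rng(seed)
    null_sum = np.zeros_like(obs)
    for _ in range(n_null):
        shuffled = np.empty_like(x)
        for j in range(n_taxa):
            shuffled[:, j] = x[rng.permutation(n_samples), j]
        null_sum += np.corrcoef(shuffled, rowvar=False)
    corrected = obs - null_sum / n_null
    np.fill_diagonal(corrected, 0.0)

    pos = np.where(corrected > 0, corrected, 0.0)
    neg = np.where(corrected < 0, corrected, 0.0)
    npos = (corrected > 0).sum(axis=1)
    nneg = (corrected < 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        conn_pos = np.where(npos > 0, pos.sum(axis=1) / np.maximum(npos, 1), 0.0)
        conn_neg = np.where(nneg > 0, neg.sum(axis=1) / np.maximum(nneg, 1), 0.0)

    coh_pos = x @ conn_pos
    coh_neg = x @ conn_neg
    taxa = [t for t, k in zip(table.taxon_ids, keep) if k]
    per_sample = pd.DataFrame({"positive": coh_pos, "negative": coh_neg}, index=list(samples))
    connectedness = pd.DataFrame({"positive": conn_pos, "negative": conn_neg}, index=taxa)
    positive = float(coh_pos.mean())
    negative = float(coh_neg.mean())
    return CohesionResult(
        positive=positive,
        negative=negative,
        total=positive + abs(negative),
        per_sample=per_sample,
        connectedness=connectedness,
    )


def write_graphml(net: CooccurrenceNetwork, path) -> None:
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes))
    for a, b, attrs in sorted(net.graph.edges(data=True)):
        g.add_edge(a, b, **attrs)
    nx.write_graphml(g, path)
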