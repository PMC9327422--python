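"""Phosphosite-aware interaction-network integration of signatures.

Signature members rarely interact directly; to place them in context the
protein-protein interaction graph is augmented so that every phosphosite of
interest becomes its own node: the substrate protein connects to the site
at cost m/4 and the site connects to each of its annotated kinases at cost
3m/2, where m is the mean cost of the base PPI edges (cost = 1 -
confidence, clipped to [0.01, 1]). The cheap substrate edge keeps sites
anchored to their parent protein; the expensive kinase edges admit kinase
context only when it pays for itself.

Signature members receive prizes proportional to their absolute
coefficients (max-normalized to 1) and a Prize-Collecting Steiner Forest
is solved over many edge-cost randomizations; nodes recurring across runs
form the consensus subnetwork.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import KinaseSubstrateMap, PPIEdgeList, site_parent_gene
from .models import Signature
from . import pcsf as _pcsf


@dataclass
class AugmentedGraph:
    """Typed protein/phosphosite graph with PCSF edge costs.

    Edge kinds: ``ppi`` (base), ``substrate_site`` (protein -> its site,
    cost m/4), ``site_kinase`` (site -> annotated kinase, cost 3m/2).
    ``m`` is the mean base-edge cost, computed before augmentation.
    """

    graph: nx.Graph
    m: float

    @property
    def proteins(self) -> set:
        return {v for v, d in self.graph.nodes(data=True) if d["kind"] == "protein"}

    @property
    def sites(self) -> set:
        return {v for v, d in self.graph.nodes(data=True) if d["kind"] == "phosphosite"}

    def edge_list(self) -> list[tuple]:
        return [(u, v, d["cost"]) for u, v, d in self.graph.edges(data=True)]


@dataclass
class PCSFConfig:
    """Prize scale beta, per-tree cost omega (None = use m), randomization
    count and multiplicative cost-noise width, and the consensus node
    frequency threshold."""

    beta: float = 1.0
    omega: float | None = None
    n_randomizations: int = 100
    noise_delta: float = 0.05
    consensus_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.omega is not None and self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if not (0 <= self.noise_delta < 1):
            raise ValueError("noise_delta must lie in [0, 1)")

    def resolved_omega(self, m: float) -> float:
        return self.omega if self.omega is not None else m


@dataclass
class ForestResult:
    """A PCSF solution: node/edge selection, objective, and (for the
    randomized variant) per-node selection frequencies plus the consensus
    subgraph induced on recurrent nodes."""

    nodes: set = field(default_factory=set)
    edges: list[tuple] = field(default_factory=list)
    objective: float = 0.0
    frequencies: dict | None = None
    consensus: nx.Graph | None = None


def build_augmented_graph(
    ppi: PPIEdgeList, ks: KinaseSubstrateMap, sites: list[str]
) -> AugmentedGraph:
    """Augment the PPI graph with one node per phosphosite.

    Base edge cost is 1 - confidence clipped to [0.01, 1]; m is the mean
    cost over base edges only (computed before augmentation, so the
    m/4 and 3m/2 site-edge rules are not self-referential). Sites whose
    parent gene is absent from the PPI node set are dropped with a
    warning; sites with no kinase annotation keep only their substrate
    edge.
    """
    if ppi.edges.empty:
        raise ValueError("empty PPI edge list")
    g = nx.Graph()
    costs = []
    for _i, row in ppi.edges.iterrows():
        cost = float(np.clip(1.0 - row["confidence"], 0.01, 1.0))
        g.add_edge(row["node_a"], row["node_b"], cost=cost, kind="ppi")
        costs.append(cost)
    m = float(np.mean(costs))
    nx.set_node_attributes(g, "protein", "kind")

    ks_index: dict[str, list[str]] = {}
    for _i, row in ks.pairs.iterrows():
        ks_index.setdefault(row["site"], []).append(row["kinase"])

    dropped = 0
    for site in sites:
        gene = site_parent_gene(site)
        if gene not in g:
            dropped += 1
            continue
        g.add_node(site, kind="phosphosite")
        g.add_edge(gene, site, cost=m / 4.0, kind="substrate_site")
        for kinase in sorted(set(ks_index.get(site, []))):
            if kinase in g and g.nodes[kinase]["kind"] == "protein" and kinase != gene:
                g.add_edge(site, kinase, cost=3.0 * m / 2.0, kind="site_kinase")
    if dropped:
        warnings.warn(f"{dropped} phosphosites had no parent protein in the PPI; dropped")
    return AugmentedGraph(graph=g, m=m)


def assign_prizes(signature: Signature, graph: AugmentedGraph) -> dict:
    """Map signature members onto graph nodes with prizes
    |coefficient| / max|coefficient| (so the top feature has prize 1).

    Transcripts and mutations map to the protein node of the same gene;
    phosphosites map to their own site node. Members absent from the
    graph are skipped with a warning; an empty post-mapping prize set is
    an error.
    """
    if not signature.features:
        raise ValueError("empty signature")
    max_abs = max(abs(c) for _f, _m, c in signature.features)
    prizes: dict = {}
    skipped = []
    for feature, modality, coef in signature.features:
        node = feature  # gene ids double as protein nodes; site ids as site nodes
        if node in graph.graph:
            prizes[node] = max(prizes.get(node, 0.0), abs(coef) / max_abs)
        else:
            skipped.append(feature)
    if skipped:
        warnings.warn(f"{len(skipped)} signature members absent from graph: {skipped[:5]}")
    if not prizes:
        raise ValueError("no signature member could be mapped onto the graph")
    return prizes


def _site_constraint_filter(graph: AugmentedGraph):
    """Subset filter enforcing that a selected phosphosite brings its
    parent protein (hence its substrate edge) along."""
    parents = {s: site_parent_gene(s) for s in graph.sites}

    def ok(subset: set) -> bool:
        return all(parents[s] in subset for s in subset if s in parents)

    return ok


def _repair_site_edges(graph: AugmentedGraph, nodes: set, edges: list[tuple]) -> tuple[set, list[tuple]]:
    """Enforce the structural rule that a phosphosite in a tree is anchored
    by its substrate edge: swap or drop site attachments that only use
    kinase edges. Swaps never increase cost; drops forfeit the site."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v, c in edges:
        g.add_edge(u, v, cost=c)
    for site in sorted(s for s in nodes if s in graph.sites):
        gene = site_parent_gene(site)
        if g.has_edge(site, gene):
            continue
        deg = g.degree(site)
        if gene in g.nodes and nx.has_path(g, site, gene):
            if deg == 1:  # leaf: swap attachment to the cheap substrate edge
                nbr = next(iter(g.neighbors(site)))
                g.remove_edge(site, nbr)
                g.add_edge(site, gene, cost=graph.graph[site][gene]["cost"])
            else:  # interior: add substrate edge, break the cycle at its costliest edge
                path = nx.shortest_path(g, site, gene)
                worst = max(
                    zip(path[:-1], path[1:]), key=lambda e: g[e[0]][e[1]]["cost"]
                )
                g.remove_edge(*worst)
                g.add_edge(site, gene, cost=graph.graph[site][gene]["cost"])
        else:
            if deg <= 1:
                g.remove_node(site)
            else:
                g.remove_node(site)  # splits the tree; remaining parts stay valid
    return set(g.nodes()), [(u, v, d["cost"]) for u, v, d in g.edges(data=True)]


def solve_pcsf(
    graph: AugmentedGraph,
    prizes: dict,
    cfg: PCSFConfig,
    mode: str = "heuristic",
    edge_costs: dict | None = None,
) -> ForestResult:
    """Solve one PCSF instance on the augmented graph.

    ``mode='heuristic'`` runs dummy-root Goemans-Williamson moat growth
    with strong pruning; ``mode='exact'`` enumerates node subsets (small
    graphs only) under the site-anchoring constraint. ``edge_costs`` may
    override per-edge costs (used by the randomization wrapper).
    """
    if any(p < 0 for p in prizes.values()):
        raise ValueError("prizes must be nonnegative")
    nodes = list(graph.graph.nodes())
    edges = []
    for u, v, d in graph.graph.edges(data=True):
        c = edge_costs.get(frozenset((u, v)), d["cost"]) if edge_costs else d["cost"]
        if c <= 0:
            raise ValueError(f"nonpositive edge cost on ({u}, {v})")
        edges.append((u, v, c))
    omega = cfg.resolved_omega(graph.m)
    if mode == "exact":
        sel_nodes, sel_edges, obj = _pcsf.exact_pcsf(
            nodes, edges, prizes, beta=cfg.beta, omega=omega,
            subset_filter=_site_constraint_filter(graph) if graph.sites else None,
        )
    elif mode == "heuristic":
        sel_nodes, sel_edges, obj = _pcsf.gw_pcsf(
            nodes, edges, prizes, beta=cfg.beta, omega=omega
        )
        if graph.sites:
            sel_nodes, sel_edges = _repair_site_edges(graph, sel_nodes, sel_edges)
            obj = _pcsf.forest_objective(
                prizes, sel_edges, sel_nodes, cfg.beta, omega, all_nodes=set(nodes)
            )
    else:
        raise ValueError("mode must be 'heuristic' or 'exact'")
    return ForestResult(nodes=sel_nodes, edges=sel_edges, objective=obj)


def randomized_pcsf(
    graph: AugmentedGraph, prizes: dict, cfg: PCSFConfig, mode: str = "heuristic"
) -> ForestResult:
    """PCSF over ``cfg.n_randomizations`` runs with multiplicative edge-cost
    noise Uniform(1 - delta, 1 + delta).

    The returned result carries the unperturbed-cost solution, per-node
    selection frequencies, and the consensus subgraph induced on nodes
    selected in at least ``consensus_fraction`` of runs.
    """
    rng = np.random.default_rng(cfg.seed)
    base = solve_pcsf(graph, prizes, cfg, mode=mode)
    counts: dict = {v: 0 for v in graph.graph.nodes()}
    edge_ids = [frozenset((u, v)) for u, v in graph.graph.edges()]
    base_costs = {frozenset((u, v)): d["cost"] for u, v, d in graph.graph.edges(data=True)}
    for _r in range(cfg.n_randomizations):
        noise = rng.uniform(1 - cfg.noise_delta, 1 + cfg.noise_delta, size=len(edge_ids))
        costs = {eid: base_costs[eid] * w for eid, w in zip(edge_ids, noise)}
        res = solve_pcsf(graph, prizes, cfg, mode=mode, edge_costs=costs)
        for v in res.nodes:
            counts[v] += 1
    freq = {v: counts[v] / cfg.n_randomizations for v in counts}
    keep = {v for v, f in freq.items() if f >= cfg.consensus_fraction}
    consensus = graph.graph.subgraph(keep).copy()
    return ForestResult(
        nodes=base.nodes,
        edges=base.edges,
        objective=base.objective,
        frequencies=freq,
        consensus=consensus,
    )


def export_consensus(result: ForestResult, graph: AugmentedGraph,
                     prizes: dict, edge_path, node_path) -> None:
    """Write the consensus network as an edge-list TSV plus a node
    attribute TSV (type, prize, frequency) for graph viewers."""
    cons = result.consensus if result.consensus is not None else nx.Graph()
    erows = [
        (u, v, d["cost"], d["kind"]) for u, v, d in cons.edges(data=True)
    ]
    pd.DataFrame(erows, columns=["node_a", "node_b", "cost", "kind"]).to_csv(
        edge_path, sep="\t", index=False
    )
    nrows = [
        (v, graph.graph.nodes[v]["kind"], prizes.get(v, 0.0),
         (result.frequencies or {}).get(v, float("nan")))
        for v in cons.nodes()
    ]
    pd.DataFrame(nrows, columns=["node", "type", "prize", "frequency"]).to_csv(
        node_path, sep="\t", index=False
    )
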